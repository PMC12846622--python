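# Methods

This note documents the models, conventions and defaults behind
`gcscreen`, the choices made where the design was genuinely open, and what
the synthetic validation does and does not demonstrate.

## Preprocessing

The pipeline order is fixed: blank subtraction → Savitzky–Golay smoothing →
time alignment → positivity offset. Order matters and is recorded in the
provenance of every run.

* **Blank subtraction** removes the media background by subtracting the
  pointwise *mean* of all media-only wells (mean rather than median: blanks
  are few and well behaved; a robust statistic would hide a failed blank
  rather than expose it). Negative values are permitted at this stage.
* **Smoothing** uses a Savitzky–Golay filter, window 3 samples, polynomial
  order 1 — at this width equivalent to a centred 3-point moving average on
  the interior, with one-sided polynomial fits at the boundaries so series
  length is preserved. The light setting suppresses read-to-read jitter
  without flattening genuine lysis kinetics.
* **Alignment** shifts the time axis so t = 0 falls at the minimum of the
  mean uninfected-control curve. Aligning on the mean of all controls
  (rather than a single well) makes t* robust to one noisy control. Points
  before the minimum keep negative times; nothing is discarded.
* **Positivity offset**: if any reading is negative after the steps above,
  the absolute value of the global dataset minimum is added to *every*
  reading. The offset is a preprocessing constant of the dataset, not a
  fitted parameter, so cross-validation folds reuse it. It is applied after
  smoothing (pipeline order as listed). Differences between readings are
  unchanged, so drop slope and drop magnitude are offset-invariant, while
  OD at bottom, the 110% regrowth threshold, and the post-lysis AUC are
  deliberately level-dependent.

## GC7 feature extraction

Peaks are local maxima with prominence > 0.01 OD, evaluated within a
30-sample window (300 min at the standard 10-min grid), admitting
flat-topped peaks from one sample up. The window is interpreted as the
prominence-computation window — the only windowed quantity in this style of
peak detection.

The lysis phase starts at the *first* detected peak, even when later
regrowth peaks are higher. The instantaneous slope is the central-difference
gradient (non-uniform-grid safe), in OD/min. The maximum lysis rate is the
most negative gradient between the first peak and the subsequent global
minimum. The **bottom** is located at the first sample after the steepest
decline where |slope| has fallen to a fraction (default 10%) of the maximum
lysis rate; because the central difference straddles kinks, the landmark is
then refined to the earliest minimum-OD sample up to that crossing — on
smooth monotone decays the two coincide, while on piecewise-linear curves
the refinement pins the bottom to the kink where the decline actually ends.
If the slope never falls below the threshold before the run ends, the
global minimum after the first peak is used and the fallback is logged.

Regrowth is the first post-bottom sample at or above 110% of the bottom OD;
when no such sample exists, the time-to-regrowth is censored at the run end
rather than set to NaN, keeping feature matrices complete (the censored
value is a lower bound, consistent with "no regrowth within 24 h"). The
drop slope regresses *all* samples between peak and bottom inclusive, not
just the endpoints, so it reflects the mean kill rate rather than a chord.

The 10% slope fraction is the one tunable landmark threshold;
`sensitivity_scan` re-runs feature extraction and LOSOCV at 5/10/15% to
verify that clustering metrics do not hinge on it.

Features are standardised to zero mean and unit population variance; the
scaler is part of the learned pipeline, so every cross-validation fold
refits it on its own samples. A zero-variance feature is an error by
design: it usually means the panel lacks phenotypic diversity on that axis
and silently dropping it would change the feature space unannounced.

## Clustering and model selection

All four engines label every sample; none accepts ground-truth labels.

* **K-means**: k = max(elbow k, silhouette k). "Maximum curvature" of the
  WCSS plot is made concrete as the maximum second central difference
  (ties to the smaller k); the WCSS table starts at k = 1 so curvature is
  defined at the low end. Fits use 10 seeded initialisations. Taking the
  larger of the two suggestions biases against under-clustering, which
  would merge distinct species — the costlier error in triage.
* **Gaussian mixture**: full covariances, k = argmin BIC, covariance
  regularisation floor 1e-6 (needed with ~3 replicates per component in
  7-D). Note that with n ≈ 21 the BIC penalty of a full-covariance
  component (36 parameters) exceeds the likelihood gain from splitting a
  close species pair, so mixtures systematically report fewer clusters
  than species on small panels; this matches how mixtures behave on real
  reference-phage panels and is documented rather than patched.
* **DBSCAN**: eps from the sorted 2-nearest-neighbour distance graph at the
  point of maximum distance-to-chord (Kneedle convention; a flat graph
  returns the common distance, a zero knee falls back to the smallest
  positive distance). min_samples = 1 turns clusters into connected
  components of the eps-graph — every isolate is classified, since the
  goal is characterising all candidates, not outlier removal. Because the
  2-NN graph only sees within-cluster scales, this estimator tends to
  oversegment clusters of heterogeneous density; its sampling score stays
  high even when its cluster counts are inflated.
* **Ward**: cuts of the Ward dendrogram scored by silhouette, ties broken
  by the lower Davies–Bouldin index, then the smaller k.

The candidate range is k ∈ 2..min(10, n−1), widened to min(20, n−1) when
n > 30: combined-MOI designs legitimately split each species into
per-condition sub-clusters, and a capped range would hide that.

## Evaluation

ARI and NMI are the standard chance-corrected and information-theoretic
partition agreements; NMI uses the arithmetic-mean normalisation and the
choice is recorded in every serialised output, since NMI variants are not
interchangeable. The sampling score is computed exactly by
inclusion–exclusion over species subsets (cost 2^|S|·k, trivial for
|S| ≤ 10) rather than by Monte Carlo; a brute-force enumeration oracle
backs it in the tests. It is 1 exactly when every species owns at least one
pure cluster and 0 whenever there are fewer clusters than species.

LOSOCV builds one fold per species; each fold re-standardises, re-selects
the model order and re-clusters the retained samples, then scores against
their true labels. Folds that would retain fewer than 3 samples are skipped
with a warning. Per-feature species differences use the tie-corrected
Kruskal–Wallis test with Holm step-down correction across the seven
features (the feature set is the test family).

## Baselines

Virulence and centroid indices are computed per infected well against the
pointwise mean uninfected control of its plate (the sources give no pairing
rule; the mean control is the natural plate-level reference). The VI
integration horizon defaults to the full 24 h record and is exposed as a
flag. CI is normalised by the control centroid time by default, with a
run-duration normalisation available (`--ci-norm duration`) because the
original normalisation constant is not uniquely fixed; at a single MOI the
per-well local virulence itself is the clustering feature, with the
log10-MOI-integrated index reserved for multi-MOI designs. NMDS minimises
stress-1 over 16 seeded random restarts of non-metric MDS on the L1
curve-distance matrix; the vegan-style autotransform/Wisconsin
standardisation is intentionally not reproduced.

## Synthetic data

The generator emulates the acquisition protocol — 24 h runs sampled every
10 min (145 points), 96-well plates with media blanks and uninfected
controls — with piecewise-smooth parametric curves rather than a
mechanistic phage–host ODE. The package under test measures landmarks and
clusters; the piecewise construction gives analytic ground truth for the
landmarks (onset, maximum lysis rate, bottom level, regrowth timing), which
a mechanistic model would not.

A control follows logistic growth from OD 0.05. An infected well follows
the same logistic until the lysis onset (shifted earlier by
`moi_sensitivity` minutes per log10 MOI above the 0.01 reference), decays
exponentially toward the bottom OD, holds through the regrowth lag, regrows
logistically toward the regrowth capacity, and may carry one damped
secondary hump. The default panel of seven archetypes
(`src/gcscreen/data/default7.yaml`, versioned) spans early/late onset,
deep/shallow lysis, and fast/slow/absent regrowth; two archetypes carry
secondary humps so the peak-count feature retains variance in every LOSOCV
fold. Noise is Gaussian per read (sd 0.003 OD) plus a constant per-well
offset (sd 0.002 OD), approximating shaken-plate-reader repeatability; at
substantially higher read noise the fixed 0.01-OD prominence threshold
starts counting noise peaks, which no screen run at that threshold could
tolerate either. Raw wells sit on a 0.04-OD media background so blank
subtraction is exercised.

What passing on this panel shows: the pipeline recovers planted phenotype
structure end to end — parsing, preprocessing, landmark detection, feature
extraction, model selection, clustering and scoring are internally
consistent. What it does not show: performance on real plates, where
replicate curves differ by biology (adsorption stochasticity,
resistant-mutant timing) and not just measurement noise, where lysis
phenotypes form a continuum rather than seven well-separated archetypes,
and where species labels themselves come from thresholded genomic
similarity. Reported ARIs on the synthetic panel are therefore upper bounds
in spirit, not forecasts.

## Numerical choices and degenerate inputs

* Trapezoidal integration for all areas; linear regression via ordinary
  least squares.
* Time grids must be strictly increasing; curves compared pairwise (VI, CI,
  distance matrices) must share their grid exactly.
* A curve with no prominent peak carries no lysis signal and is excluded
  with a logged warning (`NoLysisError`), mirroring how non-lysing wells
  are dropped from screening panels.
* Ties: elbow and Ward selection resolve ties toward the smaller k; the
  triage representative (nearest to the cluster centroid in standardised
  space) resolves distance ties toward the lexicographically smallest
  sample id. DBSCAN ignores its seed argument (deterministic given eps);
  the argument exists for API uniformity.
* Seeds propagate explicitly: panels derive per-well generators from a
  master `SeedSequence`, clusterings are seeded, and repeated runs of the
  same configuration are byte-identical apart from timestamps.

## Problem sizes

The validation designs are those of a reference screen: 7 species × 3
replicates at MOI 0.01 (21 infected wells) and 7 × 3 × 3 MOIs (63 wells),
plus 3 blanks and 3 controls — a single 96-well plate per design. The
acceptance script runs both designs, all four clustering engines, all four
feature sets and the threshold sensitivity scan in about half a minute on
one core.

## Known limitations

* Landmark times are quantised to the 10-min grid; time-valued features on
  short lysis phases carry a corresponding discretisation error.
* The censored time-to-regrowth conflates "no regrowth" with "regrowth
  after 24 h".
* GMM/BIC under-counts clusters on panels with few replicates (see above).
* The DBSCAN eps heuristic assumes roughly homogeneous within-cluster
  density.
* No growth-model fitting (Gompertz/logistic), no outlier-well rejection,
  no consensus clustering, and no mechanistic burst-size or latent-period
  estimation: out of scope by design.
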