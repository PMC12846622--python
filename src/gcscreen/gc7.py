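"""GC7 feature extraction from processed co-culture growth curves.

A lytic phage infection in liquid culture produces a characteristic OD600
trajectory: growth to a peak, a lysis-driven drop to a bottom, and
(depending on resistant subpopulations) regrowth, sometimes with further
peaks. Seven features summarise that trajectory:

==================  ===========  ==================================================
feature             units        definition
==================  ===========  ==================================================
peak_count          count        local maxima with prominence > 0.01 OD
drop_slope          OD/min       least-squares slope of OD vs t over [peak, bottom]
drop_magnitude      OD           OD(peak) - OD(bottom)
od_at_bottom        OD           OD at the bottom landmark
time_peak_to_bottom minutes      t(bottom) - t(peak)
time_bottom_to_rise minutes      time until OD first reaches 110% of bottom OD
                                 (censored at run end if never reached)
auc_bottom_to_end   OD*min       trapezoidal integral from bottom to run end
==================  ===========  ==================================================

Landmarks: the *first* detected peak starts the lysis phase even when later
peaks are higher. The steepest decline is the most negative instantaneous
gradient (central differences, non-uniform-grid safe) between that peak and
the subsequent global minimum. The bottom is the first point after the
steepest decline where the gradient magnitude has shrunk to a fraction
(default 10%) of the maximum lysis rate; if it never shrinks that far, the
global minimum after the first peak is used and the fallback is logged.

Curves with no detectable peak carry no lysis signal and raise
:class:`NoLysisError`; callers exclude them, mirroring how wells showing no
lysis are dropped from screening panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import linregress
from sklearn.preprocessing import StandardScaler

from .preprocess import GrowthCurve

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "peak_count",
    "drop_slope",
    "drop_magnitude",
    "od_at_bottom",
    "time_peak_to_bottom",
    "time_bottom_to_rise",
    "auc_bottom_to_end",
)

#: Default peak-detection parameters: minimum prominence in OD units, the
#: window (in samples) over which prominence is computed, and the minimum
#: plateau size in samples.
DEFAULT_PROMINENCE = 0.01
DEFAULT_PROMINENCE_WINDOW = 30
DEFAULT_PLATEAU_SIZE = 1
DEFAULT_SLOPE_FRACTION = 0.10
REGROWTH_FACTOR = 1.10


class NoLysisError(ValueError):
    """The curve shows no lysis signal (no prominent peak)."""

    def __init__(self, sample_id: str):
        super().__init__(f"{sample_id}: no lysis detected (no prominent peak)")
        self.sample_id = sample_id


@dataclass
class LysisLandmarks:
    """Indices/times of the lysis landmarks on one curve."""

    peak_index: int
    peak_time: float
    bottom_index: int
    bottom_time: float
    max_negative_slope: float  # OD/min, < 0
    regrowth_index: Optional[int]  # None when censored at run end
    regrowth_time: float  # run-end time when censored
    censored: bool

    def __post_init__(self) -> None:
        if not (self.peak_time <= self.bottom_time <= self.regrowth_time):
            raise ValueError("landmarks out of order: peak <= bottom <= regrowth required")


@dataclass
class GC7Features:
    """The seven-feature vector for one sample."""

    sample_id: str
    peak_count: int
    drop_slope: float
    drop_magnitude: float
    od_at_bottom: float
    time_peak_to_bottom: float
    time_bottom_to_rise: float
    auc_bottom_to_end: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


@dataclass
class FeatureMatrix:
    """Samples x features table with optional z-scoring state."""

    values: pd.DataFrame  # index sample_id, columns FEATURE_NAMES (or other features)
    standardized: bool = False
    means: Optional[pd.Series] = None
    sds: Optional[pd.Series] = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def as_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def detect_peaks(
    curve: GrowthCurve,
    prominence: float = DEFAULT_PROMINENCE,
    prominence_window: int = DEFAULT_PROMINENCE_WINDOW,
    plateau_size: int = DEFAULT_PLATEAU_SIZE,
) -> np.ndarray:
    """Indices of local maxima whose prominence exceeds the threshold.

    Prominence is evaluated within ``prominence_window`` samples (300 min at
    the standard 10-min grid); flat-topped peaks are admitted from
    ``plateau_size`` samples up. An empty result is legal and signals a
    curve without lysis.
    """
    peaks, _ = find_peaks(
        curve.od,
        prominence=prominence,
        wlen=prominence_window,
        plateau_size=plateau_size,
    )
    return peaks


def locate_landmarks(
    curve: GrowthCurve,
    slope_fraction: float = DEFAULT_SLOPE_FRACTION,
    peaks: Optional[np.ndarray] = None,
    **peak_kwargs,
) -> LysisLandmarks:
    """Locate peak, bottom and regrowth landmarks on a processed curve.

    ``slope_fraction`` is the fraction of the maximum lysis rate at which
    the drop is considered over (the bottom); the regrowth landmark is the
    first post-bottom point at or above 110% of the bottom OD, censored at
    the end of the run when no such point exists.
    """
    if peaks is None:
        peaks = detect_peaks(curve, **peak_kwargs)
    if len(peaks) == 0:
        raise NoLysisError(curve.sample_id)
    peak = int(peaks[0])

    grad = np.gradient(curve.od, curve.times)
    # search window: first peak .. subsequent global minimum
    tail = curve.od[peak:]
    min_after_peak = peak + int(np.argmin(tail))
    if min_after_peak == peak:
        raise NoLysisError(curve.sample_id)
    seg = grad[peak : min_after_peak + 1]
    steepest = peak + int(np.argmin(seg))
    max_neg_slope = float(grad[steepest])
    if max_neg_slope >= 0:
        raise NoLysisError(curve.sample_id)

    threshold = slope_fraction * abs(max_neg_slope)
    crossing = None
    for i in range(steepest + 1, curve.od.size):
        if abs(grad[i]) <= threshold:
            crossing = i
            break
    if crossing is None:
        bottom = min_after_peak
        logger.info(
            "%s: gradient never reached %.3g of max lysis rate; "
            "falling back to global minimum after first peak",
            curve.sample_id,
            slope_fraction,
        )
    else:
        # The central-difference gradient straddles a kink where the decline
        # stops, so the first sub-threshold sample can sit one step past the
        # true bottom; take the earliest minimum-OD point up to the crossing.
        window = curve.od[steepest : crossing + 1]
        bottom = steepest + int(np.argmin(window))

    bottom_od = float(curve.od[bottom])
    rise_level = REGROWTH_FACTOR * bottom_od
    regrowth_index: Optional[int] = None
    for i in range(bottom + 1, curve.od.size):
        if curve.od[i] >= rise_level:
            regrowth_index = i
            break
    censored = regrowth_index is None
    regrowth_time = float(curve.times[-1] if censored else curve.times[regrowth_index])

    return LysisLandmarks(
        peak_index=peak,
        peak_time=float(curve.times[peak]),
        bottom_index=bottom,
        bottom_time=float(curve.times[bottom]),
        max_negative_slope=max_neg_slope,
        regrowth_index=regrowth_index,
        regrowth_time=regrowth_time,
        censored=censored,
    )


def extract_gc7(
    curve: GrowthCurve,
    slope_fraction: float = DEFAULT_SLOPE_FRACTION,
    prominence: float = DEFAULT_PROMINENCE,
    prominence_window: int = DEFAULT_PROMINENCE_WINDOW,
    plateau_size: int = DEFAULT_PLATEAU_SIZE,
) -> GC7Features:
    """Extract the GC7 feature vector from one processed curve.

    Raises :class:`NoLysisError` when the curve has no prominent peak; the
    caller decides whether to exclude the sample or abort.
    """
    peaks = detect_peaks(
        curve,
        prominence=prominence,
        prominence_window=prominence_window,
        plateau_size=plateau_size,
    )
    lm = locate_landmarks(curve, slope_fraction=slope_fraction, peaks=peaks)

    seg = slice(lm.peak_index, lm.bottom_index + 1)
    if lm.bottom_index > lm.peak_index:
        fit = linregress(curve.times[seg], curve.od[seg])
        drop_slope = float(fit.slope)
    else:  # degenerate: bottom coincides with peak
        drop_slope = 0.0
    peak_od = float(curve.od[lm.peak_index])
    bottom_od = float(curve.od[lm.bottom_index])
    auc = float(
        np.trapezoid(
            curve.od[lm.bottom_index :], curve.times[lm.bottom_index :]
        )
    )
    return GC7Features(
        sample_id=curve.sample_id,
        peak_count=int(len(peaks)),
        drop_slope=drop_slope,
        drop_magnitude=peak_od - bottom_od,
        od_at_bottom=bottom_od,
        time_peak_to_bottom=lm.bottom_time - lm.peak_time,
        time_bottom_to_rise=lm.regrowth_time - lm.bottom_time,
        auc_bottom_to_end=auc,
    )


def extract_dataset(
    curves: Sequence[GrowthCurve],
    slope_fraction: float = DEFAULT_SLOPE_FRACTION,
    **peak_kwargs,
) -> tuple[FeatureMatrix, list[str]]:
    """Extract GC7 features for every infected curve in a dataset.

    Returns the feature matrix plus the sample ids excluded for showing no
    lysis. Control and blank curves are skipped.
    """
    rows, excluded = [], []
    for c in curves:
        if c.role != "infected":
            continue
        try:
            f = extract_gc7(c, slope_fraction=slope_fraction, **peak_kwargs)
        except NoLysisError:
            excluded.append(c.sample_id)
            continue
        rows.append({"sample_id": f.sample_id, **f.as_dict()})
    if excluded:
        logger.warning("excluded (no lysis): %s", excluded)
    df = pd.DataFrame(rows).set_index("sample_id") if rows else pd.DataFrame(
        columns=list(FEATURE_NAMES)
    )
    return FeatureMatrix(values=df), excluded


def standardize(
    matrix: FeatureMatrix, fit_on: Optional[Sequence[str]] = None
) -> FeatureMatrix:
    """Z-score each feature column to zero mean and unit (population) variance.

    ``fit_on`` restricts the samples used to estimate means and sds (the
    scaler is part of the learned pipeline, so cross-validation folds refit
    it on their own samples); the transform is applied to all rows. A
    zero-variance column cannot be scaled and is an error naming the
    feature.
    """
    df = matrix.values
    if len(df) < 2:
        raise ValueError("need at least two samples to standardize")
    fit_df = df.loc[list(fit_on)] if fit_on is not None else df
    scaler = StandardScaler()
    scaler.fit(fit_df.to_numpy(dtype=float))
    sds = np.sqrt(scaler.var_)
    zero = [c for c, s in zip(df.columns, sds) if s == 0 or not np.isfinite(s)]
    if zero:
        raise ValueError(f"zero-variance feature(s), cannot standardize: {zero}")
    z = pd.DataFrame(
        scaler.transform(df.to_numpy(dtype=float)), index=df.index, columns=df.columns
    )
    return FeatureMatrix(
        values=z,
        standardized=True,
        means=pd.Series(scaler.mean_, index=df.columns),
        sds=pd.Series(sds, index=df.columns),
    )


def sensitivity_scan(
    curves: Sequence[GrowthCurve],
    slope_fractions: Sequence[float] = (0.05, 0.10, 0.15),
    seed: int = 0,
    algorithm: str = "kmeans",
) -> pd.DataFrame:
    """Robustness of clustering to the bottom-threshold slope fraction.

    For each candidate fraction the GC7 features are re-extracted and
    leave-one-species-out cross-validation is re-run; the returned table
    holds the mean ARI/NMI/sampling score per fraction. Stable metrics
    across fractions indicate the bottom landmark is not an artifact of the
    10% default.
    """
    from .evaluation import losocv  # local import: evaluation depends on this module

    rows = []
    for frac in slope_fractions:
        matrix, _ = extract_dataset(curves, slope_fraction=frac)
        species = pd.Series(
            {c.sample_id: c.species for c in curves if c.role == "infected"}
        ).loc[matrix.values.index]
        summary = losocv(matrix, species, algorithm=algorithm, seed=seed)
        rows.append(
            {
                "slope_fraction": frac,
                "mean_ari": summary.mean_ari,
                "mean_nmi": summary.mean_nmi,
                "mean_sampling_score": summary.mean_sampling_score,
                "mean_n_clusters": summary.mean_n_clusters,
            }
        )
    return pd.DataFrame(rows).set_index("slope_fraction")
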