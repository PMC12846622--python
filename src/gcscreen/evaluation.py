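"""Clustering evaluation: ARI, NMI, sampling score, LOSOCV, feature tests.

Ground-truth species labels (from known reference phages or genomic ANI
groups) enter only here, strictly post hoc; the clustering engines never
see them.

The *sampling score* is the screening-oriented metric: the exact
probability that drawing one uniformly random representative from each
cluster recovers every species present. Writing ``c[j, s]`` for the number
of isolates of species ``s`` in cluster ``j`` and ``n_j`` for the cluster
size, inclusion-exclusion over species subsets ``T`` gives

    P(all species covered)
        = sum_{T subset S} (-1)^{|T|} * prod_j ( sum_{s not in T} c[j,s] / n_j )

which equals brute-force enumeration over all pick combinations but costs
only 2^|S| * k. A score of 1 means every species owns at least one pure
cluster; the score is 0 whenever there are fewer clusters than species.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kruskal
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from statsmodels.stats.multitest import multipletests

from .clustering import cluster_auto
from .gc7 import FeatureMatrix, standardize

logger = logging.getLogger(__name__)


def _check_lengths(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    return a, b


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected Rand agreement between two partitions, in [-1, 1]."""
    a, b = _check_lengths(labels_a, labels_b)
    return float(adjusted_rand_score(a, b))


def normalized_mutual_information(labels_a, labels_b) -> float:
    """Mutual information normalised by the arithmetic mean of entropies.

    The arithmetic-mean convention is recorded in output metadata wherever
    the value is serialised, since NMI variants are not interchangeable.
    """
    a, b = _check_lengths(labels_a, labels_b)
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def build_contingency(cluster_labels, species_labels) -> pd.DataFrame:
    """Clusters x species count table."""
    c, s = _check_lengths(cluster_labels, species_labels)
    return pd.crosstab(pd.Series(c, name="cluster"), pd.Series(s, name="species"))


def sampling_score(cluster_labels, species_labels) -> float:
    """Probability that one random pick per cluster covers every species.

    Computed exactly by inclusion-exclusion over species subsets (see module
    docstring); equivalent to enumerating all pick combinations.
    """
    table = build_contingency(cluster_labels, species_labels)
    counts = table.to_numpy(dtype=float)  # clusters x species
    n_j = counts.sum(axis=1)
    n_species = counts.shape[1]
    if counts.shape[0] < n_species:
        return 0.0
    frac = counts / n_j[:, None]
    total = 0.0
    for mask in range(1 << n_species):
        excluded = [s for s in range(n_species) if mask >> s & 1]
        sign = -1.0 if len(excluded) % 2 else 1.0
        keep = np.ones(n_species, dtype=bool)
        keep[excluded] = False
        total += sign * float(np.prod(frac[:, keep].sum(axis=1)))
    return float(min(max(total, 0.0), 1.0))


def sampling_score_bruteforce(cluster_labels, species_labels) -> float:
    """Enumeration oracle for :func:`sampling_score` (small clusters only).

    Iterates over every combination of one pick per cluster; intended for
    testing the inclusion-exclusion formula, not for production use.
    """
    c, s = _check_lengths(np.asarray(cluster_labels), np.asarray(species_labels))
    clusters = {}
    for ci, si in zip(c, s):
        clusters.setdefault(ci, []).append(si)
    members = list(clusters.values())
    sizes = [len(m) for m in members]
    if int(np.prod(sizes)) > 10**6:
        raise ValueError("too many pick combinations for brute force")
    all_species = set(s.tolist())
    covered = 0
    total = 0
    for picks in itertools.product(*members):
        total += 1
        if set(picks) == all_species:
            covered += 1
    return covered / total


@dataclass
class EvaluationSummary:
    """Per-fold LOSOCV metrics plus their aggregates."""

    folds: pd.DataFrame  # columns: left_out, n_samples, n_clusters, ari, nmi, sampling_score
    algorithm: str
    feature_set: str
    nmi_normalization: str = "arithmetic"

    def _agg(self, col: str) -> tuple[float, float]:
        vals = self.folds[col].to_numpy(dtype=float)
        return float(np.mean(vals)), float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    @property
    def mean_ari(self) -> float:
        return self._agg("ari")[0]

    @property
    def sd_ari(self) -> float:
        return self._agg("ari")[1]

    @property
    def mean_nmi(self) -> float:
        return self._agg("nmi")[0]

    @property
    def sd_nmi(self) -> float:
        return self._agg("nmi")[1]

    @property
    def mean_sampling_score(self) -> float:
        return self._agg("sampling_score")[0]

    @property
    def sd_sampling_score(self) -> float:
        return self._agg("sampling_score")[1]

    @property
    def mean_n_clusters(self) -> float:
        return self._agg("n_clusters")[0]

    @property
    def sd_n_clusters(self) -> float:
        return self._agg("n_clusters")[1]

    def as_dict(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "algorithm": self.algorithm,
            "nmi_normalization": self.nmi_normalization,
            "n_folds": self.n_folds,
            "ari": {"mean": self.mean_ari, "sd": self.sd_ari},
            "nmi": {"mean": self.mean_nmi, "sd": self.sd_nmi},
            "sampling_score": {
                "mean": self.mean_sampling_score,
                "sd": self.sd_sampling_score,
            },
            "n_clusters": {"mean": self.mean_n_clusters, "sd": self.sd_n_clusters},
            "folds": self.folds.to_dict(orient="records"),
        }


def evaluate_labels(cluster_labels, species_labels) -> dict[str, float]:
    """ARI, NMI, sampling score and cluster count for one clustering."""
    return {
        "ari": adjusted_rand_index(cluster_labels, species_labels),
        "nmi": normalized_mutual_information(cluster_labels, species_labels),
        "sampling_score": sampling_score(cluster_labels, species_labels),
        "n_clusters": int(len(np.unique(np.asarray(cluster_labels)))),
    }


def losocv(
    features: FeatureMatrix | pd.DataFrame,
    species: pd.Series,
    algorithm: str = "kmeans",
    seed: int = 0,
    k_range: Optional[tuple[int, int]] = None,
    nmds_distance=None,
    feature_set: str = "gc7",
) -> EvaluationSummary:
    """Leave-one-species-out cross-validation of an unsupervised pipeline.

    Each fold removes every sample of one species, refits the standardiser
    on the retained samples, re-selects the model order and re-clusters,
    then scores the labels against the retained samples' true species —
    species information is consumed only for fold construction and post hoc
    scoring, never by the clustering itself. For the NMDS feature set pass
    ``nmds_distance`` (a :class:`gcscreen.baselines.CurveDistanceMatrix`);
    the embedding is recomputed inside each fold.

    Folds that would retain fewer than 3 samples are skipped with a warning.
    """
    from .baselines import nmds_embed  # local import to avoid a cycle

    df = features.values if isinstance(features, FeatureMatrix) else features
    species = pd.Series(species).loc[df.index] if df is not None else pd.Series(species)
    unique_species = sorted(species.unique())
    if len(unique_species) < 2:
        raise ValueError("LOSOCV needs at least two species")
    rows = []
    for left_out in unique_species:
        keep = species.index[species != left_out]
        if len(keep) < 3:
            logger.warning("fold %s skipped: only %d samples retained", left_out, len(keep))
            continue
        if nmds_distance is not None:
            fold_df = nmds_embed(
                nmds_distance.subset(list(keep)), seed=seed
            )[0]
        else:
            fold_df = df.loc[keep]
        fold_matrix = standardize(FeatureMatrix(values=fold_df))
        result = cluster_auto(fold_matrix, algorithm=algorithm, k_range=k_range, seed=seed)
        metrics = evaluate_labels(result.labels, species.loc[keep].to_numpy())
        rows.append({"left_out": left_out, "n_samples": len(keep), **metrics})
    if not rows:
        raise ValueError("no evaluable folds")
    return EvaluationSummary(
        folds=pd.DataFrame(rows), algorithm=algorithm, feature_set=feature_set
    )


def kruskal_holm(
    features: pd.DataFrame, species: pd.Series
) -> pd.DataFrame:
    """Per-feature Kruskal-Wallis test across species, Holm-adjusted.

    Returns a table with the tie-corrected H statistic, raw chi-square
    p-value and Holm step-down adjusted p-value per feature column. A
    feature constant across all samples has an undefined test and is
    reported with p = 1 and a warning.
    """
    species = pd.Series(species).loc[features.index]
    groups = sorted(species.unique())
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    stats, raw_p = [], []
    for col in features.columns:
        vals = [features.loc[species == g, col].to_numpy(dtype=float) for g in groups]
        if np.all(features[col].to_numpy() == features[col].iloc[0]):
            warnings.warn(f"feature {col!r} is constant; Kruskal-Wallis undefined, p set to 1")
            stats.append(np.nan)
            raw_p.append(1.0)
            continue
        h, p = kruskal(*vals)
        stats.append(float(h))
        raw_p.append(float(p))
    adjusted = holm_adjust(raw_p)
    return pd.DataFrame(
        {"H": stats, "p_raw": raw_p, "p_holm": adjusted}, index=features.columns
    )


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values."""
    _, adjusted, _, _ = multipletests(np.asarray(p_values, dtype=float), method="holm")
    return adjusted
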