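"""Established comparison features: Virulence Index, Centroid Index, NMDS.

These are the one-dimensional and ordination-based growth-curve summaries
the GC7 feature set is benchmarked against:

* **local virulence / Virulence Index (VI)** — the killing strength of an
  infection relative to the uninfected control, ``v = 1 - AUC_i / AUC_c``
  over a time horizon; ``v = 1`` only for a completely lysed (identically
  zero) culture. Multi-MOI runs integrate v over log10(MOI), normalised by
  the log10-MOI range.
* **Centroid Index (CI)** — the shift of the growth curve's area centroid
  time ``x_c = sum(OD_i * t_i) / sum(OD_i)`` caused by infection, here
  normalised by the control centroid (``--ci-norm duration`` normalises by
  run duration instead). Earlier lysis moves OD mass earlier in time and
  gives a negative CI.
* **NMDS** — non-metric multidimensional scaling of whole curves under the
  L1 distance (sum of absolute OD differences at each time point), retaining
  a 2-D rank-preserving embedding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.manifold import MDS

from .preprocess import GrowthCurve


@dataclass
class CurveDistanceMatrix:
    """Symmetric L1 distance matrix between curves on a shared time grid."""

    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")
        self.matrix = m

    def subset(self, ids: Sequence[str]) -> "CurveDistanceMatrix":
        pos = [self.sample_ids.index(i) for i in ids]
        return CurveDistanceMatrix(list(ids), self.matrix[np.ix_(pos, pos)])


def _check_shared_grid(a: GrowthCurve, b: GrowthCurve) -> None:
    if a.times.shape != b.times.shape or not np.allclose(a.times, b.times):
        raise ValueError("curves must share an identical time grid")


def local_virulence(
    infected: GrowthCurve,
    control: GrowthCurve,
    horizon: Optional[float] = None,
) -> float:
    """Local virulence v = 1 - AUC(infected)/AUC(control) over [start, horizon].

    The default horizon is the full run. v is bounded above by 1 (complete
    lysis); a curve indistinguishable from the control scores 0.
    """
    _check_shared_grid(infected, control)
    mask = np.ones_like(infected.times, dtype=bool)
    if horizon is not None:
        mask = infected.times <= horizon
        if mask.sum() < 2:
            raise ValueError("horizon leaves fewer than two time points")
    t = infected.times[mask]
    auc_c = float(np.trapezoid(control.od[mask], t))
    if auc_c == 0:
        raise ValueError("control AUC is zero; local virulence undefined")
    auc_i = float(np.trapezoid(infected.od[mask], t))
    return 1.0 - auc_i / auc_c


def virulence_index_over_moi(
    local_virulences: Sequence[float], mois: Sequence[float]
) -> float:
    """Integrate local virulence over log10(MOI), normalised by the range.

    Requires at least two distinct MOIs; for a single MOI the per-sample
    local virulence itself is the clustering feature.
    """
    mois = np.asarray(mois, dtype=float)
    v = np.asarray(local_virulences, dtype=float)
    if mois.size != v.size:
        raise ValueError("mois and virulences length mismatch")
    if np.unique(mois).size < 2:
        raise ValueError(
            "virulence index needs >=2 distinct MOIs; use local_virulence for one"
        )
    order = np.argsort(mois)
    logm = np.log10(mois[order])
    return float(np.trapezoid(v[order], logm) / (logm[-1] - logm[0]))


def centroid_time(curve: GrowthCurve) -> float:
    """Area-centroid time x_c = sum(OD_i * t_i) / sum(OD_i), in minutes."""
    total = float(np.sum(curve.od))
    if total == 0:
        raise ValueError(f"{curve.sample_id}: total OD is zero; centroid undefined")
    return float(np.sum(curve.od * curve.times) / total)


def centroid_index(
    infected: GrowthCurve, control: GrowthCurve, norm: str = "control"
) -> float:
    """Normalised centroid shift of the infected vs the control curve.

    ``norm='control'`` divides by the control centroid time (default);
    ``norm='duration'`` divides by the run duration instead. Earlier lysis
    shifts OD mass to earlier times and yields a negative index.
    """
    _check_shared_grid(infected, control)
    xc_i = centroid_time(infected)
    xc_c = centroid_time(control)
    if norm == "control":
        if xc_c == 0:
            raise ValueError("control centroid time is zero; cannot normalise")
        return (xc_i - xc_c) / xc_c
    if norm == "duration":
        duration = float(control.times[-1] - control.times[0])
        return (xc_i - xc_c) / duration
    raise ValueError(f"unknown normalisation {norm!r}")


def curve_distance_matrix(curves: Sequence[GrowthCurve]) -> CurveDistanceMatrix:
    """Pairwise L1 distances: D[i,j] = sum_t |OD_i(t) - OD_j(t)|.

    All curves must share the time grid. Adding the same constant to every
    curve leaves D unchanged, so the matrix is offset-invariant.
    """
    if not curves:
        raise ValueError("no curves")
    grid = curves[0].times
    for c in curves[1:]:
        _check_shared_grid(curves[0], c)
    X = np.vstack([c.od for c in curves])
    D = squareform(pdist(X, metric="cityblock"))
    return CurveDistanceMatrix([c.sample_id for c in curves], D)


def nmds_embed(
    dist: CurveDistanceMatrix,
    dims: int = 2,
    restarts: int = 16,
    seed: int = 0,
    max_iter: int = 300,
) -> tuple[pd.DataFrame, float]:
    """Non-metric MDS embedding of a curve distance matrix.

    Runs ``restarts`` seeded initialisations of stress-1 minimising NMDS and
    keeps the best; returns the coordinates (DataFrame indexed by sample id)
    and the final normalised stress. Raises if no restart converges to a
    finite stress.
    """
    n = len(dist.sample_ids)
    if n < dims + 1:
        raise ValueError(f"need at least {dims + 1} samples for a {dims}-D embedding")
    best_coords, best_stress = None, np.inf
    trace = []
    for r in range(restarts):
        mds = MDS(
            n_components=dims,
            metric_mds=False,
            metric="precomputed",
            n_init=1,
            init="random",
            max_iter=max_iter,
            random_state=seed + r,
            normalized_stress=True,
        )
        coords = mds.fit_transform(dist.matrix)
        trace.append(float(mds.stress_))
        if np.isfinite(mds.stress_) and mds.stress_ < best_stress:
            best_stress = float(mds.stress_)
            best_coords = coords
    if best_coords is None:
        raise RuntimeError(f"NMDS failed to converge in {restarts} restarts; stress trace {trace}")
    df = pd.DataFrame(
        best_coords,
        index=dist.sample_ids,
        columns=[f"nmds{i + 1}" for i in range(dims)],
    )
    return df, best_stress


def baseline_features(
    curves: Sequence[GrowthCurve],
    metric: str = "vi",
    seed: int = 0,
    ci_norm: str = "control",
    horizon: Optional[float] = None,
) -> pd.DataFrame:
    """Per-sample baseline feature table (vi, ci, or nmds coordinates).

    VI and CI are computed for each infected curve against the pointwise
    mean of the uninfected control curves of the dataset; NMDS embeds the
    infected curves' L1 distance matrix in 2-D.
    """
    infected = [c for c in curves if c.role == "infected"]
    if not infected:
        raise ValueError("no infected curves")
    if metric == "nmds":
        coords, _ = nmds_embed(curve_distance_matrix(infected), seed=seed)
        return coords
    controls = [c for c in curves if c.role == "control"]
    if not controls:
        raise ValueError("vi/ci need at least one control curve")
    mean_control = controls[0].copy_with(
        od=np.mean(np.vstack([c.od for c in controls]), axis=0),
        sample_id="mean_control",
    )
    rows = {}
    for c in infected:
        if metric == "vi":
            rows[c.sample_id] = local_virulence(c, mean_control, horizon=horizon)
        elif metric == "ci":
            rows[c.sample_id] = centroid_index(c, mean_control, norm=ci_norm)
        else:
            raise ValueError(f"unknown baseline metric {metric!r}")
    return pd.DataFrame.from_dict(rows, orient="index", columns=[metric])
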