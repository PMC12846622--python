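"""Auto-tuned unsupervised clustering engines.

Four algorithms with automatic model selection, each labelling every input
sample (no noise label):

* **K-means** — k chosen as the *larger* of the elbow k (maximum discrete
  curvature of the within-cluster sum of squares) and the silhouette k
  (maximum mean silhouette), to avoid under-clustering that would merge
  distinct phage species.
* **Gaussian mixture** — full covariance matrices; k minimises the Bayesian
  Information Criterion.
* **DBSCAN** — eps from the knee of the sorted 2-nearest-neighbour distance
  graph (maximum distance to the chord); ``min_samples=1`` so every isolate
  is classified, since the goal is to characterise all candidates rather
  than find core clusters.
* **Ward hierarchical** — cut height chosen by maximum silhouette, ties
  broken by minimum Davies-Bouldin index.

"Maximum curvature" is made concrete as the maximum second central
difference for the elbow and the maximum distance-to-chord (Kneedle-style)
for the k-distance graph; both conventions are deterministic with ties
broken toward the smaller k / earlier point.

None of these functions accepts ground-truth species labels: clustering is
strictly unsupervised and labels are only compared to truth downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.cluster import DBSCAN, AgglomerativeClustering, KMeans
from sklearn.metrics import davies_bouldin_score, silhouette_score
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

KMEANS_N_INIT = 10
GMM_REG_COVAR = 1e-6


@dataclass
class ClusteringResult:
    """Labels plus model-selection provenance for one clustering run."""

    labels: np.ndarray  # ints 0..k-1
    k: int
    algorithm: str
    diagnostics: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min(initial=0) < 0:
            raise ValueError("all samples must be labelled (no noise label)")
        if len(np.unique(self.labels)) != self.k:
            raise ValueError("k must equal the number of distinct labels")


def default_k_range(n: int) -> tuple[int, int]:
    """Candidate cluster-number range for n samples.

    2..min(10, n-1) for small panels; widened to min(20, n-1) beyond 30
    samples, where condition gradients (e.g. several MOI levels per phage)
    legitimately split species into more clusters.
    """
    upper = min(20, n - 1) if n > 30 else min(10, n - 1)
    return 2, max(2, upper)


def _as_array(X) -> np.ndarray:
    arr = getattr(X, "as_array", None)
    if callable(arr):
        return arr()
    return np.asarray(X, dtype=float)


def choose_k_elbow(wcss_by_k: dict[int, float]) -> int:
    """Elbow point of a WCSS-vs-k table: the k of maximum discrete curvature.

    Curvature at interior k is the second central difference
    ``wcss[k-1] - 2*wcss[k] + wcss[k+1]``; ties (including the degenerate
    linear-decay case with zero curvature everywhere) resolve to the
    smallest k.
    """
    ks = sorted(wcss_by_k)
    if len(ks) < 3:
        raise ValueError("elbow selection needs WCSS at >=3 consecutive k values")
    best_k, best_curv = None, -np.inf
    for k_prev, k, k_next in zip(ks, ks[1:], ks[2:]):
        curv = wcss_by_k[k_prev] - 2 * wcss_by_k[k] + wcss_by_k[k_next]
        if curv > best_curv:
            best_curv, best_k = curv, k
    return int(best_k)


def _kmeans_fit(X: np.ndarray, k: int, seed: Optional[int]) -> KMeans:
    return KMeans(n_clusters=k, n_init=KMEANS_N_INIT, random_state=seed).fit(X)


def wcss_table(
    X, k_range: Optional[tuple[int, int]] = None, seed: Optional[int] = 0
) -> dict[int, float]:
    """Within-cluster sum of squares from seeded K-means fits at each k.

    The table starts at k=1 (total sum of squares) so the elbow curvature
    is defined at the lower end of the candidate range.
    """
    X = _as_array(X)
    lo, hi = k_range if k_range is not None else default_k_range(len(X))
    return {
        k: float(_kmeans_fit(X, k, seed).inertia_)
        for k in range(1, min(hi, len(X) - 1) + 1)
    }


def choose_k_silhouette(
    X, k_range: Optional[tuple[int, int]] = None, seed: Optional[int] = 0
) -> tuple[int, float]:
    """k maximising the mean silhouette over seeded K-means fits.

    Returns (k, silhouette at k); a near-zero best silhouette warns that the
    data may hold a single cluster, which the silhouette cannot express.
    """
    X = _as_array(X)
    if len(X) < 3:
        raise ValueError("silhouette selection needs >=3 samples")
    lo, hi = k_range if k_range is not None else default_k_range(len(X))
    lo = max(2, lo)
    hi = min(hi, len(X) - 1)
    best_k, best_s = None, -np.inf
    for k in range(lo, hi + 1):
        labels = _kmeans_fit(X, k, seed).labels_
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(X, labels)
        if s > best_s:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("silhouette undefined for every candidate k")
    return int(best_k), float(best_s)


def cluster_kmeans_auto(
    X, k_range: Optional[tuple[int, int]] = None, seed: Optional[int] = 0
) -> ClusteringResult:
    """K-means with k = max(elbow k, silhouette k).

    Taking the larger of the two suggestions guards against under-clustering
    that would merge biologically distinct species.
    """
    arr = _as_array(X)
    wcss = wcss_table(arr, k_range=k_range, seed=seed)
    k_elbow = choose_k_elbow(wcss)
    k_sil, sil = choose_k_silhouette(arr, k_range=k_range, seed=seed)
    k = max(k_elbow, k_sil)
    fit = _kmeans_fit(arr, k, seed)
    return ClusteringResult(
        labels=fit.labels_,
        k=k,
        algorithm="kmeans",
        seed=seed,
        diagnostics={
            "wcss_by_k": wcss,
            "k_elbow": k_elbow,
            "k_silhouette": k_sil,
            "silhouette": sil,
            "inertia": float(fit.inertia_),
        },
    )


def cluster_gmm_auto(
    X, k_range: Optional[tuple[int, int]] = None, seed: Optional[int] = 0
) -> ClusteringResult:
    """Gaussian mixture with full covariances; k = argmin BIC.

    A small covariance regularisation floor keeps full covariances well
    posed on small panels; labels are maximum-posterior assignments.
    """
    arr = _as_array(X)
    lo, hi = k_range if k_range is not None else default_k_range(len(arr))
    hi = min(hi, len(arr) - 1)
    bic_by_k, fits = {}, {}
    for k in range(max(1, lo), hi + 1):
        gmm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            reg_covar=GMM_REG_COVAR,
            random_state=seed,
            n_init=3,
        ).fit(arr)
        bic_by_k[k] = float(gmm.bic(arr))
        fits[k] = gmm
    k = min(bic_by_k, key=bic_by_k.get)
    labels = fits[k].predict(arr)
    # relabel to 0..k'-1 in case a component is empty
    _, labels = np.unique(labels, return_inverse=True)
    return ClusteringResult(
        labels=labels,
        k=int(len(np.unique(labels))),
        algorithm="gmm",
        seed=seed,
        diagnostics={"bic_by_k": bic_by_k, "k_bic": int(k)},
    )


def estimate_eps_kdistance(X, k_neighbors: int = 2) -> float:
    """DBSCAN eps from the knee of the sorted k-NN distance graph.

    Each point's distance to its ``k_neighbors``-th nearest neighbour
    (excluding itself) is sorted ascending; eps is the value at the point of
    maximum perpendicular distance to the chord joining the curve's
    endpoints (Kneedle convention). A flat graph returns the common
    distance; if the knee lands on a zero distance (duplicated points) the
    smallest positive distance is used instead.
    """
    X = _as_array(X)
    n = len(X)
    if n < 3:
        raise ValueError("eps estimation needs >=3 samples")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    dists, _ = nn.kneighbors(X)
    kdist = np.sort(dists[:, k_neighbors])
    if np.allclose(kdist, kdist[0]):
        return float(kdist[0]) if kdist[0] > 0 else 1e-12
    # distance from each point of the curve to the chord (first..last point)
    x = np.arange(n, dtype=float)
    p0 = np.array([x[0], kdist[0]])
    p1 = np.array([x[-1], kdist[-1]])
    chord = p1 - p0
    chord /= np.linalg.norm(chord)
    rel = np.stack([x - p0[0], kdist - p0[1]], axis=1)
    perp = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    eps = float(kdist[int(np.argmax(perp))])
    if eps <= 0:
        positive = kdist[kdist > 0]
        eps = float(positive[0]) if positive.size else 1e-12
    return eps


def cluster_dbscan_auto(X, seed: Optional[int] = 0, k_neighbors: int = 2) -> ClusteringResult:
    """DBSCAN with auto-estimated eps and min_samples=1.

    With ``min_samples=1`` clusters are the connected components of the
    eps-neighbourhood graph and no point is noise. The seed is accepted for
    API uniformity; the algorithm is deterministic given eps.
    """
    arr = _as_array(X)
    eps = estimate_eps_kdistance(arr, k_neighbors=k_neighbors)
    labels = DBSCAN(eps=eps, min_samples=1).fit(arr).labels_
    _, labels = np.unique(labels, return_inverse=True)
    return ClusteringResult(
        labels=labels,
        k=int(len(np.unique(labels))),
        algorithm="dbscan",
        seed=seed,
        diagnostics={"eps": eps, "k_neighbors": k_neighbors},
    )


def cluster_ward_auto(
    X, k_range: Optional[tuple[int, int]] = None, seed: Optional[int] = 0
) -> ClusteringResult:
    """Ward-linkage hierarchical clustering with silhouette-selected cut.

    Every candidate cut in the k range is scored; the cut with the highest
    silhouette wins, ties broken by the lower Davies-Bouldin index (smaller
    is better), then by the smaller k. The seed is accepted for API
    uniformity; Ward linkage is deterministic.
    """
    arr = _as_array(X)
    if len(arr) < 3:
        raise ValueError("ward clustering needs >=3 samples")
    lo, hi = k_range if k_range is not None else default_k_range(len(arr))
    lo = max(2, lo)
    hi = min(hi, len(arr) - 1)
    sil_by_k, db_by_k, labels_by_k = {}, {}, {}
    for k in range(lo, hi + 1):
        labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(arr)
        if len(np.unique(labels)) < 2:
            continue
        sil_by_k[k] = float(silhouette_score(arr, labels))
        db_by_k[k] = float(davies_bouldin_score(arr, labels))
        labels_by_k[k] = labels
    if not sil_by_k:
        raise ValueError("no valid cut in the candidate range")
    k = min(sil_by_k, key=lambda kk: (-round(sil_by_k[kk], 12), db_by_k[kk], kk))
    return ClusteringResult(
        labels=labels_by_k[k],
        k=int(k),
        algorithm="ward",
        seed=seed,
        diagnostics={"silhouette_by_k": sil_by_k, "davies_bouldin_by_k": db_by_k},
    )


ALGORITHMS = {
    "kmeans": cluster_kmeans_auto,
    "gmm": cluster_gmm_auto,
    "dbscan": lambda X, k_range=None, seed=0: cluster_dbscan_auto(X, seed=seed),
    "ward": cluster_ward_auto,
}


def cluster_auto(
    X,
    algorithm: str = "kmeans",
    k_range: Optional[tuple[int, int]] = None,
    seed: Optional[int] = 0,
) -> ClusteringResult:
    """Dispatch to one of the four auto-tuned engines by name."""
    try:
        fn = ALGORITHMS[algorithm]
    except KeyError:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {list(ALGORITHMS)}")
    return fn(X, k_range=k_range, seed=seed)
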