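"""Shrub-cover groups from spectral similarity.

Quadrats with intermediate shrub cover (strictly between 0% and 100%) are
clustered on their preprocessed spectra with K-means and Ward agglomeration
(Euclidean distance).  The cluster count is chosen by majority vote of a
panel of internal-validity indices over a 2..15 search range.  Clusters are
then turned into ordered cover groups: clusters are ranked by mean visual
shrub cover, clusters whose cover ranges overlap are merged, and the
breakpoints are the midpoints between adjacent cluster cover ranges.
Quadrats with exactly 0% shrub always form group 1 and the pure-shrub
endmember spectra are appended as the final (~100%) group.  When several
clusterings yield candidate schemes, the scheme with the most balanced
group sizes (minimum variance of counts) wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import (calinski_harabasz_score, davies_bouldin_score,
                             silhouette_score)

__all__ = [
    "DEFAULT_INDEX_PANEL",
    "ClusterResult",
    "CoverGroupScheme",
    "optimal_cluster_count",
    "cluster_spectra",
    "build_cover_scheme",
    "select_balanced_scheme",
]

#: Internal-validity index panel used for the majority vote.  Each index
#: votes for the k in the search range that optimises it.
DEFAULT_INDEX_PANEL = ("silhouette", "calinski_harabasz", "davies_bouldin",
                       "dunn", "bic")


@dataclass
class ClusterResult:
    method: str
    k: int
    labels: np.ndarray            # 1-based cluster ids, one per sample
    index_votes: dict = field(default_factory=dict)


def _dunn_index(X: np.ndarray, labels: np.ndarray) -> float:
    """Minimum between-cluster distance over maximum cluster diameter."""
    uniq = np.unique(labels)
    diam = 0.0
    for u in uniq:
        pts = X[labels == u]
        if len(pts) > 1:
            diam = max(diam, pdist(pts).max())
    if diam == 0:
        return np.inf
    sep = np.inf
    for i, a in enumerate(uniq):
        for b in uniq[i + 1:]:
            d = np.linalg.norm(X[labels == a][:, None, :] - X[labels == b][None, :, :],
                               axis=2).min()
            sep = min(sep, d)
    return sep / diam


def _spherical_bic(X: np.ndarray, labels: np.ndarray) -> float:
    """BIC of a spherical Gaussian mixture with hard assignments (lower better)."""
    n, d = X.shape
    uniq = np.unique(labels)
    k = len(uniq)
    rss = 0.0
    for u in uniq:
        pts = X[labels == u]
        rss += ((pts - pts.mean(axis=0)) ** 2).sum()
    var = max(rss / max(n * d - k, 1), 1e-300)
    ll = -0.5 * n * d * (np.log(2 * np.pi * var) + 1.0)
    n_params = k * d + k - 1 + 1
    return -2 * ll + n_params * np.log(n)


def _fit_labels(X: np.ndarray, k: int, method: str, seed: int) -> np.ndarray:
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        return km.fit_predict(X) + 1
    if method == "ward":
        ag = AgglomerativeClustering(n_clusters=k, linkage="ward")
        return ag.fit_predict(X) + 1
    raise ValueError(f"unknown clustering method {method!r}")


def optimal_cluster_count(X: np.ndarray, method: str = "kmeans",
                          k_range: tuple[int, int] = (2, 15),
                          index_panel: tuple[str, ...] = DEFAULT_INDEX_PANEL,
                          seed: int = 0) -> tuple[int, dict]:
    """Majority vote of internal-validity indices over k in ``k_range``.

    Ties are broken toward the smallest k.  Returns (k, votes).
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    k_min, k_max = k_range
    if n <= k_max:
        k_max = n - 1
        warnings.warn(f"fewer samples than k_max; truncating search to [{k_min}, {k_max}]",
                      stacklevel=2)
    if k_max < k_min:
        raise ValueError("not enough samples to cluster")
    ks = list(range(k_min, k_max + 1))
    scores: dict[str, dict[int, float]] = {idx: {} for idx in index_panel}
    for k in ks:
        labels = _fit_labels(X, k, method, seed)
        for idx in index_panel:
            if idx == "silhouette":
                scores[idx][k] = silhouette_score(X, labels)
            elif idx == "calinski_harabasz":
                scores[idx][k] = calinski_harabasz_score(X, labels)
            elif idx == "davies_bouldin":
                scores[idx][k] = -davies_bouldin_score(X, labels)
            elif idx == "dunn":
                scores[idx][k] = _dunn_index(X, labels)
            elif idx == "bic":
                scores[idx][k] = -_spherical_bic(X, labels)
            else:
                raise ValueError(f"unknown index {idx!r}")
    votes = {idx: min(k for k in ks if s[k] == max(s.values()))
             for idx, s in scores.items()}
    counts: dict[int, int] = {}
    for k in votes.values():
        counts[k] = counts.get(k, 0) + 1
    best = max(counts.values())
    k_opt = min(k for k, c in counts.items() if c == best)
    return k_opt, votes


def cluster_spectra(X: np.ndarray, k: int, method: str = "kmeans",
                    seed: int = 0) -> ClusterResult:
    """K-means (10 seeded restarts, best inertia kept) or Ward at Euclidean distance."""
    X = np.asarray(X, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(X):
        raise ValueError(f"k={k} exceeds the {len(X)} samples")
    return ClusterResult(method=method, k=k, labels=_fit_labels(X, k, method, seed))


@dataclass
class CoverGroupScheme:
    """Ordered shrub-cover groups.

    Group 1 holds exactly the 0%-cover quadrats; intermediate groups are
    half-open cover intervals (low, high]; the final group is the
    ~100%-cover endmember set.  ``breakpoints`` are the upper bounds of
    the intermediate groups (one per group); cover above the last
    breakpoint falls into the final group together with the endmembers.
    """

    breakpoints: tuple[float, ...]
    group_of: dict                       # quadrat_id -> group id (intermediates + zeros)
    counts: tuple[int, ...]              # per group, endmember group last
    includes_zero_group: bool = True
    includes_endmember_group: bool = True
    method: str = ""

    @property
    def n_groups(self) -> int:
        return len(self.counts)

    @property
    def endmember_group(self) -> int:
        return self.n_groups

    def assign(self, cover_pct: float) -> int:
        """Group id for a visual cover percentage (endmembers not assignable here)."""
        if cover_pct < 0 or cover_pct > 100:
            raise ValueError("cover must be in [0, 100]")
        if cover_pct == 0:
            return 1
        g = 2
        for bp in self.breakpoints:
            if cover_pct <= bp:
                return g
            g += 1
        return g  # above the last breakpoint: the ~100% endmember group

    def count_variance(self) -> float:
        return float(np.var(self.counts))


def build_cover_scheme(result: ClusterResult, cover_pct: np.ndarray,
                       quadrat_ids: list[str],
                       n_endmembers: int,
                       zero_quadrat_ids: list[str] = (),
                       ) -> CoverGroupScheme:
    """Derive a cover-group scheme from one clustering of intermediate quadrats.

    ``cover_pct`` are the visual shrub covers of the clustered quadrats
    (all strictly between 0 and 100).  Clusters are ordered by mean cover,
    merged while their cover ranges overlap, and breakpoints placed at
    midpoints between adjacent merged ranges; the max cover of the top
    cluster closes the last intermediate group, so cover beyond it joins
    the endmember group.
    """
    cover_pct = np.asarray(cover_pct, dtype=float)
    if len(cover_pct) != len(result.labels):
        raise ValueError("cover and labels length mismatch")
    if cover_pct.size and (cover_pct.min() <= 0 or cover_pct.max() >= 100):
        raise ValueError("clustered quadrats must have cover strictly in (0, 100)")
    if cover_pct.size and np.ptp(cover_pct) == 0:
        warnings.warn("all clustered quadrats share one cover value; degenerate scheme",
                      stacklevel=2)

    # order clusters by mean cover, then merge overlapping cover ranges
    uniq = np.unique(result.labels)
    ranges = []
    for u in uniq:
        c = cover_pct[result.labels == u]
        ranges.append([c.min(), c.max(), c.mean()])
    ranges.sort(key=lambda r: r[2])
    merged: list[list[float]] = []
    for lo, hi, _ in ((r[0], r[1], r[2]) for r in ranges):
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    internal = [(merged[i][1] + merged[i + 1][0]) / 2.0
                for i in range(len(merged) - 1)]
    breakpoints = tuple(internal + ([merged[-1][1]] if merged else []))

    scheme = CoverGroupScheme(breakpoints=breakpoints, group_of={}, counts=(),
                              method=result.method)
    group_of = {qid: 1 for qid in zero_quadrat_ids}
    for qid, c in zip(quadrat_ids, cover_pct):
        group_of[qid] = scheme.assign(c)
    counts = [0] * (1 + len(merged) + 1)
    for g in group_of.values():
        counts[g - 1] += 1
    counts[-1] += n_endmembers
    scheme.group_of = group_of
    scheme.counts = tuple(counts)
    return scheme


def select_balanced_scheme(schemes: list[CoverGroupScheme]) -> CoverGroupScheme:
    """The scheme with the lowest variance of group counts (first on ties)."""
    if not schemes:
        raise ValueError("no candidate schemes")
    return min(schemes, key=lambda s: (s.count_variance(),))
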