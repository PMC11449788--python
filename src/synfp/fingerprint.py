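"""Shape fingerprinting: embedding, clustering, and pseudotime.

The nine shape features are log-transformed (``log(x + eps)`` with a small
feature-specific eps, since the volume ratio can be exactly 0), centered and
scaled, and reduced to the first three principal components.  In PC space,
partitional clustering is done with CLARA (k-medoids on repeated subsamples,
best total dissimilarity kept) and the number of clusters is selected by the
Gap statistic against uniform reference data drawn over the PCA-aligned
bounding box, using the firstSEmax rule.  Clusters are reordered by ascending
medoid volume so that cluster identity runs along the small-spherical ->
voluminous-complex continuum, and a principal curve through the ordered
medoids assigns each object an arc-length pseudotime (centered and scaled),
read as an ordinal proxy for synaptic maturity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .scaffold_shapes import FEATURE_COLUMNS

__all__ = [
    "Embedding",
    "ClusterModel",
    "PseudotimeAssignment",
    "embed",
    "cluster",
    "pseudotime",
    "composition_table",
    "clara",
]


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

@dataclass
class Embedding:
    """PC1-3 scores plus the stored log/center/scale/rotation transform."""

    scores: np.ndarray                 # (n, 3)
    loadings: np.ndarray               # (n_features, 3), orthonormal columns
    feature_names: list[str]
    eps: np.ndarray                    # per-feature log offset
    center: np.ndarray                 # mean of log features
    scale: np.ndarray                  # sd of log features
    pca_mean: np.ndarray               # mean of scaled features (≈ 0)
    log: bool = True

    def transform(self, records: pd.DataFrame) -> np.ndarray:
        """Apply the stored transform to raw feature records."""
        X = records[self.feature_names].to_numpy(dtype=float)
        L = np.log(X + self.eps) if self.log else X
        Z = (L - self.center) / self.scale
        return (Z - self.pca_mean) @ self.loadings


def embed(records: pd.DataFrame, n_components: int = 3,
          features: list[str] | None = None, log: bool = True) -> Embedding:
    """log -> z-score -> PCA to the first ``n_components`` components.

    ``log=False`` skips the log transform (features already on a linear
    scale); centering/scaling and PCA are applied either way.
    """
    features = features or FEATURE_COLUMNS
    if len(records) < 10:
        raise ValueError("need at least 10 records to embed")
    missing = [c for c in features if c not in records.columns]
    if missing:
        raise ValueError(f"missing features: {missing}")
    X = records[features].to_numpy(dtype=float)

    eps = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        pos = X[:, j][X[:, j] > 0]
        eps[j] = 1e-6 * pos.min() if pos.size else 1e-12
    if not log:
        eps = np.zeros(X.shape[1])
    L = np.log(X + eps) if log else X
    center = L.mean(axis=0)
    scale = L.std(axis=0, ddof=0)
    for j, c in enumerate(features):
        if scale[j] <= 1e-12 * max(1.0, abs(center[j])):
            raise ValueError(f"zero-variance feature after log transform: {c!r}")
    Z = (L - center) / scale

    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    return Embedding(scores, pca.components_.T, list(features), eps, center, scale,
                     pca.mean_, log=log)


# ---------------------------------------------------------------------------
# CLARA k-medoids
# ---------------------------------------------------------------------------

def _pam(D: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100):
    """PAM (build + swap) on a full distance matrix; returns medoid indices."""
    n = D.shape[0]
    # build: greedy minimization of total distance
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dmin = D[:, medoids].min(axis=1)
        gains = np.maximum(dmin[None, :] - D, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = np.array(medoids)
    # swap until no improvement (vectorized over candidate replacements)
    for _ in range(max_iter):
        cost = D[:, medoids].min(axis=1).sum()
        best = None
        for mi in range(k):
            others = np.delete(medoids, mi)
            dothers = (D[:, others].min(axis=1) if k > 1
                       else np.full(n, np.inf))
            new_costs = np.minimum(dothers[:, None], D).sum(axis=0)
            new_costs[medoids] = np.inf
            h = int(np.argmin(new_costs))
            if new_costs[h] < cost - 1e-12:
                cost = new_costs[h]
                best = (mi, h)
        if best is None:
            break
        medoids[best[0]] = best[1]
    return medoids


def clara(
    X: np.ndarray,
    k: int,
    *,
    n_subsamples: int = 50,
    subsample_size: int | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """CLARA: k-medoids via repeated subsampled PAM.

    Each of ``n_subsamples`` subsamples of size ``40 + k`` (default) is
    clustered with PAM; the medoid set with the smallest total Euclidean
    dissimilarity over the *full* dataset is kept.  Returns
    ``(assignments in 0..k-1, medoid row indices, total cost)``.
    """
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    if k < 1 or n < 2 * k:
        raise ValueError("need n >= 2k points")
    size = min(n, subsample_size or (40 + k))

    from scipy.spatial.distance import cdist

    best_cost = np.inf
    best_medoids = None
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=size, replace=False)
        sub = X[idx]
        med_local = _pam(cdist(sub, sub), k, rng)
        med = idx[med_local]
        cost = cdist(X, X[med]).min(axis=1).sum()
        if cost < best_cost:
            best_cost = cost
            best_medoids = med
        if size == n:
            break  # subsample is the full dataset; further draws are identical
    assign = cdist(X, X[best_medoids]).argmin(axis=1)
    return assign, best_medoids, float(best_cost)


# ---------------------------------------------------------------------------
# Gap statistic and the clustering model
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    k: int
    assignments: np.ndarray            # values in 1..k, reordered
    medoids: np.ndarray                # object row indices, ordered 1..k
    gap_curve: pd.DataFrame            # k, gap, se, log_w
    order: np.ndarray                  # permutation mapping raw -> ordered id


def _within_dispersion(X: np.ndarray, assign: np.ndarray, k: int) -> float:
    """Tibshirani W_k: sum over clusters of pairwise-d^2 / (2 n_r)."""
    w = 0.0
    for c in range(k):
        pts = X[assign == c]
        if len(pts) > 1:
            cen = pts.mean(axis=0)
            w += ((pts - cen) ** 2).sum()
    return max(w, 1e-300)


def _first_se_max(gap: np.ndarray, se: np.ndarray, ks: np.ndarray,
                  se_factor: float = 1.0) -> int:
    """firstSEmax rule: smallest k whose gap is within ``se_factor`` standard
    errors of the gap at the first local maximum (the first k after which the
    gap curve decreases; the last k when the curve never decreases)."""
    decr = np.diff(gap) < 0
    nc = int(np.argmax(decr)) if decr.any() else len(gap) - 1
    thresh = gap[nc] - se_factor * se[nc]
    for i in range(nc):
        if gap[i] >= thresh:
            return int(ks[i])
    return int(ks[nc])


def cluster(
    embedding: Embedding,
    k_range: range | list[int] = range(1, 11),
    *,
    gap_B: int = 50,
    seed: int | None = None,
    volumes: np.ndarray | None = None,
    n_subsamples: int = 50,
    forced_k: int | None = None,
) -> ClusterModel:
    """CLARA over a k range with Gap-statistic model selection.

    Reference datasets are drawn uniformly over the bounding box of the PC
    scores (which are PCA-aligned by construction).  ``volumes`` orders the
    final clusters by ascending medoid volume; when omitted, PC1 of the
    medoid is used as the ordering proxy.
    """
    X = embedding.scores
    n = X.shape[0]
    ks = np.array(sorted(k_range))
    if ks.max() > n / 2:
        raise ValueError("k range too large for the number of points")
    rng = np.random.default_rng(seed)

    if forced_k is None:
        log_w = np.empty(len(ks))
        for i, k in enumerate(ks):
            if k == 1:
                log_w[i] = np.log(_within_dispersion(X, np.zeros(n, dtype=int), 1))
            else:
                a, _, _ = clara(X, k, n_subsamples=n_subsamples,
                                seed=int(rng.integers(2**31)))
                log_w[i] = np.log(_within_dispersion(X, a, k))

        lo, hi = X.min(axis=0), X.max(axis=0)
        ref_log_w = np.empty((gap_B, len(ks)))
        for b in range(gap_B):
            R = rng.uniform(lo, hi, size=X.shape)
            for i, k in enumerate(ks):
                if k == 1:
                    ref_log_w[b, i] = np.log(
                        _within_dispersion(R, np.zeros(n, dtype=int), 1))
                else:
                    a, _, _ = clara(R, k, n_subsamples=n_subsamples,
                                    seed=int(rng.integers(2**31)))
                    ref_log_w[b, i] = np.log(_within_dispersion(R, a, k))

        gap = ref_log_w.mean(axis=0) - log_w
        se = ref_log_w.std(axis=0, ddof=0) * np.sqrt(1 + 1 / gap_B)
        k_opt = _first_se_max(gap, se, ks)
        gap_curve = pd.DataFrame({"k": ks, "gap": gap, "se": se, "log_w": log_w})
    else:
        k_opt = forced_k
        gap_curve = pd.DataFrame(columns=["k", "gap", "se", "log_w"])

    if k_opt == 1:
        assign = np.ones(n, dtype=int)
        med = np.array([int(np.argmin(((X - X.mean(axis=0)) ** 2).sum(axis=1)))])
        order = np.array([0])
    else:
        raw, med, _ = clara(X, k_opt, n_subsamples=n_subsamples,
                            seed=int(np.random.default_rng(seed).integers(2**31) + 1))
        key = (np.asarray(volumes, dtype=float)[med] if volumes is not None
               else X[med, 0])
        order = np.argsort(key)                 # raw medoid index -> rank
        rank_of = np.empty(k_opt, dtype=int)
        rank_of[order] = np.arange(k_opt)
        assign = rank_of[raw] + 1
        med = med[order]
    return ClusterModel(k_opt, assign, med, gap_curve, order)


# ---------------------------------------------------------------------------
# principal-curve pseudotime
# ---------------------------------------------------------------------------

@dataclass
class PseudotimeAssignment:
    values: np.ndarray                 # centered and scaled pseudotime
    arc_length: np.ndarray             # raw arc-length positions
    curve: np.ndarray                  # fitted control points in PC space
    converged: bool = True


def _project_to_polyline(X: np.ndarray, P: np.ndarray):
    """Project points onto polyline P; return (arc length, squared distance).

    Points projecting beyond the curve ends are extrapolated along the
    terminal segments so their arc-length ordering is preserved instead of
    piling up at the endpoints.
    """
    seg = P[1:] - P[:-1]                       # (m-1, d)
    seg_len = np.linalg.norm(seg, axis=1)
    keep = seg_len > 1e-12
    starts, seg, seg_len = P[:-1][keep], seg[keep], seg_len[keep]
    cum = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(P, axis=0), axis=1))])
    cum = cum[:-1][keep]

    diff = X[:, None, :] - starts[None, :, :]            # (n, m, d)
    t_raw = (diff * seg[None]).sum(axis=2) / seg_len[None] ** 2
    t = np.clip(t_raw, 0, 1)
    proj = starts[None] + t[..., None] * seg[None]
    d2 = ((X[:, None, :] - proj) ** 2).sum(axis=2)
    best = d2.argmin(axis=1)
    rows = np.arange(len(X))
    t_best = t[rows, best]
    # extrapolate on the terminal segments
    m = len(seg_len)
    t_best = np.where((best == 0) & (t_raw[rows, best] < 0),
                      t_raw[rows, best], t_best)
    t_best = np.where((best == m - 1) & (t_raw[rows, best] > 1),
                      t_raw[rows, best], t_best)
    lam = cum[best] + t_best * seg_len[best]
    return lam, d2[rows, best]


def pseudotime(
    embedding: Embedding,
    model: ClusterModel,
    *,
    span: float = 0.2,
    max_iter: int = 30,
    tol: float = 1e-4,
    n_control: int = 100,
) -> PseudotimeAssignment:
    """Principal-curve pseudotime through the ordered cluster medoids.

    The curve is initialized on the polyline through the medoids in cluster
    order and refined by project -> smooth-against-arc-length -> reproject
    iterations (running-mean smoother with window = ``span`` of the sample,
    curve resampled to ``n_control`` control points).  Pseudotime is each
    object's arc-length position, centered and scaled to unit sd.
    """
    from scipy.ndimage import uniform_filter1d

    X = embedding.scores
    P = X[model.medoids].astype(float)
    if len(P) < 2:  # single cluster: fall back to the PC1 axis
        lo, hi = X[:, 0].min(), X[:, 0].max()
        P = np.zeros((2, X.shape[1]))
        P[0, 0], P[1, 0] = lo, hi

    lam, d2 = _project_to_polyline(X, P)
    prev = d2.sum()
    converged = False
    window = max(3, int(span * len(X)))
    for _ in range(max_iter):
        order = np.argsort(lam, kind="stable")
        smoothed = np.column_stack(
            [uniform_filter1d(X[order, j], size=window, mode="nearest")
             for j in range(X.shape[1])]
        )
        # resample to control points along the ordered sequence
        take = np.linspace(0, len(X) - 1, min(n_control, len(X))).astype(int)
        P = smoothed[take]
        lam, d2 = _project_to_polyline(X, P)
        cur = d2.sum()
        if prev > 0 and abs(prev - cur) / prev < tol:
            converged = True
            break
        prev = cur
    if not converged:
        warnings.warn("principal curve did not converge; returning last iterate")

    sd = lam.std(ddof=0)
    values = (lam - lam.mean()) / (sd if sd > 0 else 1.0)
    return PseudotimeAssignment(values, lam, P, converged)


# ---------------------------------------------------------------------------
# composition tables
# ---------------------------------------------------------------------------

def composition_table(cluster_ids: np.ndarray, group_labels,
                      k: int | None = None) -> pd.DataFrame:
    """k x groups contingency table of cluster membership counts.

    Empty clusters are retained as zero rows so group columns always span
    clusters 1..k.
    """
    ids = np.asarray(cluster_ids)
    groups = pd.Series(group_labels)
    if len(ids) != len(groups):
        raise ValueError("cluster ids and group labels differ in length")
    if groups.isna().any():
        raise ValueError("unknown (missing) group label")
    k = k or int(ids.max())
    tab = pd.crosstab(pd.Series(ids, name="cluster"), groups)
    tab = tab.reindex(range(1, k + 1), fill_value=0)
    tab.columns.name = "group"
    return tab
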