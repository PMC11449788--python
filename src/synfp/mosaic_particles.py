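"""Per-synapse 2D analysis of subsynaptic particles.

En-face STED stacks are background-subtracted (rolling ball), maximum-
intensity projected, and cleared outside the synapse ROI.  Channels are
rigidly aligned by exhaustive correlation search.  Particles are detected by
a FindFoci-style procedure (smoothing, local maxima, descending-intensity
region growing, saddle-based merging) and summarized per synapse: basic
properties (size, intensity, density), Manders colocalization coefficients,
nearest-neighbor-distance profiles, Ripley's K with a summed CSR-deviation
scalar, and center-of-mass distances between overlapping particle pairs of
co-stained channels.  All length-derived quantities are divided by the
per-animal expansion correction factor (areas by its square, densities
multiplied by its square).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import Polygon
from skimage.restoration import rolling_ball
from skimage.segmentation import watershed

from .containers import PointPattern, SynapseImage

__all__ = [
    "SpatialSummary",
    "preprocess",
    "align_channels",
    "detect_particles",
    "particle_summary",
    "manders",
    "nnd_profile",
    "ripley_csr",
    "overlap_pair_distances",
    "center_scale",
]

RIPLEY_RMAX_PX = 20  # 20 px x 25 nm = 500 nm in expanded units


@dataclass
class SpatialSummary:
    """Spatial statistics of one synapse."""

    nnd_means: pd.DataFrame = field(default_factory=pd.DataFrame)
    k_radii_nm: np.ndarray = field(default_factory=lambda: np.empty(0))
    k_estimate: np.ndarray = field(default_factory=lambda: np.empty(0))
    csr_deviation: float = np.nan
    manders_m1: float = np.nan
    manders_m2: float = np.nan
    mean_pair_distance_nm: float = np.nan


# ---------------------------------------------------------------------------
# preprocessing and alignment
# ---------------------------------------------------------------------------

def preprocess(
    stack1: np.ndarray,
    stack2: np.ndarray,
    roi_mask: np.ndarray,
    *,
    ball_radius_px: int = 10,
    pixel_size_nm: float = 25.0,
    synapse_id: str = "",
    **meta,
) -> SynapseImage:
    """Rolling-ball background subtraction per slice, MIP, clear outside ROI."""
    roi = np.asarray(roi_mask, dtype=bool)
    mips = []
    for stack in (stack1, stack2):
        arr = np.atleast_3d(np.asarray(stack, dtype=float))
        if arr.ndim == 2:
            arr = arr[None]
        if roi.shape != arr.shape[-2:]:
            raise ValueError("ROI mask does not match image shape")
        sub = np.stack([sl - rolling_ball(sl, radius=ball_radius_px) for sl in arr])
        mip = sub.max(axis=0)
        mip[~roi] = 0.0
        mips.append(mip)
    return SynapseImage(mips[0], mips[1], roi, pixel_size_nm, synapse_id, meta)


def align_channels(
    ch1: np.ndarray,
    ch2: np.ndarray,
    roi_mask: np.ndarray,
    *,
    max_shift_px: int = 10,
    max_angle_deg: int = 10,
    angle_step_deg: int = 1,
) -> tuple[dict, np.ndarray]:
    """Rigidly align channel 2 to channel 1 by maximum Pearson correlation.

    Exhaustive search over integer translations (±max_shift) and rotations
    (±max_angle, 1° steps, about the image center).  The identity transform
    is part of the search space, so the post-alignment correlation is never
    below the pre-alignment one.  A flat channel (zero variance in the ROI)
    returns the identity with a warning.
    """
    roi = np.asarray(roi_mask, dtype=bool)
    a = np.asarray(ch1, dtype=float)
    b = np.asarray(ch2, dtype=float)

    def corr(u, v):
        x, y = u[roi], v[roi]
        if x.std() == 0 or y.std() == 0:
            return np.nan
        return float(np.corrcoef(x, y)[0, 1])

    before = corr(a, b)
    if not np.isfinite(before):
        warnings.warn("flat channel in ROI; returning identity transform")
        return {"dx": 0, "dy": 0, "angle_deg": 0.0,
                "corr_before": np.nan, "corr_after": np.nan}, b.copy()

    best = (before, 0, 0, 0.0, b)
    for ang in range(-max_angle_deg, max_angle_deg + 1, angle_step_deg):
        rot = b if ang == 0 else ndimage.rotate(b, ang, reshape=False, order=1)
        for dy in range(-max_shift_px, max_shift_px + 1):
            for dx in range(-max_shift_px, max_shift_px + 1):
                shifted = np.roll(np.roll(rot, dy, axis=0), dx, axis=1)
                c = corr(a, shifted)
                if np.isfinite(c) and c > best[0]:
                    best = (c, dx, dy, float(ang), shifted)
    after, dx, dy, ang, out = best
    return {"dx": dx, "dy": dy, "angle_deg": ang,
            "corr_before": before, "corr_after": after}, out.copy()


# ---------------------------------------------------------------------------
# particle detection (FindFoci-style)
# ---------------------------------------------------------------------------

def detect_particles(
    image: np.ndarray,
    mask: np.ndarray,
    *,
    pixel_size_nm: float = 25.0,
    smooth_sd_px: float = 1.0,
    merge_fraction: float = 0.2,
    min_size_px: int = 4,
    window: Polygon | None = None,
    synapse_id: str = "",
    channel: int = 1,
) -> PointPattern:
    """Detect particles inside ``mask`` and return them as a point pattern.

    Pipeline: Gaussian presmooth; local maxima within the mask seed a
    descending-intensity region growing (watershed on the inverted smooth
    image) assigning every mask pixel to a peak; adjacent regions are merged
    while a peak's height above its highest saddle is below
    ``merge_fraction`` of the peak height, or while a region is smaller than
    ``min_size_px``.  Marks: area (nm^2), total and average intensity from
    the raw image.
    """
    msk = np.asarray(mask).astype(bool)
    img = np.asarray(image, dtype=float)
    if not msk.any():
        return PointPattern(np.empty((0, 2)), window or Polygon(),
                            channel=channel, synapse_id=synapse_id)

    smooth = ndimage.gaussian_filter(img, smooth_sd_px)
    from skimage.feature import peak_local_max

    peaks = peak_local_max(smooth, labels=msk.astype(int), min_distance=1,
                           exclude_border=False)
    if len(peaks) == 0:
        return PointPattern(np.empty((0, 2)), window or Polygon(),
                            channel=channel, synapse_id=synapse_id)
    markers = np.zeros_like(msk, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-smooth, markers=markers, mask=msk)

    labels = _merge_regions(labels, smooth, merge_fraction, min_size_px)

    rows, coords = [], []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        yy, xx = np.nonzero(labels == lab)
        inten = img[yy, xx]
        total = float(inten.sum())
        if total > 0:
            cx = float(((xx + 0.5) * inten).sum() / total) * pixel_size_nm
            cy = float(((yy + 0.5) * inten).sum() / total) * pixel_size_nm
        else:
            cx = float((xx + 0.5).mean()) * pixel_size_nm
            cy = float((yy + 0.5).mean()) * pixel_size_nm
        coords.append((cx, cy))
        rows.append(
            {"area_nm2": yy.size * pixel_size_nm**2, "total_intensity": total,
             "avg_intensity": total / yy.size}
        )
    return PointPattern(np.array(coords), window or Polygon(),
                        marks=pd.DataFrame(rows), channel=channel,
                        synapse_id=synapse_id)


def _merge_regions(labels: np.ndarray, smooth: np.ndarray,
                   merge_fraction: float, min_size_px: int) -> np.ndarray:
    """Merge watershed regions by the saddle rule until stable."""
    labels = labels.copy()
    while True:
        labs = [l for l in np.unique(labels) if l != 0]
        if len(labs) <= 1:
            break
        peak = {l: smooth[labels == l].max() for l in labs}
        size = {l: int((labels == l).sum()) for l in labs}
        # saddle height between adjacent regions: max over boundary pixel
        # pairs of the lower of the two smoothed intensities
        saddles: dict[tuple[int, int], float] = {}
        for axis in (0, 1):
            a = labels.take(range(labels.shape[axis] - 1), axis=axis)
            b = labels.take(range(1, labels.shape[axis]), axis=axis)
            va = smooth.take(range(labels.shape[axis] - 1), axis=axis)
            vb = smooth.take(range(1, labels.shape[axis]), axis=axis)
            sel = (a != b) & (a > 0) & (b > 0)
            for la, lb, s in zip(a[sel].ravel(), b[sel].ravel(),
                                 np.minimum(va[sel], vb[sel]).ravel()):
                key = (min(la, lb), max(la, lb))
                if s > saddles.get(key, -np.inf):
                    saddles[key] = s

        merged = False
        # candidate merges: (priority, small label, absorb-into label)
        candidates = []
        for (la, lb), s in saddles.items():
            for small, other in ((la, lb), (lb, la)) :
                if peak[small] > peak[other]:
                    continue
                if (peak[small] - s) < merge_fraction * peak[small] or \
                        size[small] < min_size_px:
                    candidates.append((s, small, other))
        # also: undersized regions with no saddle partner stay (isolated)
        if candidates:
            candidates.sort(reverse=True)
            _, small, other = candidates[0]
            labels[labels == small] = other
            merged = True
        if not merged:
            break
    return labels


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def particle_summary(
    pattern: PointPattern,
    mask: np.ndarray,
    *,
    pixel_size_nm: float = 25.0,
    correction_factor: float = 1.0,
) -> dict:
    """Per-synapse basic properties, expansion-normalized.

    Areas are divided by the squared correction factor, the density
    (particles per nm^2 of mask area) is multiplied by it squared, and
    intensities are left unchanged.  Centering/scaling across the analysis
    set is applied later via :func:`center_scale`.
    """
    msk = np.asarray(mask).astype(bool)
    area_px = int(msk.sum())
    if area_px == 0:
        raise ValueError("mask area is zero")
    f = correction_factor
    area_nm2 = area_px * pixel_size_nm**2
    out = {
        "n_particles": pattern.n,
        "density_per_nm2": pattern.n / area_nm2 * f**2,
        "synapse_id": pattern.synapse_id,
        "flagged_empty": pattern.n == 0,
    }
    if pattern.n:
        out["mean_area_nm2"] = float(pattern.marks["area_nm2"].mean()) / f**2
        out["mean_total_intensity"] = float(pattern.marks["total_intensity"].mean())
        out["mean_avg_intensity"] = float(pattern.marks["avg_intensity"].mean())
    else:
        out.update(mean_area_nm2=np.nan, mean_total_intensity=np.nan,
                   mean_avg_intensity=np.nan)
    return out


def center_scale(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Center and scale the given columns across the analysis set."""
    out = df.copy()
    for c in columns:
        v = out[c].to_numpy(dtype=float)
        sd = np.nanstd(v, ddof=0)
        out[c] = (v - np.nanmean(v)) / (sd if sd > 0 else 1.0)
    return out


def manders(ch1: np.ndarray, ch2: np.ndarray, mask1: np.ndarray,
            mask2: np.ndarray) -> tuple[float, float]:
    """Manders colocalization coefficients on particle-support masks.

    ``M1`` is the fraction of channel-1 intensity within its own mask that
    falls inside channel 2's mask; ``M2`` symmetrically.  Both lie in
    [0, 1].  A zero denominator yields NaN (flagged undefined).
    """
    m1 = np.asarray(mask1).astype(bool)
    m2 = np.asarray(mask2).astype(bool)
    c1 = np.asarray(ch1, dtype=float)
    c2 = np.asarray(ch2, dtype=float)
    den1 = c1[m1].sum()
    den2 = c2[m2].sum()
    M1 = c1[m1 & m2].sum() / den1 if den1 > 0 else np.nan
    M2 = c2[m1 & m2].sum() / den2 if den2 > 0 else np.nan
    return float(M1), float(M2)


def nnd_profile(pattern: PointPattern, K: int = 20,
                correction_factor: float = 1.0) -> pd.DataFrame:
    """Mean distance to the k nearest neighbors, k = 1..K, per synapse.

    If the pattern has n <= K points the profile is computed to k = n - 1
    and flagged (``truncated=True``).  Distances are divided by the
    expansion correction factor.  Means are non-decreasing in k.
    """
    from scipy.spatial import cKDTree

    n = pattern.n
    if n < 2:
        raise ValueError("need at least 2 points for nearest neighbors")
    kmax = min(K, n - 1)
    tree = cKDTree(pattern.coords)
    d, _ = tree.query(pattern.coords, k=kmax + 1)
    means = d[:, 1:].mean(axis=0) / correction_factor
    return pd.DataFrame(
        {"k": np.arange(1, kmax + 1), "mean_nnd_nm": means,
         "truncated": n <= K, "synapse_id": pattern.synapse_id}
    )


def _isotropic_weights(coords: np.ndarray, pairs_i: np.ndarray, d: np.ndarray,
                       window: Polygon, n_angles: int) -> np.ndarray:
    """1 / (fraction of the circle of radius d around point i inside window).

    Circles entirely inside the window (radius below the point's distance to
    the boundary) get weight 1 without angular sampling.
    """
    w = np.ones_like(d)
    # distance of each unique point to the window boundary
    uniq = np.unique(pairs_i)
    bdist = np.full(coords.shape[0], np.inf)
    boundary = window.exterior
    for i in uniq:
        bdist[i] = boundary.distance(shapely.points(coords[i]))
    need = d > bdist[pairs_i] - 1e-9
    if not need.any():
        return w
    pi, dn = pairs_i[need], d[need]
    theta = (np.arange(n_angles) + 0.5) * (2 * np.pi / n_angles)
    cx = coords[pi, 0][:, None] + dn[:, None] * np.cos(theta)[None]
    cy = coords[pi, 1][:, None] + dn[:, None] * np.sin(theta)[None]
    shapely.prepare(window)
    inside = shapely.contains_xy(window, cx.ravel(), cy.ravel())
    frac = inside.reshape(cx.shape).mean(axis=1)
    w[need] = 1.0 / np.maximum(frac, 1.0 / n_angles)
    return w


def ripley_csr(
    pattern: PointPattern,
    *,
    r_max_px: int = RIPLEY_RMAX_PX,
    step_px: float = 1.0,
    pixel_size_nm: float = 25.0,
    correction: str = "isotropic",
    n_angles: int = 180,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Ripley's K on the ROI window and the summed CSR-deviation scalar.

    ``K(r) = |W| / (n (n-1)) * sum_{i != j} w_ij 1(d_ij <= r)`` with the
    isotropic edge-correction weight ``w_ij`` equal to the reciprocal
    fraction of the circle of radius ``d_ij`` around point i lying inside
    the window (computed by angular sampling); ``correction='none'`` sets
    all weights to 1.  The deviation scalar subtracts the CSR expectation
    ``pi r^2`` at each radius, sums, and divides by the number of radii:
    positive for clustered, negative for inhibited patterns.

    Returns ``(radii_nm, K_estimate, deviation)``.
    """
    n = pattern.n
    if n < 2:
        raise ValueError("need at least 2 points for Ripley's K")
    W = pattern.window
    area = W.area
    if area <= 0:
        raise ValueError("window area must be positive")
    radii = np.arange(step_px, r_max_px + step_px / 2, step_px) * pixel_size_nm

    diff = pattern.coords[:, None, :] - pattern.coords[None, :, :]
    dmat = np.sqrt((diff**2).sum(axis=2))
    ii, jj = np.nonzero((dmat <= radii[-1]) & ~np.eye(n, dtype=bool))
    d = dmat[ii, jj]
    if correction == "isotropic":
        w = _isotropic_weights(pattern.coords, ii, d, W, n_angles)
    elif correction == "none":
        w = np.ones_like(d)
    else:
        raise ValueError(f"unknown edge correction {correction!r}")

    K = np.array([w[d <= r].sum() for r in radii]) * area / (n * (n - 1))
    deviation = float(np.sum(K - np.pi * radii**2) / len(radii))
    return radii, K, deviation


def overlap_pair_distances(
    mask1: np.ndarray,
    mask2: np.ndarray,
    *,
    pixel_size_nm: float = 25.0,
    correction_factor: float = 1.0,
) -> tuple[pd.DataFrame, float]:
    """Center-of-mass distances between overlapping particle pairs.

    Masks are labeled particle supports (boolean masks are labeled with
    8-connectivity first).  Every region in mask 1 overlapping a region in
    mask 2 by at least one pixel forms a pair; a region overlapping several
    partners contributes one pair per partner.  Distances are divided by
    the expansion correction factor.  Returns the pair table and the mean
    distance (NaN, flagged, when no pair overlaps).
    """
    def as_labels(m):
        m = np.asarray(m)
        if m.dtype == bool or set(np.unique(m)) <= {0, 1}:
            lab, _ = ndimage.label(m.astype(bool), structure=np.ones((3, 3)))
            return lab
        return m.astype(int)

    l1, l2 = as_labels(mask1), as_labels(mask2)
    com1 = {lab: c for lab, c in zip(
        np.unique(l1)[1:], ndimage.center_of_mass(l1 > 0, l1, np.unique(l1)[1:]))}
    com2 = {lab: c for lab, c in zip(
        np.unique(l2)[1:], ndimage.center_of_mass(l2 > 0, l2, np.unique(l2)[1:]))}

    both = (l1 > 0) & (l2 > 0)
    pairs = {(a, b) for a, b in zip(l1[both].ravel(), l2[both].ravel())}
    rows = []
    for a, b in sorted(pairs):
        (y1, x1), (y2, x2) = com1[a], com2[b]
        dist = np.hypot(x1 - x2, y1 - y2) * pixel_size_nm / correction_factor
        rows.append({"label1": int(a), "label2": int(b), "distance_nm": float(dist)})
    table = pd.DataFrame(rows)
    mean = float(table["distance_nm"].mean()) if len(rows) else np.nan
    return table, mean
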