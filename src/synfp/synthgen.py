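"""Seeded synthetic data emulating the three imaging-data kinds.

Every downstream stage of the pipeline is exercised against data with known
ground truth:

* **line profiles** across side-view synapses — two Gaussian peaks (AZ and
  PSD) on a baseline, plus additive Gaussian noise;
* **3D probability maps** of postsynaptic scaffolds at 43 x 43 x 120 nm
  voxels — objects drawn from a morphology continuum running from small
  spheres over ellipsoids and lobed shapes to large perforated scaffolds,
  built by constructive solid geometry (unions of ellipsoids minus holes)
  in physical nm coordinates and then sampled on the anisotropic grid;
* **two-channel en-face STED mosaics** at 25 nm pixels — point patterns
  (CSR, Thomas-clustered, or hard-core) rendered as Gaussian spots with
  Poisson/Gaussian noise inside an elliptical ROI, with channel 2 either
  independent of or paired to channel 1 at a fixed nm offset.

All generators are deterministic given the :class:`SimConfig` (including
its seed), and every generated object/point/profile appears exactly once in
the returned :class:`GroundTruth` tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .containers import PointPattern, SynapseImage, VoxelVolume
from .expansion_qc import ProfileTrace

__all__ = [
    "SimConfig",
    "GroundTruth",
    "InvalidConfigError",
    "PlacementError",
    "MosaicSample",
    "gen_profiles",
    "gen_scaffolds",
    "gen_mosaics",
    "TEMPLATE_CLASSES",
]


class InvalidConfigError(ValueError):
    """Configuration violates a generator precondition."""


class PlacementError(RuntimeError):
    """Objects could not be placed without overlap within bounded retries."""


@dataclass(frozen=True)
class SimConfig:
    """All generator knobs.  Lengths in nm; identical config => identical output."""

    seed: int = 0
    voxel_size_nm: tuple[float, float, float] = (43.0, 43.0, 120.0)  # (x, y, z)
    sted_pixel_size_nm: float = 25.0

    # --- line profiles -----------------------------------------------------
    n_profiles: int = 60
    peak_separation_nm: float = 536.7
    peak_sd_nm: float = 30.0
    peak_amplitude: float = 100.0
    baseline: float = 10.0
    profile_noise_sd_frac: float = 0.02   # Gaussian sd as fraction of amplitude
    profile_step_nm: float = 10.0
    profile_margin_nm: float = 150.0

    # --- 3D scaffolds ------------------------------------------------------
    n_objects: int = 300
    volume_shape: tuple[int, int, int] = (64, 320, 320)  # (z, y, x) voxels
    n_template_classes: int = 6
    border_fraction: float = 0.0
    placement_retries: int = 500
    background_prob: float = 0.05
    background_prob_sd: float = 0.03
    object_prob: float = 0.92
    object_prob_sd: float = 0.04

    # --- 2D mosaics ----------------------------------------------------------
    n_synapses: int = 16
    n_points: int = 40
    image_shape: tuple[int, int] = (64, 64)
    n_slices: int = 6
    roi_semiaxes_px: tuple[float, float] = (26.0, 20.0)
    spot_sd_px: float = 2.0
    spot_amplitude: float = 120.0
    poisson_gain: float = 1.0          # 0 disables Poisson noise
    gauss_noise_sd: float = 0.0
    point_process: str = "CSR"         # CSR | thomas | hardcore
    thomas_parents: int = 5
    thomas_sd_nm: float = 60.0
    hardcore_radius_nm: float = 100.0
    coupling: str = "independent"      # independent | paired
    pairing_offset_nm: float = 50.0
    pairing_fraction: float = 1.0
    support_radius_px: int = 2

    def __post_init__(self):
        for name in ("voxel_size_nm", "sted_pixel_size_nm", "peak_sd_nm",
                     "profile_step_nm"):
            val = getattr(self, name)
            vals = val if isinstance(val, tuple) else (val,)
            if any(v <= 0 for v in vals):
                raise InvalidConfigError(f"{name} must be strictly positive")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """One truth record per generated profile/object/point, plus pairings."""

    profiles: pd.DataFrame = field(default_factory=pd.DataFrame)
    objects: pd.DataFrame = field(default_factory=pd.DataFrame)
    points: pd.DataFrame = field(default_factory=pd.DataFrame)
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)


# ===========================================================================
# line profiles
# ===========================================================================

def gen_profiles(
    config: SimConfig,
    *,
    animals: dict[str, str] | None = None,
    separations: dict[str, float] | None = None,
) -> tuple[list[ProfileTrace], GroundTruth]:
    """Two-Gaussian AZ-PSD profiles with additive noise.

    ``animals`` maps animal id -> batch id (default: one animal ``A1`` in
    batch ``B1``); ``separations`` optionally overrides the true peak
    separation per animal.  ``config.n_profiles`` traces are drawn per
    animal.  Requires separation > 4 x peak sd so both peaks are resolvable.
    """
    if config.peak_separation_nm <= 0:
        raise InvalidConfigError("peak separation must be positive")
    animals = animals or {"A1": "B1"}
    separations = separations or {}
    rng = np.random.default_rng(config.seed)

    traces: list[ProfileTrace] = []
    rows = []
    for animal, batch in animals.items():
        sep = float(separations.get(animal, config.peak_separation_nm))
        if sep <= 0:
            raise InvalidConfigError("peak separation must be positive")
        if sep <= 4 * config.peak_sd_nm:
            raise InvalidConfigError("separation must exceed 4x peak sd")
        length = sep + 2 * config.profile_margin_nm
        x = np.arange(0.0, length + config.profile_step_nm / 2, config.profile_step_nm)
        for i in range(config.n_profiles):
            p1 = config.profile_margin_nm
            p2 = p1 + sep
            y = (
                config.baseline
                + config.peak_amplitude * np.exp(-0.5 * ((x - p1) / config.peak_sd_nm) ** 2)
                + config.peak_amplitude * np.exp(-0.5 * ((x - p2) / config.peak_sd_nm) ** 2)
            )
            if config.profile_noise_sd_frac > 0:
                y = y + rng.normal(
                    0, config.profile_noise_sd_frac * config.peak_amplitude, x.size
                )
            tid = f"{animal}-prof{i:03d}"
            traces.append(ProfileTrace(x, y, synapse_id=tid, animal=animal, batch=batch))
            rows.append(
                {"profile_id": tid, "animal": animal, "batch": batch,
                 "true_separation_nm": sep, "peak1_nm": p1, "peak2_nm": p2}
            )
    return traces, GroundTruth(profiles=pd.DataFrame(rows))


# ===========================================================================
# 3D scaffold probability maps
# ===========================================================================

# Morphology continuum: template class -> (kind, size range in nm).  Classes
# run from small spheres (straddling the 200-voxel exclusion threshold) to
# large perforated scaffolds, mirroring the observed small-spherical ->
# voluminous-complex continuum of postsynaptic shapes.
TEMPLATE_CLASSES = (
    ("sphere_small", (160.0, 230.0)),
    ("sphere_large", (270.0, 340.0)),
    ("ellipsoid", (300.0, 380.0)),
    ("lobed2", (330.0, 420.0)),
    ("lobed3", (360.0, 460.0)),
    ("perforated", (420.0, 540.0)),
)


def _template_geometry(kind: str, r: float, rng: np.random.Generator):
    """Return (list of (center, semiaxes) ellipsoids, list of hole ellipsoids,
    bounding radius).  Centers are offsets from the object center in nm."""
    zero = np.zeros(3)
    if kind == "sphere_small" or kind == "sphere_large":
        return [(zero, np.array([r, r, r]))], [], r
    if kind == "ellipsoid":
        ax = np.array([1.6 * r, r, 0.8 * r])
        return [(zero, ax)], [], 1.6 * r
    if kind == "lobed2":
        off = np.array([0.9 * r, 0, 0])
        ax = np.array([r, 0.9 * r, 0.8 * r])
        return [(-off, ax), (off, ax)], [], 1.9 * r
    if kind == "lobed3":
        ax = np.array([0.9 * r, 0.8 * r, 0.7 * r])
        offs = [np.array([-1.1 * r, -0.4 * r, 0]), np.array([0, 0.6 * r, 0]),
                np.array([1.1 * r, -0.4 * r, 0])]
        return [(o, ax) for o in offs], [], 2.1 * r
    if kind == "perforated":
        body = [(zero, np.array([1.5 * r, 1.3 * r, 0.7 * r]))]
        # central perforation -> torus-like scaffold
        holes = [(zero, np.array([0.45 * r, 0.45 * r, 1.2 * r]))]
        return body, holes, 1.5 * r
    raise InvalidConfigError(f"unknown template kind {kind!r}")


def _inside(points_nm: np.ndarray, parts, holes, center_nm: np.ndarray) -> np.ndarray:
    rel = points_nm - center_nm
    inside = np.zeros(rel.shape[0], dtype=bool)
    for off, ax in parts:
        q = (rel - off) / ax
        inside |= (q * q).sum(axis=1) <= 1.0
    for off, ax in holes:
        q = (rel - off) / ax
        inside &= (q * q).sum(axis=1) > 1.0
    return inside


def gen_scaffolds(config: SimConfig) -> tuple[VoxelVolume, GroundTruth]:
    """Probability map of non-overlapping scaffold objects plus ground truth.

    Geometry is generated in physical nm coordinates and sampled at the
    anisotropic voxel grid (centers at ``(index + 0.5) * voxel_size``).  A
    ``border_fraction`` of objects is deliberately centered near a volume
    face so it is clipped and must be flagged border-touching downstream.
    """
    nz, ny, nx = config.volume_shape
    sx, sy, sz = config.voxel_size_nm
    extent = np.array([nx * sx, ny * sy, nz * sz])  # (x, y, z) in nm
    rng = np.random.default_rng(config.seed + 1)

    kinds = TEMPLATE_CLASSES[: config.n_template_classes]
    labels = np.zeros(config.volume_shape, dtype=np.int32)
    # voxels adjacent (26-neighborhood) to any placed object: placing there
    # would merge objects during segmentation
    blocked = np.zeros(config.volume_shape, dtype=bool)
    rows = []
    vox = np.array([sx, sy, sz])

    def voxelize(parts, holes, center, bound):
        lo = np.maximum(np.floor((center - bound) / vox - 1), 0).astype(int)
        hi = np.minimum(np.ceil((center + bound) / vox + 1), [nx, ny, nz]).astype(int)
        gx, gy, gz = np.meshgrid(*(np.arange(lo[d], hi[d]) for d in range(3)),
                                 indexing="ij")
        pts = np.stack(
            [(gx.ravel() + 0.5) * sx, (gy.ravel() + 0.5) * sy, (gz.ravel() + 0.5) * sz],
            axis=1,
        )
        ins = _inside(pts, parts, holes, center)
        return gx.ravel()[ins], gy.ravel()[ins], gz.ravel()[ins]

    n_border = int(round(config.border_fraction * config.n_objects))
    for obj_i in range(config.n_objects):
        cls = obj_i % len(kinds)
        kind, (rlo, rhi) = kinds[cls]
        r = rng.uniform(rlo, rhi)
        parts, holes, bound = _template_geometry(kind, r, rng)

        placed = False
        for _ in range(config.placement_retries):
            if obj_i < n_border:
                # center within one bounding radius of a random face
                c = rng.uniform(bound, extent - bound)
                axis = rng.integers(3)
                c[axis] = rng.uniform(-0.3 * bound, 0.3 * bound)
                if rng.random() < 0.5:
                    c[axis] = extent[axis] - c[axis]
            else:
                c = rng.uniform(bound * 1.05, extent - bound * 1.05)
            xs, ys, zs = voxelize(parts, holes, c, bound)
            if xs.size == 0 or blocked[zs, ys, xs].any():
                continue
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place object {obj_i} after {config.placement_retries} tries"
            )
        center = c
        labels[zs, ys, xs] = obj_i + 1
        # block the object plus its 26-neighborhood shell
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    blocked[np.clip(zs + dz, 0, nz - 1),
                            np.clip(ys + dy, 0, ny - 1),
                            np.clip(xs + dx, 0, nx - 1)] = True

        count = int(xs.size)
        touches = bool(
            count and (
                (zs.min() == 0) or (zs.max() == nz - 1)
                or (ys.min() == 0) or (ys.max() == ny - 1)
                or (xs.min() == 0) or (xs.max() == nx - 1)
            )
        )
        if count:
            cx = float(((xs + 0.5) * sx).mean())
            cy = float(((ys + 0.5) * sy).mean())
            cz = float(((zs + 0.5) * sz).mean())
        else:
            cx = cy = cz = np.nan
        rows.append(
            {"label": obj_i + 1, "template_class": cls, "template_kind": kind,
             "size_nm": r, "voxel_count": count, "border": touches,
             "center_x_nm": center[0], "center_y_nm": center[1],
             "center_z_nm": center[2],
             "centroid_x_nm": cx, "centroid_y_nm": cy, "centroid_z_nm": cz}
        )

    prob = np.clip(
        rng.normal(config.background_prob, config.background_prob_sd,
                   config.volume_shape),
        0.0, 1.0,
    )
    objmask = labels > 0
    prob[objmask] = np.clip(
        rng.normal(config.object_prob, config.object_prob_sd, int(objmask.sum())),
        0.0, 1.0,
    )
    vol = VoxelVolume(prob, config.voxel_size_nm, volume_id=f"scaffolds-seed{config.seed}",
                      meta={"true_labels": labels})
    return vol, GroundTruth(objects=pd.DataFrame(rows))


# ===========================================================================
# 2D two-channel mosaics
# ===========================================================================

@dataclass
class MosaicSample:
    """One synthetic en-face synapse: image stacks, ROI, truth-support masks."""

    stack1: np.ndarray          # (slices, y, x)
    stack2: np.ndarray
    roi_mask: np.ndarray        # bool (y, x)
    mask1: np.ndarray           # labeled truth particle supports, channel 1
    mask2: np.ndarray
    synapse_id: str = ""


def _ellipse_mask(shape, center_px, semiaxes_px):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return ((xx + 0.5 - center_px[0]) / semiaxes_px[0]) ** 2 + (
        (yy + 0.5 - center_px[1]) / semiaxes_px[1]
    ) ** 2 <= 1.0


def _sample_points(config: SimConfig, rng, center_nm, semi_nm) -> np.ndarray:
    """Draw n_points inside the ROI ellipse under the configured process."""
    def in_roi(p):
        q = (p - center_nm) / semi_nm
        return (q * q).sum(axis=-1) <= 1.0

    def uniform(n):
        out = np.empty((0, 2))
        while out.shape[0] < n:
            cand = center_nm + rng.uniform(-1, 1, (4 * n, 2)) * semi_nm
            cand = cand[in_roi(cand)]
            out = np.vstack([out, cand])
        return out[:n]

    proc = config.point_process.lower()
    if proc == "csr":
        return uniform(config.n_points)
    if proc == "thomas":
        parents = uniform(config.thomas_parents)
        pts = []
        while len(pts) < config.n_points:
            par = parents[rng.integers(len(parents))]
            cand = par + rng.normal(0, config.thomas_sd_nm, 2)
            if in_roi(cand[None])[0]:
                pts.append(cand)
        return np.array(pts)
    if proc == "hardcore":
        pts: list[np.ndarray] = []
        tries = 0
        while len(pts) < config.n_points:
            tries += 1
            if tries > 2000 * config.n_points:
                raise PlacementError("hard-core pattern not placeable at this density")
            cand = uniform(1)[0]
            if all(np.linalg.norm(cand - q) >= config.hardcore_radius_nm for q in pts):
                pts.append(cand)
        return np.array(pts)
    raise InvalidConfigError(f"unknown point process {config.point_process!r}")


def _render_stack(config: SimConfig, rng, coords_nm) -> np.ndarray:
    ny, nx = config.image_shape
    px = config.sted_pixel_size_nm
    yy, xx = np.mgrid[:ny, :nx]
    cx = (xx + 0.5) * px
    cy = (yy + 0.5) * px
    sd_nm = config.spot_sd_px * px
    base = np.zeros((ny, nx))
    for x0, y0 in coords_nm:
        base += np.exp(-((cx - x0) ** 2 + (cy - y0) ** 2) / (2 * sd_nm**2))
    base *= config.spot_amplitude
    # axial weighting across slices peaking at the stack center
    s = np.arange(config.n_slices)
    w = np.exp(-0.5 * ((s - (config.n_slices - 1) / 2) / (config.n_slices / 4)) ** 2)
    stack = base[None] * w[:, None, None]
    if config.poisson_gain > 0:
        stack = rng.poisson(stack * config.poisson_gain) / config.poisson_gain
    if config.gauss_noise_sd > 0:
        stack = stack + rng.normal(0, config.gauss_noise_sd, stack.shape)
    return stack.astype(float)


def gen_mosaics(config: SimConfig) -> tuple[list[MosaicSample], GroundTruth]:
    """Per-synapse two-channel mosaics with truth coordinates and pairings.

    Channel-1 points follow ``config.point_process``; channel-2 points are
    independent CSR or, with ``coupling='paired'``, displaced from a
    ``pairing_fraction`` of channel-1 points by ``pairing_offset_nm`` in a
    uniformly random direction (re-drawn until inside the ROI).
    """
    if config.spot_amplitude <= 0:
        raise InvalidConfigError("spot amplitude must be positive")
    rng = np.random.default_rng(config.seed + 2)
    px = config.sted_pixel_size_nm
    ny, nx = config.image_shape

    samples: list[MosaicSample] = []
    point_rows, pair_rows = [], []
    for s_i in range(config.n_synapses):
        sid = f"syn{s_i:03d}"
        center_px = np.array([nx / 2, ny / 2])
        semi_px = np.array(config.roi_semiaxes_px)
        center_nm = center_px * px
        semi_nm = semi_px * px
        roi = _ellipse_mask((ny, nx), center_px, semi_px)

        c1 = _sample_points(config, rng, center_nm, semi_nm)
        if config.coupling == "paired":
            n_paired = int(round(config.pairing_fraction * len(c1)))
            order = rng.permutation(len(c1))[:n_paired]
            c2 = []
            for j, i1 in enumerate(order):
                for _ in range(200):
                    th = rng.uniform(0, 2 * np.pi)
                    cand = c1[i1] + config.pairing_offset_nm * np.array(
                        [np.cos(th), np.sin(th)]
                    )
                    q = (cand - center_nm) / semi_nm
                    if (q * q).sum() <= 1.0:
                        break
                c2.append(cand)
                pair_rows.append(
                    {"synapse_id": sid, "ch1_point": int(i1), "ch2_point": j,
                     "offset_nm": config.pairing_offset_nm}
                )
            c2 = np.array(c2) if c2 else np.empty((0, 2))
        elif config.coupling == "independent":
            csr_cfg = config.with_(point_process="CSR")
            c2 = _sample_points(csr_cfg, rng, center_nm, semi_nm)
        else:
            raise InvalidConfigError(f"unknown coupling {config.coupling!r}")

        stack1 = _render_stack(config, rng, c1)
        stack2 = _render_stack(config, rng, c2)

        masks = []
        for coords in (c1, c2):
            m = np.zeros((ny, nx), dtype=np.int32)
            yy, xx = np.mgrid[:ny, :nx]
            for lab, (x0, y0) in enumerate(coords, start=1):
                d2 = ((xx + 0.5) * px - x0) ** 2 + ((yy + 0.5) * px - y0) ** 2
                m[d2 <= (config.support_radius_px * px) ** 2] = lab
            masks.append(m)

        samples.append(MosaicSample(stack1, stack2, roi, masks[0], masks[1], sid))
        for ch, coords in ((1, c1), (2, c2)):
            for j, (x0, y0) in enumerate(coords):
                point_rows.append(
                    {"synapse_id": sid, "channel": ch, "point": j,
                     "x_nm": x0, "y_nm": y0}
                )

    gt = GroundTruth(points=pd.DataFrame(point_rows), pairs=pd.DataFrame(pair_rows))
    return samples, gt


def gen_feature_clusters(
    seed: int,
    n_objects: int = 3000,
    n_clusters: int = 6,
    separation_sd: float = 8.66,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Nine-feature vectors from well-separated multivariate-normal clusters.

    Emulates the clustered structure of the shape-feature space with known
    labels: cluster centroids lie in a 3-dimensional subspace of the
    9-feature space (features covary, as shape features do, so PC1-3
    capture the planted structure).  The six centroids form three pairs at
    distinct mutual scales — a multi-level hierarchy, like the observed
    small-spherical -> voluminous-complex shape continuum — with every
    pairwise centroid separation at least ``separation_sd`` within-cluster
    standard deviations (unit within-cluster SD).  Returns
    ``(records, true labels)``.
    """
    if n_clusters != 6:
        raise InvalidConfigError("the planted layout is defined for 6 clusters")
    rng = np.random.default_rng(seed)
    s = separation_sd / 8.66
    groups = s * np.array([[0, 0, 0], [26, 0, 0], [10, 20, 8]], float)
    half = [s * np.array(v) for v in ([4.33, 0, 0], [0, 5, 0], [0, 0, 6])]
    cent3 = np.vstack([np.vstack([groups[i] - half[i], groups[i] + half[i]])
                       for i in range(3)])
    Q, _ = np.linalg.qr(rng.standard_normal((9, 3)))  # embed into feature space
    centers = cent3 @ Q.T
    per = n_objects // n_clusters
    X = np.vstack([rng.normal(c, 1.0, (per, 9)) for c in centers])
    from .scaffold_shapes import FEATURE_COLUMNS

    labels = np.repeat(np.arange(n_clusters), per)
    return pd.DataFrame(X, columns=FEATURE_COLUMNS), labels


def roi_polygon(config: SimConfig) -> "Point":
    """ROI ellipse of a mosaic synapse as a shapely polygon (nm units)."""
    px = config.sted_pixel_size_nm
    ny, nx = config.image_shape
    cx, cy = nx / 2 * px, ny / 2 * px
    a, b = config.roi_semiaxes_px[0] * px, config.roi_semiaxes_px[1] * px
    circ = Point(0, 0).buffer(1.0, quad_segs=64)
    import shapely.affinity as aff

    return aff.translate(aff.scale(circ, a, b), cx, cy)
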