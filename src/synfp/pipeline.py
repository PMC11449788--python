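"""End-to-end orchestration: simulate -> QC -> shapes -> fingerprint ->
particles -> stats -> report.

A run is driven by a :class:`RunConfig`, executes the stages in dependency
order into a single run directory (immutable config snapshot, plain-text
log, CSV tables, markdown report), and is byte-identical on rerun with the
same config.  Every filter logs its accounting: objects in = border-excluded
+ volume-excluded + analyzed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import expansion_qc, fingerprint, mosaic_particles, scaffold_shapes, stat_engine
from .containers import VoxelVolume
from .synthgen import GroundTruth, MosaicSample, SimConfig, gen_mosaics, gen_profiles, gen_scaffolds

__all__ = ["RunConfig", "run", "read_stack", "write_stack", "write_table", "read_table"]


@dataclass
class RunConfig:
    """Parameters of one full synthetic run.

    Alpha levels follow the two analysis arms: 0.01 for the shape arm
    (large sample sizes), 0.05 for the particle arm.
    """

    seed: int = 1
    outdir: str = "runs/run"
    genotypes: tuple[str, ...] = ("WT", "KO")
    regions: tuple[str, ...] = ("STR", "SENS")
    animals_per_genotype: int = 2

    # expansion QC
    n_profiles_per_animal: int = 20
    peak_separation_nm: float = 536.7
    animal_separation_sd_nm: float = 8.0
    fit_degree: int = 8

    # shape arm
    n_objects_per_condition: int = 40
    volume_shape: tuple[int, int, int] = (40, 224, 224)
    probability_cutoff: float = 0.2
    min_voxels: int = 200
    k_range_max: int = 8
    gap_B: int = 20
    clara_subsamples: int = 30
    alpha_shape: float = 0.01
    manova_B: int = 199

    # particle arm
    n_synapses_per_condition: int = 8
    n_points: int = 40
    ball_radius_px: int = 10
    mosaic_cutoff: float = 0.5          # mask threshold as fraction of ROI max
    ripley_rmax_px: int = 20
    nnd_k: int = 10
    alpha_particles: float = 0.05

    def validate(self):
        if self.seed is None:
            raise ValueError("a seed is required for every stochastic stage")
        for name in ("probability_cutoff", "mosaic_cutoff"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    def config_hash(self) -> str:
        """Hash of the analysis parameters (the output path is excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("genotypes", "regions", "volume_shape"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_stack(path: str | Path, voxel_size_nm=(43.0, 43.0, 120.0)) -> VoxelVolume:
    """Read a multi-page grayscale TIFF as a VoxelVolume."""
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface the file name
        raise ValueError(f"malformed TIFF: {path}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected a grayscale stack in {path}, got shape {data.shape}")
    return VoxelVolume(data, voxel_size_nm, volume_id=str(path))


def write_stack(volume: VoxelVolume | np.ndarray, path: str | Path,
                scale_to_uint16: bool = False,
                value_range: tuple[float, float] | None = None) -> None:
    """Write a stack as multi-page TIFF (16-bit when requested).

    ``value_range`` fixes the intensity range mapped onto 0..65535 (use
    ``(0, 1)`` for probability maps so the scale is self-describing);
    by default the data min/max is used.
    """
    data = volume.data if isinstance(volume, VoxelVolume) else np.asarray(volume)
    if scale_to_uint16:
        lo, hi = value_range if value_range else (float(data.min()), float(data.max()))
        rng = hi - lo if hi > lo else 1.0
        data = np.clip((data - lo) / rng, 0, 1) * 65535
        data = data.astype(np.uint16)
    tifffile.imwrite(path, data)


def write_table(records: pd.DataFrame, path: str | Path, **meta) -> None:
    """CSV with provenance comment header (config hash, seed, stage)."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("# coordinates: 0-based voxel indices; "
                 "physical = (index + 0.5) * voxel size\n")
        pd.DataFrame(records).to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------

def run(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    meta = {"config_hash": config.config_hash(), "seed": config.seed, "stage": ""}

    def log(msg: str):
        log_lines.append(msg)

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)

    rng = np.random.default_rng(config.seed)
    animals = {}
    for g in config.genotypes:
        for i in range(config.animals_per_genotype):
            animals[f"{g}{i + 1}"] = {"genotype": g, "batch": "B1"}

    # --- stage 1: expansion QC --------------------------------------------
    seps = {a: config.peak_separation_nm + rng.normal(0, config.animal_separation_sd_nm)
            for a in animals}
    sim = SimConfig(seed=config.seed, n_profiles=config.n_profiles_per_animal)
    traces, gt_prof = gen_profiles(
        sim, animals={a: animals[a]["batch"] for a in animals}, separations=seps)
    rows = []
    failed = 0
    for t in traces:
        try:
            d = expansion_qc.measure_az_psd(t, config.fit_degree)
        except expansion_qc.MeasurementError:
            failed += 1
            continue
        rows.append({"profile_id": t.synapse_id, "animal": t.animal,
                     "batch": t.batch, "distance_nm": d})
    dist = pd.DataFrame(rows)
    summary = expansion_qc.summarize_expansion(dist)
    log(f"expansion_qc: {len(traces)} profiles in, {failed} failed, "
        f"{len(dist)} measured")
    write_table(dist, outdir / "az_psd_distances.csv", **{**meta, "stage": "expansion_qc"})
    write_table(summary.correction_factors.rename("correction_factor").reset_index(),
                outdir / "correction_factors.csv", **{**meta, "stage": "expansion_qc"})

    # --- stage 2: scaffold shapes -----------------------------------------
    records = []
    for g in config.genotypes:
        for r in config.regions:
            for i in range(config.animals_per_genotype):
                animal = f"{g}{i + 1}"
                sub_seed = int(rng.integers(2**31))
                scfg = SimConfig(seed=sub_seed, n_objects=config.n_objects_per_condition,
                                 volume_shape=config.volume_shape)
                vol, gt = gen_scaffolds(scfg)
                mask = scaffold_shapes.threshold_probability(vol, config.probability_cutoff)
                objs = scaffold_shapes.segment_objects(mask)
                cf = float(summary.correction_factors[animal])
                n_border = sum(o.border for o in objs)
                feats = [
                    scaffold_shapes.shape_features(
                        o, vol.voxel_size_nm, cf, animal=animal, genotype=g, region=r)
                    for o in objs if not o.border
                ]
                df = pd.DataFrame(feats)
                kept = scaffold_shapes.volume_filter(df, config.min_voxels)
                n_volume = len(df) - len(kept)
                log(f"shapes[{g},{r},{animal}]: objects_in={len(objs)} "
                    f"border_excluded={n_border} volume_excluded={n_volume} "
                    f"analyzed={len(kept)}")
                assert len(objs) == n_border + n_volume + len(kept)
                records.append(kept)
    shapes = pd.concat(records, ignore_index=True)
    write_table(shapes, outdir / "shape_records.csv", **{**meta, "stage": "shapes"})

    # --- stage 3: fingerprint ---------------------------------------------
    emb = fingerprint.embed(shapes)
    model = fingerprint.cluster(
        emb, range(1, config.k_range_max + 1), gap_B=config.gap_B,
        seed=config.seed, volumes=shapes["volume_nm3"].to_numpy(),
        n_subsamples=config.clara_subsamples)
    pt = fingerprint.pseudotime(emb, model)
    scores = pd.DataFrame(emb.scores, columns=["PC1", "PC2", "PC3"])
    scores["cluster"] = model.assignments
    scores["pseudotime"] = pt.values
    scores[["animal", "genotype", "region"]] = shapes[["animal", "genotype", "region"]]
    write_table(scores, outdir / "fingerprint.csv", **{**meta, "stage": "fingerprint"})
    write_table(model.gap_curve, outdir / "gap_curve.csv", **{**meta, "stage": "fingerprint"})
    log(f"fingerprint: k={model.k} selected over k=1..{config.k_range_max}")

    # chi-square on cluster composition
    tab_geno = fingerprint.composition_table(model.assignments, shapes["genotype"],
                                             k=model.k)
    chi_geno = stat_engine.chisq_independence(tab_geno, alpha=config.alpha_shape)
    tab_reg = fingerprint.composition_table(model.assignments, shapes["region"],
                                            k=model.k)
    chi_reg = stat_engine.chisq_independence(tab_reg, pairwise_columns=True,
                                             alpha=config.alpha_shape)

    # MANOVA on raw features + pseudotime, moments 2-4 excluded
    mano_df = shapes[scaffold_shapes.FEATURE_COLUMNS].copy()
    mano_df["pseudotime"] = pt.values
    manova = stat_engine.mats_manova(
        mano_df, shapes["genotype"], B=config.manova_B, seed=config.seed,
        exclude=("M2", "M3", "M4"), alpha=config.alpha_shape)

    # --- stage 4: particles -------------------------------------------------
    part_rows, nnd_rows, dev_rows = [], [], []
    for g in config.genotypes:
        sub_seed = int(rng.integers(2**31))
        mcfg = SimConfig(seed=sub_seed, n_synapses=config.n_synapses_per_condition,
                         n_points=config.n_points, coupling="paired",
                         pairing_fraction=0.8)
        samples, gt = gen_mosaics(mcfg)
        from .synthgen import roi_polygon

        window = roi_polygon(mcfg)
        cf = float(np.mean([summary.correction_factors[f"{g}{i + 1}"]
                            for i in range(config.animals_per_genotype)]))
        for s in samples:
            sid = f"{g}-{s.synapse_id}"
            img = mosaic_particles.preprocess(
                s.stack1, s.stack2, s.roi_mask, ball_radius_px=config.ball_radius_px,
                pixel_size_nm=mcfg.sted_pixel_size_nm, synapse_id=sid)
            _, ch2_aligned = mosaic_particles.align_channels(
                img.ch1, img.ch2, img.roi_mask, max_shift_px=2, max_angle_deg=2)
            masks = []
            for ch in (img.ch1, ch2_aligned):
                level = config.mosaic_cutoff * (ch[img.roi_mask].max() or 1.0)
                masks.append((ch >= level) & img.roi_mask)
            pat = mosaic_particles.detect_particles(
                img.ch1, masks[0], pixel_size_nm=mcfg.sted_pixel_size_nm,
                window=window, synapse_id=sid)
            summ = mosaic_particles.particle_summary(
                pat, masks[0], pixel_size_nm=mcfg.sted_pixel_size_nm,
                correction_factor=cf)
            M1, M2 = mosaic_particles.manders(img.ch1, ch2_aligned, masks[0], masks[1])
            _, pair_mean = mosaic_particles.overlap_pair_distances(
                masks[0], masks[1], pixel_size_nm=mcfg.sted_pixel_size_nm,
                correction_factor=cf)
            summ.update(genotype=g, manders_m1=M1, manders_m2=M2,
                        mean_pair_distance_nm=pair_mean)
            part_rows.append(summ)
            if pat.n >= 2:
                nnd = mosaic_particles.nnd_profile(pat, config.nnd_k, cf)
                nnd["genotype"] = g
                nnd["synapse_id"] = sid
                nnd_rows.append(nnd)
                _, _, dev = mosaic_particles.ripley_csr(
                    pat, r_max_px=config.ripley_rmax_px,
                    pixel_size_nm=mcfg.sted_pixel_size_nm)
                dev_rows.append({"synapse_id": sid, "genotype": g, "csr_deviation": dev})
    particles = pd.DataFrame(part_rows)
    nnd_long = pd.concat(nnd_rows, ignore_index=True)
    devs = pd.DataFrame(dev_rows)
    log(f"particles: {len(particles)} synapses analyzed")
    write_table(particles, outdir / "particle_summaries.csv", **{**meta, "stage": "particles"})
    write_table(nnd_long, outdir / "nnd_profiles.csv", **{**meta, "stage": "particles"})
    write_table(devs, outdir / "csr_deviations.csv", **{**meta, "stage": "particles"})

    # --- stage 5: statistics ------------------------------------------------
    # balance the within-factor: use the largest k available to at least 80%
    # of synapses and drop the sparser synapses (logged)
    kmax_per_syn = nnd_long.groupby("synapse_id")["k"].max()
    kmax_common = max(2, int(np.quantile(kmax_per_syn, 0.2)))
    keep_syn = kmax_per_syn[kmax_per_syn >= kmax_common].index
    log(f"nnd: k=1..{kmax_common}; {len(kmax_per_syn) - len(keep_syn)} sparse "
        f"synapse(s) dropped from the RM-ANOVA")
    nnd_bal = nnd_long[nnd_long["synapse_id"].isin(keep_syn)
                       & (nnd_long["k"] <= kmax_common)]
    rm = stat_engine.rm_anova(
        nnd_bal, subject="synapse_id", within="k", between="genotype",
        value="mean_nnd_nm", alpha=config.alpha_particles)
    ws = stat_engine.rank_sum(
        devs.loc[devs.genotype == config.genotypes[0], "csr_deviation"],
        devs.loc[devs.genotype == config.genotypes[1], "csr_deviation"],
        alpha=config.alpha_particles)

    report = outdir / "report.md"
    with open(report, "w") as fh:
        fh.write("# Synthetic run report\n\n")
        fh.write(f"Config hash: {config.config_hash()}  |  seed: {config.seed}\n\n")
        fh.write("## Cluster composition (chi-square)\n\n")
        fh.write(f"- genotype: X-squared = {chi_geno.statistic:.4f}, "
                 f"df = {chi_geno.df}, p = {chi_geno.p_value:.4g}\n")
        fh.write(f"- region: X-squared = {chi_reg.statistic:.4f}, "
                 f"df = {chi_reg.df}, p = {chi_reg.p_value:.4g}\n\n")
        fh.write("## Shape MANOVA (MATS, parametric bootstrap)\n\n")
        fh.write(f"- MATS = {manova.statistic:.4f}, p = {manova.p_value:.4g} "
                 f"(B = {manova.bootstrap['B']}, alpha = {config.alpha_shape})\n\n")
        fh.write("## NND repeated-measures ANOVA\n\n")
        fh.write(f"- F = {rm.statistic:.4f}, df = {rm.df}, p = {rm.p_value:.4g}\n\n")
        fh.write("## CSR deviation rank-sum\n\n")
        fh.write(f"- W = {ws.statistic:.4f}, p = {ws.p_value:.4g}\n")

    with open(outdir / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return outdir
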