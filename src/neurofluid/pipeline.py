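"""End-to-end orchestration: synthetic dataset generation, per-subject
quantification into SubjectRecords, cohort assembly and the statistics plan.

The synthetic head phantom is schematic, not anatomical: nested ellipsoids
for intracranial space, grey and white matter; boxes for cerebellar GM (the
reference region), the global amyloid mask, and the choroid plexus; and a
parasagittal strip, carved voxel-exactly to each subject's target volume,
for the PSD with subregion compartments laid out along the
posterior-anterior axis. Tissue and intracranial volumes are controlled by
scaling the ellipsoid radii monotonically in the cohort-table targets, so
rank-based cohort statistics see the intended ordering even though absolute
phantom volumes are smaller than human ones. The aqueduct is a separate
single-slice phase-contrast phantom.

Per-subject failures (corrupt or missing files) are recorded and the run
continues; a modality that was never acquired yields missing fields, not a
failure, mirroring the per-analysis sample sizes of real cohorts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats as cstats
from .asl import ASLParams, quantify_cbf, roi_perfusion, surround_subtract, ASLSeries
from .core import DynamicImage, FrameSchedule, LabelAtlas, load_nifti, save_nifti
from .flow import PCSeries, net_flow, phase_to_velocity
from .pet import fit_srtm2_map, frame_average, suvr_global, trimmed_mean
from .pvc import gtm_region_tacs, rbv_pvc
from .synth.asl import simulate_asl
from .synth.cohort import CohortSpec, simulate_cohort
from .synth.flow import simulate_phase_contrast
from .synth.pet import KineticGroundTruth, simulate_dynamic_pet
from .volumetrics import LandmarkSet, partition_psd, region_volume, icv_adjust

logger = logging.getLogger("neurofluid")

__all__ = ["PipelineConfig", "simulate_dataset", "run_subject", "run_cohort", "run_all"]

# phantom label scheme
LBL_CEREB_GM = 1
LBL_GLOBAL = 2
LBL_CHP = 3
LBL_PSD = 4
LBL_GM = 5
LBL_WM = 6
LBL_CSF = 7

LABEL_NAMES = {
    LBL_CEREB_GM: "cerebellar_gm",
    LBL_GLOBAL: "global_amyloid_mask",
    LBL_CHP: "choroid_plexus",
    LBL_PSD: "psd",
    LBL_GM: "gm",
    LBL_WM: "wm",
    LBL_CSF: "csf_space",
}

GRID_SHAPE = (32, 64, 32)
VOXEL_MM = (2.0, 2.0, 2.0)

# PSD subregion carving zones: (name, x range, y range, z range); filling is
# slab-by-slab along y so volumes are voxel-exact
_PSD_ZONES = {
    "occipital": ((10, 22), (6, 18), (26, 32)),
    "parietal": ((10, 22), (18, 30), (26, 32)),
    "frontal": ((10, 22), (30, 51), (26, 32)),
    "prefrontal": ((10, 22), (52, 58), (20, 26)),
}

_LANDMARKS = LandmarkSet(
    pituitary=(16.0, 38.0, 8.0),
    cc_rostrum=(16.0, 44.0, 16.0),
    central_sulcus=(16.0, 30.0, 30.0),
    parieto_occipital=(16.0, 18.0, 28.0),
)


@dataclass
class PipelineConfig:
    """One config drives every subcommand; YAML-loadable."""

    data_dir: str = "scratch/cohort"
    out_dir: str = "results"
    n_subjects: int = 24
    seed: int = 20230
    # cohort marginals default to CohortSpec defaults
    target_spearman: float = 0.529
    # ASL
    asl: ASLParams = field(default_factory=lambda: ASLParams(slice_time_inc_ms=30.0))
    asl_n_pairs: int = 8
    asl_noise_sd: float = 0.15
    # PET
    pet_noise_scale: float = 1.0
    psf_fwhm_mm: float = 6.0
    trim_fraction: float = 0.10
    bp_threshold: float = 0.1
    suv_window_s: tuple = (3000.0, 4200.0)
    srtm_refine: bool = False  # parametric maps use the basis grid only
    # phase contrast
    venc_cm_s: float = 12.0
    pc_noise_sd_rad: float = 0.02
    # paper-style missing modalities (0-based subject indices)
    missing_asl: tuple = (7,)
    missing_flow: tuple = (3, 15)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        asl_kwargs = raw.pop("asl", None)
        cfg = cls(**raw)
        if asl_kwargs:
            cfg.asl = ASLParams(**asl_kwargs)
        cfg.missing_asl = tuple(cfg.missing_asl)
        cfg.missing_flow = tuple(cfg.missing_flow)
        cfg.suv_window_s = tuple(cfg.suv_window_s)
        return cfg


# ---------------------------------------------------------------------------
# phantom construction


def _ellipsoid(grid, label, center, radii):
    ix, iy, iz = np.ogrid[: grid.shape[0], : grid.shape[1], : grid.shape[2]]
    cx, cy, cz = center
    rx, ry, rz = radii
    m = ((ix - cx) / rx) ** 2 + ((iy - cy) / ry) ** 2 + ((iz - cz) / rz) ** 2 <= 1.0
    grid[m] = label


def _box(grid, label, center, radii):
    cx, cy, cz = center
    rx, ry, rz = radii
    grid[
        int(cx - rx) : int(cx + rx) + 1,
        int(cy - ry) : int(cy + ry) + 1,
        int(cz - rz) : int(cz + rz) + 1,
    ] = label


def _carve_psd(grid, psd_cm3: float, fractions) -> None:
    """Fill the PSD zones with voxel-exact counts at the target fractions."""
    vox_mm3 = float(np.prod(VOXEL_MM))
    n_total = int(round(psd_cm3 * 1000.0 / vox_mm3))
    f = np.asarray(fractions, dtype=float)
    counts = {
        "prefrontal": int(round(f[0] * n_total)),
        "frontal": int(round(f[1] * n_total)),
        "parietal": int(round(f[2] * n_total)),
    }
    counts["occipital"] = n_total - sum(counts.values())
    for name, ((x0, x1), (y0, y1), (z0, z1)) in _PSD_ZONES.items():
        need = counts[name]
        capacity = (x1 - x0) * (y1 - y0) * (z1 - z0)
        if need > capacity:
            raise ValueError(f"PSD zone {name} too small for {need} voxels")
        filled = 0
        for y in range(y0, y1):
            for z in range(z0, z1):
                for x in range(x0, x1):
                    if filled >= need:
                        break
                    grid[x, y, z] = LBL_PSD
                    filled += 1


def build_subject_atlas(row: pd.Series) -> LabelAtlas:
    """Schematic head atlas whose measurable volumes track the cohort row."""
    grid = np.zeros(GRID_SHAPE, dtype=np.int32)
    s_icv = (row["icv_cm3"] / 1450.0) ** (1.0 / 3.0)
    s_tis = (row["gm_wm_volume_cm3"] / 1050.0) ** (1.0 / 3.0)
    center = (16.0, 30.0, 13.0)
    _ellipsoid(grid, LBL_CSF, center, (12.0 * s_icv, 16.5 * s_icv, 11.0 * s_icv))
    _ellipsoid(grid, LBL_GM, center, (10.5 * s_tis, 14.5 * s_tis, 9.5 * s_tis))
    _ellipsoid(grid, LBL_WM, center, (8.0 * s_tis, 11.0 * s_tis, 7.0 * s_tis))
    _box(grid, LBL_CEREB_GM, (16, 12, 6), (4, 3, 2))
    _box(grid, LBL_GLOBAL, (16, 36, 16), (4, 4, 2))
    _box(grid, LBL_CHP, (16, 30, 12), (2, 2, 1))
    _carve_psd(grid, row["psd_total_cm3"], CohortSpec().subregion_fractions)
    return LabelAtlas(grid, VOXEL_MM, dict(LABEL_NAMES))


def _kinetic_truth(bp_nd: float, k2prime: float = 0.18) -> KineticGroundTruth:
    """Shared-k2' kinetics (k2 = R1 * k2'), the regime SRTM2 assumes."""

    def p(r1, bp):
        return (r1, r1 * k2prime, bp)

    return KineticGroundTruth(
        params={
            LBL_CEREB_GM: p(1.0, 0.0),
            LBL_GLOBAL: p(1.1, float(bp_nd)),
            LBL_CHP: p(0.9, 0.05),
            LBL_GM: p(1.0, 0.3 * float(bp_nd)),
            # white matter carries substantial non-specific amyloid-tracer
            # retention, so its BP_ND sits well above the k2' threshold
            LBL_WM: p(0.7, 0.3),
            LBL_CSF: p(0.2, 0.0),
            LBL_PSD: p(0.2, 0.0),
        },
        reference_label=LBL_CEREB_GM,
    )


# ---------------------------------------------------------------------------
# dataset generation


def simulate_dataset(config: PipelineConfig) -> pd.DataFrame:
    """Generate the full synthetic cohort dataset under config.data_dir.

    Returns the ground-truth cohort table (also written as TSV).
    """
    root = Path(config.data_dir)
    root.mkdir(parents=True, exist_ok=True)
    spec = CohortSpec(
        n_subjects=config.n_subjects,
        target_spearman=config.target_spearman,
        seed=config.seed,
    )
    cohort = simulate_cohort(spec)
    cohort.to_csv(root / "cohort_truth.tsv", sep="\t", index=False)
    cohort[["subject_id", "age_years", "sex"]].to_csv(
        root / "participants.tsv", sep="\t", index=False
    )

    schedule = FrameSchedule.pib_default()
    seeds = np.random.SeedSequence(config.seed).generate_state(4 * config.n_subjects)
    seeds = (seeds % (2**31)).astype(np.int64)

    for i, row in cohort.iterrows():
        t0 = time.time()
        sdir = root / row["subject_id"]
        sdir.mkdir(exist_ok=True)
        atlas = build_subject_atlas(row)
        atlas.save(sdir / "atlas.nii.gz")
        _LANDMARKS.to_json(sdir / "landmarks.json")

        # dynamic PET
        truth = _kinetic_truth(row["bp_nd"])
        dyn = simulate_dynamic_pet(
            atlas, truth, schedule,
            noise_scale=config.pet_noise_scale, seed=int(seeds[4 * i]),
            psf_fwhm_mm=config.psf_fwhm_mm,
        )
        save_nifti(dyn.data.astype(np.float32), VOXEL_MM, sdir / "pet_dynamic.nii.gz")
        schedule.to_json(sdir / "frame_schedule.json")

        # ASL
        if i not in config.missing_asl:
            cbf_truth = {
                LBL_CHP: row["chp_perfusion_ml_100g_min"],
                LBL_GM: 50.0,
                LBL_CEREB_GM: 50.0,
                LBL_GLOBAL: 50.0,
                LBL_WM: 20.0,
            }
            asl = simulate_asl(
                atlas, cbf_truth, config.asl,
                n_pairs=config.asl_n_pairs,
                noise_sd=config.asl_noise_sd,
                seed=int(seeds[4 * i + 1]),
            )
            save_nifti(asl.volumes.astype(np.float32), VOXEL_MM, sdir / "asl.nii.gz")
            save_nifti(asl.m0.astype(np.float32), VOXEL_MM, sdir / "m0.nii.gz")

        # phase contrast
        if i not in config.missing_flow:
            roi = np.zeros((16, 16, 1), dtype=bool)
            roi[6:9, 6:9, 0] = True
            area_cm2 = roi.sum() * 0.59 * 0.59 / 100.0
            k = np.arange(12)
            heart_rate = 60.0 + 2.0 * (i % 7)
            # mean-velocity amplitude 7 cm/s: for faster-flow subjects the
            # profile core exceeds the 12 cm/s VENC and wraps while the ROI
            # median stays unwrapped
            q = row["net_csf_flow_ml_min"] / 60.0 + (7.0 * area_cm2) * np.sin(
                2 * np.pi * k / 12
            )
            pc = simulate_phase_contrast(
                q, roi, config.venc_cm_s, (0.59, 0.59, 4.0), heart_rate,
                wrap=True, noise_sd_rad=config.pc_noise_sd_rad,
                seed=int(seeds[4 * i + 2]), profile="parabolic",
            )
            save_nifti(pc.phase.astype(np.float32), (0.59, 0.59, 4.0), sdir / "pc_phase.nii.gz")
            save_nifti(pc.magnitude.astype(np.float32), (0.59, 0.59, 4.0), sdir / "pc_mag.nii.gz")
            save_nifti(roi.astype(np.int16), (0.59, 0.59, 4.0), sdir / "pc_roi.nii.gz")
            (sdir / "pc_sidecar.json").write_text(
                json.dumps({"venc_cm_s": config.venc_cm_s, "heart_rate_bpm": heart_rate})
            )
        logger.info(
            "simulated %s in %.1f s", row["subject_id"], time.time() - t0
        )
    return cohort


# ---------------------------------------------------------------------------
# per-subject quantification


def _quantify_asl(sdir: Path, atlas: LabelAtlas, config: PipelineConfig):
    vols, vox = load_nifti(sdir / "asl.nii.gz")
    m0, _ = load_nifti(sdir / "m0.nii.gz")
    series = ASLSeries(vols, m0, config.asl, voxel_size_mm=vox)
    dm = surround_subtract(series)
    cbf = quantify_cbf(dm, m0, config.asl)
    return roi_perfusion(cbf, atlas, LBL_CHP)


def _quantify_flow(sdir: Path, config: PipelineConfig):
    phase, vox = load_nifti(sdir / "pc_phase.nii.gz")
    mag, _ = load_nifti(sdir / "pc_mag.nii.gz")
    roi, _ = load_nifti(sdir / "pc_roi.nii.gz")
    sidecar = json.loads((sdir / "pc_sidecar.json").read_text())
    pc = PCSeries(
        phase, mag, sidecar["venc_cm_s"], vox, sidecar["heart_rate_bpm"]
    )
    vel = phase_to_velocity(pc)
    res = net_flow(
        vel, roi > 0.5, vox, pc.heart_rate_bpm,
        apply_unalias=True, venc_cm_s=pc.venc_cm_s,
    )
    return res.net_flow_ml_min, res.n_unaliased


def _quantify_pet(sdir: Path, atlas: LabelAtlas, config: PipelineConfig):
    data, vox = load_nifti(sdir / "pet_dynamic.nii.gz")
    schedule = FrameSchedule.from_json(sdir / "frame_schedule.json")
    dyn = DynamicImage(data, schedule, vox)

    # static route: late-window SUV image -> RBV PVC -> SUVr
    static = frame_average(dyn, *config.suv_window_s)
    static_pvc = rbv_pvc(static, atlas, config.psf_fwhm_mm)
    suvr = suvr_global(
        static_pvc.image, atlas, LBL_GLOBAL, LBL_CEREB_GM, config.trim_fraction
    )

    # dynamic route: SRTM2 parametric BP over the brain mask -> RBV PVC
    # partial-volume-corrected reference TAC: the cerebellar region is small
    # enough that raw spill-out would deflate the reference and inflate every
    # downstream binding estimate
    labels, region_tacs = gtm_region_tacs(dyn.data, atlas, config.psf_fwhm_mm)
    ref_mask = atlas.mask(LBL_CEREB_GM)
    ref_tac = region_tacs[list(labels).index(LBL_CEREB_GM)]
    # brain mask for parametric fitting: reference + global ROI + a central
    # white-matter core (keeps the k2' median defined even at low cortical
    # binding while holding the voxel count down)
    wm_core = atlas.mask(LBL_WM)
    wm_core[:12, :, :] = wm_core[20:, :, :] = False
    wm_core[:, :26, :] = wm_core[:, 34:, :] = False
    wm_core[:, :, :11] = wm_core[:, :, 15:] = False
    brain_mask = ref_mask | atlas.mask(LBL_GLOBAL) | wm_core
    srtm2 = fit_srtm2_map(
        dyn, ref_tac, brain_mask,
        bp_threshold=config.bp_threshold, refine=config.srtm_refine,
    )
    bp_filled = np.where(np.isfinite(srtm2.bp_map), srtm2.bp_map, 0.0)
    # PVC of the parametric map uses the atlas restricted to the fitted
    # mask, so the GTM sees consistent region means (everything outside the
    # mask is zero in the map)
    masked_atlas = LabelAtlas(
        np.where(brain_mask, atlas.data, 0), atlas.voxel_size_mm, atlas.labels
    )
    bp_pvc = rbv_pvc(bp_filled, masked_atlas, config.psf_fwhm_mm)
    bp_global = trimmed_mean(
        bp_pvc.image[masked_atlas.mask(LBL_GLOBAL)], config.trim_fraction
    )
    return suvr, bp_global, srtm2


def _quantify_volumes(atlas: LabelAtlas, landmarks: LandmarkSet):
    psd_total = region_volume(atlas, LBL_PSD)
    subs = partition_psd(atlas.mask(LBL_PSD), landmarks)
    vox_cm3 = atlas.voxel_volume_mm3 / 1000.0
    sub_vols = {name: float(m.sum()) * vox_cm3 for name, m in subs.items()}
    gm_wm = sum(
        region_volume(atlas, lab)
        for lab in (LBL_GM, LBL_WM, LBL_CEREB_GM, LBL_GLOBAL)
    )
    icv = sum(
        region_volume(atlas, lab)
        for lab in (LBL_CSF, LBL_GM, LBL_WM, LBL_CEREB_GM, LBL_GLOBAL, LBL_CHP)
    )
    return psd_total, sub_vols, gm_wm, icv


def run_subject(config: PipelineConfig, subject_id: str) -> dict:
    """Quantify every available modality for one subject; missing modalities
    yield missing (NaN) fields rather than failures."""
    root = Path(config.data_dir)
    sdir = root / subject_id
    participants = pd.read_csv(root / "participants.tsv", sep="\t")
    prow = participants[participants.subject_id == subject_id].iloc[0]
    atlas = LabelAtlas.load(sdir / "atlas.nii.gz")
    landmarks = LandmarkSet.from_json(sdir / "landmarks.json")

    rec = {
        "subject_id": subject_id,
        "age_years": float(prow.age_years),
        "sex": int(prow.sex),
        "chp_perfusion_ml_100g_min": np.nan,
        "net_csf_flow_ml_min": np.nan,
        "n_unaliased": 0,
    }

    t0 = time.time()
    if (sdir / "asl.nii.gz").exists():
        rec["chp_perfusion_ml_100g_min"] = _quantify_asl(sdir, atlas, config)
    if (sdir / "pc_phase.nii.gz").exists():
        flow_val, n_unal = _quantify_flow(sdir, config)
        rec["net_csf_flow_ml_min"] = flow_val
        rec["n_unaliased"] = n_unal
    suvr, bp_global, srtm2 = _quantify_pet(sdir, atlas, config)
    rec["suvr"] = suvr
    rec["bp_nd"] = bp_global
    rec["k2prime_fixed"] = srtm2.k2prime_fixed
    rec["n_theta_boundary"] = srtm2.n_boundary_hits

    psd_total, sub_vols, gm_wm, icv = _quantify_volumes(atlas, landmarks)
    rec["psd_total_cm3"] = psd_total
    for name, v in sub_vols.items():
        rec[f"psd_{name}_cm3"] = v
    rec["gm_wm_volume_cm3"] = gm_wm
    rec["icv_cm3"] = icv
    logger.info("quantified %s in %.1f s", subject_id, time.time() - t0)
    return rec


def quantify_cohort(config: PipelineConfig) -> pd.DataFrame:
    """Run every subject found under data_dir; isolate per-subject failures."""
    root = Path(config.data_dir)
    participants = pd.read_csv(root / "participants.tsv", sep="\t")
    records, failures = [], []
    for sid in participants.subject_id:
        try:
            records.append(run_subject(config, sid))
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            logger.error("subject %s failed: %s", sid, exc)
            failures.append((sid, str(exc)))
    if not records:
        raise RuntimeError(f"no subject succeeded; failures: {failures}")
    df = pd.DataFrame(records)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "cohort_measured.tsv", sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# cohort statistics


def _one_test(df, outcome, predictor, covariates=()):
    x = df[outcome].to_numpy(dtype=float)
    y = df[predictor].to_numpy(dtype=float)
    covs = [df[c].to_numpy(dtype=float) for c in covariates]
    try:
        if covariates:
            res = cstats.partial_spearman(x, y, covs)
        else:
            res = cstats.spearman(x, y)
        return {
            "outcome": outcome,
            "predictor": predictor,
            "covariates": "+".join(covariates),
            "n": res.n,
            "rho": res.rho,
            "p": res.p_value,
            "skipped": "",
        }
    except ValueError as exc:
        n_complete = int(np.isfinite(np.column_stack([x, y] + covs)).all(axis=1).sum())
        return {
            "outcome": outcome,
            "predictor": predictor,
            "covariates": "+".join(covariates),
            "n": n_complete,
            "rho": np.nan,
            "p": np.nan,
            "skipped": str(exc),
        }


def run_cohort(records: pd.DataFrame, covary_age_sex: bool = True) -> pd.DataFrame:
    """The cohort statistics plan.

    Primary: BP_ND against ChP perfusion, net CSF flow and total PSD volume.
    Exploratory: BP_ND against the four PSD subregions, BH-FDR adjusted as a
    family of four. Atrophy control: GM+WM against total PSD, raw and
    ICV-adjusted. Method agreement: SUVr against BP_ND + 1. Partial-Spearman
    variants covary age and sex for the primary tests.
    """
    df = records.copy()
    df["dvr"] = df["bp_nd"] + 1.0
    df["gm_wm_frac_icv"] = [
        icv_adjust(v, i) if np.isfinite(v) and np.isfinite(i) else np.nan
        for v, i in zip(df["gm_wm_volume_cm3"], df["icv_cm3"])
    ]
    df["psd_frac_icv"] = [
        icv_adjust(v, i) if np.isfinite(v) and np.isfinite(i) else np.nan
        for v, i in zip(df["psd_total_cm3"], df["icv_cm3"])
    ]

    rows = []
    primary = [
        ("bp_nd", "chp_perfusion_ml_100g_min"),
        ("bp_nd", "net_csf_flow_ml_min"),
        ("bp_nd", "psd_total_cm3"),
    ]
    for outcome, predictor in primary:
        rows.append(_one_test(df, outcome, predictor))
        if covary_age_sex:
            rows.append(_one_test(df, outcome, predictor, ("age_years", "sex")))

    family = []
    for name in ("prefrontal", "frontal", "parietal", "occipital"):
        family.append(_one_test(df, "bp_nd", f"psd_{name}_cm3"))
    fam_p = [r["p"] for r in family]
    if all(np.isfinite(fam_p)):
        adj = cstats.bh_fdr(fam_p)
        for r, q in zip(family, adj):
            r["p_fdr"] = q
    rows.extend(family)

    rows.append(_one_test(df, "gm_wm_volume_cm3", "psd_total_cm3"))
    rows.append(_one_test(df, "gm_wm_frac_icv", "psd_frac_icv"))
    rows.append(_one_test(df, "suvr", "dvr"))

    out = pd.DataFrame(rows)
    if "p_fdr" not in out.columns:
        out["p_fdr"] = np.nan
    return out[["outcome", "predictor", "covariates", "n", "rho", "p", "p_fdr", "skipped"]]


def normality_table(records: pd.DataFrame) -> pd.DataFrame:
    """Anderson-Darling normality screen of the quantitative measures."""
    rows = []
    for col in (
        "bp_nd",
        "suvr",
        "chp_perfusion_ml_100g_min",
        "net_csf_flow_ml_min",
        "psd_total_cm3",
    ):
        vals = records[col].dropna().to_numpy(dtype=float)
        if vals.size >= 5 and np.ptp(vals) > 0:
            a2, p = cstats.anderson_darling(vals)
            rows.append({"variable": col, "n": vals.size, "A2_adjusted": a2, "p": p})
        else:
            rows.append({"variable": col, "n": vals.size, "A2_adjusted": np.nan, "p": np.nan})
    return pd.DataFrame(rows)


def run_all(config: PipelineConfig) -> dict:
    """simulate -> quantify -> statistics; returns the three tables."""
    cohort_truth = simulate_dataset(config)
    measured = quantify_cohort(config)
    results = run_cohort(measured)
    normality = normality_table(measured)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.to_csv(out / "correlations.tsv", sep="\t", index=False)
    normality.to_csv(out / "normality.tsv", sep="\t", index=False)
    summary = {
        "n_subjects": int(len(measured)),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return {
        "truth": cohort_truth,
        "measured": measured,
        "correlations": results,
        "normality": normality,
    }
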