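"""End-to-end runs: simulate / human / mouse / calibrate modes.

A run is described by a single :class:`RunConfig` (usually loaded from
YAML). Every resolved threshold, density and seed is echoed into the run
log and the output manifest, so a report is auditable and reproducible:
rerunning with the same config and seed yields a byte-identical report body.

Modes
-----
simulate
    Generate a paired CT/PET phantom, derive the fat/red-marrow cutpoint by
    ROC between the designated fat-rich and fat-poor marrow regions, segment
    every marrow region, and compute adiposity, SUVs and (with placeholder
    composition models) capacity indices.
human
    Load co-registered CT/PET/masks from disk, apply (or derive) the
    diagnostic scheme, then segment, quantify and extrapolate capacity.
mouse
    Load CT/PET/masks, split bone from marrow with a calibration-derived HU
    threshold, and quantify SUVs; gamma-count tables are normalized to %ID/g.
calibrate
    Fit the rod-phantom calibration line only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from bmatquant import __version__ as _version
from bmatquant import synthetic
from bmatquant.calibration import (
    bone_bm_threshold,
    fit_calibration,
    measure_rods,
    rods_to_frame,
)
from bmatquant.capacity import (
    PLACEHOLDER_BONE_MASS_MODEL,
    PLACEHOLDER_MUSCLE_TABLE,
    Anthropometrics,
    BoneMassModel,
    CompositionParams,
    MuscleFractionTable,
    bm_volumes,
    bone_volume,
    capacity,
    muscle_volume,
)
from bmatquant.errors import BmatQuantError, ConfigurationError
from bmatquant.quantify import (
    GammaSample,
    MarrowClass,
    SUVParams,
    adiposity_fraction,
    compartment_suv,
    percent_id_per_g,
    segment_bm,
)
from bmatquant.thresholds import ThresholdScheme, compute_roc, extract_voi_hu, optimal_threshold
from bmatquant.volumes import read_mask, read_volume

logger = logging.getLogger("bmatquant")

__all__ = ["RunConfig", "RunReport", "load_config", "run_pipeline", "write_report"]

MODES = ("simulate", "human", "mouse", "calibrate")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    mode: str
    seed: int = 0
    out_dir: Path = Path("bmatquant_out")
    raw: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}, got {self.mode!r}")
        self.out_dir = Path(self.out_dir)

    def section(self, name: str) -> dict[str, Any]:
        value = self.raw.get(name, {})
        if value is None:
            return {}
        if not isinstance(value, dict):
            raise ConfigurationError(f"config section {name!r} must be a mapping")
        return value

    def config_hash(self) -> str:
        blob = json.dumps({"mode": self.mode, "seed": self.seed, **self.raw}, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path, seed: int | None = None, out_dir: str | None = None) -> RunConfig:
    """Load a YAML run config; CLI-supplied seed/out_dir override the file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "mode" not in raw:
        raise ConfigurationError(f"config {path} has no 'mode'")
    return RunConfig(
        mode=str(raw["mode"]),
        seed=int(seed if seed is not None else raw.get("seed", 0)),
        out_dir=Path(out_dir if out_dir is not None else raw.get("out_dir", "bmatquant_out")),
        raw={k: v for k, v in raw.items() if k not in ("mode", "seed", "out_dir")},
    )


@dataclass
class RunReport:
    """All tabular outputs of a run plus provenance."""

    mode: str
    seed: int
    scheme: ThresholdScheme | None
    derived_bmat_rm: int | None
    adiposity: pd.DataFrame | None
    suv: pd.DataFrame | None
    capacity_table: pd.DataFrame | None
    calibration: dict | None
    gamma: pd.DataFrame | None
    provenance: dict[str, Any]


def _composition_params(cfg: RunConfig) -> CompositionParams:
    sect = cfg.section("composition")
    return CompositionParams(**sect) if sect else CompositionParams()


def _models(cfg: RunConfig) -> tuple[BoneMassModel | None, MuscleFractionTable | None]:
    bone_sect = cfg.section("bone_mass_model")
    muscle_sect = cfg.section("muscle_table")
    ack = bool(cfg.raw.get("acknowledge_placeholder_models", False)) or cfg.mode == "simulate"
    if bone_sect:
        bone = BoneMassModel(
            a=float(bone_sect["a"]),
            b=float(bone_sect["b"]),
            form=str(bone_sect.get("form", "linear")),
            source=str(bone_sect.get("source", "user config")),
        )
    elif ack:
        bone = PLACEHOLDER_BONE_MASS_MODEL
    else:
        bone = None
    if muscle_sect:
        muscle = MuscleFractionTable(
            bands={
                sex: tuple((float(lo), float(hi), float(pct)) for lo, hi, pct in rows)
                for sex, rows in muscle_sect.items()
                if sex in ("male", "female")
            },
            source="user config",
        )
    elif ack:
        muscle = PLACEHOLDER_MUSCLE_TABLE
    else:
        muscle = None
    return bone, muscle


def _capacity_table(
    subjects: pd.DataFrame,
    suv_by_tissue: dict[str, float],
    params: CompositionParams,
    bone_model: BoneMassModel | None,
    muscle_table: MuscleFractionTable | None,
) -> pd.DataFrame:
    """Per-subject tissue volumes and capacity indices."""
    rows = []
    for _, s in subjects.iterrows():
        subj = Anthropometrics(
            age=float(s["age"]), sex=str(s["sex"]), height_m=float(s["height_m"]),
            body_mass_kg=float(s["mass_kg"]),
        )
        v_bmat, v_rm = bm_volumes(subj.body_mass_kg, params)
        vols = {
            "BMAT": v_bmat,
            "RM": v_rm,
            "bone": bone_volume(subj.height_m, bone_model, params),
            "muscle": muscle_volume(subj, muscle_table, params),
        }
        est = capacity(vols, suv_by_tissue)
        for tissue in vols:
            rows.append(
                {
                    "id": s["id"],
                    "tissue": tissue,
                    "volume_l": round(est.volumes_l[tissue], 2),
                    "mean_suv": est.suvs[tissue],
                    "uptake_index": est.uptake_index[tissue],
                    "percent_of_muscle": est.percent_of_muscle[tissue],
                }
            )
    return pd.DataFrame(rows)


def _resolve_scheme(cfg: RunConfig, ct, masks) -> tuple[ThresholdScheme, int | None]:
    """Fixed scheme, or scheme with the fat/RM cutpoint derived by ROC."""
    sect = cfg.section("thresholds")
    base = ThresholdScheme(**sect.get("scheme", {}))
    if not sect.get("derive", cfg.mode == "simulate"):
        logger.info("using fixed threshold scheme %s", base.to_dict())
        return base, None
    pos_region = sect.get("positive_region", "sternum_BM")
    neg_region = sect.get("negative_region", "vertebrae_BM")
    pos = extract_voi_hu(ct, masks, pos_region)
    neg = extract_voi_hu(ct, masks, neg_region)
    roc = compute_roc(pos, neg)
    derived = optimal_threshold(roc)
    scheme = ThresholdScheme(yellow_low=base.yellow_low, bmat_rm=derived, rm_bone=base.rm_bone)
    logger.info(
        "derived fat/RM cutpoint %d HU by ROC (%s vs %s, AUC %.4f); scheme %s",
        derived, pos_region, neg_region, roc.auc, scheme.to_dict(),
    )
    return scheme, derived


def _quantify_regions(ct, pet, masks, scheme, suv_params, bm_regions) -> tuple[pd.DataFrame, pd.DataFrame]:
    adip_rows, suv_rows = [], []
    for region in bm_regions:
        seg = segment_bm(ct, masks, scheme, region=region)
        adip = adiposity_fraction(seg)
        counts = seg.counts
        adip_rows.append(
            {
                "region": region,
                "n_voxels": seg.n_voxels,
                **{f"n_{cls.name}": counts[cls] for cls in MarrowClass},
                "ad_v_ma_v_pct": adip.ad_v_over_ma_v_pct,
                "bmat_volume_ml": adip.class_volumes_ml[MarrowClass.BMAT],
            }
        )
        if pet is not None and suv_params is not None:
            for cls, value in compartment_suv(pet, seg, suv_params).items():
                suv_rows.append({"region": region, "class": cls.name, "mean_suv": value})
    return pd.DataFrame(adip_rows), pd.DataFrame(suv_rows)


def _run_simulate(cfg: RunConfig) -> RunReport:
    sect = cfg.section("phantom")
    bm_specs = tuple(
        synthetic.BMRegionSpec(str(r["name"]), int(r["n_voxels"]), float(r["bmat_fraction"]))
        for r in sect.get("bm_regions", [])
    ) or synthetic.PhantomConfig().bm_regions
    pconfig = synthetic.PhantomConfig(
        grid_shape=tuple(sect.get("grid_shape", (50, 50, 48))),
        bm_regions=bm_specs,
        seed=cfg.seed,
    )
    ct, pet, masks, truth = synthetic.generate_human_phantom(pconfig)
    logger.info("generated phantom: grid %s, %d marrow regions", ct.shape, len(bm_specs))

    scheme, derived = _resolve_scheme(cfg, ct, masks)

    suv_sect = cfg.section("suv")
    suv_params = SUVParams(
        injected_dose_mbq=float(suv_sect.get("injected_dose_mbq", 185.0)),
        body_mass_g=float(suv_sect.get("body_mass_g", 59_700.0)),
    )
    bm_names = [r.name for r in bm_specs]
    adip, suv = _quantify_regions(ct, pet, masks, scheme, suv_params, bm_names)
    for _, row in adip.iterrows():
        logger.info(
            "region %s: Ad.V/Ma.V %.2f%% (truth %.2f%%)",
            row["region"], row["ad_v_ma_v_pct"], 100 * truth.true_bmat_fraction[row["region"]],
        )

    cohort = synthetic.generate_cohort(synthetic.CohortSpec(seed=cfg.seed))
    params = _composition_params(cfg)
    bone_model, muscle_table = _models(cfg)
    suv_by_tissue = {
        "BMAT": truth.true_uptake["BMAT"] / (suv_params.injected_dose_mbq * 1000 / suv_params.body_mass_g),
        "RM": truth.true_uptake["RM"] / (suv_params.injected_dose_mbq * 1000 / suv_params.body_mass_g),
        "bone": truth.true_uptake["trabecular_bone"] / (suv_params.injected_dose_mbq * 1000 / suv_params.body_mass_g),
        "muscle": truth.true_uptake["muscle"] / (suv_params.injected_dose_mbq * 1000 / suv_params.body_mass_g),
    }
    cap = _capacity_table(cohort, suv_by_tissue, params, bone_model, muscle_table)

    return RunReport(
        mode=cfg.mode,
        seed=cfg.seed,
        scheme=scheme,
        derived_bmat_rm=derived,
        adiposity=adip,
        suv=suv,
        capacity_table=cap,
        calibration=None,
        gamma=None,
        provenance=_provenance(cfg, scheme=scheme.to_dict(), composition=vars(params)),
    )


def _load_inputs(cfg: RunConfig):
    inputs = cfg.section("inputs")
    if "ct" not in inputs or "masks" not in inputs:
        raise ConfigurationError(f"{cfg.mode} mode requires inputs.ct and inputs.masks paths")
    ct = read_volume(inputs["ct"], "CT")
    masks = read_mask(inputs["masks"])
    pet = read_volume(inputs["pet"], "PET") if "pet" in inputs else None
    return inputs, ct, pet, masks


def _run_human(cfg: RunConfig) -> RunReport:
    inputs, ct, pet, masks = _load_inputs(cfg)
    scheme, derived = _resolve_scheme(cfg, ct, masks)
    suv_sect = cfg.section("suv")
    suv_params = None
    if pet is not None:
        suv_params = SUVParams(
            injected_dose_mbq=float(suv_sect["injected_dose_mbq"]),
            body_mass_g=float(suv_sect["body_mass_g"]),
        )
    bm_regions = cfg.raw.get("bm_regions") or [
        name for name in masks.region_names.values() if name.endswith("_BM")
    ]
    if not bm_regions:
        raise ConfigurationError("no marrow regions: list them under 'bm_regions' or suffix mask names with _BM")
    adip, suv = _quantify_regions(ct, pet, masks, scheme, suv_params, bm_regions)

    cap = None
    if "anthropometrics" in inputs:
        subjects = pd.read_csv(inputs["anthropometrics"])
        params = _composition_params(cfg)
        bone_model, muscle_table = _models(cfg)
        suv_by_tissue = cfg.raw.get("capacity_suvs")
        if suv_by_tissue:
            cap = _capacity_table(subjects, dict(suv_by_tissue), params, bone_model, muscle_table)

    return RunReport(
        mode=cfg.mode,
        seed=cfg.seed,
        scheme=scheme,
        derived_bmat_rm=derived,
        adiposity=adip,
        suv=suv,
        capacity_table=cap,
        calibration=None,
        gamma=None,
        provenance=_provenance(cfg, scheme=scheme.to_dict()),
    )


def _fit_from_config(cfg: RunConfig):
    sect = cfg.section("calibration")
    if "phantom_ct" in sect and "rod_masks" in sect:
        ct = read_volume(sect["phantom_ct"], "UCT")
        rod_masks = read_mask(sect["rod_masks"])
        densities = [float(d) for d in sect["densities"]]
    else:
        densities = [float(d) for d in sect.get("densities", np.linspace(1.08, 1.57, 5))]
        ct, rod_masks, _ = synthetic.generate_tem_phantom(densities, seed=cfg.seed)
        logger.info("no phantom paths given: generated a synthetic rod phantom")
    rods = measure_rods(ct, rod_masks, densities)
    model = fit_calibration(rods, weight_by_voxels=bool(sect.get("weight_by_voxels", False)))
    logger.info(
        "calibration: HU = %.2f * density %+.2f (r^2 %.5f, range %.2f-%.2f g/mL)",
        model.slope, model.intercept, model.r_squared, *model.density_range,
    )
    report: dict[str, Any] = {"model": model.to_dict(), "rods": rods_to_frame(rods).to_dict("records")}
    cutoff = sect.get("density_cutoff_g_ml")
    if cutoff is not None:
        thr = bone_bm_threshold(model, float(cutoff))
        logger.info("bone/BM threshold at %.3f g/mL: %d HU", float(cutoff), thr)
        report["bone_bm_threshold_hu"] = thr
        report["density_cutoff_g_ml"] = float(cutoff)
    return model, report


def _run_calibrate(cfg: RunConfig) -> RunReport:
    _, report = _fit_from_config(cfg)
    return RunReport(
        mode=cfg.mode, seed=cfg.seed, scheme=None, derived_bmat_rm=None,
        adiposity=None, suv=None, capacity_table=None, calibration=report,
        gamma=None, provenance=_provenance(cfg, calibration=report["model"]),
    )


def _run_mouse(cfg: RunConfig) -> RunReport:
    model, cal_report = _fit_from_config(cfg)
    if "bone_bm_threshold_hu" not in cal_report:
        raise ConfigurationError(
            "mouse mode needs calibration.density_cutoff_g_ml to split bone from marrow"
        )
    thr = int(cal_report["bone_bm_threshold_hu"])
    scheme = None
    adip = suv = None
    inputs = cfg.section("inputs")
    if "ct" in inputs and "masks" in inputs:
        ct = read_volume(inputs["ct"], "CT")
        masks = read_mask(inputs["masks"])
        pet = read_volume(inputs["pet"], "PET") if "pet" in inputs else None
        suv_sect = cfg.section("suv")
        suv_params = None
        if pet is not None:
            suv_params = SUVParams(
                injected_dose_mbq=float(suv_sect["injected_dose_mbq"]),
                body_mass_g=float(suv_sect["body_mass_g"]),
            )
        regions = cfg.raw.get("bm_regions") or list(masks.region_names.values())
        # bone/BM split: below thr = marrow, above = bone
        split_scheme = ThresholdScheme(yellow_low=-1000, bmat_rm=thr, rm_bone=thr + 1)
        adip, suv = _quantify_regions(ct, pet, masks, split_scheme, suv_params, regions)
        scheme = split_scheme

    gamma = None
    if "gamma_counts" in inputs:
        table = pd.read_csv(inputs["gamma_counts"])
        dose = float(cfg.section("suv")["injected_dose_mbq"])
        rows = []
        for _, r in table.iterrows():
            sample = GammaSample(
                counts_per_minute=float(r["cpm"]),
                counter_conversion_mbq_per_cpm=float(r["conversion"]),
                tissue_mass_g=float(r["mass_g"]),
                elapsed_since_injection_min=float(r["elapsed_min"]),
            )
            rows.append({"tissue": r["tissue"], "pct_id_per_g": percent_id_per_g(sample, dose)})
        gamma = pd.DataFrame(rows)

    return RunReport(
        mode=cfg.mode, seed=cfg.seed, scheme=scheme, derived_bmat_rm=None,
        adiposity=adip, suv=suv, capacity_table=None, calibration=cal_report,
        gamma=gamma, provenance=_provenance(cfg, bone_bm_threshold_hu=thr),
    )


def _provenance(cfg: RunConfig, **extra: Any) -> dict[str, Any]:
    return {
        "mode": cfg.mode,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "version": _version,
        **extra,
    }


_RUNNERS = {
    "simulate": _run_simulate,
    "human": _run_human,
    "mouse": _run_mouse,
    "calibrate": _run_calibrate,
}


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute one run; stage errors propagate with the stage name attached."""
    runner = _RUNNERS[config.mode]
    try:
        return runner(config)
    except BmatQuantError as exc:
        raise type(exc)(f"[{config.mode}] {exc}") from exc


def write_report(report: RunReport, directory: str | Path) -> list[Path]:
    """Write CSV tables, a JSON manifest and the run log to ``directory``."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        from bmatquant.errors import VolumeIOError

        raise VolumeIOError(f"cannot create output directory {directory}: {exc}") from exc
    written: list[Path] = []
    for name, frame in (
        ("adiposity.csv", report.adiposity),
        ("suv.csv", report.suv),
        ("capacity.csv", report.capacity_table),
        ("gamma.csv", report.gamma),
    ):
        if frame is not None:
            path = directory / name
            frame.to_csv(path, index=False)
            written.append(path)
    manifest = dict(report.provenance)
    if report.scheme is not None:
        manifest["threshold_scheme"] = report.scheme.to_dict()
    if report.derived_bmat_rm is not None:
        manifest["derived_bmat_rm_hu"] = report.derived_bmat_rm
    if report.calibration is not None:
        manifest["calibration"] = report.calibration
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    written.append(path)
    return written
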