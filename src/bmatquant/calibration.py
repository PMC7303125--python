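"""Linear HU-to-density calibration from a tissue-equivalent rod phantom.

Small-animal CT is calibrated against a phantom whose hydroxyapatite rods
span known mass densities (1.08-1.57 g/mL). A VOI is placed on each rod, the
rod-mean HU are regressed on density by ordinary least squares, and the
fitted line maps tissue HU to density — from which a density cutoff yields
the HU threshold separating bone from marrow inside whole bones.

The regression is over rod means (one point per rod), mirroring per-rod VOI
extraction; an optional weighting by rod voxel count is available. The
bone/marrow density cutoff has no default: it must be supplied explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from bmatquant.errors import ConfigurationError
from bmatquant.volumes import VOIMask, VoxelVolume, validate_alignment

__all__ = [
    "RodMeasurement",
    "CalibrationModel",
    "DensityEstimate",
    "measure_rods",
    "fit_calibration",
    "density_at",
    "bone_bm_threshold",
]


@dataclass(frozen=True)
class RodMeasurement:
    """Mean HU of one calibration rod of known mass density."""

    rod: str
    density_g_ml: float
    mean_hu: float
    voxel_count: int

    def __post_init__(self) -> None:
        if self.voxel_count < 1:
            raise ConfigurationError(f"rod {self.rod!r}: voxel count must be >= 1")
        if self.density_g_ml <= 0:
            raise ConfigurationError(f"rod {self.rod!r}: density must be > 0")


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted line HU = slope * density + intercept with fit quality."""

    slope: float  # HU per g/mL
    intercept: float  # HU
    r_squared: float
    density_range: tuple[float, float]  # g/mL, calibrated span

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ConfigurationError("calibration slope must be non-zero")

    def predict_hu(self, density_g_ml: float) -> float:
        return self.slope * density_g_ml + self.intercept

    def to_dict(self) -> dict:
        return {
            "slope_hu_per_g_ml": self.slope,
            "intercept_hu": self.intercept,
            "r_squared": self.r_squared,
            "density_range_g_ml": list(self.density_range),
        }


@dataclass(frozen=True)
class DensityEstimate:
    """Density inferred from HU, flagged when outside the calibrated span."""

    density_g_ml: float
    extrapolated: bool


def measure_rods(
    ct: VoxelVolume,
    rod_masks: VOIMask,
    densities: list[float],
) -> list[RodMeasurement]:
    """Mean HU per rod VOI, paired with the rods' known densities.

    Rod regions are taken in ascending label order; their count must equal
    the number of supplied densities.
    """
    validate_alignment(ct, rod_masks)
    labels = sorted(rod_masks.region_names)
    if len(labels) != len(densities):
        raise ConfigurationError(
            f"{len(densities)} densities supplied for {len(labels)} rod regions"
        )
    flat = ct.values.ravel()
    out = []
    for label, rho in zip(labels, densities):
        name = rod_masks.region_names[label]
        idx = rod_masks.region_indices(name)
        if idx.size == 0:
            raise ConfigurationError(f"rod region {name!r} has no voxels")
        out.append(
            RodMeasurement(
                rod=name,
                density_g_ml=float(rho),
                mean_hu=float(flat[idx].mean()),
                voxel_count=int(idx.size),
            )
        )
    return out


def fit_calibration(rods: list[RodMeasurement], weight_by_voxels: bool = False) -> CalibrationModel:
    """Ordinary least squares of rod-mean HU on rod density.

    Needs at least two rods with distinct densities. ``weight_by_voxels``
    weights each rod by its VOI voxel count.
    """
    if len(rods) < 2:
        raise ConfigurationError(f"calibration needs >= 2 rods, got {len(rods)}")
    rho = np.array([r.density_g_ml for r in rods], dtype=float)
    hu = np.array([r.mean_hu for r in rods], dtype=float)
    if np.unique(rho).size < 2:
        raise ConfigurationError("calibration needs >= 2 distinct rod densities")
    w = np.array([r.voxel_count for r in rods], dtype=float) if weight_by_voxels else np.ones_like(rho)

    # weighted normal equations for the straight line
    W = w / w.sum()
    xm, ym = np.sum(W * rho), np.sum(W * hu)
    sxx = np.sum(W * (rho - xm) ** 2)
    sxy = np.sum(W * (rho - xm) * (hu - ym))
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_res = np.sum(W * (hu - (slope * rho + intercept)) ** 2)
    ss_tot = np.sum(W * (hu - ym) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationModel(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        density_range=(float(rho.min()), float(rho.max())),
    )


def density_at(model: CalibrationModel, hu: float) -> DensityEstimate:
    """Invert the calibration at a HU value: density = (HU - intercept)/slope.

    The estimate is flagged extrapolated when it falls outside the calibrated
    density span.
    """
    rho = (float(hu) - model.intercept) / model.slope
    lo, hi = model.density_range
    return DensityEstimate(density_g_ml=rho, extrapolated=not (lo <= rho <= hi))


def bone_bm_threshold(model: CalibrationModel, density_cutoff_g_ml: float | None) -> int:
    """HU threshold separating bone from marrow at a given density cutoff.

    The cutoff is a deliberate, explicit parameter with no default: pass the
    mass density (g/mL) above which a voxel counts as bone for your scanner
    and species. Returns ``slope * cutoff + intercept`` rounded to the
    nearest integer HU.
    """
    if density_cutoff_g_ml is None:
        raise ConfigurationError(
            "bone/BM density cutoff is required: supply density_cutoff_g_ml "
            "(g/mL) explicitly — there is no defensible default"
        )
    return int(round(model.predict_hu(float(density_cutoff_g_ml))))


def rods_to_frame(rods: list[RodMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rod": [r.rod for r in rods],
            "density_g_ml": [r.density_g_ml for r in rods],
            "mean_hu": [r.mean_hu for r in rods],
            "voxel_count": [r.voxel_count for r in rods],
        }
    )
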