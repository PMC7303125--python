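"""Synthetic phantoms, voxel samples, cohorts and adipocyte annotations.

No imaging data ships with this package; every downstream stage is exercised
on inputs produced here. The generators emulate:

* paired CT/PET phantoms with per-compartment Gaussian HU populations and
  known per-region marrow-fat fractions (ground truth for recovery tests);
* labeled voxel-class samples for ROC analysis (fat-rich sternum-like vs
  fat-poor vertebra-like marrow populations);
* a tissue-equivalent-material (TEM) calibration phantom with hydroxyapatite
  rods of known mass density (1.08-1.57 g/mL);
* subject cohorts (age, sex, height, body mass);
* 2-D adipocyte annotations for histomorphometry.

Default HU distributions are constructions, not measured values: they place
the equal-variance fat/red-marrow midpoint at 115 HU and the red-marrow/bone
midpoint at 300 HU, so phantoms built from the defaults reproduce the
diagnostic cutpoints used for human marrow.

Reproducibility: all randomness flows from one integer seed through named
substreams (``numpy`` ``SeedSequence`` spawn keys), one per compartment or
purpose, so outputs are bit-identical for identical (config, seed) and
independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bmatquant.errors import ConfigurationError
from bmatquant.volumes import VOIMask, VoxelVolume, round_hu

__all__ = [
    "CompartmentSpec",
    "BMRegionSpec",
    "PhantomConfig",
    "PhantomTruth",
    "CohortSpec",
    "Adipocyte",
    "AdipocyteAnnotationSet",
    "LabeledHUSample",
    "DEFAULT_COMPARTMENTS",
    "generate_human_phantom",
    "sample_voxel_classes",
    "generate_tem_phantom",
    "generate_cohort",
    "generate_adipocyte_annotations",
]


def _substream(seed: int, key: int) -> np.random.Generator:
    """Deterministic substream ``key`` of master ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass(frozen=True)
class CompartmentSpec:
    """Gaussian HU and PET uptake model for one tissue compartment."""

    name: str
    hu_mean: float
    hu_sd: float
    uptake: float  # true PET value, kBq/mL
    uptake_sd: float

    def validate(self) -> None:
        if self.hu_sd < 0 or self.uptake_sd < 0:
            raise ConfigurationError(f"compartment {self.name!r}: SDs must be >= 0")


@dataclass(frozen=True)
class BMRegionSpec:
    """A marrow VOI with a known fraction of fat (BMAT) voxels."""

    name: str
    n_voxels: int
    bmat_fraction: float

    def validate(self) -> None:
        if not 0.0 <= self.bmat_fraction <= 1.0:
            raise ConfigurationError(
                f"bm_region {self.name!r}: bmat_fraction must be in [0,1], got {self.bmat_fraction}"
            )
        if self.n_voxels < 1:
            raise ConfigurationError(f"bm_region {self.name!r}: needs at least one voxel")


# Constructed defaults (the source study reports no numeric HU distribution
# parameters): midpoints of BMAT/RM and RM/bone sit at 115 and 300 HU.
DEFAULT_COMPARTMENTS: tuple[CompartmentSpec, ...] = (
    CompartmentSpec("scWAT", -100.0, 20.0, 0.4, 0.05),
    CompartmentSpec("BMAT", 42.0, 30.0, 2.0, 0.2),
    CompartmentSpec("RM", 188.0, 30.0, 2.8, 0.3),
    CompartmentSpec("trabecular_bone", 412.0, 55.0, 1.2, 0.15),
    CompartmentSpec("cortical_bone", 1000.0, 100.0, 0.5, 0.1),
    CompartmentSpec("muscle", 55.0, 10.0, 0.85, 0.1),
)

_BACKGROUND_HU = -1000  # air


@dataclass
class PhantomConfig:
    """Configuration of a paired CT/PET digital phantom.

    Geometry is deliberately simple (regions occupy consecutive voxel runs of
    the flattened grid): the pipeline operates on voxel values within masks,
    so anatomical shape is irrelevant to every statistic computed downstream.
    """

    grid_shape: tuple[int, int, int] = (50, 50, 48)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm
    compartments: tuple[CompartmentSpec, ...] = DEFAULT_COMPARTMENTS
    bm_regions: tuple[BMRegionSpec, ...] = (
        BMRegionSpec("sternum_BM", 50_000, 0.70),
        BMRegionSpec("vertebrae_BM", 50_000, 0.10),
    )
    voxels_per_compartment: int = 2_000
    seed: int = 0

    def validate(self) -> None:
        if any(int(s) < 1 for s in self.grid_shape) or len(self.grid_shape) != 3:
            raise ConfigurationError(f"grid_shape must be three positive ints, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ConfigurationError(f"voxel_spacing must be positive, got {self.voxel_spacing}")
        for comp in self.compartments:
            comp.validate()
        for region in self.bm_regions:
            region.validate()
        names = [c.name for c in self.compartments]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate compartment names")
        if self.bm_regions:
            for needed in ("BMAT", "RM"):
                if needed not in names:
                    raise ConfigurationError(
                        f"bm_regions require a {needed!r} compartment to sample from"
                    )
        n_grid = int(np.prod(self.grid_shape))
        n_needed = sum(r.n_voxels for r in self.bm_regions)
        n_needed += self.voxels_per_compartment * sum(
            1 for c in self.compartments if c.name not in ("BMAT", "RM")
        )
        if n_needed > n_grid:
            raise ConfigurationError(
                f"grid of {n_grid} voxels too small for {n_needed} region voxels"
            )

    def compartment(self, name: str) -> CompartmentSpec:
        for comp in self.compartments:
            if comp.name == name:
                return comp
        raise ConfigurationError(f"no compartment named {name!r}")


@dataclass
class PhantomTruth:
    """Exact generation record for a phantom.

    ``label_grid`` holds the per-voxel compartment id (0 = background); in
    marrow regions each voxel carries the id of the compartment it was
    actually drawn from (BMAT or RM), so class fractions recomputed from the
    grid reproduce ``true_bmat_fraction`` exactly.
    """

    label_grid: np.ndarray
    compartment_ids: dict[str, int]
    true_bmat_fraction: dict[str, float]
    true_uptake: dict[str, float]

    def bmat_fraction_from_labels(self, mask: VOIMask, region: str) -> float:
        """Recompute the fat-voxel fraction of ``region`` from the label grid."""
        idx = mask.region_indices(region)
        labels = self.label_grid.ravel()[idx]
        return float(np.mean(labels == self.compartment_ids["BMAT"]))


def generate_human_phantom(
    config: PhantomConfig,
) -> tuple[VoxelVolume, VoxelVolume, VOIMask, PhantomTruth]:
    """Generate a paired CT/PET phantom with masks and exact ground truth.

    Marrow regions use an exact split: ``floor(bmat_fraction * n)`` voxels are
    drawn from the BMAT HU/uptake distributions and the rest from RM, with
    positions shuffled within the region, so the recorded truth fraction is
    the realized voxel proportion (not a Bernoulli expectation).
    """
    config.validate()
    shape = tuple(int(s) for s in config.grid_shape)
    n_grid = int(np.prod(shape))

    comp_ids = {c.name: i + 1 for i, c in enumerate(config.compartments)}
    ct = np.full(n_grid, _BACKGROUND_HU, dtype=np.int32)
    pet = np.zeros(n_grid, dtype=np.float32)
    mask_labels = np.zeros(n_grid, dtype=np.int32)
    truth_labels = np.zeros(n_grid, dtype=np.int32)

    region_names: dict[int, str] = {}
    true_fraction: dict[str, float] = {}
    cursor = 0
    next_label = 1

    def draw(comp: CompartmentSpec, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        hu = round_hu(rng.normal(comp.hu_mean, comp.hu_sd, size=n)) if comp.hu_sd > 0 else np.full(
            n, round_hu(np.array([comp.hu_mean]))[0], dtype=np.int32
        )
        up = comp.uptake + (rng.normal(0.0, comp.uptake_sd, size=n) if comp.uptake_sd > 0 else 0.0)
        return hu, np.asarray(up, dtype=np.float32)

    # marrow regions first, then pure compartments; substream index is fixed
    # by position so generation order never matters
    for k, region in enumerate(config.bm_regions):
        rng = _substream(config.seed, k)
        n = region.n_voxels
        n_bmat = int(np.floor(region.bmat_fraction * n))
        bmat, rm = config.compartment("BMAT"), config.compartment("RM")
        hu = np.empty(n, dtype=np.int32)
        up = np.empty(n, dtype=np.float32)
        hu[:n_bmat], up[:n_bmat] = draw(bmat, n_bmat, rng)
        hu[n_bmat:], up[n_bmat:] = draw(rm, n - n_bmat, rng)
        labels = np.concatenate(
            [np.full(n_bmat, comp_ids["BMAT"]), np.full(n - n_bmat, comp_ids["RM"])]
        ).astype(np.int32)
        order = rng.permutation(n)
        sl = slice(cursor, cursor + n)
        ct[sl], pet[sl], truth_labels[sl] = hu[order], up[order], labels[order]
        mask_labels[sl] = next_label
        region_names[next_label] = region.name
        true_fraction[region.name] = n_bmat / n
        cursor += n
        next_label += 1

    for k, comp in enumerate(config.compartments):
        if comp.name in ("BMAT", "RM"):
            continue
        rng = _substream(config.seed, 1000 + k)
        n = config.voxels_per_compartment
        hu, up = draw(comp, n, rng)
        sl = slice(cursor, cursor + n)
        ct[sl], pet[sl] = hu, up
        truth_labels[sl] = comp_ids[comp.name]
        mask_labels[sl] = next_label
        region_names[next_label] = comp.name
        cursor += n
        next_label += 1

    spacing = tuple(float(s) for s in config.voxel_spacing)
    ct_vol = VoxelVolume(ct.reshape(shape), spacing, modality="CT")
    pet_vol = VoxelVolume(pet.reshape(shape), spacing, modality="PET")
    masks = VOIMask(mask_labels.reshape(shape), region_names, spacing)
    truth = PhantomTruth(
        label_grid=truth_labels.reshape(shape),
        compartment_ids=comp_ids,
        true_bmat_fraction=true_fraction,
        true_uptake={c.name: c.uptake for c in config.compartments},
    )
    return ct_vol, pet_vol, masks, truth


@dataclass(frozen=True)
class LabeledHUSample:
    """Integer HU values with binary class labels (True = positive class)."""

    hu: np.ndarray
    positive: np.ndarray

    @property
    def pos(self) -> np.ndarray:
        return self.hu[self.positive]

    @property
    def neg(self) -> np.ndarray:
        return self.hu[~self.positive]


def sample_voxel_classes(
    n_pos: int,
    n_neg: int,
    pos_dist: tuple[float, float],
    neg_dist: tuple[float, float],
    seed: int,
) -> LabeledHUSample:
    """Draw labeled integer-HU samples from two Gaussian voxel populations.

    The positive class is the low-attenuation (fat-rich) population by the
    package's ROC convention; distributions are (mean, SD) in HU.
    """
    if n_pos < 1 or n_neg < 1:
        raise ConfigurationError("both classes need at least one voxel")
    for name, (_, sd) in (("pos_dist", pos_dist), ("neg_dist", neg_dist)):
        if sd < 0:
            raise ConfigurationError(f"{name}: SD must be >= 0")
    rng_pos = _substream(seed, 0)
    rng_neg = _substream(seed, 1)
    pos = round_hu(rng_pos.normal(pos_dist[0], pos_dist[1], size=n_pos))
    neg = round_hu(rng_neg.normal(neg_dist[0], neg_dist[1], size=n_neg))
    return LabeledHUSample(
        hu=np.concatenate([pos, neg]),
        positive=np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)]),
    )


def generate_tem_phantom(
    densities: list[float],
    slope: float = 1000.0,
    intercept: float = -800.0,
    noise_sd: float = 10.0,
    voxels_per_rod: int = 500,
    seed: int = 0,
) -> tuple[VoxelVolume, VOIMask, pd.DataFrame]:
    """Generate a tissue-equivalent-material rod phantom CT.

    Rod ``i`` voxels are drawn from ``Normal(slope * density_i + intercept,
    noise_sd)`` and rounded to integer HU; rods occupy disjoint mask regions
    named ``rod_1`` .. ``rod_k``. Returns the CT, the rod masks and a truth
    table ``(rod, density_g_ml)``.
    """
    densities = [float(d) for d in densities]
    if len(densities) < 1:
        raise ConfigurationError("need at least one rod density")
    if any(b <= a for a, b in zip(densities, densities[1:])):
        raise ConfigurationError(f"densities must be strictly increasing, got {densities}")
    if voxels_per_rod < 1:
        raise ConfigurationError("voxels_per_rod must be >= 1")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")

    k = len(densities)
    n = k * voxels_per_rod
    # pack rods along one axis; geometry is irrelevant to rod statistics
    shape = (voxels_per_rod, k, 1)
    ct = np.empty(n, dtype=np.int32)
    labels = np.zeros(n, dtype=np.int32)
    names: dict[int, str] = {}
    for i, rho in enumerate(densities):
        rng = _substream(seed, i)
        mean_hu = slope * rho + intercept
        vals = rng.normal(mean_hu, noise_sd, size=voxels_per_rod) if noise_sd > 0 else np.full(
            voxels_per_rod, mean_hu
        )
        sl = slice(i * voxels_per_rod, (i + 1) * voxels_per_rod)
        ct[sl] = round_hu(vals)
        labels[sl] = i + 1
        names[i + 1] = f"rod_{i + 1}"

    spacing = (0.1, 0.1, 0.1)  # 100 um, small-animal CT scale
    order = "F"  # rods contiguous along axis 0
    ct_vol = VoxelVolume(ct.reshape(shape, order=order), spacing, modality="UCT")
    masks = VOIMask(labels.reshape(shape, order=order), names, spacing)
    truth = pd.DataFrame({"rod": list(names.values()), "density_g_ml": densities})
    return ct_vol, masks, truth


@dataclass
class CohortSpec:
    """Summary statistics from which a synthetic subject cohort is sampled.

    Defaults follow a room-temperature clinical cohort (n = 10, age
    51.5 +/- 19.6 y, 20% male). Height and body mass are not reported for
    that cohort; the defaults below give BMI near the reported 20.7 +/- 2.4
    kg/m^2, with mean mass 59.7 kg — the mass at which the tissue-volume
    model returns the reported cohort-mean marrow fat volume.
    """

    n_subjects: int = 10
    age_mean: float = 51.5
    age_sd: float = 19.6
    sex_ratio: float = 0.2  # proportion male
    height_mean: float = 1.66  # m
    height_sd: float = 0.09
    mass_mean: float = 59.7  # kg
    mass_sd: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if min(self.age_sd, self.height_sd, self.mass_sd) < 0:
            raise ConfigurationError("SDs must be >= 0")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigurationError("sex_ratio must be in [0,1]")


def _positive_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal draws, resampling any non-positive values."""
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Sample a subject table (id, age, sex, height_m, mass_kg)."""
    spec.validate()
    spec_rngs = {name: _substream(spec.seed, k) for k, name in enumerate(["age", "sex", "height", "mass"])}
    n = spec.n_subjects
    age = _positive_normal(spec_rngs["age"], spec.age_mean, spec.age_sd, n) if spec.age_sd else np.full(n, spec.age_mean)
    sex = np.where(spec_rngs["sex"].random(n) < spec.sex_ratio, "male", "female")
    height = (
        _positive_normal(spec_rngs["height"], spec.height_mean, spec.height_sd, n)
        if spec.height_sd
        else np.full(n, spec.height_mean)
    )
    mass = (
        _positive_normal(spec_rngs["mass"], spec.mass_mean, spec.mass_sd, n)
        if spec.mass_sd
        else np.full(n, spec.mass_mean)
    )
    return pd.DataFrame(
        {
            "id": [f"S{i + 1:03d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "height_m": height,
            "mass_kg": mass,
        }
    )


@dataclass(frozen=True)
class Adipocyte:
    """One annotated adipocyte: cross-sectional area and small-droplet count.

    A cell is multilocular when three or more smaller lipid droplets accompany
    the main droplet; unilocular cells have at most two.
    """

    area_mm2: float
    small_droplet_count: int


@dataclass
class AdipocyteAnnotationSet:
    """2-D histomorphometry annotations for one marrow section."""

    marrow_area_mm2: float
    adipocytes: list[Adipocyte] = field(default_factory=list)

    def validate(self) -> None:
        if self.marrow_area_mm2 <= 0:
            raise ConfigurationError("marrow_area must be > 0")
        if any(a.area_mm2 <= 0 for a in self.adipocytes):
            raise ConfigurationError("every adipocyte area must be > 0")
        if any(a.small_droplet_count < 0 for a in self.adipocytes):
            raise ConfigurationError("small_droplet_count must be >= 0")
        total = sum(a.area_mm2 for a in self.adipocytes)
        if total > self.marrow_area_mm2 * (1 + 1e-12):
            raise ConfigurationError(
                f"adipocyte area {total:.4g} mm^2 exceeds marrow area {self.marrow_area_mm2:.4g} mm^2"
            )


#: Mean single-adipocyte cross-section, mm^2 (~50 um diameter cell).
_MEAN_AD_AREA_MM2 = 2.0e-3


def generate_adipocyte_annotations(
    n_unilocular: int,
    n_multilocular: int,
    marrow_area_mm2: float,
    seed: int = 0,
    mean_cell_area_mm2: float = _MEAN_AD_AREA_MM2,
) -> AdipocyteAnnotationSet:
    """Generate an annotation set with the requested cell composition.

    Areas are lognormal around ``mean_cell_area_mm2``; unilocular cells carry
    0-2 small droplets, multilocular cells 3-8. Raises a configuration error
    if the drawn cells cannot fit in ``marrow_area_mm2``.
    """
    if n_unilocular < 0 or n_multilocular < 0:
        raise ConfigurationError("cell counts must be >= 0")
    if marrow_area_mm2 <= 0:
        raise ConfigurationError("marrow_area must be > 0")
    rng = _substream(seed, 0)
    n = n_unilocular + n_multilocular
    sigma = 0.3
    mu = np.log(mean_cell_area_mm2) - sigma**2 / 2
    areas = rng.lognormal(mu, sigma, size=n)
    droplets = np.concatenate(
        [
            rng.integers(0, 3, size=n_unilocular),  # 0..2
            rng.integers(3, 9, size=n_multilocular),  # 3..8
        ]
    )
    cells = [Adipocyte(float(a), int(d)) for a, d in zip(areas, droplets)]
    out = AdipocyteAnnotationSet(marrow_area_mm2=float(marrow_area_mm2), adipocytes=cells)
    out.validate()
    return out
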