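"""Compartment segmentation, adiposity, SUV, gamma-count and morphometry metrics.

Segmentation applies the diagnostic HU scheme voxelwise inside a marrow VOI:
``[-200, 115)`` HU is marrow fat (BMAT), ``[115, 300]`` red marrow, above
300 bone; voxels below the lower bound are out of range (air/artefact) but
stay in the marrow-volume denominator, since adiposity is expressed relative
to total marrow cavity volume (Ad.V/Ma.V). Boundary inclusivity is half-open
at 115 and closed at 300 so the partition is exhaustive and "above 300" is
bone.

SUV is body-weight normalized (SUVbw): voxel concentration divided by
injected dose per body mass. PET inputs are assumed scanner decay-corrected;
explicit decay correction applies to ex vivo gamma counts only, which are
reported as percent injected dose per gram tissue (%ID/g).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from bmatquant.errors import ConfigurationError, EmptyRegionError
from bmatquant.synthetic import AdipocyteAnnotationSet
from bmatquant.thresholds import ThresholdScheme
from bmatquant.volumes import VOIMask, VoxelVolume, validate_alignment

__all__ = [
    "F18_HALF_LIFE_MIN",
    "MarrowClass",
    "CompartmentSegmentation",
    "AdiposityResult",
    "SUVParams",
    "GammaSample",
    "MorphometryResult",
    "classify_hu",
    "classify_hu_codes",
    "segment_bm",
    "adiposity_fraction",
    "decay_correct",
    "percent_id_per_g",
    "compartment_suv",
    "morphometry",
]

#: Physical half-life of fluorine-18, minutes.
F18_HALF_LIFE_MIN = 109.77


class MarrowClass(Enum):
    """Voxel class within a bone marrow VOI (value = array code)."""

    BMAT = 0
    RM = 1
    BONE = 2
    OUT_OF_RANGE = 3


def classify_hu_codes(hu: np.ndarray, scheme: ThresholdScheme = ThresholdScheme()) -> np.ndarray:
    """Vectorized classification into :class:`MarrowClass` codes (uint8)."""
    arr = np.asarray(hu, dtype=np.int64)
    out = np.full(arr.shape, MarrowClass.OUT_OF_RANGE.value, dtype=np.uint8)
    out[(arr >= scheme.yellow_low) & (arr < scheme.bmat_rm)] = MarrowClass.BMAT.value
    out[(arr >= scheme.bmat_rm) & (arr <= scheme.rm_bone)] = MarrowClass.RM.value
    out[arr > scheme.rm_bone] = MarrowClass.BONE.value
    return out


def classify_hu(hu, scheme: ThresholdScheme = ThresholdScheme()):
    """Classify integer HU into marrow compartments.

    BMAT iff ``yellow_low <= hu < bmat_rm``; RM iff ``bmat_rm <= hu <=
    rm_bone``; BONE iff ``hu > rm_bone``; OUT_OF_RANGE iff ``hu <
    yellow_low``. Scalar input returns a :class:`MarrowClass`; array input
    returns a list of classes.
    """
    arr = np.asarray(hu)
    scalar = arr.ndim == 0
    codes = classify_hu_codes(np.atleast_1d(arr), scheme)
    if scalar:
        return MarrowClass(int(codes[0]))
    return [MarrowClass(int(c)) for c in codes]


@dataclass
class CompartmentSegmentation:
    """Per-voxel marrow classes for one BM VOI.

    ``voxel_indices`` are flat indices into the CT/PET grid; ``class_codes``
    is the parallel uint8 array of :class:`MarrowClass` codes, so PET
    statistics can be taken over exactly the classified voxels.
    """

    region: str
    voxel_indices: np.ndarray
    class_codes: np.ndarray
    scheme: ThresholdScheme
    voxel_volume_ml: float

    @property
    def counts(self) -> dict[MarrowClass, int]:
        return {cls: int(np.sum(self.class_codes == cls.value)) for cls in MarrowClass}

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_indices.size)


def segment_bm(
    ct: VoxelVolume,
    bm_mask: VOIMask,
    scheme: ThresholdScheme = ThresholdScheme(),
    region: str | None = None,
) -> CompartmentSegmentation:
    """Segment a marrow VOI into BMAT / RM / bone / out-of-range voxels.

    ``region`` selects one named mask region; ``None`` uses every non-zero
    label (the whole marrow VOI set).
    """
    validate_alignment(ct, bm_mask)
    if region is None:
        idx = np.flatnonzero(bm_mask.labels.ravel() > 0)
        name = "all_BM"
    else:
        idx = bm_mask.region_indices(region)
        name = region
    if idx.size == 0:
        raise EmptyRegionError(f"BM VOI {name!r} contains no voxels")
    hu = np.asarray(ct.values.ravel()[idx], dtype=np.int64)
    return CompartmentSegmentation(
        region=name,
        voxel_indices=idx,
        class_codes=classify_hu_codes(hu, scheme),
        scheme=scheme,
        voxel_volume_ml=ct.voxel_volume_ml,
    )


@dataclass
class AdiposityResult:
    """Marrow adiposity of one VOI: Ad.V/Ma.V (%) and per-class volumes (mL)."""

    region: str
    ad_v_over_ma_v_pct: float
    class_volumes_ml: dict[MarrowClass, float]
    denominator: str  # 'total' or 'in_range'


def adiposity_fraction(
    seg: CompartmentSegmentation,
    include_out_of_range_in_denominator: bool = True,
) -> AdiposityResult:
    """Adipose volume relative to marrow cavity volume, Ad.V/Ma.V (%).

    The default denominator is the total BM-VOI voxel count (out-of-range
    voxels are still marrow cavity); setting
    ``include_out_of_range_in_denominator=False`` restricts it to in-range
    voxels.
    """
    counts = seg.counts
    if seg.n_voxels == 0:
        raise EmptyRegionError("cannot compute adiposity of a zero-voxel VOI")
    if include_out_of_range_in_denominator:
        denom = seg.n_voxels
        denom_kind = "total"
    else:
        denom = seg.n_voxels - counts[MarrowClass.OUT_OF_RANGE]
        denom_kind = "in_range"
        if denom == 0:
            raise EmptyRegionError("no in-range voxels in VOI")
    return AdiposityResult(
        region=seg.region,
        ad_v_over_ma_v_pct=100.0 * counts[MarrowClass.BMAT] / denom,
        class_volumes_ml={cls: n * seg.voxel_volume_ml for cls, n in counts.items()},
        denominator=denom_kind,
    )


def decay_correct(activity_mbq: float, elapsed_min: float, half_life_min: float = F18_HALF_LIFE_MIN) -> float:
    """Back-correct a measured activity to injection time.

    Returns ``activity * 2**(elapsed / half_life)``. The correction is
    one-directional: a negative elapsed time is rejected rather than used to
    decay forward.
    """
    if half_life_min <= 0:
        raise ConfigurationError("half-life must be > 0")
    if elapsed_min < 0:
        raise ConfigurationError("elapsed time must be >= 0 (correction is back to injection only)")
    return float(activity_mbq) * 2.0 ** (elapsed_min / half_life_min)


@dataclass(frozen=True)
class GammaSample:
    """One ex vivo gamma-counter measurement of a dissected tissue."""

    counts_per_minute: float
    counter_conversion_mbq_per_cpm: float
    tissue_mass_g: float
    elapsed_since_injection_min: float

    def __post_init__(self) -> None:
        if min(
            self.counts_per_minute,
            self.counter_conversion_mbq_per_cpm,
            self.tissue_mass_g,
        ) <= 0 or self.elapsed_since_injection_min < 0:
            raise ConfigurationError("gamma sample fields must be positive (elapsed >= 0)")


def percent_id_per_g(
    sample: GammaSample,
    injected_dose_mbq: float,
    half_life_min: float = F18_HALF_LIFE_MIN,
) -> float:
    """Percent injected dose per gram tissue (%ID/g) from gamma counts.

    Counts per minute are converted to MBq with the counter's calibration
    factor, decay-corrected back to injection time, then expressed per gram
    of tissue as a percentage of the injected dose.
    """
    if injected_dose_mbq <= 0:
        raise ConfigurationError("injected dose must be > 0")
    activity = sample.counts_per_minute * sample.counter_conversion_mbq_per_cpm
    activity = decay_correct(activity, sample.elapsed_since_injection_min, half_life_min)
    return 100.0 * activity / injected_dose_mbq / sample.tissue_mass_g


@dataclass(frozen=True)
class SUVParams:
    """Dose and body-mass normalization for SUV (body-weight convention)."""

    injected_dose_mbq: float
    body_mass_g: float
    injection_time_min: float = 0.0
    measurement_time_min: float = 0.0
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if self.injected_dose_mbq <= 0:
            raise ConfigurationError("injected dose must be > 0")
        if self.body_mass_g <= 0:
            raise ConfigurationError("body mass must be > 0")
        if self.half_life_min <= 0:
            raise ConfigurationError("half-life must be > 0")
        if self.measurement_time_min < self.injection_time_min:
            raise ConfigurationError("measurement time must not precede injection time")


def suv_map(pet: VoxelVolume, params: SUVParams) -> np.ndarray:
    """Voxelwise SUV: concentration (kBq/mL) / (dose / body mass) (kBq/g).

    Dimensionless under the g/mL convention. PET input is assumed already
    decay-corrected to injection time by the scanner.
    """
    dose_kbq = params.injected_dose_mbq * 1000.0
    return np.asarray(pet.values, dtype=float) / (dose_kbq / params.body_mass_g)


def compartment_suv(
    pet: VoxelVolume,
    seg: CompartmentSegmentation,
    params: SUVParams,
) -> dict[MarrowClass, float]:
    """Mean SUV per marrow class over the segmented VOI.

    Classes with no voxels are absent from the result (not reported as 0).
    """
    suv = suv_map(pet, params).ravel()[seg.voxel_indices]
    out: dict[MarrowClass, float] = {}
    for cls in MarrowClass:
        sel = seg.class_codes == cls.value
        if sel.any():
            out[cls] = float(suv[sel].mean())
    return out


@dataclass
class MorphometryResult:
    """2-D adipocyte histomorphometry of one marrow section."""

    n_ad_per_marrow_area: float  # N.Ad/Ma.Ar, mm^-2
    ad_area_fraction_pct: float  # Ad.Ar/Ma.Ar, %
    multilocular_count: int
    multilocular_fraction: float


#: Minimum small-droplet count for a cell to be scored multilocular.
MULTILOCULAR_MIN_DROPLETS = 3


def morphometry(annotations: AdipocyteAnnotationSet) -> MorphometryResult:
    """Adipocyte density, area fraction and multilocular frequency.

    N.Ad/Ma.Ar = cell count / marrow area (mm^-2); Ad.Ar/Ma.Ar = summed cell
    area as % of marrow area; a cell is multilocular iff it has >= 3 small
    lipid droplets associated with its main droplet.
    """
    annotations.validate()
    n = len(annotations.adipocytes)
    area = sum(a.area_mm2 for a in annotations.adipocytes)
    multi = sum(
        1 for a in annotations.adipocytes if a.small_droplet_count >= MULTILOCULAR_MIN_DROPLETS
    )
    return MorphometryResult(
        n_ad_per_marrow_area=n / annotations.marrow_area_mm2,
        ad_area_fraction_pct=100.0 * area / annotations.marrow_area_mm2,
        multilocular_count=multi,
        multilocular_fraction=multi / n if n else 0.0,
    )
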