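"""Total-body tissue volumes and glucose-uptake-capacity indices.

The model extrapolates from anthropometrics to whole-body volumes of four
tissues, then weights each volume by its mean SUV to rank tissues by total
glucose-uptake capacity:

* Bone marrow is taken as 5% of body mass, partitioned 70% marrow fat
  (BMAT) / 30% red marrow, with tissue densities 0.92 g/mL (fat) and
  1.06 g/mL (haematopoietic). The default ``mass`` split applies the 70/30
  partition to marrow *mass* and divides each share by its own density —
  the only reading that reproduces both reported cohort-mean volumes
  (BMAT 2.27 L and RM 0.84 L) from a single body mass; a literal ``volume``
  split (70/30 of marrow volume) is available as an alternative mode.
* Bone volume is bone mass (a configurable function of height) over
  1.245 g/mL.
* Skeletal muscle volume is a sex- and age-specific percentage of body mass
  over 1.055 g/mL.

The height-to-bone-mass coefficients and the muscle-percentage reference
table are study inputs, not constants of this package: both must be supplied
(placeholder examples are clearly labelled) and the model refuses to run
without them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from bmatquant.errors import ConfigurationError, RegionLookupError

__all__ = [
    "Anthropometrics",
    "CompositionParams",
    "BoneMassModel",
    "MuscleFractionTable",
    "CapacityEstimate",
    "PLACEHOLDER_BONE_MASS_MODEL",
    "PLACEHOLDER_MUSCLE_TABLE",
    "bm_volumes",
    "bone_volume",
    "muscle_volume",
    "capacity",
]


@dataclass(frozen=True)
class Anthropometrics:
    """One adult subject: age (years), sex, height (m), body mass (kg)."""

    age: float
    sex: str  # 'male' | 'female'
    height_m: float
    body_mass_kg: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ConfigurationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if min(self.height_m, self.body_mass_kg) <= 0:
            raise ConfigurationError("height and body mass must be > 0")
        if self.age < 18:
            raise ConfigurationError("model assumes adult body composition (age >= 18)")


@dataclass(frozen=True)
class CompositionParams:
    """Marrow partition and tissue densities (g/mL = kg/L).

    ``split_mode``: ``mass`` (default) applies the 70/30 partition to marrow
    mass; ``volume`` applies it to marrow volume.
    """

    bm_mass_fraction: float = 0.05  # BM as proportion of body mass
    bmat_share: float = 0.70
    rm_share: float = 0.30
    density_fat: float = 0.92
    density_haematopoietic: float = 1.06
    density_bone: float = 1.245
    density_muscle: float = 1.055
    split_mode: str = "mass"

    def __post_init__(self) -> None:
        if abs(self.bmat_share + self.rm_share - 1.0) > 1e-9:
            raise ConfigurationError("bmat_share + rm_share must equal 1")
        if min(
            self.density_fat, self.density_haematopoietic, self.density_bone, self.density_muscle
        ) <= 0:
            raise ConfigurationError("densities must be > 0")
        if not 0 < self.bm_mass_fraction < 1:
            raise ConfigurationError("bm_mass_fraction must be in (0,1)")
        if self.split_mode not in ("mass", "volume"):
            raise ConfigurationError(f"split_mode must be 'mass' or 'volume', got {self.split_mode!r}")


def bm_volumes(body_mass_kg: float, params: CompositionParams = CompositionParams()) -> tuple[float, float]:
    """Total-body marrow fat and red marrow volumes (L) from body mass.

    Mass mode: ``V_BMAT = f_bm * M * s_bmat / rho_fat`` and ``V_RM = f_bm *
    M * s_rm / rho_haem``. Volume mode: total marrow volume ``f_bm * M /
    (s_bmat * rho_fat + s_rm * rho_haem)`` split 70/30 by volume.
    """
    if body_mass_kg <= 0:
        raise ConfigurationError("body mass must be > 0")
    bm_mass = params.bm_mass_fraction * body_mass_kg  # kg
    if params.split_mode == "mass":
        v_bmat = bm_mass * params.bmat_share / params.density_fat
        v_rm = bm_mass * params.rm_share / params.density_haematopoietic
    else:
        mean_density = params.bmat_share * params.density_fat + params.rm_share * params.density_haematopoietic
        v_bm = bm_mass / mean_density
        v_bmat = params.bmat_share * v_bm
        v_rm = params.rm_share * v_bm
    return float(v_bmat), float(v_rm)


@dataclass(frozen=True)
class BoneMassModel:
    """Configurable mapping from standing height (m) to total bone mass (kg).

    ``form='linear'``: mass = a * height + b; ``form='power'``: mass =
    a * height ** b. Coefficients come from the run configuration — they are
    reference-population values the user must choose and acknowledge.
    """

    a: float
    b: float
    form: str = "linear"
    source: str = ""

    def __post_init__(self) -> None:
        if self.form not in ("linear", "power"):
            raise ConfigurationError(f"unknown bone-mass model form {self.form!r}")

    def __call__(self, height_m: float) -> float:
        if self.form == "linear":
            mass = self.a * height_m + self.b
        else:
            mass = self.a * height_m**self.b
        if mass <= 0:
            raise ConfigurationError(
                f"bone-mass model returned non-positive mass ({mass:.3g} kg) at height {height_m} m"
            )
        return float(mass)


#: SYNTHETIC placeholder, not a published reference model: linear fit through
#: (1.5 m, 7.5 kg) and (1.9 m, 11.5 kg). Replace with reference coefficients
#: for any real analysis; the CLI requires explicit acknowledgment to use it.
PLACEHOLDER_BONE_MASS_MODEL = BoneMassModel(a=10.0, b=-7.5, form="linear", source="synthetic placeholder")


def bone_volume(
    height_m: float,
    model: BoneMassModel | None,
    params: CompositionParams = CompositionParams(),
) -> float:
    """Total-body bone volume (L): bone mass at this height over bone density."""
    if model is None:
        raise ConfigurationError(
            "no height-to-bone-mass model configured: supply coefficients from "
            "a reference population"
        )
    if height_m <= 0:
        raise ConfigurationError("height must be > 0")
    return model(height_m) / params.density_bone


@dataclass(frozen=True)
class MuscleFractionTable:
    """Skeletal muscle as % of body mass, keyed by sex and age band.

    ``bands`` maps sex -> list of (age_lo, age_hi, percent), bands inclusive
    of both endpoints. Values are reference-population inputs.
    """

    bands: dict[str, tuple[tuple[float, float, float], ...]]
    source: str = ""

    def lookup(self, sex: str, age: float) -> float:
        try:
            rows = self.bands[sex]
        except KeyError as exc:
            raise RegionLookupError(f"no muscle-fraction entries for sex {sex!r}") from exc
        for lo, hi, pct in rows:
            if lo <= age <= hi:
                if not 0 < pct < 100:
                    raise ConfigurationError(f"muscle percentage must be in (0,100), got {pct}")
                return pct
        raise RegionLookupError(
            f"no muscle-fraction band covers age {age} for sex {sex!r} "
            f"(bands: {[(lo, hi) for lo, hi, _ in rows]})"
        )


#: SYNTHETIC placeholder with plausible adult magnitudes (muscle mass declines
#: with age; higher in males). Replace with reference-population percentages.
PLACEHOLDER_MUSCLE_TABLE = MuscleFractionTable(
    bands={
        "male": ((18.0, 40.0, 42.0), (40.0, 60.0, 38.0), (60.0, 120.0, 34.0)),
        "female": ((18.0, 40.0, 34.0), (40.0, 60.0, 31.0), (60.0, 120.0, 28.0)),
    },
    source="synthetic placeholder",
)


def muscle_volume(
    subject: Anthropometrics,
    table: MuscleFractionTable | None,
    params: CompositionParams = CompositionParams(),
) -> float:
    """Skeletal muscle volume (L) from the subject's sex/age muscle fraction."""
    if table is None:
        raise ConfigurationError(
            "no muscle-fraction table configured: supply reference percentages by sex and age band"
        )
    pct = table.lookup(subject.sex, subject.age)
    return (pct / 100.0) * subject.body_mass_kg / params.density_muscle


@dataclass
class CapacityEstimate:
    """Per-tissue volume, uptake index (volume x SUV) and % of muscle."""

    volumes_l: dict[str, float]
    suvs: dict[str, float]
    uptake_index: dict[str, float]
    percent_of_muscle: dict[str, float]


def capacity(volumes_l: dict[str, float], suvs: dict[str, float]) -> CapacityEstimate:
    """Total uptake-capacity indices: volume x mean SUV, normalized to muscle.

    The uptake index is in arbitrary units (L x SUV); ``percent_of_muscle``
    expresses each tissue's index relative to skeletal muscle, which must be
    present with positive volume and SUV.
    """
    if "muscle" not in volumes_l or "muscle" not in suvs:
        raise ConfigurationError("capacity requires a 'muscle' entry in volumes and SUVs")
    common = [t for t in volumes_l if t in suvs]
    for t in common:
        if volumes_l[t] < 0:
            raise ConfigurationError(f"negative volume for {t!r}")
    if volumes_l["muscle"] <= 0 or suvs["muscle"] <= 0:
        raise ConfigurationError("muscle volume and SUV must be > 0")
    index = {t: volumes_l[t] * suvs[t] for t in common}
    ref = index["muscle"]
    return CapacityEstimate(
        volumes_l={t: volumes_l[t] for t in common},
        suvs={t: suvs[t] for t in common},
        uptake_index=index,
        percent_of_muscle={t: 100.0 * index[t] / ref for t in common},
    )
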