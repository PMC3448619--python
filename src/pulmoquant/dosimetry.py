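"""Internal dosimetry for an ¹⁸F-FDG micro-PET examination of a mouse.

The model splits the absorbed dose into a positron component and an
annihilation-photon (gamma) component.  With an administered activity
``A0`` decaying with constant ``λ``, the number of decays over an exposure
time ``T`` is

    N(T) = (A0 / λ) · (1 − exp(−λ T)),

which for complete decay (T → ∞) is ``A0/λ``.  Positrons have a range of
~1.5 mm in tissue, so essentially all their kinetic energy is absorbed in
the animal:

    D_positron = p · E_positron · N / m,

with branching ratio ``p`` (fraction of decays emitting a positron), mean
positron kinetic energy ``E_positron`` and mouse mass ``m``.  The two
511 keV annihilation photons mostly escape a mouse-sized body; only the
absorbed fraction ``a_gamma`` (≈5%, interpolated linearly in body mass
between published Monte-Carlo values) deposits:

    D_gamma = a_gamma · p · E_gamma · N / m,   E_gamma = 2 × 511 keV.

The branching ratio appears in the gamma term too because annihilation
photons are only emitted after a positron decay.

Thermoluminescence dosimeters (TLDs) placed on the skin integrate dose
only while attached (``T_TLD``), whereas the animal is exposed until the
activity has fully decayed.  A TLD reading ``D_TLD`` is scaled to the
mouse dose by the incomplete-decay ratio and corrected for the slight
attenuation of photons through the body:

    D_mouse = D_TLD · (1 − exp(−λ T_mouse)) / (1 − exp(−λ T_TLD)) / (1 − a_gamma).

All doses are reported in mGy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DoseModelError

logger = logging.getLogger(__name__)

__all__ = [
    "F18_HALF_LIFE_S",
    "EFFECTIVE_HALF_LIFE_S",
    "POSITRON_BRANCHING_RATIO",
    "MEAN_POSITRON_ENERGY_MEV",
    "ANNIHILATION_ENERGY_MEV",
    "DEFAULT_ABSORBED_FRACTION_TABLE",
    "DEFAULT_REGION_GROUPING",
    "DoseModelParams",
    "DoseResult",
    "TldRecord",
    "TldCorrectionParams",
    "cumulated_decays",
    "positron_dose",
    "absorbed_fraction",
    "gamma_dose",
    "total_dose",
    "dose_from_rate",
    "tld_correction_factor",
    "tld_to_mouse_dose",
    "region_dose_summary",
    "pet_fraction_of_total",
]

#: Physical half-life of fluorine-18 (seconds).
F18_HALF_LIFE_S = 109.77 * 60.0
#: Effective whole-body elimination half-life of FDG used for TLD correction (seconds).
EFFECTIVE_HALF_LIFE_S = 110.0 * 60.0
#: Fraction of F-18 decays that emit a positron.
POSITRON_BRANCHING_RATIO = 0.9673
#: Mean positron kinetic energy (MeV).
MEAN_POSITRON_ENERGY_MEV = 0.2428
#: Total annihilation photon energy per decay, 2 x 511 keV (MeV).
ANNIHILATION_ENERGY_MEV = 2 * 0.511
#: CODATA MeV -> joule.
MEV_TO_J = 1.602176634e-13

#: Monte-Carlo absorbed gamma fractions by body mass (kg -> fraction).
DEFAULT_ABSORBED_FRACTION_TABLE: tuple[tuple[float, float], ...] = (
    (0.020, 0.044),
    (0.040, 0.055),
)

#: TLD position ids grouped into body regions (trunk positions only; the
#: thoracoabdominal-junction positions 4 and 5 straddle both regions and are
#: left out of the default grouping).
DEFAULT_REGION_GROUPING: Mapping[str, tuple[int, ...]] = {
    "chest": (2, 3, 8),
    "abdomen": (6, 7),
    "pelvis": (9,),
}


def _half_life_to_lambda(half_life_s: float) -> float:
    return math.log(2.0) / half_life_s


@dataclass(frozen=True)
class DoseModelParams:
    """Inputs of the PET dose estimate.

    Defaults are the study conditions: 10 MBq administered to a 30 g mouse,
    complete decay in the body (no elimination).
    """

    activity_bq: float = 10e6
    mass_kg: float = 0.030
    half_life_s: float = F18_HALF_LIFE_S
    branching_ratio: float = POSITRON_BRANCHING_RATIO
    positron_energy_mev: float = MEAN_POSITRON_ENERGY_MEV
    gamma_energy_mev: float = ANNIHILATION_ENERGY_MEV
    absorbed_fraction_table: tuple[tuple[float, float], ...] = DEFAULT_ABSORBED_FRACTION_TABLE
    exposure_time_s: float = math.inf
    #: Set to use a fixed absorbed fraction instead of interpolating at mass_kg.
    absorbed_fraction_override: float | None = None

    def __post_init__(self) -> None:
        if self.activity_bq < 0:
            raise DoseModelError("administered activity must be >= 0")
        if self.mass_kg <= 0:
            raise DoseModelError("mouse mass must be > 0")
        if self.half_life_s <= 0:
            raise DoseModelError("half-life must be > 0")
        if not 0 < self.branching_ratio <= 1:
            raise DoseModelError("branching ratio must be in (0, 1]")
        if self.exposure_time_s < 0:
            raise DoseModelError("exposure time must be >= 0")
        _validate_fraction_table(self.absorbed_fraction_table)

    @property
    def decay_constant_s(self) -> float:
        return _half_life_to_lambda(self.half_life_s)

    @property
    def gamma_absorbed_fraction(self) -> float:
        if self.absorbed_fraction_override is not None:
            return self.absorbed_fraction_override
        return absorbed_fraction(self.mass_kg, self.absorbed_fraction_table)


def _validate_fraction_table(table: Iterable[tuple[float, float]]) -> None:
    table = tuple(table)
    if len(table) < 1:
        raise DoseModelError("absorbed-fraction table must have at least one entry")
    masses = [m for m, _ in table]
    if any(m2 <= m1 for m1, m2 in zip(masses, masses[1:])):
        raise DoseModelError("absorbed-fraction table masses must be strictly increasing")
    if any(not 0 < f < 1 for _, f in table):
        raise DoseModelError("absorbed fractions must lie in (0, 1)")


@dataclass(frozen=True)
class DoseResult:
    """Breakdown of the estimated dose for one administration."""

    decays: float
    positron_dose_mgy: float
    gamma_dose_mgy: float
    params: DoseModelParams

    @property
    def total_dose_mgy(self) -> float:
        return self.positron_dose_mgy + self.gamma_dose_mgy


def cumulated_decays(params: DoseModelParams) -> float:
    """Total number of decays in the body over the exposure time.

    ``N(T) = (A0/λ)(1 − e^{−λT})``; the ``T = ∞`` limit (complete decay)
    returns ``A0/λ``.
    """
    lam = params.decay_constant_s
    if math.isinf(params.exposure_time_s):
        return params.activity_bq / lam
    return params.activity_bq / lam * (1.0 - math.exp(-lam * params.exposure_time_s))


def positron_dose(params: DoseModelParams) -> float:
    """Dose from positron radiation in mGy, assuming full local absorption."""
    n = cumulated_decays(params)
    energy_j = params.branching_ratio * params.positron_energy_mev * MEV_TO_J * n
    return energy_j / params.mass_kg * 1e3


def absorbed_fraction(
    mass_kg: float,
    table: Iterable[tuple[float, float]] = DEFAULT_ABSORBED_FRACTION_TABLE,
) -> float:
    """Absorbed gamma-energy fraction at a body mass, by linear interpolation.

    Outside the tabulated mass range the nearest endpoint is used (with a
    logged warning) rather than extrapolating.
    """
    if mass_kg <= 0:
        raise DoseModelError("mass must be > 0")
    table = tuple(table)
    _validate_fraction_table(table)
    masses = np.array([m for m, _ in table])
    fractions = np.array([f for _, f in table])
    if mass_kg < masses[0] or mass_kg > masses[-1]:
        logger.warning(
            "mass %.4g kg outside absorbed-fraction table [%.4g, %.4g]; clamping",
            mass_kg,
            masses[0],
            masses[-1],
        )
    return float(np.interp(mass_kg, masses, fractions))


def gamma_dose(params: DoseModelParams) -> float:
    """Dose from annihilation photons in mGy.

    Includes the positron branching ratio: photons exist only after a
    positron decay.
    """
    n = cumulated_decays(params)
    a = params.gamma_absorbed_fraction
    energy_j = a * params.branching_ratio * params.gamma_energy_mev * MEV_TO_J * n
    return energy_j / params.mass_kg * 1e3


def total_dose(params: DoseModelParams) -> DoseResult:
    """Positron + gamma dose breakdown."""
    return DoseResult(
        decays=cumulated_decays(params),
        positron_dose_mgy=positron_dose(params),
        gamma_dose_mgy=gamma_dose(params),
        params=params,
    )


def dose_from_rate(dr0: float, decay_constant_s: float, exposure_time_s: float) -> float:
    """Integrate an exponentially decaying dose rate: ``(DR0/λ)(1 − e^{−λT})``."""
    if decay_constant_s <= 0:
        raise DoseModelError("decay constant must be > 0")
    if exposure_time_s < 0:
        raise DoseModelError("exposure time must be >= 0")
    if math.isinf(exposure_time_s):
        return dr0 / decay_constant_s
    return dr0 / decay_constant_s * (1.0 - math.exp(-decay_constant_s * exposure_time_s))


@dataclass(frozen=True)
class TldRecord:
    """One TLD measurement: skin position, mean dose and its spread."""

    position: int
    description: str
    mean_dose_mgy: float
    sd_mgy: float = 0.0
    exposure_time_s: float = 75.0 * 60.0

    def __post_init__(self) -> None:
        if self.mean_dose_mgy < 0 or self.sd_mgy < 0:
            raise DoseModelError("TLD dose and SD must be >= 0")


@dataclass(frozen=True)
class TldCorrectionParams:
    """Decay and attenuation correction applied to TLD readings.

    Defaults: effective 110 min half-life, 75 min TLD exposure, complete
    decay in the mouse, attenuation equal to the 30 g absorbed fraction.
    """

    decay_constant_s: float = _half_life_to_lambda(EFFECTIVE_HALF_LIFE_S)
    t_tld_s: float = 75.0 * 60.0
    t_mouse_s: float = math.inf
    attenuation_fraction: float = field(
        default_factory=lambda: absorbed_fraction(0.030)
    )

    def __post_init__(self) -> None:
        if self.t_tld_s <= 0:
            raise DoseModelError("TLD exposure time must be > 0")
        if self.t_mouse_s < self.t_tld_s:
            raise DoseModelError("mouse exposure time must be >= TLD exposure time")
        if not 0 <= self.attenuation_fraction < 1:
            raise DoseModelError("attenuation fraction must lie in [0, 1)")


def tld_correction_factor(corr: TldCorrectionParams) -> float:
    """Multiplier from TLD reading to mouse dose."""
    lam = corr.decay_constant_s
    denom = 1.0 - math.exp(-lam * corr.t_tld_s)
    numer = 1.0 if math.isinf(corr.t_mouse_s) else 1.0 - math.exp(-lam * corr.t_mouse_s)
    return numer / denom / (1.0 - corr.attenuation_fraction)


def tld_to_mouse_dose(record: TldRecord, corr: TldCorrectionParams) -> float:
    """Mouse dose (mGy) inferred from a single TLD reading."""
    return record.mean_dose_mgy * tld_correction_factor(corr)


def region_dose_summary(
    records: Sequence[TldRecord],
    corr: TldCorrectionParams,
    grouping: Mapping[str, tuple[int, ...]] = DEFAULT_REGION_GROUPING,
) -> dict[str, float]:
    """Mean corrected dose per body region (mGy)."""
    by_position = {r.position: r for r in records}
    out: dict[str, float] = {}
    for region, positions in grouping.items():
        missing = [p for p in positions if p not in by_position]
        if missing:
            raise DoseModelError(
                f"region {region!r} references unknown TLD positions {missing}"
            )
        out[region] = float(
            np.mean([tld_to_mouse_dose(by_position[p], corr) for p in positions])
        )
    return out


def pet_fraction_of_total(d_pet_mgy: float, d_ct_mgy: float) -> float:
    """PET share of a combined PET+CT examination dose, in percent."""
    if d_pet_mgy < 0 or d_ct_mgy < 0:
        raise DoseModelError("doses must be >= 0")
    if d_pet_mgy == 0 and d_ct_mgy == 0:
        raise DoseModelError("PET and CT dose cannot both be zero")
    return 100.0 * d_pet_mgy / (d_pet_mgy + d_ct_mgy)
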