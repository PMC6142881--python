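"""Isotope arithmetic and nitrogen budgets for ¹⁵N natural-abundance studies.

Implements the quantitative core of the ¹⁵N natural-abundance method for
measuring symbiotic N₂ fixation in grain legumes: δ¹⁵N notation, N-content
weighted whole-plant δ¹⁵N, the B value (δ¹⁵N of a plant wholly dependent on
atmospheric N₂), %Ndfa by isotope dilution between a non-fixing reference
and the B value, and the per-hectare nitrogen budget (N-fixed and soil N
uptake) obtained by scaling per-plant shoot N content with plant density.

All per-plant N masses are carried in mg N·plant⁻¹ and all areal quantities
in kg·ha⁻¹; the conversions live in :func:`mg_per_plant_to_kg_per_ha` only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from statistics import fmean

__all__ = [
    "ATM_15N_14N_RATIO",
    "InvalidInputError",
    "DegenerateInputError",
    "NdfaRangeWarning",
    "IsotopeRatio",
    "PlantSample",
    "ReferencePlantSet",
    "OrganMeasurement",
    "BValueExperiment",
    "TrialDesign",
    "SymbiosisResult",
    "delta15n",
    "ratio_from_delta15n",
    "whole_plant_delta15n",
    "b_value",
    "ndfa_percent",
    "shoot_n_content",
    "plant_density",
    "mg_per_plant_to_kg_per_ha",
    "n_fixed",
    "soil_n_uptake",
    "cn_ratio",
    "grain_yield_per_ha",
    "symbiosis_result",
]

#: ¹⁵N/¹⁴N abundance ratio of atmospheric N₂ (the δ¹⁵N = 0 standard).
ATM_15N_14N_RATIO = 0.0036765


class InvalidInputError(ValueError):
    """An input violates a precondition (negative mass, zero spacing, ...)."""


class DegenerateInputError(ValueError):
    """Inputs are formally valid but make the quantity undefined."""


class NdfaRangeWarning(UserWarning):
    """%Ndfa fell outside [0, 100]; the raw value was returned unclamped."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IsotopeRatio:
    """A sample ¹⁵N/¹⁴N abundance ratio paired with the atmospheric standard."""

    r_sample: float
    r_atm: float = ATM_15N_14N_RATIO

    def __post_init__(self) -> None:
        if not (self.r_sample > 0 and self.r_atm > 0):
            raise InvalidInputError(
                f"isotope ratios must be strictly positive, got "
                f"r_sample={self.r_sample}, r_atm={self.r_atm}"
            )


@dataclass(frozen=True)
class PlantSample:
    """One sampled plant/plot with its factorial coordinates.

    delta15n may be negative (depleted relative to air). n_pct and c_pct are
    percentages of shoot dry matter; no ordering between them is assumed.
    """

    site: str
    landrace: str
    inoculation: str
    replicate: int
    shoot_dm: float  # g·plant⁻¹
    nodule_dm: float  # mg·plant⁻¹
    n_pct: float
    c_pct: float
    delta15n: float  # ‰

    def __post_init__(self) -> None:
        if not (self.site and self.landrace and self.inoculation):
            raise InvalidInputError("factorial coordinates must be non-empty")
        if self.replicate < 1:
            raise InvalidInputError("replicate index must be >= 1")
        if self.shoot_dm < 0 or self.nodule_dm < 0:
            raise InvalidInputError("dry matter cannot be negative")
        for name in ("n_pct", "c_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise InvalidInputError(f"{name}={v} outside [0, 100]")


@dataclass(frozen=True)
class ReferencePlantSet:
    """δ¹⁵N values of the non-N₂-fixing reference species at one site."""

    site: str
    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise InvalidInputError(f"reference set for {self.site!r} is empty")

    @property
    def mean_delta15n(self) -> float:
        """Arithmetic mean δ¹⁵N over all reference species (the site δ¹⁵N_ref)."""
        return fmean(d for _, d in self.entries)


@dataclass(frozen=True)
class OrganMeasurement:
    """δ¹⁵N and N mass of one organ (shoot or root) of a glasshouse plant."""

    organ: str  # "shoot" | "root"
    delta15n: float  # ‰
    n_content: float  # mg N (organ dry mass × %N / 100)

    def __post_init__(self) -> None:
        if self.organ not in ("shoot", "root"):
            raise InvalidInputError(f"organ must be 'shoot' or 'root', got {self.organ!r}")
        if self.n_content < 0:
            raise InvalidInputError("organ N content cannot be negative")


@dataclass(frozen=True)
class BValueExperiment:
    """Glasshouse landraces grown on N-free medium, fixing all of their N.

    Each entry is (landrace, shoot measurement, root measurement). The B
    value is the mean of the *shoot* δ¹⁵N values; whole-plant δ¹⁵N is
    available for reporting but is never used as B.
    """

    landraces: tuple[tuple[str, OrganMeasurement, OrganMeasurement], ...]

    def __post_init__(self) -> None:
        if not self.landraces:
            raise InvalidInputError("B-value experiment has no landraces")


@dataclass(frozen=True)
class TrialDesign:
    """Planting geometry of the field trial, from which density follows."""

    within_row_spacing: float = 0.20  # m between plants
    between_row_spacing: float = 0.60  # m between rows
    plants_per_hole: int = 2

    def __post_init__(self) -> None:
        if self.within_row_spacing <= 0 or self.between_row_spacing <= 0:
            raise InvalidInputError("spacings must be positive")
        if self.plants_per_hole < 1:
            raise InvalidInputError("plants_per_hole must be >= 1")


@dataclass(frozen=True)
class SymbiosisResult:
    """The symbiosis budget of one plant or treatment cell."""

    ndfa_pct: float
    shoot_n_content: float  # mg N·plant⁻¹
    total_n: float  # kg N·ha⁻¹
    n_fixed: float  # kg N·ha⁻¹
    soil_n_uptake: float  # kg N·ha⁻¹
    cn_ratio: float  # g·g⁻¹
    out_of_range: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not math.isclose(
            self.n_fixed + self.soil_n_uptake, self.total_n, rel_tol=1e-9, abs_tol=1e-12
        ):
            raise InvalidInputError("n_fixed + soil_n_uptake must equal total_n")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def delta15n(ratio: IsotopeRatio) -> float:
    """δ¹⁵N (‰) of a sample: per-mil deviation of its ¹⁵N/¹⁴N ratio from air."""
    return (ratio.r_sample - ratio.r_atm) / ratio.r_atm * 1000.0


def ratio_from_delta15n(delta: float, r_atm: float = ATM_15N_14N_RATIO) -> float:
    """Invert the δ notation: the sample ratio implied by δ¹⁵N (‰)."""
    return r_atm * (1.0 + delta / 1000.0)


def whole_plant_delta15n(shoot: OrganMeasurement, root: OrganMeasurement) -> float:
    """Whole-plant δ¹⁵N: organ δ¹⁵N averaged with N-content weights.

    Raises :class:`DegenerateInputError` when both organs carry zero N.
    """
    total = shoot.n_content + root.n_content
    if total <= 0:
        raise DegenerateInputError("total organ N content is zero; weights undefined")
    return (shoot.delta15n * shoot.n_content + root.delta15n * root.n_content) / total


def b_value(experiment: BValueExperiment) -> float:
    """B value: mean shoot δ¹⁵N across the glasshouse landraces.

    Only shoots enter the mean — the field samples it calibrates are shoots.
    """
    return fmean(shoot.delta15n for _, shoot, _ in experiment.landraces)


def ndfa_percent(
    delta_ref: float, delta_leg: float, b: float, *, clamp: bool = False
) -> float:
    """Percent N derived from atmospheric fixation by isotope dilution.

    %Ndfa = 100 × (δ¹⁵N_ref − δ¹⁵N_leg) / (δ¹⁵N_ref − B).

    The raw value is returned even outside [0, 100] (with a
    :class:`NdfaRangeWarning`), unless ``clamp=True``.
    """
    denom = delta_ref - b
    if denom == 0:
        raise DegenerateInputError(
            "delta_ref equals the B value; the isotope-dilution denominator is "
            "zero and %Ndfa is undefined"
        )
    value = 100.0 * (delta_ref - delta_leg) / denom
    if not 0.0 <= value <= 100.0:
        if clamp:
            return min(100.0, max(0.0, value))
        warnings.warn(
            f"%Ndfa = {value:.2f} outside [0, 100]; returning raw value",
            NdfaRangeWarning,
            stacklevel=2,
        )
    return value


def shoot_n_content(shoot_dm: float, n_pct: float) -> float:
    """Shoot N content (mg N·plant⁻¹) = shoot dry matter (g) × %N."""
    if shoot_dm < 0 or n_pct < 0:
        raise InvalidInputError("shoot_dm and n_pct must be non-negative")
    return shoot_dm * 1000.0 * n_pct / 100.0


def plant_density(design: TrialDesign) -> float:
    """Plants per hectare implied by the planting geometry."""
    area_m2 = design.within_row_spacing * design.between_row_spacing
    return design.plants_per_hole / area_m2 * 10_000.0


def mg_per_plant_to_kg_per_ha(mg_per_plant: float, density: float) -> float:
    """Scale a per-plant mass (mg) to an areal mass (kg·ha⁻¹)."""
    return mg_per_plant * density / 1e6


def n_fixed(ndfa_pct: float, n_content: float, density: float) -> float:
    """N-fixed (kg N·ha⁻¹) = (%Ndfa/100) × shoot N content scaled by density."""
    if density <= 0:
        raise InvalidInputError("plant density must be positive")
    return mg_per_plant_to_kg_per_ha(ndfa_pct / 100.0 * n_content, density)


def soil_n_uptake(total_n: float, fixed: float) -> float:
    """Soil N uptake (kg·ha⁻¹): shoot N not attributable to fixation."""
    return total_n - fixed


def cn_ratio(c_pct: float, n_pct: float) -> float:
    """Shoot C/N mass ratio."""
    if n_pct == 0:
        raise DegenerateInputError("n_pct is zero; C/N ratio undefined")
    return c_pct / n_pct


def grain_yield_per_ha(
    total_seed_mass: float, n_plants_sampled: int, density: float
) -> float:
    """Grain yield (kg·ha⁻¹) from the seed mass (g) of a plant sample."""
    if n_plants_sampled < 1:
        raise InvalidInputError("need at least one sampled plant")
    return total_seed_mass / n_plants_sampled * density / 1000.0


def symbiosis_result(
    *,
    delta_ref: float,
    delta_leg: float,
    b: float,
    shoot_dm: float,
    n_pct: float,
    c_pct: float,
    density: float,
    clamp_ndfa: bool = False,
) -> SymbiosisResult:
    """Full symbiosis budget for one plant (or one cell of treatment means).

    Computes %Ndfa, shoot N content, total shoot N per hectare, N-fixed and
    soil N uptake; the budget closes exactly by construction
    (soil uptake is defined by difference).
    """
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", NdfaRangeWarning)
        ndfa = ndfa_percent(delta_ref, delta_leg, b, clamp=clamp_ndfa)
        out_of_range = any(issubclass(w.category, NdfaRangeWarning) for w in caught)
    content = shoot_n_content(shoot_dm, n_pct)
    total = mg_per_plant_to_kg_per_ha(content, density)
    fixed = n_fixed(ndfa, content, density)
    return SymbiosisResult(
        ndfa_pct=ndfa,
        shoot_n_content=content,
        total_n=total,
        n_fixed=fixed,
        soil_n_uptake=soil_n_uptake(total, fixed),
        cn_ratio=cn_ratio(c_pct, n_pct),
        out_of_range=out_of_range,
    )
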