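"""Occupational-limit extrapolation and cross-system dose-band comparison.

The synthesis step of the dosimetry pipeline: express an occupational
exposure limit set "as Fe" on the particle-mass scale, build a human
exposure scenario at that limit, push it through the same regional dose
chain used for the rodent study (deposited dose only — clearance is
deliberately not considered), and compare effect/exposure dose intervals
(per cm² of cells or per macrophage) between the in vitro, in vivo and
human-scenario systems as closed-interval overlap reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .inhalation_dosimetry import (
    DepositionTable,
    ExposureScenario,
    RespiratoryPhysiology,
    regional_dose_table,
    total_inhaled_mass,
)

__all__ = [
    "DoseBand",
    "OccupationalLimit",
    "iron_mass_fraction",
    "adjust_limit_for_iron",
    "cumulative_exposure",
    "human_scenario_doses",
    "compare_dose_bands",
]

# IUPAC standard atomic weights
_FE = 55.845
_O = 15.999

_IRON_OXIDES = {
    "Fe3O4": (3 * _FE) / (3 * _FE + 4 * _O),
    "Fe2O3": (2 * _FE) / (2 * _FE + 3 * _O),
    "FeO": _FE / (_FE + _O),
}


@dataclass(frozen=True)
class DoseBand:
    """A closed dose interval tagged with its system and context.

    metric is ``per_area`` (μg/cm²) or ``per_cell`` (pg/cell); system is
    ``in_vitro``, ``in_vivo`` or ``human_scenario``; effect_observed is
    "yes", "no" or "unknown".
    """

    lower: float
    upper: float
    metric: str
    system: str
    cell_context: str = ""
    effect_observed: str = "unknown"

    def __post_init__(self) -> None:
        if not 0 <= self.lower <= self.upper:
            raise ValueError(f"need 0 <= lower <= upper, got [{self.lower}, {self.upper}]")
        if self.metric not in ("per_area", "per_cell"):
            raise ValueError(f"metric must be per_area or per_cell, got {self.metric!r}")
        if self.system not in ("in_vitro", "in_vivo", "human_scenario"):
            raise ValueError(f"unknown system {self.system!r}")
        if self.effect_observed not in ("yes", "no", "unknown"):
            raise ValueError(f"effect_observed must be yes/no/unknown")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)

    def scaled(self, factor: float) -> "DoseBand":
        """Band with both endpoints multiplied by ``factor`` (e.g. a
        macrophage scavenging fraction)."""
        if factor < 0:
            raise ValueError("factor must be >= 0")
        return DoseBand(
            self.lower * factor,
            self.upper * factor,
            self.metric,
            self.system,
            self.cell_context,
            self.effect_observed,
        )


@dataclass(frozen=True)
class OccupationalLimit:
    """A regulatory air-concentration limit (mg/m³) with its chemical basis
    (``as_Fe`` or ``as_oxide``) and averaging duration (h)."""

    limit_value_mg_m3: float
    basis: str = "as_Fe"
    duration_h: float = 8.0

    def __post_init__(self) -> None:
        if self.limit_value_mg_m3 < 0:
            raise ValueError("limit_value_mg_m3 must be >= 0")
        if self.basis not in ("as_Fe", "as_oxide"):
            raise ValueError("basis must be as_Fe or as_oxide")


def iron_mass_fraction(species: str) -> float:
    """Mass fraction of iron in an iron-oxide species (Fe3O4, Fe2O3, FeO)."""
    try:
        return _IRON_OXIDES[species]
    except KeyError:
        raise ValueError(
            f"unknown iron oxide {species!r}; known: {sorted(_IRON_OXIDES)}"
        ) from None


def adjust_limit_for_iron(limit: OccupationalLimit, iron_fraction: float) -> float:
    """Convert a limit expressed as Fe to the particle-mass scale (mg/m³).

    A limit of L mg/m³ as Fe allows L / f mg/m³ of particles whose iron mass
    fraction is f.
    """
    if not 0 < iron_fraction <= 1:
        raise ValueError("iron_fraction must be in (0, 1]")
    return limit.limit_value_mg_m3 / iron_fraction


def cumulative_exposure(scenario: ExposureScenario) -> float:
    """Time-weighted cumulative exposure, mg·hr/m³ = concentration × duration."""
    return scenario.mass_concentration_mg_m3 * scenario.duration_h


def human_scenario_doses(
    table: DepositionTable,
    phys: RespiratoryPhysiology,
    scenario: ExposureScenario,
    total_macrophages: float,
    scavenging_fraction: float = 1.0,
) -> pd.DataFrame:
    """Regional deposited doses for a human exposure scenario.

    Same chain as the rodent dosimetry, except there is no measured total
    deposited mass: the table's deposition fractions are interpreted as
    fractions of *inhaled* mass, so total deposited = TIM × Σ fractions and
    per-generation masses are TIM × fraction (no renormalization needed).
    Clearance is explicitly not considered.

    Note: any packaged human deposition table is a synthetic stand-in — a
    real multiple-path deposition model output should be supplied where
    available.
    """
    tim = total_inhaled_mass(phys, scenario)
    total_deposited = tim * table.df["deposition_fraction"].sum()
    return regional_dose_table(
        table, total_deposited, total_macrophages, scavenging_fraction
    )


def compare_dose_bands(a: DoseBand, b: DoseBand) -> dict:
    """Closed-interval overlap report between two dose bands.

    Returns {overlaps, overlap_interval (or None), midpoint_ratio (a/b)}.
    Bands must share a metric; the overlap verdict is symmetric in a, b.
    """
    if a.metric != b.metric:
        raise ValueError(f"metric mismatch: {a.metric!r} vs {b.metric!r}")
    lo, hi = max(a.lower, b.lower), min(a.upper, b.upper)
    overlaps = lo <= hi
    ratio = a.midpoint / b.midpoint if b.midpoint > 0 else float("inf")
    return {
        "overlaps": overlaps,
        "overlap_interval": (lo, hi) if overlaps else None,
        "midpoint_ratio": ratio,
    }
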