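"""In vivo inhalation dose chain.

From external aerosol exposure to target-cell dose in the lung:
total inhaled mass (minute volume × duration × concentration), overall
deposition fraction, allocation of the measured deposited mass across airway
generations using a fractional-deposition table (an MPPD-style model output
consumed as data, not re-derived), per-cm² surface doses, per-macrophage
doses in the alveolar region (macrophages distributed in proportion to
alveoli), and the bifurcation hot-spot enhancement of the regional average.

Deposition tables carry one row per airway generation with a region label
(trachea/main bronchus, bronchiolar, alveolar), the fraction of deposited
mass landing in that generation, its epithelial surface area, and its
alveolus count (zero outside the alveolar region).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "REGIONS",
    "RespiratoryPhysiology",
    "ExposureScenario",
    "DepositionTable",
    "total_inhaled_mass",
    "deposition_fraction",
    "allocate_regional_mass",
    "surface_area_dose",
    "macrophage_dose",
    "regional_dose_table",
    "hotspot_dose",
]

logger = logging.getLogger(__name__)

REGIONS = ("trachea_main_bronchus", "bronchiolar", "alveolar")

DEPOSITION_COLUMNS = [
    "generation",
    "region",
    "deposition_fraction",
    "surface_area_cm2",
    "n_alveoli",
]


@dataclass(frozen=True)
class RespiratoryPhysiology:
    """Breathing parameters: tidal volume (ml/breath), respiratory rate
    (breaths/min) and minute volume (ml/min; TV × RR when not given).

    Deposition models are often run with a different (resting) respiratory
    rate than the one measured during exposure; keep separate instances for
    the two roles rather than overwriting either.
    """

    tidal_volume_ml: float
    respiratory_rate_per_min: float
    minute_volume_ml_min: float | None = None

    def __post_init__(self) -> None:
        if not self.tidal_volume_ml > 0:
            raise ValueError("tidal_volume_ml must be > 0")
        if not self.respiratory_rate_per_min > 0:
            raise ValueError("respiratory_rate_per_min must be > 0")
        if self.minute_volume_ml_min is not None and not self.minute_volume_ml_min > 0:
            raise ValueError("minute_volume_ml_min must be > 0 when given")

    @property
    def mv_ml_min(self) -> float:
        if self.minute_volume_ml_min is not None:
            return self.minute_volume_ml_min
        return self.tidal_volume_ml * self.respiratory_rate_per_min


@dataclass(frozen=True)
class ExposureScenario:
    """An exposure: aerosol mass concentration (mg/m³) for a duration (h)."""

    mass_concentration_mg_m3: float
    duration_h: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.mass_concentration_mg_m3 < 0:
            raise ValueError("mass_concentration_mg_m3 must be >= 0")
        if self.duration_h < 0:
            raise ValueError("duration_h must be >= 0")


class DepositionTable:
    """Validated per-generation fractional-deposition table."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in DEPOSITION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"deposition table missing columns: {missing}")
        df = df.copy().reset_index(drop=True)
        if len(df) == 0:
            raise ValueError("deposition table is empty")
        bad_regions = set(df["region"]) - set(REGIONS)
        if bad_regions:
            raise ValueError(f"unknown regions: {sorted(bad_regions)}")
        if (df["deposition_fraction"] < 0).any():
            raise ValueError("deposition fractions must be >= 0")
        total = df["deposition_fraction"].sum()
        if total > 1.0 + 1e-9:
            raise ValueError(f"deposition fractions sum to {total:.4f} > 1")
        if (df["surface_area_cm2"] <= 0).any():
            raise ValueError("surface areas must be > 0")
        outside = df["region"] != "alveolar"
        if (df.loc[outside, "n_alveoli"] != 0).any():
            raise ValueError("n_alveoli must be 0 outside the alveolar region")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def regional_fractions(self) -> pd.Series:
        """Deposition fraction rolled up by region."""
        return self.df.groupby("region")["deposition_fraction"].sum()

    @classmethod
    def from_csv(cls, path) -> "DepositionTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def total_inhaled_mass(phys: RespiratoryPhysiology, scenario: ExposureScenario) -> float:
    """Total inhaled mass (μg) = minute volume × duration × concentration.

    MV in ml/min → m³; concentration mg/m³ → μg.
    """
    volume_m3 = phys.mv_ml_min * 1e-6 * scenario.duration_h * 60.0
    return volume_m3 * scenario.mass_concentration_mg_m3 * 1e3


def deposition_fraction(deposited_ug: float, inhaled_ug: float) -> float:
    """Deposited / inhaled mass; logs a warning if the ratio exceeds 1."""
    if inhaled_ug <= 0:
        raise ValueError("inhaled mass must be > 0")
    if deposited_ug < 0:
        raise ValueError("deposited mass must be >= 0")
    frac = deposited_ug / inhaled_ug
    if frac > 1:
        logger.warning("deposition fraction %.3f exceeds 1", frac)
    return frac


def allocate_regional_mass(table: DepositionTable, total_deposited_ug: float) -> pd.DataFrame:
    """Distribute the measured total deposited mass across generations.

    Fractions are renormalized to sum to 1 over the table (logged when the
    raw sum differs from 1), so the per-generation masses sum exactly to
    ``total_deposited_ug`` by construction.
    """
    if total_deposited_ug < 0:
        raise ValueError("total_deposited_ug must be >= 0")
    fracs = table.df["deposition_fraction"].to_numpy(dtype=float)
    s = fracs.sum()
    if s == 0:
        raise ValueError("all deposition fractions are zero")
    if abs(s - 1.0) > 1e-9:
        logger.info("renormalizing deposition fractions (sum %.6f -> 1)", s)
    out = table.df.copy()
    out["mass_ug"] = fracs / s * total_deposited_ug
    return out


def surface_area_dose(regional: pd.DataFrame) -> pd.DataFrame:
    """Per-generation surface dose (μg/cm²) = deposited mass / surface area."""
    if (regional["surface_area_cm2"] <= 0).any():
        raise ValueError("surface areas must be > 0")
    out = regional.copy()
    out["surface_dose_ug_cm2"] = out["mass_ug"] / out["surface_area_cm2"]
    return out


def macrophage_dose(
    regional: pd.DataFrame,
    total_macrophages: float = 1.25e6,
    scavenging_fraction: float = 1.0,
) -> pd.DataFrame:
    """Per-macrophage dose (pg/cell) in alveolar generations.

    Macrophages are distributed in proportion to the number of alveoli in
    each generation; the dose is the scavenged share of the generation's
    deposited mass divided by its macrophage count.  scavenging_fraction is
    the portion of alveolar-deposited particles actually taken up by
    macrophages (default 1.0 = complete scavenging).
    """
    if not 0 < scavenging_fraction <= 1:
        raise ValueError("scavenging_fraction must be in (0, 1]")
    if not total_macrophages > 0:
        raise ValueError("total_macrophages must be > 0")
    out = regional.copy()
    alveolar = out["region"] == "alveolar"
    n_alv = out.loc[alveolar, "n_alveoli"].to_numpy(dtype=float)
    if alveolar.any():
        if (out.loc[alveolar, "mass_ug"] > 0).any() and n_alv.sum() == 0:
            raise ValueError("alveolar mass present but no alveoli in the table")
        macs = total_macrophages * n_alv / n_alv.sum()
    else:
        macs = np.array([])
    out["n_macrophages"] = 0.0
    out.loc[alveolar, "n_macrophages"] = macs
    out["macrophage_dose_pg"] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        dose = (
            scavenging_fraction
            * out.loc[alveolar, "mass_ug"].to_numpy(dtype=float)
            * 1e6
            / macs
        )
    out.loc[alveolar, "macrophage_dose_pg"] = dose
    return out


def regional_dose_table(
    table: DepositionTable,
    total_deposited_ug: float,
    total_macrophages: float = 1.25e6,
    scavenging_fraction: float = 1.0,
) -> pd.DataFrame:
    """Full per-generation dose table: mass, surface dose, macrophage dose."""
    out = allocate_regional_mass(table, total_deposited_ug)
    out = surface_area_dose(out)
    return macrophage_dose(out, total_macrophages, scavenging_fraction)


def hotspot_dose(average_surface_dose_ug_cm2: float, enhancement_factor: float) -> float:
    """Local dose at an airway-bifurcation hot spot: regional average × EF."""
    if average_surface_dose_ug_cm2 < 0 or enhancement_factor < 0:
        raise ValueError("inputs must be >= 0")
    return average_surface_dose_ug_cm2 * enhancement_factor
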