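"""Synthetic input generators for every pipeline stage.

The pipeline's real inputs are either instrument outputs (retained-burden
time series, cellular-dose time courses, magnetic-detection standard
curves) or another model's output (a multiple-path lung-deposition table).
None of those can be redistributed here, so each generator produces data
with the statistical structure the corresponding analysis stage assumes:

* deposition tables whose regional rollup matches a requested split exactly
  (default: the 2.8 / 34 / 62 % trachea–bronchiolar–alveolar split);
* linear single-phase retention decay with multiplicative lognormal noise;
* in vitro cellular-dose time courses equal to the transport model's
  delivered dose times a known association fraction, plus calibration noise;
* linear standard curves (signal = gain × mass) with noise, and the inverse
  quantification step.

Noise is multiplicative lognormal everywhere (doses and signals are
positive) and mean-preserving; every generator is bit-reproducible for a
fixed seed, and its noiseless mode is an exact fixture for the downstream
fitting stage.  Generated deposition tables are synthetic stand-ins, not
real airway morphometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell_association import CellularDoseMeasurement
from .clearance import RetentionSeries
from .inhalation_dosimetry import DepositionTable
from .invitro_transport import SuspensionExposure, simulate_delivery

__all__ = [
    "SyntheticSpec",
    "gen_deposition_table",
    "gen_retention_series",
    "gen_invitro_timecourse",
    "gen_mpd_standard_curve",
    "mpd_quantify",
]

# Regional geometry defaults for the two fixture kinds.  Areas in cm²,
# per-region generation ranges 1-based inclusive.  Synthetic morphometry:
# orders of magnitude follow published lung anatomy, not a specific dataset.
_KINDS = {
    "mouse_like": {
        "n_generations": 22,
        "regions": {
            "trachea_main_bronchus": (1, 2),
            "bronchiolar": (3, 15),
            "alveolar": (16, 22),
        },
        "region_area_cm2": {
            "trachea_main_bronchus": 1.5,
            "bronchiolar": 5.0,
            "alveolar": 500.0,
        },
        "total_alveoli": 4.0e6,
    },
    "human_like": {
        "n_generations": 23,
        "regions": {
            "trachea_main_bronchus": (1, 2),
            "bronchiolar": (3, 15),
            "alveolar": (16, 23),
        },
        "region_area_cm2": {
            "trachea_main_bronchus": 250.0,
            "bronchiolar": 2000.0,
            "alveolar": 7.0e5,
        },
        "total_alveoli": 4.8e8,
    },
}

DEFAULT_REGIONAL_SPLIT = (0.028, 0.34, 0.62)


@dataclass(frozen=True)
class SyntheticSpec:
    """Seed plus per-instrument relative noise SDs for a full synthetic run.

    Identical spec + seed → identical output everywhere.  The 5% default
    relative SD is of the order of the instrument repeatabilities the
    analyses assume (filter gravimetry ~11%, calibration curves a few %).
    """

    seed: int
    noise_rel_sd: dict = field(
        default_factory=lambda: {"mpd": 0.05, "retention": 0.05, "invitro": 0.02}
    )


def _lognormal_factors(rng: np.random.Generator, rel_sd: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with relative SD ``rel_sd``."""
    if rel_sd < 0:
        raise ValueError("rel_sd must be >= 0")
    if rel_sd == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(rel_sd**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _geometric_profile(n: int, ratio: float, total: float) -> np.ndarray:
    """n strictly increasing values with common ratio, summing to ``total``."""
    w = ratio ** np.arange(n)
    return w / w.sum() * total


def gen_deposition_table(
    kind: str = "mouse_like",
    n_generations: int | None = None,
    regional_split=DEFAULT_REGIONAL_SPLIT,
    seed: int = 0,
) -> DepositionTable:
    """Synthetic per-generation fractional-deposition table.

    ``regional_split`` gives the (trachea/main-bronchus, bronchiolar,
    alveolar) fractions; the per-generation detail is a smooth within-region
    profile with seeded jitter, renormalized so the regional rollup equals
    the requested split *exactly*.  Surface areas increase distally within
    each region; alveoli appear only in alveolar rows, in proportion to
    surface area.  For a human-style scenario, pass a split scaled by an
    overall deposition efficiency (fractions of inhaled rather than of
    deposited mass).
    """
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {sorted(_KINDS)}, got {kind!r}")
    spec = _KINDS[kind]
    split = np.asarray(regional_split, dtype=float)
    if split.shape != (3,) or np.any(split < 0):
        raise ValueError("regional_split must be three non-negative fractions")
    if split.sum() > 1.0 + 1e-9:
        raise ValueError(f"regional_split sums to {split.sum():.4f} > 1")
    n_gen = n_generations or spec["n_generations"]
    if n_gen < 3:
        # degenerate miniature lung: single region absorbs everything
        if n_gen < 1:
            raise ValueError("n_generations must be >= 1")

    rng = np.random.default_rng(seed)
    rows = []
    region_names = list(spec["regions"])
    # clip the generation ranges to the requested generation count
    for ri, region in enumerate(region_names):
        lo, hi = spec["regions"][region]
        lo, hi = min(lo, n_gen), min(hi, n_gen)
        if ri == len(region_names) - 1:
            hi = n_gen
        if lo > n_gen:
            continue
        gens = np.arange(lo, hi + 1)
        n = len(gens)
        areas = _geometric_profile(
            n, 1.8 if region == "alveolar" else 1.25, spec["region_area_cm2"][region]
        )
        # flat base deposition weights + seeded jitter, renormalized exactly
        weights = np.ones(n) * _lognormal_factors(rng, 0.10, n)
        weights = weights / weights.sum() * split[ri]
        if region == "alveolar":
            alveoli = areas / areas.sum() * spec["total_alveoli"]
        else:
            alveoli = np.zeros(n)
        for g, f, a, na in zip(gens, weights, areas, alveoli):
            rows.append(
                {
                    "generation": int(g),
                    "region": region,
                    "deposition_fraction": float(f),
                    "surface_area_cm2": float(a),
                    "n_alveoli": float(na),
                }
            )
    df = pd.DataFrame(rows).sort_values("generation").reset_index(drop=True)
    # rollup must reproduce the requested split exactly (fix rounding drift)
    for ri, region in enumerate(region_names):
        mask = df["region"] == region
        s = df.loc[mask, "deposition_fraction"].sum()
        if s > 0:
            df.loc[mask, "deposition_fraction"] *= split[ri] / s
    return DepositionTable(df)


def gen_retention_series(
    m0_ug: float,
    rate_ug_per_h: float,
    times_h,
    noise_rel_sd: float = 0.05,
    seed: int = 0,
) -> RetentionSeries:
    """Linear single-phase retention decay with multiplicative noise.

    mean(t) = m0 − rate·t; draws are mean × lognormal factor, hence always
    positive.  Raises if the line depletes before the last timepoint.
    """
    times_h = np.asarray(times_h, dtype=float)
    mean = m0_ug - rate_ug_per_h * times_h
    if np.any(mean < 0):
        raise ValueError("retention line depletes before the last timepoint")
    rng = np.random.default_rng(seed)
    noisy = mean * _lognormal_factors(rng, noise_rel_sd, len(times_h))
    return RetentionSeries(times_h=times_h, mass_ug=noisy)


def gen_invitro_timecourse(
    exposure: SuspensionExposure,
    times_h,
    true_fractions,
    n_cells: float,
    well_area_cm2: float,
    noise_rel_sd: float = 0.02,
    seed: int = 0,
) -> list[CellularDoseMeasurement]:
    """Synthetic cellular-dose time course: delivered × fraction × noise.

    ``true_fractions`` are the association fractions at each time (in
    [0, 1]).  The delivered dose comes from the transport solver on the
    given exposure, so the noiseless output is an exact fixture for
    association-fraction fitting, and measurements are linear in the nominal
    concentration at fixed time.
    """
    times_h = np.asarray(times_h, dtype=float)
    fracs = np.asarray(true_fractions, dtype=float)
    if fracs.shape != times_h.shape:
        raise ValueError("true_fractions must align with times_h")
    if np.any((fracs < 0) | (fracs > 1)):
        raise ValueError("true_fractions must be in [0, 1]")
    delivered = simulate_delivery(exposure, times_h)
    rng = np.random.default_rng(seed)
    noise = _lognormal_factors(rng, noise_rel_sd, len(times_h))
    out = []
    for t, m, f, z in zip(times_h, delivered.mass_delivered_ug, fracs, noise):
        out.append(
            CellularDoseMeasurement(
                time_h=float(t),
                nominal_concentration_ug_ml=exposure.nominal_concentration_ug_ml,
                measured_cell_mass_ug=float(m * f * z),
                n_cells=n_cells,
                well_area_cm2=well_area_cm2,
            )
        )
    return out


def gen_mpd_standard_curve(
    true_masses_ug,
    gain: float = 1.0,
    noise_rel_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Magnetic-detection standard curve: signal = gain × mass × noise.

    Different biological matrices (cells vs tissue) are emulated simply by
    different gains.  Returns a calibration DataFrame (mass_ug, signal).
    """
    masses = np.asarray(true_masses_ug, dtype=float)
    if np.any(masses < 0):
        raise ValueError("masses must be >= 0")
    rng = np.random.default_rng(seed)
    signal = gain * masses * _lognormal_factors(rng, noise_rel_sd, len(masses))
    return pd.DataFrame({"mass_ug": masses, "signal": signal})


def mpd_quantify(signal, calibration: pd.DataFrame):
    """Quantify unknown signals against a standard curve.

    Fits signal = a·mass + b to the calibration set by least squares and
    inverts: mass = (signal − b) / a.  Needs >= 3 calibration points with
    non-degenerate mass spread.
    """
    masses = calibration["mass_ug"].to_numpy(dtype=float)
    signals = calibration["signal"].to_numpy(dtype=float)
    if len(masses) < 3:
        raise ValueError("need >= 3 calibration points")
    if np.ptp(masses) == 0:
        raise ValueError("degenerate calibration: zero mass spread")
    slope, intercept = np.polyfit(masses, signals, 1)
    if slope == 0:
        raise ValueError("degenerate calibration: zero slope")
    return (np.asarray(signal, dtype=float) - intercept) / slope
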