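"""Particle, agglomerate, medium and aerosol physics; dose-metric conversions.

Nanoparticles suspended in culture medium travel to cells as fractal
agglomerates, not as primary spheres.  This module provides the geometry and
transport coefficients of those agglomerates — Sterling particle count,
effective (fractal) density, Stokes–Einstein diffusivity and Stokes settling
velocity — plus the bookkeeping conversions between mass, particle number and
surface area for primary spheres, and the Hatch–Choate count↔mass median
conversions for a single lognormal aerosol mode.

Unit policy
-----------
Public interfaces accept the mixed practical units used at the bench (nm for
diameters, g/cm³ for densities, Pa·s for viscosity, K for temperature, mg/m³
for aerosol concentration) and convert to SI internally.  Units are encoded
explicitly in field and key names (``surface_area_cm2``) or stated in the
docstring of every return value; transport coefficients are returned in SI
(m²/s, m/s) because they feed the PDE solver directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BOLTZMANN_J_PER_K",
    "GRAVITY_M_PER_S2",
    "ParticleSpec",
    "AgglomerateSpec",
    "MediumSpec",
    "AerosolDistribution",
    "particles_per_agglomerate",
    "effective_density",
    "diffusion_coefficient",
    "sedimentation_velocity",
    "mass_number_surface_convert",
    "cmd_to_mmd",
    "mmd_to_cmd",
]

# Exact SI defined values; fixed here for reproducibility.
BOLTZMANN_J_PER_K = 1.380649e-23
GRAVITY_M_PER_S2 = 9.80665

_NM_TO_M = 1e-9
_G_CM3_TO_KG_M3 = 1000.0


@dataclass(frozen=True)
class ParticleSpec:
    """Primary (unagglomerated) sphere.

    Parameters
    ----------
    diameter_nm : float
        Primary particle diameter in nm (e.g. TEM diameter).
    density_g_cm3 : float
        Bulk material density in g/cm³.
    """

    diameter_nm: float
    density_g_cm3: float

    def __post_init__(self) -> None:
        if not self.diameter_nm > 0:
            raise ValueError(f"diameter_nm must be > 0, got {self.diameter_nm}")
        if not self.density_g_cm3 > 0:
            raise ValueError(f"density_g_cm3 must be > 0, got {self.density_g_cm3}")


@dataclass(frozen=True)
class AgglomerateSpec:
    """Fractal agglomerate of primary spheres.

    ``hydrodynamic_diameter_nm`` is the in-suspension size (e.g. by DLS);
    ``fractal_dimension`` (1, 3] and ``packing_factor`` (0, 1] control how
    much of the hydrodynamic envelope is solid material.
    """

    hydrodynamic_diameter_nm: float
    fractal_dimension: float
    packing_factor: float
    primary: ParticleSpec

    def __post_init__(self) -> None:
        if self.hydrodynamic_diameter_nm < self.primary.diameter_nm:
            raise ValueError(
                "hydrodynamic_diameter_nm must be >= primary diameter "
                f"({self.hydrodynamic_diameter_nm} < {self.primary.diameter_nm})"
            )
        if not 1.0 < self.fractal_dimension <= 3.0:
            raise ValueError(
                f"fractal_dimension must be in (1, 3], got {self.fractal_dimension}"
            )
        if not 0.0 < self.packing_factor <= 1.0:
            raise ValueError(
                f"packing_factor must be in (0, 1], got {self.packing_factor}"
            )


@dataclass(frozen=True)
class MediumSpec:
    """Suspending liquid: density (g/cm³), dynamic viscosity (Pa·s), temperature (K)."""

    density_g_cm3: float
    viscosity_pa_s: float
    temperature_k: float

    def __post_init__(self) -> None:
        for name in ("density_g_cm3", "viscosity_pa_s", "temperature_k"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class AerosolDistribution:
    """Single lognormal aerosol mode.

    cmd_nm : count median diameter; gsd : geometric standard deviation (>= 1);
    mass_concentration_mg_m3 : airborne mass concentration;
    effective_density_g_cm3 : density used for count→mass moment conversion.
    """

    cmd_nm: float
    gsd: float
    mass_concentration_mg_m3: float
    effective_density_g_cm3: float

    def __post_init__(self) -> None:
        if not self.cmd_nm > 0:
            raise ValueError(f"cmd_nm must be > 0, got {self.cmd_nm}")
        if self.gsd < 1.0:
            raise ValueError(f"gsd must be >= 1, got {self.gsd}")
        if self.mass_concentration_mg_m3 < 0:
            raise ValueError("mass_concentration_mg_m3 must be >= 0")
        if not self.effective_density_g_cm3 > 0:
            raise ValueError("effective_density_g_cm3 must be > 0")


def particles_per_agglomerate(agg: AgglomerateSpec) -> float:
    """Number of primary particles per agglomerate (Sterling relation).

    N = PF · (d_agg / d_p)^DF.  Dimensionless; >= PF, and exactly 1 for a
    bare primary particle with PF = 1.
    """
    ratio = agg.hydrodynamic_diameter_nm / agg.primary.diameter_nm
    return agg.packing_factor * ratio**agg.fractal_dimension


def effective_density(agg: AgglomerateSpec, medium: MediumSpec) -> float:
    """Effective agglomerate density in g/cm³.

    The agglomerate envelope is part solid, part trapped medium:
    ρ_eff = ρ_f + (ρ_p − ρ_f)·φ with solid volume fraction
    φ = N·(d_p/d_agg)³ = PF·(d_agg/d_p)^(DF−3).  Bounded by the medium and
    bulk densities.
    """
    n = particles_per_agglomerate(agg)
    phi = n * (agg.primary.diameter_nm / agg.hydrodynamic_diameter_nm) ** 3
    phi = min(phi, 1.0)  # a DF=3, PF=1 envelope is fully solid
    rho_f = medium.density_g_cm3
    rho_p = agg.primary.density_g_cm3
    return rho_f + (rho_p - rho_f) * phi


def diffusion_coefficient(diameter_nm: float, medium: MediumSpec) -> float:
    """Stokes–Einstein diffusivity D = k_B·T / (3π·μ·d), in m²/s."""
    if not diameter_nm > 0:
        raise ValueError(f"diameter_nm must be > 0, got {diameter_nm}")
    d_m = diameter_nm * _NM_TO_M
    return BOLTZMANN_J_PER_K * medium.temperature_k / (
        3.0 * math.pi * medium.viscosity_pa_s * d_m
    )


def sedimentation_velocity(
    diameter_nm: float, effective_density_g_cm3: float, medium: MediumSpec
) -> float:
    """Stokes settling velocity V = g·d²·(ρ_eff − ρ_f) / (18μ), in m/s.

    Positive downward; negative for buoyant particles (ρ_eff < ρ_f).
    """
    if not diameter_nm > 0:
        raise ValueError(f"diameter_nm must be > 0, got {diameter_nm}")
    d_m = diameter_nm * _NM_TO_M
    delta_rho = (effective_density_g_cm3 - medium.density_g_cm3) * _G_CM3_TO_KG_M3
    return GRAVITY_M_PER_S2 * d_m**2 * delta_rho / (18.0 * medium.viscosity_pa_s)


def mass_number_surface_convert(mass_pg: float, particle: ParticleSpec) -> dict:
    """Convert a mass of primary spheres to particle number and surface area.

    Parameters
    ----------
    mass_pg : float
        Particle mass in picograms.

    Returns
    -------
    dict with keys ``number`` (count) and ``surface_area_cm2``.  Per-sphere
    mass is ρπd³/6 and the surface-to-mass ratio is 6/(ρd); both outputs are
    linear in mass.
    """
    if mass_pg < 0:
        raise ValueError(f"mass_pg must be >= 0, got {mass_pg}")
    d_cm = particle.diameter_nm * 1e-7
    rho = particle.density_g_cm3  # g/cm3
    mass_g = mass_pg * 1e-12
    per_sphere_mass_g = rho * math.pi * d_cm**3 / 6.0
    return {
        "number": mass_g / per_sphere_mass_g,
        "surface_area_cm2": mass_g * 6.0 / (rho * d_cm),
    }


def cmd_to_mmd(dist: AerosolDistribution) -> float:
    """Mass median diameter (nm) of a lognormal mode via Hatch–Choate.

    MMD = CMD · exp(3·ln²GSD).  Equals CMD for a monodisperse aerosol.
    Valid for a single mode only; the conversion is density-independent
    (density enters only when converting number to mass concentration).
    """
    return dist.cmd_nm * math.exp(3.0 * math.log(dist.gsd) ** 2)


def mmd_to_cmd(mmd_nm: float, gsd: float) -> float:
    """Inverse Hatch–Choate: CMD = MMD · exp(−3·ln²GSD)."""
    if gsd < 1.0:
        raise ValueError(f"gsd must be >= 1, got {gsd}")
    if not mmd_nm > 0:
        raise ValueError(f"mmd_nm must be > 0, got {mmd_nm}")
    return mmd_nm * math.exp(-3.0 * math.log(gsd) ** 2)
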