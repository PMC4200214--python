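"""Shared fixtures: the study-default particle system and solver output.

The expensive PDE solves are session-scoped so the suite pays for them once.
"""

import numpy as np
import pytest

from particledose import (
    AgglomerateSpec,
    MediumSpec,
    ParticleSpec,
    SuspensionExposure,
    WellGeometry,
    simulate_delivery,
)

STUDY_TIMES_H = np.array([1.0, 2.0, 4.0, 8.0, 24.0])
STUDY_FRACTIONS = np.array([0.93, 0.93, 0.89, 0.67, 0.68])


@pytest.fixture(scope="session")
def primary_particle():
    return ParticleSpec(diameter_nm=13.0, density_g_cm3=5.2)


@pytest.fixture(scope="session")
def agglomerate(primary_particle):
    return AgglomerateSpec(
        hydrodynamic_diameter_nm=276.0,
        fractal_dimension=2.1,
        packing_factor=0.637,
        primary=primary_particle,
    )


@pytest.fixture(scope="session")
def medium():
    return MediumSpec(density_g_cm3=1.0, viscosity_pa_s=0.00074, temperature_k=310.0)


@pytest.fixture(scope="session")
def well_geometry():
    return WellGeometry(media_height_mm=2.6, media_volume_ml=2.5)


@pytest.fixture(scope="session")
def exposure(agglomerate, medium, well_geometry):
    return SuspensionExposure(
        nominal_concentration_ug_ml=50.0,
        agglomerate=agglomerate,
        medium=medium,
        geometry=well_geometry,
    )


@pytest.fixture(scope="session")
def delivered(exposure):
    """Delivered-dose series at the study timepoints, default resolution."""
    return simulate_delivery(exposure, STUDY_TIMES_H)


@pytest.fixture(scope="session")
def delivered_fine(exposure):
    """Independent fine-grid reference (4x spatial and temporal resolution)."""
    return simulate_delivery(exposure, STUDY_TIMES_H, n_nodes=1600, dt_s=1.25)
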