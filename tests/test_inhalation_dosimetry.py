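"""In vivo dose chain: inhaled mass, regional allocation, macrophage dose."""

import numpy as np
import pandas as pd
import pytest

from particledose import (
    DepositionTable,
    ExposureScenario,
    RespiratoryPhysiology,
    allocate_regional_mass,
    deposition_fraction,
    gen_deposition_table,
    hotspot_dose,
    macrophage_dose,
    regional_dose_table,
    surface_area_dose,
    total_inhaled_mass,
)

MOUSE_PHYS = RespiratoryPhysiology(
    tidal_volume_ml=0.24, respiratory_rate_per_min=371.0, minute_volume_ml_min=77.0
)
MOUSE_SCENARIO = ExposureScenario(19.9, 4.0, "mouse")


@pytest.fixture(scope="module")
def mouse_table():
    return gen_deposition_table("mouse_like", seed=0)


class TestTotalInhaledMass:
    def test_zero_concentration(self):
        assert total_inhaled_mass(MOUSE_PHYS, ExposureScenario(0.0, 4.0)) == 0.0

    def test_study_exposure(self):
        # MV 77 ml/min x 4 h x 19.9 mg/m3
        tim = total_inhaled_mass(MOUSE_PHYS, MOUSE_SCENARIO)
        assert 365 <= tim <= 368

    def test_arithmetic_oracle(self):
        phys = RespiratoryPhysiology(1.0, 1.0, minute_volume_ml_min=100.0)
        assert total_inhaled_mass(phys, ExposureScenario(10.0, 1.0)) == pytest.approx(
            60.0
        )

    def test_minute_volume_defaults_to_tv_times_rr(self):
        phys = RespiratoryPhysiology(0.24, 317.0)
        assert phys.mv_ml_min == pytest.approx(0.24 * 317.0)


class TestDepositionFraction:
    def test_identity_and_zero(self):
        assert deposition_fraction(10.0, 10.0) == 1.0
        assert deposition_fraction(0.0, 365.0) == 0.0

    def test_study_value(self):
        assert deposition_fraction(14.5, 365.0) == pytest.approx(0.0397, abs=0.001)

    def test_zero_inhaled_rejected(self):
        with pytest.raises(ValueError):
            deposition_fraction(1.0, 0.0)


class TestAllocation:
    def test_regional_rollup_arithmetic(self, mouse_table):
        # the printed 2.8/34/62% split sums to 0.988; allocation renormalizes
        # for conservation, so the desk values 0.41/4.93/8.99 ug shift ~1.2%
        regional = allocate_regional_mass(mouse_table, 14.5)
        rollup = regional.groupby("region")["mass_ug"].sum()
        assert rollup["trachea_main_bronchus"] == pytest.approx(0.41, rel=0.015)
        assert rollup["bronchiolar"] == pytest.approx(4.93, rel=0.015)
        assert rollup["alveolar"] == pytest.approx(8.99, rel=0.015)

    def test_mass_conserved_exactly(self, mouse_table):
        regional = allocate_regional_mass(mouse_table, 14.5)
        assert regional["mass_ug"].sum() == pytest.approx(14.5, rel=1e-10)

    def test_single_row_table(self):
        df = pd.DataFrame(
            [
                {
                    "generation": 1,
                    "region": "alveolar",
                    "deposition_fraction": 1.0,
                    "surface_area_cm2": 10.0,
                    "n_alveoli": 100.0,
                }
            ]
        )
        regional = allocate_regional_mass(DepositionTable(df), 5.0)
        assert regional["mass_ug"].iloc[0] == 5.0

    def test_non_unit_fractions_renormalized(self, mouse_table):
        df = mouse_table.df.copy()
        df["deposition_fraction"] *= 0.97
        regional = allocate_regional_mass(DepositionTable(df), 14.5)
        assert regional["mass_ug"].sum() == pytest.approx(14.5, rel=1e-10)

    def test_all_zero_fractions_rejected(self, mouse_table):
        df = mouse_table.df.copy()
        df["deposition_fraction"] = 0.0
        with pytest.raises(ValueError):
            allocate_regional_mass(DepositionTable(df), 14.5)


class TestSurfaceDose:
    def test_dose_is_mass_over_area(self, mouse_table):
        regional = surface_area_dose(allocate_regional_mass(mouse_table, 14.5))
        np.testing.assert_allclose(
            regional["surface_dose_ug_cm2"],
            regional["mass_ug"] / regional["surface_area_cm2"],
        )

    def test_alveolar_regional_average(self, mouse_table):
        # 8.99 ug over the 500 cm2 alveolar fixture area
        regional = surface_area_dose(allocate_regional_mass(mouse_table, 14.5))
        alv = regional[regional["region"] == "alveolar"]
        assert alv["mass_ug"].sum() / alv["surface_area_cm2"].sum() == pytest.approx(
            0.018, abs=0.001
        )


class TestMacrophageDose:
    def test_whole_alveolar_mean(self, mouse_table):
        # 62% of 14.5 ug over 1.25e6 macrophages -> ~7.2 pg/cell
        full = regional_dose_table(mouse_table, 14.5, 1.25e6, 1.0)
        alv = full[full["region"] == "alveolar"]
        mean = alv["mass_ug"].sum() * 1e6 / alv["n_macrophages"].sum()
        assert mean == pytest.approx(7.2, rel=0.02)  # 1.2% above the desk value
        assert 0.62 * 14.5 / 1.25 == pytest.approx(7.19, abs=0.01)  # arithmetic oracle

    def test_macrophage_count_conserved(self, mouse_table):
        full = regional_dose_table(mouse_table, 14.5, 1.25e6, 1.0)
        assert full["n_macrophages"].sum() == pytest.approx(1.25e6, rel=1e-12)

    def test_alveolar_mass_conserved_through_doses(self, mouse_table):
        scav = 0.5
        full = regional_dose_table(mouse_table, 14.5, 1.25e6, scav)
        alv = full[full["region"] == "alveolar"]
        recovered = (
            (alv["macrophage_dose_pg"] * alv["n_macrophages"]).sum() / scav / 1e6
        )
        assert recovered == pytest.approx(alv["mass_ug"].sum(), rel=1e-10)

    def test_scavenging_halves_dose_band(self, mouse_table):
        # halving by a 0.5 scavenging fraction: 18.5-61.7 -> 9.25-30.85 pg
        band = np.array([18.5, 61.7])
        np.testing.assert_allclose(band * 0.5, [9.25, 30.85])
        full = regional_dose_table(mouse_table, 14.5, 1.25e6, 1.0)
        half = regional_dose_table(mouse_table, 14.5, 1.25e6, 0.5)
        np.testing.assert_allclose(
            half["macrophage_dose_pg"].dropna(),
            full["macrophage_dose_pg"].dropna() * 0.5,
            rtol=1e-12,
        )

    def test_all_alveoli_in_one_generation(self):
        df = pd.DataFrame(
            [
                {
                    "generation": 1,
                    "region": "bronchiolar",
                    "deposition_fraction": 0.5,
                    "surface_area_cm2": 1.0,
                    "n_alveoli": 0.0,
                },
                {
                    "generation": 2,
                    "region": "alveolar",
                    "deposition_fraction": 0.5,
                    "surface_area_cm2": 1.0,
                    "n_alveoli": 1000.0,
                },
            ]
        )
        full = regional_dose_table(DepositionTable(df), 10.0, 1.25e6, 1.0)
        assert full.loc[1, "n_macrophages"] == pytest.approx(1.25e6)

    def test_alveolar_mass_without_alveoli_rejected(self):
        df = pd.DataFrame(
            [
                {
                    "generation": 1,
                    "region": "alveolar",
                    "deposition_fraction": 1.0,
                    "surface_area_cm2": 1.0,
                    "n_alveoli": 0.0,
                }
            ]
        )
        with pytest.raises(ValueError):
            regional_dose_table(DepositionTable(df), 10.0)


def test_dose_metrics_scale_linearly_with_total_mass(mouse_table):
    base = regional_dose_table(mouse_table, 14.5)
    scaled = regional_dose_table(mouse_table, 14.5 * 3)
    for col in ("mass_ug", "surface_dose_ug_cm2", "macrophage_dose_pg"):
        np.testing.assert_allclose(
            scaled[col].dropna(), base[col].dropna() * 3, rtol=1e-12
        )


def test_hotspot_dose():
    assert hotspot_dose(0.1, 65.0) == pytest.approx(6.5)
    assert hotspot_dose(0.37, 1.0) == 0.37
    assert hotspot_dose(0.0, 65.0) == 0.0
    with pytest.raises(ValueError):
        hotspot_dose(-0.1, 65.0)


def test_table_validation():
    with pytest.raises(ValueError):
        DepositionTable(pd.DataFrame({"generation": [1]}))
    good = gen_deposition_table("mouse_like", seed=0).df
    bad = good.copy()
    bad.loc[0, "region"] = "pharynx"
    with pytest.raises(ValueError):
        DepositionTable(bad)
    bad = good.copy()
    bad["deposition_fraction"] *= 2.0
    with pytest.raises(ValueError):
        DepositionTable(bad)
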