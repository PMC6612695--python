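"""Stopping-power, range and absorber-calibration physics."""

import numpy as np
import pytest

from pbscatter.materials import load_materials
from pbscatter.stopping import (
    PROTON_MASS,
    build_stopping_table,
    calibrate_absorber_wet,
    default_physics,
    highland_angle,
    residual_range_water,
    straggling_sigma,
)

# Reference electronic stopping powers of water (MeV cm^2/g), recorded from
# published proton stopping-power tables before this implementation was
# written; the uncorrected Bethe formula must agree within 5%.
WATER_REFERENCE = {10.0: 45.67, 50.0: 12.45, 100.0: 7.289, 200.0: 4.492}


@pytest.fixture(scope="module")
def physics():
    return default_physics()


class TestStoppingPower:
    @pytest.mark.parametrize("energy,expected", sorted(WATER_REFERENCE.items()))
    def test_water_within_5pct_of_reference(self, physics, energy, expected):
        got = physics.table.stopping_power(energy, "water")
        assert got == pytest.approx(expected, rel=0.05)

    def test_100mev_water_is_about_073_mev_per_mm(self, physics):
        # independent hand evaluation of the Bethe formula with I = 75 eV
        assert physics.table.stopping_power(100.0, "water") == pytest.approx(
            7.3, rel=0.01
        )

    def test_strictly_decreasing_over_therapeutic_range(self, physics):
        energies = np.linspace(10.0, 250.0, 200)
        s = [physics.table.stopping_power(e, "water") for e in energies]
        assert all(a > b for a, b in zip(s, s[1:]))

    def test_low_edge_is_table_maximum(self, physics):
        tab = physics.table
        grid_max = max(
            tab.stopping_power(e, "water") for e in np.geomspace(10, 250, 50)
        )
        assert tab.stopping_power(10.0, "water") == pytest.approx(grid_max)

    def test_brass_to_water_ratio_tracks_density_times_mass_ratio(self, physics):
        # the mass-stopping ratio is approximately energy independent
        tab = physics.table
        brass = physics.materials["brass"]
        ratios = [
            tab.stopping_power(e, "brass") / tab.stopping_power(e, "water")
            for e in np.linspace(30, 200, 30)
        ]
        expected = brass.density * brass.water_equivalence_ratio
        assert all(r == pytest.approx(expected, rel=0.10) for r in ratios)

    def test_out_of_range_energy_raises_with_bound(self, physics):
        with pytest.raises(ValueError, match="outside table range"):
            physics.table.stopping_power(500.0, "water")


class TestCSDARange:
    def test_zero_energy_zero_range(self, physics):
        assert physics.table.csda_range(0.0, "water") == 0.0

    def test_100mev_water_about_7_7cm(self, physics):
        assert physics.table.csda_range(100.0, "water") == pytest.approx(7.7, abs=0.1)

    def test_monotone_in_energy(self, physics):
        r = physics.table.csda_ranges["water"]
        assert np.all(np.diff(r) > 0)

    def test_inverse_consistency(self, physics):
        tab = physics.table
        for e in (30.0, 74.9, 142.5, 192.4, 250.0):
            r = tab.csda_range(e, "water")
            assert tab.energy_from_range(r, "water") == pytest.approx(e, rel=1e-3)

    def test_dr_de_equals_reciprocal_stopping(self, physics):
        # finite differences on the table grid, 0.5% tolerance
        tab = physics.table
        e = tab.energies
        r = tab.csda_ranges["water"]
        mid = 0.5 * (e[1:] + e[:-1])
        drde = np.diff(r) / np.diff(e)
        s_mid = np.array([tab.stopping_power(em, "water") for em in mid])
        sel = mid > 1.0  # below ~1 MeV the low-energy extension takes over
        assert np.allclose(drde[sel], 1.0 / s_mid[sel], rtol=0.005)


class TestAbsorberCalibration:
    def test_single_wet_reproduces_all_three_anchors(self, physics):
        for energy, residual in ((74.9, 0.5), (142.5, 10.0), (192.4, 20.0)):
            got = physics.residual_range_water(energy)
            assert got == pytest.approx(residual, abs=0.5)

    def test_wet_is_least_squares_mean(self, physics):
        tab = physics.table
        wet = calibrate_absorber_wet(tab)
        diffs = [tab.csda_range(e, "water") - r
                 for e, r in ((74.9, 0.5), (142.5, 10.0), (192.4, 20.0))]
        assert wet == pytest.approx(np.mean(diffs))

    def test_zero_wet_is_identity(self, physics):
        e = 120.0
        assert residual_range_water(e, 0.0, physics.table) == pytest.approx(
            physics.table.csda_range(e, "water")
        )

    def test_negative_wet_rejected(self, physics):
        with pytest.raises(ValueError):
            residual_range_water(100.0, -1.0, physics.table)

    def test_floor_at_zero(self, physics):
        assert residual_range_water(20.0, 50.0, physics.table) == 0.0


class TestHighland:
    def test_matches_hand_evaluation(self, physics):
        # theta0 = 14.1/pv * sqrt(t/X0) * (1 + log10(t/X0)/9), pv relativistic
        water = physics.materials["water"]
        e, path = 150.0, 1.0
        gamma = 1.0 + e / PROTON_MASS
        pc = np.sqrt(e**2 + 2 * e * PROTON_MASS)
        pv = pc**2 / (e + PROTON_MASS)
        x0 = water.radiation_length / water.density
        expected = 14.1 / pv * np.sqrt(path / x0) * (
            1 + np.log10(path / x0) / 9
        )
        assert highland_angle(e, path, water) == pytest.approx(expected, rel=1e-12)

    def test_vanishes_with_path(self, physics):
        water = physics.materials["water"]
        assert highland_angle(150.0, 1e-9, water) < 1e-4

    def test_brass_scatters_more_than_water(self, physics):
        brass = physics.materials["brass"]
        water = physics.materials["water"]
        assert highland_angle(150.0, 0.5, brass) > highland_angle(150.0, 0.5, water)

    def test_increasing_in_path(self, physics):
        water = physics.materials["water"]
        x0 = water.radiation_length_cm
        paths = np.geomspace(1e-3 * x0, x0, 40)
        angles = [highland_angle(100.0, p, water) for p in paths]
        assert all(a < b for a, b in zip(angles, angles[1:]))

    def test_nonpositive_path_rejected(self, physics):
        with pytest.raises(ValueError):
            highland_angle(100.0, 0.0, physics.materials["water"])


class TestStraggling:
    def test_zero_path_zero_sigma(self, physics):
        w = physics.materials["water"]
        assert straggling_sigma(150.0, 150.0, 0.0, w) == 0.0

    def test_sqrt_path_scaling(self, physics):
        w = physics.materials["water"]
        s1 = straggling_sigma(150.0, 140.0, 1.0, w)
        s2 = straggling_sigma(150.0, 140.0, 2.0, w)
        assert s2 == pytest.approx(np.sqrt(2) * s1, rel=1e-12)

    def test_small_against_mean_loss(self, physics):
        # 150 -> 140 MeV over ~1.7 cm of water: fluctuation << 10 MeV loss
        w = physics.materials["water"]
        assert straggling_sigma(150.0, 140.0, 1.7, w) < 1.0

    def test_inverted_energies_rejected(self, physics):
        with pytest.raises(ValueError):
            straggling_sigma(100.0, 150.0, 1.0, physics.materials["water"])


class TestMaterials:
    def test_water_equivalence_ratio_of_water_is_one(self, physics):
        assert physics.materials["water"].water_equivalence_ratio == pytest.approx(1.0)

    def test_required_materials_present(self):
        lib = load_materials()
        assert {"water", "air", "abs_plastic", "brass"} <= set(lib)

    def test_invalid_density_rejected(self):
        from pbscatter.materials import Material

        with pytest.raises(ValueError):
            Material(name="x", density=-1.0, mean_excitation_energy=75.0,
                     Z_over_A=0.5, radiation_length=36.0)

    def test_table_positive_and_ranges_monotone_all_materials(self):
        table = build_stopping_table()
        for name in table.stopping_powers:
            assert np.all(np.asarray(table.stopping_powers[name]) > 0)
            assert np.all(np.diff(table.csda_ranges[name]) > 0)
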