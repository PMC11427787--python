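"""Closed-form photophysics: worked values, identities, and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trapquench import core

CN_1PCT = 0.01 / 0.69  # 1 mol% at 0.69 nm^2 per lipid


class TestConcentrationConversions:
    @pytest.mark.parametrize(
        "c_pct, expected",
        [(6.9, 0.1), (0.0, 0.0), (1.0, 0.0144928)],
    )
    def test_mol_percent_to_number_density(self, c_pct, expected, cfg):
        assert core.mol_percent_to_number_density(c_pct, cfg) == pytest.approx(
            expected, abs=1e-6
        )

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            core.mol_percent_to_number_density(-0.1)

    @given(st.floats(0.0, 50.0))
    @settings(derandomize=True, deadline=None)
    def test_density_round_trip_exact(self, c_pct):
        cn = core.mol_percent_to_number_density(c_pct)
        back = core.number_density_to_mol_percent(cn)
        assert back == pytest.approx(c_pct, rel=1e-12, abs=1e-300)

    @pytest.mark.parametrize(
        "w, mw_dye, mw_bulk, expected",
        [
            (0.5, 1381.9, 786.1, 0.285),  # 0.5% w/w dye-lipid in DOPC
            (0.0, 1000.0, 800.0, 0.0),
            (3.0, 700.0, 700.0, 3.0),  # equal MWs: w% == mol%
        ],
    )
    def test_weight_to_mol_percent(self, w, mw_dye, mw_bulk, expected):
        got = core.weight_percent_to_mol_percent(w, mw_dye, mw_bulk)
        assert got == pytest.approx(expected, abs=5e-4)

    def test_weight_percent_domain(self):
        with pytest.raises(ValueError):
            core.weight_percent_to_mol_percent(101.0, 1000.0, 800.0)


class TestSeparations:
    def test_mean_separation_at_one_percent(self):
        # the canonical worked value for a typical labeling density
        assert core.mean_separation(CN_1PCT) == pytest.approx(4.69, abs=0.005)

    def test_mean_separation_derived(self):
        assert core.mean_separation(0.1) == pytest.approx(1.784, abs=1e-3)

    def test_zero_density_is_infinite_separation(self):
        assert core.mean_separation(0.0) == np.inf
        assert core.nearest_neighbor_mean_separation(0.0) == np.inf

    def test_nearest_neighbor_value(self):
        got = core.nearest_neighbor_mean_separation(0.0144928)
        assert got == pytest.approx(4.153, abs=2e-3)

    @given(st.floats(1e-6, 10.0))
    @settings(derandomize=True, deadline=None)
    def test_nn_to_effective_area_ratio_constant(self, cn):
        # the two separation definitions differ by sqrt(pi)/2 for every C_N
        ratio = core.nearest_neighbor_mean_separation(cn) / core.mean_separation(cn)
        assert ratio == pytest.approx(np.sqrt(np.pi) / 2.0, rel=1e-12)

    def test_separation_monotone_decreasing(self):
        cn = np.geomspace(1e-4, 1.0, 50)
        assert np.all(np.diff(core.mean_separation(cn)) < 0)

    def test_separation_inverse(self):
        cn = 0.037
        r = core.mean_separation(cn)
        assert core.separation_to_number_density(r) == pytest.approx(cn, rel=1e-12)


class TestDiffusionDisplacement:
    def test_lipid_dye_displacement_is_subnanometer(self, tr):
        # diffusion during one excited-state lifetime is far below the
        # inter-fluorophore separation: collisional quenching is implausible
        assert core.diffusion_displacement(tr) == pytest.approx(0.20, abs=0.005)

    def test_unit_conversion(self):
        f = core.FluorophoreParams(name="x", tau0_ns=1.0, phi=0.5,
                                   diffusion_um2_s=1.0)
        assert core.diffusion_displacement(f) == pytest.approx(0.0632, abs=1e-4)

    def test_no_diffusion(self):
        f = core.FluorophoreParams(name="x", tau0_ns=1.0, phi=0.5,
                                   diffusion_um2_s=0.0)
        assert core.diffusion_displacement(f) == 0.0


class TestForsterRadius:
    @pytest.mark.parametrize(
        "J, phi, expected, tol",
        [
            (3.08e15, 0.93, 5.73, 0.02),  # printed 3-s.f. inputs: ~2% slack
            (2.13e15, 0.99, 5.51, 0.005),
        ],
    )
    def test_forster_radius_values(self, J, phi, expected, tol, cfg):
        assert core.forster_radius(J, phi, cfg) == pytest.approx(
            expected, rel=tol
        )

    def test_forbidden_orientation_gives_zero(self):
        cfg = core.ModelConfig(kappa_sq=0.0)
        assert core.forster_radius(1e15, 0.9, cfg) == 0.0

    @given(st.floats(1e13, 1e16), st.floats(0.05, 1.0))
    @settings(derandomize=True, deadline=None)
    def test_monotone_in_overlap_and_yield(self, J, phi):
        r = core.forster_radius(J, phi)
        assert core.forster_radius(J * 1.5, phi) > r
        assert core.forster_radius(J, min(phi * 1.1, 1.0)) >= r


class TestTrapStatistics:
    def test_trap_fraction_at_critical_concentration(self):
        rc = 1.7
        cc = core.critical_concentration(rc)
        assert core.trap_fraction(cc, rc) == pytest.approx(1 - np.exp(-1), rel=1e-12)

    def test_trap_fraction_derived_value(self):
        assert core.trap_fraction(0.028986, 2.02) == pytest.approx(0.3103, abs=5e-4)

    def test_prob_fret_half_at_forster_radius(self):
        r0 = 5.73
        cn = core.separation_to_number_density(r0)
        assert core.prob_fret(cn, r0) == pytest.approx(0.5, rel=1e-12)

    def test_prob_fret_at_one_percent(self):
        assert core.prob_fret(CN_1PCT, 5.73) == pytest.approx(0.770, abs=1e-3)

    def test_prob_ett_product(self):
        # published theory-figure parameters: R0 = 5.71 nm, R_C = 2.00 nm at 1%
        got = core.prob_ett(CN_1PCT, 5.71, 2.00)
        assert got == pytest.approx(0.7659 * 0.16651, abs=2e-4)

    def test_zero_concentration_probabilities(self):
        for fn in (
            lambda cn: core.trap_fraction(cn, 2.0),
            lambda cn: core.prob_fret(cn, 5.7),
            lambda cn: core.prob_ett(cn, 5.7, 2.0),
            lambda cn: core.qe_theoretical(cn, 2.0),
        ):
            assert fn(0.0) == 0.0

    @given(
        st.floats(1e-5, 0.5), st.floats(0.5, 8.0), st.floats(0.1, 4.0)
    )
    @settings(derandomize=True, deadline=None)
    def test_probability_bounds_and_ordering(self, cn, r0, rc):
        ft = core.trap_fraction(cn, rc)
        pf = core.prob_fret(cn, r0)
        pe = core.prob_ett(cn, r0, rc)
        for p in (ft, pf, pe):
            assert 0.0 <= p < 1.0
        assert pe <= min(pf, ft) + 1e-15

    def test_monotone_in_concentration(self):
        cn = np.linspace(0, 0.3, 100)
        for y in (
            core.trap_fraction(cn, 2.0),
            core.prob_fret(cn, 5.7),
            core.prob_ett(cn, 5.7, 2.0),
        ):
            assert np.all(np.diff(y) >= 0)

    def test_simplified_vs_exact_discrepancy_shrinks(self, cfg, tr):
        # the strong-FRET simplification (QE = f_T) deviates only at low
        # concentration: the absolute gap peaks below ~1.5% and decreases above
        c = np.linspace(0.1, 15.0, 300)
        cn = core.mol_percent_to_number_density(c, cfg)
        gap = np.abs(
            core.trap_fraction(cn, tr.critical_radius_nm)
            - core.prob_ett(cn, tr.forster_radius_nm, tr.critical_radius_nm)
        )
        assert c[np.argmax(gap)] < 1.5
        above = gap[c >= 1.5]
        assert np.all(np.diff(above) < 0)

    def test_relative_gap_below_quarter_above_1p5(self, cfg, tr):
        c = np.linspace(1.5, 15.0, 100)
        cn = core.mol_percent_to_number_density(c, cfg)
        ft = core.trap_fraction(cn, tr.critical_radius_nm)
        pe = core.prob_ett(cn, tr.forster_radius_nm, tr.critical_radius_nm)
        rel = np.abs(pe - ft) / ft
        assert np.all(rel < 0.25)
        assert np.all(np.diff(rel) < 0)


class TestQuenchingLaws:
    @pytest.mark.parametrize(
        "tau, tau0, expected",
        [(2.93, 4.23, 0.307), (4.23, 4.23, 0.0), (2.0, 4.0, 0.5)],
    )
    def test_qe_from_lifetimes(self, tau, tau0, expected):
        assert core.qe_from_lifetimes(tau, tau0) == pytest.approx(
            expected, abs=5e-4
        )

    def test_qe_clamps_noisy_lifetimes(self):
        with pytest.warns(UserWarning):
            assert core.qe_from_lifetimes(4.5, 4.23) == 0.0

    def test_lifetime_ratio_value(self):
        assert core.lifetime_ratio(0.028986, 2.02) == pytest.approx(0.690, abs=1e-3)

    def test_intensity_ratio_value(self):
        assert core.intensity_ratio(0.028986, 2.02) == pytest.approx(0.476, abs=1e-3)

    @given(st.floats(0.0, 0.5), st.floats(0.0, 4.0))
    @settings(derandomize=True, deadline=None)
    def test_intensity_is_lifetime_ratio_squared(self, cn, rc):
        lt = core.lifetime_ratio(cn, rc)
        assert core.intensity_ratio(cn, rc) == pytest.approx(lt**2, rel=1e-12)

    @given(st.floats(1e-4, 0.3), st.floats(0.2, 4.0))
    @settings(derandomize=True, deadline=None)
    def test_log_lifetime_linear_with_trap_area_slope(self, cn, rc):
        y = np.log(1.0 / core.lifetime_ratio(cn, rc))
        assert y == pytest.approx(np.pi * rc**2 * cn, rel=1e-10)

    def test_qe_theoretical_equals_trap_fraction(self):
        cn = np.linspace(0, 0.2, 20)
        np.testing.assert_allclose(
            core.qe_theoretical(cn, 2.02), core.trap_fraction(cn, 2.02)
        )

    def test_unquench_round_trip(self):
        # composing the forward quenching laws with the correction recovers F0
        cn, rc, tau0, f0 = 0.05, 2.02, 4.23, 1234.5
        f = f0 * core.intensity_ratio(cn, rc)
        tau = tau0 * core.lifetime_ratio(cn, rc)
        assert core.unquench_intensity(f, tau, tau0) == pytest.approx(
            f0, rel=1e-12
        )

    @pytest.mark.parametrize(
        "F, tau, tau0, expected",
        [(100.0, 2.0, 4.0, 400.0), (57.0, 4.23, 4.23, 57.0)],
    )
    def test_unquench_examples(self, F, tau, tau0, expected):
        assert core.unquench_intensity(F, tau, tau0) == pytest.approx(expected)

    def test_unquench_rejects_nonpositive_tau(self):
        with pytest.raises(ValueError):
            core.unquench_intensity(10.0, 0.0, 4.23)


class TestPresets:
    def test_preset_lookup_and_aliases(self):
        assert core.get_preset("TR").name == "texas_red"
        assert core.get_preset("BODIPY").critical_radius_nm == 2.70
        with pytest.raises(KeyError):
            core.get_preset("rhodamine")

    def test_preset_ordering_of_quenching_strength(self):
        rcs = {k: v.critical_radius_nm for k, v in core.PRESETS.items()}
        assert rcs["bodipy"] > rcs["texas_red"] > rcs["nbd"]

    def test_json_round_trip(self, tmp_path, tr):
        p = tmp_path / "tr.json"
        core.save_fluorophore(tr, p)
        assert core.load_fluorophore(p) == tr

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            core.FluorophoreParams(name="bad", tau0_ns=-1.0, phi=0.5)
        with pytest.raises(ValueError):
            core.FluorophoreParams(name="bad", tau0_ns=1.0, phi=1.5)
        with pytest.raises(ValueError):
            core.ModelConfig(kappa_sq=5.0)
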