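import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tacmpa import reference
from tacmpa.models import (InteractionSpec, RandomEffectsSpec, ResidualModel,
                           ResidualSpec, apply_etas, ehc_split,
                           interaction_factor, simulate_individual,
                           solve_integrated_ode, solve_tac_closed_form,
                           typical_cl_tac)

GRID = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 48.0, 72.0,
                 96.0, 120.0, 168.0])


class TestInteractionFactor:
    def test_exponential_slope_gives_13_7_percent_reduction_at_5(self):
        f = interaction_factor(InteractionSpec("exponential", slope=0.0294), 5.0)
        assert f == pytest.approx(0.8633, abs=5e-5)
        assert 100 * (1 - f) == pytest.approx(13.7, abs=0.05)

    @pytest.mark.parametrize("spec", [
        InteractionSpec("exponential", slope=0.0294),
        InteractionSpec("linear", slope=-0.02),
        InteractionSpec("emax", emax=-0.4, ec50=2.0),
    ])
    def test_zero_concentration_is_identity(self, spec):
        assert interaction_factor(spec, 0.0) == pytest.approx(1.0)

    def test_emax_asymptote_is_one_plus_emax(self):
        spec = InteractionSpec("emax", emax=-0.4, ec50=2.0)
        assert interaction_factor(spec, 1e9) == pytest.approx(0.6, rel=1e-6)

    @given(st.floats(0.0, 50.0), st.floats(0.0, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_exponential_form_strictly_decreasing(self, c1, c2):
        spec = InteractionSpec("exponential", slope=0.0294)
        lo, hi = sorted((c1, c2))
        assert interaction_factor(spec, hi) <= interaction_factor(spec, lo)
        if hi - lo > 1e-9:  # strict once the gap is float-representable
            assert interaction_factor(spec, hi) < interaction_factor(spec, lo)

    def test_negative_concentration_raises(self):
        with pytest.raises(ValueError):
            interaction_factor(InteractionSpec("exponential", slope=0.03), -1.0)


class TestEhcSplit:
    def test_integrated_model_values(self):
        assert ehc_split(0.251, 0.367) == pytest.approx(0.1455, abs=5e-4)

    def test_zero_fraction_gives_zero_secretion(self):
        assert ehc_split(0.3, 0.0) == 0.0

    def test_half_fraction_gives_equal_rates(self):
        assert ehc_split(0.3, 0.5) == pytest.approx(0.3)

    @given(st.floats(0.01, 5.0), st.floats(0.0, 0.99))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_recovers_fraction(self, k70, frac):
        k78 = ehc_split(k70, frac)
        assert k78 / (k70 + k78) == pytest.approx(frac, abs=1e-12) or frac == 0

    def test_fraction_of_one_raises(self):
        with pytest.raises(ValueError):
            ehc_split(0.3, 1.0)


class TestTypicalClTac:
    def test_nonexpresser_without_mpa_is_theta(self):
        spec = InteractionSpec("exponential", slope=0.0294)
        assert typical_cl_tac(13.8, False, 1.48, spec, 0.0) == pytest.approx(13.8)

    def test_expresser_fold_multiplies(self):
        spec = InteractionSpec("exponential", slope=0.0294)
        assert typical_cl_tac(13.8, True, 1.48, spec, 0.0) == pytest.approx(20.424)

    def test_interaction_reduces_clearance(self):
        spec = InteractionSpec("exponential", slope=0.0294)
        assert typical_cl_tac(13.8, False, 1.48, spec, 5.0) == \
            pytest.approx(13.8 * np.exp(-0.147), rel=1e-9)


class TestTacClosedForm:
    def test_zero_before_and_at_lag(self):
        p = reference.independent_spec().tac
        t = np.array([0.0, 0.3, p.tlag])
        assert np.all(solve_tac_closed_form(p, 5.0, t) == 0.0)

    def test_matches_ode_when_mmf_absent(self):
        spec = reference.integrated_spec()
        conc = solve_integrated_ode(spec, 5.0, 0.0, GRID)
        cf = solve_tac_closed_form(spec.tac, 5.0, GRID)
        mask = cf > 0
        assert np.max(np.abs(conc["TAC"][mask] - cf[mask]) / cf[mask]) < 1e-6

    def test_reduces_to_bateman_without_peripheral(self):
        p = dataclasses.replace(reference.independent_spec().tac,
                                k23=0.0, k32=0.0, tlag=0.0)
        t = GRID[1:]
        ke, ka, v = p.cl / p.v2, p.ka, p.v2
        bateman = 1000.0 * ka * 5.0 / v * (np.exp(-ke * t) - np.exp(-ka * t)) / (ka - ke)
        got = solve_tac_closed_form(p, 5.0, t)
        assert got == pytest.approx(bateman, rel=1e-9)


class TestIntegratedOde:
    def test_mass_balance_at_all_times(self):
        spec = reference.integrated_spec()
        _, am = solve_integrated_ode(spec, 5.0, 1000.0, GRID,
                                     return_amounts=True, rtol=1e-10, atol=1e-12)
        tac_total = am[:, 0] + am[:, 1] + am[:, 2] + am[:, 9]
        mpa_total = am[:, 3:9].sum(axis=1) + am[:, 10] + am[:, 11]
        assert np.max(np.abs(tac_total - 5.0) / 5.0) < 1e-8
        assert np.max(np.abs(mpa_total - 1000.0) / 1000.0) < 1e-8

    def test_gallbladder_emptying_creates_secondary_mpa_peak(self):
        spec = reference.integrated_spec()
        t = np.linspace(0, 24, 481)
        conc = solve_integrated_ode(spec, 0.0, 1000.0, t)
        after = conc["MPA"][t > spec.mpa.mtime1]
        # a local maximum exists after the gallbladder opens
        rising = np.diff(after) > 0
        falling = np.diff(after) < 0
        assert np.any(rising) and np.any(falling[np.argmax(rising):])

    def test_no_secondary_peak_without_recirculation(self):
        spec = reference.integrated_spec()
        for variant in (dataclasses.replace(spec.mpa, ehc_frac=0.0),
                        dataclasses.replace(spec.mpa, k84=1e-9)):
            s = dataclasses.replace(spec, mpa=variant)
            t = np.linspace(0, 48, 481)
            mpa = solve_integrated_ode(s, 0.0, 1000.0, t)["MPA"]
            peak = np.argmax(mpa)
            assert np.all(np.diff(mpa[peak:]) <= 1e-9)

    def test_dose_proportionality_of_linear_subsystem(self):
        spec = dataclasses.replace(reference.integrated_spec(),
                                   interaction=InteractionSpec("exponential", slope=0.0))
        c1 = solve_integrated_ode(spec, 0.0, 1000.0, GRID)
        c2 = solve_integrated_ode(spec, 0.0, 2000.0, GRID)
        for analyte in ("MPA", "MPAG", "AcMPAG"):
            m = c1[analyte] > 1e-10
            assert c2[analyte][m] / c1[analyte][m] == pytest.approx(2.0, rel=1e-6)

    def test_interaction_raises_tac_exposure(self):
        spec = reference.integrated_spec()
        alone = solve_integrated_ode(spec, 5.0, 0.0, GRID)["TAC"]
        combo = solve_integrated_ode(spec, 5.0, 1000.0, GRID)["TAC"]
        assert np.trapezoid(combo, GRID) > np.trapezoid(alone, GRID)


class TestSimulateIndividual:
    def _noise_free_spec(self):
        spec = reference.integrated_spec()
        return dataclasses.replace(
            spec, iiv=RandomEffectsSpec({}),
            residual=ResidualSpec({a: ResidualModel("add", sigma_add=1e-12)
                                   for a in ("TAC", "MPA", "MPAG", "AcMPAG")}))

    def test_zero_eta_zero_sigma_reproduces_typical_profile(self):
        spec = self._noise_free_spec()
        rng = np.random.default_rng(0)
        recs = simulate_individual(spec, False, 5.0, 0.0, GRID[1:], {}, rng,
                                   period=2)
        obs = np.array([r.value for r in recs if r.event_type == "observation"])
        expected = solve_tac_closed_form(spec.tac, 5.0, GRID[1:])
        assert obs == pytest.approx(expected, abs=1e-9)

    def test_median_individual_clearance_matches_typical(self):
        spec = reference.integrated_spec()
        rng = np.random.default_rng(42)
        om = np.sqrt(spec.iiv.omega2["cl_tac"])
        cls = spec.tac.cl * np.exp(rng.standard_normal(10000) * om)
        assert np.median(cls) == pytest.approx(spec.tac.cl, rel=0.02)

    def test_fixed_seed_reproduces_output(self):
        spec = reference.integrated_spec()
        out = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            recs = simulate_individual(spec, True, 5.0, 1000.0, GRID[1:],
                                       {"cl_tac": 0.2}, rng, period=3)
            out.append([(r.drug_or_analyte, r.time, r.value) for r in recs])
        assert out[0] == out[1]


class TestApplyEtas:
    def test_exponential_scaling(self):
        spec = reference.integrated_spec()
        ind = apply_etas(spec, {"cl_tac": np.log(2.0)})
        assert ind.tac.cl == pytest.approx(2.0 * spec.tac.cl)

    def test_ehc_fraction_capped_below_one(self):
        spec = reference.integrated_spec()
        ind = apply_etas(spec, {"ehc_frac": 5.0})
        assert ind.mpa.ehc_frac <= 0.999
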