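import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad, solve_ivp

from myelosim.chemo_toxicity import (
    DrugApplication,
    ToxicityParameterSet,
    chemo_pulse,
    combine_toxicities,
    delay_chain_rhs,
    erlang4_impulse_response,
    load_toxicity_table,
    prednisone_effect,
    save_toxicity_table,
    toxicity_function,
    wbc_from_anc,
)


def _application(times_day=(0.0,), infusion_h=1.0, **kw):
    return DrugApplication(drug="X", times_day=times_day, infusion_h=infusion_h, **kw)


class TestChemoPulse:
    def test_rectangular_values(self):
        app = _application(times_day=(0.0,), infusion_h=1.0)
        assert chemo_pulse(app, 0.5) == 1.0
        assert chemo_pulse(app, 2.0) == 0.0
        assert chemo_pulse(app, -0.1) == 0.0

    @pytest.mark.parametrize("t_inf", [1.0, 3.0, 24.0])
    def test_unit_area_per_injection(self, t_inf):
        app = _application(infusion_h=t_inf)
        area, _ = quad(lambda t: chemo_pulse(app, t), -1.0, t_inf + 1.0,
                       points=[0.0, t_inf], limit=200)
        assert area == pytest.approx(1.0, abs=1e-9)

    def test_two_injections_double_area(self):
        app = _application(times_day=(0.0, 1.0), infusion_h=1.0)
        area, _ = quad(lambda t: chemo_pulse(app, t), -1.0, 50.0,
                       points=[0.0, 1.0, 24.0, 25.0], limit=400)
        assert area == pytest.approx(2.0, abs=1e-8)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(t=st.floats(-10, 100, allow_nan=False))
    def test_total_function_nonnegative(self, t):
        app = _application(times_day=(0.0, 2.0), infusion_h=3.0)
        assert chemo_pulse(app, t) >= 0.0


class TestDelayChain:
    @pytest.mark.parametrize("k", [0.01, 0.1, 1.0])
    def test_erlang_impulse_oracle(self, k):
        """An impulse through the four-stage chain is the Erlang-4 density
        k (kt)^3 exp(-kt) / 3! (closed form), to < 1e-6 everywhere."""

        def rhs(t, y):
            deriv, _ = delay_chain_rhs(y, 0.0, k)
            return deriv

        horizon = 12.0 / k
        grid = np.linspace(0.0, horizon, 400)
        sol = solve_ivp(rhs, (0.0, horizon), [1.0, 0.0, 0.0, 0.0],
                        t_eval=grid, rtol=1e-11, atol=1e-13, method="LSODA")
        output = k * sol.y[3]
        expected = erlang4_impulse_response(grid, k)
        assert np.max(np.abs(output - expected)) < 1e-6

    def test_erlang_peak_location_and_value(self):
        t_peak = 3.0
        assert erlang4_impulse_response(t_peak, 1.0) == pytest.approx(
            27.0 * math.exp(-3.0) / 6.0
        )
        grid = np.linspace(0, 12, 4001)
        vals = erlang4_impulse_response(grid, 1.0)
        assert grid[np.argmax(vals)] == pytest.approx(3.0, abs=0.01)

    def test_chop_delay_peak_near_47_hours(self):
        k = 0.0635  # marrow delay rate of the CHOP combination
        grid = np.linspace(0, 300, 30001)
        vals = erlang4_impulse_response(grid, k)
        assert grid[np.argmax(vals)] == pytest.approx(3.0 / k, abs=0.1)

    @pytest.mark.parametrize("k,n_injections", [(0.0635, 1), (0.0635, 2), (0.3, 3)])
    def test_area_conservation(self, k, n_injections):
        """The chain output integrates to the number of injections."""
        app = _application(times_day=tuple(range(n_injections)), infusion_h=1.0)

        def rhs(t, y):
            deriv, out = delay_chain_rhs(y[:4], chemo_pulse(app, t), k)
            return np.append(deriv, out)  # 5th state accumulates the area

        horizon = 24.0 * (n_injections - 1) + 40.0 / k  # covers the Erlang tail
        sol = solve_ivp(rhs, (0.0, horizon), np.zeros(5), rtol=1e-10, atol=1e-12,
                        method="LSODA", max_step=0.5)
        assert sol.y[4, -1] == pytest.approx(n_injections, abs=1e-6)

    def test_linearity_superposition(self):
        """Two injections equal the sum of shifted single-injection responses."""
        k = 0.1
        grid = np.linspace(0.0, 200.0, 801)

        def response(times):
            app = _application(times_day=times, infusion_h=1.0)

            def rhs(t, y):
                deriv, _ = delay_chain_rhs(y, chemo_pulse(app, t), k)
                return deriv

            sol = solve_ivp(rhs, (0.0, 200.0), np.zeros(4), t_eval=grid,
                            rtol=1e-11, atol=1e-14, method="LSODA", max_step=0.25)
            return k * sol.y[3]

        both = response((0.0, 2.0))
        first = response((0.0,))
        second = response((2.0,))
        assert np.max(np.abs(both - first - second)) < 1e-8

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            delay_chain_rhs(np.zeros(4), 0.0, 0.0)


class TestToxicityFunction:
    def test_first_cycle_amplification(self):
        pset = ToxicityParameterSet(label="X", first_cycle_factor=2.0,
                                    k_delay_per_h=0.1, k_s=0.1, k_cg=0.0,
                                    k_pgb=0.0, k_mgb=0.0)
        before = toxicity_function(pset, "S", 0.05, t_h=10.0, t_second_application_h=100.0)
        after = toxicity_function(pset, "S", 0.05, t_h=200.0, t_second_application_h=100.0)
        assert before == pytest.approx(0.01)
        assert after == pytest.approx(0.005)

    def test_factor_one_is_identity_across_cycles(self):
        pset = ToxicityParameterSet(label="X", first_cycle_factor=1.0,
                                    k_delay_per_h=0.1, k_s=0.1, k_cg=0.0,
                                    k_pgb=0.0, k_mgb=0.0)
        assert toxicity_function(pset, "S", 0.05, 10.0, 100.0) == toxicity_function(
            pset, "S", 0.05, 200.0, 100.0
        )

    def test_single_application_keeps_factor_throughout(self):
        app = _application(times_day=(0.0,))
        assert app.second_application_h == math.inf

    def test_ta_first_cycle_factor_from_reference_table(self, toxicity_table):
        assert toxicity_table["TA"].first_cycle_factor == pytest.approx(2.01)

    def test_unknown_compartment_rejected(self, toxicity_table):
        with pytest.raises(ValueError):
            toxicity_function(toxicity_table["CHOPo"], "LY", 0.1, 0.0)


class TestCombineToxicities:
    def test_sum_and_empty(self):
        assert combine_toxicities([]) == 0.0
        assert combine_toxicities([0.3]) == pytest.approx(0.3)
        assert combine_toxicities([0.3, 0.3]) == pytest.approx(0.6)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            combine_toxicities([0.1, -0.2])


class TestWbcFromAnc:
    def test_no_lymphotoxicity_adds_constant_baseline(self):
        assert wbc_from_anc(5000.0, 0.0) == 8000.0

    def test_complete_lymphodepletion_limit(self):
        assert wbc_from_anc(1000.0, 1e6) == pytest.approx(1000.0)

    def test_formula_value(self):
        assert wbc_from_anc(1000.0, 1.0) == pytest.approx(1000.0 + 3000.0 * math.exp(-1))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            wbc_from_anc(-1.0, 0.0)
        with pytest.raises(ValueError):
            wbc_from_anc(1.0, -0.5)


class TestPrednisone:
    def test_multiplier_during_coverage_and_after_washout(self):
        app = _application(times_day=(0.0, 1.0), infusion_h=24.0, cytotoxic=False)
        assert prednisone_effect(app, 12.0, multiplier=0.7) == 0.7
        assert prednisone_effect(app, 30.0, multiplier=0.7) == 0.7  # day 2 + washout
        assert prednisone_effect(app, 100.0, multiplier=0.7) == 1.0

    def test_cytotoxic_drug_rejected(self):
        with pytest.raises(ValueError):
            prednisone_effect(_application(cytotoxic=True), 0.0)

    def test_granulocytes_not_lower_with_prednisone(self, toxicity_table):
        """Pointwise, the prednisone arm has at least the granulocytes of the
        prednisone-free arm, all else equal."""
        from myelosim.regimens import CycleAgent, Regimen
        from myelosim.sim_engine import simulate

        agents = (CycleAgent(drug="combo", days=(1,), toxicity_label="CHOPo"),)
        pred = CycleAgent(drug="prednisone", days=(1, 2, 3, 4, 5), cytotoxic=False)
        base = Regimen(name="no-pred", cycle_days=21, n_cycles=1, agents=agents)
        with_pred = Regimen(name="pred", cycle_days=21, n_cycles=1, agents=agents + (pred,))
        r0 = simulate(base, horizon_days=21)
        r1 = simulate(with_pred, horizon_days=21)
        gra0 = np.interp(r1.time_day, r0.time_day, r0.cells[4])
        covered = r1.time_day <= 5.0  # prednisone days
        assert np.all(r1.cells[4][covered] >= gra0[covered] - 1e-9)
        assert r1.cells[4][covered].max() > gra0[covered].max()


class TestReferenceTable:
    def test_row_count_and_spot_checks(self, toxicity_table):
        assert len(toxicity_table) == 22
        chop_elderly = toxicity_table["CHOPo"]
        assert chop_elderly.k_s == pytest.approx(2.16e-1)
        assert chop_elderly.first_cycle_factor == pytest.approx(1.11)
        assert chop_elderly.k_delay_per_h == pytest.approx(6.35e-2)
        assert chop_elderly.k_ly == pytest.approx(12.7)

    def test_anc_only_rows_have_no_lymphocyte_branch(self, toxicity_table):
        anc_only = {l for l, s in toxicity_table.items() if not s.has_lymphocyte_toxicity}
        assert anc_only == {"VB", "CP", "TA", "Cyta", "Cisp", "ET40"}

    def test_round_trip(self, toxicity_table, tmp_path):
        path = tmp_path / "table.csv"
        save_toxicity_table(toxicity_table, path)
        again = load_toxicity_table(path)
        assert again == toxicity_table

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ToxicityParameterSet(label="bad", first_cycle_factor=0.9,
                                 k_delay_per_h=0.1, k_s=0.1, k_cg=0.0,
                                 k_pgb=0.0, k_mgb=0.0)
        with pytest.raises(ValueError):
            ToxicityParameterSet(label="bad", first_cycle_factor=1.0,
                                 k_delay_per_h=0.1, k_s=-0.1, k_cg=0.0,
                                 k_pgb=0.0, k_mgb=0.0)
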