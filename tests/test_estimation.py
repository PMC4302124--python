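import math

import numpy as np
import pytest

from myelosim.chemo_toxicity import load_toxicity_table
from myelosim.estimation import (
    VALIDATION_SCENARIOS,
    EsOptions,
    FitScenario,
    ObservedSeries,
    cost,
    default_protocol,
    evolution_strategy,
    fit_toxicity,
    read_observed_csv,
    stepwise_protocol,
    write_observed_csv,
)
from myelosim.fixtures import NoiseModel, generate_observed
from myelosim.regimens import get_regimen


def _series(days, values, **kw):
    return ObservedSeries(days=days, values=values, **kw)


class TestCost:
    def test_exact_match_is_zero(self):
        t = np.linspace(0, 10, 101)
        data = _series((0, 5, 10), (4000, 4000, 4000))
        assert cost(t, np.full_like(t, 4000.0), data) == 0.0

    def test_constant_ratio_closed_form(self):
        """model = 2 x data over 10 days costs 10 ln 2."""
        t = np.linspace(0, 10, 101)
        data = _series((0, 5, 10), (4000, 4000, 4000))
        value = cost(t, np.full_like(t, 8000.0), data)
        assert value == pytest.approx(10 * math.log(2), rel=1e-9)

    def test_piecewise_constant_oracle(self):
        """Data 1000 for 4 days then 2000 for 6; model constant 2000."""
        t = np.linspace(0, 10, 1001)
        data = _series((0, 4, 4.0000001, 10), (1000, 1000, 2000, 2000))
        value = cost(t, np.full_like(t, 2000.0), data)
        assert value == pytest.approx(4 * math.log(2), abs=1e-3)

    def test_strictly_increasing_in_single_day_deviation(self):
        t = np.linspace(0, 10, 101)
        data = _series((0, 5, 10), (4000, 4000, 4000))
        costs = []
        for factor in (1.1, 1.3, 2.0):
            model = np.full_like(t, 4000.0)
            model[np.abs(t - 5.0) < 1.0] *= factor
            costs.append(cost(t, model, data))
        assert costs[0] > 0
        assert costs == sorted(costs)

    def test_nonpositive_model_rejected(self):
        t = np.linspace(0, 10, 11)
        data = _series((0, 10), (100, 100))
        with pytest.raises(ValueError):
            cost(t, np.zeros_like(t), data)

    def test_model_must_span_data(self):
        t = np.linspace(0, 5, 11)
        data = _series((0, 10), (100, 100))
        with pytest.raises(ValueError, match="span"):
            cost(t, np.ones_like(t), data)


class TestObservedSeries:
    def test_validation(self):
        with pytest.raises(ValueError):
            _series((3, 1), (100, 100))       # days decreasing
        with pytest.raises(ValueError):
            _series((1, 2), (100, -5))        # non-positive value
        with pytest.raises(ValueError):
            _series((1, 2), (100, 100), count_type="PLT")

    def test_csv_round_trip(self, tmp_path):
        series = [
            _series((1, 3, 5), (4000, 2500, 3200), count_type="WBC", scenario_id="a"),
            _series((1, 4), (1500, 2500), count_type="ANC", scenario_id="b"),
        ]
        path = tmp_path / "obs.csv"
        write_observed_csv(series, path)
        again = read_observed_csv(path)
        assert sorted(s.scenario_id for s in again) == ["a", "b"]
        assert {s.scenario_id: s.values for s in again} == {
            "a": (4000.0, 2500.0, 3200.0), "b": (1500.0, 2500.0),
        }


class TestEvolutionStrategy:
    def test_minimizes_shifted_sphere(self):
        target = np.array([0.3, -1.2, 2.0])
        x, f, trace = evolution_strategy(
            lambda z: float(np.sum((z - target) ** 2)),
            lower=np.full(3, -5.0), upper=np.full(3, 5.0), seed=7,
            options=EsOptions(mu=5, lam=20, generations=80),
        )
        assert f < 1e-4
        assert np.allclose(x, target, atol=0.02)
        bests = [b for _, b in trace]
        assert bests == sorted(bests, reverse=True)  # monotone improvement

    def test_seeded_determinism(self):
        func = lambda z: float(np.sum(z**2))
        a = evolution_strategy(func, np.full(2, -1.0), np.full(2, 1.0), seed=11,
                               options=EsOptions(generations=15))
        b = evolution_strategy(func, np.full(2, -1.0), np.full(2, 1.0), seed=11,
                               options=EsOptions(generations=15))
        assert np.array_equal(a[0], b[0]) and a[1] == b[1]

    def test_respects_bounds(self):
        x, _, _ = evolution_strategy(
            lambda z: float(-z.sum()), np.zeros(2), np.ones(2), seed=1,
            options=EsOptions(generations=20),
        )
        assert np.all(x >= 0.0) and np.all(x <= 1.0)


class TestFitToxicity:
    def test_empty_free_set_returns_frozen_cost(self, toxicity_table, fast_solver):
        regimen = get_regimen("CHOP", risk_group="elderly", cycle_days=21, n_cycles=1)
        series = generate_observed(regimen, noise=NoiseModel(sigma=0.0),
                                   count_type="WBC", solver=fast_solver)
        result = fit_toxicity(
            [FitScenario(regimen=regimen, series=series)],
            free={}, initial=toxicity_table, frozen=toxicity_table,
            solver=fast_solver,
        )
        assert result.sets == dict(toxicity_table)
        assert result.cost == result.initial_cost
        assert result.cost < 1e-6  # data were generated by these parameters

    def test_seeded_determinism(self, toxicity_table, fast_solver):
        regimen = get_regimen("CHOP", risk_group="elderly", cycle_days=21, n_cycles=1)
        series = generate_observed(regimen, noise=NoiseModel(sigma=0.1, seed=5),
                                   count_type="WBC", solver=fast_solver)
        kwargs = dict(
            free={"CHOPo": ("k_s",)}, initial=toxicity_table, seed=4,
            solver=fast_solver, es_options=EsOptions(mu=2, lam=4, generations=3),
        )
        a = fit_toxicity([FitScenario(regimen=regimen, series=series)], **kwargs)
        b = fit_toxicity([FitScenario(regimen=regimen, series=series)], **kwargs)
        assert a.sets["CHOPo"] == b.sets["CHOPo"]
        assert a.cost == b.cost

    def test_infeasible_ordering_rejected_before_optimization(self, toxicity_table):
        with pytest.raises(ValueError, match="infeasible ordering"):
            fit_toxicity(
                [], free={"CHOPy": ("k_s",)}, initial=toxicity_table,
                frozen={"CHOPo": toxicity_table["CHOPo"]},
                bounds={("CHOPy", "k_s"): (1e-7, 1e-3)},
                ordering=[("CHOPy", "CHOPo")],
            )

    def test_unknown_field_rejected(self, toxicity_table):
        with pytest.raises(ValueError, match="unknown estimable field"):
            fit_toxicity([], free={"CHOPo": ("k_platelet",)}, initial=toxicity_table)


class TestStepwiseProtocol:
    def test_default_protocol_excludes_validation_scenarios(self):
        used = set()
        for step in default_protocol():
            used.update(step.scenario_ids)
        assert used.isdisjoint(VALIDATION_SCENARIOS)
        assert used <= set(range(1, 34))

    def test_default_protocol_labels_exist(self, toxicity_table):
        for step in default_protocol():
            for label in step.free:
                assert label in toxicity_table
            for upper, lower in step.ordering:
                assert upper in toxicity_table and lower in toxicity_table

    def test_missing_data_rejected(self, toxicity_table):
        with pytest.raises(ValueError, match="no data for scenarios"):
            stepwise_protocol(default_protocol()[:1], data={})

    def test_validation_scenario_use_rejected(self):
        from myelosim.estimation import FitStep

        step = FitStep("bad", (12,), {"CHOPo": ("k_s",)})
        with pytest.raises(ValueError, match="validation scenarios"):
            stepwise_protocol([step], data={12: None})

    def test_two_step_recovery_freezes_step_one(self, toxicity_table, fast_solver):
        """A second fitting step must leave frozen step-one parameters
        bit-identical while estimating the new drug's increment."""
        chop = get_regimen("CHOP", risk_group="young", cycle_days=21, n_cycles=1)
        choep = get_regimen("CHOEP", risk_group="young", cycle_days=21, n_cycles=1)
        data = {
            14: generate_observed(chop, noise=NoiseModel(sigma=0.0),
                                  count_type="WBC", solver=fast_solver),
            16: generate_observed(choep, noise=NoiseModel(sigma=0.0),
                                  count_type="WBC", solver=fast_solver),
        }
        from myelosim.estimation import FitStep

        steps = [
            FitStep("chop", (14,), {"CHOPy": ("k_s",)}),
            FitStep("choep", (16,), {"ETy": ("k_pgb",)}),
        ]

        def factory(sid):
            return {14: chop, 16: choep}[sid]

        results = stepwise_protocol(
            steps, data, seed=2, solver=fast_solver,
            es_options=EsOptions(mu=3, lam=8, generations=10),
            regimen_factory=factory,
        )
        fitted_chop = results["chop"].sets["CHOPy"]
        assert results["choep"].frozen["CHOPy"] == fitted_chop
        assert results["choep"].sets["CHOPy"] == fitted_chop
        # both steps converge to the generating parameters (noise-free data)
        assert abs(fitted_chop.k_s / toxicity_table["CHOPy"].k_s - 1) < 0.05
        assert abs(results["choep"].sets["ETy"].k_pgb
                   / toxicity_table["ETy"].k_pgb - 1) < 0.05
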