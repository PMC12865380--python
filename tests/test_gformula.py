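"""Sequential fitting structure, the intervention rule, and G-computation."""

import warnings

import numpy as np
import pandas as pd
import pytest

from gfbart.benchmark import oracle_model_set, scenario_config, truth_oracle
from gfbart.cohort import FixtureConfig, generate_cohort
from gfbart.data_model import CohortTable, CovariateSchema, RegimeSpec, TriangularPrior
from gfbart.gformula import (
    apply_intervention,
    fit_sequential,
    gcomp_estimates,
    simulate_regime,
)
from gfbart.soft_bart import BartHypers, McmcConfig

from conftest import build_cohort_df

TINY = McmcConfig(n_warmup=30, n_save=10, thin=1, seed=4)
SMALL_TREES = BartHypers(n_trees=10)


class TestApplyIntervention:
    @pytest.mark.parametrize("a_star, tau, delta, expected", [
        (120.0, 130.0, -30.0, 120.0),  # below threshold: untouched
        (150.0, 140.0, 0.0, 150.0),    # null shift
        (150.0, 140.0, -20.0, 130.0),  # downward shift by 20 units
    ])
    def test_rule(self, a_star, tau, delta, expected):
        assert apply_intervention(a_star, tau, delta) == pytest.approx(expected)

    def test_vectorized(self):
        out = apply_intervention(np.array([120.0, 150.0]), 130.0, -5.0)
        np.testing.assert_allclose(out, [120.0, 145.0])

    def test_positive_delta_rejected(self):
        with pytest.raises(ValueError):
            apply_intervention(150.0, 140.0, 2.0)


class TestFitStructure:
    def test_no_deaths_no_dropout_skips_those_models(self, simple_schema, rng):
        s = [[1, 1, 1]] * 12
        df = build_cohort_df(s, s, simple_schema, rng)
        ct = CohortTable(df, simple_schema)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ms = fit_sequential(ct, "uniform", TINY, SMALL_TREES)
        assert not ms.survival and not ms.response
        pc = simulate_regime(ms, RegimeSpec("natural_course"), 50, 0, seed=1)
        assert pc.psi == 1.0

    def test_benchmark_cohort_structure(self):
        """No deaths in the simulation design: response, covariate and
        outcome models only, with the outcome at the final wave."""
        from gfbart.benchmark import make_cohort

        cohort, _ = make_cohort(scenario_config("A", n=80, seed=0), 3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ms = fit_sequential(cohort, "uniform", TINY, SMALL_TREES)
        assert not ms.survival
        assert not ms.treatment
        assert set(ms.response) == {2, 3, 4}
        assert sorted(set(k for k, _ in ms.covariate)) == [2, 3, 4]
        assert set(ms.outcome) == {4}

    def test_single_wave_collapses_to_outcome_model(self, rng):
        schema = CovariateSchema(("z",), ("continuous",))
        s = [[1]] * 15
        df = build_cohort_df(s, s, schema, rng, with_treatment=False)
        ct = CohortTable(df, schema, has_treatment=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ms = fit_sequential(ct, "uniform", TINY, SMALL_TREES)
        assert not ms.survival and not ms.response and not ms.treatment
        assert not ms.covariate
        assert set(ms.outcome) == {1}


@pytest.fixture(scope="module")
def fitted_fixture_models():
    cohort = generate_cohort(FixtureConfig(n=250, seed=9))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_sequential(
            cohort, "dart",
            McmcConfig(n_warmup=50, n_save=20, thin=1, seed=2),
            BartHypers(n_trees=15),
        )


class TestSimulation:
    def test_null_intervention_reproduces_natural_course(self, fitted_fixture_models):
        ms = fitted_fixture_models
        g0 = RegimeSpec("natural_course")
        gnull = RegimeSpec("incremental_threshold", tau=np.inf,
                           shift_prior=TriangularPrior(-44, -44, 0))
        a = simulate_regime(ms, g0, 300, 3, seed=7)
        b = simulate_regime(ms, gnull, 300, 3, seed=7)
        assert a.survivor_mean == b.survivor_mean
        assert a.psi == b.psi
        np.testing.assert_array_equal(a.alive, b.alive)

    def test_low_threshold_shifts_every_treated_wave(self, fitted_fixture_models):
        ms = fitted_fixture_models
        gall = RegimeSpec("incremental_threshold", tau=-1e6,
                          shift_prior=TriangularPrior(-10.0, -10.0, -10.0))
        pc = simulate_regime(ms, gall, 200, 0, seed=3)
        for k in range(1, ms.T + 1):
            rows = ~np.isnan(pc.state[f"a{k}"])
            np.testing.assert_allclose(
                pc.state[f"a{k}"][rows], pc.state[f"astar{k}"][rows] - 10.0)

    def test_treatment_stochastically_lowered(self, fitted_fixture_models):
        """Mean treatment under the shift regime <= natural course, per wave."""
        ms = fitted_fixture_models
        gs = RegimeSpec("incremental_threshold", tau=130.0,
                        shift_prior=TriangularPrior(-44.0, -44.0, 0.0))
        pc0 = simulate_regime(ms, RegimeSpec("natural_course"), 500, 1, seed=5)
        pcs = simulate_regime(ms, gs, 500, 1, seed=5)
        for k in range(1, ms.T + 1):
            m0 = np.nanmean(pc0.state[f"a{k}"])
            m1 = np.nanmean(pcs.state[f"a{k}"])
            assert m1 <= m0 + 1e-9

    def test_monotone_death_and_valid_psi(self, fitted_fixture_models):
        ms = fitted_fixture_models
        draws = gcomp_estimates(ms, RegimeSpec("natural_course"), 400, 5, seed=2)
        for d in draws:
            assert 0.0 <= d.psi <= 1.0
        pc = simulate_regime(ms, RegimeSpec("natural_course"), 400, 0, seed=2)
        # a dead pseudo-subject never re-enters: NaN pattern is monotone
        aliveness = ~np.isnan(
            np.column_stack([pc.state[f"a{k}"] for k in range(1, ms.T + 1)]))
        assert (np.diff(aliveness.astype(int), axis=1) <= 0).all()

    def test_invalid_nstar(self, fitted_fixture_models):
        with pytest.raises(ValueError):
            simulate_regime(fitted_fixture_models,
                            RegimeSpec("natural_course"), 0, 0, seed=1)


class TestOracleGcomp:
    def test_oracle_models_recover_truth(self):
        """True generator conditionals in the G-comp engine reproduce the
        truth oracle within Monte-Carlo error (engine correctness)."""
        cfg = scenario_config("A", n=250, seed=0)
        truth, se_t = truth_oracle(cfg, N_mc=400_000, seed=1)
        oms = oracle_model_set(cfg)
        pc = simulate_regime(oms, RegimeSpec("natural_course"), 20_000, 0, seed=2)
        se_mc = 7.0 / np.sqrt(20_000)  # sd of f over histories is ~7
        assert pc.survivor_mean == pytest.approx(truth, abs=3 * (se_mc + se_t))

    def test_mc_error_scales_with_nstar(self):
        """Doubling N* roughly halves the variance of the survivor mean."""
        cfg = scenario_config("A", n=100, seed=0)
        oms = oracle_model_set(cfg)

        def spread(n_star, base):
            vals = [simulate_regime(oms, RegimeSpec("natural_course"),
                                    n_star, 0, seed=base + i).survivor_mean
                    for i in range(40)]
            return np.var(vals)

        v1, v2 = spread(400, 100), spread(800, 200)
        assert v2 < v1 * 0.85  # ~0.5 expected; generous for 40-rep noise
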