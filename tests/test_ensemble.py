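"""Genetic-algorithm ensemble selection and population analysis."""

import numpy as np
import pytest

import ubconj as u
from ubconj import synthetic as syn
from ubconj.ensemble import (
    GAConfig,
    EnsembleSolution,
    _population_chi2,
    run_ga,
    select_best,
    summarize_ensemble,
)
from ubconj.saxs import ScatteringCurve

FAST = GAConfig(generations=300, patience=100)


def _fake_pool(n=30, K=60, seed=0):
    """Synthetic pool curve matrix: smooth decaying curves of varying width."""
    rng = np.random.default_rng(seed)
    q = np.linspace(0.005, 0.5, K)
    widths = rng.uniform(5.0, 30.0, size=n)
    return q, np.exp(-np.outer(widths, q) ** 1.5)


class TestRunGA:
    def test_noise_free_single_member_recovered(self):
        q, pool_I = _fake_pool()
        exp = ScatteringCurve(q, pool_I[7], 0.01 * pool_I[7])
        sol = run_ga(pool_I, exp, FAST, rng=np.random.default_rng(3))
        assert set(sol.members.tolist()) == {7}
        assert sol.chi2 < 1e-6

    def test_chi2_never_worse_than_best_single(self):
        q, pool_I = _fake_pool(seed=1)
        rng = np.random.default_rng(9)
        exp_I = 0.6 * pool_I[3] + 0.4 * pool_I[20]
        exp = ScatteringCurve(q, exp_I, 0.01 * exp_I)
        sol = run_ga(pool_I, exp, FAST, rng=rng)
        best_single = _population_chi2(
            np.arange(pool_I.shape[0])[:, None], pool_I, exp.I, exp.sigma
        )[0].min()
        assert sol.chi2 <= best_single + 1e-12

    def test_monotone_convergence_trace(self):
        q, pool_I = _fake_pool(seed=2)
        exp_I = pool_I[[4, 9, 15]].mean(axis=0)
        exp = ScatteringCurve(q, exp_I, 0.01 * exp_I)
        sol = run_ga(pool_I, exp, FAST, rng=np.random.default_rng(0))
        assert np.all(np.diff(sol.trace) <= 1e-15)

    def test_constructed_mixture_weight_recovery(self, big_pool, big_pool_curves,
                                                 ensemble_qgrid):
        # 50:50 average of two well-separated pool members + 1% noise: the
        # selected weights on those members or their shape-equivalent
        # neighbors (conformers within 1 A in Rg, the resolution scale of
        # the population analysis) dominate
        pool_I = big_pool_curves
        rg = big_pool.rg
        ja = int(np.argmin(np.abs(rg - 21.8)))
        jb = int(np.argmin(np.abs(rg - 27.3)))
        truth = 0.5 * pool_I[ja] + 0.5 * pool_I[jb]
        sig = 0.01 * truth
        rng = np.random.default_rng(8)
        exp = ScatteringCurve(ensemble_qgrid, truth + rng.normal(scale=sig), sig)
        sol = select_best(pool_I, exp, GAConfig(runs=5, seed=2))
        neighbors = set(np.flatnonzero(
            (np.abs(rg - rg[ja]) <= 1.0) | (np.abs(rg - rg[jb]) <= 1.0)
        ).tolist())
        mass = sum(frac for idx, frac in sol.weights.items() if idx in neighbors)
        assert mass >= 0.7

    def test_empty_pool_rejected(self):
        exp = ScatteringCurve(np.linspace(0.01, 0.2, 10), np.ones(10), np.ones(10))
        with pytest.raises(ValueError):
            run_ga(np.empty((0, 10)), exp, FAST, rng=np.random.default_rng(0))


class TestSelectBest:
    def test_returns_minimum_over_runs(self):
        q, pool_I = _fake_pool(seed=3)
        exp_I = pool_I[[2, 11]].mean(axis=0)
        exp = ScatteringCurve(q, exp_I, 0.02 * exp_I)
        cfg = GAConfig(runs=5, seed=17, generations=200, patience=80)
        sol = select_best(pool_I, exp, cfg)
        assert len(sol.per_run_chi2) == 5
        assert sol.chi2 == sol.per_run_chi2.min()

    def test_single_run_equals_substream_zero(self):
        q, pool_I = _fake_pool(seed=4)
        exp = ScatteringCurve(q, pool_I[5], 0.01 * pool_I[5])
        cfg = GAConfig(runs=1, seed=23, generations=150, patience=60)
        a = select_best(pool_I, exp, cfg)
        b = run_ga(pool_I, exp, cfg, rng=np.random.default_rng([23, 0]), run_id=0)
        assert np.array_equal(a.members, b.members)

    def test_deterministic(self):
        q, pool_I = _fake_pool(seed=5)
        exp_I = pool_I[[1, 8]].mean(axis=0)
        exp = ScatteringCurve(q, exp_I, 0.01 * exp_I)
        cfg = GAConfig(runs=3, seed=31, generations=150, patience=60)
        a, b = select_best(pool_I, exp, cfg), select_best(pool_I, exp, cfg)
        assert np.array_equal(a.members, b.members) and a.chi2 == b.chi2


class TestSummarize:
    def test_single_repeated_member_single_mode(self, big_pool):
        j = 42
        sol = EnsembleSolution(members=np.full(20, j), scale=1.0, chi2=0.0,
                               run_id=0, trace=np.zeros(1))
        summ = summarize_ensemble(big_pool, sol)
        assert len(summ.rg_modes) == 1
        assert summ.rg_modes[0][0] == pytest.approx(big_pool.conformers[j].rg, abs=1.0)

    def test_histogram_masses_normalized(self, big_pool):
        sol = EnsembleSolution(members=np.arange(20), scale=1.0, chi2=0.0,
                               run_id=0, trace=np.zeros(1))
        summ = summarize_ensemble(big_pool, sol)
        assert sum(m for _, m in summ.rg_modes) == pytest.approx(1.0)
        assert sum(m for _, m in summ.dmax_modes) == pytest.approx(1.0)

    def test_two_state_recovery_well_separated(self, big_pool, big_pool_curves,
                                               ensemble_qgrid):
        """End-to-end: two conformational states >5 A apart in Rg are recovered
        as two modes with correct locations and mass fractions in >=90% of
        seeded replicates."""
        window_a, window_b = (21.3, 22.3), (26.8, 27.8)
        npass = 0
        for rep in range(10):
            curve, truth = syn.make_two_state_dataset(
                big_pool, window_a, window_b, 0.5,
                syn.NoiseModel(c=0.01, seed=300 + rep), ensemble_qgrid,
            )
            sol = select_best(big_pool_curves, curve, GAConfig(runs=20, seed=rep))
            modes = summarize_ensemble(big_pool, sol).rg_modes
            true_a = np.mean(truth.params["rg_a"])
            true_b = np.mean(truth.params["rg_b"])
            ok = (
                len(modes) == 2
                and abs(modes[0][0] - true_a) <= 1.0
                and abs(modes[1][0] - true_b) <= 1.0
                and abs(modes[0][1] - 0.5) <= 0.15
                and abs(modes[1][1] - 0.5) <= 0.15
            )
            npass += ok
        assert npass >= 9

    def test_one_state_dataset_single_mode(self, big_pool, big_pool_curves,
                                           ensemble_qgrid):
        for rep in range(3):
            curve, _ = syn.make_two_state_dataset(
                big_pool, (22.5, 23.5), (26.5, 27.5), 1.0,
                syn.NoiseModel(c=0.01, seed=400 + rep), ensemble_qgrid,
            )
            sol = select_best(big_pool_curves, curve, GAConfig(runs=20, seed=rep))
            modes = summarize_ensemble(big_pool, sol).rg_modes
            assert len(modes) == 1
            assert abs(modes[0][0] - 23.0) <= 1.0


class TestGAConfig:
    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            GAConfig(mutation_rate=1.5)
        with pytest.raises(ValueError):
            GAConfig(population=0)
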