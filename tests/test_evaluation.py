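import itertools

import numpy as np
import pytest

from vbfinemap.credible import CredibleSet
from vbfinemap.evaluate import (
    cs_metrics,
    grid_preset,
    pr_auc,
    residualize_covariates,
    roc_auc,
    run_grid,
    top_snp_r2,
)
from vbfinemap.simulate import SimConfig


def auc_by_pair_enumeration(q, truth):
    """Mann-Whitney AUC by enumerating all positive-negative pairs."""
    pos = [s for s, t in zip(q, truth) if t == 1]
    neg = [s for s, t in zip(q, truth) if t == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def pr_auc_by_threshold_enumeration(q, truth):
    """Average precision by stepping through every distinct threshold."""
    order = np.argsort(-np.asarray(q), kind="stable")
    truth = np.asarray(truth)[order]
    qs = np.asarray(q)[order]
    total_pos = truth.sum()
    ap = 0.0
    tp = 0
    i = 0
    n = len(qs)
    while i < n:
        j = i
        while j < n and qs[j] == qs[i]:
            j += 1
        new_tp = truth[i:j].sum()
        tp += new_tp
        precision = tp / j
        ap += precision * (new_tp / total_pos)
        i = j
    return ap


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_give_half(self):
        assert roc_auc([0.3, 0.3, 0.3, 0.3], [1, 0, 1, 0]) == 0.5

    def test_three_snp_case(self):
        assert roc_auc([0.9, 0.8, 0.1], [1, 0, 1]) == pytest.approx(0.5)

    def test_matches_pair_enumeration(self, rng):
        for _ in range(20):
            m = rng.integers(4, 12)
            truth = np.zeros(m, dtype=int)
            truth[rng.choice(m, size=rng.integers(1, m), replace=False)] = 0
            truth[rng.choice(m, size=rng.integers(1, m - 1), replace=False)] = 1
            if truth.sum() in (0, m):
                continue
            q = np.round(rng.uniform(0, 1, m), 1)  # coarse grid forces ties
            assert roc_auc(q, truth) == pytest.approx(auc_by_pair_enumeration(q, truth))

    def test_degenerate_truth_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestPrAuc:
    def test_perfect_separation_single_positive(self):
        q = np.linspace(0, 0.8, 10)
        truth = np.zeros(10, dtype=int)
        truth[9] = 1
        q[9] = 0.99
        assert pr_auc(q, truth) == 1.0

    def test_constant_scores_give_prevalence(self):
        truth = np.array([1, 0, 0, 1, 0])
        assert pr_auc(np.full(5, 0.2), truth) == pytest.approx(0.4)

    def test_matches_threshold_enumeration(self, rng):
        for _ in range(20):
            m = int(rng.integers(4, 12))
            truth = (rng.uniform(size=m) < 0.4).astype(int)
            if truth.sum() == 0:
                truth[0] = 1
            q = np.round(rng.uniform(0, 1, m), 1)
            assert pr_auc(q, truth) == pytest.approx(
                pr_auc_by_threshold_enumeration(q, truth)
            )

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_auc([0.1, 0.2], [0, 0])


class TestCsMetrics:
    def test_single_hit(self):
        sets = [CredibleSet(members=[3], pk=0.99, purity=1.0)]
        cov, pow_, size = cs_metrics(sets, np.array([0, 0, 0, 1, 0]))
        assert (cov, pow_, size) == (1.0, 1.0, 1.0)

    def test_half_coverage_half_power(self):
        sets = [
            CredibleSet(members=[0], pk=0.99, purity=1.0),
            CredibleSet(members=[2], pk=0.99, purity=1.0),
        ]
        cov, pow_, _ = cs_metrics(sets, np.array([1, 1, 0]))
        assert cov == 0.5 and pow_ == 0.5

    def test_no_sets(self):
        cov, pow_, size = cs_metrics([], np.array([1, 0, 1, 0, 1]))
        assert cov is None and pow_ == 0.0 and size is None

    def test_power_capped_at_one(self, rng):
        truth = np.array([1, 1, 0, 0])
        sets = [CredibleSet(members=[0, 1], pk=1.9, purity=0.9)]
        _, pow_, _ = cs_metrics(sets, truth)
        assert pow_ == 1.0


class TestResidualize:
    def test_intercept_is_centering(self, rng):
        y = rng.normal(size=30)
        res = residualize_covariates(y, np.ones((30, 1)))
        np.testing.assert_allclose(res, y - y.mean(), atol=1e-12)

    def test_residual_orthogonal_to_covariates(self, rng):
        c = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        res = residualize_covariates(y, c)
        np.testing.assert_allclose(c.T @ res, 0.0, atol=1e-8)

    def test_idempotent(self, rng):
        c = rng.normal(size=(40, 2))
        y = rng.normal(size=40)
        once = residualize_covariates(y, c)
        twice = residualize_covariates(once, c)
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_rank_deficient_warns(self, rng):
        base = rng.normal(size=(30, 1))
        c = np.hstack([base, base])
        with pytest.warns(UserWarning, match="rank"):
            residualize_covariates(rng.normal(size=30), c)


class TestTopSnpR2:
    def test_proportional_phenotype_gives_one(self, rng):
        g = rng.integers(0, 3, size=(100, 5)).astype(float)
        q = np.array([0.1, 0.9, 0.2, 0.1, 0.1])
        y_tr = 2.0 * g[:50, 1]
        y_te = 3.0 * g[50:, 1]
        assert top_snp_r2(q, g[:50], y_tr, g[50:], y_te) == pytest.approx(1.0)

    def test_independent_phenotype_near_zero(self, rng):
        g = rng.integers(0, 3, size=(20000, 3)).astype(float)
        q = np.array([0.5, 0.1, 0.1])
        y = rng.normal(size=20000)
        r2 = top_snp_r2(q, g[:10000], y[:10000], g[10000:], y[10000:])
        assert r2 < 0.01

    def test_invariant_to_y_train_scale(self, rng):
        g = rng.integers(0, 3, size=(80, 4)).astype(float)
        q = np.array([0.2, 0.1, 0.9, 0.3])
        y_tr = rng.normal(size=40)
        y_te = rng.normal(size=40) + g[40:, 2]
        a = top_snp_r2(q, g[:40], y_tr, g[40:], y_te)
        b = top_snp_r2(q, g[:40], 7.5 * y_tr, g[40:], y_te)
        assert a == pytest.approx(b, rel=1e-10)

    def test_tie_takes_lowest_index(self, rng):
        g = rng.integers(0, 3, size=(60, 3)).astype(float)
        q = np.array([0.5, 0.5, 0.1])
        y_tr = g[:30, 0].copy()
        r2 = top_snp_r2(q, g[:30], y_tr, g[30:], g[30:, 0])
        assert r2 == pytest.approx(1.0)


class TestRunGrid:
    def test_deterministic_given_seed(self):
        grid = [SimConfig(n=400, m=100, k=1, h2=0.05, seed=42)]
        t1 = run_grid(grid, reps=2)
        t2 = run_grid(grid, reps=2)
        assert t1.equals(t2)

    def test_strong_signal_small_locus_high_auc(self):
        grid = [SimConfig(n=10_000, m=200, k=1, h2=0.04, seed=11)]
        tab = run_grid(grid, reps=3)
        assert tab.loc[0, "auc_mean"] > 0.95

    def test_auc_decreases_with_heritability(self):
        grid = [
            SimConfig(n=10_000, m=200, k=5, h2=h2, seed=17) for h2 in (0.04, 0.001)
        ]
        tab = run_grid(grid, reps=3)
        assert tab.loc[0, "auc_mean"] > tab.loc[1, "auc_mean"]

    def test_reps_validated(self):
        with pytest.raises(ValueError):
            run_grid([SimConfig(n=100, m=50, k=1, h2=0.01)], reps=0)


class TestGridPresets:
    def test_credset_grid_has_12_configs(self):
        grid = grid_preset("credset-grid")
        assert len(grid) == 12
        assert all(cfg.m == 4000 and cfg.effect_mode == "normal" for cfg in grid)

    def test_auc_grids_truncate(self):
        grid = grid_preset("auc-beta-const", m_max=2000)
        assert len(grid) == 27
        assert {cfg.m for cfg in grid} == {200, 1000, 2000}
        assert all(cfg.effect_mode == "constant" for cfg in grid)

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            grid_preset("nope")
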