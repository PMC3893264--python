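"""The ADA statistic and its two-layer permutation adjustment."""

import itertools
import math

import numpy as np
import pytest

from adarv import (
    AdaConfig,
    AdaResult,
    DEFAULT_THRESHOLDS,
    Direction,
    InputError,
    SiteResult,
    ada_statistic,
    ada_test,
    significance_scores,
)
from adarv import direction as site_direction
from adarv import mb_weight, midp_fisher
from conftest import toy_data

D, P, T = Direction.DELETERIOUS_INCLINED, Direction.PROTECTIVE_INCLINED, Direction.TIED


def site(p, direction, w=1.0):
    return SiteResult("v", p, direction, w, 0, 0)


class TestSignificanceScores:
    def test_hand_computed_two_site_example(self):
        sites = [site(0.05, D), site(0.5, D)]
        S_D, S_P = significance_scores(sites, [0.10])
        assert S_D[0] == pytest.approx(-math.log(0.05))  # ~2.99573
        assert S_P[0] == 0.0

    def test_hand_computed_three_site_grid(self):
        # frozen worked example: weighted contributions below each threshold
        sites = [site(0.05, D, w=2.0), site(0.15, P, w=1.5), site(0.30, D, w=1.0)]
        S_D, S_P = significance_scores(sites, [0.10, 0.20, 0.40])
        np.testing.assert_allclose(
            S_D,
            [2 * -math.log(0.05),
             2 * -math.log(0.05),
             2 * -math.log(0.05) + 1 * -math.log(0.30)],
        )
        np.testing.assert_allclose(S_P, [0.0, 1.5 * -math.log(0.15), 1.5 * -math.log(0.15)])

    def test_no_p_below_thresholds_gives_zero(self):
        S_D, S_P = significance_scores([site(0.5, D), site(0.9, P)], [0.1, 0.2])
        assert not S_D.any() and not S_P.any()

    def test_tied_sites_contribute_nothing(self):
        S_D, S_P = significance_scores([site(0.01, T)], [0.1])
        assert S_D[0] == 0.0 and S_P[0] == 0.0

    def test_truncation_is_strict(self):
        S_D, _ = significance_scores([site(0.10, D)], [0.10, 0.11])
        assert S_D[0] == 0.0 and S_D[1] > 0.0

    def test_linear_in_weights(self):
        sites = [site(0.02, D, w=1.0), site(0.03, P, w=2.0)]
        doubled = [site(0.02, D, w=2.0), site(0.03, P, w=4.0)]
        S1 = significance_scores(sites, DEFAULT_THRESHOLDS)
        S2 = significance_scores(doubled, DEFAULT_THRESHOLDS)
        np.testing.assert_allclose(S2[0], 2 * S1[0])
        np.testing.assert_allclose(S2[1], 2 * S1[1])

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        sites = [site(p, D if rng.random() < 0.5 else P, w=rng.uniform(0.5, 2))
                 for p in rng.uniform(0.01, 1, size=25)]
        S_D, S_P = significance_scores(sites, DEFAULT_THRESHOLDS)
        assert (np.diff(S_D) >= 0).all() and (np.diff(S_P) >= 0).all()


class TestAdaStatistic:
    def test_max_mode(self):
        np.testing.assert_array_equal(ada_statistic([3, 4], [1, 5], "max"), [3, 5])

    def test_sum_mode(self):
        np.testing.assert_array_equal(ada_statistic([3, 4], [1, 5], "sum"), [4, 9])

    def test_zero_protective_scores(self):
        S_D = np.array([1.0, 2.0])
        for mode in ("max", "sum"):
            np.testing.assert_array_equal(ada_statistic(S_D, [0, 0], mode), S_D)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            ada_statistic([1.0], [1.0, 2.0])


class TestConfig:
    def test_default_grid_is_eleven_thresholds(self):
        cfg = AdaConfig()
        assert cfg.thresholds == tuple(np.round(np.arange(0.10, 0.201, 0.01), 2))
        assert len(cfg.thresholds) == 11

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"thresholds": (0.2, 0.1)},
            {"thresholds": (0.0, 0.1)},
            {"n_permutations": 0},
            {"statistic_mode": "median"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(InputError):
            AdaConfig(**kwargs)


def ada_oracle(data, thresholds):
    """Full-enumeration ADA oracle for tiny samples.

    Enumerates every case/control label assignment with the observed case
    count, computes per-site mid-P/direction/weight via the scalar public
    functions and the scores by explicit loops, and applies the min-P
    adjustment by counting.  Independent of the vectorised engine.
    """
    n, K = data.genotypes.shape
    n_cases = data.n_cases
    g = data.genotypes
    assignments = list(itertools.combinations(range(n), n_cases))

    def scores(case_set):
        S = []
        for th in thresholds:
            sd = sp = 0.0
            for j in range(K):
                a = sum(int(g[i, j]) for i in case_set)
                m = int(g[:, j].sum()) - a
                nc, nu = 2 * n_cases, 2 * (n - n_cases)
                p = midp_fisher(a, nc - a, m, nu - m)
                dirn = site_direction(a, nc - a, m, nu - m)
                if p < th and dirn is not T:
                    contrib = mb_weight(m, n - n_cases) * -math.log(p)
                    if dirn is D:
                        sd += contrib
                    else:
                        sp += contrib
            S.append(max(sd, sp))
        return S

    all_S = [scores(cs) for cs in assignments]
    obs_S = scores(tuple(np.nonzero(data.phenotype == 1)[0]))
    N = len(assignments)
    J = len(thresholds)

    def pvec(S_row):
        return [sum(S[j] >= S_row[j] for S in all_S) / N for j in range(J)]

    minp_obs = min(pvec(obs_S))
    minp_all = [min(pvec(S)) for S in all_S]
    return sum(mp <= minp_obs for mp in minp_all) / N


class TestAdaTest:
    def small_data(self, seed=0, n=8, K=4):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 2, size=(n, K)).astype(np.int8)
        g[0, 0] = 2
        y = np.r_[np.ones(n // 2, dtype=np.int8), np.zeros(n - n // 2, dtype=np.int8)]
        return toy_data(g, y)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exhaustive_mode_matches_enumeration_oracle(self, seed):
        data = self.small_data(seed)
        thresholds = (0.15, 0.35, 0.6)
        res = ada_test(data, AdaConfig(thresholds=thresholds), exhaustive=True)
        assert res.adjusted_p == pytest.approx(ada_oracle(data, thresholds))

    def test_deterministic_given_seed(self):
        data = self.small_data(3, n=40, K=8)
        cfg = AdaConfig(n_permutations=300, seed=7)
        r1, r2 = ada_test(data, cfg), ada_test(data, cfg)
        assert r1.adjusted_p == r2.adjusted_p
        np.testing.assert_array_equal(r1.S, r2.S)
        np.testing.assert_array_equal(r1.per_threshold_p, r2.per_threshold_p)

    def test_extreme_separation_hits_floor(self):
        # one causal site carried by many cases and no controls
        g = np.zeros((40, 3), dtype=np.int8)
        g[:12, 0] = 1
        y = np.r_[np.ones(20, dtype=np.int8), np.zeros(20, dtype=np.int8)]
        B = 500
        res = ada_test(toy_data(g, y), AdaConfig(n_permutations=B, seed=1))
        assert res.adjusted_p == pytest.approx(1 / (B + 1))

    def test_scores_monotone_and_max_consistent(self):
        data = self.small_data(5, n=60, K=10)
        res = ada_test(data, AdaConfig(n_permutations=100, seed=0))
        assert (np.diff(res.S_D) >= 0).all()
        assert (np.diff(res.S_P) >= 0).all()
        np.testing.assert_allclose(res.S, np.maximum(res.S_D, res.S_P))
        assert 1 / 101 <= res.adjusted_p <= 1

    def test_observed_scores_match_significance_scores(self):
        from adarv import maf_filter, site_scan

        data = maf_filter(self.small_data(6, n=60, K=10), 0.5)
        res = ada_test(data, AdaConfig(n_permutations=50, seed=0))
        S_D, S_P = significance_scores(site_scan(data), res.thresholds)
        np.testing.assert_allclose(res.S_D, S_D)
        np.testing.assert_allclose(res.S_P, S_P)

    def test_sum_mode(self):
        data = self.small_data(7, n=40, K=6)
        res = ada_test(data, AdaConfig(n_permutations=100, seed=2,
                                       statistic_mode="sum"))
        np.testing.assert_allclose(res.S, res.S_D + res.S_P)

    def test_all_monomorphic_region_p_one(self):
        g = np.zeros((20, 3), dtype=np.int8)
        y = np.r_[np.ones(10, dtype=np.int8), np.zeros(10, dtype=np.int8)]
        res = ada_test(toy_data(g, y), AdaConfig(n_permutations=50, seed=0))
        assert res.adjusted_p == 1.0


def test_null_super_uniformity_small_scale():
    """Label-permutation validity: rejection rate at alpha=0.05 does not
    exceed the nominal level beyond Monte-Carlo noise."""
    rng = np.random.default_rng(99)
    B, reps = 200, 300
    hits = 0
    for r in range(reps):
        g = rng.binomial(2, rng.uniform(0.005, 0.05, size=12), size=(40, 12)).astype(np.int8)
        y = np.r_[np.ones(20, dtype=np.int8), np.zeros(20, dtype=np.int8)]
        res = ada_test(toy_data(g, y), AdaConfig(n_permutations=B, seed=r))
        hits += res.adjusted_p <= 0.05
    rate = hits / reps
    assert rate <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / reps)
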