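"""Exact likelihood terms and container invariants."""

import math

import numpy as np
import pytest
from scipy import stats

import multinmix.model_core as mc


class TestExpectedAbundance:
    def test_identity_link_at_zero(self):
        params = mc.ModelParams(0.0, [0.0, 0.0], [1, 1], {}, {})
        design = mc.AbundanceDesign(np.random.default_rng(0).normal(size=(5, 2)),
                                    ["a", "b"])
        assert np.allclose(mc.expected_abundance(params, design), 1.0)

    def test_indicators_zero_out_slopes(self):
        params = mc.ModelParams(math.log(5.0), [4.0, -9.0], [0, 0], {}, {})
        design = mc.AbundanceDesign(np.ones((4, 2)), ["a", "b"])
        assert np.allclose(mc.expected_abundance(params, design), 5.0)

    def test_linear_predictor_arithmetic(self):
        # beta0 + w*beta*x = 0.5 + 0.3*2 = 1.1, evaluated independently
        params = mc.ModelParams(0.5, [0.3], [1], {}, {})
        design = mc.AbundanceDesign(np.array([[2.0]]), ["a"])
        assert mc.expected_abundance(params, design)[0] == pytest.approx(
            math.exp(0.5 + 0.3 * 2.0), rel=1e-12
        )

    def test_dimension_mismatch_raises(self):
        params = mc.ModelParams(0.0, [0.3], [1], {}, {})
        design = mc.AbundanceDesign(np.ones((4, 2)), ["a", "b"])
        with pytest.raises(ValueError, match="covariates"):
            mc.expected_abundance(params, design)

    def test_zeroed_indicator_equals_deleted_column(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(30, 3))
        full = mc.AbundanceDesign(x, ["a", "b", "c"])
        dropped = mc.AbundanceDesign(x[:, [0, 2]], ["a", "c"])
        p_full = mc.ModelParams(0.2, [0.5, 0.7, -0.3], [1, 0, 1], {}, {})
        p_drop = mc.ModelParams(0.2, [0.5, -0.3], [1, 1], {}, {})
        assert np.allclose(mc.expected_abundance(p_full, full),
                           mc.expected_abundance(p_drop, dropped), atol=1e-12)


class TestDetectionProbability:
    def _design(self, v):
        v = np.asarray(v, dtype=float)
        return mc.DetectionDesign({"hair_trap": v},
                                  {"hair_trap": [f"v{k}" for k in
                                                 range(v.shape[2])]})

    def test_logistic_of_zero(self, tiny_params, tiny_designs):
        _, det = tiny_designs
        params = mc.ModelParams(0.0, [0.0], [1],
                                {"hair_trap": 0.0, "bear_rub": 0.0},
                                {"hair_trap": np.zeros(0),
                                 "bear_rub": np.zeros(0)})
        assert mc.detection_probability(params, det, "hair_trap", 0, 0) == 0.5

    def test_saturation_stays_inside_open_interval(self):
        design = self._design(np.zeros((1, 1, 0)))
        params = mc.ModelParams(0.0, [0.0], [1], {"hair_trap": 20.0},
                                {"hair_trap": np.zeros(0)})
        p = mc.detection_probability(params, design, "hair_trap", 0, 0)
        assert 1.0 - 1e-8 < p < 1.0

    def test_covariate_arithmetic(self):
        # logit = -1 + 0.5*2 = 0 -> p = 0.5
        design = self._design(np.full((1, 1, 1), 2.0))
        params = mc.ModelParams(0.0, [0.0], [1], {"hair_trap": -1.0},
                                {"hair_trap": [0.5]})
        assert mc.detection_probability(params, design, "hair_trap", 0, 0) \
            == pytest.approx(0.5, abs=1e-12)

    def test_unknown_method_raises(self):
        design = self._design(np.zeros((1, 1, 0)))
        params = mc.ModelParams(0.0, [0.0], [1], {"hair_trap": 0.0},
                                {"hair_trap": np.zeros(0)})
        with pytest.raises(KeyError, match="bear_rub"):
            mc.detection_probability(params, design, "bear_rub", 0, 0)


class TestCountLoglik:
    def test_certain_detection(self):
        assert mc.count_loglik(4, 4, 1.0 - 1e-14) == pytest.approx(0.0, abs=1e-10)

    def test_impossible_count_is_minus_inf(self):
        assert mc.count_loglik(3, 2, 0.4) == -math.inf

    def test_matches_bruteforce_pmf(self):
        # independent arithmetic: log[C(5,2) * .3^2 * .7^3]
        expected = math.log(math.comb(5, 2) * 0.3**2 * 0.7**3)
        assert mc.count_loglik(2, 5, 0.3) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("y,N", [(-1, 5), (2, -3)])
    def test_negative_inputs_raise(self, y, N):
        with pytest.raises(ValueError):
            mc.count_loglik(y, N, 0.5)


class TestSiteJointLoglik:
    def test_all_masked_leaves_poisson_term(self, tiny_counts, tiny_designs,
                                            tiny_params):
        abund, det = tiny_designs
        masked = mc.CountData(
            tiny_counts.counts, np.zeros_like(tiny_counts.observed_mask),
            tiny_counts.site_ids, tiny_counts.method_names,
            tiny_counts.occasions_per_method,
        )
        lam = mc.expected_abundance(tiny_params, abund)
        for i in range(3):
            got = mc.site_joint_loglik(masked, 4, tiny_params, abund, det, i)
            assert got == pytest.approx(stats.poisson.logpmf(4, lam[i]),
                                        rel=1e-12)

    def test_masking_one_method_matches_single_method_terms(
            self, tiny_counts, tiny_designs, tiny_params):
        abund, det = tiny_designs
        only_m1 = tiny_counts.mask_method("bear_rub")
        # term-by-term oracle: Poisson + the two hair-trap binomials
        i, N = 1, 5
        lam = mc.expected_abundance(tiny_params, abund)[i]
        p1 = mc.detection_probability(tiny_params, det, "hair_trap", i, 0)
        expected = stats.poisson.logpmf(N, lam) + sum(
            stats.binom.logpmf(tiny_counts.counts[i, t], N, p1)
            for t in range(2)
        )
        got = mc.site_joint_loglik(only_m1, N, tiny_params, abund, det, i)
        assert got == pytest.approx(float(expected), rel=1e-10)

    def test_term_by_term_oracle(self, tiny_counts, tiny_designs, tiny_params):
        abund, det = tiny_designs
        i, N = 0, 6
        lam = mc.expected_abundance(tiny_params, abund)[i]
        p = mc.detection_prob_matrix(tiny_params, det, tiny_counts)[i]
        expected = stats.poisson.logpmf(N, lam) + sum(
            stats.binom.logpmf(tiny_counts.counts[i, t], N, p[t])
            for t in range(4)
        )
        got = mc.site_joint_loglik(tiny_counts, N, tiny_params, abund, det, i)
        assert got == pytest.approx(float(expected), rel=1e-10)

    def test_additivity_over_sites(self, tiny_counts, tiny_designs, tiny_params):
        abund, det = tiny_designs
        latent = mc.LatentAbundance(np.array([5, 6, 7]))
        total = mc.full_data_loglik(tiny_counts, latent, tiny_params, abund, det)
        parts = sum(
            mc.site_joint_loglik(tiny_counts, int(latent.N[i]), tiny_params,
                                 abund, det, i)
            for i in range(3)
        )
        assert total == pytest.approx(parts, rel=1e-12)


class TestMarginalSiteLoglik:
    def test_certain_detection_zero_counts(self, tiny_designs):
        abund, det = tiny_designs
        counts = mc.CountData(np.zeros((3, 4), dtype=int),
                              np.ones((3, 4), dtype=bool),
                              ["c1", "c2", "c3"], ["hair_trap", "bear_rub"],
                              [2, 2])
        params = mc.ModelParams(math.log(0.8), [0.0], [1],
                                {"hair_trap": 30.0, "bear_rub": 30.0},
                                {"hair_trap": np.zeros(0),
                                 "bear_rub": np.zeros(0)})
        # only N=0 carries mass -> log Poisson(0; lam) = -lam
        got = mc.marginal_site_loglik(counts, params, abund, det, 1, 30)
        assert got == pytest.approx(-0.8, abs=1e-6)

    def test_hand_enumeration(self, tiny_designs):
        abund, det = tiny_designs
        counts = mc.CountData(np.array([[1, 0, 0, 0]] * 3),
                              np.array([[True, False, False, False]] * 3),
                              ["c1", "c2", "c3"], ["hair_trap", "bear_rub"],
                              [2, 2])
        lam, p = 0.5, 0.4
        params = mc.ModelParams(math.log(lam) - 0.8 * 0.0, [0.8], [0],
                                {"hair_trap": math.log(p / (1 - p)),
                                 "bear_rub": 0.0},
                                {"hair_trap": np.zeros(0),
                                 "bear_rub": np.zeros(0)})
        K = 25
        expected = math.log(sum(
            stats.poisson.pmf(N, lam) * stats.binom.pmf(1, N, p)
            for N in range(1, K + 1)
        ))
        got = mc.marginal_site_loglik(counts, params, abund, det, 0, K)
        assert got == pytest.approx(expected, rel=1e-10)
        assert got <= 0.0  # log of a probability

    def test_invariant_to_larger_truncation(self, tiny_counts, tiny_designs,
                                            tiny_params):
        abund, det = tiny_designs
        a = mc.marginal_site_loglik(tiny_counts, tiny_params, abund, det, 2, 40)
        b = mc.marginal_site_loglik(tiny_counts, tiny_params, abund, det, 2, 80)
        assert abs(a - b) < 1e-10

    def test_insufficient_truncation_raises(self, tiny_counts, tiny_designs):
        abund, det = tiny_designs
        big = mc.ModelParams(math.log(50.0), [0.0], [1],
                             {"hair_trap": 0.0, "bear_rub": 0.0},
                             {"hair_trap": np.zeros(0),
                              "bear_rub": np.zeros(0)})
        with pytest.raises(ValueError, match="increase K"):
            mc.marginal_site_loglik(tiny_counts, big, abund, det, 0, 60)
        with pytest.raises(ValueError, match="max observed count"):
            mc.marginal_site_loglik(tiny_counts, big, abund, det, 2, 2)


class TestContainers:
    def test_negative_observed_count_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            mc.CountData(np.array([[-1, 2]]), np.ones((1, 2), bool), ["a"],
                         ["m"], [2])

    def test_occasion_bookkeeping_must_match(self):
        with pytest.raises(ValueError, match="occasion"):
            mc.CountData(np.zeros((1, 3), int), np.ones((1, 3), bool), ["a"],
                         ["m1", "m2"], [2, 2])

    def test_site_without_effort_fails_strict_validation(self):
        data = mc.CountData(np.zeros((2, 2), int),
                            np.array([[True, True], [False, False]]),
                            ["a", "b"], ["m"], [2])
        with pytest.raises(ValueError, match="no observed effort"):
            data.validate()

    def test_latent_bound_check(self, tiny_counts):
        latent = mc.LatentAbundance(np.array([1, 1, 1]))
        with pytest.raises(ValueError, match="below max observed"):
            latent.check_bounds(tiny_counts)
        mc.LatentAbundance(np.array([2, 2, 4])).check_bounds(tiny_counts)

    def test_standardization_record(self):
        rng = np.random.default_rng(4)
        design = mc.AbundanceDesign(rng.normal(3.0, 2.0, (40, 3)),
                                    ["a", "b", "c"]).standardized()
        assert np.allclose(design.x.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(design.x.std(axis=0), 1.0, atol=1e-9)
        assert design.center is not None and design.scale is not None

    def test_indicators_must_be_binary(self):
        with pytest.raises(ValueError, match="0/1"):
            mc.ModelParams(0.0, [1.0], [2], {}, {})

    def test_min_abundance_ignores_masked_entries(self, tiny_counts):
        # site 3 has a masked 0; its bound comes from observed counts only
        assert tiny_counts.min_abundance().tolist() == [2, 2, 4]
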