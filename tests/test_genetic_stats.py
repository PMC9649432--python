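"""Statistical-genetics tests: standardization, association calibration,
the interaction LRT, IVW meta-analysis, risk scores and MR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import statsmodels.api as sm

from hepatofat.genetic_stats import (
    GWS_THRESHOLDS,
    additive_assoc,
    covariate_interaction,
    grs,
    gws_threshold,
    interaction_lrt,
    inverse_normal_transform,
    ivw_meta,
    mr_ivw_egger,
)
from hepatofat.types import GRSWeights


class TestInverseNormalTransform:
    def test_moments_at_large_n(self):
        rng = np.random.default_rng(1)
        z = inverse_normal_transform(rng.exponential(2.0, 10_000))
        assert abs(z.mean()) < 1e-6
        assert abs(z.std(ddof=0) - 1.0) < 1e-3

    def test_rank_preservation(self):
        x = np.arange(50, dtype=float) ** 2
        z = inverse_normal_transform(x)
        assert np.all(np.diff(z) > 0)

    def test_idempotent_up_to_ties(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 5, 500)
        once = inverse_normal_transform(x)
        twice = inverse_normal_transform(once)
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_blom_offset_values(self):
        # direct recomputation of the quantile formula for a tiny sample
        x = np.array([3.0, 1.0, 2.0] + list(range(10, 17)))
        z = inverse_normal_transform(x)
        ranks = stats.rankdata(x)
        expected = stats.norm.ppf((ranks - 0.375) / (x.size + 0.25))
        np.testing.assert_allclose(z, expected)

    def test_covariate_residualization(self):
        rng = np.random.default_rng(3)
        cov = pd.DataFrame({"age": rng.uniform(40, 70, 400)})
        y = 0.5 * cov["age"].to_numpy() + rng.normal(0, 1, 400)
        z = inverse_normal_transform(y, cov)
        # after residualization the transform should not correlate with age
        r = stats.pearsonr(z, cov["age"]).statistic
        assert abs(r) < 0.1

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            inverse_normal_transform(np.ones(100))


class TestAdditiveAssoc:
    def test_null_calibration(self):
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            g = rng.binomial(2, 0.3, 500)
            y = rng.normal(0, 1, 500)
            rejections += additive_assoc(g, y).p_value < 0.05
        assert 0.037 <= rejections / reps <= 0.063

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(12)
        g = rng.binomial(2, 0.3, 2000)
        y = 0.3 * g + rng.normal(0, 1, 2000)
        res = additive_assoc(g, y)
        assert abs(res.beta - 0.3) < 3 * res.se

    def test_matches_statsmodels_with_covariates(self):
        rng = np.random.default_rng(13)
        g = rng.binomial(2, 0.4, 300).astype(float)
        cov = pd.DataFrame({"age": rng.uniform(40, 70, 300), "sex": rng.integers(0, 2, 300)})
        y = 0.2 * g + 0.01 * cov["age"].to_numpy() + rng.normal(0, 1, 300)
        res = additive_assoc(g, y, covariates=cov)
        X = sm.add_constant(np.column_stack([g, cov.to_numpy()]))
        ref = sm.OLS(y, X).fit()
        assert res.beta == pytest.approx(ref.params[1], rel=1e-10)
        assert res.se == pytest.approx(ref.bse[1], rel=1e-10)

    def test_logistic_log_or(self):
        rng = np.random.default_rng(14)
        g = rng.binomial(2, 0.3, 3000)
        p = 1 / (1 + np.exp(-(-1.0 + 0.4 * g)))
        y = (rng.random(3000) < p).astype(float)
        res = additive_assoc(g, y)
        assert abs(res.beta - 0.4) < 3 * res.se

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            additive_assoc(np.zeros(100), np.random.default_rng(0).normal(size=100))

    def test_separation_flagged(self):
        g = np.array([0] * 30 + [2] * 30)
        y = np.array([0.0] * 30 + [1.0] * 30)
        with pytest.warns(UserWarning, match="separation"):
            res = additive_assoc(g, y, binary=True)
        assert res.separation


class TestInteractionLRT:
    def test_identical_group_effects_give_zero_gamma(self):
        # constructed fixture: every primary group sees the identical
        # (secondary genotype, residual) data, so the three per-group fits
        # coincide exactly and the trend through them is flat
        rng = np.random.default_rng(20)
        gp = np.repeat([0, 1, 2], 200)
        gs_block = rng.binomial(2, 0.4, 200).astype(float)
        noise_block = rng.normal(0, 1, 200)
        gs = np.tile(gs_block, 3)
        y = 0.5 * gs + np.tile(noise_block, 3)
        res = interaction_lrt(gp, gs, y)
        assert res.gamma == pytest.approx(0.0, abs=1e-12)
        assert res.lrt_stat == pytest.approx(0.0, abs=1e-12)

    def test_small_group_error_names_group(self):
        gp = np.array([0] * 100 + [1] * 100 + [2] * 5)
        gs = np.random.default_rng(1).binomial(2, 0.4, 205)
        y = np.random.default_rng(2).normal(size=205)
        with pytest.raises(ValueError, match="group 2"):
            interaction_lrt(gp, gs, y)

    def test_monomorphic_secondary_in_group_rejected(self):
        gp = np.repeat([0, 1, 2], 50)
        gs = np.ones(150)
        gs[:50] = np.random.default_rng(0).binomial(2, 0.4, 50)
        y = np.random.default_rng(1).normal(size=150)
        with pytest.raises(ValueError, match="monomorphic"):
            interaction_lrt(gp, gs, y)

    def test_affine_trait_rescaling_preserves_statistic(self):
        rng = np.random.default_rng(21)
        gp = rng.binomial(2, 0.4, 1500)
        gs = rng.binomial(2, 0.4, 1500)
        y = 0.1 * gp * gs + rng.normal(0, 1, 1500)
        a = interaction_lrt(gp, gs, y)
        b = interaction_lrt(gp, gs, 3.0 * y + 7.0)
        assert b.lrt_stat == pytest.approx(a.lrt_stat, rel=1e-10)
        assert b.p_value == pytest.approx(a.p_value, rel=1e-10)

    def test_planted_gamma_recovered(self):
        rng = np.random.default_rng(22)
        estimates = []
        for _ in range(100):
            gp = rng.binomial(2, 0.3, 4000)
            gs = rng.binomial(2, 0.3, 4000)
            y = 0.1 * gp * gs + rng.normal(0, 1, 4000)
            estimates.append(interaction_lrt(gp, gs, y).gamma)
        mc_se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - 0.1) < 3 * mc_se


class TestCovariateInteraction:
    def test_null_calibration(self):
        rng = np.random.default_rng(30)
        rej = 0
        reps = 400
        for _ in range(reps):
            g = rng.binomial(2, 0.3, 400)
            bmi = rng.normal(0, 1, 400)
            y = 0.1 * g + 0.1 * bmi + rng.normal(0, 1, 400)
            rej += covariate_interaction(g, bmi, y).p_value < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) < 3 * se

    def test_planted_product_term_recovered(self):
        rng = np.random.default_rng(31)
        g = rng.binomial(2, 0.3, 5000)
        bmi = rng.normal(0, 1, 5000)
        y = 0.1 * g + 0.1 * bmi + 0.05 * g * bmi + rng.normal(0, 1, 5000)
        res = covariate_interaction(g, bmi, y)
        assert abs(res.beta - 0.05) < 3 * res.se

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            covariate_interaction(
                np.random.default_rng(0).binomial(2, 0.3, 100),
                np.ones(100),
                np.random.default_rng(1).normal(size=100),
            )


class TestIVWMeta:
    def test_single_study_identity(self):
        res = ivw_meta([0.3], [0.1])
        assert res.effect == pytest.approx(0.3)
        assert res.se == pytest.approx(0.1)
        assert res.k == 1 and np.isnan(res.p_het)

    def test_equal_se_closed_form(self):
        res = ivw_meta([0.2, 0.4], [0.1, 0.1])
        assert res.effect == pytest.approx(0.3)
        assert res.se == pytest.approx(0.1 / np.sqrt(2))

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(40)
        b = rng.normal(0.2, 0.1, 4)
        s = rng.uniform(0.05, 0.2, 4)
        res = ivw_meta(b, s)
        w = 1 / s**2
        assert res.effect == pytest.approx(float(w @ b / w.sum()), abs=1e-12)
        assert res.se == pytest.approx(float(1 / np.sqrt(w.sum())), abs=1e-12)
        assert res.q_stat == pytest.approx(float(w @ (b - res.effect) ** 2), abs=1e-12)

    def test_combined_within_range_and_order_invariant(self):
        rng = np.random.default_rng(41)
        b = rng.normal(0, 1, 6)
        s = rng.uniform(0.1, 0.5, 6)
        res = ivw_meta(b, s)
        assert b.min() <= res.effect <= b.max()
        assert res.se <= s.min()
        perm = rng.permutation(6)
        res2 = ivw_meta(b[perm], s[perm])
        assert res2.effect == pytest.approx(res.effect, abs=1e-14)
        assert res2.q_stat == pytest.approx(res.q_stat, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ivw_meta([0.1, 0.2], [0.1])
        with pytest.raises(ValueError):
            ivw_meta([0.1], [0.0])


class TestThresholds:
    def test_published_tiers(self):
        assert gws_threshold("high") == 1.8e-7
        assert gws_threshold("moderate") == 3.5e-8
        assert gws_threshold("low") == 3.2e-9
        assert gws_threshold("dhs") == 1.6e-9
        assert gws_threshold("other") == 5.3e-10
        assert len(GWS_THRESHOLDS) == 5

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            gws_threshold("modifier")


class TestGRS:
    def _weights(self, ids, w):
        return GRSWeights(variants=ids, effect_alleles=["A"] * len(ids), weights=np.asarray(w))

    def test_zero_weights_zero_scores(self):
        G = pd.DataFrame(np.random.default_rng(0).integers(0, 3, (20, 4)),
                         columns=list("abcd"))
        scores = grs(G, self._weights(list("abcd"), np.zeros(4)))
        assert (scores == 0).all()

    def test_homozygous_sum(self):
        G = pd.DataFrame(np.full((5, 3), 2), columns=list("abc"))
        w = np.array([0.1, 0.2, 0.3])
        scores = grs(G, self._weights(list("abc"), w))
        np.testing.assert_allclose(scores, 2 * w.sum())

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(50)
        G = pd.DataFrame(rng.integers(0, 3, (50, 10)),
                         columns=[f"v{i}" for i in range(10)])
        w = rng.normal(0, 0.2, 10)
        scores = grs(G, self._weights(list(G.columns), w))
        oracle = np.array([sum(w[j] * G.iloc[i, j] for j in range(10)) for i in range(50)])
        np.testing.assert_allclose(scores, oracle, atol=1e-12)

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(51)
        G = pd.DataFrame(rng.integers(0, 3, (30, 5)), columns=list("abcde"))
        w1 = rng.normal(size=5)
        w2 = rng.normal(size=5)
        s12 = grs(G, self._weights(list("abcde"), w1 + w2))
        s1 = grs(G, self._weights(list("abcde"), w1))
        s2 = grs(G, self._weights(list("abcde"), w2))
        np.testing.assert_allclose(s12, s1 + s2, atol=1e-12)

    def test_unmatched_variant_rejected(self):
        G = pd.DataFrame(np.zeros((5, 2), dtype=int), columns=["a", "b"])
        with pytest.raises(ValueError, match="missing"):
            grs(G, self._weights(["a", "z"], [0.1, 0.2]))

    def test_allele_mismatch_requires_flag(self):
        G = pd.DataFrame([[0, 1], [2, 1]], columns=["a", "b"])
        w = GRSWeights(variants=["a", "b"], effect_alleles=["A", "C"], weights=[1.0, 1.0])
        counted = {"a": "A", "b": "T"}
        with pytest.raises(ValueError, match="mismatch"):
            grs(G, w, counted_alleles=counted)
        flipped = grs(G, w, counted_alleles=counted, flip_mismatched=True)
        np.testing.assert_allclose(flipped, [0 + (2 - 1), 2 + (2 - 1)])


class TestMR:
    def test_proportional_effects(self):
        bx = np.array([0.1, 0.2, 0.3, 0.15])
        res = mr_ivw_egger(bx, 0.01 * np.ones(4), 2 * bx, 0.05 * np.ones(4))
        assert res.ivw_estimate == pytest.approx(2.0)
        assert res.egger_intercept == pytest.approx(0.0, abs=1e-12)
        assert res.egger_slope == pytest.approx(2.0)

    def test_single_instrument_rejected(self):
        with pytest.raises(ValueError):
            mr_ivw_egger([0.1], [0.01], [0.2], [0.05])

    def test_two_instruments_no_egger(self):
        res = mr_ivw_egger([0.1, 0.2], [0.01, 0.01], [0.2, 0.4], [0.05, 0.05])
        assert res.ivw_estimate == pytest.approx(2.0)
        assert res.egger_slope is None

    def test_noisy_proportional_within_ci(self):
        rng = np.random.default_rng(60)
        bx = rng.uniform(0.05, 0.3, 30)
        sy = np.full(30, 0.02)
        by = 1.5 * bx + rng.normal(0, 0.02, 30)
        res = mr_ivw_egger(bx, np.full(30, 0.005), by, sy)
        assert abs(res.ivw_estimate - 1.5) < 3 * res.ivw_se
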