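"""Group-statistics layer against independent textbook-formula oracles."""

import math

import numpy as np
import pytest

from chronodisc import (AmiRecord, addiction_severity, compare_independent_correlations,
                        cronbach_alpha, internal_details_sum, pearson_r,
                        regress_log_k, welch_t)


class TestInternalDetails:
    def test_uniform_counts_sum_of_means(self):
        rec = AmiRecord("p", "EFT", np.full((5, 5), 2.0))
        assert internal_details_sum(rec) == pytest.approx(10.0)

    def test_partial_recording_averages_over_recorded_cues(self):
        internal = np.array([[4, 2], [1, 3], [0, 2], [5, 1], [2, 2]], float)
        rec = AmiRecord("p", "AM", internal)
        assert internal_details_sum(rec) == pytest.approx(internal.mean(axis=1).sum())

    def test_all_zero_counts(self):
        assert internal_details_sum(AmiRecord("p", "AM", np.zeros((5, 5)))) == 0.0

    def test_invalid_records_rejected(self):
        with pytest.raises(ValueError):
            AmiRecord("p", "AM", np.zeros((5, 0)))
        with pytest.raises(ValueError):
            AmiRecord("p", "AM", -np.ones((5, 5)))
        with pytest.raises(ValueError):
            AmiRecord("p", "nope", np.zeros((5, 5)))


class TestAddictionSeverity:
    def test_sample_mean_participant_scores_zero(self):
        kfg = np.array([0.0, 10.0, 20.0])
        sogs = np.array([2.0, 5.0, 8.0])
        sev = addiction_severity(kfg, sogs)
        assert sev[1] == pytest.approx(0.0)  # at the mean of both scales

    def test_opposite_z_scores_cancel(self):
        kfg = np.array([0.0, 1.0, 2.0])
        sogs = np.array([2.0, 1.0, 0.0])
        sev = addiction_severity(kfg, sogs)
        assert np.allclose(sev, 0.0)

    def test_compound_correlates_at_least_as_well_as_worst_component(self):
        rng = np.random.default_rng(12)
        latent = rng.standard_normal(300)
        kfg = latent + 0.5 * rng.standard_normal(300)
        sogs = latent + 0.5 * rng.standard_normal(300)
        outcome = latent + rng.standard_normal(300)
        sev = addiction_severity(kfg, sogs)
        r_sev, _ = pearson_r(sev, outcome)
        r_k, _ = pearson_r(kfg, outcome)
        r_s, _ = pearson_r(sogs, outcome)
        assert r_sev >= min(r_k, r_s)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            addiction_severity([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


class TestWelch:
    def test_matches_hand_computed_formulas(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        t, df, p, d = welch_t(x, y)
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t_exp = (x.mean() - y.mean()) / math.sqrt(vx + vy)
        df_exp = (vx + vy) ** 2 / (vx ** 2 / (len(x) - 1) + vy ** 2 / (len(y) - 1))
        from scipy.stats import t as tdist
        p_exp = 2 * tdist.sf(abs(t_exp), df_exp)
        pooled = math.sqrt((2 * x.var(ddof=1) + 5 * y.var(ddof=1)) / 7)
        assert t == pytest.approx(t_exp, abs=1e-10)
        assert df == pytest.approx(df_exp, abs=1e-10)
        assert p == pytest.approx(p_exp, abs=1e-10)
        assert d == pytest.approx((x.mean() - y.mean()) / pooled, abs=1e-10)

    def test_identical_samples(self):
        t, _, p, d = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0) and d == 0.0

    def test_equal_variance_equal_n_satterthwaite_limit(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(20)
        y = x + 1.0  # identical variance, shifted mean
        _, df, _, _ = welch_t(x, y)
        assert df == pytest.approx(38.0, abs=1e-9)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [2.0, 2.0])


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        x = np.array([1.2, 3.4, 2.2, 5.6, 4.4, 0.1])
        y = np.array([0.3, 2.2, 1.1, 4.0, 5.2, 0.2])
        r, p = pearson_r(x, y)
        r_exp = (np.sum((x - x.mean()) * (y - y.mean()))
                 / math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        t_stat = r_exp * math.sqrt(4 / (1 - r_exp ** 2))
        from scipy.stats import t as tdist
        assert r == pytest.approx(r_exp, abs=1e-10)
        assert p == pytest.approx(2 * tdist.sf(abs(t_stat), 4), abs=1e-10)

    def test_monte_carlo_tracks_population_rho(self):
        rng = np.random.default_rng(9)
        z = rng.standard_normal(500)
        x = z + rng.standard_normal(500) / 3.0  # population corr 1/(1+1/9) = 0.9
        y = z + rng.standard_normal(500) / 3.0
        assert abs(pearson_r(x, y)[0] - 0.9) < 0.05

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFisherZ:
    def test_equal_correlations_give_zero(self):
        z, p = compare_independent_correlations(0.5, 30, 0.5, 40)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_closed_form_evaluation(self):
        z, p = compare_independent_correlations(0.9, 20, 0.0, 20)
        z_exp = math.atanh(0.9) / math.sqrt(2.0 / 17.0)
        assert z == pytest.approx(z_exp, abs=1e-10)
        assert z == pytest.approx(4.29, abs=0.01)

    def test_antisymmetry(self):
        z1, _ = compare_independent_correlations(0.8, 25, 0.3, 30)
        z2, _ = compare_independent_correlations(0.3, 30, 0.8, 25)
        assert z1 == pytest.approx(-z2, abs=1e-12)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError):
            compare_independent_correlations(1.0, 20, 0.5, 20)


class TestCronbach:
    def test_identical_raters_give_one(self):
        scores = np.tile(np.arange(10.0), (3, 1))
        assert cronbach_alpha(scores) == pytest.approx(1.0)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(4)
        alphas = [cronbach_alpha(rng.standard_normal((3, 60))) for _ in range(50)]
        assert abs(np.mean(alphas)) < 0.15

    def test_two_raters_equal_spearman_brown_on_standardized_scores(self):
        rng = np.random.default_rng(8)
        base = rng.standard_normal(40)
        m = np.vstack([base + 0.3 * rng.standard_normal(40),
                       base + 0.3 * rng.standard_normal(40)])
        m = (m - m.mean(axis=1, keepdims=True)) / m.std(axis=1, ddof=1, keepdims=True)
        r = np.corrcoef(m)[0, 1]
        assert cronbach_alpha(m) == pytest.approx(2 * r / (1 + r), abs=1e-10)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg
        rng = np.random.default_rng(2)
        m = rng.normal(5, 2, (4, 30)) + rng.standard_normal(30)
        alpha = pg.cronbach_alpha(pd.DataFrame(m.T))[0]
        assert cronbach_alpha(m) == pytest.approx(alpha, abs=1e-10)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((2, 5)))


class TestRegression:
    def _covariate_block(self, rng, n):
        return {"audit": rng.normal(8, 6, n), "ftnd": rng.normal(4, 2, n),
                "group": np.repeat(["HC", "PG"], n // 2)}

    def test_noiseless_construction_recovered_exactly(self):
        rng = np.random.default_rng(1)
        n = 60
        bdi = rng.normal(10, 6, n)
        z_bdi = (bdi - bdi.mean()) / bdi.std(ddof=1)
        preds = {"bdi": bdi, **self._covariate_block(rng, n)}
        res = regress_log_k(2.0 * z_bdi, preds)
        coefs = dict(zip(res.predictors, res.coef))
        assert coefs["bdi"] == pytest.approx(2.0, abs=1e-10)
        assert all(abs(coefs[k]) < 1e-10 for k in coefs if k != "bdi")
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-10)

    def test_null_outcome_gives_zero_adjusted_r2_on_average(self):
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(100):
            n = 40
            preds = {"bdi": rng.normal(10, 6, n), **self._covariate_block(rng, n)}
            res = regress_log_k(rng.standard_normal(n), preds)
            vals.append(res.adj_r2)
        assert abs(np.mean(vals)) < 0.05

    def test_ci_contains_point_estimate_and_scaling_invariance(self):
        rng = np.random.default_rng(7)
        n = 50
        bdi = rng.normal(10, 6, n)
        y = 0.5 * bdi + rng.standard_normal(n)
        preds = {"bdi": bdi, **self._covariate_block(rng, n)}
        res = regress_log_k(y, preds)
        assert np.all(res.ci_low <= res.coef) and np.all(res.coef <= res.ci_high)
        scaled = dict(preds, bdi=preds["bdi"] * 100.0)  # z-scoring absorbs rescaling
        res2 = regress_log_k(y, scaled)
        assert np.allclose(res.coef, res2.coef, atol=1e-10)

    def test_eft_predictor_toggle(self):
        rng = np.random.default_rng(3)
        n = 40
        preds = {"bdi": rng.normal(10, 6, n), "eft_sum": rng.normal(40, 10, n),
                 **self._covariate_block(rng, n)}
        res6 = regress_log_k(rng.standard_normal(n), preds, include_eft=True)
        res5 = regress_log_k(rng.standard_normal(n), preds, include_eft=False)
        assert "eft_sum" in res6.predictors and "eft_sum" not in res5.predictors

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(2)
        n = 30
        x = rng.standard_normal(n)
        with pytest.raises(ValueError, match="collinear"):
            regress_log_k(rng.standard_normal(n), {"a": x, "b": 2 * x})
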