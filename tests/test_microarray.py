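import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from dcismir.config import PipelineConfig
from dcismir.microarray import (NIGPrior, _group_sufficients, mixed_model_de,
                                posterior_fc_probability, presence_filter,
                                run_mrna_de, select_de_genes)
from dcismir.simulate import planted_design, simulate_expression_dataset

from conftest import make_expr


class TestPresenceFilter:
    @pytest.mark.parametrize("n_present,kept", [(2, False), (3, True)])
    def test_fraction_threshold(self, cfg, n_present, kept):
        # 16 samples; < 15% present means at most 2 of 16
        expr = make_expr(np.full((1, 8), 7.0), np.full((1, 8), 7.0))
        pres = expr.present.copy()
        pres.iloc[0, :] = False
        pres.iloc[0, :n_present] = True
        expr.present = pres
        filtered, report = presence_filter(expr, cfg)
        assert ("probe0" in filtered.values.index) == kept

    def test_zero_threshold_is_identity(self):
        cfg0 = PipelineConfig(presence_min_frac=0.0)
        expr = make_expr(np.full((4, 8), 7.0), np.full((4, 8), 7.0))
        expr.present.iloc[:] = False
        filtered, _ = presence_filter(expr, cfg0)
        assert len(filtered.values) == 4

    def test_missing_presence_requires_threshold(self, cfg):
        expr = make_expr(np.full((1, 8), 7.0), np.full((1, 8), 7.0))
        expr.present = None
        with pytest.raises(ValueError, match="presence"):
            presence_filter(expr, cfg)
        filtered, _ = presence_filter(expr, cfg, detect_threshold=5.0)
        assert len(filtered.values) == 1


def shared_model_oracle(ref, test, c, prior=NIGPrior()):
    """P(group-mean log2 difference > c) under the shared-variance conjugate
    model, by numerical integration over the variance posterior (independent
    of the closed-form scaled-t route)."""
    m0 = np.r_[ref, test].mean()
    n_a, mn_a, kn_a, s_a = _group_sufficients(ref[None, :], np.array([m0]), prior)
    n_b, mn_b, kn_b, s_b = _group_sufficients(test[None, :], np.array([m0]), prior)
    a_n = prior.a0 + 0.5 * (n_a + n_b)
    b_n = float(prior.b0 + s_a[0] + s_b[0])
    d = float(mn_b[0] - mn_a[0])

    def integrand(s2):
        sd = np.sqrt(s2 * (1.0 / kn_a + 1.0 / kn_b))
        return stats.invgamma.pdf(s2, a_n, scale=b_n) * stats.norm.sf((c - d) / sd)

    val, _ = integrate.quad(integrand, 0, np.inf, limit=300)
    return val


class TestPosteriorScreen:
    def test_identical_groups_give_half_at_screen_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(7, 0.5, (3, 8))
        expr = make_expr(x, x)
        post = posterior_fc_probability(expr, fc_screen=1.0)
        np.testing.assert_allclose(post, 0.5, atol=1e-9)

    def test_extreme_separation_saturates(self):
        expr = make_expr(np.random.default_rng(2).normal(5, 0.05, (1, 8)),
                         np.random.default_rng(3).normal(9, 0.05, (1, 8)))
        up = float(posterior_fc_probability(expr, fc_screen=1.5).iloc[0])
        assert up > 0.999
        expr_down = make_expr(np.random.default_rng(2).normal(9, 0.05, (1, 8)),
                              np.random.default_rng(3).normal(5, 0.05, (1, 8)))
        down = float(posterior_fc_probability(expr_down, fc_screen=1.5).iloc[0])
        assert down < 0.001

    @pytest.mark.parametrize("seed", range(5))
    def test_shared_model_matches_quadrature_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(6, 0.6, 4)
        test = rng.normal(6 + rng.normal(0, 1), 0.6, 4)
        # force the shared model by averaging with itself: compare the
        # shared-model component via a huge prior weight is not exposed, so
        # check the closed form directly against the oracle
        from dcismir.microarray import _log_marginal  # noqa: F401  (import check)
        prior = NIGPrior()
        c = np.log2(1.5)
        m0 = np.r_[ref, test].mean()
        n_a, mn_a, kn_a, s_a = _group_sufficients(ref[None, :], np.array([m0]), prior)
        n_b, mn_b, kn_b, s_b = _group_sufficients(test[None, :], np.array([m0]), prior)
        a_n = prior.a0 + 0.5 * (n_a + n_b)
        b_n = float(prior.b0 + s_a[0] + s_b[0])
        scale = np.sqrt((b_n / a_n) * (1.0 / kn_a + 1.0 / kn_b))
        closed = float(stats.t.sf((c - (mn_b[0] - mn_a[0])) / scale, df=2 * a_n))
        assert closed == pytest.approx(shared_model_oracle(ref, test, c), abs=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_model_average_between_component_models(self, seed):
        # the averaged posterior must lie between the two models' posteriors,
        # verified against full scipy quadrature of the separate model
        rng = np.random.default_rng(100 + seed)
        ref = rng.normal(6, 0.3, 6)
        test = rng.normal(6.7, 0.9, 6)
        expr = make_expr(ref[None, :], test[None, :])
        post = float(posterior_fc_probability(expr, fc_screen=1.5).iloc[0])
        prior = NIGPrior()
        c = np.log2(1.5)
        m0 = np.r_[ref, test].mean()
        n_a, mn_a, kn_a, s_a = _group_sufficients(ref[None, :], np.array([m0]), prior)
        n_b, mn_b, kn_b, s_b = _group_sufficients(test[None, :], np.array([m0]), prior)
        a_na, b_na = prior.a0 + 0.5 * n_a, float(prior.b0 + s_a[0])
        a_nb, b_nb = prior.a0 + 0.5 * n_b, float(prior.b0 + s_b[0])
        sc_a = np.sqrt(b_na / (a_na * kn_a))
        sc_b = np.sqrt(b_nb / (a_nb * kn_b))

        def f(u):
            return (stats.t.pdf((u - mn_a[0]) / sc_a, 2 * a_na) / sc_a
                    * stats.t.sf((c + u - mn_b[0]) / sc_b, 2 * a_nb))

        separate, _ = integrate.quad(f, -np.inf, np.inf, limit=400)
        shared = shared_model_oracle(ref, test, c)
        lo, hi = sorted([separate, shared])
        assert lo - 1e-9 <= post <= hi + 1e-9

    def test_monotone_in_observed_difference(self):
        base = np.random.default_rng(7).normal(0, 0.4, 8)
        posts = []
        for shift in np.linspace(-1.5, 1.5, 11):
            expr = make_expr(base[None, :], (base + shift)[None, :])
            posts.append(float(posterior_fc_probability(expr, fc_screen=1.5).iloc[0]))
        assert all(b >= a for a, b in zip(posts, posts[1:]))


class TestMixedModel:
    def test_equals_paired_t_on_balanced_design(self):
        rng = np.random.default_rng(11)
        hn = rng.normal(6, 0.5, (20, 8))
        dcis = hn + rng.normal(0.4, 0.3, (20, 8))
        mm = mixed_model_de(make_expr(hn, dcis))
        ref = stats.ttest_rel(dcis, hn, axis=1)
        np.testing.assert_allclose(mm["mixed_p"], ref.pvalue, atol=1e-12)
        np.testing.assert_allclose(mm["log_fc"], (dcis - hn).mean(axis=1),
                                   atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_numerical_reml_fit(self, seed):
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(40 + seed)
        n = 8
        pat = rng.normal(0, 0.6, n)
        hn = 6 + pat + rng.normal(0, 0.3, n)
        dcis = 6.5 + pat + rng.normal(0, 0.3, n)
        mm = mixed_model_de(make_expr(hn[None, :], dcis[None, :]))
        frame = pd.DataFrame({"y": np.r_[hn, dcis], "lesion": [0] * n + [1] * n,
                              "patient": list(range(n)) * 2})
        fit = smf.mixedlm("y ~ lesion", frame, groups=frame["patient"]).fit(reml=True)
        assert mm["log_fc"].iloc[0] == pytest.approx(fit.params["lesion"], abs=1e-6)
        assert mm["t"].iloc[0] == pytest.approx(
            fit.params["lesion"] / fit.bse["lesion"], abs=1e-3)
        assert mm["sigma2_patient"].iloc[0] == pytest.approx(
            float(fit.cov_re.iloc[0, 0]), abs=1e-4)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(12)
        pat = rng.normal(0, 0.5, (500, 8))
        hn = 6 + pat + rng.normal(0, 0.3, (500, 8))
        dcis = 6 + pat + rng.normal(0, 0.3, (500, 8))
        mm = mixed_model_de(make_expr(hn, dcis))
        ks = stats.kstest(mm["mixed_p"], "uniform")
        assert ks.pvalue > 0.01

    def test_scale_invariance_of_p(self):
        rng = np.random.default_rng(13)
        hn = rng.normal(6, 0.5, (10, 8))
        dcis = hn + rng.normal(0.3, 0.3, (10, 8))
        p1 = mixed_model_de(make_expr(hn, dcis))["mixed_p"]
        # multiplying linear intensities by 1000 adds log2(1000) to log values
        shift = np.log2(1000.0)
        p2 = mixed_model_de(make_expr(hn + shift, dcis + shift))["mixed_p"]
        np.testing.assert_allclose(p1, p2, atol=1e-12)


class TestSelection:
    def _table(self, posterior, mixed_p, fold):
        return pd.DataFrame({"gene_symbol": ["G1"], "posterior_prob_fc": [posterior],
                             "mixed_p": [mixed_p], "log_fc": [np.log2(fold)],
                             "fold_change": [fold]}, index=["p1"])

    def test_screened_but_not_selected(self, cfg):
        t = select_de_genes(self._table(0.98, 0.2, 2.0), cfg)
        assert bool(t["screened"].iloc[0]) and not bool(t["selected"].iloc[0])

    def test_middling_posterior_excluded(self, cfg):
        t = select_de_genes(self._table(0.5, 1e-6, 3.0), cfg)
        assert not bool(t["selected"].iloc[0])

    def test_selection_requires_fold_threshold(self, cfg):
        t = select_de_genes(self._table(0.99, 1e-4, 1.2), cfg)
        assert t["direction"].iloc[0] == "none" and not bool(t["selected"].iloc[0])

    def test_group_swap_mirrors_selection(self, cfg):
        rng = np.random.default_rng(15)
        hn = rng.normal(6, 0.2, (30, 8))
        dcis = hn + np.where(np.arange(30)[:, None] % 2 == 0, 1.0, -1.0)
        dcis = dcis + rng.normal(0, 0.1, (30, 8))
        fwd = run_mrna_de(make_expr(hn, dcis), cfg)
        rev = run_mrna_de(make_expr(dcis, hn), cfg)
        f_sel = fwd.table[fwd.table["selected"]]
        r_sel = rev.table[rev.table["selected"]]
        assert set(f_sel.index) == set(r_sel.index)
        joined = f_sel.join(r_sel, lsuffix="_f", rsuffix="_r")
        np.testing.assert_allclose(joined["fold_change_f"] * joined["fold_change_r"],
                                   1.0, rtol=1e-9)
        assert ((joined["direction_f"] == "over")
                == (joined["direction_r"] == "under")).all()

    def test_planted_gene_recovery_in_sensitivity_mode(self):
        """50 planted >= 1.8-fold genes among 2 000 probes: selection
        sensitivity >= 0.9 with false-selection rate <= 0.02 when the screen
        runs at its sensitivity threshold (fold change > 1)."""
        cfg = PipelineConfig(fc_screen=1.0)
        tp = fp = n_true = n_null = 0
        for seed in range(5):
            d = planted_design(seed=4000 + seed, n_gene_effects=50,
                               gene_effect_log2=np.log2(1.8),
                               n_coupled_pairs=0, n_mirna_effects=0)
            res = run_mrna_de(simulate_expression_dataset(d), cfg)
            truth = set(d.planted_gene_effects) & set(res.table.index)
            called = set(res.selected_probes)
            tp += len(truth & called)
            n_true += len(truth)
            fp += len(called - truth)
            n_null += len(set(res.table.index) - truth)
        assert tp / n_true >= 0.9
        assert fp / n_null <= 0.02
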