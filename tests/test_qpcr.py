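import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dcismir.config import PipelineConfig
from dcismir.containers import GROUP_LESION, GROUP_NORMAL, GROUP_POOL
from dcismir.qpcr import (COMPARISONS, ddct_fold_change, filter_nonexpressed,
                          global_median_normalize, multiple_testing_tiers,
                          pooled_reference_ttest, run_mirna_de)
from dcismir.simulate import SimulationDesign, simulate_ct_dataset

from conftest import make_ct


def ct_with_censoring(n_pool_censored, n_hn_censored, n_dcis_censored):
    """One feature with the requested undetected counts, plus two always-
    detected companions (the normalization needs >= 3 features)."""
    row = ([40.0] * n_pool_censored + [30.0] * (3 - n_pool_censored)
           + [40.0] * n_hn_censored + [30.0] * (8 - n_hn_censored)
           + [40.0] * n_dcis_censored + [30.0] * (8 - n_dcis_censored))
    filler = [25.0] * 19
    return make_ct([row, filler, [28.0] * 19])


class TestNonexpressionFilter:
    @pytest.mark.parametrize("pool,hn,dcis", list(itertools.product(
        [0, 2, 3], [0, 6, 7, 8], [0, 2, 6, 7, 8])))
    def test_rule_matches_truth_table(self, cfg, pool, hn, dcis):
        """Removal iff undetected in >2/3 pool replicates, or in >6/8 of both
        the normal and the lesion group (A or (B and C))."""
        ct = ct_with_censoring(pool, hn, dcis)
        kept, report = filter_nonexpressed(ct, cfg)
        expected = (pool > 2) or (hn > 6 and dcis > 6)
        assert bool(report.loc["miR-t0", "removed"]) == expected
        assert ("miR-t0" in kept.values.index) == (not expected)

    def test_alternative_precedence_differs(self):
        # detected in pool, dead in HN only: retained under A|(B&C),
        # removed... still retained under (A|B)&C since C is false
        cfg2 = PipelineConfig(filter_precedence="or_and")
        ct = ct_with_censoring(0, 8, 8)
        _, report = filter_nonexpressed(ct, cfg2)
        assert bool(report.loc["miR-t0", "removed"])

    def test_missing_group_rejected(self, cfg):
        ct = make_ct(np.full((3, 16), 30.0), n_pool=0)
        # zero pool columns -> group absent
        with pytest.raises(ValueError, match="absent"):
            filter_nonexpressed(ct, cfg)


class TestNormalization:
    def test_sample_at_target_unchanged(self, cfg):
        ct = make_ct(np.tile([[10.0], [12.0], [14.0]], 19))
        dct = global_median_normalize(ct, cfg)
        np.testing.assert_allclose(dct.values.to_numpy(),
                                   ct.values.to_numpy())

    def test_shift_computed_from_median(self, cfg):
        ct = make_ct(np.tile([[20.0], [22.0], [24.0]], 19))
        dct = global_median_normalize(ct, cfg)
        np.testing.assert_allclose(dct.values.iloc[:, 0], [10.0, 12.0, 14.0])
        assert dct.offsets.iloc[0] == pytest.approx(10.0)

    def test_every_sample_median_hits_target(self, cfg):
        rng = np.random.default_rng(4)
        ct = make_ct(rng.uniform(18, 36, size=(31, 19)))
        dct = global_median_normalize(ct, cfg)
        np.testing.assert_allclose(dct.values.median(axis=0), 12.0, atol=1e-12)

    def test_idempotent(self, cfg):
        rng = np.random.default_rng(5)
        ct = make_ct(rng.uniform(18, 36, size=(15, 19)))
        once = global_median_normalize(ct, cfg)
        twice = global_median_normalize(once, cfg)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_too_few_features_rejected(self, cfg):
        ct = make_ct(np.full((2, 19), 30.0))
        with pytest.raises(ValueError, match="median unstable"):
            global_median_normalize(ct, cfg)


class TestDdctFold:
    def test_equal_means_give_unit_fold(self, cfg):
        dct = global_median_normalize(make_ct(np.full((3, 19), 30.0)), cfg)
        for comparison in COMPARISONS:
            fc = ddct_fold_change(dct, comparison)
            np.testing.assert_allclose(fc["fold_change"], 1.0)

    @pytest.mark.parametrize("ddct,fold", [(-1.0, 2.0), (3.0, 0.125)])
    def test_fold_is_two_to_minus_ddct(self, cfg, ddct, fold):
        # plant a pure DCIS shift of `ddct` cycles on feature 0
        base = np.full((5, 19), 30.0)
        base[0, 11:] += ddct
        base[1] = 22.0
        base[2] = 24.0
        base[3] = 26.0
        base[4] = 28.0
        dct = global_median_normalize(make_ct(base), cfg)
        fc = ddct_fold_change(dct, "DCIS-HN")
        assert fc.loc["miR-t0", "fold_change"] == pytest.approx(fold)

    def test_planted_effect_recovered_exactly_without_noise(self, cfg):
        design = SimulationDesign(n_mirna=10, rng_seed=1,
                                  mirna_sd_biological=0.0,
                                  mirna_sd_technical=0.0,
                                  dropout_midpoint=np.inf, dropout_steepness=0.0,
                                  planted_mirna_effects={"miR-sim-0001": 2.0})
        ct = simulate_ct_dataset(design)
        dct = global_median_normalize(ct, cfg)
        fc = ddct_fold_change(dct, "DCIS-HN")
        assert fc.loc["miR-sim-0001", "fold_change"] == pytest.approx(4.0)

    def test_fold_reciprocity_under_group_swap(self, cfg):
        rng = np.random.default_rng(9)
        values = rng.uniform(20, 32, size=(7, 19))
        ct = make_ct(values)
        dct = global_median_normalize(ct, cfg)
        fwd = ddct_fold_change(dct, "DCIS-HN")
        # swap the HN/DCIS labels and recompute
        swapped_ann = ct.annotation.table.copy()
        swap = {GROUP_NORMAL: GROUP_LESION, GROUP_LESION: GROUP_NORMAL}
        swapped_ann["group"] = [swap.get(g, g) for g in swapped_ann["group"]]
        from dcismir.containers import CtMatrix, SampleAnnotation
        ct_swapped = CtMatrix(values=dct.values,
                              annotation=SampleAnnotation(swapped_ann),
                              ct_max=ct.ct_max, normalized=True)
        rev = ddct_fold_change(ct_swapped, "DCIS-HN")
        np.testing.assert_allclose(fwd["fold_change"] * rev["fold_change"],
                                   1.0, rtol=1e-12)

    def test_all_censored_group_flagged_undefined(self, cfg):
        vals = np.full((3, 19), 30.0)
        vals[0, 11:] = 40.0  # every DCIS sample undetected
        dct = global_median_normalize(make_ct(vals), cfg)
        fc = ddct_fold_change(dct, "DCIS-HN")
        assert bool(fc.loc["miR-t0", "undefined"])


class TestPooledTtest:
    def test_kappa_one_reduces_to_welch(self):
        cfg1 = PipelineConfig(pool_size=1)
        rng = np.random.default_rng(21)
        dct = global_median_normalize(make_ct(rng.uniform(20, 32, (40, 19))), cfg1)
        mine = pooled_reference_ttest(dct, "HN-PRM", cfg1)
        group = dct.group_values(GROUP_NORMAL).to_numpy()
        pool = dct.group_values(GROUP_POOL).to_numpy()
        ref = stats.ttest_ind(group, pool, axis=1, equal_var=False)
        np.testing.assert_allclose(mine["p_value"], ref.pvalue, rtol=1e-10)

    def test_inflating_kappa_never_decreases_p(self):
        rng = np.random.default_rng(22)
        ct = make_ct(rng.uniform(20, 32, (60, 19)))
        ps = []
        for pool_size in (1, 3, 9, 27):
            cfgk = PipelineConfig(pool_size=pool_size)
            dct = global_median_normalize(ct, cfgk)
            ps.append(pooled_reference_ttest(dct, "DCIS-PRM", cfgk)["p_value"])
        for lo, hi in zip(ps, ps[1:]):
            assert (hi >= lo - 1e-12).all()

    def test_paired_path_matches_scipy(self, cfg):
        rng = np.random.default_rng(23)
        dct = global_median_normalize(make_ct(rng.uniform(20, 32, (30, 19))), cfg)
        mine = pooled_reference_ttest(dct, "DCIS-HN", cfg)
        pairs = dct.annotation.paired_samples()
        d = dct.values[pairs["dcis_sample"]].to_numpy()
        h = dct.values[pairs["hn_sample"]].to_numpy()
        ref = stats.ttest_rel(d, h, axis=1)
        np.testing.assert_allclose(mine["p_value"], ref.pvalue, rtol=1e-10)

    def test_planted_shift_has_power(self, cfg):
        # 3-cycle paired shift with per-pair difference sd 0.5, 8 pairs:
        # p < 1e-4 in >= 99% of replicates (one replicate = one feature row;
        # noncentrality 3 / (0.5 / sqrt(8)) = 17)
        rng = np.random.default_rng(24)
        n_rep = 1000
        base = rng.uniform(22, 30, size=(n_rep, 8))
        hn = base
        dcis = base - 3.0 + rng.normal(0, 0.5, (n_rep, 8))
        pool = np.repeat(rng.uniform(22, 30, (n_rep, 1)), 3, axis=1)
        ct = make_ct(np.hstack([pool, hn, dcis]))
        p = pooled_reference_ttest(ct, "DCIS-HN", cfg)["p_value"]
        assert (p < 1e-4).mean() >= 0.99


class TestTiers:
    def test_flat_half_p_flags_nothing(self, cfg):
        tiers, info = multiple_testing_tiers(
            pd.Series(0.5, index=range(50)), cfg)
        assert (tiers["tier"] == "ns").all()

    def test_bonferroni_cut_at_panel_of_200(self, cfg):
        p = pd.Series([2.4e-4] + [0.5] * 199)
        tiers, info = multiple_testing_tiers(p, cfg)
        assert info["bonferroni_cut"] == pytest.approx(2.5e-4)
        assert tiers.loc[0, "tier"] == "bonferroni"

    def test_bh_matches_step_up_oracle(self, cfg):
        p = pd.Series([0.001, 0.01, 0.02, 0.03, 0.5])
        tiers, info = multiple_testing_tiers(p, cfg)

        def bh_oracle(pvals, q):
            m = len(pvals)
            order = np.argsort(pvals)
            flags = np.zeros(m, dtype=bool)
            k_max = 0
            for rank, idx in enumerate(order, start=1):
                if pvals[idx] <= rank * q / m:
                    k_max = rank
            flags[order[:k_max]] = True
            return flags

        np.testing.assert_array_equal(tiers["fdr"].to_numpy(),
                                      bh_oracle(p.to_numpy(), 0.05))
        assert info["realized_fdr_cut"] == pytest.approx(0.03)

    def test_tier_nesting(self, cfg):
        rng = np.random.default_rng(30)
        p = pd.Series(rng.uniform(0, 1, 400) ** 4)
        tiers, info = multiple_testing_tiers(p, cfg)
        assert info["bonferroni_cut"] <= cfg.alpha_nominal
        assert not (tiers["bonferroni"] & ~tiers["fdr"]).any()
        assert not (tiers["fdr"] & ~(p < cfg.fdr_level)).any()

    def test_empty_vector_rejected(self, cfg):
        with pytest.raises(ValueError, match="empty"):
            multiple_testing_tiers(pd.Series(dtype=float), cfg)


class TestRunMirnaDe:
    def test_zero_noise_null_has_empty_significant_set(self, cfg):
        design = SimulationDesign(n_mirna=20, rng_seed=2,
                                  mirna_sd_biological=0.0,
                                  mirna_sd_technical=0.0,
                                  dropout_midpoint=np.inf,
                                  dropout_steepness=0.0)
        res = run_mirna_de(simulate_ct_dataset(design), cfg)
        assert res.significant == []

    def test_fold_columns_satisfy_ddct_identity(self, cfg):
        design = SimulationDesign(n_mirna=50, rng_seed=3)
        res = run_mirna_de(simulate_ct_dataset(design), cfg)
        for comparison in COMPARISONS:
            np.testing.assert_allclose(
                res.table[f"fold_{comparison}"],
                np.exp2(-res.table[f"ddct_{comparison}"]), rtol=1e-12)

    def test_planted_recovery_single_run(self, cfg):
        from dcismir.simulate import planted_design
        d = planted_design(seed=5)
        res = run_mirna_de(simulate_ct_dataset(d), cfg)
        truth = set(d.planted_mirna_effects)
        assert truth <= set(res.significant_in("DCIS-HN"))
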