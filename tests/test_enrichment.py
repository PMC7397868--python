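import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, special, stats

from ric_activity.enrichment import (
    EnrichmentConfig,
    VariancePrior,
    adjust_p,
    enrichment_table,
    fit_variance_prior,
    impute_background,
    mean_log2_fc,
    median_normalize,
    moderated_t,
    population_flags,
    prepare_table,
)
from ric_activity.simulate import (
    BoundFractionModel,
    DistSpec,
    GeneratorConfig,
    generate_experiment,
)
from ric_activity.pipeline import run_enrichment

from conftest import make_table


class TestImputeBackground:
    def test_missing_cells_become_18_and_are_flagged(self, paired_metas):
        table = make_table(
            {"RIC_1": [np.nan, 20], "RIC_2": [19, 20], "RIC_3": [19, 20],
             "WCE_1": [21, 22], "WCE_2": [21, 22], "WCE_3": [21, 22]},
            paired_metas,
        )
        out = impute_background(table)
        assert out.values.loc["P001", "RIC_1"] == 18.0
        assert out.imputed.loc["P001", "RIC_1"]
        assert not out.imputed.loc["P002", "RIC_1"]
        # original untouched
        assert math.isnan(table.values.loc["P001", "RIC_1"])

    def test_complete_table_is_identity(self, paired_metas):
        table = make_table(
            {m[0]: [20.0, 21.0] for m in paired_metas}, paired_metas
        )
        out = impute_background(table)
        pd.testing.assert_frame_equal(out.values, table.values)
        assert not out.imputed.to_numpy().any()

    def test_fully_missing_group_has_zero_variance_after_fill(self):
        metas = [(f"noCL_{r}", "noCL", "WT", r, "B1") for r in (1, 2, 3)]
        table = make_table({m[0]: [np.nan] for m in metas}, metas)
        out = impute_background(table)
        vals = out.values.loc["P001"]
        assert (vals == 18.0).all() and vals.var(ddof=1) == 0.0


class TestMedianNormalize:
    def test_odd_count_median_subtraction(self):
        metas = [("S1", "WCE", "WT", 1, "B1")]
        table = make_table({"S1": [17.0, 18.0, 19.0]}, metas)
        out = median_normalize(table)
        assert out.values["S1"].tolist() == [-1.0, 0.0, 1.0]

    def test_even_count_uses_mean_of_central_values(self):
        metas = [("S1", "WCE", "WT", 1, "B1")]
        table = make_table({"S1": [16.0, 18.0, 20.0, 22.0]}, metas)
        out = median_normalize(table)
        assert out.values["S1"].tolist() == [-3.0, -1.0, 1.0, 3.0]

    def test_already_centered_column_unchanged(self):
        metas = [("S1", "WCE", "WT", 1, "B1")]
        table = make_table({"S1": [-1.0, 0.0, 1.0]}, metas)
        out = median_normalize(table)
        assert out.values["S1"].tolist() == [-1.0, 0.0, 1.0]

    def test_all_missing_column_rejected(self):
        metas = [("S1", "WCE", "WT", 1, "B1")]
        table = make_table({"S1": [np.nan, np.nan]}, metas)
        with pytest.raises(ValueError, match="all-missing"):
            median_normalize(table)

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=2,
            max_size=25,
        )
    )
    def test_post_median_is_zero(self, column):
        metas = [("S1", "WCE", "WT", 1, "B1")]
        table = make_table({"S1": column}, metas)
        out = median_normalize(table)
        assert abs(out.values["S1"].median()) <= 1e-12


class TestMeanLog2FC:
    def test_unpaired_cl_vs_nocl(self):
        metas = [(f"RIC_{r}", "RIC", "WT", r, "B1") for r in range(1, 7)] + [
            (f"noCL_{r}", "noCL", "WT", r, "B1") for r in range(1, 4)
        ]
        table = make_table({m[0]: [20.0 if "RIC" in m[0] else 18.0] for m in metas}, metas)
        fc, _ = mean_log2_fc(
            table, [m[0] for m in metas[:6]], [m[0] for m in metas[6:]], paired=False
        )
        assert fc.iloc[0] == 2.0

    def test_paired_differences_and_mean(self, paired_metas):
        table = make_table(
            {"RIC_1": [21.0], "RIC_2": [22.0], "RIC_3": [23.0],
             "WCE_1": [20.0], "WCE_2": [20.0], "WCE_3": [20.0]},
            paired_metas,
        )
        mean, diffs = mean_log2_fc(
            table, ["RIC_1", "RIC_2", "RIC_3"], ["WCE_1", "WCE_2", "WCE_3"], paired=True
        )
        assert sorted(diffs.iloc[0].tolist()) == [1.0, 2.0, 3.0]
        assert mean.iloc[0] == 2.0

    def test_identical_groups_give_zero(self, paired_metas):
        table = make_table({m[0]: [20.0] for m in paired_metas}, paired_metas)
        mean, _ = mean_log2_fc(
            table, ["RIC_1", "RIC_2", "RIC_3"], ["WCE_1", "WCE_2", "WCE_3"], paired=True
        )
        assert mean.iloc[0] == 0.0

    def test_unmatched_replicates_rejected(self, paired_metas):
        table = make_table({m[0]: [20.0] for m in paired_metas}, paired_metas)
        with pytest.raises(ValueError, match="matched"):
            mean_log2_fc(table, ["RIC_1", "RIC_2"], ["WCE_1", "WCE_3"], paired=True)


def _prior_oracle(s2, d):
    """Straight transcription of the closed-form moment equations.

    Independent of the implementation: the trigamma equation is solved by
    bracketed root finding instead of Newton iteration.
    """
    s2 = np.asarray(s2, float)
    e = np.log(s2) - special.digamma(d / 2) + np.log(d / 2)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, d / 2)
    if evar <= 0:
        return math.inf, math.exp(emean)
    half_d0 = optimize.brentq(
        lambda x: special.polygamma(1, x) - evar, 1e-8, 1e8, xtol=1e-14, rtol=1e-15
    )
    d0 = 2 * half_d0
    s0sq = math.exp(emean + special.digamma(half_d0) - math.log(half_d0))
    return d0, s0sq


class TestVariancePrior:
    def test_equal_variances_give_infinite_d0(self):
        prior = fit_variance_prior([0.5] * 10, 4.0)
        assert math.isinf(prior.d0)
        # zero excess dispersion: prior scale is the bias-corrected
        # geometric mean exp(mean(e)) with e = ln s2 - psi(d/2) + ln(d/2)
        expected = math.exp(math.log(0.5) - special.digamma(2.0) + math.log(2.0))
        assert prior.s0sq == pytest.approx(expected, rel=1e-12)

    def test_matches_independent_closed_form_oracle(self, rng):
        s2 = (1.3 * 5 / rng.chisquare(5, 100)) * rng.chisquare(3, 100) / 3
        prior = fit_variance_prior(s2, 3.0)
        d0, s0sq = _prior_oracle(s2, 3.0)
        assert prior.d0 == pytest.approx(d0, abs=1e-8 * d0)
        assert prior.s0sq == pytest.approx(s0sq, abs=1e-8)

    def test_recovers_simulated_hyperparameters(self):
        rng = np.random.default_rng(42)
        d0, s0sq, d, m = 4.0, 1.0, 2, 2000
        sigma2 = s0sq * d0 / rng.chisquare(d0, m)
        s2 = sigma2 * rng.chisquare(d, m) / d
        prior = fit_variance_prior(s2, float(d))
        assert prior.d0 == pytest.approx(d0, rel=0.25)
        assert prior.s0sq == pytest.approx(s0sq, rel=0.10)

    def test_too_few_usable_variances_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_variance_prior([0.0, 0.5], 2.0)


class TestModeratedT:
    def test_d0_zero_limit_equals_ordinary_one_sample_t(self):
        values = np.array([0.5, 1.0, 1.5])
        prior = VariancePrior(d0=0.0, s0sq=1.0)  # unmoderated limit
        t, df, p = moderated_t(values.mean(), values.var(ddof=1), 3, prior)
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert df == pytest.approx(2.0, abs=1e-9)
        assert p == pytest.approx(0.0742, abs=1e-4)

    def test_zero_mean_gives_t_zero_p_one(self):
        prior = VariancePrior(d0=4.0, s0sq=0.3)
        t, _, p = moderated_t(0.0, 0.5, 3, prior)
        assert t == 0.0 and p == 1.0

    def test_infinite_d0_uses_normal_distribution(self):
        prior = VariancePrior(d0=math.inf, s0sq=1.0)
        t, df, p = moderated_t(2.0, 123.0, 4, prior)  # s_g^2 ignored at d0=inf
        assert t == pytest.approx(2.0 * 2.0 / 1.0)
        assert math.isinf(df)
        assert p == pytest.approx(2 * stats.norm.sf(4.0), rel=1e-12)

    def test_t_monotone_in_mean_and_p_monotone_in_t(self):
        prior = VariancePrior(d0=3.0, s0sq=0.2)
        means = np.linspace(0.1, 3.0, 15)
        t, _, p = moderated_t(means, 0.4, 3, prior)
        assert (np.diff(t) > 0).all()
        assert (np.diff(p) < 0).all()


class TestAdjustP:
    def test_bonferroni_multiplies_by_m(self):
        out = adjust_p([0.001] + [0.5] * 99, "bonferroni")
        assert out[0] == pytest.approx(0.1)

    def test_bh_step_up_hand_computed(self):
        out = adjust_p([0.01, 0.02, 0.03, 0.04], "fdr")
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        for method in ("fdr", "bonferroni"):
            assert adjust_p([0.03], method)[0] == pytest.approx(0.03)

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=40)
    )
    def test_bh_is_monotone_step_up(self, ps):
        q = adjust_p(ps, "fdr")
        order = np.argsort(ps)
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()
        bonf = adjust_p(ps, "bonferroni")
        assert (np.asarray(bonf) >= np.asarray(ps) - 1e-12).all()


class TestPopulationFlags:
    def _table(self):
        metas = [(f"RIC_{r}", "RIC", "WT", r, "B1") for r in (1, 2, 3)] + [
            (f"WCE_{r}", "WCE", "WT", r, "B1") for r in (1, 2, 3)
        ]
        nan = np.nan
        return make_table(
            {
                "RIC_1": [20, 20, nan, nan],
                "RIC_2": [20, nan, nan, nan],
                "RIC_3": [20, nan, nan, nan],
                "WCE_1": [21, nan, 21, nan],
                "WCE_2": [21, nan, 21, nan],
                "WCE_3": [21, nan, 21, nan],
            },
            metas,
            proteins=["both", "ric", "wce", "none"],
        )

    def test_flag_assignment_and_dropping(self):
        table = self._table()
        flags = population_flags(
            table, ["RIC_1", "RIC_2", "RIC_3"], ["WCE_1", "WCE_2", "WCE_3"]
        )
        assert flags["both"] == "both"
        assert flags["ric"] == "ric_only"
        assert flags["wce"] == "wce_only"
        assert "none" not in flags.index

    def test_detection_uses_pre_imputation_missingness(self):
        table = impute_background(self._table())
        flags = population_flags(
            table, ["RIC_1", "RIC_2", "RIC_3"], ["WCE_1", "WCE_2", "WCE_3"]
        )
        assert flags["ric"] == "ric_only"
        assert "none" not in flags.index


class TestEnrichmentTable:
    def test_zero_noise_lossless_capture_gives_zero_fold_change(self):
        cfg = GeneratorConfig(
            n_proteins=40,
            n_complexes=4,
            sigma_rep=0.0,
            sigma_cplx=0.0,
            batch_effect_sd=0.0,
            bound_fraction=BoundFractionModel(fraction_high=1.0, high=DistSpec("fixed", (1.0,))),
            crosslink_eff=DistSpec("fixed", (1.0,)),
            capture_eff=1.0,
        )
        table, _ = generate_experiment(cfg, seed=0)
        rows = run_enrichment(table, "wce")
        np.testing.assert_allclose(rows["mean_log2fc"], 0.0, atol=1e-9)

    def test_high_phi_stratum_ranks_above_low_phi_stratum(self):
        cfg = GeneratorConfig(
            n_proteins=60,
            n_complexes=0,
            sigma_rep=0.0,
            sigma_cplx=0.0,
            batch_effect_sd=0.0,
            bound_fraction=BoundFractionModel(
                fraction_high=0.5,
                high=DistSpec("fixed", (0.8,)),
                low=DistSpec("fixed", (0.05,)),
            ),
            crosslink_eff=DistSpec("fixed", (0.5,)),
        )
        table, truth = generate_experiment(cfg, seed=1)
        rows = run_enrichment(table, "wce").set_index("protein_id")
        # monotonicity in phi holds for quantified proteins; fully censored
        # RIC rows are pinned at the imputation floor instead
        quantified = rows[(rows["n_imputed_ric"] == 0) & (rows["n_imputed_wce"] == 0)]
        hi = [p for p in truth.index[truth.bound_fraction == 0.8] if p in quantified.index]
        lo = [p for p in truth.index[truth.bound_fraction == 0.05] if p in quantified.index]
        assert hi and lo
        assert quantified.loc[hi, "mean_log2fc"].min() > quantified.loc[lo, "mean_log2fc"].max()

    def test_nocl_mode_unbalanced_pooled_contrast(self):
        table, _ = generate_experiment(GeneratorConfig(n_proteins=300, n_complexes=20), seed=4)
        b1 = table.subset(table.sample_ids_where(batch="B1"))
        rows = run_enrichment(b1, "nocl")
        assert (rows["df_total"] >= 4.0).all()  # d = n1 + n2 - 2 = 4 plus prior df
        assert rows["p"].between(0, 1).all()
        # strong RNA binders are enriched over the background capture
        assert rows["mean_log2fc"].max() > 2

    def test_prior_is_attached_and_valid(self):
        table, _ = generate_experiment(GeneratorConfig(n_proteins=200, n_complexes=10), seed=2)
        rows = run_enrichment(table, "wce")
        prior = rows.attrs["prior"]
        assert prior.d0 > 0 and prior.s0sq > 0


def test_prepare_table_order_impute_then_center(paired_metas):
    table = make_table(
        {"RIC_1": [np.nan, 20, 22], "RIC_2": [19, 20, 22], "RIC_3": [19, 20, 22],
         "WCE_1": [21, 22, 23], "WCE_2": [21, 22, 23], "WCE_3": [21, 22, 23]},
        paired_metas,
    )
    out = prepare_table(table)
    # imputed cell participates in the median
    assert out.imputed.loc["P001", "RIC_1"]
    for col in out.values.columns:
        assert abs(out.values[col].median()) <= 1e-12
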