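"""Design construction, moderated statistics, BH-FDR and mixed models."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.api import OLS
from statsmodels.stats.multitest import multipletests

import omiqc as oq
from conftest import toy_matrix
from omiqc.stability import Design


def _metadata(rows):
    md = pd.DataFrame(rows, columns=["sample_id", "individual", "matrix",
                                     "time_h", "temperature", "centrifugation_g"])
    return oq.validate_metadata(md)


@pytest.fixture(scope="module")
def plasma_md():
    rows = []
    for ind in ("I01", "I02", "I03"):
        for temp in ("4C", "RT"):
            for t in (0, 2, 4, 8):
                rows.append((f"p_{ind}_{temp}_{t}", ind, "plasma", t, temp, 2000))
    return _metadata(rows)


class TestBuildDesign:
    def test_time_only(self, plasma_md):
        design = oq.build_design(plasma_md, oq.DesignSpec("plasma", ("time",)))
        assert list(design.X.columns) == ["intercept", "time_h"]
        assert design.factor_map == {"time": ["time_h"]}

    def test_time_temperature_interaction_has_four_columns(self, plasma_md):
        spec = oq.DesignSpec("plasma", ("time", "temperature", "time:temperature"))
        design = oq.build_design(plasma_md, spec)
        assert design.X.shape[1] == 4
        # RT dummy with 4C as reference
        assert "temperature[RT]" in design.X.columns
        assert "time_h:temperature[RT]" in design.X.columns

    def test_serum_spec_with_temperature_rejected(self):
        with pytest.raises(ValueError):
            oq.DesignSpec("serum", ("time", "temperature"))

    def test_term_cannot_be_fixed_and_random(self):
        with pytest.raises(ValueError):
            oq.DesignSpec("plasma", ("individual", "time"), ("individual",))

    def test_single_level_factor_rejected(self):
        rows = [(f"s{t}", "I01", "plasma", t, "RT", 2000) for t in (0, 2, 4, 8)]
        md = _metadata(rows)
        with pytest.raises(ValueError, match="single level"):
            oq.build_design(md, oq.DesignSpec("plasma", ("individual", "time")))


class TestBenjaminiHochberg:
    @pytest.mark.parametrize("p, expected", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.2], [0.2]),
        ([0.005, 0.5], [0.01, 0.5]),
    ])
    def test_hand_examples(self, p, expected):
        np.testing.assert_allclose(oq.benjamini_hochberg(p), expected)

    def test_missing_values_excluded_and_reinserted(self):
        adj = oq.benjamini_hochberg([0.005, np.nan, 0.5])
        assert np.isnan(adj[1])
        np.testing.assert_allclose(adj[[0, 2]], [0.01, 0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            oq.benjamini_hochberg([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_statsmodels(self, p):
        ours = oq.benjamini_hochberg(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_adjusted_at_least_raw_and_order_preserving(self, p):
        p = np.array(p)
        adj = oq.benjamini_hochberg(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestLinearEbayes:
    def design_1col(self, x, name="x"):
        X = pd.DataFrame({"intercept": 1.0, name: x},
                         index=[f"s{j}" for j in range(len(x))])
        return Design(X=X, factor_map={name: [name]},
                      spec=oq.DesignSpec("plasma", ("time",)))

    def test_hand_ols_without_moderation(self):
        m = toy_matrix([[1.0, 2.0, 2.0, 3.0]], stage="imputed",
                       samples=["s0", "s1", "s2", "s3"])
        res = oq.fit_linear_ebayes(m, self.design_1col([0, 0, 1, 1]), prior_df=0)
        row = res.table.iloc[0]
        assert row["estimate"] == pytest.approx(1.0)
        assert row["statistic"] == pytest.approx(np.sqrt(2), rel=1e-9)

    def test_prior_df_zero_matches_per_feature_ols(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=10)
        Y = rng.normal(size=(15, 10))
        m = toy_matrix(Y, stage="imputed")
        design = self.design_1col(x)
        res = oq.fit_linear_ebayes(m, design, prior_df=0).table
        for g in range(15):
            fit = OLS(Y[g], design.X.to_numpy()).fit()
            assert res.iloc[g]["statistic"] == pytest.approx(fit.tvalues[1])
            assert res.iloc[g]["p"] == pytest.approx(fit.pvalues[1])

    def test_equal_variances_collapse_to_shared_prior(self):
        s2 = np.full(30, 0.7)
        post, d0, s02 = oq.moderate_variances(s2, df=5)
        assert np.isinf(d0)
        np.testing.assert_allclose(post, 0.7)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(1000, 24))
        x = np.tile([0.0, 2.0, 4.0, 8.0], 6)
        m = toy_matrix(Y, stage="imputed")
        res = oq.fit_linear_ebayes(m, self.design_1col(x, "time_h"))
        from scipy import stats
        d = stats.kstest(res.table["p"], "uniform").statistic
        assert d < 0.05

    def test_multi_df_factor_reports_moderated_f(self, small_imputed):
        imputed, metadata, _ = small_imputed
        res = oq.fit_linear_ebayes(imputed, oq.build_design(metadata, oq.PLASMA_LIMMA))
        ind = res.table[res.table["factor"] == "individual"]
        assert ind["estimate"].isna().all()        # multi-df: F statistic, no slope
        assert (ind["statistic"].dropna() >= 0).all()
        # dominant individual effects: most metabolites significant
        assert oq.count_significant(res, "individual") > 0.8 * len(ind)

    def test_degenerate_feature_flagged(self):
        m = toy_matrix([[5.0] * 6, [1, 2, 3, 4, 5, 6]], stage="imputed")
        res = oq.fit_linear_ebayes(m, self.design_1col(np.arange(6)), prior_df=0)
        flags = res.table.set_index("feature_id")["fit_flag"]
        assert flags["f0"] == "degenerate" and flags["f1"] == "ebayes"
        assert np.isnan(res.table.set_index("feature_id").loc["f0", "p"])

    def test_invariant_to_sample_column_order(self, small_imputed):
        imputed, metadata, _ = small_imputed
        design = oq.build_design(metadata, oq.PLASMA_LIMMA)
        res1 = oq.fit_linear_ebayes(imputed, design).table
        shuffled = oq.OmicsMatrix(
            imputed.data[list(imputed.samples[::-1])], stage="imputed")
        res2 = oq.fit_linear_ebayes(shuffled, design).table
        pd.testing.assert_frame_equal(res1, res2)


class TestMixedStability:
    def test_zero_individual_variance_triggers_fallback(self):
        params = oq.SimulationParams(n_individuals=4, n_metabolites=40,
                                     n_proteins=5, sd_individual_metab=0.0,
                                     seed=2, lod_quantile=0.0)
        metab, _, md, _ = oq.generate_cohort(params)
        imp = oq.impute_min_det(oq.glog_transform(metab))
        res = oq.fit_mixed_stability(imp, md, oq.PLASMA_MIXED)
        frac = (res.table["fit_flag"] == "anova_fallback").mean()
        assert frac >= 0.6

    def test_slope_estimates_unbiased(self):
        params = oq.SimulationParams(n_metabolites=150, n_proteins=5, seed=9,
                                     temp_interaction_multiplier=1.0,
                                     slope_abs_range=(0.1, 0.5),
                                     lod_quantile=0.0)
        metab, _, md, truth = oq.generate_cohort(params)
        log2 = toy_matrix(np.log2(metab.values()), stage="imputed",
                          features=list(metab.features),
                          samples=list(metab.samples))
        res = oq.fit_mixed_stability(log2, md, oq.PLASMA_MIXED)
        tt = res.table[res.table["factor"] == "time"].set_index("feature_id")
        aff = truth.metabolites[truth.metabolites["affected_plasma"]]
        err = tt.loc[aff.index, "estimate"] - aff["delta_plasma"]
        se = err.std(ddof=1) / np.sqrt(len(err))
        assert abs(err.mean()) < 3 * se

    def test_requires_random_term(self, small_imputed):
        imputed, metadata, _ = small_imputed
        with pytest.raises(ValueError):
            oq.fit_mixed_stability(imputed, metadata,
                                   oq.DesignSpec("plasma", ("time",)))


class TestCountSignificant:
    def make_result(self, p_adj):
        table = pd.DataFrame({
            "feature_id": [f"f{i}" for i in range(len(p_adj))],
            "factor": "time", "estimate": 0.0, "statistic": 0.0, "df": 10.0,
            "p": p_adj, "p_adj": p_adj, "fit_flag": "mixed"})
        return oq.StabilityResult(table=table, method="mixed")

    def test_counts_below_alpha(self):
        assert oq.count_significant(self.make_result([0.01, 0.06, 0.04]), "time") == 2

    def test_all_missing_counts_zero(self):
        assert oq.count_significant(self.make_result([np.nan, np.nan]), "time") == 0

    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError):
            oq.count_significant(self.make_result([0.01]), "temperature")


def test_timepoint_contrast_detects_affected_features(small_imputed):
    imputed, metadata, truth = small_imputed
    res = oq.fit_timepoint_contrast(imputed, metadata, "plasma", temperature="RT")
    assert res.factors() == ["time8_vs_0"]
    tab = res.table.set_index("feature_id")
    # RT-dominant features shifting by >= 1 log2 unit at 8 h should be caught
    strong = truth.metabolites.query(
        "affected_plasma and dominant_temp == 'RT' and abs(delta_plasma) * 8 >= 1")
    aff = [f for f in strong.index if f in tab.index]
    assert len(aff) >= 3
    assert (tab.loc[aff, "p"] < 0.05).all()
    assert (tab.loc[aff, "p_adj"] < 0.05).mean() >= 0.8
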