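import numpy as np
import pandas as pd
import pytest
from scipy import stats

from csrnc import diffexpr as de
from oracles import mannwhitney_oracle, signed_rank_oracle_all_positive


def _two_group_design(n1, n2):
    meta = pd.DataFrame(
        {"group": ["ref"] * n1 + ["alt"] * n2},
        index=[f"s{i}" for i in range(n1 + n2)],
    )
    return meta, de.make_design(meta, "group", reference="ref")


class TestFitRegionModels:
    def test_noiseless_fit_is_exact(self):
        meta, design = _two_group_design(3, 3)
        y = pd.DataFrame({"r1": [2.0, 2.0, 2.0, 4.0, 4.0, 4.0]}, index=meta.index)
        fit = de.fit_region_models(y, design)[0]
        assert fit.coefficients["group[alt]"] == pytest.approx(2.0)
        assert fit.coefficients["intercept"] == pytest.approx(2.0)
        assert fit.s2 == pytest.approx(0.0, abs=1e-20)
        assert fit.df_residual == 4

    def test_masked_samples_dropped_per_region(self):
        meta, design = _two_group_design(4, 4)
        y = pd.DataFrame(
            {"r1": [1.0, np.nan, 1.0, 1.0, 3.0, 3.0, np.nan, 3.0]}, index=meta.index
        )
        fit = de.fit_region_models(y, design)[0]
        assert fit.n_obs == 6
        assert fit.df_residual == 4
        assert fit.coefficients["group[alt]"] == pytest.approx(2.0)

    def test_rank_deficient_design_names_columns(self):
        meta = pd.DataFrame({"group": ["a"] * 4 + ["b"] * 4})
        X = de.make_design(meta, "group", reference="a").X
        X["dup"] = X["group[b]"]
        with pytest.raises(de.DesignError, match="rank deficient"):
            de.DesignMatrix(X)

    def test_coefficients_unbiased_and_s2_consistent(self):
        # Monte-Carlo calibration of the OLS stage
        rng = np.random.default_rng(5)
        meta, design = _two_group_design(25, 25)
        X = design.X.to_numpy()
        beta = np.array([1.0, 0.7])
        sigma = 1.3
        coefs, s2s = [], []
        for _ in range(400):
            y = X @ beta + rng.normal(0, sigma, 50)
            fit = de.fit_region_models(
                pd.DataFrame({"r": y}, index=meta.index), design
            )[0]
            coefs.append(fit.coefficients["group[alt]"])
            s2s.append(fit.s2)
        assert np.mean(coefs) == pytest.approx(0.7, abs=0.05)
        assert np.mean(s2s) == pytest.approx(sigma**2, rel=0.05)


class TestModeration:
    def test_identical_variances_full_shrinkage(self):
        d0, s0, s2t = de.moderate_variances([2.0, 2.0, 2.0, 2.0], d=10)
        assert np.isinf(d0)
        assert s0 == pytest.approx(2.0)
        assert s2t == pytest.approx([2.0] * 4)

    def test_shrinkage_formula_limits(self):
        s2 = np.array([0.5, 1.0, 4.0])
        # d0 -> 0: no shrinkage
        tiny = (1e-12 * 1.0 + 10 * s2) / (1e-12 + 10)
        assert tiny == pytest.approx(s2, rel=1e-9)
        # large d0: full shrinkage toward s0^2
        big = (1e12 * 1.0 + 10 * s2) / (1e12 + 10)
        assert big == pytest.approx(np.ones(3), rel=1e-9)

    def test_prior_recovery_on_scaled_f_variances(self):
        rng = np.random.default_rng(17)
        d, d0_true, s0_true = 10, 4.0, 1.0
        G = 10_000
        s2 = (
            s0_true
            * (rng.chisquare(d, G) / d)
            / (rng.chisquare(d0_true, G) / d0_true)
        )
        d0, s0, s2t = de.moderate_variances(s2, d)
        assert d0 == pytest.approx(d0_true, rel=0.2)
        assert s0 == pytest.approx(s0_true, rel=0.1)
        assert np.all(s2t > 0)

    def test_moderated_t_reduces_to_ordinary_t(self):
        # with s~2 = s2 the moderated statistic equals the classical t
        t, _ = de.moderated_t(1.5, 0.5, 2.0, 2.0, d=10, d0=0.0)
        assert t == pytest.approx(3.0)

    def test_doubling_posterior_variance_scales_t(self):
        t1, _ = de.moderated_t(1.0, 0.5, 2.0, 2.0, d=10, d0=4.0)
        t2, _ = de.moderated_t(1.0, 0.5, 2.0, 4.0, d=10, d0=4.0)
        assert t2 == pytest.approx(t1 / np.sqrt(2.0))

    def test_zero_variance_degenerate(self):
        t, p = de.moderated_t(1.0, 0.0, 0.0, 0.5, d=5, d0=2.0)
        assert np.isinf(t) and p == 0.0
        t0, p0 = de.moderated_t(0.0, 0.0, 0.0, 0.5, d=5, d0=2.0)
        assert (t0, p0) == (0.0, 1.0)

    def test_null_type_i_error_calibrated(self):
        rng = np.random.default_rng(29)
        G, n1, n2 = 4000, 6, 6
        n, d = n1 + n2, n1 + n2 - 2
        sigma2 = 1.0 / (rng.chisquare(4.0, G) / 4.0)
        Y = rng.standard_normal((G, n)) * np.sqrt(sigma2)[:, None]
        X = np.column_stack([np.ones(n), np.r_[np.zeros(n1), np.ones(n2)]])
        xtxi = np.linalg.inv(X.T @ X)
        B = Y @ X @ xtxi.T
        resid = Y - B @ X.T
        s2 = (resid**2).sum(axis=1) / d
        d0, _, s2t = de.moderate_variances(s2, d)
        unit = np.sqrt(xtxi[1, 1])
        tmod = B[:, 1] / (unit * np.sqrt(s2t))
        p = 2 * stats.t.sf(np.abs(tmod), d + d0)
        assert 0.035 < (p < 0.05).mean() < 0.065


class TestBonferroni:
    def test_ten_region_panel_example(self):
        assert de.bonferroni([0.004], m=10) == pytest.approx([0.04])

    def test_capped_at_one(self):
        assert de.bonferroni([0.2], m=10) == pytest.approx([1.0])

    def test_identity_for_single_test(self):
        assert de.bonferroni([0.3], m=1) == pytest.approx([0.3])

    def test_never_below_raw_p(self):
        p = np.array([0.001, 0.5, 0.9])
        assert np.all(de.bonferroni(p) >= p)


class TestModeratedPipeline:
    def test_end_to_end_two_group_contrast(self):
        rng = np.random.default_rng(3)
        meta, design = _two_group_design(8, 8)
        regions = {}
        for j in range(10):
            shift = 3.0 if j == 0 else 0.0  # one truly changed region
            regions[f"I{j}"] = np.r_[
                rng.normal(2, 0.5, 8), rng.normal(2 + shift, 0.5, 8)
            ]
        log2 = pd.DataFrame(regions, index=meta.index)
        result = de.moderated_de(log2, design, "group[alt]")
        assert result.set_index("region").loc["I0", "significant"]
        assert result["p_bonferroni"].max() <= 1.0
        assert (result["p_bonferroni"] >= result["p"] - 1e-15).all()


class TestRankCompare:
    def test_paired_identical_samples(self):
        assert de.rank_compare([1, 2, 3], [1, 2, 3], paired=True)[1] == 1.0

    def test_exact_signed_rank_all_positive_n5(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        _, p = de.rank_compare(x, x - 1.0, paired=True)
        assert p == pytest.approx(2 / 32)
        assert p == pytest.approx(signed_rank_oracle_all_positive(5))

    def test_unpaired_matches_enumeration_oracle(self):
        x = [1.3, 2.1, 8.4, 9.9]
        y = [0.2, 4.4, 5.1, 6.0]
        _, p = de.rank_compare(x, y, paired=False)
        assert p == pytest.approx(mannwhitney_oracle(x, y), abs=1e-12)

    def test_paired_length_mismatch_rejected(self):
        with pytest.raises(de.DesignError):
            de.rank_compare([1, 2], [1, 2, 3], paired=True)
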