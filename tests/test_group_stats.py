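import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from connectopath import make_mesh
from connectopath.group_stats import (
    MassUnivariateGLM,
    cluster_correction_permutation,
    fdr_bh,
    fit_glm,
    interaction_ftest,
    make_design,
    partial_correlation,
    two_sample_t_from_summary,
)


def two_group_design(n1: int, n2: int) -> pd.DataFrame:
    return pd.DataFrame(
        {"intercept": np.ones(n1 + n2), "group": [1.0] * n1 + [0.0] * n2}
    )


class TestFitGlm:
    def test_reproduces_classic_two_sample_t(self, rng):
        y = np.concatenate([rng.standard_normal(12) + 0.8, rng.standard_normal(15)])
        res = fit_glm(y, two_group_design(12, 15), "group")
        t_ref, p_ref = sps.ttest_ind(y[:12], y[12:])
        assert res.t == pytest.approx(t_ref, abs=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-10)
        assert res.df_resid == 25

    def test_unit_effect_gives_cohens_d_one(self):
        base = np.array([-1.5, -0.5, 0.5, 1.5])
        base = base / base.std(ddof=1)  # sample SD exactly 1
        y = np.concatenate([base + 1.0, base])  # means 1 vs 0, pooled SD 1
        res = fit_glm(y, two_group_design(4, 4), "group")
        assert res.cohens_d == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_covariate_leaves_group_beta_unchanged(self, rng):
        n = 20
        design = two_group_design(10, 10)
        y = rng.standard_normal(n)
        cov = np.tile([1.0, -1.0], 10)  # orthogonal to intercept and group
        design2 = design.assign(cov=cov)
        b1 = fit_glm(y, design, "group")
        b2 = fit_glm(y, design2, "group")
        assert b2.beta[1] == pytest.approx(b1.beta[1], abs=1e-10)

    def test_rank_deficient_design_names_columns(self, rng):
        design = two_group_design(5, 5).assign(dup=lambda d: d["group"])
        with pytest.raises(ValueError, match="dup"):
            fit_glm(rng.standard_normal(10), design, "group")

    def test_matrix_response_vectorizes_per_element(self, rng):
        y = rng.standard_normal((16, 7))
        design = two_group_design(8, 8)
        res = fit_glm(y, design, "group")
        for e in range(7):
            single = fit_glm(y[:, e], design, "group")
            assert res.t[e] == pytest.approx(single.t, abs=1e-12)

    def test_estimator_wrapper_exposes_statistics(self, rng, glm_covariates):
        y = rng.standard_normal((40, 5))
        est = MassUnivariateGLM().fit(make_design(glm_covariates), y)
        assert est.t_.shape == (5,)
        assert est.df_resid_ == 40 - make_design(glm_covariates).shape[1]


class TestDesign:
    def test_site_dummies_reference_first_alphabetical(self, glm_covariates):
        d = make_design(glm_covariates)
        assert "site_siteB" in d.columns and "site_siteA" not in d.columns

    def test_interaction_column_is_centered_age_times_group(self, glm_covariates):
        d = make_design(glm_covariates, interaction=True)
        age_c = glm_covariates["age"] - glm_covariates["age"].mean()
        expected = age_c * (glm_covariates["group"] == "case")
        np.testing.assert_allclose(d["age_x_group"], expected, atol=1e-12)


def fdr_step_up_oracle(pvals, q):
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k = rank
    mask = np.zeros(m, dtype=bool)
    mask[order[:k]] = True
    return mask


class TestFdr:
    def test_spec_examples(self):
        assert fdr_bh([0.01, 0.02, 0.03, 0.04], 0.05).all()
        assert not fdr_bh([1.0, 1.0, 1.0], 0.05).any()
        assert fdr_bh([0.01], 0.05).all()
        assert fdr_bh([], 0.05).size == 0

    def test_matches_step_up_oracle_on_permutations(self):
        base = [0.004, 0.02, 0.049, 0.2]
        for perm in itertools.permutations(base):
            np.testing.assert_array_equal(fdr_bh(perm, 0.05), fdr_step_up_oracle(perm, 0.05))

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.1, 1.5], 0.05)


class TestInteraction:
    def _data(self, seed, slope_diff=0.0, n=200):
        r = np.random.default_rng(seed)
        cov = pd.DataFrame(
            {
                "group": ["case"] * (n // 2) + ["control"] * (n // 2),
                "age": r.uniform(8, 40, n),
                "fd": np.abs(r.normal(0, 0.1, n)),
                "site": ["siteA", "siteB"] * (n // 2),
            }
        )
        d = make_design(cov, interaction=True)
        g = d["group"].to_numpy()
        age_c = d["age"].to_numpy() - d["age"].mean()
        y = 0.05 * age_c + slope_diff / 10.0 * age_c * g + r.standard_normal(n)
        return y, d, cov

    def test_null_rejection_rate_calibrated(self):
        rej = 0
        n_sim = 400
        for s in range(n_sim):
            y, d, _ = self._data(s)
            _, p = interaction_ftest(y, d)
            rej += p < 0.05
        assert 0.03 <= rej / n_sim <= 0.07

    def test_power_for_half_sd_slope_difference(self):
        rej = 0
        for s in range(100):
            y, d, _ = self._data(s, slope_diff=0.5)
            _, p = interaction_ftest(y, d)
            rej += p < 0.05
        assert rej / 100 >= 0.8

    def test_group_recoding_invariance(self):
        y, _, cov = self._data(3, slope_diff=0.4)
        d1 = make_design(cov, interaction=True)
        d2 = make_design(cov, case_label="control", interaction=True)
        f1, _ = interaction_ftest(y, d1)
        f2, _ = interaction_ftest(y, d2)
        assert f1 == pytest.approx(f2, rel=1e-10)

    def test_single_group_data_rejected(self):
        r = np.random.default_rng(0)
        cov = pd.DataFrame(
            {"group": ["case"] * 20, "age": r.uniform(8, 40, 20),
             "fd": np.abs(r.normal(0, 0.1, 20)), "site": ["siteA"] * 20}
        )
        with pytest.raises(ValueError):
            make_design(cov, interaction=True)


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        x, y = rng.standard_normal((2, 30))
        r, p = partial_correlation(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-9)

    def test_matches_residualize_then_correlate_oracle(self, rng):
        n = 50
        x, y = rng.standard_normal((2, n))
        c = rng.standard_normal((n, 3))
        r, _ = partial_correlation(x, y, c)
        z = np.column_stack([np.ones(n), c])
        h = z @ np.linalg.pinv(z)
        r_ref = np.corrcoef(x - h @ x, y - h @ y)[0, 1]
        assert r == pytest.approx(r_ref, abs=1e-12)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        n = 60
        df = pd.DataFrame(rng.standard_normal((n, 4)), columns=["x", "y", "c1", "c2"])
        r, p = partial_correlation(df["x"], df["y"], df[["c1", "c2"]])
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(25)
        c = rng.standard_normal((25, 2))
        r, p = partial_correlation(x, x, c)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_collinear_covariate_rejected(self, rng):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(x, y, x[:, None])


class TestSummaryTTest:
    def test_replication_cohort_age_difference(self):
        t, df, p = two_sample_t_from_summary(12.1, 5.89, 57, 16.5, 8.21, 59)
        assert abs(round(t, 1)) == 3.3
        assert df == 114
        assert p < 0.01

    def test_equal_means_give_zero(self):
        t, _, p = two_sample_t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_degenerate_group_sizes_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t_from_summary(1.0, 1.0, 1, 0.0, 1.0, 10)

    def test_agrees_with_glm_on_matching_raw_data(self, rng):
        g1 = rng.standard_normal(14) * 2 + 1
        g2 = rng.standard_normal(11) * 1.5
        t, df, _ = two_sample_t_from_summary(
            g1.mean(), g1.std(ddof=1), 14, g2.mean(), g2.std(ddof=1), 11
        )
        res = fit_glm(np.concatenate([g1, g2]), two_group_design(14, 11), "group")
        assert t == pytest.approx(res.t, abs=1e-10)
        assert df == res.df_resid


class TestClusterPermutation:
    def setup_method(self):
        self.mesh = make_mesh(50, 1)

    def _design(self, n=40):
        r = np.random.default_rng(5)
        cov = pd.DataFrame(
            {
                "group": ["case"] * (n // 2) + ["control"] * (n // 2),
                "age": r.uniform(8, 40, n),
                "fd": np.abs(r.normal(0, 0.1, n)),
                "site": ["siteA", "siteB"] * (n // 2),
            }
        )
        return make_design(cov)

    def test_deterministic_under_fixed_seed(self, rng):
        y = rng.standard_normal((40, 50))
        y[:20, 10:20] += 0.8
        d = self._design()
        r1 = cluster_correction_permutation(y, d, self.mesh, n_perm=200, seed=3)
        r2 = cluster_correction_permutation(y, d, self.mesh, n_perm=200, seed=3)
        assert r1.to_frame().equals(r2.to_frame())

    def test_planted_effect_detected(self, rng):
        y = rng.standard_normal((80, 50))
        y[:40, 20:30] += 1.0
        n = 80
        cov = pd.DataFrame(
            {"group": ["case"] * 40 + ["control"] * 40,
             "age": np.random.default_rng(1).uniform(8, 40, n),
             "fd": np.abs(np.random.default_rng(2).normal(0, 0.1, n)),
             "site": ["siteA", "siteB"] * 40}
        )
        res = cluster_correction_permutation(y, make_design(cov), self.mesh, n_perm=500, seed=9)
        sig = res.significant_vertices()
        assert len(sig) > 0 and set(sig) <= set(range(18, 32))

    def test_monotone_in_effect_size_on_same_noise(self):
        noise = np.random.default_rng(11).standard_normal((40, 50))
        d = self._design()
        last_p = 1.1
        for delta in (0.6, 1.0, 1.6):
            y = noise.copy()
            y[:20, 15:25] += delta
            res = cluster_correction_permutation(y, d, self.mesh, n_perm=300, seed=4)
            best = min(cl["p_fwe"] for cl in res.clusters)
            assert best <= last_p
            last_p = best

    def test_no_suprathreshold_vertices_is_empty_not_error(self):
        y = np.random.default_rng(0).standard_normal((40, 50)) * 1e-3
        y += np.linspace(0, 1, 40)[:, None]  # pure nuisance-direction signal
        res = cluster_correction_permutation(y, self._design(), self.mesh, n_perm=150, seed=1)
        assert isinstance(res.clusters, list)

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError, match="n_perm"):
            cluster_correction_permutation(
                rng.standard_normal((40, 50)), self._design(), self.mesh, n_perm=50, seed=0
            )
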