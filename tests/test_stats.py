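"""Statistics layer: GLM, FDR, rank tests, correlation inference, PCA, MHD."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from connectodyn import (
    compare_correlations,
    correlation_pvalue,
    fdr_adjust,
    glm_group_comparison,
    mahalanobis_composite,
    pca_structure_function,
    pearson_correlation,
    run_statistical_battery,
    wilcoxon_rank,
)
from connectodyn.stats import normal_p_two_tailed, rank_test_pvalue


def _table(rng, n=20, effect=0.0):
    group = ["patient"] * n + ["control"] * n
    y = rng.standard_normal(2 * n)
    y[:n] += effect
    return pd.DataFrame(
        {
            "group": group,
            "y": y,
            "minority": rng.integers(0, 2, 2 * n),
            "cad_score": rng.standard_normal(2 * n),
        }
    )


class TestGlm:
    def test_no_covariates_equals_squared_t(self, rng):
        t = _table(rng, effect=0.8)
        res = glm_group_comparison(t, "y", [])
        tt = sps.ttest_ind(
            t.loc[t.group == "patient", "y"], t.loc[t.group == "control", "y"]
        )
        assert res.f_statistic == pytest.approx(tt.statistic**2, rel=1e-10)
        assert res.p == pytest.approx(tt.pvalue, rel=1e-10)

    def test_constant_outcome_is_null_result(self, rng):
        t = _table(rng)
        t["y"] = 3.14
        res = glm_group_comparison(t, "y", ["minority"])
        assert res.f_statistic == 0.0 and res.p == 1.0

    def test_matches_normal_equations_oracle(self, rng):
        t = _table(rng, effect=0.5)
        res = glm_group_comparison(t, "y", ["minority", "cad_score"])
        # independent implementation straight from the normal equations
        y = t["y"].to_numpy()
        g = (t["group"] == "patient").to_numpy(float)
        x_full = np.column_stack(
            [np.ones(len(t)), t["minority"], t["cad_score"], g]
        )
        x_red = x_full[:, :3]

        def rss(x):
            beta = np.linalg.solve(x.T @ x, x.T @ y)
            r = y - x @ beta
            return r @ r

        rss_f, rss_r = rss(x_full), rss(x_red)
        df2 = len(t) - x_full.shape[1]
        f = (rss_r - rss_f) / (rss_f / df2)
        assert res.f_statistic == pytest.approx(f, abs=1e-8)
        assert res.p == pytest.approx(sps.f.sf(f, 1, df2), abs=1e-8)

    def test_collinear_design_rejected(self, rng):
        t = _table(rng)
        t["dup"] = t["minority"]
        with pytest.raises(ValueError, match="collinear"):
            glm_group_comparison(t, "y", ["minority", "dup"])


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.05])[0] == pytest.approx(0.05)

    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12)
    )
    @settings(max_examples=60, deadline=None)
    def test_never_decreases_and_order_preserved(self, ps):
        adj = fdr_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        # monotone: sorted adjusted values track sorted raw values
        assert np.all(np.diff(np.sort(adj)) >= -1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-12)


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        x = np.arange(10.0)
        u, p = wilcoxon_rank(x, x)
        assert p == pytest.approx(1.0)

    def test_paper_scale_u_value(self):
        # U = 1271 with groups 65/50: z = (1271-1625)/177.25 -> p rounds to .046
        p = rank_test_pvalue(1271, 65, 50)
        assert round(p, 3) == 0.046

    def test_matches_scipy_asymptotic(self, rng):
        x = rng.standard_normal(40)
        y = rng.standard_normal(35) + 0.4
        u, p = wilcoxon_rank(x, y)
        ref = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_small_sample_matches_exhaustive_enumeration(self):
        x = np.array([1.0, 5.0, 9.0])
        y = np.array([2.0, 3.0, 11.0])
        u, _ = wilcoxon_rank(x, y)
        # brute-force U: count (x, y) pairs with x < y (no ties here)
        u_brute = sum(xi < yj for xi in x for yj in y)
        assert u == u_brute
        # two-tailed permutation p over all C(6,3)=20 label arrangements
        pooled = np.concatenate([x, y])
        z_obs = abs(u - 4.5)
        more_extreme = 0
        for idx in combinations(range(6), 3):
            xs = pooled[list(idx)]
            ys = np.delete(pooled, list(idx))
            u_perm = sum(a < b for a in xs for b in ys)
            if abs(u_perm - 4.5) >= z_obs:
                more_extreme += 1
        exact_p = more_extreme / 20
        _, p_norm = wilcoxon_rank(x, y)
        assert p_norm == pytest.approx(exact_p, abs=0.25)

    def test_all_tied_p_one(self):
        u, p = wilcoxon_rank(np.ones(5), np.ones(7))
        assert p == 1.0


class TestCorrelationInference:
    def test_perfect_line(self):
        x = np.arange(10.0)
        res = pearson_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p_two_tailed < 1e-12

    @pytest.mark.parametrize(
        "r,n,expected",
        [(-0.33, 65, 0.0073), (0.34, 65, 0.0056), (0.26, 65, 0.0364)],
    )
    def test_study_scale_p_values(self, r, n, expected):
        assert correlation_pvalue(r, n) == pytest.approx(expected, abs=5e-4)

    def test_p_matches_numeric_quadrature(self):
        from scipy.integrate import quad

        for r, n in [(0.2, 30), (-0.5, 65), (0.7, 12)]:
            t = abs(r) * np.sqrt((n - 2) / (1 - r * r))
            tail, _ = quad(lambda u: sps.t.pdf(u, n - 2), t, np.inf)
            assert correlation_pvalue(r, n) == pytest.approx(2 * tail, abs=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation(np.ones(10), np.arange(10.0))


class TestCompareCorrelations:
    def test_equal_correlations_null(self):
        d = compare_correlations(0.4, 30, 0.4, 30)
        assert d.z == 0.0 and d.p_two_tailed == pytest.approx(1.0)

    @pytest.mark.parametrize("z,expected", [(2.21, 0.0271), (1.4, 0.1615)])
    def test_normal_tail_values(self, z, expected):
        assert normal_p_two_tailed(z) == pytest.approx(expected, abs=5e-4)

    def test_antisymmetric(self):
        d1 = compare_correlations(0.5, 40, -0.2, 35)
        d2 = compare_correlations(-0.2, 35, 0.5, 40)
        assert d1.z == pytest.approx(-d2.z)
        assert d1.p_two_tailed == pytest.approx(d2.p_two_tailed)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_correlations(0.5, 3, 0.2, 30)


class TestPca:
    @staticmethod
    def _columns_with_exact_r(rng, n, r):
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        x = (x - x.mean()) / x.std()
        y = y - (y @ x) / (x @ x) * x
        y = (y - y.mean()) / y.std()
        return x, r * x + np.sqrt(1 - r * r) * y

    def test_anticorrelated_columns(self, rng):
        x, y = self._columns_with_exact_r(rng, 60, -1 + 1e-12)
        t = pd.DataFrame({"sc_global_clust": x, "fc_global_clust": y})
        res = pca_structure_function(t)
        assert res.variance_explained == pytest.approx(1.0, abs=1e-6)
        assert res.loadings["sc_global_clust"] == pytest.approx(0.7071, abs=1e-3)
        assert res.loadings["fc_global_clust"] == pytest.approx(-0.7071, abs=1e-3)

    def test_uncorrelated_columns_split_variance(self, rng):
        x, y = self._columns_with_exact_r(rng, 80, 0.0)
        t = pd.DataFrame({"sc_global_clust": x, "fc_global_clust": y})
        assert pca_structure_function(t).variance_explained == pytest.approx(0.5)

    @pytest.mark.parametrize("r", [-0.18, 0.18, 0.45, -0.7])
    def test_first_component_variance_identity(self, rng, r):
        # for standardized 2-column data, lambda1/2 = (1+|r|)/2 exactly
        x, y = self._columns_with_exact_r(rng, 100, r)
        t = pd.DataFrame({"sc_global_clust": x, "fc_global_clust": y})
        res = pca_structure_function(t)
        assert res.variance_explained == pytest.approx((1 + abs(r)) / 2, abs=1e-10)

    def test_structural_loading_oriented_positive(self, rng):
        x, y = self._columns_with_exact_r(rng, 50, -0.4)
        res = pca_structure_function(
            pd.DataFrame({"sc_global_clust": x, "fc_global_clust": y})
        )
        assert res.loadings["sc_global_clust"] > 0


class TestMahalanobis:
    def _frames(self, rng, n_pat=10, n_ctl=30):
        names = ["a", "b", "c", "d"]
        ctl = pd.DataFrame(rng.standard_normal((n_ctl, 4)), columns=names)
        pat = pd.DataFrame(rng.standard_normal((n_pat, 4)) + 0.5, columns=names)
        return pat, ctl, names

    def test_identity_covariance_unit_offset(self, rng):
        names = ["a", "b"]
        base = rng.standard_normal((4000, 2))
        base = (base - base.mean(0)) / base.std(0, ddof=1)
        # orthogonalize columns to make the sample covariance the identity
        q, _ = np.linalg.qr(base - base.mean(0))
        ctl = pd.DataFrame(q * np.sqrt(len(base) - 1), columns=names)
        pat = pd.DataFrame([[ctl["a"].mean() + 1.0, ctl["b"].mean()]], columns=names)
        comp = mahalanobis_composite(pat, ctl, names)
        assert comp.distance[0] == pytest.approx(1.0, abs=1e-8)
        assert comp.log_mhd[0] == pytest.approx(0.0, abs=1e-8)

    def test_patient_at_control_mean_floored(self, rng):
        pat, ctl, names = self._frames(rng)
        pat.iloc[0] = ctl[names].mean()
        comp = mahalanobis_composite(pat, ctl, names)
        assert comp.distance[0] == pytest.approx(0.0, abs=1e-10)
        assert np.isfinite(comp.log_mhd[0])

    def test_matches_direct_solve_oracle(self, rng):
        pat, ctl, names = self._frames(rng)
        comp = mahalanobis_composite(pat, ctl, names)
        mu = ctl[names].mean().to_numpy()
        cov = np.cov(ctl[names].to_numpy(), rowvar=False, ddof=1)
        for i in range(len(pat)):
            dev = pat[names].iloc[i].to_numpy() - mu
            d = np.sqrt(dev @ np.linalg.solve(cov, dev))
            assert comp.distance[i] == pytest.approx(d, abs=1e-10)

    def test_joint_affine_invariance(self, rng):
        pat, ctl, names = self._frames(rng)
        base = mahalanobis_composite(pat, ctl, names).distance
        a = rng.standard_normal((4, 4)) + 2 * np.eye(4)
        b = rng.standard_normal(4)
        pat2 = pd.DataFrame(pat[names].to_numpy() @ a.T + b, columns=names)
        ctl2 = pd.DataFrame(ctl[names].to_numpy() @ a.T + b, columns=names)
        np.testing.assert_allclose(
            mahalanobis_composite(pat2, ctl2, names).distance, base, rtol=1e-8
        )

    def test_singular_covariance_rejected(self, rng):
        pat, ctl, names = self._frames(rng)
        ctl["d"] = ctl["a"]
        with pytest.raises(ValueError, match="singular"):
            mahalanobis_composite(pat, ctl, names)

    def test_too_few_controls_rejected(self, rng):
        pat, ctl, names = self._frames(rng, n_ctl=5)
        with pytest.raises(ValueError, match="control rows"):
            mahalanobis_composite(pat, ctl, names)


class TestBattery:
    def _metric_table(self, rng, n=30, couple=False):
        from connectodyn.simulate import COGNITIVE_MOMENTS

        rows = {}
        group = ["patient"] * n + ["control"] * n
        rows["group"] = group
        rows["subject_id"] = [f"s{i}" for i in range(2 * n)]
        rows["minority"] = rng.integers(0, 2, 2 * n)
        rows["cad_score"] = rng.standard_normal(2 * n) * 9 + 48
        for test, ((mp, sp), (mc, sc)) in COGNITIVE_MOMENTS.items():
            vals = np.concatenate(
                [rng.normal(mp, sp, n), rng.normal(mc, sc, n)]
            )
            rows[test] = vals
        u = rng.standard_normal(2 * n)
        sc_c = 0.7 + 0.01 * rng.standard_normal(2 * n)
        fc_c = 0.55 + 0.02 * rng.standard_normal(2 * n)
        if couple:
            sc_c[:n] = 0.7 - 0.008 * u[:n] + 0.004 * rng.standard_normal(n)
            fc_c[:n] = 0.55 + 0.016 * u[:n] + 0.008 * rng.standard_normal(n)
        rows["sc_global_clust"] = sc_c
        rows["fc_global_clust"] = fc_c
        rows["sc_n_nodes"] = rng.integers(250, 280, 2 * n)
        rows["global_h"] = np.concatenate(
            [rng.normal(0.26, 0.02, n), rng.normal(0.29, 0.02, n)]
        )
        return pd.DataFrame(rows)

    def test_bundle_structure_and_determinism(self):
        t = self._metric_table(np.random.default_rng(0))
        r1 = run_statistical_battery(t)
        r2 = run_statistical_battery(t)
        assert set(r1["cognitive"]["outcome"]).issuperset({"ravlt_total", "cowa"})
        # performance measures carry FDR; self-reports do not
        cog = r1["cognitive"].set_index("outcome")
        assert np.isfinite(cog.loc["ravlt_total", "p_fdr"])
        assert pd.isna(cog.loc["brief_gec", "p_fdr"])
        pd.testing.assert_frame_equal(r1["cognitive"], r2["cognitive"])
        pd.testing.assert_frame_equal(r1["global_metrics"], r2["global_metrics"])
        assert r1["pca"].variance_explained == r2["pca"].variance_explained

    def test_detects_injected_coupling(self):
        hits = 0
        for rep in range(25):
            t = self._metric_table(np.random.default_rng(1000 + rep), couple=True)
            res = run_statistical_battery(t)
            fisher = res["correlation_differences"].set_index(["x", "y"])
            row = fisher.loc[("sc_global_clust", "fc_global_clust")]
            if row["p"] < 0.05 and row["r_patient"] < 0:
                hits += 1
        assert hits >= 20

    def test_type_one_error_calibrated_under_null(self):
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 200
        for _ in range(reps):
            t = self._metric_table(rng)
            res = glm_group_comparison(t, "fc_global_clust", ["minority", "cad_score"])
            rejections += res.p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.02)
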