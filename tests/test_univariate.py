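"""Rank regression, group inference, FDR, collinearity, searchlight, and
the crossed own-brain/other-ratings control."""

import numpy as np
import pytest
from scipy import stats

from memtopo import (
    COMBINED_SPEC,
    BetaStack,
    GeneratorConfig,
    PlantedEffects,
    RegressionSpec,
    collinearity_check,
    crossed_control_regression,
    fdr_correct,
    fit_rank_regression,
    generate_behavior,
    generate_brain,
    group_searchlight,
    group_slope_test,
    make_atlas,
    rank_transform,
    roi_mean_series,
    searchlight_regression,
)
from memtopo.univariate import sphere_mean_outcomes, sphere_offsets

from test_behavior import session_from


def bh_oracle(p, q):
    """Independent Benjamini-Hochberg step-up (loop implementation)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, bool)
    kmax = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i * q / m:
            kmax = i
    reject[order[:kmax]] = True
    # adjusted p: step-up minima
    adj = np.empty(m)
    prev = 1.0
    for i in range(m - 1, -1, -1):
        prev = min(prev, p[order[i]] * m / (i + 1))
        adj[order[i]] = prev
    return reject, adj


class TestRankTransform:
    def test_examples(self):
        np.testing.assert_array_equal(rank_transform([10, 20, 30]), [1, 2, 3])
        np.testing.assert_array_equal(rank_transform([5, 5, 1]), [2.5, 2.5, 1])

    def test_matches_argsort_oracle(self, rng):
        for _ in range(20):
            v = rng.normal(size=30)
            order = np.argsort(np.argsort(v)) + 1.0
            np.testing.assert_allclose(rank_transform(v), order)


class TestFitRankRegression:
    def test_hand_case_beta_half(self):
        # outcome [5,9,7] -> ranks [1,3,2]; x=[1,2,3] -> beta 0.5
        s = session_from([1, 2, 3], ages=[1, 2, 3])
        spec = RegressionSpec(predictors=("age_days",))
        sb = fit_rank_regression(np.array([5.0, 9.0, 7.0]), s, spec)
        assert sb.betas["age_days"] == pytest.approx(0.5)

    def test_matches_normal_equations_oracle(self, rng):
        cfg = GeneratorConfig(n_samples=1, n_videos_per_sample=40, seed=2)
        s = generate_behavior(cfg)[0]
        for _ in range(20):
            y = rng.normal(size=40)
            sb = fit_rank_regression(y, s, COMBINED_SPEC)
            X = np.column_stack(
                [s.predictor(p) for p in COMBINED_SPEC.predictors]
                + [np.ones(40)])
            beta = np.linalg.solve(X.T @ X, X.T @ rank_transform(y))
            for i, p in enumerate(COMBINED_SPEC.predictors):
                assert sb.betas[p] == pytest.approx(beta[i], abs=1e-8)

    def test_monotone_outcome_transform_invariance(self, rng):
        cfg = GeneratorConfig(n_samples=1, n_videos_per_sample=50, seed=3)
        s = generate_behavior(cfg)[0]
        y = rng.normal(size=50)
        base = fit_rank_regression(y, s, COMBINED_SPEC).betas
        for f in (np.exp, lambda v: 3 * v + 7, lambda v: np.log(v - v.min() + 1)):
            tb = fit_rank_regression(f(y), s, COMBINED_SPEC).betas
            for p in base:
                assert tb[p] == pytest.approx(base[p], abs=1e-10)

    def test_null_betas_centered_at_zero(self):
        cfg = GeneratorConfig(n_samples=1, n_videos_per_sample=60, seed=4)
        s = generate_behavior(cfg)[0]
        rng = np.random.default_rng(0)
        spec = RegressionSpec(predictors=("memory_strength",))
        betas = [fit_rank_regression(rng.normal(size=60), s, spec)
                 .betas["memory_strength"] for _ in range(200)]
        t, p = stats.ttest_1samp(betas, 0.0)
        assert p > 0.01

    def test_collinear_design_rejected(self):
        s = session_from([1, 2, 3, 4, 5, 1, 2], ages=[1, 2, 3, 4, 5, 6, 7],
                         dists=[2, 4, 6, 8, 10, 12, 14])
        # age and distance perfectly collinear
        spec = RegressionSpec(predictors=("age_days", "distance_km"))
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_rank_regression(np.arange(7.0), s, spec)


class TestGroupSlopeTest:
    def test_closed_form(self):
        sbs = [type("SB", (), {"betas": {"x": b}})() for b in (1.0, 2.0, 3.0)]
        g = group_slope_test(sbs, "x")
        assert g.mean_beta == 2.0
        assert g.cohens_d == pytest.approx(2.0)
        assert g.t_value == pytest.approx(2 * np.sqrt(3))
        assert g.df == 2

    def test_symmetric_betas_t_zero(self):
        sbs = [type("SB", (), {"betas": {"x": b}})() for b in (-1.0, 0.0, 1.0)]
        g = group_slope_test(sbs, "x")
        assert g.t_value == 0.0 and g.p_value == 1.0

    def test_power_matches_analytic_t_curve(self):
        """Rejection rate over simulated studies matches the noncentral-t
        power of the one-sample test."""
        rng = np.random.default_rng(12)
        n, effect, n_sim = 16, 0.8, 400
        rejections = 0
        for _ in range(n_sim):
            betas = rng.normal(effect, 1.0, n)
            sbs = [type("SB", (), {"betas": {"x": b}})() for b in betas]
            rejections += group_slope_test(sbs, "x").p_value < 0.05
        crit = stats.t.ppf(0.975, n - 1)
        nc = effect * np.sqrt(n)
        power = (stats.nct.sf(crit, n - 1, nc)
                 + stats.nct.cdf(-crit, n - 1, nc))
        assert rejections / n_sim == pytest.approx(power, abs=0.06)


class TestFdrCorrect:
    def test_step_up_hand_case(self):
        sig, _ = fdr_correct(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
        assert sig.all()

    def test_none_significant(self):
        sig, _ = fdr_correct(np.array([0.9, 0.95]), q=0.05)
        assert not sig.any()

    def test_matches_independent_oracle(self, rng):
        for _ in range(100):
            p = rng.random(rng.integers(2, 30))
            sig, adj = fdr_correct(p, q=0.05)
            osig, oadj = bh_oracle(p, 0.05)
            np.testing.assert_array_equal(sig, osig)
            np.testing.assert_allclose(adj, oadj, atol=1e-12)

    def test_never_significant_above_q(self, rng):
        for _ in range(50):
            p = rng.random(20)
            sig, _ = fdr_correct(p, q=0.05)
            assert not np.any(sig & (p > 0.05))


class TestCollinearity:
    def test_duplicated_predictor_warns(self):
        s = session_from([1, 2, 3, 4, 5], ages=[1, 2, 3, 4, 5],
                         dists=[10, 20, 30, 40, 50])
        spec = RegressionSpec(predictors=("age_days", "distance_km"))
        with pytest.warns(UserWarning, match="collinearity"):
            max_r, _ = collinearity_check(s, spec)
        assert max_r == pytest.approx(1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(8)
        ages = rng.uniform(2, 2000, 50)
        strengths = rng.integers(1, 6, 50)
        s = session_from(strengths, ages=ages)
        spec = RegressionSpec(predictors=("age_days", "memory_strength"))
        max_r, R = collinearity_check(s, spec)
        a, b = ages, strengths.astype(float)
        r = ((a - a.mean()) @ (b - b.mean())
             / np.sqrt(((a - a.mean())**2).sum() * ((b - b.mean())**2).sum()))
        assert R[0, 1] == pytest.approx(r)
        assert max_r == pytest.approx(abs(r))

    def test_independent_predictors_below_point_two(self):
        low = 0
        zero = {k: 0.0 for k in GeneratorConfig().target_correlations}
        for seed in range(20):
            cfg = GeneratorConfig(n_samples=1, n_videos_per_sample=300,
                                  seed=seed, target_correlations=zero,
                                  place_new_strength_boost=0.0)
            s = generate_behavior(cfg)[0]
            max_r, _ = collinearity_check(s, COMBINED_SPEC)
            low += max_r < 0.2
        assert low >= 18


class TestSearchlight:
    def test_sphere_sizes(self):
        assert sphere_offsets(1).shape[0] == 1
        assert sphere_offsets(3).shape[0] == 7    # center + 6 faces
        assert sphere_offsets(5).shape[0] == 33   # radius-2 digital sphere

    def test_even_diameter_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            sphere_offsets(4)

    def test_diameter_one_equals_voxelwise(self, small_sessions, atlas16,
                                           planted_stacks):
        st, se = planted_stacks[0], small_sessions[0]
        spec = RegressionSpec(predictors=("memory_strength",))
        out = searchlight_regression(st, se, spec, diameter=1)
        # voxelwise oracle at 5 random columns
        rng = np.random.default_rng(1)
        X = np.column_stack([se.predictor("memory_strength"),
                             np.ones(se.n_videos)])
        for c in rng.choice(st.n_voxels, 5, replace=False):
            y = rank_transform(st.values[:, c])
            beta = np.linalg.lstsq(X, y, rcond=None)[0][0]
            assert out["memory_strength"][c] == pytest.approx(beta, abs=1e-9)

    def test_sphere_mean_matches_brute_force(self, planted_stacks):
        st = planted_stacks[0]
        Y, counts = sphere_mean_outcomes(st, diameter=5, min_voxels=1)
        coords = st.voxel_index_map
        offs = sphere_offsets(5)
        rng = np.random.default_rng(2)
        for c in rng.choice(st.n_voxels, 5, replace=False):
            pts = coords[c] + offs
            ok = np.all((pts >= 0) & (pts < np.array(st.mask.shape)), axis=1)
            pts = pts[ok]
            inmask = st.mask[pts[:, 0], pts[:, 1], pts[:, 2]]
            pts = pts[inmask]
            flat = np.cumsum(st.mask.ravel()) - 1
            cols = flat[np.ravel_multi_index(pts.T, st.mask.shape)]
            np.testing.assert_allclose(Y[:, c], st.values[:, cols].mean(axis=1),
                                       atol=1e-9)
            assert counts[c] == len(cols)

    def test_uniform_stack_gives_zero_betas(self, small_sessions, atlas16):
        se = small_sessions[0]
        st = BetaStack(values=np.full((se.n_videos, int(atlas16.brain_mask.sum())),
                                      3.14),
                       mask=atlas16.brain_mask, affine=np.eye(4),
                       video_ids=se.video_ids)
        out = searchlight_regression(st, se, COMBINED_SPEC, diameter=3)
        for p in COMBINED_SPEC.predictors:
            vals = out[p][~np.isnan(out[p])]
            np.testing.assert_allclose(vals, 0.0, atol=1e-9)

    def test_planted_roi_recovered(self, small_sessions, atlas16,
                                   planted_stacks):
        maps = group_searchlight(planted_stacks, small_sessions,
                                 COMBINED_SPEC, diameter=3)
        gm = maps["memory_strength"]
        roi = atlas16.columns("mpc_strength")
        noise = atlas16.columns("noise_region")
        assert np.nanmean(np.abs(gm.t_value[roi])) > 5 * np.nanmean(
            np.abs(gm.t_value[noise]))


class TestCrossedControl:
    def test_misaligned_orders_rejected(self, small_sessions, atlas16,
                                        planted_stacks):
        with pytest.raises(ValueError, match="mismatch"):
            crossed_control_regression(planted_stacks[0], small_sessions[1],
                                       COMBINED_SPEC)

    def test_same_machinery_as_rank_regression(self, small_sessions,
                                               planted_stacks):
        st, se = planted_stacks[0], small_sessions[0]
        sb = crossed_control_regression(st, se, COMBINED_SPEC)
        direct = fit_rank_regression(st.values.mean(axis=1), se, COMBINED_SPEC)
        assert sb.betas == direct.betas
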