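"""The synthetic generator: determinism, marginal and copula structure,
planted-effect recovery, paired-session leakage, and run assignment."""

import numpy as np
import pytest
from scipy import stats

from memtopo import (
    COMBINED_SPEC,
    GeneratorConfig,
    PlantedEffects,
    RegressionSpec,
    assign_runs,
    default_effects,
    fit_rank_regression,
    generate_behavior,
    generate_brain,
    generate_feature_matrix,
    generate_pair,
    group_slope_test,
    make_atlas,
    neural_rdm,
    roi_mean_series,
    scalar_rdm,
)
from memtopo.synth import _copula_matrix


class TestBehaviorGenerator:
    def test_reproducible_and_valid(self):
        cfg = GeneratorConfig(n_samples=2, n_videos_per_sample=300, seed=5)
        a = generate_behavior(cfg)
        b = generate_behavior(cfg)
        for sa, sb in zip(a, b):
            assert sa.to_frame().equals(sb.to_frame())
        s = a[0]
        assert s.n_videos == 300
        ages = s.predictor("age_days")
        assert ages.min() >= 2.0 and ages.max() <= cfg.max_age_days
        assert np.isfinite(s.predictor("distance_km")).all()

    def test_zero_targets_give_near_zero_correlations(self):
        rhos = []
        for seed in range(20):
            cfg = GeneratorConfig(
                n_samples=1, n_videos_per_sample=300, seed=seed,
                target_correlations={k: 0.0 for k in
                                     GeneratorConfig().target_correlations},
                place_new_strength_boost=0.0,
            )
            s = generate_behavior(cfg)[0]
            r, _ = stats.spearmanr(s.predictor("age_days"),
                                   s.predictor("memory_strength"))
            rhos.append(r)
            assert abs(r) < 0.2
        assert abs(np.mean(rhos)) < 0.02 + 2 * np.std(rhos) / np.sqrt(20)

    def test_default_age_strength_correlation_near_target(self):
        rhos = []
        for seed in range(20):
            cfg = GeneratorConfig(n_samples=1, n_videos_per_sample=300, seed=seed)
            s = generate_behavior(cfg)[0]
            r, _ = stats.spearmanr(s.predictor("age_days"),
                                   s.predictor("memory_strength"))
            rhos.append(r)
        assert np.mean(rhos) == pytest.approx(-0.16, abs=0.05)

    def test_rating_marginals_chi2_not_rejected(self):
        cfg = GeneratorConfig(n_samples=10, n_videos_per_sample=300, seed=21)
        sessions = generate_behavior(cfg)
        strengths = np.concatenate(
            [s.predictor("memory_strength") for s in sessions]
        ).astype(int)
        counts = np.bincount(strengths, minlength=6)[1:]
        expected = np.asarray(cfg.strength_marginals) * strengths.size
        _, p = stats.chisquare(counts, expected)
        assert p > 0.01
        emotions = np.concatenate([s.predictor("emotion") for s in sessions])
        counts = np.bincount(emotions.astype(int), minlength=6)[1:]
        expected = np.asarray(cfg.emotion_marginals) * emotions.size
        _, p = stats.chisquare(counts, expected)
        assert p > 0.01

    def test_infeasible_targets_rejected(self):
        bad = {
            ("age_days", "memory_strength"): 0.95,
            ("distance_km", "memory_strength"): 0.95,
            ("age_days", "emotion"): 0.95,
            ("distance_km", "emotion"): -0.95,
        }
        with pytest.raises(ValueError, match="non-PSD"):
            _copula_matrix(bad)

    def test_distance_mixture_local_mass(self):
        cfg = GeneratorConfig(n_samples=4, n_videos_per_sample=300, seed=9)
        sessions = generate_behavior(cfg)
        frac_local = np.mean(
            [np.mean(s.predictor("distance_km") <= 50.0) for s in sessions]
        )
        assert frac_local == pytest.approx(cfg.local_fraction, abs=0.07)


class TestBrainGenerator:
    def test_noiseless_limit_perfect_rank_correlation(self, small_sessions, atlas16):
        eff = PlantedEffects(
            roi_slopes={"mpc_strength": {"memory_strength": 1.0}},
            noise_sd=0.0,
        )
        stacks = generate_brain(small_sessions[:1], atlas16, eff, seed=3)
        ser = roi_mean_series(stacks[0], atlas16.mask("mpc_strength"))
        rho, _ = stats.spearmanr(ser, small_sessions[0].predictor("memory_strength"))
        assert rho == pytest.approx(1.0)

    def test_unknown_roi_rejected(self, small_sessions, atlas16):
        eff = PlantedEffects(roi_slopes={"nope": {"memory_strength": 1.0}})
        with pytest.raises(KeyError, match="nope"):
            generate_brain(small_sessions[:1], atlas16, eff, seed=0)

    def test_null_slopes_calibrated_false_positive_rate(self):
        """With no planted effects, the group slope test rejects at ~alpha."""
        cfg = GeneratorConfig(n_samples=6, n_videos_per_sample=60, seed=31)
        sessions = generate_behavior(cfg)
        atlas = make_atlas((14, 14, 14))
        eff = PlantedEffects(noise_sd=1.0)
        spec = RegressionSpec(predictors=("memory_strength",))
        rng = np.random.default_rng(99)
        rejections = 0
        n_sim = 200
        for sim in range(n_sim):
            stacks = generate_brain(sessions, atlas, eff,
                                    seed=int(rng.integers(2**31)))
            sbs = [
                fit_rank_regression(
                    roi_mean_series(st, atlas.mask("noise_region")), se, spec
                )
                for st, se in zip(stacks, sessions)
            ]
            if group_slope_test(sbs, "memory_strength").p_value < 0.05:
                rejections += 1
        rate = rejections / n_sim
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < 3 * se + 1e-12

    def test_planted_slope_recovered_within_15_percent(self):
        """Across seeds, the mean fitted slope of a planted linear effect
        (raw outcome, single standardized predictor) matches the plant."""
        slope = 0.6
        atlas = make_atlas((14, 14, 14))
        betas = []
        for seed in range(20):
            cfg = GeneratorConfig(n_samples=1, n_videos_per_sample=150, seed=seed)
            s = generate_behavior(cfg)[0]
            eff = PlantedEffects(
                roi_slopes={"mpc_strength": {"memory_strength": slope}},
                noise_sd=1.0,
            )
            st = generate_brain([s], atlas, eff, seed=seed + 1000)[0]
            ser = roi_mean_series(st, atlas.mask("mpc_strength"))
            z = s.predictor("memory_strength")
            z = (z - z.mean()) / z.std()
            betas.append(np.polyfit(z, ser, 1)[0])
        assert np.mean(betas) == pytest.approx(slope, rel=0.15)

    def test_log_code_roi_prefers_log_model(self, small_sessions, atlas16):
        wins = 0
        for seed in range(10):
            eff = PlantedEffects(rdm_code_roi="timecode", rdm_code="log",
                                 rdm_strength=1.5, noise_sd=1.0)
            st = generate_brain(small_sessions[:1], atlas16, eff, seed=seed)[0]
            pat = st.values[:, atlas16.columns("timecode")]
            brdm = neural_rdm(pat)
            ages = small_sessions[0].predictor("age_days")
            r_log, _ = stats.spearmanr(
                brdm.upper(), scalar_rdm(ages, "log10").upper())
            r_lin, _ = stats.spearmanr(
                brdm.upper(), scalar_rdm(ages, "identity").upper())
            wins += r_log > r_lin
        assert wins >= 9


class TestGeneratePair:
    def test_leakage_off_is_null(self, small_sessions, atlas16):
        eff = default_effects()
        ps = []
        for seed in range(8):
            stack_ab = generate_pair(small_sessions[0], small_sessions[1],
                                     atlas16, eff, seed=seed, leakage=0.0)
            ser = roi_mean_series(stack_ab, atlas16.mask("hippocampus"))
            sb = fit_rank_regression(ser, small_sessions[1], COMBINED_SPEC)
            ps.append(sb.betas["memory_strength"])
        t, p = stats.ttest_1samp(ps, 0.0)
        assert p > 0.01

    def test_large_leakage_detected(self, small_sessions, atlas16):
        eff = default_effects()
        detections = 0
        for seed in range(10):
            bs = []
            for a, b in [(0, 1), (2, 3), (4, 5), (1, 0), (3, 2), (5, 4)]:
                stack_ab = generate_pair(small_sessions[a], small_sessions[b],
                                         atlas16, eff, seed=seed * 10 + a,
                                         leakage=0.8)
                ser = roi_mean_series(stack_ab, atlas16.mask("hippocampus"))
                bs.append(fit_rank_regression(ser, small_sessions[b],
                                              COMBINED_SPEC))
            g = group_slope_test(bs, "memory_strength")
            detections += (g.p_value < 0.05) and (g.mean_beta > 0)
        assert detections >= 8

    def test_count_mismatch_rejected(self, small_sessions, atlas16):
        short = small_sessions[0].subset(
            np.arange(small_sessions[0].n_videos) < 50
        )
        with pytest.raises(ValueError, match="equal video counts"):
            generate_pair(short, small_sessions[1], atlas16, default_effects())


class TestFeatureMatrix:
    def test_shape_and_errors(self, small_sessions):
        f = generate_feature_matrix(small_sessions[0], 0.5, 12, seed=1)
        assert f.shape == (small_sessions[0].n_videos, 12)
        with pytest.raises(ValueError, match="n_features"):
            generate_feature_matrix(small_sessions[0], 0.5, 0)
        with pytest.raises(ValueError, match="planted_r"):
            generate_feature_matrix(small_sessions[0], 1.5, 3)

    def test_planted_r_bounds_best_readout(self, small_sessions):
        s = small_sessions[0]
        z = s.predictor("memory_strength")
        f = generate_feature_matrix(s, 0.99, 5, seed=2)
        coef, *_ = np.linalg.lstsq(
            np.column_stack([f, np.ones(len(z))]), z, rcond=None)
        pred = np.column_stack([f, np.ones(len(z))]) @ coef
        assert np.corrcoef(pred, z)[0, 1] > 0.95
        f0 = generate_feature_matrix(s, 0.0, 5, seed=3)
        r0 = abs(np.corrcoef(f0.mean(axis=1), z)[0, 1])
        assert r0 < 0.25


class TestAssignRuns:
    def test_run_counts_and_determinism(self, small_sessions):
        s = small_sessions[0]  # 100 videos
        labels = assign_runs(s, n_runs=10, per_run=10, seed=4)
        counts = np.bincount(labels, minlength=11)
        assert counts[0] == 0 and np.all(counts[1:] == 10)
        labels2 = assign_runs(s, n_runs=10, per_run=10, seed=4)
        np.testing.assert_array_equal(labels, labels2)

    def test_each_run_spans_most_of_the_range(self, small_sessions):
        s = small_sessions[0]
        ages = s.predictor("age_days")
        total = np.ptp(ages)
        for seed in range(5):
            labels = assign_runs(s, n_runs=10, per_run=10, seed=seed)
            for r in range(1, 11):
                span = np.ptp(ages[labels == r])
                assert span >= 0.8 * total

    def test_single_run_takes_all_selected(self, small_sessions):
        s = small_sessions[0]
        labels = assign_runs(s, n_runs=1, per_run=30, seed=0)
        assert (labels == 1).sum() == 30

    def test_shortfall_and_uneven_pool(self, small_sessions):
        s = small_sessions[0].subset(np.arange(100) < 97)
        # 170-video sessions ran 10 runs of 17; here 97 -> 9 per run
        labels = assign_runs(s, n_runs=10, seed=0)
        assert (labels > 0).sum() == 90
        with pytest.raises(ValueError, match="short"):
            assign_runs(s, n_runs=10, per_run=30, seed=0)
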