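"""Length extraction, kymographs, rate fits, unit conversion and group stats."""

import numpy as np
import pytest

from crowdactin.elongation_analysis import (
    ACTIN_RISE_NM_IMPLIED,
    FilamentTrack,
    build_kymograph,
    compare_conditions,
    extract_filament_lengths,
    fit_elongation_rate,
    fold_change,
    rate_to_subunits,
)
from crowdactin.synthetic_data import (
    GrowthParams,
    TimelapseStack,
    simulate_filament_timelapse,
)


class TestExtractLengths:
    def test_noiseless_roundtrip_within_one_pixel(self, noiseless_stack):
        params, truth, stack = noiseless_stack
        track = extract_filament_lengths(stack)
        assert np.all(
            np.abs(track.lengths - truth.lengths) <= params.pixel_size + 1e-9
        )
        assert track.blank_frames.size == 0

    def test_all_zero_stack_flags_every_frame(self):
        stack = TimelapseStack(frames=np.zeros((5, 9, 20)), pixel_size=0.07,
                               frame_interval=1.0, line_row=4)
        track = extract_filament_lengths(stack)
        assert np.all(track.lengths == 0.0)
        assert np.array_equal(track.blank_frames, np.arange(5))

    def test_single_bright_pixel_gives_one_pixel_length(self):
        frames = np.zeros((3, 9, 20))
        frames[:, 4, 7] = 1.0
        stack = TimelapseStack(frames=frames, pixel_size=0.07,
                               frame_interval=1.0, line_row=4)
        track = extract_filament_lengths(stack)
        assert np.allclose(track.lengths, 0.07)

    def test_otsu_policy_runs_on_noisy_stack(self):
        _, stack = simulate_filament_timelapse(
            GrowthParams(elongation_rate=35.9, noise_sd=0.05, duration=60.0, seed=1)
        )
        track = extract_filament_lengths(stack, "otsu")
        assert np.all(np.isfinite(track.lengths))

    def test_bad_threshold_fraction_rejected(self, noiseless_stack):
        _, _, stack = noiseless_stack
        with pytest.raises(ValueError):
            extract_filament_lengths(stack, 1.5)


class TestKymograph:
    def test_single_frame_equals_profile(self):
        frames = np.arange(2 * 9 * 12, dtype=float).reshape(2, 9, 12)
        stack = TimelapseStack(frames=frames[:1], pixel_size=0.07,
                               frame_interval=1.0, line_row=4)
        kymo = build_kymograph(stack, 4)
        assert kymo.intensity.shape == (1, 12)
        assert np.array_equal(kymo.intensity[0], frames[0, 4, :])

    def test_edge_advance_matches_rate(self):
        rate, px, dt = 35.9, 0.07, 1.0
        _, stack = simulate_filament_timelapse(
            GrowthParams(elongation_rate=rate, noise_sd=0.0, psf_sigma=0.0,
                         pixel_size=px, frame_interval=dt, duration=120.0)
        )
        kymo = build_kymograph(stack)
        edges = (kymo.intensity > 0.5).sum(axis=1).astype(float)
        slope = np.polyfit(np.arange(edges.size), edges, 1)[0]
        assert slope == pytest.approx(rate * dt / (1000.0 * px), abs=0.02)

    def test_permuting_frames_permutes_rows(self, rng, noiseless_stack):
        _, _, stack = noiseless_stack
        perm = rng.permutation(stack.frames.shape[0])
        permuted = TimelapseStack(frames=stack.frames[perm],
                                  pixel_size=stack.pixel_size,
                                  frame_interval=stack.frame_interval,
                                  line_row=stack.line_row)
        assert np.array_equal(
            build_kymograph(permuted).intensity,
            build_kymograph(stack).intensity[perm],
        )

    def test_out_of_bounds_line_rejected(self, noiseless_stack):
        _, _, stack = noiseless_stack
        with pytest.raises(ValueError):
            build_kymograph(stack, 99)
        with pytest.raises(ValueError):
            build_kymograph(stack, np.array([[0, 10_000]]))


class TestFitElongationRate:
    def test_exact_line(self):
        t = np.arange(0.0, 200.0)
        track = FilamentTrack(times=t, lengths=0.100 + 2e-3 * t)  # 2 nm/s
        est = fit_elongation_rate(track, (60.0, 120.0))
        assert est.rate == pytest.approx(2.0, rel=1e-10)
        assert est.r2 == pytest.approx(1.0)
        assert est.n_frames == 61

    def test_constant_track_zero_rate(self):
        t = np.arange(0.0, 200.0)
        track = FilamentTrack(times=t, lengths=np.full_like(t, 0.5))
        assert fit_elongation_rate(track).rate == pytest.approx(0.0, abs=1e-12)

    def test_synthetic_noiseless_roundtrip_control_rate(self):
        truth, stack = simulate_filament_timelapse(
            GrowthParams(elongation_rate=35.9, noise_sd=0.0, duration=120.0)
        )
        est = fit_elongation_rate(truth, (60.0, 120.0))
        assert est.rate == pytest.approx(35.9, rel=1e-10)
        extracted = fit_elongation_rate(extract_filament_lengths(stack), (60.0, 120.0))
        assert extracted.rate == pytest.approx(35.9, rel=0.03)

    def test_offset_invariance_and_time_shift_equivariance(self):
        t = np.arange(0.0, 200.0)
        lengths = 0.1 + 5e-3 * t
        base = fit_elongation_rate(FilamentTrack(times=t, lengths=lengths))
        shifted_len = fit_elongation_rate(FilamentTrack(times=t, lengths=lengths + 1.0))
        assert shifted_len.rate == pytest.approx(base.rate, rel=1e-10)
        shifted_t = fit_elongation_rate(
            FilamentTrack(times=t + 30.0, lengths=lengths), (90.0, 150.0)
        )
        assert shifted_t.rate == pytest.approx(base.rate, rel=1e-10)

    def test_roundtrip_robust_to_twenty_percent_noise(self):
        # generate -> extract -> fit stays within 3x the fit stderr of
        # truth (median over 50 seeds) even at noise_sd = 20% of signal
        rate = 61.3
        errors, stderrs = [], []
        for seed in range(50):
            _, stack = simulate_filament_timelapse(GrowthParams(
                elongation_rate=rate, noise_sd=0.20, duration=120.0, seed=seed))
            est = fit_elongation_rate(
                extract_filament_lengths(stack), (60.0, 120.0))
            errors.append(abs(est.rate - rate))
            stderrs.append(est.stderr)
        assert np.median(errors) <= 3.0 * np.median(stderrs)

    def test_too_few_points_rejected(self):
        track = FilamentTrack(times=np.arange(5.0), lengths=np.arange(5.0) * 1e-3)
        with pytest.raises(ValueError):
            fit_elongation_rate(track, (0.0, 1.0))


class TestUnitAndRatioHelpers:
    def test_control_rate_in_subunits(self):
        # 35.9 nm/s with the implied 2.626 nm rise -> 13.67 subunits/s
        assert rate_to_subunits(35.9, ACTIN_RISE_NM_IMPLIED) == pytest.approx(13.67, abs=0.005)

    def test_canonical_rise(self):
        assert rate_to_subunits(27.0, 2.7) == pytest.approx(10.0)
        assert rate_to_subunits(0.0, 2.7) == 0.0

    def test_non_positive_rise_rejected(self):
        with pytest.raises(ValueError):
            rate_to_subunits(10.0, 0.0)

    def test_fold_changes(self):
        assert round(fold_change(61.3, 35.9), 1) == 1.7
        assert round(fold_change(12.4, 5.36), 1) == 2.3
        assert fold_change(7.7, 7.7) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)


class TestCompareConditions:
    def test_f_statistic_matches_hand_formulas(self):
        groups = {"a": np.array([1.0, 2.0, 3.0]),
                  "b": np.array([2.0, 3.0, 4.0]),
                  "c": np.array([3.0, 4.0, 5.0])}
        result = compare_conditions(groups)
        all_vals = np.concatenate(list(groups.values()))
        grand = all_vals.mean()
        ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
        ss_within = sum(np.sum((v - v.mean()) ** 2) for v in groups.values())
        k, n = len(groups), all_vals.size
        f_hand = (ss_between / (k - 1)) / (ss_within / (n - k))
        assert result.anova_F == pytest.approx(f_hand, rel=1e-10)
        assert 0.0 <= result.anova_p <= 1.0
        assert len(result.tukey_table) == k * (k - 1) // 2

    def test_anova_p_matches_reference_implementation(self):
        from scipy import stats as sps

        rng = np.random.default_rng(0)
        groups = {f"g{i}": rng.normal(i * 0.3, 1.0, size=12) for i in range(4)}
        result = compare_conditions(groups)
        _, p_ref = sps.f_oneway(*groups.values())
        assert result.anova_p == pytest.approx(p_ref, abs=1e-6)

    def test_identical_groups_have_zero_mean_difference(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        result = compare_conditions({"a": vals, "b": vals.copy()})
        assert float(result.tukey_table["mean_diff_nm_s"].iloc[0]) == pytest.approx(0.0)
        assert result.tukey_table["significance"].iloc[0] == "n.s."

    def test_null_rejection_rate_calibrated(self):
        # identically distributed groups: alpha=0.05 rejections within the
        # 95% binomial interval around 0.05 over 1000 simulations
        rng = np.random.default_rng(2024)
        n_sims, rejections = 1000, 0
        for _ in range(n_sims):
            groups = {f"g{i}": rng.normal(0.0, 1.0, size=20) for i in range(3)}
            if compare_conditions(groups).anova_p <= 0.05:
                rejections += 1
        rate = rejections / n_sims
        half_width = 1.96 * np.sqrt(0.05 * 0.95 / n_sims)
        assert abs(rate - 0.05) <= half_width

    def test_degenerate_all_constant(self):
        result = compare_conditions({"a": np.array([1.0, 1.0]),
                                     "b": np.array([2.0, 2.0])})
        assert result.degenerate and result.anova_p is None

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions({"a": np.array([1.0, 2.0])})

    def test_highly_separated_groups_flagged_significant(self):
        rng = np.random.default_rng(5)
        result = compare_conditions({
            "control": rng.normal(35.9, 1.0, size=20),
            "peg": rng.normal(61.3, 1.0, size=20),
        })
        assert result.anova_p <= 0.001
        assert result.tukey_table["significance"].iloc[0] == "***"
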