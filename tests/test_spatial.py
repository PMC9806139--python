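import numpy as np
import pytest

import ratgait as rg

GRID = 0.24  # mm, spatial calibration unit


def fp(limb, start, end, heel, toes=None):
    toes = toes if toes is not None else [(heel[0] + 30, heel[1] + k) for k in range(5)]
    return rg.Footprint(limb, start, end, np.asarray(heel, float), np.asarray(toes, float))


class TestStrideAndStep:
    def test_stride_from_collinear_heels(self):
        prints = [fp("right", i * 30, i * 30 + 18, (140.0 * i, -15.0)) for i in range(3)]
        assert rg.stride_lengths(prints) == pytest.approx([140.0, 140.0])

    def test_stride_is_euclidean(self):
        prints = [fp("right", 0, 18, (0.0, 0.0)), fp("right", 30, 48, (120.0, 50.0))]
        assert rg.stride_lengths(prints) == pytest.approx([130.0])  # 5-12-13

    def test_single_print_gives_empty_result(self):
        assert rg.stride_lengths([fp("right", 0, 18, (0, 0))]).size == 0
        assert rg.step_lengths([fp("right", 0, 18, (0, 0))])["right"].size == 0

    def test_steps_from_alternating_heels(self):
        prints = [
            fp("left", 0, 18, (0.0, 15.0)),
            fp("right", 15, 33, (70.0, -15.0)),
            fp("left", 30, 48, (140.0, 15.0)),
        ]
        steps = rg.step_lengths(prints)
        assert steps["right"] == pytest.approx([70.0])
        assert steps["left"] == pytest.approx([70.0])

    def test_consecutive_ipsilateral_prints_skipped(self):
        prints = [
            fp("left", 0, 18, (0.0, 15.0)),
            fp("left", 30, 48, (140.0, 15.0)),  # missed right print
            fp("right", 45, 63, (210.0, -15.0)),
        ]
        steps = rg.step_lengths(prints)
        assert steps["left"].size == 0
        assert steps["right"] == pytest.approx([70.0])

    def test_left_plus_right_steps_equal_stride_noise_free(self, noise_free_trial):
        steps = rg.step_lengths(noise_free_trial.footprints)
        strides = rg.stride_lengths(noise_free_trial.limb_footprints("right"))
        lr = steps["left"].mean() + steps["right"].mean()
        assert lr == pytest.approx(strides.mean(), abs=GRID)


class TestPrintGeometry:
    def test_rectangular_print(self):
        toes = [(30.0, 0.0), (30.0, 4.0), (30.0, 8.0), (30.0, 12.0), (30.0, 16.0)]
        g = rg.print_geometry(fp("right", 0, 18, (0.0, 8.0), toes))
        assert g["toe_spread_mm"] == pytest.approx(16.0)
        assert g["intermediary_toe_spread_mm"] == pytest.approx(8.0)
        assert g["print_length_mm"] == pytest.approx(30.0)

    def test_degenerate_coincident_points_give_zeros(self):
        toes = [(0.0, 0.0)] * 5
        g = rg.print_geometry(fp("right", 0, 1, (0.0, 0.0), toes))
        assert all(v == 0.0 for v in g.values())

    def test_missing_toe_leaves_other_metrics_intact(self):
        toes = [(30.0, 0.0), (np.nan, np.nan), (30.0, 8.0), (30.0, 12.0), (30.0, 16.0)]
        g = rg.print_geometry(fp("right", 0, 18, (0.0, 8.0), toes))
        assert np.isnan(g["intermediary_toe_spread_mm"])
        assert g["toe_spread_mm"] == pytest.approx(16.0)
        assert g["print_length_mm"] == pytest.approx(30.0)

    def test_noise_free_trial_recovers_generating_geometry(self, noise_free_trial):
        for limb in rg.LIMBS:
            for p in noise_free_trial.limb_footprints(limb):
                g = rg.print_geometry(p)
                assert g["toe_spread_mm"] == pytest.approx(18.0, abs=GRID)
                assert g["intermediary_toe_spread_mm"] == pytest.approx(9.0, abs=GRID)
                assert g["print_length_mm"] == pytest.approx(30.0, abs=GRID)


class TestTemporalMetrics:
    def test_single_cycle_arithmetic(self):
        cyc = rg.GaitCycle("right", 0, 18, 30)
        own = np.zeros(40, dtype=bool)
        own[0:18] = True
        contra = np.zeros(40, dtype=bool)
        out = rg.temporal_metrics([cyc], own, contra, 60.0)[0]
        assert out["stance_time_s"] == pytest.approx(0.300)
        assert out["swing_time_s"] == pytest.approx(0.200)
        assert out["double_support_time_s"] == 0.0

    @pytest.mark.parametrize("duty,expected_ds_fraction", [(0.5, 0.0), (0.6, 0.2)])
    def test_double_support_of_antiphase_square_waves(self, duty, expected_ds_fraction):
        period, n = 40, 200
        stance = int(duty * period)
        own = np.zeros(n, dtype=bool)
        contra = np.zeros(n, dtype=bool)
        for start in range(0, n - period, period):
            own[start : start + stance] = True
        for start in range(period // 2, n - period, period):
            contra[start : start + stance] = True
        cycles = rg.detect_cycles(own, 60.0)
        # skip the first cycle: the contralateral pre-roll is not covered
        out = rg.temporal_metrics(cycles[1:], own, contra, 60.0)
        for row in out:
            assert row["double_support_time_s"] * 60.0 == pytest.approx(
                expected_ds_fraction * period, abs=1.0
            )

    def test_stance_plus_swing_equals_cycle_duration(self, noisy_trial):
        """Exact identity, per cycle, at any noise level."""
        for limb in rg.LIMBS:
            cycles = rg.detect_cycles(noisy_trial.contact[limb], 60.0, limb=limb)
            out = rg.temporal_metrics(
                cycles, noisy_trial.contact[limb], noisy_trial.contact["left"], 60.0
            )
            for c, row in zip(cycles, out):
                total = (c.next_contact_frame - c.initial_contact_frame) / 60.0
                assert row["stance_time_s"] + row["swing_time_s"] == pytest.approx(total)

    def test_cycle_outside_signal_rejected(self):
        with pytest.raises(rg.InvalidParameterError):
            rg.temporal_metrics(
                [rg.GaitCycle("right", 0, 18, 30)],
                np.zeros(10, dtype=bool),
                np.zeros(10, dtype=bool),
                60.0,
            )


class TestWalkingSpeed:
    def test_displacement_over_elapsed_time(self):
        prints = [fp("right", 0, 18, (0.0, -15.0)), fp("right", 300, 318, (1400.0, -15.0))]
        rec = _rec_with(prints, n_frames=400)
        assert rg.walking_speed(rec) == pytest.approx(280.0)

    def test_stationary_prints_give_zero(self):
        prints = [fp("right", 0, 18, (5.0, -15.0)), fp("right", 30, 48, (5.0, -15.0))]
        assert rg.walking_speed(_rec_with(prints, 60)) == 0.0

    def test_noise_free_speed_equals_stride_over_cycle(self, noise_free_trial):
        assert rg.walking_speed(noise_free_trial) == pytest.approx(280.0, abs=0.5)

    def test_too_few_prints_rejected(self):
        with pytest.raises(rg.InsufficientDataError):
            rg.walking_speed(_rec_with([fp("right", 0, 18, (0.0, -15.0))], 60))


class TestSummaries:
    def _metrics(self, n_steps, value=1.0):
        return rg.TrialMetrics(
            limb="right", n_footsteps=n_steps, samples={"stride_length_mm": [value] * n_steps}
        )

    def test_three_trials_of_four_steps_are_valid(self):
        s = rg.summarize_trials([self._metrics(4)] * 3, "s1", "d1", "right")
        assert s.valid and s.n_footsteps == 12

    def test_eight_pooled_steps_flagged_invalid(self):
        s = rg.summarize_trials([self._metrics(4)] * 2, "s1", "d1", "right")
        assert not s.valid and s.n_footsteps == 8

    def test_short_trials_excluded_before_pooling(self):
        s = rg.summarize_trials([self._metrics(4, 2.0), self._metrics(3, 99.0)], "s1", "d1", "right")
        assert s.means["stride_length_mm"] == pytest.approx(2.0)

    def test_constant_metric_mean_is_exact(self):
        s = rg.summarize_trials([self._metrics(5, 3.14)] * 3, "s1", "d1", "right")
        assert s.means["stride_length_mm"] == pytest.approx(3.14)

    def test_no_valid_trials_rejected(self):
        with pytest.raises(rg.InsufficientDataError):
            rg.summarize_trials([self._metrics(2)], "s1", "d1", "right")


class TestFrameInvariance:
    def test_indices_invariant_to_rigid_translation_and_x_flip(self, noise_free_trial):
        rec = noise_free_trial
        shifted = [
            rg.Footprint(
                p.limb,
                p.contact_start_frame,
                p.contact_end_frame,
                p.heel_xy + np.array([123.0, -7.0]),
                p.toe_xy + np.array([123.0, -7.0]),
            )
            for p in rec.footprints
        ]
        flipped = [
            rg.Footprint(
                p.limb,
                p.contact_start_frame,
                p.contact_end_frame,
                p.heel_xy * np.array([-1.0, 1.0]),
                p.toe_xy * np.array([-1.0, 1.0]),
            )
            for p in rec.footprints
        ]
        for variant in (shifted, flipped):
            right = [p for p in variant if p.limb == "right"]
            assert rg.stride_lengths(right) == pytest.approx(
                rg.stride_lengths(rec.limb_footprints("right"))
            )
            assert np.abs(rg.step_lengths(variant)["right"]) == pytest.approx(
                np.abs(rg.step_lengths(rec.footprints)["right"])
            )
            g0 = rg.print_geometry(rec.limb_footprints("right")[0])
            g1 = rg.print_geometry(right[0])
            assert g0 == pytest.approx(g1)


def _rec_with(prints, n_frames):
    zeros = np.zeros((n_frames, 2))
    return rg.TrialRecording(
        subject_id="s",
        group_label="sham",
        day="pre",
        frame_rate=60.0,
        mm_per_px=0.24,
        landmarks={l: {"knee": zeros, "ankle": zeros, "mt5": zeros} for l in rg.LIMBS},
        contact={l: np.zeros(n_frames, dtype=bool) for l in rg.LIMBS},
        footprints=prints,
    )
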