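import numpy as np
import pytest

import ratgait as rg


class TestSimulateTrial:
    def test_noise_free_stance_and_swing_frame_counts(self, noise_free_trial):
        """duty 0.6 x cycle 0.5 s x 60 fps: stance 18 frames, swing 12."""
        for limb in rg.LIMBS:
            cycles = rg.detect_cycles(noise_free_trial.contact[limb], 60.0, limb=limb)
            assert len(cycles) == 10
            assert all(c.stance_frames == 18 for c in cycles)
            assert all(c.swing_frames == 12 for c in cycles)

    def test_total_heel_displacement_is_cycles_times_stride(self, noise_free_trial):
        prints = noise_free_trial.limb_footprints("right")
        assert len(prints) == 11
        span = prints[-1].heel_xy[0] - prints[0].heel_xy[0]
        assert span == pytest.approx(10 * 140.0, abs=2 * 0.24)

    def test_deterministic_under_fixed_seed(self, baseline):
        a = rg.simulate_trial(baseline, 5, seed=9)
        b = rg.simulate_trial(baseline, 5, seed=9)
        for limb in rg.LIMBS:
            assert np.array_equal(a.contact[limb], b.contact[limb])
            for lm in ("knee", "ankle", "mt5"):
                assert np.array_equal(a.landmarks[limb][lm], b.landmarks[limb][lm])
        assert all(
            np.array_equal(fa.heel_xy, fb.heel_xy) and np.array_equal(fa.toe_xy, fb.toe_xy)
            for fa, fb in zip(a.footprints, b.footprints)
        )

    def test_fewer_than_four_cycles_rejected(self, baseline):
        with pytest.raises(rg.InvalidParameterError):
            rg.simulate_trial(baseline, 3, seed=0)

    def test_contact_true_exactly_during_truth_stance(self, noise_free_trial):
        rec = noise_free_trial
        for limb in rg.LIMBS:
            for cyc in rec.truth["cycles"][limb]:
                on, off = cyc["onset_frame"], cyc["toe_off_frame"]
                assert rec.contact[limb][on:off].all()
                assert not rec.contact[limb][off : cyc["end_frame"]].any()

    def test_toe_order_monotone_on_lateral_side(self, noisy_trial):
        for fp in noisy_trial.footprints:
            ys = fp.toe_xy[:, 1]
            diffs = np.diff(ys)
            assert (diffs > 0).all() if fp.limb == "left" else (diffs < 0).all()

    @pytest.mark.parametrize("duty,cycle", [(0.5, 0.4), (0.65, 0.6), (0.7, 0.5)])
    def test_stance_duration_tracks_duty_factor(self, duty, cycle):
        p = rg.GaitModelParams(duty_factor=duty, cycle_duration=cycle).noise_free()
        rec = rg.simulate_trial(p, 6, seed=0)
        cycles = rg.detect_cycles(rec.contact["right"], 60.0)
        expected = duty * cycle * 60.0
        assert all(abs(c.stance_frames - expected) <= 1.0 for c in cycles)


class TestSimulateCohort:
    def test_default_design_covers_the_study_layout(self):
        design = rg.CohortDesign()
        assert sum(design.group_sizes.values()) == 25
        assert design.group_sizes == {"sham": 5, "L5": 5, "L6": 9, "L5L6": 6}
        assert len(design.days) == 6

    def test_minimal_design_yields_one_recording_set(self):
        recs = rg.simulate_cohort(
            rg.CohortDesign(
                group_sizes={"sham": 1}, days=("pre",), trials_per_session=1
            ),
            seed=0,
        )
        assert len(recs) == 1

    def test_cohort_size_and_reproducibility(self, small_cohort):
        assert len(small_cohort) == 6 * 2 * 2  # subjects x days x trials
        again = rg.simulate_cohort(
            rg.CohortDesign(
                group_sizes={"sham": 3, "L5L6": 3}, days=("pre", "d1"), trials_per_session=2
            ),
            seed=2,
        )
        for a, b in zip(small_cohort, again):
            assert a.subject_id == b.subject_id and a.day == b.day
            assert np.array_equal(a.landmarks["right"]["ankle"], b.landmarks["right"]["ankle"])

    def test_empty_group_rejected(self):
        with pytest.raises(rg.InvalidParameterError):
            rg.CohortDesign(group_sizes={"sham": 0})

    def test_subject_effects_consistent_across_days(self, small_cohort):
        by_subject = {}
        for rec in small_cohort:
            by_subject.setdefault(rec.subject_id, set()).add(
                tuple(sorted(rec.truth["subject_effects"].items()))
            )
        assert all(len(v) == 1 for v in by_subject.values())


class TestSimulateOpenField:
    def test_zero_stop_rate_has_no_immobility(self):
        track = rg.simulate_openfield(
            rg.MobilityParams(stop_rate_per_s=0.0, duration_s=60.0), seed=0
        )
        assert track.truth["immobile_time_s"] == 0.0

    def test_zero_speed_travels_nowhere(self):
        track = rg.simulate_openfield(
            rg.MobilityParams(mean_speed_cm_s=0.0, duration_s=60.0), seed=0
        )
        assert track.truth["total_distance_cm"] == 0.0

    def test_track_stays_in_arena_with_expected_sample_count(self):
        mp = rg.MobilityParams(duration_s=120.0)
        track = rg.simulate_openfield(mp, seed=4)
        assert len(track.positions) == int(mp.duration_s * mp.sample_rate_hz)
        assert (track.positions >= 0.0).all() and (track.positions <= mp.arena_side_cm).all()

    def test_negative_rates_rejected(self):
        with pytest.raises(rg.InvalidParameterError):
            rg.MobilityParams(mean_speed_cm_s=-1.0)

    def test_mobility_preset_attenuates_with_recovery(self):
        d1 = rg.mobility_preset("L5L6", "d1")
        d21 = rg.mobility_preset("L5L6", "d21")
        sham = rg.mobility_preset("sham", "d1")
        assert d1.mean_speed_cm_s < d21.mean_speed_cm_s < sham.mean_speed_cm_s
        assert d1.stop_rate_per_s > d21.stop_rate_per_s > sham.stop_rate_per_s
        assert sham == rg.MobilityParams()
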