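"""Synthetic walkway trials, footprint sequences and open-field tracks.

The walkway generator emulates the acquisition geometry of a mirrored
walking track filmed at 60 frames per second: a lateral view yielding
per-frame 2D positions (x = direction of travel, z = vertical) of three
hindlimb landmarks (knee/shank, ankle = lateral malleolus, and fifth
metatarsal head), and a bottom view yielding digitized footprints (heel
plus five toes, x = travel, y = mediolateral) with their contact frame
intervals.

Kinematic model, per limb
-------------------------
Heel strikes occur at stride-length increments along x; the contralateral
limb is phase-lagged by ``limb_phase_lag`` (0.5 = strict alternation) and
its heels lead by ``step_offset``.  During stance the ankle is planted
over the print; during swing it advances to the next print along a
cosine-eased trajectory with a sinusoidal vertical lift.  The ankle joint
angle interpolates through its four event values (initial contact,
mid-stance, pre-swing, mid-swing) with a piecewise-cosine waveform, and
the knee and fifth-metatarsal landmarks are placed so that the interior
angle at the ankle reproduces that waveform exactly.  Gaussian per-cycle
and per-print noise perturbs timing, body displacement, footprint
geometry and event angles; every drawn quantity is recorded as ground
truth alongside the recording.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError
from .params import (
    DAYS,
    DEFAULT_GROUP_SIZES,
    DEFAULT_SUBJECT_SD,
    GAIT_EVENTS,
    LESION_PRESETS,
    LIMBS,
    GaitModelParams,
    TrialParams,
    make_preset,
)

# Lateral-view geometry (mm).  The shank direction is fixed; the foot
# segment is the shank direction rotated by the ankle angle, so the
# interior angle recovered from the landmarks equals the generated
# angle waveform identically.
_SHANK_LEN = 30.0
_FOOT_LEN = 20.0
_SHANK_TILT = -0.15  # radians from vertical (knee slightly behind ankle)
_ANKLE_X_OFFSET = 5.0  # ankle sits just ahead of the heel print
_ANKLE_Z_STANCE = 12.0
_SWING_LIFT = 15.0
_PAW_Y = {"left": 15.0, "right": -15.0}  # mediolateral lane of each paw
# Fractional forward position of each toe tip relative to print length,
# fanned so toes 1/5 sit slightly behind toe 3.
_TOE_FAN = (0.78, 0.92, 1.0, 0.92, 0.78)


@dataclass(frozen=True)
class Footprint:
    """One digitized paw contact from the bottom view (mm)."""

    limb: str
    contact_start_frame: int
    contact_end_frame: int  # half-open: contact during [start, end)
    heel_xy: np.ndarray
    toe_xy: np.ndarray  # (5, 2): toes 1 (medial) .. 5 (lateral)

    def __post_init__(self) -> None:
        if self.contact_start_frame >= self.contact_end_frame:
            raise InvalidParameterError("footprint contact interval is empty")


@dataclass
class TrialRecording:
    """One calibrated walkway pass: landmark series + footprints."""

    subject_id: str
    group_label: str
    day: str
    frame_rate: float
    mm_per_px: float
    landmarks: dict[str, dict[str, np.ndarray]]  # limb -> name -> (n, 2)
    contact: dict[str, np.ndarray]  # limb -> (n,) bool
    footprints: list[Footprint]
    truth: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.contact["left"])

    def limb_footprints(self, limb: str) -> list[Footprint]:
        return [fp for fp in self.footprints if fp.limb == limb]

    def validate(self) -> None:
        """Check the structural invariants; raise on violation."""
        if self.frame_rate <= 0:
            raise InvalidParameterError("frame_rate must be positive")
        n = self.n_frames
        for limb in LIMBS:
            if self.contact[limb].dtype != bool or len(self.contact[limb]) != n:
                raise InvalidParameterError(f"bad contact signal for {limb} limb")
            for name, arr in self.landmarks[limb].items():
                if arr.shape != (n, 2):
                    raise InvalidParameterError(
                        f"landmark {name}/{limb} has shape {arr.shape}, expected ({n}, 2)"
                    )
            prints = self.limb_footprints(limb)
            xs = [fp.heel_xy[0] for fp in prints]
            if any(b <= a for a, b in zip(xs, xs[1:])):
                raise InvalidParameterError(f"{limb} footprints not in forward order")
            for fp in prints:
                if fp.contact_start_frame < 0 or fp.contact_end_frame > n:
                    raise InvalidParameterError("footprint interval outside recording")


def _quantize(x: np.ndarray | float, grid: float) -> np.ndarray | float:
    """Snap bottom-view coordinates to the spatial calibration grid."""
    return np.round(np.asarray(x, dtype=float) / grid) * grid


def _cosine_interp(node_t: np.ndarray, node_v: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Piecewise-cosine interpolation through (node_t, node_v) at times t."""
    idx = np.clip(np.searchsorted(node_t, t, side="right") - 1, 0, len(node_t) - 2)
    t0, t1 = node_t[idx], node_t[idx + 1]
    s = np.clip((t - t0) / np.where(t1 > t0, t1 - t0, 1.0), 0.0, 1.0)
    w = 0.5 * (1.0 - np.cos(np.pi * s))
    return node_v[idx] + (node_v[idx + 1] - node_v[idx]) * w


def _rotate_cw(v: np.ndarray, theta_rad: np.ndarray) -> np.ndarray:
    """Rotate 2D vector(s) clockwise by theta (dorsiflexion -> plantarflexion)."""
    c, s = np.cos(theta_rad), np.sin(theta_rad)
    return np.stack([v[0] * c + v[1] * s, -v[0] * s + v[1] * c], axis=-1)


def simulate_trial(
    params: TrialParams | GaitModelParams,
    n_cycles: int,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    frame_rate: float = 60.0,
    mm_per_px: float = 0.24,
    subject_id: str = "subject",
    group_label: str = "sham",
    day: str = "pre",
) -> TrialRecording:
    """Synthesize one walkway pass with ``n_cycles`` complete gait cycles.

    Each limb receives ``n_cycles + 1`` stance bouts / footprints, so
    exactly ``n_cycles`` rising-edge-to-rising-edge cycles (and stride
    measurements) are recoverable downstream.  At least four steps are
    required for a satisfactory pass.
    """
    if isinstance(params, GaitModelParams):
        params = TrialParams(params, params)
    if n_cycles < 4:
        raise InvalidParameterError("a satisfactory walk needs at least four steps (cycles)")
    if frame_rate <= 0 or mm_per_px <= 0:
        raise InvalidParameterError("frame_rate and mm_per_px must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)

    base = params.left  # shared quantities agree across limbs
    sd = base.noise_sd
    n_bouts = n_cycles + 1
    lag = base.limb_phase_lag

    # --- shared (whole body) per-cycle draws -------------------------------
    cyc = np.maximum(
        base.cycle_duration + rng.normal(0.0, sd.get("cycle_duration", 0.0), n_bouts),
        0.2 * base.cycle_duration,
    )
    disp = np.maximum(
        base.stride_length + rng.normal(0.0, sd.get("stride_length", 0.0), n_bouts),
        0.1 * base.stride_length,
    )
    offset = base.step_offset + rng.normal(0.0, sd.get("step_offset", 0.0), n_bouts)

    onset_r = np.concatenate([[0.0], np.cumsum(cyc)])[:n_bouts]
    heel_r = np.concatenate([[0.0], np.cumsum(disp)])[:n_bouts]
    onset_l = onset_r + lag * cyc
    heel_l = heel_r + offset

    onsets = {"right": onset_r, "left": onset_l}
    heels = {"right": heel_r, "left": heel_l}

    # --- limb-local per-cycle draws ----------------------------------------
    duty: dict[str, np.ndarray] = {}
    stance_dur: dict[str, np.ndarray] = {}
    cycle_span: dict[str, np.ndarray] = {}
    angles: dict[str, np.ndarray] = {}
    for limb in LIMBS:
        p = params.limb(limb)
        d = np.clip(
            p.duty_factor + rng.normal(0.0, p.noise_sd.get("duty_factor", 0.0), n_bouts),
            0.05,
            0.95,
        )
        span = np.diff(np.concatenate([onsets[limb], [onsets[limb][-1] + cyc[-1]]]))
        duty[limb] = d
        cycle_span[limb] = span
        stance_dur[limb] = d * span
        ev_mean = np.array([p.ankle_angle_by_event[ev] for ev in GAIT_EVENTS])
        a_sd = p.noise_sd.get("ankle_angle_deg", 0.0)
        # one extra (virtual) cycle before the first onset for the pre-roll
        angles[limb] = np.clip(
            ev_mean[None, :] + rng.normal(0.0, a_sd, (n_bouts + 1, 4)), 1.0, 179.0
        )

    total_dur = max(onsets[l][-1] + stance_dur[l][-1] for l in LIMBS) + 0.25 * base.cycle_duration
    n_frames = int(round(total_dur * frame_rate)) + 1
    t = np.arange(n_frames) / frame_rate

    shank_u = np.array([math.sin(_SHANK_TILT), math.cos(_SHANK_TILT)])
    landmarks: dict[str, dict[str, np.ndarray]] = {}
    contact: dict[str, np.ndarray] = {}
    footprints: list[Footprint] = []
    truth_cycles: dict[str, list[dict]] = {l: [] for l in LIMBS}
    truth_prints: dict[str, list[dict]] = {l: [] for l in LIMBS}

    for limb in LIMBS:
        p = params.limb(limb)
        on = onsets[limb]
        st = stance_dur[limb]
        hx = heels[limb]

        # stance intervals incl. a virtual bout before the recording start
        v_on = on[0] - cycle_span[limb][0]
        v_st = duty[limb][0] * cycle_span[limb][0]
        iv_start = np.concatenate([[v_on], on])
        iv_end = iv_start + np.concatenate([[v_st], st])
        iv_x = np.concatenate([[hx[0] - disp[0]], hx]) + _ANKLE_X_OFFSET

        # ankle trajectory: planted during stance, cosine-eased swing
        idx = np.clip(np.searchsorted(iv_start, t, side="right") - 1, 0, len(iv_start) - 1)
        in_stance = t <= iv_end[idx]
        x = np.where(in_stance, iv_x[idx], 0.0)
        z = np.full(n_frames, _ANKLE_Z_STANCE)
        swing = ~in_stance & (idx < len(iv_start) - 1)
        if swing.any():
            i0 = idx[swing]
            s = (t[swing] - iv_end[i0]) / (iv_start[i0 + 1] - iv_end[i0])
            s = np.clip(s, 0.0, 1.0)
            x[swing] = iv_x[i0] + (iv_x[i0 + 1] - iv_x[i0]) * 0.5 * (1 - np.cos(np.pi * s))
            z[swing] = _ANKLE_Z_STANCE + _SWING_LIFT * np.sin(np.pi * s)
        tail = ~in_stance & ~swing
        x[tail] = iv_x[-1]

        # ankle-angle waveform: piecewise cosine through the event nodes
        node_t: list[float] = []
        node_v: list[float] = []
        for k in range(len(iv_start)):
            t_ic = iv_start[k]
            t_to = iv_end[k]
            t_nx = iv_start[k + 1] if k + 1 < len(iv_start) else iv_end[k] + (
                cycle_span[limb][-1] - st[-1]
            )
            a = angles[limb][k]
            node_t += [t_ic, 0.5 * (t_ic + t_to), t_to, 0.5 * (t_to + t_nx)]
            node_v += list(a)
        node_t.append(node_t[-1] + 1.0)  # hold after last node
        node_v.append(node_v[0])
        theta = _cosine_interp(np.array(node_t), np.array(node_v), t)

        ankle = np.stack([x, z], axis=1)
        knee = ankle + _SHANK_LEN * shank_u
        mt5 = ankle + _FOOT_LEN * _rotate_cw(shank_u, np.deg2rad(theta))
        landmarks[limb] = {"knee": knee, "ankle": ankle, "mt5": mt5}

        # contact signal and footprints (real bouts only)
        sig = np.zeros(n_frames, dtype=bool)
        y_c = _PAW_Y[limb]
        # toe 1 (hallux) is medial: toward the midline y = 0
        y_sign = -1.0 if limb == "left" else 1.0
        for i in range(n_bouts):
            f0 = int(round(on[i] * frame_rate))
            f1 = max(int(round((on[i] + st[i]) * frame_rate)), f0 + 1)
            sig[f0:min(f1, n_frames)] = True
            ts = max(p.toe_spread + rng.normal(0.0, p.noise_sd.get("toe_spread", 0.0)), 0.1)
            its = max(
                p.intermediary_toe_spread
                + rng.normal(0.0, p.noise_sd.get("intermediary_toe_spread", 0.0)),
                0.1,
            )
            pl = max(p.print_length + rng.normal(0.0, p.noise_sd.get("print_length", 0.0)), 0.1)
            heel = _quantize(np.array([hx[i], y_c]), mm_per_px)
            half = np.array([ts / 2, its / 2, 0.0, -its / 2, -ts / 2]) * y_sign
            toes = _quantize(
                np.stack([hx[i] + pl * np.asarray(_TOE_FAN), y_c + half], axis=1), mm_per_px
            )
            footprints.append(Footprint(limb, f0, f1, heel, toes))
            truth_prints[limb].append(
                {"toe_spread": ts, "intermediary_toe_spread": its, "print_length": pl}
            )
        contact[limb] = sig

        # ground-truth event bookkeeping for the complete cycles
        for i in range(n_cycles):
            t_ic, t_to, t_nx = on[i], on[i] + st[i], on[i + 1]
            ev_frames = {
                "initial_contact": int(round(t_ic * frame_rate)),
                "mid_stance": int(round(0.5 * (t_ic + t_to) * frame_rate)),
                "pre_swing": int(round(t_to * frame_rate)),
                "mid_swing": int(round(0.5 * (t_to + t_nx) * frame_rate)),
            }
            truth_cycles[limb].append(
                {
                    "onset_frame": ev_frames["initial_contact"],
                    "toe_off_frame": ev_frames["pre_swing"],
                    "end_frame": int(round(t_nx * frame_rate)),
                    "event_frames": ev_frames,
                    # row i+1 of the angle draws: row 0 is the virtual pre-roll
                    "event_angles": dict(zip(GAIT_EVENTS, angles[limb][i + 1].tolist())),
                    "stride_mm": float(hx[i + 1] - hx[i]),
                    "stance_s": float(st[i]),
                    "swing_s": float(t_nx - t_to),
                    "cycle_s": float(t_nx - t_ic),
                }
            )

    footprints.sort(key=lambda fp: fp.contact_start_frame)
    rec = TrialRecording(
        subject_id=subject_id,
        group_label=group_label,
        day=day,
        frame_rate=frame_rate,
        mm_per_px=mm_per_px,
        landmarks=landmarks,
        contact=contact,
        footprints=footprints,
        truth={
            "params": {l: asdict(params.limb(l)) for l in LIMBS},
            "cycles": truth_cycles,
            "footprints": truth_prints,
        },
    )
    rec.validate()
    return rec


@dataclass(frozen=True)
class CohortDesign:
    """Study layout: groups with sizes, assessment days and trial counts."""

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    days: Sequence[str] = DAYS
    trials_per_session: int = 3
    cycles_per_trial: int = 4
    subject_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SUBJECT_SD))

    def __post_init__(self) -> None:
        if not self.group_sizes or any(n <= 0 for n in self.group_sizes.values()):
            raise InvalidParameterError("every group must have at least one subject")
        if self.trials_per_session < 1 or self.cycles_per_trial < 4:
            raise InvalidParameterError(
                "need >=1 trial per session and >=4 cycles per trial"
            )


def simulate_cohort(
    design: CohortDesign | None = None,
    seed: int = 0,
    baseline: GaitModelParams | None = None,
) -> list[TrialRecording]:
    """Simulate every subject x day x trial recording of a study cohort.

    Each subject carries Gaussian random intercepts (drawn once, applied
    at every day) on top of the group x day preset means; trial-level
    noise comes from the per-cycle/per-print noise model.  All randomness
    derives from the single ``seed``.
    """
    design = design if design is not None else CohortDesign()
    base = baseline if baseline is not None else GaitModelParams()
    root = np.random.SeedSequence(seed)
    recordings: list[TrialRecording] = []
    for g_idx, (group, n_subj) in enumerate(sorted(design.group_sizes.items())):
        for s_idx in range(n_subj):
            subj_ss = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(g_idx, s_idx)
            )
            eff_rng = np.random.default_rng(subj_ss.spawn(1)[0])
            deltas: dict[str, float] = {}
            for key, s in design.subject_sd.items():
                if key == "ankle_angle_deg":
                    a = float(eff_rng.normal(0.0, s))
                    deltas.update({f"ankle:{ev}": a for ev in GAIT_EVENTS})
                else:
                    deltas[key] = float(eff_rng.normal(0.0, s))
            subj_base = base.with_deltas(deltas)
            subject_id = f"{group}-{s_idx + 1:02d}"
            for d_idx, day in enumerate(design.days):
                tp = make_preset(group, day, baseline=subj_base)
                for t_idx in range(design.trials_per_session):
                    trial_ss = np.random.SeedSequence(
                        entropy=root.entropy, spawn_key=(g_idx, s_idx, d_idx, t_idx)
                    )
                    rec = simulate_trial(
                        tp,
                        design.cycles_per_trial,
                        rng=np.random.default_rng(trial_ss),
                        subject_id=subject_id,
                        group_label=group,
                        day=day,
                    )
                    rec.truth["subject_effects"] = deltas
                    rec.truth["trial_index"] = t_idx
                    recordings.append(rec)
    return recordings


# ---------------------------------------------------------------------------
# Open field
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MobilityParams:
    """Bout-structured exploratory locomotion in the open-field arena."""

    mean_speed_cm_s: float = 8.0
    stop_rate_per_s: float = 0.05  # hazard of entering a stop while moving
    mean_stop_s: float = 4.0
    duration_s: float = 600.0
    sample_rate_hz: float = 25.0
    arena_side_cm: float = 60.0

    def __post_init__(self) -> None:
        if self.mean_speed_cm_s < 0 or self.stop_rate_per_s < 0 or self.mean_stop_s < 0:
            raise InvalidParameterError("speeds and rates must be non-negative")
        if self.duration_s <= 0 or self.sample_rate_hz <= 0 or self.arena_side_cm <= 0:
            raise InvalidParameterError("duration, sample rate and arena side must be positive")


@dataclass
class OpenFieldTrack:
    """Position samples of one open-field session (cm)."""

    sample_rate: float
    duration: float
    positions: np.ndarray  # (n, 2) within [0, arena_side]^2
    arena_side: float
    truth: dict = field(default_factory=dict)


def mobility_preset(group_label: str, day: str | int) -> MobilityParams:
    """Open-field mobility parameters for a group at an assessment day.

    Lesioned animals pause more often and for longer and move more
    slowly; the deficit follows the same recovery curve as the gait
    presets.  Sham (and the pre-lesion day) return the baseline.
    """
    from .errors import UnknownPresetError

    if group_label not in LESION_PRESETS:
        raise UnknownPresetError(f"unknown group {group_label!r}")
    preset = LESION_PRESETS[group_label]
    scale = preset.recovery_scale(day) if preset.limb_deltas else 0.0
    severity = 1.0 if group_label == "L5L6" else 0.25
    s = scale * severity
    base = MobilityParams()
    return MobilityParams(
        mean_speed_cm_s=base.mean_speed_cm_s * (1.0 - 0.30 * s),
        stop_rate_per_s=base.stop_rate_per_s * (1.0 + 1.5 * s),
        mean_stop_s=base.mean_stop_s * (1.0 + 1.0 * s),
        duration_s=base.duration_s,
        sample_rate_hz=base.sample_rate_hz,
        arena_side_cm=base.arena_side_cm,
    )


def simulate_openfield_cohort(
    design: CohortDesign | None = None, seed: int = 0
) -> list[tuple[str, str, str, "OpenFieldTrack"]]:
    """One open-field session per subject x day.

    Returns ``(subject_id, group, day, track)`` tuples; randomness
    derives deterministically from ``seed``.
    """
    design = design if design is not None else CohortDesign()
    root = np.random.SeedSequence(seed)
    out = []
    for g_idx, (group, n_subj) in enumerate(sorted(design.group_sizes.items())):
        for s_idx in range(n_subj):
            subject_id = f"{group}-{s_idx + 1:02d}"
            for d_idx, day in enumerate(design.days):
                ss = np.random.SeedSequence(
                    entropy=root.entropy, spawn_key=(7, g_idx, s_idx, d_idx)
                )
                track = simulate_openfield(
                    mobility_preset(group, day), rng=np.random.default_rng(ss)
                )
                out.append((subject_id, group, day, track))
    return out


def simulate_openfield(
    mobility_params: MobilityParams | None = None,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> OpenFieldTrack:
    """Bounded random walk with alternating move/stop bouts.

    Move-bout durations are exponential with mean ``1 / stop_rate``;
    stop-bout durations exponential with mean ``mean_stop_s``.  While
    moving, heading performs a random walk and per-sample speed varies
    around the mean; while stopped the position shows only tracker-level
    jitter.  Ground-truth distance, movement time and immobile time are
    recorded from the generator's own bookkeeping.
    """
    mp = mobility_params if mobility_params is not None else MobilityParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(mp.duration_s * mp.sample_rate_hz))
    dt = 1.0 / mp.sample_rate_hz
    pos = np.empty((n, 2))
    pos[0] = mp.arena_side_cm / 2.0
    moving = np.zeros(n, dtype=bool)
    heading = rng.uniform(0.0, 2 * np.pi)
    state_moving = True
    remaining = (
        rng.exponential(1.0 / mp.stop_rate_per_s) if mp.stop_rate_per_s > 0 else np.inf
    )
    distance = 0.0
    for i in range(1, n):
        if remaining <= 0.0:
            state_moving = not state_moving
            if state_moving:
                remaining = (
                    rng.exponential(1.0 / mp.stop_rate_per_s)
                    if mp.stop_rate_per_s > 0
                    else np.inf
                )
                heading = rng.uniform(0.0, 2 * np.pi)
            else:
                remaining = rng.exponential(mp.mean_stop_s) if mp.mean_stop_s > 0 else 0.0
        moving[i] = state_moving
        if state_moving:
            heading += rng.normal(0.0, 0.5)
            speed = max(rng.normal(mp.mean_speed_cm_s, 0.3 * mp.mean_speed_cm_s), 0.0)
            step = np.array([np.cos(heading), np.sin(heading)]) * speed * dt
            new = pos[i - 1] + step
            # reflect off the walls
            for k in range(2):
                if new[k] < 0.0:
                    new[k] = -new[k]
                    heading = heading + np.pi
                elif new[k] > mp.arena_side_cm:
                    new[k] = 2 * mp.arena_side_cm - new[k]
                    heading = heading + np.pi
            pos[i] = np.clip(new, 0.0, mp.arena_side_cm)
            distance += float(np.linalg.norm(pos[i] - pos[i - 1]))
        else:
            jitter = rng.normal(0.0, 0.02, 2)
            pos[i] = np.clip(pos[i - 1] + jitter, 0.0, mp.arena_side_cm)
        remaining -= dt
    moving[0] = moving[1] if n > 1 else True
    immobile_s = float((~moving).sum()) * dt
    track = OpenFieldTrack(
        sample_rate=mp.sample_rate_hz,
        duration=n * dt,
        positions=pos,
        arena_side=mp.arena_side_cm,
        truth={
            "total_distance_cm": distance,
            "immobile_time_s": immobile_s,
            "movement_time_s": n * dt - immobile_s,
            "params": asdict(mp),
        },
    )
    return track
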