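"""Spatial and temporal gait indices from footprints and gait cycles.

Nine indices per limb: five spatial (stride length, step length, print
length, toe spread, intermediary toe spread) and four temporal (stance
time, swing time, double-support time, walking speed).  Per-trial values
are pooled over a subject-day and averaged into a :class:`GaitSummary`;
a summary needs at least ten pooled footsteps to be valid, and trials
with fewer than four steps per limb are excluded before pooling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, InvalidParameterError
from .events import GaitCycle
from .simulate import Footprint, TrialRecording

log = logging.getLogger(__name__)

#: The nine spatiotemporal indices, in reporting order.
GAIT_METRICS = (
    "stride_length_mm",
    "step_length_mm",
    "print_length_mm",
    "toe_spread_mm",
    "intermediary_toe_spread_mm",
    "stance_time_s",
    "swing_time_s",
    "double_support_time_s",
    "walking_speed_mm_s",
)


def stride_lengths(footprints: list[Footprint]) -> np.ndarray:
    """Euclidean distances between consecutive ipsilateral heel strikes.

    Expects the prints of a single limb; returns an empty array for
    fewer than two prints.
    """
    prints = sorted(footprints, key=lambda fp: fp.contact_start_frame)
    if len(prints) < 2:
        return np.empty(0)
    heels = np.stack([fp.heel_xy for fp in prints])
    return np.linalg.norm(np.diff(heels, axis=0), axis=1)


def step_lengths(footprints: list[Footprint]) -> dict[str, np.ndarray]:
    """Along-track (x) distance from each heel strike to the preceding
    contralateral one, keyed by the limb of the *leading* print.

    Consecutive ipsilateral prints (a missed contralateral step) break
    the alternation; that pair is skipped and logged.
    """
    prints = sorted(footprints, key=lambda fp: fp.contact_start_frame)
    out: dict[str, list[float]] = {"left": [], "right": []}
    for prev, cur in zip(prints, prints[1:]):
        if prev.limb == cur.limb:
            log.debug(
                "consecutive %s prints at frames %d, %d: step skipped",
                cur.limb, prev.contact_start_frame, cur.contact_start_frame,
            )
            continue
        out[cur.limb].append(float(cur.heel_xy[0] - prev.heel_xy[0]))
    return {limb: np.asarray(v) for limb, v in out.items()}


def print_geometry(footprint: Footprint) -> dict[str, float]:
    """Print length, toe spread and intermediary toe spread of one print.

    toe spread = |toe1 - toe5|, intermediary = |toe2 - toe4|, print
    length = |heel - toe3| (all Euclidean, bottom view).  A metric whose
    defining landmarks contain NaNs is reported as NaN; the others are
    still computed.
    """
    toes = np.asarray(footprint.toe_xy, dtype=float)
    heel = np.asarray(footprint.heel_xy, dtype=float)

    def dist(a: np.ndarray, b: np.ndarray) -> float:
        d = float(np.linalg.norm(a - b))
        return d if np.isfinite(d) else float("nan")

    return {
        "toe_spread_mm": dist(toes[0], toes[4]),
        "intermediary_toe_spread_mm": dist(toes[1], toes[3]),
        "print_length_mm": dist(heel, toes[2]),
    }


def temporal_metrics(
    cycles: list[GaitCycle],
    contact_own: np.ndarray,
    contact_contra: np.ndarray,
    frame_rate: float,
) -> list[dict[str, float]]:
    """Stance, swing and double-support time (s) for each cycle.

    Stance and swing come from the cycle's own edges; double support is
    the total time within the cycle during which both limbs' contact
    signals are simultaneously true (robust to asymmetric gait).
    """
    if frame_rate <= 0:
        raise InvalidParameterError("frame_rate must be positive")
    both = np.asarray(contact_own, dtype=bool) & np.asarray(contact_contra, dtype=bool)
    out = []
    for c in cycles:
        if c.next_contact_frame > len(both):
            raise InvalidParameterError("cycle indices outside the contact signals")
        out.append(
            {
                "stance_time_s": c.stance_frames / frame_rate,
                "swing_time_s": c.swing_frames / frame_rate,
                "double_support_time_s": float(
                    both[c.initial_contact_frame : c.next_contact_frame].sum()
                )
                / frame_rate,
            }
        )
    return out


def walking_speed(trial: TrialRecording) -> float:
    """Mean forward speed (mm/s) over the pass.

    Per limb with >= 2 prints: x-displacement from first to last heel
    strike divided by the elapsed time between those contact starts;
    averaged over the available limbs.
    """
    speeds = []
    for limb in ("left", "right"):
        prints = sorted(
            trial.limb_footprints(limb), key=lambda fp: fp.contact_start_frame
        )
        if len(prints) < 2:
            continue
        dt = (prints[-1].contact_start_frame - prints[0].contact_start_frame) / trial.frame_rate
        if dt <= 0:
            raise InvalidParameterError("zero elapsed time between first and last print")
        speeds.append((prints[-1].heel_xy[0] - prints[0].heel_xy[0]) / dt)
    if not speeds:
        raise InsufficientDataError("walking speed needs >= 2 footprints on a limb")
    return float(np.mean(speeds))


@dataclass
class GaitSummary:
    """Per-subject, per-day, per-limb means of the nine gait indices."""

    subject_id: str
    day: str
    limb: str
    group_label: str = ""
    means: dict[str, float] = field(default_factory=dict)
    n_footsteps: int = 0
    valid: bool = False


@dataclass
class TrialMetrics:
    """Raw per-trial index samples for one limb (pre-averaging)."""

    limb: str
    n_footsteps: int
    samples: dict[str, list[float]] = field(default_factory=dict)


def summarize_trials(
    trial_metrics: list[TrialMetrics],
    subject_id: str,
    day: str,
    limb: str,
    group_label: str = "",
    min_footsteps: int = 10,
    min_steps_per_trial: int = 4,
) -> GaitSummary:
    """Pool one subject-day-limb's trials and average each index.

    Trials with fewer than ``min_steps_per_trial`` footsteps are dropped
    before pooling; the summary is flagged invalid when the pooled
    footstep count is below ``min_footsteps``.
    """
    kept = [tm for tm in trial_metrics if tm.limb == limb and tm.n_footsteps >= min_steps_per_trial]
    dropped = sum(1 for tm in trial_metrics if tm.limb == limb) - len(kept)
    if dropped:
        log.info("%s %s %s: dropped %d short trial(s)", subject_id, day, limb, dropped)
    if not kept:
        raise InsufficientDataError(f"no valid trials for {subject_id} {day} {limb}")
    pooled: dict[str, list[float]] = {}
    for tm in kept:
        for k, vals in tm.samples.items():
            pooled.setdefault(k, []).extend(v for v in vals if not math.isnan(v))
    means = {k: float(np.mean(v)) if v else float("nan") for k, v in pooled.items()}
    n_footsteps = sum(tm.n_footsteps for tm in kept)
    return GaitSummary(
        subject_id=subject_id,
        day=day,
        limb=limb,
        group_label=group_label,
        means=means,
        n_footsteps=n_footsteps,
        valid=n_footsteps >= min_footsteps,
    )
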