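"""Open-field locomotor summaries: distance, movement and immobile time.

A 10-minute free-exploration session in a square arena is reduced to the
three standard locomotor measures.  Immobility is speed below a
threshold sustained for a minimum bout duration (defaults 2 cm/s for
>= 1 s, both configurable — commercial trackers do not publish their
criterion); everything else is movement, so movement + immobile time
always equals the track duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError
from .simulate import OpenFieldTrack


@dataclass
class OpenFieldSummary:
    subject_id: str
    day: str
    total_distance_cm: float
    movement_time_s: float
    immobile_time_s: float


def _immobile_time(speed: np.ndarray, threshold: float, min_samples: int, dt: float) -> float:
    slow = speed < threshold
    padded = np.concatenate([[False], slow, [False]])
    rises = np.flatnonzero(~padded[:-1] & padded[1:])
    falls = np.flatnonzero(padded[:-1] & ~padded[1:])
    lengths = falls - rises
    return float(lengths[lengths >= min_samples].sum()) * dt


def summarize_track(
    track: OpenFieldTrack,
    speed_threshold_cm_s: float = 2.0,
    min_bout_s: float = 1.0,
    subject_id: str = "",
    day: str = "",
) -> OpenFieldSummary:
    """Total distance, movement time and immobile time of one session.

    Distance is the summed per-sample displacement magnitude.  Samples
    whose instantaneous speed (displacement x sample rate) stays below
    ``speed_threshold_cm_s`` for at least ``min_bout_s`` count as
    immobile; the remainder is movement time.
    """
    if speed_threshold_cm_s <= 0:
        raise InsufficientDataError("speed threshold must be positive")
    pos = np.asarray(track.positions, dtype=float)
    if len(pos) < 2:
        raise InsufficientDataError("a track needs at least two samples")
    dt = 1.0 / track.sample_rate
    disp = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    # per-sample speed; the first sample inherits the first interval's
    speed = np.concatenate([[disp[0] * track.sample_rate], disp * track.sample_rate])
    duration = len(pos) * dt
    min_samples = max(int(round(min_bout_s * track.sample_rate)), 1)
    immobile = _immobile_time(speed, speed_threshold_cm_s, min_samples, dt)
    return OpenFieldSummary(
        subject_id=subject_id,
        day=day,
        total_distance_cm=float(disp.sum()),
        movement_time_s=duration - immobile,
        immobile_time_s=immobile,
    )


def resample_uniform(t: np.ndarray, xy: np.ndarray, sample_rate: float) -> np.ndarray:
    """Linear resampling of an irregularly-timestamped track.

    Emits a warning; used by the track reader when timestamps deviate
    from a uniform grid.
    """
    warnings.warn("irregular timestamps: resampling track to a uniform grid", stacklevel=2)
    n = int(round((t[-1] - t[0]) * sample_rate)) + 1
    tu = t[0] + np.arange(n) / sample_rate
    return np.stack([np.interp(tu, t, xy[:, k]) for k in range(2)], axis=1)
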