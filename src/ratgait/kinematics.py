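"""Ankle joint angle from sagittal landmarks and its per-event ROM.

The ankle angle is the unsigned interior angle at the ankle (lateral
malleolus) between the vector to the proximal shank landmark (knee /
central shank — either defines the same shank direction) and the vector
to the fifth metatarsal head.  A larger angle is a more plantarflexed
foot, so foot drop shows up as an elevated angle in mid-swing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, InvalidParameterError
from .events import GaitEventSet
from .params import GAIT_EVENTS


def ankle_angle(shank_pt, ankle_pt, mt5_pt) -> float:
    """Interior ankle angle in degrees at the ``ankle_pt`` vertex.

    Invariant under rotation, translation and uniform scaling of the
    three points, and symmetric in the two distal arguments.
    """
    u = np.asarray(shank_pt, dtype=float) - np.asarray(ankle_pt, dtype=float)
    v = np.asarray(mt5_pt, dtype=float) - np.asarray(ankle_pt, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise InvalidParameterError("coincident landmarks: ankle angle undefined")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def ankle_angle_series(landmarks: dict[str, np.ndarray]) -> np.ndarray:
    """Per-frame ankle angle (degrees) from a limb's landmark arrays.

    ``landmarks`` maps ``knee``/``ankle``/``mt5`` to ``(n, 2)`` arrays.
    """
    u = landmarks["knee"] - landmarks["ankle"]
    v = landmarks["mt5"] - landmarks["ankle"]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    if np.any(nu == 0.0) or np.any(nv == 0.0):
        raise InvalidParameterError("coincident landmarks in series: angle undefined")
    cosang = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


@dataclass
class RomSummary:
    """Mean ankle angle at each gait event for one subject-day-limb."""

    subject_id: str
    day: str
    limb: str
    mean_angle_deg: dict[str, float] = field(default_factory=dict)
    n_cycles: dict[str, int] = field(default_factory=dict)
    valid: bool = False


def rom_at_events(
    angle_series: np.ndarray,
    event_sets: list[GaitEventSet],
    subject_id: str = "",
    day: str = "",
    limb: str = "",
    min_cycles: int = 10,
) -> RomSummary:
    """Average the ankle angle over cycles at each of the four events.

    Cycles whose mid-stance or mid-swing crossing is missing are excluded
    from that event's mean only.  The summary is valid when every event
    accumulates at least ``min_cycles`` angles.
    """
    if not event_sets:
        raise InsufficientDataError("no gait cycles to summarise")
    means: dict[str, float] = {}
    counts: dict[str, int] = {}
    for ev in GAIT_EVENTS:
        frames = [es.frame_of(ev) for es in event_sets if es.frame_of(ev) is not None]
        counts[ev] = len(frames)
        means[ev] = float(np.mean(angle_series[frames])) if frames else float("nan")
    valid = all(c >= min_cycles for c in counts.values())
    return RomSummary(subject_id, day, limb, means, counts, valid)
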