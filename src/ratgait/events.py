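"""Gait-cycle segmentation and gait-event localisation.

A gait cycle runs from one paw contact (rising edge of the contact
signal) to the next contact of the same paw; toe-off is the falling edge
in between.  Within each cycle four events are placed:

* **initial contact** — the cycle's first contact frame;
* **mid-stance** — the stance frame at which the contralateral swinging
  limb passes "opposite" the stance limb, operationalised as the
  contralateral ankle's x-position crossing the stance limb's ankle x;
* **pre-swing** — toe-off;
* **mid-swing** — the swing frame at which the swinging limb passes
  opposite the contralateral stance limb (own ankle x crossing the
  contralateral ankle x).

The crossings are found by the sign change of the ankle x-difference,
refined by linear interpolation and rounded to the nearest frame.  Gaits
without a crossing in the relevant phase (e.g. hopping, or a stationary
contralateral limb) yield a flagged-missing event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError


@dataclass(frozen=True)
class GaitCycle:
    """One stride: contact -> toe-off -> next contact (frame indices)."""

    limb: str
    initial_contact_frame: int
    toe_off_frame: int
    next_contact_frame: int

    def __post_init__(self) -> None:
        if not (
            self.initial_contact_frame < self.toe_off_frame < self.next_contact_frame
        ):
            raise InvalidParameterError(
                f"cycle frames must be ordered ic < to < nc, got "
                f"({self.initial_contact_frame}, {self.toe_off_frame}, "
                f"{self.next_contact_frame})"
            )

    @property
    def stance_frames(self) -> int:
        return self.toe_off_frame - self.initial_contact_frame

    @property
    def swing_frames(self) -> int:
        return self.next_contact_frame - self.toe_off_frame


@dataclass(frozen=True)
class GaitEventSet:
    """The four gait-event frames of one cycle.

    ``mid_stance_frame`` / ``mid_swing_frame`` are ``None`` when the
    defining contralateral crossing does not occur; such cycles are
    excluded from per-event averages downstream.
    """

    cycle: GaitCycle
    initial_contact_frame: int
    mid_stance_frame: int | None
    pre_swing_frame: int
    mid_swing_frame: int | None

    def __post_init__(self) -> None:
        ic, to, nc = (
            self.cycle.initial_contact_frame,
            self.cycle.toe_off_frame,
            self.cycle.next_contact_frame,
        )
        if self.initial_contact_frame != ic or self.pre_swing_frame != to:
            raise InvalidParameterError("event set inconsistent with its cycle")
        if self.mid_stance_frame is not None and not ic <= self.mid_stance_frame < to:
            raise InvalidParameterError("mid-stance frame outside stance phase")
        if self.mid_swing_frame is not None and not to <= self.mid_swing_frame < nc:
            raise InvalidParameterError("mid-swing frame outside swing phase")

    @property
    def complete(self) -> bool:
        return self.mid_stance_frame is not None and self.mid_swing_frame is not None

    def frame_of(self, event: str) -> int | None:
        return {
            "initial_contact": self.initial_contact_frame,
            "mid_stance": self.mid_stance_frame,
            "pre_swing": self.pre_swing_frame,
            "mid_swing": self.mid_swing_frame,
        }[event]


def _remove_short_bouts(signal: np.ndarray, min_frames: int) -> np.ndarray:
    """Drop contact bouts shorter than ``min_frames`` (sensor flicker)."""
    out = signal.copy()
    padded = np.concatenate([[False], out, [False]])
    rises = np.flatnonzero(~padded[:-1] & padded[1:])
    falls = np.flatnonzero(padded[:-1] & ~padded[1:])
    for r, f in zip(rises, falls):
        if f - r < min_frames:
            out[r:f] = False
    return out


def detect_cycles(
    contact_signal: np.ndarray,
    frame_rate: float,
    min_bout_frames: int = 3,
    limb: str = "",
) -> list[GaitCycle]:
    """Segment complete gait cycles from a boolean contact signal.

    One cycle per rising-edge-to-rising-edge span (a contact bout that
    begins at frame 0 counts as a cycle start); partial cycles at the
    recording edges are discarded.  Fewer than two bout starts yield an
    empty list.
    """
    sig = np.asarray(contact_signal)
    if sig.dtype != bool:
        raise InvalidParameterError("contact signal must be boolean")
    if frame_rate <= 0:
        raise InvalidParameterError("frame_rate must be positive")
    sig = _remove_short_bouts(sig, min_bout_frames)
    padded = np.concatenate([[False], sig, [False]])
    rises = np.flatnonzero(~padded[:-1] & padded[1:])
    falls = np.flatnonzero(padded[:-1] & ~padded[1:])
    cycles: list[GaitCycle] = []
    for i in range(len(rises) - 1):
        to = falls[np.searchsorted(falls, rises[i])]
        if to < rises[i + 1]:  # exactly one falling edge inside the span
            cycles.append(GaitCycle(limb, int(rises[i]), int(to), int(rises[i + 1])))
    return cycles


def _first_crossing(diff: np.ndarray, lo: int, hi: int) -> int | None:
    """Nearest frame of the first sign change of ``diff`` within [lo, hi)."""
    seg = diff[lo:hi]
    if len(seg) < 2:
        return None
    zero = np.flatnonzero(seg == 0.0)
    sign_change = np.flatnonzero(np.sign(seg[:-1]) * np.sign(seg[1:]) < 0)
    cand: list[float] = []
    if zero.size:
        cand.append(float(zero[0]))
    if sign_change.size:
        k = int(sign_change[0])
        cand.append(k + seg[k] / (seg[k] - seg[k + 1]))
    if not cand:
        return None
    return lo + int(round(min(cand)))


def locate_events(
    cycle: GaitCycle,
    own_ankle_x: np.ndarray,
    contra_ankle_x: np.ndarray,
) -> GaitEventSet:
    """Place the four gait events of ``cycle`` from the two ankle tracks."""
    n = min(len(own_ankle_x), len(contra_ankle_x))
    if cycle.next_contact_frame > n:
        raise InvalidParameterError("cycle extends beyond the landmark series")
    diff = np.asarray(contra_ankle_x[:n], dtype=float) - np.asarray(
        own_ankle_x[:n], dtype=float
    )
    ic, to, nc = cycle.initial_contact_frame, cycle.toe_off_frame, cycle.next_contact_frame
    ms = _first_crossing(diff, ic, to + 1)
    msw = _first_crossing(diff, to, nc)
    if ms is not None:
        ms = min(max(ms, ic), to - 1)
    if msw is not None:
        msw = min(max(msw, to), nc - 1)
    return GaitEventSet(
        cycle=cycle,
        initial_contact_frame=ic,
        mid_stance_frame=ms,
        pre_swing_frame=to,
        mid_swing_frame=msw,
    )


def locate_all_events(
    cycles: list[GaitCycle],
    own_ankle_x: np.ndarray,
    contra_ankle_x: np.ndarray,
) -> list[GaitEventSet]:
    return [locate_events(c, own_ankle_x, contra_ankle_x) for c in cycles]
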