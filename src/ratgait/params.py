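"""Gait model parameters and lesion presets.

The generative gait model is parameterised at two levels:

* **shared** (whole-body) quantities — cycle duration, stride length,
  left/right heel placement offset — that are necessarily common to both
  hindlimbs in steady straight-line gait (each limb advances exactly the
  body displacement per cycle, otherwise the footprint sequences of the
  two limbs drift apart);
* **limb-local** quantities — duty factor, footprint geometry (toe
  spread, intermediary toe spread, print length) and the ankle angle at
  the four gait events — which can differ between the lesioned (right)
  and intact (left) hindlimb.

A lumbar ventral-root avulsion produces foot drop: the ankle cannot
dorsiflex during swing, so the mid-swing (and pre-swing) ankle angle is
elevated, the toes do not spread on contact, stance is prolonged and the
animal slows down.  :class:`LesionPreset` encodes that deficit as day-1
deltas on the baseline parameters, attenuated over post-lesion days by an
exponential recovery toward a residual plateau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .errors import InvalidParameterError, UnknownPresetError

LIMBS = ("left", "right")

#: The four gait events at which the ankle angle is reported.
GAIT_EVENTS = ("initial_contact", "mid_stance", "pre_swing", "mid_swing")

#: Assessment-day labels in chronological order (pre-lesion baseline,
#: then post-lesion days 1, 5, 7, 14, 21).
DAYS = ("pre", "d1", "d5", "d7", "d14", "d21")

_DAY_NUMBER = {"pre": 0, "d1": 1, "d5": 5, "d7": 7, "d14": 14, "d21": 21}

GROUPS = ("sham", "L5", "L6", "L5L6")

#: Group sizes of the study cohort (25 animals).
DEFAULT_GROUP_SIZES = {"sham": 5, "L5": 5, "L6": 9, "L5L6": 6}


def canonical_day(day: str | int) -> str:
    """Normalise a day given as ``"pre"``, ``"d1"`` or the integer ``1``."""
    if isinstance(day, str):
        label = day if day.startswith(("p", "d")) else f"d{day}"
    else:
        label = f"d{int(day)}"
    if label not in _DAY_NUMBER:
        raise UnknownPresetError(f"unknown assessment day {day!r}; expected one of {DAYS}")
    return label


def day_number(day: str | int) -> int:
    """Days post lesion as an integer; the pre-lesion baseline is 0."""
    return _DAY_NUMBER[canonical_day(day)]


# Per-cycle / per-print measurement noise SDs used when a parameter is
# perturbed stochastically during trial synthesis.  Keys name the
# parameter they apply to; ``ankle_angle_deg`` covers all four events.
DEFAULT_NOISE_SD: dict[str, float] = {
    "stride_length": 4.0,       # mm, per cycle (body displacement jitter)
    "cycle_duration": 0.010,    # s, per cycle
    "duty_factor": 0.010,       # per cycle, per limb
    "step_offset": 2.0,         # mm, per cycle
    "toe_spread": 0.55,         # mm, per footprint
    "intermediary_toe_spread": 0.35,  # mm, per footprint
    "print_length": 0.8,        # mm, per footprint
    "ankle_angle_deg": 2.0,     # degrees, per cycle per event
}

# Between-animal SDs of the subject random intercepts used by the cohort
# simulator (consistent across days within an animal).
DEFAULT_SUBJECT_SD: dict[str, float] = {
    "stride_length": 4.0,
    "cycle_duration": 0.015,
    "duty_factor": 0.010,
    "toe_spread": 0.55,
    "intermediary_toe_spread": 0.30,
    "print_length": 1.0,
    "ankle_angle_deg": 1.5,
}


@dataclass(frozen=True)
class GaitModelParams:
    """Generative gait parameters for one hindlimb.

    Parameters
    ----------
    cycle_duration
        Full gait-cycle duration in seconds (shared across limbs).
    duty_factor
        Stance fraction of the cycle, in (0, 1).
    stride_length
        Consecutive ipsilateral heel-to-heel distance, mm (shared).
    step_offset
        Forward offset of the left heel strike relative to the preceding
        right heel strike, mm; ``stride_length / 2`` gives a symmetric
        gait with equal left and right step lengths.
    toe_spread, intermediary_toe_spread, print_length
        Footprint geometry, mm: first-to-fifth toe distance,
        second-to-fourth toe distance, and heel-to-third-toe distance.
    ankle_angle_by_event
        Ankle joint angle (degrees, interior angle at the lateral
        malleolus) at each of the four gait events.  A larger angle is a
        more plantarflexed (dropped) foot.
    noise_sd
        Per-cycle / per-print Gaussian SDs by parameter name; zero for a
        deterministic limb.
    limb_phase_lag
        Contralateral phase offset as a cycle fraction; 0.5 is strict
        alternation.
    walking_speed
        mm/s; derived as ``stride_length / cycle_duration`` and enforced
        at construction.
    """

    cycle_duration: float = 0.5
    duty_factor: float = 0.6
    stride_length: float = 140.0
    step_offset: float = 70.0
    toe_spread: float = 18.0
    intermediary_toe_spread: float = 9.0
    print_length: float = 30.0
    ankle_angle_by_event: dict[str, float] = field(
        default_factory=lambda: {
            "initial_contact": 90.0,
            "mid_stance": 80.0,
            "pre_swing": 110.0,
            "mid_swing": 95.0,
        }
    )
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    limb_phase_lag: float = 0.5
    walking_speed: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.duty_factor < 1.0:
            raise InvalidParameterError(f"duty_factor must be in (0, 1), got {self.duty_factor}")
        if not 0.0 < self.limb_phase_lag < 1.0:
            raise InvalidParameterError("limb_phase_lag must be in (0, 1)")
        for name in ("cycle_duration", "stride_length", "step_offset",
                     "toe_spread", "intermediary_toe_spread", "print_length"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive, got {getattr(self, name)}")
        if set(self.ankle_angle_by_event) != set(GAIT_EVENTS):
            raise InvalidParameterError(
                f"ankle_angle_by_event must define exactly the events {GAIT_EVENTS}"
            )
        for ev, ang in self.ankle_angle_by_event.items():
            if not 0.0 < ang < 180.0:
                raise InvalidParameterError(f"ankle angle at {ev} must be in (0, 180), got {ang}")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise InvalidParameterError("noise SDs must be non-negative")
        speed = self.stride_length / self.cycle_duration
        if self.walking_speed is not None and not math.isclose(
            self.walking_speed, speed, rel_tol=1e-9
        ):
            raise InvalidParameterError(
                f"walking_speed {self.walking_speed} inconsistent with "
                f"stride_length/cycle_duration = {speed}"
            )
        object.__setattr__(self, "walking_speed", speed)

    def noise_free(self) -> "GaitModelParams":
        """A copy with every noise SD set to zero."""
        return replace(self, noise_sd={k: 0.0 for k in self.noise_sd},
                       walking_speed=None)

    def with_deltas(self, deltas: dict[str, float], scale: float = 1.0) -> "GaitModelParams":
        """Apply additive deltas (optionally scaled) to named parameters.

        Ankle-angle deltas are keyed ``"ankle:<event>"``.
        """
        kwargs: dict = {}
        angles = dict(self.ankle_angle_by_event)
        for key, delta in deltas.items():
            if key.startswith("ankle:"):
                ev = key.split(":", 1)[1]
                angles[ev] = angles[ev] + scale * delta
            else:
                kwargs[key] = getattr(self, key) + scale * delta
        kwargs["ankle_angle_by_event"] = angles
        kwargs["walking_speed"] = None
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TrialParams:
    """Bilateral generative parameters for one walkway pass.

    ``left`` and ``right`` must agree on the shared whole-body
    quantities (cycle duration, stride length, step offset, phase lag);
    limb-local fields may differ, which is how a unilateral lesion is
    expressed.
    """

    left: GaitModelParams
    right: GaitModelParams

    def __post_init__(self) -> None:
        for name in ("cycle_duration", "stride_length", "step_offset", "limb_phase_lag"):
            lv, rv = getattr(self.left, name), getattr(self.right, name)
            if not math.isclose(lv, rv, rel_tol=1e-9):
                raise InvalidParameterError(
                    f"shared parameter {name} differs between limbs ({lv} vs {rv})"
                )

    @property
    def cycle_duration(self) -> float:
        return self.left.cycle_duration

    @property
    def stride_length(self) -> float:
        return self.left.stride_length

    @property
    def walking_speed(self) -> float:
        return self.left.walking_speed

    def limb(self, limb: str) -> GaitModelParams:
        if limb not in LIMBS:
            raise InvalidParameterError(f"limb must be one of {LIMBS}, got {limb!r}")
        return self.left if limb == "left" else self.right

    def noise_free(self) -> "TrialParams":
        return TrialParams(self.left.noise_free(), self.right.noise_free())


@dataclass(frozen=True)
class LesionPreset:
    """Day-1 lesion effect and its recovery time-course for one group.

    ``limb_deltas`` apply to the affected (right) hindlimb only;
    ``shared_deltas`` apply to the whole-body quantities of both limbs.
    All deltas are additive on the baseline parameter.  The deficit at
    ``day`` >= 1 post lesion is the day-1 delta scaled by

        plateau_fraction + (1 - plateau_fraction) * exp(-(day - 1) / tau)

    so day 1 carries the full deficit, recovery is monotone, and a
    residual ``plateau_fraction`` of the deficit persists at late days.
    The pre-lesion baseline carries no deficit at all.
    """

    group_label: str
    limb_deltas: dict[str, float]
    shared_deltas: dict[str, float]
    recovery_time_constant: float = 5.0  # days
    plateau_fraction: float = 0.3
    affected_side: str = "right"

    def __post_init__(self) -> None:
        if self.recovery_time_constant <= 0:
            raise InvalidParameterError("recovery_time_constant must be positive")
        if not 0.0 <= self.plateau_fraction <= 1.0:
            raise InvalidParameterError("plateau_fraction must be in [0, 1]")
        if self.affected_side != "right":
            raise InvalidParameterError("only right-side lesions are modelled")

    def recovery_scale(self, day: str | int) -> float:
        """Fraction of the day-1 deficit still present on ``day``."""
        d = day_number(day)
        if d == 0:
            return 0.0
        return self.plateau_fraction + (1.0 - self.plateau_fraction) * math.exp(
            -(d - 1) / self.recovery_time_constant
        )


# Day-1 deltas of the combined L5+L6 avulsion.  The two toe-spread deltas
# place the affected-side day-1 means at 11.61 mm and 6.88 mm; remaining
# deltas follow the observed deficit directions: slower, shorter-striding
# gait with prolonged stance, abbreviated swing, a longer print and an
# elevated (plantarflexed) ankle in pre- and mid-swing.
_L5L6_LIMB_DELTAS = {
    "duty_factor": 0.15,                  # stance 0.30 -> 0.42 s at day 1
    "toe_spread": -6.39,                  # 18.00 -> 11.61 mm
    "intermediary_toe_spread": -2.12,     # 9.00 -> 6.88 mm
    "print_length": 4.0,                  # mm (drag lengthens the print)
    "ankle:pre_swing": 12.0,              # degrees
    "ankle:mid_swing": 23.0,              # degrees
}
_L5L6_SHARED_DELTAS = {
    "stride_length": -35.0,               # mm
    "cycle_duration": 0.06,               # s
    "step_offset": -17.5,                 # keeps the gait symmetric
}

#: Single-root avulsions produce sub-threshold foot drop; their deltas
#: are a fixed 25% of the combined-lesion deltas per parameter.
SINGLE_ROOT_FRACTION = 0.25


def _scaled(deltas: dict[str, float], s: float) -> dict[str, float]:
    return {k: v * s for k, v in deltas.items()}


LESION_PRESETS: dict[str, LesionPreset] = {
    "sham": LesionPreset("sham", {}, {}),
    "L5": LesionPreset(
        "L5",
        _scaled(_L5L6_LIMB_DELTAS, SINGLE_ROOT_FRACTION),
        _scaled(_L5L6_SHARED_DELTAS, SINGLE_ROOT_FRACTION),
    ),
    "L6": LesionPreset(
        "L6",
        _scaled(_L5L6_LIMB_DELTAS, SINGLE_ROOT_FRACTION),
        _scaled(_L5L6_SHARED_DELTAS, SINGLE_ROOT_FRACTION),
    ),
    "L5L6": LesionPreset("L5L6", dict(_L5L6_LIMB_DELTAS), dict(_L5L6_SHARED_DELTAS)),
}


def make_preset(
    group_label: str,
    day: str | int,
    baseline: GaitModelParams | None = None,
) -> TrialParams:
    """Bilateral gait parameters for a group at an assessment day.

    The sham preset (all deltas zero) and the pre-lesion day return the
    baseline exactly; lesion groups return the baseline modified by the
    preset's day-1 deltas attenuated by the recovery curve.  Limb-local
    deltas touch the right limb only.
    """
    if group_label not in LESION_PRESETS:
        raise UnknownPresetError(
            f"unknown group {group_label!r}; expected one of {tuple(LESION_PRESETS)}"
        )
    base = baseline if baseline is not None else GaitModelParams()
    preset = LESION_PRESETS[group_label]
    scale = preset.recovery_scale(day)
    if scale == 0.0 or (not preset.limb_deltas and not preset.shared_deltas):
        return TrialParams(base, base)
    left = base.with_deltas(preset.shared_deltas, scale)
    right = base.with_deltas({**preset.shared_deltas, **preset.limb_deltas}, scale)
    return TrialParams(left, right)
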