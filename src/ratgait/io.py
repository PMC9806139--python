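"""On-disk formats and pipeline configuration.

A walkway trial is a directory of four files:

``landmarks.csv``
    ``frame, limb, landmark, x_mm, z_mm`` — per-frame lateral-view
    positions of knee, ankle and mt5 for both limbs.
``contacts.csv``
    ``frame, limb, in_contact`` — boolean paw-contact signal.
``footprints.csv``
    ``limb, start_frame, end_frame, heel_x_mm, heel_y_mm,
    toe1_x_mm .. toe5_y_mm`` — bottom-view prints with half-open
    contact frame intervals ``[start, end)``.
``meta.json``
    subject, group, day, frame rate and spatial calibration.

A ``truth.json`` with the generator's ground truth accompanies
simulated trials.  Open-field sessions are a ``track.csv``
(``t_s, x_cm, y_cm``) plus ``truth.json``.  Frame indices are 0-based
throughout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidParameterError, TrialFormatError
from .params import DAYS, DEFAULT_GROUP_SIZES, LIMBS
from .simulate import Footprint, OpenFieldTrack, TrialRecording

_LANDMARKS = ("knee", "ankle", "mt5")
_FOOTPRINT_COLS = ["limb", "start_frame", "end_frame", "heel_x_mm", "heel_y_mm"] + [
    f"toe{i}_{ax}_mm" for i in range(1, 6) for ax in ("x", "y")
]


def temporal_resolution(frame_rate: float) -> float:
    """Frame period in milliseconds, rounded to 2 decimals (60 fps -> 16.67)."""
    if frame_rate <= 0:
        raise InvalidParameterError("frame_rate must be positive")
    return round(1000.0 / frame_rate, 2)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_trial(rec: TrialRecording, directory: str | Path) -> Path:
    """Serialise a trial to its four-file directory format."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for limb in LIMBS:
        for lm in _LANDMARKS:
            arr = rec.landmarks[limb][lm]
            for f in range(len(arr)):
                rows.append((f, limb, lm, arr[f, 0], arr[f, 1]))
    pd.DataFrame(rows, columns=["frame", "limb", "landmark", "x_mm", "z_mm"]).to_csv(
        d / "landmarks.csv", index=False
    )
    rows = []
    for limb in LIMBS:
        sig = rec.contact[limb]
        rows += [(f, limb, bool(sig[f])) for f in range(len(sig))]
    pd.DataFrame(rows, columns=["frame", "limb", "in_contact"]).to_csv(
        d / "contacts.csv", index=False
    )
    fp_rows = []
    for fp in rec.footprints:
        fp_rows.append(
            [fp.limb, fp.contact_start_frame, fp.contact_end_frame,
             fp.heel_xy[0], fp.heel_xy[1]]
            + list(np.asarray(fp.toe_xy).ravel())
        )
    pd.DataFrame(fp_rows, columns=_FOOTPRINT_COLS).to_csv(d / "footprints.csv", index=False)
    meta = {
        "subject_id": rec.subject_id,
        "group_label": rec.group_label,
        "day": rec.day,
        "frame_rate_hz": rec.frame_rate,
        "mm_per_px": rec.mm_per_px,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1))
    if rec.truth:
        (d / "truth.json").write_text(json.dumps(rec.truth, default=_json_default))
    return d


def read_trial(directory: str | Path) -> TrialRecording:
    """Load and validate a trial directory; errors name the offending file."""
    d = Path(directory)
    for fname in ("landmarks.csv", "contacts.csv", "footprints.csv", "meta.json"):
        if not (d / fname).exists():
            raise TrialFormatError(f"{d}: missing required file {fname!r}")
    meta = json.loads((d / "meta.json").read_text())
    for key in ("subject_id", "group_label", "day", "frame_rate_hz", "mm_per_px"):
        if key not in meta:
            raise TrialFormatError(f"{d / 'meta.json'}: missing key {key!r}")

    lm = pd.read_csv(d / "landmarks.csv")
    _require_columns(lm, ["frame", "limb", "landmark", "x_mm", "z_mm"], d / "landmarks.csv")
    _reject_nan(lm, d / "landmarks.csv")
    n_frames = int(lm["frame"].max()) + 1
    landmarks: dict[str, dict[str, np.ndarray]] = {}
    for limb in LIMBS:
        landmarks[limb] = {}
        for name in _LANDMARKS:
            sub = lm[(lm["limb"] == limb) & (lm["landmark"] == name)].sort_values("frame")
            if len(sub) != n_frames or not np.array_equal(
                sub["frame"].to_numpy(), np.arange(n_frames)
            ):
                raise TrialFormatError(
                    f"{d / 'landmarks.csv'}: incomplete frame series for {limb}/{name}"
                )
            landmarks[limb][name] = sub[["x_mm", "z_mm"]].to_numpy(dtype=float)

    ct = pd.read_csv(d / "contacts.csv")
    _require_columns(ct, ["frame", "limb", "in_contact"], d / "contacts.csv")
    _reject_nan(ct, d / "contacts.csv")
    contact: dict[str, np.ndarray] = {}
    for limb in LIMBS:
        sub = ct[ct["limb"] == limb].sort_values("frame")
        if len(sub) != n_frames:
            raise TrialFormatError(
                f"{d / 'contacts.csv'}: {limb} signal has {len(sub)} rows, expected {n_frames}"
            )
        contact[limb] = sub["in_contact"].to_numpy(dtype=bool)

    fp = pd.read_csv(d / "footprints.csv")
    _require_columns(fp, _FOOTPRINT_COLS, d / "footprints.csv")
    _reject_nan(fp, d / "footprints.csv")
    footprints = []
    for _, row in fp.iterrows():
        toes = np.array(
            [[row[f"toe{i}_x_mm"], row[f"toe{i}_y_mm"]] for i in range(1, 6)], dtype=float
        )
        footprints.append(
            Footprint(
                limb=str(row["limb"]),
                contact_start_frame=int(row["start_frame"]),
                contact_end_frame=int(row["end_frame"]),
                heel_xy=np.array([row["heel_x_mm"], row["heel_y_mm"]], dtype=float),
                toe_xy=toes,
            )
        )
    truth = {}
    if (d / "truth.json").exists():
        truth = json.loads((d / "truth.json").read_text())
    rec = TrialRecording(
        subject_id=str(meta["subject_id"]),
        group_label=str(meta["group_label"]),
        day=str(meta["day"]),
        frame_rate=float(meta["frame_rate_hz"]),
        mm_per_px=float(meta["mm_per_px"]),
        landmarks=landmarks,
        contact=contact,
        footprints=footprints,
        truth=truth,
    )
    rec.validate()
    return rec


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TrialFormatError(f"{path}: missing columns {missing}")


def _reject_nan(df: pd.DataFrame, path: Path) -> None:
    bad = df.isna().any(axis=1)
    if bad.any():
        raise TrialFormatError(f"{path}: malformed/truncated row {int(bad.idxmax()) + 2}")


def write_track(
    track: OpenFieldTrack, directory: str | Path, subject_id: str = "", day: str = ""
) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    n = len(track.positions)
    t = np.arange(n) / track.sample_rate
    pd.DataFrame(
        {"t_s": t, "x_cm": track.positions[:, 0], "y_cm": track.positions[:, 1]}
    ).to_csv(d / "track.csv", index=False)
    info = {
        "subject_id": subject_id,
        "day": day,
        "sample_rate_hz": track.sample_rate,
        "arena_side_cm": track.arena_side,
        **track.truth,
    }
    (d / "truth.json").write_text(json.dumps(info, default=_json_default))
    return d


def read_track(directory: str | Path) -> tuple[OpenFieldTrack, dict]:
    """Load a track; irregular timestamps are resampled with a warning."""
    from .openfield import resample_uniform

    d = Path(directory)
    if not (d / "track.csv").exists():
        raise TrialFormatError(f"{d}: missing required file 'track.csv'")
    df = pd.read_csv(d / "track.csv")
    _require_columns(df, ["t_s", "x_cm", "y_cm"], d / "track.csv")
    _reject_nan(df, d / "track.csv")
    if len(df) < 2:
        raise TrialFormatError(f"{d / 'track.csv'}: a track needs at least two samples")
    t = df["t_s"].to_numpy(dtype=float)
    xy = df[["x_cm", "y_cm"]].to_numpy(dtype=float)
    dts = np.diff(t)
    rate = 1.0 / np.median(dts)
    if np.max(np.abs(dts - np.median(dts))) > 0.25 * np.median(dts):
        xy = resample_uniform(t, xy, rate)
    meta = {}
    if (d / "truth.json").exists():
        meta = json.loads((d / "truth.json").read_text())
    arena = float(meta.get("arena_side_cm", max(60.0, float(np.max(xy)))))
    track = OpenFieldTrack(
        sample_rate=float(meta.get("sample_rate_hz", rate)),
        duration=len(xy) / float(meta.get("sample_rate_hz", rate)),
        positions=xy,
        arena_side=arena,
        truth=meta,
    )
    return track, meta


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; defaults reproduce the acquisition
    protocol (60 fps, 0.24 mm calibration, >= 10 footsteps per mean)."""

    frame_rate: float = 60.0
    mm_per_px: float = 0.24
    min_contact_bout: int = 3
    speed_threshold_cm_s: float = 2.0
    min_bout_s: float = 1.0
    min_footsteps: int = 10
    min_steps_per_trial: int = 4
    min_cycles_rom: int = 10
    alpha: float = 0.05
    seed: int = 0
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    days: tuple[str, ...] = DAYS
    trials_per_session: int = 3
    cycles_per_trial: int = 4
    include_openfield: bool = True

    def __post_init__(self) -> None:
        for name in ("frame_rate", "mm_per_px", "speed_threshold_cm_s", "min_bout_s"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.min_footsteps < 1 or self.min_contact_bout < 1:
            raise InvalidParameterError("thresholds must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        if "days" in raw:
            raw["days"] = tuple(raw["days"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["days"] = list(d["days"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
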