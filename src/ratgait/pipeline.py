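"""End-to-end driver: cycles -> indices -> kinematics -> open field -> stats.

``run_pipeline`` is a pure function of (inputs, config, seed): given a
set of trial recordings (loaded from disk or freshly simulated) it
segments gait cycles, computes the nine spatiotemporal indices and the
four-event ankle ROM per subject-day-limb, summarises open-field tracks,
and runs the repeated-measures statistics layer on every measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import events as ev
from . import kinematics as kin
from . import openfield as of
from . import spatial as sp
from . import stats as st
from .errors import InsufficientDataError, RatGaitError
from .io import PipelineConfig, write_trial
from .params import GAIT_EVENTS, LIMBS
from .simulate import (
    CohortDesign,
    OpenFieldTrack,
    TrialRecording,
    simulate_cohort,
    simulate_openfield_cohort,
)

log = logging.getLogger(__name__)


@dataclass
class TrialAnalysis:
    """Per-trial analysis products for one recording."""

    metrics: dict[str, sp.TrialMetrics]
    event_angles: dict[str, dict[str, list[float]]]  # limb -> event -> angles
    n_cycles: dict[str, int]


def analyze_trial(rec: TrialRecording, config: PipelineConfig | None = None) -> TrialAnalysis:
    """Segment one walkway pass and compute every per-cycle/per-print sample."""
    cfg = config if config is not None else PipelineConfig()
    steps = sp.step_lengths(rec.footprints)
    try:
        speed = sp.walking_speed(rec)
    except RatGaitError:
        speed = float("nan")
    metrics: dict[str, sp.TrialMetrics] = {}
    event_angles: dict[str, dict[str, list[float]]] = {}
    n_cycles: dict[str, int] = {}
    for limb in LIMBS:
        contra = "left" if limb == "right" else "right"
        cycles = ev.detect_cycles(
            rec.contact[limb], rec.frame_rate, cfg.min_contact_bout, limb
        )
        esets = ev.locate_all_events(
            cycles,
            rec.landmarks[limb]["ankle"][:, 0],
            rec.landmarks[contra]["ankle"][:, 0],
        )
        angles = kin.ankle_angle_series(rec.landmarks[limb])
        temporal = sp.temporal_metrics(
            cycles, rec.contact[limb], rec.contact[contra], rec.frame_rate
        )
        prints = rec.limb_footprints(limb)
        geoms = [sp.print_geometry(fp) for fp in prints]
        samples: dict[str, list[float]] = {
            "stride_length_mm": list(sp.stride_lengths(prints)),
            "step_length_mm": list(steps[limb]),
            "walking_speed_mm_s": [speed],
        }
        for key in ("toe_spread_mm", "intermediary_toe_spread_mm", "print_length_mm"):
            samples[key] = [g[key] for g in geoms]
        for key in ("stance_time_s", "swing_time_s", "double_support_time_s"):
            samples[key] = [tm[key] for tm in temporal]
        metrics[limb] = sp.TrialMetrics(limb=limb, n_footsteps=len(prints), samples=samples)
        event_angles[limb] = {
            e: [
                float(angles[es.frame_of(e)])
                for es in esets
                if es.frame_of(e) is not None
            ]
            for e in GAIT_EVENTS
        }
        n_cycles[limb] = len(cycles)
    return TrialAnalysis(metrics=metrics, event_angles=event_angles, n_cycles=n_cycles)


@dataclass
class PipelineResult:
    """Tidy output tables of one pipeline run."""

    gait_summary: pd.DataFrame
    rom_summary: pd.DataFrame
    openfield_summary: pd.DataFrame
    anova: pd.DataFrame
    lsd: pd.DataFrame
    bonferroni: pd.DataFrame
    config: PipelineConfig = field(default_factory=PipelineConfig)

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.gait_summary.to_csv(out / "gait_summary.csv", index=False)
        self.rom_summary.to_csv(out / "rom_summary.csv", index=False)
        self.openfield_summary.to_csv(out / "openfield_summary.csv", index=False)
        self.anova.to_csv(out / "anova.csv", index=False)
        self.lsd.to_csv(out / "posthoc_lsd.csv", index=False)
        self.bonferroni.to_csv(out / "posthoc_bonferroni.csv", index=False)
        return out


def summarize_recordings(
    recordings: list[TrialRecording], config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject-day gait and ROM summary tables from raw recordings."""
    cfg = config if config is not None else PipelineConfig()
    by_session: dict[tuple[str, str, str], list[TrialAnalysis]] = {}
    for rec in recordings:
        key = (rec.subject_id, rec.group_label, rec.day)
        by_session.setdefault(key, []).append(analyze_trial(rec, cfg))

    gait_rows, rom_rows = [], []
    for (subject, group, day), analyses in by_session.items():
        for limb in LIMBS:
            try:
                summary = sp.summarize_trials(
                    [a.metrics[limb] for a in analyses],
                    subject,
                    day,
                    limb,
                    group,
                    cfg.min_footsteps,
                    cfg.min_steps_per_trial,
                )
            except InsufficientDataError:
                log.warning("no valid trials for %s %s %s", subject, day, limb)
                continue
            for metric in sp.GAIT_METRICS:
                gait_rows.append(
                    {
                        "subject": subject,
                        "group": group,
                        "day": day,
                        "limb": limb,
                        "metric": metric,
                        "value": summary.means.get(metric, float("nan")),
                        "n_footsteps": summary.n_footsteps,
                        "valid": summary.valid,
                    }
                )
            pooled = {
                e: [a for an in analyses for a in an.event_angles[limb][e]]
                for e in GAIT_EVENTS
            }
            for e in GAIT_EVENTS:
                vals = pooled[e]
                rom_rows.append(
                    {
                        "subject": subject,
                        "group": group,
                        "day": day,
                        "limb": limb,
                        "event": e,
                        "mean_deg": float(np.mean(vals)) if vals else float("nan"),
                        "n_cycles": len(vals),
                        "valid": len(vals) >= cfg.min_cycles_rom,
                    }
                )
    return pd.DataFrame(gait_rows), pd.DataFrame(rom_rows)


def summarize_tracks(
    tracks: list[tuple[str, str, str, OpenFieldTrack]],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    cfg = config if config is not None else PipelineConfig()
    rows = []
    for subject, group, day, track in tracks:
        s = of.summarize_track(
            track, cfg.speed_threshold_cm_s, cfg.min_bout_s, subject, day
        )
        rows.append(
            {
                "subject": subject,
                "group": group,
                "day": day,
                "total_distance_cm": s.total_distance_cm,
                "movement_time_s": s.movement_time_s,
                "immobile_time_s": s.immobile_time_s,
            }
        )
    return pd.DataFrame(rows)


def _stats_layer(
    gait: pd.DataFrame,
    rom: pd.DataFrame,
    openf: pd.DataFrame,
    cfg: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Mixed ANOVA + post-hoc tables over every measure in the summaries."""
    long_frames = []
    if len(gait):
        g = gait[gait["valid"]].copy()
        g["measure"] = g["limb"] + ":" + g["metric"]
        long_frames.append(g[["subject", "group", "day", "measure", "value"]])
    if len(rom):
        r = rom[rom["valid"]].copy()
        r["measure"] = r["limb"] + ":rom_" + r["event"] + "_deg"
        r = r.rename(columns={"mean_deg": "value"})
        long_frames.append(r[["subject", "group", "day", "measure", "value"]])
    if len(openf):
        o = openf.melt(
            id_vars=["subject", "group", "day"],
            value_vars=["total_distance_cm", "movement_time_s", "immobile_time_s"],
            var_name="measure",
            value_name="value",
        )
        o["measure"] = "openfield:" + o["measure"]
        long_frames.append(o)
    if not long_frames:
        log.warning("stats stage: nothing to test")
        empty = pd.DataFrame()
        return empty, empty, empty

    data = pd.concat(long_frames, ignore_index=True)
    anova_rows, lsd_frames, bonf_frames = [], [], []
    for measure, sub in data.groupby("measure"):
        if sub["day"].nunique() < 2 or sub["group"].nunique() < 2:
            log.warning("stats stage: %s lacks a full design, skipped", measure)
            continue
        try:
            table = st.mixed_anova(sub, dv="value", within="day", between="group")
        except RatGaitError as exc:
            log.warning("stats stage: %s skipped (%s)", measure, exc)
            continue
        for term in table.terms.values():
            anova_rows.append(
                {
                    "measure": measure,
                    "source": term.source,
                    "SS": term.ss,
                    "df_num": term.df_num,
                    "df_den": term.df_den,
                    "MS": term.ms,
                    "F": term.f,
                    "p": term.p,
                }
            )
        group_sig = table.terms["group"].p < cfg.alpha or table.terms["time:group"].p < cfg.alpha
        for day, at_day in sub.groupby("day"):
            if at_day["group"].nunique() < 2:
                continue
            lsd = st.lsd_posthoc(
                at_day,
                dv="value",
                between="group",
                alpha=cfg.alpha,
                require_significant_omnibus=not group_sig,
            )
            lsd.insert(0, "day", day)
            lsd.insert(0, "measure", measure)
            lsd_frames.append(lsd)
        for group, in_group in sub.groupby("group"):
            if in_group["day"].nunique() < 2:
                continue
            bonf = st.oneway_bonferroni(in_group, dv="value", within="day", alpha=cfg.alpha)
            bonf.insert(0, "group", group)
            bonf.insert(0, "measure", measure)
            bonf_frames.append(bonf)
    anova = pd.DataFrame(anova_rows)
    lsd = pd.concat(lsd_frames, ignore_index=True) if lsd_frames else pd.DataFrame()
    bonf = pd.concat(bonf_frames, ignore_index=True) if bonf_frames else pd.DataFrame()
    return anova, lsd, bonf


def run_pipeline(
    config: PipelineConfig | None = None,
    recordings: list[TrialRecording] | None = None,
    tracks: list[tuple[str, str, str, OpenFieldTrack]] | None = None,
) -> PipelineResult:
    """Execute the full analysis; simulate the cohort when no input given.

    Deterministic for fixed (inputs, config, seed).
    """
    cfg = config if config is not None else PipelineConfig()
    design = CohortDesign(
        group_sizes=dict(cfg.group_sizes),
        days=tuple(cfg.days),
        trials_per_session=cfg.trials_per_session,
        cycles_per_trial=cfg.cycles_per_trial,
    )
    if recordings is None:
        log.info("simulating cohort (seed=%d)", cfg.seed)
        recordings = simulate_cohort(design, seed=cfg.seed)
    if tracks is None and cfg.include_openfield:
        tracks = simulate_openfield_cohort(design, seed=cfg.seed)
    log.info("analyzing %d recordings", len(recordings))
    gait, rom = summarize_recordings(recordings, cfg)
    openf = summarize_tracks(tracks, cfg) if tracks else pd.DataFrame()
    anova, lsd, bonf = _stats_layer(gait, rom, openf, cfg)
    return PipelineResult(
        gait_summary=gait,
        rom_summary=rom,
        openfield_summary=openf,
        anova=anova,
        lsd=lsd,
        bonferroni=bonf,
        config=cfg,
    )


def write_cohort(
    recordings: list[TrialRecording],
    tracks: list[tuple[str, str, str, OpenFieldTrack]] | None,
    out_dir: str | Path,
) -> Path:
    """Write a simulated cohort as trial directories (plus track dirs)."""
    from .io import write_track

    out = Path(out_dir)
    counters: dict[tuple[str, str], int] = {}
    for rec in recordings:
        key = (rec.subject_id, rec.day)
        counters[key] = counters.get(key, 0) + 1
        write_trial(rec, out / "trials" / f"{rec.subject_id}_{rec.day}_t{counters[key]}")
    for subject, _group, day, track in tracks or []:
        write_track(track, out / "openfield" / f"{subject}_{day}", subject, day)
    return out


def read_cohort(
    in_dir: str | Path,
) -> tuple[list[TrialRecording], list[tuple[str, str, str, OpenFieldTrack]]]:
    """Load every trial and track directory written by :func:`write_cohort`."""
    from .io import read_track, read_trial

    root = Path(in_dir)
    recordings = [
        read_trial(p) for p in sorted((root / "trials").iterdir()) if p.is_dir()
    ] if (root / "trials").exists() else []
    tracks = []
    if (root / "openfield").exists():
        for p in sorted((root / "openfield").iterdir()):
            if p.is_dir():
                track, meta = read_track(p)
                subject = str(meta.get("subject_id", p.name))
                day = str(meta.get("day", ""))
                group = subject.split("-")[0]
                tracks.append((subject, group, day, track))
    return recordings, tracks
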