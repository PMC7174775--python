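"""End-to-end study orchestration: cohort -> per-participant tables -> report.

For each participant the stages run in acquisition-chain order: channel
repair, band-pass, notch, envelope extraction, onset segmentation,
normalization over the complete dataset, heatmap construction, spatial and
dimensionality metrics, and offline classification.  Per-participant failures
are collected into the report without aborting the cohort.  The whole study
is deterministic given the configuration and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, HDEMGError
from .grid import ElectrodeGrid
from .heatmap import (
    Heatmap,
    average_heatmap,
    build_repetition_heatmap,
    compute_cog,
    max_activation,
)
from .metrics import (
    SimilarityMatrix,
    activation_summary,
    average_similarity,
    gesture_similarity,
    pca_dimensionality,
    repeatability,
)
from .myocontrol import accuracy_vs_gesture_count, features_from_segments
from .preprocess import (
    EnvelopeSet,
    bandpass,
    detect_onsets,
    envelope,
    normalization_factors,
    notch,
    repair_channels,
)
from .session import GESTURES, ContractionProtocol, RecordingSession
from .synth import (
    DMD_PROFILE,
    HEALTHY_PROFILE,
    CohortProfile,
    NoiseModel,
    ParticipantData,
    make_cohort,
)

logger = logging.getLogger("hdemg")


@dataclass
class StudyConfig:
    """All knobs of the study analysis, with the standard values as defaults."""

    n_healthy: int = 8
    n_dmd: int = 3
    seed: int = 0
    fs: float = 2048.0
    n_repetitions: int = 10
    contraction_s: float = 3.0
    rest_s: float = 3.0
    bandpass_low: float = 20.0
    bandpass_high: float = 450.0
    bandpass_order: int = 4
    notch_hz: float = 50.0
    notch_q: float = 50.0
    envelope_lp: float = 2.0
    envelope_order: int = 3
    onset_k: float = 10.0
    steady_s: float = 1.0
    mov_avg_window_s: float = 1.0
    cog_threshold: float = 0.8
    ve_threshold: float = 0.9
    cv_splits: int = 3
    train_fraction: float = 0.7
    window_s: float = 0.2
    step_s: float = 0.1
    faulty_channels: str | list[int] = "auto"
    gestures: tuple[str, ...] = GESTURES
    baseline_sd: float = 2.0
    powerline_amplitude: float = 1.0

    def __post_init__(self):
        checks = [
            (0 < self.cog_threshold <= 1, "cog_threshold must be in (0, 1]"),
            (0 < self.ve_threshold < 1, "ve_threshold must be in (0, 1)"),
            (self.onset_k > 0, "onset_k must be > 0"),
            (0 < self.train_fraction < 1, "train_fraction must be in (0, 1)"),
            (self.cv_splits >= 1, "cv_splits must be >= 1"),
            (self.n_healthy >= 0 and self.n_dmd >= 0, "cohort sizes must be >= 0"),
            (0 < self.bandpass_low < self.bandpass_high < self.fs / 2,
             "band-pass cutoffs must satisfy 0 < low < high < fs/2"),
            (0 < self.steady_s <= self.contraction_s, "steady_s must be in (0, contraction_s]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "gestures" in raw:
            raw["gestures"] = tuple(raw["gestures"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def protocol(self) -> ContractionProtocol:
        return ContractionProtocol(
            n_repetitions=self.n_repetitions,
            contraction_s=self.contraction_s,
            rest_s=self.rest_s,
            fs=self.fs,
        )

    def noise(self) -> NoiseModel:
        return NoiseModel(
            carrier_band=(self.bandpass_low, self.bandpass_high),
            baseline_sd=self.baseline_sd,
            powerline_amplitude=self.powerline_amplitude,
        )


@dataclass
class GestureDataset:
    """Segmented, per-repetition products of one participant's gesture."""

    gesture_label: str
    steady_segments: list[np.ndarray]  # band-passed raw signal slices
    norm_maps: list[Heatmap]
    abs_maps: list[Heatmap]
    onsets_s: list[float]


@dataclass
class ParticipantResult:
    """All analysis products of one participant."""

    participant_id: str
    group: str
    grid: ElectrodeGrid
    datasets: dict[str, GestureDataset]
    repeatability_long: pd.DataFrame
    gesture_similarity: SimilarityMatrix
    cog_table: pd.DataFrame
    activation_table: pd.DataFrame
    dimensionality: "object"
    accuracy_table: pd.DataFrame
    repaired_channels: dict[str, list[int]]


def _preprocess_session(
    session: RecordingSession, config: StudyConfig
) -> tuple[np.ndarray, EnvelopeSet, list[int]]:
    """Repair -> band-pass -> notch -> envelope for one session."""
    from .grid import grid_from_anthropometrics

    grid = grid_from_anthropometrics(
        session.anthropometrics.forearm_length_cm,
        session.anthropometrics.circumference_cm,
        session.anthropometrics.handedness,
    )
    repaired, faulty = repair_channels(session.signals, grid, config.faulty_channels)
    filtered = bandpass(
        repaired, session.fs, config.bandpass_low, config.bandpass_high, config.bandpass_order
    )
    filtered = notch(filtered, session.fs, config.notch_hz, config.notch_q)
    env = envelope(filtered, session.fs, config.envelope_lp, config.envelope_order)
    return filtered, env, faulty


def process_participant(pdata: ParticipantData, config: StudyConfig) -> ParticipantResult:
    """Run the complete per-participant analysis chain."""
    grid = pdata.grid
    filtered: dict[str, np.ndarray] = {}
    envelopes: dict[str, EnvelopeSet] = {}
    repaired: dict[str, list[int]] = {}

    all_sessions = dict(pdata.sessions)
    all_sessions["mvc"] = pdata.mvc_session
    for label, session in all_sessions.items():
        filt, env, faulty = _preprocess_session(session, config)
        filtered[label] = filt
        envelopes[label] = env
        repaired[label] = faulty
        logger.info("%s/%s: repaired channels %s", pdata.participant_id, label, faulty)

    factors = normalization_factors(envelopes.values(), config.mov_avg_window_s)

    datasets: dict[str, GestureDataset] = {}
    rep_rows, act_rows, cog_rows = [], [], []
    avg_maps: list[Heatmap] = []
    all_norm_maps: list[Heatmap] = []
    for gesture in config.gestures:
        session = pdata.sessions[gesture]
        env = envelopes[gesture]
        seg = detect_onsets(env, session.protocol, k=config.onset_k, steady_s=config.steady_s)
        norm_maps, abs_maps, segments = [], [], []
        for rep, window in enumerate(seg.steady_windows):
            nm, am = build_repetition_heatmap(env, window, factors, grid, gesture, rep)
            norm_maps.append(nm)
            abs_maps.append(am)
            segments.append(filtered[gesture][:, window[0] : window[1]])
            mn, ma = max_activation(nm, am)
            act_rows.append(
                {
                    "participant": pdata.participant_id,
                    "group": pdata.group,
                    "gesture": gesture,
                    "repetition": rep,
                    "max_normalized": mn,
                    "max_absolute": ma,
                }
            )
        datasets[gesture] = GestureDataset(
            gesture, segments, norm_maps, abs_maps, seg.onset_times(env.fs).tolist()
        )
        all_norm_maps.extend(norm_maps)

        sim = repeatability(norm_maps)
        iu = np.triu_indices(len(norm_maps), k=1)
        for i, j, r2 in zip(*iu, sim.values[iu]):
            rep_rows.append(
                {
                    "participant": pdata.participant_id,
                    "group": pdata.group,
                    "gesture": gesture,
                    "rep_i": int(i),
                    "rep_j": int(j),
                    "r2": float(r2),
                }
            )

        avg = average_heatmap(norm_maps)
        avg_maps.append(avg)
        cog = compute_cog(avg, grid, pdata.anthropometrics, config.cog_threshold)
        cog_rows.append(
            {
                "participant": pdata.participant_id,
                "group": pdata.group,
                "gesture": gesture,
                "cog_row": cog.grid_coords[0],
                "cog_col": cog.grid_coords[1],
                "cog_x_pct": cog.cog_x_pct,
                "cog_y_pct": cog.cog_y_pct,
                "n_cells": cog.n_cells_included,
            }
        )

    gsim = gesture_similarity(avg_maps)
    dim = pca_dimensionality(all_norm_maps, config.ve_threshold)

    features_by_gesture = {
        g: features_from_segments(
            datasets[g].steady_segments, config.fs, config.window_s, config.step_s
        )
        for g in config.gestures
    }
    acc = accuracy_vs_gesture_count(
        features_by_gesture,
        list(config.gestures),
        seed=config.seed,
        n_splits=config.cv_splits,
        train_fraction=config.train_fraction,
    )
    acc.insert(0, "participant", pdata.participant_id)
    acc.insert(1, "group", pdata.group)

    return ParticipantResult(
        participant_id=pdata.participant_id,
        group=pdata.group,
        grid=grid,
        datasets=datasets,
        repeatability_long=pd.DataFrame(rep_rows),
        gesture_similarity=gsim,
        cog_table=pd.DataFrame(cog_rows),
        activation_table=pd.DataFrame(act_rows),
        dimensionality=dim,
        accuracy_table=acc,
        repaired_channels=repaired,
    )


@dataclass
class StudyReport:
    """Aggregated study products; every group statistic is recomputable from
    the per-participant long tables it aggregates."""

    repeatability: pd.DataFrame
    cog: pd.DataFrame
    activations: pd.DataFrame
    variance_explained: pd.DataFrame
    dimensionality: pd.DataFrame
    accuracy: pd.DataFrame
    similarity_by_group: dict[str, SimilarityMatrix]
    group_summary: dict
    failures: dict[str, str]
    provenance: dict


def run_study(config: StudyConfig, cohort: list[ParticipantData] | None = None) -> StudyReport:
    """Execute the full study on a synthetic (or supplied) cohort.

    When ``cohort`` is None, healthy and DMD cohorts of the configured sizes
    are generated from the default group profiles.  Participants whose
    processing fails are excluded from group aggregation and recorded in
    ``failures``.
    """
    if cohort is None:
        cohort = []
        protocol = config.protocol()
        noise = config.noise()
        profiles: list[tuple[CohortProfile, int]] = [
            (HEALTHY_PROFILE, config.n_healthy),
            (DMD_PROFILE, config.n_dmd),
        ]
        for profile, n in profiles:
            cohort.extend(
                make_cohort(profile, n, config.gestures, seed=config.seed,
                            protocol=protocol, noise=noise)
            )

    results: list[ParticipantResult] = []
    failures: dict[str, str] = {}
    for pdata in cohort:
        try:
            results.append(process_participant(pdata, config))
        except HDEMGError as exc:
            logger.error("participant %s failed: %s", pdata.participant_id, exc)
            failures[pdata.participant_id] = str(exc)

    def _concat(frames: list[pd.DataFrame]) -> pd.DataFrame:
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    repeat = _concat([r.repeatability_long for r in results])
    cog = _concat([r.cog_table for r in results])
    act = _concat([r.activation_table for r in results])
    accuracy = _concat([r.accuracy_table for r in results])

    ve_rows, dim_rows = [], []
    for r in results:
        for i, (v, c) in enumerate(zip(r.dimensionality.ve, r.dimensionality.cumulative_ve)):
            ve_rows.append(
                {"participant": r.participant_id, "group": r.group, "pc": i + 1,
                 "ve": float(v), "cumulative_ve": float(c)}
            )
        dim_rows.append(
            {"participant": r.participant_id, "group": r.group,
             "n_pcs_90": r.dimensionality.n_pcs_90,
             "pc1_ve": float(r.dimensionality.ve[0])}
        )
    ve_table = pd.DataFrame(ve_rows)
    dim_table = pd.DataFrame(dim_rows)

    similarity_by_group: dict[str, SimilarityMatrix] = {}
    for group in sorted({r.group for r in results}):
        mats = [r.gesture_similarity for r in results if r.group == group]
        similarity_by_group[group] = average_similarity(mats)

    group_summary = {"n_participants": {}, "failures": list(failures)}
    if len(act):
        group_summary["activation"] = activation_summary(act).to_dict(orient="records")
    if len(repeat):
        group_summary["repeatability_r2"] = (
            repeat.groupby("group")["r2"].agg(["mean", "std", "count"]).reset_index()
            .to_dict(orient="records")
        )
    if len(dim_table):
        group_summary["dimensionality"] = (
            dim_table.groupby("group")["n_pcs_90"].agg(["mean", "min", "max"]).reset_index()
            .to_dict(orient="records")
        )
    if len(accuracy):
        full_k = accuracy["k"].max()
        group_summary["accuracy_full_gesture_set"] = (
            accuracy[accuracy["k"] == full_k]
            .groupby("group")["mean_accuracy"].agg(["mean", "std"]).reset_index()
            .to_dict(orient="records")
        )
    for r in results:
        group_summary["n_participants"][r.group] = (
            group_summary["n_participants"].get(r.group, 0) + 1
        )

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "config": asdict(config),
    }
    return StudyReport(
        repeatability=repeat,
        cog=cog,
        activations=act,
        variance_explained=ve_table,
        dimensionality=dim_table,
        accuracy=accuracy,
        similarity_by_group=similarity_by_group,
        group_summary=group_summary,
        failures=failures,
        provenance=provenance,
    )


def emit_report(report: StudyReport, outdir: str | Path) -> list[Path]:
    """Write all report tables as CSV plus a JSON summary and a text digest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    tables = {
        "repeatability.csv": report.repeatability,
        "cog.csv": report.cog,
        "activations.csv": report.activations,
        "variance_explained.csv": report.variance_explained,
        "dimensionality.csv": report.dimensionality,
        "accuracy.csv": report.accuracy,
    }
    for name, frame in tables.items():
        path = outdir / name
        frame.to_csv(path, index=False)
        written.append(path)
    for group, sim in report.similarity_by_group.items():
        path = outdir / f"similarity_{group}.csv"
        sim.to_frame().to_csv(path)
        written.append(path)

    summary = {
        "group_summary": report.group_summary,
        "failures": report.failures,
        "provenance": report.provenance,
    }
    jpath = outdir / "summary.json"
    jpath.write_text(json.dumps(summary, indent=2, default=str))
    written.append(jpath)

    lines = ["HD-sEMG study report", "====================", ""]
    n_parts = report.group_summary.get("n_participants", {})
    if not n_parts:
        lines.append("Zero participants processed; no tables were produced.")
    else:
        for group, n in n_parts.items():
            lines.append(f"{group}: {n} participants")
        lines.append("")
        lines.append(f"repeatability coefficients: {len(report.repeatability)}")
        lines.append(f"COG rows: {len(report.cog)}")
        lines.append(f"activation rows: {len(report.activations)}")
    if report.failures:
        lines.append("")
        lines.append(f"failed participants: {report.failures}")
    tpath = outdir / "summary.txt"
    tpath.write_text("\n".join(lines) + "\n")
    written.append(tpath)
    return written
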