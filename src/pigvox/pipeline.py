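"""End-to-end workflow: slice annotated events, extract features,
summarise per class, and write the report bundle.

Stages are individually callable; ``run_pipeline`` chains them and
writes a manifest (config hash, seed, package versions) so a run is
reproducible byte-for-byte from its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

import pigvox
from pigvox.audio_io import (
    AnnotationRecord,
    AudioSegment,
    PreprocessConfig,
    bandpass,
    read_annotations,
    read_audio,
    slice_event,
)
from pigvox.class_stats import (
    DistributionSummary,
    compare_classes,
    radar_axes,
    summaries_to_table,
    summarize,
)
from pigvox.features import FeatureParams, extract_features, features_to_row
from pigvox.taxonomy import classify_behavior

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Everything one analysis run depends on."""

    audio: str
    annotations: str
    out_dir: str
    preprocess: PreprocessConfig = PreprocessConfig()
    features: FeatureParams = FeatureParams()
    search_window: float = 2.0
    refine: bool = True
    exclude_overlaps: bool = True
    strict_labels: bool = False
    skew_threshold: float = 0.33
    overlap_slight_threshold: float = 0.25
    radar_scale: float = 2.0
    seed: int = 0


def find_overlaps(records: Sequence[AnnotationRecord]) -> set[int]:
    """Indices of annotations whose intervals intersect another's.

    Overlap is interval intersection of positive length.
    """
    order = sorted(range(len(records)), key=lambda i: records[i].start)
    bad: set[int] = set()
    for a, b in zip(order, order[1:]):
        if records[b].start < records[a].end:
            bad.update((a, b))
    return bad


def extract_event_features(
    recording: AudioSegment,
    records: Sequence[AnnotationRecord],
    cfg: RunConfig,
) -> pd.DataFrame:
    """Band-pass the recording, slice every event, extract features."""
    filtered = bandpass(recording, cfg.preprocess)
    rows = []
    for event_id, ann in enumerate(records):
        sc = classify_behavior(ann.behavior, strict=cfg.strict_labels)
        try:
            sliced = slice_event(
                filtered, ann, search_window=cfg.search_window, refine=cfg.refine
            )
            vec = extract_features(sliced.segment, cfg.features)
        except ValueError as exc:
            raise RuntimeError(
                f"stage extract failed on event {event_id} "
                f"({ann.behavior} @ {ann.start:.2f}s): {exc}"
            ) from exc
        row = {
            "event_id": event_id,
            "behavior": sc.behavior,
            "level1": sc.level1.value,
            "valence": sc.valence.value,
            "start_s": sliced.start,
            "end_s": sliced.end,
            "refined": sliced.refined,
        }
        row.update(features_to_row(vec))
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_by(
    features_df: pd.DataFrame, by: str = "valence", skew_threshold: float = 0.33
) -> dict[str, DistributionSummary]:
    """Per-class summaries for a grouping column (valence or behavior)."""
    out = {}
    for cls, grp in features_df.groupby(by, sort=True):
        out[str(cls)] = summarize(grp, skew_threshold=skew_threshold)
    return out


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run slice → extract → summarize → report; return output paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recording = read_audio(cfg.audio)
    records = read_annotations(cfg.annotations)
    n_total = len(records)
    if cfg.exclude_overlaps:
        bad = find_overlaps(records)
        if bad:
            logger.info("excluding %d overlapping annotation(s)", len(bad))
        records = [r for i, r in enumerate(records) if i not in bad]

    df = extract_event_features(recording, records, cfg)
    paths = {"features": out / "features.csv"}
    df.to_csv(paths["features"], index=False, float_format="%.8g")

    voc = df[df["level1"] == "vocalization"]
    summaries = summarize_by(df, "valence", cfg.skew_threshold)
    table = summaries_to_table(summaries)
    paths["summary_csv"] = out / "class_summary.csv"
    table.to_csv(paths["summary_csv"], float_format="%.6g")
    paths["summary_json"] = out / "class_summary.json"
    paths["summary_json"].write_text(
        json.dumps(
            {
                cls: {"n": s.n, **{f: asdict(st) for f, st in s.stats.items()}}
                for cls, s in summaries.items()
            },
            indent=2,
        )
    )

    if len(summaries) >= 2:
        report = compare_classes(
            summaries, slight_threshold=cfg.overlap_slight_threshold
        )
        paths["comparison"] = out / "class_comparison.csv"
        report.to_csv(paths["comparison"], index=False, float_format="%.6g")
    else:
        logger.warning("only one class present; comparison report skipped")

    if len(voc) >= 4:
        ref = summarize(voc, skew_threshold=cfg.skew_threshold)
        try:
            axes = radar_axes(ref, scale_factor=cfg.radar_scale)
            paths["radar"] = out / "radar_axes.json"
            paths["radar"].write_text(
                json.dumps(
                    {"scale_factor": axes.scale_factor, "axes": axes.axes},
                    indent=2,
                )
            )
        except ValueError as exc:
            logger.warning("radar axes skipped: %s", exc)

    manifest = {
        "config": asdict(cfg),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "n_annotations": n_total,
        "n_analyzed": len(records),
        "versions": {
            "pigvox": pigvox.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": sys.version.split()[0],
        },
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=str))
    return paths


def run_demo(out_dir: str | Path, seed: int = 0, **session_kwargs) -> dict[str, Path]:
    """Generate a default synthetic session and analyse it end to end."""
    from pigvox.synth import SessionConfig, generate_session

    out = Path(out_dir)
    cfg = SessionConfig(seed=seed, **session_kwargs)
    session = generate_session(cfg)
    session_paths = session.write(out / "session")
    run_cfg = RunConfig(
        audio=str(session_paths["audio"]),
        annotations=str(session_paths["annotations"]),
        out_dir=str(out / "analysis"),
        seed=seed,
    )
    paths = run_pipeline(run_cfg)
    paths.update(session_paths)
    return paths
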