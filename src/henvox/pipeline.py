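"""End-to-end orchestration: denoise -> detect -> extract -> classify ->
aggregate -> correlate, with per-stage counts logged for audit.

Two entry points matter:

* :func:`corpus_features` runs detection + feature extraction over clips
  and pairs detected events with labels (greedy best-overlap matching,
  rating-3 labels only), yielding the (X, y) matrix the classifier sees.
* :func:`run_pipeline` is the deployment path: classify detected events
  with a trained model, count calls per thermal window and correlate the
  counts with THI.  All outputs embed the resolved config hash and the
  package version, and contain nothing wall-clock dependent, so identical
  seed/config reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .audio_io import AudioClip, CALL_TYPES, LabelRecord, read_wav
from .classify import ClassifierModel, CVResult, TrainConfig, KernelSpec, cross_validate, predict, train
from .config import PipelineConfig
from .denoise import denoise_clip
from .event_select import DetectionConfig, SoundEvent, detect_events, match_events
from .features import FEATURE_NAMES, extract_features
from .thermal import add_levels, aggregate_calls, correlate_windows, read_thermal_csv

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


def detection_config(cfg: PipelineConfig) -> DetectionConfig:
    return DetectionConfig(
        threshold=cfg.detect.threshold,
        min_duration_s=cfg.detect.min_duration_s,
        max_gap_s=cfg.detect.max_gap_s,
        smoothing_frames=cfg.detect.smoothing_frames,
        frame_len=cfg.audio.frame_len,
        overlap_fraction=cfg.audio.overlap_fraction,
        use_energy=cfg.detect.use_energy,
    )


def train_config(cfg: PipelineConfig) -> TrainConfig:
    return TrainConfig(
        C=cfg.classify.C,
        kernel=KernelSpec(
            kind=cfg.classify.kernel, gamma=cfg.classify.gamma,
            coef0=cfg.classify.coef0, degree=cfg.classify.degree,
        ),
        max_iterations=cfg.classify.max_iterations,
        tolerance=cfg.classify.tolerance,
        k_folds=cfg.classify.k_folds,
        seed=cfg.seed,
    )


def prepare_clip(clip: AudioClip, cfg: PipelineConfig) -> AudioClip:
    if not cfg.denoise.enabled:
        return clip
    return denoise_clip(
        clip,
        low_hz=cfg.denoise.low_hz,
        high_hz=cfg.denoise.high_hz,
        quantile=cfg.denoise.quantile,
        subtraction_factor=cfg.denoise.subtraction_factor,
        spectral_floor=cfg.denoise.spectral_floor,
        frame_len=cfg.audio.frame_len,
    )


def detect_all(clips: list[AudioClip], cfg: PipelineConfig) -> list[SoundEvent]:
    dcfg = detection_config(cfg)
    events: list[SoundEvent] = []
    for clip in clips:
        found = detect_events(prepare_clip(clip, cfg), dcfg)
        log.info("clip %s: %d events detected", clip.source_id, len(found))
        events.extend(found)
    return events


def extract_all(
    clips: list[AudioClip], events: list[SoundEvent], cfg: PipelineConfig
) -> tuple[np.ndarray, list[SoundEvent]]:
    """Feature matrix for the given events; drops all-missing events."""
    by_id = {c.source_id: prepare_clip(c, cfg) for c in clips}
    rows, kept = [], []
    for ev in events:
        clip = by_id.get(ev.source_id)
        if clip is None:
            log.warning("event on unknown source %s skipped", ev.source_id)
            continue
        audio = clip.slice_seconds(ev.start_s, ev.end_s)
        fv = extract_features(
            audio, fmin=cfg.features.fmin_hz, fmax=cfg.features.fmax_hz,
            frame_len=cfg.audio.frame_len, lpc_order=cfg.features.lpc_order,
        )
        if fv is None:
            continue
        rows.append(fv.values)
        kept.append(ev)
    X = np.vstack(rows) if rows else np.empty((0, len(FEATURE_NAMES)))
    log.info("extracted features for %d of %d events", len(kept), len(events))
    return X, kept


def corpus_features(
    clips: list[AudioClip],
    labels: list[LabelRecord],
    cfg: PipelineConfig,
    min_overlap: float = 0.5,
    use_truth_intervals: bool = False,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Detected-event features paired with rating-3 labels.

    Detected events are matched to clear (rating-3) labels by greedy
    best-overlap assignment at ``min_overlap``; unmatched detections are
    discarded (they have no ground truth).  With ``use_truth_intervals``
    the labelled intervals themselves are analysed (no detection step).
    Returns (X, y, stats) with per-stage counts.
    """
    clear = [r for r in labels if r.trainable]
    truth_events = [r.event for r in clear]
    if use_truth_intervals:
        X, kept = extract_all(clips, truth_events, cfg)
        idx = {id(e): i for i, e in enumerate(truth_events)}
        y = np.asarray([clear[idx[id(e)]].call_type for e in kept], dtype=object)
        stats = {"n_labels": len(clear), "n_detected": len(truth_events),
                 "n_matched": len(kept)}
        return X, y, stats
    detected = detect_all(clips, cfg)
    matches = match_events(detected, truth_events, min_overlap=min_overlap)
    matched_events = [detected[i] for i, _, _ in matches]
    matched_types = [clear[j].call_type for _, j, _ in matches]
    X, kept = extract_all(clips, matched_events, cfg)
    keep_idx = {id(e): t for e, t in zip(matched_events, matched_types)}
    y = np.asarray([keep_idx[id(e)] for e in kept], dtype=object)
    stats = {
        "n_labels": len(clear),
        "n_detected": len(detected),
        "n_matched": len(matches),
        "n_featured": len(kept),
    }
    log.info("corpus funnel: %s", stats)
    return X, y, stats


def evaluate_corpus(
    clips: list[AudioClip], labels: list[LabelRecord], cfg: PipelineConfig,
    use_truth_intervals: bool = False,
) -> tuple[CVResult, dict]:
    """Full-pipeline stratified cross-validation on a labelled corpus."""
    X, y, stats = corpus_features(clips, labels, cfg,
                                  use_truth_intervals=use_truth_intervals)
    result = cross_validate(X, y, train_config(cfg))
    return result, stats


@dataclass
class PipelineReport:
    config: dict
    config_hash: str
    version: str
    stats: dict
    windows: pd.DataFrame
    correlations: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Persist comfort_report.csv + correlations.json + metrics.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        meta = {"config_hash": self.config_hash, "version": self.version,
                "config": self.config}
        comfort = out / "comfort_report.csv"
        with open(comfort, "w") as fh:
            fh.write(f"# henvox {self.version} config_hash={self.config_hash}\n")
            self.windows.to_csv(fh, index=False)
        paths["comfort_report"] = comfort
        corr = out / "correlations.json"
        corr.write_text(json.dumps(
            {"meta": meta, "correlations": self.correlations}, indent=1, sort_keys=True))
        paths["correlations"] = corr
        metrics = out / "metrics.json"
        metrics.write_text(json.dumps(
            {"meta": meta, "stats": self.stats}, indent=1, sort_keys=True))
        paths["metrics"] = metrics
        return paths


def run_pipeline(
    audio_paths: list[str | Path],
    thermal_path: str | Path,
    cfg: PipelineConfig,
    model: ClassifierModel,
    recording_origin=None,
) -> PipelineReport:
    """Deployment path: detect and classify calls, join to THI, correlate.

    Event times are interpreted as seconds from ``recording_origin``
    (default: first thermal timestamp), with each clip's offset taken from
    its position in ``audio_paths`` order (clips are assumed contiguous).
    """
    if not audio_paths:
        raise PipelineError("no audio files given")
    clips = []
    offset = 0.0
    for p in audio_paths:
        clip = read_wav(p)
        clips.append(AudioClip(samples=clip.samples, rate=clip.rate,
                               source_id=clip.source_id, start_offset=offset))
        offset += clip.duration
    thermal = read_thermal_csv(thermal_path, coeffs=cfg.thi_coeffs())
    events = detect_all(clips, cfg)
    X, kept = extract_all(clips, events, cfg)
    labels = predict(model, X) if len(X) else np.asarray([], dtype=object)
    predictions = list(zip(kept, labels))
    windows = aggregate_calls(predictions, thermal, recording_origin=recording_origin)
    windows = add_levels(windows)
    correlations = correlate_windows(windows)
    stats = {
        "n_clips": len(clips),
        "n_events_detected": len(events),
        "n_events_featured": len(kept),
        "n_events_classified": int(len(labels)),
        "n_windows": int(len(windows)),
        "counts_by_type": {c: int((labels == c).sum()) for c in CALL_TYPES},
    }
    log.info("pipeline funnel: %s", stats)
    return PipelineReport(
        config=cfg.to_dict(), config_hash=cfg.hash(), version=__version__,
        stats=stats, windows=windows, correlations=correlations,
    )
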