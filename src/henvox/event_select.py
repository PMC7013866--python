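"""Automatic sound-event selection by energy-envelope thresholding.

Call events are located as maximal runs of the smoothed, per-file
max-normalised frame RMS envelope above a threshold (0.35 by default).
Nearby runs are merged and too-short runs discarded.  Agreement between a
detected and a labelled event is the overlap factor: temporal
intersection-over-union of the two intervals.  The detection threshold can
be tuned on labelled clips by maximising the mean best-match overlap factor
over a grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .audio_io import AudioClip, FrameSequence, LabelRecord, SoundEvent, frame_signal

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.35

__all__ = [
    "SoundEvent",
    "DetectionConfig",
    "energy_envelope",
    "detect_events",
    "overlap_factor",
    "match_events",
    "tune_threshold",
    "InsufficientLabelsError",
]


class InsufficientLabelsError(ValueError):
    pass


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of envelope-threshold event detection.

    threshold is a proportion of the per-file envelope maximum; runs
    separated by gaps <= max_gap_s merge; events shorter than min_duration_s
    are dropped (defaults keep <0.1 s squawk notes but kill 1-frame clicks).
    ``use_energy`` switches the envelope from RMS to RMS^2.
    """

    threshold: float = DEFAULT_THRESHOLD
    min_duration_s: float = 0.03
    max_gap_s: float = 0.03
    smoothing_frames: int = 3
    frame_len: int = 512
    overlap_fraction: float = 0.5
    use_energy: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.min_duration_s < 0:
            raise ValueError("min_duration_s must be >= 0")


def energy_envelope(
    frames: FrameSequence, smoothing_frames: int = 3, use_energy: bool = False
) -> np.ndarray:
    """Smoothed, max-normalised per-frame RMS (or RMS^2) energy in [0, 1].

    A centred moving average over ``smoothing_frames`` frames is applied
    before normalising by the maximum; all-zero input stays all-zero.
    """
    if len(frames) == 0:
        return np.zeros(0)
    rms = np.sqrt(np.mean(frames.frames**2, axis=1))
    env = rms**2 if use_energy else rms
    k = max(1, int(smoothing_frames))
    if k > 1:
        kernel = np.ones(k) / k
        # reflect-pad so the smoothing stays centred at the edges
        pad = k // 2
        padded = np.pad(env, pad, mode="edge")
        env = np.convolve(padded, kernel, mode="valid")[: len(rms)]
    peak = env.max()
    if peak > 0:
        env = env / peak
    return env


def detect_events(clip: AudioClip, cfg: DetectionConfig = DetectionConfig()) -> list[SoundEvent]:
    """Detect call events as supra-threshold runs of the energy envelope.

    Returned events are disjoint, sorted by start time, and carry the run's
    peak envelope value.  Event boundaries are placed at the centres of the
    first/last supra-threshold frames.
    """
    frames = frame_signal(clip, cfg.frame_len, cfg.overlap_fraction, window="hamming")
    env = energy_envelope(frames, cfg.smoothing_frames, cfg.use_energy)
    if env.size == 0:
        return []
    times = frames.frame_times()
    above = env >= cfg.threshold
    runs: list[list[int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append([start, i - 1])
            start = None
    if start is not None:
        runs.append([start, len(above) - 1])
    # merge runs whose inter-run gap is <= max_gap_s
    merged: list[list[int]] = []
    for run in runs:
        if merged and times[run[0]] - times[merged[-1][1]] <= cfg.max_gap_s:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    half = frames.frame_len / (2 * frames.rate)
    events = []
    for i0, i1 in merged:
        start_s = max(clip.start_offset, times[i0] - half)
        end_s = times[i1] + half
        if end_s - start_s < cfg.min_duration_s:
            continue
        events.append(
            SoundEvent(
                source_id=clip.source_id,
                start_s=start_s,
                end_s=end_s,
                peak_envelope=float(env[i0 : i1 + 1].max()),
            )
        )
    return events


def overlap_factor(detected: SoundEvent, labelled: SoundEvent) -> float:
    """Temporal intersection-over-union of two event intervals, in [0, 1]."""
    inter = min(detected.end_s, labelled.end_s) - max(detected.start_s, labelled.start_s)
    if inter <= 0:
        return 0.0
    union = max(detected.end_s, labelled.end_s) - min(detected.start_s, labelled.start_s)
    return inter / union


def match_events(
    detected: list[SoundEvent], labelled: list[SoundEvent], min_overlap: float = 0.0
) -> list[tuple[int, int, float]]:
    """Greedy best-overlap one-to-one assignment of detected to labelled events.

    Pairs are taken in decreasing overlap-factor order; each event matches at
    most once.  Returns (detected_index, labelled_index, overlap) triples
    with overlap > max(min_overlap, 0).
    """
    pairs = []
    for i, d in enumerate(detected):
        for j, t in enumerate(labelled):
            if d.source_id != t.source_id:
                continue
            ov = overlap_factor(d, t)
            if ov > 0 and ov >= min_overlap:
                pairs.append((ov, i, j))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_d: set[int] = set()
    used_l: set[int] = set()
    out = []
    for ov, i, j in pairs:
        if i in used_d or j in used_l:
            continue
        used_d.add(i)
        used_l.add(j)
        out.append((i, j, ov))
    return out


def detection_metrics(
    detected: list[SoundEvent], labelled: list[SoundEvent], min_overlap: float = 0.5
) -> dict[str, float]:
    """Sensitivity/precision of detection; match = overlap factor >= min_overlap."""
    matches = match_events(detected, labelled, min_overlap=min_overlap)
    tp = len(matches)
    fn = len(labelled) - tp
    fp = len(detected) - tp
    return {
        "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        "precision": 100.0 * tp / (tp + fp) if tp + fp else float("nan"),
        "n_matched": tp,
    }


def mean_best_overlap(
    clips: list[AudioClip], labels: list[LabelRecord], cfg: DetectionConfig
) -> float:
    """Mean best-match overlap factor of detection output against labels."""
    truth = [r.event for r in labels]
    if not truth:
        raise InsufficientLabelsError("no labelled events to tune against")
    detected: list[SoundEvent] = []
    for clip in clips:
        detected.extend(detect_events(clip, cfg))
    matches = match_events(detected, truth)
    total = sum(ov for _, _, ov in matches)  # unmatched labels count as 0
    return total / len(truth)


def tune_threshold(
    clips: list[AudioClip],
    labels: list[LabelRecord],
    grid: list[float],
    base_cfg: DetectionConfig = DetectionConfig(),
) -> DetectionConfig:
    """Pick the grid threshold maximising mean best-match overlap factor.

    Ties break toward the larger threshold (fewer false alarms).
    """
    if not grid:
        raise ValueError("threshold grid is empty")
    best_cfg, best_score = None, -np.inf
    for thr in sorted(grid):
        cfg = replace(base_cfg, threshold=thr)
        score = mean_best_overlap(clips, labels, cfg)
        log.debug("threshold %.3f -> mean overlap %.4f", thr, score)
        if score >= best_score:  # >= keeps the larger threshold on ties
            best_cfg, best_score = cfg, score
    return best_cfg
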