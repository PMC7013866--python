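"""WAV reading/writing, overlapping frame extraction and call-label files.

The reference recording configuration is mono 16 kHz audio in ~55 s files,
framed into N = 512-sample blocks with 50% overlap under a Hamming window.
Label files carry one annotated call event per row: a half-open time
interval [start_s, end_s), a call type (alarm / gakel / squawk / others)
and a quality rating in {1, 2, 3} where 1 = overlapped calls, 2 = unclear,
3 = clear.  Only rating-3 events are eligible for training/testing.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window

log = logging.getLogger(__name__)

DEFAULT_RATE = 16_000
DEFAULT_FRAME_LEN = 512
DEFAULT_OVERLAP = 0.5

CALL_TYPES = ("alarm", "gakel", "squawk", "others")

RATING_OVERLAPPED = 1
RATING_UNCLEAR = 2
RATING_CLEAR = 3


class AudioFormatError(ValueError):
    """Raised for unreadable or structurally invalid audio input."""


@dataclass(frozen=True)
class AudioClip:
    """A sampled mono waveform with amplitudes nominally in [-1, 1].

    Attributes
    ----------
    samples : np.ndarray
        1-D float array of amplitudes.
    rate : int
        Sampling rate in Hz (> 0).
    source_id : str
        Identifier of the originating recording (usually the file stem).
    start_offset : float
        Seconds from the recording origin to ``samples[0]``.
    """

    samples: np.ndarray
    rate: int
    source_id: str = ""
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=np.float64).ravel()
        )

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    def slice_seconds(self, start_s: float, end_s: float) -> "AudioClip":
        """Return the sub-clip covering [start_s, end_s) in clip-local time."""
        i0 = max(0, int(round(start_s * self.rate)))
        i1 = min(len(self.samples), int(round(end_s * self.rate)))
        return replace(
            self,
            samples=self.samples[i0:i1],
            start_offset=self.start_offset + i0 / self.rate,
        )


@dataclass(frozen=True)
class FrameSequence:
    """Windowed, fixed-length, overlapping frames of a clip.

    ``frames`` has shape (n_frames, frame_len); frame *i* starts at sample
    ``i * hop`` of the source, and the per-sample ``window`` taper has
    already been applied.
    """

    frames: np.ndarray
    frame_len: int
    hop: int
    rate: int
    window: np.ndarray
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=np.float64)
        if f.ndim == 1:  # allow an empty 1-D array for the degenerate case
            f = f.reshape(0, self.frame_len)
        if f.shape[1] != self.frame_len:
            raise ValueError("frame width does not match frame_len")
        object.__setattr__(self, "frames", f)

    def __len__(self) -> int:
        return self.frames.shape[0]

    def frame_times(self) -> np.ndarray:
        """Centre time (seconds) of each frame, in clip-local coordinates."""
        starts = np.arange(len(self)) * self.hop
        return self.start_offset + (starts + self.frame_len / 2) / self.rate


@dataclass(frozen=True)
class SoundEvent:
    """A detected or labelled call interval [start_s, end_s) on one source."""

    source_id: str
    start_s: float
    end_s: float
    peak_envelope: float = 0.0
    rating: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ValueError(
                f"invalid event interval [{self.start_s}, {self.end_s})"
            )

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class LabelRecord:
    """A manually annotated call event with type, quality rating, annotator."""

    event: SoundEvent
    call_type: str
    rating: int = RATING_CLEAR
    annotator: str = ""

    def __post_init__(self) -> None:
        if self.call_type not in CALL_TYPES:
            raise ValueError(f"unknown call type {self.call_type!r}")
        if self.rating not in (1, 2, 3):
            raise ValueError(f"rating must be 1, 2 or 3, got {self.rating}")

    @property
    def trainable(self) -> bool:
        """Only clear (rating-3) events enter training/testing sets."""
        return self.rating == RATING_CLEAR


def read_wav(path: str | Path) -> AudioClip:
    """Read a RIFF/WAV file into a mono :class:`AudioClip` scaled to [-1, 1].

    Integer PCM is divided by the dtype's full-scale value; float data is
    passed through.  Multi-channel input is averaged to mono with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise AudioFormatError(f"cannot parse WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise AudioFormatError(f"zero-length audio in {path}")
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max))
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    if samples.ndim > 1:
        log.warning("averaging %d channels of %s to mono", samples.shape[1], path)
        samples = samples.mean(axis=1)
    return AudioClip(samples=samples, rate=int(rate), source_id=path.stem)


def write_wav(path: str | Path, clip: AudioClip, dtype: str = "float32") -> None:
    """Write a clip as WAV; ``dtype`` in {'int16', 'int32', 'float32'}."""
    samples = clip.samples
    if dtype == "float32":
        data = samples.astype(np.float32)
    elif dtype in ("int16", "int32"):
        info = np.iinfo(dtype)
        full = float(max(abs(info.min), info.max))
        data = np.clip(np.round(samples * full), info.min, info.max).astype(dtype)
    else:
        raise ValueError(f"unsupported WAV dtype {dtype!r}")
    wavfile.write(str(path), clip.rate, data)


def frame_signal(
    clip: AudioClip,
    frame_len: int = DEFAULT_FRAME_LEN,
    overlap_fraction: float = DEFAULT_OVERLAP,
    window: str = "hamming",
) -> FrameSequence:
    """Split a clip into fixed-length overlapping frames with a taper.

    Frames start at multiples of ``hop = frame_len * (1 - overlap_fraction)``;
    trailing samples that do not fill a whole frame are dropped.  A clip
    shorter than one frame yields an empty sequence (logged, not an error).
    """
    if frame_len < 2 or frame_len % 2:
        raise ValueError(f"frame_len must be even and >= 2, got {frame_len}")
    if not 0 <= overlap_fraction < 1:
        raise ValueError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    hop = int(round(frame_len * (1 - overlap_fraction)))
    taper = get_window(window, frame_len, fftbins=True) if window else np.ones(frame_len)
    x = clip.samples
    n = len(x)
    if n < frame_len:
        log.info("clip %s shorter than one frame (%d < %d)", clip.source_id, n, frame_len)
        frames = np.empty((0, frame_len))
    else:
        n_frames = (n - frame_len) // hop + 1
        idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
        frames = x[idx] * taper[None, :]
    return FrameSequence(
        frames=frames,
        frame_len=frame_len,
        hop=hop,
        rate=clip.rate,
        window=np.asarray(taper),
        start_offset=clip.start_offset,
    )


# --- label files ------------------------------------------------------------

_LABEL_COLUMNS = ("source_id", "start_s", "end_s", "call_type", "rating", "annotator")


def read_labels_csv(path: str | Path) -> list[LabelRecord]:
    """Read the CSV label dialect: source_id,start_s,end_s,call_type,rating,annotator."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_LABEL_COLUMNS[:5]) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"label file {path} missing columns {sorted(missing)}")
        for row in reader:
            records.append(
                LabelRecord(
                    event=SoundEvent(
                        source_id=row["source_id"],
                        start_s=float(row["start_s"]),
                        end_s=float(row["end_s"]),
                    ),
                    call_type=row["call_type"].strip().lower(),
                    rating=int(row["rating"]),
                    annotator=row.get("annotator", "") or "",
                )
            )
    return records


def write_labels_csv(path: str | Path, records: Iterable[LabelRecord]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_LABEL_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.event.source_id,
                    f"{r.event.start_s:.6f}",
                    f"{r.event.end_s:.6f}",
                    r.call_type,
                    r.rating,
                    r.annotator,
                ]
            )


def read_audacity_labels(
    path: str | Path, source_id: str = "", annotator: str = ""
) -> list[LabelRecord]:
    """Import an Audacity label track (tab-separated start, end, label).

    The label text is parsed as "call_type" or "call_type/rating"; a missing
    rating defaults to 3 (clear).
    """
    source_id = source_id or Path(path).stem
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed Audacity label line: {line!r}")
            start, end, text = float(parts[0]), float(parts[1]), parts[2]
            call_type, _, rating_txt = text.partition("/")
            records.append(
                LabelRecord(
                    event=SoundEvent(source_id=source_id, start_s=start, end_s=end),
                    call_type=call_type.strip().lower(),
                    rating=int(rating_txt) if rating_txt else RATING_CLEAR,
                    annotator=annotator,
                )
            )
    return records


def write_audacity_labels(path: str | Path, records: Iterable[LabelRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.event.start_s:.6f}\t{r.event.end_s:.6f}\t{r.call_type}/{r.rating}\n"
            )


def merge_annotations(
    records: Sequence[LabelRecord],
    expert: str | None = None,
    min_agreement: int = 1,
) -> list[LabelRecord]:
    """Resolve multi-annotator label sets without guessing a merge rule.

    If ``expert`` is given, that annotator's records override others that
    overlap them in time on the same source; otherwise records annotated by
    at least ``min_agreement`` annotators (by overlapping same-type
    intervals) are kept.  Default keeps everything.
    """
    if expert is not None:
        expert_recs = [r for r in records if r.annotator == expert]
        out = list(expert_recs)
        for r in records:
            if r.annotator == expert:
                continue
            clash = any(
                e.event.source_id == r.event.source_id
                and e.event.start_s < r.event.end_s
                and r.event.start_s < e.event.end_s
                for e in expert_recs
            )
            if not clash:
                out.append(r)
        return sorted(out, key=lambda r: (r.event.source_id, r.event.start_s))
    if min_agreement <= 1:
        return list(records)
    out = []
    for r in records:
        n = len(
            {
                o.annotator
                for o in records
                if o.event.source_id == r.event.source_id
                and o.call_type == r.call_type
                and o.event.start_s < r.event.end_s
                and r.event.start_s < o.event.end_s
            }
        )
        if n >= min_agreement:
            out.append(r)
    return out
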