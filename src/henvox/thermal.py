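"""Classification metrics and thermal-comfort assessment.

Sensitivity and precision are the standard confusion-matrix rates reported
as percentages to one decimal (round half up).  Thermal comfort is indexed
by the temperature-humidity index (THI), computed from air temperature and
relative humidity, zoned as comfort (< 70), alert ([70, 76)), danger
([76, 81]) and emergency (> 81) — the published integer bands are closed
to half-open continuous intervals so every THI value has a zone.  Call
counts per 5-minute window are joined to the THI series, normalised onto
levels 1-10, and related to THI by Pearson correlation with a two-tailed
t-test on n - 2 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from .audio_io import CALL_TYPES

log = logging.getLogger(__name__)

# Default THI for laying hens: 0.8*T + (RH/100)*(T - 14.4) + 46.4
DEFAULT_THI_COEFFS = {"a": 0.8, "b": 1.0, "t_ref": 14.4, "c": 46.4}
ZONES = ("comfort", "alert", "danger", "emergency")
WINDOW_MINUTES = 5
N_LEVELS = 10


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (so 97.55 -> 97.6, unlike banker's rounding)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class UndefinedMetricError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    """4x4 counts; rows = real call type, columns = classified call type."""

    counts: np.ndarray
    classes: tuple[str, ...] = CALL_TYPES

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (len(self.classes), len(self.classes)):
            raise ValueError(f"expected square counts over {self.classes}")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())


def sensitivity(tp: int, fn: int) -> float:
    """100 * TP / (TP + FN), to one decimal; undefined when TP + FN = 0."""
    if tp + fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positives")
    return round_half_up(100.0 * tp / (tp + fn), 1)


def precision(tp: int, fp: int) -> float:
    """100 * TP / (TP + FP), to one decimal; undefined when TP + FP = 0."""
    if tp + fp == 0:
        raise UndefinedMetricError("precision undefined: nothing classified positive")
    return round_half_up(100.0 * tp / (tp + fp), 1)


def per_class_metrics(cm: ConfusionMatrix) -> dict:
    """Per-class sensitivity/precision plus unweighted macro averages.

    Class c's sensitivity comes from row c, precision from column c; the
    macro value is the mean of the four per-class values, to one decimal.
    """
    out: dict = {"per_class": {}, "macro": {}}
    sens, prec = [], []
    for i, c in enumerate(cm.classes):
        tp = int(cm.counts[i, i])
        s = sensitivity(tp, int(cm.row_totals[i]) - tp)
        p = precision(tp, int(cm.col_totals[i]) - tp)
        out["per_class"][c] = {"sensitivity": s, "precision": p}
        sens.append(s)
        prec.append(p)
    out["macro"]["sensitivity"] = round_half_up(float(np.mean(sens)), 1)
    out["macro"]["precision"] = round_half_up(float(np.mean(prec)), 1)
    return out


# --- THI --------------------------------------------------------------------


def compute_thi(
    temperature: float | np.ndarray,
    relative_humidity: float | np.ndarray,
    coeffs: dict | None = None,
) -> float | np.ndarray:
    """Temperature-humidity index: a*T + b*(RH/100)*(T - t_ref) + c.

    The default coefficient set (0.8, 1.0, 14.4, 46.4) is a standard
    laying-hen parameterisation; any coefficient can be overridden, and the
    set in force is logged into output files for provenance.
    """
    k = {**DEFAULT_THI_COEFFS, **(coeffs or {})}
    t = np.asarray(temperature, dtype=np.float64)
    rh = np.asarray(relative_humidity, dtype=np.float64)
    if ((rh < 0) | (rh > 100)).any():
        raise ValueError("relative humidity must be within [0, 100] %")
    thi = k["a"] * t + k["b"] * (rh / 100.0) * (t - k["t_ref"]) + k["c"]
    return float(thi) if thi.ndim == 0 else thi


def thi_zone(thi: float) -> str:
    """Map a THI value to its comfort zone.

    comfort < 70 <= alert < 76 <= danger <= 81 < emergency; the bands are
    continuous and monotone, so every real THI has exactly one zone.
    """
    if thi < 70:
        return "comfort"
    if thi < 76:
        return "alert"
    if thi <= 81:
        return "danger"
    return "emergency"


@dataclass(frozen=True)
class ThermalRecord:
    timestamp: datetime
    thi: float
    temperature: float | None = None
    relative_humidity: float | None = None

    @property
    def zone(self) -> str:
        return thi_zone(self.thi)


def read_thermal_csv(path, coeffs: dict | None = None) -> list[ThermalRecord]:
    """Read (timestamp, temperature_c, relative_humidity_pct) or
    (timestamp, thi) CSV rows into ThermalRecords."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    records = []
    for _, row in df.iterrows():
        ts = pd.Timestamp(row["timestamp"]).to_pydatetime()
        if "thi" in cols:
            records.append(ThermalRecord(timestamp=ts, thi=float(row["thi"])))
        elif {"temperature_c", "relative_humidity_pct"} <= cols:
            t, rh = float(row["temperature_c"]), float(row["relative_humidity_pct"])
            records.append(
                ThermalRecord(
                    timestamp=ts, thi=float(compute_thi(t, rh, coeffs)),
                    temperature=t, relative_humidity=rh,
                )
            )
        else:
            raise ValueError(
                "thermal CSV needs either a 'thi' column or "
                "'temperature_c' + 'relative_humidity_pct'"
            )
    return records


# --- call-count aggregation -------------------------------------------------


def aggregate_calls(
    predictions: list,  # (SoundEvent-like with .start_s on recording time, label) pairs
    thermal: list[ThermalRecord],
    recording_origin: datetime | None = None,
) -> pd.DataFrame:
    """Count each call type per 5-minute thermal window.

    ``predictions`` is a list of (event, call_type) pairs whose event times
    are seconds from ``recording_origin`` (default: the first thermal
    timestamp).  Windows are half-open [t, t + 5 min): an event exactly on a
    boundary belongs to the later window.  Events falling outside every
    thermal window are dropped with a log entry.
    """
    if not thermal:
        raise ValueError("no thermal records")
    origin = recording_origin or min(r.timestamp for r in thermal)
    rows = []
    for rec in sorted(thermal, key=lambda r: r.timestamp):
        rows.append(
            {
                "window_start": rec.timestamp,
                "thi": rec.thi,
                "zone": rec.zone,
                **{f"n_{c}": 0 for c in CALL_TYPES},
            }
        )
    df = pd.DataFrame(rows)
    width = timedelta(minutes=WINDOW_MINUTES)
    starts = list(df["window_start"])
    dropped = 0
    for event, call_type in predictions:
        t = origin + timedelta(seconds=float(event.start_s))
        hit = None
        for i, ws in enumerate(starts):
            if ws <= t < ws + width:
                hit = i  # later windows override earlier on exact boundaries
        if hit is None:
            dropped += 1
            continue
        df.loc[hit, f"n_{call_type}"] += 1
    if dropped:
        log.info("dropped %d events outside every thermal window", dropped)
    return df


def normalise_levels(counts: np.ndarray, n_levels: int = N_LEVELS) -> np.ndarray:
    """Min-max map of per-window counts onto integer levels 1..n_levels.

    Equal-width bins over [min, max]; a constant series maps to level 1
    everywhere.  Applied per call type, never pooled.
    """
    c = np.asarray(counts, dtype=np.float64)
    lo, hi = c.min(), c.max()
    if hi == lo:
        return np.ones(len(c), dtype=int)
    width = (hi - lo) / n_levels
    levels = 1 + np.floor((c - lo) / width).astype(int)
    return np.minimum(levels, n_levels)


def add_levels(windows: pd.DataFrame) -> pd.DataFrame:
    """Append a level_<type> column (1-10) per call type to a window table."""
    out = windows.copy()
    for c in CALL_TYPES:
        out[f"level_{c}"] = normalise_levels(out[f"n_{c}"].to_numpy())
    return out


# --- correlation ------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    significant_01: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "significant_01", bool(self.p < 0.01))


def correlate(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson r between two series with a 2-tailed p from t on n - 2 df."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length series with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedMetricError("correlation undefined: zero variance")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=len(x))


def correlate_windows(windows: pd.DataFrame) -> dict:
    """Per call type: Pearson correlation of window counts against THI."""
    out = {}
    thi = windows["thi"].to_numpy()
    for c in CALL_TYPES:
        counts = windows[f"n_{c}"].to_numpy()
        try:
            res = correlate(thi, counts)
            out[c] = {"r": res.r, "p": res.p, "n": res.n,
                      "significant_01": res.significant_01}
        except (ValueError, UndefinedMetricError) as exc:
            out[c] = {"r": None, "p": None, "n": len(thi), "note": str(exc)}
    return out
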