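"""Unified single-lead ECG preprocessing pipeline.

Lead selection -> polyphase resampling to 400 Hz -> fourth-order zero-phase
Butterworth band-pass (0.5-45 Hz) -> non-overlapping 10 s windows (4000
samples) -> binary label mapping (AF, AFL -> AF; N, J, NSR -> NonAF) ->
stratified 70:15:15 splitting at record or window level.

Filtering is applied to the full record *before* segmentation so the 0.5 Hz
high-pass edge does not ring inside every 10 s window.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .synthetic import ECGRecord

__all__ = [
    "AF", "NONAF", "EXCLUDED",
    "Window", "DatasetSplits",
    "select_lead", "resample_to", "bandpass_filter", "segment_windows",
    "map_rhythm_label", "assign_window_label", "record_to_windows",
    "records_to_windows", "split_dataset",
    "write_record_csv", "read_record_csv",
]

logger = logging.getLogger(__name__)

AF = "AF"
NONAF = "NonAF"
EXCLUDED = "excluded"

TARGET_FS = 400.0
WINDOW_S = 10.0
WINDOW_SAMPLES = 4000

# fine-grained rhythm vocabulary -> binary label
_LABEL_MAP = {
    "AF": AF,
    "AFL": AF,
    "N": NONAF,
    "J": NONAF,
    "NSR": NONAF,
    "other": EXCLUDED,
    "noisy": EXCLUDED,
}

_AF_FINE = {"AF", "AFL"}


@dataclass
class Window:
    """One fixed-length analysis segment: 4000 samples at 400 Hz."""

    samples: np.ndarray
    label: str
    fine_rhythm: str
    record_id: str
    start_time: float
    is_augmented: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (WINDOW_SAMPLES,):
            raise ValueError(
                f"window must hold exactly {WINDOW_SAMPLES} samples, "
                f"got {self.samples.shape}"
            )
        if self.label not in (AF, NONAF):
            raise ValueError(f"bad label {self.label!r}")
        if map_rhythm_label(self.fine_rhythm) != self.label:
            raise ValueError(
                f"label {self.label} inconsistent with fine rhythm "
                f"{self.fine_rhythm}"
            )


@dataclass
class DatasetSplits:
    train: list[Window] = field(default_factory=list)
    val: list[Window] = field(default_factory=list)
    test: list[Window] = field(default_factory=list)
    split_level: str = "record"

    def counts(self) -> dict[str, dict[str, int]]:
        out = {}
        for name in ("train", "val", "test"):
            ws = getattr(self, name)
            out[name] = {
                AF: sum(w.label == AF for w in ws),
                NONAF: sum(w.label == NONAF for w in ws),
            }
        return out


def select_lead(
    record: ECGRecord, policy: str = "II", fallback: str | None = None
) -> ECGRecord:
    """Return the single channel named by ``policy`` (default lead II).

    Single-channel records pass through unchanged.  If the named lead is
    absent and ``fallback`` is ``"first"``, channel 0 is used with a logged
    warning; otherwise an error naming the available leads is raised.
    """
    if record.n_channels == 0:
        raise ValueError("record has no channels")
    if record.n_channels == 1:
        return record
    if policy in record.lead_names:
        idx = record.lead_names.index(policy)
    elif fallback == "first":
        logger.warning(
            "lead %r not found in %s; falling back to channel 0 (%s)",
            policy, record.record_id, record.lead_names[0],
        )
        idx = 0
    else:
        raise ValueError(
            f"lead {policy!r} not present; available leads: {record.lead_names}"
        )
    return ECGRecord(
        record_id=record.record_id,
        signal=record.signal[idx : idx + 1],
        fs=record.fs,
        lead_names=[record.lead_names[idx]],
        rhythm_intervals=list(record.rhythm_intervals),
    )


def resample_to(x: np.ndarray, fs_in: float, fs_out: float = TARGET_FS) -> np.ndarray:
    """Band-limited (polyphase) resampling; output length = round(n*fs_out/fs_in)."""
    if fs_in <= 0:
        raise ValueError("fs_in must be positive")
    x = np.asarray(x, dtype=float)
    if math.isclose(fs_in, fs_out):
        return x.copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    y = sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    n_out = int(round(x.shape[-1] * fs_out / fs_in))
    return y[..., :n_out]


def bandpass_filter(
    x: np.ndarray,
    fs: float = TARGET_FS,
    low: float = 0.5,
    high: float = 45.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass.

    ``order`` is the order of the one-way design; the forward-backward
    application doubles the effective attenuation and cancels phase, so
    waveform landmarks are not shifted.
    """
    if not 0 < low < high < fs / 2:
        raise ValueError("need 0 < low < high < fs/2")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def segment_windows(x: np.ndarray, fs: float = TARGET_FS, window_s: float = WINDOW_S):
    """Cut a 1-D signal into consecutive non-overlapping fixed windows.

    Returns ``(list of sample vectors, list of start times)``; any trailing
    remainder shorter than one window is discarded.
    """
    n_win = fs * window_s
    if abs(n_win - round(n_win)) > 1e-9:
        raise ValueError("fs * window_s must be an integer number of samples")
    n_win = int(round(n_win))
    x = np.asarray(x, dtype=float).ravel()
    k = len(x) // n_win
    segs = [x[i * n_win : (i + 1) * n_win] for i in range(k)]
    starts = [i * n_win / fs for i in range(k)]
    return segs, starts


def map_rhythm_label(fine_rhythm: str) -> str:
    """Binary label mapping: AF, AFL -> AF; N, J, NSR -> NonAF; the
    "other"/"noisy" tags used by short-recording challenge datasets map to
    an excluded sentinel (such windows are dropped, not classified)."""
    try:
        return _LABEL_MAP[fine_rhythm]
    except KeyError:
        raise ValueError(
            f"unknown rhythm tag {fine_rhythm!r}; "
            f"supported: {sorted(_LABEL_MAP)}"
        ) from None


def assign_window_label(
    start: float, end: float, rhythm_intervals: list[tuple[float, float, str]]
) -> tuple[str, str]:
    """Label a window by the rhythm with the largest overlap duration.

    Ties are broken toward AF-type rhythms (screening sensitivity).  Returns
    ``(label, fine_rhythm)``; raises if the window overlaps no interval.
    """
    overlaps: dict[str, float] = {}
    for s, e, tag in rhythm_intervals:
        ov = min(end, e) - max(start, s)
        if ov > 0:
            overlaps[tag] = overlaps.get(tag, 0.0) + ov
    if not overlaps:
        raise ValueError("window lies outside all rhythm intervals")
    best = max(
        overlaps.items(),
        key=lambda kv: (kv[1], kv[0] in _AF_FINE),
    )[0]
    return map_rhythm_label(best), best


def record_to_windows(
    record: ECGRecord,
    lead: str = "II",
    fallback: str | None = None,
    low: float = 0.5,
    high: float = 45.0,
    order: int = 4,
    drop_excluded: bool = True,
) -> list[Window]:
    """Full per-record pipeline: lead -> resample -> filter -> windows."""
    rec = select_lead(record, lead, fallback=fallback)
    x = resample_to(rec.signal[0], rec.fs, TARGET_FS)
    x = bandpass_filter(x, TARGET_FS, low, high, order)
    segs, starts = segment_windows(x, TARGET_FS, WINDOW_S)
    out: list[Window] = []
    for seg, t0 in zip(segs, starts):
        label, fine = assign_window_label(
            t0, t0 + WINDOW_S, rec.rhythm_intervals
        )
        if label == EXCLUDED:
            if drop_excluded:
                continue
            raise ValueError(f"window at t={t0} has excluded rhythm {fine}")
        out.append(Window(seg, label, fine, rec.record_id, t0))
    return out


def records_to_windows(records: list[ECGRecord], **kwargs) -> list[Window]:
    ws: list[Window] = []
    for rec in records:
        ws.extend(record_to_windows(rec, **kwargs))
    return ws


def _stratified_window_split(windows, ratios, rng):
    splits = ([], [], [])
    for lab in (AF, NONAF):
        idx = [i for i, w in enumerate(windows) if w.label == lab]
        if not idx:
            raise ValueError(f"class {lab} absent; cannot stratify")
        idx = np.array(idx)
        rng.shuffle(idx)
        n = len(idx)
        n_train = int(round(ratios[0] * n))
        n_val = int(round(ratios[1] * n))
        chunks = (idx[:n_train], idx[n_train : n_train + n_val], idx[n_train + n_val :])
        for bucket, chunk in zip(splits, chunks):
            bucket.extend(int(i) for i in chunk)
    return tuple([windows[i] for i in sorted(b)] for b in splits)


def _greedy_record_split(windows, ratios, rng):
    # group windows by record; stratify by each record's majority label so
    # every split sees both classes, then greedily assign whole records
    # (largest first, ties broken by a seeded shuffle) to the split whose
    # fill fraction for that label is lowest
    by_rec: dict[str, list[Window]] = {}
    for w in windows:
        by_rec.setdefault(w.record_id, []).append(w)
    if len(by_rec) < 3:
        raise ValueError("record-level splitting needs at least 3 records")

    def rec_label(ws):
        return AF if sum(w.label == AF for w in ws) * 2 >= len(ws) else NONAF

    groups: dict[str, list[str]] = {}
    for rid, ws in by_rec.items():
        groups.setdefault(rec_label(ws), []).append(rid)

    splits: tuple[list[Window], ...] = ([], [], [])
    for lab, rec_ids in groups.items():
        rng.shuffle(rec_ids)
        rec_ids.sort(key=lambda r: -len(by_rec[r]))
        total = sum(len(by_rec[r]) for r in rec_ids)
        targets = [max(r * total, 1e-9) for r in ratios]
        counts = [0.0, 0.0, 0.0]
        for rid in rec_ids:
            j = int(np.argmin([counts[k] / targets[k] for k in range(3)]))
            splits[j].extend(by_rec[rid])
            counts[j] += len(by_rec[rid])
    return splits


def split_dataset(
    windows: list[Window],
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
    level: str = "record",
    seed: int = 0,
) -> DatasetSplits:
    """Deterministic stratified 70:15:15 split.

    ``level="record"`` assigns whole records greedily so each split's window
    count approximates the target ratios and no record straddles splits;
    ``level="window"`` performs per-label stratified window assignment.
    """
    total = sum(ratios)
    ratios = tuple(r / total for r in ratios)
    rng = np.random.default_rng(seed)
    if level == "window":
        tr, va, te = _stratified_window_split(windows, ratios, rng)
    elif level == "record":
        tr, va, te = _greedy_record_split(windows, ratios, rng)
    else:
        raise ValueError("level must be 'record' or 'window'")
    return DatasetSplits(train=tr, val=va, test=te, split_level=level)


# ---------------------------------------------------------------------------
# CSV record round-trip (documented dialect: one signal file, one interval
# file per record; times in seconds, amplitudes in mV)
# ---------------------------------------------------------------------------

def write_record_csv(record: ECGRecord, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``<id>_signal.csv`` (header: fs + lead names; one row per
    sample) and ``<id>_intervals.csv`` (start_s,end_s,rhythm)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sig_path = out_dir / f"{record.record_id}_signal.csv"
    iv_path = out_dir / f"{record.record_id}_intervals.csv"
    with open(sig_path, "w", newline="") as fh:
        wtr = csv.writer(fh)
        wtr.writerow(["fs", record.fs])
        wtr.writerow(["lead"] + list(record.lead_names))
        for row in record.signal.T:
            wtr.writerow([f"{v:.6f}" for v in row])
    with open(iv_path, "w", newline="") as fh:
        wtr = csv.writer(fh)
        wtr.writerow(["start_s", "end_s", "rhythm"])
        for s, e, tag in record.rhythm_intervals:
            wtr.writerow([f"{s:.6f}", f"{e:.6f}", tag])
    return sig_path, iv_path


def read_record_csv(
    signal_path: str | Path, intervals_path: str | Path | None = None
) -> ECGRecord:
    """Read a record written by :func:`write_record_csv`.

    If ``intervals_path`` is omitted it is inferred from the signal path; a
    missing interval file raises, since labels are required downstream.
    """
    signal_path = Path(signal_path)
    if not signal_path.exists():
        raise FileNotFoundError(signal_path)
    if intervals_path is None:
        intervals_path = Path(
            str(signal_path).replace("_signal.csv", "_intervals.csv")
        )
    intervals_path = Path(intervals_path)
    if not intervals_path.exists():
        raise FileNotFoundError(
            f"interval annotation file missing: {intervals_path}"
        )
    with open(signal_path, newline="") as fh:
        rdr = csv.reader(fh)
        fs_row = next(rdr)
        if fs_row[0] != "fs":
            raise ValueError(f"malformed signal file {signal_path}")
        fs = float(fs_row[1])
        lead_row = next(rdr)
        leads = lead_row[1:]
        data = np.array([[float(v) for v in row] for row in rdr])
    intervals: list[tuple[float, float, str]] = []
    with open(intervals_path, newline="") as fh:
        rdr = csv.reader(fh)
        next(rdr)  # header
        for row in rdr:
            intervals.append((float(row[0]), float(row[1]), row[2]))
    rid = signal_path.name.replace("_signal.csv", "")
    return ECGRecord(
        record_id=rid, signal=data.T, fs=fs, lead_names=leads,
        rhythm_intervals=intervals,
    )
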