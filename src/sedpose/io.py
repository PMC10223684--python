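"""Reading, writing and conditioning of accelerometer recordings and bout tables.

The recording dialect follows raw CSV exports from Axivity AX6 devices
(OmGui export): one timestamp column — either MATLAB fractional days or
seconds — followed by three acceleration columns in units of g.  The device
is worn on the lower back (L5) with the axis convention

* ``ax`` — vertical axis,
* ``ay`` — mediolateral axis,
* ``az`` — anterior–posterior axis.

Annotation and bout tables are plain CSV with columns ``start_s``, ``end_s``
and ``label``; intervals are half-open ``[start, end)`` in seconds from the
start of the recording, with labels drawn from ``{sitting, lying, upright}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .errors import DataError, ParseError, SchemaError, TapDetectionError

SECONDS_PER_DAY = 86_400.0

#: the three activity classes every bout/annotation label must come from
ACTIVITY_LABELS = ("sitting", "lying", "upright")


@dataclass
class TriaxialRecording:
    """A timestamped triaxial acceleration series in g.

    Parameters
    ----------
    timestamps : ndarray
        Seconds since the start of the recording, strictly increasing.
    ax, ay, az : ndarray
        Vertical, mediolateral and anterior–posterior acceleration (g).
    nominal_rate : float
        Nominal sampling rate in Hz (100 for the AX6).
    """

    timestamps: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    nominal_rate: float = 100.0

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = len(self.timestamps)
        if n < 1:
            raise DataError("recording must contain at least one sample")
        for name in ("ax", "ay", "az"):
            if len(getattr(self, name)) != n:
                raise DataError(
                    f"axis series {name!r} has length {len(getattr(self, name))}, "
                    f"expected {n}"
                )
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            bad = int(np.argmax(np.diff(self.timestamps) <= 0))
            raise DataError(
                f"timestamps are not strictly increasing at sample {bad + 1}"
            )
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be positive")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        """Time span in seconds (last minus first timestamp)."""
        return float(self.timestamps[-1] - self.timestamps[0])

    def is_uniform(self, tol: float = 1e-9) -> bool:
        """True if successive timestamps differ by 1/nominal_rate within *tol*."""
        if len(self) < 2:
            return True
        dt = np.diff(self.timestamps)
        return bool(np.all(np.abs(dt - 1.0 / self.nominal_rate) <= tol))

    def axes(self) -> np.ndarray:
        """Stack the three axes into an (n, 3) array (ax, ay, az columns)."""
        return np.column_stack([self.ax, self.ay, self.az])


@dataclass
class AnnotationTrack:
    """Ordered, non-overlapping labelled intervals (half-open, seconds).

    ``intervals`` is a list of ``(start_s, end_s, label)`` tuples with labels
    from :data:`ACTIVITY_LABELS`.  ``source`` records provenance (e.g.
    ``"video"`` or ``"simulator"``).
    """

    intervals: list = field(default_factory=list)
    source: str = ""

    def __post_init__(self):
        ivs = [(float(s), float(e), str(lab)) for s, e, lab in self.intervals]
        ivs.sort(key=lambda iv: iv[0])
        prev_end = -np.inf
        for s, e, lab in ivs:
            if lab not in ACTIVITY_LABELS:
                raise SchemaError(
                    f"unknown label {lab!r}; expected one of {ACTIVITY_LABELS}"
                )
            if not s < e:
                raise SchemaError(f"interval ({s}, {e}) has start >= end")
            if s < prev_end - 1e-12:
                raise SchemaError(
                    f"interval starting at {s} overlaps the previous interval"
                )
            prev_end = e
        self.intervals = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def span(self) -> tuple:
        """(first start, last end) in seconds."""
        if not self.intervals:
            raise DataError("annotation track is empty")
        return self.intervals[0][0], self.intervals[-1][1]

    def total_duration(self, label: str) -> float:
        """Summed duration (s) of all intervals carrying *label*."""
        return float(sum(e - s for s, e, lab in self.intervals if lab == label))

    def durations(self, label: str) -> list:
        """Individual interval durations (s) for *label*, in temporal order."""
        return [e - s for s, e, lab in self.intervals if lab == label]


# ---------------------------------------------------------------------------
# recording CSV I/O


def _looks_like_header(line: str) -> bool:
    for tok in line.strip().split(","):
        try:
            float(tok)
        except ValueError:
            return True
    return False


def read_ax6_csv(
    path,
    dialect: str = "fractional_day",
    timestamp_col: int = 0,
    axis_cols: Sequence[int] = (1, 2, 3),
    axis_map: Sequence[int] = (0, 1, 2),
    nominal_rate: float = 100.0,
) -> TriaxialRecording:
    """Read an AX6/OmGui-style CSV export into a :class:`TriaxialRecording`.

    Parameters
    ----------
    dialect : {"fractional_day", "seconds"}
        ``fractional_day`` — timestamps are MATLAB fractional days and are
        converted to seconds relative to the first sample (1 day = 86400 s).
        ``seconds`` — timestamps are already seconds and are kept as-is.
    timestamp_col, axis_cols :
        Column positions of the timestamp and the three acceleration columns.
        Extra columns (e.g. gyroscope channels) are tolerated and ignored.
    axis_map :
        Permutation mapping the three read columns onto (ax, ay, az), for
        exports whose column order deviates from the vertical/ML/AP convention.
    """
    if dialect not in ("fractional_day", "seconds"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first:
        raise ParseError(f"{path}: file is empty")
    header = 0 if _looks_like_header(first) else None
    df = pd.read_csv(path, header=header)
    needed = [timestamp_col, *axis_cols]
    if df.shape[1] < max(needed) + 1:
        raise ParseError(
            f"{path}: expected at least {max(needed) + 1} columns, got {df.shape[1]}"
        )
    cols = []
    for c in needed:
        col = pd.to_numeric(df.iloc[:, c], errors="coerce")
        if col.isna().any():
            row = int(col.isna().idxmax())
            raise ParseError(f"{path}: non-numeric value in column {c}, row {row}")
        cols.append(col.to_numpy(dtype=float))
    ts, a0, a1, a2 = cols
    if dialect == "fractional_day":
        ts = (ts - ts[0]) * SECONDS_PER_DAY
    axes = [a0, a1, a2]
    ax, ay, az = (axes[i] for i in axis_map)
    return TriaxialRecording(ts, ax, ay, az, nominal_rate=nominal_rate)


def write_recording(
    rec: TriaxialRecording, path, dialect: str = "seconds", header: bool = True
) -> None:
    """Write a recording back to the CSV dialect read by :func:`read_ax6_csv`."""
    if dialect == "seconds":
        ts = rec.timestamps
    elif dialect == "fractional_day":
        ts = rec.timestamps / SECONDS_PER_DAY
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.DataFrame(
        {"timestamp": ts, "ax": rec.ax, "ay": rec.ay, "az": rec.az}
    )
    df.to_csv(path, index=False, header=header, float_format="%.9f")


# ---------------------------------------------------------------------------
# resampling


def resample_uniform(
    rec: TriaxialRecording, target_rate: float | None = None
) -> TriaxialRecording:
    """Resample a (possibly non-uniform) recording onto a uniform grid.

    Each axis is interpolated with a shape-preserving piecewise-cubic Hermite
    polynomial (PCHIP): monotone between knots, no overshoot.  The output grid
    is anchored at the first timestamp and clipped to the input span — no
    extrapolation is attempted.
    """
    if target_rate is None:
        target_rate = rec.nominal_rate
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if len(rec) < 2:
        raise DataError("resampling needs at least 2 samples")
    t = rec.timestamps
    n_out = int(np.floor((t[-1] - t[0]) * target_rate + 1e-9)) + 1
    grid = t[0] + np.arange(n_out) / target_rate
    out = []
    for x in (rec.ax, rec.ay, rec.az):
        out.append(PchipInterpolator(t, x)(grid))
    return TriaxialRecording(grid, *out, nominal_rate=target_rate)


# ---------------------------------------------------------------------------
# synchronisation taps


def detect_sync_taps(
    rec: TriaxialRecording,
    expected: int = 3,
    spacing: float = 1.0,
    tolerance: float = 0.3,
    window_s: float = 0.1,
    threshold_multiple: float = 8.0,
    min_floor_g: float = 0.05,
    merge_gap_s: float = 0.3,
) -> list:
    """Locate synchronisation taps (sharp transients ~``spacing`` s apart).

    The recording is cut into non-overlapping ``window_s`` windows; per window
    the three axis standard deviations are summed.  Windows whose summed SD
    exceeds ``threshold_multiple`` times the median (or ``min_floor_g`` if the
    median is ~0) are grouped into candidate events (gaps below
    ``merge_gap_s`` merge); each event is timed at its peak window centre.
    The first run of ``expected`` events whose successive spacings match
    ``spacing`` within ``tolerance`` is returned.

    Raises
    ------
    TapDetectionError
        If fewer than ``expected`` qualifying events exist, or no run of
        events matches the spacing pattern.  ``.found`` carries the count.
    """
    w = max(int(round(window_s * rec.nominal_rate)), 1)
    n_win = len(rec) // w
    if n_win < 1:
        raise TapDetectionError("recording shorter than one window", found=0)
    axes = rec.axes()[: n_win * w].reshape(n_win, w, 3)
    std_sum = axes.std(axis=1, ddof=1).sum(axis=1) if w > 1 else np.zeros(n_win)
    med = float(np.median(std_sum))
    thr = max(threshold_multiple * med, min_floor_g)
    hot = np.flatnonzero(std_sum > thr)
    if hot.size == 0:
        raise TapDetectionError("no qualifying tap transients found", found=0)
    # group hot windows into events
    gap_win = max(int(round(merge_gap_s / window_s)), 1)
    events = []
    group = [hot[0]]
    for i in hot[1:]:
        if i - group[-1] <= gap_win:
            group.append(i)
        else:
            events.append(group)
            group = [i]
    events.append(group)
    t0 = rec.timestamps[0]
    times = []
    for grp in events:
        peak = grp[int(np.argmax(std_sum[grp]))]
        times.append(t0 + (peak + 0.5) * w / rec.nominal_rate)
    if len(times) < expected:
        raise TapDetectionError(
            f"found {len(times)} tap events, expected {expected}",
            found=len(times),
        )
    for i in range(len(times) - expected + 1):
        run = times[i : i + expected]
        gaps = np.diff(run)
        if np.all(np.abs(gaps - spacing) <= tolerance):
            return [float(t) for t in run]
    raise TapDetectionError(
        f"found {len(times)} tap events but none spaced {spacing}±{tolerance} s",
        found=len(times),
    )


# ---------------------------------------------------------------------------
# annotation / bout tables


def read_annotations(path, source: str | None = None) -> AnnotationTrack:
    """Read a start_s/end_s/label CSV into an :class:`AnnotationTrack`."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"start_s", "end_s", "label"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    intervals = [
        (float(r.start_s), float(r.end_s), str(r.label))
        for r in df.itertuples(index=False)
    ]
    return AnnotationTrack(intervals, source=source if source is not None else str(path))


def write_annotations(track: AnnotationTrack, path) -> None:
    """Write an annotation track to the start_s/end_s/label CSV schema."""
    df = pd.DataFrame(
        [(s, e, lab) for s, e, lab in track.intervals],
        columns=["start_s", "end_s", "label"],
    )
    df.to_csv(path, index=False)


def write_bouts(bouts, path) -> None:
    """Write a classified :class:`~sedpose.classify.BoutSequence` as a bout CSV."""
    write_annotations(bouts.to_annotation_track(), path)
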