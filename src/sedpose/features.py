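"""Windowed signal features: filtered axes, per-window SDs and tilt angles.

The classifier never looks at raw samples — it operates on a 10 Hz series of
per-0.1 s window features:

* movement intensity: the per-window standard deviations of the offset-removed,
  17 Hz low-passed axes, and their sum (``std_sum``), low-passed at 1 Hz;
* posture: tilt angles of each device axis against the total acceleration
  vector, ``tilt_X = arccos(x / |a|) * 180/pi`` computed on the window-mean
  of the 17 Hz-filtered (gravity-bearing, NOT offset-removed) axes, each
  low-passed at 0.25 Hz.

Two signal paths are deliberate: subtracting the mean acceleration (offset
removal) destroys the gravity component that the arccos tilt needs, so offset
removal feeds only the SD path while tilt angles are computed from the
filtered-but-unshifted axes.  All filters are zero-phase (forward–backward)
Butterworth; the secondary 1 Hz / 0.25 Hz filters run at the 10 Hz window rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .config import AlgoConfig
from .errors import LengthError
from .io import TriaxialRecording


@dataclass
class WindowFeatureSeries:
    """Per-window feature series at ``window_rate`` windows per second."""

    window_start_frame: np.ndarray  # sample index of each window
    std_ax: np.ndarray
    std_ay: np.ndarray
    std_az: np.ndarray
    std_sum: np.ndarray
    std_sum_filtered: np.ndarray
    tilt_vt: np.ndarray
    tilt_ml: np.ndarray
    tilt_ap: np.ndarray
    tilt_vt_filtered: np.ndarray
    tilt_ml_filtered: np.ndarray
    tilt_ap_filtered: np.ndarray
    window_rate: float = 10.0

    def __len__(self) -> int:
        return len(self.window_start_frame)

    @property
    def n_windows(self) -> int:
        return len(self)

    def to_frame(self) -> pd.DataFrame:
        """Tabular export (window_start_s plus every feature column)."""
        return pd.DataFrame(
            {
                "window_start_s": self.window_start_frame / (
                    self.window_rate * len_window_samples(self)
                ),
                "std_ax": self.std_ax,
                "std_ay": self.std_ay,
                "std_az": self.std_az,
                "std_sum": self.std_sum,
                "std_sum_filtered": self.std_sum_filtered,
                "tilt_vt": self.tilt_vt,
                "tilt_ml": self.tilt_ml,
                "tilt_ap": self.tilt_ap,
                "tilt_vt_filtered": self.tilt_vt_filtered,
                "tilt_ml_filtered": self.tilt_ml_filtered,
                "tilt_ap_filtered": self.tilt_ap_filtered,
            }
        )


def len_window_samples(wfs: WindowFeatureSeries) -> int:
    """Samples per window inferred from the start-frame stride (10 by default)."""
    if len(wfs.window_start_frame) > 1:
        return int(wfs.window_start_frame[1] - wfs.window_start_frame[0])
    return 1


def remove_offset(rec: TriaxialRecording) -> TriaxialRecording:
    """Subtract each axis' arithmetic mean (used only on the SD path)."""
    return TriaxialRecording(
        rec.timestamps,
        rec.ax - rec.ax.mean(),
        rec.ay - rec.ay.mean(),
        rec.az - rec.az.mean(),
        nominal_rate=rec.nominal_rate,
    )


def lowpass_zero_phase(
    series: np.ndarray, order: int, cutoff: float, rate: float
) -> np.ndarray:
    """Zero-phase (forward–backward) low-pass Butterworth filter.

    The two passes cancel phase delay and square the single-pass magnitude
    response; DC gain is 1.  Edges are handled by even extension of three
    filter lengths, the standard zero-phase padding practice.
    """
    if cutoff >= rate / 2.0:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below the Nyquist rate {rate / 2.0} Hz"
        )
    series = np.asarray(series, dtype=float)
    b, a = butter(order, cutoff, fs=rate)
    padlen = 3 * max(len(a), len(b))
    if len(series) <= padlen:
        raise LengthError(
            f"series of length {len(series)} too short for zero-phase filtering "
            f"(needs > {padlen} samples)"
        )
    return filtfilt(b, a, series, padtype="even", padlen=padlen)


def _window_tilt(mean_vecs: np.ndarray) -> np.ndarray:
    """Tilt angles (deg, n x 3) of window-mean acceleration vectors.

    Zero-magnitude vectors (degenerate input) inherit the previous window's
    angles, or 90 deg if the first window is degenerate.
    """
    norms = np.linalg.norm(mean_vecs, axis=1)
    tilts = np.empty_like(mean_vecs)
    prev = np.array([90.0, 90.0, 90.0])
    for i in range(len(mean_vecs)):
        if norms[i] == 0.0:
            tilts[i] = prev
        else:
            c = np.clip(mean_vecs[i] / norms[i], -1.0, 1.0)
            tilts[i] = np.degrees(np.arccos(c))
            prev = tilts[i]
    return tilts


def window_features(
    rec: TriaxialRecording, config: AlgoConfig | None = None
) -> WindowFeatureSeries:
    """Compute the full windowed feature series from a uniform recording.

    The recording must be on the uniform ``config.sample_rate_hz`` grid
    (resample first).  Windows are non-overlapping, ``window_seconds`` long;
    a trailing partial window is dropped.
    """
    if config is None:
        config = AlgoConfig()
    w = config.samples_per_window
    n_win = len(rec) // w
    if n_win < 1:
        raise LengthError(
            f"recording of {len(rec)} samples has no full {w}-sample window"
        )
    rate = config.sample_rate_hz
    order = config.filter_order

    # SD path: offset removal then 17 Hz low-pass
    centred = remove_offset(rec)
    sd_axes = np.column_stack(
        [
            lowpass_zero_phase(x, order, config.accel_cutoff_hz, rate)
            for x in (centred.ax, centred.ay, centred.az)
        ]
    )
    # tilt path: 17 Hz low-pass of the gravity-bearing axes (no offset removal)
    g_axes = np.column_stack(
        [
            lowpass_zero_phase(x, order, config.accel_cutoff_hz, rate)
            for x in (rec.ax, rec.ay, rec.az)
        ]
    )

    sd_win = sd_axes[: n_win * w].reshape(n_win, w, 3)
    stds = sd_win.std(axis=1, ddof=1)
    std_sum = stds[:, 0] + stds[:, 1] + stds[:, 2]

    mean_vecs = g_axes[: n_win * w].reshape(n_win, w, 3).mean(axis=1)
    tilts = _window_tilt(mean_vecs)

    wrate = config.window_rate
    std_sum_f = lowpass_zero_phase(std_sum, order, config.std_cutoff_hz, wrate)
    tilt_f = np.column_stack(
        [
            np.clip(
                lowpass_zero_phase(tilts[:, k], order, config.tilt_cutoff_hz, wrate),
                0.0,
                180.0,
            )
            for k in range(3)
        ]
    )

    return WindowFeatureSeries(
        window_start_frame=np.arange(n_win) * w,
        std_ax=stds[:, 0],
        std_ay=stds[:, 1],
        std_az=stds[:, 2],
        std_sum=std_sum,
        std_sum_filtered=std_sum_f,
        tilt_vt=tilts[:, 0],
        tilt_ml=tilts[:, 1],
        tilt_ap=tilts[:, 2],
        tilt_vt_filtered=tilt_f[:, 0],
        tilt_ml_filtered=tilt_f[:, 1],
        tilt_ap_filtered=tilt_f[:, 2],
        window_rate=wrate,
    )
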