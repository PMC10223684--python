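"""Method-agreement statistics between algorithm output and a reference.

Validation of the bout classifier against a gold-standard annotation (video
observation, or simulator ground truth) uses four layers:

* frame-level confusion at a fixed time resolution (0.01 s, one frame per
  sample at 100 Hz), summarised per class as one-vs-rest sensitivity,
  specificity, PPV and NPV;
* intraclass correlation ICC(2,1) — single-measure, absolute-agreement,
  two-way random effects — between per-subject activity durations;
* Bland–Altman bias and 95% limits of agreement (bias ± 1.96 SD of the
  paired differences, algorithm − reference);
* mean absolute error (AE, seconds) and mean absolute percentage error
  (APE, %) over matched bout durations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .io import ACTIVITY_LABELS, AnnotationTrack

log = logging.getLogger(__name__)

_NONE = "__unlabelled__"


@dataclass
class ConfusionCounts:
    """One-vs-rest frame counts per class; every class sees every frame."""

    counts: dict  # label -> dict(tp=, fp=, tn=, fn=)
    total_frames: int
    resolution: float

    def __getitem__(self, label: str) -> dict:
        return self.counts[label]


class ICCResult(NamedTuple):
    value: float
    degenerate: bool = False


class BlandAltman(NamedTuple):
    bias: float
    loa_low: float
    loa_high: float
    sd: float


@dataclass
class AgreementReport:
    """Per-class agreement between an algorithm track and a reference track."""

    confusion: ConfusionCounts
    metrics: dict  # label -> dict of sensitivity/specificity/ppv/npv (NaN if undefined)
    accuracy: float
    ae_s: dict  # label -> mean absolute duration error (s) or NaN
    ape_pct: dict  # label -> mean absolute percentage error (%) or NaN
    matched_bouts: dict  # label -> number of matched (ref, alg) bout pairs
    unmatched_ref_bouts: dict  # label -> reference bouts with no overlap partner

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lab in ACTIVITY_LABELS:
            row = {"activity": lab}
            row.update(self.metrics[lab])
            row.update(self.confusion[lab])
            row["ae_s"] = self.ae_s[lab]
            row["ape_pct"] = self.ape_pct[lab]
            row["matched_bouts"] = self.matched_bouts[lab]
            row["unmatched_ref_bouts"] = self.unmatched_ref_bouts[lab]
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# frame-level confusion


def _track_intervals(track) -> list:
    if isinstance(track, AnnotationTrack):
        return track.intervals
    # BoutSequence duck-typing
    return track.to_annotation_track().intervals


def _rasterise(intervals: list, frame_starts: np.ndarray) -> np.ndarray:
    """Label per frame by half-open membership of the frame start time."""
    starts = np.array([iv[0] for iv in intervals])
    ends = np.array([iv[1] for iv in intervals])
    labels = np.array([iv[2] for iv in intervals], dtype=object)
    idx = np.searchsorted(starts, frame_starts, side="right") - 1
    out = np.full(frame_starts.shape, _NONE, dtype=object)
    valid = idx >= 0
    inside = np.zeros_like(valid)
    inside[valid] = frame_starts[valid] < ends[idx[valid]]
    out[inside] = labels[idx[inside]]
    return out


def frame_confusion(
    pred, ref, resolution: float = 0.01
) -> ConfusionCounts:
    """Rasterise both tracks to ``resolution`` and count one-vs-rest frames.

    ``pred`` may be a :class:`~sedpose.classify.BoutSequence` or an
    :class:`AnnotationTrack`; ``ref`` likewise.  The intersection of the two
    spans is scored; a span mismatch larger than one frame is logged.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    p_iv, r_iv = _track_intervals(pred), _track_intervals(ref)
    if not p_iv or not r_iv:
        raise ValueError("empty track")
    p_span = (p_iv[0][0], p_iv[-1][1])
    r_span = (r_iv[0][0], r_iv[-1][1])
    lo, hi = max(p_span[0], r_span[0]), min(p_span[1], r_span[1])
    if hi - lo <= 0:
        raise ValueError("prediction and reference tracks do not overlap")
    mismatch = max(abs(p_span[0] - r_span[0]), abs(p_span[1] - r_span[1]))
    if mismatch > resolution:
        log.warning(
            "track span mismatch of %.3f s exceeds resolution; scoring the "
            "%.2f s intersection",
            mismatch,
            hi - lo,
        )
    n = int(np.floor((hi - lo) / resolution + 1e-9))
    frame_starts = lo + np.arange(n) * resolution
    p_lab = _rasterise(p_iv, frame_starts)
    r_lab = _rasterise(r_iv, frame_starts)
    counts = {}
    for lab in ACTIVITY_LABELS:
        pp = p_lab == lab
        rr = r_lab == lab
        counts[lab] = {
            "tp": int(np.sum(pp & rr)),
            "fp": int(np.sum(pp & ~rr)),
            "fn": int(np.sum(~pp & rr)),
            "tn": int(np.sum(~pp & ~rr)),
        }
    return ConfusionCounts(counts=counts, total_frames=n, resolution=resolution)


def classification_metrics(cc: ConfusionCounts) -> dict:
    """Sensitivity, specificity, PPV and NPV per class.

    Ratios with a zero denominator are returned as NaN and recorded in the
    per-class ``undefined`` list.
    """

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    out = {}
    for lab, c in cc.counts.items():
        m = {
            "sensitivity": ratio(c["tp"], c["tp"] + c["fn"]),
            "specificity": ratio(c["tn"], c["tn"] + c["fp"]),
            "ppv": ratio(c["tp"], c["tp"] + c["fp"]),
            "npv": ratio(c["tn"], c["tn"] + c["fn"]),
        }
        m["undefined"] = [k for k, v in m.items() if isinstance(v, float) and np.isnan(v)]
        out[lab] = m
    return out


def overall_accuracy(cc: ConfusionCounts) -> float:
    """Fraction of frames where prediction equals reference (3-class)."""
    agree = sum(c["tp"] for c in cc.counts.values())
    return agree / cc.total_frames


# ---------------------------------------------------------------------------
# ICC(2,1)


def icc_2_1(ratings: np.ndarray) -> ICCResult:
    """Single-measure absolute-agreement two-way random-effects ICC.

    ``ratings`` is an (n subjects x k raters) complete matrix.  From the
    two-way ANOVA mean squares (rows MSR, columns MSC, error MSE):

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    A matrix with (numerically) zero total variance is perfect agreement by
    convention: returns 1.0 with ``degenerate=True``.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an (n>=2) x (k>=2) matrix")
    if np.isnan(x).any():
        raise ValueError("ratings matrix must be complete (no NaN)")
    n, k = x.shape
    grand = x.mean()
    sst = float(np.sum((x - grand) ** 2))
    if sst <= 1e-12 * max(1.0, abs(grand)) ** 2:
        return ICCResult(1.0, degenerate=True)
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return ICCResult(1.0, degenerate=True)
    return ICCResult(float((msr - mse) / denom), degenerate=False)


# ---------------------------------------------------------------------------
# Bland–Altman


def bland_altman(pairs: Iterable) -> BlandAltman:
    """Bias and 95% limits of agreement for (algorithm, reference) pairs.

    Differences are signed ``algorithm - reference``; limits are
    ``bias ± 1.96 * SD`` with the sample (ddof=1) standard deviation.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (algorithm, reference) pairs")
    d = arr[:, 0] - arr[:, 1]
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd, sd)


def bland_altman_plot(pairs, path, title: str = "") -> BlandAltman:
    """Difference-vs-mean Bland–Altman plot written to *path*."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = np.asarray(list(pairs), dtype=float)
    res = bland_altman(arr)
    means = arr.mean(axis=1)
    diffs = arr[:, 0] - arr[:, 1]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=18, alpha=0.8)
    for y, style in ((res.bias, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of algorithm and reference (s)")
    ax.set_ylabel("algorithm − reference (s)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return res


# ---------------------------------------------------------------------------
# duration errors


def duration_errors(ref_durs, alg_durs) -> tuple:
    """Mean absolute error (s) and mean absolute percentage error (%).

    ``AE = (1/n) sum |R_t - A_t|``; ``APE = (100/n) sum |R_t - A_t| / R_t``.
    """
    r = np.asarray(list(ref_durs), dtype=float)
    a = np.asarray(list(alg_durs), dtype=float)
    if r.shape != a.shape or r.ndim != 1 or r.size == 0:
        raise ValueError("ref_durs and alg_durs must be equal-length non-empty lists")
    if np.any(r <= 0):
        raise ValueError("reference durations must be positive")
    ae = float(np.mean(np.abs(r - a)))
    ape = float(100.0 * np.mean(np.abs(r - a) / r))
    return ae, ape


def match_bouts(pred, ref, label: str) -> tuple:
    """Pair reference bouts of *label* with the greatest-overlap predicted bout.

    Returns ``(pairs, n_unmatched_ref)`` where pairs is a list of
    ``(ref_duration, alg_duration)``.  Each predicted bout is used at most
    once; reference bouts with no same-label overlap are excluded and counted.
    """
    p_iv = [iv for iv in _track_intervals(pred) if iv[2] == label]
    r_iv = [iv for iv in _track_intervals(ref) if iv[2] == label]
    used = set()
    pairs = []
    unmatched = 0
    for rs, re, _ in r_iv:
        best, best_ov = None, 0.0
        for j, (ps, pe, _) in enumerate(p_iv):
            if j in used:
                continue
            ov = min(re, pe) - max(rs, ps)
            if ov > best_ov:
                best, best_ov = j, ov
        if best is None:
            unmatched += 1
        else:
            used.add(best)
            ps, pe, _ = p_iv[best]
            pairs.append((re - rs, pe - ps))
    return pairs, unmatched


# ---------------------------------------------------------------------------
# assembled report


def evaluate(pred, ref, resolution: float = 0.01) -> AgreementReport:
    """Frame confusion, per-class metrics and duration errors for one pair."""
    cc = frame_confusion(pred, ref, resolution)
    metrics = classification_metrics(cc)
    ae, ape, matched, unmatched = {}, {}, {}, {}
    for lab in ACTIVITY_LABELS:
        pairs, n_un = match_bouts(pred, ref, lab)
        matched[lab] = len(pairs)
        unmatched[lab] = n_un
        if pairs:
            ae[lab], ape[lab] = duration_errors(
                [p[0] for p in pairs], [p[1] for p in pairs]
            )
        else:
            ae[lab], ape[lab] = float("nan"), float("nan")
    return AgreementReport(
        confusion=cc,
        metrics=metrics,
        accuracy=overall_accuracy(cc),
        ae_s=ae,
        ape_pct=ape,
        matched_bouts=matched,
        unmatched_ref_bouts=unmatched,
    )
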