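"""Semi-adaptive sitting / lying / upright bout classification.

The classifier runs in three phases on the windowed feature series:

1. **Candidate profiling** — the whole-recording means of the filtered tilt
   angles decide whether the wearer is an *upright-likely* candidate
   (``ceil(mean VT) >= 150`` and ``ceil(mean ML) >= 90`` and
   ``ceil(mean AP) >= 90`` degrees).  Upright-likely wearers move enough that
   movement intensity separates upright time; others are classified on
   posture alone.
2. **Upright-window detection** — upright-likely: a window is a potential
   upright window when its filtered summed SD reaches the whole-recording
   mean of that series (mode ``"strict"``), optionally also passing the
   per-window tilt test (mode ``"gated"``, the default, which confirms
   upright bouts posturally).  Otherwise: fixed tilt tests,
   ``VT_filtered >= 140`` and ``AP_filtered >= 75`` degrees.
3. **Bout labelling** — maximal runs of upright windows become potential
   upright bouts; each is relabelled from its mean filtered AP tilt
   (``< 40`` -> lying, ``< 80`` -> sitting, else upright).  Every non-upright
   segment is labelled against the *preceding confirmed upright bout*: mean
   AP below ``preceding/2.5`` -> lying, below ``preceding`` -> sitting, else
   upright.  Segments before any confirmed upright bout fall back to the
   fixed 40/80 degree rule.  Adjacent same-label bouts merge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import AlgoConfig
from .errors import DataError, LengthError
from .features import WindowFeatureSeries, window_features
from .io import ACTIVITY_LABELS, AnnotationTrack, TriaxialRecording, resample_uniform

UPRIGHT, SITTING, LYING = "upright", "sitting", "lying"


@dataclass
class CandidateProfile:
    """Whole-recording profile deciding the upright-detection branch."""

    upright_likely: bool
    mean_tilt_vt_filtered: float
    mean_tilt_ml_filtered: float
    mean_tilt_ap_filtered: float
    mean_std_sum_filtered: float


@dataclass
class Bout:
    """A labelled, half-open run of windows ``[start_frame, end_frame)``."""

    start_frame: int
    end_frame: int
    label: str
    mean_tilt_ap_filtered: float = float("nan")

    def __post_init__(self):
        if not self.start_frame < self.end_frame:
            raise DataError(
                f"bout [{self.start_frame}, {self.end_frame}) is empty or reversed"
            )
        if self.label not in ACTIVITY_LABELS:
            raise DataError(f"unknown bout label {self.label!r}")

    @property
    def n_windows(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class BoutSequence:
    """Contiguous tiling of ``[0, n_windows)`` by labelled bouts."""

    bouts: list
    window_rate: float = 10.0
    start_time: float = 0.0

    def __post_init__(self):
        if not self.bouts:
            raise DataError("bout sequence is empty")
        if self.bouts[0].start_frame != 0:
            raise DataError("bout sequence must start at frame 0")
        for prev, cur in zip(self.bouts, self.bouts[1:]):
            if cur.start_frame != prev.end_frame:
                raise DataError(
                    f"gap/overlap between bouts at frame {prev.end_frame}"
                )
            if cur.label == prev.label:
                raise DataError(
                    f"adjacent bouts share label {cur.label!r} (merge first)"
                )

    def __len__(self) -> int:
        return len(self.bouts)

    def __iter__(self):
        return iter(self.bouts)

    @property
    def n_windows(self) -> int:
        return self.bouts[-1].end_frame

    def labels(self) -> np.ndarray:
        """Per-window label array of length ``n_windows``."""
        out = np.empty(self.n_windows, dtype=object)
        for b in self.bouts:
            out[b.start_frame : b.end_frame] = b.label
        return out

    def to_annotation_track(self, source: str = "algorithm") -> AnnotationTrack:
        """Convert window indices to half-open second intervals."""
        ivs = [
            (
                self.start_time + b.start_frame / self.window_rate,
                self.start_time + b.end_frame / self.window_rate,
                b.label,
            )
            for b in self.bouts
        ]
        return AnnotationTrack(ivs, source=source)

    def as_tuples(self) -> list:
        return [(b.start_frame, b.end_frame, b.label) for b in self.bouts]


# ---------------------------------------------------------------------------


def profile_candidate(
    wfs: WindowFeatureSeries, config: AlgoConfig | None = None
) -> CandidateProfile:
    """Profile the wearer from whole-recording mean filtered tilt angles.

    ``ceiling(mean)`` is compared against the profiling thresholds — the
    ceiling makes the test pass for means within one degree below a threshold.
    """
    if config is None:
        config = AlgoConfig()
    if len(wfs) == 0:
        raise LengthError("empty feature series")
    mvt = float(np.mean(wfs.tilt_vt_filtered))
    mml = float(np.mean(wfs.tilt_ml_filtered))
    map_ = float(np.mean(wfs.tilt_ap_filtered))
    likely = (
        math.ceil(mvt) >= config.vt_upright_profile_deg
        and math.ceil(mml) >= config.ml_upright_profile_deg
        and math.ceil(map_) >= config.ap_upright_profile_deg
    )
    return CandidateProfile(
        upright_likely=likely,
        mean_tilt_vt_filtered=mvt,
        mean_tilt_ml_filtered=mml,
        mean_tilt_ap_filtered=map_,
        mean_std_sum_filtered=float(np.mean(wfs.std_sum_filtered)),
    )


def detect_upright_windows(
    wfs: WindowFeatureSeries,
    profile: CandidateProfile,
    config: AlgoConfig | None = None,
) -> np.ndarray:
    """Boolean potential-upright flag per window (see module docstring)."""
    if config is None:
        config = AlgoConfig()
    tilt_ok = (wfs.tilt_vt_filtered >= config.vt_upright_window_deg) & (
        wfs.tilt_ap_filtered >= config.ap_upright_window_deg
    )
    if profile.upright_likely:
        flags = wfs.std_sum_filtered >= profile.mean_std_sum_filtered
        if config.mode == "gated":
            flags = flags & tilt_ok
        return flags
    return tilt_ok


def extract_bouts(upright_flags: np.ndarray) -> list:
    """Run-length encode flags into alternating candidate/non-upright segments.

    Returns ``(start, end, is_candidate)`` triples with half-open window
    indices covering the whole series, including leading/trailing non-upright
    runs.
    """
    flags = np.asarray(upright_flags, dtype=bool)
    if flags.size == 0:
        raise LengthError("empty flag series")
    change = np.flatnonzero(np.diff(flags)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [flags.size]))
    return [(int(s), int(e), bool(flags[s])) for s, e in zip(starts, ends)]


def _fixed_label(mean_ap: float, config: AlgoConfig) -> str:
    if mean_ap < config.ap_lying_fixed_deg:
        return LYING
    if mean_ap < config.ap_sitting_fixed_deg:
        return SITTING
    return UPRIGHT


def label_bouts(
    segments: list,
    wfs: WindowFeatureSeries,
    config: AlgoConfig | None = None,
) -> BoutSequence:
    """Label candidate and non-upright segments and merge into a BoutSequence.

    Candidate (potential upright) segments are labelled by the fixed AP rule.
    Non-upright segments use the adaptive rule against the most recent
    candidate segment that was *confirmed* upright; before any such bout the
    fixed rule applies.
    """
    if config is None:
        config = AlgoConfig()
    preceding_upright_ap: float | None = None
    labelled = []
    for start, end, is_candidate in segments:
        mean_ap = float(np.mean(wfs.tilt_ap_filtered[start:end]))
        if is_candidate:
            label = _fixed_label(mean_ap, config)
            if label == UPRIGHT:
                preceding_upright_ap = mean_ap
        else:
            if preceding_upright_ap is None:
                label = _fixed_label(mean_ap, config)
            elif mean_ap < preceding_upright_ap / config.lying_ratio:
                label = LYING
            elif mean_ap < preceding_upright_ap:
                label = SITTING
            else:
                label = UPRIGHT
        labelled.append(Bout(start, end, label, mean_ap))
    return BoutSequence(_merge_adjacent(labelled), window_rate=wfs.window_rate)


def _merge_adjacent(bouts: list) -> list:
    merged = [bouts[0]]
    for b in bouts[1:]:
        last = merged[-1]
        if b.label == last.label:
            n1, n2 = last.n_windows, b.n_windows
            ap = (
                last.mean_tilt_ap_filtered * n1 + b.mean_tilt_ap_filtered * n2
            ) / (n1 + n2)
            merged[-1] = Bout(last.start_frame, b.end_frame, b.label, ap)
        else:
            merged.append(b)
    return merged


def _enforce_min_duration(bouts: list, min_windows: int) -> list:
    """Absorb bouts shorter than ``min_windows`` into the longer neighbour."""
    bouts = list(bouts)
    while len(bouts) > 1:
        short = [
            i for i, b in enumerate(bouts) if b.n_windows < min_windows
        ]
        if not short:
            break
        i = min(short, key=lambda j: bouts[j].n_windows)
        b = bouts[i]
        if i == 0:
            neighbour = 1
        elif i == len(bouts) - 1:
            neighbour = i - 1
        else:
            neighbour = (
                i - 1
                if bouts[i - 1].n_windows >= bouts[i + 1].n_windows
                else i + 1
            )
        keep = bouts[neighbour]
        lo, hi = min(i, neighbour), max(i, neighbour)
        bouts[lo : hi + 1] = [
            Bout(
                bouts[lo].start_frame,
                bouts[hi].end_frame,
                keep.label,
                keep.mean_tilt_ap_filtered,
            )
        ]
        bouts = _merge_adjacent(bouts)
    return bouts


def classify_recording(
    rec: TriaxialRecording, config: AlgoConfig | None = None
) -> BoutSequence:
    """Full pipeline: resample -> features -> profile -> detect -> label.

    Deterministic for fixed input and configuration.  Raw (non-uniform)
    recordings are PCHIP-resampled to ``config.sample_rate_hz`` first.
    """
    if config is None:
        config = AlgoConfig()
    if len(rec) < 2:
        raise LengthError("recording too short to classify")
    if not (rec.is_uniform() and abs(rec.nominal_rate - config.sample_rate_hz) < 1e-9):
        rec = resample_uniform(rec, config.sample_rate_hz)
    wfs = window_features(rec, config)
    profile = profile_candidate(wfs, config)
    flags = detect_upright_windows(wfs, profile, config)
    segments = extract_bouts(flags)
    seq = label_bouts(segments, wfs, config)
    if config.min_bout_s > 0:
        min_windows = int(round(config.min_bout_s * wfs.window_rate))
        bouts = _enforce_min_duration(seq.bouts, min_windows)
        seq = BoutSequence(bouts, window_rate=wfs.window_rate)
    return seq
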