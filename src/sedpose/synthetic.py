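"""Synthetic lower-back accelerometer signals with ground-truth annotations.

The simulator renders an activity script — an ordered list of posture
segments (sitting / lying / standing / walking) — as a triaxial acceleration
series the way an L5-mounted device would see it:

* each posture contributes a unit gravity vector in device axes (ax vertical,
  ay mediolateral, az anterior–posterior), slerp-interpolated across postural
  transitions;
* still postures carry small Gaussian noise (sensor noise, sway, breathing);
  walking adds a step-frequency sinusoid plus broadband noise so windowed
  movement intensity separates walking from still postures;
* synchronisation taps are short high-amplitude triphasic spikes;
* timestamps can be jittered to emulate clock drift, producing the
  non-uniform sampling that real exports show.

Ground truth is returned as an annotation track with standing and walking
collapsed to "upright" (an upright activity is anything done on the feet).
Transition time is split equally between the adjacent segments, i.e. truth
boundaries sit at the script boundaries.

Default orientations place the device per typical trunk postures: standing
nearly inverted-vertical (VT tilt 180 deg), sitting with posterior pelvic
tilt/recline (AP tilt ~50 deg), lying supine with gravity mostly along the
AP axis (AP tilt 20 deg).  These are assumptions — per-posture tilt
distributions of real cohorts are not published — and every orientation is
overridable per script or per segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import DataError
from .io import AnnotationTrack, TriaxialRecording

#: script labels; standing and walking collapse to "upright" in the truth track
SCRIPT_LABELS = ("sitting", "lying", "standing", "walking")

_TRUTH_LABEL = {
    "sitting": "sitting",
    "lying": "lying",
    "standing": "upright",
    "walking": "upright",
}


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if abs(n - 1.0) > 1e-6:
        raise ValueError(f"orientation {v.tolist()} is not unit-norm (|v|={n:.6f})")
    return v / n


def default_orientations() -> dict:
    """Per-posture unit gravity vectors in device axes (ax, ay, az)."""
    return {
        "standing": np.array([-1.0, 0.0, 0.0]),  # VT 180, ML 90, AP 90
        "walking": np.array([-1.0, 0.0, 0.0]),
        # trunk reclined ~50 deg AP: VT 140.4, AP 50.2
        "sitting": np.array([-0.77, 0.0, 0.64]) / np.linalg.norm([-0.77, 0.0, 0.64]),
        # supine, gravity along AP axis: VT 110, AP 20
        "lying": np.array([-math.sin(math.radians(20)), 0.0, math.cos(math.radians(20))]),
    }


@dataclass
class Segment:
    """One scripted activity: a label, a duration and an optional orientation."""

    label: str
    duration_s: float
    orientation: np.ndarray | None = None

    def __post_init__(self):
        if self.label not in SCRIPT_LABELS:
            raise ValueError(f"unknown segment label {self.label!r}")
        if self.duration_s <= 0:
            raise ValueError("segment duration must be positive")
        if self.orientation is not None:
            self.orientation = _unit(self.orientation)


@dataclass
class SimulationScript:
    """An activity script plus every signal-model parameter of the simulator.

    Noise levels are in g: ``still_noise_sd`` covers sensor noise and postural
    sway during still postures; walking segments carry ``walk_noise_sd``
    broadband noise plus a ``walk_swing_g`` sinusoid at ``step_freq_hz``
    (trunk accelerations at the step frequency).  ``transition_s`` is the
    duration of the slerp between posture orientations at each boundary.
    """

    segments: list
    orientations: dict = field(default_factory=default_orientations)
    still_noise_sd: float = 0.01
    walk_noise_sd: float = 0.05
    walk_swing_g: float = 0.15
    step_freq_hz: float = 1.9
    transition_s: float = 2.0
    tap_times: tuple = ()
    tap_amplitude_g: float = 4.0
    timestamp_jitter_sd: float = 0.001
    sample_rate_hz: float = 100.0
    seed: int | None = None

    def __post_init__(self):
        if not self.segments:
            raise ValueError("script has no segments")
        self.orientations = {k: _unit(v) for k, v in self.orientations.items()}
        for lab in SCRIPT_LABELS:
            if lab not in self.orientations:
                raise ValueError(f"no orientation for posture {lab!r}")
        if self.transition_s < 0:
            raise ValueError("transition_s must be non-negative")

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration_s for s in self.segments))

    def segment_orientation(self, seg: Segment) -> np.ndarray:
        return seg.orientation if seg.orientation is not None else self.orientations[seg.label]

    def truth(self) -> AnnotationTrack:
        """Ground-truth annotation: segment boundaries, upright collapsed."""
        ivs = []
        t = 0.0
        for seg in self.segments:
            lab = _TRUTH_LABEL[seg.label]
            if ivs and ivs[-1][2] == lab:
                ivs[-1] = (ivs[-1][0], t + seg.duration_s, lab)
            else:
                ivs.append((t, t + seg.duration_s, lab))
            t += seg.duration_s
        return AnnotationTrack(ivs, source="simulator")


def check_threshold_separability(
    script: SimulationScript,
    vt_standing_min: float = 150.0,
    ap_sitting_range: tuple = (40.0, 80.0),
    ap_lying_max: float = 40.0,
) -> None:
    """Assert the script's posture orientations are separable by tilt.

    Standing must have VT tilt >= 150 deg, sitting AP tilt inside (40, 80)
    deg and lying AP tilt < 40 deg — i.e. still postures land on the correct
    side of the classifier's fixed thresholds.  Raises ``ValueError`` if not.
    """

    def tilt(v, axis):
        return math.degrees(math.acos(np.clip(v[axis], -1.0, 1.0)))

    st = script.orientations["standing"]
    si = script.orientations["sitting"]
    ly = script.orientations["lying"]
    if tilt(st, 0) < vt_standing_min:
        raise ValueError(
            f"standing VT tilt {tilt(st, 0):.1f} deg below {vt_standing_min}"
        )
    ap_sit = tilt(si, 2)
    if not ap_sitting_range[0] < ap_sit < ap_sitting_range[1]:
        raise ValueError(
            f"sitting AP tilt {ap_sit:.1f} deg outside {ap_sitting_range}"
        )
    if tilt(ly, 2) >= ap_lying_max:
        raise ValueError(f"lying AP tilt {tilt(ly, 2):.1f} deg not below {ap_lying_max}")


# ---------------------------------------------------------------------------
# the scripted in-home validation protocol


def scripted_protocol(
    walk_s: float = 20.0,
    rng: np.random.Generator | None = None,
    **script_kwargs,
) -> SimulationScript:
    """The scripted in-home activity sequence used for validation.

    From standing, the wearer sits on a lounge chair for a minute, walks to
    the dining area and sits a minute, walks to the bedroom and lies supine a
    minute, sits up on the bed edge for about three seconds, stands a minute,
    walks dining-area -> bedroom -> lounge, sits a minute and finally stands
    a minute.  Three synchronisation taps ~1 s apart mark both ends.

    Walk-leg durations are not prescribed by the protocol (they depend on the
    home); ``walk_s`` sets them (20 s default, a comfortable indoor pace).
    If ``rng`` is given, segment durations are jittered around the nominal
    values with between-subject spreads typical of older-adult cohorts
    (sitting ~16 s SD, lying ~23 s SD), emulating cohort variability.
    """

    def dur(nominal, sd, floor):
        if rng is None:
            return float(nominal)
        return float(max(rng.normal(nominal, sd), floor))

    segments = [
        Segment("sitting", dur(60, 16, 25)),   # (a) lounge chair
        Segment("walking", dur(walk_s, 6, 6)),
        Segment("sitting", dur(60, 16, 25)),   # (b) dining chair
        Segment("walking", dur(walk_s, 6, 6)),
        Segment("lying", dur(60, 23, 25)),     # (c) supine on bed
        Segment("sitting", dur(3, 1, 2)),      # (d) bed edge, ~3 s
        Segment("standing", dur(60, 15, 20)),  # (d) beside bed
        Segment("walking", dur(walk_s, 6, 6)),  # (e)
        Segment("walking", dur(walk_s, 6, 6)),  # (f)
        Segment("walking", dur(walk_s, 6, 6)),  # (g)
        Segment("sitting", dur(60, 16, 25)),   # (h) lounge chair
        Segment("standing", dur(60, 15, 20)),  # (i) stand still
    ]
    total = sum(s.duration_s for s in segments)
    taps = (1.5, 2.5, 3.5, total - 3.5, total - 2.5, total - 1.5)
    return SimulationScript(segments=segments, tap_times=taps, **script_kwargs)


# ---------------------------------------------------------------------------
# rendering


def _slerp(u: np.ndarray, v: np.ndarray, frac: np.ndarray) -> np.ndarray:
    """Spherical interpolation between unit vectors, frac in [0, 1]."""
    dot = float(np.clip(np.dot(u, v), -1.0, 1.0))
    omega = math.acos(dot)
    if omega < 1e-9:
        return np.outer(np.ones_like(frac), u)
    so = math.sin(omega)
    return (
        np.outer(np.sin((1 - frac) * omega) / so, u)
        + np.outer(np.sin(frac * omega) / so, v)
    )


_TAP_SHAPE = np.array([2.0, -1.6, 1.2, -0.6, 0.25])  # triphasic, ~0.05 s


def simulate_recording(
    script: SimulationScript, seed: int | None = None
) -> tuple:
    """Render a script into a recording and its ground-truth annotation.

    Returns ``(TriaxialRecording, AnnotationTrack)``.  Deterministic for a
    fixed ``(script, seed)``; ``seed`` overrides ``script.seed``.
    """
    check_threshold_separability(script)
    rng = np.random.default_rng(seed if seed is not None else script.seed)
    rate = script.sample_rate_hz
    n = int(round(script.total_duration * rate))
    if n < 2:
        raise DataError("script renders to fewer than 2 samples")
    t = np.arange(n) / rate

    # per-sample segment index and per-segment boundaries
    bounds = np.cumsum([0.0] + [s.duration_s for s in script.segments])
    seg_idx = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, len(script.segments) - 1)

    # base gravity per sample: segment orientation, slerped across boundaries
    orients = [script.segment_orientation(s) for s in script.segments]
    acc = np.empty((n, 3))
    for i, o in enumerate(orients):
        acc[seg_idx == i] = o
    half = script.transition_s / 2.0
    if half > 0:
        for b, (u, v) in zip(bounds[1:-1], zip(orients, orients[1:])):
            lo, hi = b - half, b + half
            m = (t >= lo) & (t < hi)
            if m.any():
                frac = (t[m] - lo) / (hi - lo)
                acc[m] = _slerp(u, v, frac)

    # noise and gait oscillation
    for i, seg in enumerate(script.segments):
        m = seg_idx == i
        if seg.label == "walking":
            acc[m] += rng.normal(0.0, script.walk_noise_sd, size=(int(m.sum()), 3))
            phase = rng.uniform(0, 2 * math.pi)
            osc = np.sin(2 * math.pi * script.step_freq_hz * t[m] + phase)
            acc[m, 0] += script.walk_swing_g * osc
            acc[m, 2] += 0.5 * script.walk_swing_g * np.sin(
                4 * math.pi * script.step_freq_hz * t[m] + phase
            )
        else:
            acc[m] += rng.normal(0.0, script.still_noise_sd, size=(int(m.sum()), 3))

    # synchronisation taps: short triphasic spikes on the vertical axis
    for tap in script.tap_times:
        k = int(round(tap * rate))
        if 0 <= k < n - len(_TAP_SHAPE):
            acc[k : k + len(_TAP_SHAPE), 0] += script.tap_amplitude_g * _TAP_SHAPE

    # timestamp jitter (clock drift / non-uniform sampling)
    ts = t.copy()
    if script.timestamp_jitter_sd > 0:
        dt = 1.0 / rate
        jit = rng.normal(0.0, script.timestamp_jitter_sd, size=n)
        np.clip(jit, -0.4 * dt, 0.4 * dt, out=jit)
        ts = ts + jit
        ts[0] = 0.0

    rec = TriaxialRecording(ts, acc[:, 0], acc[:, 1], acc[:, 2], nominal_rate=rate)
    return rec, script.truth()


# ---------------------------------------------------------------------------
# script (de)serialisation


def script_from_yaml(path) -> SimulationScript:
    """Load a SimulationScript from YAML (see docs for the schema)."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict) or "segments" not in d:
        raise DataError(f"{path}: script YAML must contain a 'segments' list")
    try:
        segments = [
            Segment(
                label=s["label"],
                duration_s=float(s["duration_s"]),
                orientation=s.get("orientation"),
            )
            for s in d["segments"]
        ]
        kwargs = {k: v for k, v in d.items() if k != "segments"}
        if "orientations" in kwargs:
            kwargs["orientations"] = {
                k: np.asarray(v, dtype=float) for k, v in kwargs["orientations"].items()
            }
        if "tap_times" in kwargs:
            kwargs["tap_times"] = tuple(kwargs["tap_times"])
        return SimulationScript(segments=segments, **kwargs)
    except (KeyError, TypeError, ValueError) as exc:
        raise DataError(f"{path}: invalid script: {exc}") from exc


def script_to_yaml(script: SimulationScript, path) -> None:
    d = {
        "segments": [
            {
                "label": s.label,
                "duration_s": s.duration_s,
                **(
                    {"orientation": [float(x) for x in s.orientation]}
                    if s.orientation is not None
                    else {}
                ),
            }
            for s in script.segments
        ],
        "orientations": {
            k: [float(x) for x in v] for k, v in script.orientations.items()
        },
        "still_noise_sd": script.still_noise_sd,
        "walk_noise_sd": script.walk_noise_sd,
        "walk_swing_g": script.walk_swing_g,
        "step_freq_hz": script.step_freq_hz,
        "transition_s": script.transition_s,
        "tap_times": list(script.tap_times),
        "tap_amplitude_g": script.tap_amplitude_g,
        "timestamp_jitter_sd": script.timestamp_jitter_sd,
        "sample_rate_hz": script.sample_rate_hz,
        **({"seed": script.seed} if script.seed is not None else {}),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
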