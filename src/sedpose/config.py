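"""Algorithm configuration: every threshold and filter parameter in one place.

The posture classifier is semi-adaptive: a whole-recording profiling step
decides whether the wearer is an "upright-likely" candidate, which selects
between a movement-intensity (summed windowed SD) test and fixed tilt-angle
tests for detecting upright windows.  All thresholds below are degrees unless
noted; the defaults are the algorithm's published operating point.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass

import yaml


@dataclass
class AlgoConfig:
    # --- profiling thresholds (whole-recording mean filtered tilt, degrees)
    vt_upright_profile_deg: float = 150.0
    ml_upright_profile_deg: float = 90.0
    ap_upright_profile_deg: float = 90.0
    # --- per-window upright tests (degrees)
    vt_upright_window_deg: float = 140.0
    ap_upright_window_deg: float = 75.0
    # --- fixed bout-labelling thresholds (degrees) and adaptive lying ratio
    ap_lying_fixed_deg: float = 40.0
    ap_sitting_fixed_deg: float = 80.0
    lying_ratio: float = 2.5
    # --- signal conditioning
    sample_rate_hz: float = 100.0
    window_seconds: float = 0.1
    filter_order: int = 2
    accel_cutoff_hz: float = 17.0
    std_cutoff_hz: float = 1.0
    tilt_cutoff_hz: float = 0.25
    # --- behaviour switches
    #: "strict" marks upright-likely windows by the SD test alone (the
    #: published pseudocode); "gated" additionally requires the per-window
    #: tilt test, confirming upright bouts posturally.
    mode: str = "gated"
    #: minimum bout duration in seconds; shorter bouts are absorbed into the
    #: longer neighbour. 0 disables the pass.
    min_bout_s: float = 0.0

    def __post_init__(self):
        for name in (
            "vt_upright_profile_deg",
            "ml_upright_profile_deg",
            "ap_upright_profile_deg",
            "vt_upright_window_deg",
            "ap_upright_window_deg",
            "ap_lying_fixed_deg",
            "ap_sitting_fixed_deg",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 180.0:
                raise ValueError(f"{name}={v} must lie in (0, 180) degrees")
        if self.lying_ratio <= 1.0:
            raise ValueError("lying_ratio must exceed 1")
        if self.ap_lying_fixed_deg >= self.ap_sitting_fixed_deg:
            raise ValueError("ap_lying_fixed_deg must be below ap_sitting_fixed_deg")
        if self.mode not in ("strict", "gated"):
            raise ValueError(f"mode must be 'strict' or 'gated', got {self.mode!r}")
        if self.window_seconds <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("window_seconds and sample_rate_hz must be positive")

    @property
    def samples_per_window(self) -> int:
        return int(round(self.window_seconds * self.sample_rate_hz))

    @property
    def window_rate(self) -> float:
        """Feature-series rate in windows per second (10 Hz by default)."""
        return 1.0 / self.window_seconds

    # --- (de)serialisation ------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AlgoConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AlgoConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable SHA-256 hash of the configuration (for run manifests)."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()
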