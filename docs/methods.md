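# Methods

## The classification model

`sedpose` detects sedentary behaviour — sitting and lying, as distinct from
upright (standing/walking) activity — from a single triaxial accelerometer
worn on the lower back (L5), sampled nominally at 100 Hz with the axis
convention *ax* vertical, *ay* mediolateral (ML), *az* anterior–posterior
(AP). The algorithm is posture-first: it relies on the orientation of gravity
in the device frame (tilt angles) rather than movement intensity, and looks
for sedentary bouts *between* detected upright bouts.

### Signal conditioning

Raw recordings have non-uniform timestamps (real-time-clock drift); they are
resampled to a uniform 100 Hz grid with shape-preserving piecewise-cubic
Hermite interpolation (PCHIP — monotone, no overshoot), anchored at the first
timestamp and clipped to the recorded span (no extrapolation).

Two parallel signal paths follow, both through a 2nd-order zero-phase
(forward–backward) Butterworth low-pass at 17 Hz:

* **movement intensity** — each axis has its mean subtracted (offset removal)
  before filtering; per non-overlapping 0.1 s window (10 samples) the three
  axis standard deviations (sample SD, ddof = 1) are summed into `std_sum`,
  which is then low-passed at 1 Hz;
* **posture** — the *unshifted* filtered axes keep the gravity component;
  per window the tilt of each axis against the total acceleration vector is
  `arccos(x/|a|)·180/π` ∈ [0°, 180°], computed on the window-mean vector
  (stabler than per-sample arccos near zero magnitude; the difference is far
  below the 0.25 Hz filter's resolution). Tilt series are low-passed at
  0.25 Hz.

The two paths are deliberate: offset removal destroys gravity, and the tilt
thresholds below (e.g. VT ≥ 150°) are only meaningful on gravity-bearing
signal. The secondary 1 Hz / 0.25 Hz filters run at the 10 Hz window rate,
since they apply to window-level series. Filtered tilts are clipped to
[0°, 180°]; the filtered SD sum is left unclipped (it may ring marginally
negative near sharp transients) so that the production path stays exactly
equivalent to a plain transcription of the algorithm.

### Semi-adaptive classification

1. **Candidate profiling.** The wearer is *upright-likely* iff
   `ceil(mean VT_f) ≥ 150` **and** `ceil(mean ML_f) ≥ 90` **and**
   `ceil(mean AP_f) ≥ 90` (whole-recording means, degrees). The ceiling makes
   each test pass for means within 1° below its threshold. The prose form of
   the algorithm makes clear that this three-way test selects *which* upright
   detector runs; we implement it that way (a strictly literal reading of the
   nested pseudocode would detect nothing when only the VT test passes).
2. **Upright-window detection.**
   *Upright-likely*: window *w* is potentially upright iff
   `std_sum_f[w] ≥ mean(std_sum_f)` (whole-recording mean — it is the same
   quantity the profiling step already computes). This is mode `strict`, the
   published rule; it is known to misclassify still standing, which carries
   no postural information. Mode `gated` (the default) additionally requires
   the window tilt test below, confirming upright bouts posturally.
   *Otherwise*: fixed tilt tests, `VT_f[w] ≥ 140` and `AP_f[w] ≥ 75`.
   The window-level tests use the raw comparators (no ceiling), exactly as
   published; ties resolve on the ≥ side.
3. **Bout labelling.** Maximal runs of flagged windows are potential upright
   bouts; the gaps (including leading/trailing runs) are non-upright
   segments; indices are half-open. Each potential upright bout is labelled
   from its mean filtered AP tilt: `< 40°` → lying, `< 80°` → sitting, else
   confirmed upright. Each non-upright segment is labelled against the
   *preceding confirmed* upright bout's mean AP: below `preceding/2.5` →
   lying, below `preceding` → sitting, else upright. Demoted candidates
   (relabelled sitting/lying) do not become the adaptive reference. Segments
   before the first confirmed upright bout fall back to the fixed 40°/80°
   rule, the algorithm's own fallback for candidate bouts. Adjacent
   same-label bouts merge; postural transitions are absorbed into the
   enclosing non-upright bout (so lying durations include the sit-to-lie and
   lie-to-sit transitions — a known overestimation of lying).

No minimum bout duration is imposed by default; `min_bout_s` (default 0 s)
optionally absorbs shorter bouts into their longer neighbour.

### Parameters that matter

| key | default | meaning |
|---|---|---|
| `vt/ml/ap_upright_profile_deg` | 150/90/90° | profiling thresholds on mean filtered tilt |
| `vt_upright_window_deg`, `ap_upright_window_deg` | 140°, 75° | fixed per-window upright tests |
| `ap_lying_fixed_deg`, `ap_sitting_fixed_deg` | 40°, 80° | fixed AP labelling rule |
| `lying_ratio` | 2.5 | adaptive lying rule: AP below preceding-upright/2.5 |
| `accel/std/tilt_cutoff_hz` | 17/1/0.25 Hz | Butterworth cut-offs (order 2, two-pass) |
| `window_seconds` | 0.1 s | feature window (10 samples at 100 Hz) |
| `mode` | `gated` | `strict` = published SD-only upright rule |

## Agreement statistics

Validation against a gold-standard annotation uses frame-level confusion at
0.01 s resolution (one frame per sample at 100 Hz; frames assigned by
half-open membership of the frame start time), summarised one-vs-rest per
class as sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP) and
NPV TN/(TN+FN); ratios with zero denominators are returned as NaN and
flagged. Frames are pooled across subjects (per-subject reports remain
available by evaluating each pair separately).

ICC(2,1) — single-measure, absolute-agreement, two-way random effects — is
computed from the ANOVA mean squares,
`(MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))`; a zero-variance matrix
returns 1 with a degeneracy flag. Bland–Altman uses signed differences
algorithm − reference, bias ± 1.96·SD (sample SD; the classical multiplier,
not a t-quantile). AE = mean |R−A| and APE = 100·mean(|R−A|/R) are computed
over matched bouts; since no pairing rule is inherent to the definitions,
predicted bouts are matched to reference bouts of the same class by greatest
temporal overlap, each predicted bout used at most once, and unmatched
reference bouts are excluded but counted in the report.

## The synthetic signal generator

The simulator renders activity scripts as gravity-plus-noise signals: per
posture a unit gravity vector in device axes, slerp-interpolated over 2 s
postural transitions (transition time split equally between neighbours, so
truth boundaries sit at script boundaries); Gaussian noise of 0.01 g SD for
still postures (sensor noise, sway, breathing); walking adds 0.05 g
broadband noise plus a 0.15 g sinusoid at 1.9 Hz (an older-adult step
frequency) so windowed SD separates walking from still postures by a factor
well above 5; synchronisation taps are 0.05 s triphasic spikes of ±4 g on
the vertical axis; timestamps are jittered (SD 1 ms, clipped to keep order)
to emulate clock drift.

Default orientations — standing (−1, 0, 0) (VT 180°), sitting reclined
(−0.77, 0, 0.64)/|·| (AP ≈ 50°), lying supine (−sin 20°, 0, cos 20°)
(AP = 20°) — are *assumptions*: real per-posture tilt distributions for this
sensor placement are not published. They are chosen to be separable by the
classifier's own fixed thresholds, a property asserted at simulation time
and overridable per script. The bundled scripted protocol reproduces the
in-home validation sequence (lounge sit 1 min, walk, dining sit 1 min, walk,
supine lie 1 min, 3 s bed-edge sit, stand 1 min, three walk legs, lounge sit
1 min, stand 1 min, taps at both ends); walk legs default to 20 s, a
comfortable indoor pace, since home geometry is not prescribed. An optional
RNG jitters segment durations with between-subject spreads typical of
older-adult cohorts (sitting ±16 s, lying ±23 s) to emulate cohort
variability for ICC/Bland–Altman studies.

What the simulator does **not** model: realistic gait kinematics, soft-tissue
artefact, gyroscope channels, annotation (video-coder) error, or free-living
behaviour. Passing simulation-recovery tests therefore demonstrates internal
consistency of pipeline + thresholds under the stated signal model, not
field accuracy on real recordings.

## Numerical choices and degenerate inputs

* Zero-phase filtering pads by even extension, padlen = 3 filter lengths
  (9 samples for order 2); series must exceed the pad length, so feature
  extraction needs ≥ 1 s of signal (10 windows).
* Zero-magnitude window vectors (possible only in degenerate synthetic
  input) inherit the previous window's tilt, or 90° for a leading window.
* Fractional-day timestamps convert exactly for integer sample offsets
  (n/8 640 000 days ↔ n·0.01 s within 1e-9).
* Intervals are half-open `[start, end)` throughout, removing double counting
  at bout boundaries; time origin is the first sample.
* Tap detection — the device is simply "tapped three times" in protocol
  descriptions, with no published detector — is defined operationally:
  0.1 s-window summed SD exceeding 8× its median (configurable, with a
  0.05 g floor for noise-free signals), peaks grouped within 0.3 s, and the
  first run of the expected count matching the nominal 1 s spacing within
  tolerance is returned.

## Problem sizes used in the test and acceptance runs

Simulation-based checks use 2-minute random scripts (algorithm-fidelity
oracle, 20 recordings), the full ~7.7 min scripted protocol across 10 seeds
(recovery test), and a 12-subject jittered cohort in `scripts/acceptance.py`
(~560k scored frames). These sizes give stable statistics while keeping the
whole suite in seconds on one CPU.

## Known limitations

* The strict (published) upright-likely rule misses still standing by
  construction; the gated default mitigates but changes the published rule —
  both are available and logged.
* Lying durations absorb postural transitions and the brief bed-edge sit,
  overestimating lying — visible in the positive lying bias of the
  acceptance report, mirroring the algorithm's known behaviour.
* The adaptive rule is undefined before the first confirmed upright bout;
  the fixed-threshold fallback is a design choice.
* Whole-recording means (profiling, SD threshold) make the classifier
  sensitive to recording length and composition; it is not an online
  algorithm.
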