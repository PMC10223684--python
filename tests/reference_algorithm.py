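"""Independent, deliberately plain re-implementation of the bout algorithm.

This interpreter follows the published pseudocode step by step with explicit
Python loops — no shared code with sedpose.classify/features beyond scipy's
Butterworth filter.  It exists as an oracle: the production classifier in
"strict" mode must produce the identical bout sequence.

Interpretation choices mirror the documented ones (they are forced by
ambiguities in the pseudocode, see docs/methods.md): offset removal feeds
only the SD path; tilt angles use the window-mean filtered gravity vector;
windows are non-overlapping; the profiling test selects the SD branch only
when all three ceiling(mean tilt) tests pass, otherwise the fixed tilt-window
branch runs; segments before the first confirmed upright bout fall back to
the fixed 40/80 degree rule.
"""

import math

import numpy as np
from scipy.signal import butter, filtfilt


def _butterworth(series, order, cutoff, rate):
    b, a = butter(order, cutoff, fs=rate)
    return filtfilt(b, a, series, padtype="even", padlen=3 * max(len(a), len(b)))


def reference_classify(ax, ay, az, rate=100.0):
    """Label bouts for a uniform 100 Hz recording; returns (start, end, label)
    window-index triples (half-open, 0.1 s windows)."""
    ax, ay, az = (np.asarray(v, dtype=float) for v in (ax, ay, az))

    # data preparation: offset removal (SD path) and 17 Hz two-pass filtering
    axf_sd = _butterworth(ax - ax.mean(), 2, 17.0, rate)
    ayf_sd = _butterworth(ay - ay.mean(), 2, 17.0, rate)
    azf_sd = _butterworth(az - az.mean(), 2, 17.0, rate)
    axf = _butterworth(ax, 2, 17.0, rate)
    ayf = _butterworth(ay, 2, 17.0, rate)
    azf = _butterworth(az, 2, 17.0, rate)

    w = int(round(0.1 * rate))
    n_win = len(ax) // w
    std_sum = np.empty(n_win)
    tilt_vt = np.empty(n_win)
    tilt_ml = np.empty(n_win)
    tilt_ap = np.empty(n_win)
    prev = (90.0, 90.0, 90.0)
    for i in range(n_win):
        sl = slice(i * w, (i + 1) * w)
        std_ax = np.std(axf_sd[sl], ddof=1)
        std_ay = np.std(ayf_sd[sl], ddof=1)
        std_az = np.std(azf_sd[sl], ddof=1)
        std_sum[i] = std_ax + std_ay + std_az
        mx, my, mz = axf[sl].mean(), ayf[sl].mean(), azf[sl].mean()
        norm = math.sqrt(mx * mx + my * my + mz * mz)
        if norm == 0.0:
            tilt_vt[i], tilt_ml[i], tilt_ap[i] = prev
        else:
            tilt_vt[i] = math.degrees(math.acos(max(-1.0, min(1.0, mx / norm))))
            tilt_ml[i] = math.degrees(math.acos(max(-1.0, min(1.0, my / norm))))
            tilt_ap[i] = math.degrees(math.acos(max(-1.0, min(1.0, mz / norm))))
            prev = (tilt_vt[i], tilt_ml[i], tilt_ap[i])

    std_sum_f = _butterworth(std_sum, 2, 1.0, 10.0)
    vt_f = np.clip(_butterworth(tilt_vt, 2, 0.25, 10.0), 0.0, 180.0)
    ml_f = np.clip(_butterworth(tilt_ml, 2, 0.25, 10.0), 0.0, 180.0)
    ap_f = np.clip(_butterworth(tilt_ap, 2, 0.25, 10.0), 0.0, 180.0)

    # classification: candidate profiling selects the upright-window test
    upright = np.zeros(n_win, dtype=bool)
    if (
        math.ceil(np.mean(vt_f)) >= 150
        and math.ceil(np.mean(ml_f)) >= 90
        and math.ceil(np.mean(ap_f)) >= 90
    ):
        mean_std = np.mean(std_sum_f)
        for i in range(n_win):
            if std_sum_f[i] >= mean_std:
                upright[i] = True
    else:
        for i in range(n_win):
            if vt_f[i] >= 140 and ap_f[i] >= 75:
                upright[i] = True

    # detection: potential upright bouts and the gaps between them
    segments = []  # (start, end, is_candidate)
    i = 0
    while i < n_win:
        j = i
        while j < n_win and upright[j] == upright[i]:
            j += 1
        segments.append((i, j, bool(upright[i])))
        i = j

    labelled = []
    preceding_ap = None
    for start, end, cand in segments:
        mean_ap = float(np.mean(ap_f[start:end]))
        if cand:
            if mean_ap < 40:
                lab = "lying"
            elif mean_ap < 80:
                lab = "sitting"
            else:
                lab = "upright"
                preceding_ap = mean_ap
        else:
            if preceding_ap is None:
                lab = "lying" if mean_ap < 40 else ("sitting" if mean_ap < 80 else "upright")
            elif mean_ap < preceding_ap / 2.5:
                lab = "lying"
            elif mean_ap < preceding_ap:
                lab = "sitting"
            else:
                lab = "upright"
        labelled.append((start, end, lab))

    merged = [labelled[0]]
    for s, e, lab in labelled[1:]:
        ps, pe, plab = merged[-1]
        if lab == plab:
            merged[-1] = (ps, e, lab)
        else:
            merged.append((s, e, lab))
    return merged
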