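"""Hybrid R-peak detection.

The detector combines the classic adaptive-threshold energy pipeline
(derivative, squaring, 150-ms moving-window integration, running signal/noise
peak estimates with eighths-rule updates, a 200-ms refractory period and a
search-back at 1.66x the running mean RR) with a valley-peak refinement step:
each candidate from the integrated signal is shifted back by the integrator
group delay and snapped to the extremum of the bandpassed signal inside a
+/-50 ms window, then required to have an adjacent opposite-sign deflection
(the S valley) within 75 ms, which suppresses tall T waves.

All thresholds are relative to the running peak estimates, so the peak set is
invariant to positive amplitude scaling. Window lengths are specified in
milliseconds and converted with ``round(ms * fs / 1000)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .io import EcgRecord

__all__ = ["RPeakResult", "detect_rpeaks", "match_annotations"]


@dataclass
class RPeakResult:
    """Detected R peaks (strictly increasing sample indices) and mean RR (s)."""

    peaks: np.ndarray
    mean_rr: float
    fs: float

    def __len__(self) -> int:
        return int(self.peaks.size)


def _ms(ms: float, fs: float) -> int:
    return int(round(ms * fs / 1000.0))


def detect_rpeaks(
    rec: EcgRecord,
    *,
    refractory_ms: float = 200.0,
    integration_ms: float = 150.0,
    refine_ms: float = 50.0,
    valley_ms: float = 75.0,
    use_abs: bool = False,
) -> RPeakResult:
    """Detect R peaks in a bandpass-filtered record.

    ``use_abs=True`` rectifies the signal first, for leads with inverted QRS
    polarity; by default the detector assumes an upright R wave.
    """
    fs = rec.fs
    x = rec.samples
    n = x.size
    if n < 2 * fs:
        raise ValueError(f"record too short for R-peak detection: {n / fs:.2f} s < 2 s")
    sig = np.abs(x) if use_abs else x

    # energy pipeline: derivative -> squaring -> moving-window integration
    deriv = np.diff(sig, prepend=sig[0])
    sq = deriv * deriv
    w = max(_ms(integration_ms, fs), 1)
    mwi = np.convolve(sq, np.ones(w) / w, mode="full")[:n]
    if mwi.max() <= 0.0:
        return RPeakResult(np.array([], dtype=np.int64), float("nan"), fs)

    cand, _ = find_peaks(mwi)
    if cand.size == 0:
        return RPeakResult(np.array([], dtype=np.int64), float("nan"), fs)
    refractory = max(_ms(refractory_ms, fs), 1)

    # adaptive dual thresholds seeded from the first two seconds
    init = mwi[: int(2 * fs)]
    spki = float(init.max())
    npki = float(init.mean())
    thr1 = npki + 0.25 * (spki - npki)

    accepted: list[int] = []
    rr_hist: list[float] = []
    rejected: list[tuple[int, float]] = []  # below-threshold candidates, for search-back

    def accept(c: int, v: float, weight: float) -> None:
        nonlocal spki
        if accepted:
            rr_hist.append(c - accepted[-1])
            if len(rr_hist) > 8:
                rr_hist.pop(0)
        accepted.append(c)
        spki = weight * v + (1 - weight) * spki

    for c in cand:
        v = float(mwi[c])
        if accepted and c - accepted[-1] < refractory:
            continue
        # search-back: a long gap since the last beat re-examines sub-threshold
        # candidates against the lower threshold thr2 = 0.5 * thr1
        if accepted and rr_hist:
            mean_rr = float(np.mean(rr_hist))
            if c - accepted[-1] > 1.66 * mean_rr:
                gap = [
                    (cc, vv)
                    for cc, vv in rejected
                    if accepted[-1] + refractory <= cc <= c - refractory
                    and vv > 0.5 * thr1
                ]
                if gap:
                    cb, vb = max(gap, key=lambda p: p[1])
                    accept(cb, vb, 0.25)
        if v > thr1:
            accept(int(c), v, 0.125)
        else:
            npki = 0.125 * v + 0.875 * npki
            rejected.append((int(c), v))
        thr1 = npki + 0.25 * (spki - npki)

    if not accepted:
        return RPeakResult(np.array([], dtype=np.int64), float("nan"), fs)

    # valley-peak refinement on the bandpassed signal: the integrated peak can
    # sit anywhere on the plateau [R, R + w], so the shifting search window
    # spans the full integration support plus the +/-50 ms refinement margin
    half = max(_ms(refine_ms, fs), 1)
    vwin = max(_ms(valley_ms, fs), 1)
    refined: list[int] = []
    for c in sorted(set(accepted)):
        lo = max(c - w - half, 0)
        hi = min(c + half + 1, n)
        if lo >= hi:
            continue
        p = lo + int(np.argmax(sig[lo:hi]))
        # require an adjacent opposite-sign deflection (the S valley) unless
        # operating on the rectified signal
        if not use_abs:
            vlo = max(p - vwin, 0)
            vhi = min(p + vwin + 1, n)
            opposite = float(np.min(x[vlo:vhi])) if x[p] > 0 else float(np.max(x[vlo:vhi]))
            if not (np.sign(opposite) == -np.sign(x[p]) and abs(opposite) >= 0.05 * abs(x[p])):
                continue
        refined.append(p)

    # deduplicate and enforce the refractory period, keeping the larger peak
    peaks: list[int] = []
    for p in sorted(set(refined)):
        if peaks and p - peaks[-1] < refractory:
            if abs(sig[p]) > abs(sig[peaks[-1]]):
                peaks[-1] = p
        else:
            peaks.append(p)

    arr = np.array(peaks, dtype=np.int64)
    mean_rr = float(np.mean(np.diff(arr)) / fs) if arr.size >= 2 else float("nan")
    return RPeakResult(arr, mean_rr, fs)


def match_annotations(
    detected: RPeakResult | np.ndarray,
    truth: np.ndarray,
    tol_ms: float = 50.0,
    fs: float | None = None,
) -> tuple[float, float]:
    """Greedy one-to-one matching of detections to annotated peaks.

    Returns ``(TPR, FP rate)`` where TPR = matched / |truth| and the
    false-positive rate = unmatched detections / |detected|.
    """
    if isinstance(detected, RPeakResult):
        det = np.asarray(detected.peaks, dtype=np.int64)
        fs = detected.fs if fs is None else fs
    else:
        det = np.asarray(detected, dtype=np.int64)
        if fs is None:
            raise ValueError("fs required when detections are a bare index array")
    truth = np.asarray(truth, dtype=np.int64)
    tol = tol_ms * fs / 1000.0
    used = np.zeros(det.size, dtype=bool)
    matched = 0
    for t in truth:
        if det.size == 0:
            break
        dist = np.abs(det - t).astype(float)
        dist[used] = np.inf
        j = int(np.argmin(dist))
        if dist[j] <= tol:
            used[j] = True
            matched += 1
    tpr = matched / truth.size if truth.size else 0.0
    fp = (det.size - matched) / det.size if det.size else 0.0
    return tpr, fp
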