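"""Fiducial landmark detection and interval/amplitude/angle features.

Landmarks are located by constrained extremum search inside an 800-ms beat
window whose centre is the R peak: Q and S are the minima of the 150-ms window
centred on R (left and right halves), P is the maximum within 200 ms before R
(outside the QRS region) and T the maximum within 400 ms after it. Wave
onsets/offsets come from the triangle rule: inside a bounded search window the
boundary is the sample farthest (perpendicular distance) from the chord
joining the wave peak to the window's far end.

Intervals whose right endpoint is the T wave or a T boundary are heart-rate
corrected with the Framingham formula, QTc = QT + 0.154 * (1 - RR).

Three nested feature sets are available:

========  ==========================  ========================  =========
mode      temporal                    amplitude                 angle
========  ==========================  ========================  =========
ML3       T3, T4                      V1, V2, V7                A5
ML5       T3-T6, T11, T12, T15        V1-V4, V7                 A3-A5
ML9       T1-T15                      V1-V7                     A1-A6
========  ==========================  ========================  =========

The catalogue (a package convention; the landmark-set cardinalities are the
contract): T1 = P width, T2 = T width*, T3 = QR, T4 = RS, T5 = PR, T6 = RT*,
T7 = Pon-R, T8 = R-Toff*, T9 = Poff-Q, T10 = S-Ton*, T11 = PQ, T12 = ST*,
T13 = Pon-Q, T14 = S-Toff*, T15 = PT* (* = Framingham-scaled). Amplitudes are
relative to the beat baseline (mean of the first 50 ms): V1 = R-Q, V2 = R-S,
V3 = P-b, V4 = T-b, V5 = Pon-b, V6 = Toff-b, V7 = R-b. Angles are interior
angles at the named vertex in the (time in ms, amplitude in mV x 10) plane:
A1 at P (Pon-P-Poff), A2 at T (Ton-T-Toff), A3 at P (window start-P-Q),
A4 at T (S-T-window end), A5 at R (Q-R-S), A6 at S (R-S-T).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FiducialPoints",
    "FiducialFeatureVector",
    "detect_extrema",
    "detect_boundaries",
    "framingham_scale",
    "extract_features",
    "features_for_beats",
    "FEATURE_NAMES",
]

#: amplitude axis scaling used for angle computation (mV -> dimensionless y)
_ANGLE_AMP_SCALE = 10.0
#: time axis for angle computation is milliseconds

FEATURE_NAMES: dict[str, list[str]] = {
    "ml3": ["T3", "T4", "V1", "V2", "V7", "A5"],
    "ml5": [
        "T3", "T4", "T5", "T6", "T11", "T12", "T15",
        "V1", "V2", "V3", "V4", "V7",
        "A3", "A4", "A5",
    ],
    "ml9": [
        *(f"T{i}" for i in range(1, 16)),
        *(f"V{i}" for i in range(1, 8)),
        *(f"A{i}" for i in range(1, 7)),
    ],
}

#: intervals with a T-wave (or T-boundary) right endpoint get Framingham scaling
_SCALED = {"T2", "T6", "T8", "T10", "T12", "T14", "T15"}


@dataclass
class FiducialPoints:
    """Sample indices (within the beat window) and amplitudes of landmarks."""

    indices: dict[str, int]
    amplitudes: dict[str, float]
    boundaries: dict[str, int | None] = field(default_factory=dict)

    def require(self, names: list[str]) -> None:
        for name in names:
            where = self.indices if not name.endswith(("_on", "_off")) else self.boundaries
            if where.get(name) is None:
                raise ValueError(f"required fiducial point {name!r} is missing")


@dataclass
class FiducialFeatureVector:
    """Named feature values for one beat, in catalogue order for its mode."""

    values: np.ndarray
    names: list[str]
    mode: str
    rr: float

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


def _ms(ms: float, fs: float) -> int:
    return int(round(ms * fs / 1000.0))


def detect_extrema(beat: np.ndarray, fs: float) -> FiducialPoints:
    """Locate P, Q, R, S, T inside an 800-ms beat window centred on R."""
    beat = np.asarray(beat, dtype=np.float64)
    if np.ptp(beat) == 0.0:
        raise ValueError("no extrema: beat is flat")
    n = beat.size
    c = n // 2

    def argext(lo: int, hi: int, kind: str) -> int:
        lo = max(lo, 0)
        hi = min(hi, n)
        if lo >= hi:
            raise ValueError("no extrema: empty search window")
        seg = beat[lo:hi]
        off = int(np.argmax(seg)) if kind == "max" else int(np.argmin(seg))
        return lo + off

    q = argext(c - _ms(75, fs), c, "min")
    s = argext(c + 1, c + _ms(75, fs) + 1, "min")
    p = argext(c - _ms(200, fs), c - _ms(75, fs), "max")
    t = argext(c + _ms(75, fs) + 1, c + _ms(400, fs) + 1, "max")
    idx = {"P": p, "Q": q, "R": c, "S": s, "T": t}
    amp = {k: float(beat[v]) for k, v in idx.items()}
    return FiducialPoints(indices=idx, amplitudes=amp)


def _triangle_point(beat: np.ndarray, fs: float, peak: int, far: int) -> int | None:
    """Sample in (min, max) of [peak, far] farthest from the peak-far chord."""
    lo, hi = (peak, far) if peak <= far else (far, peak)
    lo = max(lo, 0)
    hi = min(hi, beat.size - 1)
    if hi - lo < 2:
        return None
    ts = np.arange(lo, hi + 1) * 1000.0 / fs
    ys = beat[lo : hi + 1] * _ANGLE_AMP_SCALE
    a = np.array([ts[0], ys[0]])
    b = np.array([ts[-1], ys[-1]])
    ab = b - a
    norm = np.hypot(*ab)
    if norm == 0.0:
        return None
    # perpendicular distance of each interior point to the chord a-b
    rel_t = ts[1:-1] - a[0]
    rel_y = ys[1:-1] - a[1]
    dist = np.abs(ab[0] * rel_y - ab[1] * rel_t) / norm
    if not np.any(dist > 0):
        return None  # flat window: no triangle
    return lo + 1 + int(np.argmax(dist))


def detect_boundaries(beat: np.ndarray, fp: FiducialPoints, fs: float) -> FiducialPoints:
    """Attach P/T wave onsets and offsets found by the triangle rule.

    Search windows: P_on in [P - 100 ms, P], P_off in [P, P + 100 ms],
    T_on in [T - 150 ms, T], T_off in [T, T + 200 ms]. A boundary whose window
    collapses after clipping (or is flat) is marked missing (None).
    """
    beat = np.asarray(beat, dtype=np.float64)
    fp.require(["P", "T"])
    p, t = fp.indices["P"], fp.indices["T"]
    windows = {
        "P_on": (p, p - _ms(100, fs)),
        "P_off": (p, p + _ms(100, fs)),
        "T_on": (t, t - _ms(150, fs)),
        "T_off": (t, t + _ms(200, fs)),
    }
    for name, (peak, far) in windows.items():
        fp.boundaries[name] = _triangle_point(beat, fs, peak, far)
    return fp


def framingham_scale(ti: float, trr: float) -> float:
    """Heart-rate correct a QT-type interval: Ti + 0.154 * (1 - Trr)."""
    return ti + 0.154 * (1.0 - trr)


def _angle_deg(a: tuple[float, float], x: tuple[float, float], b: tuple[float, float]) -> float:
    v1 = np.array(a) - np.array(x)
    v2 = np.array(b) - np.array(x)
    n1 = np.hypot(*v1)
    n2 = np.hypot(*v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    cosang = np.clip(float(v1 @ v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def extract_features(
    fp: FiducialPoints,
    beat: np.ndarray,
    fs: float,
    rr: float,
    mode: str = "ml5",
) -> FiducialFeatureVector:
    """Assemble the feature vector for one beat.

    ``rr`` is the beat's RR interval in seconds (used by the Framingham
    correction). ``mode`` selects the nested catalogue: ``ml3`` needs Q, R, S;
    ``ml5`` adds P and T; ``ml9`` additionally needs the four wave boundaries.
    """
    mode = mode.lower()
    if mode not in FEATURE_NAMES:
        raise ValueError(f"unknown feature mode {mode!r}; expected ml3/ml5/ml9")
    beat = np.asarray(beat, dtype=np.float64)
    needed = {"ml3": ["Q", "R", "S"], "ml5": ["P", "Q", "R", "S", "T"],
              "ml9": ["P", "Q", "R", "S", "T", "P_on", "P_off", "T_on", "T_off"]}[mode]
    fp.require(needed)

    n = beat.size
    idx = dict(fp.indices)
    for bname, bval in fp.boundaries.items():
        if bval is not None:
            idx[bname] = bval
    baseline = float(beat[: max(_ms(50, fs), 1)].mean())

    def sec(a: str, b: str) -> float:
        return abs(idx[b] - idx[a]) / fs

    def pt(name: str) -> tuple[float, float]:
        i = idx[name]
        return (i * 1000.0 / fs, beat[i] * _ANGLE_AMP_SCALE)

    start = (0.0, beat[0] * _ANGLE_AMP_SCALE)
    end = ((n - 1) * 1000.0 / fs, beat[n - 1] * _ANGLE_AMP_SCALE)

    raw: dict[str, float] = {}
    # temporal catalogue (seconds)
    pairs = {
        "T1": ("P_on", "P_off"), "T2": ("T_on", "T_off"), "T3": ("Q", "R"),
        "T4": ("R", "S"), "T5": ("P", "R"), "T6": ("R", "T"), "T7": ("P_on", "R"),
        "T8": ("R", "T_off"), "T9": ("P_off", "Q"), "T10": ("S", "T_on"),
        "T11": ("P", "Q"), "T12": ("S", "T"), "T13": ("P_on", "Q"),
        "T14": ("S", "T_off"), "T15": ("P", "T"),
    }
    wanted = set(FEATURE_NAMES[mode])
    for name, (a, b) in pairs.items():
        if name in wanted:
            v = sec(a, b)
            raw[name] = framingham_scale(v, rr) if name in _SCALED else v
    # amplitude catalogue (mV)
    amp_defs = {
        "V1": lambda: beat[idx["R"]] - beat[idx["Q"]],
        "V2": lambda: beat[idx["R"]] - beat[idx["S"]],
        "V3": lambda: beat[idx["P"]] - baseline,
        "V4": lambda: beat[idx["T"]] - baseline,
        "V5": lambda: beat[idx["P_on"]] - baseline,
        "V6": lambda: beat[idx["T_off"]] - baseline,
        "V7": lambda: beat[idx["R"]] - baseline,
    }
    for name, f in amp_defs.items():
        if name in wanted:
            raw[name] = float(f())
    # angle catalogue (degrees)
    ang_defs = {
        "A1": lambda: _angle_deg(pt("P_on"), pt("P"), pt("P_off")),
        "A2": lambda: _angle_deg(pt("T_on"), pt("T"), pt("T_off")),
        "A3": lambda: _angle_deg(start, pt("P"), pt("Q")),
        "A4": lambda: _angle_deg(pt("S"), pt("T"), end),
        "A5": lambda: _angle_deg(pt("Q"), pt("R"), pt("S")),
        "A6": lambda: _angle_deg(pt("R"), pt("S"), pt("T")),
    }
    for name, f in ang_defs.items():
        if name in wanted:
            raw[name] = f()

    names = FEATURE_NAMES[mode]
    values = np.array([raw[name] for name in names])
    return FiducialFeatureVector(values=values, names=names, mode=mode, rr=rr)


def features_for_beats(
    beats: np.ndarray, fs: float, rrs: np.ndarray, mode: str = "ml5"
) -> pd.DataFrame:
    """Feature matrix (one row per beat) with catalogue-named columns.

    Beats on which a required landmark cannot be found (e.g. a wave boundary
    in a flat window, in ml9 mode) are skipped; an error is raised only when
    no beat yields a feature row.
    """
    rows = []
    errors = []
    for beat, rr in zip(beats, rrs):
        try:
            fp = detect_extrema(beat, fs)
            if mode.lower() == "ml9":
                fp = detect_boundaries(beat, fp, fs)
            rows.append(extract_features(fp, beat, fs, rr, mode).values)
        except ValueError as exc:
            errors.append(str(exc))
    if not rows:
        raise ValueError(f"no beat yielded features: {errors[0] if errors else 'empty input'}")
    return pd.DataFrame(rows, columns=FEATURE_NAMES[mode.lower()])
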