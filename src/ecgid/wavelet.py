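"""Discrete wavelet decomposition of beats and the wavelet distance measure.

Beats are decomposed with a 5-level Daubechies-3 cascade filter bank under
periodized signal extension, the only standard extension mode for which the
coefficient counts halve exactly at each level (a 288-sample 800-ms beat at
360 Hz yields |D1..D5| = 144, 72, 36, 18, 9 and |A5| = 9). Detail level p
covers the frequency band [fs / 2^(p+1), fs / 2^p].

The template-matching score between a query and an enrolled template is the
wavelet distance: per retained level, the L1 norm of the coefficient
difference normalized by the template's largest absolute coefficient at that
level, summed over levels. The normalization makes the score dimensionless
and invariant to a common amplitude scale, and deliberately asymmetric (it is
always the enrolled template that normalizes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

__all__ = [
    "WaveletTemplate",
    "SubbandRange",
    "dwt_decompose",
    "reconstruct",
    "subband_range",
    "select_levels",
    "wdist",
    "LEVEL_SETS",
]

LEVEL_SETS: dict[str, tuple[int, ...]] = {
    "S1": (1, 2, 3, 4, 5),
    "S2": (2, 3, 4, 5),
    "S3": (3, 4, 5),
}


@dataclass
class WaveletTemplate:
    """DWT coefficients of one beat (or one subject's mean beat).

    ``details`` maps level p to the detail vector Dp; ``approx`` is the
    deepest approximation (A5), or None once the template has been restricted
    to a detail-level set.
    """

    details: dict[int, np.ndarray]
    approx: np.ndarray | None
    fs: float
    wavelet_order: int = 3

    @property
    def levels(self) -> tuple[int, ...]:
        return tuple(sorted(self.details))

    def coefficient_counts(self) -> dict[str, int]:
        out = {f"D{p}": int(self.details[p].size) for p in self.levels}
        if self.approx is not None:
            out[f"A{max(self.levels)}"] = int(self.approx.size)
        return out


@dataclass(frozen=True)
class SubbandRange:
    """Frequency band [lo, hi] Hz covered by detail level p."""

    p: int
    lo: float
    hi: float


def dwt_decompose(
    beat: np.ndarray, fs: float, levels: int = 5, order: int = 3
) -> WaveletTemplate:
    """5-level (by default) db-order cascade decomposition with periodization."""
    beat = np.asarray(beat, dtype=np.float64)
    if beat.size < 2**levels:
        raise ValueError(
            f"beat of {beat.size} samples too short for {levels}-level decomposition"
        )
    coeffs = pywt.wavedec(beat, f"db{order}", mode="periodization", level=levels)
    approx = coeffs[0]
    details = {levels - i: np.asarray(c) for i, c in enumerate(coeffs[1:])}
    return WaveletTemplate(details=details, approx=approx, fs=fs, wavelet_order=order)


def reconstruct(t: WaveletTemplate) -> np.ndarray:
    """Invert a full (unrestricted) decomposition."""
    if t.approx is None:
        raise ValueError("cannot reconstruct a level-restricted template")
    levels = max(t.levels)
    coeffs = [t.approx] + [t.details[p] for p in range(levels, 0, -1)]
    return pywt.waverec(coeffs, f"db{t.wavelet_order}", mode="periodization")


def subband_range(fs: float, p: int) -> SubbandRange:
    """Band edges of detail level p: [fs / 2^(p+1), fs / 2^p] Hz."""
    if p < 1:
        raise ValueError("decomposition level p must be >= 1")
    return SubbandRange(p=p, lo=fs / 2 ** (p + 1), hi=fs / 2**p)


def select_levels(t: WaveletTemplate, level_set: str) -> WaveletTemplate:
    """Restrict a template to a named detail-level set (A5 always excluded).

    S1 = {D1..D5}, S2 = {D2..D5}, S3 = {D3..D5}.
    """
    key = level_set.upper()
    if key not in LEVEL_SETS:
        raise ValueError(f"unknown level set {level_set!r}; expected one of {sorted(LEVEL_SETS)}")
    wanted = LEVEL_SETS[key]
    missing = [p for p in wanted if p not in t.details]
    if missing:
        raise ValueError(f"template lacks detail levels {missing}")
    return WaveletTemplate(
        details={p: t.details[p] for p in wanted},
        approx=None,
        fs=t.fs,
        wavelet_order=t.wavelet_order,
    )


def wdist(query: WaveletTemplate, template: WaveletTemplate, norm: str = "l1") -> float:
    """Wavelet distance of a query against an enrolled template.

    sum over levels p of ||Dp_query - Dp_template|| / max(|Dp_template|).
    ``norm`` selects the per-level norm ("l1" default, "l2" available).
    Asymmetric by construction: the denominator always comes from the
    enrolled template.
    """
    if query.levels != template.levels:
        raise ValueError(
            f"level sets differ: query {query.levels} vs template {template.levels}"
        )
    total = 0.0
    for p in template.levels:
        dq = query.details[p]
        dt = template.details[p]
        if dq.size != dt.size:
            raise ValueError(
                f"coefficient length mismatch at level {p} "
                f"({dq.size} vs {dt.size}); resample records to a common rate"
            )
        denom = float(np.max(np.abs(dt)))
        if denom == 0.0:
            raise ValueError(f"template level D{p} is all-zero; distance undefined")
        diff = dq - dt
        if norm == "l1":
            num = float(np.sum(np.abs(diff)))
        elif norm == "l2":
            num = float(np.sqrt(np.sum(diff**2)))
        else:
            raise ValueError(f"unknown norm {norm!r}")
        total += num / denom
    return total
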