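"""P-QRS-T complex delineation and correlation-based outlier rejection.

Each detected R peak anchors an 800-ms half-open window [R - half, R + half)
with ``half = round(0.4 * fs)`` samples, so every row of the beat matrix has
the same length and R sits exactly at the window centre. Beats whose Pearson
correlation against the mean complex falls strictly below mu - 0.5*sigma of
the correlation distribution are discarded in a single pass (the mean complex
is computed once, over all beats, and not recomputed after removal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EcgRecord
from .rpeak import RPeakResult

__all__ = ["BeatMatrix", "OutlierStats", "segment_beats", "remove_outliers"]


@dataclass
class BeatMatrix:
    """Stacked beat windows for one record.

    ``r_indices`` holds the source R sample index of each row in the original
    record; ``kept_mask`` is relative to the rows of the matrix this object was
    derived from (all True straight after segmentation).
    """

    beats: np.ndarray  # (n_beats, n_samples)
    fs: float
    r_index_in_window: int
    kept_mask: np.ndarray
    r_indices: np.ndarray

    @property
    def n_beats(self) -> int:
        return int(self.beats.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.beats.shape[1])


@dataclass
class OutlierStats:
    """Per-beat correlations against the mean complex and the removal threshold."""

    correlations: np.ndarray
    mu: float
    sigma: float
    threshold: float  # mu - 0.5 * sigma


def segment_beats(rec: EcgRecord, peaks: RPeakResult | np.ndarray) -> BeatMatrix:
    """Cut one 800-ms window per R peak whose full window fits in the record.

    Peaks closer than ``half = round(0.4 * fs)`` samples to either edge are
    dropped silently (their indices are recoverable by comparing ``r_indices``
    with the input peak list).
    """
    idx = peaks.peaks if isinstance(peaks, RPeakResult) else np.asarray(peaks, dtype=np.int64)
    if idx.size == 0:
        raise ValueError("no R peaks supplied")
    fs = rec.fs
    half = int(round(0.4 * fs))
    n = rec.samples.size
    keep = (idx - half >= 0) & (idx + half <= n)
    kept = idx[keep]
    if kept.size == 0:
        raise ValueError("no R peak admits a full 800-ms window inside the record")
    rows = np.stack([rec.samples[r - half : r + half] for r in kept])
    return BeatMatrix(
        beats=rows,
        fs=fs,
        r_index_in_window=half,
        kept_mask=np.ones(kept.size, dtype=bool),
        r_indices=kept.astype(np.int64),
    )


def _pearson_to_mean(beats: np.ndarray, mean: np.ndarray) -> np.ndarray:
    centred = beats - beats.mean(axis=1, keepdims=True)
    m = mean - mean.mean()
    denom = np.sqrt((centred**2).sum(axis=1) * (m**2).sum())
    out = np.zeros(beats.shape[0])
    ok = denom > 0
    out[ok] = (centred[ok] @ m) / denom[ok]
    # degenerate (zero-variance) beats get correlation 0: maximally unlike any
    # real complex, so they are naturally treated as outliers
    return np.clip(out, -1.0, 1.0)


def remove_outliers(bm: BeatMatrix) -> tuple[BeatMatrix, OutlierStats]:
    """Drop beats whose correlation with the mean complex is below mu - 0.5*sigma.

    Single pass: the mean complex and the correlation distribution include the
    prospective outliers; removal is strict (< threshold), so with identical
    beats (sigma = 0) nothing is removed.
    """
    if bm.n_beats < 3:
        raise ValueError(f"outlier filtering needs >= 3 beats, got {bm.n_beats}")
    mean_complex = bm.beats.mean(axis=0)
    corr = _pearson_to_mean(bm.beats, mean_complex)
    mu = float(corr.mean())
    sigma = float(corr.std())
    threshold = mu - 0.5 * sigma
    keep = ~(corr < threshold)
    filtered = BeatMatrix(
        beats=bm.beats[keep],
        fs=bm.fs,
        r_index_in_window=bm.r_index_in_window,
        kept_mask=keep,
        r_indices=bm.r_indices[keep],
    )
    return filtered, OutlierStats(corr, mu, sigma, threshold)
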