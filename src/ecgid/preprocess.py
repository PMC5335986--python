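"""FFT-domain bandpass filtering.

The front end removes baseline wander (below 2 Hz) and power-line plus other
high-frequency interference (above 50 Hz) by zeroing real-FFT bins outside a
closed passband [low, high] and inverting the transform. A brick-wall filter
is the default; an optional raised-cosine transition band can be enabled to
suppress ringing on very impulsive inputs.
"""

from __future__ import annotations

import numpy as np

from .io import EcgRecord

__all__ = ["bandpass_fft"]


def bandpass_fft(
    rec: EcgRecord, low: float = 2.0, high: float = 50.0, taper_hz: float = 0.0
) -> EcgRecord:
    """Bandpass the record to the closed band [low, high] Hz via the FFT.

    Bins strictly below ``low`` or strictly above ``high`` are zeroed (bins at
    the cutoffs are kept). With ``taper_hz > 0`` a raised-cosine ramp of that
    width replaces each hard edge. The output is real, the same length as the
    input, and carries over all record metadata.
    """
    if not 0.0 <= low < high:
        raise ValueError(f"need 0 <= low < high, got low={low}, high={high}")
    if high >= rec.fs / 2:
        raise ValueError(f"high cutoff {high} Hz must be < Nyquist {rec.fs / 2} Hz")
    x = rec.samples
    n = x.size
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / rec.fs)
    if taper_hz <= 0:
        gain = ((freqs >= low) & (freqs <= high)).astype(np.float64)
    else:
        gain = np.zeros_like(freqs)
        gain[(freqs >= low) & (freqs <= high)] = 1.0
        rise = (freqs >= low - taper_hz) & (freqs < low)
        gain[rise] = 0.5 * (1 + np.cos(np.pi * (low - freqs[rise]) / taper_hz))
        fall = (freqs > high) & (freqs <= high + taper_hz)
        gain[fall] = 0.5 * (1 + np.cos(np.pi * (freqs[fall] - high) / taper_hz))
        gain[freqs < max(low - taper_hz, 0)] = 0.0
    y = np.fft.irfft(spectrum * gain, n=n)
    out = rec.copy()
    out.samples = y
    out.meta["bandpass"] = (low, high)
    return out
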