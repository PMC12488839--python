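"""Small signal-processing primitives shared by the simulator and the
conduction-velocity estimator."""

from __future__ import annotations

import numpy as np


def fractional_shift(x: np.ndarray, delay: float, axis: int = -1) -> np.ndarray:
    """Delay ``x`` by a (possibly fractional) number of samples.

    Implemented as a linear-phase multiplication in the frequency domain,
    which realises sub-sample delays exactly for band-limited signals.
    The shift is circular; callers must ensure the waveform has decayed
    at the window edges (true for the compact MUAP templates used here).

    Positive ``delay`` moves features to later samples.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    freqs = np.fft.fftfreq(n)  # cycles/sample
    phase = np.exp(-2j * np.pi * freqs * delay)
    shape = [1] * x.ndim
    shape[axis] = n
    X = np.fft.fft(x, axis=axis) * phase.reshape(shape)
    return np.real(np.fft.ifft(X, axis=axis))


def xcorr_peak(a: np.ndarray, b: np.ndarray, max_lag: int) -> tuple[float, float]:
    """Normalized cross-correlation peak between two waveforms.

    Returns ``(coef, lag)`` where ``coef`` is the peak normalized
    cross-correlation coefficient (mean-removed) over lags in
    ``[-max_lag, max_lag]`` and ``lag`` is the sub-sample location of the
    peak, obtained by parabolic interpolation around the integer
    maximum.  Positive lag means ``b`` is delayed relative to ``a``.
    """
    a = np.asarray(a, dtype=float) - np.mean(a)
    b = np.asarray(b, dtype=float) - np.mean(b)
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if denom == 0:
        return 0.0, 0.0
    full = np.correlate(b, a, mode="full") / denom  # lag k at index n-1+k
    n = a.size
    lags = np.arange(-n + 1, n)
    keep = np.abs(lags) <= max_lag
    cc = full[keep]
    lg = lags[keep]
    i = int(np.argmax(cc))
    coef = float(cc[i])
    lag = float(lg[i])
    # parabolic refinement on the three points around the peak
    if 0 < i < cc.size - 1:
        y0, y1, y2 = cc[i - 1], cc[i], cc[i + 1]
        denom2 = y0 - 2 * y1 + y2
        if denom2 < 0:
            lag += 0.5 * (y0 - y2) / denom2
            coef = float(y1 - 0.125 * (y0 - y2) ** 2 / denom2)
    return coef, lag


def moving_rms(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving RMS with edge truncation (same-length output)."""
    x = np.asarray(x, dtype=float)
    kernel = np.ones(window)
    num = np.convolve(x**2, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return np.sqrt(num / den)
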