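"""Breath-by-breath cleaning and hypoxic response metrics.

The hypoxic ventilatory response (HVR) and hypoxic cardiac response (HCR)
normalize the exercise-phase rise in ventilation / heart rate by the
peripheral desaturation:

    HVR = (Ve_H - Ve_N) / (SpO2_N - SpO2_H)      [L min^-1 %^-1]
    HCR = (HR_H - HR_N) / (SpO2_N - SpO2_H)      [bpm %^-1]

with N = normoxia and H = a hypoxic condition.  NOTE the ΔSpO2 convention
is normoxia minus hypoxia, so both metrics are positive when ventilation or
heart rate rises while saturation falls; a sign error here inverts every
response metric.  The motor-unit responses (ΔIDR, ΔCV) and ΔVO2 are simple
hypoxia-minus-normoxia differences, not normalized to desaturation.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Optional

import numpy as np

from .core import BxBSeries

__all__ = [
    "clean_bxb",
    "exercise_median",
    "hvr",
    "hcr",
    "deltas",
]


def _clean_series(
    t: np.ndarray, x: np.ndarray, z_max: float, window: int
) -> tuple[np.ndarray, np.ndarray]:
    """Rolling-median/MAD outlier flagging with linear interpolation.

    A sample is flagged when |x - rolling median| > z_max * 1.4826 * MAD
    (window centred, edge-truncated).  Flagged samples are replaced by
    linear interpolation over time; flagged endpoints are clamped to the
    nearest valid value.  Non-flagged samples are never altered.
    """
    n = x.size
    half = window // 2
    med = np.empty(n)
    mad = np.empty(n)
    for i in range(n):
        seg = x[max(i - half, 0) : min(i + half + 1, n)]
        med[i] = np.median(seg)
        mad[i] = np.median(np.abs(seg - med[i]))
    sigma = 1.4826 * mad
    dev = np.abs(x - med)
    # MAD = 0 (locally constant series): any departure from the local
    # median is an outlier; ties are never flagged
    flagged = np.where(sigma > 0, dev > z_max * sigma, dev > 0)
    if not flagged.any():
        return x.copy(), flagged
    good = ~flagged
    cleaned = x.copy()
    cleaned[flagged] = np.interp(t[flagged], t[good], x[good])
    return cleaned, flagged


def clean_bxb(series: BxBSeries, z_max: float = 3.0, window: int = 9) -> BxBSeries:
    """Clean HR, Ve and VO2 series of a breath-by-breath record.

    Series shorter than ``window`` breaths are passed through with a
    warning (too little context for a rolling statistic).
    """
    if series.n_breaths < 5:
        raise ValueError("need at least 5 breaths")
    if series.n_breaths < window:
        warnings.warn("series shorter than cleaning window; passed through", stacklevel=2)
        return replace(series, cleaned=True)
    hr, _ = _clean_series(series.times, series.hr, z_max, window)
    ve, _ = _clean_series(series.times, series.ve, z_max, window)
    vo2, _ = _clean_series(series.times, series.vo2, z_max, window)
    return BxBSeries(times=series.times.copy(), hr=hr, ve=ve, vo2=vo2, cleaned=True)


def exercise_median(series: BxBSeries, t_start: float, t_end: float) -> dict:
    """Median HR, Ve and VO2 over the exercise window [t_start, t_end]."""
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    inside = (series.times >= t_start) & (series.times <= t_end)
    if not inside.any():
        raise ValueError("exercise window does not overlap the series")
    return {
        "hr": float(np.median(series.hr[inside])),
        "ve": float(np.median(series.ve[inside])),
        "vo2": float(np.median(series.vo2[inside])),
    }


def _response(num: float, spo2_n: float, spo2_h: float, name: str) -> float:
    dspo2 = spo2_n - spo2_h
    if dspo2 == 0:
        warnings.warn(f"ΔSpO2 = 0: {name} undefined, returned missing", stacklevel=3)
        return np.nan
    if dspo2 < 0:
        warnings.warn(
            f"SpO2 rose in hypoxia (ΔSpO2 < 0); {name} sign flips", stacklevel=3
        )
    return num / dspo2


def hvr(ve_h: float, ve_n: float, spo2_n: float, spo2_h: float) -> float:
    """Hypoxic ventilatory response, L·min⁻¹·%⁻¹."""
    return _response(ve_h - ve_n, spo2_n, spo2_h, "HVR")


def hcr(hr_h: float, hr_n: float, spo2_n: float, spo2_h: float) -> float:
    """Hypoxic cardiac response, bpm·%⁻¹."""
    return _response(hr_h - hr_n, spo2_n, spo2_h, "HCR")


def deltas(x_h: Optional[float], x_n: Optional[float]) -> float:
    """Simple hypoxia-minus-normoxia difference; missing in -> missing out.

    Applied to participant-level medians for CV (m/s) and IDR (pps) and to
    exercise-phase VO2 (mL/min).
    """
    if x_h is None or x_n is None or np.isnan(x_h) or np.isnan(x_n):
        return np.nan
    return x_h - x_n
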