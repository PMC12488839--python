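"""Per-motor-unit outcome measures: mean smoothed discharge rate and
muscle-fiber conduction velocity.

The instantaneous discharge rate (IDR) is the reciprocal inter-spike
interval; a minimally smoothed profile is obtained by convolving the IDR
sequence with a unit-sum 4-point Hanning kernel.  Motor-unit action
potentials (MUAPs) are spike-triggered averages over a 50 ms window on the
double-differential montage; conduction velocity is the maximum-likelihood
(least-squares, frequency-domain) inter-channel delay over a run of
contiguous channels in one column that show clean propagation
(adjacent-channel cross-correlation >= 0.8, consistent delay sign, delay
admissible for CV in the physiological 2-8 m/s range).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .core import DDRecording, DischargeTrain
from .dsp import fractional_shift, xcorr_peak

logger = logging.getLogger(__name__)

__all__ = [
    "IDRProfile",
    "MUAPTemplate",
    "CVEstimate",
    "hanning_kernel",
    "compute_idr",
    "smooth_idr",
    "sta_muap",
    "select_cv_channels",
    "estimate_cv",
    "summarize_mus",
    "CV_RANGE_M_S",
]

#: Physiologically admissible muscle-fiber conduction velocities, m/s.
CV_RANGE_M_S = (2.0, 8.0)


@dataclass
class IDRProfile:
    """Instantaneous and smoothed discharge-rate profile of one MU."""

    times: np.ndarray  # discharge times, s
    idr: np.ndarray  # pps, length = n_discharges - 1
    smoothed: Optional[np.ndarray] = None
    mean_smoothed_dr: Optional[float] = None
    fallback: bool = False  # True when too few IDR values for the kernel


@dataclass
class MUAPTemplate:
    """Spike-triggered average MUAP on the double-differential montage.

    ``waveforms`` has shape (n_dd_rows, n_cols, window_samples).
    """

    waveforms: np.ndarray
    fs: float
    ied: float  # mm
    n_triggers: int
    n_dropped: int = 0


@dataclass
class CVEstimate:
    cv: float  # m/s
    channels_used: list  # DD row indices within the column
    column: int
    mean_xcorr: float
    delay_per_ied: float  # s
    at_boundary: bool = False  # optimizer hit the admissible range edge


def compute_idr(train: DischargeTrain) -> IDRProfile:
    """Instantaneous discharge rate: idr_i = 1 / (t_{i+1} - t_i), in pps."""
    if train.n_discharges < 2:
        raise ValueError("need at least 2 discharges")
    t = train.times_s
    isi = np.diff(t)
    return IDRProfile(times=t, idr=1.0 / isi)


def hanning_kernel(n: int = 4) -> np.ndarray:
    """Unit-sum Hanning window with nonzero endpoints.

    The raised cosine is sampled at the ``n`` interior points of an
    ``n + 2``-point Hann window, so no discharge in the window carries
    zero weight; for n=4 the (unnormalized) weights are
    sin^2(pi k / 5), k = 1..4.
    """
    k = np.arange(1, n + 1)
    w = np.sin(np.pi * k / (n + 1)) ** 2
    return w / w.sum()


def smooth_idr(profile: IDRProfile, window_discharges: int = 4) -> IDRProfile:
    """Convolve the IDR sequence with a unit-sum Hanning kernel.

    Same-length output with edge renormalization: partial windows at the
    sequence ends have their weights rescaled to sum to one, so constant
    sequences are preserved exactly.  With fewer IDR values than the
    kernel length, the unweighted mean of the raw IDR is returned and the
    profile is flagged as a fallback.
    """
    if profile.idr.size == 0:
        raise ValueError("empty IDR profile")
    x = profile.idr
    if x.size < window_discharges:
        logger.info("IDR sequence shorter than kernel; falling back to raw mean")
        m = float(np.mean(x))
        return IDRProfile(
            times=profile.times,
            idr=x,
            smoothed=x.copy(),
            mean_smoothed_dr=m,
            fallback=True,
        )
    kern = hanning_kernel(window_discharges)
    offset = (window_discharges - 1) // 2
    sm = np.empty_like(x, dtype=float)
    for i in range(x.size):
        j0 = max(i - offset, 0)
        j1 = min(i - offset + window_discharges, x.size)
        w = kern[j0 - (i - offset) : j1 - (i - offset)]
        sm[i] = np.sum(w * x[j0:j1]) / np.sum(w)
    return IDRProfile(
        times=profile.times,
        idr=x,
        smoothed=sm,
        mean_smoothed_dr=float(np.mean(sm)),
        fallback=False,
    )


def sta_muap(
    dd: DDRecording, train: DischargeTrain, window_ms: float = 50.0
) -> MUAPTemplate:
    """Spike-triggered average over a ``window_ms`` window centred on each
    discharge; triggers whose window leaves the segment are dropped and
    counted, never zero-padded."""
    fs = dd.fs
    length = int(round(window_ms / 1000.0 * fs))
    half = length // 2
    n = dd.signal.shape[1]
    triggers = np.round(train.times).astype(np.int64)
    usable = triggers[(triggers - half >= 0) & (triggers - half + length <= n)]
    dropped = train.n_discharges - usable.size
    if usable.size == 0:
        raise ValueError("no usable triggers inside the segment")
    acc = np.zeros((dd.signal.shape[0], length))
    for t in usable:
        a = int(t) - half
        acc += dd.signal[:, a : a + length]
    acc /= usable.size
    grid = acc.reshape(dd.n_dd_rows, dd.geometry.n_cols, length)
    return MUAPTemplate(
        waveforms=grid,
        fs=fs,
        ied=dd.geometry.ied,
        n_triggers=int(usable.size),
        n_dropped=int(dropped),
    )


def _admissible_lag_range(ied: float, fs: float, cv_range=CV_RANGE_M_S) -> tuple[float, float]:
    """Inter-channel lag magnitudes (samples) compatible with the CV range."""
    ied_m = ied / 1000.0
    return ied_m * fs / cv_range[1], ied_m * fs / cv_range[0]


def select_cv_channels(
    template: MUAPTemplate,
    xcorr_min: float = 0.8,
    cv_range=CV_RANGE_M_S,
):
    """Pick the column and contiguous channel run for CV estimation.

    Per column, the longest run of contiguous DD channels is found in which
    every adjacent pair has (i) peak normalized cross-correlation >=
    ``xcorr_min`` after optimal lag alignment, (ii) a consistent lag sign
    (rejects runs straddling the innervation zone, where propagation
    reverses), and (iii) a lag magnitude admissible for CV in ``cv_range``
    (rejects non-propagating end-of-fiber channels, including the zero-lag
    case).  Among columns with runs of >= 2 channels the one with the
    highest mean adjacent-pair cross-correlation wins; ties break by longer
    run, then lower column index.

    Returns ``(rows, column, mean_xcorr, pair_lags)`` or ``None`` when no
    column yields a valid run (CV undefined for this MU).
    """
    n_rows, n_cols, length = template.waveforms.shape
    if n_rows < 2:
        raise ValueError("need at least 2 DD rows")
    lag_lo, lag_hi = _admissible_lag_range(template.ied, template.fs, cv_range)
    max_lag = int(np.ceil(lag_hi)) + 2
    best = None  # (mean_xcorr, run_len, -col, rows, lags)
    for c in range(n_cols):
        coefs = np.zeros(n_rows - 1)
        lags = np.zeros(n_rows - 1)
        ok = np.zeros(n_rows - 1, dtype=bool)
        for r in range(n_rows - 1):
            coef, lag = xcorr_peak(
                template.waveforms[r, c], template.waveforms[r + 1, c], max_lag
            )
            coefs[r], lags[r] = coef, lag
            ok[r] = coef >= xcorr_min and lag_lo <= abs(lag) <= lag_hi
        # innervation-zone exclusion: where consecutive pair lags flip sign,
        # the shared channel sits on the innervation zone and mixes both
        # propagation directions; both pairs touching it are rejected.
        for r in range(n_rows - 2):
            if lags[r] * lags[r + 1] < 0:
                ok[r] = ok[r + 1] = False
        # contiguous runs of admissible pairs with consistent sign
        r = 0
        while r < n_rows - 1:
            if not ok[r]:
                r += 1
                continue
            r2 = r
            sign = np.sign(lags[r])
            while r2 + 1 < n_rows - 1 and ok[r2 + 1] and np.sign(lags[r2 + 1]) == sign:
                r2 += 1
            pair_idx = np.arange(r, r2 + 1)
            run_rows = list(range(r, r2 + 2))  # channels, = pairs + 1
            mean_x = float(np.mean(coefs[pair_idx]))
            cand = (mean_x, len(run_rows), -c, run_rows, list(lags[pair_idx]))
            if best is None or cand[:3] > best[:3]:
                best = cand
            r = r2 + 1
    if best is None:
        logger.info("no column with a valid propagating run; CV undefined")
        return None
    mean_x, _, neg_c, rows, lags = best
    return rows, -neg_c, mean_x, lags


def estimate_cv(
    template: MUAPTemplate,
    channels: Sequence[int],
    column: int,
    cv_range=CV_RANGE_M_S,
) -> CVEstimate:
    """Maximum-likelihood inter-channel delay -> conduction velocity.

    Under additive white Gaussian noise the ML delay estimate minimizes the
    summed squared error between each channel and the mean of all channels
    aligned under the pure-propagation model (channel k = waveform delayed
    by k * theta).  Sub-sample delays are realized by frequency-domain
    phase shifts; theta is refined by bounded scalar minimization over the
    admissible range (both propagation directions), after a coarse grid
    search.  ``cv = ied * fs / |theta|``.
    """
    channels = list(channels)
    if len(channels) < 2:
        raise ValueError("need >= 2 contiguous channels")
    if sorted(channels) != list(range(min(channels), max(channels) + 1)):
        raise ValueError("channels must be contiguous within one column")
    waves = np.array([template.waveforms[r, column] for r in channels], dtype=float)
    waves = waves - waves.mean(axis=1, keepdims=True)
    # unit-energy channels: the propagation model constrains timing, not
    # amplitude, and MUAP amplitude decays with distance from the source
    norms = np.sqrt(np.sum(waves**2, axis=1, keepdims=True))
    if np.any(norms == 0):
        raise ValueError("all-zero channel in CV estimation")
    waves = waves / norms
    k = np.arange(len(channels))

    def cost(theta: float) -> float:
        aligned = np.array(
            [fractional_shift(waves[i], -k[i] * theta) for i in range(len(channels))]
        )
        resid = aligned - aligned.mean(axis=0)
        return float(np.sum(resid**2))

    lag_lo, lag_hi = _admissible_lag_range(template.ied, template.fs, cv_range)
    best_theta, best_cost = None, np.inf
    for lo, hi in ((lag_lo, lag_hi), (-lag_hi, -lag_lo)):
        grid = np.linspace(lo, hi, 41)
        cg = [cost(t) for t in grid]
        i = int(np.argmin(cg))
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, grid.size - 1)]
        res = optimize.minimize_scalar(
            cost, bounds=(a, b), method="bounded", options={"xatol": 1e-12}
        )
        if res.fun < best_cost:
            best_cost, best_theta = float(res.fun), float(res.x)
    theta = best_theta
    at_boundary = bool(
        min(abs(abs(theta) - lag_lo), abs(abs(theta) - lag_hi)) < 1e-6
    )
    if at_boundary:
        logger.warning("CV optimizer at admissible-range boundary; flagged unreliable")
    ied_m = template.ied / 1000.0
    cv = ied_m * template.fs / abs(theta)
    return CVEstimate(
        cv=float(cv),
        channels_used=channels,
        column=int(column),
        mean_xcorr=np.nan,
        delay_per_ied=abs(theta) / template.fs,
        at_boundary=at_boundary,
    )


def mu_cv(
    dd: DDRecording,
    train: DischargeTrain,
    window_ms: float = 50.0,
    xcorr_min: float = 0.8,
    cv_range=CV_RANGE_M_S,
) -> Optional[CVEstimate]:
    """Convenience: STA template -> channel selection -> CV, or None when
    the MU shows no clearly propagating MUAPs."""
    template = sta_muap(dd, train, window_ms=window_ms)
    sel = select_cv_channels(template, xcorr_min=xcorr_min, cv_range=cv_range)
    if sel is None:
        return None
    rows, col, mean_x, _ = sel
    est = estimate_cv(template, rows, col, cv_range=cv_range)
    est.mean_xcorr = mean_x
    return est


def summarize_mus(mu_table, value_cols=("idr", "cv")):
    """Per participant x condition medians of the per-MU outcome measures.

    The median (not the mean) is used to resist outlying MUs.  Missing
    values (e.g. MUs without a CV estimate) are skipped; a participant x
    condition cell with no valid MU propagates a missing value.  Returns a
    DataFrame with medians and MU counts.
    """
    import pandas as pd

    df = pd.DataFrame(mu_table)
    if df.empty:
        raise ValueError("empty MU table")
    group_cols = [c for c in ("participant", "sex", "condition") if c in df.columns]
    agg = {c: "median" for c in value_cols if c in df.columns}
    out = df.groupby(group_cols, as_index=False).agg(agg)
    counts = df.groupby(group_cols, as_index=False).agg(
        **{f"n_{c}": (c, lambda s: int(s.notna().sum())) for c in value_cols if c in df.columns}
    )
    return out.merge(counts, on=group_cols)
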