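"""Filtering, quality control, contraction segmentation/selection and the
double-differential montage."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps

from .core import ContractionSegment, DDRecording, EMGRecording
from .dsp import moving_rms

__all__ = [
    "Protocol",
    "bandpass",
    "resting_noise_qc",
    "segment_contractions",
    "select_top_contractions",
    "double_differential",
]


@dataclass(frozen=True)
class Protocol:
    """Contraction protocol: n bouts of ``on`` seconds separated by ``off``
    seconds of rest, first onset at ``start`` seconds."""

    n: int = 9
    on: float = 5.0
    off: float = 15.0
    start: float = 0.0


def bandpass(
    rec: EMGRecording, low: float = 20.0, high: float = 500.0, order: int = 2
) -> EMGRecording:
    """Zero-phase Butterworth band-pass per channel.

    Forward-backward filtering (filtfilt) is used so that spike timing is
    not biased by filter group delay; ``order`` refers to the one-pass
    Butterworth order.
    """
    nyq = rec.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"cutoffs must satisfy 0 < {low} < {high} < {nyq}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.signal, axis=1)
    return EMGRecording(signal=filtered, geometry=rec.geometry, t0=rec.t0)


def resting_noise_qc(rec: EMGRecording, threshold: float = 20.0):
    """Per-channel RMS of a rest-phase segment with pass/fail flags.

    A channel fails when its RMS is at or above ``threshold`` μV (the
    pre-acquisition noise criterion).  Returns ``(rms, passed)`` arrays.
    """
    if rec.n_samples == 0:
        raise ValueError("empty segment")
    rms = np.sqrt(np.mean(rec.signal**2, axis=1))
    passed = rms < threshold
    if not passed.all():
        warnings.warn(
            f"{int((~passed).sum())} channel(s) exceed resting RMS {threshold} μV",
            stacklevel=2,
        )
    return rms, passed


def _slice_recording(rec: EMGRecording, a: int, b: int) -> EMGRecording:
    return EMGRecording(
        signal=rec.signal[:, a:b], geometry=rec.geometry, t0=rec.t0 + a / rec.fs
    )


def segment_contractions(
    rec: EMGRecording,
    protocol: Optional[Protocol] = Protocol(),
    mode: str = "protocol",
    rms_window: float = 0.250,
    k: float = 5.0,
    resting_rms: Optional[float] = None,
    min_on: float = 2.0,
    merge_gap: float = 1.0,
) -> list[ContractionSegment]:
    """Cut contraction bouts out of a continuous recording.

    In ``protocol`` mode, fixed windows are taken from the declared onset
    times.  In ``detect`` mode, segments are the intervals where the
    grid-mean RMS envelope (window ``rms_window`` s) exceeds
    ``k * resting_rms`` for at least ``min_on`` s, merging gaps shorter
    than ``merge_gap`` s; a count differing from ``protocol.n`` raises a
    warning, not an error.
    """
    fs = rec.fs
    if mode == "protocol":
        if protocol is None:
            raise ValueError("protocol mode requires a Protocol")
        segments = []
        for i in range(protocol.n):
            onset = protocol.start + i * (protocol.on + protocol.off)
            a = int(round((onset - rec.t0) * fs))
            b = a + int(round(protocol.on * fs))
            if a < 0 or b > rec.n_samples:
                raise ValueError("recording does not span the protocol")
            segments.append(ContractionSegment(_slice_recording(rec, a, b), index=i + 1))
        return segments
    if mode != "detect":
        raise ValueError(f"unknown mode {mode!r}")
    # grid-mean RMS envelope: RMS over channels per sample, then moving RMS in time
    inst = np.sqrt(np.mean(rec.signal**2, axis=0))
    env = moving_rms(inst, max(int(round(rms_window * fs)), 1))
    if resting_rms is None:
        resting_rms = float(np.percentile(env, 20))
    active = env > k * resting_rms
    # edges of active runs
    edges = np.flatnonzero(np.diff(active.astype(int)))
    starts = list(edges[~active[edges]] + 1) if edges.size else []
    stops = list(edges[active[edges]] + 1) if edges.size else []
    if active.size and active[0]:
        starts = [0] + starts
    if active.size and active[-1]:
        stops = stops + [active.size]
    runs = list(zip(sorted(starts), sorted(stops)))
    # merge short gaps
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and (a - merged[-1][1]) < merge_gap * fs:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    segs = [
        ContractionSegment(_slice_recording(rec, a, b), index=i + 1)
        for i, (a, b) in enumerate(m for m in merged if (m[1] - m[0]) >= min_on * fs)
    ]
    expected = protocol.n if protocol is not None else None
    if expected is not None and len(segs) != expected:
        warnings.warn(
            f"detected {len(segs)} contraction(s), expected {expected}", stacklevel=2
        )
    return segs


def select_top_contractions(
    segments: list[ContractionSegment], first_n: int = 5, k: int = 2
) -> list[ContractionSegment]:
    """Keep the ``k`` highest-amplitude contractions among the first
    ``first_n`` of the protocol.

    Amplitude is the grid-mean RMS; ties break toward the earlier
    contraction; the selection is returned in protocol order.
    """
    pool = [s for s in segments if s.index <= first_n]
    if len(pool) < k:
        raise ValueError(f"need at least {k} contractions among the first {first_n}")
    ranked = sorted(pool, key=lambda s: (-s.mean_rms, s.index))
    chosen = sorted(ranked[:k], key=lambda s: s.index)
    return chosen


def double_differential(rec: EMGRecording) -> DDRecording:
    """Double-differential montage along grid columns.

    ``DD(r, c) = x(r-1, c) - 2 x(r, c) + x(r+1, c)`` for interior rows;
    a 13-row grid yields 11 DD channels per column.  Constants and
    row-linear fields are annihilated exactly.
    """
    g = rec.geometry
    if g.n_rows < 3:
        raise ValueError("double differential needs >= 3 rows")
    grid = rec.as_grid()  # (rows, cols, samples)
    dd = grid[:-2] - 2 * grid[1:-1] + grid[2:]
    return DDRecording(
        signal=dd.reshape((g.n_rows - 2) * g.n_cols, rec.n_samples),
        geometry=g,
        provenance=f"t0={rec.t0}",
    )
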