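"""Core data containers shared across the pipeline.

Conventions used throughout the package:

* signals are in microvolts (μV), time in seconds, discharge times in
  samples, discharge rates in pulses per second (pps), conduction
  velocity in m/s;
* electrode grids are addressed as (row, column) with row 0 the most
  proximal electrode; monopolar channels are stored row-major, i.e.
  channel index = row * n_cols + col, labelled ``r{row}c{col}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Minimum inter-spike interval accepted for a physiological train, in seconds.
REFRACTORY_FLOOR_S = 0.010

CONDITIONS = ("CON", "H1", "H2")
SEXES = ("F", "M")


@dataclass(frozen=True)
class GridGeometry:
    """Electrode grid geometry and sampling.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid layout; the default 13 x 5 = 64-electrode grid leaves one
        corner position empty in hardware, but the simulator fills the
        full 65-channel rectangle for simplicity (the analysis is
        agnostic to the missing corner).
    ied : float
        Inter-electrode distance in mm.
    fs : float
        Sampling frequency in Hz.
    """

    n_rows: int = 13
    n_cols: int = 5
    ied: float = 8.0
    fs: float = 2048.0

    def __post_init__(self) -> None:
        if self.n_rows < 3:
            raise ValueError("grid needs >= 3 rows (double differential)")
        if self.ied <= 0 or self.fs <= 0:
            raise ValueError("ied and fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    def channel_index(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def channel_labels(self) -> list[str]:
        return [
            f"r{r}c{c}" for r in range(self.n_rows) for c in range(self.n_cols)
        ]


@dataclass
class DischargeTrain:
    """Ordered discharge times of one motor unit.

    ``times`` are sample indices at sampling rate ``fs`` (float: the
    generator keeps exact sub-sample times, decomposition yields integer
    peak indices); ``pnr`` (dB) is absent until a decomposition assigns it.
    """

    times: np.ndarray
    fs: float
    pnr: Optional[float] = None
    mu_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("discharge times must be strictly increasing")

    @property
    def n_discharges(self) -> int:
        return int(self.times.size)

    @property
    def times_s(self) -> np.ndarray:
        return self.times / self.fs

    def isi_s(self) -> np.ndarray:
        """Inter-spike intervals in seconds."""
        return np.diff(self.times) / self.fs


@dataclass
class EMGRecording:
    """Monopolar multichannel surface EMG in μV."""

    signal: np.ndarray  # (n_channels, n_samples)
    geometry: GridGeometry
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be (n_channels, n_samples)")
        if self.signal.shape[0] != self.geometry.n_channels:
            raise ValueError(
                f"expected {self.geometry.n_channels} channels, "
                f"got {self.signal.shape[0]}"
            )
        if not np.isfinite(self.signal).all():
            raise ValueError("signal contains non-finite samples")

    @property
    def fs(self) -> float:
        return self.geometry.fs

    @property
    def n_samples(self) -> int:
        return int(self.signal.shape[1])

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def as_grid(self) -> np.ndarray:
        """Signal reshaped to (n_rows, n_cols, n_samples)."""
        g = self.geometry
        return self.signal.reshape(g.n_rows, g.n_cols, self.n_samples)

    def labels(self) -> list[str]:
        return self.geometry.channel_labels()


@dataclass
class DDRecording:
    """Double-differential derivation along grid columns.

    ``signal`` is (n_rows - 2) * n_cols channels x samples, row-major in
    (dd_row, col); dd_row r corresponds to monopolar rows (r, r+1, r+2).
    """

    signal: np.ndarray
    geometry: GridGeometry  # geometry of the SOURCE monopolar grid
    provenance: Optional[str] = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        n_dd = (self.geometry.n_rows - 2) * self.geometry.n_cols
        if self.signal.shape[0] != n_dd:
            raise ValueError(f"expected {n_dd} DD channels")

    @property
    def n_dd_rows(self) -> int:
        return self.geometry.n_rows - 2

    @property
    def fs(self) -> float:
        return self.geometry.fs

    def as_grid(self) -> np.ndarray:
        return self.signal.reshape(
            self.n_dd_rows, self.geometry.n_cols, self.signal.shape[1]
        )


@dataclass
class ContractionSegment:
    """One contraction bout cut from a session recording."""

    recording: EMGRecording
    index: int  # ordinal within session, 1-based protocol order
    mean_rms: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("contraction index is 1-based")
        if self.mean_rms == 0.0:
            self.mean_rms = grid_mean_rms(self.recording.signal)
        if self.mean_rms < 0:
            raise ValueError("mean_rms must be >= 0")


@dataclass
class BxBSeries:
    """Breath-by-breath cardiorespiratory series.

    times in s, hr in bpm, ve in L/min, vo2 in mL/min.
    """

    times: np.ndarray
    hr: np.ndarray
    ve: np.ndarray
    vo2: np.ndarray
    cleaned: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("hr", "ve", "vo2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
            if getattr(self, name).shape != self.times.shape:
                raise ValueError(f"{name} must match times in length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("breath times must be strictly increasing")

    @property
    def n_breaths(self) -> int:
        return int(self.times.size)


@dataclass
class SessionRecord:
    """One participant x condition session."""

    participant_id: str
    sex: str
    condition: str
    contractions: list  # list[EMGRecording]
    bxb: BxBSeries
    spo2_end: float
    ground_truth: Optional[dict] = None  # simulator only

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if not (0 < self.spo2_end <= 100):
            raise ValueError("spo2_end must be in (0, 100]")


def grid_mean_rms(signal: np.ndarray) -> float:
    """RMS per channel, averaged across channels (grid-mean RMS), in μV."""
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    return float(np.mean(np.sqrt(np.mean(signal**2, axis=-1))))
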