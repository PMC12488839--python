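"""Synthetic high-density surface EMG and session-level physiology.

The generator provides ground truth for every downstream stage: motor-unit
(MU) discharge trains with controlled rate and variability, action
potentials propagating bidirectionally from an innervation zone along the
grid columns, additive baseline noise, the 9 x (5 s on / 15 s off)
maximal-contraction protocol, breath-by-breath cardiorespiratory series and
endpoint SpO2 for the three inspired-oxygen conditions (CON normoxia,
H1 light hypoxia, H2 mild hypoxia).

Condition means for SpO2 default to 97.1 / 91.3 / 86.9 % (SD 0.90 / 1.60 /
1.83); conduction velocity and discharge rate shift upward from CON to H2,
with higher CV in males, mirroring the directions the analysis is designed
to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .core import (
    CONDITIONS,
    REFRACTORY_FLOOR_S,
    BxBSeries,
    DischargeTrain,
    EMGRecording,
    GridGeometry,
    SessionRecord,
)
from .dsp import fractional_shift

__all__ = [
    "MotorUnitSpec",
    "TemplateBank",
    "ConditionEffects",
    "generate_discharge_train",
    "make_propagating_template",
    "synthesize_emg",
    "make_mu_pool",
    "simulate_session",
    "simulate_cohort",
    "simulate_mu_property_table",
    "render_session_signal",
]


@dataclass(frozen=True)
class MotorUnitSpec:
    """Ground-truth parameters of one simulated motor unit."""

    mu_id: str
    mean_dr: float  # pps
    isi_cv: float  # dimensionless CV of inter-spike intervals
    cv_true: float  # m/s
    iz_row: int  # innervation-zone row, 0-based
    amp: float = 100.0  # template peak amplitude, μV
    dur_ms: float = 6.0  # biphasic wavelet duration, ms

    def validate(self, geometry: GridGeometry) -> None:
        if self.mean_dr <= 0:
            raise ValueError("mean_dr must be > 0")
        if not (0 <= self.isi_cv < 1):
            raise ValueError("isi_cv must be in [0, 1)")
        if self.cv_true <= 0:
            raise ValueError("cv_true must be > 0")
        if not (0 <= self.iz_row < geometry.n_rows):
            raise ValueError("iz_row outside grid")


@dataclass
class TemplateBank:
    """Per-channel MUAP waveforms of one motor unit.

    ``waveforms`` has shape (n_rows, n_cols, length); the waveform peak of
    the innervation-zone row sits at sample ``center``; rows further from
    the innervation zone are delayed by |row - iz_row| * ied / cv_true.
    """

    waveforms: np.ndarray
    center: int
    spec: MotorUnitSpec
    geometry: GridGeometry

    @property
    def length(self) -> int:
        return int(self.waveforms.shape[-1])


def generate_discharge_train(
    mean_dr: float,
    isi_cv: float,
    duration: float,
    fs: float,
    seed: Optional[int] = None,
    refractory: float = REFRACTORY_FLOOR_S,
    mu_id: Optional[str] = None,
) -> DischargeTrain:
    """Draw a discharge train with Gaussian inter-spike intervals.

    ISIs are drawn from a Gaussian with mean ``1/mean_dr`` and SD
    ``isi_cv/mean_dr`` truncated below at the refractory floor; the first
    discharge falls one ISI after segment onset.  A fixed seed gives an
    identical train.

    Raises
    ------
    ValueError
        If the duration cannot hold at least two discharges.
    """
    if mean_dr <= 0:
        raise ValueError("mean_dr must be > 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if not (0 <= isi_cv < 1):
        raise ValueError("isi_cv must be in [0, 1)")
    mean_isi = 1.0 / mean_dr
    if duration < 2 * mean_isi:
        raise ValueError(
            f"duration {duration} s too short for 2 discharges at {mean_dr} pps"
        )
    rng = np.random.default_rng(seed)
    n_max = int(np.ceil(duration / max(mean_isi * (1 - 4 * isi_cv), refractory))) + 8
    if isi_cv == 0:
        isis = np.full(n_max, mean_isi)
    else:
        sd = isi_cv * mean_isi
        a = (refractory - mean_isi) / sd
        isis = spstats.truncnorm.rvs(
            a, np.inf, loc=mean_isi, scale=sd, size=n_max, random_state=rng
        )
    times_s = np.cumsum(isis)
    times_s = times_s[times_s <= duration + 0.5 / fs]
    times = times_s * fs  # exact (possibly sub-sample) discharge times
    if times.size < 2:
        raise ValueError("generated fewer than 2 discharges")
    return DischargeTrain(times=times, fs=fs, mu_id=mu_id)


def _gauss_deriv_wavelet(length: int, center: int, fs: float, dur_ms: float) -> np.ndarray:
    """Biphasic base wavelet: first derivative of a Gaussian, peak |amp| = 1.

    ``dur_ms`` spans +-6 sigma of the underlying Gaussian, i.e. the default
    6 ms waveform has a 0.5 ms Gaussian sigma (1 ms peak-to-peak rise).
    The sharp rise keeps spectral energy beyond the 500 Hz analysis
    corner, as real motor-unit action potentials do through the gentle
    2nd-order acquisition roll-off; a spectrally duller waveform would
    make the pulse-to-noise regime of real decompositions (>= 28 dB for
    clean units) physically unreachable at this sampling rate.
    """
    sigma = dur_ms / 1000.0 / 12.0
    t = (np.arange(length) - center) / fs
    w = -t * np.exp(-(t**2) / (2 * sigma**2))
    peak = sigma * np.exp(-0.5)  # |w| maximum at t = +-sigma
    return w / peak


def make_propagating_template(
    spec: MotorUnitSpec,
    geometry: GridGeometry,
    decay_rows: float = 3.0,
    end_of_fiber_amp: float = 0.0,
    length: Optional[int] = None,
) -> TemplateBank:
    """Build the per-channel waveform bank of one motor unit.

    Within each column the waveform at row ``r`` is the base biphasic
    wavelet delayed by ``|r - iz_row| * ied / cv_true`` (bidirectional
    propagation away from the innervation zone), with amplitude decaying
    exponentially with row distance (space constant ``decay_rows``).
    Sub-sample delays are realised by frequency-domain phase shifts.
    Optionally a non-propagating end-of-fiber component (a Gaussian bump
    with identical timing) is added at the two extreme rows.
    """
    spec.validate(geometry)
    fs = geometry.fs
    ied_m = geometry.ied / 1000.0
    rows = np.arange(geometry.n_rows)
    delays_s = np.abs(rows - spec.iz_row) * ied_m / spec.cv_true
    max_delay = float(delays_s.max()) * fs
    sigma_samples = spec.dur_ms / 1000.0 / 6.0 * fs
    if length is None:
        half = int(np.ceil(max_delay + 8 * sigma_samples))
        length = max(2 * half + 1, 2 * int(np.ceil(0.025 * fs)) + 1)
    center = length // 2
    base = _gauss_deriv_wavelet(length, center, fs, spec.dur_ms)
    waveforms = np.zeros((geometry.n_rows, geometry.n_cols, length))
    for r in rows:
        amp = spec.amp * np.exp(-abs(r - spec.iz_row) / decay_rows)
        wave = amp * fractional_shift(base, delays_s[r] * fs)
        waveforms[r, :, :] = wave
    if end_of_fiber_amp > 0:
        # same (non-delayed relative to each other) bump at both fiber ends
        t = (np.arange(length) - center - max_delay) / fs
        sigma = spec.dur_ms / 1000.0 / 4.0
        bump = end_of_fiber_amp * spec.amp * np.exp(-(t**2) / (2 * sigma**2))
        waveforms[0, :, :] += bump
        waveforms[-1, :, :] += bump
    return TemplateBank(waveforms=waveforms, center=center, spec=spec, geometry=geometry)


def synthesize_emg(
    specs: Sequence[MotorUnitSpec],
    trains: Sequence[DischargeTrain],
    geometry: GridGeometry,
    duration: Optional[float] = None,
    noise_rms: float = 0.0,
    seed: Optional[int] = None,
    decay_rows: float = 3.0,
    end_of_fiber_amp: float = 0.0,
    t0: float = 0.0,
) -> EMGRecording:
    """Superimpose MU template trains and additive white Gaussian noise.

    ``signal = sum_mu (spike train * per-channel template) + noise`` with
    the template of the innervation-zone row centred on each discharge
    sample.  Deterministic under a fixed seed.
    """
    if len(specs) != len(trains):
        raise ValueError("one train per spec required")
    if noise_rms < 0:
        raise ValueError("noise_rms must be >= 0")
    fs = geometry.fs
    if duration is None:
        last = max((int(tr.times.max()) for tr in trains), default=0)
        duration = (last + int(0.05 * fs)) / fs
    n = int(round(duration * fs))
    out = np.zeros((geometry.n_channels, n))
    for spec, train in zip(specs, trains):
        if train.fs != fs:
            raise ValueError("train fs must match geometry fs")
        bank = make_propagating_template(
            spec, geometry, decay_rows=decay_rows, end_of_fiber_amp=end_of_fiber_amp
        )
        spikes = np.zeros(n)
        idx = np.round(train.times).astype(np.int64)
        spikes[idx[(idx >= 0) & (idx < n)]] = 1.0
        tmpl = bank.waveforms.reshape(geometry.n_channels, bank.length)
        spikes_mat = np.broadcast_to(spikes, (geometry.n_channels, n)).copy()
        out += sps.fftconvolve(spikes_mat, tmpl, mode="same", axes=1)
    if noise_rms > 0:
        rng = np.random.default_rng(seed)
        out += rng.normal(0.0, noise_rms, size=out.shape)
    return EMGRecording(signal=out, geometry=geometry, t0=t0)


def decomposition_fixture(
    n_mus: int = 5,
    duration: float = 5.0,
    noise_rms: float = 1.0,
    seed: Optional[int] = None,
    geometry: Optional[GridGeometry] = None,
):
    """Canonical high-SNR single-contraction fixture for decomposition
    validation: ``n_mus`` motor units with well-separated conduction
    velocities (evenly spread over 3.6-5.4 m/s), distinct innervation-zone
    rows and amplitudes, at low baseline noise.

    Mirrors the property of real decompositions that the retained units
    are the mutually distinguishable ones.  Returns
    ``(specs, trains, recording)`` with the ground truth attached.
    """
    geometry = geometry if geometry is not None else GridGeometry()
    if not (1 <= n_mus <= 8):
        raise ValueError("fixture supports 1-8 motor units")
    rng = np.random.default_rng(seed)
    cvs = np.linspace(3.6, 5.4, n_mus) + rng.uniform(-0.05, 0.05, n_mus)
    iz_lo = geometry.n_rows // 3
    iz_choices = rng.permutation(np.arange(iz_lo, geometry.n_rows - iz_lo))
    specs = []
    for k in range(n_mus):
        specs.append(
            MotorUnitSpec(
                mu_id=f"mu{k}",
                mean_dr=float(rng.uniform(10.0, 16.0)),
                isi_cv=0.15,
                cv_true=float(cvs[k]),
                iz_row=int(iz_choices[k % iz_choices.size]),
                amp=float(rng.uniform(70.0, 130.0)),
            )
        )
    trains = [
        generate_discharge_train(
            s.mean_dr, s.isi_cv, duration, geometry.fs,
            seed=int(rng.integers(0, 2**31)), mu_id=s.mu_id,
        )
        for s in specs
    ]
    rec = synthesize_emg(
        specs, trains, geometry, duration=duration, noise_rms=noise_rms,
        seed=int(rng.integers(0, 2**31)),
    )
    return specs, trains, rec


# ---------------------------------------------------------------------------
# Session / cohort level
# ---------------------------------------------------------------------------


def _cond_dict(con: float, h1: float, h2: float) -> dict:
    return {"CON": con, "H1": h1, "H2": h2}


@dataclass
class ConditionEffects:
    """Condition- and sex-dependent generating parameters.

    Discharge rate (pps) and conduction velocity (m/s) of a motor unit are
    drawn as ``base + sex offset + condition shift + subject intercept +
    MU-level noise``.  Cardiorespiratory levels are per-condition means of
    the exercise-phase breath-by-breath series; SpO2 is an endpoint value.
    """

    # motor-unit properties
    dr_base: float = 15.5
    dr_sex: dict = field(default_factory=lambda: {"F": 0.75, "M": -0.75})
    dr_shift: dict = field(default_factory=lambda: _cond_dict(0.0, 0.3, 1.0))
    cv_base: float = 4.1
    cv_sex: dict = field(default_factory=lambda: {"F": -0.35, "M": 0.35})
    cv_shift: dict = field(default_factory=lambda: _cond_dict(0.0, 0.10, 0.25))
    subject_sd_dr: float = 1.5
    subject_sd_cv: float = 0.4
    mu_sd_dr: float = 2.0
    mu_sd_cv: float = 0.35
    isi_cv: float = 0.15
    # cardiorespiratory levels during the physical task
    spo2_mean: dict = field(default_factory=lambda: _cond_dict(97.1, 91.3, 86.9))
    spo2_sd: dict = field(default_factory=lambda: _cond_dict(0.90, 1.60, 1.83))
    hr_mean: dict = field(default_factory=lambda: _cond_dict(95.0, 103.0, 110.0))
    ve_mean: dict = field(default_factory=lambda: _cond_dict(30.0, 35.0, 41.0))
    vo2_mean: dict = field(default_factory=lambda: _cond_dict(900.0, 940.0, 990.0))
    hr_sd: float = 3.0
    ve_sd: float = 3.0
    vo2_sd: float = 60.0
    subject_sd_hr: float = 5.0
    subject_sd_ve: float = 3.0
    subject_sd_vo2: float = 80.0
    breath_interval: float = 2.5  # s
    outlier_frac: float = 0.02  # breath-by-breath contamination rate

    @classmethod
    def null(cls) -> "ConditionEffects":
        """All condition shifts zero: CON/H1/H2 statistically exchangeable."""
        eff = cls()
        return replace(
            eff,
            dr_shift=_cond_dict(0.0, 0.0, 0.0),
            cv_shift=_cond_dict(0.0, 0.0, 0.0),
            hr_mean=_cond_dict(95.0, 95.0, 95.0),
            ve_mean=_cond_dict(30.0, 30.0, 30.0),
            vo2_mean=_cond_dict(900.0, 900.0, 900.0),
            spo2_mean=_cond_dict(97.1, 97.1, 97.1),
            spo2_sd=_cond_dict(0.90, 0.90, 0.90),
        )


def make_mu_pool(
    n_mus: int,
    geometry: GridGeometry,
    rng: np.random.Generator,
    dr_center: float = 15.0,
    cv_center: float = 4.2,
    mu_sd_dr: float = 2.0,
    mu_sd_cv: float = 0.35,
    isi_cv: float = 0.15,
    prefix: str = "mu",
) -> list[MotorUnitSpec]:
    """Draw a pool of MU specs with the stated centres and spreads.

    Innervation-zone rows are drawn without replacement from the middle
    third of the grid while they last (motor-unit territories are spread
    along the muscle, and units sharing both innervation zone and
    conduction velocity are indistinguishable at the grid).
    """
    iz_lo = geometry.n_rows // 3
    iz_hi = geometry.n_rows - geometry.n_rows // 3
    iz_band = np.arange(iz_lo, iz_hi)
    iz_rows = np.concatenate(
        [rng.permutation(iz_band) for _ in range(n_mus // iz_band.size + 1)]
    )
    specs = []
    for k in range(n_mus):
        dr = float(np.clip(rng.normal(dr_center, mu_sd_dr), 8.0, 30.0))
        cv = float(np.clip(rng.normal(cv_center, mu_sd_cv), 2.5, 7.0))
        iz = int(iz_rows[k])
        amp = float(rng.uniform(50.0, 150.0))
        specs.append(
            MotorUnitSpec(
                mu_id=f"{prefix}{k}",
                mean_dr=dr,
                isi_cv=isi_cv,
                cv_true=cv,
                iz_row=iz,
                amp=amp,
            )
        )
    return specs


def _simulate_bxb(
    rng: np.random.Generator,
    duration: float,
    effects: ConditionEffects,
    condition: str,
    subject_offsets: dict,
) -> BxBSeries:
    intervals = rng.uniform(
        0.8 * effects.breath_interval, 1.2 * effects.breath_interval, size=int(duration)
    )
    times = np.cumsum(intervals)
    times = times[times < duration]
    n = times.size
    hr = effects.hr_mean[condition] + subject_offsets["hr"] + rng.normal(0, effects.hr_sd, n)
    ve = effects.ve_mean[condition] + subject_offsets["ve"] + rng.normal(0, effects.ve_sd, n)
    vo2 = (
        effects.vo2_mean[condition]
        + subject_offsets["vo2"]
        + rng.normal(0, effects.vo2_sd, n)
    )
    ve = np.maximum(ve, 2.0)
    vo2 = np.maximum(vo2, 100.0)
    # sparse breath artifacts (sensor glitches) for the cleaning stage
    if effects.outlier_frac > 0 and n > 0:
        mask = rng.random(n) < effects.outlier_frac
        sign = rng.choice([-1.0, 1.0], size=n)
        hr = hr + mask * sign * rng.uniform(6, 12, n) * effects.hr_sd
        ve = ve + mask * sign * rng.uniform(6, 12, n) * effects.ve_sd
        vo2 = vo2 + mask * sign * rng.uniform(6, 12, n) * effects.vo2_sd
    return BxBSeries(times=times, hr=hr, ve=ve, vo2=vo2, cleaned=False)


def simulate_session(
    participant_id: str,
    sex: str,
    condition: str,
    effects: Optional[ConditionEffects] = None,
    seed: Optional[int] = None,
    geometry: Optional[GridGeometry] = None,
    n_mus: int = 5,
    n_contractions: int = 9,
    contraction_s: float = 5.0,
    rest_s: float = 15.0,
    noise_rms: float = 2.0,
    subject_offsets: Optional[dict] = None,
    synthesize_signal: bool = True,
) -> SessionRecord:
    """Simulate one participant x condition session.

    Returns ``n_contractions`` EMG segments of ``contraction_s`` seconds
    (EMG is synthesized only for the contraction windows; ``t0`` encodes
    protocol timing), a breath-by-breath series covering the task, and an
    endpoint SpO2.  Ground-truth MU specs and trains are retained in
    ``SessionRecord.ground_truth`` for recovery tests.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    effects = effects if effects is not None else ConditionEffects()
    geometry = geometry if geometry is not None else GridGeometry()
    rng = np.random.default_rng(seed)
    if subject_offsets is None:
        subject_offsets = {
            "dr": rng.normal(0, effects.subject_sd_dr),
            "cv": rng.normal(0, effects.subject_sd_cv),
            "hr": rng.normal(0, effects.subject_sd_hr),
            "ve": rng.normal(0, effects.subject_sd_ve),
            "vo2": rng.normal(0, effects.subject_sd_vo2),
        }
    dr_center = (
        effects.dr_base
        + effects.dr_sex[sex]
        + effects.dr_shift[condition]
        + subject_offsets["dr"]
    )
    cv_center = (
        effects.cv_base
        + effects.cv_sex[sex]
        + effects.cv_shift[condition]
        + subject_offsets["cv"]
    )
    specs = make_mu_pool(
        n_mus,
        geometry,
        rng,
        dr_center=dr_center,
        cv_center=cv_center,
        mu_sd_dr=effects.mu_sd_dr,
        mu_sd_cv=effects.mu_sd_cv,
        isi_cv=effects.isi_cv,
        prefix=f"{participant_id}_{condition}_mu",
    )
    contractions = []
    all_trains = []
    for k in range(n_contractions if synthesize_signal else 0):
        trains = [
            generate_discharge_train(
                s.mean_dr,
                s.isi_cv,
                contraction_s,
                geometry.fs,
                seed=rng.integers(0, 2**31),
                mu_id=s.mu_id,
            )
            for s in specs
        ]
        rec = synthesize_emg(
            specs,
            trains,
            geometry,
            duration=contraction_s,
            noise_rms=noise_rms,
            seed=int(rng.integers(0, 2**31)),
            t0=k * (contraction_s + rest_s),
        )
        contractions.append(rec)
        all_trains.append(trains)
    task_duration = n_contractions * (contraction_s + rest_s)
    bxb = _simulate_bxb(rng, task_duration, effects, condition, subject_offsets)
    spo2 = float(
        np.clip(
            rng.normal(effects.spo2_mean[condition], effects.spo2_sd[condition]),
            50.0,
            100.0,
        )
    )
    return SessionRecord(
        participant_id=participant_id,
        sex=sex,
        condition=condition,
        contractions=contractions,
        bxb=bxb,
        spo2_end=spo2,
        ground_truth={
            "specs": specs,
            "trains": all_trains,
            "subject_offsets": subject_offsets,
            "noise_rms": noise_rms,
        },
    )


def simulate_cohort(
    n_f: int = 9,
    n_m: int = 9,
    conditions: Sequence[str] = CONDITIONS,
    effects: Optional[ConditionEffects] = None,
    seed: Optional[int] = None,
    **session_kwargs,
) -> list[SessionRecord]:
    """Simulate a crossover cohort: every participant in every condition.

    Subject-level random offsets are drawn once per participant so that
    the within-subject correlation structure matches the crossover design.
    """
    effects = effects if effects is not None else ConditionEffects()
    rng = np.random.default_rng(seed)
    sessions = []
    participants = [("F", f"F{i+1:02d}") for i in range(n_f)] + [
        ("M", f"M{i+1:02d}") for i in range(n_m)
    ]
    for sex, pid in participants:
        offsets = {
            "dr": rng.normal(0, effects.subject_sd_dr),
            "cv": rng.normal(0, effects.subject_sd_cv),
            "hr": rng.normal(0, effects.subject_sd_hr),
            "ve": rng.normal(0, effects.subject_sd_ve),
            "vo2": rng.normal(0, effects.subject_sd_vo2),
        }
        for cond in conditions:
            sessions.append(
                simulate_session(
                    pid,
                    sex,
                    cond,
                    effects=effects,
                    seed=int(rng.integers(0, 2**31)),
                    subject_offsets=offsets,
                    **session_kwargs,
                )
            )
    return sessions


def simulate_mu_property_table(
    n_f: int = 9,
    n_m: int = 9,
    n_mus: int = 8,
    effects: Optional[ConditionEffects] = None,
    seed: Optional[int] = None,
):
    """Draw per-MU discharge rate and conduction velocity observations
    directly from the generator's statistical model (no signal synthesis).

    Used for statistical calibration studies where thousands of cohorts
    are needed; the distributional structure (condition + sex + subject
    intercept + MU-level noise) is identical to ``simulate_session``.

    Returns a DataFrame with columns participant, sex, condition, mu_id,
    idr (pps) and cv (m/s).
    """
    import pandas as pd

    effects = effects if effects is not None else ConditionEffects()
    rng = np.random.default_rng(seed)
    rows = []
    participants = [("F", f"F{i+1:02d}") for i in range(n_f)] + [
        ("M", f"M{i+1:02d}") for i in range(n_m)
    ]
    for sex, pid in participants:
        b_dr = rng.normal(0, effects.subject_sd_dr)
        b_cv = rng.normal(0, effects.subject_sd_cv)
        for cond in CONDITIONS:
            dr_c = effects.dr_base + effects.dr_sex[sex] + effects.dr_shift[cond] + b_dr
            cv_c = effects.cv_base + effects.cv_sex[sex] + effects.cv_shift[cond] + b_cv
            for k in range(n_mus):
                rows.append(
                    {
                        "participant": pid,
                        "sex": sex,
                        "condition": cond,
                        "mu_id": f"{pid}_{cond}_mu{k}",
                        "idr": max(rng.normal(dr_c, effects.mu_sd_dr), 1.0),
                        "cv": float(np.clip(rng.normal(cv_c, effects.mu_sd_cv), 2.0, 8.0)),
                    }
                )
    return pd.DataFrame(rows)


def render_session_signal(
    session: SessionRecord,
    rest_s: float = 15.0,
    noise_rms: Optional[float] = None,
    seed: Optional[int] = None,
) -> EMGRecording:
    """Concatenate a session's contraction segments into one continuous
    recording with noise-only rest gaps, for exercising envelope-based
    contraction detection."""
    if not session.contractions:
        raise ValueError("session has no contractions")
    geometry = session.contractions[0].geometry
    fs = geometry.fs
    if noise_rms is None:
        noise_rms = (
            session.ground_truth.get("noise_rms", 2.0) if session.ground_truth else 2.0
        )
    rng = np.random.default_rng(seed)
    gap = int(round(rest_s * fs))
    pieces = []
    for k, rec in enumerate(session.contractions):
        pieces.append(rec.signal)
        if k < len(session.contractions) - 1:
            pieces.append(rng.normal(0, noise_rms, size=(geometry.n_channels, gap)))
    return EMGRecording(signal=np.concatenate(pieces, axis=1), geometry=geometry, t0=0.0)
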