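"""Discharge-rate profiles, spike-triggered averaging, channel selection
and conduction-velocity estimation."""

import numpy as np
import pytest
from hdemg_hypoxia.core import DDRecording, DischargeTrain
from hdemg_hypoxia.dsp import fractional_shift
from hdemg_hypoxia.muprops import (
    MUAPTemplate,
    compute_idr,
    estimate_cv,
    hanning_kernel,
    mu_cv,
    select_cv_channels,
    smooth_idr,
    sta_muap,
    summarize_mus,
)
from hdemg_hypoxia.preprocess import double_differential
from hdemg_hypoxia.simulate import (
    MotorUnitSpec,
    generate_discharge_train,
    synthesize_emg,
)

FS = 2048.0


def _train_from_s(times_s, fs=FS):
    return DischargeTrain(times=np.asarray(times_s) * fs, fs=fs)


class TestIDR:
    def test_reciprocal_isi(self):
        prof = compute_idr(_train_from_s([0.0, 0.1, 0.2]))
        assert np.allclose(prof.idr, [10.0, 10.0])
        prof = compute_idr(_train_from_s([0.0, 0.05]))
        assert np.allclose(prof.idr, [20.0])

    def test_single_discharge_rejected(self):
        with pytest.raises(ValueError):
            compute_idr(_train_from_s([0.1]))

    def test_ground_truth_rate_recovery(self):
        vals = []
        for seed in range(20):
            tr = generate_discharge_train(15.0, 0.1, 5.0, FS, seed=seed)
            vals.append(np.mean(compute_idr(tr).idr))
        assert abs(np.mean(vals) - 15.0) / 15.0 < 0.05


def _smooth_brute_force(x, kern):
    """Independent renormalized weighted average (explicit loop)."""
    n, k = len(x), len(kern)
    off = (k - 1) // 2
    out = np.zeros(n)
    for i in range(n):
        num = den = 0.0
        for j in range(k):
            idx = i - off + j
            if 0 <= idx < n:
                num += kern[j] * x[idx]
                den += kern[j]
        out[i] = num / den
    return out


class TestSmoothIDR:
    def test_kernel_has_nonzero_endpoints_and_unit_sum(self):
        k = hanning_kernel(4)
        assert k.sum() == pytest.approx(1.0)
        assert np.all(k > 0)
        assert np.allclose(k, k[::-1])

    def test_constant_sequence_preserved(self):
        prof = smooth_idr(compute_idr(_train_from_s(np.arange(1, 12) * 0.1)))
        assert np.allclose(prof.smoothed, 10.0)
        assert prof.mean_smoothed_dr == pytest.approx(10.0)

    def test_matches_brute_force_oracle(self, rng):
        # profiles built from synthetic IDR sequences of varying length
        kern = hanning_kernel(4)
        for _ in range(20):
            x = rng.uniform(8, 25, size=int(rng.integers(4, 40)))
            times = np.concatenate([[0.0], np.cumsum(1.0 / x)])
            prof = smooth_idr(compute_idr(_train_from_s(times)))
            assert np.allclose(prof.smoothed, _smooth_brute_force(prof.idr, kern),
                               atol=1e-12, rtol=1e-12)

    def test_short_train_falls_back_to_raw_mean(self):
        prof = smooth_idr(compute_idr(_train_from_s([0.0, 0.1, 0.15])))
        assert prof.fallback
        assert prof.mean_smoothed_dr == pytest.approx(np.mean([10.0, 20.0]))


class TestSTA:
    def _noiseless_setup(self, geometry, seed=0):
        spec = MotorUnitSpec("m", 11.0, 0.1, 4.5, iz_row=6, amp=100.0)
        tr = generate_discharge_train(11.0, 0.1, 5.0, geometry.fs, seed=seed)
        rec = synthesize_emg([spec], [tr], geometry, duration=5.0, noise_rms=0.0)
        return spec, tr, double_differential(rec)

    def test_window_length_and_trigger_count(self, geometry):
        _, tr, dd = self._noiseless_setup(geometry)
        t = sta_muap(dd, tr, window_ms=50.0)
        assert t.waveforms.shape == (11, 5, round(0.050 * geometry.fs))
        assert t.n_triggers + t.n_dropped == tr.n_discharges

    def test_noiseless_sta_equals_template(self, geometry):
        # every window is an identical realization -> STA reproduces it
        spec, tr, dd = self._noiseless_setup(geometry)
        t = sta_muap(dd, tr)
        mid = np.round(tr.times).astype(int)[3]
        seg = dd.as_grid()[:, :, mid - 51 : mid + 51]
        rel = np.abs(t.waveforms - seg).max() / np.abs(seg).max()
        assert rel < 1e-6

    def test_edge_trigger_dropped(self, small_geometry, rng):
        n = 2048
        dd = DDRecording(
            signal=rng.normal(size=((small_geometry.n_rows - 2) * small_geometry.n_cols, n)),
            geometry=small_geometry,
        )
        tr = DischargeTrain(times=np.array([10.0, 500.0, 1000.0]), fs=small_geometry.fs)
        t = sta_muap(dd, tr, window_ms=50.0)
        assert t.n_dropped == 1 and t.n_triggers == 2

    def test_noise_sta_shrinks_with_triggers(self, small_geometry, rng):
        n = int(60 * small_geometry.fs)
        dd = DDRecording(
            signal=rng.normal(size=((small_geometry.n_rows - 2) * small_geometry.n_cols, n)),
            geometry=small_geometry,
        )
        amps = {}
        for n_trig in (10, 160):
            times = np.linspace(200, n - 200, n_trig)
            t = sta_muap(dd, DischargeTrain(times=times, fs=small_geometry.fs))
            amps[n_trig] = np.sqrt(np.mean(t.waveforms**2))
        # RMS of averaged noise scales ~ 1/sqrt(n): 4x more triggers -> ~4x smaller
        assert amps[160] < amps[10] / 2.5


def _dd_template_bank(cv, fs=FS, ied=8.0, n_rows=6, length=102, jitter=0.0, rng=None):
    """DD-domain propagating template built directly from shifted wavelets."""
    t = np.arange(length)
    base = np.exp(-((t - 45.0) ** 2) / 8.0) * np.sin((t - 45.0) / 1.5)
    theta = ied / 1000.0 * fs / cv
    waves = np.zeros((n_rows, 1, length))
    for r in range(n_rows):
        w = fractional_shift(base, r * theta)
        if rng is not None and jitter > 0:
            w = w + rng.normal(0, jitter * np.sqrt(np.mean(base**2)), length)
        waves[r, 0] = w
    return MUAPTemplate(waveforms=waves, fs=fs, ied=ied, n_triggers=10)


class TestChannelSelection:
    def test_zero_lag_rejected(self):
        tmpl = _dd_template_bank(cv=4.0)
        tmpl.waveforms[:, 0, :] = tmpl.waveforms[0, 0, :]  # identical channels
        assert select_cv_channels(tmpl) is None

    def test_column_priority_by_mean_xcorr(self, rng):
        a = _dd_template_bank(cv=4.0, jitter=0.02, rng=np.random.default_rng(0))
        b = _dd_template_bank(cv=4.0, jitter=0.25, rng=np.random.default_rng(1))
        tmpl = MUAPTemplate(
            waveforms=np.concatenate([b.waveforms, a.waveforms], axis=1),
            fs=FS,
            ied=8.0,
            n_triggers=10,
        )
        sel = select_cv_channels(tmpl)
        assert sel is not None
        rows, col, mean_x, _ = sel
        assert col == 1  # the cleaner column wins

    def test_run_avoids_innervation_zone(self, geometry):
        spec = MotorUnitSpec("m", 11.0, 0.1, 4.0, iz_row=6, amp=100.0)
        tr = generate_discharge_train(11.0, 0.1, 5.0, geometry.fs, seed=2)
        rec = synthesize_emg([spec], [tr], geometry, duration=5.0, noise_rms=0.0)
        tmpl = sta_muap(double_differential(rec), tr)
        sel = select_cv_channels(tmpl)
        assert sel is not None
        rows, _, _, _ = sel
        # the DD channel centred on the innervation zone (monopolar row 6
        # -> DD row 5) must not be part of the selected run
        assert 5 not in rows


class TestEstimateCV:
    def test_forced_arithmetic_4_sample_shift(self):
        length = 102
        t = np.arange(length)
        base = np.exp(-((t - 40.0) ** 2) / 18.0) * np.sin((t - 40.0) / 2.0)
        waves = np.zeros((2, 1, length))
        waves[0, 0] = base
        waves[1, 0] = np.roll(base, 4)
        tmpl = MUAPTemplate(waveforms=waves, fs=2048.0, ied=8.0, n_triggers=10)
        est = estimate_cv(tmpl, [0, 1], 0)
        assert est.cv == pytest.approx(4.096, abs=1e-9)

    @pytest.mark.parametrize("cv_true", [3.0, 4.5, 6.0])
    def test_noiseless_subsample_recovery(self, cv_true):
        tmpl = _dd_template_bank(cv=cv_true, n_rows=4)
        est = estimate_cv(tmpl, [0, 1, 2, 3], 0)
        assert abs(est.cv - cv_true) / cv_true < 0.01

    def test_estimated_delay_decreases_with_cv(self):
        thetas = []
        for cv in (3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0):
            est = estimate_cv(_dd_template_bank(cv=cv, n_rows=4), [0, 1, 2, 3], 0)
            thetas.append(est.delay_per_ied)
        assert np.all(np.diff(thetas) < 0)

    def test_full_pipeline_recovery(self, geometry):
        spec = MotorUnitSpec("m", 11.0, 0.1, 4.5, iz_row=6, amp=100.0)
        tr = generate_discharge_train(11.0, 0.1, 5.0, geometry.fs, seed=1)
        rec = synthesize_emg([spec], [tr], geometry, duration=5.0, noise_rms=0.0)
        est = mu_cv(double_differential(rec), tr)
        assert est is not None
        assert abs(est.cv - 4.5) / 4.5 < 0.01

    def test_noncontiguous_channels_rejected(self):
        tmpl = _dd_template_bank(cv=4.0, n_rows=4)
        with pytest.raises(ValueError):
            estimate_cv(tmpl, [0, 2], 0)


class TestSummaries:
    def test_median_resists_outlier(self):
        table = [
            {"participant": "P1", "condition": "CON", "cv": v, "idr": 12.0}
            for v in (3.8, 4.0, 9.9)
        ]
        out = summarize_mus(table)
        assert out.loc[0, "cv"] == pytest.approx(4.0)

    def test_single_mu_median_is_value(self):
        out = summarize_mus([{"participant": "P1", "condition": "H2", "cv": 4.2, "idr": 14.0}])
        assert out.loc[0, "cv"] == pytest.approx(4.2)
        assert out.loc[0, "n_cv"] == 1

    def test_missing_cv_propagates(self):
        table = [
            {"participant": "P1", "condition": "CON", "cv": np.nan, "idr": 12.0},
            {"participant": "P1", "condition": "CON", "cv": np.nan, "idr": 14.0},
        ]
        out = summarize_mus(table)
        assert np.isnan(out.loc[0, "cv"])
        assert out.loc[0, "n_cv"] == 0
        assert out.loc[0, "idr"] == pytest.approx(13.0)
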