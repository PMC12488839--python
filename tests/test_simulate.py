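"""Generator ground truth: discharge statistics, propagation physics,
superposition, and session structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdemg_hypoxia.core import REFRACTORY_FLOOR_S, GridGeometry
from hdemg_hypoxia.dsp import xcorr_peak
from hdemg_hypoxia.simulate import (
    ConditionEffects,
    MotorUnitSpec,
    generate_discharge_train,
    make_propagating_template,
    simulate_mu_property_table,
    simulate_session,
    synthesize_emg,
)


class TestDischargeTrain:
    def test_zero_variance_train_is_perfectly_regular(self):
        tr = generate_discharge_train(10.0, 0.0, 1.0, 2048.0)
        assert tr.n_discharges == 10
        assert np.allclose(np.diff(tr.times_s), 0.1)

    def test_monte_carlo_rate_recovery(self):
        rates = []
        for seed in range(20):
            tr = generate_discharge_train(15.0, 0.15, 5.0, 2048.0, seed=seed)
            rates.append(np.mean(1.0 / np.diff(tr.times_s)))
        assert abs(np.mean(rates) - 15.0) / 15.0 < 0.05

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_discharge_train(10.0, 0.1, 0.05, 2048.0)

    def test_refractory_floor_never_violated(self):
        for seed in range(10):
            tr = generate_discharge_train(25.0, 0.3, 10.0, 2048.0, seed=seed)
            assert np.diff(tr.times_s).min() >= REFRACTORY_FLOOR_S - 1e-12

    def test_isi_cv_converges_at_large_n(self):
        # >= 200 discharges: empirical ISI CV within 10% of the parameter
        tr = generate_discharge_train(15.0, 0.2, 30.0, 2048.0, seed=7)
        assert tr.n_discharges >= 200
        isi = np.diff(tr.times_s)
        assert abs(isi.std() / isi.mean() - 0.2) / 0.2 < 0.10

    def test_determinism(self):
        a = generate_discharge_train(12.0, 0.15, 5.0, 2048.0, seed=3)
        b = generate_discharge_train(12.0, 0.15, 5.0, 2048.0, seed=3)
        assert np.array_equal(a.times, b.times)


class TestPropagatingTemplate:
    def test_forced_integer_delay(self, geometry):
        # ied 8 mm, cv 4.096 m/s at 2048 Hz -> exactly 4 samples per row
        spec = MotorUnitSpec("m", 12, 0.1, 4.096, iz_row=6)
        bank = make_propagating_template(spec, geometry)
        coef, lag = xcorr_peak(bank.waveforms[7, 0], bank.waveforms[8, 0], 20)
        assert coef > 0.999
        assert abs(lag - 4.0) < 0.05

    def test_bidirectional_symmetry(self, geometry):
        spec = MotorUnitSpec("m", 12, 0.1, 4.5, iz_row=6)
        bank = make_propagating_template(spec, geometry)
        # rows equidistant from the innervation zone are identical
        assert np.allclose(bank.waveforms[5, 0], bank.waveforms[7, 0])
        assert np.allclose(bank.waveforms[2, 3], bank.waveforms[10, 3])

    def test_delay_inversely_proportional_to_cv(self, geometry):
        lags = {}
        for cv in (3.0, 6.0):
            spec = MotorUnitSpec("m", 12, 0.1, cv, iz_row=6)
            bank = make_propagating_template(spec, geometry)
            _, lag = xcorr_peak(bank.waveforms[8, 0], bank.waveforms[9, 0], 20)
            lags[cv] = lag
        assert abs(lags[3.0] / lags[6.0] - 2.0) < 0.05

    def test_amplitude_decay(self, geometry):
        spec = MotorUnitSpec("m", 12, 0.1, 4.5, iz_row=6, amp=100.0, dur_ms=6.0)
        bank = make_propagating_template(spec, geometry, decay_rows=3.0)
        peaks = np.abs(bank.waveforms[:, 0, :]).max(axis=1)
        # sampled peak sits within one sample of the analytic maximum
        assert np.isclose(peaks[6], 100.0, rtol=2e-2)
        assert np.isclose(peaks[9] / peaks[6], np.exp(-1.0), rtol=3e-2)

    def test_invalid_cv_rejected(self, geometry):
        spec = MotorUnitSpec("m", 12, 0.1, -1.0, iz_row=6)
        with pytest.raises(ValueError):
            make_propagating_template(spec, geometry)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        cv=st.floats(2.5, 7.0),
        ied=st.floats(4.0, 12.0),
        row=st.integers(7, 11),
    )
    def test_delay_arithmetic_property(self, cv, ied, row):
        # measured inter-row lag equals ied / cv (in samples) within 0.05
        geom = GridGeometry(n_rows=13, n_cols=5, ied=ied, fs=2048.0)
        spec = MotorUnitSpec("m", 12, 0.1, cv, iz_row=6)
        bank = make_propagating_template(spec, geom)
        _, lag = xcorr_peak(
            bank.waveforms[row - 1, 0],
            bank.waveforms[row, 0],
            int(np.ceil(ied / 1000 / cv * 2048)) + 3,
        )
        expected = ied / 1000.0 / cv * 2048.0
        assert abs(abs(lag) - expected) < 0.05


class TestSynthesizeEMG:
    def test_noiseless_superposition_is_linear(self, small_geometry):
        g = small_geometry
        s1 = MotorUnitSpec("a", 10, 0.0, 4.0, iz_row=3, amp=80)
        s2 = MotorUnitSpec("b", 13, 0.0, 5.0, iz_row=2, amp=60)
        t1 = generate_discharge_train(10, 0.0, 2.0, g.fs, mu_id="a")
        t2 = generate_discharge_train(13, 0.0, 2.0, g.fs, mu_id="b")
        both = synthesize_emg([s1, s2], [t1, t2], g, duration=2.0)
        a = synthesize_emg([s1], [t1], g, duration=2.0)
        b = synthesize_emg([s2], [t2], g, duration=2.0)
        assert np.allclose(both.signal, a.signal + b.signal, atol=1e-10)

    def test_noise_only_rms(self, small_geometry):
        rec = synthesize_emg([], [], small_geometry, duration=5.0, noise_rms=5.0, seed=1)
        rms = np.sqrt(np.mean(rec.signal**2, axis=1))
        assert np.all(np.abs(rms - 5.0) / 5.0 < 0.05)

    def test_determinism(self, small_geometry):
        g = small_geometry
        s = MotorUnitSpec("a", 10, 0.1, 4.0, iz_row=3)
        t = generate_discharge_train(10, 0.1, 2.0, g.fs, seed=2)
        r1 = synthesize_emg([s], [t], g, duration=2.0, noise_rms=2.0, seed=9)
        r2 = synthesize_emg([s], [t], g, duration=2.0, noise_rms=2.0, seed=9)
        assert np.array_equal(r1.signal, r2.signal)


class TestSession:
    def test_session_structure_and_determinism(self, small_geometry):
        kw = dict(
            effects=ConditionEffects(),
            seed=11,
            geometry=small_geometry,
            n_mus=2,
            n_contractions=3,
            contraction_s=1.0,
        )
        s1 = simulate_session("P01", "F", "H2", **kw)
        s2 = simulate_session("P01", "F", "H2", **kw)
        assert len(s1.contractions) == 3
        assert all(r.duration == pytest.approx(1.0) for r in s1.contractions)
        assert s1.spo2_end == s2.spo2_end
        for a, b in zip(s1.contractions, s2.contractions):
            assert np.array_equal(a.signal, b.signal)
        assert s1.bxb.n_breaths > 0

    def test_unknown_condition_rejected(self, small_geometry):
        with pytest.raises(ValueError):
            simulate_session("P01", "F", "H3", geometry=small_geometry)

    def test_spo2_default_means(self):
        eff = ConditionEffects()
        spo2 = {
            c: np.mean(
                [
                    simulate_session(
                        "P", "M", c, effects=eff, seed=s, n_mus=0,
                        n_contractions=0,
                    ).spo2_end
                    for s in range(60)
                ]
            )
            for c in ("CON", "H2")
        }
        assert abs(spo2["CON"] - 97.1) < 0.5
        assert abs(spo2["H2"] - 86.9) < 1.0

    def test_property_table_effect_directions(self):
        df = simulate_mu_property_table(seed=0)
        by_cond = df.groupby("condition")[["idr", "cv"]].mean()
        assert by_cond.loc["H2", "cv"] > by_cond.loc["CON", "cv"]
        assert by_cond.loc["H2", "idr"] > by_cond.loc["CON", "idr"]
        by_sex = df.groupby("sex")["cv"].mean()
        assert by_sex["M"] > by_sex["F"]

    def test_null_configuration_exchangeable_means(self):
        df = simulate_mu_property_table(effects=ConditionEffects.null(), seed=0, n_mus=40)
        by_cond = df.groupby("condition")["cv"].mean()
        assert by_cond.max() - by_cond.min() < 0.1
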