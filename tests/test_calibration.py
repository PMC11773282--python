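"""Level calibration, RETSPL derivation, A-weighted metering, and the noise gate."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pedscreen.calibration import (
    CalibrationTable,
    MissingFrequencyError,
    NoiseGateConfig,
    OutOfRangeError,
    RetsplTable,
    default_headphone_retspl,
    default_soundfield_retspl,
    derive_retspl_wilber,
    hl_to_spl,
    measure_dba,
    measure_harmonic_distortion,
    noise_gate,
    spl_to_hl,
    spl_to_volume,
    volume_to_spl,
)
from pedscreen.stimuli import Waveform

FS = 44_100
SIMPLE = CalibrationTable({1000.0: [(50.0, 60.0), (100.0, 80.0)]})


def _piecewise_oracle(pairs, v):
    """Brute-force segment search + line equation, independent of np.interp."""
    for (v0, s0), (v1, s1) in zip(pairs, pairs[1:]):
        if v0 <= v <= v1:
            return s0 + (s1 - s0) * (v - v0) / (v1 - v0)
    raise AssertionError("query outside table")


class TestVolumeSpl:
    def test_linear_midpoint(self):
        assert volume_to_spl(SIMPLE, 1000, 75) == pytest.approx(70.0)

    def test_passes_through_knots(self):
        table = CalibrationTable({1000.0: [(20.0, 40.0), (50.0, 61.0), (90.0, 78.0)]})
        for v, s in table.points[1000.0]:
            assert volume_to_spl(table, 1000, v) == pytest.approx(s)

    def test_matches_segment_search_oracle_and_monotone(self):
        rng = np.random.default_rng(7)
        vols = np.sort(rng.uniform(0, 100, 5))
        spls = np.sort(rng.uniform(40, 90, 5))
        pairs = list(zip(vols, spls))
        table = CalibrationTable({1000.0: pairs})
        queries = np.sort(rng.uniform(vols[0], vols[-1], 100))
        outs = [volume_to_spl(table, 1000, q) for q in queries]
        for q, o in zip(queries, outs):
            assert o == pytest.approx(_piecewise_oracle(pairs, q), abs=1e-9)
        assert all(b >= a - 1e-12 for a, b in zip(outs, outs[1:]))

    def test_no_extrapolation(self):
        with pytest.raises(OutOfRangeError):
            volume_to_spl(SIMPLE, 1000, 101)
        with pytest.raises(OutOfRangeError):
            spl_to_volume(SIMPLE, 1000, 85)

    def test_inverse_linear(self):
        assert spl_to_volume(SIMPLE, 1000, 70) == pytest.approx(75.0)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(1)
        vols = np.sort(rng.uniform(0, 100, 6))
        spls = np.sort(rng.uniform(40, 90, 6))
        spls += np.arange(6) * 1e-3  # strictly increasing segments
        table = CalibrationTable({2000.0: list(zip(vols, spls))})
        for spl in rng.uniform(spls[0], spls[-1], 50):
            back = volume_to_spl(table, 2000, spl_to_volume(table, 2000, spl))
            assert back == pytest.approx(spl, abs=1e-6)

    def test_unknown_frequency(self):
        with pytest.raises(MissingFrequencyError):
            volume_to_spl(SIMPLE, 250, 75)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            CalibrationTable({1000.0: [(50.0, 60.0)]})
        with pytest.raises(ValueError):
            CalibrationTable({1000.0: [(50.0, 60.0), (50.0, 70.0)]})
        with pytest.raises(ValueError):
            CalibrationTable({1000.0: [(50.0, 60.0), (60.0, 55.0)]})


class TestRetspl:
    def test_packaged_headphone_table_values(self):
        table = default_headphone_retspl()
        assert table.values == {500.0: 11, 1000.0: 1, 2000.0: 3, 4000.0: -2}

    def test_soundfield_table_covers_screen_frequencies(self):
        table = default_soundfield_retspl()
        assert set(table.values) == {500.0, 1000.0, 2000.0, 4000.0}

    def test_hl_to_spl_is_translation(self):
        table = default_headphone_retspl()
        assert hl_to_spl(table, 500, 60) == 71
        assert hl_to_spl(table, 4000, 0) == -2
        for f in (500, 1000, 2000, 4000):
            for hl in (-10, 0, 35.5, 90):
                assert spl_to_hl(table, f, hl_to_spl(table, f, hl)) == pytest.approx(hl)

    def test_missing_frequency(self):
        with pytest.raises(MissingFrequencyError):
            hl_to_spl(default_headphone_retspl(), 8000, 60)

    def test_implausible_values_rejected(self):
        with pytest.raises(ValueError):
            RetsplTable({500.0: 40})


class TestWilber:
    @staticmethod
    def _panel(offsets: dict[float, float], n=10, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n):
            for f, off in offsets.items():
                hl = rng.uniform(-5, 10)
                rows.append({"subject": f"s{s}", "frequency": f,
                             "audiometer_hl": hl,
                             "device_spl": hl + off + rng.normal(0, noise)})
        return pd.DataFrame(rows)

    def test_recovers_constant_offset_exactly(self):
        table = derive_retspl_wilber(self._panel({500.0: 11.0}))
        assert table.values[500.0] == 11
        assert table.unrounded[500.0] == pytest.approx(11.0)

    def test_recovers_full_packaged_table_from_synthetic_panel(self):
        offsets = {500.0: 11.0, 1000.0: 1.0, 2000.0: 3.0, 4000.0: -2.0}
        table = derive_retspl_wilber(self._panel(offsets))
        assert table.values == {f: int(v) for f, v in offsets.items()}

    def test_mean_of_constants_and_hand_mean(self):
        rows = [
            {"subject": "a", "frequency": 1000.0, "audiometer_hl": 0.0, "device_spl": 10.0},
            {"subject": "b", "frequency": 1000.0, "audiometer_hl": 0.0, "device_spl": 12.0},
        ]
        table = derive_retspl_wilber(pd.DataFrame(rows))
        assert table.unrounded[1000.0] == pytest.approx(11.0)
        assert table.values[1000.0] == 11

    def test_standard_error_shrinks_with_sqrt_n(self):
        # empirical SD of the panel mean under additive noise ~ 1/sqrt(n)
        def sd_of_mean(n, reps=200):
            vals = [derive_retspl_wilber(self._panel({500.0: 11.0}, n=n, noise=3.0,
                                                     seed=r)).unrounded[500.0]
                    for r in range(reps)]
            return np.std(vals)

        sd10, sd40 = sd_of_mean(10), sd_of_mean(40)
        assert sd40 == pytest.approx(sd10 / 2, rel=0.35)

    def test_empty_measurements_rejected(self):
        with pytest.raises(ValueError):
            derive_retspl_wilber(pd.DataFrame(columns=["subject", "frequency",
                                                       "audiometer_hl", "device_spl"]))


class TestDbaMetering:
    def _calibrated_cfg(self, amplitude, target_spl):
        rms_dbfs = 20 * np.log10(amplitude / np.sqrt(2))
        return NoiseGateConfig(cal_offset=target_spl - rms_dbfs)

    def test_one_khz_unchanged_by_a_weighting(self, sine):
        cfg = self._calibrated_cfg(0.1, 50.0)
        assert measure_dba(sine(1000, 2.0, 0.1), cfg) == pytest.approx(50.0, abs=0.2)

    def test_100_hz_attenuated_19_db(self, sine):
        cfg = self._calibrated_cfg(0.1, 60.0)
        assert measure_dba(sine(100, 2.0, 0.1), cfg) == pytest.approx(60 - 19.1, abs=0.3)

    def test_silence_floor(self):
        cfg = NoiseGateConfig(cal_offset=94.0)
        assert measure_dba(Waveform(np.zeros(FS), FS), cfg) == -120.0

    def test_short_signal_rejected(self, sine):
        with pytest.raises(ValueError):
            measure_dba(sine(1000, 0.2), NoiseGateConfig())


class TestNoiseGate:
    def test_boundary_is_strict(self):
        cfg = NoiseGateConfig(threshold_dba=50.0)
        assert noise_gate(49.9, cfg)
        assert not noise_gate(50.0, cfg)
        assert noise_gate(45.0, cfg)

    def test_sweep_flips_exactly_once_at_threshold(self):
        cfg = NoiseGateConfig(threshold_dba=50.0)
        levels = np.round(np.arange(40.0, 60.01, 0.1), 1)
        decisions = [noise_gate(lv, cfg) for lv in levels]
        flips = [i for i in range(1, len(decisions)) if decisions[i] != decisions[i - 1]]
        assert len(flips) == 1
        assert levels[flips[0]] == 50.0


class TestHarmonicDistortion:
    def test_pure_sine_near_zero(self, sine):
        assert measure_harmonic_distortion(sine(500, 1.0), 500) < 0.5

    def test_constructed_ten_percent_second_harmonic(self, sine):
        t = np.arange(FS) / FS
        w = Waveform(0.5 * np.sin(2 * np.pi * 500 * t)
                     + 0.05 * np.sin(2 * np.pi * 1000 * t), FS)
        assert measure_harmonic_distortion(w, 500) == pytest.approx(10.0, abs=0.5)

    def test_square_wave_matches_fourier_series(self):
        # odd harmonics 3 and 5 at 1/3 and 1/5 of the fundamental:
        # THD(2..5) = sqrt(1/9 + 1/25) = 38.87%
        t = np.arange(2 * FS) / FS
        w = Waveform(0.5 * np.sign(np.sin(2 * np.pi * 441 * t)), FS)
        expected = 100 * np.sqrt(1 / 9 + 1 / 25)
        assert measure_harmonic_distortion(w, 441) == pytest.approx(expected, abs=1.5)

    def test_fundamental_too_high_rejected(self, sine):
        with pytest.raises(ValueError):
            measure_harmonic_distortion(sine(6000, 1.0), 6000)


@given(hl=st.floats(-10, 110), f=st.sampled_from([500.0, 1000.0, 2000.0, 4000.0]))
@settings(max_examples=50, deadline=None)
def test_hl_spl_additive_inverse_property(hl, f):
    table = default_headphone_retspl()
    assert spl_to_hl(table, f, hl_to_spl(table, f, hl)) == pytest.approx(hl)
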