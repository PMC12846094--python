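import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from semgfatigue.errors import UndefinedFeatureError, ValidationError
from semgfatigue.features import (
    DEFAULT_CONFIG,
    FeatureConfig,
    Spectrum,
    feature_vector,
    mav,
    mdf,
    mnf,
    mpf,
    power_spectrum,
    rms,
    wamp,
    waveform_length,
    zero_crossings,
)
from semgfatigue.segmentation import Segment

FS = 1000.0


# ---------------------------------------------------------------- oracles
def oracle_rms(x):
    acc = 0.0
    for v in x:
        acc += v * v
    return math.sqrt(acc / len(x))


def oracle_mav(x):
    acc = 0.0
    for v in x:
        acc += abs(v)
    return acc / len(x)


def oracle_wl(x):
    acc = 0.0
    for a, b in zip(x[:-1], x[1:]):
        acc += abs(b - a)
    return acc


def oracle_zc(x, thr):
    count = 0
    for a, b in zip(x[:-1], x[1:]):
        if a * b < 0 and abs(b - a) >= thr:
            count += 1
    return count


def oracle_wamp(x, thr):
    count = 0
    for a, b in zip(x[:-1], x[1:]):
        if abs(a - b) >= thr:
            count += 1
    return count


def oracle_mnf(freqs, power):
    num = den = 0.0
    for f, p in zip(freqs, power):
        num += f * p
        den += p
    return num / den


finite_windows = arrays(
    np.float64,
    st.integers(min_value=16, max_value=200),
    elements=st.floats(-10, 10, allow_nan=False),
)


class TestTimeDomain:
    def test_rms_constant(self):
        assert rms(np.full(100, -2.0)) == pytest.approx(2.0)

    def test_rms_sine(self):
        t = np.arange(1000) / FS
        assert rms(np.sin(2 * np.pi * 50 * t)) == pytest.approx(1 / np.sqrt(2), abs=1e-3)

    def test_mav_constant(self):
        assert mav(np.full(10, -3.0)) == pytest.approx(3.0)

    def test_mav_alternating(self):
        assert mav(np.array([1.0, -1.0, 1.0, -1.0])) == pytest.approx(1.0)

    def test_wl_ramp(self):
        x = 0.5 * np.arange(100)
        assert waveform_length(x) == pytest.approx(0.5 * 99)

    def test_wl_constant_zero(self):
        assert waveform_length(np.full(50, 4.2)) == pytest.approx(0.0)

    def test_zc_alternating(self):
        assert zero_crossings(np.array([1.0, -1.0, 1.0, -1.0]), 0.1) == 3

    def test_zc_all_positive(self):
        assert zero_crossings(np.abs(np.random.default_rng(0).standard_normal(50)) + 0.1, 0.1) == 0

    def test_wamp_alternating(self):
        x = np.array([1.0, -1.0] * 10)
        assert wamp(x, 0.1) == len(x) - 1

    def test_wamp_constant(self):
        assert wamp(np.full(30, 2.0), 0.1) == 0

    def test_oracle_equivalence_1000_random_windows(self, rng):
        thr = 0.1
        for _ in range(1000):
            k = int(rng.integers(2, 60))
            x = rng.standard_normal(k)
            assert rms(x) == pytest.approx(oracle_rms(x), rel=1e-9)
            assert mav(x) == pytest.approx(oracle_mav(x), rel=1e-9)
            assert waveform_length(x) == pytest.approx(oracle_wl(x), rel=1e-9)
            assert zero_crossings(x, thr) == oracle_zc(x, thr)
            assert wamp(x, thr) == oracle_wamp(x, thr)

    def test_empty_window_rejected(self):
        with pytest.raises(ValidationError):
            rms(np.array([]))
        with pytest.raises(ValidationError):
            waveform_length(np.array([1.0]))

    @settings(max_examples=50, deadline=None)
    @given(finite_windows)
    def test_time_reversal_invariance(self, x):
        for fn in (rms, mav, waveform_length):
            assert fn(x[::-1]) == pytest.approx(fn(x), rel=1e-12, abs=1e-12)
        assert zero_crossings(x[::-1], 0.1) == zero_crossings(x, 0.1)
        assert wamp(x[::-1], 0.1) == wamp(x, 0.1)

    @settings(max_examples=50, deadline=None)
    @given(finite_windows)
    def test_sign_flip_invariance(self, x):
        for fn in (rms, mav, waveform_length):
            assert fn(-x) == pytest.approx(fn(x), rel=1e-12, abs=1e-12)
        assert wamp(-x, 0.1) == wamp(x, 0.1)

    @settings(max_examples=50, deadline=None)
    @given(finite_windows, st.floats(0.1, 10.0))
    def test_scale_equivariance(self, x, a):
        assert rms(a * x) == pytest.approx(a * rms(x), rel=1e-9, abs=1e-12)
        assert mav(a * x) == pytest.approx(a * mav(x), rel=1e-9, abs=1e-12)
        assert waveform_length(a * x) == pytest.approx(
            a * waveform_length(x), rel=1e-9, abs=1e-12
        )
        assert zero_crossings(a * x, a * 0.1) == zero_crossings(x, 0.1)


class TestSpectrum:
    def test_pure_tone_peak_location(self):
        t = np.arange(2500) / FS
        spec = power_spectrum(np.sin(2 * np.pi * 100 * t), FS)
        peak = spec.freqs[np.argmax(spec.power)]
        df = spec.freqs[1] - spec.freqs[0]
        assert abs(peak - 100.0) <= df

    def test_zero_signal_zero_power(self):
        spec = power_spectrum(np.zeros(512), FS)
        assert np.all(spec.power == 0.0)

    def test_parseval_white_noise(self, rng):
        from scipy.signal.windows import hann

        x = rng.standard_normal(2500)
        spec = power_spectrum(x, FS)
        df = spec.freqs[1] - spec.freqs[0]
        spectral_power = np.sum(spec.power) * df
        # taper-corrected time-domain oracle: power seen through the window
        w = hann(2500, sym=False)
        windowed_power = np.mean((x * w) ** 2) / np.mean(w**2)
        assert spectral_power == pytest.approx(windowed_power, rel=0.05)
        # and within sampling error of the raw variance
        assert spectral_power == pytest.approx(np.mean(x**2), rel=0.15)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            power_spectrum(np.ones(4), FS)

    def test_welch_config(self, rng):
        cfg = FeatureConfig(psd_method="welch")
        spec = power_spectrum(rng.standard_normal(2500), FS, cfg)
        assert len(spec.freqs) > 8


def line_spectrum(pairs):
    freqs = np.arange(0.0, 500.0, 1.0)
    power = np.zeros_like(freqs)
    for f, p in pairs:
        power[int(f)] = p
    return Spectrum(freqs=freqs, power=power)


class TestMnfMdf:
    def test_single_line(self):
        spec = line_spectrum([(120, 2.0)])
        assert mnf(spec) == pytest.approx(120.0)
        assert mdf(spec) == pytest.approx(120.0)
        assert mpf(spec) == pytest.approx(120.0)

    def test_two_equal_lines(self):
        spec = line_spectrum([(50, 1.5), (150, 1.5)])
        assert mnf(spec) == pytest.approx(100.0)
        assert mdf(spec) == pytest.approx(100.0)

    def test_mnf_matches_bruteforce(self, rng):
        for _ in range(100):
            power = rng.uniform(0, 1, 64)
            freqs = np.sort(rng.uniform(0, 500, 64))
            freqs += np.arange(64) * 1e-6  # strictly increasing
            spec = Spectrum(freqs=freqs, power=power)
            assert mnf(spec) == pytest.approx(oracle_mnf(freqs, power), rel=1e-9)

    def test_mdf_minimises_half_power_deviation(self, rng):
        # grid-search oracle: MDF is where |cum - total/2| is minimal
        for _ in range(50):
            power = rng.uniform(0.01, 1, 128)
            freqs = np.linspace(1, 500, 128)
            spec = Spectrum(freqs=freqs, power=power)
            m = mdf(spec)
            total = power.sum()
            cum_at = lambda f: power[freqs <= f].sum()
            dev_m = abs(cum_at(m) - total / 2)
            grid_devs = [abs(cum_at(f) - total / 2) for f in freqs]
            assert dev_m <= min(grid_devs) + 1e-9

    def test_mnf_bounds(self, rng):
        power = rng.uniform(0, 1, 32)
        freqs = np.linspace(10, 400, 32)
        spec = Spectrum(freqs=freqs, power=power)
        assert 10 <= mnf(spec) <= 400

    def test_zero_power_undefined(self):
        spec = Spectrum(freqs=np.arange(1.0, 10.0), power=np.zeros(9))
        with pytest.raises(UndefinedFeatureError):
            mnf(spec)
        with pytest.raises(UndefinedFeatureError):
            mdf(spec)


def make_channel_segments(rng, start_ms=0, zero=False):
    segs = []
    for ch in ("BB", "BRA", "TRI", "DEL"):
        samples = np.zeros(2500) if zero else rng.standard_normal(2500)
        segs.append(Segment(subject_id="S", channel_name=ch, start_ms=start_ms,
                            samples=samples, task_progress=0.5, borg=4))
    return segs


class TestFeatureVector:
    def test_length_32(self, rng):
        fv = feature_vector(make_channel_segments(rng))
        assert len(fv.values) == 32
        assert len(fv.names) == 32

    def test_channel_major_order(self, rng):
        fv = feature_vector(make_channel_segments(rng))
        assert fv.names[0].startswith("BB_")
        assert fv.names[8].startswith("BRA_")
        assert fv.names[16].startswith("TRI_")
        assert fv.names[24].startswith("DEL_")

    def test_zero_window_policy(self, rng):
        with pytest.warns(UserWarning):
            fv = feature_vector(make_channel_segments(rng, zero=True))
        by_name = dict(zip(fv.names, fv.values))
        for ch in ("BB", "BRA", "TRI", "DEL"):
            for f in ("RMS", "MAV", "WL", "ZC", "WAMP"):
                assert by_name[f"{ch}_{f}"] == 0.0
            for f in ("MNF", "MPF", "MDF"):
                assert np.isnan(by_name[f"{ch}_{f}"])

    def test_feature_order_permutation(self, rng):
        segs = make_channel_segments(rng)
        default = feature_vector(segs)
        permuted_order = ("WAMP", "MDF", "WL", "MPF", "MNF", "ZC", "MAV", "RMS")
        cfg = FeatureConfig(feature_order=permuted_order)
        permuted = feature_vector(segs, cfg)
        d0 = dict(zip(default.names, default.values))
        d1 = dict(zip(permuted.names, permuted.values))
        assert d0 == d1

    def test_mismatched_starts_rejected(self, rng):
        segs = make_channel_segments(rng)
        segs[1].start_ms = 250
        with pytest.raises(ValidationError):
            feature_vector(segs)

    def test_spectral_drift_on_simulator(self, processed):
        from semgfatigue.segmentation import slide_windows

        segs = [s for s in slide_windows(processed) if s.channel_name == "BB"]
        first = power_spectrum(segs[0].samples, FS)
        last = power_spectrum(segs[-1].samples, FS)
        assert mnf(last) < mnf(first)
        assert mpf(last) < mpf(first)
        assert mdf(last) < mdf(first)
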