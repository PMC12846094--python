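"""Per-window time- and frequency-domain sEMG features.

Eight features per channel window — RMS, MAV, ZC, MNF, MPF, WL, MDF, WAMP —
assembled channel-major into a 32-dimensional vector for the classical
baselines.  ZC and WAMP are threshold-gated counts (default 0.1, in the
units of the windowed signal).  Spectral statistics are computed on a
Hann-tapered periodogram (Welch available by config); on a zero-power
window they are undefined and emitted as NaN, to be dropped before model
fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import UndefinedFeatureError, ValidationError
from .segmentation import Segment

FEATURE_ORDER_DEFAULT = ("RMS", "MAV", "ZC", "MNF", "MPF", "WL", "MDF", "WAMP")


@dataclass(frozen=True)
class FeatureConfig:
    threshold_mv: float = 0.1
    psd_method: str = "periodogram"      # {"periodogram", "welch"}
    psd_window: str = "hann"
    feature_order: tuple[str, ...] = FEATURE_ORDER_DEFAULT

    def validate(self) -> None:
        if self.threshold_mv <= 0:
            raise ValidationError("threshold_mv must be positive")
        if sorted(self.feature_order) != sorted(FEATURE_ORDER_DEFAULT):
            raise ValidationError("feature_order must permute the 8 feature names")
        if self.psd_method not in ("periodogram", "welch"):
            raise ValidationError(f"unknown psd_method {self.psd_method!r}")


DEFAULT_CONFIG = FeatureConfig()


@dataclass
class Spectrum:
    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValidationError("freqs and power must have the same shape")
        if np.any(np.diff(self.freqs) <= 0) or self.freqs[0] < 0:
            raise ValidationError("freqs must be non-negative, strictly increasing")
        if np.any(self.power < 0):
            raise ValidationError("power must be non-negative")

    @property
    def total_power(self) -> float:
        return float(np.trapezoid(self.power, self.freqs))


def _window(x: np.ndarray, min_len: int = 1) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < min_len:
        raise ValidationError(f"window must be 1-D with at least {min_len} samples")
    return x


def rms(window: np.ndarray) -> float:
    """sqrt(mean of squares)."""
    x = _window(window)
    return float(np.sqrt(np.mean(x**2)))


def mav(window: np.ndarray) -> float:
    """Mean absolute value (unit weights)."""
    x = _window(window)
    return float(np.mean(np.abs(x)))


def waveform_length(window: np.ndarray) -> float:
    """Cumulative length of the waveform: sum of absolute successive differences."""
    x = _window(window, min_len=2)
    return float(np.sum(np.abs(np.diff(x))))


def zero_crossings(window: np.ndarray, threshold: float = 0.1) -> int:
    """Sign changes whose jump magnitude meets the threshold."""
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    x = _window(window, min_len=2)
    sign_change = x[:-1] * x[1:] < 0
    big_jump = np.abs(np.diff(x)) >= threshold
    return int(np.sum(sign_change & big_jump))


def wamp(window: np.ndarray, threshold: float = 0.1) -> int:
    """Willison amplitude: adjacent-sample jumps meeting the threshold."""
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    x = _window(window, min_len=2)
    return int(np.sum(np.abs(np.diff(x)) >= threshold))


def power_spectrum(
    window: np.ndarray, fs: float, config: FeatureConfig = DEFAULT_CONFIG
) -> Spectrum:
    """One-sided PSD of the window (density scaling, tapered)."""
    x = _window(window, min_len=8)
    if config.psd_method == "welch":
        nperseg = min(len(x), 1024)
        freqs, power = sps.welch(
            x, fs=fs, window=config.psd_window, nperseg=nperseg, detrend=False
        )
    else:
        freqs, power = sps.periodogram(
            x, fs=fs, window=config.psd_window, detrend=False
        )
    return Spectrum(freqs=freqs, power=power)


def mnf(spectrum: Spectrum) -> float:
    """Spectral centroid: sum f_i P(f_i) / sum P(f_i)."""
    total = float(np.sum(spectrum.power))
    if total <= 0:
        raise UndefinedFeatureError("mean frequency undefined for zero-power spectrum")
    return float(np.sum(spectrum.freqs * spectrum.power) / total)


def mpf(spectrum: Spectrum) -> float:
    """Continuous-form spectral centroid; same statistic as mnf on the PSD grid."""
    return mnf(spectrum)


def mdf(spectrum: Spectrum) -> float:
    """Median frequency: where cumulative power crosses half the total.

    The cumulative distribution is treated as a step function over the bins;
    if the half level is met exactly (an ambiguous plateau), the midpoint of
    the plateau is returned, so two equal lines yield their mean frequency.
    """
    total = float(np.sum(spectrum.power))
    if total <= 0:
        raise UndefinedFeatureError("median frequency undefined for zero-power spectrum")
    cum = np.cumsum(spectrum.power)
    half = total / 2.0
    i_lo = int(np.searchsorted(cum, half, side="left"))
    i_hi = int(np.searchsorted(cum, half, side="right"))
    if i_lo == i_hi:
        i = min(i_lo, len(cum) - 1)
        # pick whichever side of the crossing is closer to the half level
        if i > 0 and (half - cum[i - 1]) < (cum[i] - half):
            i -= 1
        return float(spectrum.freqs[i])
    if i_hi >= len(cum):
        return float(spectrum.freqs[-1])
    return float(0.5 * (spectrum.freqs[i_lo] + spectrum.freqs[i_hi]))


_SPECTRAL = {"MNF", "MPF", "MDF"}


def compute_feature(
    name: str,
    window: np.ndarray,
    fs: float,
    config: FeatureConfig = DEFAULT_CONFIG,
    spectrum: Spectrum | None = None,
) -> float:
    if name == "RMS":
        return rms(window)
    if name == "MAV":
        return mav(window)
    if name == "WL":
        return waveform_length(window)
    if name == "ZC":
        return float(zero_crossings(window, config.threshold_mv))
    if name == "WAMP":
        return float(wamp(window, config.threshold_mv))
    if name in _SPECTRAL:
        if spectrum is None:
            spectrum = power_spectrum(window, fs, config)
        fn = {"MNF": mnf, "MPF": mpf, "MDF": mdf}[name]
        try:
            return fn(spectrum)
        except UndefinedFeatureError:
            return float("nan")
    raise ValidationError(f"unknown feature {name!r}")


@dataclass
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]
    subject_id: str
    start_ms: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValidationError("values and names must be parallel")


def feature_vector(
    segments: list[Segment], config: FeatureConfig = DEFAULT_CONFIG
) -> FeatureVector:
    """The channel-major feature vector for one window (4 channels x 8 features).

    All channel segments must share the same start time.  Undefined spectral
    features are NaN; downstream fitting drops such rows.
    """
    config.validate()
    if len(segments) == 0:
        raise ValidationError("no channel segments supplied")
    starts = {s.start_ms for s in segments}
    if len(starts) != 1:
        raise ValidationError("channel segments must share one start_ms")
    channels = [s.channel_name for s in segments]
    if len(set(channels)) != len(channels):
        raise ValidationError("duplicate channel in feature_vector input")
    values = []
    names = []
    n_nan = 0
    for seg in segments:
        spectrum = None
        needs_spectrum = any(f in _SPECTRAL for f in config.feature_order)
        if needs_spectrum and np.any(seg.samples != 0.0):
            spectrum = power_spectrum(seg.samples, seg.fs, config)
        for fname in config.feature_order:
            v = compute_feature(fname, seg.samples, seg.fs, config, spectrum=spectrum)
            if np.isnan(v):
                n_nan += 1
            values.append(v)
            names.append(f"{seg.channel_name}_{fname}")
    if n_nan:
        warnings.warn(
            f"{n_nan} undefined spectral feature(s) emitted as NaN "
            f"(subject {segments[0].subject_id}, start {segments[0].start_ms} ms)",
            stacklevel=2,
        )
    return FeatureVector(
        values=np.array(values),
        names=tuple(names),
        subject_id=segments[0].subject_id,
        start_ms=segments[0].start_ms,
    )
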