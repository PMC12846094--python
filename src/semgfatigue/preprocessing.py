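"""Signal conditioning: band-pass noise reduction, linear envelope, MVC normalization.

The conditioning chain is (a) 4th-order Butterworth band-pass 20-450 Hz,
(b) full-wave rectification followed by a 10 Hz Butterworth low-pass
(the linear envelope), and (c) division by the per-channel MVC reference
(mean of the three maximal-contraction trial values).

Filtering is applied forward-backward (zero phase) by default.  Spectral
features and scalograms downstream consume the band-passed, MVC-normalized
signal; the 10 Hz envelope is retained for amplitude inspection only, since
its spectrum cannot express 20-450 Hz content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import FilterDesignError, ValidationError
from .synth import Recording

STAGES = ("raw", "bandpassed", "envelope", "normalized")


@dataclass(frozen=True)
class FilterSpec:
    kind: str = "bandpass"              # {"bandpass", "lowpass"}
    order: int = 4
    low_hz: float = 20.0                # bandpass only
    high_hz: float = 450.0              # bandpass only
    cutoff_hz: float = 10.0             # lowpass only
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if self.order < 1:
            raise ValidationError("filter order must be >= 1")
        nyq = fs / 2.0
        if self.kind == "bandpass":
            if not 0 < self.low_hz < self.high_hz:
                raise ValidationError("need 0 < low_hz < high_hz")
            if self.high_hz >= nyq:
                raise FilterDesignError(
                    f"high_hz={self.high_hz} not below Nyquist ({nyq} Hz)"
                )
        elif self.kind == "lowpass":
            if not 0 < self.cutoff_hz < nyq:
                raise FilterDesignError("cutoff_hz must lie in (0, fs/2)")
        else:
            raise ValidationError(f"unknown filter kind {self.kind!r}")


BANDPASS_DEFAULT = FilterSpec(kind="bandpass", order=4, low_hz=20.0, high_hz=450.0)
ENVELOPE_DEFAULT = FilterSpec(kind="lowpass", order=4, cutoff_hz=10.0)


def design_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    """Second-order-sections Butterworth design for the given spec."""
    spec.validate(fs)
    if spec.kind == "bandpass":
        return sps.butter(
            spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=fs, output="sos"
        )
    return sps.butter(spec.order, spec.cutoff_hz, btype="lowpass", fs=fs, output="sos")


def _apply(sos: np.ndarray, x: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def _check_signal(x: np.ndarray, min_len: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError("expected a 1-D signal")
    if not np.all(np.isfinite(x)):
        raise ValidationError("signal contains NaN or Inf")
    if len(x) <= min_len:
        raise ValidationError(f"signal too short ({len(x)} samples)")
    return x


def bandpass_filter(x: np.ndarray, fs: float, spec: FilterSpec = BANDPASS_DEFAULT) -> np.ndarray:
    """Band-pass the signal; output has the same length as the input."""
    if spec.kind != "bandpass":
        raise ValidationError("bandpass_filter needs a bandpass spec")
    x = _check_signal(x, 3 * spec.order)
    return _apply(design_sos(spec, fs), x, spec.zero_phase)


def linear_envelope(x: np.ndarray, fs: float, spec: FilterSpec = ENVELOPE_DEFAULT) -> np.ndarray:
    """Full-wave rectification + low-pass; negative ringing clipped to zero."""
    if spec.kind != "lowpass":
        raise ValidationError("linear_envelope needs a lowpass spec")
    x = _check_signal(x, 3 * spec.order)
    env = _apply(design_sos(spec, fs), np.abs(x), spec.zero_phase)
    return np.clip(env, 0.0, None)


def mvc_reference(mvc_trials: dict[str, tuple[float, ...]]) -> dict[str, float]:
    """Per-channel normalization reference: arithmetic mean of the 3 trial values."""
    refs = {}
    for ch, trials in mvc_trials.items():
        if len(trials) != 3:
            raise ValidationError(f"channel {ch}: expected exactly 3 MVC trials")
        if any(v <= 0 for v in trials):
            raise ValidationError(f"channel {ch}: MVC trial values must be positive")
        refs[ch] = float(sum(trials) / 3.0)
    return refs


def normalize(x: np.ndarray, mvc_ref: float) -> np.ndarray:
    """Express the signal as a fraction of MVC (multiply by 100 for %MVC)."""
    if mvc_ref <= 0:
        raise ValidationError("mvc_ref must be positive")
    return np.asarray(x, dtype=float) / mvc_ref


@dataclass
class ProcessedRecording:
    """A Recording carried through the conditioning chain."""

    subject_id: str
    fs: float
    channel_names: tuple[str, ...]
    signal: np.ndarray
    mvc_trials: dict[str, tuple[float, float, float]]
    borg_reports: list[tuple[float, int]]
    duration_s: float
    stage: str = "raw"
    mvc_reference: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")

    @classmethod
    def from_recording(cls, rec: Recording) -> "ProcessedRecording":
        return cls(
            subject_id=rec.subject_id,
            fs=rec.fs,
            channel_names=tuple(rec.channel_names),
            signal=np.array(rec.signal, dtype=float),
            mvc_trials=dict(rec.mvc_trials),
            borg_reports=list(rec.borg_reports),
            duration_s=rec.duration_s,
            stage="raw",
        )


def preprocess_recording(
    rec: Recording | ProcessedRecording,
    bandpass_spec: FilterSpec = BANDPASS_DEFAULT,
    zero_phase: bool = True,
) -> ProcessedRecording:
    """raw -> bandpassed -> normalized, per channel.

    Returns a ProcessedRecording at stage "normalized" whose signal is the
    band-passed waveform divided by the channel MVC reference.
    """
    if isinstance(rec, Recording):
        rec = ProcessedRecording.from_recording(rec)
    if rec.stage != "raw":
        raise ValidationError(f"expected a raw recording, got stage {rec.stage!r}")
    spec = FilterSpec(
        kind="bandpass",
        order=bandpass_spec.order,
        low_hz=bandpass_spec.low_hz,
        high_hz=bandpass_spec.high_hz,
        zero_phase=zero_phase,
    )
    refs = mvc_reference(rec.mvc_trials)
    out = np.empty_like(rec.signal)
    for row, ch in enumerate(rec.channel_names):
        filtered = bandpass_filter(rec.signal[row], rec.fs, spec)
        out[row] = normalize(filtered, refs[ch])
    return ProcessedRecording(
        subject_id=rec.subject_id,
        fs=rec.fs,
        channel_names=rec.channel_names,
        signal=out,
        mvc_trials=rec.mvc_trials,
        borg_reports=rec.borg_reports,
        duration_s=rec.duration_s,
        stage="normalized",
        mvc_reference=refs,
    )


def envelope_recording(
    rec: Recording | ProcessedRecording,
    bandpass_spec: FilterSpec = BANDPASS_DEFAULT,
    envelope_spec: FilterSpec = ENVELOPE_DEFAULT,
    normalized: bool = True,
) -> ProcessedRecording:
    """raw -> bandpassed -> envelope (optionally scaled by the MVC reference)."""
    if isinstance(rec, Recording):
        rec = ProcessedRecording.from_recording(rec)
    if rec.stage != "raw":
        raise ValidationError(f"expected a raw recording, got stage {rec.stage!r}")
    refs = mvc_reference(rec.mvc_trials)
    out = np.empty_like(rec.signal)
    for row, ch in enumerate(rec.channel_names):
        filtered = bandpass_filter(rec.signal[row], rec.fs, bandpass_spec)
        env = linear_envelope(filtered, rec.fs, envelope_spec)
        out[row] = normalize(env, refs[ch]) if normalized else env
    return ProcessedRecording(
        subject_id=rec.subject_id,
        fs=rec.fs,
        channel_names=rec.channel_names,
        signal=out,
        mvc_trials=rec.mvc_trials,
        borg_reports=rec.borg_reports,
        duration_s=rec.duration_s,
        stage="envelope",
        mvc_reference=refs,
    )
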