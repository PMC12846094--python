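"""Seeded synthetic sEMG cohort generator.

Produces multi-channel recordings carrying the two statistical signatures the
downstream pipeline assumes for a fatiguing contraction: a rising amplitude
envelope and a power spectrum that drifts toward lower frequencies as the
task progresses.  Signals are synthesised as Gaussian noise shaped block-wise
by a band-limited Gaussian spectral bump whose centre follows the mean
frequency schedule, multiplied by a slowly rising amplitude envelope with a
mild burst modulation at repetition cadence.  No claim of motor-unit-level
realism is made.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy.fft import irfft, rfftfreq
from scipy.signal.windows import hann

from .errors import ValidationError

DEFAULT_FS = 1000.0
CHANNELS = ("BB", "BRA", "TRI", "DEL")

# Mild per-channel amplitude scaling: agonist strongest, antagonist weakest.
_CHANNEL_GAIN = {"BB": 1.0, "BRA": 0.8, "TRI": 0.5, "DEL": 0.65}

# Band limits of the synthetic spectral template (Hz).
_BAND_LO = 20.0
_BAND_HI = 450.0

# Relative jitter applied to cohort profiles (fraction of the base value).
_JITTER = {
    "baseline_rms": 0.15,
    "rms_gain_end": 0.10,
    "mnf_start": 0.05,
    "mnf_end": 0.05,
    "duration_s": 0.10,
}

_BURST_DEPTH = 0.25  # fractional amplitude modulation at repetition cadence


@dataclass(frozen=True)
class SubjectProfile:
    """Parameters controlling one synthetic subject's session."""

    subject_id: str = "S00"
    baseline_rms: float = 0.15          # mV, windowed RMS at task start
    rms_gain_end: float = 2.0           # multiplier of baseline RMS at task end
    mnf_start: float = 120.0            # Hz
    mnf_end: float = 70.0               # Hz, < mnf_start for a fatiguing profile
    duration_s: float = 270.0           # seconds (~4.5 min session)
    borg_rate: int = 3                  # repetitions between self-reports
    noise_floor: float = 0.01           # mV, additive white noise
    seed: int = 0
    rep_period_s: float = 3.0           # seconds per repetition
    amplitude_scale: float = 1.0        # global multiplier; 0 yields a silent recording
    borg_bias: float = 0.0              # upward shift of self-reports (drives label upgrades)
    band_sigma_hz: float = 25.0         # width of the spectral bump

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be positive")
        if self.baseline_rms <= 0:
            raise ValidationError("baseline_rms must be positive")
        if not (_BAND_LO < self.mnf_end <= self.mnf_start < _BAND_HI):
            raise ValidationError(
                f"mean-frequency schedule must satisfy {_BAND_LO} < mnf_end <= "
                f"mnf_start < {_BAND_HI}, got {self.mnf_end}..{self.mnf_start}"
            )
        if self.rep_period_s <= 0 or self.borg_rate < 1:
            raise ValidationError("repetition cadence must be positive")
        if self.amplitude_scale < 0:
            raise ValidationError("amplitude_scale must be non-negative")

    @property
    def fatiguing(self) -> bool:
        return self.rms_gain_end > 1.0 and self.mnf_end < self.mnf_start


@dataclass
class Recording:
    """One subject's raw multi-channel session plus calibration and self-reports."""

    subject_id: str
    fs: float
    channel_names: tuple[str, ...]
    signal: np.ndarray                       # (n_channels, n_samples), mV
    mvc_trials: dict[str, tuple[float, float, float]]
    borg_reports: list[tuple[float, int]]    # (time_s, score 0-10)
    duration_s: float

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.channel_names):
            raise ValidationError("signal must have one row per channel")
        if not np.all(np.isfinite(self.signal)):
            raise ValidationError("signal contains non-finite samples")
        for ch, trials in self.mvc_trials.items():
            if len(trials) != 3:
                raise ValidationError(f"channel {ch} needs exactly 3 MVC trials")
        for _, score in self.borg_reports:
            if not 0 <= score <= 10:
                raise ValidationError("Borg score outside [0, 10]")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


def _subject_seed_sequence(master_seed: int, subject_id: str) -> SeedSequence:
    """Stable per-subject substream: hash the id so cohorts survive reordering."""
    digest = hashlib.sha256(subject_id.encode()).digest()
    sub = int.from_bytes(digest[:8], "little")
    return SeedSequence([int(master_seed), sub])


def borg_trajectory(progress: float, profile: SubjectProfile) -> int:
    """Self-reported exertion as a non-decreasing integer function of task progress."""
    if not 0.0 <= progress <= 1.0:
        raise ValidationError(f"progress must lie in [0, 1], got {progress}")
    raw = 9.0 * progress + profile.borg_bias
    return int(min(max(raw, 0.0), 10.0))


def _shaped_noise(
    rng: Generator,
    n: int,
    fs: float,
    centre_of_t,
    sigma_hz: float,
    block: int = 512,
) -> np.ndarray:
    """Unit-variance noise whose spectral bump centre follows ``centre_of_t``.

    Weighted overlap-add of independent block-stationary realisations; the
    per-sample window-power normaliser keeps the variance flat across block
    boundaries.
    """
    hop = block // 2
    win = hann(block, sym=False)
    freqs = rfftfreq(block, 1.0 / fs)
    out = np.zeros(n + block)
    wsum = np.zeros(n + block)
    n_freq = len(freqs)
    for start in range(0, n, hop):
        t_centre = min((start + block / 2) / fs, n / fs)
        centre = centre_of_t(t_centre)
        shape = np.exp(-0.5 * ((freqs - centre) / sigma_hz) ** 2)
        shape[(freqs < _BAND_LO) | (freqs > _BAND_HI)] = 0.0
        spec = np.sqrt(shape) * (
            rng.standard_normal(n_freq) + 1j * rng.standard_normal(n_freq)
        )
        spec[0] = 0.0
        g = irfft(spec, block)
        std = g.std()
        if std > 0:
            g /= std
        out[start : start + block] += win * g
        wsum[start : start + block] += win**2
    return out[:n] / np.sqrt(np.maximum(wsum[:n], 1e-12))


def _amplitude_envelope(t: np.ndarray, profile: SubjectProfile) -> np.ndarray:
    progress = t / profile.duration_s
    drift = 1.0 + (profile.rms_gain_end - 1.0) * progress
    burst = 1.0 + _BURST_DEPTH * np.sin(2.0 * np.pi * t / profile.rep_period_s)
    return profile.baseline_rms * drift * burst


def _moving_rms(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.sqrt(np.convolve(x**2, kernel, mode="same"))


def _simulate_mvc_trials(
    rng: Generator, profile: SubjectProfile, fs: float, channel: str
) -> tuple[float, float, float]:
    """Three maximal-effort trial values: peak moving-RMS of short max bursts."""
    trials = []
    centre = profile.mnf_start
    n = int(5 * fs)
    for _ in range(3):
        g = _shaped_noise(rng, n, fs, lambda _t: centre, profile.band_sigma_hz)
        amp = (
            profile.baseline_rms
            * profile.rms_gain_end
            * _CHANNEL_GAIN[channel]
            * (1.1 + 0.1 * rng.random())
            * profile.amplitude_scale
        )
        peak = float(_moving_rms(amp * g, int(0.1 * fs)).max())
        trials.append(max(peak, 1e-12))
    return tuple(trials)  # type: ignore[return-value]


def simulate_subject(profile: SubjectProfile, fs: float = DEFAULT_FS) -> Recording:
    """Generate one subject's session deterministically from the profile seed."""
    profile.validate()
    rng = default_rng(_subject_seed_sequence(profile.seed, profile.subject_id))
    n = int(round(profile.duration_s * fs))
    t = np.arange(n) / fs

    def centre_of_t(time_s: float) -> float:
        p = min(time_s / profile.duration_s, 1.0)
        return profile.mnf_start + (profile.mnf_end - profile.mnf_start) * p

    signal = np.empty((len(CHANNELS), n))
    amp = _amplitude_envelope(t, profile)
    for row, ch in enumerate(CHANNELS):
        carrier = _shaped_noise(rng, n, fs, centre_of_t, profile.band_sigma_hz)
        noise = profile.noise_floor * rng.standard_normal(n)
        signal[row] = profile.amplitude_scale * (
            _CHANNEL_GAIN[ch] * amp * carrier + noise
        )

    mvc = {ch: _simulate_mvc_trials(rng, profile, fs, ch) for ch in CHANNELS}

    # every borg_rate repetitions, but never fewer than ~8 reports per session
    # (keeps very short synthetic sessions labelable)
    report_interval = min(
        profile.borg_rate * profile.rep_period_s, profile.duration_s / 8.0
    )
    times = np.arange(0.0, profile.duration_s + 1e-9, report_interval)
    # each report stands for the interval it opens; score taken at its centre
    borg = [
        (
            float(ts),
            borg_trajectory(
                min((ts + report_interval / 2.0) / profile.duration_s, 1.0), profile
            ),
        )
        for ts in times
    ]

    return Recording(
        subject_id=profile.subject_id,
        fs=fs,
        channel_names=CHANNELS,
        signal=signal,
        mvc_trials=mvc,
        borg_reports=borg,
        duration_s=profile.duration_s,
    )


def jittered_profile(
    base: SubjectProfile, subject_id: str, master_seed: int
) -> SubjectProfile:
    """Per-subject variation of the base profile (deterministic in id + seed)."""
    rng = default_rng(_subject_seed_sequence(master_seed, "jitter:" + subject_id))
    updates: dict[str, float] = {}
    for name, frac in _JITTER.items():
        value = getattr(base, name)
        updates[name] = value * (1.0 + frac * (2.0 * rng.random() - 1.0))
    # keep the schedule ordering valid after independent jitter
    if updates["mnf_end"] > updates["mnf_start"]:
        updates["mnf_end"], updates["mnf_start"] = (
            updates["mnf_start"],
            updates["mnf_end"],
        )
    return replace(base, subject_id=subject_id, seed=master_seed, **updates)


def simulate_cohort(
    n_subjects: int, base_profile: SubjectProfile, seed: int, fs: float = DEFAULT_FS
) -> list[Recording]:
    """Simulate ``n_subjects`` jittered variants of the base profile."""
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    if n_subjects == 1:
        return [simulate_subject(replace(base_profile, seed=seed), fs=fs)]
    recordings = []
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        recordings.append(simulate_subject(jittered_profile(base_profile, sid, seed), fs=fs))
    return recordings
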