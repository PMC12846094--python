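"""Sliding-window segmentation, compound fatigue labeling and LOSO splits.

Labels combine the task-progress third with the binned self-report score;
on disagreement the higher fatigue class wins (conservative, safety-first).
The leave-one-subject-out split is defined on subjects, before windowing,
and a provenance-level disjointness check is exposed for every fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .errors import LeakageError, ValidationError
from .preprocessing import ProcessedRecording
from .synth import Recording

WINDOW_MS_DEFAULT = 2500
HOP_MS_DEFAULT = 250  # one-tenth of the window


class FatigueClass(IntEnum):
    NO_FATIGUE = 0
    MODERATE_FATIGUE = 1
    HARD_FATIGUE = 2


THREECLASS_NAMES = ("NoFatigue", "ModerateFatigue", "HardFatigue")
BINARY_NAMES = ("NoFatigue", "Fatigue")


@dataclass
class Segment:
    """One analysis window of one channel."""

    subject_id: str
    channel_name: str
    start_ms: int
    samples: np.ndarray
    task_progress: float
    borg: int
    fs: float = 1000.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not 0.0 <= self.task_progress <= 1.0:
            raise ValidationError("task_progress must lie in [0, 1]")
        if not 0 <= self.borg <= 10:
            raise ValidationError("borg must lie in [0, 10]")


@dataclass(frozen=True)
class LabelRule:
    """Three progress thirds x three score bins, resolved by conservative max."""

    progress_edges: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    borg_edges: tuple[int, int] = (3, 6)   # scores <3 | 3-5 | >=6
    disagreement_policy: str = "conservative_max"

    def progress_class(self, progress: float) -> FatigueClass:
        if not 0.0 <= progress <= 1.0:
            raise ValidationError("progress outside [0, 1]")
        if progress <= self.progress_edges[0]:
            return FatigueClass.NO_FATIGUE
        if progress <= self.progress_edges[1]:
            return FatigueClass.MODERATE_FATIGUE
        return FatigueClass.HARD_FATIGUE

    def borg_class(self, borg: int) -> FatigueClass:
        if not 0 <= borg <= 10:
            raise ValidationError("borg outside [0, 10]")
        if borg < self.borg_edges[0]:
            return FatigueClass.NO_FATIGUE
        if borg < self.borg_edges[1]:
            return FatigueClass.MODERATE_FATIGUE
        return FatigueClass.HARD_FATIGUE


DEFAULT_RULE = LabelRule()


def assign_label(
    task_progress: float, borg: int, rule: LabelRule = DEFAULT_RULE
) -> tuple[FatigueClass, str]:
    """Compound label: max of phase class and score class; flags upgrades."""
    phase = rule.progress_class(task_progress)
    score = rule.borg_class(borg)
    label = max(phase, score)
    source = "consensus" if phase == score else "upgraded"
    return FatigueClass(label), source


def borg_at(borg_reports: list[tuple[float, int]], time_s: float) -> int:
    """Nearest preceding self-report (step-function interpolation)."""
    if not borg_reports:
        raise ValidationError("recording has no Borg reports")
    reports = sorted(borg_reports)
    score = reports[0][1]
    for t, s in reports:
        if t <= time_s + 1e-9:
            score = s
        else:
            break
    return score


def slide_windows(
    recording: ProcessedRecording | Recording,
    window_ms: int = WINDOW_MS_DEFAULT,
    hop_ms: int = HOP_MS_DEFAULT,
) -> list[Segment]:
    """Fixed windows starting at 0, hop, 2*hop, ... for every channel.

    Count per channel is floor((L_ms - window_ms) / hop_ms) + 1; a recording
    shorter than one window yields an empty list with a warning.
    """
    if hop_ms < 1:
        raise ValidationError("hop_ms must be >= 1")
    fs = recording.fs
    n = recording.signal.shape[1]
    length_ms = n * 1000.0 / fs
    window_n = int(round(window_ms * fs / 1000.0))
    hop_n = int(round(hop_ms * fs / 1000.0))
    if window_n > n:
        warnings.warn(
            f"recording {recording.subject_id}: {length_ms:.0f} ms shorter than "
            f"one {window_ms} ms window; no segments produced",
            stacklevel=2,
        )
        return []
    n_windows = (n - window_n) // hop_n + 1
    segments: list[Segment] = []
    for k in range(n_windows):
        start = k * hop_n
        start_ms = int(round(start * 1000.0 / fs))
        mid_s = (start_ms + window_ms / 2.0) / 1000.0
        progress = min(max((start_ms + window_ms / 2.0) / length_ms, 0.0), 1.0)
        borg = borg_at(recording.borg_reports, mid_s)
        for row, ch in enumerate(recording.channel_names):
            segments.append(
                Segment(
                    subject_id=recording.subject_id,
                    channel_name=ch,
                    start_ms=start_ms,
                    samples=recording.signal[row, start : start + window_n],
                    task_progress=progress,
                    borg=borg,
                    fs=fs,
                )
            )
    return segments


@dataclass
class LabeledDataset:
    """Parallel lists of segments, class labels and label provenance."""

    segments: list[Segment]
    labels: np.ndarray                   # int class indices
    label_source: list[str]              # "consensus" | "upgraded"
    task: str = "threeclass"             # {"binary", "threeclass"}

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.segments) == len(self.labels) == len(self.label_source)):
            raise ValidationError("segments, labels and label_source must be parallel")
        if self.task not in ("binary", "threeclass"):
            raise ValidationError(f"unknown task {self.task!r}")

    @property
    def class_names(self) -> tuple[str, ...]:
        return BINARY_NAMES if self.task == "binary" else THREECLASS_NAMES

    def __len__(self) -> int:
        return len(self.segments)


def label_dataset(
    segments: list[Segment], rule: LabelRule = DEFAULT_RULE
) -> LabeledDataset:
    labels = []
    sources = []
    for seg in segments:
        cls, src = assign_label(seg.task_progress, seg.borg, rule)
        labels.append(int(cls))
        sources.append(src)
    return LabeledDataset(segments=segments, labels=np.array(labels, dtype=int),
                          label_source=sources, task="threeclass")


def binarize(dataset: LabeledDataset) -> LabeledDataset:
    """NoFatigue stays 0; Moderate and Hard collapse to Fatigue (1). Idempotent."""
    if dataset.task == "binary":
        return dataset
    labels = (dataset.labels > 0).astype(int)
    return LabeledDataset(
        segments=list(dataset.segments),
        labels=labels,
        label_source=list(dataset.label_source),
        task="binary",
    )


def consensus_filter(dataset: LabeledDataset) -> LabeledDataset:
    """Keep only segments whose phase and score bins agreed; order preserved."""
    keep = [i for i, s in enumerate(dataset.label_source) if s == "consensus"]
    return LabeledDataset(
        segments=[dataset.segments[i] for i in keep],
        labels=dataset.labels[keep],
        label_source=[dataset.label_source[i] for i in keep],
        task=dataset.task,
    )


@dataclass
class LosoSplit:
    folds: list[tuple[tuple[str, ...], str]]   # (train_subject_ids, test_subject_id)


def loso_split(subject_ids: list[str]) -> LosoSplit:
    """One fold per subject; fold i trains on everyone else."""
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate subject ids in LOSO split")
    if len(ids) < 2:
        raise ValidationError("LOSO needs at least 2 subjects")
    folds = []
    for test in ids:
        train = tuple(s for s in ids if s != test)
        folds.append((train, test))
    return LosoSplit(folds=folds)


def assert_no_leakage(train_segments: list[Segment], test_subject: str) -> None:
    """Hard provenance check: no training segment may come from the test subject."""
    offenders = {s.subject_id for s in train_segments if s.subject_id == test_subject}
    if offenders:
        raise LeakageError(
            f"training segments from held-out subject {sorted(offenders)} detected"
        )
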