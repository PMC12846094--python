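"""Plain-text persistence: per-recording CSV + JSON sidecar, TSV manifests."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .features import FeatureVector
from .segmentation import LabeledDataset
from .synth import Recording, SubjectProfile

_SIDECAR_SUFFIX = ".meta.json"


def write_recording(rec: Recording, out_dir: str | Path,
                    profile: SubjectProfile | None = None,
                    seed: int | None = None) -> Path:
    """One CSV (time_ms + channel columns, mV) plus a JSON metadata sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{rec.subject_id}.csv"
    time_ms = np.arange(rec.n_samples) * 1000.0 / rec.fs
    frame = pd.DataFrame({"time_ms": time_ms})
    for row, ch in enumerate(rec.channel_names):
        frame[ch] = rec.signal[row]
    frame.to_csv(csv_path, index=False, float_format="%.17g")
    meta = {
        "subject_id": rec.subject_id,
        "fs": rec.fs,
        "channel_names": list(rec.channel_names),
        "duration_s": rec.duration_s,
        "mvc_trials": {ch: list(v) for ch, v in rec.mvc_trials.items()},
        "borg_reports": [[t, s] for t, s in rec.borg_reports],
    }
    if profile is not None:
        meta["profile"] = asdict(profile)
    if seed is not None:
        meta["seed"] = seed
    with open(str(csv_path) + _SIDECAR_SUFFIX, "w") as fh:
        json.dump(meta, fh, indent=2)
    return csv_path


def read_recording(csv_path: str | Path) -> Recording:
    csv_path = Path(csv_path)
    sidecar = Path(str(csv_path) + _SIDECAR_SUFFIX)
    if not sidecar.exists():
        raise ValidationError(f"missing metadata sidecar for {csv_path}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    frame = pd.read_csv(csv_path, float_precision="round_trip")
    channels = meta["channel_names"]
    signal = np.vstack([frame[ch].to_numpy(dtype=float) for ch in channels])
    return Recording(
        subject_id=meta["subject_id"],
        fs=float(meta["fs"]),
        channel_names=tuple(channels),
        signal=signal,
        mvc_trials={ch: tuple(v) for ch, v in meta["mvc_trials"].items()},
        borg_reports=[(float(t), int(s)) for t, s in meta["borg_reports"]],
        duration_s=float(meta["duration_s"]),
    )


def read_cohort(in_dir: str | Path) -> list[Recording]:
    paths = sorted(Path(in_dir).glob("*.csv"))
    if not paths:
        raise ValidationError(f"no recordings found in {in_dir}")
    return [read_recording(p) for p in paths]


def write_manifest(ds: LabeledDataset, path: str | Path) -> None:
    """TSV index of labeled segments."""
    rows = []
    for seg, lab, src in zip(ds.segments, ds.labels, ds.label_source):
        rows.append({
            "subject_id": seg.subject_id,
            "channel": seg.channel_name,
            "start_ms": seg.start_ms,
            "progress": seg.task_progress,
            "borg": seg.borg,
            "class": ds.class_names[int(lab)],
            "label_source": src,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_feature_table(
    vectors: list[FeatureVector], labels: list[int], class_names, path: str | Path
) -> None:
    """TSV feature matrix: 32 feature columns + label/metadata columns."""
    if len(vectors) != len(labels):
        raise ValidationError("vectors and labels must be parallel")
    rows = []
    for fv, lab in zip(vectors, labels):
        row = {"subject_id": fv.subject_id, "start_ms": fv.start_ms,
               "class": class_names[int(lab)]}
        row.update(dict(zip(fv.names, fv.values)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
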