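"""Readers and writers for records, ground truth and result tables.

Signals are stored as plain CSV (columns ``sample, ecg, bipolar,
unipolar``; values in mV) with a JSON sidecar (``<stem>.meta.json``)
carrying the sampling frequency, ablation index and lesion metadata.
The CSV/JSON pair round-trips records losslessly.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import CHANNELS, LesionMeta, SignalRecord
from .synthetic import GroundTruth

__all__ = [
    "sidecar_path",
    "write_record",
    "read_record",
    "write_ground_truth",
    "read_ground_truth",
    "write_manifest",
    "read_manifest",
    "write_results_json",
]


def sidecar_path(path: Path | str) -> Path:
    return Path(path).with_suffix(".meta.json")


def write_record(record: SignalRecord, path: Path | str) -> Path:
    """Write signals as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "sample": np.arange(record.n_samples),
            "ecg": record.ecg,
            "bipolar": record.bipolar,
            "unipolar": record.unipolar,
        }
    )
    df.to_csv(path, index=False)
    meta = {
        "fs": record.fs,
        "ablation_index": int(record.ablation_index),
        "lesion_id": record.lesion_id,
        "animal_id": record.animal_id,
        "modality": record.modality,
        "transmural": record.transmural,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_record(path: Path | str, expected_fs: float | None = None) -> SignalRecord:
    """Read a CSV/JSON record pair; validates the channel schema and,
    when ``expected_fs`` is given, the sampling frequency."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    expected_cols = ["sample", *CHANNELS]
    if list(df.columns) != expected_cols:
        raise ValueError(
            f"{path}: expected columns {expected_cols}, found {list(df.columns)}"
        )
    meta_file = sidecar_path(path)
    if not meta_file.exists():
        raise FileNotFoundError(f"missing metadata sidecar {meta_file}")
    meta = json.loads(meta_file.read_text())
    if expected_fs is not None and float(meta["fs"]) != float(expected_fs):
        raise ValueError(
            f"{path}: sampling frequency mismatch (file {meta['fs']} Hz, "
            f"config {expected_fs} Hz)"
        )
    return SignalRecord(
        fs=float(meta["fs"]),
        ecg=df["ecg"].to_numpy(),
        bipolar=df["bipolar"].to_numpy(),
        unipolar=df["unipolar"].to_numpy(),
        ablation_index=int(meta["ablation_index"]),
        lesion_id=str(meta.get("lesion_id", "lesion-000")),
        animal_id=str(meta.get("animal_id", "animal-0")),
        modality=str(meta.get("modality", "PFA")),
        transmural=str(meta.get("transmural", "none")),
    )


def write_ground_truth(truth: GroundTruth, path: Path | str) -> Path:
    path = Path(path)
    payload = {
        "r_peak_indices": np.asarray(truth.r_peak_indices).tolist(),
        "beat_atrial_indices": np.asarray(truth.beat_atrial_indices).tolist(),
        "contaminated_beat_indices": np.asarray(truth.contaminated_beat_indices).tolist(),
        "saturation_interval": list(truth.saturation_interval)
        if truth.saturation_interval is not None
        else None,
        "group_label": list(truth.group_label),
    }
    path.write_text(json.dumps(payload))
    return path


def read_ground_truth(path: Path | str) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        r_peak_indices=np.asarray(payload["r_peak_indices"], dtype=int),
        beat_atrial_indices=np.asarray(payload["beat_atrial_indices"], dtype=int),
        contaminated_beat_indices=np.asarray(payload["contaminated_beat_indices"], dtype=int),
        saturation_interval=tuple(payload["saturation_interval"])
        if payload["saturation_interval"] is not None
        else None,
        group_label=tuple(payload["group_label"]),
    )


def write_manifest(metas: Iterable[LesionMeta], path: Path | str) -> Path:
    path = Path(path)
    pd.DataFrame([asdict(m) for m in metas]).to_csv(path, index=False)
    return path


def read_manifest(path: Path | str) -> list[LesionMeta]:
    df = pd.read_csv(path)
    return [
        LesionMeta(
            lesion_id=str(r.lesion_id),
            animal_id=str(r.animal_id),
            modality=str(r.modality),
            transmural=str(r.transmural),
            seed=int(getattr(r, "seed", 0)),
            amplitude_gain=float(getattr(r, "amplitude_gain", 1.0)),
        )
        for r in df.itertuples()
    ]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def write_results_json(results: dict, path: Path | str) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(results), indent=1, sort_keys=True))
    return path
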