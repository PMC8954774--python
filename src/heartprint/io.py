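"""On-disk formats: text signals with JSON sidecars, CSV manifests, template
stores (npz array container + JSON index) and JSON reports."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import ConfigurationError, ECGRecord
from .templates import ICAModel, SubjectFeatureMatrix

log = logging.getLogger(__name__)


def record_basename(rec: ECGRecord) -> str:
    return f"{rec.subject_id}_s{rec.session_id}"


def write_record(rec: ECGRecord, out_dir: Path) -> Path:
    """One sample per line at full precision, plus a JSON metadata sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = record_basename(rec)
    sig_path = out_dir / f"{base}.txt"
    np.savetxt(sig_path, rec.signal, fmt="%.17g")
    meta = {
        "subject_id": rec.subject_id,
        "session_id": rec.session_id,
        "fs": rec.fs,
        "n_samples": int(rec.signal.size),
    }
    if rec.true_r_peaks is not None:
        meta["true_r_peaks"] = [int(i) for i in rec.true_r_peaks]
    (out_dir / f"{base}.json").write_text(json.dumps(meta))
    return sig_path


def read_record(signal_path: Path, sidecar_path: Path | None = None) -> ECGRecord:
    signal_path = Path(signal_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else signal_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise ConfigurationError(f"missing metadata sidecar for {signal_path}")
    meta = json.loads(sidecar_path.read_text())
    if "fs" not in meta:
        raise ConfigurationError(f"sidecar {sidecar_path} does not declare fs")
    signal = np.loadtxt(signal_path)
    if "n_samples" in meta and signal.size != meta["n_samples"]:
        log.warning("%s: %d samples on disk vs %d declared; trusting the data",
                    signal_path, signal.size, meta["n_samples"])
    peaks = meta.get("true_r_peaks")
    return ECGRecord(
        subject_id=str(meta.get("subject_id", signal_path.stem)),
        session_id=int(meta.get("session_id", 1)),
        fs=float(meta["fs"]),
        signal=signal,
        true_r_peaks=np.asarray(peaks, dtype=int) if peaks is not None else None,
    )


def write_cohort(records: list[ECGRecord], out_dir: Path) -> Path:
    """Write every record plus a manifest CSV (subject_id, session_id, path)."""
    out_dir = Path(out_dir)
    rows = []
    for rec in records:
        path = write_record(rec, out_dir)
        rows.append({"subject_id": rec.subject_id, "session_id": rec.session_id,
                     "path": path.name})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: Path) -> list[ECGRecord]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    return [read_record(manifest_path.parent / row["path"]) for _, row in df.iterrows()]


def write_feature_matrix(matrix: SubjectFeatureMatrix, path: Path) -> None:
    """npz array container next to a JSON index describing provenance and
    the flattening convention."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, values=matrix.values)
    index = {
        "subject_ids": matrix.subject_ids,
        "kind": matrix.kind,
        "k": matrix.k,
        "size": matrix.size,
        "normalized": matrix.normalized,
        "reduced": matrix.reduced,
        "flattening": "template-major, row-major within image, channel-last",
    }
    path.with_suffix(".json").write_text(json.dumps(index))


def read_feature_matrix(path: Path) -> SubjectFeatureMatrix:
    path = Path(path)
    index = json.loads(path.with_suffix(".json").read_text())
    with np.load(path) as z:
        values = z["values"]
    return SubjectFeatureMatrix(values, index["subject_ids"], kind=index["kind"],
                                k=index["k"], size=index["size"],
                                normalized=index["normalized"],
                                reduced=index["reduced"])


def write_report(report, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = report.to_dict() if hasattr(report, "to_dict") else report
    path.write_text(json.dumps(payload, indent=2))


def read_report(path: Path) -> dict:
    return json.loads(Path(path).read_text())
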