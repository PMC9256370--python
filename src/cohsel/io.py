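"""Readers and writers: cohort matrices + manifest, feature CSV,
search-result and CV-report JSON, ROC traces.

Per-subject signal files are plain CSV with one column per channel
(header row = channel labels) and one row per sample; the reader
transposes back to the channels x samples layout used in memory. A
manifest CSV (subject_id, path, label) indexes the cohort. EDF input is
supported when ``mne`` is installed.
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .coherence import CoherenceFeatureMatrix
from .colony import SearchResult
from .crossval import CVReport
from .synthetic import EEGRecording

__all__ = [
    "write_cohort", "read_cohort", "read_recording_csv", "read_recording_edf",
    "write_features", "read_features",
    "write_search_result", "write_report", "write_roc", "write_selected_features",
    "provenance",
]


def provenance(config: dict, seed: int | None = None) -> dict:
    try:
        ver = version("cohsel")
    except PackageNotFoundError:
        ver = "unknown"
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "package_version": ver,
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        "seed": seed,
    }


def write_cohort(recs: list[EEGRecording], out_dir: str | Path) -> Path:
    """One CSV per subject plus manifest.csv; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recs:
        path = out / f"{rec.subject_id}.csv"
        pd.DataFrame(rec.data.T, columns=list(rec.channels)).to_csv(
            path, index=False, float_format="%.6g")
        rows.append({"subject_id": rec.subject_id, "path": path.name,
                     "label": rec.label, "fs": rec.fs})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_recording_csv(
    path: str | Path, fs: float, subject_id: str, label: str
) -> EEGRecording:
    df = pd.read_csv(path)
    return EEGRecording(df.to_numpy(float).T, fs, tuple(df.columns),
                       subject_id, label)


def read_recording_edf(path: str | Path, subject_id: str, label: str) -> EEGRecording:
    """Read one EDF recording (requires the optional ``mne`` dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF input needs the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGRecording(raw.get_data() * 1e6, float(raw.info["sfreq"]),
                        tuple(raw.ch_names), subject_id, label)


def read_cohort(manifest_path: str | Path, default_fs: float = 250.0) -> list[EEGRecording]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    for col in ("subject_id", "path", "label"):
        if col not in df.columns:
            raise ValueError(f"manifest missing column {col!r}")
    recs = []
    for _, row in df.iterrows():
        path = manifest_path.parent / row["path"]
        if not path.exists():
            raise FileNotFoundError(f"{path} (listed in {manifest_path})")
        fs = float(row.get("fs", default_fs) or default_fs)
        if path.suffix.lower() == ".edf":
            recs.append(read_recording_edf(path, str(row["subject_id"]),
                                           str(row["label"])))
        else:
            recs.append(read_recording_csv(path, fs, str(row["subject_id"]),
                                           str(row["label"])))
    return recs


def write_features(fm: CoherenceFeatureMatrix, path: str | Path,
                   prov: dict | None = None) -> None:
    path = Path(path)
    fm.to_dataframe().to_csv(path, index=False)
    if prov:
        path.with_suffix(path.suffix + ".provenance.json").write_text(
            json.dumps(prov, indent=2))


def read_features(path: str | Path) -> CoherenceFeatureMatrix:
    return CoherenceFeatureMatrix.from_dataframe(pd.read_csv(path))


def write_search_result(res: SearchResult, feature_names: list[str],
                        path: str | Path, prov: dict | None = None) -> None:
    path = Path(path)
    selected = [n for n, m in zip(feature_names, res.best.subset) if m]
    payload = {
        "method": res.method,
        "selected_features": selected,
        "mask": [int(b) for b in res.best.subset],
        "accuracy": res.best.accuracy,
        "fitness": res.best.fitness,
        "n_selected": res.best.n_selected,
        "evaluations": res.evaluations,
        "history": res.history,
    }
    if prov:
        payload["provenance"] = prov
    path.write_text(json.dumps(payload, indent=2))


def write_convergence(res: SearchResult, path: str | Path) -> None:
    pd.DataFrame(res.history).to_csv(path, index=False)


def write_report(report: CVReport, path: str | Path,
                 prov: dict | None = None) -> None:
    payload = report.to_dict()
    if prov:
        payload["provenance"] = prov
    Path(path).write_text(json.dumps(payload, indent=2))


def write_roc(report: CVReport, path: str | Path) -> None:
    """Per-fold ROC points (FPR, TPR) swept over the decision scores."""
    from sklearn.metrics import roc_curve

    rows = []
    for f in report.folds:
        fpr, tpr, _ = roc_curve(f["truth"], f["scores"])
        for a, b in zip(fpr, tpr):
            rows.append({"fold": f["fold"], "fpr": a, "tpr": b})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_selected_features(report: CVReport, path: str | Path) -> None:
    """Pair-by-band table of the global best subset (1 = selected)."""
    names = report.selected_features()
    split = [n.rsplit("_", 1) for n in report.feature_names]
    pairs = list(dict.fromkeys(p for p, _ in split))
    bands = list(dict.fromkeys(b for _, b in split))
    table = pd.DataFrame(0, index=pairs, columns=bands)
    for n in names:
        p, b = n.rsplit("_", 1)
        table.loc[p, b] = 1
    table.index.name = "pair"
    table.to_csv(path)
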