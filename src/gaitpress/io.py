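"""File formats: recordings (CSV + JSON sidecar), feature tables (CSV),
models (JSON) and evaluation results (JSON + a results-table CSV).

Recording CSV layout: one row per frame, columns ``t, r0c0..r7c7``
(row-major cells).  The sidecar JSON carries subject metadata, label,
section and sampling rate.  All round-trips are lossless (floats written
at full precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, reduction
from .recording import GRID_SHAPE, PressureRecording

_CELL_COLS = [f"r{r}c{c}" for r in range(GRID_SHAPE[0]) for c in range(GRID_SHAPE[1])]


def recording_to_frame(rec: PressureRecording) -> pd.DataFrame:
    flat = rec.frames.reshape(rec.n_frames, -1)
    df = pd.DataFrame(flat, columns=_CELL_COLS)
    df.insert(0, "t", rec.times())
    return df


def write_recording(rec: PressureRecording, csv_path) -> Path:
    """Write frames CSV plus a ``.json`` sidecar next to it."""
    csv_path = Path(csv_path)
    recording_to_frame(rec).to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = {
        "subject_id": rec.subject_id,
        "label": rec.label,
        "section": rec.section,
        "fs": rec.fs,
        "t0": rec.t0,
        "meta": rec.meta,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_recording(csv_path) -> PressureRecording:
    csv_path = Path(csv_path)
    side = json.loads(csv_path.with_suffix(".json").read_text())
    df = pd.read_csv(csv_path)
    missing = [c for c in _CELL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"recording CSV missing cell columns: {missing[:3]}...")
    t = df["t"].to_numpy(float)
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        fs_obs = 1.0 / np.median(dt)
        if abs(fs_obs - side["fs"]) / side["fs"] > 0.01:
            raise ValueError(
                f"timestamps inconsistent with fs={side['fs']} (observed {fs_obs:.3f})"
            )
    frames = df[_CELL_COLS].to_numpy(float).reshape(-1, *GRID_SHAPE)
    return PressureRecording(
        frames, side["fs"], side["subject_id"], side["label"], side["section"],
        side.get("t0", 0.0), side.get("meta", {}),
    )


def write_scan_csv(frames, times, path) -> Path:
    """Integer ADC scan frames as CSV (t, r0c0..r7c7)."""
    frames = np.asarray(frames)
    df = pd.DataFrame(frames.reshape(frames.shape[0], -1), columns=_CELL_COLS)
    df = df.astype(int)
    df.insert(0, "t", times)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def write_calibration(lines: dict, path) -> Path:
    """Calibration table keyed by cell index ``"r,c"``."""
    payload = {
        k: {"slope": v.slope, "intercept": v.intercept, "r_squared": v.r_squared}
        for k, v in lines.items()
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path


def write_features(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_features(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def save_model(model, path) -> Path:
    """Serialize a PCA/LDA/SVM/NN model (or a reducer+classifier pair)."""
    path = Path(path)
    if isinstance(model, tuple):
        red, clf = model
        payload = {
            "type": "pipeline",
            "reducer": None if red is None else red.to_json(),
            "classifier": clf.to_json(),
        }
    else:
        payload = model.to_json()
    path.write_text(json.dumps(payload))
    return path


def _model_from_json(d: dict):
    kind = d["type"]
    if kind == "pca":
        return reduction.PCAModel.from_json(d)
    if kind == "lda":
        return reduction.LDAModel.from_json(d)
    if kind == "svm":
        return classify.SVMModel.from_json(d)
    if kind == "nn":
        return classify.NNModel.from_json(d)
    raise ValueError(f"unknown model type {kind!r}")


def load_model(path):
    d = json.loads(Path(path).read_text())
    if d["type"] == "pipeline":
        red = None if d["reducer"] is None else _model_from_json(d["reducer"])
        return red, _model_from_json(d["classifier"])
    return _model_from_json(d)


def write_results(result, algorithm: str, json_path, csv_path=None) -> Path:
    """Evaluation results as JSON plus the results-table CSV
    (Algorithm, Recall, Average precision (%), Time cost (ms))."""
    json_path = Path(json_path)
    payload = {
        "algorithm": algorithm,
        "class_order": list(result.class_order),
        "fold_accuracies": result.fold_accuracies.tolist(),
        "per_class_recall": result.per_class_recall.tolist(),
        "macro_precision_pct": result.macro_precision_pct,
        "overall_accuracy_pct": result.overall_accuracy_pct,
        "confusion": result.confusion.tolist(),
        "time_ms": result.time_ms,
        "batch_size": result.batch_size,
    }
    json_path.write_text(json.dumps(payload, indent=1))
    if csv_path is not None:
        pd.DataFrame([result.table_row(algorithm)]).to_csv(csv_path, index=False)
    return json_path
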