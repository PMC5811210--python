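"""Readers and writers for the package's artifact files.

Tables (trial designs, accuracy curves, cluster summaries, fusion results)
are CSV with JSON sidecars carrying configuration and ordering metadata;
epoched/component data go to HDF5 with full provenance attributes.  Every
writer has a reader that round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .decoding import (AccuracyTimecourse, DecodingConfig,
                       TemporalGeneralizationMatrix)
from .fusion import FusionResult
from .preprocess import ComponentDataset
from .rsa import RDM
from .synth import EpochedDataset

__all__ = [
    "sha256_file", "save_trial_table", "load_trial_table",
    "save_epochs_h5", "load_epochs_h5",
    "save_components_h5", "load_components_h5",
    "save_timecourse_csv", "load_timecourse_csv",
    "save_tg_matrix_csv", "load_tg_matrix_csv",
    "save_rdm_csv", "load_rdm_csv", "save_rdv_csv", "load_rdv_csv",
    "save_fusion_csv", "load_fusion_csv",
]


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(path: Path, meta: dict) -> None:
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def _read_sidecar(path: Path) -> dict:
    side = _sidecar(path)
    return json.loads(side.read_text()) if side.exists() else {}


def save_trial_table(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def load_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["is_catch"] = df["is_catch"].astype(bool)
    return df


def _save_labeled_h5(path, data, time_ms, rate, trials, subject_id, extra_attrs):
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=data, compression="gzip", shuffle=True)
        f.create_dataset("time_ms", data=time_ms)
        grp = f.create_group("labels")
        for col in trials.columns:
            grp.create_dataset(col, data=np.asarray(trials[col]))
        f.attrs["sampling_rate"] = rate
        f.attrs["subject_id"] = subject_id
        for k, v in extra_attrs.items():
            f.attrs[k] = v


def _load_labeled_h5(path):
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        time_ms = f["time_ms"][()]
        trials = pd.DataFrame({c: f["labels"][c][()] for c in f["labels"]})
        if "is_catch" in trials:
            trials["is_catch"] = trials["is_catch"].astype(bool)
        attrs = dict(f.attrs)
    return data, time_ms, trials, attrs


def save_epochs_h5(epochs: EpochedDataset, path, seed: int | None = None,
                   spec: dict | None = None) -> None:
    extra = {}
    if seed is not None:
        extra["seed"] = seed
    if spec is not None:
        extra["spec_json"] = json.dumps(spec, sort_keys=True)
    _save_labeled_h5(path, epochs.data, epochs.time_ms, epochs.sampling_rate,
                     epochs.trials, epochs.subject_id, extra)


def load_epochs_h5(path) -> EpochedDataset:
    data, time_ms, trials, attrs = _load_labeled_h5(path)
    return EpochedDataset(data, time_ms, float(attrs["sampling_rate"]),
                          trials[["task", "category", "exemplar", "color",
                                  "tilt", "run", "is_catch"]],
                          subject_id=str(attrs["subject_id"]))


def save_components_h5(comp: ComponentDataset, path) -> None:
    _save_labeled_h5(path, comp.data, comp.time_ms, comp.sampling_rate,
                     comp.trials, comp.subject_id,
                     {"provenance_json": json.dumps(comp.provenance,
                                                    sort_keys=True)})


def load_components_h5(path) -> ComponentDataset:
    data, time_ms, trials, attrs = _load_labeled_h5(path)
    prov = json.loads(attrs.get("provenance_json", "{}"))
    return ComponentDataset(data, time_ms, float(attrs["sampling_rate"]),
                            trials, subject_id=str(attrs["subject_id"]),
                            provenance=prov)


def _config_meta(config: DecodingConfig | None) -> dict:
    return dataclasses.asdict(config) if config is not None else {}


def save_timecourse_csv(curves: list[AccuracyTimecourse], path) -> None:
    """Long format: subject, train_time, test_time, accuracy (train ==
    test time for plain time courses)."""
    path = Path(path)
    rows = []
    for c in curves:
        for tm, acc in zip(c.time_ms, c.accuracy):
            rows.append((c.subject_id, tm, tm, acc))
    pd.DataFrame(rows, columns=["subject", "train_time", "test_time",
                                "accuracy"]).to_csv(path, index=False)
    first = curves[0]
    _write_sidecar(path, {"factor": first.factor, "chance": first.chance,
                          "config": _config_meta(first.config)})


def load_timecourse_csv(path) -> list[AccuracyTimecourse]:
    path = Path(path)
    df = pd.read_csv(path)
    meta = _read_sidecar(path)
    out = []
    for subj, g in df.groupby("subject", sort=False):
        out.append(AccuracyTimecourse(
            g["accuracy"].to_numpy(), g["train_time"].to_numpy(),
            meta.get("factor", ""), chance=meta.get("chance", 50.0),
            subject_id=str(subj)))
    return out


def save_tg_matrix_csv(mats: list[TemporalGeneralizationMatrix], path) -> None:
    path = Path(path)
    frames = []
    for m in mats:
        tr, te = np.meshgrid(m.time_ms, m.time_ms, indexing="ij")
        frames.append(pd.DataFrame({
            "subject": m.subject_id, "train_time": tr.ravel(),
            "test_time": te.ravel(), "accuracy": m.accuracy.ravel()}))
    pd.concat(frames).to_csv(path, index=False)
    first = mats[0]
    _write_sidecar(path, {"factor": first.factor, "chance": first.chance,
                          "config": _config_meta(first.config)})


def load_tg_matrix_csv(path) -> list[TemporalGeneralizationMatrix]:
    path = Path(path)
    df = pd.read_csv(path)
    meta = _read_sidecar(path)
    out = []
    for subj, g in df.groupby("subject", sort=False):
        times = np.unique(g["train_time"].to_numpy())
        n = times.size
        acc = g.sort_values(["train_time", "test_time"])["accuracy"] \
            .to_numpy().reshape(n, n)
        out.append(TemporalGeneralizationMatrix(
            acc, times, meta.get("factor", ""),
            chance=meta.get("chance", 50.0), subject_id=str(subj)))
    return out


def _condition_labels(order) -> list[str]:
    return [f"t{t}c{c}" for t, c in order]


def save_rdm_csv(rdm: RDM, path) -> None:
    path = Path(path)
    labels = _condition_labels(rdm.condition_order)
    pd.DataFrame(rdm.values, index=labels, columns=labels).to_csv(path)
    _write_sidecar(path, {"condition_order": [list(c) for c in rdm.condition_order],
                          "label": rdm.label})


def load_rdm_csv(path) -> RDM:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    meta = _read_sidecar(path)
    order = [tuple(c) for c in meta["condition_order"]] if meta else \
        [tuple(int(x) for x in lab.replace("t", "").split("c"))
         for lab in df.index]
    return RDM(df.to_numpy(), order, label=meta.get("label"))


def save_rdv_csv(v: np.ndarray, condition_order, path) -> None:
    """Single-column RDV CSV with the condition ordering in a JSON sidecar."""
    path = Path(path)
    pd.DataFrame({"dissimilarity": np.asarray(v, dtype=float)}).to_csv(
        path, index=False)
    _write_sidecar(path, {"condition_order": [list(c) for c in condition_order],
                          "triangle": "lower, column-major, no diagonal"})


def load_rdv_csv(path) -> tuple[np.ndarray, list[tuple[int, int]]]:
    path = Path(path)
    v = pd.read_csv(path)["dissimilarity"].to_numpy()
    meta = _read_sidecar(path)
    order = [tuple(c) for c in meta.get("condition_order", [])]
    return v, order


def save_fusion_csv(result: FusionResult, path) -> None:
    path = Path(path)
    rows = []
    for roi in result.rois:
        for i, tm in enumerate(result.time_ms):
            rows.append((roi, tm, result.r2_total[roi][i],
                         result.c_task[roi][i], result.c_category[roi][i]))
    pd.DataFrame(rows, columns=["roi", "time_ms", "r2_total", "c_task",
                                "c_category"]).to_csv(path, index=False)
    _write_sidecar(path, {
        "target": result.target,
        "condition_order": [list(c) for c in result.condition_order]})


def load_fusion_csv(path) -> FusionResult:
    path = Path(path)
    df = pd.read_csv(path)
    meta = _read_sidecar(path)
    r2, ct, cc = {}, {}, {}
    time_ms = None
    for roi, g in df.groupby("roi", sort=False):
        time_ms = g["time_ms"].to_numpy()
        r2[roi] = g["r2_total"].to_numpy()
        ct[roi] = g["c_task"].to_numpy()
        cc[roi] = g["c_category"].to_numpy()
    return FusionResult(time_ms, r2, ct, cc,
                        condition_order=[tuple(c) for c in
                                         meta.get("condition_order", [])],
                        target=meta.get("target", "fmri"))
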