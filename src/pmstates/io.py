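"""Readers, writers and provenance for every pipeline artifact.

Format choices: TSV for matrices (human-diffable), HDF5 for multi-subject
time-series containers, JSON for models, configs and traces.  Every writer
emits a schema version and every reader rejects unversioned files; every
CLI run additionally writes a provenance record (config snapshot, seeds,
input digests, timestamps) next to its outputs.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np

from .core import RegionalTimeSeries, TransitionMatrix
from .fitting import ECState
from .leida import PMSModel
from .perturbation import GreedyTrace, TransitionMap
from .synthetic import Connectome

SCHEMA_VERSION = 1

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_dataset",
    "write_dataset",
    "read_connectome",
    "write_connectome",
    "read_pms_model",
    "write_pms_model",
    "read_ec_state",
    "write_ec_state",
    "write_transition_map",
    "read_transition_map",
    "write_greedy_trace",
    "read_greedy_trace",
    "write_provenance",
]


def _check_schema(meta: dict, path) -> None:
    if "schema_version" not in meta:
        raise ValueError(
            f"{path}: missing schema_version; unversioned/legacy files are "
            "not accepted"
        )


def _load_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise ValueError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    _check_schema(meta, sidecar)
    return meta


def _dump_sidecar(path: Path, meta: dict) -> None:
    meta = {"schema_version": SCHEMA_VERSION, **meta}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def _check_finite_matrix(arr: np.ndarray, path) -> None:
    if not np.all(np.isfinite(arr)):
        r, c = np.argwhere(~np.isfinite(arr))[0]
        raise ValueError(f"{path}: non-finite value at row {r}, column {c}")


# ------------------------------------------------------------ time series


def write_timeseries(ts: RegionalTimeSeries, path) -> None:
    """TSV (regions x samples) with JSON sidecar, or a single-subject HDF5."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("timeseries", data=ts.values)
            d.attrs["tr_s"] = ts.tr_s
            d.attrs["subject_id"] = ts.subject_id
            d.attrs["condition"] = ts.condition
            f.attrs["schema_version"] = SCHEMA_VERSION
    else:
        np.savetxt(path, ts.values, delimiter="\t")
        _dump_sidecar(
            path,
            {"tr_s": ts.tr_s, "subject_id": ts.subject_id, "condition": ts.condition},
        )


def read_timeseries(path) -> RegionalTimeSeries:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            if "schema_version" not in f.attrs:
                raise ValueError(f"{path}: missing schema_version attribute")
            d = f["timeseries"]
            if "tr_s" not in d.attrs:
                raise ValueError(f"{path}: timeseries dataset lacks a tr_s attribute")
            values = d[()]
            _check_finite_matrix(values, path)
            return RegionalTimeSeries(
                values,
                tr_s=float(d.attrs["tr_s"]),
                subject_id=str(d.attrs.get("subject_id", "")),
                condition=str(d.attrs.get("condition", "")),
            )
    meta = _load_sidecar(path)
    if "tr_s" not in meta:
        raise ValueError(f"{path}: sidecar lacks tr_s; it is never guessed")
    try:
        values = np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as e:
        raise ValueError(f"{path}: malformed TSV (ragged rows?): {e}") from e
    _check_finite_matrix(values, path)
    return RegionalTimeSeries(
        values,
        tr_s=float(meta["tr_s"]),
        subject_id=str(meta.get("subject_id", "")),
        condition=str(meta.get("condition", "")),
    )


def write_dataset(dataset: list[RegionalTimeSeries], path, ground_truth=None) -> None:
    """Multi-subject HDF5 container: one group per subject."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        if ground_truth is not None:
            f.attrs["ground_truth"] = json.dumps(ground_truth)
        for ts in dataset:
            g = f.create_group(ts.subject_id)
            d = g.create_dataset("timeseries", data=ts.values)
            d.attrs["tr_s"] = ts.tr_s
            d.attrs["subject_id"] = ts.subject_id
            d.attrs["condition"] = ts.condition


def read_dataset(path) -> tuple[list[RegionalTimeSeries], dict | None]:
    path = Path(path)
    dataset = []
    with h5py.File(path, "r") as f:
        if "schema_version" not in f.attrs:
            raise ValueError(f"{path}: missing schema_version attribute")
        gt = json.loads(f.attrs["ground_truth"]) if "ground_truth" in f.attrs else None
        for name in sorted(f.keys()):
            d = f[name]["timeseries"]
            values = d[()]
            _check_finite_matrix(values, path)
            dataset.append(
                RegionalTimeSeries(
                    values,
                    tr_s=float(d.attrs["tr_s"]),
                    subject_id=str(d.attrs.get("subject_id", name)),
                    condition=str(d.attrs.get("condition", "")),
                )
            )
    return dataset, gt


# ------------------------------------------------------------- connectome


def write_connectome(conn: Connectome, path) -> None:
    path = Path(path)
    np.savetxt(path, conn.weights, delimiter="\t")
    _dump_sidecar(
        path,
        {
            "region_names": conn.region_names,
            "homotopic_pairs": conn.homotopic_pairs,
            "mean_weight": conn.mean_weight,
            "name": conn.name,
        },
    )


def read_connectome(path) -> Connectome:
    path = Path(path)
    w = np.loadtxt(path, delimiter="\t", ndmin=2)
    _check_finite_matrix(w, path)
    if np.max(np.abs(w - w.T)) > 1e-9:
        raise ValueError(f"{path}: connectome asymmetric beyond 1e-9")
    meta = _load_sidecar(path)
    pairs = meta.get("homotopic_pairs")
    return Connectome(
        weights=w,
        region_names=list(meta.get("region_names", [str(i) for i in range(w.shape[0])])),
        homotopic_pairs=[tuple(p) for p in pairs] if pairs is not None else None,
        mean_weight=float(meta.get("mean_weight", float(np.mean(w[~np.eye(w.shape[0], dtype=bool)])))),
        name=str(meta.get("name", path.stem)),
    )


# -------------------------------------------------------------- PMS model


def _tpm_to_json(tpm: TransitionMatrix) -> dict:
    values = np.where(np.isnan(tpm.values), None, tpm.values)
    return {
        "values": [[None if v is None else float(v) for v in row] for row in values.tolist()],
        "visited": tpm.visited.tolist(),
    }


def _tpm_from_json(obj: dict) -> TransitionMatrix:
    values = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in obj["values"]]
    )
    return TransitionMatrix(values=values, visited=np.asarray(obj["visited"], bool))


def write_pms_model(model: PMSModel, path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "k": model.k,
        "centroids": model.centroids.tolist(),
        "probabilities": model.probabilities.tolist(),
        "tpm": _tpm_to_json(model.tpm),
        "silhouette": model.silhouette,
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_pms_model(path) -> PMSModel:
    obj = json.loads(Path(path).read_text())
    _check_schema(obj, path)
    probs = np.asarray(obj["probabilities"], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError(
            f"{path}: probabilities sum to {probs.sum():.6f}, not 1; file rejected"
        )
    return PMSModel(
        centroids=np.asarray(obj["centroids"], dtype=float),
        probabilities=probs / probs.sum(),
        tpm=_tpm_from_json(obj["tpm"]),
        k=int(obj["k"]),
        silhouette=obj.get("silhouette"),
        metadata=obj.get("metadata", {}),
    )


# ---------------------------------------------------------------- EC state


def write_ec_state(ec: ECState, path) -> None:
    path = Path(path)
    np.savetxt(path, ec.weights, delimiter="\t")
    _dump_sidecar(
        path,
        {
            "iteration": ec.iteration,
            "epsilon": ec.epsilon,
            "fit_history": [[int(i), float(o)] for i, o in ec.fit_history],
        },
    )


def read_ec_state(path) -> ECState:
    path = Path(path)
    w = np.loadtxt(path, delimiter="\t", ndmin=2)
    _check_finite_matrix(w, path)
    meta = _load_sidecar(path)
    return ECState(
        weights=w,
        iteration=int(meta["iteration"]),
        fit_history=[(int(i), float(o)) for i, o in meta["fit_history"]],
        epsilon=float(meta["epsilon"]),
    )


# --------------------------------------------------- perturbation artifacts


def write_transition_map(tmap: TransitionMap, path) -> None:
    path = Path(path)
    header = "pair\t" + "\t".join(f"{v:g}" for v in tmap.intensity_grid)
    lines = [header]
    for label, row in zip(tmap.pair_labels, tmap.kl_values):
        lines.append(label + "\t" + "\t".join(f"{v:.10g}" for v in row))
    path.write_text("\n".join(lines) + "\n")
    _dump_sidecar(
        path,
        {
            "baseline_kl": tmap.baseline_kl,
            "protocol": tmap.protocol,
            "intensity_grid": tmap.intensity_grid.tolist(),
            "pair_labels": tmap.pair_labels,
        },
    )


def read_transition_map(path) -> TransitionMap:
    path = Path(path)
    meta = _load_sidecar(path)
    rows = [l.split("\t") for l in path.read_text().strip().split("\n")[1:]]
    kl = np.array([[float(v) for v in r[1:]] for r in rows])
    return TransitionMap(
        kl_values=kl,
        intensity_grid=np.asarray(meta["intensity_grid"], float),
        baseline_kl=float(meta["baseline_kl"]),
        protocol=str(meta["protocol"]),
        pair_labels=list(meta["pair_labels"]),
    )


def write_greedy_trace(trace: GreedyTrace, path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "chosen_pairs": [int(p) for p in trace.chosen_pairs],
        "kl_to_target": trace.kl_to_target.tolist(),
        "kl_to_source": trace.kl_to_source.tolist(),
        "substate_probabilities": trace.substate_probabilities.tolist(),
        "best_step": int(trace.best_step),
        "delta_a": trace.delta_a,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_greedy_trace(path) -> GreedyTrace:
    obj = json.loads(Path(path).read_text())
    _check_schema(obj, path)
    return GreedyTrace(
        chosen_pairs=[int(p) for p in obj["chosen_pairs"]],
        kl_to_target=np.asarray(obj["kl_to_target"], float),
        kl_to_source=np.asarray(obj["kl_to_source"], float),
        substate_probabilities=np.asarray(obj["substate_probabilities"], float),
        best_step=int(obj["best_step"]),
        delta_a=float(obj["delta_a"]),
    )


# -------------------------------------------------------------- provenance


def write_provenance(out_path, config: dict, seeds=None, inputs=()) -> Path:
    """Provenance sidecar: config snapshot, seeds, timestamps, input digests."""
    from . import __version__

    out_path = Path(out_path)
    digests = {}
    for p in inputs:
        p = Path(p)
        if p.exists():
            digests[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    record = {
        "schema_version": SCHEMA_VERSION,
        "code_version": __version__,
        "timestamp_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": config,
        "seeds": seeds,
        "input_digests": digests,
    }
    prov = out_path.with_suffix(out_path.suffix + ".prov.json")
    prov.write_text(json.dumps(record, indent=1))
    return prov
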