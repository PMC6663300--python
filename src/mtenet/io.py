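"""Readers and writers for recordings, networks, ground truth, and configs.

Formats are deliberately plain: comma-delimited time series (header row of
process labels, rows are time samples, one file per replication), JSON for
inferred networks and ground-truth edge lists, YAML or JSON for run
configuration.  Network files carry a schema version and a full settings
echo so that results remain auditable and reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .data import Candidate, TimeSeriesData
from .greedy import (
    InferenceSettings,
    NetworkResult,
    SelectedVariable,
    TargetInferenceResult,
)
from .synthetic import GroundTruthNetwork

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_network",
    "write_network",
    "write_links_csv",
    "read_ground_truth",
    "write_ground_truth",
    "load_config",
    "settings_from_config",
    "write_manifest",
]

NETWORK_SCHEMA_VERSION = 1
GROUND_TRUTH_SCHEMA_VERSION = 1


# --- time series ------------------------------------------------------------


def write_timeseries(data: TimeSeriesData, paths: str | Path | Sequence) -> None:
    """Write one CSV per replication (header: process labels; rows: time)."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if len(paths) != data.n_replications:
        raise ValueError(
            f"{len(paths)} paths for {data.n_replications} replications"
        )
    for r, path in enumerate(paths):
        pd.DataFrame(data.values[:, :, r], columns=data.labels).to_csv(
            path, index=False, float_format="%.17g"  # bit-exact round-trip
        )


def _read_one(path: Path) -> pd.DataFrame:
    frame = pd.read_csv(path, float_precision="round_trip")
    for j, col in enumerate(frame.columns):
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna() & frame[col].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"{path}: non-numeric cell at row {row}, column {col!r}"
            )
        if numeric.isna().any():
            row = int(np.argmax(numeric.isna().to_numpy()))
            raise ValueError(f"{path}: missing value at row {row}, column {col!r}")
        frame[col] = numeric
    return frame


def read_timeseries(paths: str | Path | Sequence) -> TimeSeriesData:
    """Read one or more replication CSVs into a (T, N, R) recording."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = [_read_one(Path(p)) for p in paths]
    first = frames[0]
    for p, f in zip(paths, frames):
        if list(f.columns) != list(first.columns):
            raise ValueError(f"{p}: process labels differ across replications")
        if f.shape != first.shape:
            raise ValueError(
                f"{p}: replication length {f.shape[0]} differs from "
                f"{first.shape[0]}"
            )
    values = np.stack([f.to_numpy(dtype=float) for f in frames], axis=2)
    return TimeSeriesData(values, labels=list(first.columns))


# --- inferred networks ------------------------------------------------------


def _variable_record(v: SelectedVariable) -> dict:
    return {
        "process": v.candidate.process,
        "lag": v.candidate.lag,
        "cmi": v.cmi,
        "p_value": v.p_value,
        "final_cmi": v.final_cmi,
    }


def _variable_from_record(rec: dict) -> SelectedVariable:
    return SelectedVariable(
        candidate=Candidate(rec["process"], rec["lag"]),
        cmi=rec["cmi"],
        p_value=rec["p_value"],
        final_cmi=rec["final_cmi"],
    )


def write_network(result: NetworkResult, path: str | Path) -> None:
    """Serialize an inference result to versioned JSON."""
    doc = {
        "schema_version": NETWORK_SCHEMA_VERSION,
        "n_processes": result.n_processes,
        "settings": asdict(result.settings),
        "targets": [
            {
                "target": r.target,
                "selected_target_past": [
                    _variable_record(v) for v in r.selected_target_past
                ],
                "selected_sources": [
                    _variable_record(v) for v in r.selected_sources
                ],
                "removed_in_pruning": [
                    _variable_record(v) for v in r.removed_in_pruning
                ],
                "omnibus_te": r.omnibus_te,
                "omnibus_p": r.omnibus_p,
                "source_set_accepted": r.source_set_accepted,
                "n_effective": r.n_effective,
            }
            for r in (result.targets[t] for t in sorted(result.targets))
        ],
        "fdr_kept": {str(t): bool(k) for t, k in sorted(result.fdr_kept.items())},
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_network(path: str | Path) -> NetworkResult:
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != NETWORK_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported network schema version {version!r}; "
            f"expected {NETWORK_SCHEMA_VERSION}"
        )
    targets = {}
    for rec in doc["targets"]:
        targets[rec["target"]] = TargetInferenceResult(
            target=rec["target"],
            selected_target_past=[
                _variable_from_record(v) for v in rec["selected_target_past"]
            ],
            selected_sources=[
                _variable_from_record(v) for v in rec["selected_sources"]
            ],
            removed_in_pruning=[
                _variable_from_record(v) for v in rec["removed_in_pruning"]
            ],
            omnibus_te=rec["omnibus_te"],
            omnibus_p=rec["omnibus_p"],
            source_set_accepted=rec["source_set_accepted"],
            n_effective=rec["n_effective"],
        )
    return NetworkResult(
        n_processes=doc["n_processes"],
        settings=InferenceSettings(**doc["settings"]),
        targets=targets,
        fdr_kept={int(t): k for t, k in doc["fdr_kept"].items()},
    )


def write_links_csv(result: NetworkResult, path: str | Path) -> None:
    """Flat edge list: source, target, lag (representative), te, p."""
    rows = [
        {
            "source": link.source,
            "target": link.target,
            "lag": link.representative_lag,
            "te": link.te,
            "p": link.p,
        }
        for link in result.links
    ]
    pd.DataFrame(rows, columns=["source", "target", "lag", "te", "p"]).to_csv(
        path, index=False
    )


# --- ground truth -----------------------------------------------------------


def write_ground_truth(net: GroundTruthNetwork, path: str | Path) -> None:
    srcs, tgts = np.nonzero(net.adjacency)
    doc = {
        "schema_version": GROUND_TRUTH_SCHEMA_VERSION,
        "n": net.n,
        "beta": net.beta.tolist(),
        "link_probability": net.link_probability,
        "links": [
            {
                "source": int(s),
                "target": int(t),
                "lag": int(net.lags[s, t]),
                "weight": float(net.weights[s, t]),
            }
            for s, t in zip(srcs, tgts)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_ground_truth(path: str | Path) -> GroundTruthNetwork:
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != GROUND_TRUTH_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported ground-truth schema version {version!r}; "
            f"expected {GROUND_TRUTH_SCHEMA_VERSION}"
        )
    n = doc["n"]
    adjacency = np.zeros((n, n), dtype=bool)
    lags = np.zeros((n, n), dtype=int)
    weights = np.zeros((n, n))
    for link in doc["links"]:
        s, t = link["source"], link["target"]
        adjacency[s, t] = True
        lags[s, t] = link["lag"]
        weights[s, t] = link["weight"]
    return GroundTruthNetwork(
        adjacency=adjacency,
        lags=lags,
        weights=weights,
        beta=np.asarray(doc["beta"]),
        link_probability=doc.get("link_probability"),
    )


# --- configuration and provenance -------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def settings_from_config(config: dict) -> InferenceSettings:
    """Build InferenceSettings from a config dict (unknown keys rejected)."""
    known = InferenceSettings.__dataclass_fields__.keys()
    unknown = set(config) - set(known)
    if unknown:
        raise ValueError(f"unknown settings keys: {sorted(unknown)}")
    return InferenceSettings(**config)


def write_manifest(path: str | Path, config: dict, seed: int | None) -> None:
    """Record what produced a run's outputs: config hash, seed, version."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    doc = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "master_seed": seed,
        "package_version": __version__,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True, default=str))
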