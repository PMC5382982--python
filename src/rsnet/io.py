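"""On-disk formats for cohorts, matrices, graphs and result tables.

Per subject: a signals CSV (rows = volumes, columns ROI_001..ROI_RRR)
and a nuisance CSV (columns mot1..mot6, csf, valid). A cohort manifest
(JSON) records subject ids, groups, file paths and the generator seed.
Correlation matrices are square CSVs with a node-name header; binary
graphs are written both as one-based edge lists and as square 0/1 CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .graphs import BinaryGraph, ConnectivityMatrix
from .preprocess import NuisanceSet, RoiTimeSeriesSet
from .synthetic import NUISANCE_NAMES, SimulatedSubject

__all__ = [
    "write_subject",
    "read_subject",
    "write_cohort",
    "read_cohort",
    "write_connectivity",
    "read_connectivity",
    "write_graph",
]

_FLOAT_FMT = "%.10g"


def write_subject(directory: str | Path, subject: SimulatedSubject) -> dict:
    """Write one subject's signal and nuisance CSVs; returns manifest entry."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ts, nuis = subject.ts, subject.nuisance
    sig_path = directory / f"{ts.subject_id}_signals.csv"
    nui_path = directory / f"{ts.subject_id}_nuisance.csv"
    sig = pd.DataFrame(ts.data, columns=ts.node_names)
    sig.to_csv(sig_path, index=False, float_format=_FLOAT_FMT)
    nui = pd.DataFrame(nuis.regressors, columns=nuis.names)
    nui["valid"] = ts.valid.astype(int)
    nui.to_csv(nui_path, index=False, float_format=_FLOAT_FMT)
    return {
        "subject_id": ts.subject_id,
        "group": ts.group,
        "tr_seconds": ts.tr_seconds,
        "signals": sig_path.name,
        "nuisance": nui_path.name,
    }


def read_subject(directory: str | Path, entry: dict) -> SimulatedSubject:
    """Read one subject back from its manifest entry."""
    directory = Path(directory)
    sig = pd.read_csv(directory / entry["signals"])
    nui = pd.read_csv(directory / entry["nuisance"])
    valid = nui.pop("valid").to_numpy(dtype=bool) if "valid" in nui else None
    ts = RoiTimeSeriesSet(
        subject_id=entry["subject_id"],
        group=entry["group"],
        data=sig.to_numpy(dtype=float),
        tr_seconds=float(entry.get("tr_seconds", 1.0)),
        valid=valid,
        node_names=list(sig.columns),
    )
    names = [c for c in nui.columns]
    return SimulatedSubject(ts=ts, nuisance=NuisanceSet(nui.to_numpy(dtype=float), names=names))


def write_cohort(directory: str | Path, subjects: list[SimulatedSubject], seed: int | None = None) -> Path:
    """Write every subject plus a cohort manifest; returns the manifest path."""
    directory = Path(directory)
    entries = [write_subject(directory, s) for s in subjects]
    manifest = {"seed": seed, "n_subjects": len(entries), "subjects": entries}
    path = directory / "cohort.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_cohort(directory: str | Path) -> list[SimulatedSubject]:
    directory = Path(directory)
    manifest = json.loads((directory / "cohort.json").read_text())
    return [read_subject(directory, e) for e in manifest["subjects"]]


def write_connectivity(path: str | Path, c: ConnectivityMatrix) -> None:
    pd.DataFrame(c.r, columns=c.node_names).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_connectivity(path: str | Path, subject_id: str = "subject", group: str | None = None) -> ConnectivityMatrix:
    df = pd.read_csv(path)
    return ConnectivityMatrix(
        r=df.to_numpy(dtype=float),
        subject_id=subject_id,
        group=group,
        node_names=list(df.columns),
    )


def write_graph(stem: str | Path, g: BinaryGraph) -> tuple[Path, Path]:
    """Write a binary graph as edge list (one-based) and square 0/1 CSV."""
    stem = Path(stem)
    edges = g.edges() + 1
    edge_path = stem.with_suffix(".edges.csv")
    pd.DataFrame(edges, columns=["node_i", "node_j"]).to_csv(edge_path, index=False)
    adj_path = stem.with_suffix(".adj.csv")
    pd.DataFrame(g.adjacency).to_csv(adj_path, index=False, header=False)
    return edge_path, adj_path
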