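"""Readers and writers for the pipeline's file formats.

All formats are plain text except the optional HDF5 trace container:
quantification tables / cohorts / spectral counts as CSV, gene sets as GMT
(tab-delimited: name, description, members...), interaction edges as SIF
("A pp B") or 2/3-column TSV, traces as HDF5 (dataset ``traces``, attribute
``fs``) with a wide-CSV fallback, and graphs as GraphML.
"""

from __future__ import annotations

import os
from typing import Iterable

import h5py
import networkx as nx
import numpy as np
import pandas as pd

from .containers import GeneSetCollection, TraceMatrix

__all__ = [
    "read_quant_csv", "write_quant_csv",
    "read_gmt", "write_gmt", "read_gene_list", "write_gene_list",
    "read_edges", "write_sif", "write_graphml",
    "read_traces", "write_traces",
    "read_cohort_csv", "write_cohort_csv",
]


# -- quantification tables ---------------------------------------------------

def read_quant_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"protein_id": str, "replicate_id": str, "genotype": str})
    from .quant import REQUIRED_COLUMNS

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_quant_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


# -- gene sets ---------------------------------------------------------------

def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file (name TAB description TAB gene1 TAB gene2 ...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(sorted(genes)) + "\n")


# -- interaction edges -------------------------------------------------------

def read_edges(path) -> list[tuple[str, str]]:
    """Read SIF ("A pp B", whitespace-delimited) or 2/3-column TSV edge lists."""
    edges = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) == 2:
                edges.append((parts[0], parts[1]))
            elif len(parts) >= 3:
                # SIF: source relation target [target...]
                for tgt in parts[2:]:
                    edges.append((parts[0], tgt))
            else:
                raise ValueError(f"{path}: cannot parse edge line {line!r}")
    return edges


def write_sif(g: nx.Graph, path, relation: str = "pp") -> None:
    with open(path, "w") as fh:
        for u, v in sorted(g.edges):
            fh.write(f"{u} {relation} {v}\n")


def write_graphml(g: nx.Graph, path) -> None:
    h = g.copy()
    for _, _, data in h.edges(data=True):  # GraphML cannot store sets
        if isinstance(data.get("sources"), set):
            data["sources"] = ",".join(sorted(data["sources"]))
    nx.write_graphml(h, path)


# -- traces ------------------------------------------------------------------

def write_traces(tm: TraceMatrix, path) -> None:
    """Write traces to HDF5 (``.h5``/``.hdf5``) or wide CSV (one row per ROI)."""
    path = os.fspath(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            d = f.create_dataset("traces", data=tm.traces)
            d.attrs["fs"] = tm.fs
            d.attrs["kind"] = tm.kind
            d.attrs["units"] = tm.units
    else:
        df = pd.DataFrame(tm.traces)
        df.insert(0, "roi", [f"roi_{i:04d}" for i in range(tm.n_rois)])
        with open(path, "w") as fh:
            fh.write(f"# fs={tm.fs} kind={tm.kind} units={tm.units}\n")
            df.to_csv(fh, index=False)


def read_traces(path, fs: float | None = None, kind: str = "calcium_culture") -> TraceMatrix:
    path = os.fspath(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            d = f["traces"]
            return TraceMatrix(
                traces=d[...],
                fs=float(d.attrs.get("fs", fs or 0.0)),
                kind=str(d.attrs.get("kind", kind)),
                units=str(d.attrs.get("units", "raw")),
            )
    with open(path) as fh:
        first = fh.readline()
        meta = {}
        if first.startswith("#"):
            meta = dict(kv.split("=") for kv in first[1:].split())
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if "roi" in df.columns:
        df = df.drop(columns=["roi"])
    return TraceMatrix(
        traces=df.to_numpy(dtype=float),
        fs=float(meta.get("fs", fs if fs is not None else 0.0)),
        kind=str(meta.get("kind", kind)),
        units=str(meta.get("units", "raw")),
    )


# -- cohorts -----------------------------------------------------------------

def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("gtcs", "died"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
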