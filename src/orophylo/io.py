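"""Readers and writers for the pipeline's file formats.

Trees travel as Newick with branch lengths; tabular data as CSV.  The
site-by-species matrix is canonically sites-in-rows in memory; files in
either orientation are accepted via a flag.  Every CSV written by the
pipeline gets a JSON metadata sidecar recording the configuration hash
and seeds, so outputs are traceable and reruns comparable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .trees import DatedTree, SpeciesRecord


def read_newick(path: str | Path) -> DatedTree:
    return DatedTree.from_newick(str(path))


def write_newick(tree: DatedTree, path: str | Path) -> None:
    tree.to_newick(str(path))


def read_matrix(path: str | Path, orientation: str = "sites-in-rows"
                ) -> pd.DataFrame:
    """Presence/absence CSV -> sites-by-species DataFrame of 0/1 ints."""
    if orientation not in ("sites-in-rows", "species-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path) as fh:  # pandas mangles duplicate header names; check raw
        header = fh.readline().rstrip("\n").split(",")[1:]
    if len(set(header)) != len(header):
        raise ValueError("duplicate column names in matrix header")
    df = pd.read_csv(path, index_col=0)
    if orientation == "species-in-rows":
        df = df.T
    if df.index.duplicated().any():
        raise ValueError("duplicate site names")
    if df.columns.duplicated().any():
        raise ValueError("duplicate species names")
    arr = df.to_numpy()
    bad = ~np.isin(arr, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-binary cell at site {df.index[i]!r}, species {df.columns[j]!r}: "
            f"{arr[i, j]!r}"
        )
    return df.astype(int)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, index_label="site_id")


def read_checklist(path: str | Path) -> list[SpeciesRecord]:
    """CSV with columns species, genus[, family]."""
    df = pd.read_csv(path)
    required = {"species", "genus"}
    if not required.issubset(df.columns):
        raise ValueError(f"checklist needs columns {sorted(required)}")
    fam = df["family"] if "family" in df.columns else [""] * len(df)
    return [SpeciesRecord(species=s, genus=g, family=f)
            for s, g, f in zip(df["species"], df["genus"], fam)]


def read_sister_map(path: str | Path) -> dict[str, str]:
    """CSV with columns missing_genus, sister_genus."""
    df = pd.read_csv(path)
    if not {"missing_genus", "sister_genus"}.issubset(df.columns):
        raise ValueError("sister map needs columns missing_genus, sister_genus")
    return dict(zip(df["missing_genus"], df["sister_genus"]))


def read_age_constraints(path: str | Path) -> dict[str, float]:
    """CSV with columns node_label, age."""
    df = pd.read_csv(path)
    if not {"node_label", "age"}.issubset(df.columns):
        raise ValueError("age constraints need columns node_label, age")
    return dict(zip(df["node_label"], df["age"].astype(float)))


def read_predictors(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "site_id" in df.columns:
        df = df.set_index("site_id")
    else:
        df = df.set_index(df.columns[0])
    if df.index.duplicated().any():
        raise ValueError("duplicate site_id in predictor table")
    return df


def config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_with_sidecar(df: pd.DataFrame, path: str | Path, metadata: dict,
                       index_label: str = "site_id") -> None:
    """Write a CSV and a ``<name>.meta.json`` sidecar next to it."""
    path = Path(path)
    df.to_csv(path, index_label=index_label)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    with open(sidecar, "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
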