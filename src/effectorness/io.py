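"""Readers and writers for the package's tabular and sparse formats.

Conventions
-----------
* Dense TSV is the canonical interchange format: a header row of column ids
  and a first column of feature ids. Missing protein values are empty cells.
* Cell x gene matrices may alternatively be MatrixMarket (``.mtx``) triplets
  with two plain-text sidecar files listing feature and column ids, one per
  line: for ``expr.mtx`` the sidecars are ``expr.rows.tsv`` and
  ``expr.cols.tsv``. Coordinates inside the ``.mtx`` are 1-based (the
  MatrixMarket standard); everything in memory is 0-based.
* Readers never reorder features or columns.

No scientific computation happens here.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .datasets import MatrixWithMeta, validate_clonotype_table

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_sample_meta",
    "read_clonotypes",
    "write_clonotypes",
    "write_signatures",
    "read_config",
    "write_manifest",
]

Layout = Literal["dense_tsv", "mtx_triplet"]


def _check_rectangular(path: Path) -> None:
    """Raise with a line number if any row has a deviant field count."""
    with open(path) as fh:
        header = fh.readline()
        n_fields = header.rstrip("\n").count("\t") + 1
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            found = line.rstrip("\n").count("\t") + 1
            if found != n_fields:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"(expected {n_fields} fields, found {found})"
                )


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return stem.with_suffix(".rows.tsv"), stem.with_suffix(".cols.tsv")


def read_matrix(
    path: str | Path,
    layout: Layout = "dense_tsv",
    meta: pd.DataFrame | None = None,
    allow_missing: bool = False,
) -> MatrixWithMeta:
    """Read a feature x column matrix from disk.

    ``layout="dense_tsv"`` expects a header row of column ids and a first
    column of feature ids. ``layout="mtx_triplet"`` expects a MatrixMarket
    file accompanied by ``<stem>.rows.tsv`` / ``<stem>.cols.tsv`` id
    sidecars; values are read as given, with no re-normalisation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout == "dense_tsv":
        _check_rectangular(path)
        # round_trip parsing keeps write -> read bit-exact for float64
        values = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        values.index = values.index.astype(str)
        values.columns = values.columns.astype(str)
    elif layout == "mtx_triplet":
        rows_path, cols_path = _sidecar_paths(path)
        for sidecar in (rows_path, cols_path):
            if not sidecar.exists():
                raise FileNotFoundError(f"missing id sidecar: {sidecar}")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        row_ids = rows_path.read_text().splitlines()
        col_ids = cols_path.read_text().splitlines()
        if mat.shape != (len(row_ids), len(col_ids)):
            raise ValueError(
                f"{path}: matrix shape {mat.shape} does not match sidecars "
                f"({len(row_ids)} rows, {len(col_ids)} cols)"
            )
        values = pd.DataFrame(np.asarray(mat, dtype=float), index=row_ids, columns=col_ids)
    else:
        raise ValueError(f"unknown layout: {layout!r}")
    return MatrixWithMeta(values=values, column_meta=meta, allow_missing=allow_missing)


def write_matrix(matrix: MatrixWithMeta | pd.DataFrame, path: str | Path, layout: Layout = "dense_tsv") -> None:
    """Write a matrix; dense TSV round-trips bit-exactly with :func:`read_matrix`."""
    values = matrix.values if isinstance(matrix, MatrixWithMeta) else matrix
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if layout == "dense_tsv":
        # pandas writes shortest-roundtrip float representations, so a
        # write/read cycle reproduces the exact binary values.
        values.to_csv(path, sep="\t")
    elif layout == "mtx_triplet":
        rows_path, cols_path = _sidecar_paths(path)
        dense = values.to_numpy(dtype=float)
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(dense), precision=17)
        rows_path.write_text("\n".join(map(str, values.index)) + "\n")
        cols_path.write_text("\n".join(map(str, values.columns)) + "\n")
    else:
        raise ValueError(f"unknown layout: {layout!r}")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read per-column annotations (first column = sample/cell id)."""
    path = Path(path)
    _check_rectangular(path)
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    if meta.index.duplicated().any():
        dups = sorted(set(meta.index[meta.index.duplicated()]))
        raise ValueError(f"duplicate sample ids in {path}: {', '.join(dups)}")
    return meta


def read_clonotypes(path: str | Path) -> pd.DataFrame:
    """Read a per-cell clonotype table (``cell_id``, ``clonotype_id``,
    optional ``effectorness``)."""
    path = Path(path)
    _check_rectangular(path)
    table = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "clonotype_id": str})
    return validate_clonotype_table(table)


def write_clonotypes(table: pd.DataFrame, path: str | Path) -> None:
    validate_clonotype_table(table)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)


def write_signatures(signatures: pd.DataFrame, path: str | Path) -> None:
    """Write a signature set, one row per (condition, gene).

    Deterministic ordering: condition ascending, then descending specificity
    score ``S``, ties broken by gene id lexicographically. An empty set
    produces a header-only file.
    """
    cols = ["condition", "gene_id", "S", "q"]
    missing = [c for c in cols if c not in signatures.columns]
    if missing:
        raise ValueError(f"signature table lacks columns: {missing}")
    ordered = signatures.sort_values(
        ["condition", "S", "gene_id"], ascending=[True, False, True], kind="mergesort"
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ordered.to_csv(path, sep="\t", index=False, columns=cols)


def read_config(path: str | Path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if config is None:
        return {}
    if not isinstance(config, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return config


def write_manifest(
    out_dir: str | Path,
    command: str,
    inputs: dict,
    parameters: dict,
    seed: int | None,
) -> Path:
    """Record what a CLI run did: inputs, parameters, seed, package version."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "parameters": parameters,
        "seed": seed,
        "package_version": __version__,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
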