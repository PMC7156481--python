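"""In-memory containers shared across the package.

Two container conventions are used throughout:

* bulk matrices are :class:`pandas.DataFrame` objects with features (genes or
  proteins) on the rows and samples on the columns, wrapped together with
  per-sample annotations in :class:`MatrixWithMeta` or
  :class:`PairedOmicsDataset`;
* single-cell expression lives in :class:`anndata.AnnData` (cells x genes),
  with per-cell annotations (``condition``, ``replicate``, ``pseudotime``,
  ``effectorness``) in ``.obs`` and per-gene ground truth, when simulated, in
  ``.var``.

Clonotype assignments are plain data frames with columns ``cell_id``,
``clonotype_id`` and, optionally, ``effectorness``; see
:func:`validate_clonotype_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "MatrixWithMeta",
    "PairedOmicsDataset",
    "validate_clonotype_table",
]


def _check_unique(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dups = sorted(set(map(str, index[index.duplicated()])))
        raise ValueError(f"duplicate {what}: {', '.join(dups)}")


@dataclass
class MatrixWithMeta:
    """A feature x column numeric matrix with optional per-column annotations.

    Parameters
    ----------
    values
        Features on rows, samples or cells on columns. Row index holds the
        feature ids, column index the sample/cell ids.
    column_meta
        One record per column (index must equal ``values.columns``). Expected
        columns depend on the assay: ``condition`` and ``replicate`` for bulk
        samples, plus ``pseudotime`` / ``effectorness`` for cells.
    allow_missing
        Whether NaN entries are permitted. Only protein abundance matrices
        carry explicit missingness; everything else must be dense.
    """

    values: pd.DataFrame
    column_meta: pd.DataFrame | None = None
    allow_missing: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "feature ids")
        _check_unique(self.values.columns, "column ids")
        if self.column_meta is not None:
            if len(self.column_meta) != self.values.shape[1]:
                raise ValueError(
                    f"column_meta has {len(self.column_meta)} records for "
                    f"{self.values.shape[1]} columns"
                )
            if not self.column_meta.index.equals(self.values.columns):
                raise ValueError("column_meta index does not match matrix columns")
        if not self.allow_missing and self.values.isna().to_numpy().any():
            raise ValueError("matrix contains missing values but allow_missing=False")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


@dataclass
class PairedOmicsDataset:
    """Matched bulk RNA and protein matrices over a shared sample design.

    Both layers are indexed by gene name and share one sample set: every
    sample has an RNA measurement and a protein measurement (protein entries
    may be missing, encoded as NaN). ``sample_meta`` must carry a
    ``condition`` column and may carry ``cell_type`` and ``replicate``.
    ``truth`` is the ground-truth signature table (``gene_id``,
    ``condition``) attached by the simulator; ``None`` for real data.
    """

    rna: pd.DataFrame
    protein: pd.DataFrame
    sample_meta: pd.DataFrame
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.rna.index, "RNA gene ids")
        _check_unique(self.protein.index, "protein gene ids")
        if "condition" not in self.sample_meta.columns:
            raise ValueError("sample_meta must have a 'condition' column")
        for name, layer in (("rna", self.rna), ("protein", self.protein)):
            if not layer.columns.equals(self.sample_meta.index):
                raise ValueError(
                    f"{name} columns do not match sample_meta index; the two "
                    "layers must share one paired sample set"
                )
        if self.rna.isna().to_numpy().any():
            raise ValueError("RNA matrix must be dense (no missing values)")

    @property
    def shared_genes(self) -> pd.Index:
        """Genes detected on both layers, in RNA order."""
        return self.rna.index.intersection(self.protein.index, sort=False)

    @property
    def conditions(self) -> list[str]:
        return list(pd.unique(self.sample_meta["condition"]))


def validate_clonotype_table(table: pd.DataFrame, require_effectorness: bool = False) -> pd.DataFrame:
    """Validate a per-cell clonotype table and return it unchanged.

    Requires ``cell_id`` and ``clonotype_id`` columns and unique cell ids.
    When ``require_effectorness`` is set, an ``effectorness`` column with no
    missing values must be present as well.
    """
    for col in ("cell_id", "clonotype_id"):
        if col not in table.columns:
            raise ValueError(f"clonotype table lacks required column '{col}'")
    dup = table["cell_id"].duplicated()
    if dup.any():
        dups = sorted(set(map(str, table.loc[dup, "cell_id"])))
        raise ValueError(f"duplicate cell ids: {', '.join(dups)}")
    if require_effectorness:
        if "effectorness" not in table.columns or table["effectorness"].isna().any():
            raise ValueError("clonotype table lacks per-cell effectorness values")
    return table
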