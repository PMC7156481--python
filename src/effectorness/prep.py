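"""Protein abundance normalization and the concordant RNA-protein prefilter.

The prefilter feeding the specificity scorer: normalize protein abundances
(sample-wise total, then protein-wise maximum), run a simple two-group
differential test per layer, and keep genes with concordant differential
evidence on both layers. The differential engine here is a deliberately
plain Welch t-test + BH stand-in -- the deliverable is the scoring
machinery downstream, and the scorer accepts any externally produced gene
list in its place.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_adjust
from .datasets import MatrixWithMeta

__all__ = [
    "normalize_protein_abundance",
    "scale_to_row_max",
    "stand_in_differential",
    "concordant_pairs",
    "count_low_detection",
]

# Differential-evidence thresholds for the concordance filter: RNA |LFC| > 1
# at FDR 0.05; protein |LFC| > 0.5 at FDR 0.1.
RNA_LFC_MIN = 1.0
RNA_Q_MAX = 0.05
PROTEIN_LFC_MIN = 0.5
PROTEIN_Q_MAX = 0.1


def scale_to_row_max(values: pd.DataFrame) -> pd.DataFrame:
    """Divide each row by its maximum (missing values ignored).

    Idempotent: a row whose maximum is already 1 is unchanged.
    """
    row_max = values.max(axis=1, skipna=True)
    return values.div(row_max, axis=0)


def normalize_protein_abundance(raw: pd.DataFrame) -> pd.DataFrame:
    """Two-step protein normalization: sample totals, then protein maxima.

    Each column is divided by its total abundance (missing values excluded
    from the totals), then each row by its maximum, mapping every retained
    protein into [0, 1]. Rows that are entirely missing, or all zero, are
    excluded with a warning. A sample whose non-missing total is zero is an
    error.
    """
    values = raw.astype(float)
    if (values < 0).any().any():
        raise ValueError("protein abundances must be non-negative")

    all_missing = values.isna().all(axis=1)
    all_zero = ~all_missing & (values.fillna(0.0) == 0).all(axis=1)
    drop = all_missing | all_zero
    if drop.any():
        warnings.warn(
            f"excluding {int(drop.sum())} proteins with no usable abundance "
            f"(all-missing or all-zero): {', '.join(map(str, values.index[drop][:10]))}",
            stacklevel=2,
        )
        values = values.loc[~drop]

    totals = values.sum(axis=0, skipna=True)
    dead = totals[totals == 0]
    if not dead.empty:
        raise ValueError(
            f"sample(s) with zero non-missing total abundance: {', '.join(map(str, dead.index))}"
        )
    return scale_to_row_max(values.div(totals, axis=1))


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch p-value with a defined zero-variance limit."""
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def stand_in_differential(
    matrix: MatrixWithMeta,
    contrast: tuple[str, str],
    layer: str = "RNA",
) -> pd.DataFrame:
    """Per-gene Welch two-sample t-test on log-scale values, with BH.

    ``contrast`` is (condition, reference); the log-fold change is
    condition minus reference (values are already on the log2 scale). For
    the protein layer a gene is testable only if it is detected
    (non-missing) in at least two biological replicates per condition; for
    RNA at least two replicates per group are required. Untestable genes
    are reported with ``tested = False`` and a reason -- they are excluded,
    not non-significant.
    """
    if layer not in ("RNA", "protein"):
        raise ValueError("layer must be 'RNA' or 'protein'")
    if matrix.column_meta is None or "condition" not in matrix.column_meta.columns:
        raise ValueError("matrix needs column_meta with a 'condition' column")
    condition, reference = contrast
    labels = matrix.column_meta["condition"]
    group_a = matrix.values.loc[:, (labels == condition).to_numpy()]
    group_b = matrix.values.loc[:, (labels == reference).to_numpy()]
    if group_a.shape[1] < 2 or group_b.shape[1] < 2:
        raise ValueError(
            f"contrast {condition} vs {reference} needs >= 2 replicates per group "
            f"(found {group_a.shape[1]} and {group_b.shape[1]})"
        )

    records = []
    for gene in matrix.values.index:
        a = group_a.loc[gene].to_numpy(dtype=float)
        b = group_b.loc[gene].to_numpy(dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            records.append((gene, np.nan, np.nan, False, "detected in < 2 replicates per condition"))
            continue
        lfc = float(np.mean(a) - np.mean(b))
        records.append((gene, lfc, _welch(a, b), True, ""))

    out = pd.DataFrame.from_records(
        records, columns=["gene_id", "lfc", "p", "tested", "reason"]
    ).set_index("gene_id")
    if not out["tested"].any():
        raise ValueError(f"no testable genes for contrast {condition} vs {reference}")
    out["q"] = bh_adjust(out["p"].where(out["tested"]))
    out["layer"] = layer
    out["condition"] = condition
    out["reference"] = reference
    return out


def concordant_pairs(
    rna_results: pd.DataFrame,
    protein_results: pd.DataFrame,
    rna_lfc_min: float = RNA_LFC_MIN,
    rna_q_max: float = RNA_Q_MAX,
    protein_lfc_min: float = PROTEIN_LFC_MIN,
    protein_q_max: float = PROTEIN_Q_MAX,
) -> pd.Index:
    """Genes with concordant differential evidence on both layers.

    Keeps genes with |LFC_RNA| > ``rna_lfc_min`` at q < ``rna_q_max`` AND
    |LFC_protein| > ``protein_lfc_min`` at q < ``protein_q_max`` AND the
    same fold-change sign, all in the same contrast. The result is sorted
    by gene id, so it is invariant to the input gene and sample order.
    """
    for col in ("condition", "reference"):
        pair = set(rna_results[col]).union(protein_results[col])
        if len(pair) != 1:
            raise ValueError(f"RNA and protein results disagree on the contrast {col}: {pair}")
    rna = rna_results[rna_results["tested"]]
    prot = protein_results[protein_results["tested"]]
    merged = rna[["lfc", "q"]].join(prot[["lfc", "q"]], how="inner", lsuffix="_rna", rsuffix="_prot")
    keep = (
        (merged["lfc_rna"].abs() > rna_lfc_min)
        & (merged["q_rna"] < rna_q_max)
        & (merged["lfc_prot"].abs() > protein_lfc_min)
        & (merged["q_prot"] < protein_q_max)
        & (np.sign(merged["lfc_rna"]) == np.sign(merged["lfc_prot"]))
        & (merged["lfc_rna"] != 0)
    )
    return pd.Index(sorted(merged.index[keep]), name="gene_id")


def count_low_detection(
    protein: pd.DataFrame, sample_meta: pd.DataFrame, min_replicates: int = 2
) -> pd.Series:
    """Per condition, count proteins detected in fewer than ``min_replicates``.

    Diagnostic for the detected-in-at-least-two-replicates testability rule
    under heavy missingness.
    """
    counts = {}
    for cond, samples in sample_meta.groupby("condition", observed=True).groups.items():
        detected = protein.loc[:, list(samples)].notna().sum(axis=1)
        counts[cond] = int((detected < min_replicates).sum())
    return pd.Series(counts, name="n_proteins_below_min_detection")
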