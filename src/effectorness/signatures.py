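"""Proteogenomic cell-state specificity scores with a permutation null.

For gene *i* and condition *j*, with replicate-averaged RNA expression
``X_ij`` and protein abundance ``Y_ij`` (both non-negative), the layer
specificities divide each gene's row by its Euclidean norm across the *n*
conditions::

    S_RNA[i, j]  = X[i, j] / sqrt(sum_j X[i, j]**2)
    S_prot[i, j] = Y[i, j] / sqrt(sum_j Y[i, j]**2)

and the combined proteogenomic score is their weighted sum,
``S = W_RNA * S_RNA + W_prot * S_prot`` with weights in [0, 1] summing to 1
(0.5 / 0.5 by default, giving both layers equal say). A score near 1 means
the gene's expression is concentrated in a single condition on both layers.

Statistical support comes from a permutation null: sample-to-condition
labels are shuffled jointly across the RNA and protein measurements of the
same biological sample (preserving the cross-layer pairing the combined
score relies on), replicates are re-averaged, and S recomputed. The
empirical p-value uses the add-one (Phipson-Smyth) convention,
``p = (1 + #{S_perm >= S_obs}) / (1 + n_perm)``, and is BH-adjusted across
genes within each condition. A gene enters a condition's signature when
S > 0.7 and q < 0.1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._utils import as_rng, bh_adjust
from .datasets import PairedOmicsDataset

__all__ = [
    "specificity",
    "specificity_rna",
    "specificity_protein",
    "combined_specificity",
    "condition_means",
    "permutation_fdr",
    "call_signatures",
    "SpecificityScorer",
]

DEFAULT_EXCLUDED_CONDITIONS = ("resting",)


def specificity(averaged: pd.DataFrame) -> pd.DataFrame:
    """Euclidean-norm specificity of a replicate-averaged matrix.

    Rows are features, columns conditions; entries must be non-negative and
    dense. All-zero rows have no defined direction and are excluded with a
    warning. For every retained row the squared scores sum to one.
    """
    values = averaged.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("averaged matrix contains missing values")
    if (values < 0).any():
        raise ValueError("specificity requires non-negative expression values")
    norms = np.sqrt((values**2).sum(axis=1))
    keep = norms > 0
    if not keep.all():
        dropped = averaged.index[~keep]
        warnings.warn(
            f"excluding {len(dropped)} all-zero rows from specificity scoring: "
            f"{', '.join(map(str, dropped[:10]))}",
            stacklevel=2,
        )
    return pd.DataFrame(
        values[keep] / norms[keep, None], index=averaged.index[keep], columns=averaged.columns
    )


def specificity_rna(averaged_rna: pd.DataFrame) -> pd.DataFrame:
    """RNA specificity: replicate-averaged expression over its row norm."""
    return specificity(averaged_rna)


def specificity_protein(averaged_protein: pd.DataFrame) -> pd.DataFrame:
    """Protein specificity; identical contract to :func:`specificity_rna`."""
    return specificity(averaged_protein)


def combined_specificity(
    s_rna: pd.DataFrame, s_prot: pd.DataFrame, w_rna: float = 0.5, w_prot: float = 0.5
) -> pd.DataFrame:
    """Weighted sum of RNA and protein specificities.

    Weights must lie in [0, 1] and sum to one. Genes defined in only one
    layer are excluded -- the combined score requires the matched pair.
    """
    _check_weights(w_rna, w_prot)
    genes = s_rna.index.intersection(s_prot.index, sort=False)
    if not s_rna.columns.equals(s_prot.columns):
        raise ValueError("RNA and protein specificities cover different conditions")
    return w_rna * s_rna.loc[genes] + w_prot * s_prot.loc[genes]


def _check_weights(w_rna: float, w_prot: float) -> None:
    if not (0 <= w_rna <= 1 and 0 <= w_prot <= 1):
        raise ValueError("weights must lie in [0, 1]")
    if abs(w_rna + w_prot - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1 (got {w_rna} + {w_prot})")


def condition_means(values: np.ndarray, onehot: np.ndarray) -> np.ndarray:
    """Replicate means per condition, ignoring NaN entries.

    ``values`` is features x samples; ``onehot`` is samples x conditions. A
    condition with no finite value for a feature yields NaN.
    """
    finite = np.isfinite(values)
    sums = np.where(finite, values, 0.0) @ onehot
    counts = finite.astype(float) @ onehot
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / counts, np.nan)


def _prepare(
    dataset: PairedOmicsDataset,
    genes: pd.Index | list | None,
    exclude_conditions: tuple[str, ...],
):
    meta = dataset.sample_meta
    keep = ~meta["condition"].isin(exclude_conditions)
    samples = meta.index[keep]
    conditions = list(pd.unique(meta.loc[samples, "condition"]))
    if len(samples) < len(conditions):
        raise ValueError(
            f"fewer samples ({len(samples)}) than conditions ({len(conditions)})"
        )
    if len(conditions) < 2:
        raise ValueError("scoring needs at least two stimulated conditions")
    gene_index = dataset.shared_genes
    if genes is not None:
        genes = pd.Index(genes)
        gene_index = gene_index.intersection(genes, sort=False)
    codes = pd.Categorical(meta.loc[samples, "condition"], categories=conditions).codes
    onehot = np.eye(len(conditions))[codes].astype(float)  # samples x conditions
    rna = dataset.rna.loc[gene_index, samples].to_numpy(dtype=float)
    prot = dataset.protein.loc[gene_index, samples].to_numpy(dtype=float)
    return rna, prot, onehot, conditions, gene_index


def _scores_from_means(xbar: np.ndarray, ybar: np.ndarray, w_rna: float, w_prot: float):
    """Combined specificity per gene given condition means of both layers.

    Genes with a missing condition mean on the protein layer or a zero row
    norm on either layer get NaN scores (excluded from scoring).
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        xn = np.sqrt((xbar**2).sum(axis=1))
        s_rna = xbar / xn[:, None]
        yn = np.sqrt((ybar**2).sum(axis=1))
        s_prot = ybar / yn[:, None]
    bad = (xn == 0) | (yn == 0) | np.isnan(ybar).any(axis=1) | np.isnan(xbar).any(axis=1)
    s = w_rna * s_rna + w_prot * s_prot
    s[bad] = np.nan
    s_rna[bad] = np.nan
    s_prot[bad] = np.nan
    return s_rna, s_prot, s


def permutation_fdr(
    dataset: PairedOmicsDataset,
    genes: pd.Index | list | None = None,
    n_permutations: int = 10_000,
    w_rna: float = 0.5,
    w_prot: float = 0.5,
    bh_scope: str = "condition",
    exclude_conditions: tuple[str, ...] = DEFAULT_EXCLUDED_CONDITIONS,
    random_state: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Empirical p-values and BH q-values for combined specificity scores.

    Permutation happens at the replicate level, before averaging: each
    round shuffles the sample-to-condition assignment once and applies it
    jointly to the RNA and protein measurements of each sample, preserving
    the cross-layer pairing. ``bh_scope`` is ``"condition"`` (BH across
    genes within each condition, the default) or ``"global"`` (across all
    gene x condition pairs).

    Returns ``(p, q)`` as gene x condition frames; genes excluded from
    scoring carry NaN.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    _check_weights(w_rna, w_prot)
    if bh_scope not in ("condition", "global"):
        raise ValueError("bh_scope must be 'condition' or 'global'")
    rng = as_rng(random_state)
    rna, prot, onehot, conditions, gene_index = _prepare(dataset, genes, exclude_conditions)
    if (rna < 0).any():
        raise ValueError("RNA matrix contains negative values")

    _, _, s_obs = _scores_from_means(
        condition_means(rna, onehot), condition_means(prot, onehot), w_rna, w_prot
    )
    exceed = np.zeros_like(s_obs)
    valid = np.zeros_like(s_obs)
    n_samples = onehot.shape[0]
    for _ in range(n_permutations):
        perm = rng.permutation(n_samples)
        shuffled = onehot[perm]
        _, _, s_perm = _scores_from_means(
            condition_means(rna, shuffled), condition_means(prot, shuffled), w_rna, w_prot
        )
        # A permutation can leave a gene without any detected protein value
        # in some permuted group (NaN score); such rounds are uninformative
        # for that gene and are excluded from its permutation count.
        ok = ~np.isnan(s_perm)
        valid += ok
        exceed += np.where(ok, s_perm >= s_obs, False)

    p = (1.0 + exceed) / (1.0 + valid)
    p[np.isnan(s_obs)] = np.nan
    p_df = pd.DataFrame(p, index=gene_index, columns=conditions)
    if bh_scope == "condition":
        q = np.column_stack([bh_adjust(p[:, j]) for j in range(p.shape[1])])
    else:
        q = bh_adjust(p.ravel()).reshape(p.shape)
    q_df = pd.DataFrame(q, index=gene_index, columns=conditions)
    return p_df, q_df


def call_signatures(
    scores: pd.DataFrame,
    qvalues: pd.DataFrame,
    s_min: float = 0.7,
    q_max: float = 0.1,
    unique: bool = False,
) -> pd.DataFrame:
    """Call per-condition signature genes from scores and q-values.

    A gene enters condition *j*'s signature iff ``S_ij > s_min`` and
    ``q_ij < q_max`` (both strict). By default a gene may appear in several
    condition signatures; with ``unique=True`` it is assigned only to its
    argmax-S condition (ties broken by the lexicographically smallest
    condition label). Output is ordered by condition, then descending S,
    then gene id.
    """
    if not scores.index.equals(qvalues.index) or not scores.columns.equals(qvalues.columns):
        raise ValueError("scores and q-values must be aligned")
    long = (
        scores.rename_axis(index="gene_id", columns="condition")
        .stack(future_stack=True)
        .rename("S")
        .to_frame()
        .join(
            qvalues.rename_axis(index="gene_id", columns="condition")
            .stack(future_stack=True)
            .rename("q")
        )
        .reset_index()
    )
    hits = long[(long["S"] > s_min) & (long["q"] < q_max)].copy()
    if unique and not hits.empty:
        best = (
            hits.sort_values(["S", "condition"], ascending=[False, True], kind="mergesort")
            .groupby("gene_id", sort=False)
            .head(1)
        )
        hits = best
    return hits.sort_values(
        ["condition", "S", "gene_id"], ascending=[True, False, True], kind="mergesort"
    ).reset_index(drop=True)[["condition", "gene_id", "S", "q"]]


class SpecificityScorer(BaseEstimator):
    """Score gene x condition specificity and call proteogenomic signatures.

    A fit-shaped wrapper over the scoring pipeline: replicate averaging,
    layer specificities, combined score, permutation-based empirical FDR,
    and signature calling, run separately for each cell type present in
    the dataset's sample annotations.

    Parameters
    ----------
    w_rna, w_prot
        Layer weights of the combined score; must sum to 1.
    n_permutations
        Rounds of joint label shuffling for the empirical null.
    s_min, q_max
        Signature-calling thresholds (strict inequalities).
    bh_scope
        ``"condition"`` (default) or ``"global"`` multiple-testing scope.
    exclude_conditions
        Conditions dropped before scoring (unstimulated cells by default).
    random_state
        Seed for the permutation stream.

    Attributes
    ----------
    scores_ : long frame with cell_type, gene_id, condition, S_RNA, S_prot,
        S, p, q.
    signatures_ : called signature genes per cell type and condition.
    conditions_ : scored (stimulated) conditions per cell type.
    """

    def __init__(
        self,
        w_rna: float = 0.5,
        w_prot: float = 0.5,
        n_permutations: int = 10_000,
        s_min: float = 0.7,
        q_max: float = 0.1,
        bh_scope: str = "condition",
        unique_assignment: bool = False,
        exclude_conditions: tuple[str, ...] = DEFAULT_EXCLUDED_CONDITIONS,
        random_state: int | None = None,
    ) -> None:
        self.w_rna = w_rna
        self.w_prot = w_prot
        self.n_permutations = n_permutations
        self.s_min = s_min
        self.q_max = q_max
        self.bh_scope = bh_scope
        self.unique_assignment = unique_assignment
        self.exclude_conditions = exclude_conditions
        self.random_state = random_state

    def fit(self, dataset: PairedOmicsDataset, genes: pd.Index | list | None = None):
        _check_weights(self.w_rna, self.w_prot)
        rng = as_rng(self.random_state)
        meta = dataset.sample_meta
        cell_types = (
            list(pd.unique(meta["cell_type"])) if "cell_type" in meta.columns else [None]
        )
        all_scores, all_sigs, self.conditions_ = [], [], {}
        for cell_type in cell_types:
            if cell_type is None:
                sub = dataset
            else:
                cols = meta.index[meta["cell_type"] == cell_type]
                sub = PairedOmicsDataset(
                    rna=dataset.rna.loc[:, cols],
                    protein=dataset.protein.loc[:, cols],
                    sample_meta=meta.loc[cols],
                    truth=dataset.truth,
                )
            scores, sigs, conditions = self._fit_one(sub, genes, rng)
            scores.insert(0, "cell_type", cell_type)
            sigs.insert(0, "cell_type", cell_type)
            all_scores.append(scores)
            all_sigs.append(sigs)
            self.conditions_[cell_type] = conditions
        self.scores_ = pd.concat(all_scores, ignore_index=True)
        self.signatures_ = pd.concat(all_sigs, ignore_index=True)
        return self

    def _fit_one(self, dataset, genes, rng):
        rna, prot, onehot, conditions, gene_index = _prepare(
            dataset, genes, self.exclude_conditions
        )
        if (rna < 0).any():
            raise ValueError("RNA matrix contains negative values")
        s_rna, s_prot, s = _scores_from_means(
            condition_means(rna, onehot),
            condition_means(prot, onehot),
            self.w_rna,
            self.w_prot,
        )
        p, q = permutation_fdr(
            dataset,
            genes=gene_index,
            n_permutations=self.n_permutations,
            w_rna=self.w_rna,
            w_prot=self.w_prot,
            bh_scope=self.bh_scope,
            exclude_conditions=self.exclude_conditions,
            random_state=rng,
        )
        s_df = pd.DataFrame(s, index=gene_index, columns=conditions)
        scores = pd.DataFrame(
            {
                "gene_id": np.repeat(gene_index.to_numpy(), len(conditions)),
                "condition": np.tile(conditions, len(gene_index)),
                "S_RNA": s_rna.ravel(),
                "S_prot": s_prot.ravel(),
                "S": s.ravel(),
                "p": p.to_numpy().ravel(),
                "q": q.to_numpy().ravel(),
            }
        )
        sigs = call_signatures(
            s_df, q, s_min=self.s_min, q_max=self.q_max, unique=self.unique_assignment
        )
        return scores, sigs, conditions
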