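"""Synthetic-data generators with full ground truth.

Three generators emulate the statistical structure the downstream analyses
assume:

* :func:`simulate_paired_omics` -- matched bulk RNA (log2 normalized
  expression) and protein (linear-scale abundance with missingness)
  matrices in which each condition has a designated set of signature genes
  shifted up in that condition only;
* :func:`simulate_effectorness_cells` -- single cells with a latent
  effectorness value E in [0, 1] and per-gene log2 expression
  ``X = alpha + beta*E + gamma_C + delta_C*E + eps`` with
  expression-dependent dropout (exact zeros);
* :func:`simulate_clonotypes` -- clonotype assignments in which the
  probability of belonging to an expanded clone increases linearly with
  effectorness.

All three are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.special import expit

from ._utils import as_rng
from .datasets import PairedOmicsDataset

__all__ = [
    "BulkSimConfig",
    "CellSimConfig",
    "ClonotypeSimConfig",
    "simulate_paired_omics",
    "simulate_effectorness_cells",
    "simulate_clonotypes",
    "draw_gene_effects",
    "mechanism_class_from_effects",
]

BULK_CONDITIONS = ("Th0", "Th1", "Th2", "Th17", "iTreg", "IFNB")
CELL_CONDITIONS = ("Th0", "Th2", "Th17", "iTreg")


# ---------------------------------------------------------------------------
# Paired bulk RNA + protein


@dataclass
class BulkSimConfig:
    """Design of a paired bulk RNA/protein simulation.

    ``rna_baseline_range`` is the uniform range of off-state log2 expression.
    It is deliberately low: genes eligible for a state-specific signature
    are, by the nature of the Euclidean-norm specificity score, genes with a
    low expression floor outside their state. ``rna_effect_log2`` /
    ``protein_effect_log2`` are the condition-specific upward shifts applied
    to each condition's signature genes in that condition only. Noise is
    additive Gaussian on the log scale for both layers; protein values are
    independently missing with ``protein_missing_rate``.
    """

    n_genes: int = 1000
    conditions: tuple[str, ...] = BULK_CONDITIONS
    n_replicates: int = 3
    n_signature_genes: int = 50
    rna_effect_log2: float = 3.0
    protein_effect_log2: float = 1.5
    rna_noise_sd: float = 0.5
    protein_noise_sd: float = 0.5
    protein_missing_rate: float = 0.1
    rna_baseline_range: tuple[float, float] = (0.5, 2.5)
    protein_baseline_log2_range: tuple[float, float] = (8.0, 12.0)
    cell_type: str = "TN"
    seed: int = 0

    def validate(self) -> None:
        if self.n_signature_genes * len(self.conditions) > self.n_genes:
            raise ValueError(
                "n_signature_genes x number of conditions exceeds n_genes "
                f"({self.n_signature_genes} x {len(self.conditions)} > {self.n_genes})"
            )
        if self.rna_noise_sd <= 0 or self.protein_noise_sd <= 0:
            raise ValueError("noise standard deviations must be positive")
        if not 0 <= self.protein_missing_rate < 1:
            raise ValueError("protein_missing_rate must be in [0, 1)")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate per condition")


def simulate_paired_omics(config: BulkSimConfig) -> PairedOmicsDataset:
    """Generate matched RNA and protein matrices with known signature genes.

    Returns a :class:`PairedOmicsDataset` whose ``truth`` table lists each
    signature gene's condition. RNA values are on the log2 scale, clipped at
    zero (the downstream specificity score requires non-negative input);
    protein values are linear-scale abundances with NaN for missing entries.
    """
    config.validate()
    rng = as_rng(config.seed)
    n_cond = len(config.conditions)
    genes = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    samples = [
        f"{cond}_rep{r + 1}" for cond in config.conditions for r in range(config.n_replicates)
    ]
    cond_of_sample = np.repeat(np.arange(n_cond), config.n_replicates)

    # Assign signature genes blockwise from a random gene permutation.
    perm = rng.permutation(config.n_genes)
    signature_condition = np.full(config.n_genes, -1)
    for j in range(n_cond):
        block = perm[j * config.n_signature_genes : (j + 1) * config.n_signature_genes]
        signature_condition[block] = j

    effect = np.zeros((config.n_genes, n_cond))
    is_signature = signature_condition >= 0
    effect[is_signature, signature_condition[is_signature]] = 1.0

    rna_base = rng.uniform(*config.rna_baseline_range, size=config.n_genes)
    rna_mean = rna_base[:, None] + config.rna_effect_log2 * effect
    rna = rna_mean[:, cond_of_sample] + rng.normal(
        0.0, config.rna_noise_sd, size=(config.n_genes, len(samples))
    )
    np.clip(rna, 0.0, None, out=rna)

    prot_base = rng.uniform(*config.protein_baseline_log2_range, size=config.n_genes)
    prot_log2 = (
        prot_base[:, None]
        + config.protein_effect_log2 * effect[:, cond_of_sample]
        + rng.normal(0.0, config.protein_noise_sd, size=(config.n_genes, len(samples)))
    )
    protein = np.exp2(prot_log2)
    missing = rng.random(protein.shape) < config.protein_missing_rate
    protein[missing] = np.nan

    sample_meta = pd.DataFrame(
        {
            "condition": np.asarray(config.conditions)[cond_of_sample],
            "cell_type": config.cell_type,
            "replicate": [s.split("_rep")[-1] for s in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    truth = pd.DataFrame(
        {
            "gene_id": genes[is_signature],
            "condition": np.asarray(config.conditions)[signature_condition[is_signature]],
        }
    ).sort_values(["condition", "gene_id"], kind="mergesort", ignore_index=True)

    return PairedOmicsDataset(
        rna=pd.DataFrame(rna, index=genes, columns=samples),
        protein=pd.DataFrame(protein, index=genes, columns=samples),
        sample_meta=sample_meta,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Single cells along the effectorness gradient


@dataclass
class CellSimConfig:
    """Design of a single-cell effectorness simulation.

    ``effectorness_distribution`` is either ``"uniform"`` or
    ``("beta", a, b)``. The default is the U-shaped beta(0.5, 0.5): pooled
    naive + memory T-cell datasets are bimodal along the gradient, with
    dense lobes of naive-like (E near 0) and effector-memory-like (E near 1)
    cells, which a symmetric U-shaped beta emulates better than a flat
    density.

    ``effects`` is the per-gene truth table (columns ``alpha``, ``beta``,
    ``gamma_<cond>`` and ``delta_<cond>`` for every non-reference
    condition). If omitted, :func:`draw_gene_effects` generates one. The
    reference (first) condition carries gamma = delta = 0 by construction.

    Dropout is expression-dependent: a cell's observed value is its latent
    log2 expression X with probability ``1 - p_zero(X)`` and exactly zero
    otherwise, with ``p_zero(X) = expit(-(X - dropout_midpoint) /
    dropout_scale)``, a monotone decreasing function of X. Set
    ``dropout=False`` to disable.
    """

    n_cells: int = 2000
    n_genes: int = 200
    conditions: tuple[str, ...] = CELL_CONDITIONS
    effectorness_distribution: str | tuple = ("beta", 0.5, 0.5)
    effects: pd.DataFrame | None = None
    effect_size: float = 0.8
    residual_sd: float = 0.5
    dropout: bool = True
    dropout_midpoint: float = 0.0
    dropout_scale: float = 0.5
    condition_depends_on_effectorness: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < len(self.conditions) * 2:
            raise ValueError("too few cells for the number of conditions")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")
        if self.dropout_scale <= 0:
            raise ValueError("dropout_scale must be positive")
        if self.effects is not None:
            expected = _effect_columns(self.conditions)
            missing = [c for c in expected if c not in self.effects.columns]
            if missing:
                raise ValueError(f"effects table lacks columns: {missing}")


def _effect_columns(conditions: tuple[str, ...]) -> list[str]:
    nonref = list(conditions[1:])
    return ["alpha", "beta"] + [f"gamma_{c}" for c in nonref] + [f"delta_{c}" for c in nonref]


MECHANISM_CLASSES = (
    "null",
    "cytokine_only",
    "effectorness_only",
    "independent",
    "interaction_ubiquitous",
    "interaction_cytokine_specific",
)


def draw_gene_effects(
    n_genes: int,
    conditions: tuple[str, ...] = CELL_CONDITIONS,
    effect_size: float = 0.8,
    class_probs: dict[str, float] | None = None,
    random_state: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw a per-gene coefficient truth table with known mechanism classes.

    Non-zero coefficients are drawn from {-effect_size, +effect_size};
    intercepts alpha from U(2, 4) so that latent expression stays on a
    plausible positive log2 scale. The returned frame carries one row per
    gene with the coefficient columns plus a ``mechanism`` column.
    """
    rng = as_rng(random_state)
    if class_probs is None:
        class_probs = {
            "null": 0.25,
            "cytokine_only": 0.15,
            "effectorness_only": 0.15,
            "independent": 0.15,
            "interaction_ubiquitous": 0.15,
            "interaction_cytokine_specific": 0.15,
        }
    labels = list(class_probs)
    probs = np.array([class_probs[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    classes = rng.choice(labels, size=n_genes, p=probs)

    nonref = list(conditions[1:])
    cols = _effect_columns(conditions)
    out = pd.DataFrame(0.0, index=[f"G{i:05d}" for i in range(n_genes)], columns=cols)
    out["alpha"] = rng.uniform(2.0, 4.0, size=n_genes)

    def signed() -> float:
        return effect_size * (1.0 if rng.random() < 0.5 else -1.0)

    for i, cls in enumerate(classes):
        if cls == "null":
            continue
        if cls in ("effectorness_only", "independent", "interaction_ubiquitous"):
            out.iloc[i, out.columns.get_loc("beta")] = signed()
        if cls in ("cytokine_only", "independent"):
            c = nonref[rng.integers(len(nonref))]
            out.iloc[i, out.columns.get_loc(f"gamma_{c}")] = signed()
        if cls in ("interaction_ubiquitous", "interaction_cytokine_specific"):
            c = nonref[rng.integers(len(nonref))]
            out.iloc[i, out.columns.get_loc(f"delta_{c}")] = signed()
    out["mechanism"] = classes
    return out


def mechanism_class_from_effects(effects: pd.DataFrame, conditions: tuple[str, ...] = CELL_CONDITIONS) -> pd.Series:
    """Derive the mechanism class implied by a coefficient table.

    Applies the same decision rules as the fitted classifier, with
    "non-zero coefficient" in place of "significant coefficient", so
    generative truth and fitted classes share one vocabulary.
    """
    nonref = list(conditions[1:])
    beta = effects["beta"].to_numpy() != 0
    gamma = np.column_stack([effects[f"gamma_{c}"].to_numpy() != 0 for c in nonref]).any(axis=1)
    delta = np.column_stack([effects[f"delta_{c}"].to_numpy() != 0 for c in nonref]).any(axis=1)
    out = np.where(
        delta,
        np.where(beta, "interaction_ubiquitous", "interaction_cytokine_specific"),
        np.where(
            beta & gamma,
            "independent",
            np.where(beta, "effectorness_only", np.where(gamma, "cytokine_only", "null")),
        ),
    )
    return pd.Series(out, index=effects.index, name="mechanism")


def simulate_effectorness_cells(config: CellSimConfig) -> ad.AnnData:
    """Generate a cell x gene table along a latent effectorness gradient.

    Returns an :class:`anndata.AnnData` with observed (dropout-censored)
    log2 expression in ``X``, per-cell ``condition``, ``replicate``,
    ``pseudotime`` (a condition-specific positive affine transform of the
    latent effectorness, mimicking unscaled trajectory output) and
    ``effectorness`` in ``.obs``, and the generative coefficients plus
    mechanism class in ``.var``.
    """
    config.validate()
    rng = as_rng(config.seed)
    n, g = config.n_cells, config.n_genes
    conditions = list(config.conditions)

    dist = config.effectorness_distribution
    if dist == "uniform":
        e = rng.uniform(0.0, 1.0, size=n)
    elif isinstance(dist, (tuple, list)) and len(dist) == 3 and dist[0] == "beta":
        e = rng.beta(float(dist[1]), float(dist[2]), size=n)
    else:
        raise ValueError(f"unknown effectorness distribution: {dist!r}")

    if config.condition_depends_on_effectorness:
        # Confounding switch (off by default): later conditions are drawn
        # preferentially for high-effectorness cells.
        weights = np.ones((n, len(conditions)))
        weights *= 1.0 + np.outer(e, np.arange(len(conditions)))
        weights /= weights.sum(axis=1, keepdims=True)
        cond_idx = np.array([rng.choice(len(conditions), p=w) for w in weights])
    else:
        cond_idx = rng.integers(len(conditions), size=n)

    effects = config.effects
    if effects is None:
        effects = draw_gene_effects(
            g, config.conditions, effect_size=config.effect_size, random_state=rng
        )
    if len(effects) != g:
        raise ValueError("effects table length does not match n_genes")

    nonref = conditions[1:]
    alpha = effects["alpha"].to_numpy(float)
    beta = effects["beta"].to_numpy(float)
    gamma = np.zeros((g, len(conditions)))
    delta = np.zeros((g, len(conditions)))
    for k, c in enumerate(nonref, start=1):
        gamma[:, k] = effects[f"gamma_{c}"].to_numpy(float)
        delta[:, k] = effects[f"delta_{c}"].to_numpy(float)

    # latent log2 expression, cells x genes
    latent = (
        alpha[None, :]
        + np.outer(e, beta)
        + gamma[:, cond_idx].T
        + delta[:, cond_idx].T * e[:, None]
        + rng.normal(0.0, config.residual_sd, size=(n, g))
    )
    if config.dropout:
        p_zero = expit(-(latent - config.dropout_midpoint) / config.dropout_scale)
        observed = np.where(rng.random(latent.shape) < p_zero, 0.0, latent)
    else:
        observed = latent

    # Unscaled per-condition pseudotime: positive affine map of E so that
    # min-max rescaling within a condition recovers the gradient ordering.
    scale = rng.uniform(5.0, 15.0, size=len(conditions))
    offset = rng.uniform(0.0, 3.0, size=len(conditions))
    pseudotime = e * scale[cond_idx] + offset[cond_idx]

    obs = pd.DataFrame(
        {
            "condition": pd.Categorical(
                np.asarray(conditions)[cond_idx], categories=conditions
            ),
            "replicate": (rng.integers(4, size=n) + 1).astype(str),
            "pseudotime": pseudotime,
            "effectorness": e,
        },
        index=pd.Index([f"cell_{i:06d}" for i in range(n)], name="cell_id"),
    )
    var = effects.copy()
    if "mechanism" not in var.columns:
        var["mechanism"] = mechanism_class_from_effects(var, config.conditions)
    var.index.name = "gene_id"
    return ad.AnnData(X=observed, obs=obs, var=var)


# ---------------------------------------------------------------------------
# Clonotypes


@dataclass
class ClonotypeSimConfig:
    """Design of a clonal-expansion simulation.

    A cell joins an expanded clone with probability ``p0 + p1 * E``; the
    remaining cells are singleton clonotypes. Expanded clone sizes are
    geometric with success probability ``clone_size_geometric_p`` (mean
    1/p), and clone mates are adjacent in effectorness -- clonal expansion
    is an event local to a cell's activation history, so sister cells sit
    at similar points of the gradient.
    """

    n_cells: int = 5000
    base_expansion_prob: float = 0.05
    effectorness_slope: float = 0.6
    clone_size_geometric_p: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.base_expansion_prob < 0:
            raise ValueError("base_expansion_prob must be >= 0")
        if self.base_expansion_prob + self.effectorness_slope > 1:
            raise ValueError(
                "base_expansion_prob + effectorness_slope exceeds 1: expansion "
                "probability would leave [0, 1]"
            )
        if not 0 < self.clone_size_geometric_p < 1:
            raise ValueError("clone_size_geometric_p must be in (0, 1)")


def simulate_clonotypes(
    config: ClonotypeSimConfig, effectorness: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Assign every cell exactly one clonotype.

    ``effectorness`` supplies per-cell values in [0, 1]; its length overrides
    ``config.n_cells`` when they differ. Returns a data frame with columns
    ``cell_id``, ``clonotype_id``, ``effectorness``.
    """
    config.validate()
    e = np.asarray(effectorness, dtype=float)
    if e.ndim != 1 or e.size == 0:
        raise ValueError("effectorness must be a non-empty 1-D array")
    if (e < 0).any() or (e > 1).any():
        raise ValueError("effectorness values must lie in [0, 1]")
    p = config.base_expansion_prob + config.effectorness_slope * e
    if (p < 0).any() or (p > 1).any():
        raise ValueError("expansion probability out of [0, 1] after applying the slope")

    rng = as_rng(config.seed)
    n = e.size
    cell_ids = np.array([f"cell_{i:06d}" for i in range(n)])
    expanded = rng.random(n) < p

    clonotype = np.empty(n, dtype=object)
    singles = np.flatnonzero(~expanded)
    for k, i in enumerate(singles):
        clonotype[i] = f"S{k:06d}"

    # Chunk expanded cells, ordered by effectorness, into consecutive clones
    # of geometric size (the last clone may be truncated by availability).
    exp_idx = np.flatnonzero(expanded)
    exp_idx = exp_idx[np.argsort(e[exp_idx], kind="mergesort")]
    pos, clone = 0, 0
    while pos < exp_idx.size:
        size = int(rng.geometric(config.clone_size_geometric_p))
        members = exp_idx[pos : pos + size]
        for i in members:
            clonotype[i] = f"E{clone:06d}"
        pos += size
        clone += 1

    return pd.DataFrame(
        {"cell_id": cell_ids, "clonotype_id": clonotype.astype(str), "effectorness": e}
    )
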