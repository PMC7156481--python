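"""The effectorness statistic and the per-gene effectorness x cytokine model.

Effectorness is a per-cell statistic in [0, 1]: the cell's trajectory
pseudotime, min-max scaled within its stimulation condition, with the
per-condition scalings concatenated into one column. Low values are
naive-like cells; high values are effector-memory-like cells.

The interaction model explains a gene's log2 expression across cells as

    X_ij = alpha + beta * E_j + gamma_c + delta_c * E_j + eps

with ``E_j`` the cell's effectorness, ``c`` its cytokine condition (dummy
coded against the Th0 reference, so ``gamma_Th0 = delta_Th0 = 0``) and
``eps`` Gaussian noise. Cells with zero expression for a gene are omitted
from that gene's fit. Per-coefficient p-values are BH-adjusted per
coefficient family (beta; each gamma_c; each delta_c) across genes, and a
coefficient is significant at q < 0.05. Genes are then classified into
mechanism groups: modulated by cytokines only, by effectorness only, by
both independently, or through an interaction -- the latter split into
cytokine-specific (no marginal effectorness slope) and ubiquitous
(effectorness-dependent in all conditions, with cytokines modulating the
strength).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import bh_adjust

__all__ = [
    "scale_pseudotime",
    "unify_effectorness",
    "effectorness_from_pseudotime",
    "EffectornessScaler",
    "fit_interaction_model",
    "classify_genes",
    "EffectornessCytokineModel",
]


def scale_pseudotime(pseudotime: np.ndarray | pd.Series) -> np.ndarray:
    """Min-max scale one condition's pseudotime to [0, 1].

    Rank order is preserved; the minimum maps to 0 and the maximum to 1.
    Constant pseudotime is an error (there is no gradient to scale).
    """
    t = np.asarray(pseudotime, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two cells to scale pseudotime")
    if not np.isfinite(t).all():
        raise ValueError("pseudotime values must be finite")
    lo, hi = t.min(), t.max()
    if hi == lo:
        raise ValueError("constant pseudotime: no gradient to scale")
    return (t - lo) / (hi - lo)


def unify_effectorness(per_condition: Mapping[str, np.ndarray]) -> np.ndarray:
    """Concatenate independently scaled per-condition values, unchanged.

    Every condition must supply already-scaled values; per-condition minima
    (0) and maxima (1) are retained in the combined column.
    """
    parts = []
    for cond, values in per_condition.items():
        if values is None or len(values) == 0:
            raise ValueError(f"condition {cond!r} has no scaled effectorness values")
        parts.append(np.asarray(values, dtype=float))
    if not parts:
        raise ValueError("no conditions supplied")
    return np.concatenate(parts)


def effectorness_from_pseudotime(
    obs: pd.DataFrame, pseudotime_col: str = "pseudotime", condition_col: str = "condition"
) -> pd.Series:
    """Per-cell effectorness: pseudotime min-max scaled within condition.

    Index order of ``obs`` is preserved (the scaling is per condition, the
    concatenation is a no-op on values).
    """
    out = pd.Series(np.nan, index=obs.index, name="effectorness")
    for cond, idx in obs.groupby(condition_col, observed=True).groups.items():
        out.loc[idx] = scale_pseudotime(obs.loc[idx, pseudotime_col])
    return out


class EffectornessScaler(TransformerMixin, BaseEstimator):
    """Transformer mapping (pseudotime, condition) to effectorness.

    ``fit`` learns each condition's pseudotime range; ``transform`` applies
    the per-condition min-max map and returns the unified effectorness
    column. Input is a data frame with ``pseudotime`` and ``condition``
    columns.
    """

    def __init__(self, pseudotime_col: str = "pseudotime", condition_col: str = "condition"):
        self.pseudotime_col = pseudotime_col
        self.condition_col = condition_col

    def fit(self, X: pd.DataFrame, y=None):
        ranges = {}
        for cond, sub in X.groupby(self.condition_col, observed=True):
            t = np.asarray(sub[self.pseudotime_col], dtype=float)
            if t.size < 2:
                raise ValueError(f"condition {cond!r} has fewer than two cells")
            if not np.isfinite(t).all():
                raise ValueError(f"condition {cond!r} has non-finite pseudotime")
            if t.max() == t.min():
                raise ValueError(f"condition {cond!r} has constant pseudotime")
            ranges[cond] = (float(t.min()), float(t.max()))
        self.ranges_ = ranges
        return self

    def transform(self, X: pd.DataFrame) -> pd.Series:
        if not hasattr(self, "ranges_"):
            raise ValueError("EffectornessScaler is not fitted")
        out = pd.Series(np.nan, index=X.index, name="effectorness")
        for cond, idx in X.groupby(self.condition_col, observed=True).groups.items():
            if cond not in self.ranges_:
                raise ValueError(f"condition {cond!r} was not seen during fit")
            lo, hi = self.ranges_[cond]
            out.loc[idx] = (X.loc[idx, self.pseudotime_col] - lo) / (hi - lo)
        return out


def _design(
    effectorness: np.ndarray, condition: pd.Categorical, conditions: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Dummy-coded design: intercept, E, condition indicators, E x indicators."""
    cols = [np.ones_like(effectorness), effectorness]
    names = ["alpha", "beta"]
    for c in conditions[1:]:
        ind = (np.asarray(condition) == c).astype(float)
        cols.append(ind)
        names.append(f"gamma_{c}")
    for c in conditions[1:]:
        ind = (np.asarray(condition) == c).astype(float)
        cols.append(ind * effectorness)
        names.append(f"delta_{c}")
    return np.column_stack(cols), names


def fit_interaction_model(
    X: pd.DataFrame | np.ndarray,
    effectorness: np.ndarray | pd.Series,
    condition: Sequence[str] | pd.Series,
    genes: Sequence[str] | None = None,
    reference: str = "Th0",
    q_sig: float = 0.05,
) -> pd.DataFrame:
    """Per-gene OLS of log2 expression on effectorness, condition, and their
    interaction.

    ``X`` is cells x genes. For each gene, cells with zero expression are
    omitted, the model is fit by ordinary least squares with the reference
    condition as dummy-coding baseline, and two-sided per-coefficient
    p-values are taken from the OLS t-statistics. BH adjustment is applied
    across genes separately within each coefficient family (beta, each
    gamma_c, each delta_c).

    A gene whose post-omission design is unusable (expressed in fewer than
    two conditions, no non-zero cells in the reference condition, or a
    rank-deficient design) is reported with ``fitted = False`` and a
    ``reason`` rather than silently dropped. Non-reference conditions with
    fewer than two non-zero cells are dropped from that gene's fit and
    their coefficients reported as NaN.
    """
    if isinstance(X, pd.DataFrame):
        gene_ids = list(X.columns)
        values = X.to_numpy(dtype=float)
    else:
        values = np.asarray(X, dtype=float)
        gene_ids = list(genes) if genes is not None else [f"g{i}" for i in range(values.shape[1])]
    e = np.asarray(effectorness, dtype=float)
    cond = pd.Series(np.asarray(condition, dtype=object))
    if not ((e >= 0) & (e <= 1)).all():
        raise ValueError("effectorness must lie in [0, 1]")
    levels = [reference] + sorted(set(cond) - {reference})
    if reference not in set(cond):
        raise ValueError(f"reference condition {reference!r} absent from the data")

    coef_names = _design(e[:2], cond.iloc[:2], levels)[1]
    records: list[dict] = []
    for j, gene in enumerate(gene_ids):
        y_all = values[:, j]
        mask = np.isfinite(y_all) & (y_all != 0)
        row: dict = {"gene_id": gene, "fitted": False, "reason": "", "n_cells_used": int(mask.sum())}
        for name in coef_names:
            row[name] = np.nan
            row[f"p_{name}"] = np.nan
        row["resid_sd"] = np.nan

        y, ee, cc = y_all[mask], e[mask], cond[mask]
        present = [c for c in levels if (cc == c).sum() >= 2]
        if reference not in present:
            row["reason"] = "fewer than two non-zero cells in the reference condition"
            records.append(row)
            continue
        if len(present) < 2:
            row["reason"] = "non-zero expression in a single condition"
            records.append(row)
            continue
        keep = cc.isin(present).to_numpy()
        y, ee, cc = y[keep], ee[keep], cc[keep]
        design, names = _design(ee, cc, present)
        if len(y) <= design.shape[1]:
            row["reason"] = "too few non-zero cells for the design"
            records.append(row)
            continue
        if np.linalg.matrix_rank(design) < design.shape[1]:
            row["reason"] = "rank-deficient design after zero-omission"
            records.append(row)
            continue
        fit = sm.OLS(y, design).fit()
        row["fitted"] = True
        row["n_cells_used"] = int(len(y))
        row["resid_sd"] = float(np.sqrt(fit.scale))
        for name, est, pval in zip(names, fit.params, fit.pvalues):
            row[name] = float(est)
            row[f"p_{name}"] = float(pval)
        records.append(row)

    out = pd.DataFrame.from_records(records).set_index("gene_id")
    for name in coef_names:
        if name == "alpha":
            continue
        out[f"q_{name}"] = bh_adjust(out[f"p_{name}"])
    out.attrs["conditions"] = levels
    out.attrs["q_sig"] = q_sig
    return out


def classify_genes(
    fits: pd.DataFrame,
    q_sig: float = 0.05,
    beta_strong: float = 0.5,
    delta_strong: float = 0.5,
) -> pd.DataFrame:
    """Assign each fitted gene a mechanism class plus strong-effect flags.

    Classes (significance = family-wise BH q below ``q_sig``):

    * ``cytokine_only`` -- some gamma_c significant; beta and all delta_c not;
    * ``effectorness_only`` -- beta significant; no gamma_c or delta_c;
    * ``independent`` -- beta and some gamma_c significant; no delta_c;
    * ``interaction_ubiquitous`` -- some delta_c and beta significant;
    * ``interaction_cytokine_specific`` -- some delta_c significant, beta not;
    * ``null`` -- nothing significant.

    ``strong_beta`` flags significant |beta| > ``beta_strong``;
    ``strong_delta_<c>`` flags significant |delta_c| > ``delta_strong`` per
    condition. Unfitted genes are classified ``unfit``.
    """
    conditions = fits.attrs.get("conditions")
    if conditions is None:
        gamma_cols = [c for c in fits.columns if c.startswith("gamma_")]
        nonref = [c.removeprefix("gamma_") for c in gamma_cols]
    else:
        nonref = list(conditions[1:])

    sig = lambda col: (fits[f"q_{col}"] < q_sig).fillna(False).to_numpy()
    beta_sig = sig("beta")
    gamma_sig = np.column_stack([sig(f"gamma_{c}") for c in nonref]).any(axis=1)
    delta_sig = np.column_stack([sig(f"delta_{c}") for c in nonref]).any(axis=1)

    cls = np.where(
        delta_sig,
        np.where(beta_sig, "interaction_ubiquitous", "interaction_cytokine_specific"),
        np.where(
            beta_sig & gamma_sig,
            "independent",
            np.where(
                beta_sig, "effectorness_only", np.where(gamma_sig, "cytokine_only", "null")
            ),
        ),
    )
    cls = np.where(fits["fitted"].to_numpy(), cls, "unfit")
    out = pd.DataFrame({"mechanism": cls}, index=fits.index)
    out["strong_beta"] = beta_sig & (fits["beta"].abs() > beta_strong).fillna(False).to_numpy()
    for c in nonref:
        out[f"strong_delta_{c}"] = sig(f"delta_{c}") & (
            fits[f"delta_{c}"].abs() > delta_strong
        ).fillna(False).to_numpy()
    return out


class EffectornessCytokineModel(BaseEstimator):
    """Per-gene interaction model with mechanism classification.

    A fit-shaped wrapper over :func:`fit_interaction_model` and
    :func:`classify_genes`. Accepts an :class:`anndata.AnnData` (cells x
    genes, with ``condition`` and ``effectorness`` — or ``pseudotime``, from
    which effectorness is derived — in ``.obs``) or a cells x genes data
    frame plus an ``obs`` annotation frame.

    Attributes
    ----------
    fits_ : per-gene coefficients, p-values, family-wise BH q-values.
    classes_ : per-gene mechanism class and strong-effect flags.
    unfit_ : subset of genes that could not be fitted, with reasons.
    """

    def __init__(
        self,
        reference: str = "Th0",
        q_sig: float = 0.05,
        beta_strong: float = 0.5,
        delta_strong: float = 0.5,
    ) -> None:
        self.reference = reference
        self.q_sig = q_sig
        self.beta_strong = beta_strong
        self.delta_strong = delta_strong

    def fit(self, X, obs: pd.DataFrame | None = None, genes: Sequence[str] | None = None):
        if hasattr(X, "obs") and hasattr(X, "X"):  # AnnData
            obs = X.obs
            expr = pd.DataFrame(np.asarray(X.X), index=obs.index, columns=X.var_names)
        else:
            expr = pd.DataFrame(X)
            if obs is None:
                raise ValueError("obs annotations are required when X is a plain matrix")
        if genes is not None:
            expr = expr.loc[:, list(genes)]
        if "effectorness" in obs.columns:
            e = obs["effectorness"].to_numpy(dtype=float)
        elif "pseudotime" in obs.columns:
            e = effectorness_from_pseudotime(obs).to_numpy()
        else:
            raise ValueError("obs needs an 'effectorness' or 'pseudotime' column")
        self.fits_ = fit_interaction_model(
            expr, e, obs["condition"].astype(str), reference=self.reference, q_sig=self.q_sig
        )
        self.classes_ = classify_genes(
            self.fits_,
            q_sig=self.q_sig,
            beta_strong=self.beta_strong,
            delta_strong=self.delta_strong,
        )
        self.unfit_ = self.fits_.loc[~self.fits_["fitted"], ["reason", "n_cells_used"]]
        self.conditions_ = self.fits_.attrs["conditions"]
        return self
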