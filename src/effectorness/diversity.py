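"""Clonal-diversity metrics over effectorness-ordered sliding windows.

Cells are sorted by increasing effectorness and three metrics are computed
in a sliding window of fixed size (100 cells by default, advancing one
rank at a time):

* the fraction of unique clones -- distinct clonotypes over window size;
* the Shannon entropy of the clonotype frequencies, normalized by
  ``ln(window size)`` so that it lands in [0, 1] (a monoclonal window
  scores 0, an all-singleton window 1);
* the expansion index, 1 - normalized entropy.

The fixed window size removes any need for cell-number normalization
across windows. Entropy uses the natural log; the normalization makes the
base irrelevant, and the raw (unnormalized) natural-log entropy is
available via ``entropy="raw"`` for comparison (the expansion index is
always 1 minus the normalized value).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datasets import validate_clonotype_table

__all__ = [
    "normalized_shannon_entropy",
    "diversity_windows",
    "high_effectorness_subset",
    "clonotype_sizes",
    "ClonalDiversityProfiler",
]


def normalized_shannon_entropy(clone_counts) -> float:
    """Shannon entropy of clone counts, normalized by ln(window size).

    ``clone_counts`` are positive integers summing to the window size m,
    which must be at least 2. Returns ``-sum(f_k ln f_k) / ln(m)`` with
    ``f_k = count_k / m``: 0 for a single clone, 1 for all singletons.
    """
    counts = np.asarray(clone_counts, dtype=float)
    if counts.size == 0 or (counts <= 0).any():
        raise ValueError("clone counts must be positive integers")
    m = counts.sum()
    if m < 2:
        raise ValueError(f"window size must be at least 2 (got {int(m)})")
    f = counts / m
    return float(-(f * np.log(f)).sum() / np.log(m))


def _sorted_cells(clonotypes: pd.DataFrame) -> pd.DataFrame:
    validate_clonotype_table(clonotypes, require_effectorness=True)
    # Stable sort with cell id as the tie-break keeps windows deterministic.
    return clonotypes.sort_values(
        ["effectorness", "cell_id"], kind="mergesort", ignore_index=True
    )


def diversity_windows(
    clonotypes: pd.DataFrame, window: int = 100, step: int = 1, entropy: str = "normalized"
) -> pd.DataFrame:
    """Sliding-window diversity profile over the effectorness ordering.

    Returns one row per window with ``start_rank`` (0-based rank of the
    window's first cell), ``mean_effectorness``, ``fraction_unique``,
    ``shannon_entropy_norm`` (or ``shannon_entropy_raw``) and
    ``expansion_index``. With step 1 there are ``n_cells - window + 1``
    windows. The profile is invariant to the input row order.
    """
    if window < 2:
        raise ValueError("window must be at least 2")
    if step < 1:
        raise ValueError("step must be at least 1")
    if entropy not in ("normalized", "raw"):
        raise ValueError("entropy must be 'normalized' or 'raw'")
    cells = _sorted_cells(clonotypes)
    n = len(cells)
    if n < window:
        raise ValueError(f"need at least {window} cells for a window (got {n})")

    clono = cells["clonotype_id"].to_numpy()
    eff = cells["effectorness"].to_numpy(dtype=float)
    log_m = np.log(window)
    rows = []
    for start in range(0, n - window + 1, step):
        ids, counts = np.unique(clono[start : start + window], return_counts=True)
        f = counts / window
        h_raw = float(-(f * np.log(f)).sum())
        h_norm = h_raw / log_m
        rows.append(
            (
                start,
                float(eff[start : start + window].mean()),
                len(ids) / window,
                h_raw if entropy == "raw" else h_norm,
                1.0 - h_norm,
            )
        )
    entropy_col = "shannon_entropy_raw" if entropy == "raw" else "shannon_entropy_norm"
    return pd.DataFrame(
        rows,
        columns=["start_rank", "mean_effectorness", "fraction_unique", entropy_col, "expansion_index"],
    )


def high_effectorness_subset(clonotypes: pd.DataFrame, threshold: float = 0.7) -> pd.DataFrame:
    """Cells with effectorness strictly above ``threshold``.

    The returned table (sorted like the profile) feeds external TCR
    specificity grouping; clone sizes within it are available through
    :func:`clonotype_sizes`. An empty subset is a warning, not an error.
    """
    validate_clonotype_table(clonotypes, require_effectorness=True)
    subset = _sorted_cells(clonotypes[clonotypes["effectorness"] > threshold])
    if subset.empty:
        warnings.warn(f"no cells with effectorness > {threshold}", stacklevel=2)
    return subset


def clonotype_sizes(clonotypes: pd.DataFrame) -> pd.Series:
    """Clone sizes (cells per clonotype), largest first."""
    return (
        clonotypes["clonotype_id"]
        .value_counts()
        .sort_index()
        .sort_values(ascending=False, kind="mergesort")
        .rename("n_cells")
    )


class ClonalDiversityProfiler(BaseEstimator):
    """Sliding-window clonal-diversity profiler.

    ``fit`` computes the windowed profile and the high-effectorness subset;
    ``fit_transform`` returns the profile directly.

    Attributes
    ----------
    profile_ : per-window diversity metrics.
    high_effectorness_ : cells above the effectorness threshold.
    """

    def __init__(
        self,
        window: int = 100,
        step: int = 1,
        threshold: float = 0.7,
        entropy: str = "normalized",
    ) -> None:
        self.window = window
        self.step = step
        self.threshold = threshold
        self.entropy = entropy

    def fit(self, clonotypes: pd.DataFrame, y=None):
        self.profile_ = diversity_windows(
            clonotypes, window=self.window, step=self.step, entropy=self.entropy
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.high_effectorness_ = high_effectorness_subset(clonotypes, self.threshold)
        return self

    def fit_transform(self, clonotypes: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(clonotypes).profile_
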