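"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from effectorness import PairedOmicsDataset


def naive_specificity(matrix: np.ndarray) -> np.ndarray:
    """Element-by-element evaluation of the Euclidean-norm specificity.

    Deliberately scalar and loop-based: the independent oracle against
    which the vectorized implementation is checked.
    """
    n_rows, n_cols = matrix.shape
    out = np.empty((n_rows, n_cols))
    for i in range(n_rows):
        total = 0.0
        for j in range(n_cols):
            total += matrix[i, j] ** 2
        norm = total**0.5
        for j in range(n_cols):
            out[i, j] = matrix[i, j] / norm
    return out


@pytest.fixture
def tiny_paired_dataset():
    """2 conditions x 2 replicates, one strongly spiked gene, no missingness."""
    samples = ["A_rep1", "A_rep2", "B_rep1", "B_rep2"]
    meta = pd.DataFrame(
        {"condition": ["A", "A", "B", "B"], "replicate": ["1", "2", "1", "2"]},
        index=pd.Index(samples, name="sample_id"),
    )
    rna = pd.DataFrame(
        [[10.0, 9.0, 1.0, 1.5], [2.0, 2.2, 2.1, 1.9]],
        index=["spiked", "flat"],
        columns=samples,
    )
    protein = pd.DataFrame(
        [[0.9, 1.0, 0.2, 0.1], [0.5, 0.6, 0.55, 0.5]],
        index=["spiked", "flat"],
        columns=samples,
    )
    return PairedOmicsDataset(rna=rna, protein=protein, sample_meta=meta)
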