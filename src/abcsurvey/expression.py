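"""Tissue-expression classification from a genes x tissues TPM matrix.

A gene is "expressed" in a tissue when its median TPM exceeds ``tau``
(default 0 — any positive value counts, the only rule consistent with a
silent gene having all-zero medians). Categories: ubiquitous (expressed in
every tissue), silent (in none), tissue_specific (in exactly one), other.
Classification always runs on raw TPM; the log2(TPM+1) transform exists
for display export only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CATEGORIES = ("ubiquitous", "silent", "tissue_specific", "other")


class ExpressionInputError(ValueError):
    pass


def load_tpm(path, expected_tissues: list[str] | None = None) -> pd.DataFrame:
    """Load a TPM TSV (gene rows, tissue columns); validates numeric >= 0."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    for col in matrix.columns:
        values = pd.to_numeric(matrix[col], errors="coerce")
        if values.isna().any():
            row = matrix.index[values.isna().argmax()]
            raise ExpressionInputError(
                f"non-numeric or missing TPM at gene {row!r}, tissue {col!r}"
            )
        matrix[col] = values
        if (values < 0).any():
            row = matrix.index[(values < 0).argmax()]
            raise ExpressionInputError(
                f"negative TPM at gene {row!r}, tissue {col!r}"
            )
    if expected_tissues is not None:
        missing = set(expected_tissues) - set(matrix.columns)
        if missing:
            raise ExpressionInputError(f"missing tissues: {sorted(missing)}")
        matrix = matrix[list(expected_tissues)]
    return matrix


def classify_expression(
    matrix: pd.DataFrame, tau: float = 0.0
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene category + counts. Rules are exclusive and exhaustive."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    expressed = matrix.values > tau
    n_tissues = matrix.shape[1]
    n_expressed = expressed.sum(axis=1)
    categories = np.where(
        n_expressed == n_tissues,
        "ubiquitous",
        np.where(
            n_expressed == 0,
            "silent",
            np.where(n_expressed == 1, "tissue_specific", "other"),
        ),
    )
    specific_tissue = [
        matrix.columns[row.argmax()] if n == 1 else ""
        for row, n in zip(expressed, n_expressed)
    ]
    profiles = pd.DataFrame(
        {
            "gene_id": matrix.index,
            "category": categories,
            "n_tissues_expressed": n_expressed,
            "specific_tissue": specific_tissue,
        }
    ).set_index("gene_id")
    counts = {c: int((categories == c).sum()) for c in CATEGORIES}
    return profiles, counts


def tissue_membership_counts(
    matrix: pd.DataFrame, tau: float = 0.0
) -> tuple[pd.Series, pd.Series]:
    """Per-tissue expressed-gene totals and the k-tissue breadth spectrum.

    The second series counts genes expressed in exactly k tissues for
    k = 0..T; it sums to the number of genes.
    """
    expressed = matrix.values > tau
    per_tissue = pd.Series(expressed.sum(axis=0), index=matrix.columns, name="n_expressed")
    n_expressed = expressed.sum(axis=1)
    k_values = range(matrix.shape[1] + 1)
    breadth = pd.Series(
        [int((n_expressed == k).sum()) for k in k_values],
        index=pd.Index(k_values, name="k_tissues"),
        name="n_genes",
    )
    return per_tissue, breadth


def log_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(TPM+1), the conventional heatmap scale."""
    return np.log2(matrix + 1.0)
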