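"""Signature scores: mean per-gene z-score of log2 fold-change.

A signature score for a sample is the mean, over the signature's matched
genes, of the gene-wise standardized log2 fold-change.  The fold-change
reference (cohort mean or cohort median of each gene's log2 values) is a
per-gene additive shift and therefore cancels under z-scoring — the resulting
scores are identical whichever reference is used.  Zero-variance genes carry
no information and are excluded from signature means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ImmuneSignature, ValidationError, resolve_genes

__all__ = ["SignatureScoreTable", "log2fc", "zscore_by_gene", "signature_score", "score_signatures"]

DEFAULT_MIN_GENES = 3
_REFERENCES = ("cohort_mean", "cohort_median", "none")


@dataclass(frozen=True)
class SignatureScoreTable:
    """Per-sample score columns (one per signature) with gene-coverage metadata."""

    scores: pd.DataFrame            # index sample_id, one column per signature
    n_genes_used: dict[str, int]
    valid: dict[str, bool]


def log2fc(matrix: ExpressionMatrix, reference: str = "cohort_mean") -> ExpressionMatrix:
    """Subtract a per-gene reference statistic: difference of log2 values = log2 FC."""
    if reference not in _REFERENCES:
        raise ValueError(f"reference must be one of {_REFERENCES}")
    if matrix.n_samples < 2:
        raise ValidationError("log2 fold-change needs >= 2 samples")
    if reference == "none":
        return matrix
    ref = matrix.data.mean(axis=1) if reference == "cohort_mean" else matrix.data.median(axis=1)
    return ExpressionMatrix(matrix.data.sub(ref, axis=0))


def zscore_by_gene(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Standardize each gene row to mean 0, sd 1 (sample sd, n-1 denominator).

    Returns the z-scored matrix restricted to non-degenerate genes, plus the
    list of zero-variance genes that were dropped (with a warning).
    """
    if matrix.n_samples < 2:
        raise ValidationError("z-scoring needs >= 2 samples")
    mean = matrix.data.mean(axis=1)
    sd = matrix.data.std(axis=1, ddof=1)
    degenerate = sd.index[sd == 0.0].tolist()
    if degenerate:
        warnings.warn(f"{len(degenerate)} zero-variance gene(s) excluded from z-scoring")
    keep = sd.index[sd > 0.0]
    z = matrix.data.loc[keep].sub(mean.loc[keep], axis=0).div(sd.loc[keep], axis=0)
    return ExpressionMatrix(z), degenerate


def signature_score(
    matrix: ExpressionMatrix,
    sig: ImmuneSignature,
    reference: str = "cohort_mean",
    min_genes: int = DEFAULT_MIN_GENES,
) -> SignatureScoreTable:
    """Score one signature; see :func:`score_signatures` for batch use."""
    return score_signatures(matrix, [sig], reference=reference, min_genes=min_genes)


def score_signatures(
    matrix: ExpressionMatrix,
    signatures,
    reference: str = "cohort_mean",
    min_genes: int = DEFAULT_MIN_GENES,
) -> SignatureScoreTable:
    """Score several signatures against one matrix (shared transform, cheaper).

    For each signature: score(sample) = mean over matched, non-degenerate
    genes of the z-scored log2 fold-change.  Signatures matching fewer than
    ``min_genes`` usable genes are flagged invalid and their column is NaN.
    """
    if hasattr(signatures, "values") and not isinstance(signatures, (list, tuple)):
        signatures = list(signatures.values())
    z, _ = zscore_by_gene(log2fc(matrix, reference))
    cols: dict[str, pd.Series] = {}
    n_used: dict[str, int] = {}
    valid: dict[str, bool] = {}
    for sig in signatures:
        present, _ = resolve_genes(sig.genes, z)
        n_used[sig.name] = len(present)
        if len(present) < min_genes:
            warnings.warn(
                f"signature {sig.name!r}: only {len(present)} usable gene(s), "
                f"below min_genes={min_genes}; scores set to NaN"
            )
            valid[sig.name] = False
            cols[sig.name] = pd.Series(np.nan, index=z.sample_ids)
        else:
            valid[sig.name] = True
            cols[sig.name] = z.data.loc[present].mean(axis=0)
    scores = pd.DataFrame(cols)
    scores.index.name = "sample_id"
    return SignatureScoreTable(scores=scores, n_genes_used=n_used, valid=valid)
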