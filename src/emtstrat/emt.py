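"""Per-sample signed two-sample Kolmogorov-Smirnov EMT score.

For one sample, the expression values of the matched epithelial genes and the
matched mesenchymal genes form two empirical distributions.  With F_E and F_M
their right-continuous ECDFs evaluated on the pooled support,

    D+ = max_x (F_E(x) - F_M(x)),   D- = max_x (F_M(x) - F_E(x)),

the EMT score is +D+ when D+ > D- and -D- when D- > D+.  Mesenchymal genes
expressed higher than epithelial genes push F_M below F_E, so a positive score
means a mesenchymal-shifted sample and a negative score an epithelial one.
When D+ = D-, the sign is set by comparing mean ranks of the two arms in the
pooled ranking (zero if those tie as well).

The score depends on the sample's values only through their ranks, so it is
invariant to any strictly increasing per-sample transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import EMTSignature, ExpressionMatrix, resolve_genes

__all__ = ["EMTScoreResult", "ecdf_eval", "signed_ks", "emt_score_sample", "emt_score_cohort"]

DEFAULT_MIN_GENES = 10


@dataclass(frozen=True)
class EMTScoreResult:
    """Signed KS score for one sample, with its components and gene coverage."""

    sample_id: str
    score: float
    d_plus: float
    d_minus: float
    n_epi_used: int
    n_mes_used: int
    valid: bool


def _as_finite_array(values, label: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{label}: empty value list")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{label}: non-finite values")
    return arr


def ecdf_eval(values, grid) -> np.ndarray:
    """Right-continuous ECDF F(x) = #{v <= x}/n of `values`, evaluated at `grid`."""
    arr = _as_finite_array(values, "values")
    grid = np.asarray(grid, dtype=float)
    return np.searchsorted(np.sort(arr), grid, side="right") / arr.size


def signed_ks(epi_values, mes_values) -> tuple[float, float, float]:
    """Signed two-sample KS statistic (score, D+, D-); positive = mesenchymal-shifted."""
    epi = _as_finite_array(epi_values, "epithelial values")
    mes = _as_finite_array(mes_values, "mesenchymal values")
    grid = np.union1d(epi, mes)
    diff = ecdf_eval(epi, grid) - ecdf_eval(mes, grid)
    d_plus = max(float(diff.max()), 0.0)
    d_minus = max(float((-diff).max()), 0.0)
    if d_plus > d_minus:
        score = d_plus
    elif d_minus > d_plus:
        score = -d_minus
    else:
        # tie: sign from mean ranks of the arms in the pooled ranking
        ranks = rankdata(np.concatenate([epi, mes]))
        mean_epi = ranks[: epi.size].mean()
        mean_mes = ranks[epi.size :].mean()
        if mean_mes > mean_epi:
            score = d_plus
        elif mean_epi > mean_mes:
            score = -d_minus
        else:
            score = 0.0
    return score, d_plus, d_minus


def emt_score_sample(
    matrix: ExpressionMatrix,
    sample_id: str,
    sig: EMTSignature,
    min_genes: int = DEFAULT_MIN_GENES,
) -> EMTScoreResult:
    """Score one sample; invalid (score NaN) when either arm matches < min_genes genes.

    Genes with non-finite values in this sample are dropped from the arms
    before scoring (cannot occur for a validated matrix, but per-sample slices
    of external tables may carry NaN).
    """
    col = matrix.sample_values(sample_id)
    epi_genes, _ = resolve_genes(sig.epithelial, matrix)
    mes_genes, _ = resolve_genes(sig.mesenchymal, matrix)
    epi = col.loc[epi_genes].to_numpy(dtype=float)
    mes = col.loc[mes_genes].to_numpy(dtype=float)
    epi = epi[np.isfinite(epi)]
    mes = mes[np.isfinite(mes)]
    if epi.size < min_genes or mes.size < min_genes:
        return EMTScoreResult(str(sample_id), float("nan"), float("nan"), float("nan"),
                              int(epi.size), int(mes.size), False)
    score, d_plus, d_minus = signed_ks(epi, mes)
    return EMTScoreResult(str(sample_id), score, d_plus, d_minus,
                          int(epi.size), int(mes.size), True)


def emt_score_cohort(
    matrix: ExpressionMatrix,
    sig: EMTSignature,
    min_genes: int = DEFAULT_MIN_GENES,
) -> pd.DataFrame:
    """Score every sample of the matrix; one row per sample, in matrix column order."""
    rows = [emt_score_sample(matrix, s, sig, min_genes) for s in matrix.sample_ids]
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "score": [r.score for r in rows],
            "d_plus": [r.d_plus for r in rows],
            "d_minus": [r.d_minus for r in rows],
            "n_epi_used": [r.n_epi_used for r in rows],
            "n_mes_used": [r.n_mes_used for r in rows],
            "valid": [r.valid for r in rows],
        }
    )
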