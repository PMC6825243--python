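"""Paired, covariate-adjusted differential expression between two tissues.

The tissue contrast is estimated on within-subject differences
``d_s = A_s - B_s``: subject effects cancel exactly, and the differences are
regressed on an intercept plus (by default mean-centered) age, sex and
smoking status. With centered covariates the intercept is the average
tissue effect, i.e. the log2 fold change reported per gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import PairedExpressionStudy, bh_adjust

__all__ = ["DEResult", "fit_paired_de", "deg_filter"]

COVARIATES = ["age", "sex", "smoking"]


@dataclass
class DEResult:
    """Per-gene paired differential-expression results."""

    table: pd.DataFrame  # gene_id, log2fc, t, p, q, deg
    alpha: float
    fc_threshold: float

    @property
    def deg_gene_ids(self) -> list[str]:
        return self.table.loc[self.table["deg"], "gene_id"].tolist()


def _design_matrix(
    study: PairedExpressionStudy, center_covariates: bool
) -> np.ndarray:
    cov = study.design.covariate_matrix()
    if center_covariates:
        cov = cov - cov.mean(axis=0, keepdims=True)
    x = np.column_stack([np.ones(len(cov)), cov])
    # collinearity check via rank of the design
    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = []
        for j in range(1, x.shape[1]):
            others = np.delete(x, j, axis=1)
            beta, *_ = np.linalg.lstsq(others, x[:, j], rcond=None)
            if np.allclose(others @ beta, x[:, j]):
                bad.append(COVARIATES[j - 1])
        raise ValueError(f"collinear covariate column(s): {', '.join(bad) or 'unknown'}")
    return x


def fit_paired_de(
    study: PairedExpressionStudy,
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
    center_covariates: bool = True,
) -> DEResult:
    """Fit the paired difference model for every gene.

    Per gene the intercept of the difference regression is the log2 fold
    change (tissue A minus tissue B); its t statistic uses n - 4 residual
    degrees of freedom (intercept + 3 covariates). P-values are two-sided
    and BH-adjusted over all genes. Genes whose differences are fitted
    perfectly (zero residual) get t = 0 when the estimate is 0 and p = 0
    when it is not.
    """
    a, b = study.paired_values()
    d = (a - b).T  # subjects x genes
    n = d.shape[0]
    x = _design_matrix(study, center_covariates)
    k = x.shape[1]
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} subjects for {k - 1} covariates")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ d  # k x genes
    resid = d - x @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se0 = np.sqrt(sigma2 * xtx_inv[0, 0])
    log2fc = beta[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / se0
    exact = np.zeros_like(log2fc)
    exact[log2fc > 0] = np.inf
    exact[log2fc < 0] = -np.inf
    t = np.where(se0 == 0, exact, t)
    p = 2.0 * stats.t.sf(np.abs(t), df=dof)
    q = bh_adjust(p)
    deg = (q < alpha) & (np.abs(log2fc) > fc_threshold)
    table = pd.DataFrame(
        {
            "gene_id": study.gene_ids,
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "q": q,
            "deg": deg,
        }
    )
    return DEResult(table, alpha, fc_threshold)


def deg_filter(
    result: DEResult, alpha: float | None = None, fc_threshold: float | None = None
) -> dict:
    """Apply strict FDR and |log2FC| gates and split by direction.

    Returns the passing rows partitioned into genes higher in tissue A
    (positive log2fc) and lower (negative), with counts and the
    percentages of the tested universe.
    """
    alpha = result.alpha if alpha is None else alpha
    fc = result.fc_threshold if fc_threshold is None else fc_threshold
    t = result.table
    passing = t[(t["q"] < alpha) & (t["log2fc"].abs() > fc)]
    higher = passing[passing["log2fc"] > 0].reset_index(drop=True)
    lower = passing[passing["log2fc"] < 0].reset_index(drop=True)
    total = len(t)
    return {
        "higher": higher,
        "lower": lower,
        "n_higher": len(higher),
        "n_lower": len(lower),
        "n_total": total,
        "pct_higher": 100.0 * len(higher) / total if total else 0.0,
        "pct_lower": 100.0 * len(lower) / total if total else 0.0,
    }
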