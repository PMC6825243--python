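"""Cross-tissue concordance of gene expression in a matched design.

Per-gene Spearman correlation between the two tissues across matched
subjects, a permutation test that breaks the subject pairing, matched vs
mismatched whole-profile correlations, and expression summaries contrasting
concordant with non-concordant genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import PairedExpressionStudy, bh_adjust

__all__ = [
    "ConcordanceTable",
    "PermutationResult",
    "ProfileCorrelationResult",
    "spearman_per_gene",
    "permutation_pairing_test",
    "profile_correlation_comparison",
    "group_summaries",
]


@dataclass
class ConcordanceTable:
    """Per-gene cross-tissue rank correlation with BH-adjusted significance."""

    table: pd.DataFrame  # gene_id, rho, p, q, significant, positive, excluded
    alpha: float

    @property
    def significant_gene_ids(self) -> list[str]:
        return self.table.loc[self.table["significant"], "gene_id"].tolist()


@dataclass
class PermutationResult:
    observed_statistic: int
    null_statistics: np.ndarray
    p_value: float
    n_permutations: int


@dataclass
class ProfileCorrelationResult:
    """Sample-vs-sample profile correlations split by pairing status."""

    correlations: pd.DataFrame  # tissue-A samples x tissue-B samples
    matched: np.ndarray
    mismatched: np.ndarray
    p_value: float


def _rank_standardize(values: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, centered and scaled to unit sample SD.

    Rows with no variation (all ties) become NaN; Pearson on these
    standardized ranks is the tie-corrected Spearman coefficient.
    """
    ranks = stats.rankdata(values, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    sd = ranks.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sd > 0, ranks / sd, np.nan)
    return out


def _rho_pvalues(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t approximation with n-2 degrees of freedom."""
    rho_c = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho_c * np.sqrt((n - 2) / np.maximum(1.0 - rho_c**2, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rho_c), 1.0), 0.0, p)
    return p


def spearman_per_gene(
    study: PairedExpressionStudy, alpha: float = 0.05
) -> ConcordanceTable:
    """Spearman correlation per gene between the subject-ordered tissue values.

    Genes that are constant in either tissue have an undefined rank
    correlation; they are flagged ``excluded`` and left out of the BH
    adjustment, which runs over all remaining genes.
    """
    a, b = study.paired_values()
    n = study.n_subjects
    if n < 4:
        raise ValueError("at least 4 matched subjects are required")
    ra, rb = _rank_standardize(a), _rank_standardize(b)
    rho = np.nansum(ra * rb, axis=1) / (n - 1)
    excluded = np.isnan(ra).any(axis=1) | np.isnan(rb).any(axis=1)
    rho = np.where(excluded, np.nan, rho)
    p = np.full(rho.shape, np.nan)
    p[~excluded] = _rho_pvalues(rho[~excluded], n)
    q = np.full(rho.shape, np.nan)
    if (~excluded).any():
        q[~excluded] = bh_adjust(p[~excluded])
    significant = np.where(np.isnan(q), False, q < alpha)
    table = pd.DataFrame(
        {
            "gene_id": study.gene_ids,
            "rho": rho,
            "p": p,
            "q": q,
            "significant": significant.astype(bool),
            "positive": np.where(np.isnan(rho), False, rho > 0).astype(bool),
            "excluded": excluded,
        }
    )
    return ConcordanceTable(table, alpha)


QUALIFIERS = ("p05", "positive", "q05")


def _count_qualifying(
    rho: np.ndarray, n: int, qualifier: str, valid: np.ndarray
) -> int:
    if qualifier == "positive":
        return int(np.sum((rho > 0) & valid))
    p = _rho_pvalues(np.where(valid, rho, 0.0), n)
    if qualifier == "p05":
        return int(np.sum((rho > 0) & (p < 0.05) & valid))
    if qualifier == "q05":
        q = np.full(p.shape, np.nan)
        q[valid] = bh_adjust(p[valid])
        return int(np.sum((rho > 0) & (q < 0.05) & valid))
    raise ValueError(f"unknown qualifier {qualifier!r}; choose from {QUALIFIERS}")


def permutation_pairing_test(
    study: PairedExpressionStudy,
    n_permutations: int = 500,
    qualifier: str = "p05",
    seed: int | None = None,
) -> PermutationResult:
    """Does the true pairing yield more positively correlated genes than chance?

    The statistic is the count of genes qualifying as positively correlated
    (default: rho > 0 with unadjusted p < 0.05). For each permutation the
    tissue-B samples are uniformly relabelled against tissue-A and the
    statistic recomputed; the p-value is ``(1 + #{null >= observed}) / (B + 1)``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    a, b = study.paired_values()
    n = study.n_subjects
    ra, rb = _rank_standardize(a), _rank_standardize(b)
    valid = ~(np.isnan(ra).any(axis=1) | np.isnan(rb).any(axis=1))
    ra = np.nan_to_num(ra)
    rb = np.nan_to_num(rb)

    rho_obs = (ra * rb).sum(axis=1) / (n - 1)
    observed = _count_qualifying(rho_obs, n, qualifier, valid)

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations, dtype=int)
    for k in range(n_permutations):
        perm = rng.permutation(n)
        rho_perm = (ra * rb[:, perm]).sum(axis=1) / (n - 1)
        null[k] = _count_qualifying(rho_perm, n, qualifier, valid)
    p = (1 + int(np.sum(null >= observed))) / (n_permutations + 1)
    return PermutationResult(observed, null, p, n_permutations)


def profile_correlation_comparison(
    study: PairedExpressionStudy, gene_subset: list[str] | None = None
) -> ProfileCorrelationResult:
    """Whole-profile Spearman correlation for every (tissue-A, tissue-B) sample pair.

    Matched entries (the diagonal under the subject pairing) are compared to
    all mismatched entries with a two-sided Mann-Whitney rank-sum test.
    """
    if gene_subset is not None:
        if len(gene_subset) == 0:
            raise ValueError("gene_subset must not be empty")
        if len(gene_subset) < 3:
            raise ValueError("gene_subset must contain at least 3 genes")
        study = study.subset_genes(list(gene_subset))
    a, b = study.paired_values()
    g = a.shape[0]
    # rank each sample's gene profile; Pearson on ranks across genes
    ra = _rank_standardize(a.T)  # subjects x genes
    rb = _rank_standardize(b.T)
    ra, rb = np.nan_to_num(ra), np.nan_to_num(rb)
    corr = ra @ rb.T / (g - 1)
    n = study.n_subjects
    matched = np.diag(corr).copy()
    mask = ~np.eye(n, dtype=bool)
    mismatched = corr[mask]
    stat_p = stats.mannwhitneyu(matched, mismatched, alternative="two-sided").pvalue
    subjects = study.design.subject_ids
    frame = pd.DataFrame(corr, index=study.design.samples_a, columns=study.design.samples_b)
    assert matched.size == len(subjects) and mismatched.size == n * (n - 1)
    return ProfileCorrelationResult(frame, matched, mismatched, float(stat_p))


def group_summaries(
    concordance: ConcordanceTable, study: PairedExpressionStudy
) -> pd.DataFrame:
    """Mean and SD of expression, contrasted between concordant and other genes.

    Per gene, mean and sample SD are computed over all samples of both
    tissues pooled; the two groups (BH-significant vs not) are compared per
    metric with a two-sided rank-sum test. With a single group the
    comparison p-values are reported as NaN.
    """
    a, b = study.paired_values()
    pooled = np.hstack([a, b])
    per_gene = pd.DataFrame(
        {
            "gene_id": study.gene_ids,
            "mean": pooled.mean(axis=1),
            "sd": pooled.std(axis=1, ddof=1),
            "significant": concordance.table.set_index("gene_id")
            .loc[study.gene_ids, "significant"]
            .to_numpy(),
        }
    )
    rows = []
    for flag, grp in per_gene.groupby("significant"):
        rows.append(
            {
                "group": "correlated" if flag else "non_correlated",
                "n_genes": len(grp),
                "mean_expression": grp["mean"].mean(),
                "mean_sd": grp["sd"].mean(),
            }
        )
    summary = pd.DataFrame(rows)
    sig = per_gene[per_gene["significant"]]
    non = per_gene[~per_gene["significant"]]
    if len(sig) and len(non):
        summary.attrs["p_mean"] = float(
            stats.mannwhitneyu(sig["mean"], non["mean"], alternative="two-sided").pvalue
        )
        summary.attrs["p_sd"] = float(
            stats.mannwhitneyu(sig["sd"], non["sd"], alternative="two-sided").pvalue
        )
    else:
        summary.attrs["p_mean"] = float("nan")
        summary.attrs["p_sd"] = float("nan")
    summary.attrs["per_gene"] = per_gene
    return summary
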