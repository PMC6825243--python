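"""Gene-set overrepresentation with a resampling baseline.

Enrichment is a one-sided hypergeometric test per term with BH adjustment.
The *sampling contrast* puts an observed query's enrichment in context: the
same test is run on many equally sized gene sets drawn at random from a
parent set (e.g. the analysis' own gene list) and from the genome-wide
universe, and the per-term mean and standard error of -log10 p over the
draws are reported next to the observed values. When the query covers more
than half of its parent set, sampling from the parent is skipped: the two
sets are too similar for the contrast to mean anything.

The per-sample score is a deliberately simple stand-in for kernel-based
gene-set variation scores: the mean of per-gene z-scores (genes
standardized jointly across all samples) per sample and set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, FormatError, bh_adjust

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "hypergeom_enrich",
    "sampling_contrast",
    "score_gene_sets_per_sample",
]

P_FLOOR = 1e-300  # published tables report p = 0 below double precision


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise FormatError(f"gene set {name!r} contains duplicate members")

    def restricted_to(self, universe: set[str]) -> dict[str, list[str]]:
        return {
            name: [g for g in members if g in universe]
            for name, members in self.sets.items()
        }


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: per line a set name, a description, then members.

    Duplicate members within a set are removed with a warning; a line with
    fewer than three fields is a format error.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"line {lineno}: a GMT line needs a name, a description and members"
                )
            name, desc, members = fields[0], fields[1], [g for g in fields[2:] if g]
            if not members:
                raise FormatError(f"line {lineno}: gene set {name!r} has no members")
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                warnings.warn(
                    f"gene set {name!r}: removed {len(members) - len(unique)} duplicate member(s)",
                    stacklevel=2,
                )
            if name in sets:
                raise FormatError(f"line {lineno}: duplicate gene set name {name!r}")
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def hypergeom_enrich(
    query: list[str], sets: GeneSetCollection, universe: list[str]
) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation per term, BH-adjusted.

    Each term is first intersected with the universe; p is the upper-tail
    probability of observing at least the seen overlap when drawing
    ``|query|`` genes without replacement from the universe.
    """
    if not query:
        raise ValueError("query gene list must not be empty")
    uni = set(universe)
    q = set(query)
    outside = q - uni
    if outside:
        raise ValueError(
            f"query gene(s) outside the universe: {', '.join(sorted(outside)[:5])}"
        )
    n_uni, n_query = len(uni), len(q)
    rows = []
    for name, members in sets.restricted_to(uni).items():
        term = set(members)
        overlap = sorted(q & term)
        k, big_k = len(overlap), len(term)
        p = float(stats.hypergeom.sf(k - 1, n_uni, big_k, n_query)) if big_k else 1.0
        rows.append(
            {
                "term_id": name,
                "term_name": sets.descriptions.get(name, ""),
                "term_size": big_k,
                "overlap_size": k,
                "p": min(max(p, 0.0), 1.0),
                "overlap_genes": ",".join(overlap),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out.sort_values("p", ignore_index=True)


@dataclass
class SamplingContrast:
    """Observed -log10 p per term next to random-draw baselines."""

    table: pd.DataFrame
    n_draws: int
    parent_skipped: bool


def _neglog10_p_matrix(
    draws: list[list[str]], sets: GeneSetCollection, universe: list[str]
) -> np.ndarray:
    """Terms x draws matrix of -log10 hypergeometric p for each random query."""
    mats = []
    for d in draws:
        tab = hypergeom_enrich(d, sets, universe).set_index("term_id")
        mats.append(-np.log10(np.maximum(tab["p"].reindex(sorted(sets.sets)), P_FLOOR)))
    return np.column_stack(mats)


def sampling_contrast(
    query: list[str],
    sets: GeneSetCollection,
    universe: list[str],
    parent_set: list[str],
    n_draws: int = 500,
    seed: int | None = None,
) -> SamplingContrast:
    """Contrast a query's enrichment against random same-size gene samples.

    Draws ``n_draws`` sets of ``|query|`` genes without replacement from the
    parent set and from the genome universe; reports the per-term mean and
    standard error of -log10 p over each background next to the observed
    values. Parent sampling is skipped (flagged) if the query covers more
    than half the parent set.
    """
    if len(query) > len(parent_set):
        raise ValueError("query cannot be larger than its parent set")
    if not set(parent_set) <= set(universe):
        raise ValueError("parent set must be contained in the universe")
    if n_draws == 1:
        warnings.warn("n_draws = 1: standard errors are reported as 0", stacklevel=2)
    rng = np.random.default_rng(seed)
    term_ids = sorted(sets.sets)
    observed = hypergeom_enrich(query, sets, universe).set_index("term_id")
    obs = -np.log10(np.maximum(observed["p"].reindex(term_ids), P_FLOOR))

    k = len(query)
    parent_skipped = k > 0.5 * len(parent_set)
    genome_draws = [
        list(rng.choice(np.asarray(universe), size=k, replace=False))
        for _ in range(n_draws)
    ]
    genome = _neglog10_p_matrix(genome_draws, sets, universe)

    def mean_sd_se(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        mean = mat.mean(axis=1)
        if mat.shape[1] > 1:
            sd = mat.std(axis=1, ddof=1)
        else:
            sd = np.zeros(mat.shape[0])
        return mean, sd, sd / np.sqrt(mat.shape[1])

    g_mean, g_sd, g_se = mean_sd_se(genome)
    data = {
        "term_id": term_ids,
        "observed_neglog10_p": obs.to_numpy(),
        "genome_mean": g_mean,
        "genome_sd": g_sd,
        "genome_se": g_se,
    }
    if parent_skipped:
        for col in ("parent_mean", "parent_sd", "parent_se"):
            data[col] = np.full(len(term_ids), np.nan)
    else:
        parent_draws = [
            list(rng.choice(np.asarray(parent_set), size=k, replace=False))
            for _ in range(n_draws)
        ]
        p_mean, p_sd, p_se = mean_sd_se(_neglog10_p_matrix(parent_draws, sets, universe))
        data["parent_mean"] = p_mean
        data["parent_sd"] = p_sd
        data["parent_se"] = p_se
    return SamplingContrast(pd.DataFrame(data), n_draws, parent_skipped)


def score_gene_sets_per_sample(
    matrix: ExpressionMatrix, sets: GeneSetCollection
) -> pd.DataFrame:
    """Samples x sets table of mean per-gene z-scores.

    Genes are standardized across all samples of the matrix; a set's score
    in a sample is the mean z of its measured member genes. Sets with fewer
    than two measured genes are skipped with a warning.
    """
    mean = matrix.values.mean(axis=1, keepdims=True)
    sd = matrix.values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (matrix.values - mean) / sd, 0.0)
    index = {g: i for i, g in enumerate(matrix.gene_ids)}
    cols = {}
    for name, members in sets.sets.items():
        rows = [index[g] for g in members if g in index]
        if len(rows) < 2:
            warnings.warn(
                f"gene set {name!r} has fewer than 2 measured genes; skipped",
                stacklevel=2,
            )
            continue
        cols[name] = z[rows].mean(axis=0)
    return pd.DataFrame(cols, index=matrix.sample_ids)
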