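"""Synthetic matched two-tissue expression studies with known ground truth.

The generator emulates the design of a matched airway-epithelium study:
each subject contributes one sample per tissue. Ground truth is planted in
disjoint gene blocks by default so recovery can be attributed cleanly:

* **concordant genes** share a latent per-subject effect between tissues,
  with loading chosen so the cross-tissue correlation equals ``rho_target``;
* **network genes** are drawn, independently per tissue, from a zero-mean
  multivariate normal whose sparse precision matrix encodes a known edge
  set; the two tissues' edge sets overlap by ``shared_edge_fraction``;
* **differentially expressed genes** receive a mean shift of ``log2fc`` in
  tissue A only;
* **smoking genes** receive a covariate shift in both tissues for current
  smokers.

All randomness flows from a single seed through one generator, so an
identical configuration yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ExpressionMatrix, PairedDesign, PairedExpressionStudy
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "build_precision_matrix",
    "generate_paired_study",
]


@dataclass
class SimulationConfig:
    """Parameters of a synthetic matched two-tissue study."""

    n_subjects: int = 77
    n_genes: int = 500
    n_concordant: int = 100
    rho_target: float = 0.8
    n_edges_per_tissue: int = 40
    shared_edge_fraction: float = 0.5
    edge_strength: float = 0.9  # planted |partial correlation| ~ 0.3
    n_de: int = 25
    log2fc: float = 3.0
    noise_sd: float = 1.0
    covariate_effects: dict = field(default_factory=dict)
    n_smoking_genes: int = 0
    allow_block_overlap: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.rho_target < 1:
            raise ValueError("rho_target must lie strictly inside (0, 1)")
        if not 0 <= self.shared_edge_fraction <= 1:
            raise ValueError("shared_edge_fraction must lie in [0, 1]")
        if self.n_concordant > self.n_genes:
            raise ValueError("n_concordant cannot exceed n_genes")
        if self.n_de > self.n_genes:
            raise ValueError("n_de cannot exceed n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class GroundTruth:
    """What was planted: gene roles and per-tissue true edge sets."""

    concordant_gene_ids: list[str]
    edges_a: set[tuple[str, str]]
    edges_b: set[tuple[str, str]]
    shared_edges: set[tuple[str, str]]
    de_gene_ids: list[str]
    de_log2fc: dict[str, float]
    smoking_gene_ids: list[str]
    precision_a: np.ndarray
    precision_b: np.ndarray

    def __post_init__(self) -> None:
        if not self.shared_edges <= self.edges_a or not self.shared_edges <= self.edges_b:
            raise ValueError("shared edges must be contained in both tissue edge sets")


def build_precision_matrix(
    n_genes: int,
    edges,
    edge_strength: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Symmetric strictly diagonally dominant precision matrix with given support.

    Off-diagonal entries are ``+/- edge_strength`` (random sign under the
    generator) exactly at the requested index pairs; each diagonal entry is
    one plus the row-wise sum of absolute off-diagonals, which guarantees
    positive definiteness.
    """
    rng = rng or np.random.default_rng(0)
    omega = np.zeros((n_genes, n_genes))
    seen: set[tuple[int, int]] = set()
    for i, j in edges:
        if i == j:
            raise ValueError(f"self edge ({i}, {j}) is not allowed")
        if not (0 <= i < n_genes and 0 <= j < n_genes):
            raise ValueError(f"edge ({i}, {j}) references an invalid gene index")
        key = (min(i, j), max(i, j))
        if key in seen:
            raise ValueError(f"duplicate edge ({i}, {j})")
        seen.add(key)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        omega[key[0], key[1]] = omega[key[1], key[0]] = sign * edge_strength
    np.fill_diagonal(omega, np.abs(omega).sum(axis=1) + 1.0)
    return omega


def true_partial_correlations(omega: np.ndarray) -> np.ndarray:
    """Partial correlations implied by a precision matrix (unit diagonal)."""
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return pcor


def _sample_edge_sets(
    rng: np.random.Generator,
    gene_indices: np.ndarray,
    n_edges: int,
    shared_fraction: float,
) -> tuple[list, list, list]:
    """Erdos-Renyi G(n, m)-style edge sampling with a planted shared core."""
    n = len(gene_indices)
    n_pairs = n * (n - 1) // 2
    n_shared = int(np.floor(shared_fraction * n_edges))
    needed = n_shared + 2 * (n_edges - n_shared)
    if needed > n_pairs:
        raise ValueError(
            f"cannot place {needed} distinct edges among {n} network genes "
            f"({n_pairs} pairs available)"
        )
    chosen = rng.choice(n_pairs, size=needed, replace=False)
    # map linear pair index -> (i, j), i < j, over the gene block
    ii, jj = np.triu_indices(n, k=1)
    pairs = [(int(gene_indices[ii[c]]), int(gene_indices[jj[c]])) for c in chosen]
    shared = pairs[:n_shared]
    only_a = pairs[n_shared : n_shared + (n_edges - n_shared)]
    only_b = pairs[n_shared + (n_edges - n_shared) :]
    return shared, shared + only_a, shared + only_b


def generate_paired_study(
    config: SimulationConfig,
) -> tuple[PairedExpressionStudy, GroundTruth]:
    """Draw a synthetic paired study plus the ground truth planted in it."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_subjects, config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(p)]
    sigma = config.noise_sd

    concordant = np.arange(config.n_concordant)
    if config.allow_block_overlap:
        network_pool = np.arange(p)
    else:
        network_pool = np.arange(config.n_concordant, p)

    shared, edges_a_idx, edges_b_idx = _sample_edge_sets(
        rng, network_pool, config.n_edges_per_tissue, config.shared_edge_fraction
    )
    omega_a = build_precision_matrix(p, edges_a_idx, config.edge_strength, rng)
    omega_b = build_precision_matrix(p, edges_b_idx, config.edge_strength, rng)

    # Per-tissue draws from N(0, Omega^-1); independent across tissues.
    chol_a = np.linalg.cholesky(np.linalg.inv(omega_a))
    chol_b = np.linalg.cholesky(np.linalg.inv(omega_b))
    x_a = (chol_a @ rng.standard_normal((p, n)))
    x_b = (chol_b @ rng.standard_normal((p, n)))

    # Concordant genes: replace with latent-subject construction.
    # loading a solves a^2 / (a^2 + sigma^2) = rho  =>  a = sigma*sqrt(rho/(1-rho))
    if config.n_concordant:
        a_load = sigma * np.sqrt(config.rho_target / (1.0 - config.rho_target))
        u = rng.standard_normal((config.n_concordant, n))
        x_a[concordant] = a_load * u + sigma * rng.standard_normal((config.n_concordant, n))
        x_b[concordant] = a_load * u + sigma * rng.standard_normal((config.n_concordant, n))

    # DE genes: mean shift in tissue A only; drawn preferentially from genes
    # free of other planted structure so recovery tests stay unambiguous.
    structured = set(concordant.tolist())
    for i, j in edges_a_idx + edges_b_idx:
        structured.update((i, j))
    free = [g for g in range(p) if g not in structured]
    if config.n_de <= len(free):
        de_idx = np.asarray(free[: config.n_de], dtype=int)
    else:
        de_idx = rng.choice(p, size=config.n_de, replace=False)
    x_a[de_idx] += config.log2fc

    # Covariates: roughly balanced cohort of adults.
    age = rng.uniform(20.0, 60.0, size=n)
    sex = rng.integers(0, 2, size=n)
    smoking = rng.integers(0, 2, size=n)

    smoking_idx = np.array([], dtype=int)
    if config.n_smoking_genes:
        pool = [g for g in range(p) if g not in set(de_idx.tolist())]
        smoking_idx = np.asarray(pool[-config.n_smoking_genes :], dtype=int)
        effect = float(config.covariate_effects.get("smoking", 1.0))
        x_a[smoking_idx] += effect * smoking[None, :]
        x_b[smoking_idx] += effect * smoking[None, :]

    subjects = [f"S{i:03d}" for i in range(n)]
    samples_a = [f"{s}_A" for s in subjects]
    samples_b = [f"{s}_B" for s in subjects]
    design = PairedDesign(
        pd.DataFrame(
            {
                "subject_id": subjects,
                "sample_a": samples_a,
                "sample_b": samples_b,
                "age": age,
                "sex": sex,
                "smoking": smoking,
            }
        )
    )
    study = PairedExpressionStudy(
        ExpressionMatrix(gene_ids, samples_a, x_a),
        ExpressionMatrix(gene_ids, samples_b, x_b),
        design,
    )

    def name_pairs(pairs) -> set[tuple[str, str]]:
        return {
            tuple(sorted((gene_ids[i], gene_ids[j])))  # type: ignore[misc]
            for i, j in pairs
        }

    truth = GroundTruth(
        concordant_gene_ids=[gene_ids[i] for i in concordant],
        edges_a=name_pairs(edges_a_idx),
        edges_b=name_pairs(edges_b_idx),
        shared_edges=name_pairs(shared),
        de_gene_ids=[gene_ids[i] for i in de_idx],
        de_log2fc={gene_ids[i]: config.log2fc for i in de_idx},
        smoking_gene_ids=[gene_ids[i] for i in smoking_idx],
        precision_a=omega_a,
        precision_b=omega_b,
    )
    return study, truth
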