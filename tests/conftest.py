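import numpy as np
import pandas as pd
import pytest

from dualnet.core import ExpressionMatrix, PairedDesign, PairedExpressionStudy
from dualnet.simulate import SimulationConfig, generate_paired_study


def make_study(a_values, b_values, covariates=None) -> PairedExpressionStudy:
    """Build a paired study from two genes x subjects arrays."""
    a_values = np.asarray(a_values, dtype=float)
    b_values = np.asarray(b_values, dtype=float)
    g, n = a_values.shape
    genes = [f"G{i:03d}" for i in range(g)]
    subjects = [f"S{j:03d}" for j in range(n)]
    samples_a = [f"{s}_A" for s in subjects]
    samples_b = [f"{s}_B" for s in subjects]
    if covariates is None:
        rng = np.random.default_rng(42)
        covariates = {
            "age": rng.uniform(20, 60, n),
            "sex": rng.integers(0, 2, n),
            "smoking": rng.integers(0, 2, n),
        }
    design = PairedDesign(
        pd.DataFrame(
            {
                "subject_id": subjects,
                "sample_a": samples_a,
                "sample_b": samples_b,
                **covariates,
            }
        )
    )
    return PairedExpressionStudy(
        ExpressionMatrix(genes, samples_a, a_values),
        ExpressionMatrix(genes, samples_b, b_values),
        design,
    )


@pytest.fixture(scope="session")
def concordant_study():
    """Strongly concordant synthetic study reused across tests (fixed seed)."""
    config = SimulationConfig(
        n_subjects=60,
        n_genes=300,
        n_concordant=100,
        rho_target=0.8,
        n_edges_per_tissue=20,
        n_de=10,
        seed=7,
    )
    return generate_paired_study(config)
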