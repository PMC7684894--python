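import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from mlrgwas.genotypes import GenotypeMatrix
from mlrgwas.null_models import fit_pql_null
from mlrgwas.simulate import simulate_structured_cohort


def make_genotypes(dosages, samples=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame({
        "chrom": "1",
        "pos": np.arange(1, m + 1),
        "id": [f"v{j}" for j in range(m)],
        "ref": "A",
        "alt": "B",
    })
    return GenotypeMatrix(dosages, samples or [f"s{i}" for i in range(n)], variants)


@pytest.fixture(scope="session")
def small_cohort():
    """120-sample structured cohort with relatedness, reused across tests."""
    return simulate_structured_cohort(
        n=120, n_snps=300, cells_x=4, cells_y=4, founders_per_cell=12,
        couples_per_cell=6, seed=42,
    )


@pytest.fixture(scope="session")
def small_null(small_cohort):
    """Converged PQL null fit on the small cohort (intercept + stratum-free X)."""
    rng = np.random.default_rng(7)
    from mlrgwas.genotypes import compute_grm, compute_pcs
    from mlrgwas.simulate import SimulationConfig, kinship_factor, simulate_phenotype

    k = compute_grm(small_cohort.genotypes)
    x = np.column_stack([np.ones(120), compute_pcs(k, 2)])
    cfg = SimulationConfig(p0=0.15, p1=0.35, tau=0.5)
    y = simulate_phenotype(cfg, small_cohort.z, small_cohort.k_pheno, seed=rng)
    fit = fit_pql_null(y, x, k)
    return fit, k, x
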