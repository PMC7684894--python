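import numpy as np
import pytest

from mlrgwas.diagnostics import StrataVector
from mlrgwas.simulate import (
    SimulationConfig,
    fst,
    gene_drop,
    kinship_factor,
    run_bias_experiment,
    run_power_experiment,
    run_type1_experiment,
    simulate_grid_genotypes,
    simulate_phenotype,
    simulate_structured_cohort,
)


def test_config_logit_parameterization():
    cfg = SimulationConfig(p0=0.05, p1=0.30)
    from scipy.special import logit
    assert cfg.a0 == pytest.approx(logit(0.05))
    assert cfg.a1 == pytest.approx(logit(0.30) - logit(0.05))
    with pytest.raises(ValueError):
        SimulationConfig(p0=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(tau=-1)


def test_grid_genotypes_deterministic_and_valid():
    g1, pop1 = simulate_grid_genotypes(5, 5, 4, n_snps=200, seed=11)
    g2, _ = simulate_grid_genotypes(5, 5, 4, n_snps=200, seed=11)
    np.testing.assert_array_equal(g1.dosages, g2.dosages)
    assert set(np.unique(g1.dosages)) <= {0.0, 1.0, 2.0}
    assert g1.n_samples == 100
    with pytest.raises(ValueError):
        simulate_grid_genotypes(0, 5, 4, n_snps=10)


def test_panmictic_limit_no_differentiation():
    g, pop = simulate_grid_genotypes(10, 10, 5, n_snps=4000,
                                     structure_param=0.0, seed=12)
    labels = (pop.cell % 10 < 5).astype(int)
    assert abs(fst(g, labels)) < 0.002


def test_default_calibration_half_grid_fst_below_bound():
    """20x20 grid at default structure: half-grid F_ST < 0.01."""
    g, pop = simulate_grid_genotypes(20, 20, 4, n_snps=4000, seed=13)
    labels = (pop.cell % 20 < 10).astype(int)
    f = fst(g, labels)
    assert 0.0 < f < 0.01


def test_gene_drop_kinship_structure():
    g, pop = simulate_grid_genotypes(3, 3, 6, n_snps=500, seed=14)
    g_all, pop_all, idx = gene_drop(g, pop, couples_per_cell=3,
                                    offspring_per_couple=2, seed=14)
    phi = pop_all.kinship()
    off = np.where(~pop_all.is_founder)[0]
    # parent-offspring kinship 0.25 (K = 2 Phi entry 0.5)
    i = off[0]
    pa, ma = pop_all.parents[i]
    assert phi[i, pa] == 0.25 and phi[i, ma] == 0.25
    # full sibs 0.25; self 0.5
    sibs = [j for j in off if (pop_all.parents[j] == pop_all.parents[i]).all()]
    assert len(sibs) == 2
    assert phi[sibs[0], sibs[1]] == 0.25
    assert phi[i, i] == 0.5
    # founders unrelated
    f0, f1 = np.where(pop_all.is_founder)[0][:2]
    assert phi[f0, f1] == 0.0


def test_gene_drop_sib_genotype_correlation():
    """Full sibs share half their genome: standardized-dosage correlation
    ~ 0.5 in a panmictic population (structure would add shared-cell
    covariance on top of the pedigree)."""
    g, pop = simulate_grid_genotypes(2, 2, 10, n_snps=5000,
                                     structure_param=0.0, seed=15)
    g_all, pop_all, _ = gene_drop(g, pop, couples_per_cell=5,
                                  offspring_per_couple=2, seed=15)
    off = np.where(~pop_all.is_founder)[0]
    # standardize per locus: raw dosage correlation across loci is inflated
    # by the shared allele-frequency spectrum
    p = g_all.dosages.mean(0) / 2.0
    zstd = (g_all.dosages - 2 * p) / np.sqrt(2 * p * (1 - p))
    cors = []
    for a, b in zip(off[0::2], off[1::2]):
        if (pop_all.parents[a] == pop_all.parents[b]).all():
            cors.append(np.corrcoef(zstd[a], zstd[b])[0, 1])
    assert abs(np.mean(cors) - 0.5) < 0.05


def test_gene_drop_zero_offspring():
    g, pop = simulate_grid_genotypes(2, 2, 4, n_snps=50, seed=16)
    g_all, pop_all, idx = gene_drop(g, pop, couples_per_cell=2,
                                    offspring_per_couple=0, seed=16)
    assert g_all.n_samples == g.n_samples
    phi = pop_all.kinship()
    np.testing.assert_allclose(np.diag(phi), 0.5)
    assert np.abs(phi - np.diag(np.diag(phi))).max() == 0.0


def test_gene_drop_sample_size_guard():
    g, pop = simulate_grid_genotypes(2, 2, 4, n_snps=50, seed=17)
    with pytest.raises(ValueError):
        gene_drop(g, pop, couples_per_cell=2, sample_size=10_000, seed=17)
    with pytest.raises(ValueError):
        gene_drop(g, pop, couples_per_cell=3, seed=17)  # needs 6 founders/cell


def test_structured_cohort_strata_and_kinship(small_cohort):
    z = small_cohort.z.z
    assert set(np.unique(z)) == {0.0, 1.0}
    k = small_cohort.k_pheno.matrix
    np.testing.assert_allclose(np.diag(k), 1.0)
    assert small_cohort.k_pheno.source == "pedigree"
    vals = np.unique(np.round(k[~np.eye(len(k), dtype=bool)], 6))
    assert set(vals) <= {0.0, 0.5}


def test_phenotype_prevalence_matches_strata():
    """tau=0, gamma=0: mean prevalence hits p0 in stratum 0 and p1 in 1."""
    n = 100_000
    z = np.zeros(n)
    cfg = SimulationConfig(p0=0.05, p1=0.30, tau=0.0)
    y0 = simulate_phenotype(cfg, z, None, seed=18)
    assert abs(y0.mean() - 0.05) < 0.005
    y1 = simulate_phenotype(cfg, np.ones(n), None, seed=19)
    assert abs(y1.mean() - 0.30) < 0.01


def test_phenotype_deterministic_and_centered_genotype():
    rng_k = np.random.default_rng(20)
    n = 200
    a = rng_k.standard_normal((n, 400))
    k = a @ a.T / 400
    z = (np.arange(n) < 50).astype(float)
    g = rng_k.binomial(2, 0.4, n).astype(float)
    cfg = SimulationConfig(p0=0.1, p1=0.2, tau=0.5, gamma=0.4)
    y1 = simulate_phenotype(cfg, z, k, g=g, seed=21)
    y2 = simulate_phenotype(cfg, z, k, g=g, seed=21)
    np.testing.assert_array_equal(y1, y2)
    with pytest.raises(ValueError):
        simulate_phenotype(cfg, z, -np.eye(n), seed=21)


def test_kinship_factor_reproduces_matrix():
    rng = np.random.default_rng(22)
    a = rng.standard_normal((30, 60))
    k = a @ a.T / 60
    l = kinship_factor(k)
    np.testing.assert_allclose(l @ l.T, k, atol=1e-8)


def test_type1_alpha_one_rejects_everything(small_cohort):
    cfg = SimulationConfig(p0=0.1, p1=0.3, tau=0.3, alpha=1.0)
    res = run_type1_experiment(small_cohort, cfg, methods=("amle",),
                               pcs=2, n_replicates=1, seed=23)
    assert (res["table"]["rejection_rate"] == 1.0).all()
    with pytest.raises(ValueError):
        run_type1_experiment(small_cohort, SimulationConfig(gamma=0.5), seed=0)


def test_power_saturates_at_huge_effect(small_cohort):
    cfg = SimulationConfig(p0=0.3, p1=0.3, tau=0.3, gamma=3.0,
                           maf_bin=(0.35, 0.50), n_replicates=15, alpha=1e-4)
    tab = run_power_experiment(small_cohort, cfg, methods=("amle",), pcs=2,
                               seed=24)
    assert tab["power"].iloc[0] > 0.8


def test_power_null_effect_near_alpha(small_cohort):
    cfg = SimulationConfig(p0=0.3, p1=0.3, tau=0.3, gamma=0.0,
                           maf_bin=(0.2, 0.5), n_replicates=30, alpha=0.5)
    tab = run_power_experiment(small_cohort, cfg, methods=("amle",), pcs=2,
                               seed=25)
    # with gamma = 0 the rejection rate is the level (alpha = 0.5 for power)
    assert abs(tab["power"].iloc[0] - 0.5) < 0.25


def test_bias_experiment_deterministic(small_cohort):
    kwargs = dict(
        scenarios={"A": {"p0": 0.10, "p1": 0.20, "tau": 0.3}},
        maf_bins=[(0.2, 0.5)], gammas=(0.4,), n_replicates=5,
        methods=("amle", "offset"), pcs=2,
    )
    t1 = run_bias_experiment(small_cohort, seed=26, **kwargs)
    t2 = run_bias_experiment(small_cohort, seed=26, **kwargs)
    assert t1.equals(t2)
    assert set(t1["method"]) == {"amle", "offset"}
    assert (t1["n_ok"] + t1["n_fail"] >= 5).all()
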