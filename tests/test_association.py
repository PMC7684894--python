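import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import chi2, kstest

from mlrgwas.association import (
    amle_test,
    gwas_scan,
    lr_test,
    mlm_score_test,
    offset_linear_gamma,
    offset_test,
)
from mlrgwas.null_models import fit_lmm_null, fit_pql_null, fit_pql_snp
from .conftest import make_genotypes


@pytest.fixture(scope="module")
def null_and_g(small_null):
    fit, k, x = small_null
    rng = np.random.default_rng(20)
    g = rng.binomial(2, 0.3, fit.n_samples).astype(float)
    return fit, k, x, g


def test_amle_wald_equals_score(null_and_g):
    """The AMLE Wald p-value is the score-test p-value U^2/(g'Pg)."""
    fit, _, _, g = null_and_g
    res = amle_test(fit, g)
    u = float(g @ (fit.y - fit.mu0))
    v = float(g @ fit.projection @ g)
    p_score = float(chi2.sf(u * u / v, 1))
    assert res.p == pytest.approx(p_score, abs=1e-12)
    assert res.score_u == pytest.approx(u, abs=1e-12)


def test_amle_reciprocal_consistency(null_and_g):
    fit, _, _, g = null_and_g
    res = amle_test(fit, g)
    assert res.stat * res.se**2 == pytest.approx(res.gamma_hat**2, abs=1e-10)
    assert 0 < res.p <= 1


def test_amle_zero_score_vector(null_and_g):
    """A genotype orthogonal to the residual gives gamma = 0, stat = 0, p = 1."""
    fit, _, _, g = null_and_g
    r = fit.y - fit.mu0
    g_orth = g - (g @ r) / (r @ r) * r
    res = amle_test(fit, g_orth)
    assert abs(res.score_u) < 1e-8
    assert res.stat < 1e-12
    assert res.p == pytest.approx(1.0, abs=1e-10)


def test_amle_constant_shift_invariance(null_and_g):
    """X contains an intercept, so X'(y - mu0) = 0 at convergence and adding
    a constant to g leaves statistic and estimate unchanged."""
    fit, _, _, g = null_and_g
    a = amle_test(fit, g)
    b = amle_test(fit, g + 3.0)
    assert b.stat == pytest.approx(a.stat, rel=1e-4, abs=1e-6)
    assert b.gamma_hat == pytest.approx(a.gamma_hat, rel=1e-4, abs=1e-6)


def test_amle_agrees_with_full_pql_at_small_effect():
    """gamma_hat from the one-step approximation tracks the full PQL refit
    when the true effect is small."""
    rng = np.random.default_rng(21)
    n = 200
    from scipy.linalg import block_diag
    blk = np.full((4, 4), 0.5); np.fill_diagonal(blk, 1.0)
    k = block_diag(*[blk] * 50)
    l = np.linalg.cholesky(k + 1e-10 * np.eye(n))
    x = np.ones((n, 1))
    diffs = []
    for s in range(15):
        r = np.random.default_rng(500 + s)
        g = r.binomial(2, 0.4, n).astype(float)
        om = np.sqrt(0.3) * (l @ r.standard_normal(n))
        y = r.binomial(1, expit(-0.4 + 0.1 * (g - g.mean()) + om)).astype(float)
        if y.min() == y.max():
            continue
        null = fit_pql_null(y, x, k)
        gam_a = amle_test(null, g).gamma_hat
        gam_p, _, _ = fit_pql_snp(y, x, g, k)
        diffs.append(abs(gam_a - gam_p))
    assert np.median(diffs) < 0.05


def test_offset_orthogonal_genotype_untouched(null_and_g):
    """g already orthogonal to X: residualization is the identity."""
    fit, _, x, g = null_and_g
    q, _ = np.linalg.qr(x)
    g_orth = g - q @ (q.T @ g)
    from mlrgwas.association import _residualize
    np.testing.assert_allclose(_residualize(g_orth, x), g_orth, atol=1e-10)


def test_offset_linear_analogue_equals_ols():
    """Identity-link two-step procedure reproduces the multiple-regression
    OLS coefficient exactly."""
    rng = np.random.default_rng(22)
    n = 150
    x = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
    g = rng.binomial(2, 0.35, n).astype(float)
    y = rng.standard_normal(n)
    full = np.linalg.lstsq(np.column_stack([x, g]), y, rcond=None)[0]
    assert offset_linear_gamma(y, x, g) == pytest.approx(full[-1], abs=1e-10)


def test_offset_null_calibration_unstructured():
    """tau = 0, gamma = 0: offset p-values are uniform over many null SNPs."""
    rng = np.random.default_rng(23)
    n = 400
    x = np.ones((n, 1))
    y = rng.binomial(1, 0.3, n).astype(float)
    null = fit_pql_null(y, x, np.zeros((n, n)))
    g = make_genotypes(rng.binomial(2, rng.uniform(0.1, 0.5, 2000), (n, 2000)))
    tab = gwas_scan(null, g, method="offset")
    p = tab["p"].to_numpy()
    p = p[np.isfinite(p)]
    frac = (p < 0.05).mean()
    half = 1.96 * np.sqrt(0.05 * 0.95 / p.size)
    assert 0.05 - half < frac < 0.05 + half


def test_lr_null_pvalues_uniform():
    rng = np.random.default_rng(24)
    n = 300
    x = np.ones((n, 1))
    y = rng.binomial(1, 0.5, n).astype(float)
    pvals = []
    for _ in range(400):
        g = rng.binomial(2, 0.3, n).astype(float)
        pvals.append(lr_test(y, x, g).p)
    assert kstest(pvals, "uniform").pvalue > 0.01


def test_lr_hand_computable_table():
    """Genotype counts cases (10,20,10) / controls (20,20,10); the frozen
    coefficient comes from direct likelihood maximization."""
    g = np.repeat([0.0, 1.0, 2.0], [30, 40, 20])
    y = np.concatenate([
        np.ones(10), np.zeros(20), np.ones(20), np.zeros(20),
        np.ones(10), np.zeros(10),
    ])
    x = np.ones((90, 1))
    res = lr_test(y, x, g)
    assert res.gamma_hat == pytest.approx(0.3714561380858633, abs=1e-6)


def test_lr_collinear_rejected():
    rng = np.random.default_rng(25)
    n = 100
    x = np.column_stack([np.ones(n), rng.binomial(2, 0.4, n)])
    y = rng.binomial(1, 0.4, n).astype(float)
    with pytest.raises(ValueError):
        lr_test(y, x, x[:, 1])


def test_mlm_identity_kinship_matches_ols_score():
    rng = np.random.default_rng(26)
    n = 250
    x = np.column_stack([np.ones(n), rng.standard_normal(n)])
    y = rng.standard_normal(n)
    g = rng.binomial(2, 0.3, n).astype(float)
    null = fit_lmm_null(y, x, np.eye(n))
    res = mlm_score_test(null, g)
    q, _ = np.linalg.qr(x)
    my = y - q @ (q.T @ y)
    mg = g - q @ (q.T @ g)
    s2 = (my @ my) / (n - x.shape[1])
    stat = (g @ my) ** 2 / ((mg @ mg) * s2)
    assert res.stat == pytest.approx(stat, abs=1e-8)


def test_mlm_orthogonal_genotype_null_result():
    rng = np.random.default_rng(27)
    n = 100
    x = np.ones((n, 1))
    y = rng.standard_normal(n)
    null = fit_lmm_null(y, x, np.eye(n))
    py = null.py
    g = rng.binomial(2, 0.4, n).astype(float)
    g_orth = g - (g @ py) / (py @ py) * py
    res = mlm_score_test(null, g_orth)
    assert res.stat < 1e-12 and res.p == pytest.approx(1.0, abs=1e-10)


def test_scan_equals_per_snp_calls(small_null, small_cohort):
    """The vectorized scans agree with the per-variant functions row by row."""
    fit, k, x = small_null
    g = small_cohort.genotypes
    sub = g.take_variants(np.arange(60))
    dos = sub.imputed()
    for method, fun in [("amle", amle_test), ("offset", offset_test)]:
        tab = gwas_scan(fit, sub, method=method)
        for j in range(sub.n_variants):
            if tab["status"].iloc[j] != "ok":
                continue
            r = fun(fit, dos[:, j])
            assert tab["gamma_hat"].iloc[j] == pytest.approx(r.gamma_hat, abs=1e-8)
            assert tab["p"].iloc[j] == pytest.approx(r.p, abs=1e-8)


def test_scan_empty_variant_set(small_null, small_cohort):
    fit, _, _ = small_null
    g = small_cohort.genotypes.take_variants(np.arange(0))
    tab = gwas_scan(fit, g, method="amle")
    assert len(tab) == 0


def test_scan_sample_mismatch_rejected(small_null):
    fit, _, _ = small_null
    g = make_genotypes(np.zeros((10, 3)))
    with pytest.raises(ValueError):
        gwas_scan(fit, g, method="amle")


def test_scan_monomorphic_recorded_not_fatal(small_null, small_cohort):
    fit, _, _ = small_null
    n = fit.n_samples
    dos = np.column_stack([
        np.ones(n) * 2,
        small_cohort.genotypes.dosages[:, 0],
    ])
    tab = gwas_scan(fit, make_genotypes(dos), method="amle")
    assert tab["status"].iloc[0] == "monomorphic"
    assert np.isnan(tab["p"].iloc[0])
    assert tab["status"].iloc[1] == "ok"
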