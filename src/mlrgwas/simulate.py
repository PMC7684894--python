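"""Synthetic structured cohorts and the type-I / power / bias experiments.

The generator emulates a two-strata cohort with cryptic relatedness:

* founder genotypes come from a seedable spatial Balding–Nichols model on a
  rectangular grid — per-variant ancestral frequencies drawn uniform(0.05,
  0.95), per-cell frequencies perturbed by a spatially autocorrelated
  Gaussian field whose scale is calibrated so that splitting the grid into
  two halves gives Wright's F_ST below 0.01 (the level seen within Europe);
* first-degree relatives are added by gene dropping: founders are paired
  into couples within cells and offspring receive one uniformly chosen
  parental allele per locus;
* the binary phenotype follows logit P(y_i = 1) = a0 + a1 z_i + gamma g_i +
  omega_i with omega ~ MVN(0, tau K), z the high-risk stratum indicator
  (top-left quarter of the grid) and a0 = logit(p0), a1 = logit(p1) -
  logit(p0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .association import amle_test, gwas_scan, lr_test, mlm_score_test, offset_test
from .diagnostics import StrataVector, snp_categories
from .genotypes import GRM, GenotypeMatrix, compute_grm, compute_pcs
from .null_models import ConvergenceError, fit_lmm_null, fit_pql_null, fit_pql_snp

__all__ = [
    "GridPopulation",
    "SimulationConfig",
    "Cohort",
    "simulate_grid_genotypes",
    "gene_drop",
    "simulate_structured_cohort",
    "simulate_phenotype",
    "fst",
    "run_type1_experiment",
    "run_power_experiment",
    "run_bias_experiment",
    "binomial_ci",
]

# default spatial Balding-Nichols calibration: per-cell differentiation scale
# and correlation length (in cells) chosen so a 20x20 grid split into two
# halves shows F_ST ~ 0.007 < 0.01
DEFAULT_STRUCTURE = 0.04
DEFAULT_CORR_LENGTH = 8.0


@dataclass
class GridPopulation:
    """Pedigreed population on a grid: founders plus gene-dropped offspring."""

    cells_x: int
    cells_y: int
    founders_per_cell: int
    cell: np.ndarray                 # cell index per individual
    parents: np.ndarray              # (n, 2) row indices, -1 -1 for founders
    cell_freqs: np.ndarray = field(repr=False)  # (n_cells, m) founder freqs

    @property
    def n_individuals(self) -> int:
        return self.cell.shape[0]

    @property
    def is_founder(self) -> np.ndarray:
        return self.parents[:, 0] < 0

    def kinship(self) -> np.ndarray:
        """Pedigree kinship Phi: 0.5 self, 0.25 parent-offspring/full sibs.

        Founders are unrelated and non-inbred; the pedigree has depth one, so
        the coefficients follow directly.
        """
        n = self.n_individuals
        phi = np.zeros((n, n))
        np.fill_diagonal(phi, 0.5)
        off = np.where(~self.is_founder)[0]
        if off.size:
            pa = self.parents[off, 0]
            ma = self.parents[off, 1]
            phi[off, pa] = phi[pa, off] = 0.25
            phi[off, ma] = phi[ma, off] = 0.25
            # full sibs: offspring sharing the same ordered parent pair
            _, inv = np.unique(self.parents[off], axis=0, return_inverse=True)
            order = np.argsort(inv, kind="stable")
            bounds = np.flatnonzero(np.diff(inv[order])) + 1
            for grp in np.split(off[order], bounds):
                if grp.size > 1:
                    phi[np.ix_(grp, grp)] = 0.25
                    phi[grp, grp] = 0.5
        return phi

    def strata_indicator(self) -> np.ndarray:
        """High-risk stratum: the top-left quarter of the grid."""
        cx, cy = self.cells_x, self.cells_y
        col = self.cell % cx
        row = self.cell // cx
        return ((col < cx / 2) & (row < cy / 2)).astype(float)


@dataclass
class SimulationConfig:
    """Phenotype-model and experiment parameters.

    ``p0``/``p1`` are the prevalences in the low- and high-risk strata;
    ``a0 = logit(p0)`` and ``a1 = logit(p1) - logit(p0)`` are the implied
    intercept and stratum effect in log-odds.  ``gamma`` is the causal SNP
    effect (log odds-ratio), ``maf_bin`` the half-open interval (lo, hi] the
    causal SNP is drawn from.
    """

    p0: float = 0.05
    p1: float = 0.30
    tau: float = 1.0
    gamma: float = 0.0
    maf_bin: tuple[float, float] | None = None
    n_replicates: int = 100
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p0 < 1 and 0 < self.p1 < 1):
            raise ValueError("prevalences must be in (0, 1)")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")

    @property
    def a0(self) -> float:
        return float(logit(self.p0))

    @property
    def a1(self) -> float:
        return float(logit(self.p1) - logit(self.p0))


@dataclass
class Cohort:
    """Analysis-ready sample: genotypes, strata, phenotype kinship."""

    genotypes: GenotypeMatrix
    z: StrataVector
    k_pheno: GRM                      # kinship used to draw random effects
    population: GridPopulation | None = None


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------

def _cell_field_factor(cells_x: int, cells_y: int, corr_length: float) -> np.ndarray:
    """Cholesky factor of the exponential spatial correlation over cells."""
    xs, ys = np.meshgrid(np.arange(cells_x), np.arange(cells_y))
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    c = np.exp(-d / corr_length)
    c[np.diag_indices_from(c)] += 1e-8
    return np.linalg.cholesky(c)


def simulate_grid_genotypes(
    cells_x: int = 20,
    cells_y: int = 20,
    founders_per_cell: int = 20,
    n_snps: int = 10_000,
    structure_param: float = DEFAULT_STRUCTURE,
    corr_length: float = DEFAULT_CORR_LENGTH,
    seed: int | np.random.Generator = 0,
) -> tuple[GenotypeMatrix, GridPopulation]:
    """Founder genotypes under the spatial Balding–Nichols model.

    Per variant s with ancestral frequency p_s ~ U(0.05, 0.95), the frequency
    in cell c is p_s + sqrt(structure_param * p_s (1 - p_s)) * f_cs with f a
    unit Gaussian field with correlation exp(-d/corr_length) between cells;
    founder dosages are Binomial(2, p_cell).  ``structure_param`` -> 0 gives
    a panmictic grid.
    """
    if cells_x < 1 or cells_y < 1 or founders_per_cell < 1 or n_snps < 1:
        raise ValueError("grid dimensions, founders and SNP count must be positive")
    if structure_param < 0:
        raise ValueError("structure_param must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_cells = cells_x * cells_y
    p_anc = rng.uniform(0.05, 0.95, size=n_snps)
    if structure_param > 0:
        lfac = _cell_field_factor(cells_x, cells_y, corr_length)
        fld = lfac @ rng.standard_normal((n_cells, n_snps))
        scale = np.sqrt(structure_param * p_anc * (1.0 - p_anc))
        cell_freqs = np.clip(p_anc[None, :] + scale[None, :] * fld, 1e-3, 1 - 1e-3)
    else:
        cell_freqs = np.broadcast_to(p_anc, (n_cells, n_snps)).copy()
    cell_of = np.repeat(np.arange(n_cells), founders_per_cell)
    dosages = rng.binomial(2, cell_freqs[cell_of, :]).astype(float)
    n = dosages.shape[0]
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, n_snps + 1),
            "id": [f"snp{j}" for j in range(n_snps)],
            "ref": "A",
            "alt": "B",
        }
    )
    g = GenotypeMatrix(dosages, [f"F{i}" for i in range(n)], variants)
    pop = GridPopulation(
        cells_x=cells_x, cells_y=cells_y, founders_per_cell=founders_per_cell,
        cell=cell_of, parents=np.full((n, 2), -1, dtype=int),
        cell_freqs=cell_freqs,
    )
    return g, pop


def gene_drop(
    founders: GenotypeMatrix,
    pop: GridPopulation,
    couples_per_cell: int,
    offspring_per_couple: int = 2,
    sample_size: int | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[GenotypeMatrix, GridPopulation, np.ndarray]:
    """Add gene-dropped offspring and (optionally) sample a cohort.

    Within each cell, ``couples_per_cell`` disjoint founder pairs are drawn;
    each couple gets ``offspring_per_couple`` children whose per-locus
    dosage is the sum of one uniformly transmitted allele from each parent
    (an allele of a parent with dosage d is alt with probability d/2).

    Returns the full population genotypes and pedigree and, if
    ``sample_size`` is given, the indices of a uniform without-replacement
    sample; otherwise indices of all individuals.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if 2 * couples_per_cell > pop.founders_per_cell:
        raise ValueError("not enough founders per cell for the requested couples")
    n_f = founders.n_samples
    m = founders.n_variants
    fathers, mothers = [], []
    n_cells = pop.cells_x * pop.cells_y
    for c in range(n_cells):
        members = np.where(pop.cell[:n_f] == c)[0]
        picked = rng.choice(members, size=2 * couples_per_cell, replace=False)
        fathers.extend(picked[0::2])
        mothers.extend(picked[1::2])
    fathers = np.repeat(np.array(fathers, int), offspring_per_couple)
    mothers = np.repeat(np.array(mothers, int), offspring_per_couple)
    n_off = fathers.shape[0]
    if n_off:
        dos_f = founders.dosages[fathers, :]
        dos_m = founders.dosages[mothers, :]
        child = (
            rng.binomial(1, dos_f / 2.0) + rng.binomial(1, dos_m / 2.0)
        ).astype(float)
        dosages = np.vstack([founders.dosages, child])
    else:
        dosages = founders.dosages.copy()
    samples = list(founders.samples) + [f"O{i}" for i in range(n_off)]
    g_all = GenotypeMatrix(dosages, samples, founders.variants.copy())
    cell_all = np.concatenate([pop.cell[:n_f], pop.cell[fathers]]) if n_off \
        else pop.cell[:n_f].copy()
    parents = np.vstack([
        np.full((n_f, 2), -1, dtype=int),
        np.column_stack([fathers, mothers]),
    ]) if n_off else np.full((n_f, 2), -1, dtype=int)
    pop_all = GridPopulation(
        cells_x=pop.cells_x, cells_y=pop.cells_y,
        founders_per_cell=pop.founders_per_cell,
        cell=cell_all, parents=parents, cell_freqs=pop.cell_freqs,
    )
    n_tot = g_all.n_samples
    if sample_size is None:
        idx = np.arange(n_tot)
    else:
        if sample_size > n_tot:
            raise ValueError(f"sample_size {sample_size} > population {n_tot}")
        idx = np.sort(rng.choice(n_tot, size=sample_size, replace=False))
    return g_all, pop_all, idx


def simulate_structured_cohort(
    n: int = 800,
    n_snps: int = 2000,
    cells_x: int = 10,
    cells_y: int = 10,
    founders_per_cell: int = 10,
    couples_per_cell: int = 5,
    offspring_per_couple: int = 2,
    structure_param: float = DEFAULT_STRUCTURE,
    corr_length: float | None = None,
    seed: int | np.random.Generator = 0,
    pheno_kinship: str = "pedigree",
) -> Cohort:
    """Desk-scale two-strata cohort with relatedness.

    A scaled-down version of the full 20x20/8000-founder design: founders on
    a grid, gene-dropped sibships, a uniform sample of size ``n`` and the
    top-left-quarter high-risk indicator.  ``pheno_kinship`` selects the K
    used to draw phenotype random effects: "pedigree" (K = 2 Phi) or "grm"
    (empirical GRM from the cohort's own variants, as when real genotypes
    are the starting point).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if corr_length is None:
        # keep the field's range proportional to the grid so the half-grid
        # F_ST calibration carries over to smaller grids
        corr_length = DEFAULT_CORR_LENGTH * min(cells_x, cells_y) / 20.0
    founders_g, pop = simulate_grid_genotypes(
        cells_x, cells_y, founders_per_cell, n_snps,
        structure_param=structure_param, corr_length=corr_length, seed=rng,
    )
    g_all, pop_all, idx = gene_drop(
        founders_g, pop, couples_per_cell, offspring_per_couple,
        sample_size=n, seed=rng,
    )
    g = GenotypeMatrix(
        g_all.dosages[idx, :],
        [g_all.samples[i] for i in idx],
        g_all.variants.copy(),
    )
    z_full = pop_all.strata_indicator()
    z = StrataVector(z_full[idx], kind="indicator")
    pop_sampled = GridPopulation(
        cells_x=pop_all.cells_x, cells_y=pop_all.cells_y,
        founders_per_cell=pop_all.founders_per_cell,
        cell=pop_all.cell, parents=pop_all.parents,
        cell_freqs=pop_all.cell_freqs,
    )
    if pheno_kinship == "pedigree":
        phi = pop_all.kinship()[np.ix_(idx, idx)]
        k = GRM(2.0 * phi, list(g.samples), source="pedigree")
    elif pheno_kinship == "grm":
        k = compute_grm(g)
    else:
        raise ValueError("pheno_kinship must be 'pedigree' or 'grm'")
    return Cohort(genotypes=g, z=z, k_pheno=k, population=pop_sampled)


# ---------------------------------------------------------------------------
# phenotype
# ---------------------------------------------------------------------------

def kinship_factor(k: GRM | np.ndarray) -> np.ndarray:
    """Symmetric factor L with L L' = K for MVN draws (eigenvalue floor 0)."""
    mat = k.matrix if isinstance(k, GRM) else np.asarray(k, dtype=float)
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() < -1e-8 * max(1.0, vals.max()):
        raise ValueError("kinship matrix is not positive semi-definite")
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def simulate_phenotype(
    config: SimulationConfig,
    z: StrataVector | np.ndarray,
    k: GRM | np.ndarray | None,
    g: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    k_factor: np.ndarray | None = None,
) -> np.ndarray:
    """Draw a binary phenotype from the liability-free logistic model.

    logit P(y_i=1) = a0 + a1 z_i + gamma * (g_i - mean g) + omega_i with
    omega ~ MVN(0, tau K).  The causal genotype is centered so the expected
    prevalences stay at (p0, p1).  ``k_factor`` may carry a precomputed
    factor of K (as from :func:`kinship_factor`) to amortize the
    eigendecomposition across replicates.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    zv = z.z if isinstance(z, StrataVector) else np.asarray(z, dtype=float)
    n = zv.shape[0]
    eta = config.a0 + config.a1 * zv
    if g is not None and config.gamma != 0.0:
        g = np.asarray(g, dtype=float)
        eta = eta + config.gamma * (g - g.mean())
    if config.tau > 0:
        if k_factor is None:
            if k is None:
                raise ValueError("tau > 0 requires a kinship matrix or factor")
            k_factor = kinship_factor(k)
        eta = eta + np.sqrt(config.tau) * (k_factor @ rng.standard_normal(n))
    return rng.binomial(1, expit(eta)).astype(float)


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def fst(g: GenotypeMatrix | np.ndarray, labels: np.ndarray) -> float:
    """Hudson's F_ST between two groups (ratio-of-averages over variants)."""
    dosages = g.imputed() if isinstance(g, GenotypeMatrix) else np.asarray(g, float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("F_ST requires exactly two groups")
    a = dosages[labels == groups[0]]
    b = dosages[labels == groups[1]]
    n1, n2 = a.shape[0], b.shape[0]
    p1 = a.mean(axis=0) / 2.0
    p2 = b.mean(axis=0) / 2.0
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    return float(num[keep].sum() / den[keep].sum())


# ---------------------------------------------------------------------------
# experiment harnesses
# ---------------------------------------------------------------------------

def binomial_ci(p: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation binomial confidence band for a rejection rate."""
    from scipy.stats import norm

    half = norm.ppf(0.5 + level / 2.0) * np.sqrt(p * (1.0 - p) / n)
    return max(p - half, 0.0), min(p + half, 1.0)


def _design(n: int, pcs_mat: np.ndarray | None) -> np.ndarray:
    cols = [np.ones(n)]
    if pcs_mat is not None:
        cols.append(pcs_mat)
    return np.column_stack(cols)


def run_type1_experiment(
    cohort: Cohort,
    config: SimulationConfig,
    methods: tuple[str, ...] = ("amle", "offset", "mlm"),
    pcs: int = 10,
    n_replicates: int = 3,
    th: float = 0.8,
    seed: int | np.random.Generator | None = None,
    fit_tol: float = 1e-5,
) -> dict:
    """Null-SNP rejection rates per method and SNP category.

    Each replicate draws a fresh phenotype under gamma = 0 and scans every
    cohort variant with each method; rejections at ``config.alpha`` are
    tabulated per category (between-strata variance ratio against ``th``).
    Returns a dict with the rejection table, pooled p-values per method and
    the category assignment.
    """
    if config.gamma != 0.0:
        raise ValueError("type-I experiment requires gamma = 0")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(config.seed if seed is None else seed)
    g = cohort.genotypes
    n = g.n_samples
    k_analysis = compute_grm(g)
    pcs_mat = compute_pcs(k_analysis, pcs) if pcs else None
    x = _design(n, pcs_mat)
    cats = snp_categories(g, cohort.z, th=th)
    k_fac = kinship_factor(cohort.k_pheno)
    k_eig = np.linalg.eigh(k_analysis.matrix)

    pvals: dict[str, list[np.ndarray]] = {m: [] for m in methods}
    tau_warm = 0.5
    for _ in range(n_replicates):
        y = simulate_phenotype(config, cohort.z, None, seed=rng, k_factor=k_fac)
        if y.min() == y.max():
            continue
        null_pql = None
        if any(m in methods for m in ("amle", "offset")):
            null_pql = fit_pql_null(y, x, k_analysis, tau0=tau_warm, tol=fit_tol)
            tau_warm = max(null_pql.tau, 1e-3)
        for m in methods:
            if m in ("amle", "offset"):
                tab = gwas_scan(null_pql, g, method=m)
            elif m == "mlm":
                null_lmm = fit_lmm_null(y, x, k_analysis, k_eig=k_eig)
                tab = gwas_scan(null_lmm, g, method="mlm")
            elif m == "lr":
                ps = np.full(g.n_variants, np.nan)
                dos = g.imputed()
                for j in range(g.n_variants):
                    try:
                        ps[j] = lr_test(y, x, dos[:, j]).p
                    except (ValueError, ConvergenceError):
                        pass
                pvals[m].append(ps)
                continue
            else:
                raise ValueError(f"unknown method {m!r}")
            pvals[m].append(tab["p"].to_numpy())

    rows = []
    alpha = config.alpha
    for m in methods:
        p_all = np.concatenate(pvals[m]) if pvals[m] else np.empty(0)
        cat_all = np.tile(cats.category, len(pvals[m]))
        for c in (1, 2, 3):
            mask = (cat_all == c) & np.isfinite(p_all)
            n_tests = int(mask.sum())
            if n_tests == 0:
                continue
            rate = float((p_all[mask] < alpha).mean())
            lo, hi = binomial_ci(alpha, n_tests)
            rows.append({"method": m, "category": c, "n_tests": n_tests,
                         "rejection_rate": rate, "ci_lo": lo, "ci_hi": hi})
    table = pd.DataFrame(rows)
    return {"table": table,
            "pvalues": {m: (np.concatenate(v) if v else np.empty(0))
                        for m, v in pvals.items()},
            "categories": cats}


def _draw_bin_snp(maf: np.ndarray, maf_bin: tuple[float, float],
                  rng: np.random.Generator) -> int:
    lo, hi = maf_bin
    candidates = np.where((maf > lo) & (maf <= hi))[0]
    if candidates.size == 0:
        raise ValueError(f"no variants with MAF in ({lo}, {hi}]")
    return int(rng.choice(candidates))


def run_power_experiment(
    cohort: Cohort,
    config: SimulationConfig,
    methods: tuple[str, ...] = ("lr", "amle", "offset"),
    pcs: int = 10,
    seed: int | np.random.Generator | None = None,
    fit_tol: float = 1e-4,
) -> pd.DataFrame:
    """Power at significance level ``config.alpha`` for the causal variant.

    Each replicate draws a causal SNP from ``config.maf_bin``, simulates the
    phenotype with effect ``config.gamma`` and tests that SNP with each
    method; power is the fraction of replicates below alpha, reported with
    its Monte-Carlo standard error.
    """
    if config.maf_bin is None:
        raise ValueError("power experiment needs a MAF bin for the causal SNP")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(config.seed if seed is None else seed)
    g = cohort.genotypes
    n = g.n_samples
    maf = g.maf
    dosages = g.imputed()
    k_analysis = compute_grm(g)
    pcs_mat = compute_pcs(k_analysis, pcs) if pcs else None
    x = _design(n, pcs_mat)
    k_fac = kinship_factor(cohort.k_pheno)

    hits = {m: 0 for m in methods}
    n_ok = {m: 0 for m in methods}
    tau_warm = 0.5
    for _ in range(config.n_replicates):
        j = _draw_bin_snp(maf, config.maf_bin, rng)
        gj = dosages[:, j]
        y = simulate_phenotype(config, cohort.z, None, g=gj, seed=rng,
                               k_factor=k_fac)
        if y.min() == y.max():
            continue
        null_pql = None
        if any(m in methods for m in ("amle", "offset", "pql")):
            try:
                null_pql = fit_pql_null(y, x, k_analysis, tau0=tau_warm,
                                        tol=fit_tol)
                tau_warm = max(null_pql.tau, 1e-3)
            except ConvergenceError:
                null_pql = None
        for m in methods:
            try:
                if m == "amle":
                    if null_pql is None:
                        continue
                    p = amle_test(null_pql, gj).p
                elif m == "offset":
                    if null_pql is None:
                        continue
                    p = offset_test(null_pql, gj).p
                elif m == "pql":
                    if null_pql is None:
                        continue
                    _, _, p = fit_pql_snp(y, x, gj, k_analysis, tol=fit_tol)
                elif m == "lr":
                    p = lr_test(y, x, gj).p
                elif m == "mlm":
                    null_lmm = fit_lmm_null(y, x, k_analysis)
                    p = mlm_score_test(null_lmm, gj).p
                else:
                    raise ValueError(f"unknown method {m!r}")
            except (ValueError, ConvergenceError):
                continue
            n_ok[m] += 1
            hits[m] += p < config.alpha
    rows = []
    for m in methods:
        power = hits[m] / n_ok[m] if n_ok[m] else np.nan
        mc_se = np.sqrt(power * (1 - power) / n_ok[m]) if n_ok[m] else np.nan
        rows.append({"method": m, "power": power, "mc_se": mc_se,
                     "n_ok": n_ok[m], "n_replicates": config.n_replicates})
    return pd.DataFrame(rows)


SCENARIOS = {
    "A": {"p0": 0.10, "p1": 0.20, "tau": 0.3},
    "B": {"p0": 0.10, "p1": 0.20, "tau": 1.0},
    "C": {"p0": 0.05, "p1": 0.30, "tau": 0.3},
}
MAF_BINS = [(0.05, 0.10), (0.20, 0.25), (0.45, 0.50)]


def run_bias_experiment(
    cohort: Cohort,
    scenarios: dict[str, dict] = SCENARIOS,
    maf_bins: list[tuple[float, float]] = MAF_BINS,
    gammas: tuple[float, ...] = (np.log(1.5), np.log(2.0)),
    n_replicates: int = 100,
    methods: tuple[str, ...] = ("pql", "amle", "offset"),
    pcs: int = 10,
    seed: int | np.random.Generator = 0,
    fit_tol: float = 1e-4,
) -> pd.DataFrame:
    """Mean estimation bias of gamma_hat per method, scenario and MAF bin.

    For each condition, ``n_replicates`` phenotypes are drawn (random effects
    and causal SNP redrawn each time) and gamma is re-estimated; the table
    reports mean(gamma_hat - gamma) with its Monte-Carlo standard error and
    the count of failed replicates (dropped).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = cohort.genotypes
    n = g.n_samples
    maf = g.maf
    dosages = g.imputed()
    k_analysis = compute_grm(g)
    pcs_mat = compute_pcs(k_analysis, pcs) if pcs else None
    x = _design(n, pcs_mat)
    k_fac = kinship_factor(cohort.k_pheno)

    rows = []
    for name, sc in scenarios.items():
        for maf_bin in maf_bins:
            for gamma in gammas:
                config = SimulationConfig(p0=sc["p0"], p1=sc["p1"],
                                          tau=sc["tau"], gamma=gamma,
                                          maf_bin=tuple(maf_bin))
                est = {m: [] for m in methods}
                n_fail = 0
                tau_warm = max(sc["tau"] / 2.0, 0.05)
                for _ in range(n_replicates):
                    j = _draw_bin_snp(maf, config.maf_bin, rng)
                    gj = dosages[:, j]
                    y = simulate_phenotype(config, cohort.z, None, g=gj,
                                           seed=rng, k_factor=k_fac)
                    if y.min() == y.max():
                        n_fail += 1
                        continue
                    try:
                        null = fit_pql_null(y, x, k_analysis, tau0=tau_warm,
                                            tol=fit_tol)
                        tau_warm = max(null.tau, 1e-3)
                        for m in methods:
                            if m == "amle":
                                est[m].append(amle_test(null, gj).gamma_hat)
                            elif m == "offset":
                                est[m].append(offset_test(null, gj).gamma_hat)
                            elif m == "pql":
                                gam, _, _ = fit_pql_snp(y, x, gj, k_analysis,
                                                        tau0=tau_warm,
                                                        tol=fit_tol)
                                est[m].append(gam)
                            else:
                                raise ValueError(f"unknown method {m!r}")
                    except (ValueError, ConvergenceError):
                        n_fail += 1
                        continue
                for m in methods:
                    vals = np.asarray(est[m])
                    rows.append({
                        "scenario": name, "maf_lo": maf_bin[0],
                        "maf_hi": maf_bin[1], "gamma": gamma, "method": m,
                        "mean_bias": float(np.mean(vals - gamma)) if vals.size else np.nan,
                        "se_bias": float(np.std(vals - gamma, ddof=1)
                                         / np.sqrt(vals.size)) if vals.size > 1 else np.nan,
                        "n_ok": int(vals.size), "n_fail": n_fail,
                    })
    return pd.DataFrame(rows)
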