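"""Stratified QQ-plot diagnostics for population-structure correction.

When disease prevalence differs between population strata, a pooled QQ-plot
can look calibrated while subsets of variants are tested anti-conservatively
and others conservatively.  Variants are therefore classified by the ratio of
their genotype variances between strata, r(G) = var_1(G) / var_0(G), and the
QQ-plot is drawn per category.  The stratifying variable Z may be a binary
indicator (categories then use within-stratum allele frequencies) or any
vector with components in [0, 1] — e.g. a min-max rescaled principal
component when strata are unknown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .genotypes import GenotypeMatrix

__all__ = [
    "StrataVector",
    "CategoryAssignment",
    "snp_categories",
    "stratified_qq",
    "genomic_inflation",
    "plot_stratified_qq",
    "pc_strata",
]

CHI2_MEDIAN = float(chi2.ppf(0.5, 1))  # 0.454936...


@dataclass
class StrataVector:
    """Stratifying variable Z with components in [0, 1]."""

    z: np.ndarray
    kind: str = "indicator"

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float).ravel()
        if self.z.min() < 0 or self.z.max() > 1:
            raise ValueError("strata components must lie in [0, 1]")
        if self.z.min() == self.z.max():
            raise ValueError("strata vector is constant")
        if self.kind == "indicator" and not np.isin(self.z, (0.0, 1.0)).all():
            self.kind = "continuous"


def pc_strata(pc: np.ndarray) -> StrataVector:
    """Min-max rescale a principal component to [0, 1] for use as Z."""
    pc = np.asarray(pc, dtype=float).ravel()
    lo, hi = pc.min(), pc.max()
    if hi == lo:
        raise ValueError("constant principal component")
    return StrataVector((pc - lo) / (hi - lo), kind="continuous")


@dataclass
class CategoryAssignment:
    """Per-variant frequencies in the two (pseudo-)strata and category.

    Category 1: r < th (less variance in the high-risk stratum); category 2:
    th <= r <= 1/th; category 3: r > 1/th.  Category 0 marks variants
    monomorphic in both strata (excluded from the plots).
    """

    q0: np.ndarray
    q1: np.ndarray
    r: np.ndarray
    category: np.ndarray
    th: float


def snp_categories(g: GenotypeMatrix | np.ndarray, z: StrataVector | np.ndarray,
                   th: float = 0.8) -> CategoryAssignment:
    """Categorize variants by the between-strata genotype-variance ratio.

    q1 = Z'G / (2 Z'1), q0 = (1-Z)'G / (2 (1-Z)'1); under panmixia within
    stratum i the genotype variance is var_i = 2 p_i q_i with p_i = 1 - q_i,
    and r = var_1 / var_0.
    """
    if not 0.0 < th < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if not isinstance(z, StrataVector):
        z = StrataVector(np.asarray(z))
    dosages = g.imputed() if isinstance(g, GenotypeMatrix) else np.asarray(g, float)
    zv = z.z
    s1 = float(zv.sum())
    s0 = float((1.0 - zv).sum())
    if s1 == 0 or s0 == 0:
        raise ValueError("degenerate strata: one stratum has zero total weight")
    q1 = (zv @ dosages) / (2.0 * s1)
    q0 = ((1.0 - zv) @ dosages) / (2.0 * s0)
    var1 = 2.0 * q1 * (1.0 - q1)
    var0 = 2.0 * q0 * (1.0 - q0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = var1 / var0
    category = np.zeros(dosages.shape[1], dtype=int)
    both_poly = (var0 > 0) & (var1 > 0)
    category[both_poly & (r < th)] = 1
    category[both_poly & (r >= th) & (r <= 1.0 / th)] = 2
    category[both_poly & (r > 1.0 / th)] = 3
    # monomorphic in stratum 0 only: all the variance sits in stratum 1
    category[(var0 == 0) & (var1 > 0)] = 3
    category[(var1 == 0) & (var0 > 0)] = 1
    return CategoryAssignment(q0=q0, q1=q1, r=r, category=category, th=th)


def stratified_qq(pvalues: np.ndarray,
                  categories: CategoryAssignment | np.ndarray | None = None
                  ) -> pd.DataFrame:
    """Expected vs observed -log10 p per category, plus the pooled curve.

    Within each group the sorted observed -log10 p are paired with -log10 of
    the uniform order statistics i/(n+1).  Empty categories are omitted.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("no p-values")
    if np.nanmin(p) <= 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must be in (0, 1]")
    if categories is None:
        cat = np.full(p.size, 2)
    elif isinstance(categories, CategoryAssignment):
        cat = categories.category
    else:
        cat = np.asarray(categories)
    keep = np.isfinite(p)
    frames = []
    groups = [("all", keep)] + [
        (str(c), keep & (cat == c)) for c in (1, 2, 3)
    ]
    for label, mask in groups:
        pc = np.sort(p[mask])
        nc = pc.size
        if nc == 0:
            continue
        expected = -np.log10(np.arange(1, nc + 1) / (nc + 1.0))[::-1]
        observed = -np.log10(pc)[::-1]
        frames.append(pd.DataFrame(
            {"category": label, "expected": expected, "observed": observed}
        ))
    return pd.concat(frames, ignore_index=True)


def genomic_inflation(pvalues: np.ndarray) -> float:
    """Genomic-control lambda: median association chi2 over the null median.

    p-values are converted back to chi-square(1) quantiles; lambda is their
    median divided by chi2(1)'s median (~0.4549).
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values")
    if p.min() <= 0 or p.max() > 1:
        raise ValueError("p-values must be in (0, 1]")
    stats = chi2.isf(p, 1)
    return float(np.median(stats) / CHI2_MEDIAN)


def plot_stratified_qq(table: pd.DataFrame, path=None, title: str | None = None):
    """Render a stratified QQ-plot from :func:`stratified_qq` output.

    The pooled ("all") curve is drawn as the embedded reference in grey.
    Returns the matplotlib figure; saves to ``path`` if given.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    colors = {"1": "tab:blue", "2": "tab:green", "3": "tab:red", "all": "0.6"}
    for label, sub in table.groupby("category"):
        ax.plot(sub["expected"], sub["observed"], ".", ms=3,
                color=colors.get(label, "k"),
                label=f"category {label}" if label != "all" else "pooled")
    lim = max(table["expected"].max(), table["observed"].max()) * 1.05
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
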