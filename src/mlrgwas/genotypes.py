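"""Genotype containers, file I/O, allele frequencies, GRM and principal components.

Dosages are stored as a dense float matrix of alt-allele counts (0/1/2) with
``nan`` marking missing genotypes.  Variant metadata live in a pandas DataFrame
aligned with the matrix columns; sample identifiers align with the rows.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GRM",
    "read_genotypes",
    "write_genotypes",
    "filter_maf",
    "compute_grm",
    "compute_pcs",
    "read_grm",
    "write_grm",
]

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


class GenotypeParseError(ValueError):
    """Raised when an input file does not follow the declared format."""


@dataclass
class GenotypeMatrix:
    """n samples x m variants dosage matrix with aligned metadata.

    Parameters
    ----------
    dosages : ndarray of shape (n, m)
        Alt-allele counts in {0, 1, 2}; missing entries are ``nan``.
    samples : list of str
        Sample identifiers, one per row.
    variants : DataFrame
        One row per column with fields chrom, pos (1-based), id, ref, alt.
    """

    dosages: np.ndarray
    samples: list[str]
    variants: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample ids for {n} rows")
        if len(self.variants) != m:
            raise ValueError(f"{len(self.variants)} variant records for {m} columns")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing (nan)")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def alt_freq(self) -> np.ndarray:
        """Per-variant alt-allele frequency, ignoring missing genotypes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        """Per-variant minor allele frequency in [0, 0.5]."""
        p = self.alt_freq
        return np.minimum(p, 1.0 - p)

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the column mean."""
        x = self.dosages.copy()
        if np.isnan(x).any():
            col_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(x))
            x[idx] = col_mean[idx[1]]
        return x

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, index],
            list(self.samples),
            self.variants.iloc[np.asarray(index)].reset_index(drop=True),
        )


@dataclass
class GRM:
    """Symmetric n x n relatedness matrix with aligned sample identifiers.

    ``source`` tags provenance: "genotype" (empirical GRM), "pedigree"
    (K = 2*kinship) or "user".
    """

    matrix: np.ndarray
    samples: list[str]
    source: str = "user"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("GRM must be square")
        if len(self.samples) != n:
            raise ValueError("sample ids must match GRM dimension")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes from VCF, PLINK BED or a plain dosage-matrix file.

    ``format`` is one of "vcf", "plink_bed", "matrix"; when omitted it is
    guessed from the file extension (.vcf/.vcf.gz, .bed, anything else =
    matrix).
    """
    path = Path(path)
    if format is None:
        name = path.name.lower()
        if name.endswith((".vcf", ".vcf.gz")):
            format = "vcf"
        elif name.endswith(".bed"):
            format = "plink_bed"
        else:
            format = "matrix"
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink_bed":
        return _read_plink_bed(path)
    if format == "matrix":
        return _read_matrix(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosages: list[np.ndarray] = []
    records = []
    for i, rec in enumerate(vcf):
        gts = rec.genotype.array()  # (n, ploidy+1), -1 = missing
        alleles = gts[:, :-1]
        if alleles.shape[1] != 2:
            raise GenotypeParseError(
                f"record {i} ({rec.CHROM}:{rec.POS}): only diploid GT supported"
            )
        miss = (alleles < 0).any(axis=1)
        dos = np.clip(alleles, 0, None).sum(axis=1).astype(float)
        dos[miss] = np.nan
        dosages.append(dos)
        alt = rec.ALT[0] if rec.ALT else "."
        records.append((rec.CHROM, rec.POS, rec.ID or f"var{i}", rec.REF, alt))
    vcf.close()
    variants = pd.DataFrame(records, columns=VARIANT_COLUMNS)
    mat = np.column_stack(dosages) if dosages else np.empty((len(samples), 0))
    return GenotypeMatrix(mat, samples, variants)


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write an uncompressed VCF 4.2 with GT fields only."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.samples) + "\n")
        code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, v in g.variants.iterrows():
            gts = [
                "./." if np.isnan(d) else code[d] for d in g.dosages[:, j]
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def _read_matrix(path: Path) -> GenotypeMatrix:
    """Whitespace-delimited dosage matrix.

    First (header) line: ``id chrom pos ref alt`` followed by the sample ids;
    each following line is one variant: the five metadata fields then one
    dosage (0/1/2 or NA) per sample.
    """
    if not path.exists():
        raise FileNotFoundError(path)
    with Path(path).open() as fh:
        header = fh.readline().split()
        if len(header) < 6 or header[0].lstrip("#") != "id":
            raise GenotypeParseError(f"{path}: bad matrix header")
        samples = header[5:]
        rows, records = [], []
        for ln, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 5 + len(samples):
                raise GenotypeParseError(f"{path}: line {ln}: wrong field count")
            vid, chrom, pos, ref, alt = parts[:5]
            try:
                dos = [np.nan if t in ("NA", ".") else float(t) for t in parts[5:]]
            except ValueError as exc:
                raise GenotypeParseError(f"{path}: line {ln}: {exc}") from exc
            rows.append(dos)
            records.append((chrom, int(pos), vid, ref, alt))
    variants = pd.DataFrame(records, columns=VARIANT_COLUMNS)
    mat = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(mat, samples, variants)


def write_matrix(g: GenotypeMatrix, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("id chrom pos ref alt " + " ".join(g.samples) + "\n")
        for j, v in g.variants.iterrows():
            dos = [
                "NA" if np.isnan(d) else str(int(d)) for d in g.dosages[:, j]
            ]
            fh.write(f"{v.id} {v.chrom} {v.pos} {v.ref} {v.alt} " + " ".join(dos) + "\n")


_BED_MAGIC = b"\x6c\x1b\x01"  # SNP-major
# 2-bit PLINK codes -> dosage of the A1 (minor, by convention alt) allele
_BED_CODE = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}


def _read_plink_bed(path: Path) -> GenotypeMatrix:
    """Variant-major PLINK 1 .bed with companion .bim and .fam."""
    stem = path.with_suffix("")
    bim = stem.with_suffix(".bim")
    fam = stem.with_suffix(".fam")
    for p in (path, bim, fam):
        if not p.exists():
            raise FileNotFoundError(p)
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None)
    samples = fam_df[1].astype(str).tolist()
    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
    )
    n, m = len(samples), len(bim_df)
    raw = path.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise GenotypeParseError(f"{path}: not a SNP-major PLINK .bed file")
    bytes_per_var = (n + 3) // 4
    body = raw[3:]
    if len(body) < m * bytes_per_var:
        raise GenotypeParseError(f"{path}: truncated .bed body")
    lut = np.full((256, 4), np.nan)
    for b in range(256):
        for k in range(4):
            lut[b, k] = _BED_CODE[(b >> (2 * k)) & 0b11]
    arr = np.frombuffer(body[: m * bytes_per_var], dtype=np.uint8)
    arr = arr.reshape(m, bytes_per_var)
    dosages = lut[arr].reshape(m, -1)[:, :n].T
    variants = pd.DataFrame(
        {
            "chrom": bim_df["chrom"].astype(str),
            "pos": bim_df["pos"].astype(int),
            "id": bim_df["id"].astype(str),
            "ref": bim_df["a2"].astype(str),
            "alt": bim_df["a1"].astype(str),
        }
    )
    return GenotypeMatrix(dosages, samples, variants)


def write_plink_bed(g: GenotypeMatrix, path: str | Path) -> None:
    """Write PLINK 1 .bed/.bim/.fam (variant-major); alt allele stored as A1."""
    path = Path(path)
    stem = path.with_suffix("")
    n = g.n_samples
    rev = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
    with path.open("wb") as fh:
        fh.write(_BED_MAGIC)
        bytes_per_var = (n + 3) // 4
        for j in range(g.n_variants):
            buf = bytearray(bytes_per_var)
            for i, d in enumerate(g.dosages[:, j]):
                code = 0b01 if np.isnan(d) else rev[d]
                buf[i // 4] |= code << (2 * (i % 4))
            fh.write(bytes(buf))
    with stem.with_suffix(".bim").open("w") as fh:
        for _, v in g.variants.iterrows():
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\t{v.alt}\t{v.ref}\n")
    with stem.with_suffix(".fam").open("w") as fh:
        for s in g.samples:
            fh.write(f"{s} {s} 0 0 0 -9\n")


def write_genotypes(g: GenotypeMatrix, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        name = path.name.lower()
        format = "vcf" if name.endswith(".vcf") else "plink_bed" if name.endswith(".bed") else "matrix"
    if format == "vcf":
        write_vcf(g, path)
    elif format == "plink_bed":
        write_plink_bed(g, path)
    elif format == "matrix":
        write_matrix(g, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def read_grm(path: str | Path) -> GRM:
    """Square delimited GRM: header = sample ids, one row per sample."""
    df = pd.read_csv(path, sep=r"\s+")
    samples = list(df.columns)
    return GRM(df.to_numpy(dtype=float), samples, source="user")


def write_grm(k: GRM, path: str | Path) -> None:
    pd.DataFrame(k.matrix, columns=k.samples).to_csv(path, sep=" ", index=False)


# ---------------------------------------------------------------------------
# frequency filtering, GRM, PCs
# ---------------------------------------------------------------------------

def filter_maf(g: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Keep variants with minor allele frequency >= threshold."""
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must be in [0, 0.5]")
    maf = g.maf
    # threshold 0 keeps every polymorphic variant; monomorphic are never kept
    keep = np.where((maf >= threshold) & (maf > 0.0))[0]
    return g.take_variants(keep)


def compute_grm(g: GenotypeMatrix) -> GRM:
    """Empirical genomic relationship matrix from standardized dosages.

    K[i,j] = (1/m) sum_s (g_is - 2 p_s)(g_js - 2 p_s) / (2 p_s (1 - p_s)),
    with p_s the sample alt-allele frequency; monomorphic variants are
    excluded from both the sum and m.  Missing dosages are mean-imputed.
    """
    x = g.imputed()
    p = x.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("no polymorphic variants: cannot compute a GRM")
    x = x[:, poly]
    p = p[poly]
    z = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    k = (z @ z.T) / z.shape[1]
    k = (k + k.T) / 2.0
    return GRM(k, list(g.samples), source="genotype")


def compute_pcs(k: GRM | np.ndarray, n_components: int) -> np.ndarray:
    """Top eigenvectors of the GRM, unit norm, by decreasing eigenvalue.

    The sign of each component is fixed so its largest-magnitude loading is
    positive.
    """
    mat = k.matrix if isinstance(k, GRM) else np.asarray(k, dtype=float)
    n = mat.shape[0]
    if not 1 <= n_components <= n:
        raise ValueError(f"n_components must be in [1, {n}]")
    vals, vecs = np.linalg.eigh(mat)
    order = np.argsort(vals)[::-1][:n_components]
    v = vecs[:, order]
    for j in range(v.shape[1]):
        i = np.argmax(np.abs(v[:, j]))
        if v[i, j] < 0:
            v[:, j] = -v[:, j]
    return v
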