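"""Genotype container, SNP quality control and genomic relatedness matrices.

QC follows the usual array pipeline for common variants: drop SNPs with
minor allele frequency < 1%, missing rate > 3% or Hardy-Weinberg
disequilibrium at p < 1e-6.  The IBS relatedness matrix is the average
over SNPs of products of standardized dosages (the GCTA estimator); the
IBD-flavoured matrix zeroes every off-diagonal entry below 0.05 so that
it carries only within-family genome sharing.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.linalg import eigsh
from scipy.stats import chi2

__all__ = [
    "GenotypeMatrix",
    "QCConfig",
    "GRM",
    "hwe_test",
    "qc_filter",
    "compute_grm",
    "make_ibd_matrix",
    "grm_pca",
    "read_vcf",
    "write_vcf",
    "read_raw",
    "write_raw",
    "write_grm",
    "read_grm",
]


@dataclass
class GenotypeMatrix:
    """Additive dosages for n individuals x m SNPs.

    ``dosages`` counts copies of the effect allele (a1), entries in
    {0, 1, 2} or NaN for missing.  SNP metadata lives in ``snps``
    (columns id, chrom, pos, a1, a2), 1-based positions as in VCF.
    """

    samples: list
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, float)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError("dosage matrix shape does not match samples/snps")
        for _, grp in self.snps.groupby("chrom"):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("positions must be non-decreasing within chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def allele_freq(self) -> np.ndarray:
        """Effect-allele frequency per SNP, over non-missing entries."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def genotype_counts(self) -> np.ndarray:
        """(m, 3) counts of dosage 0/1/2 per SNP (missing excluded)."""
        d = self.dosages
        return np.stack([np.nansum(d == k, axis=0) for k in (0, 1, 2)], axis=1)


@dataclass
class QCConfig:
    maf_min: float = 0.01
    missing_max: float = 0.03
    hwe_p_min: float = 1e-6
    n_pcs: int = 20

    def __post_init__(self) -> None:
        for name in ("maf_min", "missing_max", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be >= 0")


@dataclass
class GRM:
    """Symmetric relatedness matrix with the SNP count behind each entry."""

    ids: list
    matrix: np.ndarray
    snp_counts: np.ndarray
    flavor: str = "IBS"

    @property
    def n(self) -> int:
        return len(self.ids)


def hwe_test(counts) -> float:
    """Chi-square (1 df) Hardy-Weinberg test from genotype counts (n0, n1, n2).

    Monomorphic SNPs return p = 1 by convention.
    """
    n0, n1, n2 = (float(c) for c in counts)
    n = n0 + n1 + n2
    if n <= 0:
        raise ValueError("no genotype observations")
    p = (n1 + 2 * n2) / (2 * n)
    if p <= 0.0 or p >= 1.0:
        return 1.0
    exp = np.array([n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p**2])
    obs = np.array([n0, n1, n2])
    stat = np.sum((obs - exp) ** 2 / exp)
    return float(chi2.sf(stat, df=1))


def qc_filter(G: GenotypeMatrix, cfg: QCConfig | None = None):
    """Apply MAF / missingness / HWE filters; returns (filtered, counts).

    A SNP failing several rules is attributed to the first failing rule
    in the order maf, missing, hwe.
    """
    cfg = cfg or QCConfig()
    freq = G.allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    miss = G.missing_rate()
    hwe_p = np.array([hwe_test(c) for c in G.genotype_counts()])

    fail_maf = (maf < cfg.maf_min) | np.isnan(maf)
    fail_miss = miss > cfg.missing_max
    fail_hwe = hwe_p < cfg.hwe_p_min
    counts = {
        "maf": int(np.sum(fail_maf)),
        "missing": int(np.sum(fail_miss & ~fail_maf)),
        "hwe": int(np.sum(fail_hwe & ~fail_maf & ~fail_miss)),
    }
    keep = ~(fail_maf | fail_miss | fail_hwe)
    if not keep.any():
        raise ValueError("all SNPs removed by QC")
    out = GenotypeMatrix(
        samples=list(G.samples),
        snps=G.snps.loc[keep].reset_index(drop=True),
        dosages=G.dosages[:, keep],
    )
    return out, counts


def compute_grm(G: GenotypeMatrix) -> GRM:
    """IBS relatedness: mean over SNPs of (x_j-2p)(x_k-2p)/(2p(1-p)).

    Missing dosages are handled pairwise-complete: each entry averages
    over the SNPs observed in both individuals, and the per-entry SNP
    count is retained.  SNPs fixed in the sample are excluded.
    """
    freq = G.allele_freq()
    usable = (freq > 0.0) & (freq < 1.0)
    if not usable.all():
        warnings.warn(f"excluding {int((~usable).sum())} fixed SNPs from GRM",
                      RuntimeWarning)
    X = G.dosages[:, usable]
    p = freq[usable]
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    miss = np.isnan(Z)
    if miss.any():
        Z = np.where(miss, 0.0, Z)
        obs = (~miss).astype(float)
        counts = obs @ obs.T
    else:
        counts = np.full((G.n_samples, G.n_samples), Z.shape[1], float)
    A = (Z @ Z.T) / np.maximum(counts, 1.0)
    A = 0.5 * (A + A.T)
    return GRM(ids=list(G.samples), matrix=A, snp_counts=counts, flavor="IBS")


def make_ibd_matrix(grm: GRM, threshold: float = 0.05) -> GRM:
    """IBD-flavoured matrix: off-diagonal relatedness below 0.05 set to 0."""
    A = grm.matrix.copy()
    off = ~np.eye(grm.n, dtype=bool)
    A[off & (A < threshold)] = 0.0
    return GRM(ids=list(grm.ids), matrix=A, snp_counts=grm.snp_counts.copy(),
               flavor="IBD")


def grm_pca(grm: GRM, n_pcs: int) -> np.ndarray:
    """Top principal component scores (eigenvectors scaled by sqrt eigenvalue).

    Sign convention: the largest-magnitude loading of each component is
    positive, so results are reproducible across runs and libraries.
    """
    n = grm.n
    if n_pcs > n:
        raise ValueError(f"n_pcs={n_pcs} exceeds {n} individuals")
    if n_pcs == 0:
        return np.empty((n, 0))
    A = 0.5 * (grm.matrix + grm.matrix.T)
    if n > 200 and n_pcs < n // 5:
        v0 = np.full(n, 1.0 / np.sqrt(n))
        vals, vecs = eigsh(A, k=n_pcs, which="LA", v0=v0)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
    else:
        vals, vecs = np.linalg.eigh(A)
        vals, vecs = vals[::-1][:n_pcs], vecs[:, ::-1][:, :n_pcs]
    vals = np.maximum(vals, 0.0)
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vecs * np.sqrt(vals)


# ---------------------------------------------------------------------------
# file formats

def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Minimal VCF 4.2 with GT genotypes; a1 is written as ALT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = G.snps["chrom"].astype(str).unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in G.samples) + "\n")
        code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, rec in enumerate(G.snps.itertuples(index=False)):
            col = G.dosages[:, j]
            gts = [code.get(d, "./.") if not np.isnan(d) else "./." for d in col]
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.id}\t{rec.a2}\t{rec.a1}"
                     f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


def read_vcf(path: str) -> GenotypeMatrix:
    """Read GT dosages from a (plain or bgzipped) VCF via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    ids, chroms, poss, a1s, a2s, rows = [], [], [], [], [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        a2s.append(var.REF)
        a1s.append(var.ALT[0] if var.ALT else ".")
        # gt_types: 0=hom ref, 1=het, 2=hom alt (gts012), 3=missing
        g = np.asarray(var.gt_types, float)
        g[g == 3] = np.nan
        rows.append(g)
    vcf.close()
    snps = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss,
                         "a1": a1s, "a2": a2s})
    dos = np.array(rows).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(samples=samples, snps=snps, dosages=dos)


def write_raw(G: GenotypeMatrix, path: str) -> None:
    """PLINK-.raw-style additive dosage text (effect-allele counts)."""
    cols = [f"{r.id}_{r.a1}" for r in G.snps.itertuples(index=False)]
    df = pd.DataFrame(G.dosages, columns=cols)
    df.insert(0, "IID", G.samples)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_raw(path: str, snps: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a .raw-style dosage table; SNP metadata optional.

    Without a metadata table, chromosome/position default to a single
    pseudo-chromosome with SNPs in file order.
    """
    df = pd.read_csv(path, sep="\t")
    samples = df["IID"].tolist()
    dos = df.drop(columns=["IID"]).to_numpy(float)
    if snps is None:
        names = [c.rsplit("_", 1) for c in df.columns if c != "IID"]
        snps = pd.DataFrame({
            "id": [n[0] for n in names],
            "chrom": "1",
            "pos": np.arange(1, len(names) + 1),
            "a1": [n[1] if len(n) > 1 else "A" for n in names],
            "a2": "N",
        })
    return GenotypeMatrix(samples=samples, snps=snps, dosages=dos)


def write_grm(grm: GRM, prefix: str, gz: bool = False) -> None:
    """GCTA text-triplet convention: index1 index2 snp-count value (+ .id)."""
    opener = gzip.open if gz else open
    suffix = ".grm.gz" if gz else ".grm"
    with opener(prefix + suffix, "wt") as fh:
        for i in range(grm.n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{int(grm.snp_counts[i, j])}"
                         f"\t{grm.matrix[i, j]:.6g}\n")
    with open(prefix + ".grm.id", "w") as fh:
        for s in grm.ids:
            fh.write(f"{s}\t{s}\n")


def read_grm(prefix: str, flavor: str = "IBS") -> GRM:
    ids = [line.split()[1] for line in open(prefix + ".grm.id")]
    n = len(ids)
    A = np.zeros((n, n))
    cnt = np.zeros((n, n))
    try:
        fh = open(prefix + ".grm")
    except FileNotFoundError:
        fh = gzip.open(prefix + ".grm.gz", "rt")
    with fh:
        for line in fh:
            i, j, m, v = line.split()
            i, j = int(i) - 1, int(j) - 1
            A[i, j] = A[j, i] = float(v)
            cnt[i, j] = cnt[j, i] = float(m)
    return GRM(ids=ids, matrix=A, snp_counts=cnt, flavor=flavor)
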