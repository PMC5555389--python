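"""Synthetic twin cohorts under a known sexual-dimorphism liability model.

Two generators are provided.  The path-coefficient generator draws pair
liabilities directly from the bivariate normal implied by the ACDE
variance proportions and the cross-sex genetic correlation; it is what
the twin-model machinery is tested against.  The genotype-driven
generator simulates SNPs through two parents per family (MZ co-twins
get identical genotypes) and builds the liability from causal SNP
effects plus a pedigree-correlated family component, for the GREML and
polygenic-score stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .grm import GenotypeMatrix
from .pair_stats import threshold_from_prevalence

__all__ = [
    "CohortSpec",
    "GenoSpec",
    "DEFAULT_GROUP_SIZES",
    "simulate_twin_cohort",
    "simulate_genotypes",
    "attach_genetic_liability",
    "simulate_sumstats",
    "write_phenotypes",
    "write_sumstats",
]

# complete-pair counts of the study sample (female MZ/DZ, male MZ/DZ,
# opposite-sex)
DEFAULT_GROUP_SIZES = {
    "MZ-f": 513,
    "DZ-f": 814,
    "MZ-m": 513,
    "DZ-m": 549,
    "OS": 1223,
}

_GROUP_SEXES = {
    "MZ-f": ("female", "female"),
    "DZ-f": ("female", "female"),
    "MZ-m": ("male", "male"),
    "DZ-m": ("male", "male"),
    "OS": ("male", "female"),
}


@dataclass
class CohortSpec:
    """Generating conditions for a path-coefficient twin cohort.

    Defaults are the study conditions: the observed complete-pair group
    sizes, AE architecture with heritability 0.474 in both sexes, no
    shared environment or dominance, independent male/female genetic
    effects (rg_os = 0), prevalences 0.126 (women) / 0.143 (men), birth
    years 1911-1958 and a 43% singleton share (2718 of 6330 families).
    """

    n_pairs_by_group: dict = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    h2_f: float = 0.474
    h2_m: float = 0.474
    c2_f: float = 0.0
    c2_m: float = 0.0
    d2_f: float = 0.0
    d2_m: float = 0.0
    rg_os: float = 0.0
    prevalence_f: float = 0.126
    prevalence_m: float = 0.143
    birth_year_range: tuple = (1911, 1958)
    birth_year_effect: float = 0.0
    edu_mean: float = 11.0
    edu_sd: float = 3.0
    edu_liability_coef: float = 0.0
    singleton_fraction: float = 0.43
    seed: int = 0

    def __post_init__(self) -> None:
        for sex in ("f", "m"):
            comps = {k: getattr(self, f"{k}_{sex}") for k in ("h2", "c2", "d2")}
            if any(v < 0 for v in comps.values()) or sum(comps.values()) > 1 + 1e-12:
                raise ValueError(
                    f"variance components for sex {sex!r} must be >= 0 and "
                    f"sum to <= 1 (got {comps})")
        if not -1.0 <= self.rg_os <= 1.0:
            raise ValueError("rg_os must lie in [-1, 1]")
        for k in (self.prevalence_f, self.prevalence_m):
            if not 0.0 < k < 1.0:
                raise ValueError("prevalences must lie in (0, 1)")
        if not 0.0 <= self.singleton_fraction < 1.0:
            raise ValueError("singleton_fraction must lie in [0, 1)")

    def e2(self, sex: str) -> float:
        s = "f" if sex.startswith("f") else "m"
        return 1.0 - getattr(self, f"h2_{s}") - getattr(self, f"c2_{s}") \
            - getattr(self, f"d2_{s}")

    def pair_correlation(self, group: str) -> float:
        """Liability correlation implied by the path coefficients.

        A correlates 1 (MZ), 0.5 (same-sex DZ) and rg_os (OS, replacing
        the 0.5 as in the sex-limitation parameterization); C correlates
        1 everywhere; D correlates 1 (MZ) and 0.25 (DZ and OS).
        """
        if group == "OS":
            af, am = np.sqrt(self.h2_f), np.sqrt(self.h2_m)
            cf, cm = np.sqrt(self.c2_f), np.sqrt(self.c2_m)
            df_, dm = np.sqrt(self.d2_f), np.sqrt(self.d2_m)
            return self.rg_os * af * am + cf * cm + 0.25 * df_ * dm
        s = "f" if group.endswith("f") else "m"
        h2, c2, d2 = (getattr(self, f"{k}_{s}") for k in ("h2", "c2", "d2"))
        if group.startswith("MZ"):
            return h2 + c2 + d2
        return 0.5 * h2 + c2 + 0.25 * d2

    def threshold(self, sex: str) -> float:
        K = self.prevalence_f if sex == "female" else self.prevalence_m
        return threshold_from_prevalence(K)


def simulate_twin_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a twin cohort from the path-coefficient liability model.

    Returns one row per individual with columns family_id,
    individual_id, sex, zygosity, pair_type, birth_year,
    education_years, childless, liability.  Co-twins share the birth
    year; a ``singleton_fraction`` share of pairs loses one member at
    random.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.birth_year_range
    by_center = 0.5 * (lo + hi)
    frames = []
    fam = 0
    for group, n_pairs in spec.n_pairs_by_group.items():
        if n_pairs == 0:
            continue
        r = spec.pair_correlation(group)
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"pair correlation {r} outside [-1, 1] for {group}")
        z = rng.standard_normal((n_pairs, 2))
        liab = np.empty_like(z)
        liab[:, 0] = z[:, 0]
        liab[:, 1] = r * z[:, 0] + np.sqrt(max(1.0 - r * r, 0.0)) * z[:, 1]
        by = rng.integers(lo, hi + 1, size=n_pairs)
        sexes = _GROUP_SEXES[group]
        zyg = "MZ" if group.startswith("MZ") else "DZ"
        drop = rng.random(n_pairs) < spec.singleton_fraction
        which = rng.integers(0, 2, size=n_pairs)
        edu = rng.normal(spec.edu_mean, spec.edu_sd, size=(n_pairs, 2))
        if spec.edu_liability_coef != 0.0:
            edu = edu + spec.edu_liability_coef * liab * spec.edu_sd

        fids = np.array([f"F{fam + i + 1:05d}" for i in range(n_pairs)])
        fam += n_pairs
        thr = np.column_stack([
            np.full(n_pairs, spec.threshold(sexes[0])),
            np.full(n_pairs, spec.threshold(sexes[1])),
        ]) - spec.birth_year_effect * (by - by_center)[:, None]
        keep = np.ones((n_pairs, 2), bool)
        keep[np.arange(n_pairs)[drop], which[drop]] = False
        member = np.tile([1, 2], n_pairs)
        flat = keep.ravel()
        frames.append(pd.DataFrame({
            "family_id": np.repeat(fids, 2)[flat],
            "individual_id": np.char.add(
                np.repeat(fids, 2), np.where(member == 1, "_1", "_2"))[flat],
            "sex": np.tile(sexes, n_pairs)[flat],
            "zygosity": zyg,
            "pair_type": group,
            "birth_year": np.repeat(by, 2)[flat].astype(int),
            "education_years": np.maximum(edu.ravel(), 0.0)[flat],
            "childless": (liab.ravel() > thr.ravel()).astype(int)[flat],
            "liability": liab.ravel()[flat],
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass
class GenoSpec:
    """Generating conditions for SNP genotypes and genotype-driven liability.

    ``h2_snp_*`` is the liability variance carried by the causal SNPs
    per sex, ``h2_extra_*`` a residual familial-additive component that
    co-twins share with pedigree correlation (1 for MZ, 0.5 otherwise) -
    the part of narrow-sense heritability not tagged by the array.
    ``rg_snp`` correlates the male and female causal effect vectors.
    """

    n_snps: int = 5000
    maf_range: tuple = (0.05, 0.5)
    n_causal: int = 1000
    h2_snp_f: float = 0.35
    h2_snp_m: float = 0.35
    h2_extra_f: float = 0.0
    h2_extra_m: float = 0.0
    rg_snp: float = 1.0
    chrom_length: int = 250_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if not 0.0 < self.maf_range[0] <= self.maf_range[1] <= 0.5:
            raise ValueError("maf_range must lie within (0, 0.5]")
        for v in (self.h2_snp_f, self.h2_snp_m, self.h2_extra_f, self.h2_extra_m):
            if not 0.0 <= v <= 1.0:
                raise ValueError("variance fractions must lie in [0, 1]")
        if self.h2_snp_f + self.h2_extra_f > 1 or self.h2_snp_m + self.h2_extra_m > 1:
            raise ValueError("per-sex genetic variance exceeds 1")
        if not -1.0 <= self.rg_snp <= 1.0:
            raise ValueError("rg_snp must lie in [-1, 1]")


def simulate_genotypes(cohort: pd.DataFrame, spec: GenoSpec) -> GenotypeMatrix:
    """SNP dosages for a cohort: MZ co-twins identical, DZ/OS by transmission.

    Each family gets two simulated parents; every non-MZ child draws one
    allele per parent per SNP (expected sharing 0.5 between sibs).
    SNPs are unlinked with allele frequencies uniform on ``maf_range``.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.n_snps
    p = rng.uniform(*spec.maf_range, size=m)
    pos = np.sort(rng.choice(spec.chrom_length, size=m, replace=False)) + 1
    snps = pd.DataFrame({
        "id": [f"rs{j + 1}" for j in range(m)],
        "chrom": "1",
        "pos": pos,
        "a1": "A",
        "a2": "G",
    })

    fams = cohort.groupby("family_id", sort=True)
    fam_ids = list(fams.groups)
    n_fam = len(fam_ids)
    # parental haplotypes per family
    hap = rng.random((n_fam, 4, m)) < p  # mother x2, father x2
    sample_ids, rows = [], []
    for fi, fid in enumerate(fam_ids):
        members = fams.get_group(fid).sort_values("individual_id")
        mz = (members["zygosity"] == "MZ").all()
        picks = []
        for k in range(len(members)):
            if mz and k > 0:
                picks.append(picks[0])
            else:
                mom = rng.random(m) < 0.5
                dad = rng.random(m) < 0.5
                picks.append((mom, dad))
        for (mom, dad), iid in zip(picks, members["individual_id"]):
            g = (np.where(mom, hap[fi, 0], hap[fi, 1]).astype(np.int8)
                 + np.where(dad, hap[fi, 2], hap[fi, 3]).astype(np.int8))
            sample_ids.append(iid)
            rows.append(g)
    dos = np.asarray(rows, float)
    return GenotypeMatrix(samples=sample_ids, snps=snps, dosages=dos)


def attach_genetic_liability(
    cohort: pd.DataFrame,
    genotypes: GenotypeMatrix,
    spec: GenoSpec,
    prevalence_f: float = 0.126,
    prevalence_m: float = 0.143,
    birth_year_effect: float = 0.0,
) -> pd.DataFrame:
    """Rebuild liabilities from causal SNPs and re-threshold the trait.

    liability = SNP score + family component + residual, with the SNP
    score scaled to variance ``h2_snp`` within each sex and male/female
    causal effect vectors correlated at ``rg_snp``.  Returns a copy of
    the cohort aligned to the genotype sample order.
    """
    rng = np.random.default_rng(spec.seed + 1)
    cohort = (cohort.set_index("individual_id")
              .loc[genotypes.samples].reset_index())
    n = len(cohort)
    causal = rng.choice(spec.n_snps, size=spec.n_causal, replace=False)
    b = rng.multivariate_normal(
        [0.0, 0.0], [[1.0, spec.rg_snp], [spec.rg_snp, 1.0]], size=spec.n_causal)
    X = genotypes.dosages[:, causal]
    p = X.mean(axis=0) / 2.0
    Z = (X - 2 * p) / np.sqrt(np.maximum(2 * p * (1 - p), 1e-12))
    raw = Z @ b  # (n, 2): female-effect score, male-effect score

    is_f = (cohort["sex"] == "female").to_numpy()
    score = np.where(is_f, raw[:, 0], raw[:, 1])
    # scale the SNP component to its target variance per sex
    for mask, h2 in ((is_f, spec.h2_snp_f), (~is_f, spec.h2_snp_m)):
        if mask.any():
            sd = score[mask].std()
            score[mask] *= np.sqrt(h2) / max(sd, 1e-12)

    # pedigree-correlated familial component (MZ share fully, DZ/OS half)
    fam_codes, fam_idx = np.unique(cohort["family_id"], return_inverse=True)
    shared = rng.standard_normal(len(fam_codes))[fam_idx]
    unique = rng.standard_normal(n)
    mz = (cohort["zygosity"] == "MZ").to_numpy()
    rho_fam = np.where(mz, 1.0, 0.5)
    fam_eff = np.sqrt(rho_fam) * shared + np.sqrt(1 - rho_fam) * unique
    h2_extra = np.where(is_f, spec.h2_extra_f, spec.h2_extra_m)
    e2 = 1.0 - np.where(is_f, spec.h2_snp_f + spec.h2_extra_f,
                        spec.h2_snp_m + spec.h2_extra_m)
    liab = score + np.sqrt(h2_extra) * fam_eff \
        + np.sqrt(e2) * rng.standard_normal(n)

    by = cohort["birth_year"].to_numpy(float)
    t = np.where(is_f,
                 threshold_from_prevalence(prevalence_f),
                 threshold_from_prevalence(prevalence_m))
    t = t - birth_year_effect * (by - by.mean())
    out = cohort.copy()
    out["liability"] = liab
    out["childless"] = (liab > t).astype(int)
    out.attrs["causal_snps"] = causal
    out.attrs["causal_betas"] = b
    return out


def simulate_sumstats(
    genotypes: GenotypeMatrix,
    true_beta: np.ndarray,
    n_gwas: int = 250_000,
    seed: int = 0,
) -> pd.DataFrame:
    """GWAS-style summary statistics for a standardized source trait.

    Per SNP, the reported beta is the true per-allele effect plus noise
    with standard error 1/sqrt(n * 2p(1-p)); the p-value is the
    two-sided normal test of beta/se.
    """
    true_beta = np.asarray(true_beta, float)
    if true_beta.shape[0] != genotypes.n_snps:
        raise ValueError("true_beta must align with the SNP table")
    rng = np.random.default_rng(seed)
    p = genotypes.allele_freq()
    se = 1.0 / np.sqrt(n_gwas * np.maximum(2 * p * (1 - p), 1e-12))
    beta = true_beta + rng.normal(0.0, se)
    zstat = beta / se
    pval = np.clip(2 * norm.sf(np.abs(zstat)), 1e-300, 1.0)
    out = genotypes.snps.rename(columns=str.upper)[["ID", "CHROM", "POS", "A1", "A2"]]
    out = out.rename(columns={"ID": "SNP", "CHROM": "CHR"})
    out["BETA"] = beta
    out["SE"] = se
    out["P"] = pval
    return out


def write_phenotypes(cohort: pd.DataFrame, path: str) -> None:
    cols = ["family_id", "individual_id", "sex", "zygosity", "pair_type",
            "birth_year", "education_years", "childless"]
    cohort[cols].to_csv(path, sep="\t", index=False)


def write_sumstats(stats: pd.DataFrame, path: str) -> None:
    stats.to_csv(path, sep="\t", index=False)
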