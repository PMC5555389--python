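"""Polygenic scores by greedy LD clumping and p-value thresholding,
and logistic sex-interaction models of the binary outcome.

Clumping mirrors the PRSice/PLINK rule: accept SNPs in order of
ascending p-value and discard any not-yet-accepted SNP on the same
chromosome within 250 kb of, or with squared dosage correlation >= 0.1
against, an accepted one.  Scores are effect-allele dosage sums
weighted by the summary-statistic betas, standardized in the analysis
sample.  The interaction model is
outcome ~ PGS + sex + PGS x sex + birth year + education
on one member per family (sex coded women = 0, men = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .grm import GenotypeMatrix

__all__ = [
    "ScoreSpec",
    "PGSResult",
    "LogisticFit",
    "clump",
    "score",
    "select_one_per_family",
    "logistic_interaction_fit",
    "sex_specific_or",
    "pgs_model_table",
]

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class ScoreSpec:
    p_thresholds: tuple = (5e-8, 0.05, 0.5, 1.0)
    ld_r2_max: float = 0.1
    clump_distance: int = 250_000

    def __post_init__(self) -> None:
        self.p_thresholds = tuple(sorted(self.p_thresholds))


@dataclass
class PGSResult:
    threshold: float
    snps: list
    raw: np.ndarray
    standardized: np.ndarray
    n_dropped_ambiguous: int = 0


@dataclass
class LogisticFit:
    """Odds ratios, Wald CIs and p-values per model term."""

    terms: list
    odds_ratio: dict
    ci_low: dict
    ci_high: dict
    p_value: dict
    coef: dict
    cov_params: pd.DataFrame
    n: int
    converged: bool


def clump(stats: pd.DataFrame, reference: GenotypeMatrix,
          spec: ScoreSpec | None = None) -> list:
    """Greedy p-value clumping against a genotype reference panel.

    Returns the retained SNP ids.  SNPs absent from the reference are
    dropped with a warning; p-value ties break toward the smaller
    genomic position.  LD r2 is computed on the reference dosages,
    pairwise-complete over missing genotypes.
    """
    spec = spec or ScoreSpec()
    ref_ids = {s: j for j, s in enumerate(reference.snps["id"])}
    present = stats["SNP"].isin(ref_ids)
    if not present.any():
        raise ValueError("no summary-stat SNPs present in the reference panel")
    if not present.all():
        warnings.warn(f"{int((~present).sum())} summary-stat SNPs absent from "
                      "reference; dropped", RuntimeWarning)
    work = stats.loc[present, ["SNP", "CHR", "POS", "P"]].copy()
    work = work.sort_values(["P", "POS"], kind="mergesort").reset_index(drop=True)

    dos = reference.dosages
    has_nan = bool(np.isnan(dos).any())
    col = np.array([ref_ids[s] for s in work["SNP"]])
    chrom = work["CHR"].to_numpy()
    pos = work["POS"].to_numpy()
    if not has_nan:
        # centered dosages once: r2 against an accepted SNP is then one
        # matrix-vector product instead of per-pair correlation calls
        Dc = dos - dos.mean(axis=0)
        ss = np.einsum("ij,ij->j", Dc, Dc)
    retained: list = []
    alive = np.ones(len(work), bool)
    for i in range(len(work)):
        if not alive[i]:
            continue
        retained.append(work.at[i, "SNP"])
        alive[i] = False
        same = alive & (chrom == chrom[i])
        if not same.any():
            continue
        near = same & (np.abs(pos - pos[i]) <= spec.clump_distance)
        alive[near] = False
        rest = np.flatnonzero(same & ~near)
        if len(rest) == 0:
            continue
        if has_nan:
            x = dos[:, col[i]]
            r2 = _pairwise_r2(x, dos[:, col[rest]])
        else:
            num = Dc[:, col[i]] @ Dc      # one matvec over all SNPs
            with np.errstate(invalid="ignore", divide="ignore"):
                r2 = num[col[rest]]**2 / (ss[col[i]] * ss[col[rest]])
            r2 = np.where(np.isfinite(r2), r2, 0.0)
        alive[rest[r2 >= spec.ld_r2_max]] = False
    return retained


def _pairwise_r2(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Squared correlation of ``x`` against each column of ``Y``,
    pairwise-complete over missing entries."""
    if np.isnan(x).any() or np.isnan(Y).any():
        out = np.empty(Y.shape[1])
        for j in range(Y.shape[1]):
            ok = ~(np.isnan(x) | np.isnan(Y[:, j]))
            if ok.sum() < 3 or x[ok].std() == 0 or Y[ok, j].std() == 0:
                out[j] = 0.0
            else:
                out[j] = np.corrcoef(x[ok], Y[ok, j])[0, 1] ** 2
        return out
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    denom = np.sqrt((xc @ xc) * np.einsum("ij,ij->j", Yc, Yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ Yc) / denom
    return np.where(np.isfinite(r), r, 0.0) ** 2


def _reconcile(stats_row, snp_row) -> float | None:
    """Sign multiplier for the reference effect allele, or None to drop."""
    sa1, sa2 = stats_row["A1"], stats_row["A2"]
    ga1, ga2 = snp_row["a1"], snp_row["a2"]
    if frozenset((sa1, sa2)) in _AMBIGUOUS:
        return None
    if (sa1, sa2) == (ga1, ga2):
        return 1.0
    if (sa1, sa2) == (ga2, ga1):
        return -1.0
    return None


def score(G: GenotypeMatrix, stats: pd.DataFrame, retained: list,
          threshold: float) -> PGSResult:
    """Weighted effect-allele dosage sum over retained SNPs at a threshold.

    Alleles are reconciled between summary statistics and genotypes
    (swapped alleles flip the beta sign; strand-ambiguous A/T / C/G
    SNPs are dropped and counted).  The standardized score has sample
    mean 0 and sd 1.
    """
    sub = stats[stats["SNP"].isin(retained) & (stats["P"] <= threshold)]
    snp_meta = G.snps.set_index("id")
    col_of = {s: j for j, s in enumerate(G.snps["id"])}
    raw = np.zeros(G.n_samples)
    used, dropped = [], 0
    for _, row in sub.iterrows():
        meta = snp_meta.loc[row["SNP"]]
        sign = _reconcile(row, meta)
        if sign is None:
            dropped += 1
            continue
        d = G.dosages[:, col_of[row["SNP"]]]
        d = np.where(np.isnan(d), np.nanmean(d), d)
        raw = raw + sign * row["BETA"] * d
        used.append(row["SNP"])
    sd = raw.std()
    std = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    return PGSResult(threshold=threshold, snps=used, raw=raw,
                     standardized=std, n_dropped_ambiguous=dropped)


def select_one_per_family(records: pd.DataFrame, seed: int | None = None
                          ) -> pd.DataFrame:
    """Keep exactly one member per family (lowest individual id, or a
    seeded random pick); singletons are retained as-is."""
    if seed is None:
        picked = (records.sort_values("individual_id")
                  .groupby("family_id", sort=True).head(1))
    else:
        rng = np.random.default_rng(seed)
        picked = (records.sort_values("individual_id")
                  .groupby("family_id", sort=True)
                  .sample(n=1, random_state=rng.integers(2**31)))
    return picked.sort_index()


def logistic_interaction_fit(outcome, pgs, sex, covariates: pd.DataFrame,
                             tol: float = 1e-10) -> LogisticFit:
    """ML logistic fit of outcome ~ pgs + sex + pgs:sex + covariates.

    ``sex`` is coded women = 0, men = 1.  Estimated by Newton/IRLS to
    tolerance 1e-10; Wald 95% CIs and p-values per term.  Perfect
    separation raises with the offending term named.
    """
    y = np.asarray(outcome, float)
    pgs = np.asarray(pgs, float)
    if sex is None:
        X = pd.DataFrame({"intercept": 1.0, "pgs": pgs})
    else:
        sex = np.asarray(sex, float)
        X = pd.DataFrame({"intercept": 1.0, "pgs": pgs, "sex": sex,
                          "pgs_x_sex": pgs * sex})
    for c in covariates.columns:
        X[c] = np.asarray(covariates[c], float)
    if not np.isfinite(X.to_numpy()).all():
        raise ValueError("non-finite covariate values")
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            res = sm.Logit(y, X).fit(disp=0, method="newton", tol=tol,
                                     maxiter=200)
        except Exception as exc:  # statsmodels raises on separation
            for term in X.columns[1:]:
                lo = y[X[term] <= np.median(X[term])]
                hi = y[X[term] > np.median(X[term])]
                if len(lo) and len(hi) and (lo.max() < hi.min()
                                            or hi.max() < lo.min()):
                    raise RuntimeError(
                        f"perfect separation on term {term!r}") from exc
            raise RuntimeError(f"logistic fit failed: {exc}") from exc
    ci = res.conf_int()
    return LogisticFit(
        terms=list(X.columns),
        odds_ratio={t: float(np.exp(res.params[t])) for t in X.columns},
        ci_low={t: float(np.exp(ci.loc[t, 0])) for t in X.columns},
        ci_high={t: float(np.exp(ci.loc[t, 1])) for t in X.columns},
        p_value={t: float(res.pvalues[t]) for t in X.columns},
        coef={t: float(res.params[t]) for t in X.columns},
        cov_params=res.cov_params(),
        n=len(y),
        converged=bool(res.mle_retvals.get("converged", True)),
    )


def sex_specific_or(fit: LogisticFit) -> dict:
    """Per-sex PGS odds ratios from the interaction fit.

    Women carry the main effect; the male OR is main x interaction,
    with a delta-method (summed log-odds) CI.
    """
    if "pgs" not in fit.coef or "pgs_x_sex" not in fit.coef:
        raise ValueError("fit lacks pgs / pgs x sex terms")
    b, g = fit.coef["pgs"], fit.coef["pgs_x_sex"]
    var_b = fit.cov_params.loc["pgs", "pgs"]
    var_sum = (var_b + fit.cov_params.loc["pgs_x_sex", "pgs_x_sex"]
               + 2 * fit.cov_params.loc["pgs", "pgs_x_sex"])
    zc = norm.ppf(0.975)
    return {
        "female": {
            "or": float(np.exp(b)),
            "ci": (float(np.exp(b - zc * np.sqrt(var_b))),
                   float(np.exp(b + zc * np.sqrt(var_b)))),
        },
        "male": {
            "or": float(np.exp(b + g)),
            "ci": (float(np.exp(b + g - zc * np.sqrt(var_sum))),
                   float(np.exp(b + g + zc * np.sqrt(var_sum)))),
        },
    }


def pgs_model_table(cohort: pd.DataFrame, G: GenotypeMatrix,
                    stats: pd.DataFrame, spec: ScoreSpec | None = None,
                    one_per_family_seed: int | None = None) -> pd.DataFrame:
    """Per-threshold interaction models on one member per family.

    Standardization of each score happens on the final analysis sample.
    Thresholds retaining no SNPs are reported with a notice row and no
    model, mirroring an empty genome-wide-significant score.
    """
    spec = spec or ScoreSpec()
    retained = clump(stats, G, spec)
    analysis = select_one_per_family(cohort, seed=one_per_family_seed)
    idx = [G.samples.index(i) for i in analysis["individual_id"]]
    rows = []
    for thr in spec.p_thresholds:
        res = score(G, stats, retained, thr)
        raw = res.raw[idx]
        if len(res.snps) == 0 or raw.std() == 0:
            rows.append({"threshold": thr, "n_snps": len(res.snps),
                         "term": "(no SNPs retained: model skipped)",
                         "odds_ratio": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p_value": np.nan,
                         "n": len(analysis)})
            continue
        std = (raw - raw.mean()) / raw.std()
        sexn = (analysis["sex"] == "male").astype(float).to_numpy()
        cov = pd.DataFrame({
            "birth_year": analysis["birth_year"].to_numpy(float)
            - analysis["birth_year"].mean(),
            "education_years": analysis["education_years"].to_numpy(float),
        })
        fit = logistic_interaction_fit(
            analysis["childless"].to_numpy(float), std, sexn, cov)
        for term in fit.terms:
            rows.append({"threshold": thr, "n_snps": len(res.snps),
                         "term": term,
                         "odds_ratio": round(fit.odds_ratio[term], 3),
                         "ci_low": round(fit.ci_low[term], 3),
                         "ci_high": round(fit.ci_high[term], 3),
                         "p_value": round(fit.p_value[term], 4),
                         "n": fit.n})
    return pd.DataFrame(rows)
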