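"""Cohort filters, run configuration and pipeline orchestration.

The cohort filter applies the study's inclusion rules: women aged 45
and over, men 50 and over (age at a configurable reference year), with
childlessness defined per sex — a woman is childless only if she has
neither living nor dead children, a man if he has no living children.
``run_pipeline`` chains simulation, concordance, twin-model, GRM/GREML
and polygenic-score stages and writes the four report tables plus a
machine-readable manifest.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grm import QCConfig, compute_grm, make_ibd_matrix, grm_pca, qc_filter, \
    write_vcf, write_raw
from .greml import bivariate_reml, reml_fit
from .pair_stats import table1_report
from .pgs import ScoreSpec, pgs_model_table
from .synthetic import CohortSpec, GenoSpec, attach_genetic_liability, \
    simulate_genotypes, simulate_sumstats, simulate_twin_cohort, \
    write_phenotypes, write_sumstats
from .twin_model import twin_model_table

__all__ = ["CohortFilter", "RunConfig", "apply_cohort_filter", "run_pipeline"]

log = logging.getLogger("twinherit")


@dataclass
class CohortFilter:
    """Age and childlessness inclusion rules.

    Ages are computed at ``reference_year`` from the birth year.  The
    male childlessness definition ignores dead children; the female
    definition requires no living and no dead children.
    """

    min_age_female: int = 45
    min_age_male: int = 50
    reference_year: int = 2002
    male_counts_dead_children: bool = False

    def __post_init__(self) -> None:
        if self.min_age_female <= 0 or self.min_age_male <= 0:
            raise ValueError("minimum ages must be positive")


def apply_cohort_filter(records: pd.DataFrame,
                        filt: CohortFilter | None = None):
    """Apply age restrictions and resolve childlessness per sex.

    ``records`` needs sex, birth_year, n_children_living and
    n_children_dead columns.  Returns (kept records with a ``childless``
    column, exclusion counts by reason).
    """
    filt = filt or CohortFilter()
    counts = {"missing_birth_year": 0, "too_young": 0}
    rec = records.copy()
    missing = rec["birth_year"].isna()
    counts["missing_birth_year"] = int(missing.sum())
    rec = rec[~missing]
    age = filt.reference_year - rec["birth_year"]
    min_age = np.where(rec["sex"] == "female",
                       filt.min_age_female, filt.min_age_male)
    young = age < min_age
    counts["too_young"] = int(young.sum())
    rec = rec[~young]
    no_living = rec["n_children_living"] == 0
    no_dead = rec["n_children_dead"] == 0
    female_rule = no_living & no_dead
    male_rule = female_rule if filt.male_counts_dead_children else no_living
    rec["childless"] = np.where(rec["sex"] == "female",
                                female_rule, male_rule).astype(int)
    return rec, counts


@dataclass
class RunConfig:
    """Everything a full synthetic run needs, in one (YAML-able) object."""

    seed: int = 1
    out_dir: str = "results"
    cohort: dict = field(default_factory=dict)
    geno: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    score: dict = field(default_factory=dict)
    prevalence: float = 0.134
    n_gwas: int = 250_000
    stages: tuple = ("simulate", "concord", "twinfit", "grm", "greml", "pgs")
    greml_max_n: int = 1200     # GREML stage subsamples to keep runs desk-scale

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        """Independent, reproducible RNG stream per stage."""
        h = np.random.SeedSequence([self.seed, sum(map(ord, stage))])
        return int(h.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns {stage: output path or object}.

    Each stage logs to stderr with its own prefix, writes TSV outputs
    under ``config.out_dir`` and halts the pipeline on failure with
    partial outputs preserved.  A manifest (seed, package version,
    stage timings, thresholds) is written at the end.
    """
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="[%(name)s] %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    timings: dict = {}

    cohort = geno = stats = None
    cohort_geno = None

    def run_stage(name, fn):
        t0 = time.time()
        stage_log = logging.getLogger(f"twinherit.{name}")
        stage_log.info("start")
        try:
            fn()
        except Exception:
            stage_log.error("stage failed; partial outputs kept in %s", out)
            raise
        timings[name] = round(time.time() - t0, 3)
        stage_log.info("done in %.1fs", timings[name])

    if "simulate" in config.stages:
        def _simulate():
            nonlocal cohort, geno, stats, cohort_geno
            cspec = CohortSpec(seed=config.stage_seed("simulate"),
                               **config.cohort)
            cohort = simulate_twin_cohort(cspec)
            gspec = GenoSpec(seed=config.stage_seed("simulate-geno"),
                             **config.geno)
            geno = simulate_genotypes(cohort, gspec)
            cohort_geno = attach_genetic_liability(
                cohort, geno, gspec,
                prevalence_f=cspec.prevalence_f,
                prevalence_m=cspec.prevalence_m)
            true_beta = np.zeros(geno.n_snps)
            causal = cohort_geno.attrs["causal_snps"]
            true_beta[causal] = cohort_geno.attrs["causal_betas"][:, 0] \
                / np.sqrt(len(causal))
            stats = simulate_sumstats(geno, true_beta, n_gwas=config.n_gwas,
                                      seed=config.stage_seed("sumstats"))
            write_phenotypes(cohort, out / "phenotypes.tsv")
            write_vcf(geno, out / "genotypes.vcf")
            write_raw(geno, out / "genotypes.raw")
            write_sumstats(stats, out / "sumstats.tsv")
            artifacts["simulate"] = str(out / "phenotypes.tsv")
        run_stage("simulate", _simulate)
    else:
        raise ValueError("pipeline currently starts from the simulate stage")

    if "concord" in config.stages:
        def _concord():
            tab = table1_report(cohort)
            tab.to_csv(out / "table1_concordance.tsv", sep="\t", index=False)
            artifacts["concord"] = str(out / "table1_concordance.tsv")
        run_stage("concord", _concord)

    if "twinfit" in config.stages:
        def _twinfit():
            tab = twin_model_table(cohort)
            tab.to_csv(out / "table2_twin_models.tsv", sep="\t", index=False)
            artifacts["twinfit"] = str(out / "table2_twin_models.tsv")
        run_stage("twinfit", _twinfit)

    grm_obj = ibd_obj = pcs = None
    qc_cfg = QCConfig(**config.qc)
    if "grm" in config.stages:
        def _grm():
            nonlocal geno, grm_obj, ibd_obj, pcs, cohort_geno
            rng = np.random.default_rng(config.stage_seed("grm"))
            if geno.n_samples > config.greml_max_n:
                fams = cohort_geno["family_id"].unique()
                rng.shuffle(fams)
                keep_fams = set()
                count = 0
                for f in fams:
                    size = int((cohort_geno["family_id"] == f).sum())
                    if count + size > config.greml_max_n:
                        break
                    keep_fams.add(f)
                    count += size
                keep = cohort_geno["family_id"].isin(keep_fams).to_numpy()
                cohort_geno = cohort_geno[keep].reset_index(drop=True)
                geno = type(geno)(
                    samples=[s for s, k in zip(geno.samples, keep) if k],
                    snps=geno.snps, dosages=geno.dosages[keep])
            filtered, qc_counts = qc_filter(geno, qc_cfg)
            grm_obj = compute_grm(filtered)
            ibd_obj = make_ibd_matrix(grm_obj)
            pcs = grm_pca(grm_obj, qc_cfg.n_pcs)
            artifacts["grm"] = {"qc_removed": qc_counts,
                                "n_snps": filtered.n_snps,
                                "n_samples": filtered.n_samples}
        run_stage("grm", _grm)

    if "greml" in config.stages and grm_obj is not None:
        def _greml():
            rows = []
            df = cohort_geno
            y_all = df["childless"].to_numpy(float)
            by = df["birth_year"].to_numpy(float)
            X = np.column_stack([np.ones(len(df)), by - by.mean(), pcs])
            fit = reml_fit(y_all, X, [grm_obj, ibd_obj], K=config.prevalence)
            rows.append({"sample": "overall", "coeff": "h2",
                         "estimate": round(fit.h2_liab, 3),
                         "se_obs": round(fit.se["sigma2_snp"], 4),
                         "n": fit.n})
            for sex in ("female", "male"):
                m = (df["sex"] == sex).to_numpy()
                if m.sum() < 40:
                    continue
                sub_ids = np.flatnonzero(m)
                A = grm_obj.matrix[np.ix_(sub_ids, sub_ids)]
                D = ibd_obj.matrix[np.ix_(sub_ids, sub_ids)]
                Xs = X[m][:, [0, 1]]
                fit_s = reml_fit(y_all[m], np.column_stack([Xs, pcs[m]]),
                                 [A, D], K=config.prevalence)
                rows.append({"sample": sex, "coeff": "h2",
                             "estimate": round(fit_s.h2_liab, 3),
                             "se_obs": round(fit_s.se["sigma2_snp"], 4),
                             "n": int(m.sum())})
            males = np.flatnonzero((df["sex"] == "male").to_numpy())
            females = np.flatnonzero((df["sex"] == "female").to_numpy())
            if len(males) > 40 and len(females) > 40:
                bfit = bivariate_reml(
                    y_all[males], y_all[females], grm_obj,
                    X1=X[males][:, :2], X2=X[females][:, :2],
                    idx1=males, idx2=females, do_tests=False)
                rows.append({"sample": "male-female", "coeff": "rg",
                             "estimate": round(bfit.rg, 3)
                             if np.isfinite(bfit.rg) else np.nan,
                             "se_obs": round(bfit.rg_se, 3)
                             if np.isfinite(bfit.rg_se) else np.nan,
                             "n": bfit.n1 + bfit.n2})
            pd.DataFrame(rows).to_csv(out / "table3_greml.tsv", sep="\t",
                                      index=False)
            artifacts["greml"] = str(out / "table3_greml.tsv")
        run_stage("greml", _greml)

    if "pgs" in config.stages:
        def _pgs():
            tab = pgs_model_table(cohort_geno, geno, stats,
                                  ScoreSpec(**config.score))
            tab.to_csv(out / "table4_pgs.tsv", sep="\t", index=False)
            artifacts["pgs"] = str(out / "table4_pgs.tsv")
        run_stage("pgs", _pgs)

    manifest = {
        "seed": config.seed,
        "version": __version__,
        "stages": list(config.stages),
        "timings_s": timings,
        "thresholds": {
            "qc": asdict(qc_cfg),
            "score": asdict(ScoreSpec(**config.score)),
            "prevalence": config.prevalence,
        },
        "artifacts": {k: v for k, v in artifacts.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    artifacts["manifest"] = str(out / "manifest.json")
    return artifacts
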