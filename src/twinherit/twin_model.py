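"""Liability-threshold twin models fitted by full-information ML.

A binary trait is modelled as a thresholded standard-normal liability
whose pair correlation is composed from variance proportions: additive
genetic effects correlate 1 in MZ and 0.5 in same-sex DZ pairs,
dominance 1 / 0.25, shared environment 1 everywhere.  In opposite-sex
pairs the additive cross-correlation is a free parameter rg that plays
the role of the DZ 0.5 (rg = 0.5 means no qualitative sex difference,
rg = 0 independent male/female genetic effects).  Covariates shift the
thresholds linearly (probit-style); singletons contribute marginal
univariate probabilities.  Models are compared by likelihood-ratio
chi-square and AIC differences (delta AIC = delta chi2 - 2 delta df).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.special import ndtr
from scipy.stats import chi2, norm

from .bvnorm import pair_cell_probs

__all__ = [
    "TwinModelSpec",
    "TwinModelParams",
    "TwinFit",
    "ModelComparison",
    "SexLimitationSuite",
    "pair_loglik",
    "fit_twin_model",
    "compare_models",
    "sex_limitation_suite",
    "profile_ci_a2",
    "twin_model_table",
]

SAME_SEX_GROUPS = {"female": ("MZ-f", "DZ-f"), "male": ("MZ-m", "DZ-m")}
ALL_GROUPS = ("MZ-f", "DZ-f", "MZ-m", "DZ-m", "OS")


@dataclass(frozen=True)
class TwinModelSpec:
    """Which variance components, sex structure and rg constraint to fit."""

    components: tuple = ("A", "C", "E")
    sex_mode: str = "single-sex"       # single-sex | heterogeneous | homogeneous
    sex: str | None = None             # for single-sex fits
    rg_mode: str = "fixed-0.5"         # free | fixed-0.5 | fixed-0
    covariates: tuple = ("birth_year",)

    def __post_init__(self) -> None:
        comps = set(self.components)
        if "E" not in comps:
            raise ValueError("E must always be included")
        if {"C", "D"} <= comps:
            raise ValueError("C and D are confounded and cannot both be fitted")
        if not comps <= {"A", "C", "D", "E"}:
            raise ValueError(f"unknown components {comps}")
        if self.sex_mode not in ("single-sex", "heterogeneous", "homogeneous"):
            raise ValueError(f"bad sex_mode {self.sex_mode!r}")
        if self.sex_mode == "single-sex" and self.sex not in ("female", "male"):
            raise ValueError("single-sex fits need spec.sex")
        if self.rg_mode not in ("free", "fixed-0.5", "fixed-0"):
            raise ValueError(f"bad rg_mode {self.rg_mode!r}")

    @property
    def free_components(self) -> tuple:
        return tuple(c for c in self.components if c != "E")


@dataclass
class TwinModelParams:
    """Variance proportions, thresholds and covariate effect of one fit."""

    a2_f: float = 0.0
    c2_f: float = 0.0
    d2_f: float = 0.0
    e2_f: float = 1.0
    a2_m: float = 0.0
    c2_m: float = 0.0
    d2_m: float = 0.0
    e2_m: float = 1.0
    rg: float = 0.5
    tau_f: float = np.nan
    tau_m: float = np.nan
    beta_by: float = 0.0

    def pair_correlation(self, pair_type: str) -> float:
        if pair_type == "OS":
            r = (self.rg * np.sqrt(self.a2_f * self.a2_m)
                 + np.sqrt(self.c2_f * self.c2_m)
                 + 0.25 * np.sqrt(self.d2_f * self.d2_m))
        else:
            s = "f" if pair_type.endswith("f") else "m"
            a2, c2, d2 = (getattr(self, f"{k}2_{s}") for k in "acd")
            if pair_type.startswith("MZ"):
                r = a2 + c2 + d2
            else:
                r = 0.5 * a2 + c2 + 0.25 * d2
        return float(r)

    def threshold(self, sex: str) -> float:
        return self.tau_f if sex == "female" else self.tau_m


@dataclass
class ModelComparison:
    delta_minus2LL: float
    delta_df: int
    p_value: float
    delta_aic: float


@dataclass
class TwinFit:
    params: TwinModelParams
    minus2LL: float
    df: int
    n_pairs: int
    n_singletons: int
    spec: TwinModelSpec
    n_free_params: int
    ci95: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        """OpenMx-style AIC = -2LL - 2 df (df = observations - parameters)."""
        return self.minus2LL - 2.0 * self.df


# ---------------------------------------------------------------------------
# likelihood

def _group_sexes(group: str) -> tuple:
    if group == "OS":
        return ("male", "female")
    s = "female" if group.endswith("f") else "male"
    return (s, s)


def pair_loglik(params: TwinModelParams, pair_type: str, outcomes,
                covariates=None) -> np.ndarray:
    """Log-likelihood contributions of complete pairs of one type.

    ``outcomes`` is (n, 2) binary (member 1 first; male first for OS);
    ``covariates`` the per-member birth-year deviations, same shape.
    A singleton member is encoded as outcome -1 and contributes the
    univariate tail probability.
    """
    y = np.atleast_2d(np.asarray(outcomes))
    cov = np.zeros_like(y, dtype=float) if covariates is None \
        else np.atleast_2d(np.asarray(covariates, float))
    r = params.pair_correlation(pair_type)
    if not -1.0 < r < 1.0:
        raise ValueError(f"composed pair correlation {r} outside (-1, 1)")
    s1, s2 = _group_sexes(pair_type)
    t1 = params.threshold(s1) - params.beta_by * cov[:, 0]
    t2 = params.threshold(s2) - params.beta_by * cov[:, 1]
    p00, p01, p10, p11 = pair_cell_probs(t1, t2, r)
    probs = np.stack([p00, p01, p10, p11])
    both = (y[:, 0] >= 0) & (y[:, 1] >= 0)
    out = np.empty(len(y))
    idx = 2 * np.maximum(y[:, 0], 0) + np.maximum(y[:, 1], 0)
    out[both] = np.log(np.clip(probs[idx[both], np.flatnonzero(both)], 1e-300, 1))
    if not both.all():
        solo = ~both
        t = np.where(y[solo, 0] >= 0, t1[solo], t2[solo])
        ys = np.where(y[solo, 0] >= 0, y[solo, 0], y[solo, 1])
        marg = np.where(ys == 1, 1.0 - ndtr(t), ndtr(t))
        out[solo] = np.log(np.clip(marg, 1e-300, 1))
    return out


class _TwinData:
    """Pairs and singletons extracted from a cohort table, by group."""

    def __init__(self, records: pd.DataFrame, groups) -> None:
        records = records[records["pair_type"].isin(groups)]
        if records.empty:
            raise ValueError(f"no records in groups {groups}")
        self.by_center = float(records["birth_year"].mean())
        self.pairs = {}
        self.n_pairs = 0
        self.singletons = {"female": ([], []), "male": ([], [])}
        for g in groups:
            sub = records[records["pair_type"] == g]
            if sub.empty:
                continue
            sizes = sub.groupby("family_id")["childless"].size()
            comp = set(sizes.index[sizes == 2])
            pair_rows = sub[sub["family_id"].isin(comp)]
            if g == "OS":
                pair_rows = pair_rows.sort_values(
                    ["family_id", "sex"],
                    key=lambda s: s.map({"male": 0, "female": 1})
                    if s.name == "sex" else s)
            else:
                pair_rows = pair_rows.sort_values(["family_id", "individual_id"])
            y = pair_rows["childless"].to_numpy().reshape(-1, 2)
            cov = (pair_rows["birth_year"].to_numpy(float)
                   - self.by_center).reshape(-1, 2)
            if len(y):
                self.pairs[g] = (y, cov)
                self.n_pairs += len(y)
            solo = sub[~sub["family_id"].isin(comp)]
            for sex in ("female", "male"):
                rows = solo[solo["sex"] == sex]
                if len(rows):
                    self.singletons[sex][0].append(
                        rows["childless"].to_numpy())
                    self.singletons[sex][1].append(
                        rows["birth_year"].to_numpy(float) - self.by_center)
        self.solo = {}
        self.n_singletons = 0
        for sex, (ys, covs) in self.singletons.items():
            if ys:
                y = np.concatenate(ys)
                self.solo[sex] = (y, np.concatenate(covs))
                self.n_singletons += len(y)
        self.n_individuals = 2 * self.n_pairs + self.n_singletons


def _loglik(params: TwinModelParams, data: _TwinData) -> float:
    ll = 0.0
    for g, (y, cov) in data.pairs.items():
        r = params.pair_correlation(g)
        if not -1.0 < r < 1.0:
            return -np.inf
        s1, s2 = _group_sexes(g)
        t1 = params.threshold(s1) - params.beta_by * cov[:, 0]
        t2 = params.threshold(s2) - params.beta_by * cov[:, 1]
        p00, p01, p10, p11 = pair_cell_probs(t1, t2, r)
        probs = np.stack([p00, p01, p10, p11])
        idx = 2 * y[:, 0] + y[:, 1]
        ll += np.sum(np.log(np.clip(probs[idx, np.arange(len(y))], 1e-300, 1)))
    for sex, (y, cov) in data.solo.items():
        t = params.threshold(sex) - params.beta_by * cov
        marg = np.where(y == 1, 1.0 - ndtr(t), ndtr(t))
        ll += np.sum(np.log(np.clip(marg, 1e-300, 1)))
    return float(ll)


# ---------------------------------------------------------------------------
# parameter packing

class _Packer:
    """Maps an unconstrained optimizer vector to TwinModelParams.

    Variance proportions use squared path coefficients normalized to
    the simplex (the E coefficient is pinned at 1), which keeps the
    optimization smooth and strictly interior.
    """

    def __init__(self, spec: TwinModelSpec, use_covariate: bool,
                 fixed_a2: float | None = None) -> None:
        self.spec = spec
        self.k = len(spec.free_components)
        self.two_sets = spec.sex_mode == "heterogeneous"
        self.single = spec.sex_mode == "single-sex"
        self.use_cov = use_covariate and bool(spec.covariates)
        self.rg_free = (spec.rg_mode == "free" and not self.single
                        and "A" in spec.components)
        self.fixed_a2 = fixed_a2
        ku = self.k if fixed_a2 is None else self.k - 1
        self.n_u = ku * (2 if self.two_sets else 1)
        self.n_tau = 1 if self.single else 2
        self.size = self.n_u + self.n_tau + int(self.use_cov) + int(self.rg_free)

    def _comps(self, u: np.ndarray) -> dict:
        vals = {c: 0.0 for c in "ACDE"}
        free = list(self.spec.free_components)
        if self.fixed_a2 is not None:
            free.remove("A")
        w = np.concatenate([u**2, [1.0]])
        scale = 1.0 if self.fixed_a2 is None else 1.0 - self.fixed_a2
        w = scale * w / w.sum()
        for c, v in zip(free + ["E"], w):
            vals[c] = float(v)
        if self.fixed_a2 is not None:
            vals["A"] = self.fixed_a2
        return vals

    def unpack(self, theta: np.ndarray) -> TwinModelParams:
        i = 0
        ku = self.n_u // (2 if self.two_sets else 1)
        cf = self._comps(theta[i:i + ku]); i += ku
        cm = self._comps(theta[i:i + ku]) if self.two_sets else cf
        if self.two_sets:
            i += ku
        if self.single:
            tau = theta[i]; i += 1
            tau_f = tau_m = tau
        else:
            tau_f, tau_m = theta[i], theta[i + 1]; i += 2
        beta = theta[i] if self.use_cov else 0.0
        if self.use_cov:
            i += 1
        if self.rg_free:
            rg = float(np.tanh(theta[i])); i += 1
        else:
            rg = {"fixed-0.5": 0.5, "fixed-0": 0.0}[self.spec.rg_mode]
        if self.single and self.spec.sex == "male":
            cf = {c: np.nan for c in "ACDE"}
            tau_f = np.nan
        if self.single and self.spec.sex == "female":
            cm = {c: np.nan for c in "ACDE"}
            tau_m = np.nan
        return TwinModelParams(
            a2_f=cf["A"], c2_f=cf["C"], d2_f=cf["D"], e2_f=cf["E"],
            a2_m=cm["A"], c2_m=cm["C"], d2_m=cm["D"], e2_m=cm["E"],
            rg=rg, tau_f=tau_f, tau_m=tau_m, beta_by=beta)

    def starts(self, data: _TwinData) -> list:
        """Five deterministic starting vectors."""
        kvals = {}
        for sex in ("female", "male"):
            ys = [data.pairs[g][0].ravel() for g in data.pairs
                  if sex in _group_sexes(g)]
            if sex in data.solo:
                ys.append(data.solo[sex][0])
            obs = np.concatenate(ys) if ys else np.array([0.13])
            kvals[sex] = float(norm.ppf(1 - np.clip(obs.mean(), 0.01, 0.99)))
        out = []
        ku = self.n_u // (2 if self.two_sets else 1)
        for ua, urg in [(1.0, 0.0), (0.4, 0.3), (2.0, -0.3), (0.7, 0.8), (1.4, 0.1)]:
            u = np.full(ku, ua) * (1 + 0.1 * np.arange(ku))
            theta = [u] * (2 if self.two_sets else 1)
            if self.single:
                theta.append([kvals[self.spec.sex]])
            else:
                theta.append([kvals["female"], kvals["male"]])
            if self.use_cov:
                theta.append([0.0])
            if self.rg_free:
                theta.append([urg])
            out.append(np.concatenate(theta))
        return out


# ---------------------------------------------------------------------------
# fitting

def _records_for(spec: TwinModelSpec):
    return (SAME_SEX_GROUPS[spec.sex] if spec.sex_mode == "single-sex"
            else ALL_GROUPS)


def fit_twin_model(records: pd.DataFrame, spec: TwinModelSpec,
                   compute_ci: bool = False, _fixed_a2: float | None = None,
                   _data: _TwinData | None = None) -> TwinFit:
    """Maximize the full-information likelihood from 5 deterministic starts."""
    data = _data or _TwinData(records, _records_for(spec))
    packer = _Packer(spec, use_covariate=True, fixed_a2=_fixed_a2)

    def nll(theta: np.ndarray) -> float:
        return -_loglik(packer.unpack(theta), data)

    best = None
    for x0 in packer.starts(data):
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8,
                                "maxiter": 4000, "maxfev": 4000})
        if best is None or res.fun < best.fun:
            best = res
    # polish: restart from the winner until no meaningful improvement
    for _ in range(3):
        res = minimize(nll, best.x, method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-9,
                                "maxiter": 4000, "maxfev": 4000})
        improved = best.fun - res.fun
        best = res if res.fun < best.fun else best
        if improved < 1e-7:
            break
    if not np.isfinite(best.fun):
        raise RuntimeError("twin model did not converge from any start")
    params = packer.unpack(best.x)
    fit = TwinFit(
        params=params,
        minus2LL=2.0 * float(best.fun),
        df=data.n_individuals - packer.size,
        n_pairs=data.n_pairs,
        n_singletons=data.n_singletons,
        spec=spec,
        n_free_params=packer.size,
    )
    fit._theta = best.x          # used by profile CIs
    fit._data = data
    if compute_ci and "A" in spec.components and _fixed_a2 is None:
        fit.ci95["a2"] = profile_ci_a2(records, spec, fit)
    return fit


def profile_ci_a2(records: pd.DataFrame, spec: TwinModelSpec,
                  fit: TwinFit) -> tuple:
    """95% profile-likelihood CI for the additive proportion a2.

    Re-optimizes all nuisance parameters at fixed a2 and finds where
    -2LL rises by chi2_1(0.95) = 3.84; respects the [0, 1] boundary.
    """
    data = getattr(fit, "_data", None) or _TwinData(records, _records_for(spec))
    target = fit.minus2LL + chi2.ppf(0.95, 1)
    sex = "m" if spec.sex == "male" else "f"
    a2_hat = getattr(fit.params, f"a2_{sex}")

    def m2ll_at(v: float) -> float:
        sub = fit_twin_model(records, spec, _fixed_a2=float(v), _data=data)
        return sub.minus2LL

    def g(v: float) -> float:
        return m2ll_at(v) - target

    lo_edge, hi_edge = 1e-6, 1 - 1e-6
    lo = lo_edge if g(lo_edge) <= 0 else brentq(g, lo_edge, max(a2_hat, 2e-6),
                                                xtol=1e-4)
    hi = hi_edge if g(hi_edge) <= 0 else brentq(g, min(a2_hat, hi_edge), hi_edge,
                                                xtol=1e-4)
    return float(lo), float(hi)


def compare_models(full: TwinFit, sub: TwinFit) -> ModelComparison:
    """Likelihood-ratio comparison of a nested sub-model against a full model."""
    d_df = sub.df - full.df
    if d_df <= 0:
        raise ValueError("sub-model must have fewer free parameters than full")
    d = sub.minus2LL - full.minus2LL
    if d < -1e-4:
        raise ValueError(
            f"sub-model fits better than full by {-d:.4g}: models not nested "
            "or optimizer failure")
    d = max(d, 0.0)
    return ModelComparison(
        delta_minus2LL=d,
        delta_df=int(d_df),
        p_value=float(chi2.sf(d, d_df)),
        delta_aic=d - 2.0 * d_df,
    )


@dataclass
class SexLimitationSuite:
    """Fits and comparisons of the qualitative/quantitative sex-difference ladder."""

    fits: dict
    comparisons: dict
    best: str

    def table(self) -> pd.DataFrame:
        rows = []
        for label, fit in self.fits.items():
            cmp_ = self.comparisons.get(label)
            p = fit.params
            rows.append({
                "model": label,
                "minus2LL": round(fit.minus2LL, 2),
                "df": fit.df,
                "delta_minus2LL": round(cmp_.delta_minus2LL, 2) if cmp_ else np.nan,
                "delta_df": cmp_.delta_df if cmp_ else np.nan,
                "p_value": round(cmp_.p_value, 3) if cmp_ else np.nan,
                "delta_aic": round(cmp_.delta_aic, 3) if cmp_ else np.nan,
                "h2_f": round(p.a2_f, 3), "c2_f": round(p.c2_f, 3),
                "e2_f": round(p.e2_f, 3),
                "h2_m": round(p.a2_m, 3), "c2_m": round(p.c2_m, 3),
                "e2_m": round(p.e2_m, 3),
                "rg": round(p.rg, 3),
                "best": label == self.best,
            })
        return pd.DataFrame(rows)


def sex_limitation_suite(records: pd.DataFrame,
                         compute_ci: bool = False) -> SexLimitationSuite:
    """Qualitative then quantitative sex-limitation ladder on AE models.

    Fits: AE with rg free; rg fixed at 0.5 and at 0 (each against the
    free model); the homogeneous (equal male/female proportions) rg=0
    model against the heterogeneous one; and the E-only model against
    the homogeneous AE.  The best model has the lowest AIC, with ties
    closer than 0.01 resolved toward fewer parameters.
    """
    data = _TwinData(records, ALL_GROUPS)

    def ae(sex_mode, rg_mode):
        return fit_twin_model(records, TwinModelSpec(
            components=("A", "E"), sex_mode=sex_mode, rg_mode=rg_mode),
            _data=data)

    fits = {
        "AE rg free": ae("heterogeneous", "free"),
        "AE rg 0.5": ae("heterogeneous", "fixed-0.5"),
        "AE rg 0": ae("heterogeneous", "fixed-0"),
        "AE rg 0 M=F": ae("homogeneous", "fixed-0"),
        "E M=F": fit_twin_model(records, TwinModelSpec(
            components=("E",), sex_mode="homogeneous"), _data=data),
    }
    comparisons = {
        "AE rg 0.5": compare_models(fits["AE rg free"], fits["AE rg 0.5"]),
        "AE rg 0": compare_models(fits["AE rg free"], fits["AE rg 0"]),
        "AE rg 0 M=F": compare_models(fits["AE rg 0"], fits["AE rg 0 M=F"]),
        "E M=F": compare_models(fits["AE rg 0 M=F"], fits["E M=F"]),
    }
    labels = list(fits)
    aics = np.array([fits[l].aic for l in labels])
    order = np.lexsort((-np.array([fits[l].df for l in labels]),
                        np.round(aics / 0.01).astype(int)))
    best = labels[order[0]]
    if compute_ci and "A" in fits[best].spec.components:
        fits[best].ci95["a2"] = profile_ci_a2(records, fits[best].spec, fits[best])
    return SexLimitationSuite(fits=fits, comparisons=comparisons, best=best)


def twin_model_table(records: pd.DataFrame) -> pd.DataFrame:
    """Full model-comparison table: per-sex ACE/AE/CE/E, male ADE, sex limitation."""
    rows = []

    def add(label, fit, cmp_=None, bold=False):
        p = fit.params
        rows.append({
            "model": label, "minus2LL": round(fit.minus2LL, 2), "df": fit.df,
            "delta_minus2LL": round(cmp_.delta_minus2LL, 2) if cmp_ else np.nan,
            "delta_df": cmp_.delta_df if cmp_ else np.nan,
            "p_value": round(cmp_.p_value, 3) if cmp_ else np.nan,
            "delta_aic": round(cmp_.delta_aic, 3) if cmp_ else np.nan,
            "h2_f": round(p.a2_f, 3), "c2_f": round(p.c2_f, 3),
            "d2_f": round(p.d2_f, 3), "e2_f": round(p.e2_f, 3),
            "h2_m": round(p.a2_m, 3), "c2_m": round(p.c2_m, 3),
            "d2_m": round(p.d2_m, 3), "e2_m": round(p.e2_m, 3),
            "rg": round(p.rg, 3),
        })

    for sex in ("female", "male"):
        base_comps = [("A", "C", "E"), ("A", "E"), ("C", "E"), ("E",)]
        fits = {}
        for comps in base_comps:
            spec = TwinModelSpec(components=comps, sex_mode="single-sex", sex=sex)
            fits[comps] = fit_twin_model(records, spec)
        full = fits[("A", "C", "E")]
        add(f"{sex} ACE", full)
        for comps in base_comps[1:]:
            add(f"{sex} " + "".join(comps), fits[comps],
                compare_models(full, fits[comps]))
        if sex == "male":
            ade = fit_twin_model(records, TwinModelSpec(
                components=("A", "D", "E"), sex_mode="single-sex", sex=sex))
            add("male ADE", ade)
            add("male AE (vs ADE)", fits[("A", "E")],
                compare_models(ade, fits[("A", "E")]))
            add("male E (vs ADE)", fits[("E",)],
                compare_models(ade, fits[("E",)]))
    suite = sex_limitation_suite(records)
    for label, fit in suite.fits.items():
        add(label, fit, suite.comparisons.get(label))
    return pd.DataFrame(rows)
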