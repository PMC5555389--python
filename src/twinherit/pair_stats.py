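"""Twin-pair concordance tables and tetrachoric correlations.

Builds 2x2 concordance tables per pair group (MZ/DZ by sex, opposite
sex), computes casewise/pairwise concordance, and estimates the
tetrachoric correlation of the underlying liabilities by maximum
likelihood with profile-likelihood confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import norm, chi2

from .bvnorm import pair_cell_probs

__all__ = [
    "PairTable",
    "ConcordanceStats",
    "TetrachoricEstimate",
    "build_pair_table",
    "concordance",
    "tetrachoric",
    "threshold_from_prevalence",
    "table1_report",
]

PAIR_GROUPS = ("MZ-f", "DZ-f", "MZ-m", "DZ-m", "OS")


class EmptyGroupError(ValueError):
    """Raised when a pair group contains no complete pairs."""


@dataclass
class PairTable:
    """2x2 concordance counts for one group of complete twin pairs.

    Discordant pairs are split into ``d_10`` (member 1 affected) and
    ``d_01`` (member 2 affected); for opposite-sex groups member 1 is
    the male.  Same-sex groups have an arbitrary within-pair order, so
    the split is made even (up to integer rounding).
    """

    group: str
    c_cc: int          # concordant affected
    d_10: int          # discordant, member 1 affected
    d_01: int          # discordant, member 2 affected
    c_nn: int          # concordant unaffected

    def __post_init__(self) -> None:
        if min(self.c_cc, self.d_10, self.d_01, self.c_nn) < 0:
            raise ValueError("pair-table counts must be non-negative")

    @property
    def d_cnc(self) -> int:
        return self.d_10 + self.d_01

    @property
    def n_pairs(self) -> int:
        return self.c_cc + self.d_cnc + self.c_nn

    @property
    def prevalence(self) -> float:
        """Affected individuals / total individuals in complete pairs."""
        return (2 * self.c_cc + self.d_cnc) / (2 * self.n_pairs)


@dataclass
class ConcordanceStats:
    casewise: float
    pairwise: float
    prevalence: float


@dataclass
class TetrachoricEstimate:
    rho: float
    threshold_1: float
    threshold_2: float
    ci_low: float
    ci_high: float
    loglik: float
    boundary: bool = False


def threshold_from_prevalence(K: float) -> float:
    """Liability threshold t with P(Z > t) = K for prevalence K."""
    if not 0.0 < K < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {K}")
    return float(norm.ppf(1.0 - K))


def build_pair_table(records: pd.DataFrame, group: str) -> PairTable:
    """Count complete-pair outcomes for one pair group.

    ``records`` needs columns family_id, pair_type, sex, childless.
    Singletons (families with one member present) are excluded.  For
    the OS group member 1 is the male; same-sex discordant pairs are
    split evenly between d_10 and d_01.
    """
    sub = records[records["pair_type"] == group]
    sizes = sub.groupby("family_id")["childless"].size()
    complete = sizes.index[sizes == 2]
    if len(complete) == 0:
        raise EmptyGroupError(f"no complete pairs in group {group!r}")
    sub = sub[sub["family_id"].isin(complete)]
    if group == "OS":
        # member 1 = male
        sub = sub.sort_values(["family_id", "sex"],
                              key=lambda s: s.map({"male": 0, "female": 1})
                              if s.name == "sex" else s)
    else:
        sub = sub.sort_values(["family_id", "individual_id"])
    y = sub["childless"].to_numpy().reshape(-1, 2)
    c_cc = int(np.sum((y[:, 0] == 1) & (y[:, 1] == 1)))
    c_nn = int(np.sum((y[:, 0] == 0) & (y[:, 1] == 0)))
    d_10 = int(np.sum((y[:, 0] == 1) & (y[:, 1] == 0)))
    d_01 = int(np.sum((y[:, 0] == 0) & (y[:, 1] == 1)))
    if group != "OS":
        d = d_10 + d_01
        d_10, d_01 = d // 2 + d % 2, d // 2
    return PairTable(group, c_cc, d_10, d_01, c_nn)


def concordance(table: PairTable) -> ConcordanceStats:
    """Casewise 2C/(2C+D) and pairwise C/(C+D) concordance."""
    c, d = table.c_cc, table.d_cnc
    if c + d == 0:
        raise ValueError("no affected pairs: concordance undefined")
    return ConcordanceStats(
        casewise=2 * c / (2 * c + d),
        pairwise=c / (c + d),
        prevalence=table.prevalence,
    )


def _table_loglik(table: PairTable, rho: float, t1: float, t2: float) -> float:
    p00, p01, p10, p11 = pair_cell_probs(t1, t2, rho)
    probs = np.array([p11, p10, p01, p00])
    counts = np.array([table.c_cc, table.d_10, table.d_01, table.c_nn], float)
    probs = np.clip(probs, 1e-300, 1.0)
    return float(np.sum(counts * np.log(probs)))


def tetrachoric(table: PairTable, ci: float = 0.95) -> TetrachoricEstimate:
    """ML tetrachoric correlation for a 2x2 concordance table.

    Two-step estimator: the thresholds are fixed at the values implied
    by the row/column margins, then rho maximizes the multinomial
    likelihood of the four cells; the CI comes from the profile
    likelihood in rho at the chi-square(1) cutoff.
    """
    n = table.n_pairs
    m1 = (table.c_cc + table.d_10) / n   # member-1 affected fraction
    m2 = (table.c_cc + table.d_01) / n
    boundary = False
    if m1 in (0.0, 1.0) or m2 in (0.0, 1.0):
        warnings.warn("empty margin: tetrachoric at boundary", RuntimeWarning)
        t1 = threshold_from_prevalence(min(max(m1, 0.5 / n), 1 - 0.5 / n))
        t2 = threshold_from_prevalence(min(max(m2, 0.5 / n), 1 - 0.5 / n))
        boundary = True
    else:
        t1 = threshold_from_prevalence(m1)
        t2 = threshold_from_prevalence(m2)

    res = minimize_scalar(
        lambda r: -_table_loglik(table, r, t1, t2),
        bounds=(-0.99999, 0.99999), method="bounded",
        options={"xatol": 1e-6},
    )
    rho_hat = float(res.x)
    ll_max = -float(res.fun)

    cut = chi2.ppf(ci, df=1) / 2.0

    def prof(r: float) -> float:
        return _table_loglik(table, r, t1, t2) - (ll_max - cut)

    lo = -0.99999 if prof(-0.99999) >= 0 else brentq(prof, -0.99999, rho_hat, xtol=1e-6)
    hi = 0.99999 if prof(0.99999) >= 0 else brentq(prof, rho_hat, 0.99999, xtol=1e-6)
    return TetrachoricEstimate(rho_hat, t1, t2, float(lo), float(hi), ll_max,
                               boundary=boundary)


def table1_report(records: pd.DataFrame,
                  groups: Sequence[str] = PAIR_GROUPS) -> pd.DataFrame:
    """Concordance-and-tetrachoric summary table, one row per pair group.

    Percentages are rounded to one decimal in the emitted table.
    """
    rows = []
    for g in groups:
        sub_all = records[records["pair_type"] == g]
        try:
            tab = build_pair_table(records, g)
        except EmptyGroupError:
            continue
        cs = concordance(tab) if tab.c_cc + tab.d_cnc > 0 else None
        tet = tetrachoric(tab)
        rows.append({
            "group": g,
            "n_individuals": len(sub_all),
            "n_pairs": tab.n_pairs,
            "pct_childless": round(100 * sub_all["childless"].mean(), 1),
            "c_cc": tab.c_cc,
            "d_cnc": tab.d_cnc,
            "casewise_pct": round(100 * cs.casewise, 1) if cs else np.nan,
            "pairwise_pct": round(100 * cs.pairwise, 1) if cs else np.nan,
            "tetrachoric": round(tet.rho, 2),
            "ci_low": round(tet.ci_low, 2),
            "ci_high": round(tet.ci_high, 2),
        })
    return pd.DataFrame(rows)
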