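"""Vectorized standard bivariate normal rectangle probabilities.

The liability-threshold machinery (tetrachoric likelihoods, twin-pair
log-likelihoods) needs Phi2(h, k; rho) = P(X <= h, Y <= k) for many
(h, k) pairs at once.  We evaluate it through Owen's T function
(Owen, 1956), which scipy provides to near machine precision, rather
than per-point numerical integration.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, owens_t

__all__ = ["bvn_cdf", "pair_cell_probs"]

_EPS = 1e-15


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    All arguments broadcast against each other; returns an ndarray (or
    scalar for scalar input).  Accurate to ~1e-14 for |rho| < 1; the
    degenerate rho = +/-1 limits are handled exactly.
    """
    h, k, rho = np.broadcast_arrays(
        np.asarray(h, float), np.asarray(k, float), np.asarray(rho, float)
    )
    out = np.empty(h.shape, float)

    ph = ndtr(h)
    pk = ndtr(k)

    # degenerate correlations
    hi = rho >= 1.0 - _EPS
    lo = rho <= -1.0 + _EPS
    out[hi] = np.minimum(ph, pk)[hi]
    out[lo] = np.maximum(ph + pk - 1.0, 0.0)[lo]

    gen = ~(hi | lo)
    if np.any(gen):
        hg, kg, rg = h[gen], k[gen], rho[gen]
        # exact zeros are replaced by +eps; Phi2 is continuous so the
        # one-sided limit is the value, and the delta term below is
        # evaluated consistently on the substituted arguments.
        hh = np.where(hg == 0.0, _EPS, hg)
        kk = np.where(kg == 0.0, _EPS, kg)
        s = np.sqrt((1.0 - rg) * (1.0 + rg))
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            ah = (kk / hh - rg) / s
            ak = (hh / kk - rg) / s
        ah = np.nan_to_num(ah, posinf=1e300, neginf=-1e300)
        ak = np.nan_to_num(ak, posinf=1e300, neginf=-1e300)
        delta = np.where(hh * kk < 0.0, 0.5, 0.0)
        val = 0.5 * (ph[gen] + pk[gen]) - owens_t(hh, ah) - owens_t(kk, ak) - delta
        # infinite thresholds: Phi2(-inf, .) = 0, Phi2(inf, k) = Phi(k)
        val = np.where(np.isneginf(hg) | np.isneginf(kg), 0.0, val)
        val = np.where(np.isposinf(hg), pk[gen], val)
        val = np.where(np.isposinf(kg) & np.isfinite(hg), ph[gen], val)
        out[gen] = np.clip(val, 0.0, np.minimum(ph, pk)[gen])

    if out.ndim == 0:
        return float(out)
    return out


def pair_cell_probs(t1, t2, rho):
    """Probabilities of the four binary outcome cells of a liability pair.

    Member j is "affected" when its liability exceeds threshold ``tj``.
    Returns (p00, p01, p10, p11) where the first index is member 1:
    p01 = member 2 affected only, p10 = member 1 affected only.
    The four entries sum to 1 to ~1e-14.
    """
    p_le = bvn_cdf(t1, t2, rho)
    c1 = ndtr(np.asarray(t1, float))
    c2 = ndtr(np.asarray(t2, float))
    p00 = p_le
    p10 = c2 - p_le          # 1 affected (X > t1), 2 not
    p01 = c1 - p_le
    p11 = 1.0 - c1 - c2 + p_le
    return p00, p01, p10, p11
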