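"""Rarefaction and extrapolation of Hill numbers (orders q = 0, 1, 2).

Interpolation uses the exact expected diversity of a hypergeometric
subsample: for q = 0 the classic rarefaction formula

    E[S(m)] = S_obs - sum_i C(n - x_i, m) / C(n, m),

for q = 1 the exact expected plug-in entropy of the subsample computed
from per-category hypergeometric probabilities, and for q = 2 the
closed form 1 / (1/m + (1 - 1/m) * sum x_i (x_i - 1) / (n (n - 1))),
which is exact for every m (it is also used for extrapolation).

Extrapolation beyond the sample follows the unified sampling-curve
framework of Chao and colleagues: q = 0 grows toward the Chao1 (or
Chao2) asymptote S_obs + f0_hat along

    S(n + m*) = S_obs + f0_hat * [1 - (1 - f1 / (n f0_hat + f1))**m*],

and q = 1 mixes the observed plug-in entropy with the asymptotic
entropy estimator (Good-Turing corrected, with the (1-A)^(1-n) tail
term) in proportion n/(n+m*) : m*/(n+m*).

Incidence data substitute sampling units T, incidence counts y_i and
incidence frequency counts Q_k throughout.

Confidence bands come from the unseen-category bootstrap: the observed
assemblage is augmented with f0_hat undetected categories at estimated
shares, n individuals (or T units) are resampled n_boot times and the
band is the normal approximation estimate +/- z * SD at each knot.
All binomial coefficients are computed in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, psi
from scipy.stats import hypergeom, norm

from .tabulate import AbundanceFreq, IncidenceFreq


@dataclass
class HillCurve:
    """Interpolated/extrapolated diversity of one order q with CI band."""

    data_type: str  # "abundance" or "incidence"
    q: int
    knots: pd.DataFrame  # columns: m, estimate, ci_low, ci_high, regime
    n_boot: int
    conf_level: float
    endpoint: int


def hill_number(proportions: Sequence[float], q: int) -> float:
    """Hill number (effective number of categories) of order q.

    q = 0 counts categories, q = 1 is the exponential of Shannon
    entropy, q = 2 the inverse Simpson concentration.
    """
    p = np.asarray(proportions, dtype=float)
    if p.size == 0:
        raise ValueError("empty proportion vector")
    if (p < 0).any():
        raise ValueError("proportions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    p = p[p > 0]
    if q == 0:
        return float(p.size)
    if q == 1:
        return float(math.exp(-(p * np.log(p)).sum()))
    if q == 2:
        return float(1.0 / (p * p).sum())
    raise ValueError("q must be 0, 1 or 2")


def _lchoose(a: np.ndarray | float, b: float) -> np.ndarray | float:
    """log C(a, b); -inf where a < b."""
    a = np.asarray(a, dtype=float)
    out = np.full_like(a, -np.inf)
    ok = a >= b
    out[ok] = gammaln(a[ok] + 1) - gammaln(b + 1) - gammaln(a[ok] - b + 1)
    return out


def _f0_hat(f1: float, f2: float, size: float) -> float:
    """Chao-type estimate of the number of undetected categories."""
    factor = (size - 1.0) / size if size > 1 else 0.0
    if f2 > 0:
        return factor * f1 * f1 / (2.0 * f2)
    return factor * f1 * (f1 - 1.0) / 2.0


def _entropy_asymptotic(counts: np.ndarray, size: int, f1: int, f2: int, a_size: float) -> float:
    """Asymptotic Shannon entropy estimator (Good-Turing tail correction).

    ``a_size`` is the effective number of draws entering the A constant:
    n - 1 for abundance data and T - 1 for incidence data.
    """
    x = counts.astype(float)
    n = float(size)
    h = float((x / n * (psi(n) - psi(x))).sum())
    if f1 == 0:
        return h
    if f2 > 0:
        a = 2.0 * f2 / (a_size * f1 + 2.0 * f2)
    elif f1 > 1:
        a = 2.0 / (a_size * (f1 - 1.0) + 2.0)
    else:
        a = 1.0
    if a < 1.0:
        r = np.arange(1, size)
        tail = float(((1.0 - a) ** r / r).sum())
        h += f1 / n * (1.0 - a) ** (1 - size) * (-math.log(a) - tail)
    return h


def _interp_entropy(counts: np.ndarray, size: int, m: int) -> float:
    """Exact expected plug-in entropy of a size-m subsample (no replacement)."""
    h = 0.0
    for x, mult in zip(*np.unique(counts, return_counts=True)):
        kmax = min(int(x), m)
        k = np.arange(1, kmax + 1)
        pmf = hypergeom.pmf(k, size, int(x), m)
        share = k / m
        h += mult * float(-(share * np.log(share) * pmf).sum())
    return h


def _abundance_estimate(counts: np.ndarray, m: int, q: int) -> float:
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    n = int(counts.sum())
    s_obs = counts.size
    if m < 1:
        raise ValueError("m must be >= 1")
    if q == 2:
        simpson = float((counts * (counts - 1.0)).sum()) / (n * (n - 1.0)) if n > 1 else 0.0
        return 1.0 / (1.0 / m + (1.0 - 1.0 / m) * simpson)
    if m <= n:
        if q == 0:
            num = _lchoose(n - counts, float(m))
            den = float(_lchoose(np.array([n], dtype=float), float(m))[0])
            return s_obs - float(np.exp(num - den).sum())
        return math.exp(_interp_entropy(counts, n, m))
    # extrapolation
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    m_star = m - n
    if q == 0:
        f0 = _f0_hat(f1, f2, n)
        if f0 == 0 or f1 == 0:
            return float(s_obs)
        return s_obs + f0 * (1.0 - (1.0 - f1 / (n * f0 + f1)) ** m_star)
    # q == 1: entropy mixture between observed plug-in and asymptotic
    p = counts / n
    h_obs = float(-(p * np.log(p)).sum())
    h_inf = _entropy_asymptotic(counts, n, f1, f2, a_size=n - 1.0)
    h_inf = max(h_inf, h_obs)
    w = n / (n + m_star)
    return math.exp(w * h_obs + (1.0 - w) * h_inf)


def _incidence_estimate(incidences: np.ndarray, t_units: int, t: int, q: int) -> float:
    y = np.asarray(incidences, dtype=np.int64)
    y = y[y > 0]
    big_t = int(t_units)
    u = int(y.sum())
    s_obs = y.size
    if t < 1:
        raise ValueError("t must be >= 1")
    if q == 2:
        ss = float((y * (y - 1.0)).sum())
        num = (t * u / big_t) ** 2
        den = t * u / big_t + t * (t - 1.0) / (big_t * (big_t - 1.0)) * ss if big_t > 1 else t * u / big_t
        return num / den if den > 0 else 1.0
    if t <= big_t:
        if q == 0:
            numer = _lchoose(big_t - y, float(t))
            den = float(_lchoose(np.array([big_t], dtype=float), float(t))[0])
            return s_obs - float(np.exp(numer - den).sum())
        # expected plug-in entropy over units, shares relative to E[U(t)]
        u_t = t * u / big_t
        h = 0.0
        for yy, mult in zip(*np.unique(y, return_counts=True)):
            kmax = min(int(yy), t)
            k = np.arange(1, kmax + 1)
            pmf = hypergeom.pmf(k, big_t, int(yy), t)
            share = k / u_t
            h += mult * float(-(share * np.log(share) * pmf).sum())
        return math.exp(h)
    t_star = t - big_t
    q1 = int((y == 1).sum())
    q2 = int((y == 2).sum())
    if q == 0:
        q0 = _f0_hat(q1, q2, big_t)
        if q0 == 0 or q1 == 0:
            return float(s_obs)
        return s_obs + q0 * (1.0 - (1.0 - q1 / (big_t * q0 + q1)) ** t_star)
    p = y / u
    h_obs = float(-(p * np.log(p)).sum())
    h_inf = _entropy_asymptotic(y, u, q1, q2, a_size=big_t - 1.0)
    h_inf = max(h_inf, h_obs)
    w = big_t / (big_t + t_star)
    return math.exp(w * h_obs + (1.0 - w) * h_inf)


def rarefy_extrapolate(
    freq: AbundanceFreq | IncidenceFreq, m: int, q: int
) -> float:
    """Diversity of order q at sample size m (abundance) or m units (incidence).

    Interpolates below the observed size, matches the observed Hill
    number exactly at the observed size and extrapolates above it.
    """
    if q not in (0, 1, 2):
        raise ValueError("q must be 0, 1 or 2")
    if isinstance(freq, AbundanceFreq):
        return _abundance_estimate(freq.counts, m, q)
    if isinstance(freq, IncidenceFreq):
        return _incidence_estimate(freq.incidences, freq.t, m, q)
    raise TypeError("freq must be AbundanceFreq or IncidenceFreq")


def _default_knots(observed: int, endpoint: int, n_knots: int) -> np.ndarray:
    grid = np.unique(np.round(np.linspace(1, endpoint, n_knots)).astype(int))
    return np.unique(np.concatenate([grid, [observed]]))


def _bootstrap_assemblage_abundance(
    freq: AbundanceFreq,
) -> np.ndarray:
    """Estimated category shares of the augmented (seen + unseen) assemblage."""
    x = freq.counts.astype(float)
    n = freq.n
    f1, f2 = freq.f(1), freq.f(2)
    f0 = int(math.ceil(_f0_hat(f1, f2, n)))
    if f1 == 0:
        c_hat = 1.0
    else:
        denom = (n - 1.0) * f1 + 2.0 * f2
        c_hat = 1.0 - f1 / n * ((n - 1.0) * f1 / denom) if denom > 0 else 1.0 - f1 / n
    w = (x / n) * (1.0 - x / n) ** n
    lam = (1.0 - c_hat) / w.sum() if w.sum() > 0 else 0.0
    p_seen = (x / n) * (1.0 - lam * (1.0 - x / n) ** n)
    if f0 > 0:
        p_unseen = np.full(f0, (1.0 - c_hat) / f0)
        p = np.concatenate([p_seen, p_unseen])
    else:
        p = p_seen
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def _bootstrap_assemblage_incidence(freq: IncidenceFreq) -> np.ndarray:
    """Estimated per-unit detection probabilities (seen + unseen categories)."""
    y = freq.incidences.astype(float)
    t, u = freq.t, freq.u
    q1, q2 = freq.q(1), freq.q(2)
    q0 = int(math.ceil(_f0_hat(q1, q2, t)))
    if q1 == 0:
        c_hat = 1.0
    else:
        denom = (t - 1.0) * q1 + 2.0 * q2
        c_hat = 1.0 - q1 / u * ((t - 1.0) * q1 / denom) if denom > 0 else 1.0 - q1 / u
    w = (y / t) * (1.0 - y / t) ** t
    lam = (1.0 - c_hat) * (u / t) / w.sum() if w.sum() > 0 else 0.0
    pi_seen = (y / t) * (1.0 - lam * (1.0 - y / t) ** t)
    if q0 > 0:
        pi_unseen = np.full(q0, min((u / t) * (1.0 - c_hat) / q0, 1.0))
        pi = np.concatenate([pi_seen, pi_unseen])
    else:
        pi = pi_seen
    return np.clip(pi, 0.0, 1.0)


def inext_curve(
    freq: AbundanceFreq | IncidenceFreq,
    q: int = 0,
    endpoint: int | None = None,
    n_knots: int = 40,
    n_boot: int = 10000,
    conf_level: float = 0.95,
    seed: int = 0,
    band: str = "normal",
    knots: Sequence[int] | None = None,
) -> HillCurve:
    """Rarefaction/extrapolation curve of order q with a bootstrap band.

    Defaults mirror common survey practice: 10,000 bootstrap replicates,
    0.95 confidence level, endpoints of 10,000 samples (abundance) or
    500 sampling units (incidence).  ``band`` selects the normal
    approximation (default) or bootstrap percentiles.
    """
    is_abund = isinstance(freq, AbundanceFreq)
    if not is_abund and not isinstance(freq, IncidenceFreq):
        raise TypeError("freq must be AbundanceFreq or IncidenceFreq")
    observed = freq.n if is_abund else freq.t
    if endpoint is None:
        endpoint = 10000 if is_abund else 500
    if endpoint <= observed:
        raise ValueError("endpoint must exceed the observed sample size")
    if knots is None:
        if n_knots < 2:
            raise ValueError("need at least two knots")
        knots = _default_knots(observed, endpoint, n_knots)
    else:
        knots = np.unique(np.asarray(knots, dtype=int))
        if knots.size < 1 or knots[0] < 1:
            raise ValueError("explicit knots must be positive integers")
    est = np.array([rarefy_extrapolate(freq, int(m), q) for m in knots])

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, knots.size))
    if is_abund:
        p = _bootstrap_assemblage_abundance(freq)
        n = freq.n
        for b in range(n_boot):
            counts = rng.multinomial(n, p)
            counts = counts[counts > 0]
            bf = AbundanceFreq(counts)
            boot[b] = [rarefy_extrapolate(bf, int(m), q) for m in knots]
    else:
        pi = _bootstrap_assemblage_incidence(freq)
        t = freq.t
        for b in range(n_boot):
            y = rng.binomial(t, pi)
            y = y[y > 0]
            if y.size == 0:
                boot[b] = np.nan
                continue
            bf = IncidenceFreq(y, n_units=t)
            boot[b] = [rarefy_extrapolate(bf, int(m), q) for m in knots]

    z = norm.ppf(0.5 + conf_level / 2.0)
    with np.errstate(invalid="ignore"):
        if band == "percentile":
            lo = np.nanpercentile(boot, 100 * (0.5 - conf_level / 2), axis=0)
            hi = np.nanpercentile(boot, 100 * (0.5 + conf_level / 2), axis=0)
        else:
            sd = np.nanstd(boot, axis=0, ddof=1)
            lo, hi = est - z * sd, est + z * sd
    regime = np.where(knots < observed, "interpolated",
                      np.where(knots == observed, "observed", "extrapolated"))
    frame = pd.DataFrame(
        {"m": knots, "estimate": est, "ci_low": lo, "ci_high": hi, "regime": regime}
    )
    return HillCurve(
        data_type="abundance" if is_abund else "incidence",
        q=q, knots=frame, n_boot=n_boot, conf_level=conf_level, endpoint=endpoint,
    )
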