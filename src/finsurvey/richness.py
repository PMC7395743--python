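"""Nonparametric species-richness estimators.

Six abundance-based models (homogeneous, Chao1, Chao1-bc, iChao1, ACE,
ACE-1) and their six incidence-based analogs (homogeneous, Chao2,
Chao2-bc, iChao2, ICE, ICE-1).  All use the frequencies of rare
categories — singletons f1/Q1, doubletons f2/Q2, ... — to estimate the
number of categories present in the assemblage but missed by the
sample, under the assumption that no category is structurally
undetectable.

Standard errors come from the asymptotic delta method with the
multinomial frequency-count covariance

    cov(f_i, f_j) = f_i (delta_ij - f_i / S_hat),

the approach used by coverage-based estimation software; a bootstrap
SE (resampling individuals or units from the observed assemblage) is
available as a cross-check.  95% confidence intervals use the
log-transform of Chao (1987) applied to the estimated number of
undetected categories, which keeps the lower bound above the observed
richness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .tabulate import AbundanceFreq, IncidenceFreq

ABUNDANCE_MODELS = ("homogeneous", "chao1", "chao1_bc", "ichao1", "ace", "ace1")
INCIDENCE_MODELS = ("homogeneous", "chao2", "chao2_bc", "ichao2", "ice", "ice1")

#: rare / infrequent category cutoff for the coverage-based estimators
DEFAULT_RARE_CUTOFF = 10


@dataclass
class RichnessEstimate:
    """Point estimate, SE and asymmetric 95% CI for one estimator model."""

    model: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    s_obs: int
    warnings: list[str] = field(default_factory=list)


def _f_vector(freq: AbundanceFreq) -> np.ndarray:
    """f[k] = number of categories with exactly k individuals (f[0] unused)."""
    kmax = int(freq.counts.max())
    f = np.zeros(kmax + 1)
    ks, cnts = np.unique(freq.counts, return_counts=True)
    f[ks] = cnts
    return f


# ---------------------------------------------------------------------------
# point estimators, written as functions of the frequency-count vector so the
# same code drives the point estimate and the delta-method gradient
# ---------------------------------------------------------------------------

def _s_obs(f: np.ndarray) -> float:
    return float(f[1:].sum())


def _n_total(f: np.ndarray) -> float:
    k = np.arange(len(f))
    return float((k * f).sum())


def _chao_extra(f1: float, f2: float, factor: float) -> float:
    """Estimated number of undetected categories, Chao-type."""
    if f2 > 0:
        return factor * f1 * f1 / (2.0 * f2)
    return factor * f1 * (f1 - 1.0) / 2.0


def _est_homogeneous(f: np.ndarray, size: float) -> float:
    f1 = f[1] if len(f) > 1 else 0.0
    c_hat = 1.0 - f1 / size
    if c_hat <= 0:
        return math.nan
    return _s_obs(f) / c_hat


def _est_chao(f: np.ndarray, factor: float) -> float:
    f1 = f[1] if len(f) > 1 else 0.0
    f2 = f[2] if len(f) > 2 else 0.0
    return _s_obs(f) + _chao_extra(f1, f2, factor)


def _est_chao_bc(f: np.ndarray, factor: float) -> float:
    f1 = f[1] if len(f) > 1 else 0.0
    f2 = f[2] if len(f) > 2 else 0.0
    return _s_obs(f) + factor * f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0))


def _est_ichao(f: np.ndarray, size: float, factor: float) -> float:
    """Improved Chao estimator using f3 and f4 (f4 -> 1 when zero)."""
    f1 = f[1] if len(f) > 1 else 0.0
    f2 = f[2] if len(f) > 2 else 0.0
    f3 = f[3] if len(f) > 3 else 0.0
    f4 = f[4] if len(f) > 4 else 0.0
    if f4 == 0:
        f4 = 1.0
    base = _est_chao(f, factor)
    c1 = (size - 3.0) / (4.0 * size)
    c2 = (size - 3.0) / (2.0 * (size - 1.0))
    return base + c1 * (f3 / f4) * max(f1 - c2 * f2 * f3 / f4, 0.0)


def _coverage_parts(f: np.ndarray, cutoff: int) -> tuple[float, float, float, float]:
    """(S_rare, S_abun, n_rare, sum_{i<=k} i(i-1) f_i)."""
    k = np.arange(len(f))
    rare = k <= cutoff
    s_rare = float(f[1:][rare[1:]].sum()) if len(f) > 1 else 0.0
    s_abun = float(f[1:][~rare[1:]].sum()) if len(f) > 1 else 0.0
    n_rare = float((k[rare] * f[rare]).sum())
    ssq = float((k[rare] * (k[rare] - 1) * f[rare]).sum())
    return s_rare, s_abun, n_rare, ssq


def _est_ace(
    f: np.ndarray, cutoff: int, order1: bool, correction: float = 1.0
) -> float:
    """ACE / ACE-1 (abundance) and, with ``correction``, ICE / ICE-1.

    ``correction`` is the finite-unit CV factor: 1 for abundance, and
    T_infreq/(T_infreq - 1) for incidence data.
    """
    f1 = f[1] if len(f) > 1 else 0.0
    s_rare, s_abun, n_rare, ssq = _coverage_parts(f, cutoff)
    if s_rare == 0:
        return s_abun
    if n_rare <= 1:
        return s_abun + s_rare
    c_rare = 1.0 - f1 / n_rare
    if c_rare <= 0:
        return math.nan
    gamma2 = max(s_rare / c_rare * correction * ssq / (n_rare * (n_rare - 1.0)) - 1.0, 0.0)
    if order1:
        gamma2 = max(
            gamma2 * (1.0 + (1.0 - c_rare) / c_rare * correction * ssq / (n_rare - 1.0)),
            0.0,
        )
    return s_abun + s_rare / c_rare + f1 / c_rare * gamma2


def _abundance_point(f: np.ndarray, model: str, cutoff: int) -> float:
    n = _n_total(f)
    factor = (n - 1.0) / n if n > 1 else 0.0
    if model == "homogeneous":
        return _est_homogeneous(f, n)
    if model == "chao1":
        return _est_chao(f, factor)
    if model == "chao1_bc":
        return _est_chao_bc(f, factor)
    if model == "ichao1":
        return _est_ichao(f, n, factor)
    if model == "ace":
        return _est_ace(f, cutoff, order1=False)
    if model == "ace1":
        return _est_ace(f, cutoff, order1=True)
    raise ValueError(f"unknown abundance model {model!r}")


def _incidence_point(f: np.ndarray, model: str, t: int, cutoff: int) -> float:
    u = _n_total(f)
    factor = (t - 1.0) / t
    corr = t / (t - 1.0)
    if model == "homogeneous":
        return _est_homogeneous(f, u)
    if model == "chao2":
        return _est_chao(f, factor)
    if model == "chao2_bc":
        return _est_chao_bc(f, factor)
    if model == "ichao2":
        return _est_ichao(f, float(t), factor)
    if model == "ice":
        return _est_ace(f, cutoff, order1=False, correction=corr)
    if model == "ice1":
        return _est_ace(f, cutoff, order1=True, correction=corr)
    raise ValueError(f"unknown incidence model {model!r}")


# ---------------------------------------------------------------------------
# variance: generic delta method over the frequency counts
# ---------------------------------------------------------------------------

def _delta_var(f: np.ndarray, point: Callable[[np.ndarray], float]) -> float:
    s_hat = point(f)
    if not math.isfinite(s_hat) or s_hat <= 0:
        return math.nan
    kmax = len(f) - 1
    grad = np.zeros(kmax + 1)
    h = 1e-5
    for k in range(1, kmax + 1):
        if f[k] == 0:
            continue
        fp, fm = f.copy(), f.copy()
        fp[k] += h
        fm[k] -= h
        grad[k] = (point(fp) - point(fm)) / (2.0 * h)
    idx = np.arange(1, kmax + 1)
    fv = f[idx]
    cov = np.diag(fv) - np.outer(fv, fv) / s_hat
    g = grad[idx]
    return float(max(g @ cov @ g, 0.0))


def log_ci(s_obs: float, estimate: float, variance: float) -> tuple[float, float]:
    """Chao (1987) log-transform 95% CI on the undetected-richness scale.

    The transform is applied to D = S_hat - S_obs, which guarantees the
    lower limit never drops below the observed richness.
    """
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    d = estimate - s_obs
    if d <= 0:
        return (float(s_obs), float(s_obs))
    r = math.exp(1.96 * math.sqrt(math.log(1.0 + variance / (d * d))))
    return (s_obs + d / r, s_obs + d * r)


def _bootstrap_var_abundance(
    freq: AbundanceFreq, point: Callable[[np.ndarray], float], n_boot: int, seed: int
) -> float:
    # resample from the unseen-augmented assemblage (estimated f0 extra
    # categories), otherwise the rare-frequency variability is understated
    from .rarefaction import _bootstrap_assemblage_abundance

    rng = np.random.default_rng(seed)
    n = freq.n
    p = _bootstrap_assemblage_abundance(freq)
    out = np.empty(n_boot)
    for b in range(n_boot):
        counts = rng.multinomial(n, p)
        counts = counts[counts > 0]
        f = np.zeros(int(counts.max()) + 1)
        ks, cs = np.unique(counts, return_counts=True)
        f[ks] = cs
        out[b] = point(f)
    out = out[np.isfinite(out)]
    return float(out.var(ddof=1)) if out.size > 1 else math.nan


def _bootstrap_var_incidence(
    freq: IncidenceFreq, point: Callable[[np.ndarray], float], n_boot: int, seed: int
) -> float:
    from .rarefaction import _bootstrap_assemblage_incidence

    rng = np.random.default_rng(seed)
    t = freq.t
    pi = _bootstrap_assemblage_incidence(freq)
    out = np.empty(n_boot)
    for b in range(n_boot):
        y = rng.binomial(t, pi)
        y = y[y > 0]
        if y.size == 0:
            out[b] = math.nan
            continue
        f = np.zeros(int(y.max()) + 1)
        ks, cs = np.unique(y, return_counts=True)
        f[ks] = cs
        out[b] = point(f)
    out = out[np.isfinite(out)]
    return float(out.var(ddof=1)) if out.size > 1 else math.nan


def _finish(
    model: str, f: np.ndarray, s_obs: int, point: Callable[[np.ndarray], float],
    var_fn: Callable[[Callable[[np.ndarray], float]], float],
) -> RichnessEstimate:
    warnings: list[str] = []
    est = point(f)
    if math.isnan(est):
        warnings.append("zero estimated sample coverage; estimate undefined")
        return RichnessEstimate(model, math.nan, math.nan, math.nan, math.nan, s_obs, warnings)
    est = max(est, float(s_obs))
    var = _delta_var(f, point)
    if math.isnan(var):
        var = var_fn(point)
        warnings.append("delta-method variance unavailable; bootstrap SE used")
    se = math.sqrt(var) if var >= 0 else math.nan
    lo, hi = log_ci(s_obs, est, var if math.isfinite(var) else 0.0)
    return RichnessEstimate(model, est, se, lo, hi, s_obs, warnings)


def abundance_richness(
    freq: AbundanceFreq,
    model: str,
    rare_cutoff: int = DEFAULT_RARE_CUTOFF,
    se_method: str = "delta",
    n_boot: int = 500,
    seed: int = 0,
) -> RichnessEstimate:
    """Estimate total richness from abundance frequency counts."""
    if model not in ABUNDANCE_MODELS:
        raise ValueError(f"model must be one of {ABUNDANCE_MODELS}")
    f = _f_vector(freq)
    point = lambda fv: _abundance_point(fv, model, rare_cutoff)
    if se_method == "bootstrap":
        est = point(f)
        if math.isnan(est):
            return _finish(model, f, freq.s_obs, point, lambda p: math.nan)
        est = max(est, float(freq.s_obs))
        var = _bootstrap_var_abundance(freq, point, n_boot, seed)
        lo, hi = log_ci(freq.s_obs, est, var)
        return RichnessEstimate(model, est, math.sqrt(var), lo, hi, freq.s_obs)
    return _finish(
        model, f, freq.s_obs, point,
        lambda p: _bootstrap_var_abundance(freq, p, n_boot, seed),
    )


def incidence_richness(
    freq: IncidenceFreq,
    model: str,
    infreq_cutoff: int = DEFAULT_RARE_CUTOFF,
    se_method: str = "delta",
    n_boot: int = 500,
    seed: int = 0,
) -> RichnessEstimate:
    """Estimate total richness from incidence frequency counts."""
    if model not in INCIDENCE_MODELS:
        raise ValueError(f"model must be one of {INCIDENCE_MODELS}")
    if freq.t < 2:
        raise ValueError("need at least two sampling units")
    fake = AbundanceFreq(freq.incidences)  # reuse the f-vector builder
    f = _f_vector(fake)
    point = lambda fv: _incidence_point(fv, model, freq.t, infreq_cutoff)
    if se_method == "bootstrap":
        est = point(f)
        if math.isnan(est):
            return _finish(model, f, freq.s_obs, point, lambda p: math.nan)
        est = max(est, float(freq.s_obs))
        var = _bootstrap_var_incidence(freq, point, n_boot, seed)
        lo, hi = log_ci(freq.s_obs, est, var)
        return RichnessEstimate(model, est, math.sqrt(var), lo, hi, freq.s_obs)
    return _finish(
        model, f, freq.s_obs, point,
        lambda p: _bootstrap_var_incidence(freq, p, n_boot, seed),
    )


def estimate_table(freq_a: AbundanceFreq, freq_i: IncidenceFreq, **kwargs):
    """All twelve estimators: abundance block then incidence block.

    Returns a pandas DataFrame with columns model, data_type, estimate,
    se, ci_low, ci_high (estimates rounded to 3 decimals in the CSV
    writer, full precision here).
    """
    import pandas as pd

    rows = []
    for model in ABUNDANCE_MODELS:
        e = abundance_richness(freq_a, model, **kwargs)
        rows.append(("abundance", e))
    for model in INCIDENCE_MODELS:
        e = incidence_richness(freq_i, model, **kwargs)
        rows.append(("incidence", e))
    return pd.DataFrame(
        {
            "data_type": [d for d, _ in rows],
            "model": [e.model for _, e in rows],
            "estimate": [e.estimate for _, e in rows],
            "se": [e.se for _, e in rows],
            "ci_low": [e.ci_low for _, e in rows],
            "ci_high": [e.ci_high for _, e in rows],
        }
    )
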