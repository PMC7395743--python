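"""Bayesian Poisson-multinomial model of market species composition.

Per-bag category counts y[b, c] are modeled as

    y[b, c] ~ Poisson(lambda_c * eps_b)

with category rates lambda_c and multiplicative bag effects eps_b
(eps_1 = 1 for identifiability).  Conditioned on bag totals this is the
multinomial composition model (the "Poisson trick"): the quantity of
interest is pi_c = lambda_c / sum_c lambda_c, the market share of each
category.  Priors are vague Gammas — lambda_c ~ Gamma(a, a) with
a = 0.01 by default, eps_b ~ Gamma(1, 1) — making every full
conditional conjugate, so the model is fitted by plain Gibbs sampling
with no external MCMC engine.  In the single-bag case the pi posterior
reduces exactly to Dirichlet(a + y), which serves as the closed-form
oracle in the test suite.

Species with more than ``cutoff`` trimmings are modeled individually;
rarer ones are pooled by genus (requiem sharks *Carcharhinus*,
chimaeras *Callorhinchus*) or into "Other", and failed amplifications
form their own "Unidentified" category, never redistributed.  The
cutoff is lowered stepwise for as long as all chains keep converging
(split Gelman-Rubin R-hat < 1.1).
"""

from __future__ import annotations

import math
import warnings as _warnings
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .tabulate import CountTable, SPECIES_RANKS

GENUS_BINS = ("Carcharhinus", "Callorhinchus")
OTHER = "Other"
UNIDENTIFIED = "Unidentified"


@dataclass
class ModelCategories:
    """Mapping from ledger taxa to modeled composition categories."""

    cutoff: int
    individual: list[str]           # species/complex categories modeled on their own
    bin_map: dict[str, str]         # taxon -> modeled category label

    @property
    def categories(self) -> list[str]:
        seen: list[str] = list(self.individual)
        for label in self.bin_map.values():
            if label not in seen:
                seen.append(label)
        return seen


@dataclass
class BagCountMatrix:
    """Trimming counts per (bag, modeled category)."""

    counts: np.ndarray              # shape (n_bags, n_categories), ints
    categories: list[str]
    bag_ids: list[tuple]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("bag counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("bag counts must be nonnegative")

    @property
    def bag_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class CompositionPosterior:
    """Posterior draws and summaries of the composition model."""

    categories: list[str]
    pi_draws: np.ndarray            # (n_draws, n_categories), each row sums to 1
    lambda_draws: np.ndarray
    eps_draws: np.ndarray
    summary: pd.DataFrame           # category, mean, ci_low, ci_high, rhat
    rhat: np.ndarray                # per lambda parameter
    dic: float
    chains: int
    iterations: int
    burn_in: int
    thin: int
    seed: int
    warnings: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return bool(np.all(self.rhat < 1.1))


def _genus_of(taxon: str) -> str:
    return taxon.split()[0].split("/")[0]


def bin_categories(count_table: CountTable, cutoff: int = 20) -> ModelCategories:
    """Assign every observed taxon to a modeled composition category.

    Strictly more than ``cutoff`` trimmings at species/complex rank
    earns an individual category; rarer species fall into their genus
    bin (for *Carcharhinus* and *Callorhinchus*) or "Other"; taxa only
    identified to genus/family join the same bins; unidentified
    trimmings keep their own category.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be nonnegative")
    individual: list[str] = []
    bin_map: dict[str, str] = {}
    df = count_table.table
    for _, row in df[df["count"] > 0].iterrows():
        taxon, rank, count = row["taxon"], row["rank"], int(row["count"])
        if rank == "unidentified":
            bin_map[taxon] = UNIDENTIFIED
        elif rank in SPECIES_RANKS and count > cutoff:
            individual.append(taxon)
            bin_map[taxon] = taxon
        else:
            genus = _genus_of(taxon)
            bin_map[taxon] = genus if genus in GENUS_BINS else OTHER
    return ModelCategories(cutoff=cutoff, individual=individual, bin_map=bin_map)


def bag_count_matrix(ledger: pd.DataFrame, cats: ModelCategories) -> BagCountMatrix:
    """Tally the ledger into the per-bag modeled-category count matrix."""
    work = ledger.copy()
    labels = work["assigned_taxon"].where(
        work["assignment_rank"] != "unidentified", UNIDENTIFIED
    )
    work["category"] = [
        cats.bin_map.get(t, UNIDENTIFIED if t == UNIDENTIFIED else OTHER) for t in labels
    ]
    categories = cats.categories
    for label in work["category"].unique():
        if label not in categories:
            categories.append(label)
    pivot = (
        work.groupby(["event_id", "vendor_id", "bag_id", "category"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=categories, fill_value=0)
    )
    return BagCountMatrix(
        pivot.to_numpy(), categories=categories, bag_ids=list(pivot.index)
    )


def _split_rhat(chains: np.ndarray) -> float:
    """Split Gelman-Rubin potential scale reduction for one parameter.

    ``chains`` has shape (n_chains, n_draws); each chain is split in
    half, giving 2*n_chains sequences.
    """
    m, n = chains.shape
    half = n // 2
    seqs = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    means = seqs.mean(axis=1)
    variances = seqs.var(axis=1, ddof=1)
    w = variances.mean()
    b = half * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (half - 1) / half * w + b / half
    return float(math.sqrt(var_plus / w))


def fit_composition(
    y: BagCountMatrix,
    cats: ModelCategories | None = None,
    chains: int = 3,
    iterations: int = 20000,
    burn_in: int | None = None,
    thin: int = 5,
    prior_shape: float = 0.01,
    seed: int = 0,
) -> CompositionPosterior:
    """Gibbs-sample the Poisson-multinomial composition posterior.

    Full conditionals (shape/rate parameterization):

        lambda_c | . ~ Gamma(a + sum_b y[b,c],  a + sum_b eps_b)
        eps_b    | . ~ Gamma(1 + sum_c y[b,c],  1 + sum_c lambda_c)   (b >= 2)

    ``burn_in`` defaults to half the iterations.  Deterministic under a
    fixed seed; per-chain streams are spawned from the seed so results
    do not depend on category order beyond relabeling.
    """
    counts = y.counts
    n_bags, n_cat = counts.shape
    if n_cat < 2:
        raise ValueError("need at least two categories")
    if n_bags < 1:
        raise ValueError("need at least one bag")
    if burn_in is None:
        burn_in = iterations // 2
    if burn_in >= iterations:
        raise ValueError("burn_in must be smaller than iterations")
    warn: list[str] = []
    zero_cats = np.flatnonzero(counts.sum(axis=0) == 0)
    if zero_cats.size:
        warn.append(
            "categories with zero total count: "
            + ", ".join(y.categories[i] for i in zero_cats)
        )

    cat_tot = counts.sum(axis=0).astype(float)
    bag_tot = counts.sum(axis=1).astype(float)
    kept = (iterations - burn_in) // thin
    lam_store = np.empty((chains, kept, n_cat))
    eps_store = np.empty((chains, kept, n_bags))
    # each category gets its own substream keyed by (seed, chain, label),
    # so reordering categories relabels the posterior without changing it
    cat_keys = [zlib.crc32(label.encode("utf-8")) for label in y.categories]
    for ci in range(chains):
        cat_rngs = [
            np.random.default_rng(np.random.SeedSequence(entropy=[seed, ci, key]))
            for key in cat_keys
        ]
        bag_rng = np.random.default_rng(np.random.SeedSequence(entropy=[seed, ci, 2**33]))
        eps = np.ones(n_bags)
        lam = np.array(
            [r.gamma(prior_shape + tot + 1.0, 1.0) for r, tot in zip(cat_rngs, cat_tot)]
        )
        k = 0
        for it in range(iterations):
            rate = prior_shape + eps.sum()
            lam = np.array(
                [r.gamma(prior_shape + tot, 1.0 / rate) for r, tot in zip(cat_rngs, cat_tot)]
            )
            if n_bags > 1:
                eps[1:] = bag_rng.gamma(1.0 + bag_tot[1:], 1.0 / (1.0 + lam.sum()))
            if it >= burn_in and (it - burn_in) % thin == 0:
                lam_store[ci, k] = lam
                eps_store[ci, k] = eps
                k += 1
    rhat = np.array([_split_rhat(lam_store[:, :, c]) for c in range(n_cat)])
    lam_draws = lam_store.reshape(-1, n_cat)
    eps_draws = eps_store.reshape(-1, n_bags)
    pi_draws = lam_draws / lam_draws.sum(axis=1, keepdims=True)
    mean = pi_draws.mean(axis=0)
    lo = np.percentile(pi_draws, 2.5, axis=0)
    hi = np.percentile(pi_draws, 97.5, axis=0)
    summary = pd.DataFrame(
        {"category": y.categories, "mean": mean, "ci_low": lo, "ci_high": hi, "rhat": rhat}
    )
    post = CompositionPosterior(
        categories=list(y.categories),
        pi_draws=pi_draws,
        lambda_draws=lam_draws,
        eps_draws=eps_draws,
        summary=summary,
        rhat=rhat,
        dic=math.nan,
        chains=chains,
        iterations=iterations,
        burn_in=burn_in,
        thin=thin,
        seed=seed,
        warnings=warn,
    )
    post.dic = dic(post, y)
    return post


def _deviance(lam: np.ndarray, eps: np.ndarray, counts: np.ndarray) -> float:
    mu = np.outer(eps, lam)
    mu = np.clip(mu, 1e-300, None)
    ll = counts * np.log(mu) - mu - gammaln(counts + 1.0)
    return float(-2.0 * ll.sum())


def dic(posterior: CompositionPosterior, y: BagCountMatrix) -> float:
    """Deviance Information Criterion, DIC = D_bar + p_D (Spiegelhalter).

    p_D = D_bar - D(theta_bar) with theta_bar the posterior means of the
    rates and bag effects.
    """
    draws = posterior.lambda_draws
    if draws.shape[0] < 100:
        raise ValueError("need at least 100 retained draws for DIC")
    counts = y.counts
    devs = np.array(
        [_deviance(lam, eps, counts) for lam, eps in zip(draws, posterior.eps_draws)]
    )
    d_bar = float(devs.mean())
    d_hat = _deviance(draws.mean(axis=0), posterior.eps_draws.mean(axis=0), counts)
    p_d = d_bar - d_hat
    if devs.std() == 0:
        _warnings.warn("degenerate posterior: zero deviance variance, p_D = 0")
        p_d = 0.0
    return d_bar + p_d


CUTOFF_GRID = (20, 15, 10, 5, 1)


def cutoff_search(
    count_table: CountTable,
    ledger: pd.DataFrame,
    start: int = 20,
    grid: Sequence[int] = CUTOFF_GRID,
    **fit_kwargs,
) -> tuple[ModelCategories, CompositionPosterior]:
    """Lower the individual-category cutoff while the model keeps converging.

    Fits at ``start``, then walks down the cutoff grid; stops at the
    first non-converged fit (any split R-hat >= 1.1) and returns the
    last converged one.
    """
    if start < 0:
        raise ValueError("start must be nonnegative")
    steps = [start] + [g for g in grid if g < start]
    best: tuple[ModelCategories, CompositionPosterior] | None = None
    for cutoff in steps:
        cats = bin_categories(count_table, cutoff=cutoff)
        matrix = bag_count_matrix(ledger, cats)
        post = fit_composition(matrix, cats, **fit_kwargs)
        if not post.converged:
            if best is None:
                raise RuntimeError(
                    f"model did not converge at starting cutoff {start}: "
                    f"max R-hat = {post.rhat.max():.3f}"
                )
            break
        best = (cats, post)
    assert best is not None
    return best
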