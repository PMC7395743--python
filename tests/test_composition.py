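"""Composition model: binning rules, Gibbs oracle checks, DIC, cutoff search."""

import numpy as np
import pandas as pd
import pytest

from finsurvey import (
    BagCountMatrix,
    MarketSimConfig,
    bag_count_matrix,
    bin_categories,
    build_count_table,
    cutoff_search,
    dic,
    fit_composition,
    simulate_market,
)
from finsurvey.composition import OTHER, UNIDENTIFIED

from conftest import small_pool


def single_bag(y, labels=None):
    labels = labels or [f"cat{i}" for i in range(len(y))]
    return BagCountMatrix(np.array([y]), categories=labels, bag_ids=[(1, 1, 1)])


def test_binning_respects_strict_cutoff(gz_table):
    table, _ = gz_table
    cats = bin_categories(table, cutoff=20)
    assert len(cats.individual) == 13
    # a 22-count species is individual, the 20-boundary is strict
    assert "Carcharhinus leucas" in cats.individual
    cats5 = bin_categories(table, cutoff=5)
    assert len(cats5.individual) > 13
    # exact-cutoff taxon is binned, not individual
    boundary = bin_categories(table, cutoff=22)
    assert "Carcharhinus leucas" not in boundary.individual
    assert boundary.bin_map["Carcharhinus leucas"] == "Carcharhinus"


def test_binning_routes_genus_and_other(gz_table):
    table, _ = gz_table
    cats = bin_categories(table, cutoff=20)
    assert cats.bin_map["Carcharhinus spp."] == "Carcharhinus"
    assert cats.bin_map["Callorhinchus spp."] == "Callorhinchus"
    assert cats.bin_map["Galeocerdo cuvier"] == OTHER
    assert cats.bin_map["Carcharhinidae"] == OTHER
    # every observed taxon maps somewhere
    observed = set(table.table.loc[table.table["count"] > 0, "taxon"])
    assert observed <= set(cats.bin_map)


def test_cutoff_zero_keeps_every_species_individual(gz_table):
    table, _ = gz_table
    cats = bin_categories(table, cutoff=0)
    n_species = (
        (table.table["count"] > 0)
        & table.table["rank"].isin(["species", "complex"])
    ).sum()
    assert len(cats.individual) == n_species


def test_bag_count_matrix_shapes(default_ledger):
    ledger, _ = default_ledger
    table = build_count_table(ledger)
    cats = bin_categories(table, cutoff=20)
    matrix = bag_count_matrix(ledger, cats)
    assert matrix.counts.shape[0] == 200
    assert matrix.counts.sum() == len(ledger)
    assert (matrix.bag_totals == 10).all()
    assert UNIDENTIFIED in matrix.categories


def test_non_integer_counts_rejected():
    with pytest.raises(ValueError, match="integers"):
        BagCountMatrix(np.array([[1.5, 2.0]]), categories=["a", "b"], bag_ids=[(1, 1, 1)])


def test_single_bag_posterior_matches_dirichlet_oracle():
    """With one bag and prior shape a, pi is exactly Dirichlet(a + y)."""
    y = np.array([3, 1])
    post = fit_composition(
        single_bag(y), chains=3, iterations=16000, prior_shape=1.0, seed=2
    )
    kept = post.pi_draws.shape[0]
    expected = (y + 1.0) / (y.sum() + 2.0)        # Dirichlet mean
    var = expected * (1 - expected) / (y.sum() + 2 + 1)  # Dirichlet variance
    mc_se = np.sqrt(var / kept)
    # MCMC autocorrelation inflates the naive MC SE; 3 SEs on an ESS-deflated
    # draw count is the criterion, use a conservative 10x inflation guard
    assert np.all(np.abs(post.pi_draws.mean(axis=0) - expected) < 3 * mc_se * 10)
    assert np.abs(post.pi_draws.mean(axis=0) - expected).max() < 0.01


def test_pi_draws_sum_to_one_exactly():
    post = fit_composition(single_bag([5, 3, 2]), chains=2, iterations=2000, seed=1)
    assert np.allclose(post.pi_draws.sum(axis=1), 1.0, atol=1e-12)
    s = post.summary
    assert ((s["ci_low"] <= s["mean"]) & (s["mean"] <= s["ci_high"])).all()


def test_degenerate_single_category_dominance():
    y = np.array([[50, 0], [48, 0], [52, 0]])
    m = BagCountMatrix(y, categories=["A", "B"], bag_ids=[(1, 1, b) for b in range(3)])
    post = fit_composition(m, chains=2, iterations=4000, seed=3)
    assert post.summary.set_index("category").loc["A", "mean"] > 0.99
    assert any("zero total count" in w for w in post.warnings)


def test_category_permutation_only_relabels_posterior():
    y = np.array([[6, 3, 1], [5, 4, 2], [7, 2, 2]])
    bags = [(1, 1, b) for b in range(3)]
    m1 = BagCountMatrix(y, categories=["A", "B", "C"], bag_ids=bags)
    m2 = BagCountMatrix(y[:, [2, 0, 1]], categories=["C", "A", "B"], bag_ids=bags)
    p1 = fit_composition(m1, chains=2, iterations=2000, seed=9)
    p2 = fit_composition(m2, chains=2, iterations=2000, seed=9)
    s1 = p1.summary.set_index("category").sort_index()
    s2 = p2.summary.set_index("category").sort_index()
    pd.testing.assert_frame_equal(s1, s2)


def test_parameter_recovery_on_simulated_market():
    rng = np.random.default_rng(21)
    pi = np.array([0.36, 0.19, 0.08, 0.07, 0.06, 0.05, 0.05, 0.04, 0.04, 0.03, 0.02, 0.01])
    pi = pi / pi.sum()
    y = rng.multinomial(10, pi, size=200)
    m = BagCountMatrix(y, categories=[f"c{i}" for i in range(pi.size)],
                       bag_ids=[(1, 1, b) for b in range(200)])
    post = fit_composition(m, chains=3, iterations=6000, seed=4)
    assert post.converged
    means = post.summary["mean"].to_numpy()
    assert np.abs(means - pi).max() < 0.03
    covered = ((post.summary["ci_low"] <= pi) & (pi <= post.summary["ci_high"])).sum()
    assert covered >= pi.size - 2


def test_dic_penalty_tracks_free_parameter_count():
    """Refit to posterior-mean data: p_D approx = #free parameters (+-30%)."""
    rng = np.random.default_rng(30)
    n_bags, n_cat = 40, 6
    lam = np.array([40.0, 20.0, 10.0, 8.0, 6.0, 4.0])
    y = rng.poisson(np.tile(lam, (n_bags, 1)))
    m = BagCountMatrix(y, categories=[f"c{i}" for i in range(n_cat)],
                       bag_ids=[(1, 1, b) for b in range(n_bags)])
    post = fit_composition(m, chains=3, iterations=8000, seed=6)
    n_free = n_cat + (n_bags - 1)
    from finsurvey.composition import _deviance

    d_bar = np.mean([
        _deviance(l, e, m.counts) for l, e in zip(post.lambda_draws, post.eps_draws)
    ])
    d_hat = _deviance(post.lambda_draws.mean(axis=0), post.eps_draws.mean(axis=0), m.counts)
    p_d = d_bar - d_hat
    assert abs(p_d - n_free) / n_free < 0.30


def test_dic_requires_enough_draws():
    post = fit_composition(single_bag([4, 4]), chains=2, iterations=2000, seed=1)
    with pytest.raises(ValueError):
        short = post
        short.lambda_draws = short.lambda_draws[:50]
        dic(short, single_bag([4, 4]))


def test_rhat_agrees_with_arviz():
    import arviz as az

    post = fit_composition(single_bag([8, 4, 2]), chains=3, iterations=4000, seed=11)
    kept = post.lambda_draws.shape[0] // 3
    chains = post.lambda_draws.reshape(3, kept, -1)
    ref = az.rhat(az.convert_to_dataset(chains))["x"].values
    assert np.allclose(post.rhat, ref, atol=0.01)


def test_cutoff_search_reaches_floor_on_clean_data():
    pool = small_pool([0.4, 0.3, 0.2, 0.1])
    config = MarketSimConfig(
        species_pool=pool, n_events=4, vendors_per_event=5, fail_rate=0.0,
        genus_only_rate=0.0, vendor_heterogeneity=50.0, seed=13,
    )
    ledger, _ = simulate_market(config)
    table = build_count_table(ledger)
    cats, post = cutoff_search(table, ledger, start=20, chains=3, iterations=3000, seed=13)
    assert cats.cutoff == 1
    assert post.converged


def test_cutoff_search_start_zero_equals_direct_fit():
    pool = small_pool([0.6, 0.4])
    config = MarketSimConfig(
        species_pool=pool, n_events=2, vendors_per_event=2, fail_rate=0.0,
        genus_only_rate=0.0, seed=14,
    )
    ledger, _ = simulate_market(config)
    table = build_count_table(ledger)
    cats, post = cutoff_search(table, ledger, start=0, chains=2, iterations=2000, seed=14)
    direct_cats = bin_categories(table, cutoff=0)
    direct = fit_composition(
        bag_count_matrix(ledger, direct_cats), direct_cats,
        chains=2, iterations=2000, seed=14,
    )
    assert cats.cutoff == 0
    pd.testing.assert_frame_equal(post.summary, direct.summary)
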