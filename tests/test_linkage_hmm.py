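"""Tests of the three-state beta-binomial linkage HMM."""

import itertools

import numpy as np
import pytest
from scipy.stats import betabinom

from poolqtl import (
    CrossConfig,
    HMMParams,
    MarkerSet,
    PoolCounts,
    call_qtls,
    compare_pools,
    emission_logprob,
    estimate_background,
    forward_backward,
    recomb_prob,
    simulate_cross,
    select_pool,
    simulate_pool_counts,
    transition_matrix,
)
from poolqtl.linkage_hmm import SUP, INF, BG


def _pool(pos, k, n, chrom="chrI"):
    m = len(pos)
    ms = MarkerSet(
        chrom=np.array([chrom] * m, dtype=object),
        pos=np.asarray(pos),
        inferior_allele=np.array(["C"] * m, dtype=object),
        superior_allele=np.array(["T"] * m, dtype=object),
    )
    return PoolCounts(marker_set=ms, k=np.asarray(k), n=np.asarray(n))


def brute_force_posteriors(k, n, pos, params):
    """Exhaustive path enumeration over all 3^L state sequences."""
    L = len(k)
    logE = np.array([[emission_logprob(k[t], n[t], s, params)
                      for s in (SUP, INF, BG)] for t in range(L)])
    r = [recomb_prob(float(pos[t + 1] - pos[t]), params.map_scale)
         for t in range(L - 1)]
    T = [transition_matrix(ri) for ri in r]
    post = np.zeros((L, 3))
    total = 0.0
    for path in itertools.product(range(3), repeat=L):
        lp = np.log(params.initial_probs[path[0]]) + logE[0, path[0]]
        for t in range(1, L):
            lp += np.log(T[t - 1][path[t - 1], path[t]]) + logE[t, path[t]]
        w = np.exp(lp)
        total += w
        for t in range(L):
            post[t, path[t]] += w
    return post / total


# ---------------------------------------------------------------------------
# transition model

def test_recomb_prob_closed_form():
    L = 125_000
    assert recomb_prob(0, L) == 0.0
    assert recomb_prob(L * np.log(2), L) == pytest.approx(0.25, abs=1e-12)
    assert recomb_prob(1e9, L) == pytest.approx(0.5, abs=1e-12)
    d = np.linspace(0, 1e6, 50)
    r = recomb_prob(d, L)
    assert (np.diff(r) > 0).all()  # monotone increasing
    with pytest.raises(ValueError):
        recomb_prob(-1, L)
    with pytest.raises(ValueError):
        recomb_prob(10, 0)


def test_transition_matrix_values():
    assert np.array_equal(transition_matrix(0.0), np.eye(3))
    T = transition_matrix(0.5)
    assert np.allclose(np.diag(T), 0.5)
    assert np.allclose(T[~np.eye(3, dtype=bool)], 0.25)
    for r in (0.0, 0.1, 0.37, 0.5):
        T = transition_matrix(r)
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-15)
        assert np.array_equal(T, T.T)
    with pytest.raises(ValueError):
        transition_matrix(0.6)


# ---------------------------------------------------------------------------
# emissions

def test_emission_one_draw_closed_form():
    params = HMMParams()
    # BetaBinomial(1; 1, a, b) = a / (a + b): brute-force beta-density integral
    assert np.exp(emission_logprob(1, 1, SUP, params)) == pytest.approx(10 / 11,
                                                                        abs=1e-12)
    assert np.exp(emission_logprob(0, 1, BG, HMMParams(alpha_bg=7, beta_bg=7))
                  ) == pytest.approx(0.5, abs=1e-12)


@pytest.mark.parametrize("n", [1, 5, 38, 200])
@pytest.mark.parametrize("state", [SUP, INF, BG])
def test_emission_normalizes(n, state):
    params = HMMParams(alpha_bg=3.7, beta_bg=5.2)
    k = np.arange(n + 1)
    total = np.exp(emission_logprob(k, np.full(n + 1, n), state, params)).sum()
    assert total == pytest.approx(1.0, abs=1e-10)


def test_emission_matches_scipy_betabinom():
    params = HMMParams(alpha_bg=4.5, beta_bg=6.25)
    rng = np.random.default_rng(0)
    ab = {SUP: (10, 1), INF: (1, 10), BG: (4.5, 6.25)}
    for state, (a, b) in ab.items():
        n = rng.integers(1, 120, 50)
        k = rng.integers(0, n + 1)
        ours = emission_logprob(k, n, state, params)
        ref = betabinom.logpmf(k, n, a, b)
        assert np.allclose(ours, ref, atol=1e-10)


def test_emission_rejects_invalid():
    with pytest.raises(ValueError):
        emission_logprob(5, 3, SUP, HMMParams())
    with pytest.raises(ValueError):
        emission_logprob(-1, 3, SUP, HMMParams())


# ---------------------------------------------------------------------------
# forward-backward

def test_single_site_posterior_proportional_to_emissions():
    params = HMMParams(alpha_bg=50, beta_bg=50)
    counts = _pool([1000], [30], [38])
    post = forward_backward(counts, params, estimate_bg=False)
    e = np.exp([emission_logprob(30, 38, s, params) for s in (SUP, INF, BG)])
    expected = e / e.sum()
    row = post.iloc[0]
    assert np.allclose([row.p_sup, row.p_inf, row.p_bg], expected, atol=1e-12)


def test_forward_backward_matches_enumeration():
    rng = np.random.default_rng(42)
    params = HMMParams(alpha_bg=8, beta_bg=8)
    for _ in range(20):
        L = rng.integers(2, 9)
        pos = np.sort(rng.choice(np.arange(1, 500_000), L, replace=False))
        n = rng.poisson(38, L) + 1
        k = rng.binomial(n, rng.uniform(0, 1, L))
        counts = _pool(pos, k, n)
        post = forward_backward(counts, params, estimate_bg=False)
        ours = post[["p_sup", "p_inf", "p_bg"]].to_numpy()
        exact = brute_force_posteriors(k, n, pos, params)
        assert np.max(np.abs(ours - exact)) < 1e-10


def test_posteriors_normalized_on_long_chain():
    rng = np.random.default_rng(3)
    S = 5000
    pos = np.arange(1, S + 1) * 200
    n = rng.poisson(38, S) + 1
    k = rng.binomial(n, 0.5)
    post = forward_backward(_pool(pos, k, n), HMMParams(), estimate_bg=False)
    total = post[["p_sup", "p_inf", "p_bg"]].sum(axis=1)
    assert np.allclose(total, 1.0, atol=1e-9)
    assert (post["linkage_score"].abs() <= 1).all()


def test_parent_swap_negates_scores_bitwise(selected_counts):
    params = HMMParams(alpha_bg=2.0, beta_bg=3.0)
    fwd = forward_backward(selected_counts, params, estimate_bg=False)
    swapped = PoolCounts(
        marker_set=selected_counts.marker_set,
        k=selected_counts.n - selected_counts.k,
        n=selected_counts.n,
    )
    rev = forward_backward(swapped, params.swapped(), estimate_bg=False)
    assert np.array_equal(rev["linkage_score"].to_numpy(),
                          -fwd["linkage_score"].to_numpy())
    assert np.array_equal(rev["p_sup"].to_numpy(), fwd["p_inf"].to_numpy())


# ---------------------------------------------------------------------------
# background estimation

def test_background_recovers_simulated_betabinom(rng):
    n = rng.poisson(38, 10_000) + 1
    p = rng.beta(8, 8, 10_000)
    k = rng.binomial(n, p)
    counts = _pool(np.arange(1, 10_001) * 100, k, n)
    for symmetric in (False, True):
        a, b = estimate_background(counts, symmetric=symmetric)
        assert a == pytest.approx(8, rel=0.25)
        assert b == pytest.approx(8, rel=0.25)


def test_background_falls_back_on_binomial_data(rng):
    n = np.full(5000, 38)
    k = rng.binomial(n, 0.5)
    counts = _pool(np.arange(1, 5001) * 100, k, n)
    assert estimate_background(counts) == (50.0, 50.0)


def test_background_on_null_pool_is_symmetric(null_counts):
    a, b = estimate_background(null_counts)
    assert a > 1 and b > 1
    assert a == pytest.approx(b, rel=0.35)


def test_background_requires_enough_sites():
    counts = _pool(np.arange(1, 11) * 100, np.full(10, 5), np.full(10, 10))
    with pytest.raises(ValueError, match=">= 30"):
        estimate_background(counts)


# ---------------------------------------------------------------------------
# QTL calling

def _posterior_frame(chrom, pos, score):
    import pandas as pd

    p_sup = np.clip(score, 0, 1)
    p_inf = np.clip(-np.asarray(score), 0, 1)
    return pd.DataFrame({
        "chrom": chrom, "pos": pos, "k": 0, "n": 0,
        "p_sup": p_sup, "p_inf": p_inf,
        "p_bg": 1 - p_sup - p_inf,
        "linkage_score": score,
    })


def test_no_significant_sites_no_calls():
    df = _posterior_frame("chrI", np.arange(1, 101) * 1000, np.zeros(100))
    assert call_qtls(df) == []


def test_threshold_is_strict():
    df = _posterior_frame("chrI", np.arange(1, 21) * 1000, np.full(20, 0.95))
    assert call_qtls(df, threshold=0.95) == []


def test_gap_and_min_snps_rules():
    pos = np.concatenate([np.arange(1, 13) * 1000,          # run of 12
                          100_000 + np.arange(12) * 1000])  # far-away run of 12
    score = np.full(24, 0.99)
    calls = call_qtls(_posterior_frame("chrI", pos, score), min_snps=10,
                      max_gap_bp=30_000)
    assert len(calls) == 2
    merged = call_qtls(_posterior_frame("chrI", pos, score), min_snps=10,
                       max_gap_bp=200_000)
    assert len(merged) == 1
    small = call_qtls(_posterior_frame("chrI", pos[:5], score[:5]), min_snps=10)
    assert small == []


def test_sign_convention_and_span():
    pos = np.arange(1, 31) * 1000
    score = np.concatenate([np.full(15, 0.99), np.full(15, -0.99)])
    calls = call_qtls(_posterior_frame("chrI", pos, score), min_snps=10)
    assert len(calls) == 2
    sup, inf = calls
    assert sup.parent == "superior" and sup.mean_linkage > 0
    assert inf.parent == "inferior" and inf.mean_linkage < 0
    assert (sup.start, sup.end) == (1000, 15000)
    assert (inf.start, inf.end) == (16000, 30000)


def test_planted_qtl_recovered(default_population):
    pop = default_population
    counts = simulate_pool_counts(pop, select_pool(pop, 22))
    post = forward_backward(counts)
    calls = call_qtls(post)
    for chrom, qpos, _ in pop.config.qtls:
        assert any(c.chrom == chrom and c.start <= qpos <= c.end
                   for c in calls), f"missed {chrom}:{qpos}"


def test_compare_pools_self_and_null(default_population):
    pop = default_population
    counts = simulate_pool_counts(pop, select_pool(pop, 22))
    post = forward_backward(counts)
    calls = call_qtls(post)
    assert calls
    same = compare_pools(calls, post)
    assert all(c.presence_in_other_pool == "Yes" for c in same)
    flat = post.copy()
    flat["linkage_score"] = 0.0
    absent = compare_pools(calls, flat)
    assert all(c.presence_in_other_pool == "No" for c in absent)


def test_compare_pools_shared_and_specific():
    pos = np.arange(1, 31) * 1000
    a = _posterior_frame("chrI", pos,
                         np.where(pos <= 15_000, 0.99, 0.0))
    calls = call_qtls(a, min_snps=10)
    assert len(calls) == 1
    weak = _posterior_frame("chrI", pos, np.where(pos <= 15_000, 0.7, 0.0))
    assert compare_pools(calls, weak)[0].presence_in_other_pool == "Weak"
    opposite = _posterior_frame("chrI", pos, np.where(pos <= 15_000, -0.99, 0.0))
    assert compare_pools(calls, opposite)[0].presence_in_other_pool == "No"
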