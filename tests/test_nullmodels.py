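import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from poolfilter import (
    BatteryConfig,
    ConfigurationError,
    NotTestableError,
    NullTestResult,
    ValidationError,
    build_pools,
    format_summary_grid,
    generate_dataset,
    mc_richness_test,
    null_trait_test,
    results_to_frame,
    run_test_battery,
    spearman_rho,
    standardize_rain,
    summarize_tests,
    trait_statistic,
    weighted_sample_wor,
)
from poolfilter.cli import _site_abundance
from poolfilter.nullmodels import _draw_index_matrix


# ---------------------------------------------------------------------------
# Spearman rho


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ((1, 2, 3), (2, 4, 6), 1.0),
        ((1, 2, 3), (3, 2, 1), -1.0),
        # ties: average ranks x=(1, 2.5, 2.5, 4), y=(1, 3, 2, 4), then Pearson
        ((1, 2, 2, 4), (1, 3, 2, 4), 0.9486832980505138),
    ],
)
def test_spearman_rho_matches_rank_pearson(x, y, expected):
    assert spearman_rho(x, y) == pytest.approx(expected)


def test_spearman_rho_rejects_constant_vectors():
    with pytest.raises(ValidationError, match="constant"):
        spearman_rho([1, 1, 1], [1, 2, 3])


def test_spearman_rho_is_rank_invariant():
    x = np.array([3, 8, 1, 12, 5])
    y = np.array([2, 9, 4, 30, 6])
    assert spearman_rho(x, y) == pytest.approx(spearman_rho(x**3, y))


# ---------------------------------------------------------------------------
# Monte Carlo richness test


def exact_richness_p(regional, observed):
    """Exhaustive-enumeration oracle for the richness-test p-value.

    Enumerates every joint outcome of the per-site uniform integer draws
    and accumulates P(rho_sim >= rho_obs); draws with undefined rho
    (constant across sites) never exceed the observed value.
    """
    obs_rho = stats.spearmanr(regional, observed).statistic
    hits = total = 0
    for draw in itertools.product(*(range(r + 1) for r in regional)):
        total += 1
        if len(set(draw)) == 1:
            continue
        rho = stats.spearmanr(regional, draw).statistic
        if rho >= obs_rho - 1e-9:
            hits += 1
    return obs_rho, hits / total


@pytest.mark.parametrize("observed, expected_rho", [((2, 3, 4), 1.0), ((2, 1, 0), -1.0)])
def test_mc_richness_p_matches_exhaustive_enumeration(observed, expected_rho):
    regional = (2, 3, 4)
    rho_exact, p_exact = exact_richness_p(regional, observed)
    assert rho_exact == pytest.approx(expected_rho)
    res = mc_richness_test(regional, observed, n_iter=4999, seed=42)
    assert res.obs_rho == pytest.approx(expected_rho)
    se = np.sqrt(p_exact * (1 - p_exact) / res.n_iter)
    assert abs(res.p_value - p_exact) <= 3 * se


def test_mc_richness_preconditions():
    with pytest.raises(ValidationError, match="exceed"):
        mc_richness_test((2, 3, 4), (3, 3, 3), seed=0)
    with pytest.raises(ValidationError, match="constant"):
        mc_richness_test((3, 3, 3), (1, 2, 3), seed=0)


def test_mc_richness_is_deterministic_given_seed():
    a = mc_richness_test((5, 9, 14, 20), (2, 4, 9, 11), n_iter=999, seed=7)
    b = mc_richness_test((5, 9, 14, 20), (2, 4, 9, 11), n_iter=999, seed=7)
    assert a == b


# ---------------------------------------------------------------------------
# weighted sampling without replacement


def test_weighted_first_draw_frequency_matches_probability():
    rng = np.random.default_rng(3)
    n_rep = 20_000
    hits = sum(weighted_sample_wor([2, 1, 1], 1, rng)[0] == 0 for _ in range(n_rep))
    se = np.sqrt(0.5 * 0.5 / n_rep)
    assert abs(hits / n_rep - 0.5) <= 3 * se


def test_k_equals_n_returns_all_indices():
    rng = np.random.default_rng(0)
    assert set(weighted_sample_wor([1, 2, 3], 3, rng)) == {0, 1, 2}


def test_weighted_sampling_input_errors():
    rng = np.random.default_rng(0)
    with pytest.raises(ValidationError):
        weighted_sample_wor([1, 1], 3, rng)
    with pytest.raises(ValidationError):
        weighted_sample_wor([1, 0], 1, rng)


def successive_inclusion_probs(weights, k):
    """Exact inclusion probabilities under successive sampling (oracle)."""
    w = np.asarray(weights, float)
    n = len(w)
    incl = np.zeros(n)
    for perm in itertools.permutations(range(n), k):
        p = 1.0
        remaining = w.sum()
        for i in perm:
            p *= w[i] / remaining
            remaining -= w[i]
        for i in perm:
            incl[i] += p
    return incl


def test_vectorized_engine_matches_sequential_scheme():
    """Exponential-key draws reproduce successive-sampling inclusion probs."""
    weights, k = np.array([3.0, 2.0, 1.0]), 2
    exact = successive_inclusion_probs(weights, k)

    rng = np.random.default_rng(5)
    n_rep = 20_000
    idx = _draw_index_matrix(3, k, n_rep, rng, weights)
    freq_vec = np.bincount(idx.ravel(), minlength=3) / n_rep

    freq_seq = np.zeros(3)
    for _ in range(4000):
        freq_seq[weighted_sample_wor(weights, k, rng)] += 1
    freq_seq /= 4000

    for i in range(3):
        se = np.sqrt(exact[i] * (1 - exact[i]))
        assert abs(freq_vec[i] - exact[i]) <= 4 * se / np.sqrt(n_rep)
        assert abs(freq_seq[i] - exact[i]) <= 4 * se / np.sqrt(4000)


def test_equal_weights_reduce_to_uniform_sampling():
    """EP and WP null distributions coincide when all weights are equal."""
    rng = np.random.default_rng(11)
    values = np.arange(10.0)
    ep = values[_draw_index_matrix(10, 4, 2000, rng)].mean(axis=1)
    wp = values[_draw_index_matrix(10, 4, 2000, rng, np.full(10, 2.5))].mean(axis=1)
    assert stats.ks_2samp(ep, wp).pvalue > 0.01


# ---------------------------------------------------------------------------
# trait statistics


@pytest.mark.parametrize(
    "values, statistic, kwargs, expected",
    [
        ((1, 1, 1), "sdNTD", {}, 0.0),
        # nearest-neighbour distances of (1,2,4,8) are (1,1,2,4); SD = sqrt(2)
        ((1, 2, 4, 8), "sdNTD", {}, np.sqrt(2)),
        ((1, 2, 3, 4), "mean", {}, 2.5),
        ((1, 2, 3, 4), "variance", {}, 5 / 3),
        (
            ("unassisted", "wind", "unassisted", "animal"),
            "category_proportion",
            {"category": "unassisted"},
            0.5,
        ),
    ],
)
def test_trait_statistics(values, statistic, kwargs, expected):
    assert trait_statistic(values, statistic, **kwargs) == pytest.approx(expected)


@pytest.mark.parametrize(
    "values, statistic", [((), "mean"), ((1,), "variance"), ((1, 2), "sdNTD")]
)
def test_insufficient_sample_raises_not_testable(values, statistic):
    with pytest.raises(NotTestableError):
        trait_statistic(values, statistic)


def test_unknown_statistic_is_configuration_error():
    with pytest.raises(ConfigurationError):
        trait_statistic((1, 2, 3), "kurtosis")


# ---------------------------------------------------------------------------
# null_trait_test


def test_ep_p_value_matches_subset_enumeration():
    # among the C(5,3)=10 subsets of (1..5), only {1,2,3} has mean <= 2
    source, target = np.arange(1.0, 6.0), np.array([1.0, 2.0, 3.0])
    res = null_trait_test(source, target, statistic="mean", n_iter=4999, seed=2)
    se = np.sqrt(0.1 * 0.9 / 4999)
    assert abs(res.p_low - 0.1) <= 3 * se
    assert res.p_high == 1.0  # every subset mean is >= 2
    assert res.outcome == "random"  # p_low ~ 0.1 is above alpha = 0.025


def test_degenerate_target_equals_source_is_random():
    v = np.array([1.0, 2.0, 3.0])
    res = null_trait_test(v, v, statistic="mean", seed=0)
    assert (res.p_low, res.p_high, res.outcome) == (1.0, 1.0, "random")
    assert res.null_sd == 0.0


def test_wp_weights_favouring_small_values_shift_null_down():
    source, target = np.arange(1.0, 6.0), np.array([1.0, 2.0, 3.0])
    weights = np.array([16.0, 8.0, 4.0, 2.0, 1.0])
    ep = null_trait_test(source, target, statistic="mean", n_iter=4999, seed=3)
    wp = null_trait_test(
        source, target, statistic="mean", weighting="WP", weights=weights,
        n_iter=4999, seed=3,
    )
    assert wp.null_mean < ep.null_mean
    assert wp.p_low > ep.p_low


def test_small_target_propagates_as_not_testable():
    res = null_trait_test(np.arange(5.0), np.array([1.0, 2.0]), statistic="sdNTD", seed=0)
    assert res.outcome == "not_testable"
    assert np.isnan(res.p_low)


def test_identical_seeds_give_identical_results():
    src = np.random.default_rng(0).lognormal(size=20)
    tgt = src[:7]
    a = null_trait_test(src, tgt, statistic="variance", n_iter=999, seed=12)
    b = null_trait_test(src, tgt, statistic="variance", n_iter=999, seed=12)
    assert a == b


def test_plus_one_convention():
    src = np.random.default_rng(1).normal(size=12)
    tgt = src[:5]
    plain = null_trait_test(src, tgt, statistic="mean", n_iter=999, seed=4)
    plus = null_trait_test(src, tgt, statistic="mean", n_iter=999, seed=4, plus_one=True)
    assert plus.p_low == pytest.approx((plain.p_low * 999 + 1) / 1000)


# ---------------------------------------------------------------------------
# battery and summary


@pytest.fixture(scope="module")
def small_battery():
    from poolfilter import SyntheticConfig

    ds = generate_dataset(SyntheticConfig(n_sites=2, n_regional=40), seed=9)
    rain = standardize_rain(ds.observations)
    pools = build_pools(ds.observations, rain)
    abund = _site_abundance(ds.observations)
    cfg = BatteryConfig(n_iter=199)
    results = run_test_battery(pools, ds.traits, abund, cfg, seed=13)
    return ds, pools, abund, cfg, results


def test_battery_grid_composition(small_battery):
    _, pools, _, _, results = small_battery
    df = results_to_frame(results)
    # dispersal method is categorical: proportion tests only, never spread
    assert df.query("trait == 'dispersal_method' and statistic != 'category_proportion'").empty
    # abundance: mean under EP only, and only out of the regional pool
    ab = df.query("trait == 'abundance'")
    assert set(ab.statistic) == {"mean"} and set(ab.weighting) == {"EP"}
    assert set(ab.source_pool) == {"regional"}
    # establishment transition is equiprobable only
    est = df.query("source_pool == 'propagule'")
    assert set(est.weighting) == {"EP"}
    # per site and regional transition: 1 + 4*5 + 2 = 23 tests
    per = df.query("site_id == 'site01' and target_pool == 'propagule'")
    assert len(per) == 23


def test_battery_is_deterministic(small_battery):
    ds, pools, abund, cfg, results = small_battery
    again = run_test_battery(pools, ds.traits, abund, cfg, seed=13)
    pd.testing.assert_frame_equal(results_to_frame(results), results_to_frame(again))


def test_summarize_counts_and_grid_rendering():
    def fake(site, outcome):
        return NullTestResult(
            site, "regional", "propagule", "height", "mean", "EP", 99,
            1.0, 1.0, 0.1, 0.5, 0.5, outcome, 0,
        )

    results = [fake(f"s{i}", "lower") for i in range(3)]
    results += [fake("s3", "higher")]
    results += [fake(f"s{i}", "random") for i in range(4, 12)]
    summary = summarize_tests(results)
    row = summary.iloc[0]
    assert (row.n_lower, row.n_higher, row.n_sites_tested) == (3, 1, 12)
    grid = format_summary_grid(summary)
    assert grid.loc["regional->propagule | mean (EP)", "height"] == "-3/+1"
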