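"""Monte Carlo richness test and trait-based null models.

Two resampling analyses form the core of the pipeline.

**Richness test.** Whether local richness (propagule pool, community, seed
rain or seed bank) tracks regional richness is tested against a null in
which each site's local richness is an integer drawn uniformly from
``[0, R_j]``, ``R_j`` being the site's regional richness. Spearman's rho
between regional and simulated local richness is computed for each of
``n_iter`` replicates and the one-tailed p-value is the proportion of
simulated rho greater than or equal to the observed rho.

**Trait null models.** For each site and transition (regional pool to
propagule pool / seed rain / seed bank, and propagule pool to community),
the observed value of a trait statistic — mean, sample variance, or the
standard deviation of nearest trait distances (sdNTD) — is compared with
its distribution over ``n_iter`` random assemblies of the same size drawn
without replacement from the source pool. Draws are either equiprobable
(EP) or weighted by regional abundance (WP, successive sampling: each
draw proportional to the remaining weights). Both one-sided p-values are
reported; with the default alpha = 0.025 an assembly is called ``lower``
or ``higher`` than random, else ``random``. Simulated values exactly
tying the observed count toward both tails.

Following the field's summary-table convention, a variance or sdNTD
significantly *lower* than the null indicates trait convergence
(underdispersion, environmental filtering) and *higher* indicates
divergence (overdispersion, limiting similarity); the mapping lives in
:data:`OUTCOME_INTERPRETATION` and can be overridden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, NotTestableError, ValidationError
from .pools import PoolMembership

logger = logging.getLogger(__name__)

N_ITER_DEFAULT = 4999
ALPHA_DEFAULT = 0.025
#: float slack used when counting simulated values tying the observed one
TIE_TOL = 1e-9

#: ecological reading of each (statistic, outcome) pair; swappable
OUTCOME_INTERPRETATION = {
    ("variance", "lower"): "convergence",
    ("variance", "higher"): "divergence",
    ("sdNTD", "lower"): "convergence",
    ("sdNTD", "higher"): "divergence",
    ("mean", "lower"): "lower_mean",
    ("mean", "higher"): "higher_mean",
    ("category_proportion", "lower"): "lower_proportion",
    ("category_proportion", "higher"): "higher_proportion",
}

#: minimum sample size for each statistic to be defined
_MIN_N = {"mean": 1, "category_proportion": 1, "variance": 2, "sdNTD": 3}

NUMERIC_TRAITS = ("height", "seed_mass", "cgi", "sla")


# ---------------------------------------------------------------------------
# elementary statistics


def spearman_rho(x, y) -> float:
    """Tie-corrected Spearman rank correlation (Pearson on average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("spearman_rho needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("spearman_rho is undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def _rho_against(sims: np.ndarray, x_ranks: np.ndarray) -> np.ndarray:
    """Spearman rho of each row of ``sims`` against a fixed ranked vector.

    Rows that are constant have undefined rho and yield NaN.
    """
    ry = stats.rankdata(sims, axis=1)
    xc = x_ranks - x_ranks.mean()
    yc = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum() * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, yc @ xc / denom, np.nan)


def trait_statistic(
    values, statistic: str, category: str | None = None, sdntd_ddof: int = 1
) -> float:
    """One of the four assembly test statistics on a species sample.

    ``mean`` and ``variance`` (n-1 denominator) are the usual moments.
    ``sdNTD`` is the sample SD across species of each species' distance to
    its nearest neighbour on the trait axis (duplicated values have
    distance 0). ``category_proportion`` is the fraction of species in the
    named category of a categorical trait.
    """
    if statistic not in _MIN_N:
        raise ConfigurationError(f"unknown statistic {statistic!r}")
    if statistic == "category_proportion":
        if category is None:
            raise ConfigurationError("category_proportion requires a category name")
        vals = np.asarray(values, dtype=object)
        if len(vals) < 1:
            raise NotTestableError("category_proportion needs at least 1 species")
        return float(np.mean(vals == category))
    vals = np.asarray(values, dtype=float)
    if len(vals) < _MIN_N[statistic]:
        raise NotTestableError(
            f"{statistic} needs at least {_MIN_N[statistic]} species, got {len(vals)}"
        )
    if statistic == "mean":
        return float(vals.mean())
    if statistic == "variance":
        return float(vals.var(ddof=1))
    # sdNTD
    return float(_sdntd_rows(np.sort(vals)[None, :], ddof=sdntd_ddof)[0])


def _sdntd_rows(sorted_rows: np.ndarray, ddof: int = 1) -> np.ndarray:
    """sdNTD of each (already sorted) row of a matrix; needs >= 3 columns."""
    d = np.diff(sorted_rows, axis=1)
    nn = np.empty_like(sorted_rows)
    nn[:, 0] = d[:, 0]
    nn[:, -1] = d[:, -1]
    nn[:, 1:-1] = np.minimum(d[:, :-1], d[:, 1:])
    return nn.std(axis=1, ddof=ddof)


# ---------------------------------------------------------------------------
# sampling


def weighted_sample_wor(weights, k: int, rng: np.random.Generator) -> np.ndarray:
    """Successive sampling without replacement, proportional to weight.

    Items are drawn one at a time, each with probability proportional to
    the weights of the items still available. Returns ``k`` distinct
    indices in draw order.
    """
    w = np.asarray(weights, dtype=float)
    n = len(w)
    if k > n:
        raise ValidationError(f"cannot draw {k} items from {n}")
    if np.any(w <= 0):
        raise ValidationError("weights must be strictly positive")
    avail = np.arange(n)
    w_avail = w.copy()
    out = np.empty(k, dtype=np.intp)
    for i in range(k):
        p = w_avail / w_avail.sum()
        j = rng.choice(len(avail), p=p)
        out[i] = avail[j]
        avail = np.delete(avail, j)
        w_avail = np.delete(w_avail, j)
    return out


def _draw_index_matrix(
    n: int,
    k: int,
    n_iter: int,
    rng: np.random.Generator,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """``n_iter`` samples of ``k`` distinct indices out of ``n``, vectorized.

    Equiprobable draws use uniform random keys. Weighted draws use
    exponential keys ``Exp(1) / w_i`` and take the ``k`` smallest, which
    reproduces exactly the successive-sampling distribution of
    :func:`weighted_sample_wor`.
    """
    if k > n:
        raise ValidationError(f"cannot draw {k} items from {n}")
    if weights is None:
        keys = rng.random((n_iter, n))
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValidationError("weights must be strictly positive")
        keys = rng.exponential(size=(n_iter, n)) / w
    if k == n:
        return np.tile(np.arange(n), (n_iter, 1))
    return np.argpartition(keys, k - 1, axis=1)[:, :k]


# ---------------------------------------------------------------------------
# Monte Carlo richness test


@dataclass
class RichnessTestResult:
    """Observed rank correlation and its one-tailed Monte Carlo p-value."""

    pool_pair: str
    obs_rho: float
    p_value: float
    n_iter: int
    rng_seed: int | None


def mc_richness_test(
    regional_richness,
    observed_local,
    n_iter: int = N_ITER_DEFAULT,
    seed: int | None = None,
    pool_pair: str = "",
) -> RichnessTestResult:
    """Test whether local richness tracks regional richness.

    Under the null each site's local richness is uniform on the integers
    ``0..R_j``. ``p = #(rho_sim >= rho_obs) / n_iter`` (one-tailed).
    Being rank-based, the result is invariant to strictly monotone
    transforms of the regional vector.
    """
    R = np.asarray(regional_richness, dtype=int)
    local = np.asarray(observed_local, dtype=int)
    if R.shape != local.shape or R.ndim != 1 or len(R) < 3:
        raise ValidationError("need equal-length richness vectors over >= 3 sites")
    if np.any(local > R):
        raise ValidationError("local richness cannot exceed regional richness")
    if np.any(R < 0) or np.any(local < 0):
        raise ValidationError("richness must be non-negative")
    if np.ptp(R) == 0:
        raise ValidationError("regional richness is constant; rho undefined")

    rng = np.random.default_rng(seed)
    x_ranks = stats.rankdata(R)
    obs_rho = float(_rho_against(local[None, :].astype(float), x_ranks)[0])
    sims = rng.integers(0, R + 1, size=(n_iter, len(R)))
    rho_sim = _rho_against(sims.astype(float), x_ranks)
    # undefined (constant-draw) replicates never exceed the observed rho
    p = float(np.sum(rho_sim >= obs_rho - TIE_TOL) / n_iter)
    return RichnessTestResult(pool_pair, obs_rho, p, n_iter, seed)


# ---------------------------------------------------------------------------
# trait null models


@dataclass
class NullTestResult:
    """One site x trait x statistic x weighting randomization test."""

    site_id: str
    source_pool: str
    target_pool: str
    trait: str
    statistic: str
    weighting: str
    n_iter: int
    observed: float
    null_mean: float
    null_sd: float
    p_low: float
    p_high: float
    outcome: str  # lower | higher | random | not_testable
    rng_seed: int | None

    @property
    def interpretation(self) -> str | None:
        return OUTCOME_INTERPRETATION.get((self.statistic, self.outcome))


def _outcome(p_low: float, p_high: float, alpha: float) -> str:
    low = p_low < alpha
    high = p_high < alpha
    if low and high:
        raise ValidationError(
            f"both one-sided p-values significant (p_low={p_low}, p_high={p_high}); "
            "refusing to choose a side"
        )
    if low:
        return "lower"
    if high:
        return "higher"
    return "random"


def null_trait_test(
    source_values,
    target_values,
    *,
    statistic: str,
    weighting: str = "EP",
    weights=None,
    category: str | None = None,
    n_iter: int = N_ITER_DEFAULT,
    seed: int | None = None,
    alpha: float = ALPHA_DEFAULT,
    plus_one: bool = False,
    sdntd_ddof: int = 1,
    site_id: str = "",
    trait: str = "",
    source_pool: str = "",
    target_pool: str = "",
) -> NullTestResult:
    """Randomization test of one trait statistic for one assembly.

    ``source_values`` are the trait values of the source pool (trait-
    complete; drop missing values from both pools beforehand) and
    ``target_values`` those of the observed assembly, a subset of the
    source pool. The null redraws ``len(target_values)`` species from the
    source without replacement, uniformly (``weighting="EP"``) or
    proportionally to ``weights`` (``"WP"``), ``n_iter`` times.

    ``p_low``/``p_high`` are the proportions of simulated statistics at or
    below / at or above the observed value; ties count toward both. With
    ``plus_one=True`` the ``(count + 1) / (n_iter + 1)`` convention is
    used instead. A target equal in size to its source is degenerate —
    every draw reproduces it — and is reported as ``random`` with both
    p-values 1.
    """
    if weighting not in ("EP", "WP"):
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    if weighting == "WP" and weights is None:
        raise ConfigurationError("WP weighting requires weights")

    meta = dict(
        site_id=site_id,
        source_pool=source_pool,
        target_pool=target_pool,
        trait=trait,
        statistic=statistic,
        weighting=weighting,
        n_iter=n_iter,
        rng_seed=seed,
    )

    is_cat = statistic == "category_proportion"
    if is_cat:
        src = np.asarray(np.asarray(source_values, dtype=object) == category, dtype=float)
        tgt = np.asarray(np.asarray(target_values, dtype=object) == category, dtype=float)
    else:
        src = np.asarray(source_values, dtype=float)
        tgt = np.asarray(target_values, dtype=float)
    n, k = len(src), len(tgt)

    if k < _MIN_N[statistic] or n < _MIN_N[statistic]:
        return NullTestResult(
            **meta,
            observed=np.nan,
            null_mean=np.nan,
            null_sd=np.nan,
            p_low=np.nan,
            p_high=np.nan,
            outcome="not_testable",
        )
    if k > n:
        raise ValidationError(f"target larger than source ({k} > {n})")

    stat_kwargs = {"category": category, "sdntd_ddof": sdntd_ddof}
    if is_cat:
        observed = float(tgt.mean())
    else:
        observed = trait_statistic(tgt, statistic, **stat_kwargs)

    if k == n:
        # every possible draw reproduces the observed assembly
        return NullTestResult(
            **meta,
            observed=observed,
            null_mean=observed,
            null_sd=0.0,
            p_low=1.0,
            p_high=1.0,
            outcome="random",
        )

    rng = np.random.default_rng(seed)
    idx = _draw_index_matrix(n, k, n_iter, rng, None if weighting == "EP" else weights)
    sampled = src[idx]
    if statistic in ("mean", "category_proportion"):
        sims = sampled.mean(axis=1)
    elif statistic == "variance":
        sims = sampled.var(axis=1, ddof=1)
    else:  # sdNTD
        sims = _sdntd_rows(np.sort(sampled, axis=1), ddof=sdntd_ddof)

    tol = TIE_TOL * max(1.0, abs(observed))
    n_low = int(np.sum(sims <= observed + tol))
    n_high = int(np.sum(sims >= observed - tol))
    if plus_one:
        p_low = (n_low + 1) / (n_iter + 1)
        p_high = (n_high + 1) / (n_iter + 1)
    else:
        p_low = n_low / n_iter
        p_high = n_high / n_iter

    return NullTestResult(
        **meta,
        observed=observed,
        null_mean=float(sims.mean()),
        null_sd=float(sims.std(ddof=1)),
        p_low=float(p_low),
        p_high=float(p_high),
        outcome=_outcome(p_low, p_high, alpha),
    )


# ---------------------------------------------------------------------------
# the full test battery


@dataclass
class BatteryConfig:
    """Settings for :func:`run_test_battery`."""

    n_iter: int = N_ITER_DEFAULT
    alpha: float = ALPHA_DEFAULT
    plus_one: bool = False
    sdntd_ddof: int = 1
    #: proportion of this dispersal category is the categorical "mean"
    focal_category: str = "unassisted"
    #: optional per-trait log transform, e.g. {"seed_mass": True}
    log_transform: dict = field(default_factory=dict)
    #: optional transform applied to WP weights (None = raw commonness codes)
    weight_transform: object = None


#: (statistic, weighting) cells tested for regional -> X transitions
_REGIONAL_STATS = (
    ("mean", "EP"),
    ("mean", "WP"),
    ("variance", "EP"),
    ("variance", "WP"),
    ("sdNTD", "EP"),
)
#: cells tested for the propagule -> vegetation transition (EP only)
_ESTABLISHMENT_STATS = (("mean", "EP"), ("variance", "EP"), ("sdNTD", "EP"))

TRANSITIONS = (
    ("regional", "propagule"),
    ("regional", "seed_rain"),
    ("regional", "seed_bank"),
    ("propagule", "vegetation"),
)


def _spawn_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_test_battery(
    pools: Mapping[str, PoolMembership],
    traits: pd.DataFrame,
    site_abundance: Mapping[str, Mapping[str, float]],
    config: BatteryConfig | None = None,
    seed: int | None = None,
    transitions: Sequence[tuple[str, str]] = TRANSITIONS,
) -> list[NullTestResult]:
    """Run the full per-site randomization grid.

    For each site, regional -> {propagule, seed rain, seed bank}
    transitions are tested with mean (EP, WP), variance (EP, WP) and
    sdNTD (EP) for each numeric trait (height, seed mass, CGI, SLA); the
    proportion of unassisted dispersal with mean (EP, WP); and regional
    abundance with mean (EP) only. The propagule -> vegetation transition
    uses EP only, with no abundance test. Targets are restricted to their
    intersection with the source pool; species missing the focal trait
    are dropped from source and target alike.

    ``site_abundance`` maps site -> species -> regional commonness code;
    it provides both the WP weights and the abundance "trait".
    Deterministic given ``seed``: every test draws from its own spawned
    seed in a fixed grid order.
    """
    cfg = config or BatteryConfig()
    tindex = traits.set_index("species_id")
    ss = np.random.SeedSequence(seed)
    results: list[NullTestResult] = []

    def trait_values(species: list[str], trait: str) -> pd.Series:
        vals = tindex[trait].reindex(species)
        if trait in cfg.log_transform and cfg.log_transform[trait]:
            vals = np.log(vals)
        return vals

    for site in sorted(pools):
        m = pools[site]
        abund = site_abundance.get(site, {})
        for source_name, target_name in transitions:
            source = sorted(m.pool(source_name))
            target = sorted(m.pool(target_name) & m.pool(source_name))
            is_regional = source_name == "regional"
            cells = _REGIONAL_STATS if is_regional else _ESTABLISHMENT_STATS

            plan: list[tuple[str, str, str]] = []
            if is_regional:
                plan.append(("abundance", "mean", "EP"))
            for trait in NUMERIC_TRAITS:
                for statistic, weighting in cells:
                    plan.append((trait, statistic, weighting))
            plan.append(("dispersal_method", "category_proportion", "EP"))
            if is_regional:
                plan.append(("dispersal_method", "category_proportion", "WP"))

            for trait, statistic, weighting in plan:
                test_seed = _spawn_seed(ss.spawn(1)[0])
                if trait == "abundance":
                    sv = pd.Series([abund.get(sp, np.nan) for sp in source], index=source)
                    gv = pd.Series([abund.get(sp, np.nan) for sp in target], index=target)
                elif trait == "dispersal_method":
                    sv = tindex["dispersal_method"].reindex(source)
                    gv = tindex["dispersal_method"].reindex(target)
                else:
                    sv = trait_values(source, trait)
                    gv = trait_values(target, trait)
                src_keep = sv.dropna()
                tgt_keep = gv.dropna()
                weights = None
                if weighting == "WP":
                    w = pd.Series(
                        [abund.get(sp, np.nan) for sp in src_keep.index],
                        index=src_keep.index,
                    )
                    # species without an abundance code cannot be weighted
                    ok = w.notna() & (w > 0)
                    src_keep = src_keep[ok]
                    weights = w[ok].to_numpy(dtype=float)
                    if cfg.weight_transform is not None:
                        weights = np.asarray(cfg.weight_transform(weights), dtype=float)
                    tgt_keep = tgt_keep[tgt_keep.index.isin(src_keep.index)]
                results.append(
                    null_trait_test(
                        src_keep.to_numpy(),
                        tgt_keep.to_numpy(),
                        statistic=statistic,
                        weighting=weighting,
                        weights=weights,
                        category=cfg.focal_category,
                        n_iter=cfg.n_iter,
                        seed=test_seed,
                        alpha=cfg.alpha,
                        plus_one=cfg.plus_one,
                        sdntd_ddof=cfg.sdntd_ddof,
                        site_id=site,
                        trait=trait,
                        source_pool=source_name,
                        target_pool=target_name,
                    )
                )
    logger.info("test battery produced %d results", len(results))
    return results


def results_to_frame(results: Iterable[NullTestResult]) -> pd.DataFrame:
    """Flatten battery results into one row per test."""
    rows = []
    for r in results:
        d = r.__dict__.copy()
        d["interpretation"] = r.interpretation
        rows.append(d)
    return pd.DataFrame(rows)


def summarize_tests(
    results: Iterable[NullTestResult], alpha: float | None = None
) -> pd.DataFrame:
    """Signed cross-site significance counts per grid cell.

    For every (transition, trait, statistic, weighting) cell, counts the
    sites whose observed statistic fell significantly below (``n_lower``,
    conventionally printed with a minus sign) or above (``n_higher``, plus
    sign) its null distribution, out of ``n_sites_tested`` testable sites.
    For the dispersal-method cells the "higher" count is the number of
    sites with a higher proportion of unassisted dispersal than random.
    If ``alpha`` is given, outcomes are recomputed from the stored
    p-values at that level.
    """
    rows = []
    for r in results:
        outcome = r.outcome
        if alpha is not None and outcome != "not_testable":
            outcome = _outcome(r.p_low, r.p_high, alpha)
        rows.append(
            (
                f"{r.source_pool}->{r.target_pool}",
                r.trait,
                r.statistic,
                r.weighting,
                outcome,
            )
        )
    df = pd.DataFrame(
        rows, columns=["transition", "trait", "statistic", "weighting", "outcome"]
    )
    out = (
        df.groupby(["transition", "trait", "statistic", "weighting"])
        .agg(
            n_lower=("outcome", lambda s: int((s == "lower").sum())),
            n_higher=("outcome", lambda s: int((s == "higher").sum())),
            n_sites_tested=("outcome", lambda s: int((s != "not_testable").sum())),
        )
        .reset_index()
    )
    return out


def format_summary_grid(summary: pd.DataFrame) -> pd.DataFrame:
    """Render the signed-count summary as a trait-by-cell grid of strings.

    Cells read like ``-3/+1`` (3 sites lower, 1 higher), a single signed
    number when only one direction occurred, or ``0``; combinations never
    tested are ``NA``.
    """

    def cell(row) -> str:
        lo, hi = int(row["n_lower"]), int(row["n_higher"])
        if lo and hi:
            return f"-{lo}/+{hi}"
        if lo:
            return f"-{lo}"
        if hi:
            return f"+{hi}"
        return "0"

    tmp = summary.copy()
    tmp["cell"] = tmp.apply(cell, axis=1)
    tmp["row"] = tmp["transition"] + " | " + tmp["statistic"] + " (" + tmp["weighting"] + ")"
    grid = tmp.pivot(index="row", columns="trait", values="cell")
    return grid.fillna("NA")
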