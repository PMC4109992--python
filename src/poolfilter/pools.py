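"""Seed-rain standardization, nested species pools, and filtering summaries.

The analysis tracks each site's species through three nested observation
levels: the **regional species pool** (everything recorded within 100 m of
the site), the **local propagule pool** (species that demonstrably reached
the site: seed rain, seed bank, or established vegetation), and the
**local community** (vegetation of the 10 x 10 m plot). The fraction of
species lost between the first two levels measures seed limitation; the
fraction lost between the last two measures microsite limitation.

Seed-rain counts are first standardized for trap loss. With ``rule=
"as_printed"`` the cumulative per-species seedling count is multiplied by
the proportion of traps recovered (out of 20); ``rule="scale_up"``
multiplies by its reciprocal instead, extrapolating to a full trap set.
Both rules preserve zero/nonzero status, so pool membership is identical
under either; only downstream abundance values differ.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io import RAIN_POOLS

logger = logging.getLogger(__name__)

#: names of the per-site pools exposed by :class:`PoolMembership`
POOL_NAMES = ("regional", "propagule", "vegetation", "seed_rain", "seed_bank")

N_TRAPS_DEFAULT = 20


def standardize_seed_rain(
    counts,
    n_recovered: int,
    n_total: int = N_TRAPS_DEFAULT,
    rule: str = "as_printed",
) -> np.ndarray:
    """Standardize raw per-species seed-rain counts for trap loss.

    Parameters
    ----------
    counts
        Cumulative seedling counts over the recovered traps of one site
        and season.
    n_recovered
        Number of traps recovered (0..``n_total``).
    rule
        ``"as_printed"`` multiplies by ``n_recovered / n_total``;
        ``"scale_up"`` multiplies by ``n_total / n_recovered``.
    """
    if rule not in ("as_printed", "scale_up"):
        raise ConfigurationError(f"unknown standardization rule {rule!r}")
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValidationError("seed-rain counts must be non-negative")
    if not 0 <= n_recovered <= n_total:
        raise ValidationError(
            f"n_recovered must be in 0..{n_total}, got {n_recovered}"
        )
    if n_recovered == 0:
        if np.any(counts > 0):
            raise ValidationError(
                "no traps recovered but nonzero seed-rain counts: "
                "standardization has no basis"
            )
        return counts.copy()
    factor = n_recovered / n_total if rule == "as_printed" else n_total / n_recovered
    return counts * factor


def total_site_rain(
    summer_std: Mapping[str, float], winter_std: Mapping[str, float]
) -> dict[str, float]:
    """Sum standardized summer and winter rain per species (absent = 0)."""
    species = sorted(set(summer_std) | set(winter_std))
    out = {}
    for sp in species:
        s = float(summer_std.get(sp, 0.0))
        w = float(winter_std.get(sp, 0.0))
        if s < 0 or w < 0:
            raise ValidationError(f"negative standardized rain for {sp!r}")
        out[sp] = s + w
    return out


def standardize_rain(
    obs: pd.DataFrame,
    n_total: int = N_TRAPS_DEFAULT,
    rule: str = "as_printed",
) -> pd.DataFrame:
    """Standardize both seasons and total them into a site seed rain table.

    Returns a frame with columns ``site_id, species_id, summer_std,
    winter_std, total_std``; the rule used is recorded in
    ``result.attrs["rule"]``. A site missing one season entirely is
    treated as zero rain for that season, with a warning.
    """
    rain = obs[obs["pool"].isin(RAIN_POOLS)]
    rows: list[tuple] = []
    season_of = {"seed_rain_summer": "summer", "seed_rain_winter": "winter"}
    for site, g in rain.groupby("site_id", sort=True):
        per_season: dict[str, dict[str, float]] = {}
        for pool, season in season_of.items():
            sg = g[g["pool"] == pool]
            if sg.empty:
                warnings.warn(
                    f"site {site!r}: no {season} seed-rain rows; season treated as 0",
                    stacklevel=2,
                )
                per_season[season] = {}
                continue
            nrec_vals = sg["n_samples_recovered"].dropna().unique()
            if len(nrec_vals) != 1:
                raise ValidationError(
                    f"inconsistent n_samples_recovered for site {site!r}, "
                    f"{season} rain: {sorted(nrec_vals)}"
                )
            std = standardize_seed_rain(
                sg["value"].to_numpy(), int(nrec_vals[0]), n_total, rule
            )
            per_season[season] = dict(zip(sg["species_id"], std))
        total = total_site_rain(per_season["summer"], per_season["winter"])
        for sp in sorted(total):
            rows.append(
                (
                    site,
                    sp,
                    per_season["summer"].get(sp, 0.0),
                    per_season["winter"].get(sp, 0.0),
                    total[sp],
                )
            )
    out = pd.DataFrame(
        rows, columns=["site_id", "species_id", "summer_std", "winter_std", "total_std"]
    )
    out.attrs["rule"] = rule
    return out


@dataclass(frozen=True)
class PoolMembership:
    """Per-site species sets for the nested observation pools."""

    site_id: str
    regional: frozenset
    vegetation: frozenset
    seed_bank: frozenset
    seed_rain: frozenset

    @property
    def propagule(self) -> frozenset:
        """Seed rain, seed bank and established vegetation combined."""
        return self.seed_rain | self.seed_bank | self.vegetation

    def pool(self, name: str) -> frozenset:
        if name == "propagule":
            return self.propagule
        if name not in ("regional", "vegetation", "seed_bank", "seed_rain"):
            raise KeyError(name)
        return getattr(self, name)


def build_pools(
    obs: pd.DataFrame, rain: pd.DataFrame | None = None
) -> dict[str, PoolMembership]:
    """Build per-site pool membership from validated observations.

    Membership is strictly ``value > 0`` (the 0.1 vegetation sentinel
    counts as present). If a standardized rain table is given, seed-rain
    membership is taken from its ``total_std`` (equivalent to the raw
    counts, since standardization preserves zeros); any site appearing in
    ``rain`` but absent from ``obs`` is an error.
    """
    sites = sorted(obs["site_id"].unique())
    if rain is not None:
        extra = sorted(set(rain["site_id"]) - set(sites))
        if extra:
            raise ValidationError(
                f"site(s) present in seed-rain table but not in observations: {extra}"
            )
    pos = obs[obs["value"] > 0]
    pools: dict[str, PoolMembership] = {}
    for site in sites:
        g = pos[pos["site_id"] == site]
        regional = frozenset(g.loc[g["pool"] == "regional", "species_id"])
        vegetation = frozenset(g.loc[g["pool"] == "vegetation", "species_id"])
        seed_bank = frozenset(g.loc[g["pool"] == "seed_bank", "species_id"])
        if rain is not None:
            rg = rain[(rain["site_id"] == site) & (rain["total_std"] > 0)]
            seed_rain = frozenset(rg["species_id"])
        else:
            seed_rain = frozenset(
                g.loc[g["pool"].isin(RAIN_POOLS), "species_id"]
            )
        if not vegetation <= regional:
            warnings.warn(
                f"site {site!r}: vegetation species missing from the regional "
                f"survey: {sorted(vegetation - regional)}",
                stacklevel=2,
            )
        pools[site] = PoolMembership(site, regional, vegetation, seed_bank, seed_rain)
    return pools


@dataclass
class FilteringSummary:
    """Per-site filtering fractions with cross-site mean +- SE."""

    per_site: pd.DataFrame
    mean_regional_to_propagule: float
    se_regional_to_propagule: float
    mean_propagule_to_vegetation: float
    se_propagule_to_vegetation: float
    n_sites: int


def _mean_se(values: pd.Series) -> tuple[float, float]:
    v = values.dropna()
    mean = float(v.mean()) if len(v) else np.nan
    se = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) >= 2 else np.nan
    return mean, se


def filtering_fractions(pools: Mapping[str, PoolMembership]) -> FilteringSummary:
    """Fraction of species passing each assembly filter, per site.

    ``regional_to_propagule`` = |regional AND propagule| / |regional| — the
    share of candidate colonizers that demonstrably arrived (its complement
    measures seed limitation). ``propagule_to_vegetation`` = |propagule AND
    vegetation| / |propagule| — the share of arrivals that established (its
    complement measures microsite limitation). The standard error is the
    cross-site sample SD divided by sqrt(n sites).
    """
    rows = []
    for site in sorted(pools):
        m = pools[site]
        if not m.regional:
            raise ValidationError(f"site {site!r} has an empty regional pool")
        prop = m.propagule
        p1 = len(m.regional & prop) / len(m.regional)
        if prop:
            p2 = len(prop & m.vegetation) / len(prop)
        else:
            warnings.warn(
                f"site {site!r}: empty propagule pool; establishment fraction "
                "undefined and excluded from the mean",
                stacklevel=2,
            )
            p2 = np.nan
        rows.append((site, p1, p2))
    per_site = pd.DataFrame(
        rows, columns=["site_id", "regional_to_propagule", "propagule_to_vegetation"]
    )
    m1, s1 = _mean_se(per_site["regional_to_propagule"])
    m2, s2 = _mean_se(per_site["propagule_to_vegetation"])
    return FilteringSummary(per_site, m1, s1, m2, s2, len(per_site))


@dataclass
class OriginSummary:
    """Dispersal-origin proportions of each pool of interest."""

    per_site: pd.DataFrame
    summary: pd.DataFrame


def classify_origin(
    pools: Mapping[str, PoolMembership],
    pools_of_interest: tuple[str, ...] = ("propagule", "seed_rain", "seed_bank"),
) -> OriginSummary:
    """Label each arriving species Local / Regional-only / Distant.

    Within a pool of interest, a species found in the site's vegetation is
    **local**; one found in the regional survey but not the vegetation is
    **regional-only**; one absent from the regional survey indicates long
    distance dispersal, **distant**. Proportions sum to 1 per site/pool.
    """
    rows = []
    for site in sorted(pools):
        m = pools[site]
        for pname in pools_of_interest:
            s = m.pool(pname)
            if not s:
                warnings.warn(
                    f"site {site!r}: empty {pname} pool skipped in origin summary",
                    stacklevel=2,
                )
                continue
            n = len(s)
            n_local = len(s & m.vegetation)
            n_regional_only = len((s & m.regional) - m.vegetation)
            n_distant = len(s - m.regional - m.vegetation)
            rows.append(
                (site, pname, n, n_local / n, n_regional_only / n, n_distant / n)
            )
    per_site = pd.DataFrame(
        rows,
        columns=["site_id", "pool", "n_species", "p_local", "p_regional_only", "p_distant"],
    )
    summary_rows = []
    for pname in pools_of_interest:
        sub = per_site[per_site["pool"] == pname]
        if sub.empty:
            continue
        for col in ("p_local", "p_regional_only", "p_distant"):
            mean, se = _mean_se(sub[col])
            summary_rows.append((pname, col.removeprefix("p_"), mean, se, len(sub)))
    summary = pd.DataFrame(
        summary_rows, columns=["pool", "origin", "mean", "se", "n_sites"]
    )
    return OriginSummary(per_site, summary)


def richness_by_pool(pools: Mapping[str, PoolMembership]) -> pd.DataFrame:
    """Species richness of every pool at every site (one row per site)."""
    rows = [
        (
            site,
            len(pools[site].regional),
            len(pools[site].propagule),
            len(pools[site].vegetation),
            len(pools[site].seed_rain),
            len(pools[site].seed_bank),
        )
        for site in sorted(pools)
    ]
    return pd.DataFrame(
        rows, columns=["site_id", "regional", "propagule", "vegetation", "seed_rain", "seed_bank"]
    ).set_index("site_id")
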