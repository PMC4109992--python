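"""Per-site Spearman correlations between pool abundance vectors.

For each site, abundance in one pool is correlated against abundance in
another across species, for the five pairs reported in the field
convention's naming: RSP (regional commonness code), VEG (local cover-
abundance), SR (standardized total seed rain), SB (seed bank count).

The species universe of a pair is configurable: ``union`` (species
present in at least one of the two pools at the site; absences coded 0),
``intersection`` (species present in both), or ``regional`` (every member
of the site's regional pool). ``union`` is the default — it does not
condition on joint presence, and zeros carry the absence information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .io import RAIN_POOLS

logger = logging.getLogger(__name__)

POOL_PAIRS = ("RSP-VEG", "RSP-SB", "RSP-SR", "VEG-SB", "VEG-SR")
SCOPES = ("union", "intersection", "regional")

_POOL_CODE = {"RSP": "regional", "VEG": "vegetation", "SB": "seed_bank", "SR": "seed_rain"}


@dataclass
class AbundanceCorrelation:
    """Spearman rho between two abundance vectors at one site."""

    site_id: str
    pool_pair: str
    rho: float
    p_value: float
    n_species: int
    species_scope: str
    testable: bool


def _abundance_vectors(
    obs: pd.DataFrame, rain: pd.DataFrame | None
) -> dict[str, dict[str, dict[str, float]]]:
    """site -> pool code -> species -> abundance (>0 entries only)."""
    out: dict[str, dict[str, dict[str, float]]] = {}
    for site in sorted(obs["site_id"].unique()):
        g = obs[(obs["site_id"] == site) & (obs["value"] > 0)]

        def vec(pool: str) -> dict[str, float]:
            sub = g[g["pool"] == pool]
            return dict(zip(sub["species_id"], sub["value"]))

        vecs: dict[str, dict[str, float]] = {
            "RSP": vec("regional"),
            "VEG": vec("vegetation"),
            "SB": vec("seed_bank"),
        }
        if rain is not None:
            rg = rain[(rain["site_id"] == site) & (rain["total_std"] > 0)]
            vecs["SR"] = dict(zip(rg["species_id"], rg["total_std"]))
        else:
            rr = g[g["pool"].isin(RAIN_POOLS)]
            vecs["SR"] = rr.groupby("species_id")["value"].sum().to_dict()
        out[site] = vecs
    return out


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p-value for |rho| (n <= 9)."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    xc = rx - rx.mean()
    denom_x = np.sqrt((xc**2).sum())
    count = 0
    total = 0
    target = abs(rho) - 1e-12
    for perm in permutations(range(n)):
        yp = ry[list(perm)]
        yc = yp - yp.mean()
        denom = denom_x * np.sqrt((yc**2).sum())
        r = (xc @ yc) / denom if denom > 0 else 0.0
        if abs(r) >= target:
            count += 1
        total += 1
    return count / total


def abundance_correlations(
    obs: pd.DataFrame,
    rain: pd.DataFrame | None = None,
    scope: str = "union",
    pairs: tuple[str, ...] = POOL_PAIRS,
    method: str = "t",
) -> list[AbundanceCorrelation]:
    """Spearman rho and p for each pool pair at each site.

    ``method="t"`` uses the large-sample t approximation (scipy's
    default); ``method="exact"`` enumerates all rank permutations, only
    feasible for n < 10 species. Pairs with fewer than 3 species in
    scope, or with a constant vector, are emitted untestable (NaN p).
    """
    if scope not in SCOPES:
        raise ConfigurationError(f"unknown scope {scope!r}; choose from {SCOPES}")
    if method not in ("t", "exact"):
        raise ConfigurationError(f"unknown p-value method {method!r}")
    vectors = _abundance_vectors(obs, rain)
    results: list[AbundanceCorrelation] = []
    for site, vecs in vectors.items():
        for pair in pairs:
            a_code, b_code = pair.split("-")
            a, b = vecs[a_code], vecs[b_code]
            if scope == "union":
                universe = sorted(set(a) | set(b))
            elif scope == "intersection":
                universe = sorted(set(a) & set(b))
            else:
                universe = sorted(vecs["RSP"])
            n = len(universe)
            x = np.array([a.get(sp, 0.0) for sp in universe])
            y = np.array([b.get(sp, 0.0) for sp in universe])
            if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                results.append(
                    AbundanceCorrelation(site, pair, np.nan, np.nan, n, scope, False)
                )
                continue
            res = stats.spearmanr(x, y)
            rho = float(res.statistic)
            if method == "exact":
                if n >= 10:
                    raise ConfigurationError(
                        f"exact permutation p only supported for n < 10 (site {site!r},"
                        f" pair {pair}: n = {n})"
                    )
                p = _exact_spearman_p(x, y, rho)
            else:
                p = float(res.pvalue)
            results.append(AbundanceCorrelation(site, pair, rho, p, n, scope, True))
    return results


def correlations_to_frame(results: list[AbundanceCorrelation]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def count_significant(
    results: list[AbundanceCorrelation],
    threshold: float = 0.05,
    direction: str = "positive",
) -> pd.DataFrame:
    """Number of sites per pool pair with a significant correlation.

    ``direction="positive"`` counts sites with rho > 0 and p below the
    threshold; ``"negative"`` the mirror image; ``"any"`` ignores sign.
    """
    if direction not in ("positive", "negative", "any"):
        raise ConfigurationError(f"unknown direction {direction!r}")
    rows: dict[str, list[int]] = {}
    for r in results:
        rows.setdefault(r.pool_pair, [0, 0])
        rows[r.pool_pair][1] += 1
        if not r.testable or not np.isfinite(r.p_value):
            continue
        sign_ok = (
            (r.rho > 0) if direction == "positive"
            else (r.rho < 0) if direction == "negative"
            else True
        )
        if sign_ok and r.p_value < threshold:
            rows[r.pool_pair][0] += 1
    return pd.DataFrame(
        [(pair, c[0], c[1]) for pair, c in sorted(rows.items())],
        columns=["pool_pair", "n_significant", "n_sites"],
    )
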