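"""Reading, validation, grouping and filtering of the tabular inputs.

Observation tables are long format: one row per (site, species, pool) with a
single ``value`` column whose scale depends on the pool:

=================  ======================================================
pool               value scale
=================  ======================================================
regional           ordinal commonness 0-3 (0 = absent from the 100-m
                   regional survey)
vegetation         cover-abundance 0-8 from the subplots, with the
                   sentinel 0.1 marking species seen in the 10 x 10 m
                   plot but in no subplot
seed_bank          seedling count, the site's soil samples compiled
seed_rain_summer   seedling count over the recovered summer traps
seed_rain_winter   seedling count over the recovered winter traps
=================  ======================================================

Seed-rain rows additionally carry ``n_samples_recovered``, the number of
traps (out of 20) recovered for that site and season; it is the basis of
the seed-rain standardization in :mod:`poolfilter.pools`.

Trait tables are one row per species: ``species_id, height, seed_mass,
sla, cgi, dispersal_method, regional_abundance`` with empty cells meaning
missing. Heights are metres, seed mass milligrams, SLA mm^2/mg; CGI is an
ordinal clonal growth index; dispersal_method is categorical.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

POOLS = ("regional", "vegetation", "seed_bank", "seed_rain_summer", "seed_rain_winter")
#: pools whose values are seedling counts (combined by summation when grouping)
COUNT_POOLS = ("seed_bank", "seed_rain_summer", "seed_rain_winter")
#: pools whose values are ordinal scales (combined by maximum when grouping)
ORDINAL_POOLS = ("regional", "vegetation")
RAIN_POOLS = ("seed_rain_summer", "seed_rain_winter")

REQUIRED_COLUMNS = ("site_id", "species_id", "pool", "value")
OBS_COLUMNS = ("site_id", "species_id", "pool", "value", "n_samples_recovered")

MAX_TRAPS = 20
REGIONAL_VALUES = frozenset({0.0, 1.0, 2.0, 3.0})

TRAIT_COLUMNS = (
    "species_id",
    "height",
    "seed_mass",
    "sla",
    "cgi",
    "dispersal_method",
    "regional_abundance",
)
NUMERIC_TRAITS = ("height", "seed_mass", "sla", "cgi")
DISPERSAL_CATEGORIES = ("unassisted", "animal", "wind", "other")


def _rows(mask: pd.Series) -> str:
    """1-based data-row numbers (excluding header) for an error message."""
    idx = np.flatnonzero(np.asarray(mask)) + 1
    shown = ", ".join(str(i) for i in idx[:10])
    if len(idx) > 10:
        shown += f", ... ({len(idx)} rows)"
    return shown


def validate_observations(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a long-format observation table.

    Returns a copy with trimmed identifiers, float ``value`` and a float
    ``n_samples_recovered`` column (NaN outside seed-rain rows).

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValidationError
        On out-of-range values, non-integer counts, or duplicated
        (site_id, species_id, pool) keys.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    out = df.copy()
    for col in ("site_id", "species_id", "pool"):
        out[col] = out[col].astype(str).str.strip()

    bad_pool = ~out["pool"].isin(POOLS)
    if bad_pool.any():
        raise ValidationError(
            f"unknown pool name(s) {sorted(out.loc[bad_pool, 'pool'].unique())} "
            f"at row(s) {_rows(bad_pool)}"
        )

    out["value"] = pd.to_numeric(out["value"], errors="coerce")
    nonnum = out["value"].isna()
    if nonnum.any():
        raise ValidationError(f"non-numeric value at row(s) {_rows(nonnum)}")
    neg = out["value"] < 0
    if neg.any():
        raise ValidationError(f"negative value at row(s) {_rows(neg)}")

    is_count = out["pool"].isin(COUNT_POOLS)
    frac = is_count & (out["value"] % 1 != 0)
    if frac.any():
        raise ValidationError(
            f"seed_bank/seed_rain values must be integer counts; row(s) {_rows(frac)}"
        )

    is_veg = out["pool"] == "vegetation"
    v = out["value"]
    veg_ok = np.isclose(v, 0.1) | ((v % 1 == 0) & (v >= 0) & (v <= 8))
    bad_veg = is_veg & ~veg_ok
    if bad_veg.any():
        raise ValidationError(
            f"vegetation values must be in {{0, 0.1, 1..8}}; row(s) {_rows(bad_veg)}"
        )

    is_reg = out["pool"] == "regional"
    bad_reg = is_reg & ~v.isin(REGIONAL_VALUES)
    if bad_reg.any():
        raise ValidationError(
            f"regional commonness must be in {{0, 1, 2, 3}}; row(s) {_rows(bad_reg)}"
        )

    is_rain = out["pool"].isin(RAIN_POOLS)
    if "n_samples_recovered" not in out.columns:
        if is_rain.any():
            raise SchemaError(
                "missing required column(s): n_samples_recovered "
                "(required for seed_rain_* rows)"
            )
        out["n_samples_recovered"] = np.nan
    out["n_samples_recovered"] = pd.to_numeric(
        out["n_samples_recovered"], errors="coerce"
    )
    nrec = out["n_samples_recovered"]
    bad_rec = is_rain & (nrec.isna() | (nrec % 1 != 0) | (nrec < 0) | (nrec > MAX_TRAPS))
    if bad_rec.any():
        raise ValidationError(
            f"n_samples_recovered must be an integer in 0..{MAX_TRAPS} on "
            f"seed_rain rows; row(s) {_rows(bad_rec)}"
        )
    out.loc[~is_rain, "n_samples_recovered"] = np.nan

    dup = out.duplicated(subset=["site_id", "species_id", "pool"], keep=False)
    if dup.any():
        keys = (
            out.loc[dup, ["site_id", "species_id", "pool"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        raise ValidationError(
            "duplicated (site_id, species_id, pool) key(s): "
            + "; ".join(map(str, keys))
        )

    return out.loc[:, list(OBS_COLUMNS)].reset_index(drop=True)


def read_observations(path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a long-format observation CSV/TSV.

    ``sep=None`` sniffs the delimiter. Lines starting with ``#`` are
    treated as comments (output files written by the CLI carry a config
    digest in such a header line).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    obs = validate_observations(df)
    logger.info("read %d observation rows from %s", len(obs), path)
    return obs


def write_observations(obs: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write an observation table; inverse of :func:`read_observations`."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        obs.to_csv(fh, index=False)


def apply_grouping(
    obs: pd.DataFrame,
    gmap: Mapping[str, str],
    modes: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Merge taxa that could not be told apart (e.g. *Poa compressa/pratensis*).

    ``gmap`` maps raw species names to group names; unmapped names pass
    through unchanged. After renaming, rows sharing a (site, group, pool)
    key are combined: counts (seed bank, seed rain) by the ``counts`` mode
    (default ``sum``), ordinal scales (regional, vegetation) by the
    ``ordinal`` mode, which must be ``max`` — summing an ordinal scale is a
    :class:`ConfigurationError`.
    """
    resolved = {"counts": "sum", "ordinal": "max"}
    if modes:
        resolved.update(modes)
    if resolved["ordinal"] != "max":
        raise ConfigurationError(
            f"ordinal pools (regional, vegetation) can only be combined with "
            f"'max', got {resolved['ordinal']!r}"
        )
    if resolved["counts"] not in ("sum", "max"):
        raise ConfigurationError(f"unknown counts mode {resolved['counts']!r}")

    out = obs.copy()
    if gmap:
        out["species_id"] = out["species_id"].map(lambda s: gmap.get(s, s))

    parts = []
    for pool_set, mode in ((COUNT_POOLS, resolved["counts"]), (ORDINAL_POOLS, resolved["ordinal"])):
        sub = out[out["pool"].isin(pool_set)]
        if sub.empty:
            continue
        grouped = sub.groupby(["site_id", "species_id", "pool"], as_index=False).agg(
            value=("value", mode),
            n_samples_recovered=("n_samples_recovered", "max"),
        )
        parts.append(grouped)
    if not parts:
        return out.reset_index(drop=True)
    merged = pd.concat(parts, ignore_index=True)
    merged = merged.sort_values(["site_id", "species_id", "pool"], kind="stable")
    n_merged = len(obs) - len(merged)
    if n_merged:
        logger.info("grouping merged %d observation rows", n_merged)
    return merged.loc[:, list(OBS_COLUMNS)].reset_index(drop=True)


def apply_exclusions(
    obs: pd.DataFrame,
    excluded: Iterable[str] = (),
    contaminants: Iterable[str] = (),
) -> pd.DataFrame:
    """Drop excluded taxa everywhere; contaminants from seed pools only.

    ``excluded`` (trees, non-seed-bearing plants) are removed from every
    pool. ``contaminants`` (greenhouse weeds, wind-blown seed such as
    *Betula*) are removed only from the seed bank and seed rain, since
    their field vegetation and regional records are genuine. Names absent
    from the data produce a warning, not an error.
    """
    excluded = set(excluded)
    contaminants = set(contaminants)
    known = set(obs["species_id"])
    for name in sorted((excluded | contaminants) - known):
        warnings.warn(f"exclusion list name not present in data: {name!r}", stacklevel=2)

    drop_all = obs["species_id"].isin(excluded)
    drop_seed = obs["species_id"].isin(contaminants) & obs["pool"].isin(COUNT_POOLS)
    keep = ~(drop_all | drop_seed)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("exclusions removed %d observation rows", n_dropped)
    return obs.loc[keep].reset_index(drop=True)


def validate_trait_table(
    df: pd.DataFrame, categories: Iterable[str] = DISPERSAL_CATEGORIES
) -> pd.DataFrame:
    """Validate the per-species trait table; empty cells denote missing."""
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    out = df.copy()
    out["species_id"] = out["species_id"].astype(str).str.strip()
    dup = out["species_id"].duplicated(keep=False)
    if dup.any():
        raise ValidationError(
            f"duplicated species_id in trait table: "
            f"{sorted(out.loc[dup, 'species_id'].unique())}"
        )
    for col in NUMERIC_TRAITS + ("regional_abundance",):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    for col in ("height", "seed_mass", "sla"):
        bad = out[col].notna() & (out[col] <= 0)
        if bad.any():
            raise ValidationError(f"{col} must be strictly positive; row(s) {_rows(bad)}")
    bad = out["cgi"].notna() & (out["cgi"] < 0)
    if bad.any():
        raise ValidationError(f"cgi must be >= 0; row(s) {_rows(bad)}")
    bad = out["regional_abundance"].notna() & (out["regional_abundance"] < 0)
    if bad.any():
        raise ValidationError(f"regional_abundance must be >= 0; row(s) {_rows(bad)}")

    cats = set(categories)
    dm = out["dispersal_method"]
    dm = dm.where(dm.notna(), None)
    dm = dm.map(lambda x: x.strip() if isinstance(x, str) else x)
    dm = dm.map(lambda x: None if (x == "" or x is None) else x)
    bad = dm.map(lambda x: x is not None and x not in cats)
    if bad.any():
        raise ValidationError(
            f"dispersal_method outside category set {sorted(cats)}; row(s) {_rows(bad)}"
        )
    out["dispersal_method"] = dm
    return out.loc[:, list(TRAIT_COLUMNS)].reset_index(drop=True)


def read_trait_table(path, categories: Iterable[str] = DISPERSAL_CATEGORIES) -> pd.DataFrame:
    """Read and validate a species trait table CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    traits = validate_trait_table(df, categories)
    logger.info("read traits for %d species from %s", len(traits), path)
    return traits


def read_grouping(path) -> dict[str, str]:
    """Read a ``raw_name,group_id`` CSV into a mapping."""
    df = pd.read_csv(path, comment="#")
    for col in ("raw_name", "group_id"):
        if col not in df.columns:
            raise SchemaError(f"missing required column(s): {col}")
    return dict(
        zip(df["raw_name"].astype(str).str.strip(), df["group_id"].astype(str).str.strip())
    )


def read_species_list(path) -> list[str]:
    """Read a one-name-per-line species list (blank lines and # comments skipped)."""
    names = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                names.append(line)
    return names
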