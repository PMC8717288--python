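"""Delimited-text readers/writers and tabulations for stem maps.

File formats (comma-separated, UTF-8, header required, decimal point):

* stem map:        tree_id,transect_id,x,y,species,dbh
* environment:     subplot_id,transect_id,cx,cy,slope_pct,topography,altitude_m,dist_water_m
* species lookup:  species,guild[,deciduousness]

Coordinates in files are 0-based metres within each transect's rectangle.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .datamodel import (
    DBH_THRESHOLD_CM,
    GUILDS,
    STEM_COLUMNS,
    SUBPLOT_COLUMNS,
    TOPOGRAPHY_CATEGORIES,
    StemDataError,
    TransectWindow,
    validate_stems,
)

logger = logging.getLogger("stemspat")

_STEM_FILE_COLUMNS = ["tree_id", "transect_id", "x", "y", "species", "dbh"]


def read_species_lookup(path) -> pd.DataFrame:
    lookup = pd.read_csv(path, dtype=str)
    missing = [c for c in ("species", "guild") if c not in lookup.columns]
    if missing:
        raise StemDataError(f"species lookup missing columns: {missing}")
    bad = ~lookup["guild"].isin(GUILDS)
    if bad.any():
        raise StemDataError(
            f"lookup guilds outside {GUILDS}: {sorted(lookup.loc[bad, 'guild'].unique())}"
        )
    return lookup


def read_stem_map(
    path,
    species_guild_lookup: pd.DataFrame,
    dbh_threshold: float = DBH_THRESHOLD_CM,
) -> pd.DataFrame:
    """Read and validate a stem map, attaching guilds from the lookup.

    Rows with dbh below the survey threshold are dropped (the count is kept
    in ``result.attrs['n_rejected']`` and logged); non-numeric coordinates
    or dbh raise an error naming the offending line numbers, unknown species
    codes raise a lookup error.
    """
    raw = pd.read_csv(path, dtype=str)
    missing = [c for c in _STEM_FILE_COLUMNS if c not in raw.columns]
    if missing:
        raise StemDataError(f"stem map missing columns: {missing}")
    numeric = {}
    for col in ("x", "y", "dbh"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna()
        if bad.any():
            # +2: header line plus 1-based indexing
            lines = (raw.index[bad] + 2).tolist()
            raise StemDataError(f"non-numeric {col} at file lines {lines}")
        if vals.isna().any():
            lines = (raw.index[vals.isna()] + 2).tolist()
            raise StemDataError(f"missing {col} at file lines {lines}")
        numeric[col] = vals.astype(float)
    stems = raw[["tree_id", "transect_id", "species"]].copy()
    for col, vals in numeric.items():
        stems[col] = vals

    mapping = species_guild_lookup.set_index("species")["guild"]
    unknown = sorted(set(stems["species"]) - set(mapping.index))
    if unknown:
        raise StemDataError(f"species absent from lookup: {unknown}")
    stems["guild"] = mapping.loc[stems["species"]].to_numpy()

    below = stems["dbh"] < dbh_threshold
    n_rejected = int(below.sum())
    if n_rejected:
        logger.warning(
            "rejected %d stems below the %.1f cm dbh threshold", n_rejected, dbh_threshold
        )
    stems = stems.loc[~below, STEM_COLUMNS].reset_index(drop=True)
    stems.attrs["n_rejected"] = n_rejected
    return validate_stems(stems, dbh_threshold=dbh_threshold)


def write_stem_map(stems: pd.DataFrame, path) -> None:
    stems[_STEM_FILE_COLUMNS].to_csv(path, index=False, float_format="%.3f")


def read_environment(path) -> pd.DataFrame:
    env = pd.read_csv(path)
    missing = [c for c in SUBPLOT_COLUMNS if c not in env.columns]
    if missing:
        raise StemDataError(f"environment table missing columns: {missing}")
    bad = ~env["topography"].isin(TOPOGRAPHY_CATEGORIES)
    if bad.any():
        raise StemDataError(
            f"unknown topography categories: {sorted(env.loc[bad, 'topography'].unique())}"
        )
    if (env["slope_pct"] < 0).any():
        raise StemDataError("negative slope in environment table")
    return env


def write_environment(env: pd.DataFrame, path) -> None:
    env[SUBPLOT_COLUMNS].to_csv(path, index=False, float_format="%.3f")


def tabulate_abundance(
    stems: pd.DataFrame,
    subplots: pd.DataFrame,
    by: str = "species",
    subplot_size: tuple[float, float] = (25.0, 50.0),
) -> pd.DataFrame:
    """Subplot x unit abundance matrix (unit = species or guild).

    Stems are assigned by coordinates to the subplot whose half-open
    footprint [cx - sx/2, cx + sx/2) x [cy - sy/2, cy + sy/2) (within the
    same transect) contains them, so boundary stems belong to exactly one
    subplot.  Counts conserve the number of stems; subplots without any
    target stem are kept as all-zero rows.
    """
    if by not in ("species", "guild"):
        raise ValueError("by must be 'species' or 'guild'")
    sx, sy = subplot_size
    units = sorted(stems[by].unique()) if len(stems) else []
    counts = pd.DataFrame(
        0, index=pd.Index(subplots["subplot_id"], name="subplot_id"), columns=units, dtype=int
    )
    if len(stems) == 0:
        return counts

    for tid, sub in stems.groupby("transect_id", sort=False):
        plots_t = subplots[subplots["transect_id"].astype(str) == str(tid)]
        if len(plots_t) == 0:
            raise StemDataError(
                f"stems on transect {tid!r} but no subplots declared there "
                f"(e.g. tree {sub['tree_id'].iloc[0]!r})"
            )
        x = sub["x"].to_numpy(dtype=float)
        y = sub["y"].to_numpy(dtype=float)
        cx = plots_t["cx"].to_numpy(dtype=float)
        cy = plots_t["cy"].to_numpy(dtype=float)
        inside = (
            (x[:, None] >= cx[None, :] - sx / 2)
            & (x[:, None] < cx[None, :] + sx / 2)
            & (y[:, None] >= cy[None, :] - sy / 2)
            & (y[:, None] < cy[None, :] + sy / 2)
        )
        n_hits = inside.sum(axis=1)
        if np.any(n_hits == 0):
            tree = sub["tree_id"].to_numpy()[n_hits == 0][0]
            raise StemDataError(f"stem {tree!r} falls outside every subplot")
        if np.any(n_hits > 1):
            tree = sub["tree_id"].to_numpy()[n_hits > 1][0]
            raise StemDataError(f"stem {tree!r} assigned to more than one subplot")
        plot_ids = plots_t["subplot_id"].to_numpy()[inside.argmax(axis=1)]
        tallied = (
            pd.DataFrame({"subplot_id": plot_ids, by: sub[by].to_numpy()})
            .value_counts()
            .unstack(fill_value=0)
        )
        counts = counts.add(
            tallied.reindex(index=counts.index, columns=units, fill_value=0),
            fill_value=0,
        )
    return counts.astype(int)


def filter_species(
    stems: pd.DataFrame, min_n: int = 50
) -> tuple[pd.DataFrame, list[str]]:
    """Keep only species with at least ``min_n`` stems (survey robustness rule)."""
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    counts = stems["species"].value_counts()
    retained = sorted(counts.index[counts >= min_n])
    out = stems[stems["species"].isin(retained)].reset_index(drop=True)
    return out, retained


def standardize_dbh_by_species(stems: pd.DataFrame) -> pd.DataFrame:
    """Add a ``mark`` column: dbh divided by the species mean dbh.

    Removes interspecific differences in growth rate and maximum size before
    pooling species into guild-level correlograms; per-species standardized
    marks average exactly 1.
    """
    out = stems.copy()
    single = stems["species"].value_counts()
    lonely = single.index[single < 2]
    if len(lonely):
        warnings.warn(
            f"species with a single stem get mark = 1: {sorted(lonely)}", stacklevel=2
        )
    means = stems.groupby("species")["dbh"].transform("mean")
    if (means <= 0).any():
        raise StemDataError("non-positive species mean dbh")
    out["mark"] = stems["dbh"] / means
    return out


def guild_density(stems: pd.DataFrame, window: TransectWindow, guild: str) -> float:
    """Stems of a guild per hectare of surveyed window."""
    area = window.total_area_ha
    if area <= 0:
        raise ZeroDivisionError("window has zero area")
    return float((stems["guild"] == guild).sum()) / area
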