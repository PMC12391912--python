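"""Reading and writing the sub-block / block census CSV schemas.

Column names are never hard-coded in the analysis: a :class:`ColumnMap` binds
semantic roles (block id, sub-block index, census year, species counts,
covariates, presence flags, signed boundary distance) to concrete CSV columns,
so foreign schemas can be read by supplying a different mapping (``--colmap``
on the command line).  Missing covariate values are serialized as empty
fields, never sentinel numbers, because downstream stages distinguish observed
from imputed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ColumnMap",
    "CensusGrid",
    "SchemaError",
    "read_subblock_csv",
    "write_subblock_csv",
    "read_block_csv",
    "write_block_csv",
]


class SchemaError(ValueError):
    """A mapped column is missing or malformed."""


DEFAULT_SPECIES = [
    "wildebeest",
    "zebra",
    "thomsons_gazelle",
    "impala",
    "topi",
    "grants_gazelle",
    "buffalo",
    "warthog",
    "eland",
    "giraffe",
    "hartebeest",
    "waterbuck",
    "elephant",
    "ostrich",
    "dikdik",
    "reedbuck",
    "bushbuck",
    "oribi",
    "duiker",
]

DEFAULT_COVARIATES = [
    "grass_cover",
    "grass_height",
    "grass_color",
    "shrub_cover",
    "shrub_height",
    "shrub_color",
    "tree_cover",
    "tree_height",
    "tree_color",
    "elevation_m",
    "slope_deg",
    "rain_wet_mm",
    "rain_dry_mm",
    "rain_prev_mm",
    "dist_water_km",
    "dist_boma_occupied_km",
    "dist_boma_abandoned_km",
    "dist_infrastructure_km",
]

DEFAULT_FLAGS = [
    "fire_scar",
    "sheep_goats",
    "cattle",
    "carnivores",
    "vehicles",
    "litter",
]


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from semantic roles to CSV column names."""

    block_id: str = "block_id"
    sub_block: str = "sub_block"
    year: str = "year"
    land_use: str = "land_use"
    dist_boundary: str = "dist_boundary_km"
    x: str = "x_m"
    y: str = "y_m"
    species: tuple = tuple(DEFAULT_SPECIES)
    covariates: tuple = tuple(DEFAULT_COVARIATES)
    flags: tuple = tuple(DEFAULT_FLAGS)

    def __post_init__(self):
        roles = [self.block_id, self.sub_block, self.year, self.land_use,
                 self.dist_boundary, self.x, self.y]
        all_cols = roles + list(self.species) + list(self.covariates) + list(self.flags)
        if len(set(all_cols)) != len(all_cols):
            raise SchemaError("column roles must be disjoint")
        if not self.species:
            raise SchemaError("at least one species column is required")

    @classmethod
    def default(cls):
        return cls()

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("species", "covariates", "flags"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return replace(cls(), **raw)

    def to_yaml(self, path):
        data = {
            "block_id": self.block_id,
            "sub_block": self.sub_block,
            "year": self.year,
            "land_use": self.land_use,
            "dist_boundary": self.dist_boundary,
            "x": self.x,
            "y": self.y,
            "species": list(self.species),
            "covariates": list(self.covariates),
            "flags": list(self.flags),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @property
    def core(self):
        return [self.block_id, self.sub_block, self.year, self.land_use,
                self.x, self.y, self.dist_boundary]

    @property
    def ordered_columns(self):
        return self.core + list(self.species) + list(self.covariates) + list(self.flags)


@dataclass
class CensusGrid:
    """A typed sub-block census table plus its column mapping."""

    df: pd.DataFrame
    colmap: ColumnMap = field(default_factory=ColumnMap.default)

    def __len__(self):
        return len(self.df)

    @property
    def years(self):
        return sorted(self.df[self.colmap.year].unique())

    def counts(self):
        return self.df[list(self.colmap.species)]

    def zero_fraction(self, year=None):
        """Share of censused sub-blocks with no wild ungulates at all."""
        df = self.df
        if year is not None:
            df = df[df[self.colmap.year] == year]
        totals = df[list(self.colmap.species)].sum(axis=1)
        return float((totals == 0).mean())

    def validate(self):
        cm = self.colmap
        counts = self.df[list(cm.species)]
        arr = counts.to_numpy()
        if np.any(arr < 0):
            row = int(np.argwhere((arr < 0).any(axis=1))[0][0])
            raise SchemaError(f"negative species count at row {row}")
        if not np.allclose(arr, np.round(arr)):
            row = int(np.argwhere(~np.isclose(arr, np.round(arr)).all(axis=1))[0][0])
            raise SchemaError(f"non-integer species count at row {row}")
        sizes = self.df.groupby([cm.block_id, cm.year])[cm.sub_block].nunique()
        counts_per = self.df.groupby([cm.block_id, cm.year])[cm.sub_block].size()
        if (sizes != counts_per).any() or (sizes > 9).any() or (sizes < 1).any():
            raise SchemaError("each (block, year) must hold 1-9 distinct sub-block indices")
        return self


def _require_columns(df, cols, path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mapped column(s) {missing}")


def read_subblock_csv(path, colmap=None) -> CensusGrid:
    """Read a sub-block census CSV into a validated :class:`CensusGrid`.

    Counts are parsed as integers; empty covariate fields stay missing (NaN).
    """
    cm = colmap or ColumnMap.default()
    df = pd.read_csv(path)
    if len(df) == 0:
        _require_columns(df, cm.core + list(cm.species), path)
        return CensusGrid(df=df, colmap=cm)
    _require_columns(df, cm.ordered_columns, path)
    grid = CensusGrid(df=df, colmap=cm)
    grid.validate()
    grid.df[list(cm.species)] = grid.df[list(cm.species)].astype(int)
    grid.df[list(cm.flags)] = grid.df[list(cm.flags)].astype(int)
    return grid


def write_subblock_csv(grid: CensusGrid, path):
    """Write the grid in the documented schema (deterministic column order)."""
    cols = [c for c in grid.colmap.ordered_columns if c in grid.df.columns]
    grid.df[cols].to_csv(path, index=False, na_rep="")
    return path


def write_block_csv(blocks: pd.DataFrame, path, colmap=None):
    """Write a block-level table, one row per (block, year).

    Raises an integrity error on duplicated (block, year) keys.
    """
    cm = colmap or ColumnMap.default()
    if len(blocks) == 0:
        raise ValueError("refusing to write an empty block table")
    key = [cm.block_id, cm.year]
    if blocks.duplicated(subset=key).any():
        dupes = blocks.loc[blocks.duplicated(subset=key), key].iloc[0].tolist()
        raise SchemaError(f"duplicate (block, year) key: {dupes}")
    blocks.sort_values(key).to_csv(path, index=False, na_rep="")
    return path


def read_block_csv(path, colmap=None) -> pd.DataFrame:
    cm = colmap or ColumnMap.default()
    df = pd.read_csv(path)
    _require_columns(df, [cm.block_id, cm.year], path)
    return df
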