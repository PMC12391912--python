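"""Sub-block to block aggregation with missing-sub-block correction.

Each 1 km-by-1 km block nests nine 333 m sub-blocks, but edges and
inaccessible terrain leave some blocks with fewer censused sub-blocks.  To
avoid underestimating block totals the expected total of species ``u`` in
block ``i`` is

    c_ui = (sum_j d_uij) * 9 / Q_i

where ``Q_i`` is the number of censused sub-blocks and ``d_uij`` the count in
sub-block ``j``.  Metric covariates are averaged over the sub-blocks where
they were observed (after imputation, when configured) and presence flags are
OR-ed to the block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from savannagrad.censusio import CensusGrid, ColumnMap

__all__ = ["expected_block_total", "aggregate_block", "aggregate_grid", "BlockRecord"]

N_SUBBLOCKS = 9


class IntegrityError(ValueError):
    """Inconsistent block composition (labels, keys or sub-block counts)."""


def expected_block_total(subblock_counts, q_i):
    """Expected block total ``(sum d) * 9 / Q`` for one species.

    ``subblock_counts`` must hold one nonnegative integer per censused
    sub-block, so its length equals ``Q_i``.
    """
    counts = np.asarray(subblock_counts)
    if q_i < 1 or q_i > N_SUBBLOCKS:
        raise IntegrityError(f"Q_i must be in 1..{N_SUBBLOCKS}, got {q_i}")
    if counts.size != q_i:
        raise IntegrityError(f"got {counts.size} sub-block counts for Q_i = {q_i}")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("sub-block counts must be nonnegative integers")
    return float(counts.sum() * N_SUBBLOCKS / q_i)


@dataclass
class BlockRecord:
    """One aggregated (block, year) unit."""

    block_id: str
    year: int
    land_use: str
    q: int
    dist_boundary_km: float
    species_totals: dict = field(default_factory=dict)
    covariates: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)


def aggregate_block(subblocks: pd.DataFrame, colmap: ColumnMap) -> BlockRecord:
    """Aggregate the sub-block rows of one (block, year) into a BlockRecord."""
    cm = colmap
    n = len(subblocks)
    if n < 1 or n > N_SUBBLOCKS:
        raise IntegrityError(f"a block must hold 1..{N_SUBBLOCKS} sub-blocks, got {n}")
    subs = subblocks[cm.sub_block]
    if subs.duplicated().any():
        raise IntegrityError("duplicate sub-block indices within a block")
    land_use = subblocks[cm.land_use].unique()
    if len(land_use) != 1:
        raise IntegrityError(
            f"inconsistent land-use labels within block "
            f"{subblocks[cm.block_id].iloc[0]!r}: {sorted(land_use)}"
        )
    totals = {
        sp: expected_block_total(subblocks[sp].to_numpy(), n) for sp in cm.species
    }
    covs = {c: float(subblocks[c].mean()) for c in cm.covariates}
    flags = {f: bool((subblocks[f] > 0).any()) for f in cm.flags}
    return BlockRecord(
        block_id=str(subblocks[cm.block_id].iloc[0]),
        year=int(subblocks[cm.year].iloc[0]),
        land_use=str(land_use[0]),
        q=n,
        dist_boundary_km=float(subblocks[cm.dist_boundary].mean()),
        species_totals=totals,
        covariates=covs,
        flags=flags,
    )


def aggregate_grid(grid: CensusGrid) -> pd.DataFrame:
    """Aggregate a full census grid to one row per (block, year).

    Returns a block table with columns: block id, year, land use, Q, mean
    signed boundary distance, the expected species totals, covariate means
    and OR-ed flags.
    """
    cm = grid.colmap
    df = grid.df
    key = [cm.block_id, cm.year]
    g = df.groupby(key, sort=True)

    q = g[cm.sub_block].nunique()
    sizes = g[cm.sub_block].size()
    if (q != sizes).any() or (q > N_SUBBLOCKS).any():
        raise IntegrityError("each (block, year) must hold 1-9 distinct sub-block indices")
    land = g[cm.land_use].nunique()
    if (land > 1).any():
        bad = land[land > 1].index[0]
        raise IntegrityError(f"inconsistent land-use labels within block {bad}")

    counts = df[list(cm.species)]
    if (counts.to_numpy() < 0).any():
        raise ValueError("sub-block counts must be nonnegative integers")

    out = pd.DataFrame(index=q.index)
    out["q_subblocks"] = q
    out[cm.land_use] = g[cm.land_use].first()
    out[cm.dist_boundary] = g[cm.dist_boundary].mean()
    sums = g[list(cm.species)].sum()
    out[list(cm.species)] = sums.mul(N_SUBBLOCKS / q, axis=0)
    out[list(cm.covariates)] = g[list(cm.covariates)].mean()
    out[list(cm.flags)] = (g[list(cm.flags)].max() > 0).astype(int)
    out = out.reset_index()
    cols = [cm.block_id, cm.year, cm.land_use, "q_subblocks", cm.dist_boundary]
    cols += list(cm.species) + list(cm.covariates) + list(cm.flags)
    return out[cols].sort_values(key, ignore_index=True)
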