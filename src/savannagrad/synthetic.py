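"""Synthetic two-year block censuses of a savanna ungulate community.

The generator emulates the statistical structure of a fine-scale ungulate
census on a 1-km block grid (nine 333-m sub-blocks per block) straddling a
protected-area / pastoral-land boundary, observed in a drought year and a
normal-rainfall year:

* a geometric rank-abundance distribution over the species pool, heavily
  dominated by the two migratory grazers (wildebeest, zebra);
* a biomass gradient: total ungulate intensity follows a Gaussian kernel in
  the signed boundary distance peaking inside the reserve, scaled down by the
  drought multiplier in the drought year;
* a diversity gradient: resident-species occupancy is lifted by a second
  Gaussian kernel peaking on the pastoral side of the boundary (intermediate
  human use), flattened in the drought year; migratory occupancy follows the
  biomass kernel, which produces the large share of migratory-biomass zeros
  on far pastoral land;
* high sub-block zero fractions: a structural-empty probability per sub-block
  is calibrated by bisection so the realized share of censused sub-blocks
  with no wild ungulates matches the per-year targets (defaults 73% drought,
  63% normal).  Animals are placed only into non-empty sub-blocks, so the
  calibration changes where animals are recorded but not block totals;
* spatially autocorrelated vegetation covariates with planned missingness
  (grass attributes sampled in every third sub-block, shrub/tree attributes
  in the central sub-block only), plus landscape and rainfall predictors and
  presence flags, for about 26 block-level model covariates;
* incomplete blocks: a per-year share of blocks loses 1-3 sub-blocks, which
  exercises the missing-sub-block correction downstream.

Counts of the wild species pool only; livestock and other human-use variables
enter as covariates, never as community members.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter

from savannagrad.censusio import CensusGrid, ColumnMap, DEFAULT_SPECIES

__all__ = [
    "CovariateField",
    "ScenarioConfig",
    "geometric_rank_abundance",
    "simulate_landscape",
    "write_truth",
    "CalibrationError",
]

SUBS_PER_SIDE = 3
SUBS_PER_BLOCK = SUBS_PER_SIDE**2
SUB_KM = 1.0 / SUBS_PER_SIDE


class CalibrationError(RuntimeError):
    """The requested zero fraction cannot be reached for this scenario."""


def geometric_rank_abundance(n_species, shape):
    """Relative abundances ``k (1-k)^(i-1)`` (renormalized), rank-ordered.

    The geometric series is the classic niche-preemption model for strongly
    dominated communities; ``shape`` is the preemption fraction k.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if not 0.0 < shape < 1.0:
        raise ValueError("rank-abundance shape must lie strictly in (0, 1)")
    ranks = np.arange(n_species)
    p = shape * (1.0 - shape) ** ranks
    return p / p.sum()


@dataclass(frozen=True)
class CovariateField:
    """A spatially correlated sub-block covariate.

    ``missing`` is either a float fraction of randomly unsampled sub-blocks or
    one of the planned patterns ``"none"`` (fully observed), ``"thirds"``
    (observed in sub-blocks 1, 4, 7 -- the every-third-sub-block plot design)
    and ``"center"`` (observed in the central sub-block only).
    ``trend_per_km`` adds a linear trend in the signed boundary distance and
    ``year_shift`` a per-year additive offset (e.g. faded grass in a drought).
    """

    name: str
    range_km: float = 5.0
    mean: float = 0.0
    sd: float = 1.0
    missing: object = "none"
    lower: float = None
    upper: float = None
    trend_per_km: float = 0.0
    year_shift: dict = field(default_factory=dict)


def _default_covariates():
    veg = [
        CovariateField("grass_cover", 6.0, 55.0, 14.0, "thirds", 0.0, 100.0,
                       year_shift={"drought": -15.0}),
        CovariateField("grass_height", 5.0, 28.0, 9.0, "thirds", 0.0, None,
                       trend_per_km=-0.45, year_shift={"drought": -9.0}),
        CovariateField("grass_color", 6.0, 3.2, 0.65, "thirds", 1.0, 5.0,
                       trend_per_km=-0.04, year_shift={"drought": -0.7}),
        CovariateField("shrub_cover", 7.0, 18.0, 8.0, "center", 0.0, 100.0,
                       trend_per_km=0.25),
        CovariateField("shrub_height", 6.0, 1.6, 0.5, "center", 0.0, None),
        CovariateField("shrub_color", 6.0, 3.0, 0.5, "center", 1.0, 5.0),
        CovariateField("tree_cover", 8.0, 9.0, 5.0, "center", 0.0, 100.0),
        CovariateField("tree_height", 7.0, 4.5, 1.5, "center", 0.0, None),
        CovariateField("tree_color", 7.0, 3.1, 0.5, "center", 1.0, 5.0),
    ]
    return tuple(veg)


@dataclass(frozen=True)
class ScenarioConfig:
    """Generating parameters of one synthetic census scenario.

    Distances are signed: negative inside the reserve, positive on pastoral
    land, zero on the boundary.  Defaults give a 30 km x 30 km landscape with
    the boundary in the middle, a 19-species pool dominated by the two
    migratory species, a biomass peak deep inside the reserve and a diversity
    peak on the pastoral side of the boundary.
    """

    nx: int = 30
    ny: int = 30
    boundary_col: int = 15
    n_species: int = 19
    rank_shape: float = 0.4
    years: tuple = (1999, 2002)
    drought_year: int = 1999
    drought_multiplier: float = 0.5
    zero_fraction: dict = field(default_factory=lambda: {1999: 0.73, 2002: 0.63})
    missing_block_fraction: dict = field(default_factory=lambda: {1999: 0.18, 2002: 0.29})
    diversity_peak_km: float = 5.0
    diversity_width_km: float = 6.0
    biomass_peak_km: float = -15.0
    biomass_width_km: float = 12.0
    base_intensity: float = 60.0
    block_heterogeneity_sd: float = 0.5
    covariates: tuple = field(default_factory=_default_covariates)
    seed: int = 0

    def __post_init__(self):
        if self.nx < 4 or self.ny < 4:
            raise ValueError("grid must be at least 4x4 blocks")
        if self.n_species < 2:
            raise ValueError("species pool must hold at least 2 species")
        if not 0.0 < self.rank_shape < 1.0:
            raise ValueError("rank_shape must lie in (0, 1)")
        if not 0.0 < self.drought_multiplier <= 1.0:
            raise ValueError("drought multiplier must lie in (0, 1]")
        for y, z in self.zero_fraction.items():
            if not 0.0 <= z <= 1.0:
                raise ValueError(f"zero fraction for {y} outside [0, 1]")
        for y, m in self.missing_block_fraction.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"missing-block fraction for {y} outside [0, 1]")
        if self.diversity_width_km <= 0 or self.biomass_width_km <= 0:
            raise ValueError("kernel widths must be positive")
        if not 0 < self.boundary_col < self.nx:
            raise ValueError("boundary column must split the grid")

    # -- derived quantities ------------------------------------------------
    def species_names(self):
        base = list(DEFAULT_SPECIES)
        if self.n_species <= len(base):
            return base[: self.n_species]
        extra = [f"species_{i:02d}" for i in range(len(base) + 1, self.n_species + 1)]
        return base + extra

    def year_multiplier(self, year):
        return self.drought_multiplier if year == self.drought_year else 1.0

    def biomass_kernel(self, d):
        return np.exp(-((np.asarray(d, float) - self.biomass_peak_km) ** 2)
                      / (2.0 * self.biomass_width_km**2))

    def diversity_kernel(self, d):
        return np.exp(-((np.asarray(d, float) - self.diversity_peak_km) ** 2)
                      / (2.0 * self.diversity_width_km**2))

    def occupancy(self, d, year):
        """Per-species presence probability at signed distance ``d``.

        Rows: species (rank order); columns: the entries of ``d``.  Migratory
        ranks 1-2 track the biomass kernel; resident ranks have rank-dependent
        floors lifted toward 1 by the diversity kernel, damped in drought.
        """
        d = np.atleast_1d(np.asarray(d, float))
        amp = 0.75 * np.sqrt(self.year_multiplier(year))
        gb = self.biomass_kernel(d)
        gd = self.diversity_kernel(d)
        pi = np.empty((self.n_species, d.size))
        n_mig = min(2, self.n_species)
        pi[:n_mig] = 0.25 + 0.75 * gb
        for u in range(n_mig, self.n_species):
            floor = 0.02 + 0.85 * 0.7 ** (u - n_mig)
            pi[u] = floor + (1.0 - floor) * amp * gd
        return np.clip(pi, 0.0, 1.0)

    def intensity(self, d, year):
        """Per-species conditional count intensity (before heterogeneity)."""
        d = np.atleast_1d(np.asarray(d, float))
        a = geometric_rank_abundance(self.n_species, self.rank_shape)
        lam = (self.base_intensity * self.year_multiplier(year)
               * self.biomass_kernel(d)[None, :] * a[:, None])
        return lam


def _ztp_mean(lam):
    lam = np.asarray(lam, dtype=float)
    with np.errstate(over="ignore"):
        return np.where(lam < 1e-8, 1.0, lam / -np.expm1(-np.minimum(lam, 700.0)))


def _sample_ztp(rng, lam):
    """Zero-truncated Poisson draws, one per entry of lam."""
    lam = np.asarray(lam, dtype=float)
    p0 = np.exp(-lam)
    u = rng.uniform(np.minimum(p0, 1.0 - 1e-16), 1.0)
    out = stats.poisson.ppf(u, np.maximum(lam, 1e-300)).astype(int)
    return np.maximum(out, 1)


def _grf(shape, range_km, rng):
    """Standardized Gaussian random field on the sub-block lattice."""
    noise = rng.normal(size=shape)
    sigma = max(range_km / SUB_KM / 2.0, 0.5)
    f = gaussian_filter(noise, sigma=sigma, mode="reflect")
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else f


def _expected_zero_fraction(z, block_totals):
    """Exact expected share of zero sub-blocks given structural prob ``z``.

    With ``k ~ Binomial(9, z)`` structurally empty sub-blocks and ``N``
    individuals placed uniformly over the remaining ``9-k``, a non-empty
    sub-block stays without animals with probability ``(1 - 1/(9-k))^N``.
    """
    n = np.asarray(block_totals, dtype=float)
    total = np.zeros_like(n)
    for k in range(SUBS_PER_BLOCK + 1):
        w = stats.binom.pmf(k, SUBS_PER_BLOCK, z)
        if k == SUBS_PER_BLOCK:
            term = float(SUBS_PER_BLOCK)
        else:
            m = SUBS_PER_BLOCK - k
            term = k + m * (1.0 - 1.0 / m) ** n
        total = total + w * term
    return float(np.mean(total) / SUBS_PER_BLOCK)


def _calibrate_structural_zero(target, block_totals):
    f0 = _expected_zero_fraction(0.0, block_totals)
    if target < f0 - 0.005:
        raise CalibrationError(
            f"target zero fraction {target:.2f} below the floor {f0:.2f} "
            "implied by the count intensities"
        )
    if target <= f0:
        return 0.0
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _expected_zero_fraction(mid, block_totals) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _landscape_tables(config, rng):
    """Year-invariant landscape covariates at sub-block resolution."""
    nxs, nys = config.nx * SUBS_PER_SIDE, config.ny * SUBS_PER_SIDE
    xs = (np.arange(nxs) + 0.5) * SUB_KM
    ys = (np.arange(nys) + 0.5) * SUB_KM
    gx, gy = np.meshgrid(xs, ys, indexing="ij")

    out = {}
    out["elevation_m"] = 1550.0 + 8.0 * gx + 40.0 * _grf((nxs, nys), 8.0, rng)
    out["slope_deg"] = np.abs(2.5 * _grf((nxs, nys), 4.0, rng)) + 0.4

    def dist_to(points):
        px, py = points[:, 0], points[:, 1]
        d2 = (gx[..., None] - px) ** 2 + (gy[..., None] - py) ** 2
        return np.sqrt(d2.min(axis=-1))

    bx = float(config.boundary_col)
    water = np.column_stack([rng.uniform(0, config.nx, 10), rng.uniform(0, config.ny, 10)])
    out["dist_water_km"] = dist_to(water)
    occ = np.column_stack(
        [np.clip(bx + np.abs(rng.normal(5.0, 4.0, 40)), 0, config.nx),
         rng.uniform(0, config.ny, 40)]
    )
    out["dist_boma_occupied_km"] = dist_to(occ)
    aban = np.column_stack(
        [np.clip(bx + rng.normal(4.0, 5.0, 25), 0, config.nx),
         rng.uniform(0, config.ny, 25)]
    )
    out["dist_boma_abandoned_km"] = dist_to(aban)
    infra = np.column_stack(
        [np.clip(config.nx - np.abs(rng.normal(4.0, 3.0, 15)), 0, config.nx),
         rng.uniform(0, config.ny, 15)]
    )
    out["dist_infrastructure_km"] = dist_to(infra)
    return out, (gx, gy)


_RAIN_BASE = {  # (wet season, dry season, preceding month) means in mm
    "drought": (620.0, 250.0, 40.0),
    "normal": (790.0, 200.0, 70.0),
}


def simulate_landscape(config: ScenarioConfig) -> CensusGrid:
    """Simulate the full two-year sub-block census for one scenario.

    Fully reproducible from ``config.seed``.  The returned grid carries a
    ``meta`` attribute with the calibrated structural-zero probabilities.
    """
    rng_master = np.random.default_rng(config.seed)
    seeds = rng_master.spawn(6)
    rng_land, rng_cov, rng_counts, rng_mask, rng_flags, rng_drop = seeds

    species = config.species_names()
    nxs, nys = config.nx * SUBS_PER_SIDE, config.ny * SUBS_PER_SIDE
    land, (gx, gy) = _landscape_tables(config, rng_land)

    # block/sub-block geometry
    sub_i, sub_j = np.meshgrid(np.arange(nxs), np.arange(nys), indexing="ij")
    block_ix, block_iy = sub_i // SUBS_PER_SIDE, sub_j // SUBS_PER_SIDE
    within = (sub_i % SUBS_PER_SIDE) + SUBS_PER_SIDE * (sub_j % SUBS_PER_SIDE) + 1
    dist_sub = gx - config.boundary_col
    block_dist = {}  # block (ix, iy) -> signed center distance
    for ix in range(config.nx):
        block_dist[ix] = (ix + 0.5) - config.boundary_col

    # covariate fields per year
    mults = {y: config.year_multiplier(y) for y in config.years}
    cov_values = {}
    for f in config.covariates:
        for year in config.years:
            kind = "drought" if year == config.drought_year else "normal"
            shift = f.year_shift.get(kind, f.year_shift.get(year, 0.0))
            vals = f.mean + shift + f.sd * _grf((nxs, nys), f.range_km, rng_cov)
            vals = vals + f.trend_per_km * dist_sub
            if f.lower is not None:
                vals = np.maximum(vals, f.lower)
            if f.upper is not None:
                vals = np.minimum(vals, f.upper)
            cov_values[(f.name, year)] = vals

    rain = {}
    for year in config.years:
        kind = "drought" if year == config.drought_year else "normal"
        wet, dry, prev = _RAIN_BASE[kind]
        rain[("rain_wet_mm", year)] = wet + 2.5 * gx + 40.0 * _grf((nxs, nys), 10.0, rng_cov)
        rain[("rain_dry_mm", year)] = dry - 1.0 * gx + 20.0 * _grf((nxs, nys), 10.0, rng_cov)
        rain[("rain_prev_mm", year)] = prev + 10.0 * _grf((nxs, nys), 10.0, rng_cov)

    # per-block occupancy draws and counts
    abund = geometric_rank_abundance(config.n_species, config.rank_shape)
    frames = []
    meta = {"structural_zero": {}}
    for year in config.years:
        mult = mults[year]
        rows = []
        block_counts = {}
        totals = []
        for ix in range(config.nx):
            d = block_dist[ix]
            pi = config.occupancy(d, year)[:, 0]
            lam = (config.base_intensity * mult * float(config.biomass_kernel(d)) * abund)
            for iy in range(config.ny):
                hetero = float(
                    np.exp(rng_counts.normal(-0.5 * config.block_heterogeneity_sd**2,
                                             config.block_heterogeneity_sd))
                )
                present = rng_counts.uniform(size=config.n_species) < pi
                n_u = np.zeros(config.n_species, dtype=int)
                if present.any():
                    lam_p = np.maximum(lam[present] * hetero, 1e-9)
                    n_u[present] = _sample_ztp(rng_counts, lam_p)
                block_counts[(ix, iy)] = n_u
                totals.append(int(n_u.sum()))

        z = _calibrate_structural_zero(config.zero_fraction.get(year, 0.0), totals)
        meta["structural_zero"][year] = z

        # structural-empty mask and multinomial placement over open sub-blocks
        counts_grid = np.zeros((config.n_species, nxs, nys), dtype=int)
        for (ix, iy), n_u in block_counts.items():
            mask = rng_mask.uniform(size=SUBS_PER_BLOCK) < z
            open_subs = np.flatnonzero(~mask)
            if open_subs.size == 0 or n_u.sum() == 0:
                continue
            probs = np.full(open_subs.size, 1.0 / open_subs.size)
            for u in np.flatnonzero(n_u):
                alloc = rng_mask.multinomial(n_u[u], probs)
                for s_local, c in zip(open_subs, alloc):
                    if c:
                        sx, sy = s_local % SUBS_PER_SIDE, s_local // SUBS_PER_SIDE
                        counts_grid[u, ix * SUBS_PER_SIDE + sx, iy * SUBS_PER_SIDE + sy] += c

        # assemble rows
        flat = {
            "block_id": np.char.add(
                np.char.add("B", np.char.zfill(block_ix.astype(str), 3)),
                np.char.add("_", np.char.zfill(block_iy.astype(str), 3)),
            ).ravel(),
            "sub_block": within.ravel(),
            "year": np.full(nxs * nys, year),
            "land_use": np.where(dist_sub.ravel() < 0, "reserve", "pastoral"),
            "x_m": np.round(gx.ravel() * 1000.0, 1),
            "y_m": np.round(gy.ravel() * 1000.0, 1),
            "dist_boundary_km": np.round(
                ((block_ix + 0.5) - config.boundary_col).ravel(), 4
            ),
        }
        for u, sp in enumerate(species):
            flat[sp] = counts_grid[u].ravel()

        d_ravel = dist_sub.ravel()
        for f in config.covariates:
            vals = cov_values[(f.name, year)].ravel().copy()
            if f.missing == "thirds":
                observed = np.isin(within.ravel(), (1, 4, 7))
            elif f.missing == "center":
                observed = within.ravel() == 5
            elif f.missing in ("none", 0, 0.0, None):
                observed = np.ones(vals.size, dtype=bool)
            else:
                observed = rng_cov.uniform(size=vals.size) >= float(f.missing)
            vals[~observed] = np.nan
            flat[f.name] = np.round(vals, 3)
        for name in ("elevation_m", "slope_deg", "dist_water_km",
                     "dist_boma_occupied_km", "dist_boma_abandoned_km",
                     "dist_infrastructure_km"):
            flat[name] = np.round(land[name].ravel(), 3)
        for name in ("rain_wet_mm", "rain_dry_mm", "rain_prev_mm"):
            flat[name] = np.round(rain[(name, year)].ravel(), 2)

        # presence flags
        d_r = d_ravel
        gb = config.biomass_kernel(d_r)
        in_reserve = d_r < 0
        p_live = np.where(in_reserve, 0.30 * np.exp(d_r / 2.5) * (d_r > -7.1), 0.35)
        flat["sheep_goats"] = (rng_flags.uniform(size=d_r.size) < p_live).astype(int)
        flat["cattle"] = (rng_flags.uniform(size=d_r.size) < 0.8 * p_live).astype(int)
        flat["fire_scar"] = (
            rng_flags.uniform(size=d_r.size) < np.where(in_reserve, 0.12, 0.05)
        ).astype(int)
        flat["carnivores"] = (
            rng_flags.uniform(size=d_r.size) < 0.03 + 0.12 * gb * mult
        ).astype(int)
        flat["vehicles"] = (
            rng_flags.uniform(size=d_r.size) < np.where(in_reserve, 0.06, 0.02)
        ).astype(int)
        flat["litter"] = (
            rng_flags.uniform(size=d_r.size) < np.where(in_reserve, 0.02, 0.08)
        ).astype(int)

        df = pd.DataFrame(flat)

        # incomplete blocks: drop 1-3 sub-blocks from a share of blocks
        frac = config.missing_block_fraction.get(year, 0.0)
        if frac > 0:
            blocks = df["block_id"].unique()
            hit = blocks[rng_drop.uniform(size=blocks.size) < frac]
            drop_idx = []
            for b in hit:
                n_drop = rng_drop.integers(1, 4)
                subs = rng_drop.choice(np.arange(1, 10), size=n_drop, replace=False)
                drop_idx.append(df.index[(df["block_id"] == b) & df["sub_block"].isin(subs)])
            if drop_idx:
                df = df.drop(np.concatenate([ix.to_numpy() for ix in drop_idx]))
        frames.append(df)

    colmap = ColumnMap(species=tuple(species))
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["year", "block_id", "sub_block"], ignore_index=True)
    grid = CensusGrid(df=out[colmap.ordered_columns], colmap=colmap)
    grid.meta = meta
    return grid


def write_truth(config: ScenarioConfig, grid: CensusGrid) -> pd.DataFrame:
    """Latent generating quantities per (block, year), for recovery tests.

    Expected counts, expected richness (the sum of occupancy probabilities)
    and expected unit-weight biomass are computed at unit block heterogeneity;
    the configured kernel peaks are passed through for each row.
    """
    from savannagrad.metrics import SpeciesAttributes

    attrs = SpeciesAttributes.default()
    species = config.species_names()
    masses = np.array(
        [attrs.mass(s) if s in attrs.table.index else 50.0 for s in species]
    )
    cm = grid.colmap
    keys = (
        grid.df[[cm.block_id, cm.year, cm.dist_boundary]]
        .groupby([cm.block_id, cm.year], as_index=False)
        .mean()
    )
    rows = []
    for _, rec in keys.iterrows():
        year = int(rec[cm.year])
        # distance of the block center (sub-block mean equals it on full blocks)
        d = float(rec[cm.dist_boundary])
        pi = config.occupancy(d, year)[:, 0]
        lam = config.intensity(d, year)[:, 0]
        expected_counts = pi * _ztp_mean(lam)
        rows.append(
            {
                cm.block_id: rec[cm.block_id],
                cm.year: year,
                cm.dist_boundary: d,
                "expected_total_count": float(expected_counts.sum()),
                "expected_richness": float(pi.sum()),
                "expected_biomass_kg": float((expected_counts * masses).sum()),
                "total_intensity": float(lam.sum()),
                "diversity_peak_km": config.diversity_peak_km,
                "biomass_peak_km": config.biomass_peak_km,
                "year_multiplier": config.year_multiplier(year),
            }
        )
    return pd.DataFrame(rows)
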