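"""Seeded synthetic island populations, surveys, and planted-effect responses.

This module generates data with the statistical structure the analysis
assumes: a long, narrow island with permanent freshwater ponds concentrated
toward one end (an east-west water gradient), a feral-horse-like social
system of bands (one dominant stallion, optionally a subordinate "tag" male,
a harem of mares, juveniles) plus unattached bachelor males, and repeated
island-wide survey occasions in which every member of a band is recorded at
the band's current location.

Ground-truth covariate effects ("planted" effects) can be attached to the
modelling table so that the downstream two-stage mixed-model inference can be
exercised as a parameter-recovery experiment with a known answer.

Everything is driven by :func:`numpy.random.default_rng` seeded generators:
identical seeds give byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from functools import lru_cache

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats
from shapely.geometry import box

from .errors import ConfigurationError

#: Yearly summer precipitation index (z-scored island weather record).
PRECIP_INDEX = {
    2008: -0.747,
    2009: 0.878,
    2010: -1.239,
    2011: 0.339,
    2012: -0.545,
}

AGE_CLASSES = ("0", "1", "2-3", "4+")


@dataclass
class IslandConfig:
    """Geometry and survey design of a synthetic island.

    The default island is a 49 km by 1.5 km sandbar surveyed for five
    breeding seasons with eight island-wide census occasions each.  Ponds
    are placed in the western portion so that distance to the nearest
    permanent pond spans roughly 0-15 km across band home sites.
    """

    length_km: float = 49.0
    width_km: float = 1.5
    n_ponds: int = 12
    pond_positions: list[tuple[float, float]] | None = None
    n_years: int = 5
    occasions_per_year: int = 8
    start_year: int = 2008
    precipitation_index: dict[int, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.length_km <= 0 or self.width_km <= 0:
            raise ConfigurationError(
                f"island dimensions must be positive, got "
                f"{self.length_km} x {self.width_km}"
            )
        if not 2 <= self.occasions_per_year:
            raise ConfigurationError("need at least 2 survey occasions per year")
        if self.n_years < 1:
            raise ConfigurationError("n_years must be >= 1")
        if self.pond_positions is not None:
            for x, y in self.pond_positions:
                if not (0 <= x <= self.length_km and 0 <= y <= self.width_km):
                    raise ConfigurationError(f"pond ({x}, {y}) outside island")
        for y, v in self.precip_by_year().items():
            if not np.isfinite(v):
                raise ConfigurationError(f"precipitation index for {y} not finite")

    @property
    def years(self) -> list[int]:
        return [self.start_year + t for t in range(self.n_years)]

    def precip_by_year(self) -> dict[int, float]:
        if self.precipitation_index is not None:
            return {y: float(self.precipitation_index[y]) for y in self.years}
        return {y: PRECIP_INDEX.get(y, 0.0) for y in self.years}


@dataclass
class TruthParams:
    """Ground-truth demographic structure and planted covariate effects.

    Demographic defaults follow the annual band counts and mean harem sizes
    of the study system (52-79 bands over five years, 2.1-2.7 mares per
    harem), a resighting regime of mean 2.84 (SD 1.43) repeat sightings per
    individual, and breeding-dispersal rates of 0.16 (adults) and 0.34
    (1-3 year olds) used as per-individual annual reassignment
    probabilities.

    ``asr_slopes`` are the per-episode links between local adult sex ratio
    and the opportunity statistics (total I, I_harem, I_mares|harem) used
    when planting responses; ``unpaired_effect_on_Iharem`` and the
    ``water_by_precip_*`` pairs are the stage-two effects that the AICc
    competition is expected to recover.  Each ``water_by_precip`` pair gives
    the distance-from-water slope in average versus extreme precipitation
    years (|index| above ``extreme_precip_threshold`` counts as extreme).
    """

    n_bands_per_year: tuple[int, ...] | int = (52, 58, 73, 73, 79)
    mean_harem_size: tuple[float, ...] | float = (2.60, 2.71, 2.33, 2.12, 2.32)
    bachelor_fraction: float = 0.58
    tag_probability: float = 0.03
    asr_gradient_slope: float = 0.01
    asr_slopes: tuple[float, float, float] = (0.6, 1.725, 0.396)
    episode_intercepts: tuple[float, float, float] = (0.85, 0.47, 0.42)
    unpaired_effect_on_Iharem: float = 0.30
    water_by_precip_effect_on_Imares: tuple[float, float] = (0.02, -0.05)
    water_by_precip_effect_on_I: tuple[float, float] = (0.04, -0.10)
    extreme_precip_threshold: float = 0.8
    year_effect_sd: float = 0.08
    male_intercept_sd: float = 0.08
    residual_sd: float = 0.12
    resight_mean: float = 2.84
    resight_sd: float = 1.43
    breeding_dispersal_adult: float = 0.16
    breeding_dispersal_young: float = 0.34

    def validate(self, n_years: int) -> None:
        for f in (self.bachelor_fraction, self.tag_probability,
                  self.breeding_dispersal_adult, self.breeding_dispersal_young):
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"fraction {f} outside [0, 1]")
        if self.bachelor_fraction >= 1.0 and max(self.bands_for(n_years)) > 0:
            raise ConfigurationError(
                "bachelor_fraction = 1 is infeasible with bands present"
            )
        if min(self.bands_for(n_years)) < 1:
            raise ConfigurationError("need at least one band per year")
        if min(self.harem_means_for(n_years)) < 1.0:
            raise ConfigurationError("mean harem size must be >= 1")
        if self.resight_mean < 1.0 or self.resight_sd <= 0:
            raise ConfigurationError("resight moments infeasible")

    def bands_for(self, n_years: int) -> list[int]:
        v = self.n_bands_per_year
        if np.isscalar(v):
            return [int(v)] * n_years
        return [int(v[t % len(v)]) for t in range(n_years)]

    def harem_means_for(self, n_years: int) -> list[float]:
        v = self.mean_harem_size
        if np.isscalar(v):
            return [float(v)] * n_years
        return [float(v[t % len(v)]) for t in range(n_years)]

    def water_slope(self, precip_index: float, pair: tuple[float, float]) -> float:
        """Planted distance-from-water slope for a year with the given index."""
        avg, extreme = pair
        return extreme if abs(precip_index) >= self.extreme_precip_threshold else avg


@dataclass
class Island:
    """A generated island: rectangle polygon plus permanent pond points."""

    config: IslandConfig
    polygon: object  # shapely Polygon
    ponds: np.ndarray  # (n_ponds, 2) in km
    quality_phase: float = 0.0  # phase of the forage-quality field

    def quality(self, x: np.ndarray) -> np.ndarray:
        """Smooth forage-quality multiplier along the island (about 0.5-1.5).

        Harem sizes scale with local quality, which gives the local adult
        sex ratio female-driven spatial variation of its own.
        """
        x = np.asarray(x, dtype=float)
        return 1.0 + 0.5 * np.sin(2.0 * np.pi * (3.0 * x / self.config.length_km)
                                  + self.quality_phase)

    @property
    def area_km2(self) -> float:
        return self.polygon.area


def generate_island(config: IslandConfig) -> Island:
    """Build the island rectangle and place permanent freshwater ponds.

    Ponds are clustered toward the west end (x below ``length - 15`` km where
    the island is long enough) so that distance to the nearest pond spans
    approximately 0-15 km across the island.  Deterministic for a fixed
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    polygon = box(0.0, 0.0, config.length_km, config.width_km)
    if config.pond_positions is not None:
        ponds = np.asarray(config.pond_positions, dtype=float).reshape(-1, 2)
    else:
        x_max = max(1.0, config.length_km - 15.0)
        x = np.sort(rng.uniform(0.3, x_max, size=config.n_ponds))
        y = rng.uniform(0.15 * config.width_km, 0.85 * config.width_km,
                        size=config.n_ponds)
        ponds = np.column_stack([x, y])
    return Island(config=config, polygon=polygon, ponds=ponds,
                  quality_phase=float(rng.uniform(0, 2 * np.pi)))


def distance_to_water(points: np.ndarray, ponds: np.ndarray) -> np.ndarray:
    """Euclidean distance (km) from each point to its nearest pond."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.linalg.norm(pts[:, None, :] - ponds[None, :, :], axis=2)
    return d.min(axis=1)


# ---------------------------------------------------------------------------
# population generation


def _new_ids(prefix: str, start: int, n: int) -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(start, start + n)]


class _IdPool:
    """Monotone ID factory so identities never collide across years."""

    def __init__(self) -> None:
        self.counters: dict[str, int] = {}

    def take(self, prefix: str, n: int) -> list[str]:
        start = self.counters.get(prefix, 1)
        self.counters[prefix] = start + n
        return _new_ids(prefix, start, n)


def _bachelor_sites(rng, island: Island, n: int, truth: TruthParams,
                    band_x: np.ndarray | None = None) -> np.ndarray:
    """Home sites for unattached males.

    Bachelor males range in loose groups: sites follow a few
    moderate-contrast bachelor-group hotspots redrawn each year, mildly
    repelled from band clusters (dominant stallions exclude bachelor groups
    from prime breeding areas).  The muted contrast keeps the male-driven
    share of local ASR variance below the female-driven share (harem sizes
    track forage quality and water access), so accounting for ASR does not
    soak up the unpaired-male density signal.  The rising ASR with distance
    from water is produced on the female side (see
    :func:`generate_population`), leaving the bachelor field uncorrelated
    with the water gradient.
    """
    cfg = island.config
    grid = np.linspace(0.0, cfg.length_km, 400)
    centers = rng.uniform(0.0, cfg.length_km, size=5)
    w = 1.0 + 2.0 * np.exp(
        -((grid[:, None] - centers[None, :]) ** 2) / (2.0 * 2.0 ** 2)).sum(axis=1)
    if band_x is not None and len(band_x):
        bandfield = np.exp(-((grid[:, None] - band_x[None, :]) ** 2)
                           / (2.0 * 2.0 ** 2)).sum(axis=1)
        w = w / (0.6 + bandfield / max(bandfield.mean(), 1e-9))
    w /= w.sum()
    x = grid[rng.choice(grid.size, size=n, p=w)]
    x = np.clip(x + rng.normal(0, 0.5, size=n), 0.0, cfg.length_km)
    y = rng.uniform(0.05 * cfg.width_km, 0.95 * cfg.width_km, size=n)
    return np.column_stack([x, y])


def _draw_harem_sizes(rng, n: int, mean: float) -> np.ndarray:
    """Harem sizes as 1 + Poisson(mean - 1): at least one mare per band."""
    return 1 + rng.poisson(max(mean - 1.0, 0.0), size=n)


def generate_population(
    island: Island,
    truth: TruthParams,
    year: int,
    rng: np.random.Generator,
    prev: pd.DataFrame | None = None,
    id_pool: _IdPool | None = None,
) -> pd.DataFrame:
    """Generate one year's population as an individual table.

    Columns: ``individual_id, sex, age_class, status, band_id, home_x,
    home_y``.  Every band has exactly one dominant male; tag males occur in a
    small fraction of bands; bachelors are qualified males (age 4+) holding
    no harem.  When ``prev`` (the previous year's table) is given, dominant
    males, bands, and mares persist subject to the breeding-dispersal rates.
    """
    cfg = island.config
    truth.validate(cfg.n_years)
    id_pool = id_pool or _IdPool()
    t = year - cfg.start_year
    n_bands = truth.bands_for(cfg.n_years)[t % max(cfg.n_years, 1)]
    harem_mean = truth.harem_means_for(cfg.n_years)[t % max(cfg.n_years, 1)]

    rows: list[dict] = []

    # --- bands and their dominant males -----------------------------------
    if prev is None:
        band_ids = id_pool.take("B", n_bands)
        # band home ranges cluster around good forage patches, giving total
        # density spatial variation of its own (independent of bachelors)
        patch = rng.uniform(0.0, cfg.length_km, size=5)
        gx = np.linspace(0.0, cfg.length_km, 400)
        wb = 0.20 + np.exp(-((gx[:, None] - patch[None, :]) ** 2)
                           / (2.0 * 2.0 ** 2)).sum(axis=1)
        wb /= wb.sum()
        band_x = np.clip(gx[rng.choice(gx.size, size=n_bands, p=wb)]
                         + rng.normal(0, 0.8, n_bands), 0.0, cfg.length_km)
        band_y = rng.uniform(0.1 * cfg.width_km, 0.9 * cfg.width_km, n_bands)
        dom_ids = id_pool.take("M", n_bands)
        prev_bachelors: list[str] = []
        prev_mares: list[tuple[str, str]] = []
    else:
        prev_bands = (
            prev[prev["status"] == "dominant"][["band_id", "home_x", "home_y",
                                                "individual_id"]]
            .rename(columns={"individual_id": "dom"})
            .reset_index(drop=True)
        )
        keep = min(n_bands, len(prev_bands))
        order = rng.permutation(len(prev_bands))[:keep]
        prev_bands = prev_bands.iloc[np.sort(order)].reset_index(drop=True)
        band_ids = list(prev_bands["band_id"])
        band_x = np.clip(prev_bands["home_x"].to_numpy()
                         + rng.normal(0, 1.0, keep), 0.0, cfg.length_km)
        band_y = np.clip(prev_bands["home_y"].to_numpy()
                         + rng.normal(0, 0.2, keep),
                         0.05 * cfg.width_km, 0.95 * cfg.width_km)
        dom_ids = list(prev_bands["dom"])
        prev_bachelors = list(
            prev[prev["status"] == "bachelor"]["individual_id"]
        )
        prev_mares = list(
            prev[prev["status"] == "mare"][["individual_id", "age_class"]]
            .itertuples(index=False, name=None)
        )
        # dominant turnover: displaced stallions join the bachelor pool,
        # replacements promoted from it (or new recruits)
        turnover = rng.random(keep) < truth.breeding_dispersal_adult
        pool = list(prev_bachelors)
        for i in np.flatnonzero(turnover):
            prev_bachelors.append(dom_ids[i])
            if pool:
                j = rng.integers(len(pool))
                new_dom = pool.pop(j)
                if new_dom in prev_bachelors:
                    prev_bachelors.remove(new_dom)
            else:
                new_dom = id_pool.take("M", 1)[0]
            dom_ids[i] = new_dom
        if n_bands > keep:
            extra = n_bands - keep
            band_ids += id_pool.take("B", extra)
            band_x = np.concatenate([band_x,
                                     rng.uniform(0, cfg.length_km, extra)])
            band_y = np.concatenate(
                [band_y, rng.uniform(0.1 * cfg.width_km,
                                     0.9 * cfg.width_km, extra)])
            for _ in range(extra):
                if prev_bachelors and rng.random() < 0.7:
                    j = rng.integers(len(prev_bachelors))
                    dom_ids.append(prev_bachelors.pop(j))
                else:
                    dom_ids.append(id_pool.take("M", 1)[0])

    for b, (bid, did) in enumerate(zip(band_ids, dom_ids)):
        rows.append(dict(individual_id=did, sex="M", age_class="4+",
                         status="dominant", band_id=bid,
                         home_x=band_x[b], home_y=band_y[b]))

    # --- tag males ---------------------------------------------------------
    has_tag = rng.random(n_bands) < truth.tag_probability
    tag_ids = id_pool.take("M", int(has_tag.sum()))
    ti = 0
    for b in np.flatnonzero(has_tag):
        rows.append(dict(individual_id=tag_ids[ti], sex="M", age_class="4+",
                         status="tag", band_id=band_ids[b],
                         home_x=band_x[b], home_y=band_y[b]))
        ti += 1

    # --- mares (qualified females, age >= 2) -------------------------------
    # Previous mares stay with their band unless they disperse (rate 0.34
    # for 2-3 year olds, 0.16 for adults) or the band dissolved; dispersers
    # are reassigned at random.  Age class 2-3 graduates to 4+ next season.
    # harem sizes track forage quality and decline away from permanent
    # water (females cluster around the limiting resource); the water-access
    # factor realizes an adult sex ratio rising by about
    # ``asr_gradient_slope`` per km from water
    d_band = distance_to_water(np.column_stack([band_x, band_y]), island.ponds)
    q = island.quality(band_x) * np.exp(-4.0 * truth.asr_gradient_slope * d_band)
    lam = np.maximum(harem_mean - 1.0, 0.0) * q / q.mean()
    harem_sizes = 1 + rng.poisson(lam)
    band_index = {bid: b for b, bid in enumerate(band_ids)}
    prev_band_of: dict[str, str] = {}
    if prev is not None:
        prev_band_of = dict(
            prev[prev["status"] == "mare"][["individual_id", "band_id"]]
            .itertuples(index=False, name=None))
    stayers: dict[int, list[tuple[str, str]]] = {}
    mare_pool: list[tuple[str, str]] = []
    for mid, age in prev_mares:
        disp = (truth.breeding_dispersal_young if age == "2-3"
                else truth.breeding_dispersal_adult)
        b = band_index.get(prev_band_of.get(mid))
        if b is not None and rng.random() >= disp:
            stayers.setdefault(b, []).append((mid, "4+"))
        else:
            mare_pool.append((mid, "4+"))
    rng.shuffle(mare_pool)
    mi = 0
    for b in range(n_bands):
        kept = stayers.get(b, [])[: harem_sizes[b]]
        need = harem_sizes[b] - len(kept)
        for _ in range(need):
            if mi < len(mare_pool):
                kept.append(mare_pool[mi])
                mi += 1
            else:
                kept.append((id_pool.take("F", 1)[0],
                             "2-3" if rng.random() < 0.35 else "4+"))
        for mid, age in kept:
            rows.append(dict(individual_id=mid, sex="F", age_class=age,
                             status="mare", band_id=band_ids[b],
                             home_x=band_x[b], home_y=band_y[b]))

    # --- juveniles (foals/yearlings attached to bands) ----------------------
    # foaling tracks forage quality, steepening the band-driven (female side)
    # component of local density fields
    n_juv = rng.poisson(0.9 * harem_sizes * q / q.mean()).astype(int)
    juv_ids = id_pool.take("J", int(n_juv.sum()))
    ji = 0
    for b in range(n_bands):
        for _ in range(n_juv[b]):
            rows.append(dict(
                individual_id=juv_ids[ji],
                sex="M" if rng.random() < 0.5 else "F",
                age_class="0" if rng.random() < 0.55 else "1",
                status="juvenile", band_id=band_ids[b],
                home_x=band_x[b], home_y=band_y[b]))
            ji += 1

    # --- bachelors ----------------------------------------------------------
    n_paired = n_bands + int(has_tag.sum())
    f = truth.bachelor_fraction
    n_bach = int(round(f / (1.0 - f) * n_paired)) if f < 1 else 0
    bach_ids = list(prev_bachelors[:n_bach]) if prev is not None else []
    if len(bach_ids) < n_bach:
        bach_ids += id_pool.take("M", n_bach - len(bach_ids))
    else:
        bach_ids = bach_ids[:n_bach]
    sites = _bachelor_sites(rng, island, n_bach, truth, band_x=band_x)
    for i, mid in enumerate(bach_ids):
        rows.append(dict(individual_id=mid, sex="M", age_class="4+",
                         status="bachelor", band_id=None,
                         home_x=sites[i, 0], home_y=sites[i, 1]))

    df = pd.DataFrame(rows)
    df["year"] = year
    return df


def generate_populations(island: Island, truth: TruthParams,
                         rng: np.random.Generator) -> pd.DataFrame:
    """All years of the study, with individual identities persisting."""
    pool = _IdPool()
    frames = []
    prev = None
    for year in island.config.years:
        prev = generate_population(island, truth, year, rng, prev=prev,
                                   id_pool=pool)
        frames.append(prev)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# survey simulation


@lru_cache(maxsize=8)
def _resight_pmf(mean: float, sd: float, upper: int) -> tuple[np.ndarray, np.ndarray]:
    """Truncated negative-binomial pmf on {1..upper} matching target moments.

    The (r, p) parameters are chosen numerically to minimise the squared
    moment error of the truncated distribution; the mean is weighted more
    heavily than the SD.  The target pair (2.84, 1.43) is underdispersed
    relative to any untruncated negative binomial, so the optimum sits near
    the Poisson limit and matches the mean essentially exactly while the SD
    comes out slightly above target; the truncation bounds [1, occasions]
    absorb most of the gap.
    """
    ks = np.arange(1, upper + 1)

    def moments(log_r, logit_p):
        r = np.exp(log_r)
        p = 1.0 / (1.0 + np.exp(-logit_p))
        pmf = stats.nbinom.pmf(ks, r, p)
        s = pmf.sum()
        if s <= 0:
            return None
        pmf = pmf / s
        m = float(np.sum(ks * pmf))
        v = float(np.sum(ks * ks * pmf) - m * m)
        return pmf, m, np.sqrt(max(v, 0.0))

    def loss(x):
        out = moments(*x)
        if out is None:
            return 1e6
        _, m, s = out
        return 25.0 * (m - mean) ** 2 + (s - sd) ** 2

    best = None
    for x0 in ([np.log(50.0), 0.0], [np.log(5.0), -1.0], [np.log(500.0), 2.0]):
        res = optimize.minimize(loss, x0, method="Nelder-Mead",
                                options=dict(xatol=1e-8, fatol=1e-12,
                                             maxiter=2000))
        if best is None or res.fun < best.fun:
            best = res
    pmf, _, _ = moments(*best.x)
    return ks, pmf


def draw_resight_counts(rng: np.random.Generator, n: int, truth: TruthParams,
                        occasions: int) -> np.ndarray:
    ks, pmf = _resight_pmf(truth.resight_mean, truth.resight_sd, occasions)
    return ks[rng.choice(ks.size, size=n, p=pmf)]


def simulate_surveys(population: pd.DataFrame, island: Island,
                     truth: TruthParams, rng: np.random.Generator) -> pd.DataFrame:
    """Simulate mark-resight sightings for the given population table.

    Each band follows a slightly jittered path around its home site over the
    season's occasions; every individual is sighted on a random subset of
    occasions (at least one), with the repeat-sighting count drawn from the
    calibrated truncated negative binomial.  All members of a band sighted at
    an occasion share the band's location for that occasion, as in
    group-living survey protocols.
    """
    cfg = island.config
    n_occ = cfg.occasions_per_year
    frames = []
    for year, pop in population.groupby("year", sort=True):
        # per-band (and per-bachelor) location for each occasion
        units = {}
        for key, sub in pop.groupby(pop["band_id"].fillna(pop["individual_id"]),
                                    sort=True):
            hx = float(sub["home_x"].iloc[0])
            hy = float(sub["home_y"].iloc[0])
            # bands are site-faithful; unattached bachelors range widely
            # between occasions
            sd_x = 2.5 if (sub["status"] == "bachelor").all() else 0.7
            xs = np.clip(hx + rng.normal(0, sd_x, n_occ), 0.0, cfg.length_km)
            ys = np.clip(hy + rng.normal(0, 0.25, n_occ),
                         0.02 * cfg.width_km, 0.98 * cfg.width_km)
            units[key] = np.column_stack([xs, ys])
        counts = draw_resight_counts(rng, len(pop), truth, n_occ)
        season_start = date(int(year), 6, 1)
        rows = []
        for (row, c) in zip(pop.itertuples(index=False), counts):
            unit = row.band_id if row.band_id is not None else row.individual_id
            occs = np.sort(rng.choice(n_occ, size=int(c), replace=False))
            for o in occs:
                loc = units[unit][o]
                rows.append((
                    (season_start + timedelta(days=int(o) * 3)).isoformat(),
                    int(o) + 1, int(year), row.individual_id, row.sex,
                    row.age_class, row.status,
                    row.band_id if row.band_id is not None else "NA",
                    round(float(loc[0]), 4), round(float(loc[1]), 4)))
        frames.append(pd.DataFrame(rows, columns=[
            "date", "occasion", "year", "individual_id", "sex", "age_class",
            "status", "band_id", "x_km", "y_km"]))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# planted responses


def plant_effects(blueprint: pd.DataFrame, truth: TruthParams,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Attach ground-truth responses to a modelling-table blueprint.

    ``blueprint`` must carry one row per (male, year) with columns
    ``male_id, year, asr, dist_water_km, unpaired_male_density,
    precipitation_index``.  Response columns ``I, I_harem,
    I_mares_given_harem`` are synthesised as

        intercept + asr_slope * (ASR - mean)            (stage-one signal)
        + year effect + planted covariate term          (stage-two signal)
        + male random intercept + Gaussian noise

    with the planted stage-two terms: unpaired-male density on I_harem, and
    a precipitation-regime-dependent distance-from-water slope on I and on
    I_mares|harem.  Setting an effect to zero removes the corresponding
    signal, which is what null-recovery experiments rely on.
    """
    df = blueprint.copy()
    years = np.sort(df["year"].unique())
    males = np.sort(df["male_id"].unique())
    asr_c = df["asr"] - df["asr"].mean()
    dist_c = df["dist_water_km"] - df["dist_water_km"].mean()
    dens_c = df["unpaired_male_density"] - df["unpaired_male_density"].mean()
    precip = df.drop_duplicates("year").set_index("year")["precipitation_index"]

    episodes = ("I", "I_harem", "I_mares_given_harem")
    for e, name in enumerate(episodes):
        year_eff = pd.Series(rng.normal(0, truth.year_effect_sd, len(years)),
                             index=years)
        male_eff = pd.Series(rng.normal(0, truth.male_intercept_sd, len(males)),
                             index=males)
        if name == "I_harem":
            cov_term = truth.unpaired_effect_on_Iharem * dens_c
        else:
            pair = (truth.water_by_precip_effect_on_I if name == "I"
                    else truth.water_by_precip_effect_on_Imares)
            slopes = df["year"].map(
                lambda y: truth.water_slope(float(precip.loc[y]), pair))
            cov_term = slopes * dist_c
        df[name] = (truth.episode_intercepts[e]
                    + truth.asr_slopes[e] * asr_c
                    + df["year"].map(year_eff)
                    + cov_term
                    + df["male_id"].map(male_eff)
                    + rng.normal(0, truth.residual_sd, len(df)))
    return df


def climate_table(config: IslandConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-year climate covariates (standardized across years).

    Summer precipitation is the configured index; the remaining variables
    (winter precipitation, summer maximum and winter minimum temperature)
    are synthetic standardized draws so that the climate model competition
    has the full candidate list to choose from.
    """
    years = config.years
    precip = config.precip_by_year()

    def z(v):
        v = np.asarray(v, dtype=float)
        s = v.std(ddof=1)
        return (v - v.mean()) / s if s > 0 else v * 0.0

    df = pd.DataFrame({
        "year": years,
        "summer_precip": [precip[y] for y in years],
        "winter_precip": z(rng.normal(size=len(years))),
        "summer_tmax": z(rng.normal(size=len(years))),
        "winter_tmin": z(rng.normal(size=len(years))),
    })
    return df


# ---------------------------------------------------------------------------
# one-call dataset


@dataclass
class SimulatedDataset:
    island: Island
    population: pd.DataFrame  # all years, one row per individual-year
    sightings: pd.DataFrame
    truth: TruthParams

    def ponds_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pond_id": [f"P{i:03d}" for i in range(len(self.island.ponds))],
            "x_km": self.island.ponds[:, 0],
            "y_km": self.island.ponds[:, 1],
        })


def simulate_dataset(config: IslandConfig | None = None,
                     truth: TruthParams | None = None) -> SimulatedDataset:
    """Generate island, multi-year population, and survey sightings."""
    config = config or IslandConfig()
    truth = truth or TruthParams()
    config.validate()
    truth.validate(config.n_years)
    island = generate_island(config)
    rng = np.random.default_rng(config.seed + 1)
    population = generate_populations(island, truth, rng)
    sightings = simulate_surveys(population, island, truth, rng)
    return SimulatedDataset(island=island, population=population,
                            sightings=sightings, truth=truth)


def truth_to_yaml(truth: TruthParams, config: IslandConfig) -> str:
    doc = {
        "island": {k: v for k, v in dataclasses.asdict(config).items()},
        "truth": {k: (list(v) if isinstance(v, tuple) else v)
                  for k, v in dataclasses.asdict(truth).items()},
    }
    doc["island"]["precipitation_index"] = config.precip_by_year()
    return yaml.safe_dump(doc, sort_keys=True)
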