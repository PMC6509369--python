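"""Buffer-overlap neighborhoods and spatial covariates.

A focal band's neighborhood contains every band and every bachelor male
whose season sighting locations fall within a fixed buffer radius (default
2.06 km, the median maximum distance moved within a breeding season) of the
focal band's sighting locations.  With a single shared radius the "any
point inside the union of focal buffers" rule is equivalent to a minimum
pairwise distance test, which is how overlap is evaluated here; the
comparison is boundary-inclusive.

Covariates per neighborhood: mean distance from the focal band's locations
to the nearest permanent pond, and unpaired-male / total densities per km²
of terrestrial buffered area (the union of focal buffers clipped to the
island polygon).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint

from .errors import IntegrityError
from .survey_io import BandSeason

DEFAULT_RADIUS_KM = 2.06

_EPS = 1e-9  # boundary tolerance for the inclusive distance rule


def overlaps(entity_locations: np.ndarray, focal_locations: np.ndarray,
             radius_km: float) -> bool:
    """True iff the minimum pairwise distance is within the buffer radius."""
    a = np.atleast_2d(np.asarray(entity_locations, dtype=float))
    b = np.atleast_2d(np.asarray(focal_locations, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("overlaps() requires non-empty location sets")
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return bool(d.min() <= radius_km + _EPS)


def min_distance(a: np.ndarray, b: np.ndarray) -> float:
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    return float(np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2).min())


@dataclass
class SpatialCovariates:
    dist_water_km: float
    unpaired_male_density: float
    total_density: float


@dataclass
class Neighborhood:
    """A focal band-season plus everything overlapping its buffered locations."""

    focal: BandSeason
    radius_km: float
    member_bands: list[BandSeason]
    member_bachelors: list[str]
    buffered_area_km2: float

    @property
    def qualified_male_count(self) -> int:
        """Dominants + tags + bachelors of breeding age in the neighborhood."""
        return (len(self.member_bands)
                + sum(len(b.tag_ids) for b in self.member_bands)
                + len(self.member_bachelors))

    @property
    def harem_holder_count(self) -> int:
        return len(self.member_bands)

    @property
    def qualified_female_count(self) -> int:
        return sum(b.qualified_mare_count for b in self.member_bands)


def buffered_terrestrial_area(locations: np.ndarray, island_polygon,
                              radius_km: float) -> float:
    """Area (km²) of the union of radius-km discs clipped to the island."""
    pts = np.atleast_2d(np.asarray(locations, dtype=float))
    buf = MultiPoint([tuple(p) for p in pts]).buffer(radius_km,
                                                    quad_segs=64)
    return float(buf.intersection(island_polygon).area)


def mean_distance_to_water(locations: np.ndarray, ponds: np.ndarray) -> float:
    """Mean over locations of the per-location nearest-pond distance."""
    pts = np.atleast_2d(np.asarray(locations, dtype=float))
    d = np.linalg.norm(pts[:, None, :] - ponds[None, :, :], axis=2)
    return float(d.min(axis=1).mean())


def build_neighborhood(
    focal: BandSeason,
    all_bands: list[BandSeason],
    all_bachelors: dict[tuple[str, int], np.ndarray],
    ponds: np.ndarray,
    island_polygon,
    radius_km: float = DEFAULT_RADIUS_KM,
) -> tuple[Neighborhood, SpatialCovariates]:
    """Assemble a focal band's neighborhood and its spatial covariates.

    ``all_bands`` may span several years; only same-year entries are
    considered.  Densities use unique individuals over the whole season per
    km² of buffered terrestrial area.  A focal band whose buffer does not
    intersect the island raises :class:`IntegrityError`.
    """
    if len(focal.locations) == 0:
        raise ValueError("focal band has no locations")
    members = [b for b in all_bands
               if b.year == focal.year
               and overlaps(b.locations, focal.locations, radius_km)]
    bachelors = [ind for (ind, year), locs in all_bachelors.items()
                 if year == focal.year
                 and overlaps(locs, focal.locations, radius_km)]
    area = buffered_terrestrial_area(focal.locations, island_polygon, radius_km)
    if area <= 0:
        raise IntegrityError(
            f"band {focal.band_id}/{focal.year} buffer misses the island")
    n_total = (len(set().union(*(b.member_ids for b in members)))
               + len(bachelors)) if members else len(bachelors)
    cov = SpatialCovariates(
        dist_water_km=mean_distance_to_water(focal.locations, ponds),
        unpaired_male_density=len(bachelors) / area,
        total_density=n_total / area,
    )
    return Neighborhood(focal=focal, radius_km=radius_km,
                        member_bands=members, member_bachelors=bachelors,
                        buffered_area_km2=area), cov
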