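"""Spatially explicit opportunity-for-selection statistics.

The opportunity for selection I is the variance in mating success divided
by the squared mean mating success (Crow's index), computed here over
buffer-overlap neighborhoods so that each harem-holding male gets a local
estimate.  I is partitioned into sequential episodes:

* ``i_harem``      — success in acquiring a harem (0/1) among all qualified
                     males (dominants, tags, bachelors aged 4+); with
                     holder fraction p this equals (1 - p) / p.
* ``i_mares_given_harem`` — number of qualified mares per male among
                     harem-holders only.
* ``i_total``      — mates per band counting dominant-plus-tag males in
                     each band's male group.

Mating success is attributed to the dominant male of a band even when a tag
male is present; tags count as competitors but receive no mates.

All statistics work on grouped counts (f mates per male, m males with that
success), matching the band-grouped summation of the neighborhood
definition, and agree exactly with the expanded per-male success list.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError
from .neighborhoods import (DEFAULT_RADIUS_KM, Neighborhood,
                            build_neighborhood)
from .survey_io import (QUALIFIED_FEMALE_AGES, QUALIFIED_MALE_AGE, BandSeason,
                        bachelor_locations)

log = logging.getLogger(__name__)

GroupedSuccess = Sequence[tuple[int, int]]  # (f mates-per-male, m males)


def opportunity(groups: GroupedSuccess) -> float:
    """Variance in relative mating success, variance / mean², from grouped counts.

    ``groups`` is a list of (f, m) pairs: m males each with mating success
    f.  Equals the plain variance/mean² of the expanded per-male list.
    Raises :class:`UndefinedStatisticError` when no males are present or the
    mean success is zero.
    """
    f = np.array([g[0] for g in groups], dtype=float)
    m = np.array([g[1] for g in groups], dtype=float)
    if m.sum() < 1:
        raise UndefinedStatisticError("no males in success groups")
    total_m = m.sum()
    mean = float((f * m).sum() / total_m)
    if mean <= 0:
        raise UndefinedStatisticError("mean mating success is zero")
    variance = float((f * f * m).sum() / total_m - mean ** 2)
    return max(variance, 0.0) / mean ** 2


def i_total(neighborhood: Neighborhood) -> float:
    """Total opportunity for selection over the neighborhood's bands.

    Each band contributes one group: f = qualified mares, m = dominant plus
    tag males (tags are competitors without mates, so they dilute the mean).
    """
    groups = [(b.qualified_mare_count, 1 + len(b.tag_ids))
              for b in neighborhood.member_bands]
    if not groups:
        raise UndefinedStatisticError("neighborhood has no bands")
    return opportunity(groups)


def i_harem(neighborhood: Neighborhood) -> float:
    """Opportunity for selection in harem acquisition: (1 - p) / p.

    p is the fraction of qualified males (dominants, tags, bachelors, all
    aged 4+) currently holding a harem.  Computed through the grouped
    statistic on {(1, holders), (0, non-holders)}, which reduces to the
    Bernoulli closed form.
    """
    holders = neighborhood.harem_holder_count
    qualified = neighborhood.qualified_male_count
    if qualified < 1:
        raise UndefinedStatisticError("no qualified males in neighborhood")
    if holders < 1:
        raise UndefinedStatisticError("no harem holders in neighborhood")
    value = opportunity([(1, holders), (0, qualified - holders)])
    p = holders / qualified
    closed = (1.0 - p) / p
    assert abs(value - closed) < 1e-9, "grouped and closed forms diverged"
    return value


def i_mares_given_harem(neighborhood: Neighborhood) -> float:
    """Opportunity for selection in mate acquisition among harem-holders.

    Only dominant males participate; f is each male's count of qualified
    mares.
    """
    groups = [(b.qualified_mare_count, 1) for b in neighborhood.member_bands]
    if not groups:
        raise UndefinedStatisticError("no dominant males in neighborhood")
    return opportunity(groups)


# ---------------------------------------------------------------------------
# local adult sex ratio


def local_asr(focal: BandSeason, records: pd.DataFrame,
              radius_km: float = DEFAULT_RADIUS_KM,
              mode: str = "occasion") -> float:
    """Local adult sex ratio around a focal band over its field season.

    Adults are males aged >= 4 (any social status) and females aged >= 2.
    An adult overlaps the focal band if any of its sightings lies within
    ``radius_km`` of any focal-band location.  With ``mode="occasion"``
    (default) the ratio males/(males + females) is computed per survey
    occasion among overlapping adults sighted at that occasion, then
    averaged over occasions with at least one overlapping adult.
    ``mode="season"`` instead uses unique overlapping individuals over the
    whole season.
    """
    year_rec = records[records["year"] == focal.year]
    adult = year_rec[
        ((year_rec["sex"] == "M") & (year_rec["age_class"] == QUALIFIED_MALE_AGE))
        | ((year_rec["sex"] == "F")
           & year_rec["age_class"].isin(QUALIFIED_FEMALE_AGES))
    ]
    if adult.empty:
        raise UndefinedStatisticError("no adults recorded in focal year")
    pts = adult[["x_km", "y_km"]].to_numpy(dtype=float)
    d = np.linalg.norm(pts[:, None, :] - focal.locations[None, :, :], axis=2)
    near = adult[(d.min(axis=1) <= radius_km + 1e-9)]
    if near.empty:
        raise UndefinedStatisticError("no overlapping adults for focal band")
    if mode == "season":
        by_ind = near.drop_duplicates("individual_id")
        males = (by_ind["sex"] == "M").sum()
        return float(males / len(by_ind))
    ratios = []
    for _, occ in near.groupby("occasion"):
        by_ind = occ.drop_duplicates("individual_id")
        ratios.append(float((by_ind["sex"] == "M").sum() / len(by_ind)))
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# the modelling table


def build_selection_table(
    band_seasons: Iterable[BandSeason],
    records: pd.DataFrame,
    ponds: np.ndarray,
    island_polygon,
    precip_index: dict[int, float],
    radius_km: float = DEFAULT_RADIUS_KM,
    asr_mode: str = "occasion",
) -> tuple[pd.DataFrame, int]:
    """One row per focal dominant male per year: I metrics, ASR, covariates.

    Rows whose statistics are undefined (e.g. a neighborhood where the mean
    mating success is zero) are dropped with a logged count; the count is
    returned alongside the table.
    """
    band_seasons = list(band_seasons)
    bach = bachelor_locations(records)
    rows = []
    n_dropped = 0
    for focal in band_seasons:
        nb, cov = build_neighborhood(focal, band_seasons, bach, ponds,
                                     island_polygon, radius_km)
        try:
            row = dict(
                male_id=focal.dominant_male_id,
                band_id=focal.band_id,
                year=focal.year,
                I=i_total(nb),
                I_harem=i_harem(nb),
                I_mares_given_harem=i_mares_given_harem(nb),
                asr=local_asr(focal, records, radius_km, mode=asr_mode),
            )
        except UndefinedStatisticError:
            n_dropped += 1
            continue
        row.update(
            dist_water_km=cov.dist_water_km,
            unpaired_male_density=cov.unpaired_male_density,
            total_density=cov.total_density,
            precipitation_index=precip_index.get(focal.year, 0.0),
        )
        rows.append(row)
    if n_dropped:
        log.info("dropped %d focal male-years with undefined statistics",
                 n_dropped)
    df = pd.DataFrame(rows)
    return df, n_dropped
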