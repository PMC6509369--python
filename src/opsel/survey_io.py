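"""Sighting-table I/O, band-season construction, and sampling saturation.

The sighting schema is one row per individual per survey occasion:
``date, occasion, year, individual_id, sex, age_class, status, band_id,
x_km, y_km`` with ``band_id = "NA"`` for unattached animals.  Qualified
mares are females aged >= 2 (age classes ``2-3`` and ``4+``); qualified
males are dominants, tags and bachelors aged >= 4 (class ``4+``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FitError, IntegrityError, SchemaError

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["date", "occasion", "year", "individual_id", "sex",
                    "age_class", "status", "band_id", "x_km", "y_km"]

QUALIFIED_FEMALE_AGES = {"2-3", "4+"}
QUALIFIED_MALE_AGE = "4+"


@dataclass
class ValidationReport:
    """Row-level outcomes of loading a sightings table."""

    n_input: int = 0
    n_kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def drop(self, reason: str, n: int) -> None:
        if n:
            self.dropped[reason] = self.dropped.get(reason, 0) + int(n)


def validate_sightings(df: pd.DataFrame) -> tuple[pd.DataFrame, ValidationReport]:
    """Type, validate, flag and deduplicate a raw sightings table.

    Rules: non-numeric coordinates drop the row (logged); duplicate
    ``(individual_id, occasion, year)`` rows keep the first record (logged);
    a mare without a band is flagged but retained.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    report = ValidationReport(n_input=len(df))
    out = df.copy()
    out["band_id"] = out["band_id"].replace({"NA": None, "": None, np.nan: None})
    for col in ("x_km", "y_km"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    bad = out["x_km"].isna() | out["y_km"].isna()
    report.drop("non-numeric coordinates", bad.sum())
    out = out[~bad]
    out["occasion"] = pd.to_numeric(out["occasion"], errors="coerce")
    bad = out["occasion"].isna() | (out["occasion"] < 1)
    report.drop("invalid occasion", bad.sum())
    out = out[~bad]
    out["occasion"] = out["occasion"].astype(int)
    out["year"] = pd.to_numeric(out["year"]).astype(int)

    dup = out.duplicated(["individual_id", "occasion", "year"], keep="first")
    report.drop("duplicate (individual, occasion)", dup.sum())
    out = out[~dup]

    bandless_mares = out[(out["status"] == "mare") & out["band_id"].isna()]
    for ind in bandless_mares["individual_id"].unique():
        report.flags.append(f"mare without band: {ind}")

    report.n_kept = len(out)
    if report.dropped:
        log.info("validation dropped rows: %s", report.dropped)
    return out.reset_index(drop=True), report


def load_sightings(path) -> tuple[pd.DataFrame, ValidationReport]:
    """Read a sightings CSV and validate it (see :func:`validate_sightings`)."""
    df = pd.read_csv(path, dtype={"individual_id": str, "band_id": str},
                     keep_default_na=False, na_values=[])
    return validate_sightings(df)


def load_ponds(path) -> np.ndarray:
    df = pd.read_csv(path)
    missing = [c for c in ("x_km", "y_km") if c not in df.columns]
    if missing:
        raise SchemaError(f"pond table missing columns: {missing}")
    return df[["x_km", "y_km"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# band-seasons


@dataclass
class BandSeason:
    """One band in one breeding season with its season location set."""

    band_id: str
    year: int
    dominant_male_id: str
    tag_ids: frozenset
    mare_ids: frozenset       # qualified mares (age >= 2)
    other_ids: frozenset      # juveniles / sub-qualified members
    locations: np.ndarray     # (n_occasions_seen, 2), one per sighting occasion

    @property
    def qualified_mare_count(self) -> int:
        return len(self.mare_ids)

    @property
    def member_ids(self) -> frozenset:
        return (frozenset({self.dominant_male_id}) | self.tag_ids
                | self.mare_ids | self.other_ids)


def build_band_seasons(records: pd.DataFrame) -> list[BandSeason]:
    """One :class:`BandSeason` per (band_id, year) from validated records.

    Raises :class:`IntegrityError` (listing the band ids) if any band-year
    has zero or more than one dominant male.
    """
    banded = records[records["band_id"].notna()]
    out: list[BandSeason] = []
    bad: list[str] = []
    for (bid, year), sub in banded.groupby(["band_id", "year"], sort=True):
        doms = sub[sub["status"] == "dominant"]["individual_id"].unique()
        if len(doms) != 1:
            bad.append(f"{bid}/{year} ({len(doms)} dominant males)")
            continue
        tags = frozenset(sub[sub["status"] == "tag"]["individual_id"])
        mares = frozenset(
            sub[(sub["status"] == "mare")
                & sub["age_class"].isin(QUALIFIED_FEMALE_AGES)]["individual_id"])
        others = frozenset(sub["individual_id"]) - tags - mares - {doms[0]}
        locs = (sub.drop_duplicates("occasion")
                   .sort_values("occasion")[["x_km", "y_km"]]
                   .to_numpy(dtype=float))
        out.append(BandSeason(band_id=str(bid), year=int(year),
                              dominant_male_id=str(doms[0]), tag_ids=tags,
                              mare_ids=mares, other_ids=others,
                              locations=locs))
    if bad:
        raise IntegrityError("bands without a unique dominant male: "
                             + ", ".join(bad))
    return out


def bachelor_locations(records: pd.DataFrame) -> dict[tuple[str, int], np.ndarray]:
    """Season location sets of unattached adult males keyed by (id, year)."""
    bach = records[(records["status"] == "bachelor")
                   & (records["age_class"] == QUALIFIED_MALE_AGE)]
    return {
        (str(ind), int(year)): sub[["x_km", "y_km"]].to_numpy(dtype=float)
        for (ind, year), sub in bach.groupby(["individual_id", "year"])
    }


# ---------------------------------------------------------------------------
# competitor-encounter saturation


@dataclass
class SaturationCurve:
    """Cumulative proportion of competitor males encountered by occasion.

    The pooled points are fitted with ``y = a * ln(x) + b``;
    ``saturation_occasion`` is the smallest integer occasion at which the
    fitted curve reaches 1 (None if it never does).
    """

    occasions: np.ndarray          # pooled per-male-per-occasion x values
    proportions: np.ndarray        # matching cumulative proportions
    a: float
    b: float
    r2: float
    saturation_occasion: int | None
    per_male: pd.DataFrame | None = None  # per-male (a, b, r2) when requested

    def per_occasion_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"occasion": self.occasions,
                           "proportion": self.proportions})
        return (df.groupby("occasion", as_index=False)["proportion"]
                  .mean())

    def to_json(self) -> str:
        return json.dumps({"a": self.a, "b": self.b, "r2": self.r2,
                           "saturation_occasion": self.saturation_occasion})


def saturation_occasion_from_fit(a: float, b: float,
                                 max_occasion: int = 10_000) -> int | None:
    """Smallest integer x with a*ln(x) + b >= 1, or None if never reached."""
    for x in range(1, max_occasion + 1):
        if a * np.log(x) + b >= 1.0 - 1e-12:
            return x
    return None


def _cumulative_proportions(records: pd.DataFrame, radius_km: float
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled (occasion, cumulative proportion) points over focal males.

    Competitors are dominant stallions and bachelors aged >= 4.  A focal
    dominant male "encounters" a competitor at the first occasion at which
    some sighting of the competitor lies within ``radius_km`` of some
    sighting of the focal male up to that occasion.  The denominator is the
    focal male's season total of unique competitors.
    """
    comp = records[(records["status"].isin(["dominant", "bachelor"]))
                   & (records["age_class"] == QUALIFIED_MALE_AGE)]
    xs, ys, who = [], [], []
    for year, sub in comp.groupby("year"):
        occs = np.sort(sub["occasion"].unique())
        locs = {ind: g[["occasion", "x_km", "y_km"]].to_numpy(dtype=float)
                for ind, g in sub.groupby("individual_id")}
        focals = sub[sub["status"] == "dominant"]["individual_id"].unique()
        for f in focals:
            fl = locs[f]
            first_met: dict[str, int] = {}
            for other, ol in locs.items():
                if other == f:
                    continue
                # earliest occasion t at which min distance between the two
                # males' sightings up to t is within the radius
                d = np.linalg.norm(fl[:, None, 1:] - ol[None, :, 1:], axis=2)
                within = d <= radius_km + 1e-9
                if not within.any():
                    continue
                pair_occ = np.maximum(fl[:, 0][:, None], ol[None, :, 0])
                first_met[other] = int(pair_occ[within].min())
            total = len(first_met)
            if total == 0:
                continue
            met = np.array(sorted(first_met.values()))
            for t in occs:
                xs.append(int(t))
                ys.append(float((met <= t).sum()) / total)
                who.append(f)
    return (np.asarray(xs, dtype=float), np.asarray(ys, dtype=float),
            np.asarray(who))


def _log_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    A = np.column_stack([np.log(x), np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    pred = A @ coef
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(coef[0]), float(coef[1]), r2


def saturation_analysis(records: pd.DataFrame, radius_km: float,
                        per_male: bool = False) -> SaturationCurve:
    """Fit the competitor-encounter saturation curve y = a ln(x) + b.

    Points are pooled over all focal dominant males (one point per focal
    male per occasion); the fit is ordinary least squares on ln(occasion).
    With ``per_male=True`` a per-focal-male (a, b, r2) table is attached as
    well (the pooled fit remains the headline coefficients).
    """
    if records["occasion"].nunique() < 2:
        raise FitError("saturation fit undefined with a single occasion")
    x, y, males = _cumulative_proportions(records, radius_km)
    if x.size < 2:
        raise FitError("not enough encounter data to fit saturation curve")
    a, b, r2 = _log_fit(x, y)
    sat = saturation_occasion_from_fit(a, b) if a > 0 or b >= 1 else None
    pm = None
    if per_male:
        rows = []
        df = pd.DataFrame({"male": males, "x": x, "y": y})
        for m, g in df.groupby("male"):
            if g["x"].nunique() < 2:
                continue
            am, bm, r2m = _log_fit(g["x"].to_numpy(), g["y"].to_numpy())
            rows.append(dict(male_id=m, a=am, b=bm, r2=r2m))
        pm = pd.DataFrame(rows)
    return SaturationCurve(occasions=x.astype(int), proportions=y,
                           a=a, b=b, r2=r2, saturation_occasion=sat,
                           per_male=pm)
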