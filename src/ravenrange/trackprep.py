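"""Track preparation: reading, daytime filtering, season/age assignment, segmentation.

The analysis unit downstream is the *individual-season-year* segment: one
bird's daytime GPS fixes within one astronomical season of one calendar
year, together with sampling covariates (number of fixes, tracking days,
fixes per day).

Fixes travel through the pipeline as a pandas DataFrame with columns
``individual_id``, ``timestamp`` (tz-naive UTC), ``lon``, ``lat``, sorted by
(individual, time).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solar
from .solar import daylight_window  # noqa: F401  (public re-export)

FIX_COLUMNS = ["individual_id", "timestamp", "lon", "lat"]

#: Movebank-style CSV headers mapped onto internal column names.
MOVEBANK_COLUMNS = {
    "individual-local-identifier": "individual_id",
    "timestamp": "timestamp",
    "location-long": "lon",
    "location-lat": "lat",
}

SEASONS = ("spring", "summer", "autumn", "winter")

#: Astronomical season start dates (month, day): equinoxes/solstices used to
#: split the tracking year.
SEASON_STARTS = {"spring": (3, 21), "summer": (6, 21), "autumn": (9, 23), "winter": (12, 21)}

#: Fixed UTC offset (hours) defining local civil midnight for season
#: boundaries and year labels. Default is CET, the study region's standard time.
DEFAULT_UTC_OFFSET_H = 1.0


class SchemaError(ValueError):
    """A required input column is missing."""


@dataclass(frozen=True)
class Individual:
    """Tagged bird with its cohort attributes."""

    id: str
    sex: str  # 'male' | 'female'
    origin: str  # 'wild-caught' | 'captive-released'
    age_class_at_tagging: str  # 'juvenile' | 'adult'
    tagging_date: dt.date

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.origin not in ("wild-caught", "captive-released"):
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.age_class_at_tagging not in ("juvenile", "adult"):
            raise ValueError(f"unknown age class {self.age_class_at_tagging!r}")


@dataclass
class ParseReport:
    """Row accounting from :func:`read_movebank_csv`."""

    n_rows: int = 0
    n_parsed: int = 0
    n_bad_timestamp: int = 0
    n_bad_coords: int = 0
    n_duplicates: int = 0


@dataclass
class SeasonYearSegment:
    """One individual's daytime fixes in one season of one year."""

    individual_id: str
    season: str
    year_label: int
    fixes: pd.DataFrame
    age_class: str
    n_fixes: int = field(init=False)
    n_tracking_days: int = field(init=False)
    fixes_per_day: float = field(init=False)

    def __post_init__(self):
        self.n_fixes = len(self.fixes)
        self.n_tracking_days = int(self.fixes["timestamp"].dt.normalize().nunique())
        self.fixes_per_day = self.n_fixes / self.n_tracking_days if self.n_tracking_days else 0.0

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.individual_id, self.season, self.year_label)


def read_movebank_csv(path) -> tuple[pd.DataFrame, ParseReport]:
    """Read a Movebank-style CSV into the canonical fixes frame.

    Rows with unparseable timestamps or out-of-range coordinates are dropped
    and counted in the report; exact (individual, timestamp, lon, lat)
    duplicates keep the first record; output is sorted by (individual, time).
    """
    raw = pd.read_csv(path, dtype=str)
    missing = [c for c in MOVEBANK_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    report = ParseReport(n_rows=len(raw))

    df = raw[list(MOVEBANK_COLUMNS)].rename(columns=MOVEBANK_COLUMNS)
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True).dt.tz_localize(None)
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")

    bad_ts = ts.isna()
    bad_coord = lon.isna() | lat.isna() | (lon.abs() > 180) | (lat.abs() > 90)
    report.n_bad_timestamp = int(bad_ts.sum())
    report.n_bad_coords = int((bad_coord & ~bad_ts).sum())

    out = pd.DataFrame(
        {"individual_id": df["individual_id"], "timestamp": ts, "lon": lon, "lat": lat}
    )[~(bad_ts | bad_coord)]
    n_before = len(out)
    out = out.drop_duplicates(subset=["individual_id", "timestamp"], keep="first")
    report.n_duplicates = n_before - len(out)
    out = out.sort_values(["individual_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    report.n_parsed = len(out)
    return out, report


def read_attributes_csv(path) -> dict[str, Individual]:
    """Read the individual-attribute table (id, sex, origin, age class, tagging date)."""
    df = pd.read_csv(path, dtype=str)
    required = ["id", "sex", "origin", "age_class_at_tagging", "tagging_date"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    out: dict[str, Individual] = {}
    for row in df.itertuples(index=False):
        out[str(row.id)] = Individual(
            id=str(row.id),
            sex=row.sex,
            origin=row.origin,
            age_class_at_tagging=row.age_class_at_tagging,
            tagging_date=dt.date.fromisoformat(str(row.tagging_date)),
        )
    return out


def filter_daytime(fixes: pd.DataFrame) -> pd.DataFrame:
    """Keep fixes between sunrise and sunset at each fix's own location/date.

    The solar window is evaluated per fix (birds range widely, so a single
    site's window would drift by minutes across the study area). Idempotent;
    preserves order.
    """
    if fixes.empty:
        return fixes.copy()
    ts = fixes["timestamp"]
    ordinal = np.array([d.toordinal() for d in ts.dt.date])
    rise_min, set_min = solar.daylight_minutes(ordinal, fixes["lat"].to_numpy(), fixes["lon"].to_numpy())
    minute_of_day = (
        ts.dt.hour.to_numpy() * 60.0 + ts.dt.minute.to_numpy() + ts.dt.second.to_numpy() / 60.0
    )
    keep = (minute_of_day >= rise_min) & (minute_of_day <= set_min)
    return fixes[keep].reset_index(drop=True)


def _season_of(month: int, day: int) -> str:
    md = (month, day)
    if SEASON_STARTS["spring"] <= md < SEASON_STARTS["summer"]:
        return "spring"
    if SEASON_STARTS["summer"] <= md < SEASON_STARTS["autumn"]:
        return "summer"
    if SEASON_STARTS["autumn"] <= md < SEASON_STARTS["winter"]:
        return "autumn"
    return "winter"


def assign_season_year(
    timestamp: dt.datetime, utc_offset_h: float = DEFAULT_UTC_OFFSET_H
) -> tuple[str, int]:
    """Season and calendar-year label of a UTC instant.

    Boundaries fall at local civil midnight of the equinox/solstice dates;
    a December-March winter therefore carries two year labels (one per
    calendar year), matching a year factor whose levels are calendar years.
    """
    local = timestamp + dt.timedelta(hours=utc_offset_h)
    return _season_of(local.month, local.day), local.year


def season_year_frame(
    timestamps: pd.Series, utc_offset_h: float = DEFAULT_UTC_OFFSET_H
) -> pd.DataFrame:
    """Vectorised :func:`assign_season_year`: columns ``season``, ``year_label``."""
    local = timestamps + pd.Timedelta(hours=utc_offset_h)
    md = local.dt.month * 100 + local.dt.day
    codes = {k: m * 100 + d for k, (m, d) in SEASON_STARTS.items()}
    season = np.select(
        [
            (md >= codes["spring"]) & (md < codes["summer"]),
            (md >= codes["summer"]) & (md < codes["autumn"]),
            (md >= codes["autumn"]) & (md < codes["winter"]),
        ],
        ["spring", "summer", "autumn"],
        default="winter",
    )
    return pd.DataFrame({"season": season, "year_label": local.dt.year.to_numpy()})


def adult_transition_date(individual: Individual) -> dt.date | None:
    """First March 21 strictly after tagging, when a tagged juvenile becomes adult.

    Returns None for birds tagged as adults (absorbing state).
    """
    if individual.age_class_at_tagging == "adult":
        return None
    tag = individual.tagging_date
    year = tag.year if tag < dt.date(tag.year, 3, 21) else tag.year + 1
    return dt.date(year, 3, 21)


def assign_age_class(
    individual: Individual,
    timestamp: dt.datetime,
    utc_offset_h: float = DEFAULT_UTC_OFFSET_H,
) -> str:
    """Age class of the bird at a given instant ('juvenile' or 'adult').

    Juveniles hatch in spring, so the start of spring (March 21) is the
    population-wide transition date: a bird tagged as a juvenile is adult
    from the first March 21 after its tagging date.
    """
    local_date = (timestamp + dt.timedelta(hours=utc_offset_h)).date()
    if local_date < individual.tagging_date:
        raise ValueError(
            f"timestamp {timestamp} precedes tagging date {individual.tagging_date} "
            f"for individual {individual.id}"
        )
    transition = adult_transition_date(individual)
    if transition is None:
        return "adult"
    return "adult" if local_date >= transition else "juvenile"


def segment(
    fixes: pd.DataFrame,
    individuals: dict[str, Individual],
    utc_offset_h: float = DEFAULT_UTC_OFFSET_H,
) -> list[SeasonYearSegment]:
    """Split daytime fixes into individual-season-year segments.

    Every fix lands in exactly one segment (total count conserved). Age
    class is constant within a segment because the juvenile-adult transition
    coincides with a season boundary.
    """
    unknown = set(fixes["individual_id"].unique()) - set(individuals)
    if unknown:
        raise ValueError(f"individuals missing from attribute table: {sorted(unknown)}")
    if fixes.empty:
        return []
    sy = season_year_frame(fixes["timestamp"], utc_offset_h)
    work = fixes.assign(season=sy["season"].to_numpy(), year_label=sy["year_label"].to_numpy())
    segments = []
    for (ind_id, season, year), grp in work.groupby(["individual_id", "season", "year_label"], sort=True):
        grp = grp.sort_values("timestamp")
        age = assign_age_class(individuals[ind_id], grp["timestamp"].iloc[0].to_pydatetime(), utc_offset_h)
        segments.append(
            SeasonYearSegment(
                individual_id=ind_id,
                season=season,
                year_label=int(year),
                fixes=grp[FIX_COLUMNS].reset_index(drop=True),
                age_class=age,
            )
        )
    return segments


def subsample_min_interval(fixes: pd.DataFrame, min_gap: dt.timedelta = dt.timedelta(minutes=15)) -> pd.DataFrame:
    """Greedy forward thinning to a minimum inter-fix interval, per individual.

    Keeps a fix iff at least ``min_gap`` has elapsed since the last *kept*
    fix of the same individual; the first fix of each individual is always
    kept. Used before plotting/cluster detection so that dense summer
    sampling does not dominate.
    """
    if fixes.empty:
        return fixes.copy()
    gap_ns = min_gap / dt.timedelta(microseconds=1) * 1000.0
    keep_masks = []
    for _, grp in fixes.groupby("individual_id", sort=False):
        t = grp["timestamp"].astype("int64").to_numpy()
        keep = np.zeros(len(t), dtype=bool)
        last = -np.inf
        for i, ti in enumerate(t):
            if ti - last >= gap_ns:
                keep[i] = True
                last = ti
        keep_masks.append(pd.Series(keep, index=grp.index))
    mask = pd.concat(keep_masks).reindex(fixes.index)
    return fixes[mask.to_numpy()].reset_index(drop=True)


def segment_summary(segments: list[SeasonYearSegment]) -> pd.DataFrame:
    """One row per segment: sampling covariates for reporting and modelling."""
    return pd.DataFrame(
        {
            "individual_id": [s.individual_id for s in segments],
            "season": [s.season for s in segments],
            "year_label": [s.year_label for s in segments],
            "age_class": [s.age_class for s in segments],
            "n_fixes": [s.n_fixes for s in segments],
            "n_tracking_days": [s.n_tracking_days for s in segments],
            "fixes_per_day": [s.fixes_per_day for s in segments],
        }
    )
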