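"""Synthetic multi-individual GPS datasets with known ground truth.

Emulates the structure of a non-breeder corvid tracking study: a cohort of
birds (juvenile/adult at tagging, wild-caught/captive-released, male/female)
released at a central game park, moving daily between point-like
anthropogenic food sources (AFSs) and exploratory foraging locations, with
season-dependent sampling rates, daytime-biased fixes plus one nightly
roost fix, and per-day censoring (mortality / transmitter failure).

The movement kernel is deliberately simple — a two-state dwell/transit
switching process on a local metric plane — because the downstream analysis
consumes only positions and times.  Cohort and season effects enter as
log-scale multipliers on four channels:

* ``range``: radius of the daily exploration disk (area scales as exp(b));
* ``displacement``: propensity to pick far rather than near destinations;
* ``visits``: size of the individual's known-site repertoire;
* ``presence``: probability that a chosen destination is an AFS.

All randomness flows from one integer seed; a fixed seed reproduces the
output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import solar
from .geo import LocalProjection

#: Tagging site of the emulated study population (Alm valley game park).
FIELD_SITE_LON = 13.949
FIELD_SITE_LAT = 47.805

SITE_TYPES = ("game park", "refuse site", "hut")

#: Typical dwell radius (m) of birds using a site, by resource type.
TRUE_DWELL_RADIUS = {"game park": 80.0, "refuse site": 100.0, "hut": 50.0}

SEASONS = ("spring", "summer", "autumn", "winter")


@dataclass
class EffectSizes:
    """Log-scale cohort/season coefficients injected into the simulation.

    Defaults echo effect magnitudes reported for Alpine non-breeding ravens:
    juveniles range less than adults, wild-caught birds range more than
    captive-released ones, ranging peaks in autumn/winter while presence at
    food sources peaks in spring/summer.
    """

    range_juvenile: float = -0.84
    range_wild: float = 2.20
    range_season: dict = field(
        default_factory=lambda: {"spring": -2.73, "summer": -1.78, "autumn": 0.0, "winter": -0.44}
    )
    disp_juvenile: float = -0.53
    disp_wild: float = 1.29
    disp_season: dict = field(
        default_factory=lambda: {"spring": -0.29, "summer": -0.18, "autumn": 0.0, "winter": -0.05}
    )
    visits_juvenile: float = -0.21
    visits_wild: float = 0.48
    visits_season: dict = field(
        default_factory=lambda: {"spring": 0.0, "summer": -0.04, "autumn": 0.0, "winter": 0.35}
    )
    presence_juvenile: float = -0.13
    presence_wild: float = 0.0
    presence_season: dict = field(
        default_factory=lambda: {"spring": 1.16, "summer": 0.67, "autumn": 0.0, "winter": 0.60}
    )

    @classmethod
    def null(cls) -> "EffectSizes":
        """All-zero effects: individuals statistically exchangeable."""
        zero = {s: 0.0 for s in SEASONS}
        return cls(
            range_juvenile=0.0, range_wild=0.0, range_season=dict(zero),
            disp_juvenile=0.0, disp_wild=0.0, disp_season=dict(zero),
            visits_juvenile=0.0, visits_wild=0.0, visits_season=dict(zero),
            presence_juvenile=0.0, presence_wild=0.0, presence_season=dict(zero),
        )


@dataclass
class SyntheticConfig:
    """Study-design parameters of the generator.

    Defaults mirror the emulated field study: 81 birds tracked July 2017 to
    March 2020 at 45 food sources, cohort fractions 56/81 wild-caught,
    49/81 female, 51/81 juvenile-at-tagging, summer sampling every ~5 min
    and winter sampling every ~1.5 h, and a per-day censoring hazard sized
    to the study's 36 track terminations among 81 birds.
    """

    n_individuals: int = 81
    cohort_proportions: dict = field(
        default_factory=lambda: {"wild_caught": 56 / 81, "female": 49 / 81, "juvenile": 51 / 81}
    )
    n_sites: int = 45
    site_type_mix: dict = field(
        default_factory=lambda: {"game park": 3 / 45, "refuse site": 18 / 45, "hut": 24 / 45}
    )
    effect_sizes: EffectSizes = field(default_factory=EffectSizes)
    #: mean fix interval (s) per season; intervals are exponential around it
    sampling_scheme: dict = field(
        default_factory=lambda: {"spring": 300.0, "summer": 300.0, "autumn": 3600.0, "winter": 5400.0}
    )
    tracking_start: dt.date = dt.date(2017, 7, 1)
    tracking_end: dt.date = dt.date(2020, 3, 31)
    censor_rate_per_day: float = 0.0011
    #: half-width (m) of the square study area
    area_half_width: float = 30_000.0
    #: baseline daily exploration radius (m) before effect multipliers
    base_range_m: float = 4_000.0
    #: baseline known-site repertoire size before effect multipliers
    base_repertoire: int = 5
    #: baseline probability that a destination is an AFS (logit shifted by effects)
    base_p_afs: float = 0.5
    flight_speed_ms: float = 10.0
    #: mean dwell-bout duration at an AFS; exploratory bouts are shorter and
    #: the bird keeps drifting (search flight), so they do not masquerade as
    #: fix clusters
    mean_dwell_s: float = 7200.0
    mean_dwell_explore_s: float = 600.0
    wander_speed_ms: float = 3.0
    #: smallest exploration radius (m): even sedentary birds spread their
    #: foraging stops over more than a cluster-detection neighbourhood
    min_range_m: float = 1500.0
    #: between-individual SD of the log/logit-scale channel offsets — the
    #: heterogeneity the individual random intercept absorbs downstream
    individual_sd: dict = field(
        default_factory=lambda: {"range": 0.3, "disp": 0.2, "visits": 0.2, "presence": 0.4}
    )
    gps_noise_m: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for name, group in (("cohort_proportions", self.cohort_proportions),
                            ("site_type_mix", self.site_type_mix)):
            for key, frac in group.items():
                if not 0.0 <= frac <= 1.0:
                    raise ValueError(f"{name}[{key!r}] = {frac} outside [0, 1]")
        if abs(sum(self.site_type_mix.values()) - 1.0) > 1e-9:
            raise ValueError("site_type_mix fractions must sum to 1")
        if self.tracking_end <= self.tracking_start:
            raise ValueError("tracking_end must follow tracking_start")

    @classmethod
    def scaled(cls, n_individuals=12, n_sites=8, n_days=80, seed=0, **kw) -> "SyntheticConfig":
        """A reduced problem size with the same structure, for fast experiments."""
        start = dt.date(2018, 7, 1)
        defaults = dict(
            n_individuals=n_individuals,
            n_sites=n_sites,
            site_type_mix={"game park": 1 / n_sites,
                           "refuse site": (n_sites // 2) / n_sites,
                           "hut": (n_sites - 1 - n_sites // 2) / n_sites},
            tracking_start=start,
            tracking_end=start + dt.timedelta(days=n_days),
            sampling_scheme={"spring": 900.0, "summer": 900.0, "autumn": 1800.0, "winter": 2700.0},
            area_half_width=15_000.0,
            censor_rate_per_day=0.0,
            seed=seed,
        )
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class TrueSite:
    """Ground-truth food source: centre, type, dwell radius, seasonality."""

    site_id: str
    x: float
    y: float
    lon: float
    lat: float
    resource_type: str
    dwell_radius: float
    winter_peaking: bool


@dataclass
class GroundTruth:
    """Everything the generator knows: attributes, sites, injected coefficients."""

    individuals: pd.DataFrame
    sites: list[TrueSite]
    effect_sizes: EffectSizes
    projection: LocalProjection

    def to_json(self, path) -> None:
        payload = {
            "individuals": self.individuals.to_dict(orient="records"),
            "sites": [dataclasses.asdict(s) for s in self.sites],
            "effect_sizes": dataclasses.asdict(self.effect_sizes),
            "projection": {"lon0": self.projection.lon0, "lat0": self.projection.lat0},
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=str))


class AreaTooSmallError(ValueError):
    """Bounding box cannot host the requested number of separated sites."""


MIN_SITE_SEPARATION_M = 2 * 150.0  # twice the maximum buffer radius


def simulate_sites(config: SyntheticConfig, rng: np.random.Generator | None = None) -> list[TrueSite]:
    """Place ground-truth sites with unambiguous (> 300 m) separation.

    The first site is always a game park at the area centre — the trapping
    and release location every simulated bird knows. Hut-type sites are
    flagged winter-peaking.
    """
    rng = rng or np.random.default_rng(config.seed)
    proj = LocalProjection(FIELD_SITE_LON, FIELD_SITE_LAT)
    if config.n_sites == 0:
        return []
    half = config.area_half_width
    if (2 * half) ** 2 < config.n_sites * (2 * MIN_SITE_SEPARATION_M) ** 2:
        raise AreaTooSmallError(
            f"area {2 * half:.0f} m square cannot fit {config.n_sites} sites "
            f"separated by > {MIN_SITE_SEPARATION_M:.0f} m"
        )
    # deterministic type counts honouring the configured mix
    types: list[str] = []
    for stype in SITE_TYPES:
        types += [stype] * int(round(config.site_type_mix.get(stype, 0.0) * config.n_sites))
    while len(types) < config.n_sites:
        types.append("hut")
    types = types[: config.n_sites]
    if "game park" in types:  # the trap site comes first
        types.remove("game park")
        types.insert(0, "game park")

    xs, ys = [0.0], [0.0]
    attempts = 0
    while len(xs) < config.n_sites:
        attempts += 1
        if attempts > 200 * config.n_sites:
            raise AreaTooSmallError("could not place sites with the required separation")
        x = rng.uniform(-half, half)
        y = rng.uniform(-half, half)
        d2 = (np.array(xs) - x) ** 2 + (np.array(ys) - y) ** 2
        if np.all(d2 > (MIN_SITE_SEPARATION_M * 1.05) ** 2):
            xs.append(x)
            ys.append(y)

    sites = []
    for k, (x, y, stype) in enumerate(zip(xs, ys, types)):
        lon, lat = proj.inverse(x, y)
        sites.append(
            TrueSite(
                site_id=f"T{k + 1:02d}",
                x=float(x),
                y=float(y),
                lon=float(lon),
                lat=float(lat),
                resource_type=stype,
                dwell_radius=TRUE_DWELL_RADIUS[stype],
                winter_peaking=(stype == "hut"),
            )
        )
    return sites


def _season_of_date(d: dt.date) -> str:
    md = (d.month, d.day)
    if (3, 21) <= md < (6, 21):
        return "spring"
    if (6, 21) <= md < (9, 23):
        return "summer"
    if (9, 23) <= md < (12, 21):
        return "autumn"
    return "winter"


def _cohort_lp(attrs: dict, season: str, eff: EffectSizes, channel: str) -> float:
    juv = attrs["age_class_at_tagging"] == "juvenile"
    wild = attrs["origin"] == "wild-caught"
    j = getattr(eff, f"{channel}_juvenile")
    w = getattr(eff, f"{channel}_wild")
    s = getattr(eff, f"{channel}_season")[season]
    return (j if juv else 0.0) + (w if wild else 0.0) + s


def simulate_individual(
    attrs: dict,
    sites: list[TrueSite],
    config: SyntheticConfig,
    seed: int | np.random.SeedSequence,
) -> pd.DataFrame:
    """Simulate one bird's ordered GPS fixes (canonical fixes frame).

    Days alternate dwell bouts at chosen destinations (AFS or exploratory
    points) with straight-line transits; fix times are drawn from the
    season's sampling scheme inside the daylight window, plus one roost fix
    6 h after sunset. Timestamps are strictly increasing; the track ends at
    the configured end date or an earlier geometric censoring event.
    """
    if attrs["age_class_at_tagging"] not in ("juvenile", "adult"):
        raise ValueError(f"unknown age class {attrs['age_class_at_tagging']!r}")
    if attrs["origin"] not in ("wild-caught", "captive-released"):
        raise ValueError(f"unknown origin {attrs['origin']!r}")
    if not sites:
        raise ValueError("at least the release/trap site must exist")
    rng = np.random.default_rng(seed)
    proj = LocalProjection(FIELD_SITE_LON, FIELD_SITE_LAT)
    eff = config.effect_sizes
    home = sites[0]
    ind_re = {
        ch: rng.normal(0.0, config.individual_sd.get(ch, 0.0))
        for ch in ("range", "disp", "visits", "presence")
    }

    start: dt.date = attrs["tagging_date"]
    n_days = (config.tracking_end - start).days + 1
    if config.censor_rate_per_day > 0:
        lifetime = rng.geometric(config.censor_rate_per_day)
        n_days = min(n_days, int(lifetime))

    site_xy = np.array([[s.x, s.y] for s in sites])
    dist_home = np.hypot(site_xy[:, 0] - home.x, site_xy[:, 1] - home.y)

    times: list[dt.datetime] = []
    pos_x: list[float] = []
    pos_y: list[float] = []
    pos = np.array([home.x, home.y])
    season_cache: dict[str, dict] = {}

    for day_idx in range(n_days):
        date = start + dt.timedelta(days=day_idx)
        season = _season_of_date(date)
        if season not in season_cache:
            lp_visits = _cohort_lp(attrs, season, eff, "visits") + ind_re["visits"]
            n_know = max(1, int(round(config.base_repertoire * math.exp(lp_visits))))
            order = np.argsort(dist_home)  # birds know the nearest sites first
            known = [int(i) for i in order[: min(n_know, len(sites))]]
            season_cache[season] = {
                "range_m": max(
                    config.min_range_m,
                    config.base_range_m
                    * math.exp((_cohort_lp(attrs, season, eff, "range") + ind_re["range"]) / 2.0),
                ),
                "p_far": _expit(_logit(0.5) + _cohort_lp(attrs, season, eff, "disp") + ind_re["disp"]),
                "p_afs": _expit(
                    _logit(config.base_p_afs)
                    + _cohort_lp(attrs, season, eff, "presence")
                    + ind_re["presence"]
                ),
                "known": known,
            }
        sc = season_cache[season]
        rise, set_ = solar.daylight_window(FIELD_SITE_LAT, FIELD_SITE_LON, date)
        day_len = (set_ - rise).total_seconds()

        # build the day's bout schedule: (t_start, t_end, x0, y0, x1, y1)
        sched = []
        t = 0.0
        cur = pos.copy()
        while t < day_len:
            at_afs = rng.random() < sc["p_afs"]
            if at_afs:
                weights = np.array(
                    [
                        (2.0 if (sites[i].winter_peaking and season == "winter") else 1.0)
                        for i in sc["known"]
                    ]
                )
                target_site = sites[sc["known"][rng.choice(len(sc["known"]), p=weights / weights.sum())]]
                jitter = rng.normal(0.0, target_site.dwell_radius / 2.0, 2)
                dest = np.array([target_site.x, target_site.y]) + jitter
            else:
                r = sc["range_m"] * (1.0 if rng.random() < sc["p_far"] else 0.4) * math.sqrt(rng.random())
                th = rng.uniform(0, 2 * math.pi)
                dest = np.array([home.x + r * math.cos(th), home.y + r * math.sin(th)])
            flight = float(np.hypot(*(dest - cur))) / config.flight_speed_ms
            sched.append((t, t + flight, cur.copy(), dest.copy()))
            t += flight
            if at_afs:  # stationary dwell at the food source
                dwell = rng.exponential(config.mean_dwell_s)
                end = dest.copy()
            else:  # exploratory bout: the bird keeps drifting while foraging
                dwell = rng.exponential(config.mean_dwell_explore_s)
                th_w = rng.uniform(0, 2 * math.pi)
                end = dest + dwell * config.wander_speed_ms * np.array(
                    [math.cos(th_w), math.sin(th_w)]
                )
            sched.append((t, t + dwell, dest.copy(), end.copy()))
            t += dwell
            cur = end
        pos = cur

        # sample fix times from the season's scheme and read positions off the schedule
        mean_gap = config.sampling_scheme[season]
        ft = []
        tt = rng.exponential(mean_gap)
        while tt < day_len:
            ft.append(tt)
            tt += max(1.0, rng.exponential(mean_gap))
        si = 0
        for tf in ft:
            while si < len(sched) - 1 and sched[si][1] <= tf:
                si += 1
            t0, t1, p0, p1 = sched[si]
            frac = 0.0 if t1 <= t0 else min(max((tf - t0) / (t1 - t0), 0.0), 1.0)
            xy = p0 + frac * (p1 - p0) + rng.normal(0.0, config.gps_noise_m, 2)
            times.append(rise + dt.timedelta(seconds=tf))
            pos_x.append(float(xy[0]))
            pos_y.append(float(xy[1]))
        # nightly roost fix 6 h after sunset (removed by the daytime filter)
        night_xy = pos + rng.normal(0.0, config.gps_noise_m, 2)
        times.append(set_ + dt.timedelta(hours=6))
        pos_x.append(float(night_xy[0]))
        pos_y.append(float(night_xy[1]))

    lon, lat = proj.inverse(np.array(pos_x), np.array(pos_y))
    df = pd.DataFrame(
        {
            "individual_id": attrs["id"],
            "timestamp": pd.to_datetime(times),
            "lon": np.atleast_1d(lon),
            "lat": np.atleast_1d(lat),
        }
    ).sort_values("timestamp")
    df = df[~df["timestamp"].duplicated()].reset_index(drop=True)
    return df


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _draw_attributes(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    p = config.cohort_proportions
    n = config.n_individuals
    span_days = (config.tracking_end - config.tracking_start).days
    rows = []
    for i in range(n):
        tag_offset = int(rng.integers(0, max(1, int(span_days * 0.6))))
        rows.append(
            {
                "id": f"B{i + 1:03d}",
                "sex": "female" if rng.random() < p["female"] else "male",
                "origin": "wild-caught" if rng.random() < p["wild_caught"] else "captive-released",
                "age_class_at_tagging": "juvenile" if rng.random() < p["juvenile"] else "adult",
                "tagging_date": config.tracking_start + dt.timedelta(days=tag_offset),
            }
        )
    return pd.DataFrame(rows)


def simulate_population(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the whole population; optionally write the standard files.

    Returns (tracks, attributes, ground truth).  When ``out_dir`` is given,
    writes ``tracks.csv`` (Movebank-style headers), ``individuals.csv`` and
    ``ground_truth.json`` there.
    """
    root = np.random.SeedSequence(config.seed)
    site_ss, attr_ss, *bird_ss = root.spawn(2 + config.n_individuals)
    sites = simulate_sites(config, np.random.default_rng(site_ss))
    attrs = _draw_attributes(config, np.random.default_rng(attr_ss))
    truth = GroundTruth(
        individuals=attrs.copy(),
        sites=sites,
        effect_sizes=config.effect_sizes,
        projection=LocalProjection(FIELD_SITE_LON, FIELD_SITE_LAT),
    )
    tracks = pd.concat(
        [
            simulate_individual(row._asdict() if hasattr(row, "_asdict") else row, sites, config, ss)
            for row, ss in zip(attrs.to_dict(orient="records"), bird_ss)
        ],
        ignore_index=True,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_movebank_csv(tracks, out / "tracks.csv")
        attrs.to_csv(out / "individuals.csv", index=False)
        truth.to_json(out / "ground_truth.json")
    return tracks, attrs, truth


def write_movebank_csv(tracks: pd.DataFrame, path) -> None:
    """Write fixes with Movebank-style headers and ISO-8601 UTC timestamps."""
    out = pd.DataFrame(
        {
            "individual-local-identifier": tracks["individual_id"],
            "timestamp": tracks["timestamp"].dt.strftime("%Y-%m-%d %H:%M:%S.%f").str[:-3],
            "location-long": tracks["lon"].map(lambda v: f"{v:.7f}"),
            "location-lat": tracks["lat"].map(lambda v: f"{v:.7f}"),
        }
    )
    out.to_csv(path, index=False)
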