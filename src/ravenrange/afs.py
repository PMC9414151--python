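"""Anthropogenic food source (AFS) detection, buffer calibration and use metrics.

Heavily used feeding sites (game parks, refuse sites, alpine huts) show up
in corvid telemetry as dense clusters of fixes.  The workflow here is:

1. detect candidate sites as density clusters of (15-min subsampled) fixes;
2. for each site, build a *revisitation curve*: the number of separate
   visits (maximal runs of temporally consecutive in-circle fixes) as a
   function of buffer radius;
3. calibrate a site-specific buffer at the radius where revisitations
   plateau (visits merge as circles grow), capped at 150 m;
4. per individual-season-year segment, count distinct sites visited and the
   proportion of fixes inside any buffer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .geo import haversine_m, projection_for
from .trackprep import SeasonYearSegment

DEFAULT_RADIUS_GRID = tuple(range(20, 151, 10))
MAX_BUFFER_M = 150.0
DEFAULT_VISIT_GAP_S = 5 * 3600.0

RESOURCE_TYPES = ("game park", "refuse site", "hut")


@dataclass
class AfsSite:
    """A (candidate or confirmed) food-source point with its calibrated buffer."""

    site_id: str
    lon: float
    lat: float
    resource_type: str = "unknown"
    buffer_radius: float | None = None  # metres, <= 150 once calibrated
    n_individuals_recorded: int = 0
    n_member_fixes: int = 0

    def __post_init__(self):
        if self.buffer_radius is not None and not (0 < self.buffer_radius <= MAX_BUFFER_M):
            raise ValueError(f"buffer radius must lie in (0, {MAX_BUFFER_M}] m")


@dataclass
class RevisitationCurve:
    """Visits and fix coverage of one site as a function of buffer radius."""

    site_id: str
    radii: np.ndarray  # ascending metres
    revisits: np.ndarray  # visits per radius (not necessarily monotone)
    coverage: np.ndarray  # fixes inside per radius (monotone non-decreasing)

    def __post_init__(self):
        self.radii = np.asarray(self.radii, float)
        self.revisits = np.asarray(self.revisits, int)
        self.coverage = np.asarray(self.coverage, int)
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly ascending")


def detect_clusters(
    subsampled_fixes: pd.DataFrame,
    min_count: int = 10,
    radius: float = 200.0,
) -> list[AfsSite]:
    """Density-cluster fixes into candidate sites.

    A cluster needs at least ``min_count`` fixes within ``radius`` metres
    (DBSCAN core-point rule); the site centre is the centroid of member
    fixes, and clusters whose centroids lie within ``radius`` are merged.
    Input should be subsampled to >= 15-min intervals so dense summer
    sampling does not manufacture clusters.
    """
    if subsampled_fixes.empty:
        return []
    lon = subsampled_fixes["lon"].to_numpy()
    lat = subsampled_fixes["lat"].to_numpy()
    proj = projection_for(lon, lat)
    x, y = proj.forward(lon, lat)
    labels = DBSCAN(eps=radius, min_samples=min_count).fit_predict(np.column_stack([x, y]))

    centroids = []  # [x, y, n_fixes, member_index_list]
    for lab in sorted(set(labels) - {-1}):
        m = labels == lab
        centroids.append([x[m].mean(), y[m].mean(), int(m.sum())])

    # merge clusters whose centroids fall within `radius` (transitively)
    merged = True
    while merged and len(centroids) > 1:
        merged = False
        for i in range(len(centroids)):
            for j in range(i + 1, len(centroids)):
                xi, yi, ni = centroids[i]
                xj, yj, nj = centroids[j]
                if np.hypot(xi - xj, yi - yj) <= radius:
                    n = ni + nj
                    centroids[i] = [(xi * ni + xj * nj) / n, (yi * ni + yj * nj) / n, n]
                    centroids.pop(j)
                    merged = True
                    break
            if merged:
                break

    sites = []
    for k, (cx, cy, n) in enumerate(sorted(centroids, key=lambda c: -c[2])):
        clon, clat = proj.inverse(cx, cy)
        sites.append(
            AfsSite(site_id=f"S{k + 1:02d}", lon=float(clon), lat=float(clat), n_member_fixes=n)
        )
    return sites


def _visits_in_circle(times_s: np.ndarray, inside: np.ndarray, max_gap_s: float) -> int:
    """Count maximal runs of consecutive inside fixes, splitting runs at data gaps."""
    if not inside.any():
        return 0
    visits = 0
    prev_in = False
    prev_t = None
    for t, is_in in zip(times_s, inside):
        if is_in and (not prev_in or (prev_t is not None and t - prev_t > max_gap_s)):
            visits += 1
        if is_in:
            prev_t = t
        prev_in = is_in
    return visits


def revisitation_curve(
    all_fixes: pd.DataFrame,
    site: AfsSite,
    radii=DEFAULT_RADIUS_GRID,
    max_gap_s: float = DEFAULT_VISIT_GAP_S,
) -> RevisitationCurve:
    """Visits and coverage of one site across a grid of buffer radii.

    A visit is a maximal run of temporally consecutive fixes of one
    individual inside the circle (runs split at data gaps longer than
    ``max_gap_s``); revisits are pooled over individuals.
    """
    radii = np.asarray(sorted(radii), float)
    if radii.max() > MAX_BUFFER_M:
        raise ValueError(f"radii must not exceed {MAX_BUFFER_M} m")
    all_fixes = all_fixes.reset_index(drop=True)
    dist = haversine_m(all_fixes["lon"].to_numpy(), all_fixes["lat"].to_numpy(), site.lon, site.lat)
    revisits = np.zeros(len(radii), int)
    coverage = np.zeros(len(radii), int)
    for _, grp in all_fixes.groupby("individual_id", sort=False):
        order = grp["timestamp"].argsort().to_numpy()
        t = grp["timestamp"].astype("int64").to_numpy()[order] / 1e9
        d = dist[grp.index.to_numpy()[order]]
        for k, r in enumerate(radii):
            inside = d <= r
            coverage[k] += int(inside.sum())
            revisits[k] += _visits_in_circle(t, inside, max_gap_s)
    return RevisitationCurve(site.site_id, radii, revisits, coverage)


def select_buffer(
    curve: RevisitationCurve,
    r_max: float = MAX_BUFFER_M,
    plateau_tol: float = 0.05,
) -> float | None:
    """Pick the buffer radius where revisitations stop increasing.

    Returns the smallest radius r* such that no subsequent radius raises
    the revisit count by ``plateau_tol`` (relative) or more; if the curve
    keeps rising, returns ``r_max``. An all-zero curve means the site is
    unused: returns None.
    """
    if len(curve.radii) == 0:
        raise ValueError("empty revisitation curve")
    if curve.revisits.max() == 0:
        return None
    for k, r in enumerate(curve.radii):
        if r > r_max:
            break
        later = curve.revisits[k + 1 :][curve.radii[k + 1 :] <= r_max]
        if len(later) == 0 or later.max() < (1.0 + plateau_tol) * max(curve.revisits[k], 1):
            return float(min(r, r_max))
    return float(r_max)


def calibrate_buffers(
    all_fixes: pd.DataFrame,
    sites: list[AfsSite],
    radii=DEFAULT_RADIUS_GRID,
    plateau_tol: float = 0.05,
    max_gap_s: float = DEFAULT_VISIT_GAP_S,
) -> list[RevisitationCurve]:
    """Calibrate each site's buffer in place; returns the curves for inspection."""
    curves = []
    for site in sites:
        curve = revisitation_curve(all_fixes, site, radii, max_gap_s)
        site.buffer_radius = select_buffer(curve, plateau_tol=plateau_tol)
        if site.buffer_radius is not None:
            inside = (
                haversine_m(all_fixes["lon"].to_numpy(), all_fixes["lat"].to_numpy(), site.lon, site.lat)
                <= site.buffer_radius
            )
            site.n_individuals_recorded = int(all_fixes.loc[inside, "individual_id"].nunique())
        curves.append(curve)
    return curves


def _inside_matrix(segment: SeasonYearSegment, sites: list[AfsSite]) -> np.ndarray:
    """Boolean (n_fixes, n_sites): fix within the site's calibrated buffer."""
    lon = segment.fixes["lon"].to_numpy()
    lat = segment.fixes["lat"].to_numpy()
    cols = []
    for site in sites:
        if site.buffer_radius is None:
            cols.append(np.zeros(len(lon), dtype=bool))
        else:
            cols.append(haversine_m(lon, lat, site.lon, site.lat) <= site.buffer_radius)
    return np.column_stack(cols) if cols else np.zeros((len(lon), 0), dtype=bool)


def count_afs_visited(segment: SeasonYearSegment, sites: list[AfsSite]) -> int:
    """Number of distinct sites whose buffer contains at least one fix."""
    return int(_inside_matrix(segment, sites).any(axis=0).sum())


def prop_in_any_buffer(segment: SeasonYearSegment, sites: list[AfsSite]) -> float | None:
    """Fraction of the segment's fixes inside the union of buffers.

    Returns None for zero-visit segments — they are excluded from the
    presence-probability analysis rather than scored 0.
    """
    inside = _inside_matrix(segment, sites)
    if not inside.any():
        return None
    return float(inside.any(axis=1).mean())


def max_single_site_prop(segment: SeasonYearSegment, sites: list[AfsSite]) -> float:
    """Largest per-site fraction of the segment's fixes inside one buffer."""
    inside = _inside_matrix(segment, sites)
    if inside.shape[1] == 0:
        return 0.0
    return float(inside.mean(axis=0).max())


def afs_use_metrics(segments: list[SeasonYearSegment], sites: list[AfsSite]) -> pd.DataFrame:
    """Per-segment AFS-use table, including binomial (inside, outside) counts."""
    rows = []
    for seg in segments:
        inside = _inside_matrix(seg, sites)
        any_inside = inside.any(axis=1)
        n_visited = int(inside.any(axis=0).sum())
        rows.append(
            {
                "individual_id": seg.individual_id,
                "season": seg.season,
                "year_label": seg.year_label,
                "n_afs_visited": n_visited,
                "n_fixes_inside": int(any_inside.sum()),
                "n_fixes_total": len(seg.fixes),
                "prop_in_any_buffer": float(any_inside.mean()) if n_visited else np.nan,
                "max_single_site_prop": float(inside.mean(axis=0).max()) if inside.shape[1] else 0.0,
            }
        )
    return pd.DataFrame(rows)


def buffers_geojson(sites: list[AfsSite], n_vertices: int = 72) -> dict:
    """Calibrated buffers as a GeoJSON FeatureCollection of circle polygons."""
    feats = []
    for s in sites:
        if s.buffer_radius is None:
            continue
        proj = projection_for([s.lon], [s.lat])
        th = np.linspace(0.0, 2 * np.pi, n_vertices + 1)
        lon, lat = proj.inverse(s.buffer_radius * np.cos(th), s.buffer_radius * np.sin(th))
        feats.append(
            {
                "type": "Feature",
                "properties": {
                    "site_id": s.site_id,
                    "resource_type": s.resource_type,
                    "buffer_radius_m": s.buffer_radius,
                },
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [list(map(list, zip(lon, lat)))],
                },
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def curves_table(curves: list[RevisitationCurve]) -> pd.DataFrame:
    """Revisitation curves in tidy form (site_id, radius_m, revisits, coverage)."""
    rows = []
    for c in curves:
        for r, v, cov in zip(c.radii, c.revisits, c.coverage):
            rows.append({"site_id": c.site_id, "radius_m": r, "revisits": v, "coverage": cov})
    return pd.DataFrame(rows)


def sites_table(sites: list[AfsSite]) -> pd.DataFrame:
    """Sites as a tidy frame (site_id, lon, lat, resource_type, buffer, usage)."""
    return pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "lon": [s.lon for s in sites],
            "lat": [s.lat for s in sites],
            "resource_type": [s.resource_type for s in sites],
            "buffer_radius_m": [s.buffer_radius for s in sites],
            "n_individuals_recorded": [s.n_individuals_recorded for s in sites],
        }
    )
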