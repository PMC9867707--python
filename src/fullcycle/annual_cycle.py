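"""Annual-cycle geometry: great-circle displacement, relocation-day
classification, stage segmentation, winter-area estimation, migration-strategy
assignment and habitat-class reduction.

The annual cycle of a migratory bird-year is partitioned into four stages —
breeding, autumn migration, wintering, spring migration — from GPS alone.
Breeding is anchored on association with the colony (last/first detection
within 10 km), the wintering area is the southernmost 95% kernel-density core
area of the nonbreeding locations, and the winter period runs from the first
to the last stationary day inside it. Days move the bird or they do not: net
displacement between the fixes closest to consecutive midnights above 70 km
marks a relocation day; relocation days inside the migratory periods are
migration days and stationary ones are stopover days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import gaussian_kde

__all__ = [
    "EARTH_RADIUS_KM",
    "great_circle_km",
    "daily_displacement",
    "classify_day",
    "WinterArea",
    "winter_core_area",
    "StageSegmentation",
    "segment_stages",
    "assign_strategy",
    "remap_habitat",
    "DEFAULT_REGIONS",
    "DEFAULT_HABITAT_MAP",
]

EARTH_RADIUS_KM = 6371.0088

STAGES = ("breeding", "autumn_migration", "wintering", "spring_migration")


def _check_coords(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates out of range (|lat|<=90, |lon|<=180)")


def great_circle_km(p1, p2):
    """Haversine great-circle distance in km between (lat, lon) points.

    Accepts scalar pairs or arrays of equal shape.
    """
    lat1, lon1 = np.asarray(p1[0], float), np.asarray(p1[1], float)
    lat2, lon2 = np.asarray(p2[0], float), np.asarray(p2[1], float)
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def daily_displacement(bird_year, tolerance_h: float = 6.0) -> pd.DataFrame:
    """Net displacement per calendar day of a bird-year.

    For each day the fixes closest to its starting and ending midnights are
    found (within ``tolerance_h`` hours); the day's displacement is their
    great-circle distance. Days lacking a fix near either midnight (data gaps)
    get NaN. Returns a DataFrame with columns date, lat, lon (position nearest
    the starting midnight) and displacement_km.
    """
    fixes = bird_year.fixes
    t = fixes["t"].to_numpy()
    days = bird_year.year_days()
    midnights = np.append(days.to_numpy(), np.datetime64(bird_year.end))
    tol = np.timedelta64(int(tolerance_h * 3600), "s")

    idx = np.searchsorted(t, midnights)
    lo = np.clip(idx - 1, 0, len(t) - 1)
    hi = np.clip(idx, 0, len(t) - 1)
    d_lo = np.abs(midnights - t[lo])
    d_hi = np.abs(t[hi] - midnights)
    nearest = np.where(d_lo <= d_hi, lo, hi)
    ok = np.minimum(d_lo, d_hi) <= tol

    lat = fixes["lat"].to_numpy()[nearest]
    lon = fixes["lon"].to_numpy()[nearest]
    disp = great_circle_km((lat[:-1], lon[:-1]), (lat[1:], lon[1:]))
    disp = np.where(ok[:-1] & ok[1:], disp, np.nan)
    return pd.DataFrame({
        "date": days,
        "lat": np.where(ok[:-1], lat[:-1], np.nan),
        "lon": np.where(ok[:-1], lon[:-1], np.nan),
        "displacement_km": disp,
    })


def classify_day(displacement_km, threshold_km: float = 70.0):
    """'relocation' when displacement strictly exceeds the threshold,
    'stationary' otherwise, 'missing' for NaN. Vectorised."""
    disp = np.asarray(displacement_km, dtype=float)
    out = np.where(np.isnan(disp), "missing",
                   np.where(disp > threshold_km, "relocation", "stationary"))
    return out.item() if out.ndim == 0 else out


# ---------------------------------------------------------------- winter area


def _laea_forward(lat, lon, lat0, lon0):
    """Lambert azimuthal equal-area projection (km), centered on (lat0, lon0)."""
    phi, lam = np.radians(lat), np.radians(lon)
    phi0, lam0 = np.radians(lat0), np.radians(lon0)
    cosc = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    k = np.sqrt(2.0 / np.clip(1.0 + cosc, 1e-12, None))
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_KM * k * (np.cos(phi0) * np.sin(phi)
                               - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0))
    return x, y


def _laea_inverse(x, y, lat0, lon0):
    phi0, lam0 = np.radians(lat0), np.radians(lon0)
    x = np.asarray(x, float) / EARTH_RADIUS_KM
    y = np.asarray(y, float) / EARTH_RADIUS_KM
    rho = np.sqrt(x ** 2 + y ** 2)
    c = 2.0 * np.arcsin(np.clip(rho / 2.0, 0.0, 1.0))
    with np.errstate(invalid="ignore"):
        phi = np.where(
            rho > 1e-12,
            np.arcsin(np.clip(np.cos(c) * np.sin(phi0)
                              + y * np.sin(c) * np.cos(phi0) / np.where(rho > 1e-12, rho, 1.0),
                              -1.0, 1.0)),
            phi0,
        )
        lam = np.where(
            rho > 1e-12,
            lam0 + np.arctan2(x * np.sin(c),
                              rho * np.cos(phi0) * np.cos(c) - y * np.sin(phi0) * np.sin(c)),
            lam0,
        )
    return np.degrees(phi), np.degrees(lam)


@dataclass
class WinterArea:
    """A 95% KDE core area on an equal-area projection.

    ``mask`` flags grid cells of the *selected* (southernmost) core area;
    ``mass`` is the KDE probability mass inside it, ``mass_all`` the mass
    inside all core areas at the same density level.
    """

    centroid: tuple[float, float]  # (lat, lon)
    mask: np.ndarray  # (grid, grid) bool, selected component
    xs: np.ndarray  # projected grid x (km)
    ys: np.ndarray  # projected grid y (km)
    origin: tuple[float, float]  # projection center (lat0, lon0)
    level: float  # KDE density at the contour
    mass: float
    mass_all: float
    n_components: int

    def contains(self, lat, lon):
        """Whether (lat, lon) falls inside the selected core area (by nearest
        grid cell; points outside the grid are outside). Vectorised."""
        x, y = _laea_forward(np.asarray(lat, float), np.asarray(lon, float), *self.origin)
        ix = np.searchsorted(self.xs, x).clip(1, len(self.xs) - 1)
        iy = np.searchsorted(self.ys, y).clip(1, len(self.ys) - 1)
        ix = np.where(np.abs(self.xs[ix] - x) <= np.abs(self.xs[ix - 1] - x), ix, ix - 1)
        iy = np.where(np.abs(self.ys[iy] - y) <= np.abs(self.ys[iy - 1] - y), iy, iy - 1)
        inside_grid = (
            (x >= self.xs[0]) & (x <= self.xs[-1])
            & (y >= self.ys[0]) & (y <= self.ys[-1])
        )
        out = self.mask[iy, ix] & inside_grid
        return bool(out) if out.ndim == 0 else out

    def to_geojson(self) -> dict:
        """Contour polygons of the selected core area as a GeoJSON feature."""
        from skimage import measure

        contours = measure.find_contours(self.mask.astype(float), 0.5)
        dx = self.xs[1] - self.xs[0]
        dy = self.ys[1] - self.ys[0]
        polys = []
        for c in contours:
            x = self.xs[0] + c[:, 1] * dx
            y = self.ys[0] + c[:, 0] * dy
            lat, lon = _laea_inverse(x, y, *self.origin)
            polys.append([[float(lo), float(la)] for lo, la in zip(lon, lat)])
        return {
            "type": "Feature",
            "geometry": {"type": "MultiPolygon", "coordinates": [[p] for p in polys]},
            "properties": {
                "centroid": [self.centroid[1], self.centroid[0]],
                "kde_mass": self.mass,
            },
        }


def winter_core_area(
    lat,
    lon,
    level: float = 0.95,
    grid_size: int = 200,
    max_points: int = 800,
    bandwidth_km: float | None = 25.0,
    min_component_mass: float = 0.01,
) -> WinterArea:
    """Southernmost core area of the nonbreeding locations.

    Fits a Gaussian KDE to the positions on a Lambert azimuthal equal-area
    projection centered on their mean, evaluates it on a ``grid_size``² grid,
    thresholds at the density level enclosing ``level`` of the grid mass, and —
    when several disjoint core areas emerge — returns the one whose
    mass-weighted centroid lies furthest south. Components holding less than
    ``min_component_mass`` of the KDE mass are discarded as grid artifacts.

    ``bandwidth_km`` sets a fixed isotropic kernel bandwidth (default 25 km,
    small enough that residence clusters ≳150 km apart resolve as distinct
    core areas while each core spans ~130 km). ``None`` falls back
    to Scott's rule on the full data covariance, which oversmooths tracks
    whose residence clusters sit thousands of km apart — use it only for
    single-cluster inputs.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat.size < 50:
        raise ValueError(f"winter_core_area needs >= 50 positions, got {lat.size}")
    if lat.size > max_points:  # uniform thinning keeps the spatial structure
        sel = np.linspace(0, lat.size - 1, max_points).round().astype(int)
        lat, lon = lat[sel], lon[sel]

    lat0, lon0 = float(lat.mean()), float(lon.mean())
    x, y = _laea_forward(lat, lon, lat0, lon0)

    if bandwidth_km is None:
        # jitter degenerate axes so the KDE covariance is full rank
        if np.ptp(x) < 1e-9 or np.ptp(y) < 1e-9:
            rng = np.random.default_rng(0)
            x = x + rng.normal(0, 1e-3, x.size)
            y = y + rng.normal(0, 1e-3, y.size)
        kde = gaussian_kde(np.vstack([x, y]))
        h_x = float(np.sqrt(kde.covariance[0, 0]))
        h_y = float(np.sqrt(kde.covariance[1, 1]))
        density = lambda px, py: kde(np.vstack([px, py]))
    else:
        h_x = h_y = float(bandwidth_km)

        def density(px, py, h=float(bandwidth_km)):
            out = np.zeros(px.size)
            norm = 1.0 / (x.size * 2.0 * np.pi * h * h)
            for i0 in range(0, px.size, 8192):  # chunked to bound memory
                sl = slice(i0, i0 + 8192)
                d2 = (px[sl, None] - x[None, :]) ** 2 + (py[sl, None] - y[None, :]) ** 2
                out[sl] = norm * np.exp(-0.5 * d2 / (h * h)).sum(axis=1)
            return out

    pad_x = 0.15 * max(np.ptp(x), 1.0) + 3.0 * h_x
    pad_y = 0.15 * max(np.ptp(y), 1.0) + 3.0 * h_y
    xs = np.linspace(x.min() - pad_x, x.max() + pad_x, grid_size)
    ys = np.linspace(y.min() - pad_y, y.max() + pad_y, grid_size)
    gx, gy = np.meshgrid(xs, ys)
    dens = density(gx.ravel(), gy.ravel()).reshape(grid_size, grid_size)

    cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
    order = np.argsort(dens.ravel())[::-1]
    cum = np.cumsum(dens.ravel()[order]) * cell
    total = dens.sum() * cell
    k = int(np.searchsorted(cum, level * total))
    thr = dens.ravel()[order[min(k, order.size - 1)]]
    mask_all = dens >= thr

    labels, n_comp = ndimage.label(mask_all)
    if n_comp == 0:
        raise ValueError("no core area found (degenerate density)")
    best = None
    fallback = None
    for comp in range(1, n_comp + 1):
        m = labels == comp
        w = dens[m]
        cx = float((gx[m] * w).sum() / w.sum())
        cy = float((gy[m] * w).sum() / w.sum())
        clat, clon = _laea_inverse(cx, cy, lat0, lon0)
        mass = float(w.sum() * cell / total)
        cand = (float(clat), float(clon), m, mass)
        if fallback is None or mass > fallback[3]:
            fallback = cand
        if mass < min_component_mass:
            continue
        if best is None or clat < best[0]:
            best = cand
    clat, clon, mask, mass = best if best is not None else fallback
    return WinterArea(
        centroid=(clat, clon),
        mask=mask,
        xs=xs,
        ys=ys,
        origin=(lat0, lon0),
        level=float(thr),
        mass=mass,
        mass_all=float(dens[mask_all].sum() * cell / total),
        n_components=n_comp,
    )


# ---------------------------------------------------------------- segmentation


@dataclass
class StageSegmentation:
    """Per-day stage labels, winter-area geometry and migration strategy."""

    days: pd.DataFrame  # date, stage, day_type, displacement_km
    winter_area: WinterArea
    strategy: str
    boundaries: dict  # departure, winter_start, winter_end, arrival (Timestamps)

    def stage_of(self, date) -> str:
        date = pd.Timestamp(date).normalize()
        row = self.days.loc[self.days["date"] == date, "stage"]
        if row.empty:
            raise KeyError(f"date {date.date()} outside the bird-year")
        return row.iloc[0]


def segment_stages(
    bird_year,
    colony: tuple[float, float] | None = None,
    radius_km: float = 10.0,
    threshold_km: float = 70.0,
    kde_level: float = 0.95,
    regions=None,
) -> StageSegmentation:
    """Partition a bird-year into the four annual-cycle stages.

    Breeding ends with the last detection within ``radius_km`` of the colony
    before the bird's long absence and resumes with the first detection on
    return. The wintering stage spans the first to last stationary day inside
    the (southernmost) 95% KDE core area of the nonbreeding locations; the two
    migration stages are what lies between.
    """
    colony = colony or bird_year.colony
    fixes = bird_year.fixes
    d_colony = great_circle_km(
        (fixes["lat"].to_numpy(), fixes["lon"].to_numpy()), colony
    )
    at_colony = d_colony <= radius_km
    if not at_colony.any():
        raise ValueError("bird never detected within the colony radius")

    daily = daily_displacement(bird_year)
    daily["day_type"] = classify_day(daily["displacement_km"].to_numpy(), threshold_km)

    fix_date = fixes["t"].dt.normalize()
    colony_days = set(fix_date[at_colony].unique())
    away = np.array([d not in colony_days for d in daily["date"]])
    if not away.any():
        raise ValueError("bird never left the colony radius; no migration to segment")

    # longest contiguous absence = the nonbreeding excursion
    runs, start = [], None
    for i, a in enumerate(np.append(away, False)):
        if a and start is None:
            start = i
        elif not a and start is not None:
            runs.append((start, i - 1))
            start = None
    a0, a1 = max(runs, key=lambda r: r[1] - r[0])

    colony_fix_days = fix_date[at_colony]
    before = colony_fix_days[colony_fix_days < daily["date"].iloc[a0]]
    after = colony_fix_days[colony_fix_days > daily["date"].iloc[a1]]
    departure = before.max() if len(before) else daily["date"].iloc[0]
    arrival = after.min() if len(after) else daily["date"].iloc[-1]

    # KDE over residence positions only: fixes on stationary days between
    # departure and arrival. Transit fixes strung along travel legs would
    # bridge otherwise-distinct core areas at the 95% level.
    stationary_days = set(daily.loc[daily["day_type"] == "stationary", "date"])
    in_window = (
        (fixes["t"] > departure + pd.Timedelta(days=1))
        & (fixes["t"] < arrival)
        & fix_date.isin(stationary_days)
    )
    if in_window.sum() < 50:
        raise ValueError("too few nonbreeding positions to estimate a winter area")
    area = winter_core_area(
        fixes.loc[in_window, "lat"].to_numpy(),
        fixes.loc[in_window, "lon"].to_numpy(),
        level=kde_level,
    )

    # mean day position for the stationary-day-in-area test
    day_pos = fixes.groupby(fix_date)[["lat", "lon"]].mean()
    daily = daily.merge(
        day_pos.rename(columns={"lat": "mlat", "lon": "mlon"}),
        left_on="date", right_index=True, how="left",
    )
    stationary = daily["day_type"].to_numpy() == "stationary"
    has_pos = daily["mlat"].notna().to_numpy()
    inside = np.zeros(len(daily), dtype=bool)
    cand = stationary & has_pos & (daily["date"] > departure).to_numpy() \
        & (daily["date"] < arrival).to_numpy()
    if cand.any():
        inside[cand] = area.contains(
            daily.loc[cand, "mlat"].to_numpy(), daily.loc[cand, "mlon"].to_numpy()
        )
    if not inside.any():
        raise ValueError("no stationary day inside the winter core area")
    winter_start = daily["date"].iloc[int(np.argmax(inside))]
    winter_end = daily["date"].iloc[len(inside) - 1 - int(np.argmax(inside[::-1]))]

    date = daily["date"]
    stage = np.full(len(daily), "breeding", dtype=object)
    stage[(date > departure) & (date < winter_start)] = "autumn_migration"
    stage[(date >= winter_start) & (date <= winter_end)] = "wintering"
    stage[(date > winter_end) & (date < arrival)] = "spring_migration"
    daily["stage"] = stage

    # missing days flanked by stationary days inherit stationary (stopover)
    dt = daily["day_type"].to_numpy(dtype=object)
    miss = np.where(dt == "missing")[0]
    for i in miss:
        left = dt[i - 1] if i > 0 else None
        j = i + 1
        while j < len(dt) and dt[j] == "missing":
            j += 1
        right = dt[j] if j < len(dt) else None
        if left == "stationary" and right == "stationary":
            dt[i] = "stationary"
    daily["day_type"] = dt

    subtype = np.where(
        np.isin(stage, ("autumn_migration", "spring_migration")),
        np.where(dt == "relocation", "migration_day",
                 np.where(dt == "stationary", "stopover_day", "missing")),
        dt,
    )
    daily["day_subtype"] = subtype

    strategy = assign_strategy(area.centroid, regions)
    out = daily[["date", "stage", "day_type", "day_subtype",
                 "displacement_km", "mlat", "mlon"]].copy()
    return StageSegmentation(
        days=out,
        winter_area=area,
        strategy=strategy,
        boundaries={
            "departure": departure, "winter_start": winter_start,
            "winter_end": winter_end, "arrival": arrival,
        },
    )


# ---------------------------------------------------------------- strategy


#: (name, lat_min, lat_max, lon_min, lon_max), checked in order. Boxes, not
#: coastlines: Africa is split at 25°N; Iberia is checked before North Africa
#: so the Gibraltar overlap resolves to Spain.
DEFAULT_REGIONS = [
    ("WestAfrica", -35.0, 25.0, -20.0, 40.0),
    ("Iberia", 36.0, 44.0, -10.0, 3.0),
    ("NorthAfrica", 25.0, 37.5, -20.0, 40.0),
    ("FRUK", 43.0, 60.0, -11.0, 8.0),
]


def assign_strategy(winter_centroid: tuple[float, float], regions=None) -> str:
    """Migration strategy from the winter-area centroid.

    Returns 'unassigned' (with a warning) when the centroid falls outside all
    configured regions.
    """
    lat, lon = winter_centroid
    _check_coords(lat, lon)
    for name, lat0, lat1, lon0, lon1 in (regions or DEFAULT_REGIONS):
        if lat0 <= lat <= lat1 and lon0 <= lon <= lon1:
            return name
    warnings.warn(f"winter centroid ({lat:.2f}, {lon:.2f}) outside all regions")
    return "unassigned"


# ---------------------------------------------------------------- habitat


HABITATS = ("marine", "built_up", "agricultural", "terrestrial_open",
            "inland_wet", "forest")

DEFAULT_HABITAT_MAP: dict[str, str] = {
    "sea": "marine", "ocean": "marine", "marine": "marine",
    "built-up": "built_up", "builtup": "built_up", "urban": "built_up",
    "cropland": "agricultural", "croplands": "agricultural",
    "agriculture": "agricultural",
    "herbaceous_vegetation": "terrestrial_open", "grassland": "terrestrial_open",
    "bare": "terrestrial_open", "sparse_vegetation": "terrestrial_open",
    "shrubland": "terrestrial_open", "moss_lichen": "terrestrial_open",
    "permanent_water": "inland_wet", "inland_water": "inland_wet",
    "herbaceous_wetland": "inland_wet", "wetland": "inland_wet",
    "forest_evergreen": "forest", "forest_deciduous": "forest",
    "forest_mixed": "forest", "forest": "forest",
}


def remap_habitat(
    raw_class: str,
    within_colony: bool = False,
    habitat_map: dict[str, str] | None = None,
) -> str:
    """Reduce a land-cover code to one of six habitat classes.

    Fixes inside a breeding colony are corrected to terrestrial open habitat
    regardless of the raster class (colonies sit on dunes misclassified as
    built-up or bare).
    """
    if within_colony:
        return "terrestrial_open"
    mapping = DEFAULT_HABITAT_MAP if habitat_map is None else habitat_map
    key = raw_class.strip().lower().replace(" ", "_")
    if key not in mapping:
        raise KeyError(f"unmapped land-cover class: {raw_class!r}")
    return mapping[key]
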