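"""Life-history classification and territory-associated fix removal.

Each tracked individual-winter is assigned to one of five groups — adult or
non-adult, migrant or non-migrant, and for resident adults territory holder
("breeder") versus non-territorial ("floater") — by a deterministic rule
cascade built on three ingredients: a migrant latitude rule (origin or
summer range north of 58.25 deg N), age in biological years (the biological
year starts in April, around hatching), and 95% kernel-density (KDE) summer
home ranges with a 200 km^2 territory threshold.  Winter fixes inside a
territory holder's governing summer home range, and early fixes near a
known natal site, are removed so the retained data represent use away from
breeding territories.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon
from shapely.ops import unary_union
from skimage import measure

from .grid import Grid
from .synthio import MIGRANT_LATITUDE

NATAL_RADIUS_M = 3_200.0
STUDY_EDGE_BUFFER_M = 16_000.0
TERRITORY_AREA_KM2 = 200.0
ADEQUATE_N = 25
ADEQUATE_SPAN_DAYS = 30.0

LABELS = [
    "adult_migrant",
    "adult_resident_breeder",
    "adult_resident_floater",
    "nonadult_resident",
    "nonadult_migrant",
]


class ClassificationError(ValueError):
    pass


@dataclass
class HomeRange:
    deployment_id: str
    season: str
    polygon: shapely.geometry.base.BaseGeometry | None
    area_km2: float
    n_points: int
    span_days: float
    level: float = 0.95

    @property
    def adequate(self) -> bool:
        return self.n_points >= ADEQUATE_N and self.span_days >= ADEQUATE_SPAN_DAYS


def _reference_bandwidth(v: np.ndarray) -> float:
    """Ad hoc (reference) bandwidth for one axis of a bivariate normal
    kernel: sigma * n^(-1/6)."""
    n = len(v)
    return float(np.std(v, ddof=1)) * n ** (-1.0 / 6.0)


def kde_home_range(
    x: np.ndarray,
    y: np.ndarray,
    deployment_id: str = "",
    season: str = "",
    span_days: float = np.nan,
    level: float = 0.95,
    smoothing_prop: float = 0.7,
    grid_cells: int = 256,
) -> HomeRange:
    """95% KDE home range with per-axis bandwidth = smoothing_prop x the
    bivariate-normal reference bandwidth.

    The density is evaluated on a ``grid_cells``-square raster (binned KDE:
    a 2-D histogram smoothed by a Gaussian of the kernel bandwidth), the
    isopleth is the smallest-density contour containing ``level`` of the
    total mass, and the polygon is extracted from that contour.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ClassificationError(f"{deployment_id}: <5 points, KDE inadequate")
    hx = max(smoothing_prop * _reference_bandwidth(x), 1e-6)
    hy = max(smoothing_prop * _reference_bandwidth(y), 1e-6)
    pad = 4.0 * max(hx, hy)
    xmin, xmax = x.min() - pad, x.max() + pad
    ymin, ymax = y.min() - pad, y.max() + pad
    res = max((xmax - xmin), (ymax - ymin)) / grid_cells
    nx = max(int(np.ceil((xmax - xmin) / res)), 8)
    ny = max(int(np.ceil((ymax - ymin) / res)), 8)
    H, xe, ye = np.histogram2d(x, y, bins=[nx, ny], range=[[xmin, xmax], [ymin, ymax]])
    dens = gaussian_filter(H, sigma=(hx / res, hy / res), mode="constant")
    dens = dens / dens.sum()
    # smallest density threshold whose superlevel set holds `level` mass
    flat = np.sort(dens.ravel())[::-1]
    cum = np.cumsum(flat)
    k = int(np.searchsorted(cum, level))
    thr = flat[min(k, len(flat) - 1)]
    inside = dens >= thr
    area_km2 = inside.sum() * (res / 1000.0) ** 2
    padded = np.pad(dens, 1, mode="constant")
    contours = measure.find_contours(padded, thr)
    polys = []
    for cont in contours:
        # contour coords are (ix, iy) on the padded histogram grid
        cx = xmin + (cont[:, 0] - 1 + 0.5) * res
        cy = ymin + (cont[:, 1] - 1 + 0.5) * res
        if len(cx) >= 4:
            p = Polygon(np.column_stack([cx, cy]))
            if p.is_valid and p.area > 0:
                polys.append(p)
    polygon = unary_union(polys) if polys else None
    return HomeRange(
        deployment_id=deployment_id,
        season=season,
        polygon=polygon,
        area_km2=float(area_km2),
        n_points=len(x),
        span_days=float(span_days),
        level=level,
    )


def _biological_year(d: date) -> int:
    return d.year if d.month >= 4 else d.year - 1


def assign_age_class(tag_date: date, age_at_tagging: float, on_date: date) -> tuple[int, str]:
    """Age (biological years, April start) and class at ``on_date``."""
    if tag_date is None or age_at_tagging is None or not np.isfinite(age_at_tagging):
        raise ClassificationError("missing tagging date or age metadata")
    age = int(age_at_tagging) + _biological_year(on_date) - _biological_year(tag_date)
    return age, ("adult" if age >= 4 else "nonadult")


def _points_in_polygon(poly, x, y) -> np.ndarray:
    if poly is None or poly.is_empty:
        return np.zeros(len(x), dtype=bool)
    return shapely.contains_xy(poly, x, y)


def classify_and_filter(
    meta_row: pd.Series,
    winter: pd.DataFrame,
    summer: pd.DataFrame,
    study_area,
    crs,
) -> tuple[str | None, pd.DataFrame, str]:
    """Classify one deployment and filter its winter fixes.

    Returns ``(label, retained winter fixes, note)``; ``label`` is None when
    the individual is removed entirely (the note carries the reason).  The
    cascade, in order: (1) migrants by the 58.25 N origin/summer-range rule;
    (2) natal-site removals for nestling-tagged birds and the conservative
    unknown-natal first-year rule; (3) 2-3-year-olds kept outright;
    (4, 5) adults partitioned by summer home-range location and size into
    non-territorial birds, territory holders (in-range winter fixes
    removed), and floaters.
    """
    dep = str(meta_row["deployment_id"])
    tag_date = pd.Timestamp(meta_row["tag_date"]).date()
    age_at_tagging = meta_row["age_at_tagging"]
    nestling = bool(meta_row.get("tagged_as_nestling", False))
    if nestling and age_at_tagging >= 4:
        raise ClassificationError(f"{dep}: tagged as nestling but adult-aged at tagging")
    winter = winter.copy()
    if len(winter) == 0:
        return None, winter, "no winter fixes"
    ref_date = winter["timestamp"].iloc[0].date()
    age, age_class = assign_age_class(tag_date, age_at_tagging, ref_date)

    # study-area clip applies to every retained set
    in_area = _points_in_polygon(study_area, winter["x"].to_numpy(), winter["y"].to_numpy())
    winter = winter.loc[in_area]
    if len(winter) == 0:
        return None, winter, "no winter fixes in study area"

    def summer_range(points: pd.DataFrame) -> HomeRange | None:
        if len(points) < 5:
            return None
        span = (points["timestamp"].max() - points["timestamp"].min()).total_seconds() / 86400
        return kde_home_range(
            points["x"].to_numpy(), points["y"].to_numpy(), dep, "summer", span_days=span
        )

    # -- rule 1: migrants ---------------------------------------------------
    origin_north = float(meta_row.get("tag_lat", np.nan)) > MIGRANT_LATITUDE
    summer_centroid_north = len(summer) > 0 and float(summer["lat"].mean()) > MIGRANT_LATITUDE
    if origin_north or summer_centroid_north:
        return f"{'adult' if age_class == 'adult' else 'nonadult'}_migrant", winter, "migrant rule"

    # -- rule 2: natal-site handling ---------------------------------------
    if nestling and np.isfinite(meta_row.get("natal_lat", np.nan)):
        nx, ny = crs.forward(meta_row["natal_lon"], meta_row["natal_lat"])
        within_year = winter["timestamp"] <= pd.Timestamp(tag_date, tz="UTC") + pd.Timedelta(days=365)
        near_natal = (
            np.hypot(winter["x"].to_numpy() - nx, winter["y"].to_numpy() - ny) <= NATAL_RADIUS_M
        )
        winter = winter.loc[~(within_year.to_numpy() & near_natal)]
        if age_class == "nonadult":
            return "nonadult_resident", winter, "nestling natal rule"
    elif age_at_tagging == 0 and not np.isfinite(meta_row.get("natal_lat", np.nan)):
        s_hr = summer_range(summer)
        w_hr = (
            kde_home_range(winter["x"].to_numpy(), winter["y"].to_numpy(), dep, "winter")
            if len(winter) >= 5
            else None
        )
        if (
            s_hr is not None
            and w_hr is not None
            and s_hr.polygon is not None
            and w_hr.polygon is not None
            and s_hr.polygon.intersects(w_hr.polygon)
            and s_hr.area_km2 < TERRITORY_AREA_KM2
            and w_hr.area_km2 < TERRITORY_AREA_KM2
        ):
            return None, winter.iloc[0:0], "unknown natal, overlapping small seasonal ranges"
        if age_class == "nonadult":
            return "nonadult_resident", winter, "unknown natal, ranges distinct"

    # -- rule 3: 2-3-year-olds not tagged as nestlings ----------------------
    if age_class == "nonadult":
        return "nonadult_resident", winter, "young non-adult"

    # -- rules 4-5: adults -------------------------------------------------
    if len(summer) == 0:
        return "adult_resident_floater", winter, "no summer data; treated as non-territorial"
    sdist = _distance_to_area(study_area, summer["x"].to_numpy(), summer["y"].to_numpy())
    if np.all(sdist > STUDY_EDGE_BUFFER_M):
        return "adult_resident_floater", winter, "summer range far outside study area"
    s_hr = summer_range(summer)
    if s_hr is None or not s_hr.adequate:
        return None, winter.iloc[0:0], "inadequate summer data for territory assessment"
    if s_hr.area_km2 < TERRITORY_AREA_KM2:
        inside = _points_in_polygon(s_hr.polygon, winter["x"].to_numpy(), winter["y"].to_numpy())
        return "adult_resident_breeder", winter.loc[~inside], "territory holder; in-range fixes removed"
    return "adult_resident_floater", winter, "large summer range; floater"


def _distance_to_area(study_area, x, y) -> np.ndarray:
    """Distance (m) from points to the study-area polygon (0 inside)."""
    pts = shapely.points(x, y)
    return shapely.distance(study_area, pts)


def classify_all(
    winter: pd.DataFrame,
    summer: pd.DataFrame,
    meta: pd.DataFrame,
    study_area,
    crs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the cascade for every deployment.

    Returns ``(labels, retained)`` where ``labels`` has one row per
    deployment (label or removal note) and ``retained`` is the winter fix
    table annotated with a ``group`` column.
    """
    label_rows = []
    kept = []
    for _, m in meta.iterrows():
        dep = str(m["deployment_id"])
        w = winter.loc[winter["deployment_id"] == dep]
        s = summer.loc[summer["deployment_id"] == dep]
        label, retained, note = classify_and_filter(m, w, s, study_area, crs)
        label_rows.append(
            {"deployment_id": dep, "group": label, "note": note,
             "n_winter_in": len(w), "n_winter_kept": len(retained)}
        )
        if label is not None and len(retained):
            retained = retained.copy()
            retained["group"] = label
            kept.append(retained)
    labels = pd.DataFrame(label_rows)
    retained_all = (
        pd.concat(kept).sort_index()
        if kept
        else winter.iloc[0:0].assign(group=pd.Series(dtype=object))
    )
    return labels, retained_all
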