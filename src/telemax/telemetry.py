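"""Telemetry proofing, standardisation, and behavioural filtering.

The filtering ladder (applied in this order) mirrors standard practice for
satellite-tracked raptors:

1.  proofing — Argos location-class screen, spike (angle/length) removal,
    and a velocity filter;
    then temporal standardisation to at most one fix per hour;
2.  season and time-of-day selection: daytime winter fixes for modelling,
    with summer fixes kept aside for home-range estimation;
4.  behavioural state: residence-in-space-and-time (RST) segmentation of
    tracking bouts into sedentary vs transit fixes;
5.  temporal thinning to two fixes per individual-day (one each side of
    local solar noon, at least an hour apart);
6.  a random 75/25 train/test split.

(Step 3, life-history classification, lives in :mod:`telemax.lifehistory`.)
Every filter only removes rows — coordinates and timestamps are never
altered — and each removal records the first rule that fired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solar

WINTER_MONTHS = (12, 1, 2)
SUMMER_MONTHS = (6, 7, 8)


@dataclass
class FilterParams:
    """Shared filtering constants.

    spike_rules: (max angle deg, min leg length m) pairs — a fix is a spike
    when its turn angle is below the angle bound AND both adjacent legs
    exceed the length bound.
    """

    spike_rules: tuple = ((15.0, 2500.0), (25.0, 5000.0))
    velocity_candidates: tuple = (20.0, 27.8, 40.0)
    vmax: float = 27.8  # m/s
    daytime_margin_h: float = 1.0
    rst_radius_m: float = 30_000.0
    rst_radius_candidates: tuple = (6_000.0, 10_500.0, 15_000.0, 22_500.0, 30_000.0)
    bout_min_days: float = 28.0
    bout_max_gap_h: float = 48.0
    thin_min_separation_h: float = 1.0
    train_frac: float = 0.75

    def __post_init__(self):
        if not (0.0 < self.train_frac < 1.0):
            raise ValueError("train fraction must be in (0, 1)")
        for v in (self.vmax, self.rst_radius_m, self.bout_min_days, self.bout_max_gap_h):
            if v <= 0:
                raise ValueError("filter thresholds must be strictly positive")


@dataclass
class Bout:
    """A gap-free tracking segment of one deployment."""

    deployment_id: str
    fixes: pd.DataFrame
    start: pd.Timestamp
    end: pd.Timestamp


def _split(fixes: pd.DataFrame, keep: np.ndarray, reason: str):
    removed = fixes.loc[~keep].copy()
    removed["removal_reason"] = reason
    return fixes.loc[keep].copy(), removed


# ------------------------------------------------------------- step 1


def argos_class_filter(fixes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep GPS fixes and Argos fixes of location class 3, 2, or 1."""
    if len(fixes) == 0:
        return fixes.copy(), fixes.iloc[0:0].assign(removal_reason=pd.Series(dtype=object))
    src = fixes["fix_type"]
    unknown = ~src.isin(["GPS", "Argos"])
    if unknown.any():
        raise ValueError(f"unknown fix source value(s): {sorted(src[unknown].unique())}")
    keep = (src == "GPS") | fixes["argos_class"].astype(str).isin(["3", "2", "1"])
    return _split(fixes, keep.to_numpy(), "argos_class")


def _turn_angles_and_legs(x: np.ndarray, y: np.ndarray):
    """Interior angle (deg) at each interior fix and adjacent leg lengths."""
    v1 = np.column_stack([x[:-2] - x[1:-1], y[:-2] - y[1:-1]])
    v2 = np.column_stack([x[2:] - x[1:-1], y[2:] - y[1:-1]])
    l1 = np.hypot(v1[:, 0], v1[:, 1])
    l2 = np.hypot(v2[:, 0], v2[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip((v1 * v2).sum(axis=1) / (l1 * l2), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    ang[(l1 == 0) | (l2 == 0)] = 180.0  # coincident points: no spike geometry
    return ang, l1, l2


def spike_filter(
    fixes: pd.DataFrame, rules=((15.0, 2500.0), (25.0, 5000.0))
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Iteratively remove out-and-back spikes.

    An interior fix is a spike when its turn angle is below a rule's angle
    bound and both adjacent legs exceed the rule's length bound.  The filter
    re-runs until no spike remains (removals expose new neighbours).
    """
    removed_parts = []
    kept_parts = []
    for dep, g in fixes.groupby("deployment_id", sort=False):
        g = g.sort_values("timestamp", kind="stable")
        if len(g) < 3:
            warnings.warn(f"deployment {dep}: <3 fixes, spike filter skipped")
            kept_parts.append(g)
            continue
        while True:
            x = g["x"].to_numpy()
            y = g["y"].to_numpy()
            if len(g) < 3:
                break
            ang, l1, l2 = _turn_angles_and_legs(x, y)
            spike = np.zeros(len(g), dtype=bool)
            for amax, lmin in rules:
                spike[1:-1] |= (ang < amax) & (l1 > lmin) & (l2 > lmin)
            if not spike.any():
                break
            # remove the worst spike per pass to keep neighbour geometry honest
            interior = np.where(spike)[0]
            drop = g.index[interior]
            removed_parts.append(g.loc[drop].assign(removal_reason="spike"))
            g = g.drop(index=drop)
        kept_parts.append(g)
    kept = pd.concat(kept_parts) if kept_parts else fixes.iloc[0:0].copy()
    removed = (
        pd.concat(removed_parts)
        if removed_parts
        else fixes.iloc[0:0].assign(removal_reason=pd.Series(dtype=object))
    )
    return kept.sort_index(), removed.sort_index()


def velocity_filter(fixes: pd.DataFrame, vmax: float = 27.8) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Greedy forward pass: drop fixes implying speed > vmax from the last
    retained fix.  Duplicate timestamps keep the first occurrence."""
    kept_idx = []
    removed_idx = []
    for dep, g in fixes.groupby("deployment_id", sort=False):
        g = g.sort_values("timestamp", kind="stable")
        t = g["timestamp"].to_numpy()
        x = g["x"].to_numpy()
        y = g["y"].to_numpy()
        last = 0
        kept_idx.append(g.index[0])
        for i in range(1, len(g)):
            dt = (t[i] - t[last]) / np.timedelta64(1, "s")
            if dt <= 0:
                warnings.warn(f"deployment {dep}: duplicate timestamp, keeping first")
                removed_idx.append(g.index[i])
                continue
            speed = np.hypot(x[i] - x[last], y[i] - y[last]) / dt
            if speed > vmax:
                removed_idx.append(g.index[i])
            else:
                kept_idx.append(g.index[i])
                last = i
    kept = fixes.loc[sorted(kept_idx)].copy() if kept_idx else fixes.iloc[0:0].copy()
    removed = fixes.loc[sorted(removed_idx)].copy()
    removed["removal_reason"] = "velocity"
    return kept, removed


def hourly_subsample(fixes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """At most one fix per deployment per UTC clock-hour (earliest kept)."""
    if len(fixes) == 0:
        return fixes.copy(), fixes.iloc[0:0].assign(removal_reason=pd.Series(dtype=object))
    f = fixes.sort_values(["deployment_id", "timestamp"], kind="stable")
    hour = f["timestamp"].dt.floor("h")
    first = ~pd.DataFrame({"d": f["deployment_id"], "h": hour}).duplicated()
    keep = pd.Series(first.to_numpy(), index=f.index).reindex(fixes.index).to_numpy()
    return _split(fixes, keep, "hourly_subsample")


# ------------------------------------------------------------- step 2


def attribute_solar(fixes: pd.DataFrame) -> pd.DataFrame:
    """Annotate fixes with sunrise/sunset/solar-noon (minutes after 00:00
    UTC of the fix's UTC date) and minutes-of-day of the fix itself."""
    out = fixes.copy()
    ts = out["timestamp"]
    doy = ts.dt.dayofyear.to_numpy()
    rise, sett, noon = solar.sunrise_sunset_minutes(
        out["lat"].to_numpy(), out["lon"].to_numpy(), doy
    )
    out["sunrise_min"] = rise
    out["sunset_min"] = sett
    out["solar_noon_min"] = noon
    out["minute_of_day"] = (
        ts.dt.hour * 60 + ts.dt.minute + ts.dt.second / 60.0
    ).to_numpy()
    return out


def season_daytime_filter(
    fixes: pd.DataFrame, margin_h: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split into the winter daytime modelling set and the summer set.

    Returns ``(winter_daytime, summer_all, removed)``.  Winter fixes
    (Dec-Feb) survive when they fall within [sunrise + margin, sunset -
    margin]; summer fixes (Jun-Aug) are all kept, in a separate frame, for
    home-range estimation; everything else is removed with a season reason.
    """
    f = attribute_solar(fixes)
    month = f["timestamp"].dt.month
    is_winter = month.isin(WINTER_MONTHS).to_numpy()
    is_summer = month.isin(SUMMER_MONTHS).to_numpy()
    m = margin_h * 60.0
    day_ok = (
        (f["minute_of_day"] >= f["sunrise_min"] + m)
        & (f["minute_of_day"] <= f["sunset_min"] - m)
    ).to_numpy() & np.isfinite(f["sunrise_min"].to_numpy())
    winter = f.loc[is_winter & day_ok].copy()
    summer = f.loc[is_summer].copy()
    removed = f.loc[~(is_winter & day_ok) & ~is_summer].copy()
    removed["removal_reason"] = np.where(
        is_winter[~(is_winter & day_ok) & ~is_summer], "night_or_twilight", "off_season"
    )
    return winter, summer, removed


# ------------------------------------------------------------- step 4


def segment_bouts(
    fixes: pd.DataFrame, min_days: float = 28.0, max_gap_h: float = 48.0
) -> list[Bout]:
    """Split each deployment at gaps > max_gap_h; keep segments spanning at
    least min_days.  Discontinuous segments are treated as separate bouts."""
    bouts = []
    for dep, g in fixes.groupby("deployment_id", sort=False):
        g = g.sort_values("timestamp", kind="stable")
        t = g["timestamp"]
        gap = t.diff() > pd.Timedelta(hours=max_gap_h)
        seg_id = gap.cumsum()
        for _, seg in g.groupby(seg_id):
            span = (seg["timestamp"].iloc[-1] - seg["timestamp"].iloc[0]).total_seconds() / 86400
            if span >= min_days:
                bouts.append(
                    Bout(
                        deployment_id=dep,
                        fixes=seg.copy(),
                        start=seg["timestamp"].iloc[0],
                        end=seg["timestamp"].iloc[-1],
                    )
                )
    return bouts


def _residence_time_distance(x, y, t_s, radius):
    """Residence time (s) and path distance (m) within the circle of the
    given radius centred on every fix, via exact segment-circle clipping."""
    n = len(x)
    dx = np.diff(x)
    dy = np.diff(y)
    seg_len = np.hypot(dx, dy)
    seg_dt = np.diff(t_s)
    time_in = np.empty(n)
    dist_in = np.empty(n)
    r2 = radius * radius
    for i in range(n):
        # fraction of each segment inside the circle centred at fix i
        fx = x[:-1] - x[i]
        fy = y[:-1] - y[i]
        a = seg_len**2
        b = 2.0 * (fx * dx + fy * dy)
        c = fx * fx + fy * fy - r2
        disc = b * b - 4 * a * c
        frac = np.zeros(n - 1)
        deg = a == 0
        frac[deg & (c <= 0)] = 1.0  # zero-length segment at a point inside
        ok = (~deg) & (disc > 0)
        sq = np.sqrt(np.where(ok, disc, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.clip((-b - sq) / (2 * a), 0.0, 1.0)
            t2 = np.clip((-b + sq) / (2 * a), 0.0, 1.0)
        frac[ok] = (t2 - t1)[ok]
        time_in[i] = float(np.sum(frac * seg_dt))
        dist_in[i] = float(np.sum(frac * seg_len))
    return time_in, dist_in


def _norm01(v: np.ndarray) -> np.ndarray:
    """Normalise nonnegative residence values to [0,1] by the bout maximum.

    Residence time and distance have a natural zero (a point the track
    only brushes), so the scale is anchored there rather than at the
    within-bout minimum; subtracting the minimum would erase the sign
    structure of the residual whenever a bout contains no true transit.
    """
    hi = v.max()
    return v / hi if hi > 0 else np.zeros_like(v)


def rst_classify(bout: Bout, radius_m: float = 30_000.0) -> pd.DataFrame:
    """Residence-in-space-and-time segmentation of one bout.

    For every fix, residence time is the total track time spent within the
    circle of the given radius centred on the fix, and residence distance
    the path length within it.  Both are min-max normalised within the
    bout; the residual (normalised time - normalised distance) is negative
    for distance-intensive (transit) fixes and non-negative for sedentary
    ones (time-intensive and time-and-distance-intensive pooled).
    """
    if radius_m <= 0:
        raise ValueError("RST radius must be positive")
    g = bout.fixes.sort_values("timestamp", kind="stable")
    x = g["x"].to_numpy()
    y = g["y"].to_numpy()
    t_s = (g["timestamp"] - g["timestamp"].iloc[0]).dt.total_seconds().to_numpy()
    time_in, dist_in = _residence_time_distance(x, y, t_s, radius_m)
    resid = _norm01(time_in) - _norm01(dist_in)
    out = g.copy()
    out["rst_residual"] = resid
    out["behavior"] = np.where(resid < 0, "transit", "sedentary")
    return out


def behavioral_filter(
    fixes: pd.DataFrame, params: FilterParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply bout segmentation + RST and keep sedentary fixes only.

    Fixes outside any valid bout are removed with reason ``short_bout``;
    transit fixes with reason ``transit``.
    """
    bouts = segment_bouts(fixes, params.bout_min_days, params.bout_max_gap_h)
    classified = [rst_classify(b, params.rst_radius_m) for b in bouts]
    if classified:
        allc = pd.concat(classified)
        kept = allc.loc[allc["behavior"] == "sedentary"].copy()
        transit = allc.loc[allc["behavior"] == "transit"].copy()
        transit["removal_reason"] = "transit"
    else:
        kept = fixes.iloc[0:0].copy()
        transit = fixes.iloc[0:0].assign(removal_reason=pd.Series(dtype=object))
    in_bout = (
        pd.concat([c[[]] for c in classified]).index if classified else pd.Index([])
    )
    short = fixes.loc[~fixes.index.isin(in_bout)].copy()
    short["removal_reason"] = "short_bout"
    removed = pd.concat([transit, short]).sort_index()
    return kept.sort_index(), removed


# ------------------------------------------------------------- step 5


def thin_two_per_day(
    fixes: pd.DataFrame, rng: np.random.Generator, min_separation_h: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two random fixes per individual-day: one before and one after local
    solar noon, at least ``min_separation_h`` apart.

    Local solar noon is computed per fix from its longitude.  If one
    half-day has no fixes, only the other contributes; if no compliant pair
    exists, a single random fix is retained.
    """
    if len(fixes) == 0:
        return fixes.copy(), fixes.iloc[0:0].assign(removal_reason=pd.Series(dtype=object))
    f = fixes
    if "solar_noon_min" not in f.columns:
        f = attribute_solar(f)
    # local solar date: shift clock by longitude so days split cleanly
    solar_ts = f["timestamp"] + pd.to_timedelta(f["lon"] / 15.0, unit="h")
    day = solar_ts.dt.date
    is_morning = (f["minute_of_day"] < f["solar_noon_min"]).to_numpy()
    sep = pd.Timedelta(hours=min_separation_h)
    keep_idx: list = []
    order = pd.DataFrame({"d": f["deployment_id"], "day": day})
    for (_, _), g in f.groupby([order["d"], order["day"]], sort=True):
        morn = g.index[is_morning[f.index.get_indexer(g.index)]]
        aft = g.index.difference(morn)
        if len(morn) and len(aft):
            m_order = list(rng.permutation(morn))
            chosen = None
            for m in m_order:
                tm = f.loc[m, "timestamp"]
                cand = [a for a in aft if abs(f.loc[a, "timestamp"] - tm) >= sep]
                if cand:
                    chosen = (m, cand[int(rng.integers(len(cand)))])
                    break
            if chosen is None:
                keep_idx.append(g.index[int(rng.integers(len(g)))])
            else:
                keep_idx.extend(chosen)
        elif len(morn) or len(aft):
            half = morn if len(morn) else aft
            keep_idx.append(half[int(rng.integers(len(half)))])
    keep = fixes.index.isin(keep_idx)
    return _split(fixes, keep, "thinned")


# ------------------------------------------------------------- step 6


def train_test_split(
    fixes: pd.DataFrame, frac: float = 0.75, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uniform random partition into train (frac) and test (1 - frac)."""
    rng = rng or np.random.default_rng(0)
    n = len(fixes)
    n_train = int(round(frac * n))
    perm = rng.permutation(n)
    train = fixes.iloc[np.sort(perm[:n_train])].copy()
    test = fixes.iloc[np.sort(perm[n_train:])].copy()
    return train, test
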