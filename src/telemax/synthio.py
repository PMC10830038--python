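"""Synthetic telemetry, covariate fields, and ground-truth intensity.

This module emulates the study conditions of a winter-season raptor
tracking programme: smooth spatially autocorrelated environmental fields in
six variable categories, a known log-linear ground-truth intensity surface,
and serially autocorrelated GPS/Argos movement tracks for the four
life-history groups (adult/non-adult x migrant/non-migrant, with resident
adults split into territory-holding "breeders" and non-territorial
"floaters").  The generative model is deliberately simple — Gaussian
filtered noise fields and a two-state (sedentary/transit) biased correlated
random walk — because it yields unambiguous truth labels for every
downstream classifier while still producing realistic autocorrelation,
multicollinearity, observation error, and outliers.

Nothing here attempts realistic raptor energetics or demography.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grid import Grid, LambertAzimuthalEqualArea, LayerMeta, Raster, RasterStack

CATEGORIES = [
    "climate_weather",
    "vegetation_landcover",
    "developed",
    "topography",
    "wind_uplift",
]

GROUPS = [
    "adult_migrant",
    "adult_resident_breeder",
    "adult_resident_floater",
    "nonadult_resident",
    "nonadult_migrant",
]

# deployment counts per life-history group matching the source tracking
# programme's winter sample (54/60/44/74/36 deployments)
DEFAULT_GROUP_COUNTS = {
    "adult_migrant": 54,
    "adult_resident_breeder": 60,
    "adult_resident_floater": 44,
    "nonadult_resident": 74,
    "nonadult_migrant": 36,
}

MIGRANT_LATITUDE = 58.25  # degrees N; migrant origin / summer-range rule


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Configuration of one synthetic study.

    The seed fully determines every output (fields, tracks, labels).
    """

    nrows: int = 3000
    ncols: int = 3000
    resolution: float = 120.0  # m
    crs: LambertAzimuthalEqualArea = field(default_factory=LambertAzimuthalEqualArea)
    n_per_category: dict = field(default_factory=lambda: {c: 2 for c in CATEGORIES})
    n_ecoregions: int = 3
    smoothing_cells: float = 10.0
    intra_category_corr: float = 0.6
    true_betas: dict = field(default_factory=lambda: {"wind_uplift_1": 1.5})
    group_counts: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_COUNTS))
    fixes_per_hour: float = 1.0
    winter_start: date = date(2018, 12, 1)
    winter_end: date = date(2019, 2, 28)
    summer_start: date = date(2018, 6, 1)
    summer_end: date = date(2018, 8, 31)
    outlier_rate: float = 0.005
    argos_fraction: float = 0.09
    argos_class_mix: dict = field(
        default_factory=lambda: {"3": 0.25, "2": 0.25, "1": 0.25, "0": 0.1, "A": 0.1, "B": 0.05}
    )
    # movement-model knobs
    sedentary_sigma_m: float = 1500.0
    sedentary_rho: float = 0.9
    transit_speed_ms: float = 10.0
    n_winter_patches: int = 2
    min_patch_separation_m: float = 100_000.0
    attraction: float = 1.0  # exponent on truth intensity when drawing patch centres
    seed: int = 0

    def __post_init__(self):
        if self.resolution <= 0:
            raise ConfigError("resolution must be positive")
        if self.nrows <= 0 or self.ncols <= 0:
            raise ConfigError("grid dimensions must be positive")
        if not any(b != 0 for b in self.true_betas.values()):
            raise ConfigError("at least one true coefficient must be nonzero")

    @property
    def grid(self) -> Grid:
        w = self.ncols * self.resolution
        h = self.nrows * self.resolution
        return Grid(
            nrows=self.nrows,
            ncols=self.ncols,
            resolution=self.resolution,
            x0=-w / 2.0,
            y0=-h / 2.0,
            crs=self.crs,
        )


@dataclass
class TruthBundle:
    """Ground truth for parameter-recovery tests."""

    intensity: Raster  # sums to 1 over the grid
    betas: dict  # layer name -> true coefficient
    individuals: pd.DataFrame | None = None  # per-individual truth labels
    fix_labels: pd.DataFrame | None = None  # per-fix truth (state, outlier...)


# ------------------------------------------------------------- covariates


def _smooth_field(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma_cells, mode="reflect")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_covariate_stack(config: SimConfig) -> RasterStack:
    """Smooth, spatially autocorrelated base-variable fields plus a
    categorical ecoregion layer.

    Continuous layers are Gaussian-filtered white noise standardised to
    mean 0 / SD 1; fields within a category share a latent component
    (``intra_category_corr``) so that redundancy screening has something to
    remove.  The ecoregion layer bins a heavily smoothed field into
    ``n_ecoregions`` contiguous classes (integer codes 0..k-1).
    """
    grid = config.grid
    rng = np.random.default_rng(config.seed)
    stack = RasterStack(grid)
    shape = grid.shape
    for cat in CATEGORIES:
        n = int(config.n_per_category.get(cat, 0))
        if n <= 0:
            continue
        shared = _smooth_field(rng, shape, config.smoothing_cells)
        c = float(np.clip(config.intra_category_corr, 0.0, 1.0))
        for i in range(1, n + 1):
            own = _smooth_field(rng, shape, config.smoothing_cells)
            f = math.sqrt(c) * shared + math.sqrt(1.0 - c) * own if i > 1 else shared if n > 1 else own
            stack.add(
                f.copy(),
                LayerMeta(name=f"{cat}_{i}", base=f"{cat}_{i}", category=cat,
                          extent_m=config.resolution, statistic="mean"),
            )
    if config.n_ecoregions >= 2:
        eco_field = _smooth_field(rng, shape, config.smoothing_cells * 4)
        qs = np.quantile(eco_field, np.linspace(0, 1, config.n_ecoregions + 1)[1:-1])
        eco = np.digitize(eco_field, qs).astype(float)
        stack.add(
            eco,
            LayerMeta(name="ecoregion", base="ecoregion", category="ecoregion",
                      categorical=True),
        )
    for name in stack.names:
        if not np.all(np.isfinite(stack[name])):
            raise ConfigError(f"generated layer {name!r} contains non-finite values")
    return stack


def true_intensity(stack: RasterStack, betas: dict) -> Raster:
    """Ground-truth intensity: cell value proportional to exp(sum beta_j x_j),
    normalised to sum to 1 over the grid."""
    missing = [k for k in betas if k not in stack.names]
    if missing:
        raise KeyError(f"betas reference layers not in the stack: {missing}")
    z = np.zeros(stack.grid.shape)
    for name, b in betas.items():
        z = z + b * stack[name]
    if not np.all(np.isfinite(z)):
        raise OverflowError(
            "non-finite log-intensity; centre and scale the covariates before exponentiating"
        )
    z = z - z.max()  # overflow-safe; cancels in the normalisation
    w = np.exp(z)
    return Raster(stack.grid, w / w.sum())


def sample_presence_points(
    truth: Raster, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n points from the truth intensity (an inhomogeneous Poisson
    process conditioned on n), jittered uniformly within cells.

    Returns projected (x, y) arrays.
    """
    p = truth.data.ravel()
    idx = rng.choice(p.size, size=n, p=p / p.sum())
    r, c = np.unravel_index(idx, truth.data.shape)
    g = truth.grid
    x = g.x0 + (c + rng.random(n)) * g.resolution
    y = g.y0 + (g.nrows - r - rng.random(n)) * g.resolution
    return x, y


# ----------------------------------------------------------------- tracks


def _draw_patch_centers(rng, truth: Raster, k: int, min_sep: float, attraction: float,
                        margin_frac: float = 0.1) -> np.ndarray:
    """Winter-use patch centres drawn proportional to intensity^attraction,
    at least ``min_sep`` apart, away from the grid edge."""
    g = truth.grid
    p = np.power(truth.data, attraction)
    rr, cc = np.indices(g.shape)
    inner = (
        (rr > g.nrows * margin_frac) & (rr < g.nrows * (1 - margin_frac))
        & (cc > g.ncols * margin_frac) & (cc < g.ncols * (1 - margin_frac))
    )
    p = np.where(inner, p, 0.0).ravel()
    p = p / p.sum()
    centers = []
    for _ in range(200):
        idx = rng.choice(p.size, p=p)
        r, c = np.unravel_index(idx, g.shape)
        x = g.x0 + (c + 0.5) * g.resolution
        y = g.y0 + (g.nrows - r - 0.5) * g.resolution
        if all(math.hypot(x - cx, y - cy) >= min_sep for cx, cy in centers):
            centers.append((x, y))
        if len(centers) == k:
            break
    return np.array(centers if centers else [(0.0, 0.0)])


MAX_STEP_M = 2400.0  # per-fix displacement cap: below the spike-filter leg bound


def _ar1_cluster(rng, center, n, sigma, rho, start=None, max_step=MAX_STEP_M):
    """OU-like positions around a centre: AR(1) deviations per axis.

    Per-fix displacements are capped at ``max_step`` so that undisturbed
    sedentary movement can never trip the spike filter's leg-length rules;
    only injected outliers and Argos error create spike geometry.
    """
    out = np.empty((n, 2))
    center = np.asarray(center, dtype=float)
    d = (np.asarray(start) - center) if start is not None else rng.normal(0, sigma, 2)
    s = sigma * math.sqrt(1 - rho**2)
    prev = None
    for i in range(n):
        d = rho * d + rng.normal(0, s, 2)
        cand = center + d
        if prev is not None:
            step = cand - prev
            norm = math.hypot(step[0], step[1])
            if norm > max_step:
                cand = prev + step / norm * max_step
                d = cand - center
        out[i] = cand
        prev = cand
    return out




def _season_times(start: date, end: date, fixes_per_hour: float) -> pd.DatetimeIndex:
    step = pd.Timedelta(seconds=3600.0 / fixes_per_hour)
    return pd.date_range(
        pd.Timestamp(start, tz="UTC"), pd.Timestamp(end, tz="UTC") + pd.Timedelta(hours=23),
        freq=step,
    )


def _simulate_winter(rng, cfg: SimConfig, truth: Raster, times) -> tuple[np.ndarray, np.ndarray]:
    """Two-state movement over one winter. Returns (positions, is_transit).

    Individuals dwell around intensity-weighted patch centres (AR(1)
    jitter) and relocate between patches via directed constant-speed legs.
    Transit movement happens only during daytime hours (a window around
    local solar noon at the projection centre); overnight the bird holds
    position mid-journey.
    """
    centers = _draw_patch_centers(
        rng, truth, cfg.n_winter_patches, cfg.min_patch_separation_m, cfg.attraction
    )
    n = len(times)
    dt_s = 3600.0 / cfg.fixes_per_hour
    k = len(centers)
    noon_utc_h = (12.0 - truth.grid.crs.lon0 / 15.0) % 24.0
    hour = times.hour.to_numpy() + times.minute.to_numpy() / 60.0
    is_day = np.abs((hour - noon_utc_h + 12.0) % 24.0 - 12.0) <= 4.0
    bounds = np.linspace(0, n, k + 1).astype(int)  # dwell blocks per patch
    pos = np.empty((n, 2))
    transit = np.zeros(n, dtype=bool)
    sigma_step = cfg.sedentary_sigma_m * math.sqrt(1.0 - cfg.sedentary_rho**2)
    patch = 0
    mode = "sedentary"
    dev = rng.normal(0, cfg.sedentary_sigma_m, 2)
    cur = centers[0] + dev
    for i in range(n):
        if mode == "sedentary" and patch + 1 < k and i >= bounds[patch + 1]:
            mode = "transit"
        if mode == "transit":
            target = centers[patch + 1]
            if is_day[i]:
                vec = target - cur
                dist = math.hypot(vec[0], vec[1])
                step = cfg.transit_speed_ms * dt_s
                if dist <= step:  # arrival
                    patch += 1
                    mode = "sedentary"
                    dev = cur - centers[patch]
                else:
                    cur = cur + vec / dist * step
            pos[i] = cur
            transit[i] = mode == "transit"
            if mode == "transit":
                continue
        # sedentary AR(1) around the current patch centre, step-capped
        dev = cfg.sedentary_rho * dev + rng.normal(0, sigma_step, 2)
        cand = centers[patch] + dev
        step = cand - cur
        norm = math.hypot(step[0], step[1])
        if norm > MAX_STEP_M:
            cand = cur + step / norm * MAX_STEP_M
            dev = cand - centers[patch]
        cur = cand
        pos[i] = cur
    return pos, transit


def _apply_observation_error(rng, cfg: SimConfig, df: pd.DataFrame) -> pd.DataFrame:
    """Assign GPS/Argos source, displace Argos fixes by class-specific radii,
    and inject spike outliers."""
    n = len(df)
    is_argos = rng.random(n) < cfg.argos_fraction
    classes = np.array(list(cfg.argos_class_mix))
    probs = np.array(list(cfg.argos_class_mix.values()), dtype=float)
    probs = probs / probs.sum()
    cls = np.where(is_argos, rng.choice(classes, size=n, p=probs), "")
    radii = {"3": (0, 250), "2": (250, 500), "1": (500, 1500),
             "0": (1500, 5000), "A": (1500, 5000), "B": (1500, 5000)}
    dx = np.zeros(n)
    dy = np.zeros(n)
    for c, (lo, hi) in radii.items():
        m = cls == c
        if m.any():
            r = rng.uniform(lo, hi, m.sum())
            th = rng.uniform(0, 2 * math.pi, m.sum())
            dx[m] = r * np.cos(th)
            dy[m] = r * np.sin(th)
    out = rng.random(n) < cfg.outlier_rate
    if out.any():
        r = rng.uniform(5000, 15000, out.sum())
        th = rng.uniform(0, 2 * math.pi, out.sum())
        dx[out] += r * np.cos(th)
        dy[out] += r * np.sin(th)
    df = df.copy()
    df["x"] = df["x"] + dx
    df["y"] = df["y"] + dy
    df["fix_type"] = np.where(is_argos, "Argos", "GPS")
    df["argos_class"] = cls
    df["true_outlier"] = out
    return df


def generate_tracks(config: SimConfig, truth: TruthBundle):
    """Simulate all individuals of all life-history groups.

    Returns ``(fixes, meta, truth)`` where ``fixes`` is the telemetry table
    (one row per fix, with lon/lat, projected x/y, source and class, and
    hidden truth columns), ``meta`` is per-deployment metadata (tag date,
    age at tagging, natal site), and ``truth`` is the input bundle with
    ``individuals`` and ``fix_labels`` filled in.
    """
    if sum(config.group_counts.get(g, 0) for g in GROUPS) <= 0:
        raise ConfigError("at least one individual must be simulated")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    grid = truth.intensity.grid
    crs = grid.crs
    winter_times = _season_times(config.winter_start, config.winter_end, config.fixes_per_hour)
    summer_times = _season_times(config.summer_start, config.summer_end, config.fixes_per_hour)

    all_fixes = []
    meta_rows = []
    indiv_rows = []
    prefix = {
        "adult_migrant": "AM",
        "adult_resident_breeder": "RB",
        "adult_resident_floater": "RF",
        "nonadult_resident": "NR",
        "nonadult_migrant": "NM",
    }
    tag_year = config.winter_start.year
    for group in GROUPS:
        for i in range(int(config.group_counts.get(group, 0))):
            dep = f"{prefix[group]}{i:03d}"
            wpos, wtransit = _simulate_winter(rng, config, truth.intensity, winter_times)
            rows = [
                pd.DataFrame(
                    {
                        "deployment_id": dep,
                        "timestamp": winter_times,
                        "x": wpos[:, 0],
                        "y": wpos[:, 1],
                        "true_state": np.where(wtransit, "transit", "sedentary"),
                    }
                )
            ]
            natal = (None, None)
            tagged_nestling = False
            if group == "adult_migrant" or group == "nonadult_migrant":
                # summer range far north of the migrant latitude rule
                north_lat = rng.uniform(60.0, 64.0)
                sx, sy = crs.forward(crs.lon0 + rng.uniform(-3, 3), north_lat)
                spos = _ar1_cluster(rng, (sx, sy), len(summer_times), 3000.0, config.sedentary_rho)
                age = int(rng.integers(5, 12)) if group == "adult_migrant" else int(rng.integers(1, 4))
                tag_lonlat = crs.inverse(sx, sy)
            elif group == "adult_resident_breeder":
                # compact summer territory (<200 km^2 95% KDE) inside the area
                terr = _draw_patch_centers(rng, truth.intensity, 1, 0.0, config.attraction)[0]
                spos = _ar1_cluster(rng, terr, len(summer_times), 2000.0, config.sedentary_rho)
                age = int(rng.integers(5, 15))
                tag_lonlat = crs.inverse(*terr)
                # winter partially reuses the territory: overwrite first dwell block centre
                nw = len(winter_times) // (2 * config.n_winter_patches)
                rows[0].loc[: nw - 1, ["x", "y"]] = _ar1_cluster(
                    rng, terr, nw, config.sedentary_sigma_m, config.sedentary_rho
                )
            elif group == "adult_resident_floater":
                # sprawling non-territorial summer range (>200 km^2)
                c0 = _draw_patch_centers(rng, truth.intensity, 1, 0.0, config.attraction)[0]
                ns = len(summer_times)
                thirds = np.array_split(np.arange(ns), 3)
                spos = np.empty((ns, 2))
                for t, block in enumerate(thirds):
                    off = rng.uniform(-25_000, 25_000, 2)
                    spos[block] = _ar1_cluster(
                        rng, c0 + off, len(block), 8000.0, config.sedentary_rho
                    )
                age = int(rng.integers(5, 15))
                tag_lonlat = crs.inverse(*c0)
            else:  # nonadult_resident
                natal_xy = _draw_patch_centers(rng, truth.intensity, 1, 0.0, config.attraction)[0]
                tagged_nestling = i % 2 == 0
                age = 0 if tagged_nestling else int(rng.integers(2, 4))
                spos = None
                tag_lonlat = crs.inverse(*natal_xy)
                if tagged_nestling:
                    natal = tag_lonlat
            if spos is not None:
                rows.append(
                    pd.DataFrame(
                        {
                            "deployment_id": dep,
                            "timestamp": summer_times,
                            "x": spos[:, 0],
                            "y": spos[:, 1],
                            "true_state": "sedentary",
                        }
                    )
                )
            df = pd.concat(rows, ignore_index=True).sort_values("timestamp", kind="stable")
            df = _apply_observation_error(rng, config, df)
            lon, lat = crs.inverse(df["x"].to_numpy(), df["y"].to_numpy())
            df["lon"] = lon
            df["lat"] = lat
            all_fixes.append(df)
            meta_rows.append(
                {
                    "deployment_id": dep,
                    "tag_date": date(tag_year if age == 0 else tag_year - 0, 7, 1),
                    "age_at_tagging": age,
                    "tagged_as_nestling": tagged_nestling,
                    "tag_lon": float(tag_lonlat[0]),
                    "tag_lat": float(tag_lonlat[1]),
                    "natal_lon": float(natal[0]) if natal[0] is not None else np.nan,
                    "natal_lat": float(natal[1]) if natal[1] is not None else np.nan,
                }
            )
            indiv_rows.append({"deployment_id": dep, "true_group": group})

    fixes = pd.concat(all_fixes, ignore_index=True)
    fixes = fixes.sort_values(["deployment_id", "timestamp"], kind="stable").reset_index(drop=True)
    meta = pd.DataFrame(meta_rows)
    truth.individuals = pd.DataFrame(indiv_rows)
    truth.fix_labels = fixes[["deployment_id", "timestamp", "true_state", "true_outlier"]].copy()
    return fixes, meta, truth


def simulate(config: SimConfig):
    """Convenience wrapper: stack, truth surface, and tracks in one call."""
    stack = generate_covariate_stack(config)
    truth = TruthBundle(intensity=true_intensity(stack, config.true_betas), betas=dict(config.true_betas))
    fixes, meta, truth = generate_tracks(config, truth)
    return stack, truth, fixes, meta
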