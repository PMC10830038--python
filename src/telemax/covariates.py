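"""Multi-scale focal covariates and the two screening stages.

Base rasters are summarised over circular moving windows at a ladder of
spatial extents (window diameters) with mean/SD/min/max focal statistics.
Candidate layers per base variable are then screened by the ratio of their
mean at training locations to their mean at random locations, and the
survivors de-duplicated within variable categories by iterative variance
inflation factor (VIF) removal.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import Grid, LayerMeta, RasterStack

EXTENT_LADDER_M = (120.0, 500.0, 1000.0, 2000.0, 3200.0, 6400.0)
FOCAL_STATS = ("mean", "sd", "min", "max")

_STAT_PREFERENCE = {"mean": 0, "sd": 1, "min": 2, "max": 2}


def _disk_footprint(radius_cells: float) -> np.ndarray:
    """Boolean footprint of cells whose centres lie within the radius."""
    r = int(np.floor(radius_cells))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= radius_cells**2 + 1e-9


def focal_summarize(base: np.ndarray, grid: Grid, extent_m: float, statistic: str) -> np.ndarray:
    """Focal statistic over a circular window of diameter ``extent_m``.

    At the native extent (one cell) every statistic except SD is the
    identity.  Edge cells are summarised over the window's intersection
    with the grid (the grid is expected to already include the analysis
    buffer).
    """
    if extent_m < grid.resolution:
        raise ValueError(f"extent {extent_m} m is below the cell size {grid.resolution} m")
    if statistic not in FOCAL_STATS:
        raise ValueError(f"unknown focal statistic {statistic!r}")
    radius_cells = extent_m / (2.0 * grid.resolution)
    fp = _disk_footprint(radius_cells)
    data = np.asarray(base, dtype=float)
    valid = np.isfinite(data)
    filled = np.where(valid, data, 0.0)
    if statistic in ("mean", "sd"):
        k = fp.astype(float)
        cnt = ndimage.convolve(valid.astype(float), k, mode="constant", cval=0.0)
        s1 = ndimage.convolve(filled, k, mode="constant", cval=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = s1 / cnt
        if statistic == "mean":
            out = mean
        else:
            s2 = ndimage.convolve(filled**2, k, mode="constant", cval=0.0)
            with np.errstate(invalid="ignore"):
                var = np.maximum(s2 / cnt - mean**2, 0.0)
            out = np.sqrt(var)
    elif statistic == "min":
        out = ndimage.minimum_filter(np.where(valid, data, np.inf), footprint=fp,
                                     mode="constant", cval=np.inf)
        out = np.where(np.isfinite(out), out, np.nan)
    else:  # max
        out = ndimage.maximum_filter(np.where(valid, data, -np.inf), footprint=fp,
                                     mode="constant", cval=-np.inf)
        out = np.where(np.isfinite(out), out, np.nan)
    out = np.where(valid | (statistic in ("mean", "sd")), out, np.nan)
    return np.where(np.isfinite(out), out, np.nan)


def build_candidates(
    base_stack: RasterStack,
    extents=EXTENT_LADDER_M,
    statistics=FOCAL_STATS,
) -> RasterStack:
    """Expand each continuous base layer into its (extent, statistic)
    candidate set.  Categorical layers pass through unchanged."""
    out = RasterStack(base_stack.grid)
    for name in base_stack.names:
        meta = base_stack.meta(name)
        if meta.categorical:
            out.add(base_stack[name].copy(), meta)
            continue
        for ext in extents:
            if ext < base_stack.grid.resolution:
                continue
            for stat in statistics:
                if ext == base_stack.grid.resolution and stat != "mean":
                    continue  # identity window: min/max duplicate the mean, SD is 0
                layer = focal_summarize(base_stack[name], base_stack.grid, ext, stat)
                out.add(
                    layer,
                    LayerMeta(
                        name=f"{meta.base}__{int(ext)}m_{stat}",
                        base=meta.base,
                        category=meta.category,
                        extent_m=ext,
                        statistic=stat,
                    ),
                )
    return out


def _rescale01(v: np.ndarray) -> np.ndarray:
    lo = np.nanmin(v)
    hi = np.nanmax(v)
    return (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)


def select_best_scale(
    candidates: RasterStack,
    train_xy: tuple[np.ndarray, np.ndarray],
    n_random: int = 10_000,
    rng: np.random.Generator | None = None,
    area_mask: np.ndarray | None = None,
    tie_tolerance: float = 0.05,
    min_nonzero_frac: float = 0.2,
) -> RasterStack:
    """Keep one (extent, statistic) candidate per base variable.

    Each candidate is min-max rescaled to [0, 1] (the screen is then
    invariant to the layer's units) and scored by the ratio of its mean at
    training locations to its mean at ``n_random`` random locations in the
    modelled area.  Candidates where fewer than ``min_nonzero_frac`` of the
    training locations have non-zero values are discarded.  Near-ties
    (within ``tie_tolerance`` relative) go to mid-ladder extents and to the
    more interpretable statistic (mean over SD over min/max).  Categorical
    layers pass through unscreened.
    """
    rng = rng or np.random.default_rng(0)
    grid = candidates.grid
    if area_mask is None:
        area_mask = np.ones(grid.shape, dtype=bool)
    rows, cols = np.where(area_mask)
    pick = rng.integers(0, len(rows), size=n_random)
    rx = grid.x0 + (cols[pick] + rng.random(n_random)) * grid.resolution
    ry = grid.y0 + (grid.nrows - rows[pick] - rng.random(n_random)) * grid.resolution
    tx, ty = train_xy

    records = []
    by_base: dict[str, list] = {}
    for name in candidates.names:
        meta = candidates.meta(name)
        if meta.categorical:
            continue
        by_base.setdefault(meta.base, []).append(name)

    chosen = []
    extents_sorted = sorted({candidates.meta(n).extent_m for ns in by_base.values() for n in ns})
    mid = (len(extents_sorted) - 1) / 2.0
    for base, names in by_base.items():
        scored = []
        for name in names:
            meta = candidates.meta(name)
            layer01 = _rescale01(candidates[name])
            vals_train = grid.sample(layer01, tx, ty)
            vals_rand = grid.sample(layer01, rx, ry)
            vals_train = vals_train[np.isfinite(vals_train)]
            vals_rand = vals_rand[np.isfinite(vals_rand)]
            nonzero = np.mean(vals_train != 0.0) if len(vals_train) else 0.0
            denom = vals_rand.mean() if len(vals_rand) else 0.0
            if denom == 0.0:
                warnings.warn(f"candidate {name}: zero mean at random points, skipped")
                continue
            ratio = vals_train.mean() / denom
            screened = nonzero < min_nonzero_frac
            records.append(
                {"base": base, "candidate": name, "extent_m": meta.extent_m,
                 "statistic": meta.statistic, "ratio": ratio,
                 "nonzero_frac": nonzero, "screened_out": screened}
            )
            if not screened:
                scored.append((name, ratio, meta))
        if not scored:
            continue
        best_ratio = max(r for _, r, _ in scored)
        near = [s for s in scored if s[1] >= best_ratio * (1.0 - tie_tolerance)]
        # deterministic tie-break: prefer mid-ladder extents, then mean > SD > min/max
        def rank(s):
            _, ratio, meta = s
            e_rank = abs(extents_sorted.index(meta.extent_m) - mid)
            return (e_rank, _STAT_PREFERENCE.get(meta.statistic, 3), -ratio)

        chosen.append(min(near, key=rank)[0])

    out = candidates.subset(chosen)
    for name in candidates.names:
        if candidates.meta(name).categorical:
            out.add(candidates[name].copy(), candidates.meta(name))
    out.selection_report = pd.DataFrame.from_records(records)  # type: ignore[attr-defined]
    return out


def _vif(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1/(1-R^2_j) from regressing column j on the others (with
    intercept)."""
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_filter(
    stack: RasterStack,
    sample_xy: tuple[np.ndarray, np.ndarray],
    threshold: float = 4.0,
    group_by_category: bool = True,
    max_sample: int = 10_000,
    rng: np.random.Generator | None = None,
) -> tuple[RasterStack, pd.DataFrame]:
    """Iteratively drop the highest-VIF layer within each variable category
    until all VIFs are below the threshold.

    Layer values are taken at the supplied sample points (the model's
    background sample), subsampled to ``max_sample`` for speed.  Categorical
    layers are exempt.  Returns the surviving stack and a removal history.
    """
    rng = rng or np.random.default_rng(0)
    x, y = sample_xy
    if len(x) > max_sample:
        pick = rng.choice(len(x), size=max_sample, replace=False)
        x, y = x[pick], y[pick]
    history = []
    survivors = list(stack.names)
    groups: dict[str, list[str]] = {}
    for name in stack.names:
        meta = stack.meta(name)
        if meta.categorical:
            continue
        key = meta.category if group_by_category else "all"
        groups.setdefault(key, []).append(name)
    for cat, names in groups.items():
        names = list(names)
        while len(names) >= 2:
            M = stack.sample(names, x, y)
            ok = np.all(np.isfinite(M), axis=1)
            vifs = _vif(M[ok])
            worst = int(np.argmax(vifs))
            if vifs[worst] >= threshold:
                history.append({"category": cat, "removed": names[worst], "vif": vifs[worst]})
                if np.isinf(vifs[worst]):
                    warnings.warn(
                        f"perfectly collinear layer {names[worst]!r} removed from {cat}"
                    )
                survivors.remove(names[worst])
                names.pop(worst)
            else:
                break
    return stack.subset(survivors), pd.DataFrame(history, columns=["category", "removed", "vif"])
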