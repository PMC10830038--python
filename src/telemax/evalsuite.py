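"""Calibration and discrimination evaluation of intensity surfaces.

Everything is built on 10 equal-interval bins of the scaled intensity
surface: observed test-location counts per bin, predicted counts (the test
total shared out proportional to summed intensity), the squared Pearson
calibration R^2 between observed and predicted counts, area-adjusted
frequencies (AAF: a bin's share of locations over its share of area), the
Boyce index (Spearman rank correlation of AAF against bin rank, reported
squared), the AAF magnitude-of-difference ratio, repeated-holdout
cross-validation summaries, per-region calibration, and coarse-grid
quartile concordance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import Raster


@dataclass
class EvalBinTable:
    table: pd.DataFrame  # per-bin: area_km2, area_prop, observed, predicted, aaf
    r2: float
    boyce: float  # squared rank correlation, as reported
    boyce_raw: float  # signed rank correlation
    aaf_magnitude: float
    n_test: int


def bin_surface(surface: Raster, n_bins: int = 10):
    """Assign each valid cell to an equal-interval bin of [0, 1].

    Bin b covers ((b-1)/n, b/n]; bin 1 also includes 0.  Returns the bin
    map (0 = NoData) and per-bin areas (km^2).
    """
    v = surface.data
    valid = np.isfinite(v)
    bins = np.zeros(surface.grid.shape, dtype=int)
    b = np.ceil(np.clip(v[valid], 0.0, 1.0) * n_bins).astype(int)
    b[b == 0] = 1
    bins[valid] = b
    areas = np.array(
        [(bins == i).sum() * surface.grid.cell_area_km2 for i in range(1, n_bins + 1)]
    )
    return bins, areas


def observed_counts(surface: Raster, bins: np.ndarray, x, y, n_bins: int = 10) -> np.ndarray:
    """Count test locations per intensity bin (points on NoData excluded)."""
    b = surface.grid.sample(bins.astype(float), x, y, fill=0)
    b = b[np.isfinite(b)].astype(int)
    return np.bincount(b[b > 0], minlength=n_bins + 1)[1:]


def predicted_counts(surface: Raster, bins: np.ndarray, n_test: int, n_bins: int = 10) -> np.ndarray:
    """Share n_test out across bins proportional to the summed intensity."""
    v = surface.data
    valid = np.isfinite(v)
    total = v[valid].sum()
    out = np.empty(n_bins)
    for i in range(1, n_bins + 1):
        out[i - 1] = n_test * v[valid & (bins == i)].sum() / total
    return out


def calibration_r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Squared Pearson correlation between observed and predicted counts."""
    if np.std(observed) == 0 or np.std(predicted) == 0:
        return np.nan
    return float(stats.pearsonr(observed, predicted)[0] ** 2)


def aaf(observed: np.ndarray, areas: np.ndarray) -> np.ndarray:
    """Area-adjusted frequency per bin: (obs share) / (area share).

    Bins with zero area get NaN (undefined, excluded downstream).
    """
    obs_share = observed / observed.sum() if observed.sum() > 0 else np.zeros_like(observed, float)
    area_share = areas / areas.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(area_share > 0, obs_share / area_share, np.nan)
    return out


def boyce_index(aaf_values: np.ndarray, squared: bool = True) -> float:
    """Spearman rank correlation between AAF and bin rank (1..n).

    Reported squared by convention; bins with undefined AAF are excluded.
    """
    v = np.asarray(aaf_values, dtype=float)
    ranks = np.arange(1, len(v) + 1)
    ok = np.isfinite(v)
    rho = float(stats.spearmanr(v[ok], ranks[ok]).statistic)
    return rho**2 if squared else rho


def aaf_magnitude(aaf_values: np.ndarray) -> float:
    """AAF of the highest bin over the AAF of the lowest bin with AAF > 0."""
    v = np.asarray(aaf_values, dtype=float)
    ok = np.isfinite(v)
    top = v[ok][-1]
    positive = np.where(ok & (v > 0))[0]
    if len(positive) == 0:
        return np.nan
    return float(top / v[positive[0]])


def evaluate_surface(surface: Raster, test_xy, n_bins: int = 10) -> EvalBinTable:
    """Full bin-table evaluation of a surface against test locations."""
    x, y = test_xy
    bins, areas = bin_surface(surface, n_bins)
    obs = observed_counts(surface, bins, x, y, n_bins)
    n_test = int(obs.sum())
    pred = predicted_counts(surface, bins, n_test, n_bins)
    a = aaf(obs, areas)
    table = pd.DataFrame(
        {
            "bin": np.arange(1, n_bins + 1),
            "area_km2": areas,
            "area_prop": areas / areas.sum(),
            "observed": obs,
            "predicted": pred,
            "aaf": a,
        }
    )
    return EvalBinTable(
        table=table,
        r2=calibration_r2(obs, pred),
        boyce=boyce_index(a, squared=True),
        boyce_raw=boyce_index(a, squared=False),
        aaf_magnitude=aaf_magnitude(a),
        n_test=n_test,
    )


def crossvalidate(
    train_xy,
    fit_eval_fn,
    k: int = 10,
    holdout: float = 0.22,
    rng: np.random.Generator | None = None,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Repeated random-holdout cross-validation.

    ``fit_eval_fn(fit_xy, holdout_xy) -> (observed, predicted)`` refits the
    model without the holdout and returns per-bin counts on the holdout.
    Returns per-bin means and normal-theory 95% CIs across iterations.
    """
    rng = rng or np.random.default_rng(0)
    tx, ty = train_xy
    n = len(tx)
    obs_all = np.empty((k, n_bins))
    pred_all = np.empty((k, n_bins))
    for i in range(k):
        perm = rng.permutation(n)
        n_hold = max(int(round(holdout * n)), 1)
        hold, keep = perm[:n_hold], perm[n_hold:]
        obs, pred = fit_eval_fn((tx[keep], ty[keep]), (tx[hold], ty[hold]))
        obs_all[i] = obs
        pred_all[i] = pred
    z = stats.norm.ppf(0.975)
    out = pd.DataFrame({"bin": np.arange(1, n_bins + 1)})
    for name, arr in (("observed", obs_all), ("predicted", pred_all)):
        mean = arr.mean(axis=0)
        se = arr.std(axis=0, ddof=1) / np.sqrt(k) if k > 1 else np.zeros(n_bins)
        out[f"{name}_mean"] = mean
        out[f"{name}_lo"] = mean - z * se
        out[f"{name}_hi"] = mean + z * se
    return out


def subregion_calibration(
    surface: Raster, test_xy, region_masks: dict[str, np.ndarray], n_bins: int = 10
):
    """Per-region bin tables and the pooled calibration R^2 across all
    region-bin pairs."""
    x, y = np.asarray(test_xy[0]), np.asarray(test_xy[1])
    bins, _ = bin_surface(surface, n_bins)
    per_region = {}
    obs_pool = []
    pred_pool = []
    for name, mask in region_masks.items():
        sub = Raster(surface.grid, np.where(mask, surface.data, np.nan))
        in_region = surface.grid.sample(mask.astype(float), x, y, fill=0) > 0
        t = evaluate_surface(sub, (x[in_region], y[in_region]), n_bins)
        per_region[name] = t
        obs_pool.append(t.table["observed"].to_numpy())
        pred_pool.append(t.table["predicted"].to_numpy())
    pooled_r2 = calibration_r2(np.concatenate(obs_pool), np.concatenate(pred_pool))
    return per_region, pooled_r2


def _quartile_bins(v: np.ndarray) -> np.ndarray:
    """Quartile bin (1..4) per value from mid-rank percentiles.

    Ties share their average rank, so a block of tied values lands in the
    middle quartile rather than collapsing to the bottom one.
    """
    ranks = stats.rankdata(v, method="average")
    q = np.ceil(4.0 * ranks / len(v)).astype(int)
    return np.clip(q, 1, 4)


def grid_concordance(
    surface: Raster,
    test_xy,
    modeled_mask: np.ndarray,
    cell_km: float,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Coarse-grid quartile concordance between observed and predicted
    test-location counts.

    Each coarse cell's predicted count is its mean per-raster-cell AAF
    (every raster cell carries the AAF of its intensity bin) times the
    fraction of the modelled area in the cell, times the total number of
    test locations.  Observed and predicted counts are quartile-binned over
    cells containing test data; discordance = |obs quartile - pred
    quartile|.
    """
    g = surface.grid
    x, y = test_xy
    bins, areas = bin_surface(
        Raster(g, np.where(modeled_mask, surface.data, np.nan)), n_bins
    )
    obs = observed_counts(surface, bins, x, y, n_bins)
    aaf_b = aaf(obs, areas)
    aaf_map = np.full(g.shape, np.nan)
    for i in range(1, n_bins + 1):
        aaf_map[bins == i] = aaf_b[i - 1]

    cell_m = cell_km * 1000.0
    row, col = g.xy_to_rowcol(np.asarray(x), np.asarray(y))
    coarse = lambda r, c: (r * g.resolution // cell_m, c * g.resolution // cell_m)
    n_cr = int(np.ceil(g.nrows * g.resolution / cell_m))
    n_cc = int(np.ceil(g.ncols * g.resolution / cell_m))
    rr, cc = np.indices(g.shape)
    crr = (rr * g.resolution // cell_m).astype(int)
    ccc = (cc * g.resolution // cell_m).astype(int)
    cid = crr * n_cc + ccc
    n_total = int(len(x))
    total_modeled = modeled_mask.sum()
    records = []
    point_cid = (row * g.resolution // cell_m).astype(int) * n_cc + (
        col * g.resolution // cell_m
    ).astype(int)
    for cell in np.unique(cid):
        in_cell = (cid == cell) & modeled_mask & np.isfinite(aaf_map)
        if not in_cell.any():
            continue
        mean_aaf = float(np.nanmean(aaf_map[in_cell]))
        prop = in_cell.sum() / total_modeled
        predicted = mean_aaf * prop * n_total
        observed = int(np.sum(point_cid == cell))
        records.append({"cell": int(cell), "observed": observed, "predicted": predicted})
    df = pd.DataFrame(records)
    df["has_data"] = df["observed"] > 0
    sub = df.loc[df["has_data"]].copy()
    sub["obs_quartile"] = _quartile_bins(sub["observed"].to_numpy().astype(float))
    sub["pred_quartile"] = _quartile_bins(sub["predicted"].to_numpy())
    sub["discordance"] = (sub["obs_quartile"] - sub["pred_quartile"]).abs()
    return df.merge(sub[["cell", "obs_quartile", "pred_quartile", "discordance"]],
                    on="cell", how="left")
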