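"""Comparison of two intensity surfaces and surface-management summaries.

Used to relate a winter-use surface to an independently built second
surface (e.g. a nesting-density model): cell-wise rank correlation,
percent overlap of the top-10%/top-20% area quantiles, and the share of
high-use habitat per land-management category with observed:expected
ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .grid import Raster, assert_aligned


def surface_correlation(s1: Raster, s2: Raster, mask: np.ndarray | None = None) -> float:
    """Cell-wise Spearman correlation over the mutual valid footprint."""
    assert_aligned(s1.grid, s2.grid)
    ok = s1.valid_mask & s2.valid_mask
    if mask is not None:
        ok &= mask
    return float(stats.spearmanr(s1.data[ok], s2.data[ok]).statistic)


def top_quantile_cells(surface: Raster, q: float, mask: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask of the top fraction ``q`` of valid cells by intensity.

    The quantile is defined by area (cell count), not by value range; ties
    at the cut are resolved by intensity descending, then by deterministic
    cell order.
    """
    ok = surface.valid_mask
    if mask is not None:
        ok = ok & mask
    idx = np.where(ok.ravel())[0]
    vals = surface.data.ravel()[idx]
    k = int(round(q * len(idx)))
    order = np.lexsort((idx, -vals))  # intensity desc, then cell order
    top = idx[order[:k]]
    out = np.zeros(surface.data.size, dtype=bool)
    out[top] = True
    return out.reshape(surface.data.shape)


def top_quantile_overlap(
    s1: Raster, s2: Raster, q: float, mask: np.ndarray | None = None
) -> float:
    """Percent overlap of the two surfaces' top-q area quantiles.

    Both top sets have the same cell count by construction, so the
    denominator (the first set's area) is symmetric up to quantile ties.
    """
    assert_aligned(s1.grid, s2.grid)
    both = s1.valid_mask & s2.valid_mask
    if mask is not None:
        both &= mask
    t1 = top_quantile_cells(s1, q, both)
    t2 = top_quantile_cells(s2, q, both)
    denom = t1.sum()
    return 100.0 * float((t1 & t2).sum()) / denom if denom else np.nan


def overlap_report(
    s1: Raster, s2: Raster, region_masks: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Per-region rank correlation and top-20%/top-10% overlap table."""
    rows = []
    for name, mask in region_masks.items():
        rows.append(
            {
                "region": name,
                "rank_correlation": surface_correlation(s1, s2, mask),
                "overlap_top20_pct": top_quantile_overlap(s1, s2, 0.20, mask),
                "overlap_top10_pct": top_quantile_overlap(s1, s2, 0.10, mask),
            }
        )
    return pd.DataFrame(rows)


def management_summary(
    surface: Raster,
    category_map: np.ndarray,
    categories: dict[int, str] | None = None,
    quantiles=(0.20, 0.10),
) -> pd.DataFrame:
    """Share of area and of top-quantile habitat per management category.

    ``category_map`` assigns an integer category code to every cell
    (negative = outside).  The observed:expected ratio is the category's
    share of the top-10% habitat divided by its share of the study area.
    """
    valid = surface.valid_mask & (category_map >= 0)
    tops = {q: top_quantile_cells(surface, q, valid) for q in quantiles}
    codes = np.unique(category_map[valid])
    rows = []
    total = valid.sum()
    for code in codes:
        in_cat = valid & (category_map == code)
        row = {
            "category": categories.get(int(code), str(code)) if categories else str(code),
            "area_pct": 100.0 * in_cat.sum() / total,
        }
        for q, top in tops.items():
            row[f"top{int(q * 100)}_pct"] = (
                100.0 * (in_cat & top).sum() / top.sum() if top.sum() else np.nan
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    df["observed_expected_ratio"] = observed_expected_ratio(
        df["top10_pct"].to_numpy(), df["area_pct"].to_numpy()
    )
    return df


def observed_expected_ratio(top10_pct, area_pct) -> np.ndarray:
    """O:E = share of the top-10% habitat over share of the study area."""
    top10_pct = np.asarray(top10_pct, dtype=float)
    area_pct = np.asarray(area_pct, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(area_pct > 0, top10_pct / area_pct, np.nan)
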