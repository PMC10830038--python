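"""Small worked-example tables for the evaluation arithmetic.

These are published evaluation summaries for a winter golden-eagle
distribution model: per-bin area-adjusted frequencies (AAF) for the four
life-history groups, and the surface-management shares of the study area
and of the top-quantile habitat.  They serve as fixed inputs for worked
examples of the Boyce index, AAF magnitude-of-difference, and
observed:expected arithmetic.
"""

from __future__ import annotations

import pandas as pd


def example_aaf_table() -> pd.DataFrame:
    """Per-bin AAF by life-history group (10 equal-interval intensity bins)."""
    return pd.DataFrame(
        {
            "bin": range(1, 11),
            "adult_migrant": [0.077, 0.060, 0.186, 0.412, 0.794, 1.154, 1.980, 2.765, 4.989, 9.890],
            "adult_nonmigrant": [0.018, 0.053, 0.128, 0.298, 0.564, 1.048, 1.602, 3.093, 6.456, 15.049],
            "nonadult_migrant": [0.037, 0.140, 0.536, 0.712, 1.015, 1.518, 1.775, 1.823, 2.159, 6.006],
            "nonadult_nonmigrant": [0.000, 0.241, 0.235, 0.458, 0.711, 1.080, 1.581, 2.409, 5.485, 12.376],
        }
    ).set_index("bin")


def example_management_table() -> pd.DataFrame:
    """Surface-management shares: study area %, top-20% and top-10% habitat %."""
    rows = [
        ("Private", 53.0, 55.0, 55.0),
        ("Bureau of Land Management", 16.0, 24.0, 25.0),
        ("U.S. Forest Service", 14.0, 8.0, 7.0),
        ("Tribal", 7.0, 4.0, 4.0),
        ("State", 5.0, 8.0, 8.0),
    ]
    return pd.DataFrame(rows, columns=["category", "area_pct", "top20_pct", "top10_pct"])
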