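"""Spatial heterogeneity of breeding habitat quality.

Prerequisite check for the habitat-competition hypothesis: in years when the
population-wide mean breeding success is high, success should be high across
many patches (low spatial dispersion), whereas bad years concentrate failure
in most patches.  Dispersion of patch mean success is measured each year by
the Gini coefficient weighted by the number of occupied nests per patch, and
compared with the yearly mean via a product-moment correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def weighted_gini(values: np.ndarray, weights: np.ndarray, small_sample_correction: bool = False) -> float:
    """Weighted Gini coefficient of dispersion.

    ``G = sum_ij w_i w_j |v_i - v_j| / (2 (sum w)^2 vbar)`` with ``vbar`` the
    weighted mean.  Returns NaN when the weighted mean is zero (dispersion of
    an all-zero distribution is undefined).  The optional ``n/(n-1)``
    small-sample factor is off by default.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape or v.ndim != 1:
        raise ValueError("values and weights must be 1-D and aligned")
    if v.size < 2:
        raise ValueError("need at least 2 entries")
    if np.any(v < 0):
        raise ValueError("values must be >= 0")
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    wsum = w.sum()
    vbar = float(np.dot(w, v) / wsum)
    if vbar == 0.0:
        return float("nan")
    diff = np.abs(v[:, None] - v[None, :])
    g = float(w @ diff @ w / (2.0 * wsum ** 2 * vbar))
    if small_sample_correction:
        g *= v.size / (v.size - 1)
    return g


@dataclass
class PrerequisiteResult:
    """Per-year mean success and weighted Gini, and their association."""

    per_year: pd.DataFrame       # year, mean_success, gini, n_patches, n_nests
    correlation: float           # Pearson r between mean success and Gini
    p_value: float
    slope: float
    intercept: float

    def summary(self) -> str:
        return (f"{len(self.per_year)} years; Pearson r(mean success, Gini) = "
                f"{self.correlation:.3f}")


def prerequisite_check(table: pd.DataFrame, min_years: int = 3) -> PrerequisiteResult:
    """Per-year (nest-weighted mean success, weighted Gini) and their
    across-years correlation.

    ``table`` columns: year, patch, n_nests, n_fledglings.  Patches with no
    nests in a year are excluded from that year's distribution.  A strongly
    negative correlation indicates that good years spread success across
    patches rather than concentrating it.
    """
    required = {"year", "patch", "n_nests", "n_fledglings"}
    if not required.issubset(table.columns):
        raise ValueError(f"patch table must have columns {sorted(required)}")
    rows = []
    for year, grp in table.groupby("year"):
        occ = grp[grp["n_nests"] > 0]
        if len(occ) < 2:
            continue
        v = occ["n_fledglings"].to_numpy(float) / occ["n_nests"].to_numpy(float)
        w = occ["n_nests"].to_numpy(float)
        mean = float(np.dot(w, v) / w.sum())
        rows.append((year, mean, weighted_gini(v, w), len(occ), int(w.sum())))
    per_year = pd.DataFrame(rows, columns=["year", "mean_success", "gini", "n_patches", "n_nests"])
    per_year = per_year.dropna(subset=["gini"])
    if len(per_year) < min_years:
        raise ValueError(f"need at least {min_years} years with >= 2 occupied patches")
    x = per_year["mean_success"].to_numpy()
    y = per_year["gini"].to_numpy()
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        warnings.warn("mean success or Gini has no variance across years; "
                      "correlation undefined", stacklevel=2)
        return PrerequisiteResult(per_year, float("nan"), float("nan"), float("nan"),
                                  float(np.mean(y)))
    r, p = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return PrerequisiteResult(per_year, float(r), float(p), float(slope), float(intercept))
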