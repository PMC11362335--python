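"""Depth profiles and covariate regressions.

Per-sample Type-resolved concentrations are assembled into depth-ordered
station profiles and regressed (ordinary least squares, untransformed)
against chlorophyll-a or turbidity.  A strong Type-vs-Chl-a correlation
points to a phytoplankton-related origin of that Type; atmospherically
deposited components (iron oxides, black carbon) are expected to show none
and instead to be enriched right at the sea surface relative to 10 m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionSummary",
    "depth_profile",
    "regress_vs_covariate",
    "surface_enrichment",
]


@dataclass(frozen=True)
class RegressionSummary:
    """OLS fit summary: y = slope * x + intercept."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("regression needs n >= 3 for a defined p value")


def depth_profile(samples: pd.DataFrame, depth_col: str = "depth_m") -> pd.DataFrame:
    """Depth-sorted station profile; replicate depths are averaged.

    ``samples`` holds one row per sample with a depth column and numeric
    concentration/covariate columns.  The result has one row per depth,
    numeric columns averaged over replicates, and an ``n_replicates``
    column flagging where averaging occurred.
    """
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    if depth_col not in samples.columns:
        raise ValueError(f"missing depth column {depth_col!r}")
    num = samples.select_dtypes(include=[np.number]).columns
    grouped = samples.groupby(depth_col, sort=True)
    prof = grouped[[c for c in num if c != depth_col]].mean().reset_index()
    prof["n_replicates"] = grouped.size().to_numpy()
    return prof


def regress_vs_covariate(x, y) -> RegressionSummary:
    """OLS of a per-Type concentration series y on a covariate series x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched series with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("series must be finite")
    if np.ptp(x) == 0:
        raise ValueError("covariate has zero variance")
    fit = stats.linregress(x, y)
    return RegressionSummary(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=int(x.size),
    )


def surface_enrichment(
    profile: pd.DataFrame,
    value_col: str,
    depth_col: str = "depth_m",
    surface: float = 0.0,
    reference: float = 10.0,
    atol: float = 1.0,
) -> float:
    """Ratio of a concentration at the surface to its value at ~10 m.

    Values above 1 indicate surface enrichment (the signature of recent
    atmospheric deposition).  NaN if either depth is absent.
    """
    d = profile[depth_col].to_numpy(dtype=float)
    v = profile[value_col].to_numpy(dtype=float)
    i_s = np.flatnonzero(np.abs(d - surface) <= atol)
    i_r = np.flatnonzero(np.abs(d - reference) <= atol)
    if i_s.size == 0 or i_r.size == 0:
        return math.nan
    num, den = float(v[i_s[0]]), float(v[i_r[0]])
    return math.nan if den == 0 else num / den
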