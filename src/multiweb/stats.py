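"""Summary statistics for simulation ensembles.

Ordinary least squares for intensity–response and diversity–functioning
(BEF) slopes, an ANCOVA-style test for equality of two regression slopes
(the interaction term of the pooled model ``y ~ x * group``), diversity-
ratio histograms with per-bin mean NTI intensities, and per-trophic-level
aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionFit",
    "AncovaResult",
    "fit_linear",
    "ancova_slopes",
    "ratio_histogram",
    "per_tl_summary",
]

#: Column suffixes for the three trophic-level classes.
TL_CLASS_SUFFIX = {"TL=1": "tl1", "2<=TL<=3": "tl23", "TL>3": "tl3p"}


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    slope_stderr: float
    p_value: float
    n: int


@dataclass
class AncovaResult:
    slope1: float
    slope2: float
    interaction: float       # slope2 - slope1
    p_value: float           # two-sided, H0: equal slopes
    n: int


def fit_linear(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    """OLS fit of ``y = intercept + slope * x`` with a two-sided t-test on
    the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 2:
        raise ValueError("need at least two points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return RegressionFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_stderr=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        n=int(x.size),
    )


def ancova_slopes(x1, y1, x2, y2) -> AncovaResult:
    """Test whether two groups share a regression slope.

    Fits the pooled model ``y ~ x + group + x:group`` and reports the
    two-sided p-value of the interaction term, the classic ANCOVA test for
    slope homogeneity.
    """
    x1, y1 = np.asarray(x1, float), np.asarray(y1, float)
    x2, y2 = np.asarray(x2, float), np.asarray(y2, float)
    if min(x1.size, x2.size) < 3:
        raise ValueError("each group needs at least three points")
    x = np.concatenate([x1, x2])
    g = np.concatenate([np.zeros(x1.size), np.ones(x2.size)])
    y = np.concatenate([y1, y2])
    X = np.column_stack([np.ones_like(x), x, g, x * g])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("degenerate design matrix (constant x in a group?)")
    fit = sm.OLS(y, X).fit()
    return AncovaResult(
        slope1=float(fit.params[1]),
        slope2=float(fit.params[1] + fit.params[3]),
        interaction=float(fit.params[3]),
        p_value=float(fit.pvalues[3]),
        n=int(x.size),
    )


def ratio_histogram(
    ratios: np.ndarray,
    intensities: pd.DataFrame | None = None,
    ranges: dict | None = None,
    bin_width: float = 0.01,
) -> pd.DataFrame:
    """Histogram of diversity ratios with per-bin mean NTI intensities.

    Bins are centred on multiples of ``bin_width`` (diversity counts over
    ~100 species make the ratios near-multiples of 0.01).  Frequencies sum
    to one.  ``intensities`` holds one column per NTI intensity for the
    same runs; each column is min-max normalized to [0, 1] over its
    configured range (``ranges[col] = (lo, hi)``) before the per-bin mean
    is taken, so 0 maps to the range minimum and 1 to the maximum.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size == 0:
        raise ValueError("empty ratio vector")
    if not np.isfinite(ratios).all():
        raise ValueError("ratios must be finite")
    lo = np.floor(ratios.min() / bin_width) * bin_width - bin_width / 2
    hi = np.ceil(ratios.max() / bin_width) * bin_width + bin_width / 2
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(ratios, bins=edges)
    centres = (edges[:-1] + edges[1:]) / 2
    out = pd.DataFrame({
        "bin_center": centres,
        "count": counts,
        "frequency": counts / ratios.size,
    })
    if intensities is not None:
        idx = np.digitize(ratios, edges) - 1
        idx = np.clip(idx, 0, len(centres) - 1)
        for col in intensities.columns:
            v = intensities[col].to_numpy(dtype=float)
            if ranges and col in ranges:
                lo_r, hi_r = ranges[col]
                v = (v - lo_r) / (hi_r - lo_r) if hi_r > lo_r else v * 0.0
            means = np.full(len(centres), np.nan)
            for b in range(len(centres)):
                sel = idx == b
                if sel.any():
                    means[b] = v[sel].mean()
            out[f"mean_{col}"] = means
    return out


def per_tl_summary(table: pd.DataFrame,
                   variables: tuple = ("diversity", "biomass", "production")
                   ) -> pd.DataFrame:
    """Mean relative change per trophic-level class per variable.

    Expects an ensemble table with per-class ratio columns named
    ``{variable}_ratio_{suffix}`` (suffixes ``tl1``, ``tl23``, ``tl3p``)
    as written by the experiment runners; NaN ratios (zero baselines) are
    skipped.
    """
    rows = []
    for var in variables:
        for label, suffix in TL_CLASS_SUFFIX.items():
            col = f"{var}_ratio_{suffix}"
            if col not in table.columns:
                continue
            v = table[col].to_numpy(dtype=float)
            ok = np.isfinite(v)
            rows.append({
                "variable": var,
                "tl_class": label,
                "mean_ratio": float(v[ok].mean()) if ok.any() else np.nan,
                "n": int(ok.sum()),
            })
    return pd.DataFrame(rows)
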