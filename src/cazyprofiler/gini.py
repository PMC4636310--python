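"""Functional rarefaction of a CAZyme repertoire via the Lorenz curve and
Gini coefficient, plus the logarithmic Gini-versus-age trend fit.

The Gini coefficient treats the family abundance vector of one sample the
way econometrics treats incomes: 0 means every family contributes equally,
values approaching 1 mean a handful of families carry almost the whole
repertoire (a specialized, or in the gut context often infant-like,
microbiome).  For n families the discrete maximum is 1 - 1/n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import AbundanceProfile, retained_counts


@dataclass(frozen=True)
class GiniResult:
    """Gini coefficient of one sample with its Lorenz curve.

    ``lorenz_points`` are (cumulative family fraction, cumulative abundance
    fraction) pairs from (0, 0) to (1, 1), families sorted ascending, so
    the curve is non-decreasing and convex (at or below the diagonal).
    """

    sample_id: str
    gini: float
    lorenz_points: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class LogAgeFit:
    """OLS fit of G = intercept + slope * ln(age)."""

    intercept: float
    slope: float
    r_squared: float
    n: int


def gini_coefficient(abundances, sample_id: str = "") -> GiniResult:
    """Gini coefficient of a non-negative abundance vector.

    Computed as one minus twice the trapezoidal area under the Lorenz
    curve, which for discrete data equals the normalized mean absolute
    difference  sum_ij |x_i - x_j| / (2 n^2 mu).  Zero entries are valid
    members of the vector (they are maximal-inequality contributions);
    an all-zero vector is an error.
    """
    x = np.sort(np.asarray(abundances, dtype=float))
    if x.size == 0 or np.any(x < 0):
        raise ValueError("abundances must be a non-empty non-negative vector")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector has no Lorenz curve")
    n = x.size
    cum = np.concatenate([[0.0], np.cumsum(x)]) / total
    frac = np.arange(n + 1) / n
    # trapezoid rule on n panels of width 1/n
    area = float(np.sum((cum[:-1] + cum[1:]) / (2.0 * n)))
    g = 1.0 - 2.0 * area
    points = tuple(zip(frac.tolist(), cum.tolist()))
    return GiniResult(sample_id=sample_id, gini=g, lorenz_points=points)


def sample_gini(profile: AbundanceProfile, min_frac: float = 1e-4) -> pd.Series:
    """Per-sample Gini over each sample's retained family set.

    The family universe for a sample is its families passing the
    diversity exclusion (raw count >= ``min_frac`` of total hits), so the
    statistic measures inequality among the families the sample actually
    carries rather than against the global family axis.
    """
    out = {}
    for sid in profile.samples:
        kept = retained_counts(profile.counts.loc[sid], min_frac=min_frac)
        out[sid] = gini_coefficient(kept.to_numpy(), sample_id=sid).gini
    return pd.Series(out, name="gini")


def fit_gini_age(ginis, ages) -> LogAgeFit:
    """Ordinary least squares of Gini on ln(age in years)."""
    g = np.asarray(ginis, dtype=float)
    a = np.asarray(ages, dtype=float)
    if g.shape != a.shape:
        raise ValueError("ginis and ages must have equal length")
    if np.any(a <= 0):
        raise ValueError("ages must be strictly positive for the log fit")
    if g.size < 3:
        raise ValueError("need at least 3 points to fit the age trend")
    res = stats.linregress(np.log(a), g)
    return LogAgeFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue**2) if not np.isnan(res.rvalue) else 0.0,
        n=int(g.size),
    )
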