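"""Covariate association of CAZyme families (age, BMI).

Workflow: drop sparse families (prevalence filter), rank-transform family
abundances across samples, compute a Pearson correlation and regression
p-value per family, adjust across families (Benjamini-Hochberg by default,
Bonferroni available), and summarize a chosen marker set through the
summed-abundance sliding-window correlation.  Group comparisons of
per-sample summary statistics use one-way ANOVA with Tukey HSD post-hoc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests



@dataclass(frozen=True)
class AssociationRecord:
    family: str
    r: float
    p_value: float
    p_adjusted: float
    n_used: int
    degenerate: bool = False  # zero-variance family; r/p undefined


@dataclass(frozen=True)
class WindowCorrelation:
    """Sliding-window summed-marker correlation with a covariate."""

    window_size: int
    step: int
    r_squared: float
    window_means: tuple[tuple[float, float], ...]  # (mean covariate, mean sum)


def prevalence_filter(
    rates: pd.DataFrame,
    min_prev: float = 0.5,
    covariate: pd.Series | None = None,
) -> pd.DataFrame:
    """Keep families with nonzero abundance in at least ``min_prev``
    (inclusive) of the samples; when a covariate is given, prevalence is
    assessed over the samples where it is non-missing."""
    if covariate is not None:
        rates = rates.loc[covariate.reindex(rates.index).notna()]
    n = len(rates)
    keep = (rates > 0).sum(axis=0) >= min_prev * n
    return rates.loc[:, keep]


def correlate_families(
    rates: pd.DataFrame,
    covariate: pd.Series,
    rank_transform: bool = True,
    adjust: str = "bh",
) -> list[AssociationRecord]:
    """Per-family correlation with a covariate, multiplicity-adjusted.

    With ``rank_transform`` (default) each family's abundances are replaced
    by their ranks across samples before the Pearson/regression step, i.e.
    a Spearman-style statistic computed through a linear model.  Samples
    with missing covariate are dropped.  ``adjust`` is ``"bh"`` or
    ``"bonferroni"``; zero-variance families are flagged degenerate and
    excluded from the adjustment count.
    """
    cov = covariate.reindex(rates.index)
    ok = cov.notna()
    x = cov[ok].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 samples with a covariate value")
    sub = rates.loc[ok]
    results: list[tuple[str, float, float, bool]] = []
    for fam in sub.columns:
        y = sub[fam].to_numpy(dtype=float)
        if rank_transform:
            y = stats.rankdata(y)
        if np.std(y) == 0 or np.std(x) == 0:
            results.append((fam, np.nan, np.nan, True))
            continue
        res = stats.linregress(x, y)
        results.append((fam, float(res.rvalue), float(res.pvalue), False))
    pvals = [p for _, _, p, bad in results if not bad]
    if pvals:
        method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[adjust]
        adj = multipletests(pvals, method=method)[1]
    else:
        adj = np.array([])
    adj_iter = iter(adj)
    records = []
    for fam, r, p, bad in results:
        records.append(
            AssociationRecord(
                family=fam,
                r=r,
                p_value=p,
                p_adjusted=np.nan if bad else float(next(adj_iter)),
                n_used=int(x.size),
                degenerate=bad,
            )
        )
    return records


def significant_families(records, alpha: float = 0.05) -> list[str]:
    """Families whose adjusted p-value clears ``alpha``."""
    return [r.family for r in records if not r.degenerate and r.p_adjusted < alpha]


def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up BH adjusted p-values (statsmodels-backed convenience)."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def summed_marker_correlation(
    rates: pd.DataFrame,
    families,
    covariate: pd.Series,
    window: int | None = None,
    step: int = 1,
) -> WindowCorrelation:
    """Correlation of summed marker-family abundance with a covariate,
    smoothed by a sliding window.

    Samples are sorted by the covariate; consecutive windows of ``window``
    samples (default ceil(n/10)) advancing by ``step`` are averaged, and
    the squared Pearson correlation of the window means is returned.
    ``window=1, step=1`` reduces to the plain per-sample correlation.
    """
    families = list(families)
    missing = [f for f in families if f not in rates.columns]
    if missing:
        raise KeyError(f"marker families absent from profile: {missing}")
    cov = covariate.reindex(rates.index)
    ok = cov.notna()
    sums = rates.loc[ok, families].sum(axis=1).to_numpy(dtype=float)
    x = cov[ok].to_numpy(dtype=float)
    n = x.size
    if window is None:
        window = max(1, int(np.ceil(n / 10)))
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if window > n:
        raise ValueError(f"window {window} exceeds the {n} usable samples")
    order = np.argsort(x, kind="stable")
    x, sums = x[order], sums[order]
    starts = range(0, n - window + 1, step)
    means = tuple((float(x[s:s + window].mean()), float(sums[s:s + window].mean()))
                  for s in starts)
    mx = np.array([m[0] for m in means])
    my = np.array([m[1] for m in means])
    if mx.size < 2 or np.std(mx) == 0 or np.std(my) == 0:
        r2 = 0.0
    else:
        r2 = float(stats.pearsonr(mx, my).statistic ** 2)
    return WindowCorrelation(window_size=window, step=step, r_squared=r2,
                             window_means=means)


@dataclass
class GroupComparison:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame | None
    degenerate: bool = False  # zero within-group variance everywhere


def group_compare(values: pd.Series, groups: pd.Series) -> GroupComparison:
    """One-way ANOVA of a per-sample statistic across groups, with a
    Tukey HSD pairwise table.

    Every group needs at least 2 members.  When within-group variance is
    zero in every group the F statistic is undefined and the result is
    flagged degenerate (Tukey omitted).
    """
    groups = groups.reindex(values.index)
    ok = values.notna() & groups.notna()
    v, g = values[ok], groups[ok]
    sizes = g.value_counts()
    if len(sizes) < 2:
        raise ValueError("need at least two groups")
    small = sizes[sizes < 2].index.tolist()
    if small:
        raise ValueError(f"group(s) with fewer than 2 members: {small}")
    arrays = [v[g == lvl].to_numpy(dtype=float) for lvl in sizes.index]
    within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if within == 0:
        return GroupComparison(np.nan, np.nan, None, degenerate=True)
    f, p = stats.f_oneway(*arrays)
    tk = pairwise_tukeyhsd(v.to_numpy(dtype=float), g.to_numpy())
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return GroupComparison(float(f), float(p), tukey)


def group_compare_many(
    table: pd.DataFrame, groups: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """ANOVA per column of ``table`` with BH adjustment across columns."""
    rows = []
    for col in table.columns:
        cmp = group_compare(table[col], groups)
        rows.append({"variable": col, "f": cmp.f_statistic, "p": cmp.p_value,
                     "degenerate": cmp.degenerate})
    out = pd.DataFrame(rows).set_index("variable")
    tested = ~out["degenerate"] & out["p"].notna()
    out["p_adjusted"] = np.nan
    if tested.any():
        out.loc[tested, "p_adjusted"] = benjamini_hochberg(out.loc[tested, "p"])
    out["significant"] = out["p_adjusted"] < alpha
    return out
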