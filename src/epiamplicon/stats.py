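"""Statistical layer: stage comparisons and methylation-expression coupling.

One-way ANOVA compares a methylation (or expression) quantity across
developmental stages; pairwise two-sample t tests follow up the omnibus
test (Welch by default, pooled variance optionally, no multiple-testing
correction by default, Holm available). Pearson correlation links per-sample
methylation summaries to 2^-dCt relative expression, and the heatmap
builders tabulate r (and p) between each epiallele class or each individual
epiallele's frequency and expression, per tissue with stages pooled.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tables import EpialleleCountTable, class_distribution


@dataclass(frozen=True)
class StatResult:
    """One statistical test: statistic, p-value, group labels, sample size."""

    test: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    n: int
    note: str = ""

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> StatResult:
    """Classical one-way ANOVA across named groups (e.g. stages P1/P15/P60)."""
    names = tuple(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    note = ""
    if all(np.ptp(a) == 0 for a in arrays):
        note = "zero within-group variance"
    f, p = sps.f_oneway(*arrays)
    n = int(sum(a.size for a in arrays))
    if not np.isfinite(f):
        f, p = np.inf, 0.0
        note = note or "degenerate F (zero within-group variance)"
    return StatResult(
        test="one-way ANOVA", groups=names, statistic=float(f),
        p_value=float(p), n=n, note=note,
    )


def pairwise_t_tests(
    groups: Mapping[str, Sequence[float]],
    correction: str = "none",
    equal_var: bool = False,
) -> list[StatResult]:
    """Two-sample t test for every pair of groups.

    Welch's t (unequal variances) by default; ``equal_var=True`` gives the
    pooled-variance test whose two-group F satisfies F = t^2. ``correction``
    is "none" (raw p per pair) or "holm".
    """
    if correction not in {"none", "holm"}:
        raise ValueError("correction must be 'none' or 'holm'")
    names = list(groups)
    if len(names) < 2 or any(len(groups[g]) < 2 for g in names):
        raise ValueError("t tests need >= 2 groups with >= 2 values each")
    results = []
    for a, b in combinations(names, 2):
        x = np.asarray(groups[a], dtype=float)
        y = np.asarray(groups[b], dtype=float)
        if np.ptp(x) == 0 and np.ptp(y) == 0 and x.mean() == y.mean():
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(x, y, equal_var=equal_var)
        results.append(
            StatResult(
                test="t (pooled)" if equal_var else "t (Welch)",
                groups=(a, b),
                statistic=float(t),
                p_value=float(p),
                n=int(x.size + y.size),
            )
        )
    if correction == "holm":
        ps = np.array([r.p_value for r in results])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * ps[idx])
            adj[idx] = min(running, 1.0)
        results = [
            StatResult(
                test=r.test + " + holm", groups=r.groups,
                statistic=r.statistic, p_value=float(adj[i]), n=r.n,
            )
            for i, r in enumerate(results)
        ]
    return results


def methylation_expression_correlation(
    mean_meth: Mapping[str, float] | pd.Series,
    rel_expr: Mapping[str, float] | pd.Series,
) -> StatResult:
    """Pearson correlation of per-sample methylation with 2^-dCt expression.

    Samples are paired by id; a constant vector yields an explicit NA
    result (r and p NaN) rather than an exception.
    """
    meth = pd.Series(mean_meth, dtype=float)
    expr = pd.Series(rel_expr, dtype=float)
    common = meth.index.intersection(expr.index)
    if len(common) < 3:
        raise ValueError("correlation needs >= 3 paired samples")
    x = meth.loc[common].values
    y = expr.loc[common].values
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return StatResult(
            test="Pearson r", groups=tuple(common), statistic=float("nan"),
            p_value=float("nan"), n=len(common),
            note="undefined: constant input",
        )
    r, p = sps.pearsonr(x, y)
    return StatResult(
        test="Pearson r", groups=tuple(common), statistic=float(r),
        p_value=float(p), n=len(common),
    )


@dataclass(frozen=True)
class CorrelationHeatmap:
    """Rows (classes or epialleles) x tissues matrices of Pearson r and p."""

    r: pd.DataFrame
    p: pd.DataFrame
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        vals = self.r.values
        if np.nanmax(np.abs(vals), initial=0.0) > 1 + 1e-9:
            raise ValueError("every r must lie in [-1, 1]")


def _corr_columns(
    features: pd.DataFrame,
    rel_expr: pd.Series,
    tissues: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    tissue_names = sorted(tissues.dropna().unique())
    r = pd.DataFrame(index=features.columns, columns=tissue_names, dtype=float)
    p = pd.DataFrame(index=features.columns, columns=tissue_names, dtype=float)
    for tissue in tissue_names:
        ids = tissues.index[tissues == tissue]
        ids = ids.intersection(features.index).intersection(rel_expr.index)
        if len(ids) < 3:
            raise ValueError(
                f"tissue {tissue!r} has {len(ids)} samples; need >= 3"
            )
        y = rel_expr.loc[ids].values
        for feat in features.columns:
            x = features.loc[ids, feat].values
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r.loc[feat, tissue] = np.nan
                p.loc[feat, tissue] = np.nan
            else:
                rr, pp = sps.pearsonr(x, y)
                r.loc[feat, tissue] = rr
                p.loc[feat, tissue] = pp
    return r, p


def class_expression_heatmap(
    table: EpialleleCountTable,
    rel_expr: Mapping[str, float] | pd.Series,
    tissues: Mapping[str, str] | pd.Series | None = None,
) -> CorrelationHeatmap:
    """Correlate epiallele-class proportions with expression, per tissue.

    Stages are pooled: within each tissue, r is computed across all its
    samples between each class's proportion and relative expression.
    """
    classes = class_distribution(table)
    expr = pd.Series(rel_expr, dtype=float)
    tser = (
        pd.Series(tissues)
        if tissues is not None
        else table.meta["tissue"]
    )
    r, p = _corr_columns(classes, expr, tser)
    return CorrelationHeatmap(r=r, p=p)


def epiallele_expression_heatmap(
    table: EpialleleCountTable,
    rel_expr: Mapping[str, float] | pd.Series,
    tissues: Mapping[str, str] | pd.Series | None = None,
    min_mean_freq: float = 0.01,
) -> CorrelationHeatmap:
    """Correlate individual epiallele frequencies with expression, per tissue.

    Epialleles whose mean frequency across samples falls below
    ``min_mean_freq`` are excluded from the heatmap and listed in
    ``excluded``.
    """
    freqs = table.frequencies()
    mean_freq = freqs.mean(axis=0)
    keep = mean_freq.index[mean_freq >= min_mean_freq]
    excluded = tuple(sorted(set(freqs.columns) - set(keep)))
    if len(keep) == 0:
        raise ValueError("no epiallele clears the abundance floor")
    expr = pd.Series(rel_expr, dtype=float)
    tser = (
        pd.Series(tissues)
        if tissues is not None
        else table.meta["tissue"]
    )
    r, p = _corr_columns(freqs[keep], expr, tser)
    return CorrelationHeatmap(r=r, p=p, excluded=excluded)
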