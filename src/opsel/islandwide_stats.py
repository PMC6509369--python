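"""Island-wide annual comparisons.

Brown-Forsythe Levene-type tests of equality of variances (ANOVA on
absolute deviations from group medians), Kruskal-Wallis rank-sum tests of
annual location differences (individual adult males as the sampling unit),
and the ordinary regression of harem abundance on total population size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import OpselError


@dataclass
class TestResult:
    statistic: float
    df: tuple
    p_value: float
    method: str
    extra: dict | None = None


def brown_forsythe(groups: list[np.ndarray]) -> TestResult:
    """Brown-Forsythe test: one-way ANOVA F on |x - median(group)|."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise OpselError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise OpselError("every group needs at least 2 values")
    w, p = stats.levene(*groups, center="median")
    g = len(groups)
    n = sum(len(x) for x in groups)
    return TestResult(statistic=float(w), df=(g - 1, n - g),
                      p_value=float(p), method="Brown-Forsythe Levene")


def kruskal_wallis(groups: list[np.ndarray]) -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-square p on g-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise OpselError("need at least 2 groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        # all observations identical: no rank variation at all
        return TestResult(statistic=0.0, df=(len(groups) - 1,),
                          p_value=1.0, method="Kruskal-Wallis")
    h, p = stats.kruskal(*groups)
    return TestResult(statistic=float(h), df=(len(groups) - 1,),
                      p_value=float(p), method="Kruskal-Wallis")


def harems_population_lm(summary: pd.DataFrame) -> TestResult:
    """OLS of annual harem count on total population size.

    ``summary`` needs columns ``population_size`` and ``n_harems`` with one
    row per year (at least three).  Returns F on (1, n-2) df with the
    slope, intercept and R² in ``extra``.
    """
    if len(summary) < 3:
        raise OpselError("need at least 3 years for the regression")
    x = sm.add_constant(summary["population_size"].to_numpy(dtype=float))
    y = summary["n_harems"].to_numpy(dtype=float)
    fit = sm.OLS(y, x).fit()
    return TestResult(
        statistic=float(fit.fvalue), df=(1, int(fit.df_resid)),
        p_value=float(fit.f_pvalue), method="OLS harems ~ population",
        extra={"intercept": float(fit.params[0]),
               "slope": float(fit.params[1]),
               "r2": float(fit.rsquared)})


def annual_island_tests(table: pd.DataFrame,
                        responses: tuple[str, ...] = (
                            "I", "I_harem", "I_mares_given_harem")
                        ) -> pd.DataFrame:
    """Brown-Forsythe and Kruskal-Wallis across years for each response."""
    rows = []
    for resp in responses:
        groups = [g.to_numpy(dtype=float)
                  for _, g in table.groupby("year")[resp]]
        bf = brown_forsythe(groups)
        kw = kruskal_wallis(groups)
        rows.append(dict(response=resp, W=bf.statistic, W_p=bf.p_value,
                         K=kw.statistic, K_df=kw.df[0], K_p=kw.p_value))
    return pd.DataFrame(rows)
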