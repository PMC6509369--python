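"""Post hoc climate analysis of year-specific distance-from-water slopes.

From a residual-based mixed model with a year x distance-from-water
interaction, the year-specific slope is the distance main effect plus that
year's interaction coefficient (the reference year keeps the main effect
alone).  These annual slopes are then regressed on climate variables with
linear and linear-plus-quadratic candidates, compared by AICc with n equal
to the number of years.  Candidate k counts regression coefficients
(2 linear, 3 quadratic).  With five years the small-sample correction
denominator n - k - 1 can reach 1; such fits are reported with a warning
flag rather than suppressed, and candidates with no residual degree of
freedom at all are reported as undefined and excluded from the weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import FitError
from .lmm import LMMFit, akaike_weights


def year_slopes(fit: LMMFit) -> pd.DataFrame:
    """Per-year distance-from-water slope from a year x distance model."""
    if not fit.spec.interaction or fit.spec.covariate is None:
        raise FitError("model has no year x covariate interaction")
    cov = fit.spec.covariate
    main = fit.beta[fit.names.index(cov)]
    inter = {}
    for nm, b in zip(fit.names, fit.beta):
        if nm.startswith(f"{cov}:year["):
            inter[int(nm[len(f"{cov}:year["):-1])] = b
    # reference-year slope is the main effect alone (year = None here;
    # year_slopes_from() resolves the actual reference-year label)
    rows = [{"year": None, "beta": float(main)}]
    for yv in sorted(inter):
        rows.append({"year": int(yv), "beta": float(main + inter[yv])})
    return pd.DataFrame(rows)


def year_slopes_from(fit: LMMFit, years: list[int]) -> pd.DataFrame:
    """Like :func:`year_slopes` but labelling the reference year explicitly."""
    df = year_slopes(fit)
    ref = [y for y in sorted(years)
           if y not in set(df["year"].dropna().astype(int))]
    df.loc[df["year"].isna(), "year"] = ref[0] if ref else min(years)
    df["year"] = df["year"].astype(int)
    return df.sort_values("year").reset_index(drop=True)


@dataclass
class ClimateModelResult:
    name: str
    variable: str
    quadratic: bool
    k: int
    loglik: float
    aicc: float | None
    r2: float
    coefficients: dict
    small_sample_warning: bool


@dataclass
class ClimateCompetition:
    table: pd.DataFrame
    winner: ClimateModelResult

    def predict_winner(self, x: np.ndarray) -> np.ndarray:
        c = self.winner.coefficients
        x = np.asarray(x, dtype=float)
        z = (x - c["x_mean"]) / c["x_scale"]
        out = c["(Intercept)"] + c["linear"] * z
        if self.winner.quadratic:
            out = out + c["quadratic"] * z ** 2
        return out

    @property
    def concave(self) -> bool | None:
        if not self.winner.quadratic:
            return None
        return self.winner.coefficients["quadratic"] < 0


def _aicc_ols(llf: float, k: int, n: int) -> float | None:
    if n - k - 1 <= 0:
        return None
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def climate_fit(slopes: pd.DataFrame, climate: pd.DataFrame,
                variables: list[str] | None = None) -> ClimateCompetition:
    """Compete linear and quadratic climate models for the annual slopes.

    ``slopes`` has columns ``year, beta``; ``climate`` has ``year`` plus
    climate variables.  Each variable is standardized (z-score across
    years) before fitting.  Requires at least four years so the quadratic
    model keeps a residual degree of freedom.
    """
    merged = slopes.merge(climate, on="year", how="inner")
    n = len(merged)
    if n < 4:
        raise FitError("need >= 4 years for the quadratic climate models")
    variables = variables or [c for c in climate.columns if c != "year"]
    y = merged["beta"].to_numpy(dtype=float)
    results: list[ClimateModelResult] = []
    for var in variables:
        x_raw = merged[var].to_numpy(dtype=float)
        x_mean = float(x_raw.mean())
        x_scale = float(x_raw.std(ddof=1)) or 1.0
        z = (x_raw - x_mean) / x_scale
        for quad in (False, True):
            cols = [np.ones(n), z] + ([z ** 2] if quad else [])
            X = np.column_stack(cols)
            fit = sm.OLS(y, X).fit()
            k = X.shape[1]
            a = _aicc_ols(fit.llf, k, n)
            warn = a is not None and (n - k - 1) <= 1
            coefs = {"(Intercept)": float(fit.params[0]),
                     "linear": float(fit.params[1]),
                     "x_mean": x_mean, "x_scale": x_scale}
            if quad:
                coefs["quadratic"] = float(fit.params[2])
            results.append(ClimateModelResult(
                name=f"{var}{' + ' + var + '^2' if quad else ''}",
                variable=var, quadratic=quad, k=k, loglik=float(fit.llf),
                aicc=a, r2=float(fit.rsquared), coefficients=coefs,
                small_sample_warning=warn))
    defined = [r for r in results if r.aicc is not None]
    if not defined:
        raise FitError("AICc undefined for every climate candidate")
    aiccs = np.array([r.aicc for r in defined])
    weights = akaike_weights(aiccs)
    wmap = {r.name: w for r, w in zip(defined, weights)}
    if any(r.small_sample_warning for r in defined):
        warnings.warn("AICc small-sample denominator n-k-1 <= 1 for some "
                      "climate candidates", stacklevel=2)
    rows = []
    for r in results:
        rows.append(dict(model=r.name, k=r.k,
                         dAICc=(r.aicc - aiccs.min()) if r.aicc is not None
                         else np.nan,
                         weight=wmap.get(r.name, np.nan),
                         loglik=r.loglik, r2=r.r2,
                         aicc_defined=r.aicc is not None))
    table = pd.DataFrame(rows).sort_values(
        "dAICc", na_position="last", kind="stable").reset_index(drop=True)
    winner = min(defined, key=lambda r: r.aicc)
    return ClimateCompetition(table=table, winner=winner)
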