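"""Random-intercept linear mixed models by maximum likelihood.

The models have the form

    y_i = beta0 + x'_i beta + alpha_{g[i]} + eps_i,
    alpha_g ~ N(0, sigma2_a),   eps ~ N(0, sigma2_e * R),

with a single grouping factor (individual male identity) and, optionally, a
dense residual correlation matrix R (used for the Gaussian spatial
correlation check; R = I otherwise).  Writing V = sigma2_e * W with
W = R + lambda * Z Z' and lambda = sigma2_a / sigma2_e, both beta and
sigma2_e have closed-form profiles, so fitting reduces to a one-dimensional
search over lambda.  For R = I the Woodbury identity gives O(n) solves per
evaluation.

Also here: AICc bookkeeping (k counts fixed coefficients plus the two
variance components), Akaike weights, marginal R² (variance of the
fixed-effect predictor over total variance), standardized marginal
residuals, Wald F tests with Satterthwaite denominator degrees of freedom,
the candidate-set competition, and the Gaussian correlation refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

from .errors import FitError

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# model specification and design matrices


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure of one candidate model.

    ``covariate`` is mean-centered before fitting; ``year_effects`` adds
    categorical year terms (reference = first year); ``interaction`` adds
    year x covariate terms (and implies both).  The random intercept is
    always on ``group``; estimation is maximum likelihood.
    """

    response: str
    covariate: str | None = None
    year_effects: bool = False
    interaction: bool = False
    group: str = "male_id"
    label: str | None = None

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        if self.interaction:
            return f"{self.covariate} x year"
        if self.year_effects:
            return "Year"
        if self.covariate:
            return self.covariate
        return "Null"


def build_design(df: pd.DataFrame, spec: ModelSpec
                 ) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Response vector, design matrix, column names, and group codes."""
    y = df[spec.response].to_numpy(dtype=float)
    n = len(df)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    years = np.sort(df["year"].unique()) if (spec.year_effects
                                             or spec.interaction) else None
    xc = None
    if spec.covariate is not None:
        x = df[spec.covariate].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise FitError(f"covariate {spec.covariate} is constant")
        xc = x - x.mean()
        cols.append(xc)
        names.append(spec.covariate)
    if years is not None:
        yr = df["year"].to_numpy()
        for v in years[1:]:
            cols.append((yr == v).astype(float))
            names.append(f"year[{v}]")
        if spec.interaction:
            if xc is None:
                raise FitError("interaction requires a covariate")
            for v in years[1:]:
                cols.append(xc * (yr == v))
                names.append(f"{spec.covariate}:year[{v}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("singular fixed-effect design")
    groups, _ = pd.factorize(df[spec.group], sort=True)
    return y, X, names, groups


# ---------------------------------------------------------------------------
# core ML machinery


def _w_solve(lmbda: float, groups: np.ndarray, n_groups: int,
             M: np.ndarray, R_chol=None, R: np.ndarray | None = None
             ) -> tuple[np.ndarray, float]:
    """Solve W u = M with W = R + lambda Z Z'; returns (u, log|W|).

    With R = I the Woodbury identity avoids any dense factorization.
    """
    if R is None:
        if lmbda == 0.0:
            return M, 0.0
        counts = np.bincount(groups, minlength=n_groups).astype(float)
        GtM = np.zeros((n_groups, M.shape[1]))
        np.add.at(GtM, groups, M)
        shrink = lmbda / (1.0 + lmbda * counts)
        u = M - shrink[groups, None] * GtM[groups, :]
        logdet = float(np.sum(np.log1p(lmbda * counts)))
        return u, logdet
    W = R + 0.0
    if lmbda > 0.0:
        idx = np.arange(len(groups))
        Z = np.zeros((len(groups), n_groups))
        Z[idx, groups] = 1.0
        W = W + lmbda * (Z @ Z.T)
    # near-singular correlation matrices (very long-range kernels) get an
    # escalating diagonal jitter until the factorization succeeds
    for jitter in (0.0, 1e-10, 1e-8, 1e-6, 1e-4):
        try:
            c, low = cho_factor(W + jitter * np.eye(W.shape[0]), lower=True)
            break
        except np.linalg.LinAlgError:
            continue
    else:
        raise FitError("covariance matrix not positive definite")
    u = cho_solve((c, low), M)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    return u, logdet


def _profile(lmbda: float, y: np.ndarray, X: np.ndarray, groups: np.ndarray,
             n_groups: int, R: np.ndarray | None = None) -> dict:
    """Profile log-likelihood at a fixed variance ratio lambda."""
    n, p = X.shape
    A = np.column_stack([X, y])
    WiA, logdet = _w_solve(lmbda, groups, n_groups, A, R=R)
    WiX, Wiy = WiA[:, :p], WiA[:, p]
    XtWiX = X.T @ WiX
    beta = np.linalg.solve(XtWiX, X.T @ Wiy)
    Wir = Wiy - WiX @ beta
    quad = float((y - X @ beta) @ Wir)
    sigma2 = max(quad / n, 1e-300)
    ll = -0.5 * (n * (_LOG2PI + np.log(sigma2) + 1.0) + logdet)
    return dict(ll=ll, beta=beta, sigma2_e=sigma2, XtWiX=XtWiX, lmbda=lmbda)


def _ml_fit(y: np.ndarray, X: np.ndarray, groups: np.ndarray,
            n_groups: int, R: np.ndarray | None = None) -> dict:
    """Maximize the profile likelihood over lambda >= 0 (deterministic)."""
    grid = np.concatenate([[0.0], np.logspace(-4.0, 4.0, 25)])
    lls = np.array([_profile(l, y, X, groups, n_groups, R)["ll"]
                    for l in grid])
    i = int(np.argmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi <= lo:
        best_l = grid[i]
    else:
        lo = max(lo, 1e-10)
        res = optimize.minimize_scalar(
            lambda t: -_profile(np.exp(t), y, X, groups, n_groups, R)["ll"],
            bounds=(np.log(lo), np.log(max(hi, 2e-10))), method="bounded",
            options=dict(xatol=1e-10))
        best_l = float(np.exp(res.x))
        if _profile(0.0, y, X, groups, n_groups, R)["ll"] >= \
                _profile(best_l, y, X, groups, n_groups, R)["ll"]:
            best_l = 0.0
    out = _profile(best_l, y, X, groups, n_groups, R)
    out["sigma2_a"] = out["lmbda"] * out["sigma2_e"]
    return out


def aicc(loglik: float, k: int, n: int) -> float:
    """Second-order Akaike information criterion."""
    if n - k - 1 <= 0:
        raise FitError(f"AICc undefined: n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values: np.ndarray) -> np.ndarray:
    d = np.asarray(aicc_values, dtype=float)
    d = d - d.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


# ---------------------------------------------------------------------------
# fitted-model container


@dataclass
class LMMFit:
    """A fitted random-intercept LMM (maximum likelihood)."""

    spec: ModelSpec
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    sigma2_a: float
    sigma2_e: float
    lmbda: float
    loglik: float
    n: int
    n_groups: int
    y: np.ndarray = field(repr=False)
    X: np.ndarray = field(repr=False)
    groups: np.ndarray = field(repr=False)
    R: np.ndarray | None = field(repr=False, default=None)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def k(self) -> int:
        """Parameter count: fixed coefficients plus two variance components."""
        return self.p + 2

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n)

    @property
    def fitted_fixed(self) -> np.ndarray:
        return self.X @ self.beta

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.beta, "se": self.se},
                            index=self.names)

    def term_columns(self, term: str) -> list[int]:
        """Design-matrix columns belonging to a named model term."""
        if term == "year":
            idx = [i for i, nm in enumerate(self.names)
                   if nm.startswith("year[")]
        elif term == "interaction":
            idx = [i for i, nm in enumerate(self.names) if ":year[" in nm]
        elif term in self.names:
            idx = [self.names.index(term)]
        elif self.spec.covariate == term or term == "covariate":
            idx = [self.names.index(self.spec.covariate)]
        else:
            idx = []
        if not idx:
            raise FitError(f"term {term!r} not in fixed effects {self.names}")
        return idx

    def marginal_covariance(self) -> np.ndarray:
        """Dense V = sigma2_a Z Z' + sigma2_e R."""
        n = self.n
        R = np.eye(n) if self.R is None else self.R
        same = (self.groups[:, None] == self.groups[None, :]).astype(float)
        return self.sigma2_a * same + self.sigma2_e * R


def fit_lmm(df: pd.DataFrame, spec: ModelSpec,
            R: np.ndarray | None = None) -> LMMFit:
    """Fit the model by maximum likelihood.

    Requires at least two groups with repeated observations so the
    random-intercept variance is identifiable.
    """
    y, X, names, groups = build_design(df, spec)
    n_groups = int(groups.max()) + 1
    counts = np.bincount(groups, minlength=n_groups)
    if n_groups < 2 or (counts >= 2).sum() < 2:
        raise FitError("need >= 2 groups with >= 2 observations each")
    res = _ml_fit(y, X, groups, n_groups, R)
    C = res["sigma2_e"] * np.linalg.inv(res["XtWiX"])
    return LMMFit(spec=spec, names=names, beta=res["beta"],
                  se=np.sqrt(np.diag(C)), sigma2_a=res["sigma2_a"],
                  sigma2_e=res["sigma2_e"], lmbda=res["lmbda"],
                  loglik=res["ll"], n=len(y), n_groups=n_groups,
                  y=y, X=X, groups=groups, R=R)


def marginal_r2(fit: LMMFit) -> float:
    """Proportion of total variance explained by the fixed effects alone."""
    var_f = float(np.var(fit.fitted_fixed, ddof=1)) if fit.n > 1 else 0.0
    total = var_f + fit.sigma2_a + fit.sigma2_e
    if total <= 0 or var_f < 1e-14 * total:
        return 0.0
    return var_f / total


def extract_marginal_residuals(fit: LMMFit, standardize: bool = True
                               ) -> np.ndarray:
    """Marginal residuals y - X beta, optionally standardized.

    Standardization divides by the square root of the diagonal of the
    estimated covariance of the marginal residuals,
    Var(r) = V - X (X' V^-1 X)^-1 X'.
    """
    r = fit.y - fit.fitted_fixed
    if not standardize:
        return r
    V = fit.marginal_covariance()
    Vi = np.linalg.inv(V)
    C = np.linalg.inv(fit.X.T @ Vi @ fit.X)
    var_r = np.diag(V) - np.einsum("ij,jk,ik->i", fit.X, C, fit.X)
    var_r = np.maximum(var_r, 1e-12)
    return r / np.sqrt(var_r)


# ---------------------------------------------------------------------------
# Satterthwaite F tests


@dataclass
class SatterthwaiteResult:
    F: float
    df1: int
    df2: float
    p_value: float


def _profile_ll_theta(fit: LMMFit, s2a: float, s2e: float) -> float:
    """Log-likelihood at variance components (s2a, s2e), beta profiled."""
    lmbda = s2a / s2e
    n, p = fit.X.shape
    A = np.column_stack([fit.X, fit.y])
    WiA, logdet = _w_solve(lmbda, fit.groups, fit.n_groups, A, R=fit.R)
    WiX, Wiy = WiA[:, :p], WiA[:, p]
    beta = np.linalg.solve(fit.X.T @ WiX, fit.X.T @ Wiy)
    quad = float((fit.y - fit.X @ beta) @ (Wiy - WiX @ beta))
    return -0.5 * (n * (_LOG2PI + np.log(s2e)) + logdet + quad / s2e)


def _contrast_var(fit: LMMFit, s2a: float, s2e: float,
                  ell: np.ndarray) -> float:
    """ell' C(theta) ell with C = (X' V^-1 X)^-1."""
    lmbda = s2a / s2e
    WiX, _ = _w_solve(lmbda, fit.groups, fit.n_groups, fit.X, R=fit.R)
    C = s2e * np.linalg.inv(fit.X.T @ WiX)
    return float(ell @ C @ ell)


def _theta_vcov(fit: LMMFit) -> np.ndarray:
    """Asymptotic covariance of (sigma2_a, sigma2_e) via numeric Hessian."""
    theta = np.array([fit.sigma2_a, fit.sigma2_e])
    h = 1e-4 * np.maximum(np.abs(theta), 1e-4)
    H = np.zeros((2, 2))

    def f(t):
        return _profile_ll_theta(fit, max(t[0], 0.0), max(t[1], 1e-12))

    f0 = f(theta)
    for i in range(2):
        for j in range(i, 2):
            ei = np.zeros(2); ei[i] = h[i]
            ej = np.zeros(2); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        A = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        A = np.linalg.pinv(-H)
    if not np.all(np.isfinite(A)):
        A = np.linalg.pinv(-H)
    return A


def _satt_df_one(fit: LMMFit, A: np.ndarray, ell: np.ndarray) -> float:
    """Satterthwaite df for a single contrast ell' beta."""
    theta = np.array([fit.sigma2_a, fit.sigma2_e])
    h = 1e-4 * np.maximum(np.abs(theta), 1e-4)
    g = np.zeros(2)
    for i in range(2):
        e = np.zeros(2); e[i] = h[i]
        up = _contrast_var(fit, *(np.maximum(theta + e, 0.0)), ell=ell)
        dn = _contrast_var(fit, *(np.maximum(theta - e, 1e-14)), ell=ell)
        g[i] = (up - dn) / (2 * h[i])
    f_val = _contrast_var(fit, theta[0], theta[1], ell)
    denom = float(g @ A @ g)
    if denom <= 0:
        return float(fit.n - fit.p)
    return 2.0 * f_val ** 2 / denom


def likelihood_ratio_test(fit: LMMFit, term: str) -> SatterthwaiteResult:
    """Likelihood-ratio fallback: refit without the term, chi-square p.

    Reported on the F scale (F = chi2/q with infinite denominator df) so it
    is interchangeable with :func:`satterthwaite_f` output.
    """
    idx = fit.term_columns(term)
    keep = [i for i in range(fit.p) if i not in idx]
    X0 = fit.X[:, keep]
    res0 = _ml_fit(fit.y, X0, fit.groups, fit.n_groups, fit.R)
    q = len(idx)
    chi2 = max(2.0 * (fit.loglik - res0["ll"]), 0.0)
    return SatterthwaiteResult(F=chi2 / q, df1=q, df2=float("inf"),
                               p_value=float(stats.chi2.sf(chi2, q)))


def satterthwaite_f(fit: LMMFit, term: str,
                    method: str = "satterthwaite") -> SatterthwaiteResult:
    """Wald F test for a model term with Satterthwaite denominator df.

    For a multi-coefficient term, the contrast covariance is
    eigen-decomposed into independent one-df contrasts whose Satterthwaite
    dfs are combined as in standard mixed-model practice.  When the
    random-intercept variance collapses to zero the model is ordinary least
    squares and the exact OLS F on (q, n - p) df is returned.
    ``method="lrt"`` switches to the likelihood-ratio fallback.
    """
    if method == "lrt":
        return likelihood_ratio_test(fit, term)
    idx = fit.term_columns(term)
    q = len(idx)
    L = np.zeros((q, fit.p))
    for r, c in enumerate(idx):
        L[r, c] = 1.0

    if fit.lmbda < 1e-7 and fit.R is None:
        # degenerate case: sigma2_a = 0 -> exact OLS F with unbiased sigma2
        r = fit.y - fit.fitted_fixed
        s2 = float(r @ r) / (fit.n - fit.p)
        C = s2 * np.linalg.inv(fit.X.T @ fit.X)
        M = L @ C @ L.T
        Lb = L @ fit.beta
        F = float(Lb @ np.linalg.solve(M, Lb)) / q
        df2 = float(fit.n - fit.p)
        return SatterthwaiteResult(F=F, df1=q, df2=df2,
                                   p_value=float(stats.f.sf(F, q, df2)))

    A = _theta_vcov(fit)
    WiX, _ = _w_solve(fit.lmbda, fit.groups, fit.n_groups, fit.X, R=fit.R)
    C = fit.sigma2_e * np.linalg.inv(fit.X.T @ WiX)
    M = L @ C @ L.T
    Lb = L @ fit.beta
    F = float(Lb @ np.linalg.solve(M, Lb)) / q
    if q == 1:
        df2 = _satt_df_one(fit, A, L[0])
    else:
        vals, vecs = np.linalg.eigh(M)
        nus = []
        for m in range(q):
            ell = vecs[:, m] @ L
            nus.append(_satt_df_one(fit, A, ell))
        nus = np.asarray(nus)
        ok = nus > 2.0
        E = float(np.sum(nus[ok] / (nus[ok] - 2.0)))
        df2 = 2.0 * E / (E - q) if E > q else float(fit.n - fit.p)
    df2 = float(np.clip(df2, 1.0, 1e8))
    return SatterthwaiteResult(F=F, df1=q, df2=df2,
                               p_value=float(stats.f.sf(F, q, df2)))


# ---------------------------------------------------------------------------
# candidate-set competition


def candidate_specs(response: str, group: str = "male_id") -> dict[str, ModelSpec]:
    """The residual-model candidate set: null, year, and year x covariate."""
    return {
        "Null": ModelSpec(response, group=group, label="Null"),
        "Year": ModelSpec(response, year_effects=True, group=group,
                          label="Year"),
        "Distance from permanent freshwater x year": ModelSpec(
            response, covariate="dist_water_km", year_effects=True,
            interaction=True, group=group,
            label="Distance from permanent freshwater x year"),
        "Unpaired adult male density x year": ModelSpec(
            response, covariate="unpaired_male_density", year_effects=True,
            interaction=True, group=group,
            label="Unpaired adult male density x year"),
        "Total density x year": ModelSpec(
            response, covariate="total_density", year_effects=True,
            interaction=True, group=group,
            label="Total density x year"),
    }


def compete_models(df: pd.DataFrame, response: str, group: str = "male_id",
                   specs: dict[str, ModelSpec] | None = None
                   ) -> tuple[pd.DataFrame, dict[str, LMMFit]]:
    """Fit the candidate set and rank by AICc.

    Returns the competition table (model, k, AICc, dAICc, weight,
    log-likelihood, marginal R²) sorted by dAICc, and the fitted models.
    """
    specs = specs or candidate_specs(response, group=group)
    fits = {name: fit_lmm(df, spec) for name, spec in specs.items()}
    rows = []
    for name, fit in fits.items():
        rows.append(dict(model=name, k=fit.k, AICc=fit.aicc,
                         loglik=fit.loglik, marginal_r2=marginal_r2(fit)))
    table = pd.DataFrame(rows)
    table["dAICc"] = table["AICc"] - table["AICc"].min()
    table["weight"] = akaike_weights(table["AICc"].to_numpy())
    table = table.sort_values("dAICc", kind="stable").reset_index(drop=True)
    return table[["model", "k", "dAICc", "weight", "loglik",
                  "marginal_r2", "AICc"]], fits


# ---------------------------------------------------------------------------
# Gaussian spatial-correlation check


@dataclass
class GaussianCorrelationResult:
    delta_aicc: float        # AICc(correlated) - AICc(uncorrelated); > 0 means
    best_rho_km: float       # correlation not supported
    loglik_corr: float
    loglik_base: float


def fit_with_correlation(fit: LMMFit, R: np.ndarray) -> LMMFit:
    """Refit the same design with a dense residual correlation matrix."""
    res = _ml_fit(fit.y, fit.X, fit.groups, fit.n_groups, R)
    C = res["sigma2_e"] * np.linalg.inv(res["XtWiX"])
    return LMMFit(spec=fit.spec, names=fit.names, beta=res["beta"],
                  se=np.sqrt(np.diag(C)), sigma2_a=res["sigma2_a"],
                  sigma2_e=res["sigma2_e"], lmbda=res["lmbda"],
                  loglik=res["ll"], n=fit.n, n_groups=fit.n_groups,
                  y=fit.y, X=fit.X, groups=fit.groups, R=R)


def gaussian_correlation_check(fit: LMMFit, locations: np.ndarray,
                               rho_grid: np.ndarray | None = None
                               ) -> GaussianCorrelationResult:
    """Does a Gaussian residual correlation exp(-(d/rho)^2) improve the fit?

    The range rho is profiled over a log-spaced grid (default 16 values in
    [0.1, 50] km); the correlated model carries one extra parameter.  A
    positive AICc difference means the correlation structure is not
    supported.
    """
    locs = np.asarray(locations, dtype=float)
    D = cdist(locs, locs)
    if D.max() <= 0:
        raise FitError("degenerate geometry: all locations identical")
    if rho_grid is None:
        rho_grid = np.logspace(np.log10(0.1), np.log10(50.0), 16)
    best_ll, best_rho = -np.inf, float(rho_grid[0])
    for rho in rho_grid:
        R = np.exp(-((D / rho) ** 2))
        np.fill_diagonal(R, 1.0)
        res = _ml_fit(fit.y, fit.X, fit.groups, fit.n_groups, R)
        if res["ll"] > best_ll:
            best_ll, best_rho = res["ll"], float(rho)
    delta = aicc(best_ll, fit.k + 1, fit.n) - fit.aicc
    return GaussianCorrelationResult(delta_aicc=float(delta),
                                     best_rho_km=best_rho,
                                     loglik_corr=float(best_ll),
                                     loglik_base=float(fit.loglik))
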