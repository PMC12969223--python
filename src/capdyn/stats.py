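"""Robust moderation statistics for CAP metrics.

The workhorse is an MM-estimator with Tukey's bisquare loss: a high-breakdown
S-estimate of scale (bisquare with tuning constant 1.5476, breakdown point
50%) obtained by a fast-S subset search, followed by an IRLS M-step with the
95%-efficiency constant 4.6851 at fixed scale.  Observations are downweighted
smoothly as a function of their scaled residuals; the fitted weights are part
of the report.

Inference is nonparametric: case-resampling bootstrap for percentile
confidence intervals and two-sided sign-share p-values, Freedman–Lane
permutation for nested model comparison (linear vs polynomial), BIC from
robustness-weighted residual sums, and Benjamini–Hochberg FDR over families
of tests.  Moderation models follow standard practice: continuous predictors
are mean-centered before the product term is formed, and standardized
coefficients come from refitting on z-scored variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ConvergenceError, InputError

logger = logging.getLogger(__name__)

# Tukey bisquare tuning constants: 50% breakdown for the S-scale,
# 95% Gaussian efficiency for the M-step.
C_SCALE = 1.5476
C_EFFICIENCY = 4.6851
BREAKDOWN_B = 0.5


def bisquare_rho(u: np.ndarray, c: float) -> np.ndarray:
    """Tukey bisquare loss, normalized to max 1."""
    x = np.clip(np.abs(u) / c, 0, 1)
    return 1.0 - (1.0 - x**2) ** 3


def bisquare_weights(u: np.ndarray, c: float) -> np.ndarray:
    """IRLS weights w(u) = psi(u)/u in [0, 1]."""
    x = np.abs(u) / c
    w = (1.0 - x**2) ** 2
    w[x > 1] = 0.0
    return w


def mscale(resid: np.ndarray, c: float = C_SCALE, b: float = BREAKDOWN_B,
           s0: float | None = None, tol: float = 1e-10, max_iter: int = 200) -> float:
    """M-estimate of scale solving mean(rho(r/s)) = b."""
    r = np.abs(np.asarray(resid, dtype=np.float64))
    if not r.any():
        return 0.0
    s = s0 if s0 and s0 > 0 else np.median(r[r > 0]) / 0.6745
    for _ in range(max_iter):
        avg = bisquare_rho(r / s, c).mean()
        s_new = s * np.sqrt(avg / b) if avg > 0 else s * 0.5
        if abs(s_new - s) <= tol * s:
            return float(s_new)
        s = s_new
    return float(s)


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    Xw = X * w[:, None]
    beta, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ y, rcond=None)
    return beta


def _mscale_batch(R: np.ndarray, n_iter: int = 12) -> np.ndarray:
    """Approximate M-scale per column of a residual matrix (fixed-point)."""
    A = np.abs(R)
    exact = A.max(axis=0) == 0
    s = np.median(A, axis=0) / 0.6745
    fallback = A.mean(axis=0) / 0.6745
    s = np.where(s > 0, s, fallback)
    s = np.where(exact, 1.0, s)          # placeholder; restored to 0 below
    for _ in range(n_iter):
        avg = bisquare_rho(A / s, C_SCALE).mean(axis=0)
        s = s * np.sqrt(np.maximum(avg, 1e-12) / BREAKDOWN_B)
    return np.where(exact, 0.0, s)


def _s_candidates(y: np.ndarray, X: np.ndarray, n_subsets: int, s_refine: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Fast-S search: refine elemental-subset candidates (plus the LS fit) in
    batch and return the (coefficients, scale) pair with the smallest scale."""
    n, p = X.shape
    betas = [np.linalg.lstsq(X, y, rcond=None)[0]]
    for _ in range(n_subsets):
        idx = rng.choice(n, size=p, replace=False)
        try:
            betas.append(np.linalg.solve(X[idx], y[idx]))
        except np.linalg.LinAlgError:
            continue
    B = np.stack(betas)                      # (m, p)
    R = y[:, None] - X @ B.T                 # (n, m)
    s = _mscale_batch(R)
    for _ in range(s_refine):
        live = s > 0
        if not live.any():
            break
        U = np.where(live, R / np.where(live, s, 1.0), 0.0)
        W = bisquare_weights(U, C_SCALE)     # (n, m)
        G = np.einsum("nm,np,nq->mpq", W, X, X)
        h = np.einsum("nm,np->mp", W * y[:, None], X)
        try:
            B_new = np.linalg.solve(G, h[..., None])[..., 0]
        except np.linalg.LinAlgError:
            break
        B = np.where(live[:, None], B_new, B)
        R = y[:, None] - X @ B.T
        s = _mscale_batch(R)
    j = int(np.argmin(s))
    return B[j], float(s[j])


@dataclass
class MMFitResult:
    """Coefficients, scale and robustness weights of one MM fit."""

    coef: np.ndarray
    scale: float
    weights: np.ndarray
    fitted: np.ndarray
    resid: np.ndarray
    r2_weighted: float
    rss_weighted: float
    n_iter: int
    converged: bool

    @property
    def n(self) -> int:
        return self.weights.size


def _weighted_r2(y: np.ndarray, resid: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    rss = float(np.sum(w * resid**2))
    if w.sum() == 0:
        return 0.0, rss
    ybar = np.average(y, weights=w)
    tss = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return r2, rss


def mm_fit(y, X, *, n_subsets: int = 50, s_refine: int = 2, tol: float = 1e-8,
           max_iter: int = 500, seed: int = 0) -> MMFitResult:
    """Tukey-bisquare MM regression.

    An S-estimate of (coefficients, scale) is found by refining ``n_subsets``
    random elemental-subset candidates and keeping the smallest scale; the
    M-step then iterates IRLS with the efficiency constant at fixed scale to
    a coefficient fixed point.  Deterministic for a given seed.  Exact fits
    (zero residual scale) short-circuit with unit weights.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    if n <= p:
        raise InputError(f"need more observations ({n}) than parameters ({p})")
    _, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise InputError("design matrix is rank deficient")

    rng = np.random.default_rng(seed)
    beta, scale = _s_candidates(y, X, n_subsets, s_refine, rng)
    scale_floor = 1e-12 * max(1.0, float(np.abs(y).max()))
    if scale <= scale_floor:             # exact fit: zero-residual fixed point
        r = y - X @ beta
        r2, rss = 1.0, 0.0
        return MMFitResult(coef=beta, scale=0.0, weights=np.ones(n), fitted=X @ beta,
                           resid=r, r2_weighted=r2, rss_weighted=rss, n_iter=0,
                           converged=True)
    # polish the S-scale at the winning candidate
    r = y - X @ beta
    scale = mscale(r, s0=scale)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = bisquare_weights(r / scale, C_EFFICIENCY)
        if w.sum() == 0:
            raise ConvergenceError("all observations rejected by the bisquare weights",
                                   last_result=beta)
        beta_new = _wls(X, y, w)
        delta = np.max(np.abs(beta_new - beta)) / max(1.0, np.max(np.abs(beta_new)))
        beta = beta_new
        r = y - X @ beta
        if delta < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"M-step did not converge in {max_iter} iterations",
                               last_result=beta)
    w = bisquare_weights(r / scale, C_EFFICIENCY)
    r2, rss = _weighted_r2(y, r, w)
    return MMFitResult(coef=beta, scale=scale, weights=w, fitted=X @ beta, resid=r,
                       r2_weighted=r2, rss_weighted=rss, n_iter=it, converged=True)


# ---------------------------------------------------------------------------
# bootstrap inference


def bootstrap_coefs(y, X, n_boot: int = 10000, seed: int = 0,
                    build=None, data=None, max_redraws: int = 100,
                    **fit_kwargs) -> np.ndarray:
    """Case-resampling bootstrap distribution of MM coefficients.

    When ``build`` is given it maps a resampled DataFrame (``data`` rows) to
    (y, X), so that design construction (centering, products) is repeated
    within each resample.  Rank-deficient resamples are rejected and redrawn.
    """
    rng = np.random.default_rng(seed)
    if build is None:
        y = np.asarray(y, dtype=np.float64)
        X = np.asarray(X, dtype=np.float64)
        n = len(y)
    else:
        n = len(data)
    draws = []
    n_rejected = 0
    while len(draws) < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            if build is None:
                fit = mm_fit(y[idx], X[idx], **fit_kwargs)
            else:
                yb, Xb = build(data.iloc[idx])
                fit = mm_fit(yb, Xb, **fit_kwargs)
            draws.append(fit.coef)
        except (InputError, ConvergenceError):
            n_rejected += 1
            if n_rejected > max_redraws + n_boot:
                raise
    if n_rejected:
        logger.info("redrew %d degenerate bootstrap resamples", n_rejected)
    return np.vstack(draws)


def percentile_ci(draws: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Percentile CIs per column; shape (p, 2)."""
    lo = np.percentile(draws, 100 * alpha / 2, axis=0)
    hi = np.percentile(draws, 100 * (1 - alpha / 2), axis=0)
    return np.column_stack([lo, hi])


def sign_share_p(draws: np.ndarray) -> np.ndarray:
    """Two-sided bootstrap p per column: 2 * min share of draws on either
    side of zero, with the add-one correction, capped at 1."""
    B = draws.shape[0]
    le = (draws <= 0).sum(axis=0)
    ge = (draws >= 0).sum(axis=0)
    p = 2.0 * (np.minimum(le, ge) + 1) / (B + 1)
    return np.minimum(p, 1.0)


@dataclass
class FitReport:
    """One robust regression with bootstrap inference."""

    outcome: str
    terms: pd.DataFrame          # index term; columns B, beta, ci_low, ci_high, p
    n: int
    fit: MMFitResult
    boot_coefs: np.ndarray = field(repr=False)
    moderator_sd: float | None = None
    term_names: list[str] = field(default_factory=list)

    @property
    def weights(self) -> np.ndarray:
        return self.fit.weights


def _standardized_coefs(y, X, continuous: np.ndarray, **fit_kwargs) -> np.ndarray:
    """Refit on z-scored outcome and continuous predictors; the product term
    is rebuilt from the z-scored factors.  Columns flagged non-continuous
    (intercept, binary) are left untouched."""
    y = np.asarray(y, float)
    Xz = np.asarray(X, float).copy()
    ysd = y.std()
    yz = (y - y.mean()) / ysd if ysd > 0 else y - y.mean()
    for j in np.flatnonzero(continuous):
        sd = Xz[:, j].std()
        if sd > 0:
            Xz[:, j] = (Xz[:, j] - Xz[:, j].mean()) / sd
    return mm_fit(yz, Xz, **fit_kwargs).coef


def _report(outcome, term_names, y, X, continuous, data, build, n_boot, seed,
            moderator_sd=None, **fit_kwargs) -> FitReport:
    fit = mm_fit(y, X, **fit_kwargs)
    beta_std = _standardized_coefs(y, X, continuous, **fit_kwargs)
    if n_boot == 0:                      # point estimates only
        nan = np.full(fit.coef.size, np.nan)
        terms = pd.DataFrame({"B": fit.coef, "beta": beta_std, "ci_low": nan,
                              "ci_high": nan, "p": nan},
                             index=pd.Index(term_names, name="term"))
        return FitReport(outcome=outcome, terms=terms, n=len(y), fit=fit,
                         boot_coefs=np.empty((0, fit.coef.size)),
                         moderator_sd=moderator_sd, term_names=list(term_names))
    draws = bootstrap_coefs(y, X, n_boot=n_boot, seed=seed, build=build,
                            data=data, **fit_kwargs)
    ci = percentile_ci(draws)
    p = sign_share_p(draws)
    outside = (fit.coef < ci[:, 0]) | (fit.coef > ci[:, 1])
    for j in np.flatnonzero(outside):
        logger.warning("estimate for %s lies outside its bootstrap CI "
                       "(extreme bootstrap skew)", term_names[j])
    terms = pd.DataFrame({"B": fit.coef, "beta": beta_std,
                          "ci_low": ci[:, 0], "ci_high": ci[:, 1], "p": p},
                         index=pd.Index(term_names, name="term"))
    return FitReport(outcome=outcome, terms=terms, n=len(y), fit=fit,
                     boot_coefs=draws, moderator_sd=moderator_sd,
                     term_names=list(term_names))


def _encode_sex(col: pd.Series) -> np.ndarray:
    if col.dtype.kind in "ifu":
        return col.to_numpy(dtype=float)
    return (col.astype(str) == "F").to_numpy(dtype=float)


def _moderation_design(df: pd.DataFrame, outcome: str, include_interaction: bool):
    y = df[outcome].to_numpy(dtype=float)
    rnt_c = df["rnt"].to_numpy(float) - df["rnt"].mean()
    neu_c = df["neu"].to_numpy(float) - df["neu"].mean()
    cols = [np.ones(len(df)), rnt_c, neu_c]
    names = ["intercept", "rnt", "neu"]
    if include_interaction:
        cols.append(rnt_c * neu_c)
        names.append("rnt_x_neu")
    cols += [df["age"].to_numpy(float), _encode_sex(df["sex"])]
    names += ["age", "sex"]
    return y, np.column_stack(cols), names


def moderation(data: pd.DataFrame, outcome: str, n_boot: int = 10000,
               seed: int = 0, include_interaction: bool = True,
               **fit_kwargs) -> FitReport:
    """Robust moderation model: outcome ~ rnt * neu + age + sex.

    rnt and neu are mean-centered before the product term is formed
    (re-done inside every bootstrap resample).  Incomplete cases are dropped
    listwise.  Set ``include_interaction=False`` to omit the product term
    when moderation is judged uninformative.
    """
    cols = [outcome, "rnt", "neu", "age", "sex"]
    complete = data.dropna(subset=cols).reset_index(drop=True)
    dropped = len(data) - len(complete)
    if dropped:
        logger.info("listwise deletion removed %d incomplete cases", dropped)

    def build(df):
        yb, Xb, _ = _moderation_design(df, outcome, include_interaction)
        return yb, Xb

    y, X, names = _moderation_design(complete, outcome, include_interaction)
    continuous = np.array([name in ("rnt", "neu", "rnt_x_neu", "age") for name in names])
    return _report(outcome, names, y, X, continuous, complete, build, n_boot,
                   seed, moderator_sd=float(complete["neu"].std(ddof=1)), **fit_kwargs)


def simple_slopes(report: FitReport, levels=(-1.0, 1.0)) -> pd.DataFrame:
    """Conditional slope of rnt at moderator values mean + level * SD(neu),
    with CIs from the joint bootstrap distribution of (b_rnt, b_interaction)."""
    if "rnt_x_neu" not in report.term_names:
        raise InputError("model has no rnt x neu interaction term")
    j_rnt = report.term_names.index("rnt")
    j_int = report.term_names.index("rnt_x_neu")
    sd = report.moderator_sd
    rows = []
    for level in levels:
        slope = report.fit.coef[j_rnt] + level * sd * report.fit.coef[j_int]
        draws = report.boot_coefs[:, j_rnt] + level * sd * report.boot_coefs[:, j_int]
        lo, hi = np.percentile(draws, [2.5, 97.5])
        p = sign_share_p(draws[:, None])[0]
        rows.append((level, slope, lo, hi, p))
    return pd.DataFrame(rows, columns=["moderator_level_sd", "slope",
                                       "ci_low", "ci_high", "p"])


def cap_to_cap(data: pd.DataFrame, outcome: str, predictor: str,
               covariates=("age", "sex"), n_boot: int = 10000, seed: int = 0,
               **fit_kwargs) -> FitReport:
    """Association between two CAP metrics with age/sex covariates."""
    cols = [outcome, predictor, *covariates]
    complete = data.dropna(subset=cols).reset_index(drop=True)

    def design(df):
        y = df[outcome].to_numpy(float)
        parts = [np.ones(len(df)), df[predictor].to_numpy(float)]
        for c in covariates:
            parts.append(_encode_sex(df[c]) if c == "sex" else df[c].to_numpy(float))
        return y, np.column_stack(parts)

    names = ["intercept", predictor, *covariates]
    y, X = design(complete)
    continuous = np.array([name not in ("intercept", "sex") for name in names])
    return _report(outcome, names, y, X, continuous, complete, design, n_boot,
                   seed, **fit_kwargs)


# ---------------------------------------------------------------------------
# polynomial model comparison


@dataclass
class ModelComparison:
    delta_r2: float              # percentage points
    delta_r2_ci: tuple[float, float]
    p_perm: float
    delta_bic: float
    n_perm: int
    n_boot: int


def _bic(fit: MMFitResult, n: int, p: int) -> float:
    rss = max(fit.rss_weighted, 1e-300)
    return n * np.log(rss / n) + p * np.log(n)


def compare_polynomial(data: pd.DataFrame, outcome: str, focal: str = "rnt",
                       covariates=("neu", "age", "sex"), n_boot: int = 1000,
                       n_perm: int = 5000, seed: int = 0,
                       **fit_kwargs) -> ModelComparison:
    """Does a quadratic term in the focal predictor improve the robust fit?

    Reports the change in robustness-weighted R-squared (percentage points)
    with a case-resampling bootstrap CI, a Freedman–Lane permutation p-value
    (null-model residuals are permuted, both models refit), and the BIC
    difference (polynomial minus null) from weighted residual sums.
    """
    cols = [outcome, focal, *covariates]
    complete = data.dropna(subset=cols).reset_index(drop=True)
    n = len(complete)

    def designs(df, y_override=None):
        y = df[outcome].to_numpy(float) if y_override is None else y_override
        f = df[focal].to_numpy(float)
        f_c = f - f.mean()
        parts = [np.ones(len(df)), f_c]
        for c in covariates:
            parts.append(_encode_sex(df[c]) if c == "sex" else df[c].to_numpy(float))
        X_null = np.column_stack(parts)
        X_poly = np.column_stack(parts + [f_c**2])
        return y, X_null, X_poly

    def delta_r2_of(df, y_override=None):
        y, X0, X1 = designs(df, y_override)
        fit0 = mm_fit(y, X0, **fit_kwargs)
        fit1 = mm_fit(y, X1, **fit_kwargs)
        return (fit1.r2_weighted - fit0.r2_weighted) * 100.0, fit0, fit1

    observed, fit_null, fit_poly = delta_r2_of(complete)
    delta_bic = _bic(fit_poly, n, fit_poly.coef.size) - _bic(fit_null, n, fit_null.coef.size)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            boot[b], *_ = delta_r2_of(complete.iloc[idx].reset_index(drop=True))
        except (InputError, ConvergenceError):
            boot[b] = np.nan
    boot = boot[~np.isnan(boot)]
    ci = tuple(np.percentile(boot, [2.5, 97.5]))

    exceed = 0
    for _ in range(n_perm):
        y_star = fit_null.fitted + rng.permutation(fit_null.resid)
        try:
            d, *_ = delta_r2_of(complete, y_override=y_star)
        except (InputError, ConvergenceError):
            continue
        if d >= observed:
            exceed += 1
    p_perm = (1 + exceed) / (n_perm + 1)
    return ModelComparison(delta_r2=observed, delta_r2_ci=ci, p_perm=p_perm,
                           delta_bic=float(delta_bic), n_perm=n_perm, n_boot=n_boot)


def fdr_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InputError("p must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
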