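"""Frequentist random-effects meta-regression.

Estimators for the between-study variance tau^2 and regression coefficients
beta in the model ``y_i ~ N(x_i beta, sigma_i^2 + tau^2)``:

* DerSimonian–Laird (``dl``): method of moments from the fixed-effect
  residual Q statistic, generalized to meta-regression.
* Maximum likelihood (``ml``): profile likelihood in tau^2.
* Restricted maximum likelihood (``reml``): profile likelihood plus the
  ``-1/2 log |X' W X|`` correction for estimating beta.

Confidence intervals for tau^2 come from inverting the generalized Q statistic
against chi-square quantiles (Q-profile); intervals for coefficients are Wald
intervals with the standard normal quantile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .data_model import Dataset

__all__ = ["FitResult", "fit", "fit_dl", "fit_ml", "fit_reml", "qprofile_ci", "wald_ci"]

_TAU2_EPS = 1e-10


@dataclass(frozen=True)
class FitResult:
    """Meta-regression fit: coefficients, tau^2 and diagnostics.

    ``coefficients`` holds beta-hat (a single mu-hat for a plain
    meta-analysis); ``coef_cov`` its covariance ``(X' W X)^{-1}`` at
    ``W = diag(1/(sigma_i^2 + tau2))``.  ``Q``/``df``/``I2`` are the
    fixed-effect heterogeneity diagnostics; ``truncated`` flags a tau^2
    estimate clipped at zero.
    """

    coefficients: np.ndarray
    coef_cov: np.ndarray
    tau2: float
    tau2_ci: tuple[float, float] | None
    method: str
    Q: float
    df: int
    I2: float
    n_used: int
    truncated: bool

    @property
    def mu(self) -> float:
        """The summary effect for a single-coefficient model."""
        if self.coefficients.size != 1:
            raise ValueError("mu is defined only for single-coefficient fits")
        return float(self.coefficients[0])

    @property
    def mu_se(self) -> float:
        if self.coefficients.size != 1:
            raise ValueError("mu_se is defined only for single-coefficient fits")
        return float(math.sqrt(self.coef_cov[0, 0]))

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.coef_cov))

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.tolist(),
            "coef_cov": self.coef_cov.tolist(),
            "tau2": self.tau2,
            "tau2_ci": list(self.tau2_ci) if self.tau2_ci is not None else None,
            "method": self.method,
            "Q": self.Q,
            "df": self.df,
            "I2": self.I2,
            "n_used": self.n_used,
            "truncated": self.truncated,
        }


def wald_ci(estimate: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """``estimate +/- z_{(1+level)/2} * se`` with the normal quantile."""
    if se < 0:
        raise ValueError("standard error must be >= 0")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return estimate - z * se, estimate + z * se


def _wls(y: np.ndarray, X: np.ndarray, w: np.ndarray):
    """Weighted least squares: beta-hat, (X'WX)^{-1} and residuals."""
    XtW = X.T * w
    A = XtW @ X
    try:
        A_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular design matrix in weighted least squares") from exc
    beta = A_inv @ (XtW @ y)
    return beta, A_inv, y - X @ beta


def _fe_diagnostics(y, v, X):
    """Fixed-effect residual Q, its df and the moments denominator C."""
    n, p = X.shape
    w = 1.0 / v
    beta, A_inv, resid = _wls(y, X, w)
    Q = float(np.sum(w * resid**2))
    df = n - p
    XtW2X = (X.T * w**2) @ X
    C = float(np.sum(w) - np.trace(A_inv @ XtW2X))
    return Q, df, C


def _nll_profile(tau2: float, y, v, X, reml: bool) -> float:
    """Negative profile log-likelihood of tau^2 (beta profiled out by WLS)."""
    s = v + tau2
    w = 1.0 / s
    XtW = X.T * w
    A = XtW @ X
    sign, logdet = np.linalg.slogdet(A)
    if sign <= 0:
        return math.inf
    beta = np.linalg.solve(A, XtW @ y)
    resid = y - X @ beta
    nll = 0.5 * float(np.sum(np.log(2.0 * np.pi * s)) + np.sum(resid**2 * w))
    if reml:
        nll += 0.5 * logdet
    return nll


def _optimize_tau2(y, v, X, reml: bool) -> float:
    """Maximize the (restricted) profile likelihood over tau2 >= 0.

    Search on log(tau2 + eps) over [0, 10 * max marginal variance], with a
    coarse grid pass to localize the optimum before Brent refinement —
    bounded, scale free and reproducible.
    """
    upper = 10.0 * float(np.max(v) + np.var(y) + 1.0)
    lo_t, hi_t = math.log(_TAU2_EPS), math.log(upper + _TAU2_EPS)

    def g(t: float) -> float:
        return _nll_profile(math.exp(t) - _TAU2_EPS, y, v, X, reml)

    ts = np.linspace(lo_t, hi_t, 80)
    vals = np.array([g(t) for t in ts])
    i = int(np.argmin(vals))
    a, b = ts[max(i - 1, 0)], ts[min(i + 1, len(ts) - 1)]
    res = optimize.minimize_scalar(
        g, bounds=(a, b), method="bounded", options={"xatol": 1e-12}
    )
    if not res.success:  # pragma: no cover - bounded Brent rarely fails
        raise RuntimeError(f"tau2 optimization failed: {res.message}")
    tau2 = max(0.0, math.exp(res.x) - _TAU2_EPS)
    # the boundary tau2 = 0 may beat the interior optimum; estimates below
    # the optimizer's own resolution are numerically zero
    if tau2 < _TAU2_EPS:
        tau2 = 0.0
    elif _nll_profile(0.0, y, v, X, reml) < _nll_profile(tau2, y, v, X, reml):
        tau2 = 0.0
    return tau2


def _finalize(data, y, v, X, tau2, method, level, compute_tau2_ci) -> FitResult:
    Q, df, _ = _fe_diagnostics(y, v, X)
    I2 = max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    w = 1.0 / (v + tau2)
    beta, A_inv, _ = _wls(y, X, w)
    ci = qprofile_ci(data, level=level) if compute_tau2_ci else None
    return FitResult(
        coefficients=beta,
        coef_cov=A_inv,
        tau2=float(tau2),
        tau2_ci=ci,
        method=method,
        Q=Q,
        df=df,
        I2=I2,
        n_used=len(y),
        truncated=(tau2 == 0.0),
    )


def _prepare(data: Dataset):
    data.validate_for_fit()
    y, v, X = data.effects(), data.variances(), data.design()
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more studies than coefficients (n={n}, p={p})")
    return y, v, X


def fit_dl(
    data: Dataset, level: float = 0.95, compute_tau2_ci: bool = True
) -> FitResult:
    """DerSimonian–Laird method-of-moments fit.

    tau2-hat = max(0, (Q - df) / C) with C = tr(W) - tr[(X'WX)^{-1} X'W^2 X]
    at the fixed-effect weights W = diag(1/sigma_i^2), then weighted least
    squares at weights 1/(sigma_i^2 + tau2-hat).
    """
    y, v, X = _prepare(data)
    Q, df, C = _fe_diagnostics(y, v, X)
    tau2 = max(0.0, (Q - df) / C)
    return _finalize(data, y, v, X, tau2, "dl", level, compute_tau2_ci)


def fit_ml(
    data: Dataset, level: float = 0.95, compute_tau2_ci: bool = True
) -> FitResult:
    """Maximum-likelihood fit (beta profiled out, tau2 by scalar search)."""
    y, v, X = _prepare(data)
    tau2 = _optimize_tau2(y, v, X, reml=False)
    return _finalize(data, y, v, X, tau2, "ml", level, compute_tau2_ci)


def fit_reml(
    data: Dataset, level: float = 0.95, compute_tau2_ci: bool = True
) -> FitResult:
    """Restricted maximum-likelihood fit."""
    y, v, X = _prepare(data)
    tau2 = _optimize_tau2(y, v, X, reml=True)
    return _finalize(data, y, v, X, tau2, "reml", level, compute_tau2_ci)


_FITTERS = {"dl": fit_dl, "ml": fit_ml, "reml": fit_reml}


def fit(data: Dataset, method: str = "reml", **kwargs) -> FitResult:
    """Dispatch to :func:`fit_dl`, :func:`fit_ml` or :func:`fit_reml`."""
    try:
        fitter = _FITTERS[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_FITTERS)}")
    return fitter(data, **kwargs)


def generalized_q(data: Dataset, tau2: float) -> float:
    """Q(tau2) = sum (y_i - x_i beta-hat(tau2))^2 / (sigma_i^2 + tau2)
    with beta-hat(tau2) the WLS fit at that tau2."""
    y, v, X = data.effects(), data.variances(), data.design()
    w = 1.0 / (v + tau2)
    _, _, resid = _wls(y, X, w)
    return float(np.sum(w * resid**2))


def qprofile_ci(data: Dataset, level: float = 0.95) -> tuple[float, float]:
    """Q-profile confidence interval for tau^2.

    Solves ``Q(lo) = chi2_{df, (1+level)/2}`` and
    ``Q(hi) = chi2_{df, (1-level)/2}`` by bracketed root-finding; Q(tau2) is
    decreasing in tau2 so each limit is truncated at 0 when Q(0) already lies
    below the target quantile.  df = n - p, pseudo rows included when applied
    to augmented data.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    y, v, X = _prepare(data)
    n, p = X.shape
    df = n - p
    q_hi = stats.chi2.ppf(0.5 + level / 2.0, df)
    q_lo = stats.chi2.ppf(0.5 - level / 2.0, df)

    def solve(target: float) -> float:
        if generalized_q(data, 0.0) <= target:
            return 0.0
        upper = max(1.0, float(np.max(v)))
        while generalized_q(data, upper) > target:
            upper *= 2.0
            if upper > 1e12:  # pragma: no cover - Q -> 0 guarantees a root
                raise RuntimeError("Q-profile bracket growth failed")
        return float(
            optimize.brentq(
                lambda t: generalized_q(data, t) - target,
                0.0,
                upper,
                rtol=1e-10,
                maxiter=500,
            )
        )

    lo = solve(q_hi)
    hi = solve(q_lo)
    return lo, hi
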