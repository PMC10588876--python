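"""Four-parameter log-logistic (4pLL) concentration-response model.

The model for a response :math:`y` at concentration :math:`x \\ge 0` is

.. math::

    f(x; b, c, d, \\tilde e) = c + \\frac{d - c}{1 + \\exp(b(\\log x - \\tilde e))}

where *c* and *d* are the lower and upper asymptotes, *b* is proportional
to the slope at the inflection point, and :math:`\\tilde e = \\log(e)` is the
natural log of the EC50 — the concentration at which half of the maximal
effect is attained.  The log-scale parameterization keeps the EC50 positive
by construction and makes the sampling distribution of its estimator closer
to normal for small designs, which is what the cross-gene shrinkage in
:mod:`ec50shrink.empirical_bayes` relies on.

Fitting is ordinary least squares: the residual sum of squares is minimised
with a quasi-Newton (BFGS) iteration using an analytic gradient.  Standard
errors come from the usual nonlinear-regression delta method,
``resid_var * diag((J'J)^{-1})`` with ``J`` the Jacobian of the model
predictions at the optimum, and confidence intervals use the t distribution
with ``p - 4`` degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit
from scipy.stats import t as t_dist

__all__ = [
    "LL4Params",
    "ConcentrationDesign",
    "LL4Results",
    "LL4Model",
    "VPA_DESIGN",
    "predict_ll4",
    "fit_ll4",
    "confidence_interval",
    "PARAM_NAMES",
]

PARAM_NAMES = ("b", "c", "d", "e_tilde")


@dataclass(frozen=True)
class LL4Params:
    """Parameters of one 4pLL curve.

    Attributes
    ----------
    b : float
        Slope-proportional shape parameter (unitless).  Positive *b* gives a
        curve decreasing in concentration (from *d* down to *c*).
    c : float
        Lower asymptote, in response units (log2 expression for microarrays).
    d : float
        Upper asymptote, same units as *c*.
    e_tilde : float
        Natural log of the EC50 (log concentration units).
    """

    b: float
    c: float
    d: float
    e_tilde: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {name!r} must be finite, got {v}")

    @property
    def ec50(self) -> float:
        """EC50 on the concentration scale, ``exp(e_tilde)``."""
        return math.exp(self.e_tilde)

    def as_array(self) -> np.ndarray:
        return np.array([self.b, self.c, self.d, self.e_tilde], dtype=float)

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "LL4Params":
        b, c, d, e_tilde = (float(v) for v in theta)
        return cls(b=b, c=c, d=d, e_tilde=e_tilde)


@dataclass(frozen=True)
class ConcentrationDesign:
    """An experimental design: distinct concentrations and replicate counts."""

    concentrations: tuple
    replicates: tuple

    def __post_init__(self) -> None:
        conc = tuple(float(x) for x in self.concentrations)
        reps = tuple(int(r) for r in self.replicates)
        if len(conc) != len(reps):
            raise ValueError("concentrations and replicates length mismatch")
        if any(x < 0 for x in conc):
            raise ValueError("concentrations must be non-negative")
        if len(set(conc)) != len(conc):
            raise ValueError("concentrations must be distinct")
        if sum(x == 0.0 for x in conc) > 1:
            raise ValueError("at most one control (zero) concentration allowed")
        if any(r < 1 for r in reps):
            raise ValueError("replicate counts must be >= 1")
        if sum(reps) < 5:
            raise ValueError("design must yield at least 5 observations (p - 4 >= 1)")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "replicates", reps)

    @property
    def n_obs(self) -> int:
        return int(sum(self.replicates))

    def expand(self) -> np.ndarray:
        """Concentration vector with each level repeated per its replicate count."""
        return np.repeat(np.asarray(self.concentrations, dtype=float), self.replicates)


#: The valproic-acid case-study design: 6 untreated controls plus 7 treated
#: concentrations (25–1000 μM) with 3 replicates each — 27 observations.
VPA_DESIGN = ConcentrationDesign(
    concentrations=(0.0, 25.0, 150.0, 350.0, 450.0, 550.0, 800.0, 1000.0),
    replicates=(6, 3, 3, 3, 3, 3, 3, 3),
)


def _log_conc(x: np.ndarray) -> np.ndarray:
    """log(x) with x == 0 mapped to -inf (the model's control limit)."""
    with np.errstate(divide="ignore"):
        return np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), -np.inf)


def predict_ll4(params: LL4Params, x) -> np.ndarray | float:
    """Evaluate the 4pLL curve at concentration(s) ``x >= 0``.

    At ``x == 0`` the analytic right-limit is used: *d* for ``b > 0``,
    *c* for ``b < 0`` and ``(c + d)/2`` for ``b == 0``.
    """
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0):
        raise ValueError("concentrations must be non-negative")
    scalar = xa.ndim == 0
    xa = np.atleast_1d(xa)
    lx = _log_conc(xa)
    if params.b == 0.0:
        z = np.zeros_like(lx)
    else:
        z = params.b * (lx - params.e_tilde)
    # 1/(1 + exp(z)) = expit(-z); expit handles +-inf exactly
    f = params.c + (params.d - params.c) * expit(-z)
    return float(f[0]) if scalar else f


def _model_and_jacobian(theta: np.ndarray, lx: np.ndarray, is_zero: np.ndarray):
    """Predictions f and Jacobian df/d(b,c,d,e_tilde), vectorised over obs."""
    b, c, d, e_tilde = theta
    if b == 0.0:
        z = np.zeros_like(lx)
    else:
        z = b * (lx - e_tilde)
    w = expit(-z)          # 1/(1+u): weight on the upper asymptote
    wc = expit(z)          # u/(1+u): weight on the lower asymptote
    f = c + (d - c) * w
    s = w * wc             # logistic derivative term
    diff = np.where(is_zero, 0.0, lx - e_tilde)   # no b/e_tilde sensitivity at x=0
    J = np.empty((lx.size, 4))
    J[:, 0] = -(d - c) * diff * s
    J[:, 1] = wc
    J[:, 2] = w
    J[:, 3] = (d - c) * b * s
    return f, J


def _sse_and_grad(theta, lx, is_zero, y):
    f, J = _model_and_jacobian(theta, lx, is_zero)
    r = y - f
    return float(r @ r), -2.0 * (J.T @ r)


def _self_start(x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Deterministic starting values in the style of dose-response self-starters.

    d0 = mean response at the lowest concentration (control if present),
    c0 = mean response at the highest concentration; b0 and e_tilde0 from a
    linear regression of the clipped logit of the scaled response on log
    concentration over x > 0.  Fallback starts with b0 = +-1 are always
    included so a failed logit regression never leaves the optimiser
    without a sensible start.
    """
    lo, hi = x.min(), x.max()
    d0 = float(np.mean(y[x == lo]))
    c0 = float(np.mean(y[x == hi]))
    pos = x > 0
    lx = np.log(x[pos])
    med = float(np.median(lx))
    starts = []
    if d0 != c0:
        w = np.clip((y[pos] - c0) / (d0 - c0), 0.01, 0.99)
        logit_w = np.log(w / (1.0 - w))
        # model: logit(w) = -b*lx + b*e_tilde
        slope, intercept = np.polyfit(lx, logit_w, 1)
        b0 = -slope
        if np.isfinite(b0) and abs(b0) > 1e-8:
            e0 = intercept / b0
            if not np.isfinite(e0) or abs(e0 - med) > 20:
                e0 = med
            starts.append(np.array([b0, c0, d0, e0]))
    mid_c, mid_d = (c0, d0) if d0 != c0 else (y.min(), y.max())
    if mid_c == mid_d:
        mid_d = mid_c + 1.0
    # fallbacks with b0 = +-1; when the logit regression produced a start,
    # keep only the opposite-sign fallback (the same-sign basin is covered)
    if not starts or starts[0][0] < 0:
        starts.append(np.array([1.0, mid_c, mid_d, med]))
    if not starts or starts[0][0] > 0:
        starts.append(np.array([-1.0, mid_d, mid_c, med]))
    return starts


@dataclass
class LL4Results:
    """Least-squares fit of one 4pLL curve.

    ``params`` and ``std_errors`` are in the (b, c, d, e_tilde) order;
    ``residual_variance`` is SSE/(p-4) and ``df`` is p-4.  ``converged``
    is False (never an exception) when the optimiser failed or the
    information matrix J'J was numerically singular — downstream pipelines
    treat such fits as missing values.
    """

    params: LL4Params
    std_errors: np.ndarray
    residual_variance: float
    df: int
    converged: bool
    n_obs: int
    sse: float = field(default=float("nan"))

    @property
    def bse(self) -> dict:
        return dict(zip(PARAM_NAMES, self.std_errors))

    def se(self, which: str) -> float:
        return float(self.std_errors[PARAM_NAMES.index(which)])

    def predict(self, x):
        return predict_ll4(self.params, x)

    def conf_int(self, which: str = "e_tilde", level: float = 0.95):
        return confidence_interval(self, which=which, level=level)

    def summary(self) -> str:
        lines = [
            "4pLL least-squares fit",
            f"  n_obs={self.n_obs}  df={self.df}  converged={self.converged}",
            f"  SSE={self.sse:.6g}  resid_var={self.residual_variance:.6g}",
            f"  {'param':>8} {'estimate':>12} {'std err':>12}",
        ]
        for name, est, se in zip(
            PARAM_NAMES, self.params.as_array(), self.std_errors
        ):
            lines.append(f"  {name:>8} {est:12.6g} {se:12.6g}")
        return "\n".join(lines)


def fit_ll4(x, y, *, gtol: float = 1e-8, max_iter: int = 500) -> LL4Results:
    """Fit the 4pLL model to (x, y) by least squares.

    Parameters
    ----------
    x, y : array-like
        Concentrations (>= 0) and responses; at least 5 observations.
    gtol, max_iter : optimizer settings
        Gradient tolerance and iteration cap for the BFGS search.

    Returns
    -------
    LL4Results
        With ``converged=False`` (not an exception) when no usable optimum
        with a well-conditioned information matrix was found.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    p = x.size
    if p < 5:
        raise ValueError(f"need at least 5 observations, got {p}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if np.any(x < 0):
        raise ValueError("concentrations must be non-negative")

    lx = _log_conc(x)
    is_zero = x == 0

    best = None
    for theta0 in _self_start(x, y):
        sse0 = _sse_and_grad(theta0, lx, is_zero, y)[0]
        try:
            res = optimize.minimize(
                _sse_and_grad,
                theta0,
                args=(lx, is_zero, y),
                jac=True,
                method="BFGS",
                options={"gtol": gtol, "maxiter": max_iter},
            )
        except (ValueError, FloatingPointError):  # pathological line search
            continue
        theta, sse = res.x, float(res.fun)
        if not (np.all(np.isfinite(theta)) and np.isfinite(sse)):
            continue
        if sse > sse0:  # optimiser must never degrade the start
            theta, sse = theta0, sse0
        if best is None or sse < best[1]:
            best = (theta, sse)

    df = p - 4
    if best is None:
        nanp = LL4Params(0.0, 0.0, 0.0, 0.0)
        return LL4Results(nanp, np.full(4, np.nan), float("nan"), df, False, p)

    theta, sse = best
    # (b, c, d) -> (-b, d, c) leaves the curve unchanged; report the
    # canonical orientation with d >= c (upper asymptote above lower)
    if theta[2] < theta[1]:
        theta = np.array([-theta[0], theta[2], theta[1], theta[3]])
    params = LL4Params.from_array(theta)
    resid_var = sse / df
    _, J = _model_and_jacobian(theta, lx, is_zero)
    jtj = J.T @ J
    converged = True
    se = np.full(4, np.nan)
    try:
        cov = resid_var * np.linalg.inv(jtj)
        diag = np.diag(cov)
        if np.any(~np.isfinite(diag)) or np.any(diag < 0):
            converged = False
        else:
            se = np.sqrt(diag)
    except np.linalg.LinAlgError:
        converged = False
    if converged and not np.isfinite(se[3]):
        converged = False
    return LL4Results(params, se, float(resid_var), df, converged, p, sse=sse)


def confidence_interval(
    fit: LL4Results, which: str = "e_tilde", level: float = 0.95
) -> tuple:
    """t-based confidence interval ``estimate +- t_{1-a/2, p-4} * se``."""
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if not fit.converged:
        raise ValueError("confidence interval requires a converged fit")
    est = float(getattr(fit.params, which))
    se = fit.se(which)
    if not np.isfinite(se):
        raise ValueError(f"standard error for {which!r} is undefined")
    k = t_dist.ppf(1 - (1 - level) / 2, fit.df)
    return est - k * se, est + k * se


class LL4Model:
    """Concentration-response model for a single gene.

    statsmodels-style wrapper: construct from data, call :meth:`fit`.

    Examples
    --------
    >>> model = LL4Model(y, x)
    >>> res = model.fit()
    >>> res.params.e_tilde, res.conf_int("e_tilde")
    """

    def __init__(self, endog, exog):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)

    @classmethod
    def from_dataframe(cls, data, response: str = "response", conc: str = "concentration"):
        return cls(data[response].to_numpy(), data[conc].to_numpy())

    def fit(self, **options) -> LL4Results:
        return fit_ll4(self.exog, self.endog, **options)
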