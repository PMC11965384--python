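"""Binned (interval-censored) log-likelihood and maximum-likelihood fitting.

Species covers recorded on a class scale are known only up to their class
interval, so each species contributes the log of the probability mass of its
class: L(theta) = sum_i n_i ln(P_i), with P_i = F(U_i|theta) - F(L_i|theta).
Fitting maximises this over theta by derivative-free simplex search on
log-transformed parameters with a quasi-Newton polish, and reports standard
errors from the inverse numerical Hessian of the negative log-likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .models import SADModel, class_probabilities
from .scales import ClassCounts, CoverScale, class_midpoints

__all__ = [
    "FitOptions",
    "SADFit",
    "log_likelihood",
    "initial_values",
    "fit_model",
    "pareto_fixed_xm",
]

log = logging.getLogger(__name__)

# parameters this far (in log units) from the start are treated as divergent
_LOG_BOUNDARY = 20.0


@dataclass(frozen=True)
class FitOptions:
    """Optimiser settings.

    multistart jittered restarts (best kept) guard against local optima; the
    jitter stream is seeded so fits are reproducible.  ``floor`` is applied to
    P_i inside the log during optimisation only, letting the optimiser escape
    regions where an occupied class has zero mass; reported log-likelihoods
    are recomputed without it.
    """

    method: str = "Nelder-Mead"
    maxiter: int = 2000
    tol: float = 1e-8
    multistart: int = 3
    jitter_sd: float = 0.5
    seed: int = 0
    floor: float = 1e-300
    polish: bool = True
    truncate: bool = False


@dataclass
class SADFit:
    """One distribution fitted to one plot's class counts."""

    model: SADModel
    theta_hat: np.ndarray
    se: np.ndarray  # NaN where unavailable
    loglik: float
    k: int
    n: int  # sample size for AICc (= species richness S)
    aicc: float  # NaN when n - k - 1 <= 0
    converged: bool
    scale: CoverScale
    message: str = ""

    @property
    def params(self) -> dict[str, float]:
        return dict(zip(self.model.param_names, np.atleast_1d(self.theta_hat)))


def log_likelihood(
    counts: ClassCounts,
    model: SADModel,
    theta,
    truncate: bool = False,
    floor: float | None = None,
) -> float:
    """Binned log-likelihood sum_i n_i ln(P_i) over occupied classes.

    Returns ``-inf`` (a sentinel, not an exception) when some occupied class
    has zero probability mass.  An optional floor on P_i is used internally
    during optimisation.
    """
    p = class_probabilities(model, theta, counts.scale, truncate=truncate)
    n = counts.counts
    occ = n > 0
    if not occ.any():
        return 0.0
    p_occ = p[occ]
    if floor is not None:
        p_occ = np.maximum(p_occ, floor)
    elif np.any(p_occ <= 0):
        return -np.inf
    with np.errstate(divide="ignore"):
        return float(np.dot(n[occ], np.log(p_occ)))


def _weighted_moments(counts: ClassCounts) -> tuple[float, float, np.ndarray]:
    m = class_midpoints(counts.scale)
    w = counts.counts.astype(float)
    s = w.sum()
    mean = float(np.dot(w, m) / s)
    var = float(np.dot(w, (m - mean) ** 2) / s)
    return mean, var, m


def pareto_fixed_xm(counts: ClassCounts) -> float:
    """Default fixed Pareto scale: lower limit of the lowest occupied class,
    or the first positive breakpoint when class 1 (lower limit 0) is occupied."""
    occ = np.flatnonzero(counts.counts)
    if occ.size == 0:
        raise ValueError("cannot fix the Pareto scale on empty counts")
    lo = counts.scale.lower[occ[0]]
    return float(lo) if lo > 0 else float(counts.scale.breakpoints[1])


def initial_values(counts: ClassCounts, model: SADModel) -> np.ndarray:
    """Moment-matching starting values on class-midpoint pseudo-data."""
    if counts.richness < 1:
        raise ValueError("cannot compute starting values: no species (S = 0)")
    mean, var, mids = _weighted_moments(counts)
    w = counts.counts.astype(float)
    name = model.name
    if name == "exponential":
        return np.array([1.0 / mean])
    if name == "gamma":
        if var <= 0:  # all mass in one class: fall back to exponential-like start
            return np.array([1.0, 1.0 / mean])
        return np.array([mean**2 / var, mean / var])
    if name == "lognormal":
        lm = np.log(mids)
        s = w.sum()
        mu = float(np.dot(w, lm) / s)
        sd = float(np.sqrt(np.dot(w, (lm - mu) ** 2) / s))
        return np.array([mu, sd if sd > 0 else 0.5])
    if name == "weibull":
        return np.array([1.0, mean])
    if name == "pareto":
        xm = model.xm if model.xm is not None else pareto_fixed_xm(counts)
        # Hill-style estimator on midpoints at or above xm
        use = mids > xm
        denom = float(np.dot(w[use], np.log(mids[use] / xm))) if use.any() else 0.0
        shape = w.sum() / denom if denom > 0 else 1.0
        if model.xm is None:
            return np.array([shape, xm])
        return np.array([shape])
    raise KeyError(f"no starting-value rule for model {name!r}")


def _to_z(model: SADModel, theta: np.ndarray) -> np.ndarray:
    """Log-transform positive parameters (lognormal meanlog stays linear)."""
    z = np.empty_like(np.asarray(theta, dtype=float))
    for i, (lo, _hi) in enumerate(model.param_bounds()):
        z[i] = theta[i] if lo == -np.inf else np.log(theta[i])
    return z


def _from_z(model: SADModel, z: np.ndarray) -> np.ndarray:
    theta = np.empty_like(np.asarray(z, dtype=float))
    for i, (lo, _hi) in enumerate(model.param_bounds()):
        theta[i] = z[i] if lo == -np.inf else np.exp(z[i])
    return theta


def _neg_loglik_z(z, counts, model, options):
    try:
        theta = _from_z(model, z)
        return -log_likelihood(
            counts, model, theta, truncate=options.truncate, floor=options.floor
        )
    except (ValueError, FloatingPointError, OverflowError):
        return np.inf


def _numerical_hessian(f, x, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of scalar f at x."""
    k = x.size
    h = rel_step * np.maximum(np.abs(x), 1e-8)
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def _standard_errors(counts, model, theta_hat, options) -> np.ndarray:
    """SEs from the inverse Hessian of the negative log-likelihood at theta_hat.

    NaN where the Hessian is not positive definite (flagged unavailable)."""

    def nll(theta):
        try:
            return -log_likelihood(
                counts, model, theta, truncate=options.truncate, floor=options.floor
            )
        except (ValueError, FloatingPointError):
            return np.inf

    k = theta_hat.size
    try:
        H = _numerical_hessian(nll, theta_hat)
        if not np.all(np.isfinite(H)):
            return np.full(k, np.nan)
        np.linalg.cholesky(H)  # positive-definiteness check
        cov = np.linalg.inv(H)
        se = np.sqrt(np.diag(cov))
        if np.any(~np.isfinite(se)) or np.any(se <= 0):
            return np.full(k, np.nan)
        return se
    except np.linalg.LinAlgError:
        return np.full(k, np.nan)


def fit_model(
    counts: ClassCounts,
    model: SADModel,
    options: FitOptions | None = None,
) -> SADFit:
    """Maximise the binned log-likelihood for one model on one plot.

    For a Pareto model constructed without a fixed scale via
    :func:`coversad.models.get_model`, pass ``get_model("pareto",
    xm=pareto_fixed_xm(counts))`` for the default fixed-scale convention.

    Optimiser failure or parameter divergence yields ``converged=False``,
    never a silent success; S = 0 raises.
    """
    if counts.richness < 1:
        raise ValueError("cannot fit a model to empty counts (S = 0)")
    options = options or FitOptions()
    # with a single occupied class the supremum is attained only in a
    # parameter limit (all mass piled on one interval): never a clean MLE
    degenerate = int(np.count_nonzero(counts.counts)) < 2
    theta0 = initial_values(counts, model)
    z0 = _to_z(model, theta0)
    rng = np.random.default_rng(options.seed)

    best = None
    for start in range(max(1, options.multistart)):
        z_start = z0 if start == 0 else z0 + rng.normal(0, options.jitter_sd, z0.size)
        res = optimize.minimize(
            _neg_loglik_z,
            z_start,
            args=(counts, model, options),
            method=options.method,
            options={
                "maxiter": options.maxiter,
                "fatol": options.tol,
                "xatol": 1e-8,
            },
        )
        if options.polish and np.isfinite(res.fun):
            polished = optimize.minimize(
                _neg_loglik_z,
                res.x,
                args=(counts, model, options),
                method="BFGS",
                options={"gtol": 1e-8},
            )
            if np.isfinite(polished.fun) and polished.fun <= res.fun:
                res = polished
        if best is None or res.fun < best.fun:
            best = res

    z_hat = np.atleast_1d(best.x)
    theta_hat = _from_z(model, z_hat)
    diverged = degenerate or bool(np.any(np.abs(z_hat - z0) > _LOG_BOUNDARY))
    converged = bool(best.success or np.isfinite(best.fun)) and not diverged
    # report the likelihood without the optimisation floor
    loglik = log_likelihood(counts, model, theta_hat, truncate=options.truncate)
    if not np.isfinite(loglik):
        converged = False
    se = (
        _standard_errors(counts, model, theta_hat, options)
        if converged
        else np.full(model.k, np.nan)
    )

    n = counts.richness
    k = model.k
    if n - k - 1 > 0 and np.isfinite(loglik):
        from .selection import aicc

        aicc_val = aicc(loglik, k, n)
    else:
        aicc_val = np.nan

    msg = "boundary/divergent parameters" if diverged else str(best.message)
    return SADFit(
        model=model,
        theta_hat=theta_hat,
        se=se,
        loglik=loglik,
        k=k,
        n=n,
        aicc=aicc_val,
        converged=converged,
        scale=counts.scale,
        message=msg,
    )
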