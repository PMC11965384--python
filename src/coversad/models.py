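"""Candidate species abundance distribution (SAD) models.

Five continuous distributions over cover x in (0, 1]: exponential, gamma,
lognormal, Pareto and Weibull.  Each model exposes its CDF, density, random
sampling and per-class probabilities P_i = F(U_i) - F(L_i) on a cover scale.
Class probabilities are plain CDF differences; their sum may fall below 1
because no truncation at full cover is applied (a truncated-renormalised
mode is available for sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .scales import CoverScale

__all__ = [
    "SADModel",
    "Exponential",
    "Gamma",
    "Lognormal",
    "Pareto",
    "Weibull",
    "get_model",
    "model_names",
    "class_probabilities",
]


class ParameterError(ValueError):
    """A parameter vector lies outside the model's domain."""


@dataclass(frozen=True)
class SADModel:
    """Base class: a named distribution with an ordered free-parameter list."""

    name: str = ""
    param_names: tuple[str, ...] = ()

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(self.param_names)

    # bounds are open; (low, high) per free parameter
    def param_bounds(self) -> tuple[tuple[float, float], ...]:
        return tuple((0.0, np.inf) for _ in self.param_names)

    def validate_theta(self, theta) -> np.ndarray:
        t = np.atleast_1d(np.asarray(theta, dtype=float))
        if t.shape != (self.k,):
            raise ParameterError(
                f"{self.name}: expected {self.k} parameter(s) {self.param_names}, got {t.shape}"
            )
        for val, (lo, hi), nm in zip(t, self.param_bounds(), self.param_names):
            if not (lo < val < hi) or not np.isfinite(val):
                raise ParameterError(f"{self.name}: parameter {nm}={val} outside ({lo}, {hi})")
        return t

    def cdf(self, theta, x) -> np.ndarray:
        raise NotImplementedError

    def pdf(self, theta, x) -> np.ndarray:
        raise NotImplementedError

    def rvs(self, theta, size: int, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError


class Exponential(SADModel):
    """Exponential(rate beta): CDF 1 - exp(-beta x)."""

    def __init__(self) -> None:
        super().__init__("exponential", ("rate",))

    def cdf(self, theta, x):
        (beta,) = self.validate_theta(theta)
        x = np.asarray(x, dtype=float)
        return np.where(x > 0, -np.expm1(-beta * np.maximum(x, 0.0)), 0.0)

    def pdf(self, theta, x):
        (beta,) = self.validate_theta(theta)
        x = np.asarray(x, dtype=float)
        return np.where(x > 0, beta * np.exp(-beta * x), 0.0)

    def rvs(self, theta, size, rng):
        (beta,) = self.validate_theta(theta)
        return rng.exponential(scale=1.0 / beta, size=size)


class Gamma(SADModel):
    """Gamma(shape alpha, rate beta): CDF via the regularised incomplete gamma."""

    def __init__(self) -> None:
        super().__init__("gamma", ("shape", "rate"))

    def cdf(self, theta, x):
        alpha, beta = self.validate_theta(theta)
        x = np.asarray(x, dtype=float)
        return special.gammainc(alpha, beta * np.maximum(x, 0.0))

    def pdf(self, theta, x):
        alpha, beta = self.validate_theta(theta)
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = (
                alpha * np.log(beta)
                + (alpha - 1) * np.log(x)
                - beta * x
                - special.gammaln(alpha)
            )
        return np.where(x > 0, np.exp(logp), 0.0)

    def rvs(self, theta, size, rng):
        alpha, beta = self.validate_theta(theta)
        return rng.gamma(shape=alpha, scale=1.0 / beta, size=size)


class Lognormal(SADModel):
    """Lognormal(meanlog mu, sdlog sigma) on the natural log of proportion cover."""

    def __init__(self) -> None:
        super().__init__("lognormal", ("meanlog", "sdlog"))

    def param_bounds(self):
        return ((-np.inf, np.inf), (0.0, np.inf))

    def cdf(self, theta, x):
        mu, sigma = self.validate_theta(theta)
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore"):
            z = (np.log(np.maximum(x, 0.0)) - mu) / sigma
        return np.where(x > 0, special.ndtr(z), 0.0)

    def pdf(self, theta, x):
        mu, sigma = self.validate_theta(theta)
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (np.log(x) - mu) / sigma
            dens = np.exp(-0.5 * z * z) / (x * sigma * np.sqrt(2 * np.pi))
        return np.where(x > 0, dens, 0.0)

    def rvs(self, theta, size, rng):
        mu, sigma = self.validate_theta(theta)
        return rng.lognormal(mean=mu, sigma=sigma, size=size)


class Pareto(SADModel):
    """Pareto(shape alpha[, scale x_m]): CDF 1 - (x_m / x)^alpha for x >= x_m.

    With ``xm`` given at construction the scale is held fixed and only the
    shape is free (k = 1), mirroring the convention of pinning the scale at
    the sample minimum; with ``xm=None`` both parameters are free (k = 2).
    """

    def __init__(self, xm: float | None = None) -> None:
        if xm is None:
            super().__init__("pareto", ("shape", "xm"))
        else:
            if not (0 < xm < 1):
                raise ParameterError(f"pareto fixed scale xm={xm} outside (0, 1)")
            super().__init__("pareto", ("shape",))
        object.__setattr__(self, "xm", xm)

    def _unpack(self, theta):
        t = self.validate_theta(theta)
        if self.xm is None:
            return t[0], t[1]
        return t[0], self.xm

    def cdf(self, theta, x):
        alpha, xm = self._unpack(theta)
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore"):
            val = -np.expm1(alpha * (np.log(xm) - np.log(np.maximum(x, xm))))
        return np.where(x > xm, val, 0.0)

    def pdf(self, theta, x):
        alpha, xm = self._unpack(theta)
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            dens = alpha * xm**alpha / x ** (alpha + 1)
        return np.where(x >= xm, dens, 0.0)

    def rvs(self, theta, size, rng):
        alpha, xm = self._unpack(theta)
        # numpy's pareto samples the Lomax form; shift back to classical Pareto
        return xm * (1.0 + rng.pareto(alpha, size=size))


class Weibull(SADModel):
    """Weibull(shape phi, scale lam): CDF 1 - exp(-(x / lam)^phi).

    Low phi signals an excess of highly abundant species; phi > 1 places the
    mode above the lowest abundance class.  lam expresses overall spread.
    """

    def __init__(self) -> None:
        super().__init__("weibull", ("shape", "scale"))

    def cdf(self, theta, x):
        phi, lam = self.validate_theta(theta)
        x = np.asarray(x, dtype=float)
        return np.where(x > 0, -np.expm1(-((np.maximum(x, 0.0) / lam) ** phi)), 0.0)

    def pdf(self, theta, x):
        phi, lam = self.validate_theta(theta)
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = x / lam
            dens = (phi / lam) * z ** (phi - 1) * np.exp(-(z**phi))
        return np.where(x > 0, dens, 0.0)

    def rvs(self, theta, size, rng):
        phi, lam = self.validate_theta(theta)
        return lam * rng.weibull(phi, size=size)


_FACTORIES = {
    "exponential": Exponential,
    "gamma": Gamma,
    "lognormal": Lognormal,
    "pareto": Pareto,
    "weibull": Weibull,
}

_ALIASES = {"exp": "exponential", "lnorm": "lognormal", "weib": "weibull"}


def model_names() -> tuple[str, ...]:
    return tuple(_FACTORIES)


def get_model(name: str, **kwargs) -> SADModel:
    """Instantiate a model by name (aliases: exp, lnorm, weib).

    ``get_model("pareto", xm=0.01)`` fixes the Pareto scale (k = 1).
    """
    key = _ALIASES.get(name, name)
    try:
        factory = _FACTORIES[key]
    except KeyError:
        known = ", ".join(_FACTORIES)
        raise KeyError(f"unknown SAD model {name!r}; known models: {known}") from None
    return factory(**kwargs)


def class_probabilities(
    model: SADModel,
    theta,
    scale: CoverScale,
    truncate: bool = False,
) -> np.ndarray:
    """Probability mass P_i assigned to each cover class.

    P_i = F(U_i | theta) - F(L_i | theta).  Without truncation the vector sums
    to F(1) - F(0) <= 1; with ``truncate=True`` it is renormalised by that sum.
    """
    cdf_at = model.cdf(theta, np.asarray(scale.breakpoints))
    p = np.maximum(np.diff(cdf_at), 0.0)
    if truncate:
        total = cdf_at[-1] - cdf_at[0]
        if total <= 0:
            raise ParameterError(f"{model.name}: no probability mass on (0, 1]")
        p = p / total
    return p
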