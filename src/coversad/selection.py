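"""AICc multimodel selection and chi-square goodness of fit.

Candidate models fitted to the same plot are ranked by the small-sample
corrected Akaike criterion AICc = -2L + 2k + 2k(k+1)/(n - k - 1), with n the
plot's species richness.  Models within 2 AICc units of the minimum form the
"equally plausible" set.  The correction matters here because alpine plots can
hold very few species: at n = 10 an extra parameter costs 3.21 delta-AICc
units at equal likelihood, and at n = 4 it costs 12, versus a flat 2 for
uncorrected AIC — which is why parsimonious one-parameter models win on
species-poor plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .likelihood import FitOptions, SADFit, fit_model, pareto_fixed_xm
from .models import SADModel, class_probabilities, get_model
from .scales import ClassCounts

__all__ = [
    "AICcUndefinedError",
    "GofResult",
    "ModelComparison",
    "aicc",
    "compare_models",
    "chisq_gof",
    "PLAUSIBLE_DELTA",
]

#: delta-AICc threshold for the equally-plausible set (inclusive)
PLAUSIBLE_DELTA = 2.0


class AICcUndefinedError(ValueError):
    """AICc is undefined because n - k - 1 <= 0."""


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion corrected for small sample size.

    -2*loglik + 2k + 2k(k+1)/(n - k - 1); requires n - k - 1 > 0.
    """
    if n - k - 1 <= 0:
        raise AICcUndefinedError(
            f"AICc undefined for k={k} parameters on n={n} observations (n - k - 1 <= 0)"
        )
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class GofResult:
    """Chi-square goodness of fit of one fitted model.

    ``available`` is False when fewer than two usable (pooled) classes remain.
    """

    statistic: float
    df: int
    p_value: float
    pooling_map: list[tuple[int, int]]
    available: bool = True

    @classmethod
    def unavailable(cls) -> "GofResult":
        return cls(np.nan, 0, np.nan, [], available=False)


def _pool_classes(
    observed: np.ndarray, expected: np.ndarray, min_expected: float
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Merge adjacent classes right-to-left until each group's expected count
    reaches ``min_expected``; an underfull leftover group merges into its
    neighbour.  Returns pooled observed, pooled expected and the (first, last)
    original class indices of each group, left to right."""
    C = observed.size
    groups: list[tuple[int, int]] = []
    hi = C - 1
    while hi >= 0:
        lo = hi
        while expected[lo : hi + 1].sum() < min_expected and lo > 0:
            lo -= 1
        groups.append((lo, hi))
        hi = lo - 1
    groups.reverse()
    if len(groups) > 1 and expected[groups[0][0] : groups[0][1] + 1].sum() < min_expected:
        g0, g1 = groups[0], groups[1]
        groups = [(g0[0], g1[1])] + groups[2:]
    obs = np.array([observed[a : b + 1].sum() for a, b in groups], dtype=float)
    exp = np.array([expected[a : b + 1].sum() for a, b in groups], dtype=float)
    return obs, exp, groups


def chisq_gof(
    counts: ClassCounts,
    fit: SADFit,
    min_expected: float = 1.0,
) -> GofResult:
    """Pearson chi-square test of observed class counts against S * P_i.

    Adjacent classes are pooled right-to-left until each pooled expected count
    reaches ``min_expected`` (sparse upper cover classes otherwise inflate the
    statistic).  df = (#pooled classes) - 1 - k, floored at 1; p is the upper
    tail.  With fewer than two usable classes the result is flagged
    unavailable rather than raising.
    """
    if not fit.converged:
        raise ValueError("goodness of fit requires a converged fit")
    S = counts.richness
    if S < 1:
        raise ValueError("goodness of fit requires S >= 1")
    p = class_probabilities(fit.model, fit.theta_hat, counts.scale)
    expected = S * p
    obs, exp, groups = _pool_classes(counts.counts.astype(float), expected, min_expected)
    usable = exp > 0
    if usable.sum() < 2:
        return GofResult.unavailable()
    stat = float(np.sum((obs[usable] - exp[usable]) ** 2 / exp[usable]))
    df = max(int(usable.sum()) - 1 - fit.k, 1)
    return GofResult(stat, df, float(stats.chi2.sf(stat, df)), groups)


@dataclass
class ModelComparison:
    """All candidate fits to one plot, ranked by AICc."""

    fits: dict[str, SADFit]
    delta_aicc: dict[str, float]  # NaN for undefined/failed fits
    plausible: dict[str, bool]
    gof: dict[str, GofResult] = field(default_factory=dict)

    @property
    def best(self) -> str:
        defined = {m: d for m, d in self.delta_aicc.items() if np.isfinite(d)}
        return min(defined, key=defined.get)

    def plausible_set(self) -> set[str]:
        return {m for m, ok in self.plausible.items() if ok}


class ComparisonError(RuntimeError):
    """No candidate model could be fitted and ranked."""


def _instantiate(name: str | SADModel, counts: ClassCounts, pareto_scale: str):
    if isinstance(name, SADModel):
        return name
    if name in ("pareto", "par") and pareto_scale == "fixed":
        return get_model("pareto", xm=pareto_fixed_xm(counts))
    if name == "pareto":
        return get_model("pareto")  # free x_m, k = 2
    return get_model(name)


def compare_models(
    counts: ClassCounts,
    models: list[str | SADModel] | None = None,
    options: FitOptions | None = None,
    pareto_scale: str = "fixed",
    gof_min_expected: float = 1.0,
) -> ModelComparison:
    """Fit every candidate model to one plot and form the plausible set.

    Models whose AICc is undefined (n - k - 1 <= 0) or whose fit failed are
    flagged with NaN delta-AICc and excluded from ranking, mirroring the
    "not assessable" cells on species-poor plots.  Raises
    :class:`ComparisonError` when no model yields a defined AICc.
    """
    if counts.richness < 1:
        raise ValueError("cannot compare models on empty counts (S = 0)")
    names = list(models) if models else list(
        ("exponential", "gamma", "lognormal", "pareto", "weibull")
    )
    if not names:
        raise ValueError("at least one candidate model is required")

    fits: dict[str, SADFit] = {}
    for name in names:
        model = _instantiate(name, counts, pareto_scale)
        try:
            fits[model.name] = fit_model(counts, model, options)
        except (ValueError, FloatingPointError) as err:
            fits[model.name] = SADFit(
                model=model,
                theta_hat=np.full(model.k, np.nan),
                se=np.full(model.k, np.nan),
                loglik=np.nan,
                k=model.k,
                n=counts.richness,
                aicc=np.nan,
                converged=False,
                scale=counts.scale,
                message=f"fit failed: {err}",
            )

    defined = {m: f.aicc for m, f in fits.items() if f.converged and np.isfinite(f.aicc)}
    if not defined:
        raise ComparisonError("no candidate model produced a defined AICc on this plot")
    best = min(defined.values())
    delta = {
        m: (fits[m].aicc - best if m in defined else np.nan) for m in fits
    }
    plausible = {m: bool(np.isfinite(d) and d <= PLAUSIBLE_DELTA) for m, d in delta.items()}

    gof: dict[str, GofResult] = {}
    for m, f in fits.items():
        gof[m] = (
            chisq_gof(counts, f, min_expected=gof_min_expected)
            if f.converged
            else GofResult.unavailable()
        )
    return ModelComparison(fits=fits, delta_aicc=delta, plausible=plausible, gof=gof)
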