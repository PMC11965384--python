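"""Synthetic communities and transects with known SAD structure.

Emulates the study design the package targets: an elevational transect split
into 100 m belts with three 100 m^2 plots per belt (one at the topmost belt),
per-plot species richness declining with elevation, and covers drawn from a
known distribution then censored into cover classes.  Because truth is known,
every pipeline stage (binning, fitting, selection, trend smoothing) can be
validated end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .models import SADModel, get_model
from .scales import ClassCounts, CoverScale, bin_cover_values, get_scale

__all__ = [
    "CommunitySample",
    "GradientConfig",
    "simulate_community",
    "simulate_transect",
    "default_richness",
    "default_theta",
]

# design anchors: richness ~46 at 2,000 m declining to 5 at 4,500 m; total
# vegetation cover ~80% declining to ~5% over the same range
_E_LO, _E_HI = 2000.0, 4500.0
_S_LO, _S_HI = 46.0, 5.0
_COVER_LO, _COVER_HI = 0.80, 0.05


def default_richness(elevation_m: float) -> int:
    """Linear richness decline through (2,000 m, 46) and (4,500 m, 5), rounded."""
    t = (elevation_m - _E_LO) / (_E_HI - _E_LO)
    return max(1, round(_S_LO + t * (_S_HI - _S_LO)))


def default_theta(elevation_m: float) -> np.ndarray:
    """Exponential rate giving a realistic mean per-species cover.

    Mean cover per species is taken as (total vegetation cover) / richness,
    both declining linearly along the gradient; the exponential rate is its
    reciprocal.
    """
    t = (elevation_m - _E_LO) / (_E_HI - _E_LO)
    total = _COVER_LO + t * (_COVER_HI - _COVER_LO)
    mean_cover = total / default_richness(elevation_m)
    return np.array([1.0 / mean_cover])


@dataclass
class CommunitySample:
    """Covers drawn for one plot, their binned counts, and the fraction of
    raw draws rejected for falling outside (0, 1]."""

    values: np.ndarray
    counts: ClassCounts
    truncation_fraction: float


def simulate_community(
    model: SADModel | str,
    theta,
    S: int,
    scale: CoverScale | str = "londo",
    seed: int | np.random.Generator = 0,
) -> CommunitySample:
    """Draw S independent species covers from a model and bin them.

    Draws outside (0, 1] are rejected and redrawn so the realised covers share
    the fitting likelihood's support; the rejected fraction is reported
    because the fitting likelihood itself is untruncated.  An acceptance rate
    below 1e-3 raises.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if isinstance(model, str):
        model = get_model(model)
    if isinstance(scale, str):
        scale = get_scale(scale)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    values = np.empty(0)
    drawn = 0
    while values.size < S:
        batch = max(S - values.size, 32)
        x = model.rvs(theta, batch, rng)
        drawn += batch
        values = np.concatenate([values, x[(x > 0) & (x <= 1)]])
        if drawn >= 1000 * S and values.size / drawn < 1e-3:
            raise ValueError(
                f"{model.name}: acceptance rate {values.size / drawn:.2e} below 1e-3; "
                "the parameters put almost no mass on (0, 1]"
            )
    values = values[:S]
    counts = bin_cover_values(values, scale)
    return CommunitySample(values, counts, 1.0 - S / drawn)


@dataclass
class GradientConfig:
    """Design of a synthetic transect.

    Defaults replicate the target study layout: belts every 100 m from 2,000
    to 4,500 m, three plots per belt except a single plot at the top, linear
    richness decline from 46 to 5 species, exponential covers with an
    elevation-dependent rate.
    """

    belt_elevations: tuple[float, ...] = tuple(np.arange(2000.0, 4600.0, 100.0))
    plots_per_belt: int = 3
    top_belt_plots: int = 1
    richness: Callable[[float], int] = default_richness
    model: str | SADModel = "exponential"
    theta: Callable[[float], np.ndarray] = default_theta
    scale: CoverScale | str = "londo"
    seed: int = 0

    def validate(self) -> None:
        if len(self.belt_elevations) == 0 or any(e <= 0 for e in self.belt_elevations):
            raise ValueError("belt_elevations: must be non-empty and positive")
        if self.plots_per_belt < 1:
            raise ValueError("plots_per_belt: must be >= 1")
        if self.top_belt_plots < 1:
            raise ValueError("top_belt_plots: must be >= 1")
        for e in self.belt_elevations:
            if self.richness(e) < 1:
                raise ValueError(f"richness: S({e}) < 1")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed: must be a fixed integer")


def simulate_transect(config: GradientConfig | None = None) -> pd.DataFrame:
    """Generate a long-format plot table for a whole synthetic transect.

    Returns one row per (plot, species) with columns ``plot_id``,
    ``elevation_m``, ``species_id``, ``cover`` (proportion) and a per-plot
    ``total_cover_percent`` (sum of species covers, as a field estimate
    stand-in).  Plot-level randomness derives from ``config.seed`` via
    independent spawned streams.
    """
    config = config or GradientConfig()
    config.validate()
    model = (
        get_model(config.model) if isinstance(config.model, str) else config.model
    )
    scale = get_scale(config.scale) if isinstance(config.scale, str) else config.scale

    belts = list(config.belt_elevations)
    n_plots = [
        config.top_belt_plots if i == len(belts) - 1 else config.plots_per_belt
        for i in range(len(belts))
    ]
    streams = np.random.SeedSequence(config.seed).spawn(sum(n_plots))

    rows = []
    stream = iter(streams)
    for elev, k in zip(belts, n_plots):
        S = config.richness(elev)
        theta = config.theta(elev)
        for rep in range(1, k + 1):
            rng = np.random.default_rng(next(stream))
            sample = simulate_community(model, theta, S, scale, seed=rng)
            plot_id = f"E{int(elev)}_P{rep}"
            total = float(sample.values.sum()) * 100.0
            for j, cover in enumerate(sample.values, start=1):
                rows.append(
                    {
                        "plot_id": plot_id,
                        "elevation_m": float(elev),
                        "species_id": f"sp{int(elev)}_{rep}_{j}",
                        "cover": float(cover),
                        "total_cover_percent": total,
                    }
                )
    return pd.DataFrame(rows)
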