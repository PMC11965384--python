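"""Cover-class scales and binning of cover observations.

Vegetation surveys record plant cover on ordinal class scales rather than as
continuous proportions.  A :class:`CoverScale` holds the class breakpoints on
the proportion scale [0, 1]; the Londo scale is built in.  Observations binned
on a scale become per-class species counts (:class:`ClassCounts`), the
sufficient statistic for the interval-censored likelihood.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "CoverScale",
    "ClassCounts",
    "get_scale",
    "register_scale",
    "load_scales",
    "class_midpoints",
    "bin_cover_values",
]


@dataclass(frozen=True)
class CoverScale:
    """An ordered partition of the cover range (0, 1] into classes.

    Parameters
    ----------
    name
        Short identifier, e.g. ``"londo"``.
    breakpoints
        Strictly increasing class limits ``b0 .. bC`` as proportions, with
        ``b0 = 0`` and ``bC = 1``.  Class ``i`` (1-based) is the half-open
        interval ``(b[i-1], b[i]]``.
    labels
        Optional symbolic class codes, one per class.
    """

    name: str
    breakpoints: tuple[float, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        if bp.ndim != 1 or bp.size < 3:
            raise ValueError("a scale needs at least 3 breakpoints (C >= 2)")
        if not np.all(np.diff(bp) > 0):
            raise ValueError(f"breakpoints of scale {self.name!r} must be strictly increasing")
        if bp[0] != 0.0 or bp[-1] != 1.0:
            raise ValueError("breakpoints must start at 0 and end at 1 (proportion scale)")
        object.__setattr__(self, "breakpoints", tuple(bp.tolist()))
        if self.labels is not None:
            labels = tuple(self.labels)
            if len(labels) != self.n_classes:
                raise ValueError(
                    f"scale {self.name!r}: {len(labels)} labels for {self.n_classes} classes"
                )
            if len(set(labels)) != len(labels):
                raise ValueError(f"scale {self.name!r}: labels must be distinct")
            object.__setattr__(self, "labels", labels)

    @property
    def n_classes(self) -> int:
        """Number of classes C."""
        return len(self.breakpoints) - 1

    @property
    def lower(self) -> np.ndarray:
        """Lower limits L_i of the C classes."""
        return np.asarray(self.breakpoints[:-1], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        """Upper limits U_i of the C classes."""
        return np.asarray(self.breakpoints[1:], dtype=float)

    def midpoints(self) -> np.ndarray:
        return class_midpoints(self)

    def label_to_class(self) -> dict[str, int]:
        """Map each label to its 0-based class index."""
        if self.labels is None:
            raise ValueError(f"scale {self.name!r} has no labels")
        return {lab: i for i, lab in enumerate(self.labels)}


@dataclass
class ClassCounts:
    """Per-class species counts n_i for one plot."""

    scale: CoverScale
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 1 or c.shape[0] != self.scale.n_classes:
            raise ValueError(
                f"counts length {c.shape[0] if c.ndim == 1 else c.shape} does not match "
                f"the {self.scale.n_classes} classes of scale {self.scale.name!r}"
            )
        if np.any(c < 0) or not np.all(np.equal(np.mod(c, 1), 0)):
            raise ValueError("counts must be non-negative integers")
        self.counts = c.astype(np.int64)

    @property
    def richness(self) -> int:
        """Species richness S = sum of counts."""
        return int(self.counts.sum())


# Londo scale: percent breakpoints 0, 1, 3, 5, 10, 15, then steps of 10 up to
# 95, closing at 100 — fourteen classes.
_LONDO_PERCENT = (0, 1, 3, 5, 10, 15, 25, 35, 45, 55, 65, 75, 85, 95, 100)

_REGISTRY: dict[str, CoverScale] = {
    "londo": CoverScale("londo", tuple(b / 100 for b in _LONDO_PERCENT)),
}


def get_scale(name: str) -> CoverScale:
    """Return a registered cover scale by name.

    Raises
    ------
    KeyError
        If ``name`` is not registered; the message lists known scales.
    """
    try:
        return _REGISTRY[name]
    except KeyError:
        known = ", ".join(sorted(_REGISTRY))
        raise KeyError(f"unknown cover scale {name!r}; registered scales: {known}") from None


def register_scale(scale: CoverScale, overwrite: bool = False) -> None:
    if scale.name in _REGISTRY and not overwrite:
        raise ValueError(f"scale {scale.name!r} already registered")
    _REGISTRY[scale.name] = scale


def load_scales(path: str | Path) -> list[CoverScale]:
    """Register custom scales from a YAML/JSON config file.

    The file maps scale names to ``{"percent_breakpoints": [...],
    "labels": [...]}`` (labels optional).  Breakpoints are given in percent
    and divided by 100 on load.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: expected a mapping of scale name -> definition")
    loaded = []
    for name, spec in data.items():
        bp = spec["percent_breakpoints"]
        labels = spec.get("labels")
        scale = CoverScale(
            name,
            tuple(b / 100 for b in bp),
            tuple(labels) if labels is not None else None,
        )
        register_scale(scale, overwrite=True)
        loaded.append(scale)
    return loaded


def class_midpoints(scale: CoverScale) -> np.ndarray:
    """Midpoint m_i = (L_i + U_i) / 2 of every class."""
    return (scale.lower + scale.upper) / 2.0


def bin_cover_values(values: Sequence[float], scale: CoverScale) -> ClassCounts:
    """Bin raw cover proportions into per-class counts.

    Classes are right-closed: a value exactly on a breakpoint belongs to the
    lower class.  Values must lie in (0, 1]; zero cover means absence and is
    rejected.
    """
    v = np.asarray(values, dtype=float)
    if v.size:
        bad = np.flatnonzero((v <= 0) | (v > 1) | ~np.isfinite(v))
        if bad.size:
            raise ValueError(
                f"cover values must lie in (0, 1]; offending value {v[bad[0]]!r} "
                f"at position {bad[0]}"
            )
    bp = np.asarray(scale.breakpoints)
    idx = np.searchsorted(bp, v, side="left") - 1
    counts = np.bincount(idx, minlength=scale.n_classes)
    return ClassCounts(scale, counts)
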