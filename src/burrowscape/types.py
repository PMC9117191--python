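"""Shared domain types: labelled point sets, survey plots and zones.

All coordinates are planar metric (metres). Inputs in geographic
coordinates must be projected before use; no CRS handling is done here.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np

__all__ = ["Zone", "PointSet2D", "SamplePlot"]


class Zone(str, Enum):
    """Survey zone of a presence/absence plot.

    BURROW  — plot centred on an inhabited souslik nest burrow.
    COLONY  — random plot inside the colony range (KDE-95% isopleth of
              burrow locations) excluding a buffer band around burrows.
    CONTROL — random plot in the remaining study area, outside the colony.
    """

    BURROW = "BURROW"
    COLONY = "COLONY"
    CONTROL = "CONTROL"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class PointSet2D:
    """A labelled set of planar points (burrow entrances or mound centroids).

    Parameters
    ----------
    xy : (n, 2) array of float
        Point coordinates in metres.
    label : str
        Free-text species/feature label (e.g. ``"burrow"``, ``"mound"``).
    """

    xy: np.ndarray
    label: str = "point"

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float)
        if xy.size == 0:
            xy = xy.reshape(0, 2)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError(f"xy must be an (n, 2) array, got shape {xy.shape}")
        if not np.all(np.isfinite(xy)):
            raise ValueError("xy contains non-finite coordinates")
        self.xy = xy

    def __len__(self) -> int:
        return self.xy.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.xy[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xy[:, 1]

    def subset(self, mask: np.ndarray) -> "PointSet2D":
        return PointSet2D(self.xy[mask], label=self.label)


@dataclass
class SamplePlot:
    """A circular presence/absence survey plot.

    ``presence`` is tri-state: ``None`` (not yet scored), 0 (no mounds
    found) or 1 (at least one mound found).
    """

    x: float
    y: float
    radius: float
    zone: Zone
    year: int
    presence: Optional[int] = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("plot radius must be positive")
        if self.presence is not None and self.presence not in (0, 1):
            raise ValueError("presence must be None, 0 or 1")
        self.zone = Zone(self.zone)

    @property
    def center(self) -> np.ndarray:
        return np.array([self.x, self.y])

    @property
    def area(self) -> float:
        """Plot area in m^2."""
        return float(np.pi * self.radius**2)

    def scored(self, presence: int) -> "SamplePlot":
        return replace(self, presence=int(presence))
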