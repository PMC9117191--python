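"""Survey-zone construction and spacing-constrained random plot placement.

The study area is split into three zones:

* BURROW — one circular plot of configurable area (default 10 m^2, i.e.
  radius 1.784 m, diameter 3.57 m ~ the protocol's printed 3.56 m)
  centred on each inhabited nest burrow;
* COLONY — the colony range, taken as the 95% isopleth of a fixed-radius
  kernel density of the burrow locations, minus a buffer band (default
  4 m) around every burrow that is cut out to limit autocorrelation with
  the BURROW plots;
* CONTROL — the remaining study area outside the full colony isopleth
  (the burrow buffer band is cut from it as well, so no random plot can
  sit on an outlier burrow that the 95% isopleth excluded).

Random plot centres within COLONY/CONTROL are drawn by rejection
sampling with a minimum inter-point spacing (default 8 m) enforced
within each zone, so adjacent plots never overlap.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import shapely
from scipy.spatial import cKDTree

from .rangekde import GridRegion, IsoplethRegion, density_grid, isopleth_area
from .types import PointSet2D, SamplePlot, Zone

__all__ = [
    "ZoneConfig",
    "ZonePartition",
    "SamplingError",
    "plot_radius",
    "build_zones",
    "sample_plots",
]


class SamplingError(RuntimeError):
    """Raised when rejection sampling cannot place the requested points.

    ``placed`` records how many points were accepted before the proposal
    cap was exhausted.
    """

    def __init__(self, message: str, placed: int):
        super().__init__(message)
        self.placed = placed


@dataclass
class ZoneConfig:
    """Field-protocol parameters for zone construction and plot sampling.

    ``colony_kernel_radius`` has no protocol default and must be set
    explicitly: the field study fixed kernel radii only for the mole
    range (5 and 10 m), not for the colony delineation.
    """

    colony_kernel_radius: float
    plot_area: float = 10.0  # m^2
    colony_isopleth: float = 0.95
    burrow_exclusion_buffer: float = 4.0  # m
    min_plot_spacing: float = 8.0  # m
    cell_size: float = 1.0  # m, zone raster resolution
    max_proposals_per_point: int = 10_000

    def __post_init__(self) -> None:
        if not 0 < self.colony_isopleth < 1:
            raise ValueError("colony_isopleth must be in (0, 1)")
        for name in ("colony_kernel_radius", "plot_area", "burrow_exclusion_buffer",
                     "cell_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_plot_spacing < 0:
            raise ValueError("min_plot_spacing must be non-negative")

    @property
    def plot_radius(self) -> float:
        return plot_radius(self.plot_area)


def plot_radius(plot_area: float) -> float:
    """Radius (m) of a circular plot of the given area (m^2).

    A 10 m^2 plot has radius 1.7841 m (diameter 3.5682 m, printed in the
    protocol truncated to 3.56 m).
    """
    if plot_area <= 0:
        raise ValueError("plot_area must be positive")
    return math.sqrt(plot_area / math.pi)


@dataclass
class ZonePartition:
    """Result of :func:`build_zones`: the three pairwise-disjoint zones.

    ``colony``, ``control`` and ``buffer_band`` are masks on one common
    grid and partition the landscape exactly: colony + control + band
    = landscape (cell-wise).
    """

    colony: GridRegion
    control: GridRegion
    buffer_band: GridRegion
    landscape: GridRegion
    colony_isopleth: IsoplethRegion
    burrow_plots: list[SamplePlot]


def build_zones(
    burrows: PointSet2D,
    boundary: "shapely.Polygon",
    cfg: ZoneConfig,
    year: int = 0,
) -> ZonePartition:
    """Construct the BURROW/COLONY/CONTROL partition from burrow locations.

    The colony isopleth is clipped to the landscape boundary; the buffer
    band is the part of the isopleth within ``burrow_exclusion_buffer``
    of any burrow. All regions share one raster grid (``cfg.cell_size``).
    """
    if len(burrows) < 3:
        raise ValueError("need at least 3 burrow points to delineate a colony")
    if np.allclose(burrows.xy, burrows.xy[0], atol=1e-9):
        raise ValueError("degenerate burrow set: all points coincident")

    x0, y0, x1, y1 = boundary.bounds
    pad = cfg.colony_kernel_radius + cfg.cell_size
    bounds = (x0 - pad, y0 - pad, x1 + pad, y1 + pad)
    grid = density_grid(burrows, cfg.colony_kernel_radius, cfg.cell_size, bounds=bounds)
    iso = isopleth_area(grid, cfg.colony_isopleth)

    cx, cy = grid.cell_centers()
    gx, gy = np.meshgrid(cx, cy)
    land_mask = shapely.contains_xy(boundary, gx.ravel(), gy.ravel()).reshape(gx.shape)
    landscape = GridRegion(grid.origin, cfg.cell_size, land_mask)

    iso_mask = iso.mask & land_mask
    # stamp the exclusion buffer around every burrow (cell-centre distance);
    # the band is cut from COLONY and CONTROL alike, so no survey plot can
    # land on top of a burrow even when the 95% isopleth drops an outlier
    # burrow from the colony
    near = np.zeros_like(land_mask)
    cs = cfg.cell_size
    half = int(np.ceil(cfg.burrow_exclusion_buffer / cs)) + 1
    off = np.arange(-half, half + 1)
    oy, ox = np.meshgrid(off, off, indexing="ij")
    ny, nx = land_mask.shape
    for bx, by in burrows.xy:
        ix = int(np.floor((bx - grid.origin[0]) / cs))
        iy = int(np.floor((by - grid.origin[1]) / cs))
        ccx = grid.origin[0] + (ix + ox + 0.5) * cs
        ccy = grid.origin[1] + (iy + oy + 0.5) * cs
        disc = (ccx - bx) ** 2 + (ccy - by) ** 2 <= cfg.burrow_exclusion_buffer**2
        sel_y = np.clip(iy + oy, 0, ny - 1)
        sel_x = np.clip(ix + ox, 0, nx - 1)
        near[sel_y[disc], sel_x[disc]] = True
    near &= land_mask

    colony = GridRegion(grid.origin, cfg.cell_size, iso_mask & ~near)
    band = GridRegion(grid.origin, cfg.cell_size, near)
    control = GridRegion(grid.origin, cfg.cell_size, land_mask & ~iso_mask & ~near)

    r = cfg.plot_radius
    plots = [SamplePlot(float(p[0]), float(p[1]), r, Zone.BURROW, year) for p in burrows.xy]
    return ZonePartition(
        colony=colony,
        control=control,
        buffer_band=band,
        landscape=landscape,
        colony_isopleth=IsoplethRegion(grid.origin, cfg.cell_size, iso_mask,
                                       cfg.colony_isopleth, iso.threshold_density),
        burrow_plots=plots,
    )


def sample_plots(
    region: GridRegion,
    n: int,
    cfg: ZoneConfig,
    seed: int | np.random.Generator,
    zone: Zone = Zone.CONTROL,
    year: int = 0,
) -> list[SamplePlot]:
    """Draw ``n`` random plot centres in ``region`` with minimum spacing.

    Rejection sampling: proposals are uniform over the region's bounding
    box, accepted when they fall in the region and keep at least
    ``cfg.min_plot_spacing`` from every previously accepted centre.
    Conditional on acceptance the centres are exactly uniform. A cap of
    ``cfg.max_proposals_per_point`` proposals per accepted point guards
    against impossible packings; exhaustion raises :class:`SamplingError`
    reporting how many points were placed.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if region.is_empty and n > 0:
        raise SamplingError("region is empty", placed=0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # bounding box of occupied cells, not of the whole grid
    rows = np.any(region.mask, axis=1)
    cols = np.any(region.mask, axis=0)
    iy0, iy1 = np.flatnonzero(rows)[[0, -1]]
    ix0, ix1 = np.flatnonzero(cols)[[0, -1]]
    cs = region.cell_size
    bx0 = region.origin[0] + ix0 * cs
    bx1 = region.origin[0] + (ix1 + 1) * cs
    by0 = region.origin[1] + iy0 * cs
    by1 = region.origin[1] + (iy1 + 1) * cs

    spacing2 = cfg.min_plot_spacing**2
    accepted: list[tuple[float, float]] = []
    proposals_since_accept = 0
    while len(accepted) < n:
        if proposals_since_accept >= cfg.max_proposals_per_point:
            raise SamplingError(
                f"placed {len(accepted)} of {n} points before exhausting "
                f"{cfg.max_proposals_per_point} proposals per point "
                f"(spacing {cfg.min_plot_spacing} m)",
                placed=len(accepted),
            )
        px = rng.uniform(bx0, bx1)
        py = rng.uniform(by0, by1)
        proposals_since_accept += 1
        if not region.contains(np.array([[px, py]]))[0]:
            continue
        if accepted:
            arr = np.asarray(accepted)
            if np.min((arr[:, 0] - px) ** 2 + (arr[:, 1] - py) ** 2) < spacing2:
                continue
        accepted.append((px, py))
        proposals_since_accept = 0
    r = cfg.plot_radius
    return [SamplePlot(px, py, r, zone, year) for px, py in accepted]
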