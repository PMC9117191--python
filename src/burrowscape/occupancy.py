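"""Presence/absence scoring of survey plots and zone frequency tables."""
from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .types import PointSet2D, SamplePlot, Zone

__all__ = ["score_plots", "frequency_table", "pooled_means"]

logger = logging.getLogger(__name__)


def score_plots(plots: Sequence[SamplePlot], mounds: PointSet2D) -> list[SamplePlot]:
    """Score each plot 1 if at least one mound centroid lies in its disc.

    The disc is closed: a mound at exactly ``radius`` from the centre
    counts as present. Mound extent is not modelled — the centroid is the
    reproducible proxy for the field observer's by-eye call. Returns new
    plots; the inputs are not mutated.
    """
    if len(mounds) == 0:
        return [p.scored(0) for p in plots]
    tree = cKDTree(mounds.xy)
    out = []
    for p in plots:
        d, _ = tree.query([p.x, p.y], k=1)
        out.append(p.scored(int(d <= p.radius)))
    return out


def frequency_table(plots: Sequence[SamplePlot]) -> pd.DataFrame:
    """Per-(zone, year) presence counts and exact proportions.

    All plots must be scored; an unscored plot is an error, never
    silently treated as absent. Empty zone-year combinations are simply
    absent from the table (a warning is logged when a zone present in
    one year is missing in another).
    """
    if any(p.presence is None for p in plots):
        raise ValueError("all plots must be scored before tabulation")
    if not plots:
        raise ValueError("no plots to tabulate")
    df = pd.DataFrame(
        {
            "zone": [p.zone.value for p in plots],
            "year": [p.year for p in plots],
            "presence": [p.presence for p in plots],
        }
    )
    tab = (
        df.groupby(["zone", "year"])
        .agg(n_plots=("presence", "size"), n_present=("presence", "sum"))
        .reset_index()
    )
    tab["proportion"] = tab["n_present"] / tab["n_plots"]
    zones = set(tab["zone"])
    years = set(tab["year"])
    for z in zones:
        missing = years - set(tab.loc[tab["zone"] == z, "year"])
        if missing:
            logger.warning("zone %s has no plots in years %s; rows omitted", z, sorted(missing))
    order = {z.value: i for i, z in enumerate(Zone)}
    return tab.sort_values(["zone", "year"], key=lambda s: s.map(order) if s.name == "zone" else s).reset_index(drop=True)


def pooled_means(table: pd.DataFrame, weighted: bool = False) -> pd.Series:
    """Zone-level mean presence proportion pooled across years.

    The default is the unweighted mean of yearly proportions (matching
    how multi-year zone averages are conventionally reported alongside
    yearly ranges); ``weighted=True`` pools plot counts instead.
    """
    if weighted:
        g = table.groupby("zone")
        return g["n_present"].sum() / g["n_plots"].sum()
    return table.groupby("zone")["proportion"].mean()
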