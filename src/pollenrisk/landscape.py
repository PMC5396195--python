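"""Land-cover composition inside circular buffers and buffer-scale selection.

Percent natural / agricultural / focal-crop (apple) cover is computed over
all non-NODATA cells whose centers fall within a Euclidean buffer radius of
a hive location — the cell-center membership rule conventional for 30 m
categorical rasters.  The analysis radius is chosen among candidate buffer
sizes by AIC of simple linear models of a site-level response on each
landscape predictor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import LandCoverGrid
from .stats import ols

__all__ = ["buffer_percent", "select_scale", "BufferSummary", "DEFAULT_RADII"]

DEFAULT_RADII = (1000.0, 2000.0, 3000.0)  # meters; typical honey bee foraging radii
_PREDICTORS = ("pct_natural", "pct_agricultural", "pct_apple")


@dataclass(frozen=True)
class BufferSummary:
    """Percent cover by group within one buffer around one site.

    With ``apple_in_agricultural`` (the default grouping), apple cells count
    toward both ``pct_apple`` and ``pct_agricultural``, so natural +
    agricultural + other = 100; otherwise the four percents partition 100.
    """

    site_id: str
    radius: float
    pct_natural: float
    pct_agricultural: float
    pct_apple: float
    pct_other: float
    n_cells: int


def buffer_percent(
    grid: LandCoverGrid,
    center: tuple[float, float],
    radius: float,
    site_id: str = "",
    apple_in_agricultural: bool = True,
) -> BufferSummary:
    """Group percentages over cells whose centers lie within ``radius``
    meters of ``center``.

    All group percents share the same denominator (in-buffer non-NODATA
    cells).  A buffer entirely off-grid or all NODATA is an error.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    cx, cy = center
    cs = grid.cell_size
    nrows, ncols = grid.codes.shape

    # Window the grid to the buffer's bounding box before the distance test.
    col_lo = max(0, int(math.floor((cx - radius - grid.xll) / cs)))
    col_hi = min(ncols, int(math.ceil((cx + radius - grid.xll) / cs)) + 1)
    row_top_y = grid.yll + nrows * cs
    row_lo = max(0, int(math.floor((row_top_y - (cy + radius)) / cs)))
    row_hi = min(nrows, int(math.ceil((row_top_y - (cy - radius)) / cs)) + 1)
    if col_lo >= col_hi or row_lo >= row_hi:
        raise ValueError(f"{site_id}: buffer at {center} r={radius} is entirely off-grid")

    sub = grid.codes[row_lo:row_hi, col_lo:col_hi]
    cols = np.arange(col_lo, col_hi)
    rows = np.arange(row_lo, row_hi)
    xs = grid.xll + (cols + 0.5) * cs
    ys = grid.yll + (nrows - 1 - rows + 0.5) * cs
    dx2 = (xs[None, :] - cx) ** 2
    dy2 = (ys[:, None] - cy) ** 2
    inside = (dx2 + dy2) <= radius**2

    codes_in = sub[inside]
    codes_in = codes_in[codes_in != grid.nodata]
    if codes_in.size == 0:
        raise ValueError(
            f"{site_id}: no valid cells in buffer at {center} r={radius}"
        )

    group_of = {code: lc.group for code, lc in grid.class_map.items()}
    counts = {"natural": 0, "agricultural": 0, "apple": 0, "other": 0}
    vals, cnts = np.unique(codes_in, return_counts=True)
    for v, c in zip(vals.tolist(), cnts.tolist()):
        counts[group_of[v]] += c
    denom = codes_in.size
    pct_apple = 100.0 * counts["apple"] / denom
    pct_agri = 100.0 * counts["agricultural"] / denom
    if apple_in_agricultural:
        pct_agri += pct_apple
    return BufferSummary(
        site_id=site_id,
        radius=radius,
        pct_natural=100.0 * counts["natural"] / denom,
        pct_agricultural=pct_agri,
        pct_apple=pct_apple,
        pct_other=100.0 * counts["other"] / denom,
        n_cells=denom,
    )


def select_scale(
    summaries: Mapping[float, Sequence[BufferSummary]],
    response: Mapping[str, float],
    predictors: Sequence[str] = _PREDICTORS,
) -> float:
    """Choose the buffer radius whose landscape predictors best fit a
    site-level response, by AIC.

    For each radius, one simple linear model of the response on each listed
    predictor is fitted and the radius is scored by its best (lowest) AIC;
    the radius with the lowest score wins, with ties broken toward the
    LARGEST radius.  All radii must cover the same sites.
    """
    if not summaries:
        raise ValueError("no buffer summaries given")
    site_order = None
    scores: dict[float, float] = {}
    for radius, rows in summaries.items():
        sites = [b.site_id for b in rows]
        if site_order is None:
            site_order = sites
            missing = [s for s in sites if s not in response]
            if missing:
                raise ValueError(f"response missing for sites {missing}")
        elif set(sites) != set(site_order):
            raise ValueError(f"radius {radius} covers different sites")
        by_site = {b.site_id: b for b in rows}
        y = np.array([response[s] for s in site_order], dtype=float)
        aics = []
        for pred in predictors:
            x = np.array([getattr(by_site[s], pred) for s in site_order], dtype=float)
            try:
                aics.append(ols(x, y).aic)
            except ValueError:  # constant predictor at this radius
                continue
        if not aics:
            raise ValueError(f"radius {radius}: no fittable predictor")
        scores[radius] = min(aics)

    best = min(scores.values())
    # ties (to numerical precision) resolve toward the largest radius
    return max(r for r, s in scores.items() if s <= best + 1e-9)
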