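"""Gain of life expectancy and the geographic equity of its distribution.

The health benefit of a control stage (begin year y1, end year y2) is the
per-cell gain of life expectancy

    GLE_s = LLE_{s, y1} - LLE_{s, y2}        (years per capita)

from which the population-adjusted years of life gain follows as

    YLG_s = GLE_s * P_{s, y2} / LE_0.

Treating GLE as a *health income*, its geographic distribution is
summarised by a population-weighted Lorenz curve (cells sorted by
per-capita GLE ascending; cumulative population share against cumulative
benefit share) and the Gini index, one minus twice the area under the
curve.  A perfectly even distribution gives the diagonal and GI = 0.

Cells where air quality worsened can carry negative GLE.  They are
included by default (sorted first; the Gini index may then exceed 1 and
the result records how many such cells there were); an option drops them
with explicit logging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import ComputationError, ValidationError

log = logging.getLogger(__name__)

ArrayLike = Union[np.ndarray, pd.Series, list, tuple]


@dataclass
class GLEField:
    """Per-cell gain of life expectancy between two years."""

    y1: int
    y2: int
    table: pd.DataFrame  # index cell_id; columns gle, ylg, p_y2

    @property
    def gle(self) -> pd.Series:
        return self.table["gle"]

    @property
    def ylg(self) -> pd.Series:
        return self.table["ylg"]

    @property
    def p_y2(self) -> pd.Series:
        return self.table["p_y2"]


def gain_of_life_expectancy(
    lle_y1: pd.Series,
    lle_y2: pd.Series,
    p_y1: pd.Series,
    p_y2: pd.Series,
    le0: float,
    y1: int = 0,
    y2: int = 0,
) -> GLEField:
    """Per-cell GLE field between two years of one burden computation.

    ``gle`` is exactly the LLE difference; ``ylg = gle * p_y2 / le0`` is
    kept algebraically consistent with that definition.  ``p_y1`` is
    accepted for interface completeness and alignment checking only — the
    population-ratio form it would enter is inconsistent with the LLE
    difference and is not used (see the methods note).
    """
    for name, s in (("lle_y2", lle_y2), ("p_y1", p_y1), ("p_y2", p_y2)):
        if not lle_y1.index.equals(s.index):
            raise ValidationError(f"cell keys of lle_y1 and {name} do not align")
    if le0 <= 0:
        raise ValidationError("life expectancy at birth must be positive")
    gle = lle_y1 - lle_y2
    ylg = gle * p_y2 / le0
    table = pd.DataFrame({"gle": gle, "ylg": ylg, "p_y2": p_y2})
    table.index.name = "cell_id"
    return GLEField(y1=y1, y2=y2, table=table)


@dataclass
class LorenzResult:
    """Polygonal Lorenz curve of a benefit distribution plus its Gini index.

    ``points`` holds the exact curve at every cell boundary, starting at
    (0, 0) and ending at (1, 1): columns ``pop_share`` (horizontal axis)
    and ``benefit_share``.
    """

    points: pd.DataFrame
    n_negative_cells: int
    gini: Optional[float] = field(default=None)


def lorenz_curve(
    gle: ArrayLike,
    population: ArrayLike,
    cell_ids: Optional[ArrayLike] = None,
    drop_negative: bool = False,
) -> LorenzResult:
    """Population-weighted Lorenz curve of per-capita benefits.

    Cells are sorted by per-capita GLE ascending with a stable tie-break on
    ``cell_ids`` (defaults to input order), so the curve is reproducible.
    Raises if the total benefit is zero (curve undefined).
    """
    g = np.asarray(gle, dtype=float)
    p = np.asarray(population, dtype=float)
    if g.shape != p.shape or g.ndim != 1:
        raise ValidationError("gle and population must be 1-d and aligned")
    if g.size < 1:
        raise ValidationError("need at least one cell")
    if (p < 0).any():
        raise ValidationError("populations must be non-negative")
    if p.sum() <= 0:
        raise ComputationError("total population must be positive")
    ids = np.arange(g.size) if cell_ids is None else np.asarray(cell_ids)

    n_negative = int((g < 0).sum())
    if n_negative:
        if drop_negative:
            log.warning("dropping %d cells with negative benefit from the Lorenz curve",
                        n_negative)
            keep = g >= 0
            g, p, ids = g[keep], p[keep], ids[keep]
        else:
            log.warning("%d cells carry negative benefit; the Gini index may exceed 1",
                        n_negative)

    benefit = g * p  # proportional to years of life gain per cell
    if benefit.sum() == 0:
        raise ComputationError("total benefit is zero; Lorenz curve undefined")

    order = np.lexsort((ids, g))  # ascending per-capita benefit, stable by id
    p_sorted, b_sorted = p[order], benefit[order]
    x = np.concatenate([[0.0], np.cumsum(p_sorted) / p_sorted.sum()])
    y = np.concatenate([[0.0], np.cumsum(b_sorted) / b_sorted.sum()])
    x[-1], y[-1] = 1.0, 1.0  # exact endpoints
    points = pd.DataFrame({"pop_share": x, "benefit_share": y})
    return LorenzResult(points=points, n_negative_cells=n_negative)


def gini_index(lorenz: LorenzResult) -> float:
    """Gini index: 1 minus twice the trapezoid area under the Lorenz curve.

    For all-non-negative benefits this equals the population-weighted
    mean-absolute-difference form; with negative cells included it may
    exceed 1.  The result is also stored on ``lorenz.gini``.
    """
    pts = lorenz.points
    if len(pts) < 2:
        raise ValidationError("Lorenz curve needs at least one cell segment")
    area = float(np.trapezoid(pts["benefit_share"].to_numpy(),
                              pts["pop_share"].to_numpy()))
    lorenz.gini = 1.0 - 2.0 * area
    return lorenz.gini


def benefit_share_at(lorenz: LorenzResult, pop_share: float) -> float:
    """Benefit share of the population below a cumulative population share
    (linear interpolation along the polygonal curve)."""
    pts = lorenz.points
    return float(np.interp(pop_share, pts["pop_share"].to_numpy(),
                           pts["benefit_share"].to_numpy()))
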