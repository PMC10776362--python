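"""Nonlinear exposure-response curves, relative risk, attributable fraction.

Curves are tabulated (concentration knots, one relative-risk column per
draw plus a central column) in the style of GBD meta-regression output.
Relative risk at a concentration C is the tabulated curve value divided by
its value at the theoretical minimum-risk exposure level (TMREL), linearly
interpolated between knots, clipped to 1 below the TMREL and extrapolated
flat beyond the last knot.  The attributable fraction is 1 - 1/RR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ComputationError, SchemaError, ValidationError

ERF_DIALECT_HEADER = "# airburden-erf v1"

_MONO_TOL = 1e-12


@dataclass
class ERFCurve:
    """One tabulated exposure-response curve with uncertainty draws.

    ``rr_draws`` has shape (n_knots, n_draws); ``rr_central`` is the central
    curve. ``tmrel_draws``, if present, carries one TMREL per draw (sampled
    TMREL policy); otherwise ``tmrel`` applies to every draw.
    """

    pollutant: str
    cause: str
    age_band: str  # a band label, or "all" for a uniform adult curve
    tmrel: float
    conc: np.ndarray
    rr_central: np.ndarray
    rr_draws: np.ndarray
    tmrel_draws: Optional[np.ndarray] = field(default=None)

    def __post_init__(self):
        self.conc = np.asarray(self.conc, dtype=float)
        self.rr_central = np.asarray(self.rr_central, dtype=float)
        self.rr_draws = np.asarray(self.rr_draws, dtype=float)
        if self.conc.size == 0:
            raise ValidationError(f"{self.key()}: empty concentration table")
        if np.any(np.diff(self.conc) <= 0):
            raise ValidationError(f"{self.key()}: concentration knots must be strictly increasing")
        if self.rr_draws.ndim != 2 or self.rr_draws.shape[0] != self.conc.size:
            raise ValidationError(f"{self.key()}: draw table shape mismatch")
        cols = np.column_stack([self.rr_central, self.rr_draws])
        if np.any(np.diff(cols, axis=0) < -_MONO_TOL):
            raise ValidationError(f"{self.key()}: relative risk must be non-decreasing in concentration")
        if self.tmrel < 0:
            raise ValidationError(f"{self.key()}: TMREL must be non-negative")

    def key(self) -> tuple[str, str, str]:
        return (self.pollutant, self.cause, self.age_band)

    @property
    def n_draws(self) -> int:
        return self.rr_draws.shape[1]

    def tmrel_for(self, draw: Optional[int]) -> float:
        if draw is not None and self.tmrel_draws is not None:
            return float(self.tmrel_draws[draw])
        return self.tmrel


def relative_risk(
    curve: ERFCurve,
    concentration: Union[float, np.ndarray],
    draw: Optional[int] = None,
):
    """Relative risk at a concentration, normalised at the TMREL.

    ``draw=None`` evaluates the central curve.  Linear interpolation between
    knots; flat extrapolation beyond the last knot; RR clipped to 1 at and
    below the TMREL so attributable fractions are non-negative.
    """
    c = np.asarray(concentration, dtype=float)
    scalar = c.ndim == 0
    c = np.atleast_1d(c)
    if (c < 0).any():
        raise ValidationError("concentration must be non-negative")
    if draw is not None and not (0 <= draw < curve.n_draws):
        raise ValidationError(f"draw index {draw} out of range (n_draws={curve.n_draws})")
    col = curve.rr_central if draw is None else curve.rr_draws[:, draw]
    tm = curve.tmrel_for(draw)
    val = np.interp(c, curve.conc, col)
    ref = float(np.interp(tm, curve.conc, col))
    if ref <= 0:
        raise ComputationError(f"{curve.key()}: non-positive curve value at TMREL")
    rr = np.where(c <= tm, 1.0, np.maximum(val / ref, 1.0))
    return float(rr[0]) if scalar else rr


def attributable_fraction(rr: Union[float, np.ndarray]):
    """Attributable fraction 1 - 1/RR; lies in [0, 1) for RR >= 1."""
    arr = np.asarray(rr, dtype=float)
    if (arr <= 0).any():
        raise ValidationError("relative risk must be strictly positive")
    out = 1.0 - 1.0 / arr
    return float(out) if np.ndim(rr) == 0 else out


# ---------------------------------------------------------------------------
# table dialect
# ---------------------------------------------------------------------------

def save_erf_table(curves: Sequence[ERFCurve], path: Union[str, Path]) -> None:
    """Write curves in the delimited dialect (versioned header + CSV).

    Columns: pollutant, cause, age_band, tmrel, concentration, central,
    draw_0..draw_{n-1}; one row per (curve, knot).
    """
    frames = []
    for cv in curves:
        meta = pd.DataFrame({
            "pollutant": cv.pollutant,
            "cause": cv.cause,
            "age_band": cv.age_band,
            "tmrel": cv.tmrel,
            "concentration": cv.conc,
            "central": cv.rr_central,
        })
        draws = pd.DataFrame(cv.rr_draws,
                             columns=[f"draw_{d}" for d in range(cv.n_draws)])
        frames.append(pd.concat([meta, draws], axis=1))
    table = pd.concat(frames, ignore_index=True)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(ERF_DIALECT_HEADER + "\n")
        table.to_csv(fh, index=False, float_format="%.12g")


def load_erf_table(path: Union[str, Path]) -> list[ERFCurve]:
    """Read and validate a curve collection; rejects non-monotone curves."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"ERF table not found: {path}")
    with open(path) as fh:
        first = fh.readline().strip()
        if first != ERF_DIALECT_HEADER:
            raise SchemaError(f"{path}: missing dialect header {ERF_DIALECT_HEADER!r}")
        table = pd.read_csv(fh)
    required = {"pollutant", "cause", "age_band", "tmrel", "concentration", "central"}
    missing = required - set(table.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    draw_cols = sorted(
        (c for c in table.columns if c.startswith("draw_")),
        key=lambda c: int(c.split("_", 1)[1]),
    )
    curves = []
    for (pol, cause, band), grp in table.groupby(
        ["pollutant", "cause", "age_band"], sort=True
    ):
        grp = grp.sort_values("concentration")
        tmrels = grp["tmrel"].unique()
        if len(tmrels) != 1 or pd.isna(tmrels[0]):
            raise SchemaError(f"curve ({pol}, {cause}, {band}): TMREL missing or inconsistent")
        if grp[draw_cols].isna().any().any():
            raise SchemaError(f"curve ({pol}, {cause}, {band}): ragged draw columns")
        try:
            curves.append(ERFCurve(
                pollutant=str(pol), cause=str(cause), age_band=str(band),
                tmrel=float(tmrels[0]),
                conc=grp["concentration"].to_numpy(),
                rr_central=grp["central"].to_numpy(),
                rr_draws=grp[draw_cols].to_numpy(),
            ))
        except ValidationError as exc:
            raise SchemaError(f"{path}: {exc}") from exc
    if not curves:
        raise SchemaError(f"{path}: no curves found")
    return curves


def curves_by_pollutant(curves: Sequence[ERFCurve]) -> dict[str, dict[str, list[ERFCurve]]]:
    """Group a curve collection as {pollutant: {cause: [curves by age band]}}."""
    out: dict[str, dict[str, list[ERFCurve]]] = {}
    for cv in curves:
        out.setdefault(cv.pollutant, {}).setdefault(cv.cause, []).append(cv)
    return out
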