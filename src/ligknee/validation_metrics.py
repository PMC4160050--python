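"""Validation metrics: Pearson r, RMSE and 95%-CI corridor containment.

Predicted kinematic curves are compared against an experimental-style
reference corridor (pointwise mean and 95% confidence band over a specimen
ensemble).  Following the source methodology, r and RMSE are computed
against the corridor mean, and containment is the fraction of prediction
points lying inside the confidence band.  Curves are resampled to the
corridor abscissa by linear interpolation before any metric is taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CaseMismatchError, CorridorRangeError, UndefinedCorrelationError
from .knee_simulator import KinematicCurve

__all__ = ["Corridor", "pearson_r", "rmse", "corridor_containment", "build_report"]

_EDGE_TOL = 1e-9  # float slack when testing band membership


@dataclass(frozen=True)
class Corridor:
    """Mean +/- 95% CI reference band over a specimen ensemble."""

    abscissa: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_specimens: int
    angle: str = "abduction"
    case_name: str = ""

    def __post_init__(self):
        x = np.asarray(self.abscissa, dtype=float)
        for attr in ("abscissa", "mean", "ci_low", "ci_high"):
            v = np.asarray(getattr(self, attr), dtype=float)
            if v.shape != x.shape:
                raise ValueError("corridor columns must have equal lengths")
            object.__setattr__(self, attr, v)
        if np.any(self.ci_low > self.mean + _EDGE_TOL) or np.any(self.mean > self.ci_high + _EDGE_TOL):
            raise ValueError("corridor bounds must satisfy ci_low <= mean <= ci_high")


def pearson_r(pred, ref) -> float:
    """Product-moment correlation between two equal-length sequences."""
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    if p.shape != r.shape or p.size < 3:
        raise ValueError("need equal-length sequences of at least 3 points")
    if np.ptp(p) == 0.0 or np.ptp(r) == 0.0:
        raise UndefinedCorrelationError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(p, r).statistic)


def rmse(pred, ref) -> float:
    """Root-mean-square difference; zero iff the sequences are identical."""
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    if p.shape != r.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((p - r) ** 2)))


def _resample_curve(curve: KinematicCurve, angle: str, abscissa: np.ndarray) -> np.ndarray:
    return np.interp(abscissa, curve.abscissa, curve.angle_values(angle))


def corridor_containment(pred: KinematicCurve, corr: Corridor, angle: str | None = None) -> float:
    """Fraction of prediction points inside the corridor's 95% band.

    Corridor bounds are linearly interpolated onto the prediction abscissa;
    prediction points outside the corridor's abscissa range raise
    CorridorRangeError naming the offending points.
    """
    angle = angle or corr.angle
    x = pred.abscissa
    lo_x, hi_x = corr.abscissa[0], corr.abscissa[-1]
    bad = x[(x < lo_x - _EDGE_TOL) | (x > hi_x + _EDGE_TOL)]
    if bad.size:
        raise CorridorRangeError(
            f"prediction abscissa outside corridor range [{lo_x:g}, {hi_x:g}]: {bad.tolist()}"
        )
    v = pred.angle_values(angle)
    lo = np.interp(x, corr.abscissa, corr.ci_low)
    hi = np.interp(x, corr.abscissa, corr.ci_high)
    inside = (v >= lo - _EDGE_TOL) & (v <= hi + _EDGE_TOL)
    return float(np.mean(inside))


def build_report(
    pred_3d: dict[str, KinematicCurve],
    pred_uniaxial: dict[str, KinematicCurve],
    corridors: dict[str, Corridor],
) -> pd.DataFrame:
    """Per-(case, representation) validation table.

    One row per case and representation with Pearson r, RMSE (deg) and
    containment of the case's primary angle against the corridor, plus the
    between-representation RMSE for the same angle.  Requires matching case
    names across all three inputs.
    """
    names = set(pred_3d)
    if names != set(pred_uniaxial) or names != set(corridors):
        raise CaseMismatchError(
            f"case names differ: 3d={sorted(pred_3d)}, uniaxial={sorted(pred_uniaxial)}, "
            f"corridors={sorted(corridors)}"
        )
    rows = []
    for case in sorted(names):
        corr = corridors[case]
        angle = corr.angle
        between = rmse(
            pred_3d[case].angle_values(angle), pred_uniaxial[case].angle_values(angle)
        )
        for tag, curve in (("anatomic_3d", pred_3d[case]), ("uniaxial", pred_uniaxial[case])):
            v = _resample_curve(curve, angle, corr.abscissa)
            rows.append(
                {
                    "case": case,
                    "representation": tag,
                    "angle": angle,
                    "r": pearson_r(v, corr.mean),
                    "rmse_deg": rmse(v, corr.mean),
                    "containment": corridor_containment(curve, corr, angle),
                    "between_repr_rmse_deg": between,
                }
            )
    return pd.DataFrame(rows)
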