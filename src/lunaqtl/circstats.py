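"""Circular summary statistics for lunar emergence rhythms.

Emergence days of the marine midge *Clunio marinus* are recorded on a periodic
axis (a 30-day moonlight cycle or a 15-day tidal-turbulence cycle).  The
strength of synchronization to the zeitgeber is quantified by the mean
resultant vector length R of the emergence-day distribution: R = 1 means all
individuals emerged on the same lunar day, R = 0 means the distribution is
uniform (arrhythmic, i.e. insensitive to the zeitgeber).  The derived
dispersion measures are

    circular SD        sqrt(-2 ln R)
    angular variance   2 (1 - R)
    angular deviation  sqrt(2 (1 - R))

and the mean/median vector directions measure the lunar phase of emergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CircularSummary",
    "day_to_angle",
    "angle_to_day",
    "circular_summary",
    "read_emergence_csv",
    "write_summary_csv",
]


def day_to_angle(day, period: int):
    """Map lunar day(s) in [1, period] to angle(s) in radians.

    The convention is theta = 2*pi*day/period, so day == period wraps to
    angle 0.  This matters at the period boundary: a mean direction of e.g.
    0.04 lunar days is an emergence peak just past the cycle anchor.
    """
    day_arr = np.asarray(day, dtype=float)
    if np.any(day_arr < 1) or np.any(day_arr > period):
        raise ValueError(f"lunar day outside [1, {period}]: {day!r}")
    return 2.0 * np.pi * np.mod(day_arr, period) / period


def angle_to_day(angle, period: int):
    """Inverse of :func:`day_to_angle`; returns values in [0, period)."""
    return np.mod(np.asarray(angle, dtype=float) * period / (2.0 * np.pi), period)


@dataclass(frozen=True)
class CircularSummary:
    """Summary circular statistics of one emergence distribution.

    ``circular_sd`` is ``inf`` for a uniform sample (R = 0), where the
    dispersion is undefined.  ``degenerate`` flags single-individual input.
    """

    n: int
    period: int
    mean_direction: float
    median_direction: int
    vector_length: float
    circular_sd: float
    angular_variance: float
    angular_deviation: float
    cos_component: float
    sin_component: float
    degenerate: bool = False


def _circular_median(days, weights, period, mean_dir):
    """Observed day minimizing mean circular arc distance.

    Ties are broken by proximity to the mean direction, then by smaller day.
    """
    cand = np.unique(days)
    arc = np.abs(cand[:, None] - days[None, :])
    arc = np.minimum(arc, period - arc)
    score = (arc * weights[None, :]).sum(axis=1)
    best = score.min()
    tied = cand[np.isclose(score, best)]
    if len(tied) == 1:
        return int(tied[0])
    d_mean = np.abs(tied - mean_dir)
    d_mean = np.minimum(d_mean, period - d_mean)
    tied = tied[np.isclose(d_mean, d_mean.min())]
    return int(tied.min())


def circular_summary(days, period: int, counts=None) -> CircularSummary:
    """Compute circular summary statistics of lunar emergence days.

    Parameters
    ----------
    days
        Lunar days, each in [1, period].  Per-individual observations or the
        distinct days of an aggregated table.
    period
        Zeitgeber period in days (15 for tidal turbulence, 30 for moonlight).
    counts
        Optional per-day weights (individuals per day).  Per-individual and
        weighted per-day input give identical results.
    """
    days = np.asarray(days, dtype=float)
    if days.size == 0:
        raise ValueError("empty emergence sample")
    if counts is None:
        counts = np.ones_like(days)
    counts = np.asarray(counts, dtype=float)
    if counts.shape != days.shape:
        raise ValueError("counts must match days in shape")
    if np.any(counts < 1):
        raise ValueError("counts must be >= 1")

    theta = day_to_angle(days, period)
    w = counts / counts.sum()
    c = float(np.sum(w * np.cos(theta)))
    s = float(np.sum(w * np.sin(theta)))
    r = math.hypot(c, s)
    r = min(r, 1.0)
    mean_dir = float(angle_to_day(math.atan2(s, c), period))
    ang_var = 2.0 * (1.0 - r)
    ang_dev = math.sqrt(ang_var)
    sd = math.inf if r == 0.0 else math.sqrt(max(-2.0 * math.log(r), 0.0))
    n = int(round(counts.sum()))
    return CircularSummary(
        n=n,
        period=period,
        mean_direction=mean_dir,
        median_direction=_circular_median(days, w, period, mean_dir),
        vector_length=r,
        circular_sd=sd,
        angular_variance=ang_var,
        angular_deviation=ang_dev,
        cos_component=c,
        sin_component=s,
        degenerate=(n == 1),
    )


# ---------------------------------------------------------------------------
# CSV dialects

_INDIVIDUAL_COLS = {"family", "individual", "experimental_day"}
_AGGREGATED_COLS = {"family", "lunar_day", "count"}


def read_emergence_csv(path) -> pd.DataFrame:
    """Read an emergence table, per-individual or aggregated per-day.

    Per-individual dialect: ``family,individual,experimental_day[,sex][,count]``.
    Aggregated dialect: ``family,lunar_day,count``.  Aggregated rows are given
    ``count`` weights; per-individual rows default to count 1 and sex unknown.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if _INDIVIDUAL_COLS <= cols:
        if "count" not in cols:
            df["count"] = 1
        if "sex" not in cols:
            df["sex"] = "unknown"
        if (df["experimental_day"] < 1).any():
            raise ValueError("experimental_day must be strictly positive")
    elif _AGGREGATED_COLS <= cols:
        pass
    else:
        raise ValueError(
            f"unrecognized emergence CSV columns {sorted(cols)}; expected "
            f"{sorted(_INDIVIDUAL_COLS)} or {sorted(_AGGREGATED_COLS)}"
        )
    if "count" in df.columns and (df["count"] < 1).any():
        raise ValueError("counts must be >= 1")
    return df


def write_summary_csv(path, summaries: dict[str, CircularSummary]) -> None:
    """Write one row per family with the six summary statistics."""
    rows = []
    for family, s in summaries.items():
        rows.append(
            {
                "family": family,
                "n": s.n,
                "period": s.period,
                "median_direction": s.median_direction,
                "mean_direction": round(s.mean_direction, 4),
                "vector_length": round(s.vector_length, 4),
                "circular_sd": round(s.circular_sd, 4),
                "angular_variance": round(s.angular_variance, 4),
                "angular_deviation": round(s.angular_deviation, 4),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
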