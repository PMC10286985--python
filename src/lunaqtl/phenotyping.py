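"""Probability phenotyping of cross progeny from emergence days.

F2/backcross progeny of a zeitgeber-sensitive x insensitive cross emerge
either inside the sensitive-parent peak or uniformly across the cycle, but the
peak also hides some truly insensitive individuals.  The phenotyping chain
resolves this:

1. fold experimental days onto lunar days at the zeitgeber period,
2. phase-correct the progeny distribution onto the sensitive reference so
   that only rhythmicity (not phase) is scored,
3. estimate wrapped kernel densities (default bandwidth 10 days) of the
   sensitive and insensitive reference distributions,
4. fit the progeny sample as a two-component mixture
   pi * f_I(d) + (1 - pi) * f_S(d) by EM, and assign each individual the
   posterior probability of being insensitive given its emergence day,
5. optionally reduce to binary phenotypes (p > 0.7 -> insensitive,
   p < 0.3 -> sensitive, in-between excluded) and estimate the
   sensitive:insensitive ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circstats import CircularSummary, circular_summary

__all__ = [
    "ZeitgeberRegime",
    "MOONLIGHT",
    "TURBULENCE",
    "DayProbabilityProfile",
    "assign_lunar_days",
    "phase_correction",
    "kde_density",
    "mixture_posterior",
    "assign_probability_phenotypes",
    "reduce_dataset",
    "estimate_ratio",
    "probability_phenotypes",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ZeitgeberRegime:
    """An entrainment regime and its day-1 anchoring convention."""

    kind: str
    period: int
    day1_rule: str

    def __post_init__(self):
        if self.period not in (15, 30):
            raise ValueError("period must be 15 or 30")


MOONLIGHT = ZeitgeberRegime(
    "moonlight", 30, "day 1 = first 24 h period with artificial moonlight"
)
TURBULENCE = ZeitgeberRegime(
    "turbulence", 15, "day 1 = vibration onset in the middle of subjective night"
)


def assign_lunar_days(table: pd.DataFrame, regime: ZeitgeberRegime, day1: int) -> pd.DataFrame:
    """Fold experimental days onto lunar days: ((day - day1) mod period) + 1."""
    if day1 is None:
        raise ValueError(
            "day1 anchor missing: supply the zeitgeber-log day on which the "
            "stimulus convention marks day 1"
        )
    if day1 < 1:
        raise ValueError("day1 must be >= 1")
    out = table.copy()
    exp = out["experimental_day"].to_numpy()
    if (exp < 1).any():
        raise ValueError("experimental days must be >= 1")
    out["lunar_day"] = ((exp - day1) % regime.period) + 1
    return out


def circular_shift(reference_mean: float, progeny_mean: float, period: int) -> int:
    """Signed integer circular difference, in (-period/2, period/2]."""
    delta = (reference_mean - progeny_mean) % period
    if delta > period / 2:
        delta -= period
    shift = int(round(delta))
    if shift == -period // 2 and period % 2 == 0:
        shift = period // 2
    return shift


def phase_correction(
    progeny: pd.DataFrame,
    reference: CircularSummary,
    progeny_summary: CircularSummary,
    min_reference_r: float = 0.2,
) -> tuple[pd.DataFrame, int]:
    """Shift progeny lunar days so their phase matches the reference.

    Only integer-day shifts are applied (lunar days are integers).  If the
    reference rhythm is too weak for its phase to be meaningful
    (R < ``min_reference_r``) no shift is applied.
    """
    if reference.period != progeny_summary.period:
        raise ValueError("reference and progeny periods differ")
    period = reference.period
    if reference.vector_length < min_reference_r:
        log.warning(
            "reference vector length %.3f below %.2f: phase undefined, shift 0",
            reference.vector_length,
            min_reference_r,
        )
        return progeny.copy(), 0
    shift = circular_shift(reference.mean_direction, progeny_summary.mean_direction, period)
    out = progeny.copy()
    out["lunar_day"] = ((out["lunar_day"].to_numpy() - 1 + shift) % period) + 1
    return out, shift


def kde_density(
    days, period: int, bandwidth: float = 10.0, counts=None, kernel: str = "vonmises"
) -> np.ndarray:
    """Circular kernel density at integer days 1..period, summing to 1.

    The default kernel is von Mises with concentration ``bandwidth`` — the
    circular-KDE convention (as in R's ``density.circular``), under which
    bandwidth 10 corresponds to a kernel SD of roughly kappa^(-1/2) radians,
    about 0.8 days on a 15-day cycle.  ``kernel='wrapped_gaussian'`` instead
    treats ``bandwidth`` as the kernel SD in days, wrapping the Gaussian over
    enough period images to cover +-8 SD.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    days = np.asarray(days, dtype=float)
    if days.size == 0:
        raise ValueError("empty sample")
    if counts is None:
        counts = np.ones_like(days)
    counts = np.asarray(counts, dtype=float)
    w = counts / counts.sum()
    grid = np.arange(1, period + 1, dtype=float)
    if kernel == "vonmises":
        two_pi = 2.0 * np.pi
        delta = two_pi * (grid[:, None] - days[None, :]) / period
        dens = (np.exp(bandwidth * (np.cos(delta) - 1.0)) * w[None, :]).sum(axis=1)
    elif kernel == "wrapped_gaussian":
        n_wrap = int(math.ceil(8.0 * bandwidth / period)) + 1
        wraps = np.arange(-n_wrap, n_wrap + 1) * period
        d = grid[:, None, None] - days[None, :, None] + wraps[None, None, :]
        dens = (np.exp(-0.5 * (d / bandwidth) ** 2).sum(axis=2) * w[None, :]).sum(axis=1)
    else:
        raise ValueError("kernel must be 'vonmises' or 'wrapped_gaussian'")
    return dens / dens.sum()


@dataclass(frozen=True)
class DayProbabilityProfile:
    """Per-lunar-day mixture components and posterior insensitivity."""

    period: int
    f_sensitive: np.ndarray
    f_insensitive: np.ndarray
    mixing_proportion: float
    posterior_insensitive: np.ndarray
    bandwidth: float = 10.0
    n_iter: int = field(default=0, compare=False)

    def p_insensitive(self, lunar_day) -> np.ndarray:
        day = np.asarray(lunar_day, dtype=int)
        if np.any(day < 1) or np.any(day > self.period):
            raise ValueError("lunar day outside profile support")
        return self.posterior_insensitive[day - 1]


def mixture_posterior(
    progeny_days,
    f_sensitive: np.ndarray,
    f_insensitive: np.ndarray,
    counts=None,
    bandwidth: float = 10.0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    init: float = 0.5,
) -> DayProbabilityProfile:
    """Estimate the insensitive mixing proportion by EM and per-day posteriors.

    Maximizes sum_j log(pi f_I(d_j) + (1-pi) f_S(d_j)) over the progeny days.
    The per-day posterior is p_I(d) = pi f_I / (pi f_I + (1-pi) f_S).
    """
    f_s = np.asarray(f_sensitive, dtype=float)
    f_i = np.asarray(f_insensitive, dtype=float)
    if f_s.shape != f_i.shape:
        raise ValueError("component densities must share the day grid")
    period = len(f_s)
    days = np.asarray(progeny_days, dtype=int)
    if np.any(days < 1) or np.any(days > period):
        raise ValueError("progeny lunar day outside [1, period]")
    if counts is None:
        counts = np.ones_like(days, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if np.allclose(f_s, f_i):
        raise ValueError(
            "sensitive and insensitive densities are identical everywhere: "
            "the mixing proportion is unidentifiable"
        )
    fs = f_s[days - 1]
    fi = f_i[days - 1]
    if np.any((fs <= 0) & (fi <= 0)):
        raise ValueError("both densities vanish on an observed day")

    pi = float(init)
    it = 0
    for it in range(1, max_iter + 1):
        denom = pi * fi + (1.0 - pi) * fs
        resp = np.where(denom > 0, pi * fi / np.where(denom > 0, denom, 1.0), 0.5)
        new_pi = float(np.sum(counts * resp) / counts.sum())
        if abs(new_pi - pi) < tol:
            pi = new_pi
            break
        pi = new_pi

    denom = pi * f_i + (1.0 - pi) * f_s
    post = np.where(denom > 0, pi * f_i / np.where(denom > 0, denom, 1.0), np.nan)
    return DayProbabilityProfile(
        period=period,
        f_sensitive=f_s,
        f_insensitive=f_i,
        mixing_proportion=pi,
        posterior_insensitive=post,
        bandwidth=bandwidth,
        n_iter=it,
    )


def assign_probability_phenotypes(table: pd.DataFrame, profile: DayProbabilityProfile) -> pd.DataFrame:
    """Per-individual probability of being insensitive, from the day posterior."""
    if "lunar_day" not in table.columns:
        raise ValueError("lunar days not assigned; run assign_lunar_days first")
    out = table[[c for c in ("individual", "lunar_day") if c in table.columns]].copy()
    out["p_insensitive"] = profile.p_insensitive(table["lunar_day"].to_numpy())
    return out


def reduce_dataset(p_insensitive, lo: float = 0.3, hi: float = 0.7):
    """Binarize probability phenotypes; uncertain individuals are excluded.

    Strict inequalities: p > hi -> 1, p < lo -> 0, lo <= p <= hi -> excluded.
    Returns (binary array with NaN for excluded, number excluded).
    """
    if not (0 <= lo < hi <= 1):
        raise ValueError("need 0 <= lo < hi <= 1")
    p = np.asarray(p_insensitive, dtype=float)
    binary = np.full(p.shape, np.nan)
    binary[p > hi] = 1.0
    binary[p < lo] = 0.0
    n_excluded = int(np.isnan(binary).sum())
    if n_excluded == p.size:
        raise ValueError("all individuals excluded by the reduction thresholds")
    log.info("reduced dataset: %d of %d individuals excluded", n_excluded, p.size)
    return binary, n_excluded


def estimate_ratio(p_insensitive) -> tuple[int, int]:
    """Percent sensitive : percent insensitive, from mean probability."""
    p = np.asarray(p_insensitive, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("empty phenotype vector")
    insens = int(round(100.0 * float(p.mean())))
    return 100 - insens, insens


def probability_phenotypes(
    progeny: pd.DataFrame,
    sensitive_ref: pd.DataFrame,
    insensitive_ref: pd.DataFrame,
    regime: ZeitgeberRegime,
    day1: int = 1,
    bandwidth: float = 10.0,
    phase_correct: bool = True,
) -> tuple[pd.DataFrame, DayProbabilityProfile, int]:
    """Full chain: lunar days -> phase correction -> KDEs -> mixture posterior.

    ``sensitive_ref`` is the sensitive parent (or F1) emergence table and
    ``insensitive_ref`` the insensitive parent's.  All three tables need an
    ``experimental_day`` column; returns the per-individual phenotype frame,
    the day-probability profile and the applied phase shift.
    """
    tables = []
    for t in (progeny, sensitive_ref, insensitive_ref):
        t = t if "lunar_day" in t.columns else assign_lunar_days(t, regime, day1)
        tables.append(t)
    prog, sens, insens = tables

    sens_summary = circular_summary(sens["lunar_day"], regime.period, sens.get("count"))
    prog_summary = circular_summary(prog["lunar_day"], regime.period, prog.get("count"))
    shift = 0
    if phase_correct:
        prog, shift = phase_correction(prog, sens_summary, prog_summary)

    f_s = kde_density(sens["lunar_day"], regime.period, bandwidth, sens.get("count"))
    f_i = kde_density(insens["lunar_day"], regime.period, bandwidth, insens.get("count"))
    profile = mixture_posterior(
        prog["lunar_day"], f_s, f_i, counts=prog.get("count"), bandwidth=bandwidth
    )
    pheno = assign_probability_phenotypes(prog, profile)
    return pheno, profile, shift
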