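"""Gradient-slope statistics for positional profiles.

The slope statistic is an ordinary least-squares fit of the per-position mean
GC (percent) on the raw codon index, rescaled to GC%-change per 100 codons:
a slope of -5 means the GC content drops 5 percentage points per 100 codons
along the direction of translation.  The default fit range is codons 26-100;
the first 25 codons are excluded because they sit under separate constraints
on local secondary structure near the start codon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .profiles import PositionalProfile

DEFAULT_FIT_RANGE = (26, 100)


@dataclass(frozen=True)
class GradientFit:
    slope_per100: float
    intercept: float
    r_squared: float
    fit_range: tuple[int, int]
    n_points: int


@dataclass(frozen=True)
class CrossGenomeFit:
    slope: float  # change in slope_per100 per unit coding GC%
    intercept: float
    r_squared: float
    n_species: int
    group_label: str


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    if np.isnan(r2):  # constant y: zero residuals around the flat fit
        r2 = 1.0
    return float(res.slope), float(res.intercept), float(r2)


def fit_gradient(
    profile: PositionalProfile, fit_range: tuple[int, int] = DEFAULT_FIT_RANGE
) -> GradientFit:
    """Least-squares slope of a positional profile over ``fit_range``.

    Positions with undefined means are dropped, never imputed.  The returned
    ``slope_per100`` is the per-codon OLS coefficient x100.
    """
    lo, hi = fit_range
    sel = (profile.positions >= lo) & (profile.positions <= hi)
    x = profile.positions[sel].astype(float)
    y = profile.mean_value[sel]
    ok = ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"fit_gradient: only {x.size} defined positions in {fit_range}")
    slope, intercept, r2 = _ols(x, y)
    return GradientFit(
        slope_per100=slope * 100.0,
        intercept=intercept,
        r_squared=r2,
        fit_range=(lo, hi),
        n_points=int(x.size),
    )


def cross_genome_regression(
    fits: Iterable[tuple[float, GradientFit]], group_label: str = ""
) -> CrossGenomeFit:
    """OLS of per-genome gradient slope on overall coding GC content.

    ``fits`` pairs each genome's coding GC percentage with its GradientFit.
    """
    pairs = [(gc, f.slope_per100) for gc, f in fits]
    if len(pairs) < 3:
        raise ValueError("cross_genome_regression: need >= 3 genomes")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("cross_genome_regression: coding GC is constant across genomes")
    slope, intercept, r2 = _ols(x, y)
    return CrossGenomeFit(
        slope=slope, intercept=intercept, r_squared=r2,
        n_species=len(pairs), group_label=group_label,
    )


def gc_threshold_crossing(fit: CrossGenomeFit) -> float:
    """Coding GC% at which the predicted gradient slope changes sign."""
    if fit.slope == 0:
        raise ValueError("gc_threshold_crossing: undefined for zero slope")
    return -fit.intercept / fit.slope
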