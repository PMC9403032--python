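"""Amino-acid cost profiles, the cost-gradient slope and the saved-ATP statistic.

Amino-acid biosynthesis costs (ATP equivalents; bundled Akashi-type table,
user-overridable) are averaged per codon position across genes.  A positive
OLS slope over codons 26-100 means cheaper residues sit toward the start
codon; the saved-ATP statistic converts that slope into an energy saving per
protein: slope x n/2 x 100, where n is the number of regression codons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Union

import numpy as np
import pandas as pd

from .codon_sites import classify_codon
from .profiles import (
    ClassSelector,
    Fragment,
    FragmentSpec,
    PositionalProfile,
    _as_spec,
    extract_fragment,
)
from .gradients import DEFAULT_FIT_RANGE, _ols
from .sequence_io import GenomeSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CostTable:
    aa_cost: dict[str, float]
    nt_cost: dict[str, float]
    source_label: str = "bundled"

    def __post_init__(self):
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.aa_cost)
        if missing:
            raise ValueError(f"cost table missing amino acid(s): {sorted(missing)}")
        if any(v <= 0 for v in self.aa_cost.values()) or any(
            v <= 0 for v in self.nt_cost.values()
        ):
            raise ValueError("all costs must be positive")


def _read_two_col(path_or_buf, key_col: str, val_col: str) -> dict[str, float]:
    df = pd.read_csv(path_or_buf, sep="\t", comment="#")
    return dict(zip(df[key_col].astype(str), df[val_col].astype(float)))


def load_cost_table(aa_path=None, nt_path=None, source_label: Optional[str] = None) -> CostTable:
    """Load amino-acid and nucleotide cost tables (bundled defaults)."""
    data = resources.files("gcgradients.data")
    if aa_path is None:
        aa_path = data / "aa_costs.tsv"
    if nt_path is None:
        nt_path = data / "nt_costs.tsv"
    aa = _read_two_col(aa_path, "aa", "cost")
    nt = _read_two_col(nt_path, "nt", "cost")
    return CostTable(aa, nt, source_label or "bundled")


@dataclass(frozen=True)
class CostGradientFit:
    slope_per_codon: float  # raw per-codon OLS coefficient (cost units / codon)
    intercept: float
    r_squared: float
    fit_range: tuple[int, int]
    n_points: int


def positional_cost(
    genes: GenomeSet,
    costs: CostTable,
    fragment: Union[Fragment, FragmentSpec] = Fragment.START,
) -> PositionalProfile:
    """Per-position mean amino-acid cost across genes (stop/N codons skipped)."""
    spec = _as_spec(fragment)
    k = spec.length_codons
    sums = np.zeros(k)
    counts = np.zeros(k, dtype=int)
    n_skipped = 0
    for rec in genes:
        try:
            codons = extract_fragment(rec, spec)
        except ValueError:
            n_skipped += 1
            continue
        for p, codon in enumerate(codons):
            sc = classify_codon(codon)
            if sc.amino_acid is None or sc.is_stop:
                continue
            try:
                c = costs.aa_cost[sc.amino_acid]
            except KeyError:
                raise ValueError(f"amino acid {sc.amino_acid} missing from cost table")
            sums[p] += c
            counts[p] += 1
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return PositionalProfile(
        positions=np.arange(1, k + 1),
        mean_value=means,
        n_genes=counts,
        site_class=ClassSelector.ALL,
        fragment=spec,
        unit="atp_equivalents",
        n_skipped_genes=n_skipped,
    )


def fit_cost_gradient(
    profile: PositionalProfile, fit_range: tuple[int, int] = DEFAULT_FIT_RANGE
) -> CostGradientFit:
    """OLS of mean cost on codon position; the raw per-codon slope is reported."""
    lo, hi = fit_range
    sel = (profile.positions >= lo) & (profile.positions <= hi)
    x = profile.positions[sel].astype(float)
    y = profile.mean_value[sel]
    ok = ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"fit_cost_gradient: only {x.size} defined positions in {fit_range}")
    slope, intercept, r2 = _ols(x, y)
    return CostGradientFit(
        slope_per_codon=slope, intercept=intercept, r_squared=r2,
        fit_range=(lo, hi), n_points=int(x.size),
    )


def saved_atp(slope_per_codon: float, n: int = 75) -> float:
    """ATP equivalents saved per protein from the positional cost gradient.

    Evaluates slope x n/2 x 100 where ``n`` is the number of codon positions
    used in the regression (75 for the default 26-100 fit range).
    """
    if n <= 0:
        raise ValueError("saved_atp: n must be positive")
    return slope_per_codon * (n / 2.0) * 100.0
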