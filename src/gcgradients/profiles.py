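"""Positional GC profiles over 100-codon CDS fragments.

Each valid CDS contributes three non-overlapping fragments of 100 codons —
start, middle and end — numbered 1..100 within the fragment.  For each
position the mean codon GC (overall, or restricted to NS/2s/4s sites) is
averaged across genes; a gene whose codon has no site of the requested class
simply does not contribute at that position.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Union

import numpy as np
import pandas as pd

from .codon_sites import SiteClass, classify_codon, ALL_CODONS, mask_codons
from .sequence_io import GenomeSet, TranscriptRecord

logger = logging.getLogger(__name__)

FRAGMENT_CODONS = 100


class Fragment(enum.Enum):
    START = "start"
    MIDDLE = "middle"
    END = "end"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass(frozen=True)
class FragmentSpec:
    which: Fragment
    length_codons: int = FRAGMENT_CODONS


class ClassSelector(enum.Enum):
    """Which codon sites enter the per-codon GC value."""

    ALL = "all"
    NS = "ns"
    TWOFOLD = "2s"
    FOURFOLD = "4s"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


_SELECTOR_TO_CLASS = {
    ClassSelector.NS: SiteClass.NS,
    ClassSelector.TWOFOLD: SiteClass.TWOFOLD,
    ClassSelector.FOURFOLD: SiteClass.FOURFOLD,
}


def _as_spec(fragment: Union[Fragment, FragmentSpec]) -> FragmentSpec:
    return fragment if isinstance(fragment, FragmentSpec) else FragmentSpec(fragment)


def extract_fragment(
    record: TranscriptRecord, fragment: Union[Fragment, FragmentSpec]
) -> list[str]:
    """The 100 codons of the requested fragment, terminal stop removed first.

    START = codons 1..100 (codon 1 is the start codon); END = the last 100
    coding codons; MIDDLE = 100 codons centered on the midpoint, first codon
    index floor((L-100)/2)+1 for L coding codons.
    """
    spec = _as_spec(fragment)
    k = spec.length_codons
    codons = record.coding_codons()
    L = len(codons)
    if L < 3 * k:
        raise ValueError(
            f"{record.gene_id}: {L} coding codons < {3 * k}; should have been filtered"
        )
    if spec.which is Fragment.START:
        lo = 0
    elif spec.which is Fragment.END:
        lo = L - k
    else:
        lo = (L - k) // 2
    return codons[lo : lo + k]


@lru_cache(maxsize=8)
def _codon_gc_table(selector: ClassSelector) -> dict[str, float]:
    """Per-codon GC value (percent) under a selector; NaN when undefined."""
    table: dict[str, float] = {}
    for codon in ALL_CODONS:
        sc = classify_codon(codon)
        if sc.is_stop:
            table[codon] = math.nan
            continue
        if selector is ClassSelector.ALL:
            table[codon] = 100.0 * sum(b in "GC" for b in codon) / 3.0
        else:
            cls = _SELECTOR_TO_CLASS[selector]
            sites = [i for i, c in enumerate(sc.classes) if c is cls]
            if not sites:
                table[codon] = math.nan
            else:
                table[codon] = 100.0 * sum(codon[i] in "GC" for i in sites) / len(sites)
    return table


def codon_gc(codon: str, selector: ClassSelector = ClassSelector.ALL) -> Optional[float]:
    """GC percentage of one codon over the selected site class.

    Returns ``None`` (undefined) for stop codons, codons containing N, or
    codons without a site of the requested class.
    """
    table = _codon_gc_table(selector)
    value = table.get(codon.upper(), math.nan)
    return None if math.isnan(value) else value


@dataclass
class PositionalProfile:
    """Per-position mean values (GC% or cost units) across a gene set."""

    positions: np.ndarray
    mean_value: np.ndarray  # NaN where no gene contributes
    n_genes: np.ndarray
    site_class: ClassSelector
    fragment: FragmentSpec
    unit: str = "gc_percent"
    n_skipped_genes: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "site_class": str(self.site_class),
                "fragment": str(self.fragment.which),
                "mean_value": self.mean_value,
                "n_genes": self.n_genes,
            }
        )


def positional_mean(
    genes: GenomeSet,
    fragment: Union[Fragment, FragmentSpec],
    site_class: ClassSelector = ClassSelector.ALL,
    exclude_aas=None,
) -> PositionalProfile:
    """Mean codon GC per fragment position across all genes of a set.

    Averaging is per-gene-then-across-genes: each gene contributes its codon
    GC value at each position, undefined values are skipped, and codons
    encoding amino acids in ``exclude_aas`` are masked without renumbering.
    Genes too short for three non-overlapping fragments are skipped and
    counted in ``n_skipped_genes``.
    """
    spec = _as_spec(fragment)
    k = spec.length_codons
    table = _codon_gc_table(site_class)
    sums = np.zeros(k)
    counts = np.zeros(k, dtype=int)
    n_skipped = 0
    for rec in genes:
        try:
            codons = extract_fragment(rec, spec)
        except ValueError:
            n_skipped += 1
            continue
        if exclude_aas:
            keep = mask_codons("".join(codons), exclude_aas)
        else:
            keep = None
        for p, codon in enumerate(codons):
            if keep is not None and not keep[p]:
                continue
            v = table.get(codon, math.nan)
            if not math.isnan(v):
                sums[p] += v
                counts[p] += 1
    if n_skipped:
        logger.info("positional_mean: skipped %d gene(s) shorter than 3 fragments", n_skipped)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if np.any(counts == 0):
        logger.info(
            "positional_mean: %d position(s) with no contributing gene", int((counts == 0).sum())
        )
    return PositionalProfile(
        positions=np.arange(1, k + 1),
        mean_value=means,
        n_genes=counts,
        site_class=site_class,
        fragment=spec,
        n_skipped_genes=n_skipped,
    )


def profile_table(profiles) -> pd.DataFrame:
    """Stack profiles into the long TSV layout (position, site_class, fragment, ...)."""
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)
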