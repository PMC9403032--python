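"""Degeneracy classification of codon positions.

Every position of every sense codon is classified by how many of the three
alternative nucleotides at that position encode the same amino acid under the
standard genetic code (NCBI translation table 1):

* 0 synonymous alternatives  -> nonsynonymous (NS)
* 1 or 2                     -> two-fold degenerate (TWOFOLD); this bin also
  absorbs the three-fold third position of isoleucine by default
* 3                          -> four-fold degenerate (FOURFOLD)

Substitutions that create a stop codon never count as synonymous.  Under this
convention the 61 sense codons contribute 183 site slots: 116 NS, 35 TWOFOLD
and 32 FOURFOLD, so roughly 60% of coding positions are nonsynonymous.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from typing import Optional

from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"
STOP = "*"

#: The nine dietarily essential amino acids.
ESSENTIAL_AAS = frozenset("FVTWMLIKH")
#: Positively charged residues (lysine, arginine, histidine).
POSITIVELY_CHARGED_AAS = frozenset("KRH")
PROLINE = frozenset("P")


class SiteClass(enum.Enum):
    NS = "ns"
    TWOFOLD = "2s"
    THREEFOLD = "3s"  # only emitted when three-fold folding is disabled
    FOURFOLD = "4s"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class SiteClassification:
    """Per-position degeneracy classes of one codon.

    ``classes`` is a triple of :class:`SiteClass`, or a triple of ``None``
    for codons containing ambiguous bases (N), which are unclassifiable.
    ``amino_acid`` is the one-letter code, ``"*"`` for stop codons, or
    ``None`` for unclassifiable codons.
    """

    codon: str
    classes: tuple[Optional[SiteClass], ...]
    amino_acid: Optional[str]

    @property
    def is_stop(self) -> bool:
        return self.amino_acid == STOP


_FORWARD = dict(standard_dna_table.forward_table)
_STOPS = frozenset(standard_dna_table.stop_codons)
ALL_CODONS = tuple("".join(p) for p in product(NUCLEOTIDES, repeat=3))
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in _STOPS)


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon, ``"*"`` for a stop codon."""
    if codon in _STOPS:
        return STOP
    return _FORWARD[codon]


@lru_cache(maxsize=8)
def _classification_table(fold_threefold: bool) -> dict[str, SiteClassification]:
    table: dict[str, SiteClassification] = {}
    for codon in ALL_CODONS:
        aa = translate_codon(codon)
        classes = []
        for pos in range(3):
            synonymous = 0
            for alt in NUCLEOTIDES:
                if alt == codon[pos]:
                    continue
                mutant = codon[:pos] + alt + codon[pos + 1 :]
                # stop-creating substitutions count as nonsynonymous
                if mutant not in _STOPS and translate_codon(mutant) == aa:
                    synonymous += 1
            if synonymous == 0:
                cls = SiteClass.NS
            elif synonymous == 3:
                cls = SiteClass.FOURFOLD
            elif synonymous == 2 and not fold_threefold:
                cls = SiteClass.THREEFOLD
            else:
                cls = SiteClass.TWOFOLD
            classes.append(cls)
        table[codon] = SiteClassification(codon, tuple(classes), aa)
    return table


def classify_codon(codon: str, fold_threefold: bool = True) -> SiteClassification:
    """Classify the three positions of ``codon`` by degeneracy.

    Parameters
    ----------
    codon:
        Three-letter string over ``{A, C, G, T}``; lower case is accepted.
        Codons containing any other character (e.g. N) yield an
        unclassified marker with ``classes == (None, None, None)``.
    fold_threefold:
        When true (default) the three-fold degenerate isoleucine third
        position is binned as TWOFOLD, so only NS/2s/4s are emitted.

    Stop codons are classified but flagged via ``amino_acid == "*"``;
    downstream averaging excludes them.
    """
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    codon = codon.upper()
    table = _classification_table(fold_threefold)
    try:
        return table[codon]
    except KeyError:
        return SiteClassification(codon, (None, None, None), None)


def site_class_counts(fold_threefold: bool = True) -> dict[SiteClass, int]:
    """Site-slot counts over all 61 sense codons (3 positions each, 183 slots)."""
    counts: dict[SiteClass, int] = {}
    table = _classification_table(fold_threefold)
    for codon in SENSE_CODONS:
        for cls in table[codon].classes:
            counts[cls] = counts.get(cls, 0) + 1
    return counts


def _codons_of(cds: str) -> list[str]:
    return [cds[i : i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]


def mask_codons(record_or_cds, exclude_aas) -> list[bool]:
    """Per-codon keep (True) / drop (False) flags for amino-acid exclusion.

    Codons encoding any amino acid in ``exclude_aas`` are dropped from
    positional averaging; positions are not renumbered (the caller keeps the
    codon index).  Stop and N-containing codons are kept here — profile code
    already skips them.  Accepts a TranscriptRecord or a raw CDS string.
    """
    exclude = frozenset(a.upper() for a in exclude_aas)
    valid_codes = frozenset(_FORWARD.values())
    unknown = exclude - valid_codes
    if unknown:
        raise ValueError(f"unknown amino-acid code(s): {sorted(unknown)}")
    cds = record_or_cds if isinstance(record_or_cds, str) else record_or_cds.cds
    flags = []
    for codon in _codons_of(cds):
        cls = classify_codon(codon) if set(codon.upper()) <= set(NUCLEOTIDES) else None
        aa = cls.amino_acid if cls is not None else None
        flags.append(aa not in exclude)
    return flags


def export_classification_tsv(path) -> None:
    """Write the full 64-codon classification table for audit."""
    table = _classification_table(True)
    with open(path, "w") as fh:
        fh.write("codon\tamino_acid\tpos1\tpos2\tpos3\n")
        for codon in ALL_CODONS:
            sc = table[codon]
            cols = [codon, sc.amino_acid] + [str(c) for c in sc.classes]
            fh.write("\t".join(cols) + "\n")
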