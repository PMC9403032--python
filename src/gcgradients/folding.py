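"""Sliding-window folding-stability profiles around the start codon.

Each CDS codon centers a 39-nt window (the codon plus 18-nt flanks); windows
step 3 nt per codon and may extend into the 5'-UTR.  The folding engine is
pluggable: the thermodynamic ViennaRNA engine is used when its python
bindings are importable, and a bundled weighted base-pair-maximization engine
(Nussinov-style dynamic program) is always available.  The bundled engine's
scores (GC = -3, AU = -2, GU = -1, minimum hairpin loop of 3 unpaired nt) are
stated constants of the surrogate; absolute values are engine-dependent, so
analyses compare windows and gene bins, never absolute free energies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Protocol

import numpy as np
import pandas as pd

from .sequence_io import TranscriptRecord

logger = logging.getLogger(__name__)

DEFAULT_FLANK_NT = 18
WINDOW_NT = 39  # codon + two 18-nt flanks

PAIR_SCORE = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}
MIN_HAIRPIN_LOOP = 3  # unpaired nt enclosed by any pair


class FoldingEngine(Protocol):
    name: str

    def fold(self, seq: str) -> float: ...


def _normalize_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def bundled_fold(seq: str) -> float:
    """Optimal weighted nested-pairing score of ``seq`` (<= 0).

    Dynamic program over all nested (pseudoknot-free) pairings with a
    minimum hairpin loop of MIN_HAIRPIN_LOOP unpaired nucleotides; N never
    pairs.  The empty sequence and any sequence admitting no pair score 0.
    """
    s = _normalize_rna(seq)
    n = len(s)
    if n == 0:
        return 0.0
    # M[i][j]: best (most negative) score of s[i..j]
    M = [[0.0] * n for _ in range(n)]
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1][j]  # i unpaired
            row_i1 = M[i + 1]
            for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
                w = PAIR_SCORE.get((s[i], s[k]))
                if w is None:
                    continue
                inner = row_i1[k - 1] if k - 1 > i else 0.0
                outer = M[k + 1][j] if k + 1 <= j else 0.0
                cand = w + inner + outer
                if cand < best:
                    best = cand
            M[i][j] = best
    return M[0][n - 1]


class BundledEngine:
    """Base-pair-maximization surrogate folding engine."""

    name = "bundled"

    def fold(self, seq: str) -> float:
        return bundled_fold(seq)


class ViennaRNAEngine:
    """Thermodynamic MFE via the ViennaRNA python bindings (kcal/mol)."""

    name = "viennarna"

    def __init__(self):
        import RNA  # noqa: F401 — deferred; raises if bindings are absent

        self._rna = RNA

    def fold(self, seq: str) -> float:
        s = _normalize_rna(seq)
        if not s:
            return 0.0
        _, mfe = self._rna.fold(s)
        return min(0.0, float(mfe))


def get_engine(name: str = "auto") -> FoldingEngine:
    """Resolve a folding engine: "viennarna", "bundled", or "auto"."""
    if name == "bundled":
        return BundledEngine()
    if name == "viennarna":
        return ViennaRNAEngine()
    if name == "auto":
        try:
            return ViennaRNAEngine()
        except ImportError:
            logger.info("ViennaRNA bindings not importable; using bundled engine")
            return BundledEngine()
    raise ValueError(f"unknown folding engine {name!r}")


@dataclass(frozen=True)
class WindowMeta:
    codon_index: int
    actual_len: int
    used_utr_nt: int
    truncated: bool


def window_for_codon(
    record: TranscriptRecord, codon_index: int, flank_nt: int = DEFAULT_FLANK_NT
) -> tuple[str, WindowMeta]:
    """The window centered on one codon: 3 nt plus ``flank_nt`` on each side.

    Upstream overhang beyond the CDS is filled from the 3' end of the
    5'-UTR; if the UTR is too short the window is truncated at the
    transcript 5' end and the truncation recorded.
    """
    cds = record.cds
    n_codons = len(cds) // 3
    if codon_index < 1 or codon_index > n_codons:
        raise ValueError(f"codon_index {codon_index} outside CDS of {n_codons} codons")
    start = 3 * (codon_index - 1) - flank_nt
    end = 3 * (codon_index - 1) + 3 + flank_nt  # half-open in CDS coordinates
    used_utr = 0
    prefix = ""
    if start < 0:
        need = -start
        used_utr = min(need, len(record.utr5))
        prefix = record.utr5[len(record.utr5) - used_utr :] if used_utr else ""
        start = 0
    window = prefix + cds[start : min(end, len(cds))]
    nominal = 3 + 2 * flank_nt
    meta = WindowMeta(
        codon_index=codon_index,
        actual_len=len(window),
        used_utr_nt=used_utr,
        truncated=len(window) < nominal,
    )
    return window, meta


@dataclass
class MFETrack:
    """Per-codon-center window scores for one transcript."""

    gene_id: str
    window_centers: np.ndarray
    mfe: np.ndarray  # NaN where the engine failed
    window_len_nt: int
    actual_len: np.ndarray
    used_utr_nt: np.ndarray


def mfe_track(
    record: TranscriptRecord,
    engine: FoldingEngine,
    max_codon: int = 100,
    flank_nt: int = DEFAULT_FLANK_NT,
) -> MFETrack:
    """Window score per codon center 1..max_codon (T read as U before folding)."""
    n_codons = min(max_codon, len(record.cds) // 3)
    centers = np.arange(1, n_codons + 1)
    values = np.full(n_codons, np.nan)
    lens = np.zeros(n_codons, dtype=int)
    utrs = np.zeros(n_codons, dtype=int)
    for i, c in enumerate(centers):
        window, meta = window_for_codon(record, int(c), flank_nt)
        lens[i] = meta.actual_len
        utrs[i] = meta.used_utr_nt
        try:
            values[i] = engine.fold(window)
        except Exception:  # pragma: no cover - engine failure path
            logger.warning("%s: fold failed at codon %d", record.gene_id, c)
    return MFETrack(
        gene_id=record.gene_id,
        window_centers=centers,
        mfe=values,
        window_len_nt=3 + 2 * flank_nt,
        actual_len=lens,
        used_utr_nt=utrs,
    )


def mean_mfe_by_position(
    tracks: Iterable[MFETrack],
    gene_bins: Optional[Mapping[str, int]] = None,
    include_truncated: bool = False,
) -> pd.DataFrame:
    """Mean window score per codon center, optionally stratified by gene bin.

    Genes absent from ``gene_bins`` (when given) are excluded; truncated
    windows are excluded by default.  Returns a DataFrame with columns
    bin, codon_center, mean_mfe, n_genes.
    """
    rows = []
    for track in tracks:
        if gene_bins is not None:
            if track.gene_id not in gene_bins:
                continue
            b = gene_bins[track.gene_id]
        else:
            b = 0
        full = track.actual_len >= track.window_len_nt
        for c, v, ok in zip(track.window_centers, track.mfe, full):
            if math.isnan(v):
                continue
            if not ok and not include_truncated:
                continue
            rows.append((b, int(c), v))
    if not rows:
        logger.warning("mean_mfe_by_position: no usable windows")
        return pd.DataFrame(columns=["bin", "codon_center", "mean_mfe", "n_genes"])
    df = pd.DataFrame(rows, columns=["bin", "codon_center", "mfe"])
    out = (
        df.groupby(["bin", "codon_center"])["mfe"]
        .agg(mean_mfe="mean", n_genes="size")
        .reset_index()
    )
    return out
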