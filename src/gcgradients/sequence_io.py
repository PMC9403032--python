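"""Reading cDNA FASTA + GFF3 into per-gene transcript records.

The expected GFF3 dialect places feature coordinates on the cDNA sequences
themselves (seqid = transcript identifier, 1-based inclusive), i.e. the CDS
and 5'-UTR are sliced out of each cDNA by coordinate.  CDS features are
grouped by their ``Parent`` attribute; ``five_prime_UTR`` features are used
when present, otherwise the UTR is empty.  When a gene has several
transcripts, only the one with the longest cDNA is kept (ties broken by
lexicographically smallest transcript id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

from .codon_sites import _codons_of, _STOPS

logger = logging.getLogger(__name__)

DEFAULT_MIN_CDS_LEN = 900


@dataclass
class TranscriptRecord:
    """One gene's representative transcript: CDS, 5'-UTR and metadata."""

    gene_id: str
    transcript_id: str
    cds: str
    utr5: str = ""
    source_species: str = ""

    @property
    def cds_length_nt(self) -> int:
        return len(self.cds)

    @property
    def has_internal_stop(self) -> bool:
        """True when a stop codon occurs before the last codon (flagged, not dropped)."""
        codons = _codons_of(self.cds)
        return any(c in _STOPS for c in codons[:-1])

    def coding_codons(self) -> list[str]:
        """Codons of the CDS with a terminal stop codon (if any) removed."""
        codons = _codons_of(self.cds)
        if codons and codons[-1] in _STOPS:
            codons = codons[:-1]
        return codons


@dataclass
class GenomeSet:
    """An ordered set of per-gene transcript records for one genome."""

    species_label: str
    records: list[TranscriptRecord] = field(default_factory=list)
    taxon_group: Optional[str] = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def coding_gc_percent(self) -> float:
        return coding_gc(self)


def _prescan_gff(gff_path) -> None:
    """Reject malformed GFF3 lines with a line number before parsing."""
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise ValueError(
                    f"{gff_path}: unparseable GFF3 line {lineno}: "
                    f"expected 9 tab-separated columns"
                )


def _attr_first(feature, key: str) -> Optional[str]:
    vals = feature.attributes.get(key, [])
    return vals[0] if vals else None


def load_transcripts(
    fasta_path, gff_path, species_label: str = "", taxon_group: Optional[str] = None
) -> GenomeSet:
    """Assemble one representative TranscriptRecord per gene.

    CDS and 5'-UTR sequences are sliced from the cDNA by the GFF3
    coordinates; on the minus strand the slice is reverse-complemented and
    the parts are concatenated in transcript (translated) orientation.
    Transcripts present in the GFF3 but missing from the FASTA are skipped,
    counted, and logged.
    """
    _prescan_gff(gff_path)
    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    cdna = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}

    # transcript -> gene mapping from mRNA/transcript features when present
    tx_gene: dict[str, str] = {}
    for ftype in ("mRNA", "transcript"):
        for feat in db.features_of_type(ftype):
            tid = _attr_first(feat, "ID") or feat.id
            gid = _attr_first(feat, "Parent") or tid
            tx_gene[tid] = gid

    cds_parts: dict[str, list] = {}
    utr_parts: dict[str, list] = {}
    strands: dict[str, str] = {}
    seqids: dict[str, str] = {}
    for ftype, parts in (("CDS", cds_parts), ("five_prime_UTR", utr_parts)):
        for feat in db.features_of_type(ftype):
            parent = _attr_first(feat, "Parent") or _attr_first(feat, "ID")
            if parent is None:
                raise ValueError(f"{ftype} feature without Parent in {gff_path}")
            parts.setdefault(parent, []).append((feat.start, feat.end))
            strands[parent] = feat.strand
            seqids[parent] = feat.seqid

    n_missing = 0
    candidates: dict[str, list[TranscriptRecord]] = {}
    cdna_len: dict[str, int] = {}
    for tid, intervals in cds_parts.items():
        seqid = seqids[tid]
        seq = cdna.get(seqid)
        if seq is None:
            n_missing += 1
            logger.warning("transcript %s: seqid %s absent from FASTA, skipped", tid, seqid)
            continue
        strand = strands.get(tid, "+")

        def splice(ivals: Iterable[tuple[int, int]]) -> str:
            ivals = sorted(ivals)
            s = "".join(seq[a - 1 : b] for a, b in ivals)
            if strand == "-":
                s = str(Seq(s).reverse_complement())
            return s

        cds = splice(intervals)
        utr5 = splice(utr_parts.get(tid, []))
        gene_id = tx_gene.get(tid, tid)
        rec = TranscriptRecord(gene_id, tid, cds, utr5, source_species=species_label)
        candidates.setdefault(gene_id, []).append(rec)
        cdna_len[tid] = len(seq)

    records = []
    for gene_id in sorted(candidates):
        recs = candidates[gene_id]
        # longest cDNA wins; ties go to the lexicographically smallest id
        recs.sort(key=lambda r: (-cdna_len[r.transcript_id], r.transcript_id))
        records.append(recs[0])

    if n_missing:
        logger.info("%d transcript(s) skipped: absent from FASTA", n_missing)
    return GenomeSet(species_label=species_label, records=records, taxon_group=taxon_group)


@dataclass
class FilterResult:
    """Filtered genome plus the per-gene removal report."""

    genome: GenomeSet
    removed: list[tuple[str, str]]  # (gene_id, reason)
    counts: dict[str, int]

    def write_report(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\treason\n")
            for gene_id, reason in self.removed:
                fh.write(f"{gene_id}\t{reason}\n")


def filter_valid(
    genome: GenomeSet,
    min_cds_len: int = DEFAULT_MIN_CDS_LEN,
    require_start_atg: bool = True,
) -> FilterResult:
    """Apply the validity filters: minimum CDS length (annotated length,
    including any terminal stop codon), frame integrity (length divisible by
    3) and, by default, an ATG start codon.

    Records with internal stop codons are retained but flagged via
    :attr:`TranscriptRecord.has_internal_stop`.
    """
    kept: list[TranscriptRecord] = []
    removed: list[tuple[str, str]] = []
    counts = {"short": 0, "frame": 0, "non_atg_start": 0}
    for rec in genome:
        if rec.cds_length_nt < min_cds_len:
            removed.append((rec.gene_id, "short"))
            counts["short"] += 1
        elif rec.cds_length_nt % 3 != 0:
            removed.append((rec.gene_id, "frame"))
            counts["frame"] += 1
        elif require_start_atg and not rec.cds.startswith("ATG"):
            removed.append((rec.gene_id, "non_atg_start"))
            counts["non_atg_start"] += 1
        else:
            kept.append(rec)
    if not kept:
        logger.warning("filter_valid: no records passed the filters")
    filtered = GenomeSet(genome.species_label, kept, genome.taxon_group)
    return FilterResult(filtered, removed, counts)


def coding_gc(genome: GenomeSet) -> float:
    """Pooled coding GC percentage over all records in the set.

    G+C over A+C+G+T across all CDS nucleotides, x100; N excluded from both
    numerator and denominator.  Apply after :func:`filter_valid`.
    """
    gc = 0
    total = 0
    for rec in genome:
        for base in rec.cds:
            if base in "GC":
                gc += 1
                total += 1
            elif base in "AT":
                total += 1
    if total == 0:
        raise ValueError("coding_gc: no countable (A/C/G/T) nucleotides")
    return 100.0 * gc / total
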