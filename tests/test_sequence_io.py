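"""FASTA+GFF3 assembly, validity filters and pooled coding GC."""

import pytest
from Bio.Seq import Seq

from gcgradients import (
    GenomeSet,
    TranscriptRecord,
    coding_gc,
    filter_valid,
    load_transcripts,
)
from gcgradients.synthetic_data import SyntheticSpec, generate_genome, write_outputs


def write_fasta(path, entries):
    with open(path, "w") as fh:
        for name, seq in entries.items():
            fh.write(f">{name}\n{seq}\n")


def gff_line(seqid, ftype, start, end, attrs, strand="+"):
    return f"{seqid}\tt\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n"


def test_longest_cdna_retained_with_tie_break(tmp_path):
    cds = "ATG" + "GCT" * 20 + "TAA"  # 66 nt
    fasta = tmp_path / "c.fa"
    gff = tmp_path / "a.gff3"
    write_fasta(
        fasta,
        {
            "t1": cds + "A" * (1200 - len(cds)),
            "t2": cds + "A" * (1500 - len(cds)),
            "tB": cds + "A" * 100,
            "tA": cds + "A" * 100,
        },
    )
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for tid, gid in [("t1", "g1"), ("t2", "g1"), ("tB", "g2"), ("tA", "g2")]:
            fh.write(gff_line(tid, "mRNA", 1, 100, f"ID={tid};Parent={gid}"))
            fh.write(gff_line(tid, "CDS", 1, len(cds), f"ID={tid}.c;Parent={tid}"))
    genome = load_transcripts(fasta, gff)
    chosen = {r.gene_id: r.transcript_id for r in genome}
    assert chosen == {"g1": "t2", "g2": "tA"}  # longest cDNA; ties by smallest id


def test_minus_strand_record_is_reverse_complemented(tmp_path):
    utr5 = "CCCTTTGGGAGA"  # 12 nt
    cds = "ATG" + "GAT" * 8 + "TGA"  # 30 nt
    mrna = utr5 + cds
    stored = str(Seq(mrna).reverse_complement())
    fasta, gff = tmp_path / "c.fa", tmp_path / "a.gff3"
    write_fasta(fasta, {"t1": stored})
    L = len(mrna)
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(gff_line("t1", "mRNA", 1, L, "ID=t1;Parent=g1", "-"))
        # mRNA coordinates map to stored coordinates L-i+1 on the minus strand
        fh.write(gff_line("t1", "CDS", 1, len(cds), "ID=t1.c;Parent=t1", "-"))
        fh.write(gff_line("t1", "five_prime_UTR", len(cds) + 1, L, "ID=t1.u;Parent=t1", "-"))
    rec = load_transcripts(fasta, gff).records[0]
    assert rec.cds == cds
    assert rec.utr5 == utr5


def test_missing_transcript_skipped_and_bad_gff_rejected(tmp_path):
    fasta, gff = tmp_path / "c.fa", tmp_path / "a.gff3"
    write_fasta(fasta, {"t1": "ATGAAATAA"})
    with open(gff, "w") as fh:
        fh.write(gff_line("t1", "CDS", 1, 9, "ID=c1;Parent=t1"))
        fh.write(gff_line("tX", "CDS", 1, 9, "ID=c2;Parent=tX"))
    genome = load_transcripts(fasta, gff)
    assert [r.transcript_id for r in genome] == ["t1"]

    bad = tmp_path / "bad.gff3"
    bad.write_text("t1\tonly\tthree\n")
    with pytest.raises(ValueError, match="line 1"):
        load_transcripts(fasta, bad)


def _rec(gene, cds):
    return TranscriptRecord(gene, f"{gene}.t", cds)


def test_filter_valid_rules_and_idempotence():
    recs = [
        _rec("short", "ATG" + "GCA" * 99),            # 300 nt
        _rec("ok900", "ATG" + "GCA" * 298 + "TAA"),    # 900 nt
        _rec("ok903", "ATG" + "GCA" * 299 + "TAA"),    # 903 nt
        _rec("noatg", "TTG" + "GCA" * 298 + "TAA"),    # 900 nt, non-ATG start
        _rec("frame", "ATG" + "GCA" * 298 + "TAAT"),   # 901 nt
    ]
    result = filter_valid(GenomeSet("x", recs))
    assert sorted(r.gene_id for r in result.genome) == ["ok900", "ok903"]
    assert result.counts == {"short": 1, "frame": 1, "non_atg_start": 1}
    again = filter_valid(result.genome)
    assert [r.gene_id for r in again.genome] == [r.gene_id for r in result.genome]
    assert sum(again.counts.values()) == 0

    lax = filter_valid(GenomeSet("x", recs), require_start_atg=False)
    assert "noatg" in [r.gene_id for r in lax.genome]


def test_internal_stop_flagged_but_retained():
    rec = _rec("g", "ATG" + "TAA" + "GCA" * 298 + "TAA")
    assert rec.has_internal_stop
    result = filter_valid(GenomeSet("x", [rec]))
    assert len(result.genome) == 1


def test_coding_gc_pooled_and_order_invariant():
    # 300 nt at 40% GC and 900 nt at 60% GC pool to 55%
    a = _rec("a", "GC" * 60 + "AT" * 90)
    b = _rec("b", "GC" * 270 + "AT" * 180)
    assert coding_gc(GenomeSet("x", [a, b])) == pytest.approx(55.0)
    assert coding_gc(GenomeSet("x", [b, a])) == pytest.approx(55.0)
    assert coding_gc(GenomeSet("x", [_rec("g", "G" * 30)])) == 100.0
    # N excluded from both numerator and denominator
    assert coding_gc(GenomeSet("x", [_rec("n", "GCNN" + "AT")])) == pytest.approx(50.0)
    with pytest.raises(ValueError):
        coding_gc(GenomeSet("x", [_rec("n", "NNN")]))


def test_round_trip_through_writers(tmp_path):
    spec = SyntheticSpec(n_genes=5, cds_len_codons=300, utr5_len=25, seed=3)
    genome, _ = generate_genome(spec)
    write_outputs(genome, tmp_path)
    loaded = load_transcripts(tmp_path / "cdna.fasta", tmp_path / "annotation.gff3")
    assert len(loaded) == len(genome)
    for orig, back in zip(genome, loaded):
        assert back.cds == orig.cds
        assert back.utr5 == orig.utr5
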