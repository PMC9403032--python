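"""Window geometry and the bundled folding engine vs exhaustive enumeration."""

import numpy as np
import pytest

from gcgradients import (
    BundledEngine,
    TranscriptRecord,
    ViennaRNAEngine,
    bundled_fold,
    get_engine,
    mean_mfe_by_position,
    mfe_track,
    window_for_codon,
)
from gcgradients.folding import MIN_HAIRPIN_LOOP, PAIR_SCORE, _normalize_rna


def enumerate_fold(seq):
    """Minimum score over every nested pairing set, by explicit enumeration.

    Generates all pseudoknot-free pairing sets of the interval recursively
    (first position unpaired, or paired with every admissible partner, with
    all inside x outside combinations enumerated) and scores each one.  No
    memoization or pruning — an independent oracle for the dynamic program.
    """
    s = _normalize_rna(seq)

    def all_scores(i, j):
        if j - i < MIN_HAIRPIN_LOOP + 1:
            yield 0.0
            return
        yield from all_scores(i + 1, j)  # position i unpaired
        for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
            w = PAIR_SCORE.get((s[i], s[k]))
            if w is None:
                continue
            for inner in all_scores(i + 1, k - 1):
                for outer in all_scores(k + 1, j):
                    yield w + inner + outer

    return min(all_scores(0, len(s) - 1)) if s else 0.0


PANEL = [
    "",
    "A",
    "AAAAAAAAA",
    "GGGAAAACCC",
    "GCGCAAAAGCGC",
    "GUGUAUAUACAC",
    "ACGTACGTACGT",
    "NNNGAAAC",
    "CCCCUUUUGGGG",
    "GANCUANCGAUC",
]


def random_panel(n_seqs=15, max_len=12, seed=17):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_seqs):
        L = rng.integers(4, max_len + 1)
        out.append("".join(rng.choice(list("ACGUN"), size=L)))
    return out


@pytest.mark.parametrize("seq", PANEL + random_panel())
def test_bundled_fold_matches_exhaustive_enumeration(seq):
    assert bundled_fold(seq) == pytest.approx(enumerate_fold(seq))


def test_bundled_fold_examples():
    assert bundled_fold("AAAAAAAAA") == 0.0
    assert bundled_fold("GGGAAAACCC") == -9.0  # three GC pairs
    assert bundled_fold("") == 0.0
    assert bundled_fold("GCGCAAAAGCGC") == pytest.approx(enumerate_fold("GCGCAAAAGCGC"))
    assert all(bundled_fold(s) <= 0 for s in PANEL)


def test_removing_gc_cannot_strengthen_fold():
    rng = np.random.default_rng(23)
    for _ in range(10):
        seq = "".join(rng.choice(list("ACGU"), size=12))
        stripped = seq.replace("G", "").replace("C", "")
        assert bundled_fold(stripped) >= bundled_fold(seq)


def make_record(n_codons=120, utr5="A" * 30):
    rng = np.random.default_rng(11)
    cds = "ATG" + "".join(rng.choice(list("ACGT"), size=3 * (n_codons - 1))) + "TAA"
    return TranscriptRecord("g", "g.t", cds, utr5)


def test_window_geometry_interior_codon():
    rec = make_record()
    w, meta = window_for_codon(rec, 10)
    assert w == rec.cds[9:48]  # 3*(10-1)-18 = 9, half-open [9, 48)
    assert meta.actual_len == 39 and meta.used_utr_nt == 0 and not meta.truncated


def test_window_extends_into_utr_and_truncates():
    rec = make_record(utr5="A" * 18)
    w, meta = window_for_codon(rec, 1)
    assert meta.used_utr_nt == 18 and meta.actual_len == 39
    assert w == rec.utr5 + rec.cds[:21]  # 18 UTR nt + codons 1-7
    short = make_record(utr5="GGGGG")
    w2, m2 = window_for_codon(short, 1)
    assert m2.used_utr_nt == 5 and m2.actual_len == 26 and m2.truncated
    with pytest.raises(ValueError):
        window_for_codon(rec, 10_000)


def test_windows_advance_by_three_nt():
    rec = make_record()
    for c in range(7, 20):
        w1, _ = window_for_codon(rec, c)
        w2, _ = window_for_codon(rec, c + 1)
        assert w1[3:] == w2[:-3]


def test_mfe_track_polyA_and_determinism():
    rec = TranscriptRecord("g", "g.t", "A" * 360, "A" * 20)
    track = mfe_track(rec, BundledEngine(), max_codon=15)
    np.testing.assert_allclose(track.mfe, 0.0)
    again = mfe_track(rec, BundledEngine(), max_codon=15)
    np.testing.assert_allclose(track.mfe, again.mfe)


def test_gc_rich_window_folds_lower_than_at_rich():
    gc_rec = TranscriptRecord("g", "g.t", "GC" * 60)
    at_rec = TranscriptRecord("a", "a.t", "AT" * 60)
    eng = BundledEngine()
    g = mfe_track(gc_rec, eng, max_codon=8).mfe
    a = mfe_track(at_rec, eng, max_codon=8).mfe
    assert (g[7] < a[7]) and np.nanmean(g) < np.nanmean(a)


def test_vienna_engine_folds_hairpin():
    eng = ViennaRNAEngine()
    assert eng.fold("GGGGGAAAACCCCC") < 0
    assert eng.fold("AAAAAAAAAAAAAA") == 0.0
    assert get_engine("auto").name in {"viennarna", "bundled"}


def test_mean_mfe_by_position_bins_and_truncation():
    t1 = mfe_track(TranscriptRecord("g1", "g1.t", "GC" * 60, "A" * 18), BundledEngine(), 5)
    t2 = mfe_track(TranscriptRecord("g2", "g2.t", "GC" * 60, "A" * 18), BundledEngine(), 5)
    df = mean_mfe_by_position([t1, t2])
    at5 = df[df.codon_center == 5]
    assert at5.n_genes.iloc[0] == 2
    assert at5.mean_mfe.iloc[0] == pytest.approx((t1.mfe[4] + t2.mfe[4]) / 2)
    binned = mean_mfe_by_position([t1, t2], gene_bins={"g1": 1, "g2": 4})
    assert set(binned["bin"]) == {1, 4}
    # truncated 5' windows excluded by default
    trunc = mfe_track(TranscriptRecord("g3", "g3.t", "GC" * 60, ""), BundledEngine(), 10)
    df2 = mean_mfe_by_position([trunc])
    assert df2.codon_center.min() == 7  # first full window needs 18 nt upstream
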