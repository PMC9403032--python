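"""Generator ground truth: determinism, validity, target realization, coupling."""

import numpy as np
import pytest

from gcgradients import (
    ClassSelector,
    Fragment,
    filter_valid,
    fit_gradient,
    positional_mean,
)
from gcgradients.synthetic_data import (
    SyntheticSpec,
    generate_genome,
    solve_codon_distribution,
    write_outputs,
    _usage_prior,
)


def test_same_seed_byte_identical_outputs(tmp_path):
    spec = SyntheticSpec(n_genes=8, cds_len_codons=300, utr5_len=20, seed=5)
    for d in ("a", "b"):
        genome, truth = generate_genome(spec)
        write_outputs(genome, tmp_path / d, expression=truth.expression, ground_truth=truth)
    for name in ("cdna.fasta", "annotation.gff3", "expression.tsv", "ground_truth.json"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
    other, _ = generate_genome(SyntheticSpec(n_genes=8, cds_len_codons=300, utr5_len=20, seed=6))
    assert other.records[0].cds != genome.records[0].cds


def test_generated_genes_pass_default_filters(tiny_genome):
    genome, _ = tiny_genome
    result = filter_valid(genome)
    assert len(result.genome) == len(genome)
    assert all(not r.has_internal_stop for r in genome)
    assert all(len(r.coding_codons()) >= 300 for r in genome)


def test_gff_coordinates(tmp_path):
    spec = SyntheticSpec(n_genes=1, cds_len_codons=300, utr5_len=20, seed=1)
    genome, _ = generate_genome(spec, out_dir=tmp_path)
    lines = (tmp_path / "annotation.gff3").read_text().splitlines()
    cds = [l for l in lines if "\tCDS\t" in l][0].split("\t")
    assert (int(cds[3]), int(cds[4])) == (21, 20 + 903)  # 300 codons + stop
    utr = [l for l in lines if "five_prime_UTR" in l][0].split("\t")
    assert (int(utr[3]), int(utr[4])) == (1, 20)
    spec0 = SyntheticSpec(n_genes=1, cds_len_codons=300, utr5_len=0, seed=1)
    generate_genome(spec0, out_dir=tmp_path / "noutr")
    assert "five_prime_UTR" not in (tmp_path / "noutr" / "annotation.gff3").read_text()


def test_solved_distribution_hits_conditional_targets():
    from gcgradients.synthetic_data import _R, _SUPPORTED

    prior = _usage_prior("uniform")
    targets = np.array([0.62, 0.45, 0.70])
    q = solve_codon_distribution(targets, prior)
    assert q.sum() == pytest.approx(1.0)
    for k in range(3):
        sup = _SUPPORTED[:, k]
        mean = np.dot(q[sup], _R[sup, k]) / q[sup].sum()
        assert mean == pytest.approx(targets[k], abs=1e-8)


def test_realized_profiles_match_ground_truth():
    spec = SyntheticSpec(n_genes=2500, cds_len_codons=300, utr5_len=0, seed=21)
    genome, truth = generate_genome(spec)
    for sel, key in [
        (ClassSelector.NS, "ns"),
        (ClassSelector.TWOFOLD, "2s"),
        (ClassSelector.FOURFOLD, "4s"),
    ]:
        prof = positional_mean(genome, Fragment.START, sel)
        expected = np.array(truth.expected_gc["0"][key])
        dev = np.abs(prof.mean_value[1:100] - expected[1:100])  # codon 1 is fixed ATG
        assert dev.max() < 1.5, (key, dev.max())


def test_null_and_negative_slopes_recovered():
    null_spec = SyntheticSpec(n_genes=1000, cds_len_codons=300, gc_start_ns=50.0,
                              slope_ns=0.0, utr5_len=0, seed=2)
    genome, _ = generate_genome(null_spec)
    prof = positional_mean(genome, Fragment.START, ClassSelector.NS)
    assert abs(fit_gradient(prof).slope_per100) < 0.5
    # middle and end fragments sit at the flat baseline
    mid = positional_mean(genome, Fragment.MIDDLE, ClassSelector.ALL)
    assert abs(fit_gradient(mid).slope_per100) < 0.5


def test_expression_coupling_orders_start_gc():
    spec = SyntheticSpec(n_genes=400, cds_len_codons=300, utr5_len=0,
                         expression_gc_coupling=3.0, seed=31)
    genome, truth = generate_genome(spec)
    by_bin = {}
    for b in (1, 2, 3, 4):
        ids = {g for g, bb in truth.bins.items() if bb == b}
        sub = [r for r in genome if r.gene_id in ids]
        gc = np.mean([
            100.0 * sum(x in "GC" for x in r.cds[3:60]) / 57 for r in sub
        ])
        by_bin[b] = gc
    assert by_bin[1] < by_bin[2] < by_bin[3] < by_bin[4]


def test_infeasible_targets_clamped_with_warning():
    spec = SyntheticSpec(n_genes=4, cds_len_codons=300, gc_start_ns=99.0,
                         slope_ns=0.0, utr5_len=0, seed=1)
    with pytest.warns(UserWarning, match="clamped"):
        _, truth = generate_genome(spec)
    assert truth.clamped
    assert max(truth.expected_gc["0"]["ns"]) <= 95.0


def test_multinomial_mode_and_bad_inputs():
    spec = SyntheticSpec(n_genes=100, cds_len_codons=300, utr5_len=0,
                         sampling="multinomial", seed=4)
    genome, _ = generate_genome(spec)
    prof = positional_mean(genome, Fragment.START, ClassSelector.NS)
    fit = fit_gradient(prof)
    assert -10.0 < fit.slope_per100 < 0.0  # noisy but negative
    with pytest.raises(ValueError):
        generate_genome(SyntheticSpec(cds_len_codons=200))
    with pytest.raises(ValueError):
        generate_genome(SyntheticSpec(n_genes=4, sampling="bogus"))
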