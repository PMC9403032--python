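"""Synthetic genomes with known positional GC structure.

The generator emulates the statistical shape of real 5'-end composition
data: every gene starts with ATG, carries linear per-position GC targets at
nonsynonymous / two-fold / four-fold sites over its first 100 codons, relaxes
to a flat baseline downstream, and ends with a stop codon.  Optional 5'-UTRs
and lognormal expression abundances (with an optional expression-dependent
GC shift at the start region) make every pipeline stage testable without
downloads.

Targets are hit by exponential tilting of a codon-usage prior: at each codon
position a distribution over the 61 sense codons is solved so that the
expected G/C fraction at each site class matches the target.  Draws use
balanced (quota) allocation by default — per position, codon counts follow
the tilted distribution up to integer rounding and are randomly assigned to
genes — so realized profiles match their expectations with minimal variance;
an iid ``multinomial`` mode is available.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .codon_sites import SENSE_CODONS, SiteClass, classify_codon
from .expression import ExpressionBins, bin_by_expression
from .sequence_io import GenomeSet, TranscriptRecord

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")
_CLASS_ORDER = (SiteClass.NS, SiteClass.TWOFOLD, SiteClass.FOURFOLD)

GC_FLOOR, GC_CEIL = 0.05, 0.95  # clamp bounds for per-site-class targets


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; GC values in percent, slopes per 100 codons."""

    n_genes: int = 2000
    cds_len_codons: int = 400  # coding codons; a stop codon is appended
    gc_start_ns: float = 55.0
    slope_ns: float = -5.0
    slope_2s: float = 0.0
    slope_4s: float = 0.0
    baseline_gc: float = 50.0
    utr5_len: int = 50
    expression_mu: float = 1.0
    expression_sigma: float = 1.0
    expression_gc_coupling: float = 0.0  # % GC shift at start per expression bin
    n_expression_bins: int = 4
    codon_usage: str = "uniform"  # "uniform" or "human"
    sampling: str = "balanced"  # "balanced" or "multinomial"
    species_label: str = "synthetic"
    seed: int = 0


@dataclass
class GroundTruth:
    """Realized per-position expectations, expression, and the spec echo."""

    expected_gc: dict  # {bin: {"ns"/"2s"/"4s": [target % per position 1..100]}}
    expression: dict[str, float]
    bins: dict[str, int]
    spec: dict
    clamped: bool = False

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "expected_gc": self.expected_gc,
                    "expression": self.expression,
                    "bins": self.bins,
                    "spec": self.spec,
                    "clamped": self.clamped,
                },
                fh,
                indent=1,
            )


def _codon_class_stats():
    """Per sense codon: GC fraction of each class's sites (NaN when absent)."""
    r = np.full((len(SENSE_CODONS), 3), np.nan)
    for i, codon in enumerate(SENSE_CODONS):
        sc = classify_codon(codon)
        for k, cls in enumerate(_CLASS_ORDER):
            sites = [j for j, c in enumerate(sc.classes) if c is cls]
            if sites:
                r[i, k] = sum(codon[j] in "GC" for j in sites) / len(sites)
    return r


_R = _codon_class_stats()
_SUPPORTED = ~np.isnan(_R)


def _usage_prior(name: str) -> np.ndarray:
    if name == "uniform":
        return np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
    if name == "human":
        table = resources.files("gcgradients.data") / "human_codon_usage.tsv"
        df = pd.read_csv(table, sep="\t", comment="#")
        freq = dict(zip(df["codon"], df["per_1000"].astype(float)))
        p = np.array([freq.get(c, 0.0) for c in SENSE_CODONS])
        if (p <= 0).any():
            raise ValueError("usage table must cover all 61 sense codons")
        return p / p.sum()
    raise ValueError(f"unknown codon usage prior {name!r}")


def solve_codon_distribution(targets: np.ndarray, prior: np.ndarray) -> np.ndarray:
    """Tilted codon distribution whose class-conditional GC means hit ``targets``.

    ``targets`` is (g_ns, g_2s, g_4s) as fractions in [0, 1].  Solves for the
    three tilting multipliers by root finding; the conditional mean for each
    class is taken over codons that have a site of that class.
    """
    Rfill = np.where(_SUPPORTED, _R, targets[np.newaxis, :])

    def conditional_means(lam):
        w = prior * np.exp(Rfill @ lam)
        m = np.empty(3)
        for k in range(3):
            sup = _SUPPORTED[:, k]
            m[k] = np.dot(w[sup], _R[sup, k]) / w[sup].sum()
        return m

    sol = optimize.root(lambda lam: conditional_means(lam) - targets, np.zeros(3))
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-8:
        raise RuntimeError(f"codon distribution solve failed for targets {targets}")
    w = prior * np.exp(Rfill @ sol.x)
    return w / w.sum()


class _DistributionCache:
    def __init__(self, prior: np.ndarray):
        self.prior = prior
        self._cache: dict[tuple, np.ndarray] = {}

    def get(self, targets: np.ndarray) -> np.ndarray:
        key = tuple(np.round(targets, 6))
        if key not in self._cache:
            self._cache[key] = solve_codon_distribution(np.asarray(key), self.prior)
        return self._cache[key]


def _quota_counts(q: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    """Integer codon counts summing to m with E[counts] = m*q exactly.

    floor(m*q) plus a systematic (randomized-start) draw over the fractional
    parts: each codon's extra count has inclusion probability equal to its
    fractional part, so the allocation is unbiased and within 1 of m*q.
    """
    expect = q * m
    counts = np.floor(expect).astype(int)
    frac = expect - counts
    short = m - counts.sum()
    if short > 0:
        cum = np.cumsum(frac)
        points = rng.random() + np.arange(short)
        idx = np.clip(np.searchsorted(cum, points), 0, len(counts) - 1)
        counts[idx] += 1
    return counts


def _clamp_targets(t: np.ndarray) -> tuple[np.ndarray, bool]:
    clipped = np.clip(t, GC_FLOOR, GC_CEIL)
    return clipped, bool(np.any(clipped != t))


def generate_genome(
    spec: SyntheticSpec, out_dir: Optional[Path] = None
) -> tuple[GenomeSet, GroundTruth]:
    """Generate a GenomeSet with known ground truth (optionally writing files).

    All randomness flows from ``spec.seed``.  Per-gene start-region targets
    depend on the gene's expression bin when ``expression_gc_coupling`` is
    nonzero: bin b is shifted by coupling x (b - (n_bins+1)/2) GC points.
    """
    if spec.cds_len_codons < 300:
        raise ValueError("cds_len_codons must be >= 300")
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_genes, spec.cds_len_codons
    gene_ids = [f"gene{i + 1:05d}" for i in range(n)]

    # expression and bins first: start-region targets may depend on the bin
    abundances = dict(
        zip(gene_ids, np.exp(rng.normal(spec.expression_mu, spec.expression_sigma, n)))
    )
    if n >= spec.n_expression_bins:
        bin_of = bin_by_expression(abundances, spec.n_expression_bins).assignment
    else:  # too few genes to stratify: everything in the lowest bin
        bin_of = {g: 1 for g in gene_ids}

    prior = _usage_prior(spec.codon_usage)
    cache = _DistributionCache(prior)
    base = spec.baseline_gc / 100.0
    mid_bin = (spec.n_expression_bins + 1) / 2.0

    def targets_at(p: int, b: int) -> np.ndarray:
        """Class GC targets (fractions) at codon position p (1-based) for bin b."""
        delta = spec.expression_gc_coupling * (b - mid_bin) / 100.0
        if p <= 100:
            x = (p - 1) / 100.0
            return np.array(
                [
                    spec.gc_start_ns / 100.0 + spec.slope_ns / 100.0 * x + delta,
                    base + spec.slope_2s / 100.0 * x + delta,
                    base + spec.slope_4s / 100.0 * x + delta,
                ]
            )
        return np.array([base, base, base])

    clamped_any = False
    codon_idx = np.zeros((n, L), dtype=np.int16)
    atg = SENSE_CODONS.index("ATG")
    codon_idx[:, 0] = atg

    gene_bins_arr = np.array([bin_of[g] for g in gene_ids])
    expected_gc: dict[int, dict[str, list[float]]] = {}
    active_bins = (
        sorted(set(gene_bins_arr)) if spec.expression_gc_coupling != 0 else [0]
    )
    for b in active_bins:
        rows = (
            np.where(gene_bins_arr == b)[0]
            if spec.expression_gc_coupling != 0
            else np.arange(n)
        )
        m = rows.size
        per_class: dict[str, list[float]] = {"ns": [], "2s": [], "4s": []}
        for p in range(2, L + 1):
            t, clipped = _clamp_targets(targets_at(p, b))
            clamped_any |= clipped
            q = cache.get(t)
            if spec.sampling == "balanced":
                counts = _quota_counts(q, m, rng)
                col = np.repeat(np.arange(len(SENSE_CODONS), dtype=np.int16), counts)
                rng.shuffle(col)
            elif spec.sampling == "multinomial":
                col = rng.choice(len(SENSE_CODONS), size=m, p=q).astype(np.int16)
            else:
                raise ValueError(f"unknown sampling mode {spec.sampling!r}")
            codon_idx[rows, p - 1] = col
            if p <= 100:
                for k, name in enumerate(("ns", "2s", "4s")):
                    per_class[name].append(100.0 * t[k])
        # position 1 is the fixed ATG
        t1, _ = _clamp_targets(targets_at(1, b))
        for k, name in enumerate(("ns", "2s", "4s")):
            per_class[name].insert(0, 100.0 * t1[k])
        expected_gc[b] = per_class
    if clamped_any:
        warnings.warn("some GC targets fell outside [5, 95]% and were clamped")

    codon_arr = np.array(SENSE_CODONS)
    stop_choice = rng.integers(0, len(STOP_CODONS), size=n)
    p_gc = np.clip(spec.baseline_gc / 100.0, 0.0, 1.0)
    records = []
    for i, gid in enumerate(gene_ids):
        cds = "".join(codon_arr[codon_idx[i]]) + STOP_CODONS[stop_choice[i]]
        if spec.utr5_len > 0:
            # UTR base composition follows the baseline GC, G/C and A/T split evenly
            u = rng.random(spec.utr5_len)
            v = rng.random(spec.utr5_len)
            utr = "".join(
                ("G" if vv < 0.5 else "C") if uu < p_gc else ("A" if vv < 0.5 else "T")
                for uu, vv in zip(u, v)
            )
        else:
            utr = ""
        records.append(
            TranscriptRecord(gid, f"{gid}.t1", cds, utr, source_species=spec.species_label)
        )

    genome = GenomeSet(species_label=spec.species_label, records=records)
    truth = GroundTruth(
        expected_gc={str(b): v for b, v in expected_gc.items()},
        expression=abundances,
        bins=dict(bin_of),
        spec=asdict(spec),
        clamped=clamped_any,
    )
    if out_dir is not None:
        write_outputs(genome, out_dir, expression=abundances, ground_truth=truth)
    return genome, truth


def write_outputs(
    genome: GenomeSet,
    out_dir,
    expression: Optional[dict[str, float]] = None,
    ground_truth: Optional[GroundTruth] = None,
) -> dict[str, Path]:
    """Write cDNA FASTA, GFF3 (cDNA coordinates, 1-based inclusive) and TSVs.

    The cDNA is utr5 + CDS; the GFF3 carries gene/mRNA/five_prime_UTR/CDS
    features with seqid = transcript id, re-loadable by the sequence reader.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not genome.records:
        raise ValueError("write_outputs: empty genome")
    fasta = out / "cdna.fasta"
    gff = out / "annotation.gff3"
    paths = {"fasta": fasta, "gff3": gff}
    with open(fasta, "w") as fh:
        for rec in genome:
            seq = rec.utr5 + rec.cds
            fh.write(f">{rec.transcript_id}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in genome:
            tid, gid = rec.transcript_id, rec.gene_id
            total = len(rec.utr5) + len(rec.cds)
            fh.write(
                f"{tid}\tgcgradients\tgene\t1\t{total}\t.\t+\t.\tID={gid}\n"
                f"{tid}\tgcgradients\tmRNA\t1\t{total}\t.\t+\t.\tID={tid};Parent={gid}\n"
            )
            if rec.utr5:
                fh.write(
                    f"{tid}\tgcgradients\tfive_prime_UTR\t1\t{len(rec.utr5)}\t.\t+\t.\t"
                    f"ID={tid}.utr5;Parent={tid}\n"
                )
            a, b = len(rec.utr5) + 1, total
            fh.write(
                f"{tid}\tgcgradients\tCDS\t{a}\t{b}\t.\t+\t0\tID={tid}.cds;Parent={tid}\n"
            )
    if expression is not None:
        expr = out / "expression.tsv"
        with open(expr, "w") as fh:
            fh.write("gene_id\tabundance\n")
            for rec in genome:
                if rec.gene_id in expression:
                    fh.write(f"{rec.gene_id}\t{expression[rec.gene_id]:.6g}\n")
        paths["expression"] = expr
    if ground_truth is not None:
        gt = out / "ground_truth.json"
        ground_truth.to_json(gt)
        paths["ground_truth"] = gt
    return paths
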