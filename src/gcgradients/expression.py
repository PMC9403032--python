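"""Expression abundances and equal-sized rank bins (1 = lowest)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping


def load_expression(tsv_path) -> dict[str, float]:
    """Read a two-column TSV (gene_id, abundance); header row optional.

    Duplicate gene ids are an error; non-numeric abundances are reported
    with their line number.
    """
    out: dict[str, float] = {}
    with open(tsv_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{tsv_path}: line {lineno}: expected 2 tab-separated columns")
            gene_id, raw = parts[0], parts[1]
            try:
                value = float(raw)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(
                    f"{tsv_path}: line {lineno}: non-numeric abundance {raw!r}"
                ) from None
            if gene_id in out:
                raise ValueError(f"{tsv_path}: duplicate gene_id {gene_id!r}")
            out[gene_id] = value
    return out


@dataclass(frozen=True)
class ExpressionBins:
    n_bins: int
    assignment: dict[str, int]  # gene_id -> bin in 1..n_bins, 1 = lowest


def bin_by_expression(abundances: Mapping[str, float], n_bins: int = 4) -> ExpressionBins:
    """Split genes into ``n_bins`` equal-sized rank blocks by abundance.

    Genes are sorted by abundance ascending with ties broken by gene id;
    when sizes are unequal the earlier (lower-expression) blocks take the
    extra gene.
    """
    genes = sorted(abundances, key=lambda g: (abundances[g], g))
    n = len(genes)
    if n < n_bins:
        raise ValueError(f"bin_by_expression: {n} genes < {n_bins} bins")
    base, rem = divmod(n, n_bins)
    assignment: dict[str, int] = {}
    idx = 0
    for b in range(1, n_bins + 1):
        size = base + (1 if b <= rem else 0)
        for g in genes[idx : idx + size]:
            assignment[g] = b
        idx += size
    return ExpressionBins(n_bins=n_bins, assignment=assignment)


def write_bins_tsv(bins: ExpressionBins, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tbin\n")
        for g, b in sorted(bins.assignment.items()):
            fh.write(f"{g}\t{b}\n")
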