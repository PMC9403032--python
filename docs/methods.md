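# Methods

## Transcript assembly and validity filters

Input is a cDNA FASTA plus a GFF3 whose feature coordinates lie on the cDNA
sequences (seqid = transcript id, 1-based inclusive); `CDS` features are
grouped by `Parent`, `five_prime_UTR` features are used when present. When a
gene has several transcripts the one with the longest cDNA is kept, ties
broken by lexicographically smallest transcript id (a deterministic
convention; any fixed tie-break would do). Minus-strand features are
reverse-complemented so CDS and UTR are always in translated orientation.

Validity requires CDS length ≥ 900 nt, length divisible by 3, and (by
default, configurable) an ATG start. The length filter applies to the
annotated CDS *including* the terminal stop codon, matching
annotation-level lengths as distributed; the stop codon is then removed
before codon numbering, so a CDS of exactly 900 nt (299 coding codons)
passes the filter but cannot supply three non-overlapping 100-codon
fragments — such genes are skipped and counted during profiling. Records
with internal stop codons are retained but flagged, so gene counts stay
auditable. Pooled coding GC is G+C over A+C+G+T across all valid CDS
nucleotides; N is excluded from numerator and denominator.

## Site classification

Each position of each codon is classed by the number of the three
alternative nucleotides that preserve the encoded amino acid under NCBI
translation table 1: 0 → nonsynonymous (ns), 3 → four-fold (4s), otherwise
two-fold (2s). Substitutions creating stop codons count as nonsynonymous,
and the three-fold isoleucine third position folds into 2s by default (a
separate three-fold class is available). Partially synonymous first
positions (leucine TTR/CTR, arginine CGR/AGR) therefore classify as 2s.
Under these conventions the 61 sense codons carry 116 ns, 35 2s and 32 4s
site slots (63.4% ns with uniform usage). Other binning conventions shift
the class fractions by a few percent; the classification is configurable
where it is ambiguous. "Positively charged" means {K, R, H}; the essential
amino acids are {F, V, T, W, M, L, I, K, H}.

## Fragments, profiles and slopes

Each CDS contributes start (codons 1–100), middle, and end (last 100)
fragments; the middle fragment starts at codon ⌊(L−100)/2⌋+1 for L coding
codons, a deterministic centering (the exact placement convention is
otherwise arbitrary). Per-codon GC for a site class is the G/C fraction over
that codon's sites of the class (undefined when the codon has none, for stop
codons, and for codons containing N); profiles average these per-gene values
across genes at each position, so each gene contributes equally regardless
of how many sites of the class its codon has. Amino-acid exclusion masks
drop codons without renumbering positions.

The gradient statistic is unweighted OLS of the per-position mean (percent)
on the raw codon index over codons 26–100 — the first 25 codons sit under
separate initiation-related constraints and are excluded — with the
coefficient reported ×100, i.e. GC%-change per 100 codons. Missing positions
are dropped, never imputed; a constant profile reports slope 0 with r² = 1
(zero residuals). The cost gradient uses the same fit but reports the raw
per-codon coefficient, because the saved-ATP statistic
(slope × n/2 × 100, n = number of regression codons, 75 by default) is
defined on that scale. With n = 75 the published human slope of 0.0082
yields 30.75 ATP per protein; n = 100 would give 41 — the default n = 75
follows the regression range actually fitted.

Amino-acid costs are bundled as a TSV of Akashi-type de novo biosynthesis
costs in high-energy phosphate bonds (aerobic); nucleotide costs are bundled
with representative, approximate magnitudes (marked as such in the file) and
feed no computed statistic. Both are user-overridable configuration data.

## Folding windows

Window for codon c: the codon plus 18-nt flanks (39 nt nominal), stepping
3 nt per codon; upstream overhang fills from the 3′ end of the 5′-UTR and
truncates at the transcript 5′ end when the UTR is short (truncated windows
are excluded from cross-gene means by default, since their shorter length
biases scores upward). T is read as U. The engine is pluggable: ViennaRNA's
MFE when the python bindings import, else a bundled weighted
base-pair-maximization dynamic program (nested pairings only, minimum
hairpin loop 3 unpaired nt, pair scores GC −3, AU −2, GU −1, N never pairs).
The bundled engine's values are not free energies; all conclusions drawn
from folding are comparative (between positions or expression bins), never
absolute. Expression bins are equal-sized rank quartiles (ascending, ties by
gene id, earlier bins take the remainder; zero-abundance genes stay in bin 1).

## Synthetic genomes

The generator emulates the positional structure the analyses target: codon 1
is ATG; over codons 2–100 the expected G/C fraction at ns sites follows
`gc_start_ns + slope_ns·(p−1)/100` (2s and 4s sites likewise, starting from
`baseline_gc`); beyond codon 100 all classes sit at `baseline_gc`; a stop
codon is appended; 5′-UTRs are iid nucleotides at `baseline_gc`; expression
is lognormal(μ=1, σ=1). Targets outside [5, 95]% are clamped with a warning.
Defaults (2000 genes of 400 coding codons, ns start 55% with slope −5 per
100 codons — the strong-tetrapod regime — synonymous sites flat at 50%,
50-nt UTRs) were chosen once as a realistic focal condition.

Targets are met by exponential tilting: for each position a distribution
over the 61 sense codons is solved (3-parameter root find) so that the
GC mean at each site class, conditional on codons carrying such sites,
equals the target. Tilting moves amino-acid frequencies (for the ns target)
and synonymous-codon frequencies (for 2s/4s) simultaneously. Draws use
balanced allocation: per position, codon counts are ⌊m·q⌋ plus a
systematic randomized-start draw over the fractional parts (inclusion
probability exactly the fractional part), randomly assigned to genes. The
allocation is unbiased with counts within 1 of m·q, so realized per-position
profiles match their expectations to well under a GC point at study sizes,
and gradient recovery reflects the estimator rather than sampling noise of
the generator; an iid `multinomial` mode is available when realistic
position-level sampling noise is wanted. Internal stops never arise (stop
codons are not in the sampling support). With `expression_gc_coupling` = c,
a gene in expression bin b has all start-region class targets and its UTR GC
shifted by c·(b − (n_bins+1)/2) points, middle/end unchanged — so higher
bins have GC-elevated starts relative to their own downstream sequence.

What the generator does **not** emulate: real codon-usage bias along genes
(a human-like usage prior is available but stationary), amino-acid
autocorrelation and protein domain structure, length variation, isoforms,
UTR structure beyond iid composition, and any phylogenetic correlation
among synthetic "species". Passing recovery tests therefore demonstrates
correctness of the estimators under the stated generative model, not that
real genomes follow it.

## Numerical choices and problem sizes

OLS via `scipy.stats.linregress`; fits require ≥3 defined positions;
cross-genome regression requires ≥3 genomes and a non-constant predictor.
The sign-change threshold is −intercept/slope, undefined at slope 0. The
bundled folding DP is exact (verified against exhaustive enumeration of all
nested pairings for short sequences). Analyses and tests use genomes of
300–400 coding codons and 150–2500 genes, and seed-replicated recovery uses
20 seeds × 2000 genes — sizes at which generator realization error is well
below the effects studied while the full suite runs in seconds.

## Known limitations

- The 900-nt threshold's interaction with stop-codon stripping (above) makes
  genes of exactly 299 coding codons valid-but-unprofilable; they are
  counted, not silently dropped.
- Only the standard genetic code is supported.
- The cross-genome regression is plain OLS within a label; no phylogenetic
  correction.
- GTF input and Ensembl/Expression Atlas download clients are out of scope;
  inputs must already be in the cDNA-coordinate FASTA+GFF3 dialect.
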