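"""Shared study conditions for the numbered analysis drivers.

The focal genome mimics a tetrapod-like composition: start-region GC at
nonsynonymous sites 55% falling 5 points per 100 codons, synonymous sites
flat at the 50% baseline, 50-nt UTRs, lognormal expression.  The cross-genome
panel varies overall coding GC and couples the nonsynonymous gradient to it
with a zero crossing at 40% GC.
"""

from pathlib import Path

from gcgradients import SyntheticSpec

REPO = Path(__file__).resolve().parents[1]
RESULTS = REPO / "results"
SCRATCH = REPO / "scratch" / "synthetic"

FOCAL_SEED = 11

FOCAL_SPEC = SyntheticSpec(
    n_genes=2000,
    cds_len_codons=400,
    gc_start_ns=55.0,
    slope_ns=-5.0,
    slope_2s=0.0,
    slope_4s=0.0,
    baseline_gc=50.0,
    utr5_len=50,
    seed=FOCAL_SEED,
    species_label="focal",
)

# slope(GC) = PANEL_B * (GC - PANEL_CROSSING): negative gradients above 40% GC
PANEL_B = -0.2
PANEL_CROSSING = 40.0
PANEL_GC = [34 + 2 * i for i in range(16)]  # coding GC 34..64%


def panel_spec(gc: float, seed: int) -> SyntheticSpec:
    slope = PANEL_B * (gc - PANEL_CROSSING)
    return SyntheticSpec(
        n_genes=400,
        cds_len_codons=300,
        gc_start_ns=gc - slope / 2.0,  # ns gradient centered on the genome GC
        slope_ns=slope,
        baseline_gc=gc,
        utr5_len=0,
        seed=seed,
        species_label=f"syn_gc{gc:g}",
    )
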