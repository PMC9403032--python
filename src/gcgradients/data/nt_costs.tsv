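# Nucleotide de novo synthesis costs in high-energy phosphate bonds.
# Approximate, representative values for the ribonucleotide triphosphates
# (G and C are costlier than A and T/U); synthetic placeholder magnitudes —
# override with a measured table for quantitative nucleotide-cost work.
# These values feed no statistic computed by this package.
nt	cost
A	45.0
C	46.0
G	49.0
T	44.0
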