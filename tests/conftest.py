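import pytest

from gcgradients import load_cost_table
from gcgradients.synthetic_data import SyntheticSpec, generate_genome


@pytest.fixture(scope="session")
def tiny_genome():
    """Small deterministic genome: 20 genes, 310 coding codons, default gradients."""
    spec = SyntheticSpec(n_genes=20, cds_len_codons=310, utr5_len=30, seed=42)
    genome, truth = generate_genome(spec)
    return genome, truth


@pytest.fixture(scope="session")
def cost_table():
    return load_cost_table()
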