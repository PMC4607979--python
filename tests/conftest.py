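import pytest

from medipscape import binning
from medipscape.synthetic import (
    SimulationConfig,
    simulate_genome,
    simulate_reads,
)

SMALL = dict(
    chrom_lengths={"chr1": 120_000, "chr2": 60_000},
    n_genes=12,
    reads_per_sample=60_000,
    n_planted_dmrs=24,
    individuals_per_population=15,
)


@pytest.fixture(scope="session")
def default_run():
    """One full default-scale simulation, shared across tests."""
    cfg = SimulationConfig(seed=42)
    genome, genes, truth = simulate_genome(cfg)
    reads, totals = simulate_reads(cfg, truth)
    counts = binning.count_reads(truth.bins, reads, cfg.breed_of)
    retained = binning.filter_bins(counts)
    scores = binning.enrichment_matrix(retained)
    return {
        "config": cfg,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "reads": reads,
        "counts": counts,
        "retained": retained,
        "scores": scores,
    }


@pytest.fixture()
def small_config():
    return SimulationConfig(seed=7, **SMALL)
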