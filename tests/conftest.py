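import time

import pytest

from drnamap.model import PipelineParams
from drnamap.pipeline import run_pipeline
from drnamap.synthetic import (SyntheticParams, generate_genome,
                               simulate_coverage)


@pytest.fixture
def params():
    return PipelineParams()


def small_synthetic_params(seed: int = 3) -> SyntheticParams:
    """A scaled-down dataset for fast I/O and plumbing tests."""
    return SyntheticParams(
        genome_length=30_000, n_plain_genes=2, n_utr5_genes=2,
        n_utr3_genes=2, n_operons=2, n_antisense_hosts=2, n_silent_genes=1,
        n_secondary=1, n_internal=1, n_orphan=1, n_srna_intergenic=2,
        n_hc_intergenic=1, n_decoys=2, n_standalone_terminators=1,
        n_replicates=2, rng_seed=seed)


@pytest.fixture(scope="session")
def small_dataset():
    sp = small_synthetic_params()
    genome, genes, truth = generate_genome(sp)
    cov = simulate_coverage(genome, truth, sp)
    return sp, genome, genes, cov, truth


@pytest.fixture(scope="session")
def default_dataset():
    """The full study-condition dataset: 100 kb, 60 genes, 80 planted TSSs."""
    sp = SyntheticParams(rng_seed=1)
    genome, genes, truth = generate_genome(sp)
    cov = simulate_coverage(genome, truth, sp)
    return sp, genome, genes, cov, truth


@pytest.fixture(scope="session")
def default_run(default_dataset):
    """Full pipeline result on the default dataset, with wall time."""
    sp, genome, genes, cov, truth = default_dataset
    t0 = time.monotonic()
    result = run_pipeline(genome, genes, cov)
    elapsed = time.monotonic() - t0
    return result, truth, elapsed
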