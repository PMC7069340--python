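import pytest

from edikit.synthetic_data import (
    SimConfig,
    as_aligned,
    emit_all,
    make_genome,
    simulate_reads,
)


SMALL_CFG = dict(
    genome_length=20_000,
    depth=200.0,
    wgs_depth=30.0,
    n_editing_sites=15,
    n_recoding_sites=3,
    n_het_snps=5,
    n_hyper_reads=8,
)


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """One fully simulated dataset shared by the read-level tests."""
    cfg = SimConfig(seed=11, **SMALL_CFG)
    genome, truth = make_genome(cfg)
    simulate_reads(genome, truth, cfg)
    outdir = tmp_path_factory.mktemp("sim")
    paths = emit_all(genome, truth, outdir)
    return {
        "cfg": cfg,
        "genome": genome,
        "truth": truth,
        "paths": paths,
        "rna": as_aligned(truth.rna_reads),
        "wgs": as_aligned(truth.wgs_reads),
        "hyper": as_aligned(truth.hyper_reads),
    }


@pytest.fixture(scope="session")
def clean_bundle():
    """Error-free simulation (no sequencing noise) for exact-truth checks."""
    cfg = SimConfig(seed=17, base_error_rate=0.0, **{**SMALL_CFG, "depth": 100.0})
    genome, truth = make_genome(cfg)
    simulate_reads(genome, truth, cfg)
    return {
        "cfg": cfg,
        "genome": genome,
        "truth": truth,
        "rna": as_aligned(truth.rna_reads),
        "wgs": as_aligned(truth.wgs_reads),
    }
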