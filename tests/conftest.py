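import numpy as np
import pytest

from hybridscope import syndata


@pytest.fixture(scope="session")
def small_cfg():
    return syndata.SimConfig(
        seed=7,
        n_chromosomes=2,
        chrom_length=20_000,
        n_transcripts=20,
        n_reads=2000,
    )


@pytest.fixture(scope="session")
def small_bundle(small_cfg, tmp_path_factory):
    """One small end-to-end simulation shared by read-only tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    truth = syndata.simulate_all(small_cfg, outdir)
    return small_cfg, outdir, truth


@pytest.fixture(scope="session")
def noise_free_bundle(tmp_path_factory):
    """Zero sequencing error, substitutions-only divergence, extended dialect.

    In this regime read arbitration is exactly decodable: a read's CIGAR on
    its true genome is all '=', and on the other genome it mismatches at
    precisely the diagnostic substitution sites it spans.
    """
    cfg = syndata.SimConfig(
        seed=11,
        n_chromosomes=1,
        chrom_length=30_000,
        divergence=0.02,
        indel_divergence=0.0,
        n_transcripts=15,
        n_reads=3000,
        seq_error_sub=0.0,
        seq_error_indel=0.0,
    )
    outdir = tmp_path_factory.mktemp("noise_free")
    truth = syndata.simulate_all(cfg, outdir)
    return cfg, outdir, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
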