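"""Tests for the synthetic-data generator: determinism, truth consistency,
and the analytic CIGAR construction."""

import math

import numpy as np
import pytest

from hybridscope import samcompare as sc
from hybridscope import syndata


def test_config_rejects_invalid_rates_and_sizes():
    with pytest.raises(ValueError, match="divergence"):
        syndata.SimConfig(divergence=0.5)  # ambiguous coordinate mapping
    with pytest.raises(ValueError):
        syndata.SimConfig(seq_error_sub=-0.1)
    with pytest.raises(ValueError):
        syndata.SimConfig(chrom_length=0)
    with pytest.raises(ValueError):
        syndata.SimConfig(transcript_length_range=(100, 50))


def test_config_round_trip():
    cfg = syndata.SimConfig(seed=3, divergence=0.05)
    assert syndata.SimConfig.from_dict(cfg.to_dict()) == cfg


def test_zero_divergence_gives_identical_genomes():
    cfg = syndata.SimConfig(seed=5, divergence=0.0, indel_divergence=0.0,
                            n_chromosomes=1, chrom_length=5000)
    g = syndata.generate_parental_genomes(cfg)
    assert g.seqs_a == g.seqs_b
    assert g.diagnostic_sites == []
    assert (g.a2b["chr1"] == np.arange(5000)).all()


def test_diagnostic_site_count_matches_binomial_expectation():
    cfg = syndata.SimConfig(seed=13, divergence=0.02, indel_divergence=0.0,
                            n_chromosomes=1, chrom_length=100_000)
    g = syndata.generate_parental_genomes(cfg)
    n = len(g.diagnostic_sites)
    expect = 100_000 * 0.02
    sd = math.sqrt(100_000 * 0.02 * 0.98)
    assert abs(n - expect) <= 3 * sd
    assert all(s.kind == "sub" for s in g.diagnostic_sites)


def test_coordinate_maps_are_mutually_inverse():
    cfg = syndata.SimConfig(seed=17, n_chromosomes=1, chrom_length=10_000,
                            indel_divergence=0.01)
    g = syndata.generate_parental_genomes(cfg)
    a2b, b2a = g.a2b["chr1"], g.b2a["chr1"]
    mapped = np.flatnonzero(a2b >= 0)
    assert (b2a[a2b[mapped]] == mapped).all()
    # mapped positions carry the bases the diagnostic record claims
    for s in g.diagnostic_sites[:50]:
        if s.kind == "sub":
            assert g.seqs_a["chr1"][s.pos_a] == s.base_a
            assert g.seqs_b["chr1"][s.pos_b] == s.base_b


def test_simulation_is_byte_deterministic(tmp_path):
    cfg = syndata.SimConfig(seed=23, n_reads=300, n_chromosomes=1,
                            chrom_length=10_000, n_transcripts=10)
    d1, d2 = tmp_path / "r1", tmp_path / "r2"
    syndata.simulate_all(cfg, d1)
    syndata.simulate_all(cfg, d2)
    for name in ("genomeA.fasta", "genomeB.fasta", "reads.fastq", "alnA.sam",
                 "alnB.sam", "trioA.vcf", "trioB.vcf", "transcripts.gff3",
                 "truth_reads.tsv"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name


def test_no_reads_requested_gives_empty_fastq(tmp_path):
    cfg = syndata.SimConfig(seed=1, n_reads=0, n_chromosomes=1,
                            chrom_length=5000, n_transcripts=5)
    truth = syndata.simulate_all(cfg, tmp_path)
    assert truth.reads == {}
    assert (tmp_path / "reads.fastq").read_text() == ""


def test_noise_free_reads_are_exact_genome_substrings(noise_free_bundle):
    cfg, outdir, truth = noise_free_bundle
    g = syndata.generate_parental_genomes(cfg)
    for read in list(truth.reads.values())[:200]:
        seq = g.seq(read.origin)[read.chrom]
        assert read.bases == seq[read.start : read.end]


def test_balanced_origin_mixture_recovers_binomial_split(tmp_path):
    cfg = syndata.SimConfig(seed=29, n_reads=10_000, n_chromosomes=1,
                            chrom_length=30_000, n_transcripts=20,
                            frac_transcripts_a=0.0, frac_transcripts_b=0.0)
    truth = syndata.simulate_all(cfg, tmp_path)
    n_a = sum(1 for r in truth.reads.values() if r.origin == "A")
    assert abs(n_a - 5000) <= 3 * math.sqrt(10_000 * 0.25)


def test_every_read_appears_once_per_sam(small_bundle):
    cfg, outdir, truth = small_bundle
    for side in ("A", "B"):
        names = [
            line.split("\t")[0]
            for line in (outdir / f"aln{side}.sam").read_text().splitlines()
            if not line.startswith("@")
        ]
        assert sorted(names) == sorted(truth.reads)


# --- analytic alignment construction -------------------------------------

def _handmade_pair(sub_at=100, length=200):
    """Two identical genomes except one substitution; a read crossing it."""
    rng = np.random.default_rng(99)
    seq_a = "".join(rng.choice(list("ACGT"), size=length))
    base_a = seq_a[sub_at]
    base_b = "A" if base_a != "A" else "C"
    seq_b = seq_a[:sub_at] + base_b + seq_a[sub_at + 1 :]
    ident = np.arange(length)
    genomes = syndata.Genomes(
        {"chr1": seq_a}, {"chr1": seq_b}, {"chr1": ident}, {"chr1": ident},
        [syndata.DiagnosticSite("chr1", sub_at, sub_at, "sub", base_a, base_b)],
    )
    read = syndata.ReadRecord(
        "r0", "A", "chr1", 60, 160, "T0", seq_a[60:160],
        np.arange(60, 160, dtype=np.int64),
    )
    return genomes, read


def test_read_over_one_substitution_extended_dialect():
    genomes, read = _handmade_pair()
    pos_a, ops_a = syndata.align_read(read, genomes.seqs_a["chr1"], None)
    pos_b, ops_b = syndata.align_read(read, genomes.seqs_b["chr1"], genomes.a2b["chr1"])
    assert (pos_a, ops_a) == (60, [("=", 100)])
    assert pos_b == 60
    assert [op for op, _ in ops_b] == ["=", "X", "="]
    assert sum(ln for op, ln in ops_b if op == "X") == 1


def test_same_read_legacy_dialect_is_pure_m():
    """One isolated mismatch does not trigger end clipping (needs >= 2
    mismatches within the 10 bp end window), so both CIGARs are pure M."""
    genomes, read = _handmade_pair()
    pos_a, ops_a = syndata.legacy_m(*syndata.align_read(read, genomes.seqs_a["chr1"], None))
    pos_b, ops_b = syndata.legacy_m(
        *syndata.align_read(read, genomes.seqs_b["chr1"], genomes.a2b["chr1"])
    )
    assert ops_a == [("M", 100)] and ops_b == [("M", 100)]
    assert pos_a == pos_b == 60


def test_legacy_dialect_clips_mismatch_dense_end():
    """Two mismatches within 10 bp of the read start are soft-clipped, by
    hand-applying the clipping rule: the clip extends through the last
    mismatch of the dense window."""
    ops = [("X", 1), ("=", 3), ("X", 1), ("=", 95)]
    pos, legacy = syndata.legacy_m(10, ops)
    assert legacy == [("S", 5), ("M", 95)]
    assert pos == 15  # five aligned columns clipped shift the start


def test_zero_error_zero_divergence_identical_all_match_cigars(tmp_path):
    cfg = syndata.SimConfig(seed=31, divergence=0.0, indel_divergence=0.0,
                            seq_error_sub=0.0, seq_error_indel=0.0,
                            n_chromosomes=1, chrom_length=5000,
                            n_transcripts=5, n_reads=50)
    syndata.simulate_all(cfg, tmp_path)
    recs_a = [l.split("\t") for l in (tmp_path / "alnA.sam").read_text().splitlines()
              if not l.startswith("@")]
    recs_b = [l.split("\t") for l in (tmp_path / "alnB.sam").read_text().splitlines()
              if not l.startswith("@")]
    for ra, rb in zip(recs_a, recs_b):
        assert ra[5] == rb[5] == f"{len(ra[9])}="


def test_truth_cigar_reflects_only_sequencing_errors(small_bundle):
    """On its true genome a read's mismatches+indels come from the error
    model alone, so at the default rates they are few."""
    cfg, outdir, truth = small_bundle
    g = syndata.generate_parental_genomes(cfg)
    for read in list(truth.reads.values())[:100]:
        aln = syndata.align_read(read, g.seq(read.origin)[read.chrom], None)
        assert aln is not None
        _, ops = aln
        n_x = sum(ln for op, ln in ops if op == "X")
        n_indel = sum(1 for op, _ in ops if op in "ID")
        assert n_x <= 6 and n_indel <= 4  # ~0.5% sub, ~0.2% indel per base


# --- trio VCF --------------------------------------------------------------

def test_threshold_genotyper():
    assert syndata._genotype((500, 500)) == "0/1"
    assert syndata._genotype((0, 10)) == "1/1"
    assert syndata._genotype((10, 0)) == "0/0"
    assert syndata._genotype((95, 5)) == "0/0"  # minor fraction 0.05 < 0.1
    assert syndata._genotype((89, 11)) == "0/1"


def test_planted_monoallelic_fraction_within_binomial_bounds(tmp_path):
    cfg = syndata.SimConfig(seed=37, n_chromosomes=1, chrom_length=50_000,
                            divergence=0.02, indel_divergence=0.0,
                            n_reads=0, frac_monoallelic_sites=0.3)
    truth = syndata.simulate_all(cfg, tmp_path)
    n = len(truth.sites)
    planted = sum(1 for s in truth.sites.values() if s["planted_monoallelic"])
    assert abs(planted - 0.3 * n) <= 3 * math.sqrt(n * 0.3 * 0.7)


def test_trio_vcf_parents_alternatively_homozygous_at_planted_sites(small_bundle):
    cfg, outdir, truth = small_bundle
    from hybridscope import trio_alleles as ta

    sites = {(s.chrom, s.pos - 1): s for s in ta.read_trio_vcf(outdir / "trioA.vcf")}
    for site_id, info in truth.sites.items():
        s = sites.get((info["chrom"], info["pos_a"]))
        if s is None:
            continue
        if info["planted_monoallelic"]:
            assert {s.gt_sire, s.gt_dam} == {(0, 0), (1, 1)}
        else:
            assert s.gt_dam == (0, 1)
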