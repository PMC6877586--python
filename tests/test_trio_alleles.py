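"""Tests for trio-variant filtering, allelic-depth binning, and origin blocks."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridscope import trio_alleles as ta


def site(gt_sire, gt_dam, gt_hybrid=(0, 1), ad=(10, 10), ref="A", impact=None,
         chrom="chr1", pos=100):
    return ta.TrioSite(chrom, pos, "A", "G", gt_sire, gt_dam, gt_hybrid, ad,
                       ref, impact)


class TestSelectAltMonoallelic:
    def test_retains_both_orientations_and_records_alt_parent(self):
        s1 = site((0, 0), (1, 1))
        s2 = site((1, 1), (0, 0))
        kept = list(ta.select_alt_monoallelic([s1, s2]))
        assert [s.alt_parent for s in kept] == ["dam", "sire"]

    def test_drops_non_alternative_and_missing(self):
        counters = ta.FilterCounters()
        sites = [site((0, 1), (1, 1)), site((1, 1), (1, 1)), site(None, (0, 0))]
        assert list(ta.select_alt_monoallelic(sites, counters)) == []
        assert counters.not_alternative == 2
        assert counters.missing_parent_gt == 1

    def test_planted_sites_recovered_from_simulation(self, small_bundle):
        cfg, outdir, truth = small_bundle
        kept = list(ta.select_alt_monoallelic(ta.read_trio_vcf(outdir / "trioA.vcf")))
        planted = {
            (i["chrom"], i["pos_a"] + 1)
            for i in truth.sites.values() if i["planted_monoallelic"]
        }
        emitted = {(i["chrom"], i["pos_a"] + 1) for i in truth.sites.values()}
        got = {(s.chrom, s.pos) for s in kept}
        # every retained site was planted; every planted site present in the
        # VCF (nonzero depth) is retained
        assert got <= planted
        assert planted - got <= planted - emitted


def test_classify_hybrid_zygosity():
    assert ta.classify_hybrid_zygosity(site((0, 0), (1, 1), (0, 1))) == "biallelic"
    assert ta.classify_hybrid_zygosity(site((0, 0), (1, 1), (1, 1))) == "mono"
    assert ta.classify_hybrid_zygosity(site((0, 0), (1, 1), (0, 0))) == "mono"
    assert ta.classify_hybrid_zygosity(site((0, 0), (1, 1), None)) is None


@pytest.mark.parametrize("ad,expected", [
    ((10, 0), 1.0),
    ((0, 7), 1.0),
    ((5, 5), 0.0),
    ((7, 3), 0.4),
])
def test_allelic_depth_ratio_examples(ad, expected):
    assert ta.allelic_depth_ratio(ad) == pytest.approx(expected)


def test_allelic_depth_ratio_rejects_zero_and_negative():
    with pytest.raises(ValueError):
        ta.allelic_depth_ratio((0, 0))
    with pytest.raises(ValueError):
        ta.allelic_depth_ratio((-1, 5))


@settings(max_examples=300, derandomize=True)
@given(st.integers(0, 1000), st.integers(0, 1000))
def test_ratio_bounds_and_extremes(ref, alt):
    if ref + alt == 0:
        return
    r = ta.allelic_depth_ratio((ref, alt))
    assert 0.0 <= r <= 1.0
    assert (r == 1.0) == (ref == 0 or alt == 0)
    assert (r == 0.0) == (ref == alt)


@pytest.mark.parametrize("ratio,magnitude", [
    (0.0, 0.1),   # bin 0.1 holds only heterozygous (balanced) variants
    (0.05, 0.1),
    (0.25, 0.3),  # ceiling rule
    (0.2, 0.2),   # boundary stays in its bin
    (1.0, 1.0),
])
def test_signed_bin_magnitudes(ratio, magnitude):
    assert ta.signed_bin(ratio, "dam").magnitude == pytest.approx(magnitude)


def test_signed_bin_conventions():
    assert ta.signed_bin(1.0, "dam").sign == "+"  # sheep 1/1 positive (default)
    assert ta.signed_bin(1.0, "sire").sign == "-"
    assert ta.signed_bin(1.0, "dam", "figure").sign == "-"
    assert ta.signed_bin(1.0, "sire", "figure").sign == "+"
    with pytest.raises(ValueError):
        ta.signed_bin(1.2, "dam")


def test_sign_antisymmetry_under_parent_swap(rng):
    """Swapping the parental genotype columns flips every bin's sign and
    changes nothing else in the histogram."""
    sites, swapped = [], []
    for i in range(500):
        orient = rng.random() < 0.5
        gt_s, gt_d = ((0, 0), (1, 1)) if orient else ((1, 1), (0, 0))
        ad = (int(rng.integers(0, 50)), int(rng.integers(0, 50)))
        if sum(ad) == 0:
            continue
        sites.append(site(gt_s, gt_d, ad=ad, pos=i + 1))
        swapped.append(site(gt_d, gt_s, ad=ad, pos=i + 1))

    def hist(ss):
        bins = [
            ta.signed_bin(ta.allelic_depth_ratio(s.ad_hybrid), s.alt_parent)
            for s in ta.select_alt_monoallelic(ss)
        ]
        return ta.bin_histogram(bins)

    h1, h2 = hist(sites), hist(swapped)
    assert h1 != h2 or all(v == 0 for v in h1.values())
    for b, count in h1.items():
        assert h2[round(-b, 1)] == count


def test_origin_from_variant_rules():
    # vs the dam's species reference: hom-ref hybrid expresses the dam allele
    assert ta.origin_from_variant(site((1, 1), (0, 0), (0, 0), ref="A")) == "dam"
    assert ta.origin_from_variant(site((1, 1), (0, 0), (1, 1), ref="A")) == "sire"
    # vs the sire's species reference the roles mirror
    assert ta.origin_from_variant(site((0, 0), (1, 1), (0, 0), ref="B")) == "sire"
    assert ta.origin_from_variant(site((0, 0), (1, 1), (1, 1), ref="B")) == "dam"
    assert ta.origin_from_variant(site((1, 1), (0, 0), (0, 1))) is None
    assert ta.origin_from_variant(site((1, 1), (0, 0), None)) is None


class TestBuildBlocks:
    def test_run_length_merging(self):
        calls = [("chr1", p, o) for p, o in
                 [(10, "dam"), (20, "dam"), (30, "sire"), (40, "sire"), (50, "sire")]]
        blocks = ta.build_blocks(calls)
        assert [(b.origin, b.n_variants, b.start, b.end) for b in blocks] == [
            ("dam", 2, 9, 20), ("sire", 3, 29, 50)]

    def test_single_call_spans_one_bp(self):
        (b,) = ta.build_blocks([("chr2", 7, "sire")])
        assert (b.start, b.end, b.n_variants) == (6, 7, 1)

    def test_alternating_origins_make_singleton_blocks(self):
        calls = [("chr1", p, o) for p, o in
                 [(1, "dam"), (2, "sire"), (3, "dam"), (4, "sire")]]
        assert len(ta.build_blocks(calls)) == 4

    def test_chromosome_boundary_breaks_blocks(self):
        calls = [("chr1", 5, "dam"), ("chr2", 6, "dam")]
        assert len(ta.build_blocks(calls)) == 2

    def test_unsorted_input_is_an_error(self):
        with pytest.raises(ValueError, match="not sorted"):
            ta.build_blocks([("chr1", 10, "dam"), ("chr1", 5, "dam")])

    def test_min_variants_drops_small_blocks(self):
        calls = [("chr1", p, o) for p, o in
                 [(1, "dam"), (10, "sire"), (20, "sire")]]
        blocks = ta.build_blocks(calls, min_variants=2)
        assert [(b.origin, b.n_variants) for b in blocks] == [("sire", 2)]

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.sampled_from(["dam", "sire"]), max_size=60))
    def test_conservation_and_maximality(self, origins):
        calls = [("chr1", i + 1, o) for i, o in enumerate(origins)]
        blocks = ta.build_blocks(calls)
        assert sum(b.n_variants for b in blocks) == len(origins)
        for prev, nxt in zip(blocks, blocks[1:]):
            assert prev.origin != nxt.origin or prev.chrom != nxt.chrom
            assert prev.end <= nxt.start + 1  # non-overlapping
        for b in blocks:
            assert b.start < b.end and b.n_variants >= 1

    def test_origin_recovery_on_planted_block_structure(self, rng):
        """Noise-free genotypes with planted per-region origins reproduce
        the planted block structure exactly."""
        planted = [("chr1", 0, 400, "dam"), ("chr1", 400, 900, "sire"),
                   ("chr2", 0, 500, "sire")]
        calls = []
        for chrom, lo, hi, origin in planted:
            for pos in sorted(rng.choice(range(lo + 1, hi), size=20, replace=False)):
                calls.append((chrom, int(pos), origin))
        calls.sort(key=lambda c: (c[0], c[1]))
        blocks = ta.build_blocks(calls)
        assert [(b.chrom, b.origin, b.n_variants) for b in blocks] == [
            ("chr1", "dam", 20), ("chr1", "sire", 20), ("chr2", "sire", 20)]


def test_block_bp_totals():
    blocks = [ta.OriginBlock("chr1", 0, 100, "dam", 3),
              ta.OriginBlock("chr1", 200, 250, "sire", 2),
              ta.OriginBlock("chr2", 0, 10, "dam", 1)]
    totals = ta.block_bp_totals(blocks)
    assert totals == {"chr1": {"dam": 100, "sire": 50}, "chr2": {"dam": 10, "sire": 0}}


def test_impact_fractions_on_fixed_fixture():
    sites = (
        [site((0, 0), (1, 1), (0, 1), impact=i) for i in
         ("HIGH", "MODERATE", "LOW", "MODIFIER")]
        + [site((0, 0), (1, 1), (1, 1), impact="MODIFIER")] * 3
        + [site((0, 0), (1, 1), (1, 1), impact="LOW")]
        + [site((0, 0), (1, 1), None, impact="LOW")]
        + [site((0, 0), (1, 1), (0, 1), impact=None)]
    )
    out = ta.impact_fractions(sites)
    assert out["biallelic"] == {"HIGH": 25.0, "MODERATE": 25.0, "LOW": 25.0,
                                "MODIFIER": 25.0, "n_sites": 4}
    assert out["mono"] == {"HIGH": 0.0, "MODERATE": 0.0, "LOW": 25.0,
                           "MODIFIER": 75.0, "n_sites": 4}
    assert out["excluded"] == {"unclassified": 1, "unannotated": 1}


def test_impact_fractions_empty_partition_is_reported_not_error():
    out = ta.impact_fractions([site((0, 0), (1, 1), (0, 1), impact="MODIFIER")])
    assert out["mono"]["n_sites"] == 0
    assert out["biallelic"]["MODIFIER"] == 100.0


def test_vcf_round_trip_gt_ad(small_bundle):
    cfg, outdir, truth = small_bundle
    sites = list(ta.read_trio_vcf(outdir / "trioA.vcf"))
    assert sites, "simulation produced no VCF records"
    for s in sites:
        assert s.gt_sire in ((0, 0), (1, 1))
        assert sum(s.ad_hybrid) > 0
        assert s.impact in ta.IMPACT_CLASSES
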