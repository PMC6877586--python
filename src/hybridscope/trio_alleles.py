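"""Trio-variant analyses: allele-specific expression and parental origin.

Given variant calls of a hybrid and its two parents against one parental
reference genome, this module

* selects sites where the parents are *alternatively monoallelic* (one
  homozygous reference, the other homozygous alternate) — at such sites the
  hybrid inherits one allele from each parent, so its expressed allele
  balance is informative;
* classifies the hybrid's expression at each site as mono- or biallelic
  from its genotype call;
* computes the allelic depth ratio |ref - alt| / (ref + alt), which is 1
  under monoallelic expression and 0 under perfectly balanced biallelic
  expression, and bins it with a parental sign (0.1-wide bins);
* assigns a parental origin to sites where the hybrid is homozygous and
  merges runs of same-origin calls into chromosome blocks;
* tabulates variant-impact classes separately for the mono- and biallelic
  partitions.

Two sign conventions for the binned histogram are implemented because the
source descriptions of this analysis disagree on which parent gets the
positive sign; see :func:`signed_bin`.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Literal

import pysam

from .samcompare import round_half_up

__all__ = [
    "TrioSite",
    "SignedBin",
    "OriginBlock",
    "read_trio_vcf",
    "select_alt_monoallelic",
    "classify_hybrid_zygosity",
    "allelic_depth_ratio",
    "signed_bin",
    "bin_histogram",
    "origin_from_variant",
    "build_blocks",
    "impact_fractions",
]

Genotype = tuple[int, int] | None
Parent = Literal["sire", "dam"]

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")


@dataclass
class TrioSite:
    """One biallelic variant site across sire, dam and hybrid.

    ``reference_species`` records which parental genome the VCF was called
    against: "A" when the reference is the dam's species, "B" when it is
    the sire's.  Genotypes are unphased allele pairs over {0, 1} or ``None``
    when missing; ``ad_hybrid`` is (ref_depth, alt_depth).
    """

    chrom: str
    pos: int  # 1-based, as in the VCF
    ref_allele: str
    alt_allele: str
    gt_sire: Genotype
    gt_dam: Genotype
    gt_hybrid: Genotype
    ad_hybrid: tuple[int, int]
    reference_species: Literal["A", "B"]
    impact: str | None = None
    alt_parent: Parent | None = None  # filled by select_alt_monoallelic


@dataclass(frozen=True)
class SignedBin:
    """One 0.1-wide allelic-depth-ratio bin with a parental sign.

    Magnitude is one of 0.1 .. 1.0; bin 1.0 holds monoallelic expression,
    bin 0.1 balanced biallelic expression.
    """

    magnitude: float
    sign: Literal["+", "-"]

    @property
    def value(self) -> float:
        return self.magnitude if self.sign == "+" else -self.magnitude

    def __str__(self) -> str:
        return f"{self.sign}{self.magnitude:.1f}"


@dataclass
class OriginBlock:
    """Maximal run of consecutive same-origin variant calls on one chromosome.

    ``start``/``end`` are 0-based half-open (end = last call position + 1).
    """

    chrom: str
    start: int
    end: int
    origin: Parent
    n_variants: int


@dataclass
class FilterCounters:
    """Bookkeeping for sites excluded along the way."""

    missing_parent_gt: int = 0
    not_alternative: int = 0
    missing_hybrid_gt: int = 0
    multiallelic: int = 0
    zero_depth: int = 0


def _parse_gt(value) -> Genotype:
    if value is None:
        return None
    alleles = tuple(a for a in value if a is not None)
    if len(alleles) != 2 or any(a not in (0, 1) for a in alleles):
        return None
    return tuple(sorted(alleles))  # unphased: 1/0 == 0/1


def read_trio_vcf(
    path: str | Path,
    sire: str = "sire",
    dam: str = "dam",
    hybrid: str = "hybrid",
    reference_species: Literal["A", "B"] = "A",
    counters: FilterCounters | None = None,
) -> Iterator[TrioSite]:
    """Stream biallelic sites from a three-sample VCF with GT and AD fields.

    Multiallelic records are skipped (and counted).  Impact is taken from
    an ``IMPACT`` INFO field or the first ANN annotation if present.
    """
    counters = counters if counters is not None else FilterCounters()
    with pysam.VariantFile(str(path)) as vcf:
        for sample in (sire, dam, hybrid):
            if sample not in vcf.header.samples:
                raise ValueError(f"sample {sample!r} not in VCF {path}")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                counters.multiallelic += 1
                continue
            ad = rec.samples[hybrid].get("AD")
            ad = (0, 0) if ad is None or ad[0] is None else (int(ad[0]), int(ad[1]))
            impact = rec.info.get("IMPACT")
            if impact is None and "ANN" in rec.info:
                ann = rec.info["ANN"]
                first = ann[0] if isinstance(ann, tuple) else ann
                parts = str(first).split("|")
                impact = parts[2] if len(parts) > 2 else None
            yield TrioSite(
                chrom=rec.chrom,
                pos=rec.pos,
                ref_allele=rec.ref,
                alt_allele=rec.alts[0],
                gt_sire=_parse_gt(rec.samples[sire].get("GT")),
                gt_dam=_parse_gt(rec.samples[dam].get("GT")),
                gt_hybrid=_parse_gt(rec.samples[hybrid].get("GT")),
                ad_hybrid=ad,
                reference_species=reference_species,
                impact=str(impact) if impact is not None else None,
            )


def select_alt_monoallelic(
    sites: Iterable[TrioSite], counters: FilterCounters | None = None
) -> Iterator[TrioSite]:
    """Keep sites where one parent is 0/0 and the other 1/1.

    The retained site's ``alt_parent`` records which parent carries the
    homozygous-alternate genotype.  Sites with a missing parental genotype
    or any other genotype combination are dropped (counted separately).
    """
    counters = counters if counters is not None else FilterCounters()
    for s in sites:
        if s.gt_sire is None or s.gt_dam is None:
            counters.missing_parent_gt += 1
            continue
        if s.gt_sire == (0, 0) and s.gt_dam == (1, 1):
            s.alt_parent = "dam"
            yield s
        elif s.gt_sire == (1, 1) and s.gt_dam == (0, 0):
            s.alt_parent = "sire"
            yield s
        else:
            counters.not_alternative += 1


def classify_hybrid_zygosity(site: TrioSite) -> Literal["mono", "biallelic"] | None:
    """Biallelic iff the hybrid's genotype call is heterozygous.

    Returns ``None`` (caller counts the exclusion) when the hybrid genotype
    is missing.
    """
    if site.gt_hybrid is None:
        return None
    return "biallelic" if site.gt_hybrid == (0, 1) else "mono"


def allelic_depth_ratio(ad: tuple[int, int]) -> float:
    """Normalized allelic imbalance |ref - alt| / (ref + alt) in [0, 1].

    1 means every read supports one allele (monoallelic expression); 0
    means perfectly balanced biallelic expression.  Zero total depth is an
    error — such sites must be filtered out upstream.
    """
    ref, alt = ad
    if ref < 0 or alt < 0:
        raise ValueError(f"negative allelic depth {ad}")
    total = ref + alt
    if total == 0:
        raise ValueError("zero total depth; site should have been pre-filtered")
    return abs(ref - alt) / total


def signed_bin(
    ratio: float,
    alt_parent: Parent,
    sign_convention: Literal["results", "figure"] = "results",
) -> SignedBin:
    """Bin a depth ratio into a 0.1-wide signed bin.

    Magnitude is ``ceil(ratio * 10) / 10`` with a floor of 0.1, so a ratio
    of exactly 0 falls into the +/-0.1 bin (which therefore holds only
    heterozygous calls) and a boundary value such as 0.2 stays in bin 0.2.

    The sign records which parent is homozygous for the alternate allele.
    Under the default "results" convention the dam's (the sheep's) 1/1
    sites are positive and the sire's negative; the "figure" convention is
    the exact mirror.  Both exist because the two written descriptions of
    this histogram assign the positive sign to opposite parents; neither
    can be declared correct, so the choice is explicit.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"ratio {ratio} outside [0, 1]")
    magnitude = max(0.1, math.ceil(ratio * 10 - 1e-9) / 10)
    dam_is_alt = alt_parent == "dam"
    positive = dam_is_alt if sign_convention == "results" else not dam_is_alt
    return SignedBin(round(magnitude, 1), "+" if positive else "-")


def bin_histogram(bins: Iterable[SignedBin]) -> dict[float, int]:
    """Histogram over the 20 signed bins -1.0 .. -0.1, +0.1 .. +1.0."""
    hist = {round(s * k / 10, 1): 0 for s in (-1, 1) for k in range(1, 11)}
    for b in bins:
        hist[round(b.value, 1)] += 1
    return hist


def origin_from_variant(site: TrioSite) -> Parent | None:
    """Parental origin of the dominantly expressed allele at a homozygous site.

    Applies only where the parents are alternatively homozygous and the
    hybrid's call is homozygous too: a homozygous-*reference* hybrid call
    expresses the allele of the parent whose species matches the reference
    genome, a homozygous-*alternate* call the opposite parent's.
    Heterozygous or missing hybrid calls return ``None`` (not applicable).
    """
    if site.gt_hybrid is None or site.gt_hybrid == (0, 1):
        return None
    ref_parent: Parent = "dam" if site.reference_species == "A" else "sire"
    other: Parent = "sire" if ref_parent == "dam" else "dam"
    return ref_parent if site.gt_hybrid == (0, 0) else other


def build_blocks(
    origin_calls: Iterable[tuple[str, int, Parent]],
    min_variants: int = 1,
) -> list[OriginBlock]:
    """Merge consecutive same-origin calls into maximal chromosome blocks.

    ``origin_calls`` are (chrom, 1-based position, origin) sorted by
    chromosome then position; unsorted input is an error.  Emitted block
    intervals are 0-based half-open spanning the first to last call of the
    run.  Blocks with fewer than ``min_variants`` calls are dropped after
    merging (default keeps all).
    """
    blocks: list[OriginBlock] = []
    cur: OriginBlock | None = None
    prev: tuple[str, int] | None = None
    for chrom, pos, origin in origin_calls:
        if prev is not None and prev[0] == chrom and pos < prev[1]:
            raise ValueError(f"origin calls not sorted at {chrom}:{pos}")
        prev = (chrom, pos)
        start0 = pos - 1
        if cur is not None and cur.chrom == chrom and cur.origin == origin:
            cur.end = start0 + 1
            cur.n_variants += 1
        else:
            if cur is not None:
                blocks.append(cur)
            cur = OriginBlock(chrom, start0, start0 + 1, origin, 1)
    if cur is not None:
        blocks.append(cur)
    return [b for b in blocks if b.n_variants >= min_variants]


def block_bp_totals(blocks: Iterable[OriginBlock]) -> dict[str, dict[str, int]]:
    """Per-chromosome and per-origin bp spans of the origin blocks."""
    totals: dict[str, dict[str, int]] = {}
    for b in blocks:
        d = totals.setdefault(b.chrom, {"sire": 0, "dam": 0})
        d[b.origin] += b.end - b.start
    return totals


def write_blocks_bed(blocks: Iterable[OriginBlock], path: str | Path) -> None:
    """BED: name = origin, score = number of supporting variant calls."""
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.origin}\t{b.n_variants}\t.\n")


def impact_fractions(
    sites: Iterable[TrioSite],
) -> dict[str, dict[str, float]]:
    """Percent of sites per impact class, separately for mono/biallelic sites.

    Sites lacking an impact annotation or a hybrid genotype are tallied
    under ``"unannotated"``/``"unclassified"`` and excluded from the
    percentages.  Within each partition the class percentages sum to 100
    up to rounding (half-up, one decimal).
    """
    tallies: dict[str, Counter] = {"mono": Counter(), "biallelic": Counter()}
    excluded = Counter()
    for s in sites:
        zyg = classify_hybrid_zygosity(s)
        if zyg is None:
            excluded["unclassified"] += 1
            continue
        if s.impact is None:
            excluded["unannotated"] += 1
            continue
        tallies[zyg][s.impact] += 1
    out: dict[str, dict[str, float]] = {}
    for part, counter in tallies.items():
        total = sum(counter.values())
        out[part] = {
            cls: (round_half_up(100.0 * counter.get(cls, 0) / total, 1) if total else 0.0)
            for cls in IMPACT_CLASSES
        }
        out[part]["n_sites"] = total
    out["excluded"] = dict(excluded)
    return out
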