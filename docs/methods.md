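# Methods

## The problem

A hybrid animal inherits one genome copy from each of two closely related
species. RNA-seq reads from the hybrid can in principle be traced to the
parental genome they were transcribed from, because the two genomes differ
at diagnostic positions. `hybridscope` implements the two complementary
routes to parent-of-origin conclusions: (i) competitive read mapping
against both parental references with score-based arbitration, and (ii)
allele-specific expression at trio variant sites where the parents are
alternatively homozygous. Both routes feed an imprinting cross-reference:
genes expressed from exactly one parental genome are candidates for
genomic imprinting, and their observed origin can be compared with
database reports.

## Read arbitration

Each read has at most one primary alignment per reference. The score of an
alignment is the triple

    (matching_bases, indel_events, clipped_bases)

compared lexicographically: more matching bases wins; at equality fewer
indel events wins; at equality fewer clipped bases wins; full equality is
a tie and the read is discarded as carrying no discriminating signal.

Choices that the score definition leaves open, and how they are resolved:

* **Matching bases** = Σ lengths of `M` and `=` CIGAR operations, with `X`
  excluded. Aligner output in the wild conflates match and mismatch as `M`
  (the "legacy-M" dialect); where an aligner emits the extended dialect,
  counting `X` as matching would invert its meaning, so it is excluded.
* **Indels are counted as events** (number of `I`/`D` operations), not
  bases. Both readings are defensible; event counting is the default and
  `indel_metric="bases"` selects length summing.
* **Fewer clipped bases wins.** Clipping removes evidence; the
  less-clipped alignment is the better-supported one. This direction is
  fixed, not configurable.
* Reads mapped on one side only are assigned to that side without a score
  comparison; only primary alignments participate (secondary and
  supplementary records are skipped and counted).
* Reported percentages are rounded half-up to one decimal, matching how
  such tables are conventionally printed.

In the noise-free extended-dialect regime the procedure is exact, and the
test suite proves it: a read spanning ≥ 1 diagnostic substitution site is
always assigned to its true genome (the mismatch costs the wrong genome
exactly its length in matching bases), and a read spanning no diagnostic
site ties and is discarded.

## Expression comparison

FPKM is computed as `count × 10⁹ / (length × total_mapped)` from reads
assigned per transcript; transcript assembly is deliberately out of scope
because every downstream comparison operates on FPKM-thresholded *gene
symbol sets*, not on transcript structure. The expression filter keeps
FPKM ≥ 1: the threshold's boundary is genuinely ambiguous (both "neglect
< 1" and "keep > 1" describe it), and the inclusive reading is the
default with `strict_greater=True` to flip. Uncharacterized genes are
removed by a configurable pattern (default: `^LOC\d+$` or a symbol
containing "uncharacterized") since such symbols carry no cross-species
information. Top-N ranking breaks FPKM ties lexicographically so results
are deterministic. All symbol comparisons are case-insensitive.

The 4-set intersection counts are computed per gene from its membership
bitmask; regions are disjoint by construction and sum to the union size
(property-tested against a brute-force enumeration oracle).

## Trio allele analysis

Only biallelic sites are used. A site is retained when one parent is
genotyped 0/0 and the other 1/1 — then the hybrid necessarily inherited
one copy of each allele, and its allelic depths AD = (ref, alt) measure
allele-specific expression. The imbalance statistic is

    ratio = |ref − alt| / (ref + alt)  ∈ [0, 1]

— the unique simple statistic that is 1 exactly when all reads support
one allele (monoallelic expression) and 0 exactly when the depths are
balanced. Ratios are binned with magnitude `ceil(ratio × 10)/10`, floored
at 0.1, so ratio 0 lands in the ±0.1 bin (which therefore holds only
heterozygous calls) and boundary values such as 0.2 stay in their own
bin. The bin's sign records which parent carries the 1/1 genotype; the
default ("results") convention signs the dam's sites positive, and the
"figure" convention is its mirror — both exist because the two written
descriptions of this histogram contradict each other on the sign, and
neither can be declared correct.

Parental origin at a site uses the homozygous-hybrid rule: where the
parents are alternatively homozygous and the hybrid's call is also
homozygous, a homozygous-*reference* call expresses the allele of the
parent whose species matches the reference genome, and a homozygous-
*alternate* call the opposite parent's. Consecutive same-origin calls
(sorted by chromosome, position) merge into maximal blocks spanning first
to last call (0-based half-open, end = last position + 1); `min_variants`
can drop weakly supported blocks but defaults to 1, since how isolated
discordant calls inside long runs should be handled is not specified by
any authority and dropping data silently is worse. Multiallelic records
and sites with missing genotypes are excluded with counters. VCF
positions are 1-based; all emitted interval files are 0-based half-open
BED.

Variant-impact tabulation consumes impact labels (HIGH / MODERATE / LOW /
MODIFIER, snpEff-style) from an `IMPACT` INFO field or ANN annotation; it
never computes them. Percentages are per zygosity partition and sum to
100 up to rounding.

## Imprinting cross-reference

The database is a TSV of gene → reported expressed allele (paternal,
maternal, or biallelic/conflicting), with the reporting species carried
as annotation only. Classification compares poles: concordant (equal),
discordant (opposite), unresolvable (biallelic/conflicting — evidence for
neither pole, so it must not count as discordant). "Predicted" database
entries are treated identically to experimental ones. The packaged
14-gene table for the buck-ewe system classifies as 4 concordant, 9
discordant, 1 unresolvable.

## Synthetic data

The generator emulates the study design so every stage is testable
against known truth:

* **Genomes.** Genome A is uniform random; genome B is derived by
  substitutions at rate `divergence` (default 0.02 — a placeholder for
  the unquantified sheep–goat transcriptome divergence, of the right
  order for congeneric ruminants) and 1–3 bp indels at rate
  `indel_divergence` (default 0.002). Divergence above 0.2 is rejected:
  the A↔B coordinate map would be ambiguous. Every difference is recorded
  as a diagnostic site together with strictly monotone coordinate maps.
* **Transcripts.** Placed on genome A (default 40, lengths 500–2000 bp),
  log-normal expression weights (heavy-tailed like real FPKM
  distributions), parent-of-origin drawn from an (A-only, B-only,
  biparental) mixture, defaults 0.3/0.3/0.4.
* **Reads.** Drawn from transcripts proportionally to expression ×
  length; substitution errors at 0.005/bp and 1–3 bp indel errors at
  0.002/bp — indel-heavy relative to short-read platforms, reflecting
  semiconductor-sequencing error profiles; constant base quality
  (no quality realism). Reads longer than their transcript are truncated.
* **Alignments.** Constructed analytically from per-base provenance: the
  CIGAR against the true genome reflects only sequencing errors; against
  the other genome it additionally reflects diagnostic sites, composed
  through the coordinate map. No aligner runs. The extended dialect
  distinguishes `=`/`X`; the legacy-M dialect collapses them to `M` and
  soft-clips a read end while its next 10 bases contain ≥ 2 mismatches
  (extending through the last of them), mimicking end-trimming aligners.
  Reads whose interval is deleted from the other genome are written as
  unmapped there.
* **Trio VCFs.** Genome A stands for the dam's species reference and B
  for the sire's, so at every diagnostic substitution site the parents
  are truly alternatively homozygous. A fraction `frac_monoallelic_sites`
  (default 0.3) of sites is emitted with those planted genotypes; the
  rest get a heterozygous dam call so the downstream filter has work to
  do. The hybrid's planted expressed-allele fraction is 0.5 at biallelic
  sites — a fraction `frac_hybrid_biallelic` (default 0.74, the middle of
  the 72–76% study regime) of planted sites — and 0 or 1 (expressed
  parent drawn fairly) at monoallelic ones; depth is Poisson
  (`mean_depth`, default 50), allelic depths binomial, and the genotype
  call uses a minor-fraction < 0.1 homozygosity threshold. Zero-depth
  sites are omitted. Planted impact classes are MODIFIER-dominated with
  MODERATE/LOW elevated at biallelic sites, mirroring the compensation
  effect under study.

What the simulation does **not** model: splicing/isoforms, empirical
platform error profiles, quality-score variation, reference bias in
mapping, genotyping error beyond the threshold rule, or real gene
symbols. Passing tests therefore demonstrate the *logic* of the pipeline
(scoring, filtering, binning, merging, bookkeeping) and its exactness in
decodable regimes, not performance on real Ion Torrent data. Two known
one-sided simplifications: parents are never heterozygous at emitted
sites, and versus a given reference the alternate allele always belongs
to the other species' parent (individual-versus-own-reference divergence
is not simulated), so a single VCF's signed histogram is one-sided; both
signs appear across the two references, and sign antisymmetry is tested
by swapping the parent columns.

## Determinism and numerics

All randomness flows from one `numpy.random.Generator` seeded from
`SimConfig.seed`; identical configs give byte-identical FASTA / FASTQ /
SAM / VCF / GFF3 / TSV outputs, and a fixed-seed pipeline run reproduces
its report JSON exactly. Printed percentages use decimal half-up
rounding (one decimal for assignment and impact tables, two for pathway
tables). The bin-edge epsilon in `ceil(ratio × 10 − 1e-9)` keeps exact
multiples of 0.1 in their own bin despite floating-point representation.

## Problem sizes

The shipped tests run the property suites at 10⁴ random score pairs for
the comparator oracle, 10⁵ simulated reads for partition conservation
and swap symmetry, and ~10⁴ trio sites at depth ~ Poisson(50) for the
planted biallelic-fraction recovery (f = 0.72 and 0.76, 3-binomial-SD
band) — sizes at which the binomial checks are sharp while the whole
suite stays interactive.

## Known limitations

* The FPKM stand-in counts reads by leftmost aligned position within
  non-overlapping transcript intervals; it is not a transcript assembler
  and does not handle overlapping or spliced annotation.
* `pair_records` holds one side's primary records in memory; at the
  intended desk scale (≤ 10⁶ reads) this is simpler and faster than
  name-sorting, but it is not a streaming implementation for full-size
  runs.
* The legacy-M end-clipping rule is one concrete formalisation of
  "aligners trim mismatch-dense ends"; real aligners differ in detail.
* Block intervals span variant calls only; they do not extrapolate into
  the flanking sequence between the last call and the next block.
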