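"""Synthetic data with known ground truth for the hybrid-transcriptome pipeline.

Emulates the study design end to end: two closely related parental genomes
(configurable per-base divergence), transcripts with FPKM-like expression
levels, hybrid reads of mixed parental origin with an indel-prone sequencing
error model, alignments of every read against *both* genomes, and trio
variant calls (sire, dam, hybrid) with planted alternatively-monoallelic
sites and binomially sampled allelic depths.

Alignments are constructed analytically from the simulation truth rather
than by running an aligner: each read carries its per-base provenance, so
the CIGAR against the true genome reflects only sequencing errors while the
CIGAR against the other genome additionally reflects the diagnostic sites
the read spans.  This makes CIGAR content exactly checkable, which the
arbitration tests exploit.

Two CIGAR dialects are written.  The "extended" dialect distinguishes
``=``/``X`` so that match counts are mismatch-aware; the "legacy-M" dialect
collapses aligned bases to ``M`` (as STAR/TopHat-era aligners do) and
soft-clips mismatch-dense read ends, reproducing the operating regime of
real pipelines whose scorer sees only ``M`` lengths.

All randomness flows from a single :class:`numpy.random.Generator` seeded
from ``SimConfig.seed``; identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "SimConfig",
    "DiagnosticSite",
    "Genomes",
    "Transcript",
    "ReadRecord",
    "TruthTable",
    "generate_parental_genomes",
    "generate_transcripts",
    "simulate_hybrid_reads",
    "write_synthetic_alignments",
    "simulate_trio_vcf",
    "simulate_all",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")

MAX_DIVERGENCE = 0.2  # above this the A<->B coordinate map is ambiguous


@dataclass
class SimConfig:
    """All knobs of the simulator; one seed drives every random draw.

    Rates are per base and must lie in [0, 1].  Defaults describe the study
    regime: two genomes ~2% diverged (a stand-in for the unquantified
    sheep-goat transcriptome distance), short single-end reads with an
    indel-prone error profile, and trio variant calls at ~50x depth in which
    roughly three quarters of alternatively-monoallelic parental sites are
    expressed biallelically by the hybrid.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 50_000
    divergence: float = 0.02
    indel_divergence: float = 0.002
    n_transcripts: int = 40
    transcript_length_range: tuple[int, int] = (500, 2000)
    read_length: int = 100
    n_reads: int = 5000
    seq_error_sub: float = 0.005
    seq_error_indel: float = 0.002
    frac_monoallelic_sites: float = 0.3
    mean_depth: float = 50.0
    # transcript parent-of-origin mixture: remaining fraction is biparental (50/50)
    frac_transcripts_a: float = 0.3
    frac_transcripts_b: float = 0.3
    # fraction of planted alternatively-monoallelic sites at which the hybrid
    # expresses both alleles (study regime: 72-76%)
    frac_hybrid_biallelic: float = 0.74
    frac_uncharacterized_genes: float = 0.1

    def __post_init__(self) -> None:
        rates = {
            "divergence": self.divergence,
            "indel_divergence": self.indel_divergence,
            "seq_error_sub": self.seq_error_sub,
            "seq_error_indel": self.seq_error_indel,
            "frac_monoallelic_sites": self.frac_monoallelic_sites,
            "frac_transcripts_a": self.frac_transcripts_a,
            "frac_transcripts_b": self.frac_transcripts_b,
            "frac_hybrid_biallelic": self.frac_hybrid_biallelic,
            "frac_uncharacterized_genes": self.frac_uncharacterized_genes,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.divergence > MAX_DIVERGENCE:
            raise ValueError(
                f"divergence {self.divergence} > {MAX_DIVERGENCE}: coordinate "
                "mapping between the genomes would be ambiguous"
            )
        for name in ("n_chromosomes", "chrom_length", "n_transcripts", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        lo, hi = self.transcript_length_range
        if not (0 < lo <= hi):
            raise ValueError("transcript_length_range must be an increasing positive pair")
        if self.frac_transcripts_a + self.frac_transcripts_b > 1.0:
            raise ValueError("transcript origin fractions sum to > 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["transcript_length_range"] = list(self.transcript_length_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "transcript_length_range" in d:
            d["transcript_length_range"] = tuple(d["transcript_length_range"])
        return cls(**d)


@dataclass
class DiagnosticSite:
    """One position at which the parental genomes differ.

    ``pos_a``/``pos_b`` are 0-based coordinates in the respective genome.
    For ``sub`` sites both coordinates are real; for indel sites the
    coordinate on the side lacking the bases points at the flanking base.
    """

    chrom: str
    pos_a: int
    pos_b: int
    kind: Literal["sub", "ins", "del"]
    base_a: str
    base_b: str


@dataclass
class Genomes:
    """The two parental genomes plus coordinate maps between them.

    ``a2b[chrom][i]`` is the B-coordinate aligned to A-position ``i`` or -1
    if that base was deleted in B; ``b2a`` is the inverse.  Both maps are
    strictly increasing over their mapped entries.
    """

    seqs_a: dict[str, str]
    seqs_b: dict[str, str]
    a2b: dict[str, np.ndarray]
    b2a: dict[str, np.ndarray]
    diagnostic_sites: list[DiagnosticSite]

    def seq(self, origin: str) -> dict[str, str]:
        return self.seqs_a if origin == "A" else self.seqs_b

    def posmap(self, src: str) -> dict[str, np.ndarray]:
        """Coordinate map from ``src`` genome space into the other genome."""
        return self.a2b if src == "A" else self.b2a


def generate_parental_genomes(cfg: SimConfig, rng: np.random.Generator | None = None) -> Genomes:
    """Generate genome A at random and derive genome B by mutation.

    Substitutions occur at rate ``cfg.divergence`` and 1-3 bp indels at rate
    ``cfg.indel_divergence``; every difference is recorded as a
    :class:`DiagnosticSite` together with the A<->B coordinate maps.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    seqs_a: dict[str, str] = {}
    seqs_b: dict[str, str] = {}
    a2b: dict[str, np.ndarray] = {}
    b2a: dict[str, np.ndarray] = {}
    sites: list[DiagnosticSite] = []
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        n = cfg.chrom_length
        seq_a = rng.choice(BASES, size=n)
        # one event draw per A position: 0 = copy, 1 = substitute, 2 = indel
        p_ind = cfg.indel_divergence
        p_sub = cfg.divergence
        events = rng.choice(3, size=n, p=[1.0 - p_sub - p_ind, p_sub, p_ind])
        map_ab = np.full(n, -1, dtype=np.int64)
        b_chars: list[bytes] = []
        inv: list[int] = []  # b2a entries, built alongside b_chars
        i = 0
        while i < n:
            ev = events[i]
            if ev == 2:  # indel: insertion into B or deletion from A, 1-3 bp
                length = int(rng.integers(1, 4))
                if rng.random() < 0.5:  # insertion in B before A[i]
                    ins = rng.choice(BASES, size=length)
                    for b in ins:
                        b_chars.append(b)
                        inv.append(-1)
                    sites.append(
                        DiagnosticSite(chrom, i, len(b_chars) - length, "ins", "",
                                       b"".join(ins).decode())
                    )
                    # A[i] itself copies unchanged after the insertion
                    map_ab[i] = len(b_chars)
                    b_chars.append(seq_a[i])
                    inv.append(i)
                    i += 1
                else:  # deletion of A[i:i+length] from B
                    length = min(length, n - i)
                    sites.append(
                        DiagnosticSite(chrom, i, len(b_chars), "del",
                                       b"".join(seq_a[i : i + length]).decode(), "")
                    )
                    i += length
                continue
            if ev == 1:  # substitution
                old = seq_a[i]
                choices = BASES[BASES != old]
                new = choices[rng.integers(0, 3)]
                map_ab[i] = len(b_chars)
                b_chars.append(new)
                inv.append(i)
                sites.append(
                    DiagnosticSite(chrom, i, map_ab[i], "sub", old.decode(), new.decode())
                )
            else:
                map_ab[i] = len(b_chars)
                b_chars.append(seq_a[i])
                inv.append(i)
            i += 1
        seqs_a[chrom] = b"".join(seq_a).decode()
        seqs_b[chrom] = b"".join(b_chars).decode()
        a2b[chrom] = map_ab
        b2a[chrom] = np.asarray(inv, dtype=np.int64)
    return Genomes(seqs_a, seqs_b, a2b, b2a, sites)


@dataclass
class Transcript:
    transcript_id: str
    gene_symbol: str
    chrom: str
    start_a: int  # 0-based half-open, A space
    end_a: int
    start_b: int  # -1 if the interval has no mapped base in B
    end_b: int
    origin: Literal["A", "B", "both"]
    expression: float  # relative abundance weight (FPKM-like truth)

    def interval(self, origin: str) -> tuple[int, int]:
        return (self.start_a, self.end_a) if origin == "A" else (self.start_b, self.end_b)


@dataclass
class ReadRecord:
    """A simulated read plus its per-base provenance.

    ``src_pos`` holds, for each read base, the 0-based coordinate of the
    origin-genome base it copies, or -1 for a base inserted by a sequencing
    error; deletions appear as jumps between consecutive coordinates.  This
    is sufficient to reconstruct the alignment against either genome.
    """

    read_id: str
    origin: Literal["A", "B"]
    chrom: str
    start: int  # 0-based, origin-genome space
    end: int
    transcript_id: str
    bases: str
    src_pos: np.ndarray


@dataclass
class TruthTable:
    """Ground truth for every emitted read, transcript, and variant site."""

    reads: dict[str, ReadRecord] = field(default_factory=dict)
    transcripts: dict[str, Transcript] = field(default_factory=dict)
    sites: dict[str, dict] = field(default_factory=dict)

    def write_reads_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\torigin\tchrom\tstart\tend\ttranscript_id\n")
            for r in self.reads.values():
                fh.write(f"{r.read_id}\t{r.origin}\t{r.chrom}\t{r.start}\t{r.end}\t{r.transcript_id}\n")

    def write_transcripts_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("transcript_id\tgene_symbol\tchrom\tstart_a\tend_a\torigin\texpression\n")
            for t in self.transcripts.values():
                fh.write(
                    f"{t.transcript_id}\t{t.gene_symbol}\t{t.chrom}\t{t.start_a}\t{t.end_a}"
                    f"\t{t.origin}\t{t.expression:.6g}\n"
                )


def generate_transcripts(
    cfg: SimConfig, genomes: Genomes, rng: np.random.Generator
) -> list[Transcript]:
    """Place transcripts on genome A and map their intervals into B space.

    Expression weights are log-normal (heavy-tailed, as real FPKM
    distributions are); a configurable fraction of genes receive
    uncharacterized ``LOC``-style symbols so that symbol filtering is
    exercised downstream.  Parent-of-origin is drawn per transcript from
    the (A-only, B-only, biparental) mixture in the config.
    """
    chroms = sorted(genomes.seqs_a)
    transcripts: list[Transcript] = []
    lo, hi = cfg.transcript_length_range
    p_a, p_b = cfg.frac_transcripts_a, cfg.frac_transcripts_b
    for k in range(cfg.n_transcripts):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(lo, hi + 1))
        length = min(length, cfg.chrom_length)
        start = int(rng.integers(0, cfg.chrom_length - length + 1))
        end = start + length
        m = genomes.a2b[chrom][start:end]
        mapped = m[m >= 0]
        if mapped.size:
            start_b, end_b = int(mapped[0]), int(mapped[-1]) + 1
        else:
            start_b, end_b = -1, -1
        u = rng.random()
        origin = "A" if u < p_a else ("B" if u < p_a + p_b else "both")
        expr = float(rng.lognormal(mean=1.0, sigma=1.2))
        if rng.random() < cfg.frac_uncharacterized_genes:
            symbol = f"LOC10{k:04d}"
        else:
            symbol = f"GENE{k:04d}"
        transcripts.append(
            Transcript(f"T{k:04d}", symbol, chrom, start, end, start_b, end_b, origin, expr)
        )
    return transcripts


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_gff3(transcripts: list[Transcript], path: str | Path) -> None:
    """GFF3 with one ``transcript`` feature per transcript (1-based, closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            fh.write(
                f"{t.chrom}\thybridscope\ttranscript\t{t.start_a + 1}\t{t.end_a}\t.\t+\t.\t"
                f"ID={t.transcript_id};gene={t.gene_symbol}\n"
            )


def simulate_hybrid_reads(
    cfg: SimConfig,
    genomes: Genomes,
    transcripts: list[Transcript],
    truth: TruthTable,
    rng: np.random.Generator,
) -> list[ReadRecord]:
    """Draw reads from transcripts, apply sequencing errors, record truth.

    Transcript choice is proportional to expression x length (fragments,
    not molecules); the source genome is the transcript's origin, or a fair
    coin for biparental transcripts.  Substitution errors change single
    bases; indel errors insert or delete 1-3 bp.  A read longer than its
    transcript is truncated to the transcript.
    """
    truth.transcripts = {t.transcript_id: t for t in transcripts}
    reads: list[ReadRecord] = []
    if cfg.n_reads == 0:
        return reads
    usable = [t for t in transcripts]
    weights = np.array([t.expression * (t.end_a - t.start_a) for t in usable], dtype=float)
    weights /= weights.sum()
    t_idx = rng.choice(len(usable), size=cfg.n_reads, p=weights)
    for i in range(cfg.n_reads):
        t = usable[int(t_idx[i])]
        if t.origin == "both":
            origin = "A" if rng.random() < 0.5 else "B"
        else:
            origin = t.origin
        if origin == "B" and t.start_b < 0:
            origin = "A"  # interval deleted in B; fall back to the extant copy
        t_start, t_end = t.interval(origin)
        t_len = t_end - t_start
        rlen = min(cfg.read_length, t_len)
        start = t_start + int(rng.integers(0, t_len - rlen + 1))
        genome_seq = genomes.seq(origin)[t.chrom]
        src = np.arange(start, start + rlen, dtype=np.int64)
        bases = list(genome_seq[start : start + rlen])
        # substitution errors
        n_sub = rng.binomial(rlen, cfg.seq_error_sub)
        if n_sub:
            for p in sorted(rng.choice(rlen, size=n_sub, replace=False)):
                old = bases[p]
                alts = [b for b in "ACGT" if b != old]
                bases[p] = alts[int(rng.integers(0, 3))]
        # indel errors (1-3 bp each)
        n_ind = rng.binomial(rlen, cfg.seq_error_indel)
        src = src.tolist()
        for _ in range(n_ind):
            if len(bases) < 4:
                break
            length = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # insertion into the read
                at = int(rng.integers(1, len(bases)))
                ins = [b.decode() for b in rng.choice(BASES, size=length)]
                bases[at:at] = ins
                src[at:at] = [-1] * length
            else:  # deletion from the read (interior, keeps ends anchored)
                at = int(rng.integers(1, max(2, len(bases) - length)))
                del bases[at : at + length]
                del src[at : at + length]
        src = np.asarray(src, dtype=np.int64)
        real = src[src >= 0]
        end = int(real[-1]) + 1 if real.size else start
        rec = ReadRecord(
            read_id=f"read{i:06d}",
            origin=origin,
            chrom=t.chrom,
            start=int(real[0]) if real.size else start,
            end=end,
            transcript_id=t.transcript_id,
            bases="".join(bases),
            src_pos=src,
        )
        reads.append(rec)
        truth.reads[rec.read_id] = rec
    return reads


def write_fastq(reads: list[ReadRecord], path: str | Path, qual_char: str = "I") -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{qual_char * len(r.bases)}\n")


# ---------------------------------------------------------------------------
# analytic alignment construction


def _merge_ops(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, ln in ops:
        if ln == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + ln)
        else:
            out.append((op, ln))
    return out


def align_read(
    read: ReadRecord,
    genome_seq: str,
    posmap: np.ndarray | None,
) -> tuple[int, list[tuple[str, int]]] | None:
    """Reconstruct the extended-dialect alignment of a read against a genome.

    ``posmap`` maps the read's origin-genome coordinates into the target
    genome (identity if ``None``, i.e. the target is the origin genome).
    Returns ``(pos, ops)`` with ops over {=, X, I, D, S} or ``None`` if no
    read base has a counterpart in the target (unmapped there).

    Leading/trailing insertions are emitted as soft clips: an alignment
    cannot begin or end with ``I``.
    """
    cols: list[tuple[str, int]] = []  # per read base: (kind, target_pos or -1)
    for base, p in zip(read.bases, read.src_pos):
        if p < 0:
            cols.append(("I", -1))
            continue
        q = int(posmap[p]) if posmap is not None else int(p)
        if q < 0:
            cols.append(("I", -1))
        else:
            cols.append(("=" if genome_seq[q] == base else "X", q))
    mapped = [q for _, q in cols if q >= 0]
    if not mapped:
        return None
    # soft-clip unaligned run-ins at the ends
    first = next(i for i, (k, q) in enumerate(cols) if q >= 0)
    last = len(cols) - 1 - next(i for i, (k, q) in enumerate(reversed(cols)) if q >= 0)
    ops: list[tuple[str, int]] = []
    if first:
        ops.append(("S", first))
    prev_q: int | None = None
    for k, q in cols[first : last + 1]:
        if q >= 0:
            if prev_q is not None and q > prev_q + 1:
                ops.append(("D", q - prev_q - 1))
            prev_q = q
        ops.append((k, 1))
    if last < len(cols) - 1:
        ops.append(("S", len(cols) - 1 - last))
    return mapped[0], _merge_ops(ops)


def legacy_m(
    pos: int,
    ops: list[tuple[str, int]],
    clip_window: int = 10,
    clip_min_mismatches: int = 2,
) -> tuple[int, list[tuple[str, int]]]:
    """Convert an extended-dialect alignment to the legacy-M dialect.

    ``=``/``X`` collapse to ``M``; then mismatch-dense read ends are
    soft-clipped: from each end, while the next ``clip_window`` read bases
    contain at least ``clip_min_mismatches`` mismatches, the clip is
    extended through the last of them.  This mimics aligners that trim
    low-identity ends instead of reporting them aligned.
    """
    # flatten to per-read-base columns; record deletions between columns
    cols: list[str] = []
    dels: dict[int, int] = {}  # deletion of length v sits before read base k
    for op, ln in ops:
        if op == "D":
            dels[len(cols)] = dels.get(len(cols), 0) + ln
        elif op in ("=", "X", "I", "S"):
            cols.extend(op * ln)
    n = len(cols)
    mism = [i for i, k in enumerate(cols) if k == "X"]

    def grow(indices: list[int]) -> int:
        clip = 0
        while True:
            window = [i for i in indices if clip <= i < clip + clip_window]
            if len(window) >= clip_min_mismatches:
                clip = window[-1] + 1
            else:
                return clip

    clip_l = grow(mism)
    clip_r = grow([n - 1 - i for i in reversed(mism)])
    if clip_l + clip_r >= n:  # degenerate: everything clipped; keep as-is
        clip_l = clip_r = 0
    # reference shift: aligned columns (and deletions) inside the left clip
    shift = sum(1 for k in cols[:clip_l] if k in "=X")
    shift += sum(v for k, v in dels.items() if k <= clip_l)
    out: list[tuple[str, int]] = []
    if clip_l:
        out.append(("S", clip_l))
    for i in range(clip_l, n - clip_r):
        if i in dels and i != clip_l:
            out.append(("D", dels[i]))
        k = cols[i]
        if k in ("=", "X"):
            out.append(("M", 1))
        elif k == "I":
            out.append(("I", 1))
        else:
            out.append(("S", 1))
    if clip_r:
        out.append(("S", clip_r))
    return pos + shift, _merge_ops(out)


def cigar_string(ops: list[tuple[str, int]]) -> str:
    return "".join(f"{ln}{op}" for op, ln in ops)


def write_synthetic_alignments(
    reads: list[ReadRecord],
    genomes: Genomes,
    out_sam_a: str | Path,
    out_sam_b: str | Path,
    dialect: Literal["extended", "legacy-M"] = "extended",
    qual_char: str = "I",
) -> None:
    """Write one SAM per genome with analytically constructed alignments.

    Every read appears exactly once in each SAM, mapped where it has a
    counterpart and flagged unmapped where it does not (e.g. its origin
    interval was deleted from the other genome).
    """
    for side, path in (("A", out_sam_a), ("B", out_sam_b)):
        seqs = genomes.seq(side)
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unknown\n")
            for chrom in sorted(seqs):
                fh.write(f"@SQ\tSN:{chrom}\tLN:{len(seqs[chrom])}\n")
            fh.write("@PG\tID:hybridscope\tPN:hybridscope\n")
            for r in reads:
                posmap = None if r.origin == side else genomes.posmap(r.origin)[r.chrom]
                aln = align_read(r, seqs[r.chrom], posmap)
                qual = qual_char * len(r.bases)
                if aln is None:
                    fh.write(f"{r.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{r.bases}\t{qual}\n")
                    continue
                pos, ops = aln
                if dialect == "legacy-M":
                    pos, ops = legacy_m(pos, ops)
                fh.write(
                    f"{r.read_id}\t0\t{r.chrom}\t{pos + 1}\t60\t{cigar_string(ops)}"
                    f"\t*\t0\t0\t{r.bases}\t{qual}\n"
                )


# ---------------------------------------------------------------------------
# trio VCF simulation

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=IMPACT,Number=1,Type=String,Description="Planted variant impact class">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
"""

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")
# planted impact-class mixtures: moderate/low elevated under biallelic
# hybrid expression, mirroring the compensation effect under study
IMPACT_P_BIALLELIC = (0.02, 0.28, 0.30, 0.40)
IMPACT_P_MONOALLELIC = (0.02, 0.14, 0.18, 0.66)


def _genotype(ad: tuple[int, int]) -> str:
    """Threshold genotyper: minor-allele fraction < 0.1 calls homozygous."""
    ref, alt = ad
    total = ref + alt
    minor = min(ref, alt) / total
    if minor < 0.1:
        return "0/0" if ref >= alt else "1/1"
    return "0/1"


def simulate_trio_vcf(
    cfg: SimConfig,
    genomes: Genomes,
    truth: TruthTable,
    out_vcf_a: str | Path,
    out_vcf_b: str | Path,
    rng: np.random.Generator,
) -> None:
    """Write trio VCFs (sire, dam, hybrid) against both references.

    Genome A plays the dam's species reference and genome B the sire's, so
    at every diagnostic substitution site the parents are truly
    alternatively homozygous.  A fraction ``frac_monoallelic_sites`` of
    sites is emitted with those planted alternative-monoallelic parental
    genotypes; the remainder get a heterozygous dam call so that downstream
    filtering has something to drop.  The hybrid's allelic depths are
    binomial around a planted expressed-allele fraction: 0.5 at biallelic
    sites, 0 or 1 (expressed parent drawn fairly) at monoallelic ones.
    Sites drawing zero depth are omitted.  Each record carries a planted
    ``IMPACT`` class whose distribution depends on the hybrid's zygosity.
    """
    sub_sites = [s for s in genomes.diagnostic_sites if s.kind == "sub"]
    rows_a: list[str] = []
    rows_b: list[str] = []
    for idx, s in enumerate(sub_sites):
        site_id = f"site{idx:06d}"
        planted_mono = bool(rng.random() < cfg.frac_monoallelic_sites)
        if planted_mono:
            gt_sire_a, gt_dam_a = "1/1", "0/0"
        else:
            gt_sire_a, gt_dam_a = "1/1", "0/1"
        if planted_mono and rng.random() < cfg.frac_hybrid_biallelic:
            frac_alt_a = 0.5  # alt allele in A-space is the sire's
            zygosity = "biallelic"
        elif planted_mono:
            frac_alt_a = 1.0 if rng.random() < 0.5 else 0.0
            zygosity = "monoallelic"
        else:
            frac_alt_a = 0.5
            zygosity = "biallelic"
        impact_p = IMPACT_P_BIALLELIC if zygosity == "biallelic" else IMPACT_P_MONOALLELIC
        impact = IMPACT_CLASSES[int(rng.choice(4, p=impact_p))]
        truth.sites[site_id] = {
            "chrom": s.chrom,
            "pos_a": s.pos_a,
            "pos_b": s.pos_b,
            "planted_monoallelic": planted_mono,
            "frac_alt_a": frac_alt_a,
            "zygosity": zygosity,
            "impact": impact,
        }
        for side, rows in (("A", rows_a), ("B", rows_b)):
            depth = int(rng.poisson(cfg.mean_depth))
            if depth == 0:
                continue
            frac_alt = frac_alt_a if side == "A" else 1.0 - frac_alt_a
            alt_n = int(rng.binomial(depth, frac_alt))
            ad = (depth - alt_n, alt_n)
            gt_hybrid = _genotype(ad)
            if side == "A":
                ref_base, alt_base, pos = s.base_a, s.base_b, s.pos_a
                gt_sire, gt_dam = gt_sire_a, gt_dam_a
            else:
                ref_base, alt_base, pos = s.base_b, s.base_a, s.pos_b
                gt_sire = gt_sire_a.replace("1", "x").replace("0", "1").replace("x", "0")
                gt_dam = gt_dam_a.replace("1", "x").replace("0", "1").replace("x", "0")
                gt_dam = "/".join(sorted(gt_dam.split("/")))
            dp = ad[0] + ad[1]
            rows.append(
                f"{s.chrom}\t{pos + 1}\t{site_id}\t{ref_base}\t{alt_base}\t.\tPASS\t"
                f"IMPACT={impact}\tGT:AD\t{gt_sire}:.\t{gt_dam}:.\t{gt_hybrid}:{ad[0]},{ad[1]}\n"
            )
    for side, path, rows in (("A", out_vcf_a, rows_a), ("B", out_vcf_b, rows_b)):
        seqs = genomes.seq(side)
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER)
            for chrom in sorted(seqs):
                fh.write(f"##contig=<ID={chrom},length={len(seqs[chrom])}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsire\tdam\thybrid\n")
            rows.sort(key=lambda r: (r.split("\t")[0], int(r.split("\t")[1])))
            fh.writelines(rows)


def simulate_all(
    cfg: SimConfig,
    outdir: str | Path,
    dialect: Literal["extended", "legacy-M"] = "extended",
) -> TruthTable:
    """Run the full simulation and write every artifact into ``outdir``.

    Files: genomeA/B.fasta, transcripts.gff3, reads.fastq, alnA/B.sam,
    trioA/B.vcf, truth_reads.tsv, truth_transcripts.tsv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    truth = TruthTable()
    genomes = generate_parental_genomes(cfg, rng)
    transcripts = generate_transcripts(cfg, genomes, rng)
    reads = simulate_hybrid_reads(cfg, genomes, transcripts, truth, rng)
    write_fasta(genomes.seqs_a, outdir / "genomeA.fasta")
    write_fasta(genomes.seqs_b, outdir / "genomeB.fasta")
    write_gff3(transcripts, outdir / "transcripts.gff3")
    write_fastq(reads, outdir / "reads.fastq")
    write_synthetic_alignments(reads, genomes, outdir / "alnA.sam", outdir / "alnB.sam", dialect)
    simulate_trio_vcf(cfg, genomes, truth, outdir / "trioA.vcf", outdir / "trioB.vcf", rng)
    truth.write_reads_tsv(outdir / "truth_reads.tsv")
    truth.write_transcripts_tsv(outdir / "truth_transcripts.tsv")
    return truth
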