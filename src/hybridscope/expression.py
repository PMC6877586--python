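"""Transcript quantification and transcriptome set comparisons.

Implements the expression side of the hybrid analysis: a count-based FPKM
(fragments per kilobase of transcript per million mapped reads), the
FPKM >= 1 expression filter, removal of uncharacterized gene symbols, and
the set comparisons the study rests on — top-N overlap between animals,
four-set intersection (Venn) region counts, cross-reference of a gene set
against a reference list (e.g. age-dependently expressed genes), and
per-pathway percentage tabulation.

Gene symbols are compared case-insensitively and stored upper-case
throughout.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

from .samcompare import round_half_up

__all__ = [
    "ExpressionRecord",
    "GeneSet",
    "read_gff3_transcripts",
    "count_reads_per_transcript",
    "compute_fpkm",
    "filter_expressed",
    "drop_uncharacterized",
    "top_n_overlap",
    "venn4",
    "crossref_membership",
    "pathway_percentages",
]

UNCHARACTERIZED_PATTERN = re.compile(r"^LOC\d+$|uncharacterized", re.IGNORECASE)


@dataclass(frozen=True)
class ExpressionRecord:
    gene_symbol: str
    transcript_length: int
    read_count: int
    fpkm: float


@dataclass
class GeneSet:
    """A labelled set of gene symbols (upper-cased on construction)."""

    label: str
    symbols: frozenset[str]

    def __init__(self, label: str, symbols: Iterable[str]):
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "symbols", frozenset(s.upper() for s in symbols))

    def __len__(self) -> int:
        return len(self.symbols)

    @classmethod
    def from_file(cls, path: str | Path, label: str | None = None) -> "GeneSet":
        """Load a one-symbol-per-line text file; blank lines and # comments skipped."""
        path = Path(path)
        syms = [
            line.strip()
            for line in path.read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
        return cls(label or path.stem, syms)


def read_gff3_transcripts(path: str | Path) -> list[dict]:
    """Read transcript features from a GFF3 file.

    Returns dicts with transcript_id, gene_symbol, chrom, start, end
    (0-based half-open).  Only ``transcript`` features with ``ID`` and
    ``gene`` attributes are used, which is the dialect this pipeline writes.
    """
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9 or fields[2] != "transcript":
            continue
        attrs = dict(kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv)
        out.append(
            {
                "transcript_id": attrs.get("ID", ""),
                "gene_symbol": attrs.get("gene", "").upper(),
                "chrom": fields[0],
                "start": int(fields[3]) - 1,
                "end": int(fields[4]),
            }
        )
    return out


def count_reads_per_transcript(sam_path: str | Path, transcripts: list[dict]) -> dict[str, int]:
    """Count mapped primary reads whose start falls inside each transcript.

    A read is attributed to the first transcript (in file order) containing
    its leftmost aligned position — transcripts here do not meaningfully
    overlap, so a full interval index is unnecessary.
    """
    by_chrom: dict[str, list[dict]] = {}
    for t in transcripts:
        by_chrom.setdefault(t["chrom"], []).append(t)
    counts = {t["transcript_id"]: 0 for t in transcripts}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            for t in by_chrom.get(rec.reference_name, ()):
                if t["start"] <= rec.reference_start < t["end"]:
                    counts[t["transcript_id"]] += 1
                    break
    return counts


def compute_fpkm(
    counts: Mapping[str, int],
    lengths: Mapping[str, int],
    total_mapped: int,
    symbols: Mapping[str, str] | None = None,
) -> list[ExpressionRecord]:
    """FPKM = reads x 10^9 / (transcript length x total mapped reads).

    ``symbols`` maps transcript id to gene symbol; identity if omitted.
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0 to compute FPKM")
    records = []
    for tid, count in counts.items():
        length = lengths[tid]
        if length <= 0:
            raise ValueError(f"transcript {tid} has non-positive length {length}")
        fpkm = count * 1e9 / (length * total_mapped)
        symbol = (symbols[tid] if symbols else tid).upper()
        records.append(ExpressionRecord(symbol, length, count, fpkm))
    return records


def filter_expressed(
    records: Sequence[ExpressionRecord],
    threshold: float = 1.0,
    strict_greater: bool = False,
    label: str = "expressed",
) -> GeneSet:
    """Keep genes whose FPKM clears the expression threshold.

    The default keeps ``fpkm >= threshold`` (records below 1 are neglected;
    the boundary is retained).  ``strict_greater`` flips the boundary to
    ``fpkm > threshold``.
    """
    if strict_greater:
        kept = (r for r in records if r.fpkm > threshold)
    else:
        kept = (r for r in records if r.fpkm >= threshold)
    return GeneSet(label, (r.gene_symbol for r in kept))


def drop_uncharacterized(s: GeneSet, pattern: re.Pattern | str = UNCHARACTERIZED_PATTERN) -> GeneSet:
    """Remove symbols of genes of unknown function (LOC-style ids etc.)."""
    pat = re.compile(pattern, re.IGNORECASE) if isinstance(pattern, str) else pattern
    return GeneSet(s.label, (sym for sym in s.symbols if not pat.search(sym)))


def _top_n(records: Sequence[ExpressionRecord], n: int, pattern: re.Pattern) -> set[str]:
    seen: dict[str, float] = {}
    for r in records:
        sym = r.gene_symbol
        if pattern.search(sym):
            continue
        if sym not in seen or r.fpkm > seen[sym]:
            seen[sym] = r.fpkm
    if len(seen) < n:
        warnings.warn(f"only {len(seen)} genes available for top-{n} ranking")
    ranked = sorted(seen.items(), key=lambda kv: (-kv[1], kv[0]))
    return {sym for sym, _ in ranked[:n]}


def top_n_overlap(
    a: Sequence[ExpressionRecord],
    b: Sequence[ExpressionRecord],
    n: int = 100,
    pattern: re.Pattern = UNCHARACTERIZED_PATTERN,
) -> int:
    """Number of genes shared between the two top-``n`` expression lists.

    Ranking is by FPKM descending after dropping uncharacterized symbols;
    ties at the rank-``n`` boundary are broken lexicographically so the
    result is deterministic.
    """
    return len(_top_n(a, n, pattern) & _top_n(b, n, pattern))


def venn4(sets: Sequence[GeneSet]) -> dict[str, int]:
    """Counts of all 15 disjoint intersection regions of four gene sets.

    Region keys are '+'-joined sorted label combinations; a gene counts
    toward exactly the region of the sets it belongs to, so region counts
    sum to the size of the union.
    """
    if len(sets) != 4:
        raise ValueError(f"venn4 needs exactly 4 sets, got {len(sets)}")
    labels = [s.label for s in sets]
    if len(set(labels)) != 4:
        raise ValueError("set labels must be distinct")
    regions = {
        "+".join(sorted(combo)): 0
        for k in range(1, 5)
        for combo in combinations(labels, k)
    }
    universe = set().union(*(s.symbols for s in sets))
    membership = {lbl: s.symbols for lbl, s in zip(labels, sets)}
    for gene in universe:
        combo = sorted(lbl for lbl in labels if gene in membership[lbl])
        regions["+".join(combo)] += 1
    return regions


def crossref_membership(query: GeneSet, reference: GeneSet) -> tuple[int, float]:
    """How many query genes appear in the reference set, as count and percent.

    Percent is 100 x |query ∩ reference| / |query|, rounded half-up to one
    decimal.  An empty query is an error.
    """
    if len(query) == 0:
        raise ValueError("query gene set is empty")
    n_in = len(query.symbols & reference.symbols)
    return n_in, round_half_up(100.0 * n_in / len(query), 1)


def pathway_percentages(
    assignments: Mapping[str, Iterable[str]],
    universe_size: int,
) -> dict[str, tuple[int, float]]:
    """Per-pathway gene counts and their percentage of the gene universe.

    ``assignments`` maps pathway name to the genes assigned to it (a gene
    may occur in several pathways).  Percent is rounded half-up to two
    decimals.
    """
    if universe_size <= 0:
        raise ValueError("universe_size must be > 0")
    out = {}
    for pathway, genes in assignments.items():
        n = len({g.upper() for g in genes})
        out[pathway] = (n, round_half_up(100.0 * n / universe_size, 2))
    return out
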