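"""Competitive arbitration of reads aligned against two reference genomes.

A hybrid animal's reads are mapped once against each parental reference
genome.  For every read the two primary alignment records are compared with
a hierarchical score read off the CIGAR string alone:

1. number of matching bases (``M`` and ``=`` operation lengths summed);
2. if equal, number of insertion/deletion events (fewer wins);
3. if equal, number of soft/hard-clipped bases (fewer wins).

Reads whose score is strictly better on one side are assigned to that
genome; reads mapped on one side only are assigned there without a score
comparison; full ties are discarded; reads unmapped on both sides are
counted separately.  The four categories partition the input read set.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Iterator, Literal

import pysam

__all__ = [
    "CigarScore",
    "DualAlignment",
    "AssignmentResult",
    "AssignmentSummary",
    "parse_cigar",
    "score_cigar",
    "compare_scores",
    "pair_records",
    "assign_reads",
    "summarize_assignment",
]

_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])|(.)")

#: CIGAR operations that consume read bases while aligned to the reference.
_ALIGNED_OPS = frozenset("M=X")

Winner = Literal["A", "B", "tie"]
TiebreakLevel = Literal["mapped_vs_unmapped", "matches", "indels", "clips", "full_tie"]


@dataclass(frozen=True, order=False)
class CigarScore:
    """Hierarchical alignment score derived from a CIGAR string.

    Attributes
    ----------
    matching_bases:
        Summed lengths of ``M`` and ``=`` operations. ``X`` is excluded:
        aligners that emit the extended dialect mark mismatches explicitly,
        and a mismatch is not a matching base.
    indel_events:
        Number of ``I``/``D`` operations (event count, not base count; see
        :func:`score_cigar` for the base-count alternative).
    clipped_bases:
        Summed lengths of ``S`` and ``H`` operations.
    """

    matching_bases: int
    indel_events: int
    clipped_bases: int

    def sort_key(self) -> tuple[int, int, int]:
        """Key under which a plain ``max()`` picks the better score."""
        return (self.matching_bases, -self.indel_events, -self.clipped_bases)


class CigarError(ValueError):
    """Raised for a malformed CIGAR string; names the offending token."""


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """Parse a CIGAR string into ``(op, length)`` tuples.

    Raises
    ------
    CigarError
        If the string contains a token outside ``MIDNSHP=X`` or a length-less
        operation.
    """
    if cigar == "*" or cigar == "":
        return []
    ops: list[tuple[str, int]] = []
    for m in _CIGAR_TOKEN.finditer(cigar):
        if m.group(3) is not None:
            raise CigarError(f"malformed CIGAR {cigar!r}: unexpected token {m.group(3)!r}")
        ops.append((m.group(2), int(m.group(1))))
    return ops


def score_cigar(
    cigar: str | list[tuple[str, int]],
    indel_metric: Literal["events", "bases"] = "events",
) -> CigarScore:
    """Compute the three-component hierarchical score of one CIGAR.

    Parameters
    ----------
    cigar:
        CIGAR string or pre-parsed ``(op, length)`` list.  ``"*"`` (the SAM
        unmapped placeholder) is not scoreable; callers must treat that side
        as unmapped (:func:`pair_records` does).
    indel_metric:
        ``"events"`` counts each I/D operation once (default); ``"bases"``
        sums their lengths instead.

    Notes
    -----
    ``N`` (skipped region) and ``P`` (padding) contribute to no component.
    """
    ops = parse_cigar(cigar) if isinstance(cigar, str) else cigar
    if not ops:
        raise CigarError("cannot score an empty/'*' CIGAR; treat the read as unmapped")
    matching = indels = clipped = 0
    for op, length in ops:
        if op == "M" or op == "=":
            matching += length
        elif op == "I" or op == "D":
            indels += length if indel_metric == "bases" else 1
        elif op == "S" or op == "H":
            clipped += length
    return CigarScore(matching, indels, clipped)


def compare_scores(a: CigarScore, b: CigarScore) -> tuple[Winner, TiebreakLevel]:
    """Lexicographic comparison of two scores.

    More matching bases wins; then fewer indel events; then fewer clipped
    bases; all equal is a tie.  Returns the winner and the level at which
    the decision fell.
    """
    if a.matching_bases != b.matching_bases:
        return ("A" if a.matching_bases > b.matching_bases else "B", "matches")
    if a.indel_events != b.indel_events:
        return ("A" if a.indel_events < b.indel_events else "B", "indels")
    if a.clipped_bases != b.clipped_bases:
        return ("A" if a.clipped_bases < b.clipped_bases else "B", "clips")
    return ("tie", "full_tie")


@dataclass
class DualAlignment:
    """One read's primary alignment records against reference A and B.

    Either side may be ``None``: the read had no record, or only an
    unmapped-flag record, on that side.
    """

    read_id: str
    record_A: pysam.AlignedSegment | None
    record_B: pysam.AlignedSegment | None


@dataclass
class AssignmentResult:
    category: Literal["unique_A", "unique_B", "unmapped_both", "discarded_tie"]
    winning_score: CigarScore | None
    tiebreak_level: TiebreakLevel | None


@dataclass
class AssignmentSummary:
    """Counts of the four assignment categories; they partition the input."""

    unique_A: int = 0
    unique_B: int = 0
    unmapped_both: int = 0
    discarded_tie: int = 0
    skipped_secondary: int = 0
    tiebreak_levels: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return self.unique_A + self.unique_B + self.unmapped_both + self.discarded_tie

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "unique_A": self.unique_A,
            "unique_B": self.unique_B,
            "unmapped_both": self.unmapped_both,
            "discarded_tie": self.discarded_tie,
            "skipped_secondary": self.skipped_secondary,
            "tiebreak_levels": dict(self.tiebreak_levels),
        }


def _primary_records(path: str) -> tuple[dict[str, pysam.AlignedSegment], int]:
    """Load primary records keyed by read name; count skipped secondaries.

    Unmapped records are stored as ``None`` values so that presence in the
    SAM is distinguishable from absence.
    """
    records: dict[str, pysam.AlignedSegment | None] = {}
    skipped = 0
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                skipped += 1
                continue
            name = rec.query_name
            if name in records:
                raise ValueError(f"duplicate primary record for read {name!r} in {path}")
            records[name] = None if rec.is_unmapped else rec
    return records, skipped


def pair_records(sam_a: str, sam_b: str) -> tuple[list[DualAlignment], int]:
    """Pair primary records from two SAM/BAM files by read name.

    Returns one :class:`DualAlignment` per read name seen on either side
    (conservation: n reads in, n pairs out) plus the number of
    secondary/supplementary records skipped.  A read present on one side
    only is treated as absent on the other.
    """
    recs_a, skip_a = _primary_records(sam_a)
    recs_b, skip_b = _primary_records(sam_b)
    names = list(recs_a)
    names.extend(n for n in recs_b if n not in recs_a)
    pairs = [DualAlignment(n, recs_a.get(n), recs_b.get(n)) for n in names]
    return pairs, skip_a + skip_b


def _classify(pair: DualAlignment, indel_metric: str) -> AssignmentResult:
    a, b = pair.record_A, pair.record_B
    if a is None and b is None:
        return AssignmentResult("unmapped_both", None, None)
    if b is None:
        return AssignmentResult("unique_A", _score_rec(a, indel_metric), "mapped_vs_unmapped")
    if a is None:
        return AssignmentResult("unique_B", _score_rec(b, indel_metric), "mapped_vs_unmapped")
    sa, sb = _score_rec(a, indel_metric), _score_rec(b, indel_metric)
    winner, level = compare_scores(sa, sb)
    if winner == "tie":
        return AssignmentResult("discarded_tie", None, "full_tie")
    return AssignmentResult(f"unique_{winner}", sa if winner == "A" else sb, level)


def _score_rec(rec: pysam.AlignedSegment, indel_metric: str) -> CigarScore:
    return score_cigar(rec.cigarstring or "*", indel_metric)


def assign_reads(
    pairs: Iterable[DualAlignment],
    indel_metric: Literal["events", "bases"] = "events",
    out_a: pysam.AlignmentFile | None = None,
    out_b: pysam.AlignmentFile | None = None,
) -> tuple[AssignmentSummary, list[AssignmentResult]]:
    """Assign every paired read to a category; optionally write partitions.

    ``out_a``/``out_b``, when given, receive exactly the records of reads
    assigned uniquely to that side.
    """
    summary = AssignmentSummary()
    results: list[AssignmentResult] = []
    for pair in pairs:
        res = _classify(pair, indel_metric)
        results.append(res)
        setattr(summary, res.category, getattr(summary, res.category) + 1)
        if res.tiebreak_level is not None:
            summary.tiebreak_levels[res.tiebreak_level] += 1
        if res.category == "unique_A" and out_a is not None:
            out_a.write(pair.record_A)
        elif res.category == "unique_B" and out_b is not None:
            out_b.write(pair.record_B)
    return summary, results


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (0.05 at 1 digit -> 0.1), as printed reports use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_assignment(summary: AssignmentSummary) -> list[dict]:
    """Report each category as a count and a percentage of the total.

    Percentages are rounded half-up to one decimal.  Raises ``ValueError``
    on an empty summary.
    """
    total = summary.total
    if total == 0:
        raise ValueError("cannot summarize an empty assignment (total = 0)")
    rows = []
    for cat in ("unique_A", "unique_B", "unmapped_both", "discarded_tie"):
        count = getattr(summary, cat)
        rows.append(
            {"category": cat, "count": count, "percent": round_half_up(100.0 * count / total, 1)}
        )
    return rows


def write_summary(summary: AssignmentSummary, path: str) -> None:
    with open(path, "w") as fh:
        json.dump({"summary": summary.as_dict(), "rows": summarize_assignment(summary)}, fh, indent=2)
        fh.write("\n")
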