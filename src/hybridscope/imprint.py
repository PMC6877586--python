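"""Cross-reference of hybrid parental-origin calls against imprinting records.

Genes whose hybrid expression traces to exactly one parental genome are
looked up in an imprinting database (e.g. geneimprint.com, supplied as a
TSV).  Each matched gene is classified by comparing the hybrid's observed
parent-of-origin with the database's reported expressed allele:

* concordant — same pole (paternal/paternal or maternal/maternal);
* discordant — opposite poles;
* unresolvable — the database reports biallelic or conflicting evidence,
  which supports neither pole.

"Predicted" database entries count like experimental ones; the species the
report comes from is carried as annotation only and plays no role in the
classification.  A bundled fixture table of geneimprint matches for the
buck-ewe hybrid study system ships with the package.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping

__all__ = [
    "ImprintRecord",
    "CrossrefResult",
    "load_imprint_table",
    "bundled_imprint_table",
    "crossref_imprint",
]

Pole = Literal["paternal", "maternal"]
ReportedAllele = Literal["paternal", "maternal", "biallelic_or_conflicting"]


@dataclass(frozen=True)
class ImprintRecord:
    gene_symbol: str
    origin_in_hybrid: Pole
    reported_allele: ReportedAllele
    reported_species: str = ""
    classification: str | None = None


@dataclass
class CrossrefResult:
    matched: list[ImprintRecord]
    n_concordant: int
    n_discordant: int
    n_unresolvable: int

    @property
    def n_matched(self) -> int:
        return len(self.matched)


def _norm_allele(value: str) -> ReportedAllele:
    v = value.strip().lower()
    if v.startswith("pat"):
        return "paternal"
    if v.startswith("mat"):
        return "maternal"
    return "biallelic_or_conflicting"


def load_imprint_table(path: str | Path) -> list[ImprintRecord]:
    """Read a database TSV with columns gene, reported_allele[, species].

    An ``origin_in_hybrid`` column, if present, is read too so that a
    single file can carry a full cross-reference table.  Duplicate gene
    symbols are an error.
    """
    records: list[ImprintRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            sym = row["gene"].strip().upper()
            if sym in seen:
                raise ValueError(f"duplicate gene symbol {sym!r} in {path}")
            seen.add(sym)
            records.append(
                ImprintRecord(
                    gene_symbol=sym,
                    origin_in_hybrid=row.get("origin_in_hybrid", "").strip().lower() or None,
                    reported_allele=_norm_allele(row["reported_allele"]),
                    reported_species=row.get("reported_species", ""),
                )
            )
    return records


def bundled_imprint_table() -> list[ImprintRecord]:
    """The packaged cross-reference fixture for the buck-ewe hybrid system."""
    ref = resources.files("hybridscope.data") / "geneimprint_crossref.tsv"
    with resources.as_file(ref) as path:
        return load_imprint_table(path)


def crossref_imprint(
    origin_calls: Mapping[str, Pole],
    database: list[ImprintRecord],
) -> CrossrefResult:
    """Classify every gene present in both the origin calls and the database.

    Symbols are matched case-insensitively.  For each match: concordant if
    the hybrid origin equals the reported pole, discordant if the poles are
    opposite, unresolvable if the database entry is biallelic/conflicting.
    The three counts always partition the matched genes.
    """
    seen: set[str] = set()
    for rec in database:
        if rec.gene_symbol in seen:
            raise ValueError(f"duplicate gene symbol {rec.gene_symbol!r} in database")
        seen.add(rec.gene_symbol)
    calls = {g.upper(): pole for g, pole in origin_calls.items()}
    matched: list[ImprintRecord] = []
    n_con = n_dis = n_unr = 0
    for rec in database:
        if rec.gene_symbol not in calls:
            continue
        origin = calls[rec.gene_symbol]
        if rec.reported_allele == "biallelic_or_conflicting":
            cls = "unresolvable"
            n_unr += 1
        elif rec.reported_allele == origin:
            cls = "concordant"
            n_con += 1
        else:
            cls = "discordant"
            n_dis += 1
        matched.append(
            ImprintRecord(rec.gene_symbol, origin, rec.reported_allele,
                          rec.reported_species, cls)
        )
    return CrossrefResult(matched, n_con, n_dis, n_unr)
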