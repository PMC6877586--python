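"""End-to-end orchestration: simulate, arbitrate, quantify, compare, report.

Runs the stages of the hybrid-transcriptome analysis in order on synthetic
or user-supplied inputs and writes a consolidated JSON + Markdown report.
Every stage logs its input/output record counts; a fixed seed makes the
whole run deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pysam
import yaml

from . import expression, imprint, samcompare, syndata, trio_alleles

__all__ = ["RunConfig", "run_pipeline", "load_config", "save_config"]

log = logging.getLogger("hybridscope")

ALL_STAGES = ("simulate", "assign", "quantify", "compare", "alleles", "imprint")


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    outdir: str = "hybridscope_out"
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    sim: syndata.SimConfig = field(default_factory=syndata.SimConfig)
    # input paths; filled from the simulate stage when it runs
    sam_a: str | None = None
    sam_b: str | None = None
    gff3: str | None = None
    vcf_a: str | None = None
    vcf_b: str | None = None
    imprint_table: str | None = None  # None -> bundled fixture
    fpkm_threshold: float = 1.0
    strict_greater: bool = False
    min_variants: int = 1
    sign_convention: Literal["results", "figure"] = "results"
    indel_metric: Literal["events", "bases"] = "events"
    dialect: Literal["extended", "legacy-M"] = "extended"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = syndata.SimConfig.from_dict(d["sim"])
        return cls(**d)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def _require(cfg: RunConfig, stage: str, **paths: str | None) -> None:
    for name, p in paths.items():
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"stage {stage!r} needs input {name!r} (got {p})")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and return the report dictionary.

    Writes ``report.json`` and ``report.md`` into ``cfg.outdir`` along with
    each stage's artifact files.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": cfg.to_dict()}
    truth = None

    if "simulate" in cfg.stages:
        log.info("simulate: seed=%d", cfg.sim.seed)
        truth = syndata.simulate_all(cfg.sim, outdir, dialect=cfg.dialect)
        cfg.sam_a = str(outdir / "alnA.sam")
        cfg.sam_b = str(outdir / "alnB.sam")
        cfg.gff3 = str(outdir / "transcripts.gff3")
        cfg.vcf_a = str(outdir / "trioA.vcf")
        cfg.vcf_b = str(outdir / "trioB.vcf")
        report["simulate"] = {
            "n_reads": len(truth.reads),
            "n_transcripts": len(truth.transcripts),
            "n_sites": len(truth.sites),
        }
        log.info("simulate: %d reads, %d transcripts, %d variant sites",
                 len(truth.reads), len(truth.transcripts), len(truth.sites))

    summary = None
    if "assign" in cfg.stages:
        _require(cfg, "assign", sam_a=cfg.sam_a, sam_b=cfg.sam_b)
        pairs, skipped = samcompare.pair_records(cfg.sam_a, cfg.sam_b)
        with pysam.AlignmentFile(cfg.sam_a, "r", check_sq=False) as tpl_a, \
             pysam.AlignmentFile(cfg.sam_b, "r", check_sq=False) as tpl_b, \
             pysam.AlignmentFile(str(outdir / "uniqueA.sam"), "w", template=tpl_a) as out_a, \
             pysam.AlignmentFile(str(outdir / "uniqueB.sam"), "w", template=tpl_b) as out_b:
            summary, _ = samcompare.assign_reads(
                pairs, cfg.indel_metric, out_a=out_a, out_b=out_b
            )
        summary.skipped_secondary += skipped
        samcompare.write_summary(summary, str(outdir / "assignment.json"))
        report["assign"] = {
            "summary": summary.as_dict(),
            "rows": samcompare.summarize_assignment(summary),
        }
        log.info("assign: %s", summary.as_dict())

    records_a = records_b = None
    if "quantify" in cfg.stages:
        _require(cfg, "quantify", sam_a=str(outdir / "uniqueA.sam"),
                 sam_b=str(outdir / "uniqueB.sam"), gff3=cfg.gff3)
        transcripts = expression.read_gff3_transcripts(cfg.gff3)
        lengths = {t["transcript_id"]: t["end"] - t["start"] for t in transcripts}
        symbols = {t["transcript_id"]: t["gene_symbol"] for t in transcripts}
        records = {}
        for side, sam in (("A", outdir / "uniqueA.sam"), ("B", outdir / "uniqueB.sam")):
            counts = expression.count_reads_per_transcript(sam, transcripts)
            total = sum(counts.values())
            recs = expression.compute_fpkm(counts, lengths, max(total, 1), symbols)
            records[side] = recs
            with open(outdir / f"expression_{side}.tsv", "w") as fh:
                fh.write("gene_symbol\ttranscript_length\tread_count\tfpkm\n")
                for r in sorted(recs, key=lambda r: -r.fpkm):
                    fh.write(f"{r.gene_symbol}\t{r.transcript_length}\t{r.read_count}\t{r.fpkm:.4f}\n")
            log.info("quantify[%s]: %d transcripts, %d assigned reads", side, len(recs), total)
        records_a, records_b = records["A"], records["B"]
        report["quantify"] = {
            "n_reads_A": sum(r.read_count for r in records_a),
            "n_reads_B": sum(r.read_count for r in records_b),
        }

    if "compare" in cfg.stages and records_a is not None:
        set_a = expression.drop_uncharacterized(
            expression.filter_expressed(records_a, cfg.fpkm_threshold, cfg.strict_greater, "hybrid_vs_A")
        )
        set_b = expression.drop_uncharacterized(
            expression.filter_expressed(records_b, cfg.fpkm_threshold, cfg.strict_greater, "hybrid_vs_B")
        )
        # parental transcriptomes from simulation truth when available
        if truth is not None:
            parent_a = expression.GeneSet(
                "parent_A",
                (t.gene_symbol for t in truth.transcripts.values() if t.origin in ("A", "both")),
            )
            parent_b = expression.GeneSet(
                "parent_B",
                (t.gene_symbol for t in truth.transcripts.values() if t.origin in ("B", "both")),
            )
            parent_a = expression.drop_uncharacterized(parent_a)
            parent_b = expression.drop_uncharacterized(parent_b)
            regions = expression.venn4([set_a, set_b, parent_a, parent_b])
            report["compare"] = {
                "venn": regions,
                "top_n_overlap_parents": expression.top_n_overlap(records_a, records_b, n=100),
            }
            with open(outdir / "venn.json", "w") as fh:
                json.dump(regions, fh, indent=2)
            log.info("compare: venn over %d genes", sum(regions.values()))

    origin_by_gene: dict[str, str] = {}
    if "alleles" in cfg.stages:
        _require(cfg, "alleles", vcf_a=cfg.vcf_a)
        alleles_report = {}
        all_blocks = []
        for side, vcf in (("A", cfg.vcf_a), ("B", cfg.vcf_b)):
            if vcf is None:
                continue
            counters = trio_alleles.FilterCounters()
            sites = list(
                trio_alleles.select_alt_monoallelic(
                    trio_alleles.read_trio_vcf(vcf, reference_species=side, counters=counters),
                    counters,
                )
            )
            bins = [
                trio_alleles.signed_bin(
                    trio_alleles.allelic_depth_ratio(s.ad_hybrid),
                    s.alt_parent, cfg.sign_convention,
                )
                for s in sites
                if sum(s.ad_hybrid) > 0
            ]
            hist = trio_alleles.bin_histogram(bins)
            calls = [
                (s.chrom, s.pos, o)
                for s in sites
                if (o := trio_alleles.origin_from_variant(s)) is not None
            ]
            calls.sort(key=lambda c: (c[0], c[1]))
            blocks = trio_alleles.build_blocks(calls, cfg.min_variants)
            all_blocks.extend(blocks)
            trio_alleles.write_blocks_bed(blocks, outdir / f"blocks_{side}.bed")
            with open(outdir / f"adr_hist_{side}.tsv", "w") as fh:
                fh.write("bin\tcount\n")
                for b in sorted(hist):
                    fh.write(f"{b:+.1f}\t{hist[b]}\n")
            n_bi = sum(1 for s in sites if trio_alleles.classify_hybrid_zygosity(s) == "biallelic")
            alleles_report[side] = {
                "n_alt_monoallelic": len(sites),
                "biallelic_fraction": (n_bi / len(sites)) if sites else 0.0,
                "histogram": {f"{k:+.1f}": v for k, v in sorted(hist.items())},
                "n_blocks": len(blocks),
                "bp_totals": trio_alleles.block_bp_totals(blocks),
                "impact_fractions": trio_alleles.impact_fractions(sites),
                "filters": dataclasses.asdict(counters),
            }
            log.info("alleles[%s]: %d alternatively-monoallelic sites, %d blocks",
                     side, len(sites), len(blocks))
        report["alleles"] = alleles_report
        # gene-level origin calls for the imprint stage: majority origin of
        # block variants falling inside each transcript
        if truth is not None and all_blocks:
            from collections import Counter

            votes: dict[str, Counter] = {}
            for b in all_blocks:
                for t in truth.transcripts.values():
                    if t.chrom == b.chrom and b.start < t.end_a and t.start_a < b.end:
                        votes.setdefault(t.gene_symbol, Counter())[b.origin] += b.n_variants
            for gene, c in votes.items():
                origin = c.most_common(1)[0][0]
                origin_by_gene[gene] = "paternal" if origin == "sire" else "maternal"

    if "imprint" in cfg.stages:
        table = (
            imprint.load_imprint_table(cfg.imprint_table)
            if cfg.imprint_table
            else imprint.bundled_imprint_table()
        )
        calls = origin_by_gene or {
            r.gene_symbol: r.origin_in_hybrid for r in table if r.origin_in_hybrid
        }
        result = imprint.crossref_imprint(calls, table)
        report["imprint"] = {
            "n_matched": result.n_matched,
            "n_concordant": result.n_concordant,
            "n_discordant": result.n_discordant,
            "n_unresolvable": result.n_unresolvable,
            "genes": [
                {"gene": r.gene_symbol, "origin": r.origin_in_hybrid,
                 "reported": r.reported_allele, "class": r.classification}
                for r in result.matched
            ],
        }
        log.info("imprint: %d matched, %d discordant", result.n_matched, result.n_discordant)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_markdown(report, outdir / "report.md")
    return report


def _write_markdown(report: dict, path: Path) -> None:
    lines = ["# hybridscope report", ""]
    if "assign" in report:
        lines += ["## Read assignment", "", "| category | count | percent |", "|---|---|---|"]
        for row in report["assign"]["rows"]:
            lines.append(f"| {row['category']} | {row['count']} | {row['percent']} |")
        lines.append("")
    if "compare" in report:
        lines += ["## Transcriptome overlap (4-set regions)", ""]
        for region, count in sorted(report["compare"]["venn"].items()):
            lines.append(f"- {region}: {count}")
        lines.append("")
    if "alleles" in report:
        for side, d in report["alleles"].items():
            lines += [
                f"## Allele-specific expression (reference {side})",
                "",
                f"- alternatively-monoallelic sites: {d['n_alt_monoallelic']}",
                f"- hybrid biallelic fraction: {d['biallelic_fraction']:.3f}",
                f"- origin blocks: {d['n_blocks']}",
                "",
            ]
    if "imprint" in report:
        d = report["imprint"]
        lines += [
            "## Imprinting cross-reference",
            "",
            f"- matched: {d['n_matched']}",
            f"- concordant: {d['n_concordant']}",
            f"- discordant: {d['n_discordant']}",
            f"- unresolvable: {d['n_unresolvable']}",
            "",
        ]
    path.write_text("\n".join(lines))
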