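"""End-to-end orchestration: genome in, report bundle out.

Stages mirror the analysis workflow: repeat discovery (or HSP-table
ingestion), junction-conformation construction, long-read support counting,
conformation-space enumeration, SSR scanning, and MTPT detection when a
plastome is supplied.  Each stage writes plain-text artifacts so any stage
can be replaced by an external tool (a real BLAST search, a real mapper)
at the file boundary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

from . import __version__
from .conformations import build_conformations, write_conformation_fasta
from .mtpt import (
    annotate_records,
    find_mtpt,
    group_gene_clusters,
    read_annotation,
    summarize_mtpt,
    write_mtpt_bed,
    write_mtpt_table,
)
from .repeats import find_repeats, parse_hsp_table, write_repeat_table
from .sequence import InputError, read_fasta, read_reads, write_fasta
from .ssr import scan_ssrs, write_ssr_bed, write_ssr_table
from .support import (
    RecombRecord,
    call_active_repeats,
    count_support,
    recombination_frequency,
    write_support_table,
)
from .topology import (
    enumerate_conformation_space,
    genome_to_molecules,
    realize_sequence,
    write_structure_report,
)

logger = logging.getLogger("mitorecomb")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclasses.dataclass
class PipelineConfig:
    genome_path: str
    out_dir: str
    reads_path: str | None = None
    hsp_table_path: str | None = None
    plastome_path: str | None = None
    annotation_path: str | None = None
    flank: int = 500
    min_anchor: int = 100
    max_divergence: float = 0.15
    min_word: int = 7
    evalue_cutoff: float = 1e-6
    min_repeat_length: int = 50
    mtpt_min_length: int = 100
    max_repeat_span: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flank < 1 or self.min_anchor < 1:
            raise InputError("flank and min_anchor must be >= 1")
        if not 0 < self.max_divergence < 1:
            raise InputError("max_divergence must be in (0, 1)")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every applicable stage; returns a manifest of written outputs.

    A stage error aborts with a stage-tagged message; outputs of completed
    stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"outputs": {}, "skipped": []}

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("mitorecomb %s", __version__)
        logger.info("parameters: %s", dataclasses.asdict(config))

        stage = "load-genome"
        genome = read_fasta(config.genome_path)
        logger.info(
            "genome: %d chromosome(s), %d bp", len(genome), genome.total_length
        )

        stage = "repeats"
        if config.hsp_table_path:
            repeats = parse_hsp_table(config.hsp_table_path)
        else:
            repeats = find_repeats(
                genome,
                min_word=config.min_word,
                evalue_cutoff=config.evalue_cutoff,
                min_length=config.min_repeat_length,
            )
        repeat_tsv = out / "repeats.tsv"
        write_repeat_table(repeats, repeat_tsv)
        manifest["outputs"]["repeats"] = str(repeat_tsv)
        logger.info("repeats: %d pair(s)", len(repeats))

        stage = "conformations"
        junction_sets = {}
        conf_dir = out / "conformations"
        conf_dir.mkdir(exist_ok=True)
        for rep in repeats:
            js = build_conformations(
                genome, rep, flank=config.flank, max_span=config.max_repeat_span
            )
            junction_sets[rep.id] = js
            write_conformation_fasta(js, conf_dir / f"{rep.id}.fasta")
            for w in js.warnings:
                logger.warning("%s: %s", rep.id, w)
        manifest["outputs"]["conformations"] = str(conf_dir)

        stage = "support"
        if config.reads_path:
            reads = read_reads(config.reads_path)
            logger.info("reads: %d", len(reads))
            records = []
            for rep in repeats:
                counts = count_support(
                    reads,
                    junction_sets[rep.id],
                    min_anchor=config.min_anchor,
                    max_divergence=config.max_divergence,
                )
                rec = RecombRecord(repeat=rep, counts=counts)
                rec.frequency = (
                    recombination_frequency(counts) if counts.assigned else None
                )
                records.append(rec)
            records = call_active_repeats(
                records, max_repeat_span=config.max_repeat_span
            )
            support_tsv = out / "support.tsv"
            write_support_table(records, support_tsv)
            manifest["outputs"]["support"] = str(support_tsv)
            active = [r.repeat for r in records if r.active]
        else:
            manifest["skipped"].append("support (no reads supplied)")
            logger.info("support stage skipped: no reads supplied")
            active = list(repeats)

        stage = "topology"
        topo_sets = []
        topo_dir = out / "conformation_space"
        topo_dir.mkdir(exist_ok=True)
        for rep in active:
            try:
                mols = genome_to_molecules(genome, [rep])
                mic = enumerate_conformation_space(mols, [rep])
            except InputError as exc:
                logger.warning("topology: skipping %s (%s)", rep.id, exc)
                continue
            for ms in mic:
                topo_sets.append(ms)
                write_fasta(
                    ((m.id, realize_sequence(m, genome)) for m in ms.molecules),
                    topo_dir / f"{rep.id}.fasta",
                )
        struct_json = out / "conformation_space.json"
        write_structure_report(topo_sets, struct_json)
        manifest["outputs"]["conformation_space"] = str(struct_json)

        stage = "ssr"
        ssrs = scan_ssrs(genome)
        write_ssr_table(ssrs, out / "ssrs.tsv")
        write_ssr_bed(ssrs, out / "ssrs.bed")
        manifest["outputs"]["ssrs"] = str(out / "ssrs.tsv")
        logger.info("ssrs: %d", len(ssrs))

        stage = "mtpt"
        if config.plastome_path:
            plastome = read_fasta(config.plastome_path)
            mtpts = find_mtpt(
                genome,
                plastome,
                evalue_cutoff=config.evalue_cutoff,
                word_size=config.min_word,
                min_length=config.mtpt_min_length,
            )
            if config.annotation_path:
                ann = read_annotation(config.annotation_path)
                mtpts = annotate_records(mtpts, group_gene_clusters(mtpts, ann))
            write_mtpt_table(mtpts, out / "mtpt.tsv")
            write_mtpt_bed(mtpts, out / "mtpt.bed")
            summary = summarize_mtpt(
                mtpts, genome.total_length, plastome.total_length
            )
            (out / "mtpt_summary.json").write_text(
                json.dumps(summary, indent=2) + "\n"
            )
            manifest["outputs"]["mtpt"] = str(out / "mtpt.tsv")
            logger.info("mtpts: %d (%s bp)", summary["n"], summary["total_bp"])
        else:
            manifest["skipped"].append("mtpt (no plastome supplied)")

        manifest["outputs"]["log"] = str(log_path)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return manifest
    except InputError as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise InputError(f"[{stage}] {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
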