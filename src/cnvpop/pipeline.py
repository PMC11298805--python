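"""End-to-end orchestration: filter -> merge -> classify -> length filter ->
summarize -> annotate -> QTL -> Vst -> candidates, with a run manifest.

Every stage writes a TSV/JSON report into the output directory and logs its
record counts; the manifest records the configuration hash, input file
hashes, and a content hash of every output so two runs of the same seed and
inputs can be compared byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .annotation import assign_genes, CnvrAnnotation
from .cnvr_construction import (
    apply_length_filters,
    filter_calls,
    merge_calls_to_cnvrs,
    summarize_cnvr_set,
)
from .io_formats import (
    CnvCall,
    read_cnv_vcf,
    read_genome_table,
    read_gff3_genes,
    read_population_map,
    read_qtl_table,
    write_cnvr_bed,
)
from .qtl_overlap import filter_qtls, intersect_cnvr_qtl
from .vst_divergence import (
    annotate_candidates,
    build_cn_matrix,
    compute_vst,
    select_candidates,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage thresholds with their standard defaults, plus file paths.

    The thresholds default to the established CNVR-survey values: calls
    shorter than 50 bp, with under 4 supporting reads, or imprecise are
    dropped; deletion/mixed regions are capped at 50 kb and duplications
    below 500 kb; QTL confidence intervals must be under 5 Mb and a CNVR-QTL
    overlap must exceed 1 kb; candidates are the top 10 % of Vst plus
    everything above 0.5.
    """

    calls_dir: Optional[str] = None      # directory of per-sample VCFs
    genome: Optional[str] = None
    genes: Optional[str] = None
    qtls: Optional[str] = None
    pop_map: Optional[str] = None
    outdir: str = "cnvpop_out"

    min_len: int = 50
    min_support: int = 4
    require_precise: bool = True
    min_reciprocal: float = 0.0
    del_both_max: int = 50_000
    dup_max: int = 500_000
    proximal_window: int = 1000
    qtl_max_span: int = 5_000_000
    qtl_min_overlap: int = 1000
    top_frac: float = 0.10
    abs_threshold: float = 0.5
    baseline_cn: float = 2.0
    seed: int = 0
    samples_pop1: Optional[list[str]] = None
    samples_pop2: Optional[list[str]] = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))


@dataclass
class PipelineResult:
    cnvrs: list
    summary: object
    annotations: list[CnvrAnnotation]
    qtl_report: Optional[object]
    vst_report: Optional[object]
    candidates: Optional[list]
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def load_calls(calls_dir: str | Path) -> list[CnvCall]:
    """Read every .vcf in a directory; the file stem is the sample id."""
    calls: list[CnvCall] = []
    for path in sorted(Path(calls_dir).glob("*.vcf")):
        sample_calls, _ = read_cnv_vcf(path, sample_id=path.stem, caller="vcf")
        calls.extend(sample_calls)
    return calls


def run_all(
    config: PipelineConfig,
    calls: Optional[list[CnvCall]] = None,
    skip_qtl: bool = False,
    skip_vst: bool = False,
) -> PipelineResult:
    """Run every stage and write all reports under ``config.outdir``.

    ``calls`` may be passed in-memory (e.g. straight from the simulator);
    otherwise they are read from ``config.calls_dir``.  The QTL and Vst
    stages are skipped automatically when their inputs are absent.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": json.loads(config.to_json()),
        "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
        "inputs": {},
        "stages": {},
        "outputs": {},
    }
    for key in ("genome", "genes", "qtls", "pop_map"):
        p = getattr(config, key)
        if p and Path(p).exists():
            manifest["inputs"][key] = _sha256(Path(p))

    if calls is None:
        if not config.calls_dir:
            raise ValueError("no calls provided and no calls_dir configured")
        calls = load_calls(config.calls_dir)
    manifest["stages"]["input_calls"] = len(calls)

    kept, tally = filter_calls(
        calls,
        min_len=config.min_len,
        min_support=config.min_support,
        require_precise=config.require_precise,
    )
    logger.info("filter: %d kept, %d rejected (%s)", len(kept), tally.total, tally)
    manifest["stages"]["filtered_calls"] = len(kept)
    manifest["stages"]["rejected_calls"] = {
        "precise": tally.precise, "length": tally.length, "support": tally.support
    }

    merged = merge_calls_to_cnvrs(kept, min_reciprocal=config.min_reciprocal)
    manifest["stages"]["merged_cnvrs"] = len(merged)
    cnvrs, dropped = apply_length_filters(
        merged, del_both_max=config.del_both_max, dup_max=config.dup_max
    )
    manifest["stages"]["cnvrs_after_length_filter"] = len(cnvrs)
    manifest["stages"]["cnvrs_dropped_by_length"] = len(dropped)
    logger.info("merge: %d CNVRs (%d dropped by length)", len(cnvrs), len(dropped))

    bed_path = outdir / "cnvrs.bed"
    write_cnvr_bed(cnvrs, bed_path)

    genome = read_genome_table(config.genome) if config.genome else None
    summary = None
    if genome:
        summary = summarize_cnvr_set(cnvrs, genome)
        (outdir / "summary.json").write_text(
            json.dumps(summary.to_dict(), indent=1, sort_keys=True) + "\n"
        )

    annotations: list[CnvrAnnotation] = []
    genes = []
    if config.genes and Path(config.genes).exists():
        genes = read_gff3_genes(config.genes)
        for c in cnvrs:
            annotations.append(
                assign_genes(c, genes, proximal_window=config.proximal_window)
            )
        _write_tsv(
            outdir / "annotation.tsv",
            ["cnvr_id", "context", "primary_genes", "nearest_gene",
             "nearest_distance", "proximal_genes"],
            [
                [
                    a.cnvr_id,
                    a.context,
                    ",".join(g.symbol for g in a.primary_genes) or ".",
                    a.nearest_gene.symbol if a.nearest_gene else ".",
                    a.nearest_distance if a.nearest_distance is not None else ".",
                    ",".join(g.symbol for g in a.proximal_genes) or ".",
                ]
                for a in annotations
            ],
        )
        manifest["stages"]["annotated_cnvrs"] = len(annotations)

    qtl_report = None
    if not skip_qtl and config.qtls and Path(config.qtls).exists():
        qtls, _ = read_qtl_table(config.qtls)
        qtls = filter_qtls(qtls, max_span=config.qtl_max_span)
        qtl_report = intersect_cnvr_qtl(cnvrs, qtls, min_overlap=config.qtl_min_overlap)
        _write_tsv(
            outdir / "qtl_overlap.tsv",
            ["cnvr_id", "qtl_id", "trait", "overlap_bp"],
            [[p.cnvr_id, p.qtl_id, p.trait, p.overlap_bp] for p in qtl_report.pairs],
        )
        _write_tsv(
            outdir / "qtl_trait_counts.tsv",
            ["trait", "n_cnvrs"],
            sorted(qtl_report.trait_cnvr_counts.items()),
        )
        manifest["stages"]["qtl_pairs"] = len(qtl_report.pairs)

    vst_report = None
    candidates = None
    if not skip_vst and config.pop_map and Path(config.pop_map).exists():
        pop_map = read_population_map(config.pop_map)
        matrix = build_cn_matrix(cnvrs, pop_map, baseline=config.baseline_cn)
        if config.samples_pop1 or config.samples_pop2:
            keep = set(config.samples_pop1 or []) | set(config.samples_pop2 or [])
            matrix = matrix.subset_samples(keep)
        vst_report = compute_vst(matrix)
        candidates = select_candidates(
            vst_report.results,
            top_frac=config.top_frac,
            abs_threshold=config.abs_threshold,
        )
        _write_tsv(
            outdir / "vst.tsv",
            ["cnvr_id", "v_t", "v_s", "vst_raw", "vst", "percentile", "top10",
             "gt_half"],
            [
                [r.cnvr_id, f"{r.v_t:.6g}", f"{r.v_s:.6g}", f"{r.vst_raw:.6g}",
                 f"{r.vst:.6g}", f"{r.percentile_rank:.4g}",
                 int(r.top10), int(r.gt_half)]
                for r in vst_report.results
            ],
        )
        manifest["stages"]["vst_cnvrs"] = len(vst_report.results)
        manifest["stages"]["vst_mean"] = round(vst_report.mean_vst, 12)
        manifest["stages"]["candidates"] = len(candidates)
        if genes:
            per_cnvr, distinct = annotate_candidates(
                candidates, cnvrs, genes, proximal_window=config.proximal_window
            )
            _write_tsv(
                outdir / "candidates.tsv",
                ["cnvr_id", "vst", "genes"],
                [
                    [r.cnvr_id, f"{r.vst:.6g}", ",".join(per_cnvr[r.cnvr_id]) or "."]
                    for r in candidates
                ],
            )

    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return PipelineResult(
        cnvrs=cnvrs,
        summary=summary,
        annotations=annotations,
        qtl_report=qtl_report,
        vst_report=vst_report,
        candidates=candidates,
        manifest=manifest,
    )
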