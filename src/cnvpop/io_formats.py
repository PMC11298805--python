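"""Readers and writers for the external formats the pipeline touches.

All coordinates are held internally as 0-based half-open intervals (the BED
convention).  VCF and GFF3 are 1-based inclusive on disk and are converted at
this boundary, so downstream interval arithmetic never needs ±1 bookkeeping.
Chromosome names are taken verbatim; an optional rename map can be applied by
the caller.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CnvCall:
    """One caller-emitted copy-number variant for one sample.

    ``start``/``end`` are 0-based half-open.  ``copy_number`` and
    ``support_reads`` may be absent (``None``) depending on the caller;
    depth-based callers typically emit a copy number but no supporting-read
    count, split-read callers the reverse.  ``precise`` is False when the
    source record carried the IMPRECISE flag (breakpoints not base-pair
    resolved).
    """

    sample_id: str
    caller: str
    chrom: str
    start: int
    end: int
    svtype: str  # "DEL" or "DUP"
    copy_number: Optional[float] = None
    support_reads: Optional[int] = None
    precise: bool = True

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"CnvCall requires end > start, got [{self.start}, {self.end})"
            )
        if self.svtype not in ("DEL", "DUP"):
            raise ValueError(f"svtype must be DEL or DUP, got {self.svtype!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon structure, 0-based half-open coordinates."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")
        for (s, e) in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(
                    f"gene {self.gene_id}: exon [{s},{e}) outside gene span"
                )


@dataclass(frozen=True)
class QtlRecord:
    """A quantitative-trait-locus confidence interval with its trait label."""

    qtl_id: str
    trait: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"QTL {self.qtl_id}: span must be positive")

    @property
    def span(self) -> int:
        return self.end - self.start


class PopulationMap(dict):
    """sample_id -> population label; exactly two labels are required for Vst."""

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.values()))

    def samples_of(self, population: str) -> list[str]:
        return sorted(s for s, p in self.items() if p == population)


@dataclass
class ReaderStats:
    """Bookkeeping for a reader pass: ingested + skipped == records seen."""

    ingested: int = 0
    skipped: int = 0
    skip_reasons: dict = field(default_factory=dict)

    def skip(self, reason: str) -> None:
        self.skipped += 1
        self.skip_reasons[reason] = self.skip_reasons.get(reason, 0) + 1


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_SUPPORT_KEYS = ("RE", "SUPPORT", "DV", "SU", "PE")


def read_cnv_vcf(
    path: str | Path,
    sample_id: str,
    caller: str = "unknown",
    rename: Mapping[str, str] | None = None,
) -> tuple[list[CnvCall], ReaderStats]:
    """Read DEL/DUP structural-variant records from a VCF into CnvCalls.

    Records whose SVTYPE is anything else (INV, BND, INS, ...) are skipped and
    counted.  END is preferred for the right breakpoint; records lacking END
    fall back to POS + \\|SVLEN\\|; records with neither are rejected.  The
    IMPRECISE INFO flag maps to ``precise=False``.  Copy number is taken from
    a CN FORMAT field or CN INFO key when present; supporting reads from the
    first of RE/SUPPORT/DV/SU/PE found.

    Returns the calls and a :class:`ReaderStats` tally.
    """
    from cyvcf2 import VCF

    stats = ReaderStats()
    calls: list[CnvCall] = []
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise ValueError(f"malformed or unreadable VCF {path}: {exc}") from exc
    for line_no, rec in enumerate(vcf, start=1):
        svtype = rec.INFO.get("SVTYPE")
        if svtype not in ("DEL", "DUP"):
            stats.skip(f"svtype:{svtype}")
            continue
        chrom = rec.CHROM
        if rename:
            chrom = rename.get(chrom, chrom)
        start = rec.POS - 1  # 1-based -> 0-based
        # END (1-based inclusive == half-open end) is authoritative;
        # records lacking it fall back to |SVLEN|
        end = rec.INFO.get("END")
        if end is None:
            svlen = rec.INFO.get("SVLEN")
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            if svlen is None:
                stats.skip("no_end_no_svlen")
                continue
            end = start + abs(int(svlen))
        end = int(end)
        if end <= start:
            stats.skip("nonpositive_length")
            continue
        precise = rec.INFO.get("IMPRECISE") is None
        support = None
        for key in _SUPPORT_KEYS:
            val = rec.INFO.get(key)
            if val is not None:
                if isinstance(val, (tuple, list)):
                    val = val[0]
                support = int(val)
                break
        cn = _resolve_copy_number(rec)
        calls.append(
            CnvCall(
                sample_id=sample_id,
                caller=caller,
                chrom=chrom,
                start=start,
                end=end,
                svtype=str(svtype),
                copy_number=cn,
                support_reads=support,
                precise=precise,
            )
        )
        stats.ingested += 1
    vcf.close()
    if stats.skipped:
        logger.info("read_cnv_vcf(%s): skipped %d records (%s)",
                    path, stats.skipped, stats.skip_reasons)
    return calls, stats


def _resolve_copy_number(rec) -> Optional[float]:
    # CN may live in FORMAT (per-sample) or INFO depending on the caller.
    try:
        arr = rec.format("CN")
    except KeyError:
        arr = None
    if arr is not None:
        val = float(arr[0][0])
        if not math.isnan(val):
            return val
    cn = rec.INFO.get("CN")
    if cn is not None:
        if isinstance(cn, (tuple, list)):
            cn = cn[0]
        return float(cn)
    return None


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Parse gene and exon features from a GFF3 file into GeneModels.

    Exons are attached to their gene through Parent chains (exon -> mRNA ->
    gene or exon -> gene).  Exons whose parent cannot be resolved to a gene
    are dropped with a warning.  Coordinates convert 1-based inclusive ->
    0-based half-open.
    """
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except EmptyInputError:
        return []
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        exons = []
        for ex in db.children(g, featuretype="exon"):
            exons.append((ex.start - 1, ex.end))
        exons = sorted(set(exons))
        symbol = g.attributes.get("Name", [g.id])[0]
        genes.append(
            GeneModel(
                gene_id=g.id,
                symbol=symbol,
                chrom=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand or ".",
                exons=tuple(exons),
            )
        )
    # exons with unresolvable parents
    gene_ids = {g.gene_id for g in genes}
    for ex in db.features_of_type("exon"):
        parents = list(db.parents(ex))
        if not any(
            p.featuretype == "gene" or p.id in gene_ids for p in parents
        ):
            logger.warning("exon %s has no resolvable parent gene; dropped", ex.id)
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


# ---------------------------------------------------------------------------
# QTL table (QTLdb-style TSV, 1-based inclusive)
# ---------------------------------------------------------------------------

def read_qtl_table(path: str | Path) -> tuple[list[QtlRecord], ReaderStats]:
    """Read a TSV of QTL intervals (columns qtl_id, trait, chrom, start, end).

    The QTLdb dialect is 1-based inclusive; spans are computed after
    conversion to half-open.  Rows with end < start are rejected with a
    warning.  Trait strings are preserved verbatim, spaces included.
    """
    stats = ReaderStats()
    records: list[QtlRecord] = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if header is None:
                header = line.lstrip("#").split("\t")
                idx = {name: i for i, name in enumerate(header)}
                for col in ("qtl_id", "trait", "chrom", "start", "end"):
                    if col not in idx:
                        raise ValueError(f"QTL table missing column {col!r}")
                continue
            parts = line.split("\t")
            start1 = int(parts[idx["start"]])
            end1 = int(parts[idx["end"]])
            if end1 < start1:
                logger.warning("QTL %s: end < start, rejected", parts[idx["qtl_id"]])
                stats.skip("inverted_interval")
                continue
            records.append(
                QtlRecord(
                    qtl_id=parts[idx["qtl_id"]],
                    trait=parts[idx["trait"]],
                    chrom=parts[idx["chrom"]],
                    start=start1 - 1,
                    end=end1,
                )
            )
            stats.ingested += 1
    return records, stats


def write_qtl_table(qtls: Sequence[QtlRecord], path: str | Path) -> None:
    """Write QTL records back to the 1-based inclusive TSV dialect."""
    with open(path, "w") as fh:
        fh.write("qtl_id\ttrait\tchrom\tstart\tend\n")
        for q in qtls:
            fh.write(f"{q.qtl_id}\t{q.trait}\t{q.chrom}\t{q.start + 1}\t{q.end}\n")


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------

def read_population_map(path: str | Path) -> PopulationMap:
    """Read a two-column sample -> population TSV; duplicate samples error."""
    pm = PopulationMap()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split("\t")[:2]
            if sample in pm:
                raise ValueError(f"sample {sample} appears twice in population map")
            pm[sample] = pop
    return pm


def write_population_map(pm: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample in sorted(pm):
            fh.write(f"{sample}\t{pm[sample]}\n")


# ---------------------------------------------------------------------------
# CNVR BED6
# ---------------------------------------------------------------------------

def write_cnvr_bed(cnvrs: Iterable, path: str | Path) -> None:
    """Write CNVRs as BED6-style rows: chrom start end id type sample_count.

    Sorted by (chrom, start).  Round-trips losslessly through
    :func:`read_cnvr_bed` at the extent/type/carrier-count level.
    """
    rows = sorted(cnvrs, key=lambda c: (c.chrom, c.start, c.end))
    with open(path, "w") as fh:
        for c in rows:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.cnvr_id}\t{c.type}\t"
                f"{len(c.sample_ids)}\n"
            )


def read_cnvr_bed(path: str | Path) -> list:
    """Read the BED6 written by :func:`write_cnvr_bed` back into Cnvr shells.

    Member calls are not recoverable from BED; the returned regions carry
    extent, type and carrier count (as anonymous sample placeholders).
    """
    from .cnvr_construction import Cnvr

    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, cnvr_id, ctype, n = line.split("\t")[:6]
            out.append(
                Cnvr(
                    cnvr_id=cnvr_id,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    type=ctype,
                    member_calls=(),
                    sample_ids=frozenset(f"_s{i}" for i in range(int(n))),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Genome table
# ---------------------------------------------------------------------------

def read_genome_table(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom<TAB>length TSV."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, length = line.split("\t")[:2]
            lengths[chrom] = int(length)
    return lengths


def write_genome_table(lengths: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in lengths:
            fh.write(f"{chrom}\t{lengths[chrom]}\n")
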