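"""CNVR x QTL intersection under a strict >1 kb overlap rule.

QTL confidence intervals wider than 5 Mb carry too little positional
information to implicate a specific CNVR, so they are dropped before
intersection (span < 5 Mb, strict).  A CNVR-QTL pair qualifies only when the
two intervals share strictly more than ``min_overlap`` bp (default 1 kb).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .cnvr_construction import Cnvr
from .io_formats import QtlRecord


@dataclass(frozen=True)
class QtlOverlap:
    cnvr_id: str
    qtl_id: str
    trait: str
    overlap_bp: int


@dataclass
class QtlOverlapReport:
    pairs: list[QtlOverlap]
    n_cnvrs: int  # distinct CNVRs in qualifying pairs
    n_qtls: int   # distinct QTLs in qualifying pairs
    trait_cnvr_counts: dict[str, int]  # distinct CNVRs per trait


def filter_qtls(
    qtls: Iterable[QtlRecord], max_span: int = 5_000_000
) -> list[QtlRecord]:
    """Keep QTLs whose confidence-interval span is strictly below max_span."""
    return [q for q in qtls if q.span < max_span]


def intersect_cnvr_qtl(
    cnvrs: Sequence[Cnvr],
    qtls: Sequence[QtlRecord],
    min_overlap: int = 1000,
) -> QtlOverlapReport:
    """Emit every CNVR-QTL pair overlapping by strictly more than min_overlap bp.

    Also tallies distinct CNVRs, distinct QTLs, and distinct CNVRs per trait
    label (the same CNVR hitting two QTLs of one trait counts once for that
    trait).
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for q in qtls:
        trees[q.chrom].addi(q.start, q.end, q)
    pairs: list[QtlOverlap] = []
    for c in cnvrs:
        for iv in sorted(trees[c.chrom].overlap(c.start, c.end)):
            q: QtlRecord = iv.data
            ov = min(c.end, q.end) - max(c.start, q.start)
            if ov > min_overlap:
                pairs.append(QtlOverlap(c.cnvr_id, q.qtl_id, q.trait, ov))
    pairs.sort(key=lambda p: (p.cnvr_id, p.qtl_id))
    trait_sets: dict[str, set[str]] = defaultdict(set)
    for p in pairs:
        trait_sets[p.trait].add(p.cnvr_id)
    return QtlOverlapReport(
        pairs=pairs,
        n_cnvrs=len({p.cnvr_id for p in pairs}),
        n_qtls=len({p.qtl_id for p in pairs}),
        trait_cnvr_counts={t: len(s) for t, s in sorted(trait_sets.items())},
    )
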