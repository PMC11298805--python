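"""Gene assignment, genomic-context classification and overrepresentation tests.

Gene assignment follows the overlap/nearest/proximal rule set: genes
overlapping a CNVR by at least 1 bp are its primary annotation; a CNVR with
no overlapping gene is assigned its nearest gene on the chromosome; genes
within 1 kb that are neither primary nor the nearest are reported as
additional proximal genes (dosage changes this close can still perturb
expression).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

from .cnvr_construction import Cnvr
from .io_formats import GeneModel


@dataclass
class CnvrAnnotation:
    cnvr_id: str
    primary_genes: list[GeneModel] = field(default_factory=list)
    nearest_gene: Optional[GeneModel] = None
    nearest_distance: Optional[int] = None
    proximal_genes: list[GeneModel] = field(default_factory=list)
    context: str = "intergenic"

    @property
    def genes(self) -> list[GeneModel]:
        """Primary genes when any overlap; otherwise the nearest gene."""
        if self.primary_genes:
            return list(self.primary_genes)
        return [self.nearest_gene] if self.nearest_gene else []


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _boundary_distance(cnvr: Cnvr, gene: GeneModel) -> int:
    """Gap between non-overlapping intervals (0 when they touch or overlap)."""
    if gene.start >= cnvr.end:
        return gene.start - cnvr.end
    if gene.end <= cnvr.start:
        return cnvr.start - gene.end
    return 0


def assign_genes(
    cnvr: Cnvr,
    genes: Sequence[GeneModel],
    proximal_window: int = 1000,
    min_overlap: int = 1,
) -> CnvrAnnotation:
    """Assign genes to one CNVR by the overlap / nearest / within-1-kb rules.

    ``min_overlap`` is the bp overlap that makes a gene primary (1 by
    default; a stricter >=2 bp reading is available through the knob).
    Nearest-gene ties break toward the lower start coordinate, then gene id,
    deterministically.  Proximal genes exclude both primary genes and the
    nearest gene: the roles are disjoint.
    """
    ann = CnvrAnnotation(cnvr_id=cnvr.cnvr_id)
    same_chrom = [g for g in genes if g.chrom == cnvr.chrom]
    if not same_chrom:
        ann.context = "intergenic"
        return ann
    for g in same_chrom:
        if _overlap(cnvr.start, cnvr.end, g.start, g.end) >= min_overlap:
            ann.primary_genes.append(g)
    ann.primary_genes.sort(key=lambda g: (g.start, g.gene_id))
    if not ann.primary_genes:
        best = min(
            same_chrom,
            key=lambda g: (_boundary_distance(cnvr, g), g.start, g.gene_id),
        )
        ann.nearest_gene = best
        ann.nearest_distance = _boundary_distance(cnvr, best)
    primary_ids = {g.gene_id for g in ann.primary_genes}
    nearest_id = ann.nearest_gene.gene_id if ann.nearest_gene else None
    for g in same_chrom:
        if g.gene_id in primary_ids or g.gene_id == nearest_id:
            continue
        # distance 0 covers abutting genes and any sub-threshold overlaps
        # left over when a stricter min_overlap knob is in force
        if _boundary_distance(cnvr, g) <= proximal_window:
            ann.proximal_genes.append(g)
    ann.proximal_genes.sort(key=lambda g: (g.start, g.gene_id))
    ann.context = classify_context(cnvr, same_chrom)
    return ann


def classify_context(
    cnvr: Cnvr,
    genes: Sequence[GeneModel],
    flank: int = 1000,
) -> str:
    """Genomic context with precedence exonic > intronic > other-genic >
    upstream/downstream > intergenic.

    A CNVR touching any exon by >= 1 bp is exonic.  One overlapping a gene
    body without touching an exon is intronic when the gene has exons, and
    "other-genic" when the gene model carries no exon structure.  The
    up/downstream windows extend ``flank`` bp beyond the gene span,
    strand-aware (upstream of a + gene is before its start; of a - gene,
    past its end).
    """
    same_chrom = [g for g in genes if g.chrom == cnvr.chrom]
    exonic = intronic = other_genic = upstream = downstream = False
    for g in same_chrom:
        body = _overlap(cnvr.start, cnvr.end, g.start, g.end)
        if body > 0:
            if any(_overlap(cnvr.start, cnvr.end, s, e) > 0 for s, e in g.exons):
                exonic = True
            elif g.exons:
                intronic = True
            else:
                other_genic = True
            continue
        d = _boundary_distance(cnvr, g)
        if d == 0 or d > flank:
            continue
        before = cnvr.end <= g.start  # CNVR lies left of the gene
        if g.strand == "-":
            upstream |= not before
            downstream |= before
        else:  # '+' and unstranded treated as '+'
            upstream |= before
            downstream |= not before
    if exonic:
        return "exonic"
    if intronic:
        return "intronic"
    if other_genic:
        return "other-genic"
    if upstream:
        return "upstream"
    if downstream:
        return "downstream"
    return "intergenic"


# ---------------------------------------------------------------------------
# Overrepresentation analysis
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    term_id: str
    term_size: int
    overlap_count: int
    p_value: float
    adjusted_p: float


def enrichment_test(
    query_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """One-sided hypergeometric overrepresentation test per gene set.

    For a universe of M genes, a term of size n (after intersecting the set
    with the universe) and a query of N genes drawn from the universe, the
    p-value is P(X >= k) for the observed overlap k under
    Hypergeom(M, n, N).  Benjamini-Hochberg adjustment is applied across all
    tested terms and results are sorted by raw p, then term id.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query_genes) & universe
    results: list[EnrichmentResult] = []
    for term_id in sorted(gene_sets):
        members = set(gene_sets[term_id]) & universe
        k = len(query & members)
        # upper tail P(X >= k) == sf(k - 1)
        p = float(hypergeom.sf(k - 1, len(universe), len(members), len(query)))
        p = min(1.0, max(0.0, p))
        results.append(
            EnrichmentResult(
                term_id=term_id,
                term_size=len(members),
                overlap_count=k,
                p_value=p,
                adjusted_p=p,
            )
        )
    if results:
        from statsmodels.stats.multitest import multipletests

        pvals = [r.p_value for r in results]
        _, adj, _, _ = multipletests(pvals, method="fdr_bh")
        for r, a in zip(results, adj):
            r.adjusted_p = float(a)
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets in GMT format: term <TAB> description <TAB> gene..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets
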