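"""Gene assignment, genomic context and overrepresentation statistics."""

import itertools
import math
import random

import pytest

from cnvpop.annotation import (
    assign_genes,
    classify_context,
    enrichment_test,
)
from cnvpop.cnvr_construction import Cnvr
from cnvpop.io_formats import GeneModel


def gene(gid, start, end, chrom="chr1", strand="+", exons=()):
    return GeneModel(
        gene_id=gid, symbol=gid.upper(), chrom=chrom, start=start, end=end,
        strand=strand, exons=tuple(exons),
    )


def cnvr(start, end, chrom="chr1", cid="CNVR_1"):
    return Cnvr(cid, chrom, start, end, "dup")


class TestAssignGenes:
    def test_overlapping_gene_is_primary(self):
        ann = assign_genes(cnvr(100, 300), [gene("g1", 250, 900)])
        assert [g.gene_id for g in ann.primary_genes] == ["g1"]
        assert ann.nearest_gene is None

    def test_nearest_when_no_overlap_and_proximal_disjoint(self):
        genes = [gene("g1", 500, 900), gene("g2", 5000, 6000)]
        ann = assign_genes(cnvr(100, 200), genes)
        assert ann.primary_genes == []
        assert ann.nearest_gene.gene_id == "g1"
        assert ann.nearest_distance == 300
        # g1 is within 1 kb but already holds the nearest role; g2 is too far
        assert ann.proximal_genes == []

    def test_distance_tie_breaks_to_lower_coordinate(self):
        # CNVR [1200, 1300): gap to left gene = 1200-900 = 300,
        # gap to right gene = 1600-1300 = 300 -> true tie
        genes = [gene("right", 1600, 2000), gene("left", 400, 900)]
        ann = assign_genes(cnvr(1200, 1300), genes)
        assert ann.nearest_gene.gene_id == "left"
        assert [g.gene_id for g in ann.proximal_genes] == ["right"]

    def test_no_gene_on_chromosome_is_intergenic(self):
        ann = assign_genes(cnvr(100, 200), [gene("g1", 0, 100, chrom="chr9")])
        assert ann.context == "intergenic"
        assert ann.genes == []

    def test_brute_force_oracle_random_fixtures(self):
        rng = random.Random(17)
        genes = []
        for i in range(60):
            s = rng.randrange(0, 50_000)
            genes.append(gene(f"g{i}", s, s + rng.randrange(100, 3000)))
        for j in range(60):
            s = rng.randrange(0, 50_000)
            c = cnvr(s, s + rng.randrange(50, 2000), cid=f"CNVR_{j}")
            ann = assign_genes(c, genes)
            expect_primary = sorted(
                g.gene_id
                for g in genes
                if min(c.end, g.end) - max(c.start, g.start) >= 1
            )
            assert sorted(g.gene_id for g in ann.primary_genes) == expect_primary
            if not expect_primary:
                dist = lambda g: max(g.start - c.end, c.start - g.end, 0)
                best = min(dist(g) for g in genes)
                assert ann.nearest_distance == best


class TestClassifyContext:
    def test_intronic(self):
        g = gene("g1", 1000, 5000, exons=[(1000, 1500), (4500, 5000)])
        assert classify_context(cnvr(2000, 2500), [g]) == "intronic"

    def test_exonic_takes_precedence(self):
        g = gene("g1", 1000, 5000, exons=[(1000, 1500), (4500, 5000)])
        assert classify_context(cnvr(1400, 2500), [g]) == "exonic"

    def test_downstream_of_plus_strand_gene(self):
        g = gene("g1", 1000, 5000, strand="+", exons=[(1000, 5000)])
        assert classify_context(cnvr(5600, 5800), [g]) == "downstream"
        assert classify_context(cnvr(200, 400), [g]) == "upstream"

    def test_strand_flips_up_downstream(self):
        g = gene("g1", 1000, 5000, strand="-", exons=[(1000, 5000)])
        assert classify_context(cnvr(5600, 5800), [g]) == "upstream"

    def test_beyond_flank_is_intergenic(self):
        g = gene("g1", 1000, 5000, exons=[(1000, 5000)])
        assert classify_context(cnvr(6500, 6800), [g]) == "intergenic"

    def test_gene_without_exons_is_other_genic(self):
        g = gene("g1", 1000, 5000)
        assert classify_context(cnvr(2000, 2500), [g]) == "other-genic"

    def test_every_cnvr_gets_exactly_one_context(self):
        g = gene("g1", 1000, 5000, exons=[(1000, 1500)])
        contexts = {"exonic", "intronic", "other-genic", "upstream",
                    "downstream", "intergenic"}
        for start in range(0, 8000, 250):
            assert classify_context(cnvr(start, start + 200), [g]) in contexts


def exact_tail(M, n, N, k):
    """P(X >= k) for Hypergeom(M, n, N) by direct combinatorial summation."""
    denom = math.comb(M, N)
    return sum(
        math.comb(n, i) * math.comb(M - n, N - i)
        for i in range(k, min(n, N) + 1)
    ) / denom


class TestEnrichment:
    def test_worked_case_1_in_15504(self):
        universe = [f"g{i}" for i in range(20)]
        term = set(universe[:5])
        results = enrichment_test(universe[:5], {"T": term}, universe)
        (r,) = results
        assert r.overlap_count == 5
        assert r.p_value == pytest.approx(1 / 15504, rel=1e-12)

    def test_query_equals_universe_gives_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        results = enrichment_test(universe, {"T": universe[:4]}, universe)
        assert results[0].overlap_count == 4
        assert results[0].p_value == pytest.approx(1.0)

    def test_bh_adjustment_step_up(self):
        # three terms engineered to give ordered raw p-values, then check
        # adjusted_p = min over j>=i of p_j * m / j
        universe = [f"g{i}" for i in range(30)]
        sets = {
            "T1": set(universe[:6]),
            "T2": set(universe[:12]),
            "T3": set(universe[:20]),
        }
        results = enrichment_test(universe[:6], sets, universe)
        m = len(results)
        ps = [r.p_value for r in results]
        expected = [
            min(ps[j] * m / (j + 1) for j in range(i, m)) for i in range(m)
        ]
        for r, e in zip(results, expected):
            assert r.adjusted_p == pytest.approx(min(1.0, e))
            assert r.adjusted_p >= r.p_value - 1e-15

    def test_matches_enumeration_small_universes(self):
        rng = random.Random(5)
        for M in list(range(2, 13)) + [20, 30]:
            universe = [f"g{i}" for i in range(M)]
            for _ in range(6):
                n = rng.randint(0, M)
                N = rng.randint(1, M)
                term = set(rng.sample(universe, n))
                query = rng.sample(universe, N)
                (r,) = enrichment_test(query, {"T": term}, universe)
                k = len(term & set(query))
                assert r.p_value == pytest.approx(exact_tail(M, n, N, k), abs=1e-12)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            enrichment_test(["g1"], {"T": {"g1"}}, [])
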