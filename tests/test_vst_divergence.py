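"""Vst statistic: variance conventions, candidate selection, matrix building."""

import math
import random

import numpy as np
import pandas as pd
import pytest

from cnvpop.cnvr_construction import Cnvr
from cnvpop.io_formats import GeneModel, PopulationMap
from cnvpop.vst_divergence import (
    CopyNumberMatrix,
    annotate_candidates,
    build_cn_matrix,
    compute_vst,
    select_candidates,
    vst_from_groups,
)
from conftest import make_call


def matrix_from_rows(rows, n1, n2):
    """rows: cnvr_id -> list of n1+n2 copy numbers (pop A first)."""
    samples = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    pm = PopulationMap({s: ("A" if s.startswith("a") else "B") for s in samples})
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples, dtype=float)
    return CopyNumberMatrix(values=df, populations=pm)


def naive_vst(pop1, pop2):
    """Independent two-pass population-variance implementation."""

    def var(xs):
        m = sum(xs) / len(xs)
        return sum((x - m) ** 2 for x in xs) / len(xs)

    vt = var(list(pop1) + list(pop2))
    if vt == 0:
        return 0.0
    vs = (len(pop1) * var(pop1) + len(pop2) * var(pop2)) / (len(pop1) + len(pop2))
    return (vt - vs) / vt


class TestComputeVst:
    def test_no_variation_gives_zero(self):
        m = matrix_from_rows({"r1": [2, 2, 2, 2, 2, 2]}, 3, 3)
        (r,) = compute_vst(m).results
        assert r.vst == 0.0 and r.v_t == 0.0

    def test_complete_fixation_gives_exactly_one(self):
        m = matrix_from_rows({"r1": [2, 2, 2, 4, 4, 4]}, 3, 3)
        (r,) = compute_vst(m).results
        assert r.vst == 1.0 and r.v_s == 0.0

    def test_worked_example_quarter(self):
        m = matrix_from_rows({"r1": [2, 2, 2, 4, 2, 4, 4, 4]}, 4, 4)
        (r,) = compute_vst(m).results
        assert r.v_t == pytest.approx(1.0)
        assert r.v_s == pytest.approx(0.75)
        assert r.vst == pytest.approx(0.25)

    def test_label_swap_invariance(self):
        rows = {f"r{i}": list(np.random.default_rng(i).integers(0, 5, 7))
                for i in range(10)}
        m = matrix_from_rows(rows, 4, 3)
        swapped = CopyNumberMatrix(
            values=m.values,
            populations=PopulationMap(
                {s: ("B" if p == "A" else "A") for s, p in m.populations.items()}
            ),
        )
        a = compute_vst(m)
        b = compute_vst(swapped)
        assert [r.vst for r in a.results] == pytest.approx(
            [r.vst for r in b.results], abs=1e-15
        )

    def test_matches_naive_oracle_and_stays_in_range(self):
        rng = random.Random(31)
        for _ in range(200):
            n1 = rng.randint(2, 8)
            n2 = rng.randint(2, 8)
            rows = {
                f"r{j}": [rng.choice([0, 1, 2, 3, 4]) for _ in range(n1 + n2)]
                for j in range(5)
            }
            report = compute_vst(matrix_from_rows(rows, n1, n2))
            for r in report.results:
                expected = naive_vst(rows[r.cnvr_id][:n1], rows[r.cnvr_id][n1:])
                assert r.vst_raw == pytest.approx(expected, abs=1e-12)
                assert 0.0 <= r.vst <= 1.0

    def test_small_population_errors(self):
        m = matrix_from_rows({"r1": [2, 2, 4]}, 1, 2)
        with pytest.raises(ValueError):
            compute_vst(m)

    def test_mean_vst_reported(self):
        m = matrix_from_rows({"r1": [2, 2, 2, 4, 4, 4], "r2": [2, 2, 2, 2, 2, 2]}, 3, 3)
        assert compute_vst(m).mean_vst == pytest.approx(0.5)


class TestVstFromGroups:
    def test_agrees_with_matrix_path(self):
        pop1, pop2 = [2, 2, 2, 4], [2, 4, 4, 4]
        vt, vs, v = vst_from_groups(pop1, pop2)
        assert (vt, vs, v) == (pytest.approx(1.0), pytest.approx(0.75),
                               pytest.approx(0.25))


class TestSelectCandidates:
    def make_results(self, vsts):
        m = matrix_from_rows(
            {f"r{i:02d}": [2, 2, 2, 2] for i in range(len(vsts))}, 2, 2
        )
        report = compute_vst(m)
        for r, v in zip(report.results, vsts):
            r.vst = v
        return report.results

    def test_ten_distinct_gives_one_flag(self):
        results = self.make_results([i / 10 for i in range(10)])
        cands = select_candidates(results)
        assert len(cands) == 1 and cands[0].vst == pytest.approx(0.9)
        assert sum(r.top10 for r in results) == 1

    @pytest.mark.parametrize("v,flag", [(0.5, False), (0.5001, True)])
    def test_gt_half_strict(self, v, flag):
        results = self.make_results([v, 0.1, 0.1, 0.1])
        select_candidates(results)
        assert results[0].gt_half is flag

    def test_tie_break_by_id_is_stable(self):
        # 20 results, three tied at the 10% boundary -> ceil(2) selected
        vsts = [0.9] + [0.8, 0.8, 0.8] + [0.1] * 16
        first = select_candidates(self.make_results(vsts))
        second = select_candidates(self.make_results(vsts))
        assert len(first) == 2
        assert [r.cnvr_id for r in first] == [r.cnvr_id for r in second]
        # the boundary tie resolves to the lexicographically first id
        tied = sorted(r.cnvr_id for r in self.make_results(vsts)[1:4])
        assert first[1].cnvr_id == tied[0]

    def test_percentile_rank_nearest_rank(self):
        results = self.make_results([0.1, 0.2, 0.3, 0.4])
        select_candidates(results)
        assert [r.percentile_rank for r in results] == [25.0, 50.0, 75.0, 100.0]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            select_candidates([])


class TestBuildCnMatrix:
    def make_cnvr(self, members, cid="CNVR_1"):
        return Cnvr(cid, "chr1", 100, 500, "dup", member_calls=tuple(members))

    def test_cell_rules(self):
        pm = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
        members = [
            make_call(sample="s1", cn=4.0, svtype="DUP"),
            make_call(sample="s2", cn=1.0, svtype="DEL", start=100, end=180),
            make_call(sample="s2", cn=0.0, svtype="DEL", start=300, end=400),
            make_call(sample="s3", cn=None, svtype="DUP"),
        ]
        m = build_cn_matrix([self.make_cnvr(members)], pm)
        row = m.values.loc["CNVR_1"]
        assert row["s1"] == 4.0
        assert row["s2"] == pytest.approx(0.5)  # mean of member calls
        assert row["s3"] == 3.0                 # svtype default for missing CN
        assert row["s4"] == 2.0                 # diploid baseline

    def test_unknown_sample_errors(self):
        members = [make_call(sample="ghost", cn=4.0)]
        with pytest.raises(ValueError):
            build_cn_matrix([self.make_cnvr(members)], {"s1": "A"})


class TestAnnotateCandidates:
    def test_shared_gene_listed_once(self):
        g = GeneModel(gene_id="g1", symbol="G1", chrom="chr1", start=0, end=10_000)
        cnvrs = [
            Cnvr("CNVR_1", "chr1", 100, 500, "dup"),
            Cnvr("CNVR_2", "chr1", 700, 900, "dup"),
        ]
        m = matrix_from_rows({"CNVR_1": [2, 2, 4, 4], "CNVR_2": [2, 2, 4, 4]}, 2, 2)
        results = compute_vst(m).results
        per_cnvr, distinct = annotate_candidates(results, cnvrs, [g])
        assert per_cnvr == {"CNVR_1": ["G1"], "CNVR_2": ["G1"]}
        assert distinct == ["G1"]
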