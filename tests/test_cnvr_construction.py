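"""Call filtering, merging, classification, length ceilings and summaries."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from cnvpop.cnvr_construction import (
    Cnvr,
    apply_length_filters,
    classify_cnvr,
    filter_calls,
    mean_length_bp,
    merge_calls_to_cnvrs,
    summarize_cnvr_set,
)
from conftest import make_call


class TestFilterCalls:
    @pytest.mark.parametrize(
        "length,expect_kept",
        [(49, False), (50, True)],
        ids=["just-short", "at-threshold"],
    )
    def test_length_boundary(self, length, expect_kept):
        kept, _ = filter_calls([make_call(start=0, end=length)])
        assert bool(kept) is expect_kept

    @pytest.mark.parametrize("support,expect_kept", [(3, False), (4, True), (None, True)])
    def test_support_boundary_missing_passes(self, support, expect_kept):
        kept, _ = filter_calls([make_call(support=support)])
        assert bool(kept) is expect_kept

    def test_imprecise_dropped_unless_allowed(self):
        call = make_call(precise=False)
        assert not filter_calls([call])[0]
        assert filter_calls([call], require_precise=False)[0] == [call]

    def test_tally_attributes_first_failing_rule(self):
        # 10 calls: 2 imprecise (one also short), 1 short, 1 under-supported
        calls = [make_call(sample=f"s{i}") for i in range(6)]
        calls += [
            make_call(precise=False),
            make_call(precise=False, start=0, end=30),  # counted under precise
            make_call(start=0, end=30),
            make_call(support=2),
        ]
        kept, tally = filter_calls(calls)
        assert len(kept) == 6
        assert (tally.precise, tally.length, tally.support) == (2, 1, 1)
        assert tally.total == len(calls) - len(kept)


class TestMerge:
    def test_chained_overlap_merges(self):
        calls = [
            make_call(start=100, end=200, svtype="DUP"),
            make_call(start=150, end=300, svtype="DUP", sample="s2"),
            make_call(start=400, end=500, svtype="DEL"),
        ]
        cnvrs = merge_calls_to_cnvrs(calls)
        assert [(c.chrom, c.start, c.end, c.type) for c in cnvrs] == [
            ("chr1", 100, 300, "dup"),
            ("chr1", 400, 500, "del"),
        ]
        assert cnvrs[0].sample_ids == frozenset({"s1", "s2"})

    def test_single_call_identity(self):
        (c,) = merge_calls_to_cnvrs([make_call(start=7, end=77)])
        assert (c.start, c.end, c.cnvr_id) == (7, 77, "CNVR_1")

    def test_abutting_half_open_not_merged(self):
        cnvrs = merge_calls_to_cnvrs(
            [make_call(start=100, end=200), make_call(start=200, end=300, sample="s2")]
        )
        assert len(cnvrs) == 2

    def test_same_coordinates_different_chromosomes(self):
        cnvrs = merge_calls_to_cnvrs(
            [make_call(chrom="chr1"), make_call(chrom="chr2", sample="s2")]
        )
        assert len(cnvrs) == 2

    def test_order_invariance(self):
        calls = [
            make_call(start=s, end=s + 120, sample=f"s{i}")
            for i, s in enumerate([500, 100, 180, 900, 950])
        ]
        a = merge_calls_to_cnvrs(calls)
        b = merge_calls_to_cnvrs(list(reversed(calls)))
        assert [(c.start, c.end) for c in a] == [(c.start, c.end) for c in b]

    def test_idempotence_on_extents(self):
        calls = [
            make_call(start=100, end=300),
            make_call(start=250, end=600, sample="s2"),
            make_call(start=900, end=1000),
        ]
        once = merge_calls_to_cnvrs(calls)
        again = merge_calls_to_cnvrs(
            [make_call(start=c.start, end=c.end) for c in once]
        )
        assert [(c.start, c.end) for c in once] == [(c.start, c.end) for c in again]

    def test_reciprocal_overlap_mode_is_stricter(self):
        # 10 bp overlap is 10% of one call and 1% of the other
        calls = [
            make_call(start=0, end=100),
            make_call(start=90, end=1090, sample="s2"),
        ]
        assert len(merge_calls_to_cnvrs(calls)) == 1
        assert len(merge_calls_to_cnvrs(calls, min_reciprocal=0.05)) == 2


def brute_force_merge(intervals):
    """Union-find over the pairwise overlap matrix: the independent oracle."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = intervals[i], intervals[j]
            if ci[0] == cj[0] and min(ci[2], cj[2]) - max(ci[1], cj[1]) > 0:
                parent[find(j)] = find(i)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(intervals[i])
    return sorted(
        (g[0][0], min(x[1] for x in g), max(x[2] for x in g)) for g in groups.values()
    )


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.sampled_from(["chr1", "chr2"]),
            st.integers(min_value=0, max_value=2000),
            st.integers(min_value=1, max_value=400),
        ),
        min_size=1,
        max_size=60,
    )
)
def test_merge_matches_union_find_oracle(raw):
    intervals = [(c, s, s + l) for c, s, l in raw]
    calls = [
        make_call(chrom=c, start=s, end=e, sample=f"s{i}")
        for i, (c, s, e) in enumerate(intervals)
    ]
    got = sorted((c.chrom, c.start, c.end) for c in merge_calls_to_cnvrs(calls))
    assert got == brute_force_merge(intervals)


class TestClassify:
    @pytest.mark.parametrize(
        "svtypes,expected",
        [(["DUP", "DUP"], "dup"), (["DEL"], "del"), (["DUP", "DEL"], "both")],
    )
    def test_member_classification(self, svtypes, expected):
        members = tuple(
            make_call(start=100, end=200 + i, svtype=t, sample=f"s{i}")
            for i, t in enumerate(svtypes)
        )
        cnvr = Cnvr("CNVR_1", "chr1", 100, 210, "?", member_calls=members)
        assert classify_cnvr(cnvr) == expected

    def test_empty_members_error(self):
        with pytest.raises(ValueError):
            classify_cnvr(Cnvr("CNVR_1", "chr1", 0, 1, "dup"))


def region(ctype, length, i=1):
    return Cnvr(f"CNVR_{i}", "chr1", 0, length, ctype)


class TestLengthFilters:
    @pytest.mark.parametrize(
        "ctype,length,kept",
        [
            ("del", 50_000, True),
            ("del", 50_001, False),
            ("both", 50_000, True),
            ("both", 50_001, False),
            ("dup", 499_999, True),
            ("dup", 500_000, False),
        ],
    )
    def test_per_type_ceilings(self, ctype, length, kept):
        result, dropped = apply_length_filters([region(ctype, length)])
        assert (len(result) == 1) is kept
        assert (len(dropped) == 1) is not kept

    def test_empty_input(self):
        assert apply_length_filters([]) == ([], [])


class TestSummary:
    def test_full_chromosome_coverage(self):
        cnvrs = [Cnvr("CNVR_1", "chr1", 0, 1_000_000, "dup")]
        s = summarize_cnvr_set(cnvrs, {"chr1": 1_000_000})
        assert s.genome_coverage == pytest.approx(1.0)

    def test_type_counts_partition(self):
        cnvrs = (
            [region("dup", 1000, i) for i in range(3)]
            + [region("del", 1000, i + 3) for i in range(2)]
            + [region("both", 1000, 6)]
        )
        s = summarize_cnvr_set(cnvrs, {"chr1": 10_000_000})
        assert s.counts_by_type == {"dup": 3, "del": 2, "both": 1}
        assert sum(s.counts_by_type.values()) == s.n_cnvr == 6

    def test_histogram_and_mean(self):
        cnvrs = [region("dup", l, i) for i, l in enumerate([300, 1500, 1999, 7000])]
        s = summarize_cnvr_set(cnvrs, {"chr1": 10_000_000})
        counts = {(lo, hi): n for lo, hi, n in s.length_histogram}
        assert counts[(1000, 2000)] == 2
        assert counts[(5000, 10_000)] == 1
        assert counts[(50_000, math.inf)] == 0
        assert s.mean_length_bp == round((300 + 1500 + 1999 + 7000) / 4)

    def test_unknown_chromosome_errors(self):
        with pytest.raises(ValueError):
            summarize_cnvr_set([region("dup", 100)], {"chrX": 1000})


def test_mean_length_rounds_to_nearest_bp():
    assert mean_length_bp(10, 4) == 3  # 2.5 rounds up
    assert mean_length_bp(0, 0) == 0
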