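"""Call filtering, CNVR merging, classification and landscape summaries.

A CNV region (CNVR) is the union of overlapping CNV calls across samples and
callers, treated as one locus.  Merging is single-linkage: any two calls on
the same chromosome whose half-open intervals share >= 1 bp are chained, and
each connected component becomes one CNVR.  An optional minimum reciprocal
overlap gives a stricter merge for callers with sloppy breakpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .io_formats import CnvCall

DEFAULT_BIN_EDGES = (0, 500, 1000, 2000, 5000, 10_000, 50_000, math.inf)


@dataclass(frozen=True)
class Cnvr:
    """A merged CNV region: the union extent of its member calls.

    ``type`` is "dup" when every member is a duplication, "del" when every
    member is a deletion, and "both" when the region mixes gains and losses
    across carriers (the duplication-deletion category).
    """

    cnvr_id: str
    chrom: str
    start: int
    end: int
    type: str
    member_calls: tuple[CnvCall, ...] = ()
    sample_ids: frozenset[str] = frozenset()

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FilterTally:
    """Rejection counts by first failing rule, in order precise -> length -> support."""

    precise: int = 0
    length: int = 0
    support: int = 0

    @property
    def total(self) -> int:
        return self.precise + self.length + self.support


def filter_calls(
    calls: Iterable[CnvCall],
    min_len: int = 50,
    min_support: int = 4,
    require_precise: bool = True,
) -> tuple[list[CnvCall], FilterTally]:
    """Apply the call-level confidence filters.

    A call is kept iff its length is >= ``min_len``, its supporting-read
    count (when recorded) is >= ``min_support``, and it is breakpoint-precise
    (unless ``require_precise`` is off).  Calls with no support count pass the
    support rule: depth-based callers emit none, and the rule targets
    split/long-read evidence.  Each rejected call is tallied under the first
    failing rule.
    """
    kept: list[CnvCall] = []
    tally = FilterTally()
    for call in calls:
        if require_precise and not call.precise:
            tally.precise += 1
        elif call.length < min_len:
            tally.length += 1
        elif call.support_reads is not None and call.support_reads < min_support:
            tally.support += 1
        else:
            kept.append(call)
    return kept, tally


def _reciprocal_overlap(a: CnvCall, b: CnvCall) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / a.length, inter / b.length)


def merge_calls_to_cnvrs(
    calls: Iterable[CnvCall],
    min_reciprocal: float = 0.0,
) -> list[Cnvr]:
    """Merge overlapping calls into CNVRs (single-linkage, >= 1 bp overlap).

    With ``min_reciprocal == 0`` (default) a plane sweep chains every run of
    intervals where each next call starts before the running union's end;
    zero-length contact between half-open intervals is not overlap.  With a
    positive ``min_reciprocal``, two calls are linked only when their overlap
    is at least that fraction of *both* lengths, and components are found by
    union-find over the candidate pairs the sweep produces.

    CNVRs are returned sorted by (chrom, start) with ids CNVR_1..CNVR_n
    assigned in that order.  Input order never affects the output.
    """
    calls = sorted(calls, key=lambda c: (c.chrom, c.start, c.end, c.sample_id,
                                         c.svtype, c.caller))
    components: list[list[CnvCall]] = []
    if min_reciprocal <= 0.0:
        current: list[CnvCall] = []
        cur_chrom: Optional[str] = None
        cur_end = -1
        for call in calls:
            if current and call.chrom == cur_chrom and call.start < cur_end:
                current.append(call)
                cur_end = max(cur_end, call.end)
            else:
                if current:
                    components.append(current)
                current = [call]
                cur_chrom = call.chrom
                cur_end = call.end
        if current:
            components.append(current)
    else:
        parent = list(range(len(calls)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i: int, j: int) -> None:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri

        # sweep to bound the candidate pairs, then test reciprocal overlap
        active: list[int] = []
        for i, call in enumerate(calls):
            active = [
                j for j in active
                if calls[j].chrom == call.chrom and calls[j].end > call.start
            ]
            for j in active:
                if _reciprocal_overlap(call, calls[j]) >= min_reciprocal:
                    union(i, j)
            active.append(i)
        groups: dict[int, list[CnvCall]] = {}
        for i, call in enumerate(calls):
            groups.setdefault(find(i), []).append(call)
        components = list(groups.values())

    cnvrs = []
    for members in components:
        chrom = members[0].chrom
        start = min(c.start for c in members)
        end = max(c.end for c in members)
        cnvrs.append((chrom, start, end, tuple(members)))
    cnvrs.sort(key=lambda t: (t[0], t[1], t[2]))
    out = []
    for i, (chrom, start, end, members) in enumerate(cnvrs, start=1):
        out.append(
            Cnvr(
                cnvr_id=f"CNVR_{i}",
                chrom=chrom,
                start=start,
                end=end,
                type=classify_members(members),
                member_calls=members,
                sample_ids=frozenset(c.sample_id for c in members),
            )
        )
    return out


def classify_members(members: Sequence[CnvCall]) -> str:
    """dup when all members DUP, del when all DEL, both when mixed."""
    svtypes = {c.svtype for c in members}
    if svtypes == {"DUP"}:
        return "dup"
    if svtypes == {"DEL"}:
        return "del"
    return "both"


def classify_cnvr(cnvr: Cnvr) -> str:
    if not cnvr.member_calls:
        raise ValueError(f"{cnvr.cnvr_id}: cannot classify a CNVR with no members")
    return classify_members(cnvr.member_calls)


def apply_length_filters(
    cnvrs: Iterable[Cnvr],
    del_both_max: int = 50_000,
    dup_max: int = 500_000,
) -> tuple[list[Cnvr], list[tuple[Cnvr, str]]]:
    """Apply the per-type CNVR length ceilings.

    Deletion and duplication-deletion regions are kept up to and including
    ``del_both_max`` (<= 50 kb); duplication regions must be strictly shorter
    than ``dup_max`` (< 500 kb).  The asymmetry is deliberate and mirrors the
    stated rules.  Dropped regions are returned with a reason string.
    """
    kept: list[Cnvr] = []
    dropped: list[tuple[Cnvr, str]] = []
    for c in cnvrs:
        if c.type in ("del", "both"):
            if c.length <= del_both_max:
                kept.append(c)
            else:
                dropped.append((c, f"{c.type} length {c.length} > {del_both_max}"))
        elif c.type == "dup":
            if c.length < dup_max:
                kept.append(c)
            else:
                dropped.append((c, f"dup length {c.length} >= {dup_max}"))
        else:
            raise ValueError(f"unknown CNVR type {c.type!r}")
    return kept, dropped


@dataclass
class CnvrSummary:
    """Landscape summary of a CNVR set."""

    n_cnvr: int
    counts_by_type: dict[str, int]
    total_length_bp: int
    mean_length_bp: int  # rounded to nearest bp
    genome_coverage: float  # fraction of the genome covered
    per_chrom_counts: dict[str, int]
    length_histogram: list[tuple[float, float, int]]  # (lo, hi, count)

    def to_dict(self) -> dict:
        return {
            "n_cnvr": self.n_cnvr,
            "counts_by_type": self.counts_by_type,
            "total_length_bp": self.total_length_bp,
            "mean_length_bp": self.mean_length_bp,
            "genome_coverage": self.genome_coverage,
            "per_chrom_counts": self.per_chrom_counts,
            "length_histogram": [
                {"lo": lo, "hi": (None if math.isinf(hi) else hi), "count": n}
                for lo, hi, n in self.length_histogram
            ],
        }


def mean_length_bp(total_length: int, count: int) -> int:
    """Mean CNVR length rounded to the nearest bp (half away from zero)."""
    if count == 0:
        return 0
    return int(math.floor(total_length / count + 0.5))


def summarize_cnvr_set(
    cnvrs: Sequence[Cnvr],
    genome_lengths: Mapping[str, int],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> CnvrSummary:
    """Counts by type, total/mean length, genome coverage and length histogram.

    Total length sums union extents (post-merge CNVRs are disjoint, so there
    is no double counting).  Coverage is total length over the summed genome
    lengths.  Histogram bins are half-open [lo, hi).
    """
    for c in cnvrs:
        if c.chrom not in genome_lengths:
            raise ValueError(f"CNVR {c.cnvr_id} on unknown chromosome {c.chrom!r}")
    counts_by_type: dict[str, int] = {"dup": 0, "del": 0, "both": 0}
    per_chrom: dict[str, int] = {}
    total = 0
    for c in cnvrs:
        counts_by_type[c.type] = counts_by_type.get(c.type, 0) + 1
        per_chrom[c.chrom] = per_chrom.get(c.chrom, 0) + 1
        total += c.length
    genome_total = sum(genome_lengths.values())
    hist = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        hist.append((lo, hi, sum(1 for c in cnvrs if lo <= c.length < hi)))
    return CnvrSummary(
        n_cnvr=len(cnvrs),
        counts_by_type=counts_by_type,
        total_length_bp=total,
        mean_length_bp=mean_length_bp(total, len(cnvrs)),
        genome_coverage=(total / genome_total if genome_total else 0.0),
        per_chrom_counts=dict(sorted(per_chrom.items())),
        length_histogram=hist,
    )
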