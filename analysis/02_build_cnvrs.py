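#!/usr/bin/env python
"""Filter calls, merge them into CNV regions, and summarize the landscape.

Reads the cohort written by 01, applies the confidence filters (precise
breakpoints, >= 50 bp, >= 4 supporting reads where recorded), merges
overlapping calls across samples into CNVRs, applies the per-type length
ceilings, and writes results/cnvrs.bed plus results/cnvr_summary.json.
"""

import json
from pathlib import Path

from cnvpop.cnvr_construction import (
    apply_length_filters,
    filter_calls,
    merge_calls_to_cnvrs,
    summarize_cnvr_set,
)
from cnvpop.io_formats import read_genome_table, write_cnvr_bed
from cnvpop.pipeline import load_calls

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    calls = load_calls(RESULTS / "cohort" / "calls")
    kept, tally = filter_calls(calls)
    print(f"calls: {len(calls)} in, {len(kept)} kept "
          f"(rejected: imprecise={tally.precise}, short={tally.length}, "
          f"low-support={tally.support})")

    merged = merge_calls_to_cnvrs(kept)
    cnvrs, dropped = apply_length_filters(merged)
    print(f"CNVRs: {len(merged)} merged, {len(dropped)} dropped by length "
          f"ceilings, {len(cnvrs)} retained")

    genome = read_genome_table(RESULTS / "cohort" / "genome.tsv")
    summary = summarize_cnvr_set(cnvrs, genome)
    write_cnvr_bed(cnvrs, RESULTS / "cnvrs.bed")
    (RESULTS / "cnvr_summary.json").write_text(
        json.dumps(summary.to_dict(), indent=1, sort_keys=True) + "\n"
    )
    c = summary.counts_by_type
    print(f"types: {c['dup']} dup / {c['del']} del / {c['both']} both")
    print(f"total {summary.total_length_bp:,} bp, mean "
          f"{summary.mean_length_bp:,} bp, genome coverage "
          f"{100 * summary.genome_coverage:.2f}%")
    one_two_kb = next(
        n for lo, hi, n in summary.length_histogram if lo == 1000
    )
    print(f"length histogram peak: {one_two_kb} CNVRs in the 1-2 kb bin "
          f"({100 * one_two_kb / summary.n_cnvr:.0f}% of all)")


if __name__ == "__main__":
    main()
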