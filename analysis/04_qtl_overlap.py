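#!/usr/bin/env python
"""Intersect the CNVRs with QTL confidence intervals.

QTLs with spans of 5 Mb or more are discarded as positionally uninformative;
a CNVR-QTL pair is reported when the intervals share strictly more than
1 kb.  Writes results/qtl_overlap.tsv and results/qtl_trait_counts.tsv.
"""

from pathlib import Path

from cnvpop.io_formats import read_cnvr_bed, read_qtl_table
from cnvpop.qtl_overlap import filter_qtls, intersect_cnvr_qtl

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cnvrs = read_cnvr_bed(RESULTS / "cnvrs.bed")
    qtls, _ = read_qtl_table(RESULTS / "cohort" / "qtls.tsv")
    kept = filter_qtls(qtls)
    print(f"QTLs: {len(qtls)} in, {len(kept)} with span < 5 Mb")

    report = intersect_cnvr_qtl(cnvrs, kept)
    with open(RESULTS / "qtl_overlap.tsv", "w") as fh:
        fh.write("#cnvr_id\tqtl_id\ttrait\toverlap_bp\n")
        for p in report.pairs:
            fh.write(f"{p.cnvr_id}\t{p.qtl_id}\t{p.trait}\t{p.overlap_bp}\n")
    with open(RESULTS / "qtl_trait_counts.tsv", "w") as fh:
        fh.write("#trait\tn_cnvrs\n")
        for trait, n in report.trait_cnvr_counts.items():
            fh.write(f"{trait}\t{n}\n")

    print(f"{len(report.pairs)} qualifying pairs: {report.n_cnvrs} distinct "
          f"CNVRs x {report.n_qtls} distinct QTLs")
    for trait, n in sorted(report.trait_cnvr_counts.items(),
                           key=lambda t: -t[1]):
        print(f"  {trait}: {n} CNVRs")


if __name__ == "__main__":
    main()
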