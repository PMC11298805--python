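"""Vst: copy-number differentiation between two populations.

Vst is the dosage analogue of Fst.  For one CNVR with copy-number values
across all N = n1 + n2 individuals,

    Vst = (Vt - Vs) / Vt

where Vt is the variance across all individuals and Vs is the mean
within-population variance weighted by population size,
Vs = (n1*V1 + n2*V2) / (n1 + n2).  All three variances use the population
convention (denominator N, not N-1), applied consistently: that is what
makes complete fixation (every individual in one group at one copy number,
the other group at another) return exactly 1.  Vst is defined as 0 when
Vt == 0 and is clamped to [0, 1]; the raw pre-clamp value is retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cnvr_construction import Cnvr
from .io_formats import CnvCall, GeneModel, PopulationMap

_SVTYPE_DEFAULT_CN = {"DEL": 1.0, "DUP": 3.0}


@dataclass
class CopyNumberMatrix:
    """CNVR x sample copy-number values with population labels.

    ``values`` is a DataFrame indexed by cnvr_id with one column per sample;
    it holds no missing values (non-carriers are imputed with the diploid
    baseline).  Exactly two population labels are required for Vst.
    """

    values: pd.DataFrame
    populations: PopulationMap

    @property
    def cnvr_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, keep: Iterable[str]) -> "CopyNumberMatrix":
        keep = [s for s in self.sample_ids if s in set(keep)]
        return CopyNumberMatrix(
            values=self.values[keep],
            populations=PopulationMap({s: self.populations[s] for s in keep}),
        )


def build_cn_matrix(
    cnvrs: Sequence[Cnvr],
    pop_map: Mapping[str, str],
    baseline: float = 2.0,
) -> CopyNumberMatrix:
    """Per-CNVR, per-sample copy number from the merged member calls.

    Cell (r, s) is the mean copy number of sample s's member calls inside
    CNVR r; samples with no call there sit at the diploid ``baseline``.
    Calls lacking an explicit copy number contribute a type default (DEL 1,
    DUP 3).  Every carrier sample must appear in ``pop_map``.
    """
    sample_ids = sorted(pop_map)
    known = set(sample_ids)
    data = np.full((len(cnvrs), len(sample_ids)), float(baseline))
    col = {s: j for j, s in enumerate(sample_ids)}
    for i, cnvr in enumerate(cnvrs):
        per_sample: dict[str, list[float]] = {}
        for call in cnvr.member_calls:
            if call.sample_id not in known:
                raise ValueError(
                    f"sample {call.sample_id!r} has calls but no population label"
                )
            cn = call.copy_number
            if cn is None:
                cn = _SVTYPE_DEFAULT_CN[call.svtype]
            per_sample.setdefault(call.sample_id, []).append(float(cn))
        for s, vals in per_sample.items():
            data[i, col[s]] = sum(vals) / len(vals)
    values = pd.DataFrame(data, index=[c.cnvr_id for c in cnvrs], columns=sample_ids)
    return CopyNumberMatrix(values=values, populations=PopulationMap(dict(pop_map)))


@dataclass
class VstResult:
    cnvr_id: str
    v_t: float
    v_s: float
    vst_raw: float  # (Vt - Vs)/Vt before clamping; 0 when Vt == 0
    vst: float      # clamped to [0, 1]
    percentile_rank: float = float("nan")
    top10: bool = False
    gt_half: bool = False


@dataclass
class VstReport:
    results: list[VstResult]
    mean_vst: float

    def __iter__(self):
        return iter(self.results)

    def __len__(self):
        return len(self.results)


def vst_from_groups(pop1: Sequence[float], pop2: Sequence[float]) -> tuple[float, float, float]:
    """(Vt, Vs, Vst) for one CNVR from the two groups' copy numbers.

    Population-variance (denominator N) convention throughout; Vst is 0 when
    Vt is 0 and otherwise clamped to [0, 1].
    """
    a = np.asarray(pop1, dtype=float)
    b = np.asarray(pop2, dtype=float)
    n1, n2 = len(a), len(b)
    allv = np.concatenate([a, b])
    v_t = float(np.var(allv))
    v_s = (n1 * float(np.var(a)) + n2 * float(np.var(b))) / (n1 + n2)
    if v_t == 0.0:
        return 0.0, v_s, 0.0
    return v_t, v_s, (v_t - v_s) / v_t


def compute_vst(matrix: CopyNumberMatrix) -> VstReport:
    """Vst per CNVR across the matrix's two populations, plus the mean Vst.

    Requires exactly two population labels with at least two samples each.
    """
    pops = matrix.populations.populations
    if len(pops) != 2:
        raise ValueError(f"Vst requires exactly two populations, got {pops}")
    s1 = matrix.populations.samples_of(pops[0])
    s2 = matrix.populations.samples_of(pops[1])
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("each population needs at least two samples for Vst")
    a = matrix.values[s1].to_numpy(dtype=float)
    b = matrix.values[s2].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    v1 = a.var(axis=1)
    v2 = b.var(axis=1)
    v_t = np.concatenate([a, b], axis=1).var(axis=1)
    v_s = (n1 * v1 + n2 * v2) / (n1 + n2)
    results = []
    for cnvr_id, vt, vs in zip(matrix.cnvr_ids, v_t, v_s):
        raw = 0.0 if vt == 0.0 else (vt - vs) / vt
        results.append(
            VstResult(
                cnvr_id=cnvr_id,
                v_t=float(vt),
                v_s=float(vs),
                vst_raw=float(raw),
                vst=float(min(1.0, max(0.0, raw))),
            )
        )
    mean = float(np.mean([r.vst for r in results])) if results else float("nan")
    return VstReport(results=results, mean_vst=mean)


def select_candidates(
    results: Sequence[VstResult],
    top_frac: float = 0.10,
    abs_threshold: float = 0.5,
) -> list[VstResult]:
    """Flag differentiation candidates in-place and return them.

    The ``top10`` flag marks the ceil(top_frac * n) highest-Vst CNVRs, ties
    broken by cnvr_id so selection is deterministic.  ``gt_half`` marks
    vst strictly above ``abs_threshold``.  Percentile ranks use the
    nearest-rank method: rank of a value = number of Vst values <= it,
    percentile = 100 * rank / n.
    """
    if not results:
        raise ValueError("no Vst results to select from")
    n = len(results)
    k = math.ceil(top_frac * n)
    order = sorted(results, key=lambda r: (-r.vst, r.cnvr_id))
    top_ids = {r.cnvr_id for r in order[:k]}
    vst_sorted = np.sort([r.vst for r in results])
    for r in results:
        r.top10 = r.cnvr_id in top_ids
        r.gt_half = r.vst > abs_threshold
        rank = int(np.searchsorted(vst_sorted, r.vst, side="right"))
        r.percentile_rank = 100.0 * rank / n
    return [r for r in order if r.cnvr_id in top_ids]


def annotate_candidates(
    candidates: Sequence[VstResult],
    cnvrs: Sequence[Cnvr],
    genes: Sequence[GeneModel],
    proximal_window: int = 1000,
) -> tuple[dict[str, list[str]], list[str]]:
    """Attach primary/nearest genes to each candidate CNVR.

    Returns (cnvr_id -> gene symbols, distinct gene symbol list sorted).
    """
    from .annotation import assign_genes

    by_id = {c.cnvr_id: c for c in cnvrs}
    per_cnvr: dict[str, list[str]] = {}
    distinct: set[str] = set()
    for r in candidates:
        cnvr = by_id[r.cnvr_id]
        ann = assign_genes(cnvr, genes, proximal_window=proximal_window)
        symbols = [g.symbol for g in ann.genes]
        per_cnvr[r.cnvr_id] = symbols
        distinct.update(symbols)
    return per_cnvr, sorted(distinct)
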