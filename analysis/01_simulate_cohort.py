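#!/usr/bin/env python
"""Generate the standard synthetic two-population CNV cohort.

Writes per-sample call VCFs, the toy genome, gene/QTL fixtures, the
population map and the ground-truth JSON under results/cohort/.  Downstream
analysis scripts (02-05) read these files, so the whole analysis composes
through the same formats a real cohort would arrive in.
"""

from pathlib import Path

from cnvpop.synthetic_data import SimulationConfig, simulate_cohort, write_cohort

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 1


def main() -> None:
    config = SimulationConfig(seed=SEED)
    cohort = simulate_cohort(config)
    paths = write_cohort(cohort, OUTDIR)
    n_calls = len(cohort.all_calls)
    n_samples = len(cohort.calls_by_sample)
    print(f"cohort: {config.n_pop1} {config.pop1_name} + "
          f"{config.n_pop2} {config.pop2_name} samples")
    print(f"true CNV regions: {len(cohort.truth.cnvrs)} "
          f"({len(cohort.truth.planted_vst)} planted at Vst "
          f"~{config.target_vst})")
    print(f"emitted calls: {n_calls} across {n_samples} samples "
          f"(jitter {config.jitter_sd:g} bp, dropout {config.dropout_rate:.0%})")
    print(f"wrote {len(paths)} files under {OUTDIR}")


if __name__ == "__main__":
    main()
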