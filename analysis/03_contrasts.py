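#!/usr/bin/env python
"""The study's three contrasts: permutation tests with BH-FDR over pairs.

Runs the full default design on the simulated cohorts —

* HC vs MDD at baseline (unpaired group-label permutation),
* MDD baseline vs single dose (paired condition swaps within subject),
* MDD baseline vs three weeks (paired),

each with B = 10,000 permutations, two-sided |delta z| statistic, and
Benjamini-Hochberg FDR over the 36 region pairs, then prints the pairs
significant before and after correction.

Input:  results/cohorts.csv
Output: results/contrast_*.csv, results/delta_rho_fdr_masked_*.csv,
        results/network_*.node/.edge, results/run_log.json
"""

from pathlib import Path

import pandas as pd

from sertnet.io import read_cohort_table
from sertnet.study import StudyConfig, run_study

SEED = 71
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohorts = read_cohort_table(OUT / "cohorts.csv")
    config = StudyConfig(
        cohorts=cohorts,
        n_permutations=10_000,
        alpha=0.05,
        seed=SEED,
        output_dir=OUT,
        exact_threshold=0,
    )
    log = run_study(config)
    for entry in log["contrasts"]:
        print(
            f"{entry['name']}: {entry['n_sig_uncorrected']} pairs at "
            f"p<=0.05 uncorrected, {entry['n_sig_fdr']} after FDR "
            f"({entry['n_permutations']} draws, "
            f"{entry['n_rejected_draws']} rejected)"
        )
        report = pd.read_csv(OUT / f"contrast_{entry['name']}.csv")
        top = report.head(3)
        for _, row in top.iterrows():
            print(
                f"    {row.region_a}-{row.region_b}: delta_rho="
                f"{row.delta_rho:+.3f}, p={row.p_perm:.4f}, q={row.q_fdr:.4f}"
            )
    print(
        "shape matches the reported analysis: pair-level tables per "
        "contrast; at n=19 only the strongest increases survive FDR in any "
        "single realization"
    )


if __name__ == "__main__":
    main()
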