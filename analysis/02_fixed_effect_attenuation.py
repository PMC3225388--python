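#!/usr/bin/env python
"""Median single-SNP OR vs true conditional OR across prevalence and MAF.

For a 100-risk-SNP disease, sweeps the true conditional odds ratio for
several prevalences (risk allele frequency 0.25) and several risk allele
frequencies (prevalence 1%), simulating case-control studies of 3,500
subjects at a 1:1 ratio.  Writes results/fig2_prevalence_grid.tsv and
results/fig2_maf_grid.tsv.  The default replicate count here is 1,000 per
grid point (the study-scale 10,000 is available via --replicates).
"""

import argparse
import logging

from collapsim.experiments import ExperimentConfig, run_experiment


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--replicates", type=int, default=1000)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", default="results")
    args = parser.parse_args()
    logging.basicConfig(level=logging.INFO)

    for name, varied in (("fig2_prevalence_grid", "prevalence"), ("fig2_maf_grid", "maf")):
        table = run_experiment(
            ExperimentConfig(name, {"n_replicates": args.replicates, "seed": args.seed}),
            args.out,
        )
        top = table[table.or_true == table.or_true.max()]
        print(f"{name}: at true OR {top.or_true.iloc[0]:.1f} the median "
              "estimated OR plateaus at "
              + ", ".join(
                  f"{row.or_median:.2f} ({varied}={getattr(row, varied)})"
                  for row in top.itertuples()
              ))
    print(
        "Single-SNP analysis caps the estimated OR: the ceiling is lower at "
        "higher prevalence and higher risk allele frequency, so large true "
        "conditional effects become indistinguishable from moderate ones."
    )


if __name__ == "__main__":
    main()
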