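#!/usr/bin/env python
"""Penetrance curve and risk-allele distribution of the illustrative disease.

A disease with prevalence 1%, 100 risk SNPs, allelic OR 1.6 and risk allele
frequency 0.25: writes the penetrance over g = 0..200 together with the
population distribution of risk-allele counts (and a sampled histogram of
10,000 subjects) to results/fig1_model_curve.tsv.
"""

import argparse
import logging

from collapsim.experiments import ExperimentConfig, run_experiment


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", default="results")
    args = parser.parse_args()
    logging.basicConfig(level=logging.INFO)

    table = run_experiment(
        ExperimentConfig("fig1_model_curve", {"seed": args.seed}), args.out
    )
    mean_g = float((table.g * table.pmf).sum())
    g_half = table.g[(table.penetrance - 0.5).abs().idxmin()]
    print(
        f"Average subject carries {mean_g:.1f} risk alleles with penetrance "
        f"{table.penetrance[table.g == 50].iloc[0]:.2e}; disease probability "
        f"crosses 50% only near g = {g_half} — the genotype-risk relationship "
        "is a sharp threshold, so disease risk is carried by the upper tail."
    )


if __name__ == "__main__":
    main()
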