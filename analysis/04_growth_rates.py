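#!/usr/bin/env python
"""Estimate specific growth rates from synthetic OD600 cultures.

Simulates triplicate logistic-capped growth curves at each measured
condition (3% CV multiplicative noise) and recovers mu by the
exponential-window estimator; flat conditions must come back flagged
as no-growth.
"""

import argparse
import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from mucimin.growth import estimate_growth_rate
from mucimin.reference import GROWTH_RATES
from mucimin.synth import SimConfig, simulate_growth_curve

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    args = ap.parse_args()
    os.makedirs(OUT, exist_ok=True)
    seeds = np.random.SeedSequence(args.seed).generate_state(
        len(GROWTH_RATES)) % (2**31)
    rows = []
    for (cond, (mu, sd)), seed in zip(sorted(GROWTH_RATES.items()), seeds):
        est = estimate_growth_rate(
            simulate_growth_curve(
                mu, config=SimConfig(seed=int(seed), noise_cv=0.03,
                                     n_replicates=3),
                condition=cond,
            )
        )
        rows.append({"condition": cond, "mu_true": mu, "sd_reported": sd,
                     "mu_hat": est.mu, "sd_hat": est.sd,
                     "no_growth": est.no_growth})
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(OUT, "growth_rates.tsv"), sep="\t", index=False)
    print(df.to_string(index=False))
    grown = df[df.mu_true > 0]
    print(f"\nall growing conditions recovered within the reported SD: "
          f"{bool((abs(grown.mu_hat - grown.mu_true) < grown.sd_reported).all())}")
    flat = df[df.mu_true == 0]
    print(f"all flat conditions flagged no-growth: {bool(flat.no_growth.all())}")


if __name__ == "__main__":
    main()
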