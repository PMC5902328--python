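#!/usr/bin/env python
"""NagB kinetics: Km recovery and the activator null result.

Simulates triplicate initial-rate assays at the measured Michaelis
constants (aminating direction: Fru6P, NH4; deaminating: GlcN6P), fits
them by double-reciprocal regression with a nonlinear cross-check, and
tests whether adding the canonical allosteric activator GlcNAc6P (whose
simulated ground truth is unchanged, as measured) shifts Km.
"""

import argparse
import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from mucimin.kinetics import (
    compare_km,
    fit_lineweaver_burk,
    fit_michaelis_nonlinear,
)
from mucimin.reference import KM_VALUES
from mucimin.synth import SimConfig, simulate_assay

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=3)
    args = ap.parse_args()
    os.makedirs(OUT, exist_ok=True)
    rows = []
    streams = np.random.SeedSequence(args.seed).spawn(len(KM_VALUES))
    for (sub, (km, sd)), seq in zip(sorted(KM_VALUES.items()), streams):
        s0, s1 = (int(x) for x in seq.generate_state(2) % (2**31))
        plain = simulate_assay(km, 1.0, substrate_id=sub,
                               config=SimConfig(seed=s0, noise_cv=0.05,
                                                n_replicates=3))
        act = simulate_assay(km, 1.0, substrate_id=sub, activator_conc=0.25,
                             config=SimConfig(seed=s1, noise_cv=0.05,
                                              n_replicates=2))
        lb = fit_lineweaver_burk(plain)
        nls = fit_michaelis_nonlinear(plain)
        cmp = compare_km(lb.replicate_Km,
                         fit_lineweaver_burk(act).replicate_Km, sub)
        rows.append({"substrate": sub, "Km_true_mM": km, "sd_reported": sd,
                     "Km_lb_mM": lb.Km, "Km_lb_se": lb.Km_se,
                     "Km_nls_mM": nls.Km,
                     "Km_activator_mM": cmp.Km_b, "p_value": cmp.p_value,
                     "no_influence": cmp.no_influence})
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(OUT, "kinetics.tsv"), sep="\t", index=False)
    print(df.to_string(index=False))
    kept = int(df.no_influence.sum())
    print(f"\nsubstrates preserving the activator null (p > 0.05): "
          f"{kept}/{len(df)}")
    if kept < len(df):
        print("note: with three comparisons at alpha = 0.05, occasional "
              "false positives are expected on individual seeds; the null "
              "is preserved in >= 90% of seeds (see the test suite)")


if __name__ == "__main__":
    main()
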