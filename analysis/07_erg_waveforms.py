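#!/usr/bin/env python
"""Photopic flash-ERG group comparison on synthetic waveforms.

Simulates 7 control and 7 knockout animals (20 noisy 1 Hz flash
replicates each, averaged per animal), extracts a-/b-wave amplitudes,
and compares the groups with the Shapiro-Wilk-gated two-tailed t-test.
The knockout b-wave is generated 36% below control — the size of the
published photopic deficit — to show the analysis chain resolves it at
this n.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from circaretina.erg import (
    a_wave_amplitude,
    average_replicates,
    b_wave_amplitude,
    group_compare,
    percent_reduction,
)
from circaretina.synthetic import simulate_erg

OUT = Path("results/analysis")

N_PER_ARM = 7
B_CTRL, REDUCTION = 111.1, 0.36  # microvolts; fractional knockout deficit
A_AMP = 25.0  # photopic a-wave, small relative to b
ANIMAL_SD = 18.0  # between-animal b-wave spread (microvolts)
NOISE_SD = 8.0  # within-trace noise (microvolts)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    rng = np.random.default_rng(args.seed)
    OUT.mkdir(parents=True, exist_ok=True)

    rows = []
    for genotype, b_mean in (("Ctrl", B_CTRL), ("cKO", B_CTRL * (1 - REDUCTION))):
        for animal in range(N_PER_ARM):
            b_true = max(rng.normal(b_mean, ANIMAL_SD), A_AMP + 10.0)
            reps = [
                simulate_erg(A_AMP, b_true, noise_sd=NOISE_SD,
                             seed=int(rng.integers(2**31)))
                for _ in range(20)
            ]
            tr = average_replicates(reps)
            rows.append({
                "genotype": genotype, "animal": f"{genotype}{animal}",
                "a_uV": a_wave_amplitude(tr).amplitude,
                "b_uV": b_wave_amplitude(tr).amplitude,
            })
    amps = pd.DataFrame(rows)
    amps.to_csv(OUT / "erg_amplitudes.csv", index=False)

    ctrl = amps.loc[amps["genotype"] == "Ctrl", "b_uV"]
    cko = amps.loc[amps["genotype"] == "cKO", "b_uV"]
    res = group_compare(ctrl, cko)
    red = percent_reduction(ctrl.mean(), cko.mean())
    print(amps.groupby("genotype")[["a_uV", "b_uV"]].agg(["mean", "sem"]).round(2))
    print(f"\nb-wave reduction: {red:.1f}% "
          f"({res['branch']}, p = {res['p']:.4f})")
    print(f"wrote {OUT/'erg_amplitudes.csv'}")


if __name__ == "__main__":
    main()
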