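#!/usr/bin/env python
"""Cosinor analysis of clock-gene expression in control vs knockout.

Simulates relative-expression series for four clock genes (control
acrophases per the canonical retinal profile: Per1/Cry1 peaking near
ZT12, Bmal1/Dbp near ZT6) with the knockout phase-advanced by 4 h, fits
the fixed-24 h cosinor to each gene x genotype, selects
cosine/linear/flat by the extra-sum-of-squares F rule, checks residual
normality (D'Agostino-Pearson K2), and runs per-ZT genotype t-tests with
Holm-Sidak correction.
"""

import argparse
from pathlib import Path

import pandas as pd

from circaretina.rhythms import (
    cosinor_fit,
    per_zt_genotype_tests,
    residual_normality,
)
from circaretina.synthetic import simulate_expression

OUT = Path("results/analysis")

GENES = {  # gene: (baseline, amplitude, control acrophase h)
    "Bmal1": (1.0, 0.40, 6.0),
    "Dbp": (1.0, 0.60, 6.0),
    "Per1": (1.0, 0.35, 12.0),
    "Cry1": (1.0, 0.30, 12.0),
}
KO_SHIFT_H = -4.0


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    rows, frames = [], []
    for gi, (gene, (base, amp, phase)) in enumerate(GENES.items()):
        for genotype, shift in (("Ctrl", 0.0), ("cKO", KO_SHIFT_H)):
            df = simulate_expression(
                gene=gene, baseline=base, amplitude=amp, acrophase=phase,
                sigma=0.2 * amp, genotype=genotype, genotype_shift_h=shift,
                seed=args.seed + 10 * gi + (0 if genotype == "Ctrl" else 5),
            )
            frames.append(df)
            fit = cosinor_fit(df["zt"].to_numpy(float), df["value"].to_numpy())
            k2 = residual_normality(fit)
            rows.append({
                "gene": gene, "genotype": genotype, "model": fit.selected_model,
                "baseline": fit.baseline, "amplitude": fit.amplitude,
                "acrophase_h": fit.acrophase, "p_vs_flat": fit.p_vs_flat,
                "normality_p": None if k2 is None else k2[1],
            })
    fits = pd.DataFrame(rows)
    fits.to_csv(OUT / "cosinor_fits.csv", index=False)
    print(fits.round(3).to_string(index=False))

    expr = pd.concat(frames, ignore_index=True)
    wide = fits.pivot(index="gene", columns="genotype", values="acrophase_h")
    shift = ((wide["cKO"] - wide["Ctrl"] + 12.0) % 24.0 - 12.0)
    print("\nrecovered knockout phase shift per gene (injected -4 h):")
    print(shift.round(2).to_string())

    zt_rows = []
    for gene, sub in expr.groupby("gene"):
        t = per_zt_genotype_tests(sub)
        t.insert(0, "gene", gene)
        zt_rows.append(t)
    zt = pd.concat(zt_rows, ignore_index=True)
    zt.to_csv(OUT / "per_zt_genotype_tests.csv", index=False)
    n_sig = int((zt["p_adj"] < 0.05).sum())
    print(f"\nper-ZT genotype differences (Holm-Sidak): {n_sig} of {len(zt)} "
          "gene x ZT comparisons significant")
    print(f"wrote {OUT/'cosinor_fits.csv'} and {OUT/'per_zt_genotype_tests.csv'}")


if __name__ == "__main__":
    main()
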