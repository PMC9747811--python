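#!/usr/bin/env python
"""Luminance-dependent polarity maintenance, overall and by Zeitgeber time.

Each retina is recorded in both the mesopic and photopic regime; a unit
maintains its polarity when its template label coincides in the two.
Units unmatched to any template in either regime fall into the NA group
and are excluded from the maintained/switched counts.  Fisher's exact
test compares maintained-vs-switched counts between genotypes (the
generator injects elevated OFF switching in the photopic knockout at
ZT0).
"""

from pathlib import Path

import pandas as pd

from circaretina.daily_stats import (
    fisher_maintenance_test,
    match_units_across_regimes,
    polarity_maintenance,
)

RUN_DIR = Path("scratch/pipeline_run")
OUT = Path("results/analysis")


def main() -> None:
    if not RUN_DIR.exists():
        raise SystemExit("run analysis/02_classify_units.py first")
    units = pd.read_csv(RUN_DIR / "units.csv")
    OUT.mkdir(parents=True, exist_ok=True)

    pairs = []
    for retina_id, sub in units.groupby("retina_id"):
        mes = sub[sub["regime"] == "mesopic"].set_index("unit_id")["label"]
        pho = sub[sub["regime"] == "photopic"].set_index("unit_id")["label"]
        p = match_units_across_regimes(mes.to_dict(), pho.to_dict())
        p["genotype"] = sub["genotype"].iloc[0]
        p["zt"] = sub["zt"].iloc[0]
        pairs.append(p)
    pairs = pd.concat(pairs, ignore_index=True)

    overall = polarity_maintenance(pairs)
    per_zt = polarity_maintenance(pairs, by_zt=True)
    per_zt.to_csv(OUT / "maintenance_per_zt.csv", index=False)

    print("polarity maintenance (% of matched cells keeping their label):")
    print(overall.to_string(index=False))
    for polarity in ("ON", "ONOFF", "OFF"):
        sub = overall[overall["polarity"] == polarity].set_index("genotype")
        if not {"Ctrl", "cKO"} <= set(sub.index):
            continue
        p = fisher_maintenance_test(
            (sub.loc["Ctrl", "n_maintained"], sub.loc["Ctrl", "n_switched"]),
            (sub.loc["cKO", "n_maintained"], sub.loc["cKO", "n_switched"]),
        )
        verdict = "differs" if p < 0.05 else "comparable"
        print(f"{polarity}: Fisher exact p = {p:.3g} -> genotypes {verdict}")
    print(f"wrote {OUT/'maintenance_per_zt.csv'}")


if __name__ == "__main__":
    main()
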