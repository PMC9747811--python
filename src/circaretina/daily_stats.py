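"""Daily response statistics and luminance-dependent polarity maintenance.

Peak firing rates (maximum 10 ms PSTH bin during the unit's preferred
half-cycle: white for ON, black for OFF) are stratified by cluster,
Zeitgeber time, contrast and genotype.  Genotype contrasts within a
stratum use a two-sample Kolmogorov-Smirnov test on cell-level peaks;
time-of-day modulation within a genotype uses one-way ANOVA with
Tukey-Kramer pairwise comparisons.  ON-OFF units are excluded from peak
analysis (their preference flips with ambient conditions) but kept in the
polarity-maintenance accounting.

Polarity maintenance asks whether a unit keeps its ON / ON-OFF / OFF
label when the identical stimulus set is delivered at a higher ambient
luminance; maintained-vs-switched counts are compared between genotypes
with Fisher's exact test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .spikes import Psth
from .classification import NA, OFF, ON

__all__ = [
    "peak_response",
    "genotype_peak_test",
    "zt_anova",
    "normalized_peak_scatter",
    "match_units_across_regimes",
    "polarity_maintenance",
    "fisher_maintenance_test",
]


def peak_response(psth: Psth, polarity: str) -> float:
    """Maximum PSTH bin in the preferred half-cycle (spikes/s).

    ON units are scored on the white half [0, 1) s and OFF units on the
    black half [1, 2) s.  ON-OFF units have no single preferred half and
    are a contract violation here.
    """
    if polarity not in (ON, OFF):
        raise ValueError(f"peak_response is defined for ON/OFF only, got {polarity!r}")
    edges = psth.bin_centers
    half = edges < 1.0 if polarity == ON else edges >= 1.0
    if not np.any(half):
        return 0.0
    return float(psth.rates[half].max())


def genotype_peak_test(
    peaks_ctrl: np.ndarray, peaks_cko: np.ndarray
) -> tuple[float, float]:
    """Two-sided two-sample KS test on cell-level peak rates -> (D, p).

    Exact small-sample p where scipy's exact method applies, asymptotic
    otherwise (scipy's automatic switchover at n*m large).
    """
    a, b = np.asarray(peaks_ctrl, float), np.asarray(peaks_cko, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two cells per arm")
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def zt_anova(peaks_by_zt: dict[int, np.ndarray]) -> dict:
    """One-way ANOVA across ZT groups + Tukey-Kramer pairwise table.

    Groups with fewer than 2 cells are dropped (recorded under
    ``dropped``).  Tukey-Kramer handles unequal group sizes.
    """
    usable = {zt: np.asarray(v, float) for zt, v in peaks_by_zt.items() if len(v) >= 2}
    dropped = sorted(set(peaks_by_zt) - set(usable))
    if len(usable) < 2:
        raise ValueError("ANOVA needs at least two groups with >=2 cells")
    groups = [usable[zt] for zt in sorted(usable)]
    f_stat, p = stats.f_oneway(*groups)
    values = np.concatenate(groups)
    labels = np.concatenate(
        [np.full(len(usable[zt]), zt) for zt in sorted(usable)]
    )
    tk = pairwise_tukeyhsd(values, labels)
    pairwise = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    return {
        "F": float(f_stat),
        "p": float(p),
        "tukey": pairwise,
        "dropped_zt": dropped,
    }


def normalized_peak_scatter(cluster_means: pd.DataFrame) -> pd.DataFrame:
    """Control-normalized genotype comparison of cluster-mean peaks.

    ``cluster_means`` needs columns zt, ct, genotype, mean_peak (one row
    per stratum).  Within each ZT, both genotypes' means are divided by
    the maximum control mean across contrasts at that ZT, so norm_ctrl
    <= 1 with equality at the control's best contrast.  Strata whose
    denominator is zero are omitted.
    """
    required = {"zt", "ct", "genotype", "mean_peak"}
    if not required <= set(cluster_means.columns):
        raise ValueError(f"need columns {sorted(required)}")
    wide = cluster_means.pivot_table(
        index=["zt", "ct"], columns="genotype", values="mean_peak"
    ).reset_index()
    if not {"Ctrl", "cKO"} <= set(wide.columns):
        raise ValueError("both genotypes Ctrl and cKO are required")
    rows = []
    for zt, sub in wide.groupby("zt"):
        denom = sub["Ctrl"].max()
        if not denom > 0:
            continue
        for _, r in sub.iterrows():
            rows.append(
                {
                    "zt": zt,
                    "ct": r["ct"],
                    "norm_ctrl": r["Ctrl"] / denom,
                    "norm_cko": r["cKO"] / denom,
                }
            )
    return pd.DataFrame(rows)


def match_units_across_regimes(
    calls_mesopic: dict[str, str], calls_photopic: dict[str, str]
) -> pd.DataFrame:
    """Pair each unit's polarity label across the two luminance regimes.

    Units present in both regimes are tabulated with their two labels and
    a status: ``maintained`` (same non-NA label), ``switched`` (two
    different non-NA labels), or ``na`` (unmatched to a template in at
    least one regime; excluded from the maintained/switched counts).
    """
    shared = sorted(set(calls_mesopic) & set(calls_photopic))
    if not shared:
        raise ValueError("no shared unit ids between regimes")
    rows = []
    for uid in shared:
        a, b = calls_mesopic[uid], calls_photopic[uid]
        if a == NA or b == NA:
            status = "na"
        elif a == b:
            status = "maintained"
        else:
            status = "switched"
        rows.append(
            {"unit_id": uid, "label_mesopic": a, "label_photopic": b, "status": status}
        )
    return pd.DataFrame(rows)


def polarity_maintenance(
    pairs: pd.DataFrame, by_zt: bool = False
) -> pd.DataFrame:
    """Maintained / switched / NA counts and percentage per class.

    The class of a pair is its mesopic label.  Percentage maintained is
    100 * maintained / (maintained + switched); classes with no matched
    (non-NA) pair report NaN rather than 0.  Grouping columns present in
    ``pairs`` (genotype, zt) stratify the table; ``by_zt`` additionally
    splits by zt when that column exists.
    """
    keys = ["label_mesopic"]
    if "genotype" in pairs.columns:
        keys.append("genotype")
    if by_zt and "zt" in pairs.columns:
        keys.append("zt")
    rows = []
    for key, sub in pairs[pairs["label_mesopic"] != NA].groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        n_m = int((sub["status"] == "maintained").sum())
        n_s = int((sub["status"] == "switched").sum())
        n_na = int((sub["status"] == "na").sum())
        pct = 100.0 * n_m / (n_m + n_s) if (n_m + n_s) > 0 else np.nan
        rows.append(
            dict(
                zip(keys, key),
                n_maintained=n_m,
                n_switched=n_s,
                n_na=n_na,
                pct_maintained=pct,
            )
        )
    return pd.DataFrame(rows).rename(columns={"label_mesopic": "polarity"})


def fisher_maintenance_test(
    table_ctrl: tuple[int, int], table_cko: tuple[int, int]
) -> float:
    """Two-sided Fisher exact p for a (maintained, switched) x genotype table.

    Degenerate margins (an all-zero row or column) carry no information
    and return p = 1.
    """
    m1, s1 = table_ctrl
    m2, s2 = table_cko
    if min(m1, s1, m2, s2) < 0:
        raise ValueError("counts must be non-negative")
    table = np.array([[m1, s1], [m2, s2]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
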