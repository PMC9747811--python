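"""Functional sub-clustering of each polarity class.

Within a polarity class (and one luminance regime), units from all
genotypes and times of day are pooled, their maximum-contrast cumulative
cycle distributions reduced by PCA, and k-means applied at each candidate
k; the k maximizing the mean silhouette width wins.  Pooling before
clustering keeps the partition unbiased with respect to genotype and
Zeitgeber time; genotype effects are then assessed afterwards as
per-cluster composition tests across retinae.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusteringResult",
    "pca_features",
    "silhouette_select_k",
    "kmeans_cluster",
    "cluster_summary",
    "compare_cluster_proportions",
    "top_clusters",
    "run_polarity_clustering",
]


@dataclass
class ClusteringResult:
    polarity_class: str
    n_components_kept: int
    explained_variance_fraction: float
    k_selected: int
    mean_silhouette_by_k: dict[int, float]
    labels: dict[str, int]  # unit_id -> cluster id (0 = most numerous)
    numerosity: dict[int, int]
    cluster_mean_psth: dict[int, np.ndarray] = field(default_factory=dict)
    seed: int = 0
    confident: bool = True

    @property
    def silhouette_at_k(self) -> float:
        return self.mean_silhouette_by_k[self.k_selected]


def pca_features(
    curves: np.ndarray, var_threshold: float = 0.90
) -> tuple[np.ndarray, PCA | None, int, float]:
    """Mean-centered PCA scores keeping the fewest components reaching
    ``var_threshold`` explained variance.

    Returns ``(scores, fitted_pca, n_kept, explained_fraction)``.  A
    degenerate input (all curves identical) yields a single zero
    component.
    """
    curves = np.asarray(curves, float)
    if curves.shape[0] < 2:
        raise ValueError("PCA needs at least two curves")
    centered = curves - curves.mean(axis=0)
    if not np.any(np.abs(centered) > 1e-12):
        return np.zeros((curves.shape[0], 1)), None, 1, 1.0
    pca = PCA()
    scores = pca.fit_transform(curves)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    n_keep = min(n_keep, scores.shape[1])
    return scores[:, :n_keep], pca, n_keep, float(cum[n_keep - 1])


def kmeans_cluster(
    scores: np.ndarray, k: int, seed: int = 0, n_restarts: int = 10
) -> np.ndarray:
    """Seeded best-of-restarts k-means; clusters renumbered by descending size.

    Ties in size break toward the cluster whose members appear first,
    giving a stable, deterministic numbering for a fixed seed.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(scores)
    counts = np.bincount(raw, minlength=k)
    # stable size ordering: by (-count, first appearance)
    first_seen = np.full(k, len(raw))
    for i, lab in enumerate(raw):
        if i < first_seen[lab]:
            first_seen[lab] = i
    order = sorted(range(k), key=lambda c: (-counts[c], first_seen[c]))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[lab] for lab in raw])


def silhouette_select_k(
    scores: np.ndarray,
    k_range: range = range(2, 21),
    seed: int = 0,
    n_restarts: int = 10,
    confidence_floor: float = 0.25,
) -> tuple[int, dict[int, float], bool]:
    """Scan k, score each partition by mean silhouette width, pick the argmax.

    k values with too few points are skipped.  When even the best mean
    silhouette stays below ``confidence_floor`` the data show no real
    cluster structure; the argmax is still returned but flagged
    unconfident.
    """
    n = scores.shape[0]
    profile: dict[int, float] = {}
    for k in k_range:
        if n <= k:
            continue
        labels = kmeans_cluster(scores, k, seed=seed, n_restarts=n_restarts)
        if len(np.unique(labels)) < 2:
            continue
        profile[k] = float(silhouette_score(scores, labels))
    if not profile:
        raise ValueError("no feasible k in range")
    k_star = max(profile, key=lambda k: (profile[k], -k))
    return k_star, profile, profile[k_star] >= confidence_floor


def cluster_summary(
    labels: dict[str, int], psths: dict[str, np.ndarray]
) -> tuple[dict[int, np.ndarray], dict[int, int]]:
    """Per-cluster normalized mean PSTH and numerosity.

    Member PSTHs are each normalized to unit peak before averaging and
    the cluster mean is re-normalized to unit peak, so every cluster
    curve has max 1.  All-zero members count toward numerosity but are
    excluded from the average.
    """
    mean_psth: dict[int, np.ndarray] = {}
    numerosity: dict[int, int] = {}
    for cluster in sorted(set(labels.values())):
        members = [uid for uid, c in labels.items() if c == cluster]
        numerosity[cluster] = len(members)
        norm = []
        for uid in members:
            p = np.asarray(psths[uid], float)
            peak = p.max()
            if peak > 0:
                norm.append(p / peak)
        if norm:
            m = np.mean(norm, axis=0)
            mean_psth[cluster] = m / m.max()
    return mean_psth, numerosity


def top_clusters(numerosity: dict[int, int], n: int = 4) -> list[int]:
    """Ids of the n most numerous clusters (ties to the lower id)."""
    order = sorted(numerosity, key=lambda c: (-numerosity[c], c))
    return order[: min(n, len(order))]


def compare_cluster_proportions(units: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster genotype composition test.

    ``units`` needs columns retina_id, genotype, cluster (one row per
    classified unit of one polarity class).  For each retina the fraction
    of its units falling in each cluster is computed; per cluster a
    two-sample t-test compares those fractions between genotypes, with
    Holm-Sidak correction across the clusters of the class.
    """
    genos = sorted(units["genotype"].unique())
    if len(genos) != 2:
        raise ValueError(f"exactly two genotypes required, got {genos}")
    counts = (
        units.groupby(["retina_id", "genotype", "cluster"]).size().unstack(fill_value=0)
    )
    props = counts.div(counts.sum(axis=1), axis=0).reset_index()
    rows = []
    clusters = sorted(units["cluster"].unique())
    for cluster in clusters:
        a = props.loc[props["genotype"] == genos[0], cluster]
        b = props.loc[props["genotype"] == genos[1], cluster]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need >=2 retinae per genotype")
        if np.allclose(a.var(ddof=1) + b.var(ddof=1), 0) and np.isclose(
            a.mean(), b.mean()
        ):
            t, p = 0.0, 1.0  # identical composition in every retina
        else:
            t, p = stats.ttest_ind(a, b)
        rows.append(
            {
                "cluster": cluster,
                f"mean_prop_{genos[0]}": a.mean(),
                f"mean_prop_{genos[1]}": b.mean(),
                "t": t,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    # Sidak step uses log1p(-p): nudge exact-1 p-values off the boundary
    out["p_adj"] = multipletests(
        np.clip(out["p"], 0.0, 1.0 - 1e-12), method="holm-sidak"
    )[1]
    return out


def run_polarity_clustering(
    polarity_class: str,
    unit_ids: list[str],
    curves: np.ndarray,
    seed: int = 0,
    k_range: range = range(2, 21),
    var_threshold: float = 0.90,
    n_restarts: int = 10,
    psths: dict[str, np.ndarray] | None = None,
) -> ClusteringResult:
    """PCA -> silhouette k selection -> k-means for one polarity class."""
    scores, _, n_keep, expl = pca_features(curves, var_threshold)
    k_star, profile, confident = silhouette_select_k(
        scores, k_range=k_range, seed=seed, n_restarts=n_restarts
    )
    labels_arr = kmeans_cluster(scores, k_star, seed=seed, n_restarts=n_restarts)
    labels = {uid: int(lab) for uid, lab in zip(unit_ids, labels_arr)}
    numerosity = {
        int(c): int(n) for c, n in enumerate(np.bincount(labels_arr, minlength=k_star))
    }
    mean_psth: dict[int, np.ndarray] = {}
    if psths is not None:
        mean_psth, numerosity = cluster_summary(labels, psths)
    return ClusteringResult(
        polarity_class=polarity_class,
        n_components_kept=n_keep,
        explained_variance_fraction=expl,
        k_selected=k_star,
        mean_silhouette_by_k=profile,
        labels=labels,
        numerosity=numerosity,
        cluster_mean_psth=mean_psth,
        seed=seed,
        confident=confident,
    )
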