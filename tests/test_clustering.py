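import numpy as np
import pandas as pd
import pytest

from circaretina.clustering import (
    cluster_summary,
    compare_cluster_proportions,
    kmeans_cluster,
    pca_features,
    silhouette_select_k,
    top_clusters,
)


class TestPcaFeatures:
    def test_identical_curves_degenerate(self):
        curves = np.tile(np.linspace(0, 1, 50), (8, 1))
        scores, pca, n_keep, expl = pca_features(curves)
        assert n_keep == 1
        assert np.all(scores == 0)

    def test_single_direction_needs_one_component(self, rng):
        direction = rng.normal(size=30)
        coeffs = rng.normal(size=12)
        curves = np.outer(coeffs, direction) + 5.0
        _, _, n_keep, expl = pca_features(curves)
        assert n_keep == 1
        assert expl == pytest.approx(1.0)

    def test_variance_rule_bounds_reconstruction_error(self, rng):
        curves = rng.normal(size=(100, 200))
        scores, pca, n_keep, expl = pca_features(curves)
        assert expl >= 0.90
        # discarded variance is at most 10% of the total by construction
        assert 1.0 - expl <= 0.10

    def test_too_few_curves(self):
        with pytest.raises(ValueError):
            pca_features(np.ones((1, 10)))


class TestKSelection:
    def test_two_separated_clouds(self, rng):
        pts = np.vstack([rng.normal(0, 0.05, (40, 2)), rng.normal(3, 0.05, (40, 2))])
        k, prof, confident = silhouette_select_k(pts, k_range=range(2, 8), seed=0)
        assert k == 2 and confident

    def test_three_tight_simplex_clouds(self, rng):
        centers = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        pts = np.vstack([c + rng.normal(0, 0.01, (30, 2)) for c in centers])
        k, prof, confident = silhouette_select_k(pts, k_range=range(2, 10), seed=0)
        assert k == 3 and confident

    def test_single_isotropic_cloud_flagged_unconfident(self, rng):
        """A structureless cloud yields low silhouettes at every k and an
        unconfident selection.  (A 10-D cloud is used because k-means on
        very low-dimensional isotropic data always produces moderate
        silhouettes by construction.)"""
        pts = rng.normal(0, 1.0, (150, 10))
        k, prof, confident = silhouette_select_k(pts, k_range=range(2, 8), seed=0)
        assert not confident
        assert max(prof.values()) < 0.25

    def test_infeasible_k_skipped(self, rng):
        pts = rng.normal(size=(5, 2))
        k, prof, _ = silhouette_select_k(pts, k_range=range(2, 12), seed=0)
        assert max(prof) <= 4  # k >= n skipped


class TestKmeans:
    def test_recovers_two_clouds(self, rng):
        a = rng.normal(0, 0.1, (30, 2))
        b = rng.normal(5, 0.1, (20, 2))
        labels = kmeans_cluster(np.vstack([a, b]), 2, seed=1)
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
        assert labels[0] != labels[-1]
        # renumbering: cluster 0 is the more numerous one
        assert labels[0] == 0

    def test_deterministic_for_fixed_seed(self, rng):
        pts = rng.normal(size=(60, 3))
        a = kmeans_cluster(pts, 4, seed=7)
        b = kmeans_cluster(pts, 4, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_k_equals_n(self, rng):
        pts = rng.normal(size=(6, 2)) * 10
        labels = kmeans_cluster(pts, 6, seed=0)
        assert len(set(labels)) == 6


class TestClusterSummary:
    def test_singleton_cluster_returns_own_normalized_psth(self):
        p = np.array([0.0, 2.0, 4.0, 1.0])
        mean_psth, num = cluster_summary({"u": 0}, {"u": p})
        np.testing.assert_allclose(mean_psth[0], p / 4.0)
        assert num == {0: 1}

    def test_identical_members_average_to_same_curve(self):
        p = np.array([1.0, 3.0, 0.5])
        mean_psth, num = cluster_summary({"a": 0, "b": 0}, {"a": p, "b": 2 * p})
        np.testing.assert_allclose(mean_psth[0], p / 3.0)
        assert num[0] == 2

    def test_every_cluster_mean_peaks_at_one(self, rng):
        labels = {f"u{i}": i % 3 for i in range(30)}
        psths = {uid: rng.uniform(0, 10, 20) for uid in labels}
        mean_psth, _ = cluster_summary(labels, psths)
        for curve in mean_psth.values():
            assert curve.max() == pytest.approx(1.0)

    def test_all_zero_member_counted_but_excluded(self):
        p = np.array([1.0, 2.0])
        mean_psth, num = cluster_summary(
            {"a": 0, "z": 0}, {"a": p, "z": np.zeros(2)}
        )
        assert num[0] == 2
        np.testing.assert_allclose(mean_psth[0], p / 2.0)


class TestTopClusters:
    def test_takes_largest_four(self):
        num = {0: 50, 1: 40, 2: 30, 3: 20, 4: 10}
        assert top_clusters(num, 4) == [0, 1, 2, 3]

    def test_tie_at_cutoff_goes_to_lower_id(self):
        num = {0: 50, 1: 20, 2: 20, 3: 20, 4: 20}
        assert top_clusters(num, 4) == [0, 1, 2, 3]

    def test_fewer_clusters_than_requested(self):
        assert top_clusters({0: 5, 1: 3}, 4) == [0, 1]

    def test_single_largest(self):
        assert top_clusters({0: 5, 1: 9}, 1) == [1]


class TestClusterProportions:
    @staticmethod
    def _cohort(rng, n_retinae=6, enrich_cluster=None, factor=3.0, sigma=0.01):
        """Per-retina cluster proportions -> unit table."""
        base = np.array([0.4, 0.3, 0.2, 0.1])
        rows = []
        for genotype in ("Ctrl", "cKO"):
            for r in range(n_retinae):
                props = base.copy()
                if enrich_cluster is not None and genotype == "cKO":
                    props[enrich_cluster] *= factor
                props = np.abs(props + rng.normal(0, sigma, 4))
                props /= props.sum()
                counts = np.round(props * 400).astype(int)
                for c, n in enumerate(counts):
                    rows.extend(
                        {"retina_id": f"{genotype}{r}", "genotype": genotype,
                         "cluster": c}
                        for _ in range(n)
                    )
        return pd.DataFrame(rows)

    def test_identical_composition_gives_unit_adjusted_p(self):
        rows = []
        for genotype in ("Ctrl", "cKO"):
            for r in range(3):
                for c, n in enumerate([10, 6, 4]):
                    rows.extend(
                        {"retina_id": f"{genotype}{r}", "genotype": genotype,
                         "cluster": c}
                        for _ in range(n)
                    )
        out = compare_cluster_proportions(pd.DataFrame(rows))
        assert np.allclose(out["p_adj"], 1.0, atol=1e-9)

    def test_per_retina_proportions_sum_to_one(self, rng):
        df = self._cohort(rng)
        counts = df.groupby(["retina_id", "cluster"]).size().unstack(fill_value=0)
        props = counts.div(counts.sum(axis=1), axis=0)
        np.testing.assert_allclose(props.sum(axis=1), 1.0)

    def test_enriched_cluster_detected(self, rng):
        """3x enrichment of one cluster in the knockout arm is flagged in
        >=90% of seeded repetitions and carries the strongest evidence.

        (Because per-retina proportions sum to one, enriching one cluster
        necessarily depresses the rest, so the enriched cluster is
        asserted to be detected and to have the smallest adjusted p —
        not to be the only significant one.)"""
        hits = strongest = 0
        for i in range(100):
            df = self._cohort(np.random.default_rng(i), n_retinae=10,
                              enrich_cluster=2)
            out = compare_cluster_proportions(df).set_index("cluster")
            hits += out.loc[2, "p_adj"] < 0.05
            strongest += out["p"].idxmin() == 2
        assert hits >= 90
        assert strongest >= 90

    def test_null_composition_rarely_flagged(self, rng):
        """With no injected enrichment, family-corrected detections are
        rare across seeded repetitions."""
        false_hits = 0
        for i in range(50):
            df = self._cohort(np.random.default_rng(1000 + i), n_retinae=10)
            out = compare_cluster_proportions(df)
            false_hits += (out["p_adj"] < 0.05).any()
        assert false_hits <= 10

    def test_single_genotype_rejected(self):
        df = pd.DataFrame(
            {"retina_id": ["a", "b"], "genotype": ["Ctrl", "Ctrl"], "cluster": [0, 1]}
        )
        with pytest.raises(ValueError):
            compare_cluster_proportions(df)
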