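"""Bootstrap consensus clustering, k selection and centroid classification."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from epityper.epityping import (
    bootstrap_consensus,
    choose_k,
    build_centroids,
    classify_by_centroid,
    relabel,
)


def _clustered_data(rng, sizes, n_probes=300, sep=0.5, noise=0.03):
    """Samples around per-cluster random beta profiles."""
    centers = rng.random((n_probes, len(sizes)))
    cols, labels = [], []
    for c, size in enumerate(sizes):
        for i in range(size):
            cols.append(np.clip(centers[:, c] + rng.normal(0, noise, n_probes), 0, 1))
            labels.append(c)
    names = [f"s{i}" for i in range(len(cols))]
    df = pd.DataFrame(np.array(cols).T, columns=names,
                      index=[f"cg{i}" for i in range(n_probes)])
    return df, pd.Series(labels, index=names)


class TestBootstrapConsensus:
    def test_recovers_well_separated_clusters(self):
        rng = np.random.default_rng(0)
        df, truth = _clustered_data(rng, [10, 10, 10])
        res = bootstrap_consensus(df, k_range=[3], n_boot=50, seed=1)
        assert adjusted_rand_score(truth, res.labels_by_k[3]) == 1.0

    def test_single_iteration_frequencies_are_binary(self):
        rng = np.random.default_rng(1)
        df, _ = _clustered_data(rng, [6, 6])
        res = bootstrap_consensus(df, k_range=[2], n_boot=1, seed=3, on_uncovered="ignore")
        present = res.copresence_count > 0
        freq = res.cocluster_freq[2]
        assert set(np.unique(freq[present])) <= {0.0, 1.0}

    def test_duplicate_samples_always_cocluster(self):
        rng = np.random.default_rng(2)
        df, _ = _clustered_data(rng, [8, 8])
        df["dup"] = df["s0"]
        res = bootstrap_consensus(df, k_range=[2], n_boot=40, seed=5)
        i = list(res.samples).index("s0")
        j = list(res.samples).index("dup")
        assert res.copresence_count[i, j] > 0
        assert res.cocluster_freq[2][i, j] == 1.0

    def test_consensus_matrix_is_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(3)
        df, _ = _clustered_data(rng, [7, 7], noise=0.2)
        res = bootstrap_consensus(df, k_range=[2, 3], n_boot=30, seed=7)
        for k in (2, 3):
            f = res.cocluster_freq[k]
            np.testing.assert_allclose(f, f.T)
            np.testing.assert_allclose(np.diag(f), 1.0)
            assert ((f >= 0) & (f <= 1)).all()

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(4)
        df, _ = _clustered_data(rng, [6, 6])
        a = bootstrap_consensus(df, k_range=[2], n_boot=25, seed=11)
        b = bootstrap_consensus(df, k_range=[2], n_boot=25, seed=11)
        np.testing.assert_array_equal(a.cocluster_freq[2], b.cocluster_freq[2])

    def test_never_resampled_sample_is_an_error(self):
        rng = np.random.default_rng(5)
        df, _ = _clustered_data(rng, [4, 4])
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_consensus(df, k_range=[2], n_boot=0, seed=13)

    def test_monte_carlo_noise_shrinks_with_more_iterations(self):
        """Consensus entries of ambiguous pairs vary less across seeds at
        larger n_boot (~1/sqrt scaling)."""
        rng = np.random.default_rng(6)
        # structureless data: the inner split is arbitrary, so consensus
        # entries sit mid-range and carry visible Monte-Carlo noise
        df = pd.DataFrame(
            rng.random((120, 16)),
            index=[f"cg{i}" for i in range(120)],
            columns=[f"s{i}" for i in range(16)],
        )

        def spread(n_boot):
            mats = [
                bootstrap_consensus(df, k_range=[2], n_boot=n_boot, seed=s).cocluster_freq[2]
                for s in range(8)
            ]
            stack = np.stack(mats)
            iu = np.triu_indices(stack.shape[1], k=1)
            return stack[:, iu[0], iu[1]].std(axis=0).mean()

        assert spread(160) < spread(40)


class TestChooseK:
    def test_single_admissible_candidate_returned(self):
        rng = np.random.default_rng(7)
        df, _ = _clustered_data(rng, [8, 8])
        res = bootstrap_consensus(df, k_range=[2], n_boot=40, seed=17)
        assert choose_k(res).k == 2

    def test_small_cluster_makes_k_inadmissible(self):
        rng = np.random.default_rng(8)
        df, _ = _clustered_data(rng, [10, 10, 3])
        res = bootstrap_consensus(df, k_range=[2, 3], n_boot=60, seed=19)
        choice = choose_k(res, min_cluster_size=5)
        assert not bool(choice.diagnostics.loc[3, "admissible"])
        assert choice.k == 2

    def test_no_admissible_k_raises_with_diagnostics(self):
        rng = np.random.default_rng(9)
        df, _ = _clustered_data(rng, [3, 3])
        res = bootstrap_consensus(df, k_range=[2], n_boot=40, seed=23)
        with pytest.raises(ValueError, match="diagnostics"):
            choose_k(res, min_cluster_size=5)

    def test_planted_seven_epitypes_chosen(self, default_bundle):
        assert default_bundle.choice.k == 7


class TestCentroids:
    def test_centroid_is_the_member_mean(self):
        beta = pd.DataFrame(
            {"s1": [0.2, 0.5], "s2": [0.4, np.nan], "s3": [0.9, 0.7]},
            index=["cg1", "cg2"],
        )
        labels = pd.Series({"s1": "a", "s2": "a", "s3": "b"})
        model = build_centroids(beta, labels)
        # single-sample epitype equals that sample
        assert model.centroids.loc["cg1", "ET2"] == pytest.approx(0.9)
        # mean over the two members; missing excluded
        assert model.centroids.loc["cg1", "ET1"] == pytest.approx(0.3)
        assert model.centroids.loc["cg2", "ET1"] == pytest.approx(0.5)

    def test_ordering_by_similarity_to_reference(self):
        beta = pd.DataFrame(
            {"s1": [0.1, 0.2, 0.9], "s2": [0.9, 0.8, 0.1]},
            index=["cg1", "cg2", "cg3"],
        )
        labels = pd.Series({"s1": "x", "s2": "y"})
        ref = pd.Series({"cg1": 0.9, "cg2": 0.8, "cg3": 0.1})  # matches s2
        model = build_centroids(beta, labels, reference_profile=ref)
        assert model.metadata["source_labels"]["y"] == "ET1"
        assert relabel(labels, model).tolist() == ["ET2", "ET1"]

    def test_uncovered_samples_rejected(self):
        beta = pd.DataFrame({"s1": [0.1], "s2": [0.3]}, index=["cg1"])
        with pytest.raises(ValueError, match="cover"):
            build_centroids(beta, pd.Series({"s1": "a"}))


class TestClassify:
    def _model(self, n=150):
        rng = np.random.default_rng(10)
        cents = pd.DataFrame(
            rng.random((n, 3)),
            index=[f"cg{i}" for i in range(n)],
            columns=["ET1", "ET2", "ET3"],
        )
        from epityper.epityping import EpitypeModel

        return EpitypeModel(cents, ["ET1", "ET2", "ET3"], {"source_labels": {}})

    def test_sample_equal_to_centroid_gets_that_label(self):
        model = self._model()
        sample = model.centroids[["ET3"]].rename(columns={"ET3": "s"})
        out = classify_by_centroid(sample, model)
        assert out.labels["s"] == "ET3"
        assert out.correlations.loc["s", "ET3"] == pytest.approx(1.0)
        assert out.margin["s"] >= 0

    def test_anticorrelated_sample_still_assigned_to_argmax(self):
        model = self._model()
        sample = (1.0 - model.centroids[["ET2"]]).rename(columns={"ET2": "s"})
        out = classify_by_centroid(sample, model)
        assert (out.correlations.loc["s"] < 0).sum() >= 1
        assert out.labels["s"] == out.correlations.loc["s"].idxmax()

    def test_tie_broken_by_epitype_order(self):
        from epityper.epityping import EpitypeModel

        rng = np.random.default_rng(11)
        profile = rng.random(120)
        cents = pd.DataFrame(
            {"ET1": profile, "ET2": profile},  # identical centroids
            index=[f"cg{i}" for i in range(120)],
        )
        model = EpitypeModel(cents, ["ET1", "ET2"], {})
        sample = pd.DataFrame({"s": profile}, index=cents.index)
        out = classify_by_centroid(sample, model)
        assert out.labels["s"] == "ET1"
        assert out.margin["s"] == pytest.approx(0.0)

    def test_zero_variance_sample_rejected(self):
        model = self._model()
        flat = pd.DataFrame({"s": np.full(len(model.probes), 0.5)}, index=model.probes)
        with pytest.raises(ValueError, match="zero-variance"):
            classify_by_centroid(flat, model)

    def test_insufficient_overlap_rejected(self):
        model = self._model(n=50)
        sample = model.centroids[["ET1"]].rename(columns={"ET1": "s"})
        with pytest.raises(ValueError, match="overlap"):
            classify_by_centroid(sample, model, min_overlap=100)


class TestRecoveryOnSyntheticCohort:
    def test_outer_labels_match_planted_epitypes(self, default_bundle):
        b = default_bundle
        ari = adjusted_rand_score(
            b.truth.epitype_labels[b.consensus.samples], b.labels[b.consensus.samples]
        )
        assert ari >= 0.9

    def test_training_cohort_self_classification(self, default_bundle):
        b = default_bundle
        assign = classify_by_centroid(b.tumor_beta, b.model)
        agree = (assign.labels == b.labels.reindex(assign.labels.index)).mean()
        assert agree >= 0.9

    def test_held_out_classification_matches_planted_labels(
        self, default_bundle, heldout_bundle
    ):
        assign = classify_by_centroid(heldout_bundle.tumor_beta, default_bundle.model)
        predicted_planted = assign.labels.map(default_bundle.to_planted)
        truth = heldout_bundle.truth.epitype_labels[assign.labels.index]
        assert (predicted_planted == truth).mean() >= 0.95
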