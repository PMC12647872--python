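"""Trajectory autoencoder, outlier gate, K-Means subtyping and label transfer."""

import numpy as np
import pytest

from pdprog.cohort import SubtypeLabel
from pdprog.subtyping import (
    ClusteringModel,
    LSTMAutoencoderConfig,
    OutlierPolicy,
    cohort_losses,
    embed_participants,
    evaluate_k,
    fit_clusters,
    flag_outliers,
    order_subtypes,
    reconstruction_loss,
    train_autoencoder,
    transfer_labels,
    visit_mean_squared_error,
)
from pdprog.cohort import CohortError


TINY = LSTMAutoencoderConfig(epochs=2, seed=0)


@pytest.fixture(scope="module")
def tiny_model(small_normalized):
    return train_autoencoder(small_normalized, TINY)


class TestReconstructionLoss:
    def test_zero_for_exact_reconstruction(self):
        x = np.random.default_rng(0).random((3, 5))
        assert visit_mean_squared_error(x, x) == 0.0

    def test_single_visit_divides_by_one(self):
        x = np.zeros((1, 4))
        x_hat = np.array([[2.0, 0.0, 0.0, 0.0]])  # squared norm 4
        assert visit_mean_squared_error(x, x_hat) == pytest.approx(4.0)

    def test_three_visit_toy_matches_hand_evaluation(self):
        x = np.zeros((3, 2))
        x_hat = np.array([[1.0, 0.0], [0.0, 2.0], [1.0, 1.0]])
        # (1 + 4 + 2) / 3
        assert visit_mean_squared_error(x, x_hat) == pytest.approx(7.0 / 3.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(CohortError):
            visit_mean_squared_error(np.zeros((2, 3)), np.zeros((2, 4)))

    def test_model_loss_nonnegative_on_cohort(self, tiny_model, small_normalized):
        for p in small_normalized.participants[:3]:
            assert reconstruction_loss(tiny_model, p) >= 0.0


class TestEmbedding:
    def test_width_is_the_hidden_dimension_32(self, tiny_model, small_normalized):
        emb = embed_participants(tiny_model, small_normalized)
        assert emb.shape == (len(small_normalized), 32)

    def test_permuting_participants_permutes_rows(self, tiny_model, small_normalized):
        emb = embed_participants(tiny_model, small_normalized)
        ids = small_normalized.ids()
        perm = ids[::-1]
        from pdprog.cohort import Cohort
        shuffled = Cohort(small_normalized.schema,
                          [small_normalized.get(pid) for pid in perm])
        emb2 = embed_participants(tiny_model, shuffled)
        order = [ids.index(pid) for pid in perm]
        assert np.allclose(emb2, emb[order])

    def test_identical_trajectories_identical_embeddings(self, tiny_model,
                                                         small_normalized):
        emb = embed_participants(tiny_model, small_normalized)
        emb2 = embed_participants(tiny_model, small_normalized)
        assert np.array_equal(emb, emb2)

    def test_same_seed_training_is_bitwise_deterministic(self, small_normalized):
        a = train_autoencoder(small_normalized, TINY)
        b = train_autoencoder(small_normalized, TINY)
        ea = embed_participants(a, small_normalized)
        eb = embed_participants(b, small_normalized)
        assert np.array_equal(ea, eb)


class TestOutlierGate:
    def test_infinite_threshold_flags_nothing(self, tiny_model, small_normalized):
        kept, flagged = flag_outliers(tiny_model, small_normalized,
                                      OutlierPolicy(absolute=np.inf))
        assert flagged == [] and len(kept) == len(small_normalized)

    def test_quantile_one_flags_nothing(self, tiny_model, small_normalized):
        kept, flagged = flag_outliers(tiny_model, small_normalized,
                                      OutlierPolicy(quantile=1.0))
        assert flagged == []

    def test_absolute_threshold_is_monotone(self, tiny_model, small_normalized):
        losses = cohort_losses(tiny_model, small_normalized)
        cuts = np.quantile(losses, [0.3, 0.6, 0.9])
        flagged = [set(flag_outliers(tiny_model, small_normalized,
                                     OutlierPolicy(absolute=c))[1]) for c in cuts]
        assert flagged[2] <= flagged[1] <= flagged[0]


def _brute_force_silhouette(x, labels):
    n = len(x)
    d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
    s = []
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        a = d[i, same].mean()
        b = min(d[i, labels == c].mean() for c in set(labels) if c != labels[i])
        s.append((b - a) / max(a, b))
    return float(np.mean(s))


class TestKSelection:
    def test_two_tight_far_blobs_have_high_silhouette(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 0.05, (30, 4)),
                            rng.normal(10, 0.05, (30, 4))])
        report = evaluate_k(x, candidate_ks=(2,), standardize=False)
        assert report.silhouette[2] > 0.9

    def test_silhouette_matches_textbook_formula_on_hand_points(self):
        x = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0],
                      [8.0, 8.0], [8.0, 9.0], [9.0, 8.0]])
        report = evaluate_k(x, candidate_ks=(2,), standardize=False)
        from sklearn.cluster import KMeans
        labels = KMeans(2, n_init=10, random_state=0).fit_predict(x)
        assert report.silhouette[2] == pytest.approx(
            _brute_force_silhouette(x, labels), abs=1e-12)

    def test_criteria_invariant_to_coordinate_scaling(self):
        """Silhouette and Davies-Bouldin are ratios of distances, so scaling
        all coordinates by a constant leaves them unchanged; duplicating
        every point additionally leaves Davies-Bouldin (centroid-based)
        unchanged."""
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 0.5, (20, 3)), rng.normal(5, 0.5, (20, 3))])
        r1 = evaluate_k(x, candidate_ks=(2,), standardize=False)
        r_scaled = evaluate_k(7.5 * x, candidate_ks=(2,), standardize=False)
        assert r1.silhouette[2] == pytest.approx(r_scaled.silhouette[2], abs=1e-9)
        assert r1.davies_bouldin[2] == pytest.approx(r_scaled.davies_bouldin[2],
                                                     abs=1e-9)
        r_dup = evaluate_k(np.concatenate([x, x]), candidate_ks=(2,),
                           standardize=False)
        assert r1.davies_bouldin[2] == pytest.approx(r_dup.davies_bouldin[2],
                                                     abs=1e-9)

    def test_bounds_of_the_criteria(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(40, 5))
        r = evaluate_k(x, candidate_ks=(2, 3))
        for k in (2, 3):
            assert -1 <= r.silhouette[k] <= 1
            assert r.davies_bouldin[k] >= 0

    def test_too_few_points_rejected(self):
        with pytest.raises(CohortError):
            evaluate_k(np.zeros((3, 2)), candidate_ks=(2, 3))


class TestFitAndTransfer:
    def test_k_equals_one_puts_everyone_together(self):
        x = np.random.default_rng(0).normal(size=(10, 4))
        _, assign = fit_clusters(x, k=1, seed=0)
        assert set(assign) == {0}

    def test_transfer_reproduces_training_assignments(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(i * 5, 0.3, (15, 6)) for i in range(3)])
        model, assign = fit_clusters(x, k=3, seed=0)
        model.subtype_map = {0: SubtypeLabel("rapid"), 1: SubtypeLabel("moderate"),
                             2: SubtypeLabel("slow")}
        labels = transfer_labels(model, x)
        assert [model.subtype_map[int(c)].value for c in assign] == \
            [lab.value for lab in labels]

    def test_nearest_centroid_matches_brute_force(self):
        rng = np.random.default_rng(4)
        centroids = rng.normal(size=(3, 5))
        model = ClusteringModel(3, centroids, np.zeros(5), np.ones(5),
                                {0: SubtypeLabel("rapid"), 1: SubtypeLabel("moderate"),
                                 2: SubtypeLabel("slow")})
        pts = rng.normal(size=(50, 5))
        got = transfer_labels(model, pts)
        for p, lab in zip(pts, got):
            dists = [np.sum((p - c) ** 2) for c in centroids]
            assert model.subtype_map[int(np.argmin(dists))].value == lab.value

    def test_equidistant_point_takes_lowest_cluster_index(self):
        centroids = np.array([[1.0, 0.0], [-1.0, 0.0]])
        model = ClusteringModel(2, centroids, np.zeros(2), np.ones(2),
                                {0: SubtypeLabel("rapid"), 1: SubtypeLabel("slow")})
        lab = transfer_labels(model, np.array([[0.0, 3.0]]))[0]
        assert lab.value == "rapid"

    def test_dimension_mismatch_rejected(self):
        model = ClusteringModel(2, np.zeros((2, 5)), np.zeros(5), np.ones(5),
                                {0: SubtypeLabel("rapid"), 1: SubtypeLabel("slow")})
        with pytest.raises(CohortError):
            transfer_labels(model, np.zeros((3, 4)))

    def test_hc_rows_bypass_clustering(self):
        model = ClusteringModel(2, np.zeros((2, 2)), np.zeros(2), np.ones(2),
                                {0: SubtypeLabel("rapid"), 1: SubtypeLabel("slow")})
        labs = transfer_labels(model, np.zeros((2, 2)),
                               is_hc=np.array([False, True]))
        assert labs[1].value == "HC"

    def test_model_json_roundtrip(self, tmp_path):
        model = ClusteringModel(3, np.arange(9.0).reshape(3, 3), np.zeros(3),
                                np.ones(3),
                                {0: SubtypeLabel("moderate"), 1: SubtypeLabel("rapid"),
                                 2: SubtypeLabel("slow")}, l_max=1.5)
        model.to_json(tmp_path / "m.json")
        back = ClusteringModel.from_json(tmp_path / "m.json")
        assert np.array_equal(back.centroids, model.centroids)
        assert back.subtype_map[1].value == "rapid"
        assert back.l_max == 1.5


class TestOrderSubtypes:
    def _cohort_with_slopes(self, slopes_per_cluster):
        """Three participants per cluster with exact part-III slopes."""
        from pdprog.simulate import GeneratorConfig, default_profiles, generate
        profs = default_profiles(noise_sd=0.0)
        # exact integer lines, no spread
        mk = type(profs["rapid"])
        profiles = {}
        names = ["rapid", "moderate", "slow"]
        for name, s in zip(names, slopes_per_cluster):
            profiles[name] = mk(SubtypeLabel(name), (5.0, 5.0, 10.0), (0, 0, 0),
                                (0.0, 0.0, s), (0, 0, 0), 0.0, 0.0, 0.0)
        profiles["HC"] = profs["HC"]
        cfg = GeneratorConfig(
            n_per_subtype={"rapid": 3, "moderate": 3, "slow": 3, "HC": 0},
            missing_rate_even=0.0, missing_rate_odd=0.0,
            visit_count_range=(5, 5), profiles=profiles, seed=0)
        return generate(cfg)

    def test_slope_ranking_maps_rapid_moderate_slow(self):
        cohort, labels = self._cohort_with_slopes((3.0, 1.5, 0.3))
        imp_assign = np.array([0] * 3 + [1] * 3 + [2] * 3)
        model = ClusteringModel(3, np.zeros((3, 2)), np.zeros(2), np.ones(2))
        mapping = order_subtypes(model, cohort, imp_assign)
        assert [mapping[c].value for c in range(3)] == ["rapid", "moderate", "slow"]

    def test_invariant_to_cluster_index_permutation(self):
        cohort, _ = self._cohort_with_slopes((3.0, 1.5, 0.3))
        assign = np.array([0] * 3 + [1] * 3 + [2] * 3)
        perm = {0: 2, 1: 0, 2: 1}
        assign_p = np.array([perm[a] for a in assign])
        m1 = ClusteringModel(3, np.zeros((3, 2)), np.zeros(2), np.ones(2))
        m2 = ClusteringModel(3, np.zeros((3, 2)), np.zeros(2), np.ones(2))
        map1 = order_subtypes(m1, cohort, assign)
        map2 = order_subtypes(m2, cohort, assign_p)
        per_participant1 = [map1[a].value for a in assign]
        per_participant2 = [map2[a].value for a in assign_p]
        assert per_participant1 == per_participant2

    def test_all_equal_slopes_break_ties_deterministically(self):
        cohort, _ = self._cohort_with_slopes((1.0, 1.0, 1.0))
        assign = np.array([0] * 3 + [1] * 3 + [2] * 3)
        model = ClusteringModel(3, np.zeros((3, 2)), np.zeros(2), np.ones(2))
        mapping = order_subtypes(model, cohort, assign)  # no exception
        assert sorted(lab.value for lab in mapping.values()) == \
            ["moderate", "rapid", "slow"]
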