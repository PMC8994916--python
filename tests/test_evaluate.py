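"""Evaluation metrics, baselines, cross-validation, and perturbations."""

import numpy as np
import pytest

from hicmarks.datamodel import (
    ContactRecords,
    MarkAssignment,
    MarkCatalog,
    MarkPairMatrix,
    SiteIndex,
    ValidationError,
)
from hicmarks.evaluate import (
    PartitionLabels,
    boundary_confusion,
    compartment_calls,
    delete_region,
    fit_distance_decay,
    mask_marks,
    nested_cv,
    nvi,
    predict_probabilities,
    roc_auc,
    sample_negative_pairs,
    stability_correlation,
)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc(np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0]))
        assert auc == 1.0

    def test_all_equal_scores_half(self):
        auc, _ = roc_auc(np.array([0.5, 0.5, 0.5, 0.5]), np.array([1, 0, 1, 0]))
        assert auc == 0.5

    def test_mixed_example(self):
        # 2 positives x 1 negative: one win (0.9 > 0.8), one loss (0.3 < 0.8)
        auc, _ = roc_auc(np.array([0.9, 0.8, 0.3]), np.array([1, 0, 1]))
        assert auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError, match="single class"):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        scores = rng.random(50)
        truth = rng.integers(0, 2, 50)
        if truth.sum() in (0, 50):
            truth[0] = 1 - truth[0]
        a1, _ = roc_auc(scores, truth)
        a2, _ = roc_auc(np.log(scores + 1e-9) * 3 + 7, truth)
        np.testing.assert_allclose(a1, a2)


class TestDistanceDecay:
    def test_all_negative_labels(self):
        p = fit_distance_decay(np.array([1e4, 2e4]), np.array([0, 0]), beta=1.0)
        assert p.alpha == 0.0

    def test_single_distance_empirical_rate(self):
        d = np.full(100, 5e4)
        y = np.array([1, 0] * 50)
        p = fit_distance_decay(d, y, beta=1.5)
        np.testing.assert_allclose(p.predict(np.array([5e4]))[0], 0.5, atol=1e-4)

    def test_alpha_does_not_change_ranks(self):
        d = np.array([1e3, 1e4, 1e5])
        a = fit_distance_decay(d, np.array([1, 0, 0]), beta=1.0)
        s1 = a.predict(d)
        s2 = BaselineParamsLike(a.alpha * 0.5, a.beta).predict(d)
        assert np.array_equal(np.argsort(s1), np.argsort(s2))


class BaselineParamsLike:
    def __init__(self, alpha, beta):
        self.alpha, self.beta = alpha, beta

    def predict(self, d):
        return np.clip(self.alpha * np.asarray(d, float) ** (-self.beta), 0, 1)


class TestCompartmentCalls:
    def test_two_block_checkerboard(self):
        n = 6
        labels_true = np.array([0, 0, 0, 1, 1, 1])
        M = np.where(
            labels_true[:, None] == labels_true[None, :], 0.9, 0.1
        ) + np.diag(np.full(n, 0.05))
        part = compartment_calls(M)
        assert nvi(part, PartitionLabels(labels_true)) < 1e-12

    def test_sign_flip_same_partition(self):
        n = 6
        labels_true = np.array([0, 1, 0, 1, 0, 1])
        M = np.where(labels_true[:, None] == labels_true[None, :], 0.8, 0.2)
        M = M + np.random.default_rng(0).normal(scale=1e-3, size=(n, n))
        M = (M + M.T) / 2
        p = compartment_calls(M)
        flipped = PartitionLabels(1 - p.labels)
        assert nvi(p, flipped) < 1e-12

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            compartment_calls(np.ones((4, 4)))

    def test_at_most_two_clusters(self):
        rng = np.random.default_rng(1)
        M = rng.random((5, 5))
        M = (M + M.T) / 2
        part = compartment_calls(M)
        assert len(np.unique(part.labels)) <= 2


class TestNvi:
    def test_identical_partitions_zero(self):
        p = PartitionLabels([0, 1, 1, 0])
        assert nvi(p, p) == 0.0

    def test_singletons_vs_one_block(self):
        p = PartitionLabels([0, 1, 2, 3])
        q = PartitionLabels([0, 0, 0, 0])
        np.testing.assert_allclose(nvi(p, q), 1.0, rtol=1e-12)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.integers(0, 4, 30)
            b = rng.integers(0, 4, 30)
            v1, v2 = nvi(a, b), nvi(b, a)
            np.testing.assert_allclose(v1, v2)
            assert 0.0 <= v1 <= 1.0

    def test_label_permutation_invariant(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        b = np.array([5, 5, 9, 9, 7, 7])
        assert nvi(a, b) == 0.0


class TestBoundaryConfusion:
    def test_identical_sets(self):
        out = boundary_confusion([10, 20], [10, 20], tol_bins=0)
        assert out["TP"] == 2 and out["FP"] == 0 and out["TPR"] == 1.0

    def test_disjoint_sets(self):
        out = boundary_confusion([10, 20], [30, 40], tol_bins=0)
        assert out["TP"] == 0 and out["FNR"] == 1.0

    def test_tolerance_matching(self):
        out = boundary_confusion([10, 20], [11, 40], tol_bins=1)
        assert out == {"TP": 1, "FP": 1, "FN": 1, "TPR": 0.5, "FNR": 0.5}

    def test_each_prediction_matched_once(self):
        # one prediction cannot satisfy two true boundaries
        out = boundary_confusion([10, 12], [11], tol_bins=1)
        assert out["TP"] == 1 and out["FN"] == 1 and out["FP"] == 0

    def test_tpr_monotone_in_tolerance(self):
        t, p = [5, 15, 25], [7, 18, 40]
        tprs = [boundary_confusion(t, p, tol)["TPR"] for tol in range(0, 6)]
        assert all(a <= b for a, b in zip(tprs, tprs[1:]))


class TestStabilityCorrelation:
    def _mat(self, entries):
        cat = MarkCatalog(("a", "b"))
        X = np.array([[entries[0], entries[1]], [entries[1], entries[2]]])
        return MarkPairMatrix(X, cat)

    def test_identical_matrices(self):
        m = self._mat([0.1, 0.2, 0.3])
        assert stability_correlation(m, m) == 1.0

    def test_rank_reversed(self):
        a = self._mat([0.1, 0.2, 0.3])
        b = self._mat([0.3, 0.2, 0.1])
        np.testing.assert_allclose(stability_correlation(a, b), -1.0)

    def test_partial_agreement(self):
        # upper triangles rank as (1,2,3) vs (1,3,2): rho = 0.5
        a = self._mat([0.1, 0.2, 0.3])
        b = self._mat([0.1, 0.3, 0.2])
        np.testing.assert_allclose(stability_correlation(a, b), 0.5)

    def test_catalog_mismatch_rejected(self):
        a = self._mat([0.1, 0.2, 0.3])
        b = MarkPairMatrix(np.zeros((2, 2)), MarkCatalog(("x", "y")))
        with pytest.raises(ValidationError):
            stability_correlation(a, b)


class TestPredictProbabilities:
    def test_mark_free_endpoint_scores_zero(self, fixture_suite):
        s = fixture_suite["tiny"]
        a = s["assignment"].copy()
        a.counts[0, :] = 0
        X = s["truth"].X_true
        scores = predict_probabilities(X, a, np.array([[0, 1], [0, 2]]))
        np.testing.assert_allclose(scores, 0.0)

    def test_deterministic_for_duplicate_pairs(self, fixture_suite):
        s = fixture_suite["tiny"]
        scores = predict_probabilities(
            s["truth"].X_true, s["assignment"], np.array([[0, 1], [0, 1]])
        )
        assert scores[0] == scores[1]

    def test_matches_edge_probability(self, fixture_suite):
        from hicmarks.model import edge_probability

        s = fixture_suite["small"]
        a, X = s["assignment"], s["truth"].X_true
        pairs = np.array([[0, 5], [3, 100], [20, 400]])
        scores = predict_probabilities(X, a, pairs)
        for (u, v), got in zip(pairs, scores):
            np.testing.assert_allclose(
                got, edge_probability(a.counts[u], a.counts[v], X), atol=1e-12
            )


class TestNegativeSampling:
    def test_negatives_are_nonedges_within_chromosome(self, fixture_suite):
        s = fixture_suite["small"]
        neg = sample_negative_pairs(s["contacts"], s["assignment"], ratio=2, seed=3)
        edges = s["contacts"].pair_set()
        chroms = s["assignment"].index.chroms
        for u, v in neg:
            assert (u, v) not in edges
            assert u < v
            assert chroms[u] == chroms[v]

    def test_seeded_determinism(self, fixture_suite):
        s = fixture_suite["small"]
        n1 = sample_negative_pairs(s["contacts"], s["assignment"], ratio=2, seed=3)
        n2 = sample_negative_pairs(s["contacts"], s["assignment"], ratio=2, seed=3)
        assert np.array_equal(n1, n2)


@pytest.fixture(scope="module")
def cv_instance():
    from hicmarks.synthetic import make_truth, sample_assignment, sample_contacts

    truth = make_truth(
        3, sparsity=0.6, seed=21, n_sites=60, density_range=(0.3, 0.7)
    )
    a = sample_assignment(truth)
    c = sample_contacts(truth, a, mode="unbinned")
    return a, c


class TestNestedCV:

    def test_single_grid_point_chosen(self, cv_instance):
        a, c = cv_instance
        out = nested_cv(
            c, a, lambda_grid=[(0.1, 0.1)], outer_k=2, inner_k=2, seed=0,
            neg_ratio=2, admm_kwargs={"tol": 1e-3, "max_iter": 50},
        )
        assert out["chosen_lambda"] == (0.1, 0.1)

    def test_folds_partition_scored_pairs(self, cv_instance):
        a, c = cv_instance
        out = nested_cv(
            c, a, lambda_grid=[(0.1, 0.1)], outer_k=3, inner_k=2, seed=1,
            neg_ratio=2, admm_kwargs={"tol": 1e-3, "max_iter": 50},
        )
        assert len(out["pairs"]) == len(out["labels"])

    def test_determinism_under_seed(self, cv_instance):
        a, c = cv_instance
        kw = dict(
            lambda_grid=[(0.01, 0.01), (0.5, 0.5)], outer_k=2, inner_k=2,
            neg_ratio=2, admm_kwargs={"tol": 1e-3, "max_iter": 50},
        )
        o1 = nested_cv(c, a, seed=7, **kw)
        o2 = nested_cv(c, a, seed=7, **kw)
        assert o1["chosen_lambda"] == o2["chosen_lambda"]
        assert o1["folds"] == o2["folds"]

    def test_chosen_lambda_in_grid(self, cv_instance):
        a, c = cv_instance
        grid = [(0.01, 0.01), (0.1, 0.1)]
        out = nested_cv(
            c, a, lambda_grid=grid, outer_k=2, inner_k=2, seed=2,
            neg_ratio=2, admm_kwargs={"tol": 1e-3, "max_iter": 50},
        )
        assert out["chosen_lambda"] in grid

    def test_bad_mode_rejected(self, cv_instance):
        a, c = cv_instance
        with pytest.raises(ValidationError):
            nested_cv(c, a, mode="nope")


class TestMaskMarks:
    def test_masking_never_increases_probabilities(self, fixture_suite):
        s = fixture_suite["small"]
        a, X = s["assignment"], s["truth"].X_true
        rng = np.random.default_rng(5)
        pairs = rng.integers(0, a.n_sites, size=(500, 2))
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
        before = predict_probabilities(X, a, pairs)
        span = (str(a.index.chroms[0]), 0, int(a.index.positions[-1]) + 1)
        masked = mask_marks(a, span, marks=[a.catalog.names[0]])
        after = predict_probabilities(X, masked, pairs)
        assert np.all(after <= before + 1e-12)

    def test_masking_all_marks_zeroes_probabilities(self, fixture_suite):
        s = fixture_suite["tiny"]
        a, X = s["assignment"], s["truth"].X_true
        span = (str(a.index.chroms[0]), 0, int(a.index.positions[-1]) + 1)
        masked = mask_marks(a, span, marks="all")
        scores = predict_probabilities(X, masked, np.array([[0, 1], [2, 5]]))
        np.testing.assert_allclose(scores, 0.0)

    def test_counts_elementwise_bounded(self, fixture_suite):
        s = fixture_suite["small"]
        a = s["assignment"]
        masked = mask_marks(a, (str(a.index.chroms[0]), 0, 100000), marks="all")
        assert np.all(masked.counts <= a.counts)


class TestDeleteRegion:
    def test_zero_length_region_identity(self, fixture_suite):
        s = fixture_suite["tiny"]
        a, c = s["assignment"], s["contacts"]
        a2, c2 = delete_region(a, c, (str(a.index.chroms[0]), 5000, 5000))
        assert len(a2.index) == len(a.index)
        assert len(c2) == len(c)

    def test_site_count_conservation(self, fixture_suite):
        s = fixture_suite["small"]
        a, c = s["assignment"], s["contacts"]
        chrom = str(a.index.chroms[0])
        start, end = 100000, 200000
        inside = int(
            np.sum(
                (a.index.chroms == chrom)
                & (a.index.positions >= start)
                & (a.index.positions < end)
            )
        )
        a2, _ = delete_region(a, c, (chrom, start, end))
        assert len(a2.index) == len(a.index) - inside

    def test_downstream_coordinates_shifted(self):
        idx = SiteIndex(
            np.array(["c"] * 3, dtype=object), np.array([1000, 5000, 9000])
        )
        a = MarkAssignment(np.ones((3, 1), dtype=int), MarkCatalog(("m",)), idx)
        c = ContactRecords(np.array([0]), np.array([2]), np.array([1]), idx)
        a2, c2 = delete_region(a, c, ("c", 4000, 6000))
        assert list(a2.index.positions) == [1000, 7000]
        assert len(c2) == 1  # contact (0, 2) survives, endpoints remapped

    def test_contacts_incident_to_region_dropped(self):
        idx = SiteIndex(
            np.array(["c"] * 3, dtype=object), np.array([1000, 5000, 9000])
        )
        a = MarkAssignment(np.ones((3, 1), dtype=int), MarkCatalog(("m",)), idx)
        c = ContactRecords(np.array([0, 0]), np.array([1, 2]), np.array([1, 1]), idx)
        _, c2 = delete_region(a, c, ("c", 4000, 6000))
        assert len(c2) == 1
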