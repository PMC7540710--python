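"""Stratified accuracy/area estimators vs a from-first-principles oracle."""

import numpy as np
import pytest

from mangrove_drivers.accuracy import (ErrorMatrix, accuracy_report,
                                       allocate_samples, build_error_matrix,
                                       corrected_areas,
                                       simulate_reference_labels)

# ---------------------------------------------------------------------------
# brute-force oracle: explicit double loops over the estimated proportions


def oracle_estimates(counts, areas):
    counts = np.asarray(counts, float)
    areas = np.asarray(areas, float)
    k = counts.shape[0]
    w = areas / areas.sum()
    ni = counts.sum(axis=1)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            p[i, j] = w[i] * counts[i, j] / ni[i]
    oa = sum(p[j, j] for j in range(k))
    ua = np.array([p[i, i] / sum(p[i, j] for j in range(k)) for i in range(k)])
    pa = np.array([p[j, j] / sum(p[i, j] for i in range(k)) for j in range(k)])
    oa_var = sum(w[i] ** 2 * ua[i] * (1 - ua[i]) / (ni[i] - 1) for i in range(k))
    ua_var = np.array([ua[i] * (1 - ua[i]) / (ni[i] - 1) for i in range(k)])
    nhat = np.array([sum(areas[i] * counts[i, j] / ni[i] for i in range(k))
                     for j in range(k)])
    pa_var = np.zeros(k)
    for j in range(k):
        t1 = (areas[j] ** 2 * (1 - pa[j]) ** 2 * ua[j] * (1 - ua[j])
              / (ni[j] - 1))
        t2 = sum(areas[i] ** 2 * (counts[i, j] / ni[i])
                 * (1 - counts[i, j] / ni[i]) / (ni[i] - 1)
                 for i in range(k) if i != j)
        pa_var[j] = (t1 + pa[j] ** 2 * t2) / nhat[j] ** 2
    a_total = areas.sum()
    a_hat = np.array([a_total * sum(w[i] * counts[i, j] / ni[i]
                                    for i in range(k)) for j in range(k)])
    se_area = np.array([
        a_total * np.sqrt(sum(
            w[i] ** 2 * (counts[i, j] / ni[i]) * (1 - counts[i, j] / ni[i])
            / (ni[i] - 1) for i in range(k)))
        for j in range(k)])
    return dict(oa=oa, ua=ua, pa=pa, oa_var=oa_var, ua_var=ua_var,
                pa_var=pa_var, a_hat=a_hat, se_area=se_area)


def random_matrix(rng):
    k = rng.integers(3, 6)
    counts = rng.integers(0, 12, size=(k, k))
    counts[np.diag_indices(k)] += rng.integers(2, 10, size=k)  # rows >= 2
    areas = rng.uniform(10, 100, size=k)
    classes = [f"c{i}" for i in range(k)]
    return ErrorMatrix(classes, counts, areas)


class TestAllocation:
    def test_exact_proportions(self):
        assert allocate_samples({"a": 50, "b": 50}, 10) == {"a": 5, "b": 5}

    def test_largest_remainder_oracle(self):
        out = allocate_samples({"a": 1, "b": 1, "c": 1}, 10)
        vals = sorted(out.values())
        assert sum(vals) == 10 and vals[-1] - vals[0] <= 1

    def test_tiny_class_receives_floor_of_one(self):
        out = allocate_samples({"a": 1e6, "b": 1.0}, 20)
        assert out["b"] >= 1 and sum(out.values()) == 20

    def test_degenerate_areas_rejected(self):
        with pytest.raises(ValueError):
            allocate_samples({"a": 0.0, "b": 1.0}, 10)
        with pytest.raises(ValueError):
            allocate_samples({"a": 1.0, "b": 1.0}, 1)

    def test_matches_quota_on_random_inputs(self, rng):
        for _ in range(20):
            k = rng.integers(2, 6)
            areas = {f"c{i}": float(rng.uniform(1, 100)) for i in range(k)}
            n = int(rng.integers(k, 200))
            out = allocate_samples(areas, n)
            assert sum(out.values()) == n
            total = sum(areas.values())
            for c, cnt in out.items():
                assert abs(cnt - n * areas[c] / total) <= k  # near-proportional


class TestErrorMatrix:
    def test_perfect_agreement_is_diagonal(self):
        m = build_error_matrix(["a", "b", "a"], ["a", "b", "a"],
                               {"a": 10, "b": 5})
        assert np.trace(m.counts) == m.n == 3

    def test_margins_and_permutation_invariance(self, rng):
        labels = list("abcab" * 8)
        refs = list("ababc" * 8)
        m = build_error_matrix(labels, refs, {"a": 1, "b": 2, "c": 3})
        np.testing.assert_array_equal(m.row_totals, m.counts.sum(axis=1))
        np.testing.assert_array_equal(m.col_totals, m.counts.sum(axis=0))
        perm = rng.permutation(len(labels))
        m2 = build_error_matrix(np.array(labels)[perm], np.array(refs)[perm],
                                {"a": 1, "b": 2, "c": 3})
        np.testing.assert_array_equal(m.counts, m2.counts)

    def test_label_outside_class_set_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            build_error_matrix(["a", "z"], ["a", "a"], {"a": 1, "b": 1})

    def test_weights_sum_to_one(self, rng):
        m = random_matrix(rng)
        assert m.weights.sum() == pytest.approx(1.0, abs=1e-12)


class TestAccuracyReport:
    def test_identity_matrix_perfect_scores(self):
        m = ErrorMatrix(["a", "b"], np.diag([30, 20]), np.array([60.0, 40.0]))
        rep = accuracy_report(m)
        assert rep.overall == 1.0
        np.testing.assert_allclose(rep.users, 1.0)
        np.testing.assert_allclose(rep.producers, 1.0)
        assert rep.overall_se == 0.0

    def test_two_class_hand_computation(self):
        """W=(0.8,0.2), counts [[45,5],[10,40]] -> OA = 0.88."""
        m = ErrorMatrix(["a", "b"], np.array([[45, 5], [10, 40]]),
                        np.array([80.0, 20.0]))
        rep = accuracy_report(m)
        assert rep.overall == pytest.approx(0.8 * 45 / 50 + 0.2 * 40 / 50,
                                            abs=1e-12)
        assert rep.users[0] == pytest.approx(0.9, abs=1e-12)

    def test_published_count_weighted_overall(self):
        """Count-weighted mean of per-class user's accuracies.

        With per-class UAs (88.3, 81.6, 77.5, 72.3, 68.1)% at sample
        counts (1104, 522, 200, 384, 266) the pooled overall accuracy
        lands within half a point of 81.5%.
        """
        ua = np.array([88.3, 81.6, 77.5, 72.3, 68.1])
        n = np.array([1104, 522, 200, 384, 266])
        pooled = float((ua * n).sum() / n.sum())
        assert pooled == pytest.approx(81.5, abs=0.5)

    def test_empty_row_error_names_class(self):
        m = ErrorMatrix(["a", "b"], np.array([[3, 1], [0, 0]]),
                        np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="'b'"):
            accuracy_report(m)

    def test_matches_oracle_on_random_matrices(self, rng):
        """OA/UA/PA and variances agree with the double-loop oracle to 1e-12."""
        for _ in range(100):
            m = random_matrix(rng)
            rep = accuracy_report(m)
            o = oracle_estimates(m.counts, m.map_areas)
            assert rep.overall == pytest.approx(o["oa"], abs=1e-12)
            np.testing.assert_allclose(rep.users, o["ua"], atol=1e-12)
            np.testing.assert_allclose(rep.producers, o["pa"], atol=1e-12)
            assert rep.overall_se == pytest.approx(np.sqrt(o["oa_var"]),
                                                   abs=1e-12)
            np.testing.assert_allclose(rep.users_se, np.sqrt(o["ua_var"]),
                                       atol=1e-12)
            np.testing.assert_allclose(rep.producers_se, np.sqrt(o["pa_var"]),
                                       atol=1e-12)


class TestCorrectedAreas:
    def test_identity_matrix_returns_map_areas(self):
        m = ErrorMatrix(["a", "b"], np.diag([30, 20]), np.array([60.0, 40.0]))
        est = corrected_areas(m)
        np.testing.assert_allclose(est.areas, [60.0, 40.0])
        np.testing.assert_allclose(est.ci_halfwidth, 0.0)

    def test_two_class_hand_computation(self):
        m = ErrorMatrix(["a", "b"], np.array([[45, 5], [10, 40]]),
                        np.array([80.0, 20.0]))
        est = corrected_areas(m)
        assert est.areas[0] == pytest.approx(
            100 * (0.8 * 45 / 50 + 0.2 * 10 / 50), abs=1e-12)  # 76

    def test_total_area_conserved_and_oracle_match(self, rng):
        for _ in range(100):
            m = random_matrix(rng)
            est = corrected_areas(m)
            assert est.areas.sum() == pytest.approx(m.map_areas.sum(),
                                                    rel=1e-12)
            o = oracle_estimates(m.counts, m.map_areas)
            np.testing.assert_allclose(est.areas, o["a_hat"], atol=1e-9)
            np.testing.assert_allclose(est.se, o["se_area"], atol=1e-9)

    def test_single_sample_row_rejected(self):
        m = ErrorMatrix(["a", "b"], np.array([[1, 0], [5, 5]]),
                        np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="variance undefined"):
            corrected_areas(m)


class TestCoverage:
    def test_ci_covers_true_area_in_at_least_90pct_of_replicates(self):
        """95% area CIs from simulated confusion cover truth >= 90% per class.

        Reference labels are drawn from a known per-stratum confusion
        model, so the true class areas are known exactly; over 100
        seeded replicates each class's 95% CI must cover its true area
        in at least 90 of them.
        """
        rng = np.random.default_rng(2024)
        classes = ["a", "b", "c"]
        areas = {"a": 500.0, "b": 300.0, "c": 200.0}
        confusion = np.array([[0.85, 0.10, 0.05],
                              [0.10, 0.80, 0.10],
                              [0.05, 0.10, 0.85]])
        area_vec = np.array([areas[c] for c in classes])
        true_areas = confusion.T @ area_vec
        alloc = allocate_samples(areas, 300)
        map_labels = np.repeat(classes, [alloc[c] for c in classes])
        hits = np.zeros(3)
        n_rep = 100
        for _ in range(n_rep):
            refs = simulate_reference_labels(map_labels, confusion, classes, rng)
            est = corrected_areas(build_error_matrix(map_labels, refs, areas))
            hits += (np.abs(est.areas - true_areas) <= est.ci_halfwidth)
        assert (hits >= 0.90 * n_rep).all(), hits
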