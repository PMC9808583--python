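from __future__ import annotations

import math

import numpy as np
import pytest

from cohortsim.embeddings import TermVector
from cohortsim.errors import (
    EmptyRepresentationError,
    IncomparableRepresentationsError,
)
from cohortsim.patient import LabelDistribution, PatientRepresentation
from cohortsim.similarity import (
    DistanceMatrix,
    GlobalDistanceConfig,
    distance_matrix,
    emd,
    global_distance,
    label_distance,
    lambda_weight,
)
from cohortsim.transport import solve_transport

from _oracles import lp_transport_value
from conftest import random_distribution, random_representation


def unit(theta: float) -> np.ndarray:
    return np.array([math.cos(theta), math.sin(theta)])


def dist(points, weights) -> LabelDistribution:
    return LabelDistribution(
        points=tuple(TermVector(f"t{i}", p) for i, p in enumerate(points)),
        weights=np.asarray(weights, dtype=float),
    )


class TestSolveTransport:
    def test_identical_distributions_cost_zero(self):
        C = np.zeros((2, 2))
        value, _ = solve_transport(C, np.array([0.5, 0.5]), np.array([0.5, 0.5]))
        assert value == 0.0

    def test_forced_single_sink_plan(self):
        # d(x,z)=0.2, d(y,z)=0.4, all mass to z: 0.5*0.2 + 0.5*0.4 = 0.3
        C = np.array([[0.2], [0.4]])
        value, plan = solve_transport(C, np.array([0.5, 0.5]), np.array([1.0]))
        assert value == pytest.approx(0.3)
        np.testing.assert_allclose(plan, [[0.5], [0.5]])

    def test_unbalanced_marginals_rejected(self):
        with pytest.raises(ValueError):
            solve_transport(np.ones((2, 2)), np.array([0.7, 0.7]), np.array([0.5, 0.5]))

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_generic_lp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m, n = int(rng.integers(1, 6)), int(rng.integers(1, 6))
        U = rng.standard_normal((m, 4))
        V = rng.standard_normal((n, 4))
        U /= np.linalg.norm(U, axis=1, keepdims=True)
        V /= np.linalg.norm(V, axis=1, keepdims=True)
        C = np.clip(1 - U @ V.T, 0, 2)
        a = rng.integers(1, 5, m).astype(float)
        b = rng.integers(1, 5, n).astype(float)
        a, b = a / a.sum(), b / b.sum()
        value, plan = solve_transport(C, a, b)
        assert value == pytest.approx(lp_transport_value(C, a, b), abs=1e-8)
        np.testing.assert_allclose(plan.sum(axis=1), a, atol=1e-12)
        np.testing.assert_allclose(plan.sum(axis=0), b, atol=1e-12)


class TestEMD:
    def test_point_mass_pair_equals_cosine_distance(self):
        a = dist([unit(0.0)], [1.0])
        b = dist([unit(math.pi / 2)], [1.0])
        assert emd(a, b) == pytest.approx(1.0)  # orthogonal unit vectors

    def test_identical_distribution_distance_zero(self):
        a = dist([unit(0.3), unit(1.2)], [0.25, 0.75])
        assert emd(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_hand_combined_two_point_case(self):
        # cosine distance between angles t1,t2 on the circle is 1-cos(t1-t2)
        a = dist([unit(0.0), unit(1.0)], [0.5, 0.5])
        b = dist([unit(0.2)], [1.0])
        expected = 0.5 * (1 - math.cos(0.2)) + 0.5 * (1 - math.cos(0.8))
        assert emd(a, b) == pytest.approx(expected)


class TestLambdaWeight:
    @pytest.mark.parametrize(
        "args,expected",
        [((2, 3, 4, 6), 0.5), ((0, 0, 4, 6), 0.0), ((4, 6, 4, 6), 1.0)],
    )
    def test_formula(self, args, expected):
        assert lambda_weight(*args) == pytest.approx(expected)

    def test_two_empty_reports_are_incomparable(self):
        with pytest.raises(EmptyRepresentationError):
            lambda_weight(0, 0, 0, 0)

    @pytest.mark.parametrize("seed", range(25))
    def test_weights_sum_to_one_for_single_labeled_reports(self, seed):
        rng = np.random.default_rng(seed)
        labels = ["a", "b", "c"]
        r1 = random_representation(rng, "d1", labels)
        r2 = random_representation(rng, "d2", labels)
        total = math.fsum(
            lambda_weight(r1.n_terms(l), r2.n_terms(l), r1.total_terms, r2.total_terms)
            for l in labels
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_multilabel_weights_sum_to_at_least_one(self, seed):
        rng = np.random.default_rng(seed + 1000)
        labels = ["a", "b", "c"]
        r1 = random_representation(rng, "d1", labels, multilabel=True)
        r2 = random_representation(rng, "d2", labels, multilabel=True)
        universe = sorted(r1.labels | r2.labels)
        total = math.fsum(
            lambda_weight(r1.n_terms(l), r2.n_terms(l), r1.total_terms, r2.total_terms)
            for l in universe
        )
        assert total >= 1.0 - 1e-12


class TestGlobalDistance:
    def two_label_fixture(self):
        rng = np.random.default_rng(5)
        r1 = random_representation(rng, "d1", ["a", "b"])
        r2 = random_representation(rng, "d2", ["a", "b"])
        return r1, r2

    def test_self_distance_zero_and_symmetry(self):
        r1, r2 = self.two_label_fixture()
        assert global_distance(r1, r1) == pytest.approx(0.0, abs=1e-12)
        assert global_distance(r1, r2) == pytest.approx(global_distance(r2, r1))

    def test_equals_hand_combined_lambda_weighted_emds(self):
        r1, r2 = self.two_label_fixture()
        expected = 0.0
        for label in ("a", "b"):
            lam = lambda_weight(
                r1.n_terms(label), r2.n_terms(label), r1.total_terms, r2.total_terms
            )
            d1, d2 = r1.distribution(label), r2.distribution(label)
            ua = np.stack([p.vector for p in d1.points])
            ub = np.stack([p.vector for p in d2.points])
            ua /= np.linalg.norm(ua, axis=1, keepdims=True)
            ub /= np.linalg.norm(ub, axis=1, keepdims=True)
            C = np.clip(1 - ua @ ub.T, 0, 2)
            expected += lam * lp_transport_value(C, d1.weights, d2.weights)
        expected /= 2
        assert global_distance(r1, r2) == pytest.approx(expected, abs=1e-10)

    def test_label_subset_reduces_to_single_label_distance(self):
        r1, r2 = self.two_label_fixture()
        cfg = GlobalDistanceConfig(label_subset=frozenset({"a"}))
        lam = lambda_weight(r1.n_terms("a"), r2.n_terms("a"), r1.total_terms, r2.total_terms)
        assert global_distance(r1, r2, cfg) == pytest.approx(
            lam * label_distance(r1, r2, "a")
        )

    def test_no_shared_label_raises_distinct_error(self):
        rng = np.random.default_rng(9)
        r1 = random_representation(rng, "d1", ["a"])
        r2 = random_representation(rng, "d2", ["b"])
        with pytest.raises(IncomparableRepresentationsError):
            global_distance(r1, r2)
        empty = PatientRepresentation(document_id="d3", patient_id="p3")
        with pytest.raises(EmptyRepresentationError):
            global_distance(r1, empty)

    def test_penalty_mode_charges_one_sided_labels(self):
        rng = np.random.default_rng(11)
        r1 = random_representation(rng, "d1", ["a", "b"])
        r2 = random_representation(rng, "d2", ["a"])
        cfg = GlobalDistanceConfig(missing_label_mode="penalty", penalty_value=1.0)
        lam_a = lambda_weight(r1.n_terms("a"), r2.n_terms("a"), r1.total_terms, r2.total_terms)
        lam_b = lambda_weight(r1.n_terms("b"), 0, r1.total_terms, r2.total_terms)
        expected = (lam_a * label_distance(r1, r2, "a") + lam_b * 1.0) / 2
        assert global_distance(r1, r2, cfg) == pytest.approx(expected)

    def test_term_repetition_changes_the_distance(self):
        # masses follow occurrence counts, so repeating one term shifts weights
        rng = np.random.default_rng(13)
        r1 = random_representation(rng, "d1", ["a"])
        r2 = random_representation(rng, "d2", ["a"])
        base = global_distance(r1, r2)
        tv, count = r1.per_label["a"][0]
        r1.per_label["a"][0] = (tv, count * 3)
        r1.total_terms += 2 * count
        assert global_distance(r1, r2) != pytest.approx(base, abs=1e-12)


class TestLabelDistance:
    def test_missing_label_error_names_the_side(self):
        rng = np.random.default_rng(3)
        r1 = random_representation(rng, "d1", ["a"])
        r2 = random_representation(rng, "d2", ["b"])
        with pytest.raises(IncomparableRepresentationsError, match="second"):
            label_distance(r1, r2, "a")
        with pytest.raises(IncomparableRepresentationsError, match="first"):
            label_distance(r1, r2, "b")

    def test_per_label_independence(self):
        rng = np.random.default_rng(4)
        r1 = random_representation(rng, "d1", ["a", "b"])
        r2 = random_representation(rng, "d2", ["a", "b"])
        before = label_distance(r1, r2, "b")
        r1.per_label["a"] = [(TermVector("new", rng.standard_normal(6)), 5)]
        assert label_distance(r1, r2, "b") == pytest.approx(before)


class TestDistanceMatrix:
    def test_identical_representations_give_zero_matrix(self):
        rng = np.random.default_rng(6)
        r1 = random_representation(rng, "d1", ["a"])
        r2 = PatientRepresentation("d2", "p2", dict(r1.per_label), r1.total_terms)
        dm = distance_matrix([r1, r2])
        np.testing.assert_allclose(dm.values, 0.0, atol=1e-12)

    def test_symmetry_zero_diagonal_on_random_fixture(self):
        rng = np.random.default_rng(8)
        reps = [random_representation(rng, f"d{i}", ["a", "b"]) for i in range(5)]
        dm = distance_matrix(reps)
        np.testing.assert_allclose(dm.values, dm.values.T)
        np.testing.assert_allclose(np.diag(dm.values), 0.0)

    def test_planted_geometry_orders_pairs(self):
        # r1 and r2 share a tight direction, r3 is nearly antipodal
        def rep(doc, vecs):
            r = PatientRepresentation(document_id=doc, patient_id=doc)
            r.per_label["a"] = [(TermVector(f"{doc}{i}", v), 1) for i, v in enumerate(vecs)]
            r.total_terms = len(vecs)
            return r

        r1 = rep("d1", [unit(0.00), unit(0.05)])
        r2 = rep("d2", [unit(0.02), unit(0.07)])
        r3 = rep("d3", [unit(3.0), unit(3.1)])
        dm = distance_matrix([r1, r2, r3])
        assert dm.values[0, 1] < dm.values[0, 2]
        assert dm.values[0, 1] < dm.values[1, 2]

    def test_incomparable_pair_gets_na_and_csv_round_trips(self, tmp_path):
        rng = np.random.default_rng(10)
        reps = [
            random_representation(rng, "d1", ["a"]),
            random_representation(rng, "d2", ["a", "b"]),
            random_representation(rng, "d3", ["b"]),
        ]
        dm = distance_matrix(reps)
        assert dm.incomparable == [("d1", "d3")]
        assert np.isnan(dm.values[0, 2])
        p = tmp_path / "dist.csv"
        dm.to_csv(p)
        assert "NA" in p.read_text()
        back = DistanceMatrix.from_csv(p)
        assert back.ids == dm.ids
        assert back.incomparable == dm.incomparable
        np.testing.assert_allclose(back.values[0, 1], dm.values[0, 1], atol=1e-9)


class TestMetricAxioms:
    @pytest.mark.parametrize("seed", range(20))
    def test_triangle_inequality_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        a = random_distribution(rng, int(rng.integers(1, 5)))
        b = random_distribution(rng, int(rng.integers(1, 5)))
        c = random_distribution(rng, int(rng.integers(1, 5)))
        dab, dbc, dac = emd(a, b), emd(b, c), emd(a, c)
        assert dab >= 0 and dbc >= 0 and dac >= 0
        # raw cosine cost is not a metric; sqrt(2*EMD) is Wasserstein-2,
        # for which the triangle inequality is guaranteed
        assert math.sqrt(2 * dac) <= math.sqrt(2 * dab) + math.sqrt(2 * dbc) + 1e-9
        assert emd(b, a) == pytest.approx(dab, abs=1e-10)
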