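from __future__ import annotations

import math

import numpy as np
import pytest

from cohortsim.embeddings import TermVector
from cohortsim.errors import IncomparableRepresentationsError
from cohortsim.patient import PatientRepresentation
from cohortsim.retrieval import (
    CohortEntry,
    MetricSummary,
    RankedCohort,
    average_precision,
    default_routing,
    evaluate_phenotype,
    precision_at_k,
    rank_cohort,
    read_gold_tsv,
    recall_at_n,
)


def unit(theta: float) -> np.ndarray:
    return np.array([math.cos(theta), math.sin(theta)])


def rep(doc: str, patient: str, thetas, label="L") -> PatientRepresentation:
    r = PatientRepresentation(document_id=doc, patient_id=patient)
    r.per_label[label] = [
        (TermVector(f"{doc}_t{i}", unit(t)), 1) for i, t in enumerate(thetas)
    ]
    r.total_terms = len(thetas)
    return r


def cohort(flags, index="q") -> RankedCohort:
    entries = [CohortEntry(f"p{i}", f"d{i}", 0.1 * i) for i in range(len(flags))]
    return RankedCohort(index_document_id=index, entries=entries, relevance=list(flags))


class TestRankCohort:
    def test_identical_candidate_ranks_first_with_zero_distance(self):
        index = rep("q", "pq", [0.0])
        cand = rep("c", "pc", [0.0])
        out = rank_cohort(index, [cand])
        assert out.entries[0].distance == pytest.approx(0.0, abs=1e-12)

    def test_distinct_patient_deduplication_keeps_closest_document(self):
        index = rep("q", "pq", [0.0])
        near = rep("c1", "pc", [0.1])
        far = rep("c2", "pc", [1.5])
        out = rank_cohort(index, [near, far])
        assert len(out.entries) == 1
        assert out.entries[0].document_id == "c1"

    def test_same_phenotype_geometry_ranks_above_different(self):
        index = rep("q", "pq", [0.0, 0.1])
        same = rep("a", "pa", [0.05])
        other = rep("b", "pb", [2.8])
        out = rank_cohort(index, [other, same])
        assert [e.document_id for e in out.entries] == ["a", "b"]

    def test_index_patients_own_documents_are_rejected(self):
        index = rep("q", "pq", [0.0])
        with pytest.raises(ValueError, match="index patient"):
            rank_cohort(index, [rep("q2", "pq", [0.1])])

    def test_all_candidates_incomparable_is_an_error(self):
        index = rep("q", "pq", [0.0], label="L")
        stranger = rep("c", "pc", [0.0], label="M")
        with pytest.raises(IncomparableRepresentationsError):
            rank_cohort(index, [stranger])

    def test_distance_ties_break_by_document_id(self):
        index = rep("q", "pq", [0.0])
        c1 = rep("zz", "p1", [0.3])
        c2 = rep("aa", "p2", [0.3])
        out = rank_cohort(index, [c1, c2])
        assert [e.document_id for e in out.entries] == ["aa", "zz"]


class TestMetrics:
    @pytest.mark.parametrize(
        "flags,k,expected",
        [([1, 1, 1], 3, 1.0), ([1, 0, 1], 3, 2 / 3), ([0, 0, 0], 3, 0.0)],
    )
    def test_precision_at_k(self, flags, k, expected):
        assert precision_at_k(cohort(flags), k) == pytest.approx(expected)

    def test_precision_with_short_ranking_keeps_denominator_k(self):
        assert precision_at_k(cohort([1, 1]), 10) == pytest.approx(0.2)

    @pytest.mark.parametrize(
        "flags,expected",
        [([1, 1, 0, 0], 1.0), ([0, 0, 1, 1], 0.0), ([1, 0, 1, 0, 0, 1, 1], 0.5)],
    )
    def test_recall_at_n_defaults_to_cohort_size(self, flags, expected):
        # n = number of relevant patients; for the last case R=4, top-4 holds 2
        assert recall_at_n(cohort(flags)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "flags,expected",
        [([1, 1, 0], 1.0), ([0, 1], 0.5), ([1, 0, 1], (1 + 2 / 3) / 2)],
    )
    def test_average_precision_hand_values(self, flags, expected):
        assert average_precision(cohort(flags)) == pytest.approx(expected)

    def test_missing_relevance_and_zero_relevant_errors(self):
        bare = RankedCohort("q", [CohortEntry("p", "d", 0.1)])
        with pytest.raises(ValueError):
            precision_at_k(bare, 1)
        with pytest.raises(ValueError):
            average_precision(cohort([0, 0]))
        with pytest.raises(ValueError):
            recall_at_n(cohort([0, 0]))

    @pytest.mark.parametrize("seed", range(10))
    def test_ap_is_one_iff_relevant_entries_lead(self, seed):
        rng = np.random.default_rng(seed)
        flags = list(rng.integers(0, 2, size=10))
        if sum(flags) == 0:
            flags[0] = 1
        ap = average_precision(cohort(flags))
        front_loaded = sorted(flags, reverse=True) == flags
        assert (ap == pytest.approx(1.0)) == front_loaded

    def test_ap_close_to_trapezoidal_pr_area_on_random_rankings(self):
        # the step-function estimate and trapezoidal area differ by a bounded
        # amount; we report the gap rather than asserting equality
        rng = np.random.default_rng(0)
        gaps = []
        for _ in range(50):
            flags = list(rng.integers(0, 2, size=20))
            if sum(flags) == 0:
                flags[0] = 1
            R = sum(flags)
            ap = average_precision(cohort(flags))
            hits, prec, rec = 0, [1.0], [0.0]
            for r, f in enumerate(flags, 1):
                hits += f
                prec.append(hits / r)
                rec.append(hits / R)
            trap = float(np.trapezoid(prec, rec))
            gaps.append(abs(ap - trap))
        assert max(gaps) < 0.25  # same quantity up to discretization


class TestEvaluatePhenotype:
    def corpus(self):
        """Two twin lupus patients far from two background patients."""
        reps = [
            rep("d0", "p0", [0.00, 0.02], label="immune"),
            rep("d1", "p1", [0.01, 0.03], label="immune"),
            rep("d2", "p2", [2.9], label="immune"),
            rep("d3", "p3", [3.0], label="immune"),
        ]
        gold = {"d0": {"lupus"}, "d1": {"lupus"}}
        routing = {"lupus": frozenset({"immune"})}
        return reps, gold, routing

    def test_twin_positives_reach_perfect_average_precision(self):
        reps, gold, routing = self.corpus()
        ev = evaluate_phenotype(reps, gold, "lupus", routing=routing)
        assert ev.n_index == 2
        assert ev.metrics["average_precision"].mean == pytest.approx(1.0)
        assert ev.metrics["recall"].mean == pytest.approx(1.0)

    def test_single_positive_patient_is_an_error(self):
        reps, gold, routing = self.corpus()
        with pytest.raises(ValueError):
            evaluate_phenotype(reps, {"d0": {"lupus"}}, "lupus", routing=routing)

    def test_metrics_invariant_to_candidate_order(self):
        reps, gold, routing = self.corpus()
        ev1 = evaluate_phenotype(reps, gold, "lupus", routing=routing)
        ev2 = evaluate_phenotype(list(reversed(reps)), gold, "lupus", routing=routing)
        for name in ev1.metrics:
            assert ev1.metrics[name].mean == pytest.approx(ev2.metrics[name].mean)

    def test_unknown_phenotype_routing_is_an_error(self):
        reps, gold, routing = self.corpus()
        with pytest.raises(KeyError):
            evaluate_phenotype(reps, gold, "unknown", routing=routing)


def test_confidence_interval_is_normal_approximation_clamped():
    vals = [0.8, 1.0, 0.9, 1.0]
    s = MetricSummary.from_values(vals)
    mean = np.mean(vals)
    half = 1.96 * np.std(vals, ddof=1) / np.sqrt(4)
    assert s.mean == pytest.approx(mean)
    assert s.ci_low == pytest.approx(max(mean - half, 0.0))
    assert s.ci_high == pytest.approx(min(mean + half, 1.0))
    assert MetricSummary.from_values([1.0, 1.0]).ci_high == 1.0


def test_default_routing_covers_the_four_study_phenotypes():
    routing = default_routing()
    assert routing["osteoporosis"] == frozenset({"musculoskeletal", "nutritional"})
    assert routing["nephritis_sle"] == frozenset({"urogenital", "immune"})
    assert routing["ild_ssc"] == frozenset({"respiratory", "immune"})
    assert routing["lung_infection"] == frozenset({"respiratory", "infections"})


def test_gold_tsv_reader_accumulates_phenotypes(tmp_path):
    p = tmp_path / "gold.tsv"
    p.write_text("d1\tlupus\nd1\tosteoporosis\nd2\tlupus\n", encoding="utf-8")
    assert read_gold_tsv(p) == {"d1": {"lupus", "osteoporosis"}, "d2": {"lupus"}}
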