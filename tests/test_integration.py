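import itertools
import logging
import math

import numpy as np
import pytest

from annoret.core import SphericalROI
from annoret.integration import (
    integrate_and,
    integrate_cohort,
    integrate_or,
    integrate_voting,
    match_annotations,
    merge_group,
)
from conftest import make_set

logger = logging.getLogger(__name__)


class TestMatch:
    def test_within_threshold_one_group(self):
        a = make_set("A", [("c1", (0, 0, 0), 6)])
        b = make_set("B", [("c1", (0, 0, 2.9), 6)])
        res = match_annotations([a, b])
        assert len(res.groups["c1"]) == 1
        assert res.groups["c1"][0].annotator_ids == {"A", "B"}

    def test_beyond_threshold_unmatched(self):
        a = make_set("A", [("c1", (0, 0, 0), 6)])
        b = make_set("B", [("c1", (0, 0, 3.1), 6)])
        res = match_annotations([a, b])
        assert res.groups["c1"] == []
        assert len(res.unmatched["c1"]["A"]) == 1
        assert len(res.unmatched["c1"]["B"]) == 1

    def test_chain_flagged(self):
        a = make_set("A", [("c1", (0, 0, 0), 6)])
        b = make_set("B", [("c1", (0, 0, 2.5), 6)])
        c = make_set("C", [("c1", (0, 0, 5.0), 6)])
        res = match_annotations([a, b, c])
        (group,) = res.groups["c1"]
        assert len(group.members) == 3
        assert group.chain  # endpoints 5 mm apart, linked transitively

    def test_duplicate_roi_rejected(self):
        a = make_set("A", [("c1", (0, 0, 0), 6), ("c1", (0, 0, 0), 6)])
        b = make_set("B", [("c1", (1, 0, 0), 6)])
        with pytest.raises(ValueError, match="duplicate"):
            match_annotations([a, b])

    def test_one_to_one_per_pair(self):
        # one A-ROI near two B-ROIs: only the closer links
        a = make_set("A", [("c1", (0, 0, 0), 6)])
        b = make_set("B", [("c1", (0, 0, 1.0), 6), ("c1", (0, 0, 2.0), 6)])
        res = match_annotations([a, b])
        (group,) = res.groups["c1"]
        assert len(group.members) == 2
        assert (0.0, 0.0, 1.0) in [m.centroid for m in group.members]

    def test_order_invariance(self):
        a = make_set("A", [("c1", (0, 0, 0), 6), ("c1", (10, 0, 0), 8)])
        b = make_set("B", [("c1", (0, 0, 2), 7), ("c1", (10, 0, 2), 9)])
        r1 = match_annotations([a, b])
        r2 = match_annotations([b, a])
        g1 = sorted(
            tuple(sorted(m.centroid for m in g.members)) for g in r1.groups["c1"]
        )
        g2 = sorted(
            tuple(sorted(m.centroid for m in g.members)) for g in r2.groups["c1"]
        )
        assert g1 == g2


class TestMerge:
    def test_two_member_average(self):
        a = make_set("A", [("c1", (0, 0, 0), 6)])
        b = make_set("B", [("c1", (0, 0, 2.9), 8)])
        (group,) = match_annotations([a, b]).groups["c1"]
        merged = merge_group(group)
        np.testing.assert_allclose(merged.centroid, (0, 0, 1.45))
        assert merged.diameter == pytest.approx(7.0)
        assert merged.annotator_id == "integrated"

    def test_single_member(self):
        roi = SphericalROI("c1", (1, 2, 3), 5, "A")
        merged = merge_group([roi])
        assert merged.centroid == (1, 2, 3)
        assert merged.diameter == 5
        assert merged.annotator_id == "integrated"

    def test_symmetric_triple(self):
        rois = [
            SphericalROI("c1", c, 6, ann)
            for c, ann in [
                ((1, 0, 0), "A"),
                ((-0.5, math.sqrt(3) / 2, 0), "B"),
                ((-0.5, -math.sqrt(3) / 2, 0), "C"),
            ]
        ]
        merged = merge_group(rois)
        np.testing.assert_allclose(merged.centroid, (0, 0, 0), atol=1e-12)

    def test_centroid_in_convex_hull(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 5))
            pts = rng.uniform(0, 20, size=(n, 3))
            rois = [
                SphericalROI("c1", tuple(p), float(rng.uniform(2, 9)), f"A{i}")
                for i, p in enumerate(pts)
            ]
            merged = merge_group(rois)
            assert np.all(np.asarray(merged.centroid) >= pts.min(axis=0) - 1e-12)
            assert np.all(np.asarray(merged.centroid) <= pts.max(axis=0) + 1e-12)


class TestStrategies:
    def _identical_pair(self):
        rois = [("c1", (5, 5, 5), 6), ("c1", (20, 20, 20), 8), ("c2", (9, 9, 9), 7)]
        return make_set("A", rois), make_set("B", rois)

    def test_and_idempotent(self):
        a, b = self._identical_pair()
        out = integrate_and(a, b)
        assert out.n_rois() == a.n_rois()
        for case_id, rois in out.rois.items():
            got = sorted((r.centroid, r.diameter) for r in rois)
            want = sorted((r.centroid, r.diameter) for r in a.rois[case_id])
            assert got == want

    def test_and_disjoint_empty(self):
        a = make_set("A", [("c1", (0, 0, 0), 6)])
        b = make_set("B", [("c1", (30, 30, 30), 6)])
        assert integrate_and(a, b).n_rois() == 0

    def test_and_partial_overlap(self):
        a = make_set(
            "A", [("c1", (0, 0, 0), 6), ("c1", (10, 0, 0), 6), ("c1", (20, 0, 0), 6)]
        )
        b = make_set("B", [("c1", (0, 0, 1), 6), ("c1", (10, 0, 1), 6)])
        assert integrate_and(a, b).n_rois() == 2

    def test_or_idempotent(self):
        a, b = self._identical_pair()
        assert integrate_or(a, b).n_rois() == a.n_rois()

    def test_or_disjoint_union(self):
        a = make_set("A", [("c1", (0, 0, 0), 6), ("c1", (30, 0, 0), 6)])
        b = make_set(
            "B",
            [("c1", (10, 10, 10), 6), ("c1", (40, 10, 0), 6), ("c1", (20, 20, 20), 6)],
        )
        assert integrate_or(a, b).n_rois() == 5

    def test_and_or_symmetry(self):
        a = make_set("A", [("c1", (0, 0, 0), 6), ("c1", (9, 0, 0), 8)])
        b = make_set("B", [("c1", (0, 0, 2), 7), ("c1", (30, 0, 0), 5)])
        for op in (integrate_and, integrate_or):
            ab = sorted(
                (r.centroid, r.diameter) for r in op(a, b).all_rois()
            )
            ba = sorted(
                (r.centroid, r.diameter) for r in op(b, a).all_rois()
            )
            assert ab == ba

    def test_voting_unanimity(self):
        rois = [("c1", (5, 5, 5), 6), ("c2", (9, 9, 9), 7)]
        a, b, c = (make_set(x, rois) for x in "ABC")
        out = integrate_voting(a, b, c)
        assert sorted((r.centroid, r.diameter) for r in out.all_rois()) == sorted(
            (r.centroid, r.diameter) for r in a.all_rois()
        )

    def test_voting_third_only_absent(self):
        a = make_set("A", [("c1", (50, 50, 50), 6)])
        b = make_set("B", [("c1", (30, 30, 30), 6)])
        c = make_set("C", [("c1", (0, 0, 0), 6)])
        out = integrate_voting(a, b, c)
        assert all(r.centroid != (0.0, 0.0, 0.0) for r in out.all_rois())

    def test_voting_first_and_third(self):
        a = make_set("A", [("c1", (0, 0, 0), 6)])
        b = make_set("B", [("c1", (30, 30, 30), 6)])
        c = make_set("C", [("c1", (0, 0, 1), 6)])
        out = integrate_voting(a, b, c)
        assert any(
            np.allclose(r.centroid, (0, 0, 0.5)) for r in out.all_rois()
        )


def _random_triple(rng, n_findings=4, miss=0.2, fp=0.7, jitter=0.6):
    """Three annotators over shared findings with misses, FPs and jitter."""
    findings = rng.uniform(10, 50, size=(n_findings, 3))
    sets = []
    for name in "ABC":
        rois = []
        for f in findings:
            if rng.random() < miss:
                continue
            rois.append(("c1", tuple(f + rng.normal(0, jitter, 3)),
                         float(rng.uniform(4, 9))))
        for _ in range(rng.poisson(fp)):
            rois.append(("c1", tuple(rng.uniform(0, 60, 3)),
                         float(rng.uniform(4, 9))))
        sets.append(make_set(name, rois))
    return sets


class TestSetAlgebra:
    def test_and_le_or_and_voting_le_or(self, rng):
        for _ in range(100):
            a, b, c = _random_triple(rng)
            n_and = integrate_and(a, b).n_rois()
            n_or = integrate_or(a, b).n_rois()
            n_vote = integrate_voting(a, b, c).n_rois()
            assert n_and <= n_or
            assert n_vote <= n_or

    def test_and_voting_near_threshold(self, rng):
        """AND members stay within threshold of each contributing annotator."""
        for _ in range(50):
            a, b, _ = _random_triple(rng)
            for roi in integrate_and(a, b).all_rois():
                for src in (a, b):
                    dmin = min(
                        (math.dist(roi.centroid, s.centroid)
                         for s in src.rois.get(roi.case_id, [])),
                        default=math.inf,
                    )
                    assert dmin <= 3.0


def _exhaustive_best_matching(rois_a, rois_b, threshold=3.0):
    """Oracle: maximum-cardinality, minimum-total-distance one-to-one matching."""
    admissible = [
        (i, j, math.dist(ra.centroid, rb.centroid))
        for i, ra in enumerate(rois_a)
        for j, rb in enumerate(rois_b)
        if math.dist(ra.centroid, rb.centroid) <= threshold
    ]
    best: tuple[int, float, frozenset] = (0, 0.0, frozenset())
    n = len(admissible)
    for r in range(min(len(rois_a), len(rois_b)), 0, -1):
        found = None
        for combo in itertools.combinations(range(n), r):
            ii = [admissible[k][0] for k in combo]
            jj = [admissible[k][1] for k in combo]
            if len(set(ii)) < r or len(set(jj)) < r:
                continue
            total = sum(admissible[k][2] for k in combo)
            pairs = frozenset((admissible[k][0], admissible[k][1]) for k in combo)
            if found is None or total < found[0]:
                found = (total, pairs)
        if found is not None:
            return found[1]
    return frozenset()


class TestGreedyVsExhaustiveOracle:
    def test_agreement_rate(self, rng):
        agree = 0
        n_trials = 500
        for _ in range(n_trials):
            n_a = int(rng.integers(1, 6))
            n_b = int(rng.integers(1, 6))
            a = make_set(
                "A",
                [("c1", tuple(rng.uniform(0, 15, 3)), 6.0) for _ in range(n_a)],
            )
            b = make_set(
                "B",
                [("c1", tuple(rng.uniform(0, 15, 3)), 6.0) for _ in range(n_b)],
            )
            res = match_annotations([a, b])
            greedy_pairs = set()
            for g in res.groups.get("c1", []):
                ia = [a.rois["c1"].index(m) for m in g.members if m.annotator_id == "A"]
                ib = [b.rois["c1"].index(m) for m in g.members if m.annotator_id == "B"]
                if ia and ib:
                    greedy_pairs.add((ia[0], ib[0]))
            oracle_pairs = _exhaustive_best_matching(a.rois["c1"], b.rois["c1"])
            if frozenset(greedy_pairs) == oracle_pairs:
                agree += 1
            else:
                logger.info("greedy!=optimal: %s vs %s", greedy_pairs, oracle_pairs)
        assert agree / n_trials >= 0.95


class TestCohort:
    def _cohort(self, n):
        return [
            make_set(f"A{i}", [("c1", (float(i), 0, 0), 6)]) for i in range(n)
        ]

    def test_pairs_count(self):
        out = integrate_cohort(self._cohort(4), "AND")
        assert len(out) == 6

    def test_voting_triples_canonicalized(self):
        out = integrate_cohort(self._cohort(3), "VOTING")
        assert len(out) == 3  # {unordered pair} x {third}

    def test_arity_error(self):
        with pytest.raises(ValueError):
            integrate_cohort(self._cohort(1), "AND")
        with pytest.raises(ValueError):
            integrate_cohort(self._cohort(2), "VOTING")

    def test_cap_and_seeding(self):
        sets = self._cohort(12)  # 66 pairs
        out1 = integrate_cohort(sets, "OR", max_combinations=10, seed=4)
        out2 = integrate_cohort(sets, "OR", max_combinations=10, seed=4)
        out3 = integrate_cohort(sets, "OR", max_combinations=10, seed=5)
        assert len(out1) == 10
        assert [c for c, _ in out1] == [c for c, _ in out2]
        assert [c for c, _ in out1] != [c for c, _ in out3]
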