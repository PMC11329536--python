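"""Cross-annotator ROI matching and AND / OR / VOTING integration.

ROIs from different annotators are considered the same finding when their
centroids lie within a distance threshold (default 3 mm).  Links are formed
greedily in ascending distance order, one-to-one per annotator pair, and
groups are the connected components of the link graph.  Groups whose
members are only transitively within threshold ("chains") are merged but
flagged for audit.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .core import AnnotationSet, RoiTag, SphericalROI

__all__ = [
    "MatchGroup",
    "MatchResult",
    "match_annotations",
    "merge_group",
    "integrate_and",
    "integrate_or",
    "integrate_voting",
    "integrate_cohort",
]


@dataclass
class MatchGroup:
    """One matched finding: at most one ROI per contributing annotator."""

    members: list[SphericalROI]
    chain: bool = False  # some member pair exceeds the threshold (transitive link)

    @property
    def annotator_ids(self) -> set[str]:
        return {r.annotator_id for r in self.members}


@dataclass
class MatchResult:
    threshold_mm: float
    # case_id -> groups / per-annotator unmatched ROIs
    groups: dict[str, list[MatchGroup]] = field(default_factory=dict)
    unmatched: dict[str, dict[str, list[SphericalROI]]] = field(default_factory=dict)


def _distance(a: SphericalROI, b: SphericalROI) -> float:
    return math.dist(a.centroid, b.centroid)


def _match_case(
    rois_by_ann: dict[str, list[SphericalROI]], threshold_mm: float
) -> tuple[list[MatchGroup], dict[str, list[SphericalROI]]]:
    ann_ids = sorted(rois_by_ann)
    # node = (annotator_id, index)
    parent: dict[tuple[str, int], tuple[str, int]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for a in ann_ids:
        for i in range(len(rois_by_ann[a])):
            parent[(a, i)] = (a, i)

    # candidate links: all inter-annotator pairs within threshold, sorted by
    # (distance, annotator pair, indices) for a deterministic greedy pass
    links = []
    for a, b in itertools.combinations(ann_ids, 2):
        for i, ra in enumerate(rois_by_ann[a]):
            for j, rb in enumerate(rois_by_ann[b]):
                d = _distance(ra, rb)
                if d <= threshold_mm:
                    links.append((d, a, i, b, j))
    links.sort()

    # one-to-one per annotator pair: each ROI links at most once toward each
    # other annotator
    linked_toward: dict[tuple[str, int, str], bool] = {}
    accepted = []
    for d, a, i, b, j in links:
        if linked_toward.get((a, i, b)) or linked_toward.get((b, j, a)):
            continue
        linked_toward[(a, i, b)] = True
        linked_toward[(b, j, a)] = True
        accepted.append((a, i, b, j))
        union((a, i), (b, j))

    components: dict[tuple[str, int], list[tuple[str, int]]] = {}
    for node in parent:
        components.setdefault(find(node), []).append(node)

    groups: list[MatchGroup] = []
    unmatched: dict[str, list[SphericalROI]] = {a: [] for a in ann_ids}
    for root in sorted(components):
        nodes = sorted(components[root])
        members = [rois_by_ann[a][i] for a, i in nodes]
        if len(members) == 1:
            a, i = nodes[0]
            unmatched[a].append(rois_by_ann[a][i])
            continue
        chain = any(
            _distance(x, y) > threshold_mm
            for x, y in itertools.combinations(members, 2)
        )
        groups.append(MatchGroup(members=members, chain=chain))
    return groups, unmatched


def match_annotations(
    sets: list[AnnotationSet], threshold_mm: float = 3.0
) -> MatchResult:
    """Match spherical ROIs across annotators by centroid distance."""
    if threshold_mm <= 0:
        raise ValueError("threshold must be > 0")
    ids = [s.annotator_id for s in sets]
    if len(ids) != len(set(ids)):
        raise ValueError("annotator ids must be unique across sets")
    for s in sets:
        for case_id, rois in s.rois.items():
            seen = set()
            for roi in rois:
                key = (roi.centroid, roi.diameter)
                if key in seen:
                    raise ValueError(
                        f"duplicate ROI for annotator {s.annotator_id!r} in "
                        f"case {case_id!r}"
                    )
                seen.add(key)

    result = MatchResult(threshold_mm=threshold_mm)
    case_ids = sorted({cid for s in sets for cid in s.rois})
    for case_id in case_ids:
        rois_by_ann = {
            s.annotator_id: list(s.rois.get(case_id, [])) for s in sets
        }
        groups, unmatched = _match_case(rois_by_ann, threshold_mm)
        result.groups[case_id] = groups
        result.unmatched[case_id] = unmatched
    return result


def merge_group(group: MatchGroup | list[SphericalROI]) -> SphericalROI:
    """Average centroid and diameter of a matched group; tag 'integrated'."""
    members = group.members if isinstance(group, MatchGroup) else list(group)
    if not members:
        raise ValueError("cannot merge an empty group")
    centroid = np.mean([m.centroid for m in members], axis=0)
    diameter = float(np.mean([m.diameter for m in members]))
    return SphericalROI(
        case_id=members[0].case_id,
        centroid=tuple(centroid),
        diameter=diameter,
        annotator_id="integrated",
        tag=members[0].tag if len({m.tag for m in members}) == 1 else RoiTag.UNKNOWN,
    )


def _retag(roi: SphericalROI) -> SphericalROI:
    return SphericalROI(
        case_id=roi.case_id,
        centroid=roi.centroid,
        diameter=roi.diameter,
        annotator_id="integrated",
        tag=roi.tag,
    )


def _as_integrated_set(rois_by_case: dict[str, list[SphericalROI]]) -> AnnotationSet:
    out = AnnotationSet(annotator_id="integrated")
    for case_id in sorted(rois_by_case):
        for roi in rois_by_case[case_id]:
            out.add(roi)
    return out


def _relabel(ann_set: AnnotationSet, new_id: str) -> AnnotationSet:
    out = AnnotationSet(annotator_id=new_id)
    for case_id in sorted(ann_set.rois):
        for roi in ann_set.rois[case_id]:
            out.add(
                SphericalROI(
                    case_id=roi.case_id,
                    centroid=roi.centroid,
                    diameter=roi.diameter,
                    annotator_id=new_id,
                    tag=roi.tag,
                )
            )
    return out


def integrate_and(
    a: AnnotationSet, b: AnnotationSet, threshold_mm: float = 3.0
) -> AnnotationSet:
    """Product set: merged ROI per group containing both annotators."""
    match = match_annotations([a, b], threshold_mm)
    rois_by_case: dict[str, list[SphericalROI]] = {}
    for case_id, groups in match.groups.items():
        kept = [
            merge_group(g)
            for g in groups
            if {a.annotator_id, b.annotator_id} <= g.annotator_ids
        ]
        if kept:
            rois_by_case[case_id] = kept
    return _as_integrated_set(rois_by_case)


def integrate_or(
    a: AnnotationSet, b: AnnotationSet, threshold_mm: float = 3.0
) -> AnnotationSet:
    """Sum set: merged groups plus both annotators' unmatched ROIs."""
    match = match_annotations([a, b], threshold_mm)
    rois_by_case: dict[str, list[SphericalROI]] = {}
    for case_id in match.groups:
        kept = [merge_group(g) for g in match.groups[case_id]]
        for ann_id in sorted(match.unmatched[case_id]):
            kept.extend(_retag(r) for r in match.unmatched[case_id][ann_id])
        if kept:
            rois_by_case[case_id] = kept
    return _as_integrated_set(rois_by_case)


def integrate_voting(
    a: AnnotationSet,
    b: AnnotationSet,
    c: AnnotationSet,
    threshold_mm: float = 3.0,
) -> AnnotationSet:
    """Majority voting: AND between OR(a, b) and the third annotator.

    The OR-merged ROIs participate in the second matching with their
    averaged centroids.
    """
    first_or = _relabel(integrate_or(a, b, threshold_mm), "or_intermediate")
    return integrate_and(first_or, c, threshold_mm)


def integrate_cohort(
    sets: list[AnnotationSet],
    strategy: str,
    threshold_mm: float = 3.0,
    max_combinations: int = 50,
    seed: int = 0,
) -> list[tuple[tuple[str, ...], AnnotationSet]]:
    """One integrated set per annotator pair (AND/OR) or triple (VOTING).

    VOTING triples are canonicalized to {unordered pair} x {third annotator}
    since OR is symmetric.  When the enumeration exceeds
    ``max_combinations``, a seeded random subsample is used.
    """
    strategy = strategy.upper()
    if strategy not in ("AND", "OR", "VOTING"):
        raise ValueError(f"unknown strategy {strategy!r}")
    arity = 3 if strategy == "VOTING" else 2
    if len(sets) < arity:
        raise ValueError(
            f"{strategy} needs >= {arity} annotators, got {len(sets)}"
        )
    by_id = {s.annotator_id: s for s in sets}
    ids = sorted(by_id)

    if strategy == "VOTING":
        combos = [
            (pair[0], pair[1], third)
            for pair in itertools.combinations(ids, 2)
            for third in ids
            if third not in pair
        ]
    else:
        combos = list(itertools.combinations(ids, 2))

    if len(combos) > max_combinations:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(combos), size=max_combinations, replace=False)
        combos = [combos[k] for k in sorted(keep)]

    out = []
    for combo in combos:
        if strategy == "AND":
            integrated = integrate_and(by_id[combo[0]], by_id[combo[1]], threshold_mm)
        elif strategy == "OR":
            integrated = integrate_or(by_id[combo[0]], by_id[combo[1]], threshold_mm)
        else:
            integrated = integrate_voting(
                by_id[combo[0]], by_id[combo[1]], by_id[combo[2]], threshold_mm
            )
        out.append((tuple(combo), integrated))
    return out
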