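"""Lesion-level scoring: hit criterion, FROC curves, CPM, Steel-Dwass.

A candidate hits a lesion when its centroid lies within
``max(lesion radius, 3 mm)`` of the lesion centroid; each candidate counts
toward at most one lesion.  The FROC curve sweeps the score threshold over
every distinct candidate score; CPM averages sensitivity at FP/case targets
1/8, 1/4, 1/2, 1, 2, 4 and 8 using a step-function (right-continuous)
convention.  The Steel-Dwass all-pairs comparison uses tie-corrected rank
sums referred to the studentized-range distribution with infinite degrees
of freedom; a permutation mode provides a ground-truth fallback.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata, studentized_range

from .core import Candidate, DatasetManifest, SphericalROI

__all__ = [
    "FrocCurve",
    "CpmResult",
    "SteelDwassResult",
    "CPM_FP_TARGETS",
    "score_case",
    "froc",
    "cpm",
    "steel_dwass",
]

CPM_FP_TARGETS: tuple[float, ...] = (1 / 8, 1 / 4, 1 / 2, 1.0, 2.0, 4.0, 8.0)

DEFAULT_HIT_DISTANCE_MM = 3.0


@dataclass
class FrocCurve:
    """Operating points (threshold, sensitivity, FP/case), threshold descending."""

    thresholds: list[float]
    sensitivity: list[float]
    fp_per_case: list[float]
    n_lesions: int
    n_cases: int

    def __post_init__(self) -> None:
        sens = np.asarray(self.sensitivity)
        fpc = np.asarray(self.fp_per_case)
        if np.any(np.diff(sens) < -1e-12) or np.any(np.diff(fpc) < -1e-12):
            raise ValueError("FROC curve must be non-decreasing as threshold drops")
        if np.any(sens < 0) or np.any(sens > 1) or np.any(fpc < 0):
            raise ValueError("FROC operating points out of range")


@dataclass
class CpmResult:
    cpm: float
    sensitivities: dict[float, float]  # FP/case target -> sensitivity

    def __post_init__(self) -> None:
        mean = float(np.mean(list(self.sensitivities.values())))
        if abs(mean - self.cpm) > 1e-12:
            raise ValueError("cpm must equal the mean of the seven sensitivities")


@dataclass
class SteelDwassResult:
    groups: list[str]
    sizes: dict[str, int]
    statistic: dict[tuple[str, str], float]  # standardized rank-sum statistic t
    p_value: dict[tuple[str, str], float]
    significant: dict[tuple[str, str], bool]
    alpha: float = 0.05

    def pair(self, a: str, b: str) -> tuple[float, float, bool]:
        key = (a, b) if (a, b) in self.p_value else (b, a)
        return self.statistic[key], self.p_value[key], self.significant[key]


# ---------------------------------------------------------------------------
# Case scoring
# ---------------------------------------------------------------------------

def score_case(
    candidates: Sequence[Candidate],
    ground_truth_lesions: Sequence[SphericalROI],
    hit_distance_mm: float = DEFAULT_HIT_DISTANCE_MM,
    threshold: float = -math.inf,
) -> tuple[int, int]:
    """(number of lesions hit, number of FP candidates) at one threshold.

    Candidates are assigned to lesions greedily by descending score, then
    ascending distance; each candidate counts toward at most one lesion and
    each lesion absorbs at most one candidate.
    """
    supra = [c for c in candidates if c.score >= threshold]
    order = sorted(range(len(supra)), key=lambda i: (-supra[i].score, i))
    hit_lesions: set[int] = set()
    fp = 0
    for i in order:
        cand = supra[i]
        best_j = None
        best_d = math.inf
        for j, lesion in enumerate(ground_truth_lesions):
            if j in hit_lesions:
                continue
            d = lesion.distance_to(cand.centroid)
            if d <= max(lesion.radius, hit_distance_mm) and d < best_d:
                best_d = d
                best_j = j
        if best_j is None:
            fp += 1
        else:
            hit_lesions.add(best_j)
    return len(hit_lesions), fp


# ---------------------------------------------------------------------------
# FROC / CPM
# ---------------------------------------------------------------------------

def froc(
    candidates_by_case: Mapping[str, Sequence[Candidate]],
    manifest: DatasetManifest,
    hit_distance_mm: float = DEFAULT_HIT_DISTANCE_MM,
    subset: str | None = "test",
) -> FrocCurve:
    """FROC curve over the (by default test-) subset of the manifest.

    ``candidates_by_case`` may omit cases (treated as empty candidate
    lists).  FPs are divided by the total case count, positives and
    negatives alike.
    """
    cases = manifest.subset(subset) if subset is not None else manifest.cases
    if not cases:
        raise ValueError("no cases to evaluate")
    total_lesions = sum(len(c.lesions) for c in cases)
    if total_lesions == 0:
        raise ValueError("test set contains zero lesions")
    n_cases = len(cases)

    # The greedy assignment processes candidates in descending score order,
    # so the assignment at any threshold is a prefix of the full assignment:
    # classify every candidate once, then sweep thresholds with cumulative
    # counts.
    tp_scores: list[float] = []
    fp_scores: list[float] = []
    for case in cases:
        cands = list(candidates_by_case.get(case.case_id, []))
        order = sorted(range(len(cands)), key=lambda i: (-cands[i].score, i))
        hit_lesions: set[int] = set()
        for i in order:
            cand = cands[i]
            best_j = None
            best_d = math.inf
            for j, lesion in enumerate(case.lesions):
                if j in hit_lesions:
                    continue
                d = lesion.distance_to(cand.centroid)
                if d <= max(lesion.radius, hit_distance_mm) and d < best_d:
                    best_d = d
                    best_j = j
            if best_j is None:
                fp_scores.append(float(cand.score))
            else:
                hit_lesions.add(best_j)
                tp_scores.append(float(cand.score))

    scores = sorted({*tp_scores, *fp_scores}, reverse=True)
    thresholds = [math.inf] + scores
    tp_arr = np.asarray(tp_scores)
    fp_arr = np.asarray(fp_scores)
    sens_list = [
        float((tp_arr >= thr).sum()) / total_lesions if len(tp_arr) else 0.0
        for thr in thresholds
    ]
    fpc_list = [
        float((fp_arr >= thr).sum()) / n_cases if len(fp_arr) else 0.0
        for thr in thresholds
    ]
    return FrocCurve(
        thresholds=thresholds,
        sensitivity=sens_list,
        fp_per_case=fpc_list,
        n_lesions=total_lesions,
        n_cases=n_cases,
    )


def cpm(curve: FrocCurve, targets: Sequence[float] = CPM_FP_TARGETS) -> CpmResult:
    """Average sensitivity at the FP/case targets (step-function convention).

    At each target f the sensitivity of the operating point with the largest
    FP/case <= f is used; if no point qualifies the sensitivity is 0; if the
    whole curve stays below f the final (most permissive) point is used.
    """
    fpc = np.asarray(curve.fp_per_case)
    sens = np.asarray(curve.sensitivity)
    out: dict[float, float] = {}
    for f in targets:
        eligible = np.nonzero(fpc <= f + 1e-12)[0]
        if len(eligible) == 0:
            out[f] = 0.0
        else:
            # operating points are ordered by decreasing threshold, so the
            # last eligible index has the largest fp_per_case <= f
            out[f] = float(sens[eligible[-1]])
    return CpmResult(cpm=float(np.mean(list(out.values()))), sensitivities=out)


# ---------------------------------------------------------------------------
# Steel-Dwass all-pairs comparison
# ---------------------------------------------------------------------------

def _pair_statistic(x: np.ndarray, y: np.ndarray) -> float | None:
    """Standardized tie-corrected rank-sum statistic; None when degenerate."""
    n_i, n_j = len(x), len(y)
    pooled = np.concatenate([x, y])
    n = n_i + n_j
    ranks = rankdata(pooled)  # midranks
    w = float(ranks[:n_i].sum())
    e_w = n_i * (n + 1) / 2.0
    var_w = n_i * n_j / (n * (n - 1)) * float(((ranks - (n + 1) / 2.0) ** 2).sum())
    if var_w <= 0:
        return None
    return (w - e_w) / math.sqrt(var_w)


def _max_pair_stat_permutations(
    data: Mapping[str, np.ndarray],
    labels: Sequence[str],
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null distribution of max over pairs of sqrt(2)|t*| under joint
    permutation of the pooled sample across all groups (vectorized)."""
    sizes = [len(data[lab]) for lab in labels]
    bounds = np.cumsum([0] + sizes)
    pooled = np.concatenate([data[lab] for lab in labels])
    perms = rng.permuted(
        np.broadcast_to(pooled, (n_permutations, len(pooled))), axis=1
    )
    max_stats = np.zeros(n_permutations)
    for i, j in itertools.combinations(range(len(labels)), 2):
        block = np.concatenate(
            [
                perms[:, bounds[i]:bounds[i + 1]],
                perms[:, bounds[j]:bounds[j + 1]],
            ],
            axis=1,
        )
        n_i, n_j = sizes[i], sizes[j]
        n = n_i + n_j
        ranks = rankdata(block, axis=1)
        w = ranks[:, :n_i].sum(axis=1)
        e_w = n_i * (n + 1) / 2.0
        var_w = (
            n_i * n_j / (n * (n - 1))
            * ((ranks - (n + 1) / 2.0) ** 2).sum(axis=1)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var_w > 0, (w - e_w) / np.sqrt(var_w), 0.0)
        np.maximum(max_stats, math.sqrt(2.0) * np.abs(t), out=max_stats)
    return max_stats


def steel_dwass(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    alpha: float = 0.05,
    permutation: bool = False,
    n_permutations: int = 20_000,
    seed: int = 0,
) -> SteelDwassResult:
    """Nonparametric all-pairs comparison via studentized-range reference.

    For each pair: pool, midrank, compute the standardized rank-sum
    statistic t; p = P(Q_{k,inf} >= sqrt(2)|t|).  With ``permutation=True``
    the asymptotic studentized-range reference is replaced by the joint
    Monte-Carlo permutation distribution of max over pairs of sqrt(2)|t*|
    (the family-wise reference the studentized range approximates), so the
    two modes estimate the same quantity.
    """
    if not isinstance(groups, Mapping):
        groups = {f"g{i}": g for i, g in enumerate(groups)}
    labels = list(groups)
    k = len(labels)
    if k < 2:
        raise ValueError(f"need >= 2 groups, got {k}")
    data = {lab: np.asarray(groups[lab], dtype=float) for lab in labels}
    for lab, arr in data.items():
        if len(arr) < 2:
            raise ValueError(f"group {lab!r} has size {len(arr)} < 2")

    pairs = list(itertools.combinations(labels, 2))
    stat: dict[tuple[str, str], float] = {}
    pval: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        t = _pair_statistic(data[a], data[b])
        stat[(a, b)] = 0.0 if t is None else t

    if permutation:
        max_stats = _max_pair_stat_permutations(
            data, labels, n_permutations, np.random.default_rng(seed)
        )
        for a, b in pairs:
            t = stat[(a, b)]
            if t == 0.0 and _pair_statistic(data[a], data[b]) is None:
                pval[(a, b)] = 1.0
                continue
            observed = math.sqrt(2.0) * abs(t)
            pval[(a, b)] = float(np.mean(max_stats >= observed - 1e-12))
    else:
        for a, b in pairs:
            t = stat[(a, b)]
            if t == 0.0 and _pair_statistic(data[a], data[b]) is None:
                pval[(a, b)] = 1.0
                continue
            pval[(a, b)] = float(
                studentized_range.sf(math.sqrt(2.0) * abs(t), k, np.inf)
            )
    return SteelDwassResult(
        groups=labels,
        sizes={lab: len(data[lab]) for lab in labels},
        statistic=stat,
        p_value=pval,
        significant={key: p < alpha for key, p in pval.items()},
        alpha=alpha,
    )
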