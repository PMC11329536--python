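"""Orchestration of the two-round retraining protocol and the
annotation-integration experiments.

The protocol: train an initial detector on ground-truth labels; have every
simulated annotator label the first retraining subset in two passes (the
second referencing the initial detector's candidates); retrain one model
per annotator; repeat on the second retraining subset, each annotator
referencing their *own* first-round model; evaluate every model on the
held-out test subset.  Integration experiments retrain on AND / OR /
VOTING-integrated first-round labels per annotator combination and compare
CPM distributions with the Steel-Dwass all-pairs test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    AnnotationSet,
    Candidate,
    CaseRecord,
    DatasetManifest,
    SphericalROI,
    Subset,
    Task,
    Volume,
)
from .detector import (
    DetectorConfig,
    PreppedCase,
    TrainedDetector,
    prepare_case,
    run_cad,
    train,
)
from .evaluation import cpm, froc, steel_dwass
from .integration import integrate_cohort
from .synth import (
    AnnotatorProfile,
    PhantomParams,
    DEFAULT_SUBSET_COUNTS,
    generate_dataset,
    make_cohort,
    simulate_annotation,
)

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyResult", "run_protocol",
           "run_integration_experiment", "summarize"]


@dataclass
class StudyConfig:
    task: Task = Task.CHEST
    phantom: PhantomParams | None = None
    counts: dict[str, tuple[int, int]] | None = None
    annotators: list[AnnotatorProfile] | None = None
    detector: DetectorConfig | None = None
    strategies: tuple[str, ...] = ("AND", "OR", "VOTING")
    cohorts: tuple[str, ...] = ("all", "board_certified", "resident")
    threshold_mm: float = 3.0
    max_combinations: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        if self.phantom is None:
            self.phantom = PhantomParams.for_task(self.task)
        if self.annotators is None:
            self.annotators = make_cohort(self.task, seed=self.seed)
        if not self.annotators:
            raise ValueError("study needs at least one annotator")
        if self.detector is None:
            self.detector = DetectorConfig.for_task(self.task, desk=True)
        if self.counts is None:
            self.counts = dict(DEFAULT_SUBSET_COUNTS)
        for subset in ("initial", "retraining1", "retraining2", "test"):
            if subset not in self.counts:
                raise ValueError(f"counts missing subset {subset!r}")


@dataclass
class StudyResult:
    task: str
    seed: int
    initial_cpm: float | None = None
    retrained1_cpm: dict[str, float] = field(default_factory=dict)
    retrained2_cpm: dict[str, float] = field(default_factory=dict)
    # (strategy, cohort) -> list of (combo label, cpm)
    integration_cpm: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    # cohort -> per-pair {pair: p}
    steel_dwass_p: dict[str, dict[str, float]] = field(default_factory=dict)
    failed_arms: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True, default=str)


@dataclass
class ProtocolState:
    """Intermediate artifacts retained for the integration experiment."""

    manifest: DatasetManifest
    volumes: dict[str, Volume]
    cache: dict[str, PreppedCase]
    gt_by_case: dict[str, list[SphericalROI]]
    retraining1_sets: dict[str, AnnotationSet]
    retrained1_cpms: dict[str, float]


def _gt_annotations(cases: Sequence[CaseRecord]) -> dict[str, list[SphericalROI]]:
    return {c.case_id: list(c.lesions) for c in cases}


def _child_seed(master: int, *tags: int) -> int:
    ss = np.random.SeedSequence([int(master) & 0xFFFFFFFF, *tags])
    return int(ss.generate_state(1)[0])


def _evaluate(
    detector: TrainedDetector,
    manifest: DatasetManifest,
    cache: Mapping[str, PreppedCase],
) -> float:
    cands: dict[str, list[Candidate]] = {}
    for case in manifest.subset(Subset.TEST):
        prepped = cache[case.case_id]
        if not prepped.mask_nonempty:
            cands[case.case_id] = []
            continue
        cands[case.case_id] = run_cad(
            detector, prepped.volume, case.case_id, prepped=prepped
        )
    curve = froc(cands, manifest, detector.config.hit_distance_mm)
    return cpm(curve).cpm


def _displayed(candidates: Sequence[Candidate], threshold: float) -> list[Candidate]:
    return [c for c in candidates if c.score >= threshold]


def run_protocol(config: StudyConfig) -> tuple[StudyResult, ProtocolState]:
    """Execute the full two-round retraining protocol for one task."""
    seed = config.seed
    det_cfg = config.detector
    result = StudyResult(task=config.task.value, seed=seed)
    result.provenance = {
        "counts": {k: list(v) for k, v in config.counts.items()},
        "annotators": [p.annotator_id for p in config.annotators],
        "classifier": det_cfg.classifier,
    }

    logger.info("generating dataset (%s)", config.task.value)
    manifest, volumes = generate_dataset(
        config.phantom, seed=_child_seed(seed, 1), counts=config.counts
    )
    logger.info("preparing %d cases", len(manifest.cases))
    cache = {
        c.case_id: prepare_case(c, det_cfg, volumes) for c in manifest.cases
    }
    gt_by_case = _gt_annotations(manifest.cases)

    initial_cases = manifest.subset(Subset.INITIAL)
    r1_cases = manifest.subset(Subset.RETRAINING1)
    r2_cases = manifest.subset(Subset.RETRAINING2)

    logger.info("training Initial-CAD")
    initial_cad = train(
        det_cfg,
        initial_cases,
        {c.case_id: gt_by_case[c.case_id] for c in initial_cases},
        seed=_child_seed(seed, 2),
        pipeline_cache=cache,
    )
    result.initial_cpm = _evaluate(initial_cad, manifest, cache)
    logger.info("Initial-CAD CPM %.3f", result.initial_cpm)

    # CAD-assisted annotation of Retraining1 (all annotators see Initial-CAD)
    r1_candidates = {
        c.case_id: _displayed(
            run_cad(initial_cad, cache[c.case_id].volume, c.case_id,
                    prepped=cache[c.case_id]),
            det_cfg.display_score_threshold,
        )
        for c in r1_cases
    }

    ann_seed = _child_seed(seed, 3)
    r1_sets: dict[str, AnnotationSet] = {}
    for profile in config.annotators:
        ann_set = AnnotationSet(annotator_id=profile.annotator_id)
        for case in r1_cases:
            for roi in simulate_annotation(
                profile, case, r1_candidates[case.case_id], seed=ann_seed
            ):
                ann_set.add(roi)
        r1_sets[profile.annotator_id] = ann_set

    retrained1: dict[str, TrainedDetector] = {}
    for profile in config.annotators:
        aid = profile.annotator_id
        try:
            labels = {c.case_id: gt_by_case[c.case_id] for c in initial_cases}
            labels.update(
                {c.case_id: r1_sets[aid].rois.get(c.case_id, []) for c in r1_cases}
            )
            retrained1[aid] = train(
                det_cfg,
                initial_cases + r1_cases,
                labels,
                seed=_child_seed(seed, 4),
                pipeline_cache=cache,
            )
            result.retrained1_cpm[aid] = _evaluate(retrained1[aid], manifest, cache)
            logger.info("Retrained-CAD1[%s] CPM %.3f", aid, result.retrained1_cpm[aid])
        except Exception as exc:  # record and continue with remaining arms
            logger.warning("Retrained-CAD1[%s] failed: %s", aid, exc)
            result.failed_arms[f"retrained1/{aid}"] = str(exc)

    # Retraining2: each annotator references their own Retrained-CAD1
    for profile in config.annotators:
        aid = profile.annotator_id
        if aid not in retrained1:
            continue
        try:
            r2_candidates = {
                c.case_id: _displayed(
                    run_cad(retrained1[aid], cache[c.case_id].volume, c.case_id,
                            prepped=cache[c.case_id]),
                    det_cfg.display_score_threshold,
                )
                for c in r2_cases
            }
            ann2 = AnnotationSet(annotator_id=aid)
            for case in r2_cases:
                for roi in simulate_annotation(
                    profile, case, r2_candidates[case.case_id], seed=ann_seed
                ):
                    ann2.add(roi)
            labels = {c.case_id: gt_by_case[c.case_id] for c in initial_cases}
            labels.update(
                {c.case_id: r1_sets[aid].rois.get(c.case_id, []) for c in r1_cases}
            )
            labels.update(
                {c.case_id: ann2.rois.get(c.case_id, []) for c in r2_cases}
            )
            model2 = train(
                det_cfg,
                initial_cases + r1_cases + r2_cases,
                labels,
                seed=_child_seed(seed, 5),
                pipeline_cache=cache,
            )
            result.retrained2_cpm[aid] = _evaluate(model2, manifest, cache)
            logger.info("Retrained-CAD2[%s] CPM %.3f", aid, result.retrained2_cpm[aid])
        except Exception as exc:
            logger.warning("Retrained-CAD2[%s] failed: %s", aid, exc)
            result.failed_arms[f"retrained2/{aid}"] = str(exc)

    state = ProtocolState(
        manifest=manifest,
        volumes=volumes,
        cache=cache,
        gt_by_case=gt_by_case,
        retraining1_sets=r1_sets,
        retrained1_cpms=dict(result.retrained1_cpm),
    )
    return result, state


def run_integration_experiment(
    config: StudyConfig, state: ProtocolState, result: StudyResult | None = None
) -> StudyResult:
    """Retrain on integrated Retraining1 labels per strategy x cohort and
    compare CPM distributions (single vs AND vs OR vs VOTING) per cohort."""
    if result is None:
        result = StudyResult(task=config.task.value, seed=config.seed)
    det_cfg = config.detector
    manifest = state.manifest
    cache = state.cache
    initial_cases = manifest.subset(Subset.INITIAL)
    r1_cases = manifest.subset(Subset.RETRAINING1)
    by_tier = {
        "all": [p for p in config.annotators],
        "board_certified": [p for p in config.annotators if p.tier == "board_certified"],
        "resident": [p for p in config.annotators if p.tier == "resident"],
    }

    for cohort in config.cohorts:
        members = by_tier.get(cohort, [])
        member_ids = [p.annotator_id for p in members]
        groups: dict[str, list[float]] = {}
        single = [
            state.retrained1_cpms[a] for a in member_ids
            if a in state.retrained1_cpms
        ]
        if len(single) >= 2:
            groups["single"] = single
        for strategy in config.strategies:
            arity = 3 if strategy.upper() == "VOTING" else 2
            if len(members) < arity:
                logger.warning(
                    "cohort %s too small for %s (needs %d annotators); skipped",
                    cohort, strategy, arity,
                )
                result.failed_arms[f"integration/{strategy}/{cohort}"] = (
                    f"cohort of {len(members)} smaller than arity {arity}"
                )
                continue
            sets = [state.retraining1_sets[a] for a in member_ids]
            combos = integrate_cohort(
                sets,
                strategy,
                threshold_mm=config.threshold_mm,
                max_combinations=config.max_combinations,
                seed=_child_seed(config.seed, 6),
            )
            cpms: list[tuple[str, float]] = []
            for combo_ids, integrated in combos:
                label = "+".join(combo_ids)
                try:
                    labels = {
                        c.case_id: state.gt_by_case[c.case_id] for c in initial_cases
                    }
                    labels.update(
                        {
                            c.case_id: integrated.rois.get(c.case_id, [])
                            for c in r1_cases
                        }
                    )
                    model = train(
                        det_cfg,
                        initial_cases + r1_cases,
                        labels,
                        seed=_child_seed(config.seed, 7),
                        pipeline_cache=cache,
                    )
                    cpms.append((label, _evaluate(model, manifest, cache)))
                except Exception as exc:
                    logger.warning(
                        "integration %s/%s/%s failed: %s", strategy, cohort, label, exc
                    )
                    result.failed_arms[
                        f"integration/{strategy}/{cohort}/{label}"
                    ] = str(exc)
            result.integration_cpm[f"{strategy.upper()}/{cohort}"] = cpms
            if len(cpms) >= 2:
                groups[strategy.upper()] = [v for _, v in cpms]
        if len(groups) >= 2:
            sd = steel_dwass(groups)
            result.steel_dwass_p[cohort] = {
                f"{a}|{b}": p for (a, b), p in sd.p_value.items()
            }
    return result


def summarize(result: StudyResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-annotator CPM progression table, per-strategy distribution table).

    The strategy table carries a ``significant`` marker per cohort whenever
    any Steel-Dwass pair involving that strategy has p < 0.05.
    """
    annotators = sorted(set(result.retrained1_cpm) | set(result.retrained2_cpm))
    progression = pd.DataFrame(
        {
            "annotator": annotators,
            "initial_cpm": [result.initial_cpm] * len(annotators),
            "retrained1_cpm": [result.retrained1_cpm.get(a) for a in annotators],
            "retrained2_cpm": [result.retrained2_cpm.get(a) for a in annotators],
        }
    )

    rows = []
    for key, cpms in sorted(result.integration_cpm.items()):
        strategy, cohort = key.split("/")
        values = [v for _, v in cpms]
        pvals = result.steel_dwass_p.get(cohort, {})
        significant = any(
            p < 0.05 and strategy in pair.split("|")
            for pair, p in pvals.items()
        )
        rows.append(
            {
                "strategy": strategy,
                "cohort": cohort,
                "n_combinations": len(values),
                "cpm_mean": float(np.mean(values)) if values else np.nan,
                "cpm_sd": float(np.std(values, ddof=1)) if len(values) > 1 else np.nan,
                "significant": significant,
            }
        )
    strategy_table = pd.DataFrame(
        rows,
        columns=[
            "strategy", "cohort", "n_combinations", "cpm_mean", "cpm_sd",
            "significant",
        ],
    )
    return progression, strategy_table
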