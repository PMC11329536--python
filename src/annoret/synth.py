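"""Synthetic phantoms, dataset assembly, and simulated annotators.

Chest-task phantoms contain a parenchyma-filled ellipsoid with tubular
vessels and soft-edged spherical nodules (target nodules >= 6 mm, distractor
nodules < 6 mm).  Brain-task phantoms contain a bright binary-branching
vessel tree on a dark background, with hemispherical aneurysm bumps at
bifurcations (targets >= 2 mm) and cone-shaped infundibular-dilation
distractors at branch origins.

Everything is deterministic in (parameters, seed): per-case and
per-(case, annotator, pass) child streams are derived from the master seed
so that adding cases or annotators never perturbs existing draws.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .core import (
    AnnotationSet,
    Candidate,
    CaseRecord,
    DatasetManifest,
    RoiTag,
    SphericalROI,
    Subset,
    Task,
    Volume,
    write_volume,
)

__all__ = [
    "PhantomParams",
    "AnnotatorProfile",
    "GenerationError",
    "generate_phantom",
    "plan_phantom",
    "render_phantom",
    "generate_dataset",
    "simulate_annotation",
    "estimate_profile",
    "make_cohort",
    "DEFAULT_SUBSET_COUNTS",
]

# Default subset design: (positives, negatives) per subset.
DEFAULT_SUBSET_COUNTS: dict[str, tuple[int, int]] = {
    "initial": (50, 0),
    "retraining1": (40, 35),
    "retraining2": (40, 35),
    "test": (50, 50),
}

#: number of distractor-bearing ambiguous negatives per retraining/test subset
N_AMBIGUOUS_NEGATIVES = 10


class GenerationError(RuntimeError):
    """Raised when phantom construction cannot satisfy its constraints."""


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and appearance parameters for one phantom family."""

    task: Task = Task.CHEST
    grid_size: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 1.0
    noise_sd: float = 0.04
    background_level: float = 0.2
    lesion_contrast: tuple[float, float] = (0.45, 0.8)
    # lesion diameters: truncated lognormal
    lesion_diameter_log_mean: float = math.log(8.0)
    lesion_diameter_log_sd: float = 0.25
    lesion_diameter_min: float = 6.0
    lesion_diameter_max: float = 14.0
    distractor_diameter_range: tuple[float, float] = (3.0, 5.5)
    ggo_fraction: float = 0.2  # chest: low-contrast ground-glass-like variant
    n_vessels: int = 4  # chest tubular vessels
    # brain vessel tree
    tree_depth: int = 3
    vessel_radius_range: tuple[float, float] = (1.2, 2.2)
    vessel_intensity: float = 1.0
    infundibulum_cone_mm: float = 3.0
    edge_softness_mm: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "task", Task(self.task))
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be > 0")
        floor = 6.0 if self.task == Task.CHEST else 2.0
        if self.lesion_diameter_min < floor:
            raise ValueError(
                f"{self.task.value} target-lesion minimum diameter must be "
                f">= {floor} mm, got {self.lesion_diameter_min}"
            )
        if min(self.grid_size) * self.spacing_mm < 2 * self.lesion_diameter_max:
            raise ValueError("grid too small for the configured lesion sizes")

    @classmethod
    def for_task(cls, task: Task | str, **overrides) -> "PhantomParams":
        task = Task(task)
        if task == Task.BRAIN:
            defaults = dict(
                task=task,
                background_level=0.05,
                lesion_contrast=(1.0, 1.25),
                lesion_diameter_log_mean=math.log(4.5),
                lesion_diameter_log_sd=0.3,
                lesion_diameter_min=2.0,
                lesion_diameter_max=8.0,
                distractor_diameter_range=(2.0, 3.5),
                ggo_fraction=0.0,
                vessel_radius_range=(0.8, 1.4),
            )
        else:
            defaults = dict(task=task)
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_size, dtype=float) * self.spacing_mm


@dataclass
class PhantomPlan:
    """Placed geometry for one phantom, prior to voxel rendering."""

    rois: list[SphericalROI]
    # tubes: list of (start_mm, end_mm, radius_mm, intensity)
    tubes: list[tuple[np.ndarray, np.ndarray, float, float]] = field(
        default_factory=list
    )
    # cones: list of (apex_mm, direction_unit, length_mm, base_radius_mm) —
    # brain infundibular dilations
    cones: list[tuple[np.ndarray, np.ndarray, float, float]] = field(
        default_factory=list
    )
    ggo_flags: list[bool] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Geometry planning
# ---------------------------------------------------------------------------

def _sample_lesion_diameter(params: PhantomParams, rng: np.random.Generator) -> float:
    for _ in range(200):
        d = float(
            np.exp(rng.normal(params.lesion_diameter_log_mean, params.lesion_diameter_log_sd))
        )
        if params.lesion_diameter_min <= d <= params.lesion_diameter_max:
            return d
    return params.lesion_diameter_min


def _place_spheres(
    params: PhantomParams,
    diameters: Sequence[float],
    rng: np.random.Generator,
    existing: list[tuple[np.ndarray, float]],
    max_tries: int = 500,
) -> list[np.ndarray]:
    """Rejection-sample non-overlapping sphere centres inside the grid."""
    extent = params.extent_mm
    centres: list[np.ndarray] = []
    placed = list(existing)
    for d in diameters:
        r = d / 2.0
        margin = r + params.edge_softness_mm + 2.0
        lo, hi = margin, extent - margin
        if np.any(hi <= lo):
            raise GenerationError(f"grid cannot fit a {d:.1f} mm sphere")
        for attempt in range(max_tries):
            c = rng.uniform(lo, hi)
            if all(
                np.linalg.norm(c - pc) > r + pr + 2.0 for pc, pr in placed
            ):
                centres.append(c)
                placed.append((c, r))
                break
        else:
            raise GenerationError(
                f"could not place a {d:.1f} mm sphere after {max_tries} tries"
            )
    return centres


def _plan_chest(
    params: PhantomParams,
    case_id: str,
    n_lesions: int,
    n_distractors: int,
    rng: np.random.Generator,
) -> PhantomPlan:
    extent = params.extent_mm
    lesion_d = [_sample_lesion_diameter(params, rng) for _ in range(n_lesions)]
    lo, hi = params.distractor_diameter_range
    distract_d = [float(rng.uniform(lo, min(hi, 5.99))) for _ in range(n_distractors)]
    centres = _place_spheres(params, list(lesion_d) + list(distract_d), rng, [])
    rois = []
    ggo_flags = []
    for i, (c, d) in enumerate(zip(centres[:n_lesions], lesion_d)):
        rois.append(
            SphericalROI(case_id, tuple(c), d, "ground_truth", RoiTag.LESION)
        )
        ggo_flags.append(bool(rng.random() < params.ggo_fraction))
    for c, d in zip(centres[n_lesions:], distract_d):
        rois.append(
            SphericalROI(case_id, tuple(c), d, "ground_truth", RoiTag.DISTRACTOR)
        )
        ggo_flags.append(False)
    # tubular vessels crossing the parenchyma
    tubes = []
    for _ in range(params.n_vessels):
        a = rng.uniform(0.15 * extent, 0.85 * extent)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        length = float(rng.uniform(0.4, 0.8) * extent.min())
        b = np.clip(a + direction * length, 2.0, extent - 2.0)
        tubes.append((a, b, float(rng.uniform(0.8, 1.4)), 0.55))
    return PhantomPlan(rois=rois, tubes=tubes, ggo_flags=ggo_flags)


def _grow_tree(
    params: PhantomParams, rng: np.random.Generator
) -> tuple[list, list[np.ndarray], list[tuple[np.ndarray, np.ndarray]]]:
    """Random binary-branching tree; returns (tubes, bifurcations, branch origins)."""
    extent = params.extent_mm
    root = np.array([extent[0] / 2, extent[1] / 2, extent[2] * 0.12])
    direction = np.array([0.0, 0.0, 1.0])
    r_lo, r_hi = params.vessel_radius_range
    tubes: list = []
    bifurcations: list[np.ndarray] = []
    origins: list[tuple[np.ndarray, np.ndarray]] = []
    queue = [(root, direction, float(r_hi), 0)]
    while queue:
        start, d, radius, depth = queue.pop(0)
        length = float(rng.uniform(0.30, 0.45) * extent.min() / (depth + 1))
        # reflect the direction off the walls rather than clipping the end
        # point (clipping piles branch ends onto the box faces)
        end = start + d * length
        for axis in range(3):
            if end[axis] < 4.0 or end[axis] > extent[axis] - 4.0:
                d = d.copy()
                d[axis] = -d[axis]
        end = np.clip(start + d * length, 3.0, extent - 3.0)
        tubes.append((start, end, radius, params.vessel_intensity))
        if depth < params.tree_depth:
            bifurcations.append(end.copy())
            for _ in range(2):
                child = d + rng.normal(scale=0.55, size=3)
                child /= np.linalg.norm(child)
                if child[2] < 0.1:  # keep growing away from the root face
                    child[2] = 0.1
                    child /= np.linalg.norm(child)
                child_r = max(r_lo, radius * float(rng.uniform(0.7, 0.9)))
                origins.append((end.copy(), child.copy()))
                queue.append((end, child, child_r, depth + 1))
    return tubes, bifurcations, origins


def _plan_brain(
    params: PhantomParams,
    case_id: str,
    n_lesions: int,
    n_distractors: int,
    rng: np.random.Generator,
) -> PhantomPlan:
    for attempt in range(20):
        tubes, bifurcations, origins = _grow_tree(params, rng)
        if len(bifurcations) >= n_lesions and len(origins) >= n_distractors:
            break
    else:
        raise GenerationError("vessel tree too small for requested lesions")

    rois: list[SphericalROI] = []
    used: list[tuple[np.ndarray, float]] = []
    sites = list(bifurcations)
    rng.shuffle(sites)
    placed = 0
    for site in sites:
        if placed >= n_lesions:
            break
        d = _sample_lesion_diameter(params, rng)
        offset = rng.normal(size=3)
        offset /= np.linalg.norm(offset)
        centre = site + offset * (params.vessel_radius_range[1] * 0.8)
        centre = np.clip(centre, d / 2 + 1, params.extent_mm - d / 2 - 1)
        if any(np.linalg.norm(centre - pc) < d / 2 + pr + 1.5 for pc, pr in used):
            continue
        rois.append(
            SphericalROI(case_id, tuple(centre), d, "ground_truth", RoiTag.LESION)
        )
        used.append((centre, d / 2))
        placed += 1
    if placed < n_lesions:
        raise GenerationError("could not place all aneurysms on the tree")

    cones = []
    origin_sites = list(origins)
    rng.shuffle(origin_sites)
    placed_d = 0
    lo, hi = params.distractor_diameter_range
    for apex, direction in origin_sites:
        if placed_d >= n_distractors:
            break
        d = float(rng.uniform(lo, hi))
        if any(np.linalg.norm(apex - pc) < d / 2 + pr + 1.5 for pc, pr in used):
            continue
        rois.append(
            SphericalROI(case_id, tuple(apex), d, "ground_truth", RoiTag.DISTRACTOR)
        )
        cones.append((apex, direction, params.infundibulum_cone_mm, d / 2))
        used.append((apex, d / 2))
        placed_d += 1
    if placed_d < n_distractors:
        raise GenerationError("could not place all infundibular distractors")
    return PhantomPlan(rois=rois, tubes=tubes, cones=cones,
                       ggo_flags=[False] * len(rois))


def plan_phantom(
    params: PhantomParams,
    case_id: str,
    n_lesions: int,
    n_distractors: int,
    rng: np.random.Generator,
) -> PhantomPlan:
    """Place ROIs and support geometry without rendering voxels."""
    if params.task == Task.CHEST:
        return _plan_chest(params, case_id, n_lesions, n_distractors, rng)
    return _plan_brain(params, case_id, n_lesions, n_distractors, rng)


# ---------------------------------------------------------------------------
# Voxel rendering
# ---------------------------------------------------------------------------

def _mm_grid(params: PhantomParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nx, ny, nz = params.grid_size
    s = params.spacing_mm
    # voxel-centre world coordinates (origin 0)
    xs = np.arange(nx) * s
    ys = np.arange(ny) * s
    zs = np.arange(nz) * s
    return np.meshgrid(xs, ys, zs, indexing="ij")


def _stamp_sphere(
    vox: np.ndarray,
    params: PhantomParams,
    centre: np.ndarray,
    diameter: float,
    amplitude: float,
) -> None:
    """Max-composed soft-edged sphere: flat core, cosine falloff over the
    edge width.  Max composition keeps overlapping structures from summing."""
    s = params.spacing_mm
    r = diameter / 2.0
    w = params.edge_softness_mm
    lo = np.maximum(np.floor((centre - r - w) / s).astype(int), 0)
    hi = np.minimum(np.ceil((centre + r + w) / s).astype(int) + 1, vox.shape)
    if np.any(hi <= lo):
        return
    ix = [np.arange(lo[a], hi[a]) * s - centre[a] for a in range(3)]
    dist = np.sqrt(
        ix[0][:, None, None] ** 2 + ix[1][None, :, None] ** 2 + ix[2][None, None, :] ** 2
    )
    profile = np.clip((r + w - dist) / (2 * w), 0.0, 1.0)
    profile = 0.5 - 0.5 * np.cos(np.pi * np.clip(profile, 0, 1))
    region = vox[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.maximum(region, amplitude * profile, out=region)


def _stamp_tube(
    vox: np.ndarray,
    params: PhantomParams,
    start: np.ndarray,
    end: np.ndarray,
    radius: float,
    amplitude: float,
) -> None:
    length = float(np.linalg.norm(end - start))
    if length <= 0:
        return
    n_steps = max(2, int(length / (params.spacing_mm * 0.5)))
    for t in np.linspace(0.0, 1.0, n_steps):
        _stamp_sphere(vox, params, start + t * (end - start), 2 * radius, amplitude)


def _stamp_cone(
    vox: np.ndarray,
    params: PhantomParams,
    apex: np.ndarray,
    direction: np.ndarray,
    length: float,
    base_radius: float,
    amplitude: float,
) -> None:
    n_steps = max(2, int(length / (params.spacing_mm * 0.5)))
    for t in np.linspace(0.0, 1.0, n_steps):
        r = base_radius * (1.0 - t) + 0.3 * t  # funnel tapering along the branch
        _stamp_sphere(vox, params, apex + t * length * direction, 2 * r, amplitude)


def render_phantom(
    params: PhantomParams, plan: PhantomPlan, rng: np.random.Generator
) -> Volume:
    if params.task == Task.CHEST:
        # parenchyma ellipsoid with smooth texture inside an air background
        gx, gy, gz = _mm_grid(params)
        half = params.extent_mm / 2.0
        ell = (
            ((gx - half[0]) / (0.92 * half[0])) ** 2
            + ((gy - half[1]) / (0.92 * half[1])) ** 2
            + ((gz - half[2]) / (0.92 * half[2])) ** 2
        )
        body = ell <= 1.0
        texture = gaussian_filter(rng.normal(size=params.grid_size), sigma=3.0)
        background = body * (params.background_level + 0.05 * texture)
    else:
        background = np.full(params.grid_size, params.background_level)

    # structures are max-composed among themselves, then added on top
    struct = np.zeros(params.grid_size, dtype=np.float64)
    for start, end, radius, intensity in plan.tubes:
        _stamp_tube(struct, params, start, end, radius, intensity)
    for apex, direction, length, base_r in plan.cones:
        _stamp_cone(struct, params, apex, direction, length, base_r,
                    params.vessel_intensity)

    clo, chi = params.lesion_contrast
    for roi, ggo in zip(plan.rois, plan.ggo_flags):
        contrast = float(rng.uniform(clo, chi))
        if ggo:
            contrast *= 0.4
        if params.task == Task.BRAIN and roi.tag == RoiTag.DISTRACTOR:
            continue  # brain distractors are the cones, already stamped
        _stamp_sphere(struct, params, np.asarray(roi.centroid), roi.diameter, contrast)

    vox = background + struct
    vox += rng.normal(scale=params.noise_sd, size=params.grid_size)
    return Volume(
        voxels=vox.astype(np.float32),
        spacing=np.full(3, params.spacing_mm),
        origin=np.zeros(3),
        task=params.task,
    )


def generate_phantom(
    params: PhantomParams,
    n_lesions: int,
    n_distractors: int,
    seed: int,
    case_id: str = "phantom",
) -> tuple[Volume, list[SphericalROI]]:
    """Generate one phantom volume plus its exact placed ground-truth ROIs."""
    ss = np.random.SeedSequence([int(seed) & 0xFFFFFFFF, _stable_id(case_id)])
    plan_ss, render_ss = ss.spawn(2)
    plan = plan_phantom(params, case_id, n_lesions, n_distractors,
                        np.random.default_rng(plan_ss))
    volume = render_phantom(params, plan, np.random.default_rng(render_ss))
    return volume, plan.rois


# ---------------------------------------------------------------------------
# Dataset assembly (default study subset design)
# ---------------------------------------------------------------------------

def _stable_id(text: str) -> int:
    return zlib.crc32(text.encode("utf-8"))


def generate_dataset(
    params: PhantomParams,
    seed: int,
    counts: dict[str, tuple[int, int]] | None = None,
    out_dir: str | Path | None = None,
    render: bool = True,
    n_ambiguous: int = N_AMBIGUOUS_NEGATIVES,
) -> tuple[DatasetManifest, dict[str, Volume]]:
    """Build the study dataset: manifest + (optionally rendered) volumes.

    Defaults follow the study design: initial 50/0, retraining1 and
    retraining2 each 40/35, test 50/50 positives/negatives, with exactly
    ``n_ambiguous`` distractor-bearing negatives in every retraining and
    test subset.  With ``render=False`` only the geometry is planned (much
    faster; volumes dict comes back empty).  With ``out_dir`` set, volumes
    are written as NIfTI and referenced from the manifest.
    """
    counts = dict(DEFAULT_SUBSET_COUNTS if counts is None else counts)
    volumes: dict[str, Volume] = {}
    cases: list[CaseRecord] = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    for subset_name, (n_pos, n_neg) in counts.items():
        subset = Subset(subset_name)
        if n_pos < 0 or n_neg < 0:
            raise ValueError(f"negative case count for subset {subset_name}")
        ambiguous = 0
        if subset in (Subset.RETRAINING1, Subset.RETRAINING2, Subset.TEST):
            ambiguous = min(n_ambiguous, n_neg)
        for i in range(n_pos + n_neg):
            positive = i < n_pos
            case_id = f"{params.task.value}_{subset.value}_{i:03d}"
            ss = np.random.SeedSequence(
                [int(seed) & 0xFFFFFFFF, _stable_id(case_id)]
            )
            plan_ss, render_ss, count_ss = ss.spawn(3)
            crng = np.random.default_rng(count_ss)
            if positive:
                n_lesions = int(crng.integers(1, 3))
                n_distract = 0
            else:
                n_lesions = 0
                # first `ambiguous` negatives carry distractor structures
                n_distract = int(crng.integers(1, 3)) if (i - n_pos) < ambiguous else 0
            plan = plan_phantom(
                params, case_id, n_lesions, n_distract,
                np.random.default_rng(plan_ss),
            )
            volume_path = None
            if render:
                vol = render_phantom(params, plan, np.random.default_rng(render_ss))
                if out_path is not None:
                    volume_path = str(out_path / f"{case_id}.nii")
                    write_volume(vol, volume_path)
                volumes[case_id] = vol
            cases.append(
                CaseRecord(
                    case_id=case_id,
                    subset=subset,
                    is_positive=positive,
                    ground_truth=plan.rois,
                    volume_path=volume_path,
                )
            )
    return DatasetManifest(task=params.task, cases=cases), volumes


# ---------------------------------------------------------------------------
# Annotator simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotatorProfile:
    """Tunable error behaviour of one simulated annotator.

    Sensitivity is logistic in lesion diameter:
    ``plateau * expit((d - midpoint) / scale)``; ``scale == 0`` degenerates
    to a step at ``midpoint`` (so a noise-free annotator is exactly
    deterministic).
    """

    annotator_id: str
    tier: str = "board_certified"  # or "resident"
    sens_plateau: float = 1.0
    sens_midpoint: float = 0.0
    sens_scale: float = 0.0
    fp_rate: float = 0.0
    centroid_jitter_sd: float = 0.0
    diameter_jitter_sd: float = 0.0
    distractor_confusion_prob: float = 0.0
    cad_rescue_prob: float = 0.0
    cad_fp_accept_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "sens_plateau",
            "distractor_confusion_prob",
            "cad_rescue_prob",
            "cad_fp_accept_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be >= 0")
        if self.centroid_jitter_sd < 0 or self.diameter_jitter_sd < 0:
            raise ValueError("jitter SDs must be >= 0")
        if self.tier not in ("board_certified", "resident"):
            raise ValueError(f"unknown tier {self.tier!r}")

    def sensitivity(self, diameter: float) -> float:
        if self.sens_scale == 0.0:
            return self.sens_plateau if diameter >= self.sens_midpoint else 0.0
        return float(
            self.sens_plateau * expit((diameter - self.sens_midpoint) / self.sens_scale)
        )

    @classmethod
    def noise_free(cls, annotator_id: str = "oracle") -> "AnnotatorProfile":
        return cls(annotator_id=annotator_id)


def _annotation_rng(
    seed: int, case_id: str, annotator_id: str, pass_index: int
) -> np.random.Generator:
    ss = np.random.SeedSequence(
        [
            int(seed) & 0xFFFFFFFF,
            _stable_id(case_id),
            _stable_id(annotator_id),
            pass_index,
        ]
    )
    return np.random.default_rng(ss)


def _jittered_copy(
    roi: SphericalROI,
    profile: AnnotatorProfile,
    rng: np.random.Generator,
) -> SphericalROI:
    centroid = np.asarray(roi.centroid, dtype=float)
    if profile.centroid_jitter_sd > 0:
        centroid = centroid + rng.normal(0.0, profile.centroid_jitter_sd, size=3)
    diameter = roi.diameter
    if profile.diameter_jitter_sd > 0:
        diameter = diameter * float(np.exp(rng.normal(0.0, profile.diameter_jitter_sd)))
    return SphericalROI(
        case_id=roi.case_id,
        centroid=tuple(centroid),
        diameter=diameter,
        annotator_id=profile.annotator_id,
        tag=RoiTag.UNKNOWN,
    )


def simulate_annotation(
    profile: AnnotatorProfile,
    case: CaseRecord,
    cad_candidates: Sequence[Candidate] | None = None,
    seed: int = 0,
    region_mm: tuple[float, float] | None = None,
    match_mm: float = 3.0,
) -> list[SphericalROI]:
    """Simulate one annotator reading one case.

    Pass 1 is unassisted: each true lesion is annotated with probability
    ``sensitivity(diameter)`` and jittered; distractors are mistaken for
    lesions with ``distractor_confusion_prob``; Poisson(``fp_rate``)
    additional false ROIs appear at random locations (preferring distractor
    structures when present).  Pass 2 runs only when CAD candidates are
    given: candidates within ``match_mm`` of a missed lesion rescue it with
    ``cad_rescue_prob``; candidates away from all lesions are accepted as
    false annotations with ``cad_fp_accept_prob``.
    """
    if cad_candidates is not None:
        for cand in cad_candidates:
            if cand.case_id != case.case_id:
                raise ValueError(
                    f"candidate case {cand.case_id!r} does not belong to "
                    f"case {case.case_id!r}"
                )

    rng = _annotation_rng(seed, case.case_id, profile.annotator_id, 1)
    out: list[SphericalROI] = []
    annotated_lesions: set[int] = set()

    for i, lesion in enumerate(case.lesions):
        if rng.random() < profile.sensitivity(lesion.diameter):
            out.append(_jittered_copy(lesion, profile, rng))
            annotated_lesions.add(i)

    unclaimed_distractors = []
    for distractor in case.distractors:
        if rng.random() < profile.distractor_confusion_prob:
            out.append(_jittered_copy(distractor, profile, rng))
        else:
            unclaimed_distractors.append(distractor)

    n_false = int(rng.poisson(profile.fp_rate))
    lo, hi = region_mm if region_mm is not None else (4.0, 60.0)
    for _ in range(n_false):
        if unclaimed_distractors and rng.random() < 0.5:
            anchor = unclaimed_distractors[rng.integers(len(unclaimed_distractors))]
            centre = np.asarray(anchor.centroid) + rng.normal(0.0, 1.0, size=3)
        else:
            centre = rng.uniform(lo, hi, size=3)
        diameter = float(np.clip(np.exp(rng.normal(math.log(5.0), 0.3)), 2.0, 12.0))
        out.append(
            SphericalROI(
                case_id=case.case_id,
                centroid=tuple(centre),
                diameter=diameter,
                annotator_id=profile.annotator_id,
                tag=RoiTag.UNKNOWN,
            )
        )

    if cad_candidates is not None:
        rng2 = _annotation_rng(seed, case.case_id, profile.annotator_id, 2)
        for cand in cad_candidates:
            dists = [
                (lesion.distance_to(cand.centroid), i)
                for i, lesion in enumerate(case.lesions)
            ]
            near = [(d, i) for d, i in dists if d <= match_mm]
            if near:
                _, i = min(near)
                if i not in annotated_lesions and rng2.random() < profile.cad_rescue_prob:
                    out.append(_jittered_copy(case.lesions[i], profile, rng2))
                    annotated_lesions.add(i)
            else:
                if rng2.random() < profile.cad_fp_accept_prob:
                    diameter = (
                        2.0 * cand.radius_mm if cand.radius_mm is not None else 5.0
                    )
                    out.append(
                        SphericalROI(
                            case_id=case.case_id,
                            centroid=cand.centroid,
                            diameter=diameter,
                            annotator_id=profile.annotator_id,
                            tag=RoiTag.UNKNOWN,
                        )
                    )
    return out


# ---------------------------------------------------------------------------
# Profile recovery (moment estimates against ground truth)
# ---------------------------------------------------------------------------

@dataclass
class ProfileEstimate:
    n_cases: int
    sensitivity_by_bin: dict[str, float]
    fp_rate: float | None
    centroid_jitter_sd: float | None
    diameter_jitter_sd: float | None
    distractor_confusion: float | None

    @property
    def defined(self) -> bool:
        return self.n_cases > 0


def _greedy_match(
    rois: Sequence[SphericalROI],
    targets: Sequence[SphericalROI],
    floor_mm: float = 3.0,
) -> list[tuple[int, int, float]]:
    """One-to-one greedy matching by ascending distance.

    A pair is admissible when centroid distance <= max(target radius, floor).
    """
    pairs = []
    for i, roi in enumerate(rois):
        for j, tgt in enumerate(targets):
            d = tgt.distance_to(roi.centroid)
            if d <= max(tgt.radius, floor_mm):
                pairs.append((d, i, j))
    pairs.sort()
    used_r: set[int] = set()
    used_t: set[int] = set()
    matches = []
    for d, i, j in pairs:
        if i in used_r or j in used_t:
            continue
        used_r.add(i)
        used_t.add(j)
        matches.append((i, j, d))
    return matches


def estimate_profile(
    annotations: AnnotationSet,
    manifest: DatasetManifest,
    diameter_bins: Sequence[float] = (0, 4, 6, 8, 10, float("inf")),
) -> ProfileEstimate:
    """Moment estimates of an annotator's error behaviour from ground truth."""
    manifest_ids = {c.case_id for c in manifest.cases}
    for case_id in annotations.rois:
        if case_id not in manifest_ids:
            raise ValueError(f"annotated case {case_id!r} absent from manifest")

    case_ids = sorted(annotations.rois)
    if not case_ids:
        return ProfileEstimate(0, {}, None, None, None, None)

    bin_hits: dict[str, list[int]] = {}
    offsets: list[np.ndarray] = []
    log_ratios: list[float] = []
    fp_counts: list[int] = []
    distractor_hits = 0
    distractor_total = 0

    # every case the annotator saw counts toward FP rate, even if empty
    seen_cases = set(case_ids)
    for case in manifest.cases:
        if case.case_id not in seen_cases:
            continue
        rois = annotations.rois.get(case.case_id, [])
        lesions = case.lesions
        matches = _greedy_match(rois, lesions)
        matched_rois = {i for i, _, _ in matches}
        matched_lesions = {j for _, j, _ in matches}
        for i, j, _ in matches:
            offsets.append(
                np.asarray(rois[i].centroid) - np.asarray(lesions[j].centroid)
            )
            log_ratios.append(math.log(rois[i].diameter / lesions[j].diameter))
        for j, lesion in enumerate(lesions):
            for lo, hi in zip(diameter_bins[:-1], diameter_bins[1:]):
                if lo <= lesion.diameter < hi:
                    key = f"[{lo:g},{hi:g})"
                    bin_hits.setdefault(key, []).append(int(j in matched_lesions))
        # remaining ROIs: distractor confusions vs background FPs
        leftovers = [r for i, r in enumerate(rois) if i not in matched_rois]
        d_matches = _greedy_match(leftovers, case.distractors)
        distractor_hits += len(d_matches)
        distractor_total += len(case.distractors)
        fp_counts.append(len(leftovers) - len(d_matches))

    offsets_arr = np.asarray(offsets) if offsets else np.empty((0, 3))
    return ProfileEstimate(
        n_cases=len(case_ids),
        sensitivity_by_bin={k: float(np.mean(v)) for k, v in sorted(bin_hits.items())},
        fp_rate=float(np.mean(fp_counts)) if fp_counts else None,
        centroid_jitter_sd=(
            float(np.sqrt(np.mean(offsets_arr**2))) if len(offsets_arr) else None
        ),
        diameter_jitter_sd=(
            float(np.std(log_ratios)) if len(log_ratios) >= 2 else None
        ),
        distractor_confusion=(
            distractor_hits / distractor_total if distractor_total else None
        ),
    )


# ---------------------------------------------------------------------------
# Cohort construction
# ---------------------------------------------------------------------------

def make_cohort(
    task: Task | str,
    n_board: int | None = None,
    n_resident: int | None = None,
    seed: int = 0,
    heterogeneity: float = 1.0,
) -> list[AnnotatorProfile]:
    """Build a simulated annotator cohort.

    Default tier split matches the study design: chest 5 board-certified /
    7 resident; brain 4 / 8.  Per-annotator parameters are drawn around tier
    means; ``heterogeneity`` scales the spread (0 gives identical profiles
    per tier).  These defaults are free simulation inputs, not measured
    clinician error rates.
    """
    task = Task(task)
    if n_board is None or n_resident is None:
        n_board, n_resident = (5, 7) if task == Task.CHEST else (4, 8)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0xFFFFFFFF, 77]))
    tier_means = {
        "board_certified": dict(
            sens_plateau=0.95, sens_midpoint=3.5, sens_scale=1.0,
            fp_rate=0.4, centroid_jitter_sd=0.5, diameter_jitter_sd=0.08,
            distractor_confusion_prob=0.10, cad_rescue_prob=0.6,
            cad_fp_accept_prob=0.08,
        ),
        "resident": dict(
            sens_plateau=0.85, sens_midpoint=4.5, sens_scale=1.5,
            fp_rate=0.9, centroid_jitter_sd=1.0, diameter_jitter_sd=0.15,
            distractor_confusion_prob=0.25, cad_rescue_prob=0.45,
            cad_fp_accept_prob=0.18,
        ),
    }
    profiles = []
    idx = 1
    for tier, n in (("board_certified", n_board), ("resident", n_resident)):
        m = tier_means[tier]
        for _ in range(n):
            h = heterogeneity
            profiles.append(
                AnnotatorProfile(
                    annotator_id=f"{'B' if tier == 'board_certified' else 'R'}{idx:02d}",
                    tier=tier,
                    sens_plateau=float(
                        np.clip(m["sens_plateau"] + h * rng.normal(0, 0.04), 0.4, 1.0)
                    ),
                    sens_midpoint=float(m["sens_midpoint"] + h * rng.normal(0, 0.5)),
                    sens_scale=float(max(0.2, m["sens_scale"] + h * rng.normal(0, 0.2))),
                    fp_rate=float(max(0.0, m["fp_rate"] + h * rng.normal(0, 0.2))),
                    centroid_jitter_sd=float(
                        max(0.05, m["centroid_jitter_sd"] + h * rng.normal(0, 0.15))
                    ),
                    diameter_jitter_sd=float(
                        max(0.01, m["diameter_jitter_sd"] + h * rng.normal(0, 0.03))
                    ),
                    distractor_confusion_prob=float(
                        np.clip(
                            m["distractor_confusion_prob"] + h * rng.normal(0, 0.05),
                            0.0, 1.0,
                        )
                    ),
                    cad_rescue_prob=float(
                        np.clip(m["cad_rescue_prob"] + h * rng.normal(0, 0.1), 0.0, 1.0)
                    ),
                    cad_fp_accept_prob=float(
                        np.clip(
                            m["cad_fp_accept_prob"] + h * rng.normal(0, 0.04), 0.0, 1.0
                        )
                    ),
                )
            )
            idx += 1
    return profiles
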