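"""Candidate detection and VOI classification for both tasks.

The pipeline mirrors a classical two-stage CAD design: isotropic
resampling (plus piecewise-linear intensity standardization for the brain
task), organ/vessel mask extraction, multiscale Laplacian-of-Gaussian blob
candidates, and a per-candidate VOI classifier trained with positive-VOI
augmentation and per-epoch negative undersampling to a 1:1 class ratio.

Three classifier kinds are available: ``cnn3d`` (small residual 3D
conv-net), ``cnn_mip`` (conv-net on the three orthogonal maximum-intensity
projections of the VOI: two conv, two pool, two fully connected layers,
logistic output) and ``linear_baseline`` (logistic model on intensity
statistics, the fast default for study-scale experiments).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import apply_hysteresis_threshold

from . import _nn
from .core import (
    Candidate,
    CaseRecord,
    SphericalROI,
    Task,
    Volume,
    read_volume,
    voxel_to_world,
    world_to_voxel,
)

__all__ = [
    "DetectorConfig",
    "TrainedDetector",
    "TrainingError",
    "preprocess",
    "extract_organ_mask",
    "extract_candidates",
    "label_candidates",
    "extract_voi",
    "augment_positive",
    "train",
    "run_cad",
    "PreppedCase",
    "prepare_case",
]


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class DetectorConfig:
    task: Task = Task.CHEST
    target_spacing_mm: float = 1.0  # brain published value: 0.469
    voi_edge: int = 32
    classifier: str = "cnn3d"  # cnn3d | cnn_mip | linear_baseline
    # optimisation (published chest values; override for desk scale)
    learning_rate: float = 1.0e-5
    momentum: float = 0.99
    weight_decay: float = 0.001
    batch_size: int = 8
    epochs: int = 20
    # augmentation
    shift_range: int = 4
    scale_range: tuple[float, float] = (0.85, 1.15)
    n_augment: int = 29
    # candidate extraction
    diameter_range_mm: tuple[float, float] = (3.0, 12.0)
    blob_threshold: float = 0.05
    max_candidates: int = 30
    hit_distance_mm: float = 3.0
    display_score_threshold: float = 0.5  # unspecified in the source protocol
    # cnn width/depth knobs
    cnn_width: int = 4
    cnn_blocks: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "task", Task(self.task))
        if self.voi_edge <= 2 * self.shift_range:
            raise ValueError("VOI edge must exceed twice the shift range")
        if self.scale_range[0] <= 0 or self.scale_range[1] < self.scale_range[0]:
            raise ValueError("scale range must be positive and ordered")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.classifier not in ("cnn3d", "cnn_mip", "linear_baseline"):
            raise ValueError(f"unknown classifier {self.classifier!r}")

    @classmethod
    def for_task(cls, task: Task | str, desk: bool = True, **overrides) -> "DetectorConfig":
        """Published defaults, or reduced desk-scale ones (small grids, CPU)."""
        task = Task(task)
        if desk:
            base = dict(
                task=task,
                target_spacing_mm=1.0,
                voi_edge=16,
                classifier="linear_baseline",
                learning_rate=0.05,
                epochs=10,
                diameter_range_mm=(3.0, 12.0) if task == Task.CHEST else (2.0, 8.0),
            )
        elif task == Task.CHEST:
            base = dict(
                task=task, target_spacing_mm=1.0, voi_edge=32,
                classifier="cnn3d", learning_rate=1.0e-5, epochs=500,
            )
        else:
            base = dict(
                task=task, target_spacing_mm=0.469, voi_edge=32,
                classifier="cnn_mip", learning_rate=1.0e-4, epochs=10,
                diameter_range_mm=(2.0, 8.0),
            )
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

_STANDARD_LANDMARKS = (0.0, 50.0, 98.0, 100.0)
_STANDARD_SCALE = (0.0, 0.2, 0.9, 1.0)


def preprocess(volume: Volume, config: DetectorConfig) -> Volume:
    """Resample to the target isotropic spacing (cubic interpolation); the
    brain task additionally maps intensity landmarks piecewise-linearly onto
    a fixed reference scale."""
    vox = np.asarray(volume.voxels, dtype=np.float64)
    spacing = volume.spacing
    target = config.target_spacing_mm
    if not np.allclose(spacing, target):
        factors = spacing / target
        vox = ndimage.zoom(vox, factors, order=3, mode="nearest")
        spacing = np.full(3, target)
    if config.task == Task.BRAIN:
        vmin, vmax = float(vox.min()), float(vox.max())
        if vmax - vmin < 1e-9:
            warnings.warn("constant volume: intensity standardization skipped")
        else:
            # landmarks are taken over foreground (vessel-bright) voxels so
            # the upper percentiles do not land inside background noise; the
            # cut uses the robust range midpoint because histogram-based
            # thresholds are unstable when vessels are <1% of the volume
            r_lo, r_hi = np.percentile(vox, [1, 99.99])
            fg = vox > r_lo + 0.5 * (r_hi - r_lo)
            sample = vox[fg] if fg.any() else vox.ravel()
            landmarks = np.percentile(sample, _STANDARD_LANDMARKS)
            if np.all(np.diff(landmarks) > 1e-12):
                vox = np.interp(vox, landmarks, _STANDARD_SCALE)
            else:
                warnings.warn("degenerate landmarks: standardization skipped")
    return Volume(
        voxels=vox.astype(np.float32),
        spacing=spacing,
        origin=volume.origin,
        task=volume.task,
    )


def extract_organ_mask(volume: Volume, config: DetectorConfig) -> np.ndarray:
    """Binary organ mask: chest — thresholded body envelope (largest
    connected component, closed, holes filled); brain — hysteresis-threshold
    vessel mask."""
    vox = np.asarray(volume.voxels, dtype=np.float64)
    # robust intensity range: vessels can occupy well under 1% of the volume,
    # so upper percentiles must sit at the very extreme
    p_lo, p_hi = np.percentile(vox, [1, 99.99])
    if p_hi - p_lo < 1e-9:
        return np.zeros(vox.shape, dtype=bool)
    if config.task == Task.CHEST:
        # separate air (near p_lo) from parenchyma; lesions/vessels sit far
        # above, so the cut stays low in the range
        rough = vox > p_lo + 0.15 * (p_hi - p_lo)
        labels, n = ndimage.label(rough)
        if n == 0:
            return np.zeros(vox.shape, dtype=bool)
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
        mask = ndimage.binary_closing(mask, structure=np.ones((3, 3, 3)), iterations=2)
        mask = ndimage.binary_fill_holes(mask)
        return mask
    high = p_lo + 0.5 * (p_hi - p_lo)
    low = p_lo + 0.25 * (p_hi - p_lo)
    return apply_hysteresis_threshold(vox, low, high).astype(bool)


# ---------------------------------------------------------------------------
# Candidate extraction (multiscale LoG blobness)
# ---------------------------------------------------------------------------

def extract_candidates(
    volume: Volume,
    mask: np.ndarray,
    config: DetectorConfig,
    case_id: str = "case",
) -> list[Candidate]:
    """Multiscale LoG blob detection inside the mask; one candidate per
    connected supra-threshold component at its blobness-weighted centre of
    gravity, with the blobness maximum as preliminary score."""
    if not mask.any():
        warnings.warn(f"{case_id}: empty organ mask, no candidates extracted")
        return []
    vox = np.asarray(volume.voxels, dtype=np.float64)
    d_lo, d_hi = config.diameter_range_mm
    s = float(volume.spacing[0])
    sigmas = np.geomspace(d_lo / (2 * math.sqrt(3)), d_hi / (2 * math.sqrt(3)), 4) / s
    blobness = np.full(vox.shape, -np.inf)
    best_sigma = np.zeros(vox.shape)
    for sigma in sigmas:
        resp = -(sigma**2) * ndimage.gaussian_laplace(vox, sigma)
        update = resp > blobness
        blobness[update] = resp[update]
        best_sigma[update] = sigma
    blobness[~mask] = -np.inf

    # local-maxima thresholding: keep supra-threshold voxels on local-maximum
    # plateaus, then group adjacent peak voxels into components
    peak_plateau = blobness >= ndimage.maximum_filter(blobness, size=3)
    above = (blobness > config.blob_threshold) & peak_plateau
    labels, n = ndimage.label(above)
    if n == 0:
        return []
    index = np.arange(1, n + 1)
    weights = np.where(above, blobness, 0.0)
    coms = ndimage.center_of_mass(weights, labels, index)
    peaks = ndimage.maximum(blobness, labels, index)
    peak_pos = ndimage.maximum_position(blobness, labels, index)
    cands: list[Candidate] = []
    for com, peak, pos in zip(coms, peaks, peak_pos):
        radius = float(best_sigma[tuple(pos)] * s * math.sqrt(3))
        cands.append(
            Candidate(
                case_id=case_id,
                centroid=tuple(voxel_to_world(volume, com)),
                score=float(peak),
                radius_mm=max(radius, 0.5),
            )
        )
    cands.sort(key=lambda c: -c.score)
    return cands[: config.max_candidates]


def label_candidates(
    candidates: Sequence[Candidate],
    annotations: Sequence[SphericalROI],
    hit_distance_mm: float = 3.0,
) -> np.ndarray:
    """Binary training labels: positive iff the candidate centroid lies
    within max(annotation radius, hit floor) of some annotated ROI."""
    labels = np.zeros(len(candidates), dtype=bool)
    for i, cand in enumerate(candidates):
        for roi in annotations:
            if cand.case_id != roi.case_id:
                raise ValueError(
                    f"candidate case {cand.case_id!r} != annotation case "
                    f"{roi.case_id!r}"
                )
            if roi.distance_to(cand.centroid) <= max(roi.radius, hit_distance_mm):
                labels[i] = True
                break
    return labels


# ---------------------------------------------------------------------------
# VOI extraction and augmentation
# ---------------------------------------------------------------------------

def extract_voi(
    volume: Volume,
    centroid_mm: Sequence[float],
    edge: int,
    shift_voxels: Sequence[int] = (0, 0, 0),
    scale: float = 1.0,
    rotations: Sequence[int] = (0, 0, 0),
) -> np.ndarray:
    """Cube of ``edge`` voxels around a world-mm point, half-open bounds.

    ``scale`` resamples a correspondingly larger/smaller window back to
    ``edge``; ``rotations`` are quarter-turn counts in the axial, coronal
    and sagittal planes.  Out-of-grid regions are edge-padded.
    """
    centre = np.round(world_to_voxel(volume, centroid_mm)).astype(int)
    centre = centre + np.asarray(shift_voxels, dtype=int)
    size = max(2, int(round(edge * scale)))
    half = size // 2
    lo = centre - half
    hi = lo + size
    pad_lo = np.maximum(-lo, 0)
    pad_hi = np.maximum(hi - np.asarray(volume.shape), 0)
    lo_c = np.maximum(lo, 0)
    hi_c = np.minimum(hi, volume.shape)
    block = np.asarray(
        volume.voxels[lo_c[0]:hi_c[0], lo_c[1]:hi_c[1], lo_c[2]:hi_c[2]],
        dtype=np.float64,
    )
    if pad_lo.any() or pad_hi.any():
        block = np.pad(
            block,
            [(pad_lo[a], pad_hi[a]) for a in range(3)],
            mode="edge",
        )
    if size != edge:
        block = ndimage.zoom(block, edge / size, order=1, mode="nearest")
        # zoom rounding can land one voxel off
        block = block[:edge, :edge, :edge]
        if block.shape != (edge, edge, edge):
            block = np.pad(
                block,
                [(0, edge - d) for d in block.shape],
                mode="edge",
            )
    k_ax, k_co, k_sa = rotations
    if k_ax % 4:
        block = np.rot90(block, k_ax, axes=(0, 1))
    if k_co % 4:
        block = np.rot90(block, k_co, axes=(0, 2))
    if k_sa % 4:
        block = np.rot90(block, k_sa, axes=(1, 2))
    return np.ascontiguousarray(block)


def augment_positive(
    volume: Volume,
    centroid_mm: Sequence[float],
    config: DetectorConfig,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Exactly ``n_augment`` (default 29) independently drawn augmented VOIs:
    integer shift in [-shift_range, +shift_range]^3, scale in scale_range,
    quarter-turn rotations in each of the three planes."""
    out = []
    r = config.shift_range
    s_lo, s_hi = config.scale_range
    for _ in range(config.n_augment):
        shift = rng.integers(-r, r + 1, size=3)
        scale = float(rng.uniform(s_lo, s_hi))
        rots = rng.integers(0, 4, size=3)
        out.append(
            extract_voi(volume, centroid_mm, config.voi_edge, shift, scale, rots)
        )
    return out


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

def _voi_features(voi: np.ndarray) -> np.ndarray:
    """Intensity-statistics features for the linear baseline."""
    e = voi.shape[0]
    c = e // 2
    q = max(1, e // 4)
    centre = voi[c - q : c + q, c - q : c + q, c - q : c + q]
    shell = voi.copy()
    shell[c - q : c + q, c - q : c + q, c - q : c + q] = np.nan
    shell_vals = shell[np.isfinite(shell)]
    return np.array(
        [
            voi.mean(),
            voi.std(),
            voi.max(),
            np.percentile(voi, 90),
            centre.mean(),
            centre.max(),
            centre.mean() - (shell_vals.mean() if len(shell_vals) else 0.0),
            centre.std(),
        ]
    )


def _mip_channels(voi: np.ndarray) -> np.ndarray:
    """Three orthogonal full-VOI maximum-intensity projections as channels."""
    return np.stack([voi.max(axis=0), voi.max(axis=1), voi.max(axis=2)])


class _ClassifierCore:
    """Shared interface: prepare raw VOIs into model input, score, fit-step."""

    kind: str

    def __init__(self, config: DetectorConfig, rng: np.random.Generator):
        self.config = config
        edge = config.voi_edge
        w = config.cnn_width
        if config.classifier == "linear_baseline":
            self.net = _nn.Sequential(_nn.Dense(8, 1, rng))
        elif config.classifier == "cnn3d":
            layers: list[_nn.Layer] = [
                _nn.ConvND(3, 1, w, 3, rng),
                _nn.ReLU(),
                _nn.MaxPoolND(3),
            ]
            for _ in range(config.cnn_blocks):
                layers.append(_nn.ResidualBlock(3, w, 3, rng))
            layers += [_nn.MaxPoolND(3), _nn.Flatten(),
                       _nn.Dense(w * (edge // 4) ** 3, 1, rng)]
            self.net = _nn.Sequential(*layers)
        else:  # cnn_mip: two conv, two pool, two fully connected
            w2 = max(w, 8)
            self.net = _nn.Sequential(
                _nn.ConvND(2, 3, w2, 3, rng),
                _nn.ReLU(),
                _nn.MaxPoolND(2),
                _nn.ConvND(2, w2, w2, 3, rng),
                _nn.ReLU(),
                _nn.MaxPoolND(2),
                _nn.Flatten(),
                _nn.Dense(w2 * (edge // 4) ** 2, 16, rng),
                _nn.ReLU(),
                _nn.Dense(16, 1, rng),
            )
        self.kind = config.classifier
        self.feat_mean: np.ndarray | None = None
        self.feat_sd: np.ndarray | None = None

    def prepare(self, vois: Sequence[np.ndarray]) -> np.ndarray:
        if not len(vois):
            return np.empty((0,))
        if self.kind == "linear_baseline":
            x = np.stack([_voi_features(v) for v in vois])
            if self.feat_mean is None:
                self.feat_mean = x.mean(axis=0)
                self.feat_sd = np.maximum(x.std(axis=0), 1e-9)
            return (x - self.feat_mean) / self.feat_sd
        if self.kind == "cnn3d":
            return np.stack(vois)[:, None, :, :, :]
        return np.stack([_mip_channels(v) for v in vois])

    def scores(self, x: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        if len(x) == 0:
            return np.empty(0)
        return expit(self.net.predict_logits(x))


@dataclass
class TrainedDetector:
    config: DetectorConfig
    core: _ClassifierCore
    provenance: dict = field(default_factory=dict)

    def score_vois(self, vois: Sequence[np.ndarray]) -> np.ndarray:
        if not len(vois):
            return np.empty(0)
        return self.core.scores(self.core.prepare(vois))


# ---------------------------------------------------------------------------
# Per-case pipeline cache
# ---------------------------------------------------------------------------

@dataclass
class PreppedCase:
    case_id: str
    volume: Volume  # preprocessed
    mask_nonempty: bool
    candidates: list[Candidate]


VolumeSource = Mapping[str, Volume]


def _get_volume(volumes: VolumeSource | None, case: CaseRecord) -> Volume:
    if volumes is not None and case.case_id in volumes:
        return volumes[case.case_id]
    if case.volume_path is None:
        raise ValueError(f"no volume available for case {case.case_id!r}")
    return read_volume(case.volume_path)


def prepare_case(
    case: CaseRecord,
    config: DetectorConfig,
    volumes: VolumeSource | None = None,
) -> PreppedCase:
    vol = _get_volume(volumes, case)
    pvol = preprocess(vol, config)
    mask = extract_organ_mask(pvol, config)
    cands = (
        extract_candidates(pvol, mask, config, case.case_id) if mask.any() else []
    )
    return PreppedCase(
        case_id=case.case_id,
        volume=pvol,
        mask_nonempty=bool(mask.any()),
        candidates=cands,
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(
    config: DetectorConfig,
    cases: Sequence[CaseRecord],
    annotations_by_case: Mapping[str, Sequence[SphericalROI]],
    volumes: VolumeSource | None = None,
    seed: int = 0,
    pipeline_cache: Mapping[str, PreppedCase] | None = None,
    epoch_hook: Callable[[int, int, int], None] | None = None,
) -> TrainedDetector:
    """Fit the configured VOI classifier on candidate-level labels.

    Per epoch, positive VOIs are re-augmented (originals + ``n_augment``
    fresh copies each) and negatives re-undersampled to an equal count.
    ``epoch_hook(epoch, n_pos, n_neg)`` is called after balancing, for audit.
    """
    positives: list[tuple[Volume, tuple[float, float, float]]] = []
    negatives: list[tuple[Volume, tuple[float, float, float]]] = []
    train_case_ids = []
    for case in cases:
        prepped = (
            pipeline_cache.get(case.case_id)
            if pipeline_cache is not None
            else None
        )
        if prepped is None:
            prepped = prepare_case(case, config, volumes)
        labels = label_candidates(
            prepped.candidates,
            annotations_by_case.get(case.case_id, []),
            config.hit_distance_mm,
        )
        for cand, lab in zip(prepped.candidates, labels):
            (positives if lab else negatives).append((prepped.volume, cand.centroid))
        train_case_ids.append(case.case_id)

    if not positives:
        raise TrainingError("training set has no positive candidates")
    if not negatives:
        raise TrainingError("training set has no negative candidates")

    ss = np.random.SeedSequence([int(seed) & 0xFFFFFFFF, 0x5EED])
    init_ss, epoch_ss = ss.spawn(2)
    core = _ClassifierCore(config, np.random.default_rng(init_ss))
    opt = _nn.MomentumSGD(
        core.net.params(),
        lr=config.learning_rate,
        momentum=config.momentum,
        weight_decay=config.weight_decay,
    )

    edge = config.voi_edge
    base_pos = [extract_voi(vol, c, edge) for vol, c in positives]
    neg_vois = [extract_voi(vol, c, edge) for vol, c in negatives]

    for epoch, ep_ss in enumerate(epoch_ss.spawn(config.epochs)):
        rng = np.random.default_rng(ep_ss)
        pos_epoch = list(base_pos)
        for vol, centroid in positives:
            pos_epoch.extend(augment_positive(vol, centroid, config, rng))
        n_pos = len(pos_epoch)
        idx = rng.choice(len(neg_vois), size=n_pos, replace=len(neg_vois) < n_pos)
        neg_epoch = [neg_vois[i] for i in idx]
        if epoch_hook is not None:
            epoch_hook(epoch, n_pos, len(neg_epoch))

        x = core.prepare(pos_epoch + neg_epoch)
        y = np.concatenate([np.ones(n_pos), np.zeros(len(neg_epoch))])
        order = rng.permutation(len(y))
        x, y = x[order], y[order]
        for start in range(0, len(y), config.batch_size):
            xb = x[start : start + config.batch_size]
            yb = y[start : start + config.batch_size]
            logits = core.net.forward(xb).reshape(-1)
            _, grad = _nn.bce_with_logits(logits, yb)
            core.net.backward(grad.reshape(-1, 1))
            opt.step()

    return TrainedDetector(
        config=config,
        core=core,
        provenance={
            "training_cases": sorted(train_case_ids),
            "annotation_sources": sorted(annotations_by_case),
            "seed": int(seed),
            "n_positive_candidates": len(positives),
            "n_negative_candidates": len(negatives),
        },
    )


# ---------------------------------------------------------------------------
# Whole-volume inference
# ---------------------------------------------------------------------------

def run_cad(
    detector: TrainedDetector,
    volume: Volume,
    case_id: str = "case",
    prepped: PreppedCase | None = None,
) -> list[Candidate]:
    """Score every blob candidate in a volume; descending classifier score."""
    config = detector.config
    if prepped is None:
        pvol = preprocess(volume, config)
        mask = extract_organ_mask(pvol, config)
        if not mask.any():
            warnings.warn(f"{case_id}: empty organ mask, skipping detection")
            return []
        cands = extract_candidates(pvol, mask, config, case_id)
    else:
        pvol = prepped.volume
        cands = [replace(c, case_id=case_id) for c in prepped.candidates]
    if not cands:
        return []
    vois = [extract_voi(pvol, c.centroid, config.voi_edge) for c in cands]
    scores = detector.score_vois(vois)
    out = [replace(c, score=float(s)) for c, s in zip(cands, scores)]
    out.sort(key=lambda c: -c.score)
    return out
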