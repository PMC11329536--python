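"""Domain types, coordinate conventions, and volume/annotation I/O.

All geometry is expressed in world millimetres with axis order (x, y, z).
Voxel indices are 0-based; the continuous mapping between the two frames is

    world = origin + index * spacing

Volume-of-interest bounds are half-open.  No module outside this one may
interpret raw voxel indices as distances.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "Task",
    "Subset",
    "RoiTag",
    "Volume",
    "SphericalROI",
    "AnnotationSet",
    "Candidate",
    "CaseRecord",
    "DatasetManifest",
    "FormatError",
    "SchemaError",
    "read_volume",
    "write_volume",
    "read_annotations",
    "write_annotations",
    "read_annotations_csv",
    "write_annotations_csv",
    "read_manifest",
    "write_manifest",
    "world_to_voxel",
    "voxel_to_world",
]


class Task(str, Enum):
    CHEST = "chest"
    BRAIN = "brain"


class Subset(str, Enum):
    INITIAL = "initial"
    RETRAINING1 = "retraining1"
    RETRAINING2 = "retraining2"
    TEST = "test"


class RoiTag(str, Enum):
    LESION = "lesion"
    DISTRACTOR = "distractor"
    UNKNOWN = "unknown"


class FormatError(ValueError):
    """Raised when a volume file violates the expected format."""


class SchemaError(ValueError):
    """Raised when an annotation or manifest record violates the schema."""


@dataclass
class Volume:
    """A 3D scalar image with world geometry.

    ``voxels`` is indexed ``[x, y, z]``; ``spacing`` and ``origin`` are
    mm 3-vectors matching that axis order.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    task: Task | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise FormatError(
                f"volume grid must be non-empty 3D, got shape {self.voxels.shape}"
            )
        if self.spacing.shape != (3,) or not np.all(self.spacing > 0):
            raise FormatError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.origin.shape != (3,):
            raise FormatError(f"origin must be a 3-vector, got {self.origin}")
        if not np.all(np.isfinite(self.voxels)):
            raise FormatError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class SphericalROI:
    """One spherical annotation: centroid + diameter in world mm."""

    case_id: str
    centroid: tuple[float, float, float]
    diameter: float
    annotator_id: str
    tag: RoiTag = RoiTag.UNKNOWN

    def __post_init__(self) -> None:
        object.__setattr__(self, "centroid", tuple(float(c) for c in self.centroid))
        object.__setattr__(self, "diameter", float(self.diameter))
        object.__setattr__(self, "tag", RoiTag(self.tag))
        if self.diameter <= 0:
            raise ValueError(f"ROI diameter must be > 0, got {self.diameter}")
        if not all(math.isfinite(c) for c in self.centroid):
            raise ValueError(f"ROI centroid must be finite, got {self.centroid}")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def distance_to(self, point: Sequence[float]) -> float:
        return float(
            math.dist(self.centroid, tuple(float(p) for p in point))
        )


@dataclass
class AnnotationSet:
    """All ROIs from one annotator, grouped by case."""

    annotator_id: str
    rois: dict[str, list[SphericalROI]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for case_id, case_rois in self.rois.items():
            for roi in case_rois:
                if roi.annotator_id != self.annotator_id:
                    raise ValueError(
                        f"ROI annotator {roi.annotator_id!r} does not match "
                        f"set annotator {self.annotator_id!r}"
                    )
                if roi.case_id != case_id:
                    raise ValueError(
                        f"ROI case {roi.case_id!r} filed under {case_id!r}"
                    )

    def add(self, roi: SphericalROI) -> None:
        if roi.annotator_id != self.annotator_id:
            raise ValueError(
                f"ROI annotator {roi.annotator_id!r} does not match set "
                f"annotator {self.annotator_id!r}"
            )
        self.rois.setdefault(roi.case_id, []).append(roi)

    def all_rois(self) -> list[SphericalROI]:
        return [roi for rois in self.rois.values() for roi in rois]

    def n_rois(self) -> int:
        return sum(len(v) for v in self.rois.values())


@dataclass(frozen=True)
class Candidate:
    """A detector output: world-mm centroid plus a real-valued score.

    Higher score means more lesion-like.
    """

    case_id: str
    centroid: tuple[float, float, float]
    score: float
    radius_mm: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "centroid", tuple(float(c) for c in self.centroid))
        object.__setattr__(self, "score", float(self.score))
        if not math.isfinite(self.score):
            raise ValueError(f"candidate score must be finite, got {self.score}")
        if self.radius_mm is not None and self.radius_mm <= 0:
            raise ValueError(f"candidate radius must be > 0, got {self.radius_mm}")


@dataclass
class CaseRecord:
    case_id: str
    subset: Subset
    is_positive: bool
    ground_truth: list[SphericalROI] = field(default_factory=list)
    volume_path: str | None = None

    def __post_init__(self) -> None:
        self.subset = Subset(self.subset)
        n_lesions = sum(1 for r in self.ground_truth if r.tag == RoiTag.LESION)
        if self.is_positive and n_lesions < 1:
            raise ValueError(
                f"positive case {self.case_id!r} has no lesion-tagged ground truth"
            )
        if not self.is_positive and n_lesions > 0:
            raise ValueError(
                f"negative case {self.case_id!r} has lesion-tagged ground truth"
            )

    @property
    def lesions(self) -> list[SphericalROI]:
        return [r for r in self.ground_truth if r.tag == RoiTag.LESION]

    @property
    def distractors(self) -> list[SphericalROI]:
        return [r for r in self.ground_truth if r.tag == RoiTag.DISTRACTOR]


@dataclass
class DatasetManifest:
    task: Task
    cases: list[CaseRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        ids = [c.case_id for c in self.cases]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate case ids in manifest")

    def subset(self, which: Subset | str) -> list[CaseRecord]:
        which = Subset(which)
        return [c for c in self.cases if c.subset == which]

    def counts(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for s in Subset:
            cases = self.subset(s)
            out[s.value] = {
                "positive": sum(c.is_positive for c in cases),
                "negative": sum(not c.is_positive for c in cases),
                "total": len(cases),
            }
        return out

    def case(self, case_id: str) -> CaseRecord:
        for c in self.cases:
            if c.case_id == case_id:
                return c
        raise KeyError(case_id)


# ---------------------------------------------------------------------------
# Coordinate transforms
# ---------------------------------------------------------------------------

def world_to_voxel(volume: Volume, point_mm: Sequence[float]) -> np.ndarray:
    """Continuous 0-based voxel index of a world-mm point.

    Rounding to an integer index is the caller's business.  Out-of-grid
    points come back with out-of-range indices; callers clip.
    """
    point = np.asarray(point_mm, dtype=float)
    return (point - volume.origin) / volume.spacing


def voxel_to_world(volume: Volume, index: Sequence[float]) -> np.ndarray:
    """World-mm position of a (possibly fractional) 0-based voxel index."""
    idx = np.asarray(index, dtype=float)
    return volume.origin + idx * volume.spacing


# ---------------------------------------------------------------------------
# Volume I/O (NIfTI-1)
# ---------------------------------------------------------------------------

def write_volume(volume: Volume, path: str | Path) -> None:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = volume.spacing
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float32), affine)
    img.header.set_zooms(tuple(volume.spacing))
    nib.save(img, str(path))


def read_volume(path: str | Path, task: Task | str | None = None) -> Volume:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several distinct types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(
            f"{path}: header field 'dim' describes a {data.ndim}D grid; expected 3D"
        )
    affine = img.affine
    spacing = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    if not np.all(spacing > 0):
        raise FormatError(f"{path}: header field 'pixdim' has non-positive spacing")
    origin = affine[:3, 3].astype(float)
    return Volume(
        voxels=data.astype(np.float32),
        spacing=spacing,
        origin=origin,
        task=Task(task) if task is not None else None,
    )


# ---------------------------------------------------------------------------
# Annotation I/O (JSON dialect + flat CSV)
# ---------------------------------------------------------------------------

_ANNOTATION_FIELDS = ("annotator_id", "case_id", "centroid_mm", "diameter_mm", "tag")


def _roi_to_record(roi: SphericalROI) -> dict:
    return {
        "annotator_id": roi.annotator_id,
        "case_id": roi.case_id,
        "centroid_mm": [round(float(c), 6) for c in roi.centroid],
        "diameter_mm": round(float(roi.diameter), 6),
        "tag": roi.tag.value,
    }


def _record_to_roi(rec: Mapping, index: int) -> SphericalROI:
    for key in _ANNOTATION_FIELDS:
        if key not in rec:
            raise SchemaError(f"annotation record {index}: missing field {key!r}")
    centroid = rec["centroid_mm"]
    if not isinstance(centroid, (list, tuple)) or len(centroid) != 3:
        raise SchemaError(
            f"annotation record {index}: centroid_mm must be a 3-element list"
        )
    return SphericalROI(
        case_id=str(rec["case_id"]),
        centroid=tuple(float(c) for c in centroid),
        diameter=float(rec["diameter_mm"]),
        annotator_id=str(rec["annotator_id"]),
        tag=RoiTag(rec["tag"]),
    )


def _group_by_annotator(rois: Iterable[SphericalROI]) -> list[AnnotationSet]:
    by_ann: dict[str, AnnotationSet] = {}
    for roi in rois:
        if roi.annotator_id not in by_ann:
            by_ann[roi.annotator_id] = AnnotationSet(annotator_id=roi.annotator_id)
        by_ann[roi.annotator_id].add(roi)
    return [by_ann[k] for k in sorted(by_ann)]


def write_annotations(sets: Sequence[AnnotationSet], path: str | Path) -> None:
    records = []
    for ann_set in sets:
        for case_id in sorted(ann_set.rois):
            for roi in ann_set.rois[case_id]:
                records.append(_roi_to_record(roi))
    Path(path).write_text(json.dumps(records, indent=1) + "\n")


def read_annotations(path: str | Path) -> list[AnnotationSet]:
    try:
        records = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(records, list):
        raise SchemaError(f"{path}: top level must be a list of annotation records")
    rois = [_record_to_roi(rec, i) for i, rec in enumerate(records)]
    return _group_by_annotator(rois)


def write_annotations_csv(sets: Sequence[AnnotationSet], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["annotator_id", "case_id", "x_mm", "y_mm", "z_mm", "diameter_mm", "tag"]
        )
        for ann_set in sets:
            for case_id in sorted(ann_set.rois):
                for roi in ann_set.rois[case_id]:
                    writer.writerow(
                        [
                            roi.annotator_id,
                            roi.case_id,
                            f"{roi.centroid[0]:.6f}",
                            f"{roi.centroid[1]:.6f}",
                            f"{roi.centroid[2]:.6f}",
                            f"{roi.diameter:.6f}",
                            roi.tag.value,
                        ]
                    )


def read_annotations_csv(path: str | Path) -> list[AnnotationSet]:
    rois: list[SphericalROI] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader):
            try:
                rois.append(
                    SphericalROI(
                        case_id=row["case_id"],
                        centroid=(
                            float(row["x_mm"]),
                            float(row["y_mm"]),
                            float(row["z_mm"]),
                        ),
                        diameter=float(row["diameter_mm"]),
                        annotator_id=row["annotator_id"],
                        tag=RoiTag(row.get("tag", "unknown")),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise SchemaError(f"{path}: record {i}: {exc}") from exc
    return _group_by_annotator(rois)


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------

def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    payload = {
        "task": manifest.task.value,
        "cases": [
            {
                "case_id": c.case_id,
                "subset": c.subset.value,
                "is_positive": c.is_positive,
                "volume_path": c.volume_path,
                "ground_truth": [_roi_to_record(r) for r in c.ground_truth],
            }
            for c in manifest.cases
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_manifest(path: str | Path) -> DatasetManifest:
    payload = json.loads(Path(path).read_text())
    if "task" not in payload or "cases" not in payload:
        raise SchemaError(f"{path}: manifest requires 'task' and 'cases'")
    cases = []
    for i, rec in enumerate(payload["cases"]):
        try:
            cases.append(
                CaseRecord(
                    case_id=rec["case_id"],
                    subset=Subset(rec["subset"]),
                    is_positive=bool(rec["is_positive"]),
                    volume_path=rec.get("volume_path"),
                    ground_truth=[
                        _record_to_roi(r, j)
                        for j, r in enumerate(rec.get("ground_truth", []))
                    ],
                )
            )
        except (KeyError, ValueError) as exc:
            raise SchemaError(f"{path}: case record {i}: {exc}") from exc
    return DatasetManifest(task=Task(payload["task"]), cases=cases)
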