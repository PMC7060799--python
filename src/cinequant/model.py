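"""Core data types and geometry for segmented cine CMR exams.

An exam ("study") bundles one short-axis (SAX) multi-slice label stack with
two single-slice long-axis (LAX) views (2-chamber and 4-chamber), all
segmented over a full cardiac cycle.  Label grids are indexed
``(row, col, slice, frame)`` and carry a 4x4 voxel->world affine in mm.

Label convention (fixed; a remapping table in the sidecar can adapt foreign
bundles):

====  =====================
0     background
1     LV blood pool
2     LV myocardium
3     RV blood pool
====  =====================

Times are in seconds, world coordinates in mm, voxel indices 0-based.
Frame 0 is the end-diastolic trigger and the frames span one closed cycle.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

BACKGROUND = 0
LV_POOL = 1
LV_MYO = 2
RV_POOL = 3
VALID_LABELS = (BACKGROUND, LV_POOL, LV_MYO, RV_POOL)

#: labels that belong to the left ventricle (pool + myocardium)
LV_LABELS = (LV_POOL, LV_MYO)


class View(str, Enum):
    SAX = "SAX"
    LAX2CH = "LAX2CH"
    LAX4CH = "LAX4CH"


@dataclass
class SubjectMeta:
    """Demographics needed for indexing and stratified statistics."""

    sex: str = "unknown"  # "M" | "F" | "unknown"
    age: float = float("nan")  # years
    height: float = float("nan")  # cm
    weight: float = float("nan")  # kg
    rr_interval: float = 1.0  # s

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "age": self.age,
            "height_cm": self.height,
            "weight_kg": self.weight,
        }

    @classmethod
    def from_dict(cls, d: dict, rr_interval: float = 1.0) -> "SubjectMeta":
        return cls(
            sex=d.get("sex", "unknown"),
            age=float(d.get("age", float("nan"))),
            height=float(d.get("height_cm", float("nan"))),
            weight=float(d.get("weight_kg", float("nan"))),
            rr_interval=rr_interval,
        )


def _validate_labels(labels: np.ndarray) -> None:
    if labels.ndim != 4:
        raise ValueError(f"label grid must be 4-D (row, col, slice, frame); got {labels.ndim}-D")
    counts = np.bincount(labels.ravel().astype(np.int64), minlength=max(VALID_LABELS) + 1)
    bad = {v: int(c) for v, c in enumerate(counts) if c and v not in VALID_LABELS}
    if labels.min() < 0:
        neg, cnt = np.unique(labels[labels < 0], return_counts=True)
        bad.update({int(v): int(c) for v, c in zip(neg, cnt)})
    if bad:
        detail = ", ".join(f"label {v}: {c} voxels" for v, c in sorted(bad.items()))
        raise ValueError(f"unknown label value(s) in stack ({detail})")


@dataclass
class LabelledStack:
    """A 4-D label grid with geometry and cardiac timing metadata."""

    labels: np.ndarray  # (rows, cols, slices, frames), small ints
    affine: np.ndarray  # 4x4 voxel -> world (mm)
    voxel_size: tuple[float, float]  # (dr, dc) mm
    slice_thickness: float  # mm
    slice_gap: float  # mm
    frame_times: np.ndarray  # s, length n_frames, starting at 0
    view: View

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        _validate_labels(self.labels)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is singular")
        if len(self.frame_times) != self.labels.shape[3]:
            raise ValueError("frame_times length must equal number of frames")
        if self.frame_times[0] != 0 or np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing and start at 0")
        if self.view is not View.SAX and self.n_slices != 1:
            raise ValueError(f"{self.view.value} stacks must have exactly 1 slice")

    # -- basic shape accessors -------------------------------------------------
    @property
    def n_slices(self) -> int:
        return self.labels.shape[2]

    @property
    def n_frames(self) -> int:
        return self.labels.shape[3]

    @property
    def slice_spacing(self) -> float:
        """Centre-to-centre inter-slice distance in mm."""
        return self.slice_thickness + self.slice_gap

    def copy(self) -> "LabelledStack":
        return LabelledStack(
            labels=self.labels.copy(),
            affine=self.affine.copy(),
            voxel_size=tuple(self.voxel_size),
            slice_thickness=self.slice_thickness,
            slice_gap=self.slice_gap,
            frame_times=self.frame_times.copy(),
            view=self.view,
        )


@dataclass
class CineStudy:
    """One exam: SAX stack, both LAX views, optional images, subject metadata."""

    sax: LabelledStack
    lax2ch: LabelledStack
    lax4ch: LabelledStack
    subject: SubjectMeta = field(default_factory=SubjectMeta)
    images: Optional[dict] = None  # view name -> float array mirroring labels
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        nf = {v.view.value: v.n_frames for v in self.stacks()}
        if len(set(nf.values())) != 1:
            raise ValueError(f"all views must share n_frames, got {nf}")
        # resample LAX timing onto the SAX frame grid if they disagree > 1 ms
        for stk in (self.lax2ch, self.lax4ch):
            if np.max(np.abs(stk.frame_times - self.sax.frame_times)) > 1e-3:
                stk.frame_times = self.sax.frame_times.copy()

    def stacks(self) -> tuple[LabelledStack, LabelledStack, LabelledStack]:
        return (self.sax, self.lax2ch, self.lax4ch)

    def stack(self, view: View) -> LabelledStack:
        return {View.SAX: self.sax, View.LAX2CH: self.lax2ch, View.LAX4CH: self.lax4ch}[view]

    @property
    def n_frames(self) -> int:
        return self.sax.n_frames

    def copy(self) -> "CineStudy":
        return CineStudy(
            sax=self.sax.copy(),
            lax2ch=self.lax2ch.copy(),
            lax4ch=self.lax4ch.copy(),
            subject=copy.deepcopy(self.subject),
            images={k: v.copy() for k, v in self.images.items()} if self.images else None,
            provenance=copy.deepcopy(self.provenance),
        )


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def world_coords(stack: LabelledStack, voxel_index) -> np.ndarray:
    """Map (row, col, slice) voxel indices to world mm via the stack affine.

    Accepts a single index triple or an (N, 3) array; fractional indices are
    allowed as long as they stay inside the grid.
    """
    idx = np.atleast_2d(np.asarray(voxel_index, dtype=float))
    if idx.shape[-1] != 3:
        raise ValueError("voxel_index must have 3 components (row, col, slice)")
    dims = np.array(stack.labels.shape[:3], dtype=float)
    if np.any(idx < -0.5) or np.any(idx > dims - 0.5):
        raise IndexError(f"voxel index out of bounds for grid {stack.labels.shape[:3]}")
    homog = np.concatenate([idx, np.ones((len(idx), 1))], axis=1)
    pts = (stack.affine @ homog.T).T[:, :3]
    return pts[0] if np.asarray(voxel_index).ndim == 1 else pts


def voxel_coords(stack: LabelledStack, world_points) -> np.ndarray:
    """Inverse of :func:`world_coords` (no bounds check; continuous indices)."""
    pts = np.atleast_2d(np.asarray(world_points, dtype=float))
    inv = np.linalg.inv(stack.affine)
    homog = np.concatenate([pts, np.ones((len(pts), 1))], axis=1)
    idx = (inv @ homog.T).T[:, :3]
    return idx[0] if np.asarray(world_points).ndim == 1 else idx


def plane_of(stack: LabelledStack, slice_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (origin, unit normal) of a slice plane.

    The normal is the unit cross product of the in-plane affine axes,
    oriented along the slice axis (for skewed affines the slice axis itself
    need not be perpendicular to the plane).
    """
    if not 0 <= slice_index < stack.n_slices:
        raise IndexError(f"slice {slice_index} out of range (n_slices={stack.n_slices})")
    normal = np.cross(stack.affine[:3, 0], stack.affine[:3, 1])
    normal = normal / np.linalg.norm(normal)
    if np.dot(normal, stack.affine[:3, 2]) < 0:
        normal = -normal
    origin = world_coords(stack, (0, 0, slice_index))
    return origin, normal


@dataclass
class SliceFOV:
    """In-plane rectangular field of view of one slice, in world coordinates."""

    corner: np.ndarray  # world position of the (-0.5, -0.5) voxel corner
    u: np.ndarray  # unit vector along rows
    v: np.ndarray  # unit vector along cols
    width: float  # mm along u
    height: float  # mm along v


def slice_fov(stack: LabelledStack, slice_index: int) -> SliceFOV:
    a = stack.affine
    eu, ev = a[:3, 0], a[:3, 1]
    du, dv = np.linalg.norm(eu), np.linalg.norm(ev)
    nr, nc = stack.labels.shape[:2]
    origin = world_coords(stack, (0, 0, slice_index))
    corner = origin - 0.5 * eu - 0.5 * ev
    return SliceFOV(corner=corner, u=eu / du, v=ev / dv, width=nr * du, height=nc * dv)


@dataclass
class PlaneIntersection:
    """Line where two finite image planes cross, clipped to both fields of view."""

    line_origin: np.ndarray
    line_direction: np.ndarray  # unit
    sample_points: np.ndarray  # (n, 3) world, ordered along the line


def _fov_interval(fov: SliceFOV, p0: np.ndarray, d: np.ndarray) -> Optional[tuple[float, float]]:
    """Parameter interval of the line p0 + t d inside a rectangular FOV."""
    lo, hi = -np.inf, np.inf
    for axis, extent in ((fov.u, fov.width), (fov.v, fov.height)):
        num0 = np.dot(p0 - fov.corner, axis)
        rate = np.dot(d, axis)
        if abs(rate) < 1e-12:
            if not (0.0 <= num0 <= extent):
                return None
            continue
        t0, t1 = (0.0 - num0) / rate, (extent - num0) / rate
        lo, hi = max(lo, min(t0, t1)), min(hi, max(t0, t1))
    if lo >= hi:
        return None
    return lo, hi


def intersect_planes(
    plane_a: tuple[np.ndarray, np.ndarray],
    plane_b: tuple[np.ndarray, np.ndarray],
    fov_a: Optional[SliceFOV] = None,
    fov_b: Optional[SliceFOV] = None,
    n_samples: int = 64,
) -> Optional[PlaneIntersection]:
    """Intersect two planes; ``None`` if parallel or outside either FOV."""
    (oa, na), (ob, nb) = plane_a, plane_b
    na = np.asarray(na) / np.linalg.norm(na)
    nb = np.asarray(nb) / np.linalg.norm(nb)
    d = np.cross(na, nb)
    norm_d = np.linalg.norm(d)
    if norm_d < 1e-8:
        return None
    d = d / norm_d
    # point on the line: solve the two plane equations plus d.p = d.oa
    A = np.stack([na, nb, d])
    rhs = np.array([np.dot(na, oa), np.dot(nb, ob), np.dot(d, oa)])
    p0 = np.linalg.solve(A, rhs)

    lo, hi = -1e6, 1e6
    for fov in (fov_a, fov_b):
        if fov is None:
            continue
        iv = _fov_interval(fov, p0, d)
        if iv is None:
            return None
        lo, hi = max(lo, iv[0]), min(hi, iv[1])
    if lo >= hi:
        return None
    ts = np.linspace(lo, hi, n_samples)
    pts = p0[None, :] + ts[:, None] * d[None, :]
    return PlaneIntersection(line_origin=p0, line_direction=d, sample_points=pts)


# ---------------------------------------------------------------------------
# bundle IO (NIfTI volumes + JSON sidecar)
# ---------------------------------------------------------------------------

_VIEW_FILES = {View.SAX: "sax", View.LAX2CH: "lax2ch", View.LAX4CH: "lax4ch"}


def write_study(study: CineStudy, bundle_dir) -> Path:
    """Write a study as NIfTI label volumes plus a ``study.json`` sidecar."""
    out = Path(bundle_dir)
    out.mkdir(parents=True, exist_ok=True)
    sidecar: dict = {
        "rr_interval_s": study.subject.rr_interval,
        "subject": study.subject.to_dict(),
        "views": {},
    }
    for stk in study.stacks():
        name = _VIEW_FILES[stk.view]
        img = nib.Nifti1Image(stk.labels.astype(np.uint8), stk.affine)
        nib.save(img, out / f"{name}.nii.gz")
        entry = {
            "file": f"{name}.nii.gz",
            "voxel_size_mm": list(stk.voxel_size),
            "slice_thickness_mm": stk.slice_thickness,
            "slice_gap_mm": stk.slice_gap,
            "trigger_times_s": [float(t) for t in stk.frame_times],
        }
        if study.images and stk.view.value in study.images:
            iname = f"{name}_img.nii.gz"
            nib.save(
                nib.Nifti1Image(study.images[stk.view.value].astype(np.float32), stk.affine),
                out / iname,
            )
            entry["image_file"] = iname
        sidecar["views"][stk.view.value] = entry
    with open(out / "study.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return out


def read_study(bundle_dir) -> CineStudy:
    """Read a bundle directory written by :func:`write_study` (or compatible)."""
    bundle = Path(bundle_dir)
    sidecar_path = bundle / "study.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"no study.json sidecar in {bundle}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    rr = float(sidecar.get("rr_interval_s", 1.0))
    label_map = {int(k): int(v) for k, v in sidecar.get("label_map", {}).items()}

    stacks: dict[View, LabelledStack] = {}
    images: dict[str, np.ndarray] = {}
    for view in View:
        entry = sidecar.get("views", {}).get(view.value)
        if entry is None:
            raise ValueError(f"missing view {view.value}")
        path = bundle / entry["file"]
        if not path.exists():
            raise ValueError(f"missing view {view.value}: file {path.name} not found")
        img = nib.load(str(path))
        labels = np.asarray(img.dataobj).astype(np.uint8)
        if labels.ndim == 3:
            labels = labels[..., None]
        if label_map:
            remapped = np.zeros_like(labels)
            for src, dst in label_map.items():
                remapped[labels == src] = dst
            labels = remapped
        n_frames = labels.shape[3]
        times = entry.get("trigger_times_s")
        if times is None:
            times = [k * rr / n_frames for k in range(n_frames)]
        stacks[view] = LabelledStack(
            labels=labels,
            affine=np.asarray(img.affine, dtype=float),
            voxel_size=tuple(entry.get("voxel_size_mm", (1.0, 1.0))),
            slice_thickness=float(entry.get("slice_thickness_mm", 1.0)),
            slice_gap=float(entry.get("slice_gap_mm", 0.0)),
            frame_times=np.asarray(times, dtype=float),
            view=view,
        )
        if "image_file" in entry and (bundle / entry["image_file"]).exists():
            images[view.value] = np.asarray(
                nib.load(str(bundle / entry["image_file"])).dataobj
            ).astype(np.float32)

    subject = SubjectMeta.from_dict(sidecar.get("subject", {}), rr_interval=rr)
    return CineStudy(
        sax=stacks[View.SAX],
        lax2ch=stacks[View.LAX2CH],
        lax4ch=stacks[View.LAX4CH],
        subject=subject,
        images=images or None,
    )
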