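"""Iterative SAX-LAX alignment correcting per-slice breath-hold offsets.

Each SAX slice (and each LAX view) may carry a constant in-plane
translation from inconsistent breath-holds between cine acquisitions.  The
correction uses only the end-diastolic frame: along the intersection line
of a SAX slice plane with each LAX plane, label-boundary crossings seen in
the SAX slice should coincide with those seen in the LAX image.  The
mismatch score is the mean absolute distance between matched crossings.

Because an in-plane translation of a slice moves its crossings along the
intersection line by exactly the translation's component in the line
direction, each iteration solves the per-slice shift in closed form: the
mean crossing offset along each of the two LAX intersection lines gives a
small least-squares system for the 2-D in-plane shift.  A LAX-refinement
pass then does the same for each LAX view against all slices (its
component along the stack normal is unobservable from crossings and is
left at zero), and the two passes repeat until the largest update falls
below tolerance.

Only in-plane translation is modelled (no rotation or out-of-plane
motion): the dominant breath-hold error mode.  Shifts estimated at ED are
applied to all frames of the acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .model import (
    LV_LABELS,
    RV_POOL,
    CineStudy,
    LabelledStack,
    View,
    intersect_planes,
    plane_of,
    slice_fov,
)

_SAMPLE_STEP_MM = 0.25
_STRUCTURES = ("LV", "RV")


@dataclass
class AlignmentResult:
    """Estimated breath-hold displacements (mm along each stack's row/col
    axes); the applied correction is their negation."""

    per_slice_shift: np.ndarray  # (n_sax_slices, 2)
    lax_shift: dict  # view name -> (2,)
    n_iterations: int
    converged: bool
    residual: float  # mm, final mean mismatch over measurable slices
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_slice_shift_mm": self.per_slice_shift.tolist(),
            "lax_shift_mm": {k: [float(x) for x in v] for k, v in self.lax_shift.items()},
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "residual_mm": float(self.residual),
            "warnings": list(self.warnings),
        }


class _MaskSampler:
    """Bilinear sampler of ED-frame binary masks of one stack, in world mm."""

    def __init__(self, stack: LabelledStack, frame: int = 0):
        self.stack = stack
        lab = stack.labels[:, :, :, frame]
        self.masks = {
            "LV": np.isin(lab, LV_LABELS).astype(float),
            "RV": (lab == RV_POOL).astype(float),
        }
        self.inv = np.linalg.inv(stack.affine)
        self.e_row = stack.affine[:3, 0] / np.linalg.norm(stack.affine[:3, 0])
        self.e_col = stack.affine[:3, 1] / np.linalg.norm(stack.affine[:3, 1])

    def shift_world(self, shift_rc) -> np.ndarray:
        return shift_rc[0] * self.e_row + shift_rc[1] * self.e_col

    def profile(
        self,
        structure: str,
        points: np.ndarray,
        shift_rc=(0.0, 0.0),
        slice_index: Optional[int] = None,
    ) -> np.ndarray:
        """Mask values at world points, undoing a label displacement of
        +shift (i.e. the profile of ``labels`` translated by ``-shift``)."""
        shift_rc = np.asarray(shift_rc, dtype=float)
        pts = points + self.shift_world(shift_rc)[None, :]
        homog = np.concatenate([pts, np.ones((len(pts), 1))], axis=1)
        vox = (self.inv @ homog.T)[:3]
        if slice_index is not None:
            vox = vox.copy()
            vox[2, :] = slice_index
        return ndimage.map_coordinates(
            self.masks[structure], vox, order=1, mode="constant", cval=0.0
        )


def _transitions(profile: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Sub-sample positions where an interpolated mask crosses 0.5."""
    above = profile >= 0.5
    idx = np.nonzero(above[1:] != above[:-1])[0]
    out = []
    for i in idx:
        p0, p1 = profile[i], profile[i + 1]
        frac = (0.5 - p0) / (p1 - p0) if p1 != p0 else 0.5
        out.append(lams[i] + frac * (lams[i + 1] - lams[i]))
    return np.asarray(out)


def _matched_diffs(a: np.ndarray, b: np.ndarray) -> Optional[np.ndarray]:
    """Pairwise (a - b) after sorted matching; with unequal counts the
    shorter set slides over the longer and the minimum-|mean| window wins."""
    if len(a) == 0 or len(b) == 0:
        return None
    a, b = np.sort(a), np.sort(b)
    flip = False
    if len(a) > len(b):
        a, b, flip = b, a, True
    k = len(a)
    best, best_cost = None, np.inf
    for off in range(len(b) - k + 1):
        d = a - b[off : off + k]
        cost = abs(d.mean())
        if cost < best_cost:
            best, best_cost = d, cost
    return -best if flip else best


class _LinePair:
    """Precomputed intersection line between one SAX slice and one LAX view."""

    def __init__(self, study: CineStudy, slice_index: int, lax: LabelledStack):
        sax = study.sax
        inter = intersect_planes(
            plane_of(sax, slice_index),
            plane_of(lax, 0),
            slice_fov(sax, slice_index),
            slice_fov(lax, 0),
        )
        self.valid = inter is not None
        if not self.valid:
            return
        p0, p1 = inter.sample_points[0], inter.sample_points[-1]
        length = np.linalg.norm(p1 - p0)
        n = max(int(length / _SAMPLE_STEP_MM), 8)
        self.lams = np.linspace(0.0, length, n)
        self.points = p0[None, :] + (self.lams / length)[:, None] * (p1 - p0)[None, :]
        self.direction = (p1 - p0) / length
        self.slice_index = slice_index


def _line_diffs(line, sax_sampler, lax_sampler, sax_shift, lax_shift):
    """Per-structure matched (sax - lax) crossing offsets along one line."""
    diffs = []
    for s in _STRUCTURES:
        prof_sax = sax_sampler.profile(s, line.points, sax_shift, slice_index=line.slice_index)
        prof_lax = lax_sampler.profile(s, line.points, lax_shift, slice_index=0)
        d = _matched_diffs(_transitions(prof_sax, line.lams), _transitions(prof_lax, line.lams))
        if d is not None:
            diffs.append(d)
    return diffs


def mismatch_score(
    study: CineStudy,
    slice_index: int,
    shift_rc=(0.0, 0.0),
    lax_shifts: Optional[dict] = None,
) -> float:
    """Mean SAX-vs-LAX boundary mismatch (mm) for one SAX slice at ED."""
    sax_sampler = _MaskSampler(study.sax)
    lax_shifts = lax_shifts or {}
    scores = []
    for lax in (study.lax2ch, study.lax4ch):
        line = _LinePair(study, slice_index, lax)
        if not line.valid:
            continue
        diffs = _line_diffs(
            line,
            sax_sampler,
            _MaskSampler(lax),
            np.asarray(shift_rc, dtype=float),
            np.asarray(lax_shifts.get(lax.view.value, (0.0, 0.0)), dtype=float),
        )
        if diffs:
            scores.append(np.mean([np.abs(d).mean() for d in diffs]))
    if not scores:
        raise ValueError(f"slice {slice_index} does not intersect either LAX plane")
    return float(np.mean(scores))


def _solve_update(directions: list, offsets: list, weights: list) -> np.ndarray:
    """Weighted minimum-norm least squares for a 2-D shift update from
    line-direction components and measured offsets."""
    A = np.asarray(directions, dtype=float)
    b = np.asarray(offsets, dtype=float)
    w = np.sqrt(np.asarray(weights, dtype=float))
    sol, *_ = np.linalg.lstsq(A * w[:, None], b * w, rcond=None)
    return sol


def _apply_inplane_shift(stack: LabelledStack, slice_index: int, shift_rc: np.ndarray) -> None:
    """Translate one slice's labels by -shift (nearest-neighbour), all frames."""
    dr, dc = stack.voxel_size
    vr, vc = -shift_rc[0] / dr, -shift_rc[1] / dc
    if abs(vr) < 1e-9 and abs(vc) < 1e-9:
        return
    for k in range(stack.n_frames):
        stack.labels[:, :, slice_index, k] = ndimage.shift(
            stack.labels[:, :, slice_index, k], (vr, vc), order=0, cval=0
        )


def align_study(
    study: CineStudy,
    max_shift_mm: float = 15.0,
    tol_mm: float = 0.1,
    max_iter: int = 10,
) -> tuple[AlignmentResult, CineStudy]:
    """Estimate and correct per-slice breath-hold shifts; returns aligned copy."""
    sax = study.sax
    ed_lv = np.isin(sax.labels[:, :, :, 0], LV_LABELS)
    if not ed_lv.any():
        raise ValueError("no LV segmentation at ED in the SAX stack")

    sax_shifts = np.zeros((sax.n_slices, 2))
    lax_shifts = {View.LAX2CH.value: np.zeros(2), View.LAX4CH.value: np.zeros(2)}
    warns: list[str] = []

    lax_stacks = {View.LAX2CH.value: study.lax2ch, View.LAX4CH.value: study.lax4ch}
    sax_sampler = _MaskSampler(sax)
    lax_samplers = {k: _MaskSampler(v) for k, v in lax_stacks.items()}

    segmented = [s for s in range(sax.n_slices) if ed_lv[:, :, s].any()]
    slice_lines: dict[int, list] = {}
    for s in segmented:
        entries = []
        for key, lax in lax_stacks.items():
            line = _LinePair(study, s, lax)
            if line.valid:
                entries.append((line, key))
        if not entries:
            warns.append(f"slice {s}: no LAX intersection; shift kept at zero")
        slice_lines[s] = entries

    def clip(v: np.ndarray) -> np.ndarray:
        norm = np.linalg.norm(v)
        return v * (max_shift_mm / norm) if norm > max_shift_mm else v

    n_it = 0
    converged = False
    for n_it in range(1, max_iter + 1):
        max_update = 0.0
        # pass 1: per-slice SAX shifts (labels at +shift move crossings by
        # +shift . direction, so the residual offset solves the update)
        for s in segmented:
            dirs, offs, wts = [], [], []
            for line, key in slice_lines[s]:
                diffs = _line_diffs(
                    line, sax_sampler, lax_samplers[key], sax_shifts[s], lax_shifts[key]
                )
                for d in diffs:
                    dirs.append(
                        [
                            np.dot(line.direction, sax_sampler.e_row),
                            np.dot(line.direction, sax_sampler.e_col),
                        ]
                    )
                    offs.append(d.mean())  # residual displacement along the line
                    wts.append(len(d))
            if not dirs:
                continue
            upd = _solve_update(dirs, offs, wts)
            new = clip(sax_shifts[s] + upd)
            max_update = max(max_update, float(np.linalg.norm(new - sax_shifts[s])))
            sax_shifts[s] = new
        # pass 2: LAX views against the corrected stack
        for key in lax_stacks:
            sampler = lax_samplers[key]
            dirs, offs, wts = [], [], []
            for s in segmented:
                for line, k2 in slice_lines[s]:
                    if k2 != key:
                        continue
                    diffs = _line_diffs(line, sax_sampler, sampler, sax_shifts[s], lax_shifts[key])
                    for d in diffs:
                        dirs.append(
                            [
                                np.dot(line.direction, sampler.e_row),
                                np.dot(line.direction, sampler.e_col),
                            ]
                        )
                        offs.append(-d.mean())  # lax residual is the negation
                        wts.append(len(d))
            if not dirs:
                continue
            upd = _solve_update(dirs, offs, wts)
            new = clip(lax_shifts[key] + upd)
            max_update = max(max_update, float(np.linalg.norm(new - lax_shifts[key])))
            lax_shifts[key] = new
        if max_update < tol_mm:
            converged = True
            break

    residuals = []
    for s in segmented:
        for line, key in slice_lines[s]:
            diffs = _line_diffs(line, sax_sampler, lax_samplers[key], sax_shifts[s], lax_shifts[key])
            residuals.extend(np.abs(d).mean() for d in diffs)
    residual = float(np.mean(residuals)) if residuals else float("nan")

    aligned = study.copy()
    for s in segmented:
        _apply_inplane_shift(aligned.sax, s, sax_shifts[s])
    for key, stk in ((View.LAX2CH.value, aligned.lax2ch), (View.LAX4CH.value, aligned.lax4ch)):
        _apply_inplane_shift(stk, 0, lax_shifts[key])

    result = AlignmentResult(
        per_slice_shift=sax_shifts,
        lax_shift={k: tuple(v) for k, v in lax_shifts.items()},
        n_iterations=n_it,
        converged=converged,
        residual=residual,
        warnings=warns,
    )
    aligned.provenance["alignment"] = result.to_dict()
    return result, aligned
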