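"""Feature-tracking myocardial strain from ED contours.

Contours are sampled on the end-diastolic myocardium: three SAX slices at
25/50/75% of the segmented LV long-axis extent give closed endo/epicardial
polylines (sub-voxel, arc-length resampled) whose pointwise average is the
mid-wall ring; each LAX view gives an open mid-myocardial midline from one
basal point around the apex to the other.  Points are then tracked through
the cycle either by advecting them with supplied displacement fields
(phantom ground truth or an external registrar's output) or with a built-in
frame-to-frame diffeomorphic-demons tracker on intensity images.

Strains are Lagrangian percentages relative to ED: circumferential from the
mid-wall perimeter, radial from the mean endo-epi thickness, longitudinal
from the midline arc length.  Peak circumferential/longitudinal strain is
the signed minimum (negative); radial the positive maximum.  Times to peak
are reported in ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

from .model import LV_MYO, LV_POOL, CineStudy, LabelledStack, View, voxel_coords, world_coords


# ---------------------------------------------------------------------------
# contour sampling
# ---------------------------------------------------------------------------


def _resample_closed(points: np.ndarray, n_points: int) -> np.ndarray:
    """Arc-length resampling of a closed polyline; start aligned to the
    point at angle 0 about the centroid, orientation counter-clockwise."""
    pts = np.asarray(points, dtype=float)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    centroid = pts.mean(axis=0)
    # counter-clockwise in the first two in-plane coordinates
    d = pts - centroid
    signed_area = 0.5 * np.sum(d[:, 0] * np.roll(d[:, 1], -1) - np.roll(d[:, 0], -1) * d[:, 1])
    if signed_area < 0:
        pts = pts[::-1]
        d = pts - centroid
    start = int(np.argmin(np.abs(np.arctan2(d[:, 1], d[:, 0]))))
    pts = np.roll(pts, -start, axis=0)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    targets = np.linspace(0.0, total, n_points, endpoint=False)
    out = np.empty((n_points, closed.shape[1]))
    for j in range(closed.shape[1]):
        out[:, j] = np.interp(targets, cum, closed[:, j])
    return out


def _resample_open(points: np.ndarray, n_points: int) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, cum[-1], n_points)
    out = np.empty((n_points, pts.shape[1]))
    for j in range(pts.shape[1]):
        out[:, j] = np.interp(targets, cum, pts[:, j])
    return out


def _polygon_area(pts2d: np.ndarray) -> float:
    x, y = pts2d[:, 0], pts2d[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class ContourPair:
    """Endo/epi/mid-wall rings of one SAX slice at ED (world mm)."""

    endo: np.ndarray  # (n_points, 3)
    epi: np.ndarray
    midwall: np.ndarray
    slice_index: int


@dataclass
class EDContours:
    sax: list  # list[ContourPair], basal -> apical
    lax_midlines: dict  # view name -> (n_points, 3) open polyline
    n_points: int


def _sax_contour_pair(
    stack: LabelledStack, slice_index: int, n_points: int
) -> Optional[ContourPair]:
    myo = (stack.labels[:, :, slice_index, 0] == LV_MYO).astype(float)
    if myo.sum() < 8:
        return None
    contours = measure.find_contours(myo, 0.5)
    if len(contours) < 2:
        return None
    areas = [_polygon_area(c) for c in contours]
    order = np.argsort(areas)[::-1]
    epi_rc, endo_rc = contours[order[0]], contours[order[1]]

    def to_world(rc: np.ndarray) -> np.ndarray:
        idx = np.column_stack([rc, np.full(len(rc), slice_index)])
        return world_coords(stack, idx)

    endo = _resample_closed(to_world(endo_rc), n_points)
    epi = _resample_closed(to_world(epi_rc), n_points)
    return ContourPair(
        endo=endo, epi=epi, midwall=0.5 * (endo + epi), slice_index=slice_index
    )


def _lax_midline(stack: LabelledStack, n_points: int, n_rays: int = 96) -> np.ndarray:
    """Mid-myocardial open polyline by an angular sweep from the basal centre."""
    lab = stack.labels[:, :, 0, 0]
    pool = (lab == LV_POOL).astype(float)
    myo = (lab == LV_MYO).astype(float)
    wall = np.clip(pool + myo, 0, 1)
    if pool.sum() < 8:
        raise ValueError(f"no LV pool segmented in {stack.view.value} at ED")
    rows, cols = np.nonzero(pool > 0)
    # the long axis runs along image columns; base = lowest column index band
    c_base = cols.min()
    band = cols <= c_base + 2
    origin = np.array([rows[band].mean(), float(c_base)])
    max_r = float(np.hypot(lab.shape[0], lab.shape[1]))
    thetas = np.linspace(np.deg2rad(8.0), np.pi - np.deg2rad(8.0), n_rays)
    mid_rc = []
    rs = np.arange(0.5, max_r, 0.4)
    for th in thetas:
        # theta sweeps from one basal side (+row) over the apex (+col direction)
        d = np.array([np.cos(th), np.sin(th)])
        pts = origin[None, :] + rs[:, None] * d[None, :]
        inside = (
            (pts[:, 0] >= 0)
            & (pts[:, 0] <= lab.shape[0] - 1)
            & (pts[:, 1] >= 0)
            & (pts[:, 1] <= lab.shape[1] - 1)
        )
        if not inside.any():
            continue
        p = pts[inside]
        prof_pool = ndimage.map_coordinates(pool, p.T, order=1)
        prof_wall = ndimage.map_coordinates(wall, p.T, order=1)
        r_in = rs[inside]
        in_pool = prof_pool >= 0.5
        in_wall = prof_wall >= 0.5
        if not in_pool.any() or not in_wall.any():
            continue
        r_endo = r_in[np.nonzero(in_pool)[0][-1]]
        r_epi = r_in[np.nonzero(in_wall)[0][-1]]
        if r_epi <= r_endo:
            continue
        mid_rc.append(origin + 0.5 * (r_endo + r_epi) * d)
    if len(mid_rc) < 8:
        raise ValueError(f"could not trace myocardial midline in {stack.view.value}")
    mid_rc = np.asarray(mid_rc)
    idx = np.column_stack([mid_rc, np.zeros(len(mid_rc))])
    return _resample_open(world_coords(stack, idx), n_points)


def sample_ed_contours(study: CineStudy, n_sax: int = 3, n_points: int = 48) -> EDContours:
    """ED contours: ``n_sax`` SAX slices at even fractions of the LV extent
    plus the two LAX midlines."""
    sax = study.sax
    myo_per_slice = np.array(
        [np.count_nonzero(sax.labels[:, :, s, 0] == LV_MYO) for s in range(sax.n_slices)]
    )
    candidates = np.nonzero(myo_per_slice >= 16)[0]
    if len(candidates) < n_sax:
        raise ValueError(
            f"need at least {n_sax} SAX slices with ED myocardium, found {len(candidates)}"
        )
    lo, hi = candidates.min(), candidates.max()
    fracs = (np.arange(n_sax) + 1.0) / (n_sax + 1.0)  # 25/50/75% for n_sax=3
    chosen = []
    for f in fracs:
        target = lo + f * (hi - lo)
        s = int(candidates[np.argmin(np.abs(candidates - target))])
        while s in chosen and s < hi:
            s += 1
        chosen.append(s)
    pairs = []
    for s in chosen:
        pair = _sax_contour_pair(sax, s, n_points)
        if pair is None:
            raise ValueError(f"SAX slice {s} lacks a closed myocardial annulus at ED")
        pairs.append(pair)
    midlines = {
        View.LAX2CH.value: _lax_midline(study.lax2ch, n_points),
        View.LAX4CH.value: _lax_midline(study.lax4ch, n_points),
    }
    return EDContours(sax=pairs, lax_midlines=midlines, n_points=n_points)


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------


@dataclass
class TrackedContour:
    """World-mm trajectories of one contour: (n_frames, n_points, 3)."""

    points: np.ndarray
    kind: str  # endo | epi | midwall | lax_midline
    source_slice: Optional[int] = None

    def __post_init__(self) -> None:
        if self.points.ndim != 3 or self.points.shape[2] != 3:
            raise ValueError("trajectories must be (n_frames, n_points, 3)")


class NiftiDisplacementField:
    """Dense ED->frame displacement fields on a stack grid (mm vectors).

    ``data`` has shape (rows, cols, slices, frames, 3); trilinear sampling.
    """

    def __init__(self, data: np.ndarray, stack: LabelledStack):
        self.data = np.asarray(data, dtype=float)
        self.stack = stack
        if self.data.shape[:3] != stack.labels.shape[:3] or self.data.shape[-1] != 3:
            raise ValueError("field grid does not match the stack")

    @classmethod
    def load(cls, path, stack: LabelledStack) -> "NiftiDisplacementField":
        import nibabel as nib

        return cls(np.asarray(nib.load(str(path)).dataobj), stack)

    def sample(self, points: np.ndarray, frame: int) -> np.ndarray:
        vox = voxel_coords(self.stack, np.atleast_2d(points)).T
        out = np.empty((vox.shape[1], 3))
        for c in range(3):
            out[:, c] = ndimage.map_coordinates(
                self.data[:, :, :, frame, c], vox, order=1, mode="nearest"
            )
        return out


def track(
    points_ed: np.ndarray,
    field=None,
    images: Optional[np.ndarray] = None,
    stack: Optional[LabelledStack] = None,
    method: str = "fields",
    kind: str = "midwall",
    source_slice: Optional[int] = None,
    n_frames: Optional[int] = None,
) -> TrackedContour:
    """Track ED points through the cycle.

    ``method='fields'`` advects points by sampling ED->t displacement from
    ``field`` (anything with ``.sample(points, frame) -> (n, 3)``).
    ``method='demons'`` runs the built-in frame-to-frame demons tracker on
    ``images`` (the 4-D intensity cine of ``stack``).
    """
    pts = np.atleast_2d(np.asarray(points_ed, dtype=float))
    if method == "fields":
        if field is None:
            raise ValueError("fields method needs a displacement field")
        nf = n_frames if n_frames is not None else field.n_frames
        traj = np.empty((nf, len(pts), 3))
        for k in range(nf):
            disp = field.sample(pts, k)
            if not np.all(np.isfinite(disp)):
                bad = np.nonzero(~np.isfinite(disp).all(axis=1))[0]
                raise ValueError(f"points tracked outside field of view: {bad.tolist()}")
            traj[k] = pts + disp
        traj[0] = pts  # exact by construction; avoid interpolation jitter
        return TrackedContour(points=traj, kind=kind, source_slice=source_slice)
    if method == "demons":
        if images is None or stack is None:
            raise ValueError("demons method needs images and their stack")
        return _track_demons(pts, images, stack, kind, source_slice)
    raise ValueError(f"unknown tracking method {method!r}")


def _track_demons(pts, images, stack, kind, source_slice) -> TrackedContour:
    """Frame-to-frame diffeomorphic demons on one slice, composed pointwise."""
    import SimpleITK as sitk

    if source_slice is None:
        source_slice = int(round(np.median(voxel_coords(stack, pts)[:, 2])))
    dr, dc = stack.voxel_size
    nf = stack.n_frames
    demons = sitk.DiffeomorphicDemonsRegistrationFilter()
    demons.SetNumberOfIterations(30)
    demons.SetSmoothDisplacementField(True)
    demons.SetStandardDeviations(1.5)

    def to_img(frame):
        arr = np.ascontiguousarray(images[:, :, source_slice, frame].astype(np.float32))
        img = sitk.GetImageFromArray(arr)  # sitk axes: (col, row) reversed
        img.SetSpacing((dc, dr))
        return img

    traj = np.empty((nf, len(pts), 3))
    traj[0] = pts
    cur_vox = voxel_coords(stack, pts)[:, :2]  # (n, [row, col])
    for k in range(1, nf):
        fixed = to_img(k)
        moving = to_img(k - 1)
        # field maps frame-k grid -> frame-(k-1); invert by small-step negation
        disp = demons.Execute(fixed, moving)
        arr = sitk.GetArrayFromImage(disp)  # (rows, cols, 2) with (x=col, y=row) mm
        dcol = ndimage.map_coordinates(arr[:, :, 0], cur_vox.T, order=1, mode="nearest")
        drow = ndimage.map_coordinates(arr[:, :, 1], cur_vox.T, order=1, mode="nearest")
        # moving->fixed correspondence: step against the backward field
        cur_vox = cur_vox - np.column_stack([drow / dr, dcol / dc])
        idx = np.column_stack([cur_vox, np.full(len(pts), source_slice)])
        traj[k] = world_coords(stack, np.clip(idx, 0, np.array(stack.labels.shape[:3]) - 1))
    return TrackedContour(points=traj, kind=kind, source_slice=source_slice)


# ---------------------------------------------------------------------------
# strain curves
# ---------------------------------------------------------------------------


@dataclass
class StrainReport:
    """Global strain curves (%) and their peaks/times-to-peak."""

    times: np.ndarray
    ecc: np.ndarray  # circumferential, mean of the SAX slices
    err: np.ndarray  # radial (thickness-based)
    ell_2ch: np.ndarray
    ell_4ch: np.ndarray
    peaks: dict = field(default_factory=dict)  # component -> % value
    tpk_ms: dict = field(default_factory=dict)  # component -> ms

    def to_row(self) -> dict:
        row = {
            "ecc_pct": self.peaks.get("ecc"),
            "err_pct": self.peaks.get("err"),
            "ell_2ch_pct": self.peaks.get("ell_2ch"),
            "ell_4ch_pct": self.peaks.get("ell_4ch"),
        }
        row.update({f"tpk_{k}_ms": v for k, v in self.tpk_ms.items()})
        return row


def _perimeter_closed(traj: np.ndarray) -> np.ndarray:
    closed = np.concatenate([traj, traj[:, :1, :]], axis=1)
    return np.linalg.norm(np.diff(closed, axis=1), axis=2).sum(axis=1)


def _arclength_open(traj: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.diff(traj, axis=1), axis=2).sum(axis=1)


def strain_curves(
    sax_tracked: Sequence[dict],
    lax_tracked: dict,
    times: np.ndarray,
) -> StrainReport:
    """Lagrangian strain curves from tracked contours.

    ``sax_tracked``: per slice, dict with TrackedContour values for keys
    ``endo``/``epi``/``midwall``.  ``lax_tracked``: view name -> midline
    TrackedContour.
    """
    times = np.asarray(times, dtype=float)
    eccs, errs = [], []
    for slc in sax_tracked:
        mid, endo, epi = slc["midwall"].points, slc["endo"].points, slc["epi"].points
        perim = _perimeter_closed(mid)
        if perim[0] < 10.0:
            raise ValueError("degenerate mid-wall contour (perimeter < 10 mm)")
        eccs.append(100.0 * (perim / perim[0] - 1.0))
        thickness = np.linalg.norm(endo - epi, axis=2).mean(axis=1)
        errs.append(100.0 * (thickness / thickness[0] - 1.0))
    ecc = np.mean(eccs, axis=0)
    err = np.mean(errs, axis=0)

    ells = {}
    for key in ("LAX2CH", "LAX4CH"):
        arc = _arclength_open(lax_tracked[key].points)
        if arc[0] < 10.0:
            raise ValueError("degenerate LAX midline")
        ells[key] = 100.0 * (arc / arc[0] - 1.0)

    report = StrainReport(
        times=times, ecc=ecc, err=err, ell_2ch=ells["LAX2CH"], ell_4ch=ells["LAX4CH"]
    )
    for name, curve, sign in (
        ("ecc", ecc, -1),
        ("err", err, +1),
        ("ell_2ch", ells["LAX2CH"], -1),
        ("ell_4ch", ells["LAX4CH"], -1),
    ):
        idx = int(np.argmin(curve)) if sign < 0 else int(np.argmax(curve))
        report.peaks[name] = float(curve[idx])
        report.tpk_ms[name] = float(times[idx] * 1000.0)
    return report


def compute_strain(
    study: CineStudy,
    field=None,
    method: str = "fields",
    n_sax: int = 3,
    n_points: int = 48,
) -> StrainReport:
    """End-to-end: sample ED contours, track, and measure strain."""
    contours = sample_ed_contours(study, n_sax=n_sax, n_points=n_points)
    nf = study.n_frames

    def trk(pts, kind, slc=None, stack=None, view=None):
        if method == "fields":
            return track(pts, field=field, method="fields", kind=kind, source_slice=slc, n_frames=nf)
        imgs = study.images[view]
        return track(pts, images=imgs, stack=stack, method="demons", kind=kind, source_slice=slc)

    sax_tracked = []
    for pair in contours.sax:
        sax_tracked.append(
            {
                "endo": trk(pair.endo, "endo", pair.slice_index, study.sax, "SAX"),
                "epi": trk(pair.epi, "epi", pair.slice_index, study.sax, "SAX"),
                "midwall": trk(pair.midwall, "midwall", pair.slice_index, study.sax, "SAX"),
            }
        )
    lax_tracked = {
        "LAX2CH": trk(contours.lax_midlines["LAX2CH"], "lax_midline", 0, study.lax2ch, "LAX2CH"),
        "LAX4CH": trk(contours.lax_midlines["LAX4CH"], "lax_midline", 0, study.lax4ch, "LAX4CH"),
    }
    return strain_curves(sax_tracked, lax_tracked, study.sax.frame_times)
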