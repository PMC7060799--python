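"""Parametric biventricular phantom with analytic ground truth.

The phantom emulates a UK-Biobank-style cine acquisition: a SAX stack of
~10 mm-spaced slices plus 2- and 4-chamber LAX planes, 50 frames over one
R-R interval.  The LV blood pool is a half-ellipsoid capped by a concentric
epicardial half-ellipsoid (so the wall is a shell of prescribed volume);
the RV is a clipped ellipsoid-difference crescent hugging the LV free wall.

Motion is an in-plane radial deformation about the long axis: the pool
scales linearly so its volume follows a prescribed curve, and the wall
deforms area-preservingly (incompressible myocardium), which keeps the wall
volume constant through the cycle and gives closed-form mid-wall
circumferential strain.  The volume curve is piecewise raised-cosine in
dV/dt (ejection pulse, E-wave, diastasis, A-wave), so peak ejection rate,
peak early/atrial filling rates and atrial contribution all have closed
forms against which the measurement pipeline can be scored.

Everything produced here is a pure function of ``(spec, seed)``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .model import (
    BACKGROUND,
    LV_MYO,
    LV_POOL,
    RV_POOL,
    CineStudy,
    LabelledStack,
    SubjectMeta,
    View,
)

# ---------------------------------------------------------------------------
# analytic volume-time curve
# ---------------------------------------------------------------------------


def _hann_cum(u: np.ndarray) -> np.ndarray:
    """Integral of a unit-area raised-cosine pulse, as a function of pulse phase."""
    u = np.clip(u, 0.0, 1.0)
    return u - np.sin(2.0 * np.pi * u) / (2.0 * np.pi)


def _hann(u: np.ndarray) -> np.ndarray:
    """Unit-area raised-cosine pulse on [0, 1] (peak value 2)."""
    u = np.asarray(u, dtype=float)
    return np.where((u >= 0.0) & (u <= 1.0), 1.0 - np.cos(2.0 * np.pi * u), 0.0)


@dataclass
class VolumeCurveModel:
    """Analytic ventricular volume curve over one cardiac cycle.

    Times are fractions of the R-R interval; ``edv``/``esv`` and the wave
    amplitudes are in ml.  Ejection runs from t=0 to ``t_es`` as a single
    raised-cosine pulse in dV/dt; early (E) and atrial (A) filling waves are
    raised-cosine pulses centred on ``e_peak_time``/``a_peak_time`` with the
    given widths (also fractions of R-R).  Amplitudes default to a 70/30
    E/A split of the stroke volume so that V(1) = V(0) = EDV.
    """

    edv: float
    esv: float
    t_es: float = 0.35
    e_peak_time: float = 0.55
    a_peak_time: float = 0.85
    e_wave_width: float = 0.30
    a_wave_width: float = 0.20
    e_wave_amplitude: Optional[float] = None
    a_wave_amplitude: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.edv >= self.esv > 0):
            raise ValueError("need edv >= esv > 0")
        sv = self.edv - self.esv
        if sv < 1e-9:
            # degenerate constant-volume model (zero-amplitude motion)
            self.e_wave_amplitude = 0.0
            self.a_wave_amplitude = 0.0
            return
        if self.e_wave_amplitude is None and self.a_wave_amplitude is None:
            self.e_wave_amplitude = 0.7 * sv
            self.a_wave_amplitude = 0.3 * sv
        elif self.e_wave_amplitude is None:
            self.e_wave_amplitude = sv - self.a_wave_amplitude
        elif self.a_wave_amplitude is None:
            self.a_wave_amplitude = sv - self.e_wave_amplitude
        if abs(self.e_wave_amplitude + self.a_wave_amplitude - sv) > 0.1:
            raise ValueError("E + A wave amplitudes must equal the stroke volume (0.1 ml)")
        if min(self.e_wave_amplitude, self.a_wave_amplitude) <= 0:
            raise ValueError("wave amplitudes must be positive")
        if not 0.05 < self.t_es < 0.6:
            raise ValueError("t_es out of plausible range")
        eps = 1e-9
        if self._e_start < self.t_es - eps:
            raise ValueError("E wave must start after end-systole")
        if self._a_start < self._e_start + self.e_wave_width - eps:
            raise ValueError("A wave must start after the E wave ends")
        if self._a_start + self.a_wave_width > 1.0 + eps:
            raise ValueError("A wave must end within the cycle")

    # pulse start times (fractions of R-R)
    @property
    def _e_start(self) -> float:
        return self.e_peak_time - self.e_wave_width / 2.0

    @property
    def _a_start(self) -> float:
        return self.a_peak_time - self.a_wave_width / 2.0

    @property
    def sv(self) -> float:
        return self.edv - self.esv

    def volume(self, t) -> np.ndarray:
        """V(t) in ml for t as a fraction of R-R in [0, 1]."""
        t = np.asarray(t, dtype=float)
        if np.any(t < -1e-9) or np.any(t > 1.0 + 1e-9):
            raise ValueError("t must lie in [0, 1] (fraction of R-R)")
        if self.sv < 1e-9:
            return np.full_like(t, self.edv, dtype=float) if t.ndim else float(self.edv)
        v = (
            self.edv
            - self.sv * _hann_cum(t / self.t_es)
            + self.e_wave_amplitude * _hann_cum((t - self._e_start) / self.e_wave_width)
            + self.a_wave_amplitude * _hann_cum((t - self._a_start) / self.a_wave_width)
        )
        return v

    def rate(self, t, rr_interval: float = 1.0) -> np.ndarray:
        """dV/dt in ml/s (negative during ejection)."""
        t = np.asarray(t, dtype=float)
        if self.sv < 1e-9:
            return np.zeros_like(t)
        dv = (
            -self.sv / self.t_es * _hann(t / self.t_es)
            + self.e_wave_amplitude / self.e_wave_width * _hann((t - self._e_start) / self.e_wave_width)
            + self.a_wave_amplitude / self.a_wave_width * _hann((t - self._a_start) / self.a_wave_width)
        )
        return dv / rr_interval

    # closed-form dynamics (peak of a unit-area raised-cosine of width w is 2/w)
    def peak_ejection_rate(self, rr_interval: float = 1.0) -> float:
        return 2.0 * self.sv / (self.t_es * rr_interval)

    def peak_early_filling_rate(self, rr_interval: float = 1.0) -> float:
        return 2.0 * self.e_wave_amplitude / (self.e_wave_width * rr_interval)

    def peak_atrial_filling_rate(self, rr_interval: float = 1.0) -> float:
        return 2.0 * self.a_wave_amplitude / (self.a_wave_width * rr_interval)

    def atrial_contribution(self) -> float:
        return float(self.a_wave_amplitude)


def analytic_volume(model: VolumeCurveModel, t) -> np.ndarray:
    """Ground-truth ventricular volume (ml) at cycle fraction(s) ``t``."""
    return model.volume(t)


# ---------------------------------------------------------------------------
# phantom specification
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Everything needed to voxelize one synthetic exam."""

    lv: VolumeCurveModel
    rv: Optional[VolumeCurveModel] = None
    lv_wall_volume: float = 100.0  # ml, constant over the cycle
    lv_length: float = 90.0  # mm, base-to-apex length of the blood pool
    n_frames: int = 50
    voxel_size: tuple[float, float] = (1.8, 1.8)  # in-plane mm
    slice_thickness: float = 8.0  # mm
    slice_gap: float = 2.0  # mm
    n_sax_slices: Optional[int] = None  # default: cover the ventricles
    lax_voxel: float = 1.8  # in-plane mm of the LAX planes
    rr_interval: float = 1.0  # s
    margin: float = 8.0  # mm of background padding around the anatomy
    subject: SubjectMeta = field(
        default_factory=lambda: SubjectMeta(sex="M", age=55.0, height=171.0, weight=74.0)
    )
    orientation: Optional[np.ndarray] = None  # optional 3x3 world rotation
    seed: int = 0
    make_images: bool = False

    def __post_init__(self) -> None:
        if self.lv_wall_volume <= 0:
            raise ValueError("lv_wall_volume must be positive")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.orientation is not None:
            R = np.asarray(self.orientation, dtype=float)
            if R.shape != (3, 3) or abs(abs(np.linalg.det(R)) - 1.0) > 1e-6:
                raise ValueError("orientation must be a 3x3 rotation matrix")
            self.orientation = R


class _LVGeometry:
    """Radius profiles and deformation of the half-ellipsoid LV."""

    def __init__(self, spec: PhantomSpec):
        edv_mm3 = spec.lv.edv * 1000.0
        self.L = spec.lv_length
        self.R0 = np.sqrt(3.0 * edv_mm3 / (2.0 * np.pi * self.L))
        self.lam = ((spec.lv.edv + spec.lv_wall_volume) / spec.lv.edv) ** (1.0 / 3.0)
        self.L_epi = self.lam * self.L
        self.Re0 = self.lam * self.R0
        self.model = spec.lv

    def r_pool(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        u = z / self.L
        prof = np.where((z >= 0) & (u <= 1.0), np.sqrt(np.clip(1.0 - u**2, 0.0, None)), 0.0)
        return self.R0 * prof

    def r_epi(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        u = z / self.L_epi
        prof = np.where((z >= 0) & (u <= 1.0), np.sqrt(np.clip(1.0 - u**2, 0.0, None)), 0.0)
        return self.Re0 * prof

    def scale(self, t_frac) -> np.ndarray:
        """In-plane pool scaling s(t) = sqrt(V(t)/EDV)."""
        return np.sqrt(self.model.volume(t_frac) / self.model.edv)

    def deform_radius(self, r0, z, s) -> np.ndarray:
        """Map an ED in-plane radius to its frame-t radius (area-preserving wall)."""
        r0 = np.asarray(r0, dtype=float)
        rp = self.r_pool(z)
        inside = r0 <= rp
        scaled = s * r0
        wall = np.sqrt(np.clip(r0**2 + (s**2 - 1.0) * rp**2, 0.0, None))
        return np.where(inside, scaled, wall)

    def undeform_radius(self, r, z, s) -> np.ndarray:
        """Inverse of :meth:`deform_radius` (frame-t radius back to ED)."""
        r = np.asarray(r, dtype=float)
        rp = self.r_pool(z)
        inside = r <= s * rp
        unscaled = r / max(s, 1e-9)
        wall = np.sqrt(np.clip(r**2 - (s**2 - 1.0) * rp**2, 0.0, None))
        return np.where(inside, unscaled, wall)

    def midwall_radius(self, z, s=1.0) -> np.ndarray:
        r_m0 = 0.5 * (self.r_pool(z) + self.r_epi(z))
        return self.deform_radius(r_m0, z, s)

    def ecc_midwall(self, z, t_frac) -> np.ndarray:
        """Analytic mid-wall circumferential strain (%) at long-axis position z."""
        s = self.scale(t_frac)
        r0 = self.midwall_radius(z, 1.0)
        rt = self.midwall_radius(z, s)
        return 100.0 * (rt / r0 - 1.0)


@dataclass
class _RVGeometry:
    """Crescent = clipped ellipsoid minus the (deformed) LV epicardium.

    The ellipsoid E1 scales in-plane about its own centre by a per-frame
    factor ``q``; membership is evaluated in current coordinates and the
    exclusion uses the LV outer-wall radius *at that frame*, so the RV can
    never overlap the LV labels.  ``q`` is calibrated per frame so the
    voxelized volume tracks the prescribed curve.
    """

    center_x: float  # E1 centre (x; y = 0)
    ax: float
    by: float
    L1: float
    clip_x: float  # RV restricted to x <= clip_x (septal clip)
    lv: _LVGeometry
    q: Optional[np.ndarray] = None  # calibrated per-frame in-plane scales

    def z_profile(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        u = z / self.L1
        return np.where((z >= 0) & (u <= 1.0), np.sqrt(np.clip(1.0 - u**2, 0.0, None)), 0.0)


# ---------------------------------------------------------------------------
# ground truth container
# ---------------------------------------------------------------------------


class AnalyticDisplacementField:
    """ED->frame displacement sampler backed by the analytic deformation.

    ``sample(points, frame)`` returns mm displacement vectors for world
    points (the positions those ED material points occupy at ``frame``).
    """

    def __init__(self, lv_geom: _LVGeometry, frame_fracs: np.ndarray, rotation: Optional[np.ndarray]):
        self._geom = lv_geom
        self._fracs = np.asarray(frame_fracs, dtype=float)
        self._R = rotation

    @property
    def n_frames(self) -> int:
        return len(self._fracs)

    def sample(self, points: np.ndarray, frame: int) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self._R is not None:
            pts = pts @ self._R  # world -> canonical (R is orthonormal)
        s = float(self._geom.scale(self._fracs[frame]))
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        r0 = np.hypot(x, y)
        rt = self._geom.deform_radius(r0, z, s)
        ratio = np.where(r0 > 1e-9, rt / np.clip(r0, 1e-9, None), 1.0)
        out = np.stack([x * ratio, y * ratio, z], axis=1) - pts
        if self._R is not None:
            out = out @ self._R.T
        return out

    def __call__(self, points, frame):
        return self.sample(points, frame)


@dataclass
class PhantomTruth:
    """Analytic and voxel-level ground truth accompanying a phantom study."""

    spec: PhantomSpec
    frame_fracs: np.ndarray  # cycle fractions of each frame
    times: np.ndarray  # s
    lv_analytic: np.ndarray  # ml per frame (closed form)
    lv_voxel: np.ndarray  # ml per frame (voxel count x voxel volume)
    wall_voxel: np.ndarray  # ml per frame
    rv_analytic: Optional[np.ndarray]
    rv_voxel: Optional[np.ndarray]
    field: AnalyticDisplacementField
    lv_geometry: _LVGeometry
    rv_geometry: Optional[_RVGeometry]

    def lv_volume(self, t_frac) -> np.ndarray:
        return self.spec.lv.volume(t_frac)

    def ecc_midwall(self, z, frame: int) -> np.ndarray:
        """Analytic mid-wall circumferential strain (%) at canonical z, per frame."""
        return self.lv_geometry.ecc_midwall(z, self.frame_fracs[frame])

    def export_displacement_field(self, stack, path) -> None:
        """Write the ED->frame field sampled at a stack's voxel centres as a
        5-D NIfTI (rows, cols, slices, frames, 3), mm units."""
        import nibabel as nib

        nr, nc, ns = stack.labels.shape[:3]
        rr, cc, ss = np.meshgrid(np.arange(nr), np.arange(nc), np.arange(ns), indexing="ij")
        homog = np.stack([rr, cc, ss, np.ones_like(rr)], axis=-1).reshape(-1, 4).T
        world = (stack.affine @ homog)[:3].T
        nf = len(self.frame_fracs)
        data = np.zeros((nr, nc, ns, nf, 3), dtype=np.float32)
        for k in range(nf):
            data[:, :, :, k, :] = self.field.sample(world, k).reshape(nr, nc, ns, 3)
        nib.save(nib.Nifti1Image(data, stack.affine), str(path))

    def curves_dataframe(self):
        import pandas as pd

        d = {
            "time_s": self.times,
            "lv_analytic_ml": self.lv_analytic,
            "lv_voxel_ml": self.lv_voxel,
            "wall_voxel_ml": self.wall_voxel,
        }
        if self.rv_voxel is not None:
            d["rv_analytic_ml"] = self.rv_analytic
            d["rv_voxel_ml"] = self.rv_voxel
        return pd.DataFrame(d)


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------


def _sax_affine(spec: PhantomSpec, x0: float, y0: float, z0: float) -> np.ndarray:
    dr, dc = spec.voxel_size
    dz = spec.slice_thickness + spec.slice_gap
    A = np.eye(4)
    A[0, 0], A[1, 1], A[2, 2] = dr, dc, dz
    A[:3, 3] = (x0, y0, z0)
    if spec.orientation is not None:
        R4 = np.eye(4)
        R4[:3, :3] = spec.orientation
        A = R4 @ A
    return A


def _rotate_affine(A: np.ndarray, R: Optional[np.ndarray]) -> np.ndarray:
    if R is None:
        return A
    R4 = np.eye(4)
    R4[:3, :3] = R
    return R4 @ A


def _voxelize_lv(geom, xs, ys, zs, s):
    """Return (pool, myo) boolean grids for in-plane coords xs, ys and slice zs."""
    r2 = (xs[:, None] ** 2 + ys[None, :] ** 2)[:, :, None]  # (nr, nc, 1)
    rp = geom.r_pool(zs)[None, None, :]
    re = geom.r_epi(zs)[None, None, :]
    pool_r2 = (s * rp) ** 2
    out_r2 = re**2 + (s**2 - 1.0) * rp**2
    pool = (r2 <= pool_r2) & (rp > 0)
    myo = (r2 <= out_r2) & (re > 0) & ~pool
    return pool, myo

def _voxelize_rv(rvg, xs, ys, zs, q, s_lv=1.0):
    """RV crescent mask at in-plane scale ``q`` with LV wall at scale ``s_lv``."""
    x = xs[:, None, None]
    y = ys[None, :, None]
    g = rvg.z_profile(zs)[None, None, :]
    g2 = np.clip(g, 1e-12, None) ** 2
    in_e1 = (
        (x - rvg.center_x) ** 2 / ((rvg.ax * q) ** 2 * g2)
        + y**2 / ((rvg.by * q) ** 2 * g2)
    ) <= 1.0
    in_e1 &= g > 0
    rp = rvg.lv.r_pool(zs)[None, None, :]
    re = rvg.lv.r_epi(zs)[None, None, :]
    rout2 = np.clip(re**2 + (s_lv**2 - 1.0) * rp**2, 0.0, None)
    outside_lv = (x**2 + y**2) >= (1.02**2) * rout2
    return in_e1 & (x <= rvg.clip_x) & outside_lv


def _calibrate_rv_frame(rvg, xs, ys, zs, voxvol, target_ml, q0, s_lv):
    """One-step (iterated) scale correction so the voxel count hits target_ml."""
    q = q0
    mask = _voxelize_rv(rvg, xs, ys, zs, q, s_lv)
    v = mask.sum() * voxvol
    for _ in range(3):
        if v <= 0:
            raise ValueError("degenerate RV geometry during calibration")
        q_new = q * np.sqrt(target_ml / v)
        if abs(q_new / q - 1.0) < 5e-4:
            break
        q = q_new
        mask = _voxelize_rv(rvg, xs, ys, zs, q, s_lv)
        v = mask.sum() * voxvol
    return mask, q, v


def _size_rv(spec: PhantomSpec, geom: _LVGeometry) -> _RVGeometry:
    """Choose crescent dimensions so the voxelized EDV can be calibrated down."""
    rvg = _RVGeometry(
        center_x=-0.5 * geom.Re0,
        ax=1.6 * geom.Re0,
        by=1.15 * geom.Re0,
        L1=0.95 * geom.L_epi,
        clip_x=-2.0,
        lv=geom,
    )
    # coarse voxel count at 3 mm to size the ellipsoid toward ~1.5x the target EDV
    step = 3.0
    xs = np.arange(rvg.center_x - rvg.ax, 1.0, step)
    ys = np.arange(-rvg.by - step, rvg.by + step, step)
    zs = np.arange(0.0, rvg.L1 + step, step)
    mask = _voxelize_rv(rvg, xs, ys, zs, 1.0, 1.0)
    v_ml = mask.sum() * step**3 / 1000.0
    if v_ml <= 0:
        raise ValueError("degenerate RV geometry")
    f = np.sqrt(1.5 * spec.rv.edv / v_ml)
    rvg.ax *= f
    rvg.by *= f
    return rvg


def build_phantom(spec: PhantomSpec) -> tuple[CineStudy, PhantomTruth]:
    """Voxelize the phantom into a :class:`CineStudy` plus ground truth."""
    geom = _LVGeometry(spec)
    dr, dc = spec.voxel_size
    rvg = None
    if spec.rv is not None:
        rvg = _size_rv(spec, geom)

    # grid extents (canonical frame: LV axis = z, base plane z = 0)
    x_lo = (rvg.center_x - rvg.ax if rvg else -geom.Re0) - spec.margin
    x_hi = geom.Re0 + spec.margin
    y_half = max(geom.Re0, rvg.by if rvg else 0.0) + spec.margin
    xs = np.arange(x_lo, x_hi + dr, dr)
    ys = np.arange(-y_half, y_half + dc, dc)
    # slice centres at cell midpoints from the base plane, so Simpson slice
    # summation sees the midpoint-rule sample of each dz-thick cell
    dz = spec.slice_thickness + spec.slice_gap
    if spec.n_sax_slices is None:
        n_sl = int(np.ceil(geom.L_epi / dz))
        zs = dz / 2.0 + dz * np.arange(n_sl)
    else:
        zs = dz / 2.0 + dz * np.arange(spec.n_sax_slices)
    n_slices = len(zs)
    if geom.L_epi + spec.margin > zs[-1] + dz and spec.n_sax_slices is not None:
        pass  # an explicitly short stack is allowed; coverage QC will see it
    if len(xs) * len(ys) * n_slices == 0:
        raise ValueError("phantom geometry does not fit the grid")

    fracs = np.arange(spec.n_frames) / spec.n_frames
    times = fracs * spec.rr_interval
    voxvol = dr * dc * dz / 1000.0  # ml

    labels = np.zeros((len(xs), len(ys), n_slices, spec.n_frames), dtype=np.uint8)
    lv_vox = np.zeros(spec.n_frames)
    wall_vox = np.zeros(spec.n_frames)
    rv_vox = np.zeros(spec.n_frames) if rvg is not None else None
    s_frames = geom.scale(fracs)
    rv_targets = spec.rv.volume(fracs) if rvg is not None else None
    if rvg is not None:
        rvg.q = np.ones(spec.n_frames)
    q_prev = np.sqrt(2.0 / 3.0)  # ~ the 1.5x head-room sizing
    for k in range(spec.n_frames):
        pool, myo = _voxelize_lv(geom, xs, ys, zs, float(s_frames[k]))
        frame = np.zeros(labels.shape[:3], dtype=np.uint8)
        frame[pool] = LV_POOL
        frame[myo] = LV_MYO
        if rvg is not None:
            rv, q_prev, v_rv = _calibrate_rv_frame(
                rvg, xs, ys, zs, voxvol, float(rv_targets[k]), q_prev, float(s_frames[k])
            )
            rvg.q[k] = q_prev
            frame[rv & (frame == BACKGROUND)] = RV_POOL
            rv_vox[k] = v_rv
        labels[:, :, :, k] = frame
        lv_vox[k] = pool.sum() * voxvol
        wall_vox[k] = myo.sum() * voxvol

    if abs(wall_vox[0] - spec.lv_wall_volume) > 0.02 * spec.lv_wall_volume + voxvol:
        raise ValueError(
            f"voxelized wall volume {wall_vox[0]:.1f} ml misses the prescribed "
            f"{spec.lv_wall_volume:.1f} ml"
        )

    sax = LabelledStack(
        labels=labels,
        affine=_sax_affine(spec, xs[0], ys[0], zs[0]),
        voxel_size=(dr, dc),
        slice_thickness=spec.slice_thickness,
        slice_gap=spec.slice_gap,
        frame_times=times,
        view=View.SAX,
    )

    lax4, lax2 = _build_lax_views(spec, geom, rvg, xs, ys, times, s_frames)

    subject = copy.deepcopy(spec.subject)
    subject.rr_interval = spec.rr_interval
    study = CineStudy(sax=sax, lax2ch=lax2, lax4ch=lax4, subject=subject)
    study.provenance["phantom"] = {"spec": spec, "lv_geometry": geom, "rv_geometry": rvg}

    if spec.make_images:
        study.images = _make_images(study, geom, fracs, spec)

    truth = PhantomTruth(
        spec=spec,
        frame_fracs=fracs,
        times=times,
        lv_analytic=spec.lv.volume(fracs),
        lv_voxel=lv_vox,
        wall_voxel=wall_vox,
        rv_analytic=spec.rv.volume(fracs) if spec.rv is not None else None,
        rv_voxel=rv_vox,
        field=AnalyticDisplacementField(geom, fracs, spec.orientation),
        lv_geometry=geom,
        rv_geometry=rvg,
    )
    return study, truth


def _build_lax_views(spec, geom, rvg, xs, ys, times, s_frames):
    """Exact planar resamplings through the long axis (4CH: y=0, 2CH: x=0)."""
    du = spec.lax_voxel
    z_lo, z_hi = -spec.margin, geom.L_epi + spec.margin
    zf = np.arange(z_lo, z_hi + du, du)

    def lax_labels(us, plane: str):
        lab = np.zeros((len(us), len(zf), 1, spec.n_frames), dtype=np.uint8)
        for k in range(spec.n_frames):
            s = float(s_frames[k])
            if plane == "4ch":
                x, y = us, np.zeros(1)
            else:
                x, y = np.zeros(1), us
            pool, myo = _voxelize_lv(geom, x, y, zf, s)
            # _voxelize_lv builds (len(x), len(y), len(z)); squeeze the unit axis
            if plane == "4ch":
                pool, myo = pool[:, 0, :], myo[:, 0, :]
            else:
                pool, myo = pool[0, :, :], myo[0, :, :]
            frame = np.zeros((len(us), len(zf)), dtype=np.uint8)
            frame[pool] = LV_POOL
            frame[myo] = LV_MYO
            if rvg is not None:
                if plane == "4ch":
                    rv = _voxelize_rv(rvg, us, np.zeros(1), zf, float(rvg.q[k]), s)[:, 0, :]
                else:
                    rv = _voxelize_rv(rvg, np.zeros(1), us, zf, float(rvg.q[k]), s)[0, :, :]
                frame[rv & (frame == 0)] = RV_POOL
            lab[:, :, 0, k] = frame
        return lab

    thickness = 6.0

    def lax_affine(row_axis: np.ndarray, u0: float, normal: np.ndarray) -> np.ndarray:
        A = np.eye(4)
        A[:3, 0] = row_axis * du
        A[:3, 1] = np.array([0.0, 0.0, 1.0]) * du
        A[:3, 2] = normal * thickness
        A[:3, 3] = row_axis * u0 + np.array([0.0, 0.0, zf[0]])
        return _rotate_affine(A, spec.orientation)

    us4 = np.arange(xs[0], xs[-1] + du, du)
    lab4 = lax_labels(us4, "4ch")
    lax4 = LabelledStack(
        labels=lab4,
        affine=lax_affine(np.array([1.0, 0.0, 0.0]), us4[0], np.array([0.0, 1.0, 0.0])),
        voxel_size=(du, du),
        slice_thickness=thickness,
        slice_gap=0.0,
        frame_times=times,
        view=View.LAX4CH,
    )
    us2 = np.arange(ys[0], ys[-1] + du, du)
    lab2 = lax_labels(us2, "2ch")
    lax2 = LabelledStack(
        labels=lab2,
        affine=lax_affine(np.array([0.0, 1.0, 0.0]), us2[0], np.array([1.0, 0.0, 0.0])),
        voxel_size=(du, du),
        slice_thickness=thickness,
        slice_gap=0.0,
        frame_times=times,
        view=View.LAX2CH,
    )
    return lax4, lax2


def _make_images(study: CineStudy, geom: _LVGeometry, fracs, spec: PhantomSpec) -> dict:
    """Pseudo-intensity cines: tissue-class levels plus a texture that moves
    with the deformation (so image-based trackers have something to follow)."""
    rng = np.random.default_rng(spec.seed)
    levels = np.array([0.15, 0.9, 0.5, 0.8])  # bg, pool, myo, rv
    images: dict[str, np.ndarray] = {}
    for stk in study.stacks():
        lab = stk.labels
        base_ed = levels[lab[:, :, :, 0]]
        texture = ndimage.gaussian_filter(
            rng.normal(0.0, 1.0, size=lab.shape[:3]), sigma=1.5
        )
        img = np.zeros(lab.shape, dtype=np.float32)
        # voxel centre world coords for the inverse warp
        nr, nc, ns = lab.shape[:3]
        rr, cc, ss = np.meshgrid(
            np.arange(nr), np.arange(nc), np.arange(ns), indexing="ij"
        )
        homog = np.stack([rr, cc, ss, np.ones_like(rr)], axis=-1).reshape(-1, 4).T
        world = (stk.affine @ homog)[:3].T
        if spec.orientation is not None:
            world = world @ spec.orientation  # to canonical
        x, y, z = world[:, 0], world[:, 1], world[:, 2]
        r = np.hypot(x, y)
        inv_affine = np.linalg.inv(stk.affine)
        for k in range(lab.shape[3]):
            s = float(geom.scale(fracs[k]))
            r0 = geom.undeform_radius(r, z, s)
            ratio = np.where(r > 1e-9, r0 / np.clip(r, 1e-9, None), 1.0)
            canon0 = np.stack([x * ratio, y * ratio, z], axis=1)
            w0 = canon0 @ spec.orientation.T if spec.orientation is not None else canon0
            vox0 = (inv_affine @ np.concatenate([w0, np.ones((len(w0), 1))], axis=1).T)[:3]
            tex_k = ndimage.map_coordinates(texture, vox0, order=1, mode="nearest")
            frame = levels[lab[:, :, :, k]] + 0.12 * tex_k.reshape(nr, nc, ns)
            img[:, :, :, k] = frame
        images[stk.view.value] = img
    return images


# ---------------------------------------------------------------------------
# acquisition-artifact injection
# ---------------------------------------------------------------------------

ARTIFACT_KINDS = (
    "missing_basal_slices",
    "missing_apical_slices",
    "breathhold_shift",
    "off_axis_tilt",
    "rv_sv_mismatch",
    "frame_corruption",
)


@dataclass
class ArtifactSpec:
    """One injectable acquisition/analysis failure mode.

    magnitude semantics by kind: slice count (missing_*_slices), mm
    (breathhold_shift), degrees (off_axis_tilt), fractional SV deficit
    (rv_sv_mismatch), ignored (frame_corruption).
    """

    kind: str
    magnitude: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        limits = {
            "missing_basal_slices": (0, 20),
            "missing_apical_slices": (0, 20),
            "breathhold_shift": (0.0, 30.0),
            "off_axis_tilt": (0.0, 60.0),
            "rv_sv_mismatch": (0.0, 0.9),
            "frame_corruption": (0.0, 1.0),
        }
        lo, hi = limits[self.kind]
        if not lo <= self.magnitude <= hi:
            raise ValueError(f"{self.kind} magnitude {self.magnitude} outside [{lo}, {hi}]")


def inject_artifact(study: CineStudy, art: ArtifactSpec, seed: int = 0) -> CineStudy:
    """Return a copy of the study with one artifact applied.

    Details of what was actually applied (slice index, shift vector, frame)
    are recorded in ``study.provenance['artifacts']`` for ground-truth use.
    """
    rng = np.random.default_rng(seed)
    out = study.copy()
    info: dict = {"kind": art.kind, "magnitude": art.magnitude}

    if art.kind in ("missing_basal_slices", "missing_apical_slices"):
        k = int(round(art.magnitude))
        ns = out.sax.n_slices
        if k >= ns:
            raise ValueError("cannot remove all SAX slices")
        if k > 0:
            if art.kind == "missing_basal_slices":
                out.sax.labels = out.sax.labels[:, :, k:, :]
                shift_world = out.sax.affine[:3, 2] * k
                out.sax.affine = out.sax.affine.copy()
                out.sax.affine[:3, 3] += shift_world
                if out.images and "SAX" in out.images:
                    out.images["SAX"] = out.images["SAX"][:, :, k:, :]
            else:
                out.sax.labels = out.sax.labels[:, :, : ns - k, :]
                if out.images and "SAX" in out.images:
                    out.images["SAX"] = out.images["SAX"][:, :, : ns - k, :]
        info["removed"] = k

    elif art.kind == "breathhold_shift":
        ns = out.sax.n_slices
        sl = int(rng.integers(ns // 3, max(ns // 3 + 1, 2 * ns // 3)))
        theta = float(rng.uniform(0, 2 * np.pi))
        dr, dc = out.sax.voxel_size
        # quantize to whole voxels so the injected ground truth is exact
        vr = round(art.magnitude * np.cos(theta) / dr)
        vc = round(art.magnitude * np.sin(theta) / dc)
        if vr == 0 and vc == 0:
            vr = round(art.magnitude / dr)
        shifted = np.zeros_like(out.sax.labels[:, :, sl, :])
        for k in range(out.sax.n_frames):
            shifted[:, :, k] = ndimage.shift(
                out.sax.labels[:, :, sl, k], (vr, vc), order=0, cval=0
            )
        out.sax.labels = out.sax.labels.copy()
        out.sax.labels[:, :, sl, :] = shifted
        info.update({"slice": sl, "shift_mm": (vr * dr, vc * dc)})

    elif art.kind == "off_axis_tilt":
        # tilt the 4-chamber plane about its in-plane row axis, anchored near
        # the base so the basal intersection survives but the apex walks off
        stk = out.lax4ch
        axis = stk.affine[:3, 0] / np.linalg.norm(stk.affine[:3, 0])
        anchor = study.sax.affine @ np.array(
            [study.sax.labels.shape[0] / 2.0, study.sax.labels.shape[1] / 2.0, 1.0, 1.0]
        )
        anchor = anchor[:3]
        ang = np.deg2rad(art.magnitude)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
        T = np.eye(4)
        T[:3, :3] = R
        T[:3, 3] = anchor - R @ anchor
        stk.affine = T @ stk.affine
        info["tilt_deg"] = art.magnitude

    elif art.kind == "rv_sv_mismatch":
        _inject_rv_sv_mismatch(out, art.magnitude, info)

    elif art.kind == "frame_corruption":
        f = int(rng.integers(1, out.n_frames))
        out.sax.labels = out.sax.labels.copy()
        out.sax.labels[:, :, :, f] = out.sax.labels[:, :, :, f - 1]
        info["frame"] = f

    out.provenance.setdefault("artifacts", []).append(info)
    return out


def _measured_curve(stack: LabelledStack, label: int) -> np.ndarray:
    dr, dc = stack.voxel_size
    voxvol = dr * dc * stack.slice_spacing / 1000.0
    return np.array(
        [np.count_nonzero(stack.labels[:, :, :, k] == label) for k in range(stack.n_frames)]
    ) * voxvol


def _inject_rv_sv_mismatch(out: CineStudy, magnitude: float, info: dict) -> None:
    """Rescale the RV systolic excursion so RV SV = LV SV x (1 - magnitude)."""
    lv = _measured_curve(out.sax, LV_POOL)
    rv = _measured_curve(out.sax, RV_POOL)
    lv_sv = lv.max() - lv.min()
    rv_sv = rv.max() - rv.min()
    if rv_sv <= 0 or lv_sv <= 0:
        raise ValueError("rv_sv_mismatch needs non-trivial LV and RV excursions")
    target_sv = lv_sv * (1.0 - magnitude)
    kappa = target_sv / rv_sv
    target = rv[0] - (rv[0] - rv) * kappa

    prov = out.provenance.get("phantom")
    if (
        prov is not None
        and prov.get("rv_geometry") is not None
        and prov["spec"].orientation is None
    ):
        # exact path: re-voxelize the RV from the generating geometry, with the
        # per-frame scale recalibrated toward the adjusted volume curve
        rvg: _RVGeometry = prov["rv_geometry"]
        spec: PhantomSpec = prov["spec"]
        geom: _LVGeometry = prov["lv_geometry"]
        fracs = np.arange(out.n_frames) / out.n_frames
        s_lv = geom.scale(fracs)
        sax = out.sax
        nr, nc, ns = sax.labels.shape[:3]
        xs = sax.affine[0, 3] + np.arange(nr) * sax.affine[0, 0]
        ys = sax.affine[1, 3] + np.arange(nc) * sax.affine[1, 1]
        zs = sax.affine[2, 3] + np.arange(ns) * sax.affine[2, 2]
        dr, dc = sax.voxel_size
        voxvol = dr * dc * sax.slice_spacing / 1000.0
        out.sax.labels = sax.labels.copy()
        for k in range(out.n_frames):
            frame = out.sax.labels[:, :, :, k]
            frame[frame == RV_POOL] = BACKGROUND
            rv_mask, _, _ = _calibrate_rv_frame(
                rvg, xs, ys, zs, voxvol, float(target[k]), float(rvg.q[k]), float(s_lv[k])
            )
            frame[rv_mask & (frame == BACKGROUND)] = RV_POOL
        info["path"] = "re-voxelized"
        info["target_sv_ml"] = float(target_sv)
        return
    # fallback: scale the RV mask in-plane about its ED centroid, frame by frame
    sax = out.sax
    out.sax.labels = sax.labels.copy()
    ed = sax.labels[:, :, :, 0] == RV_POOL
    idx = np.nonzero(ed)
    cr, cc_ = idx[0].mean(), idx[1].mean()
    for k in range(out.n_frames):
        frame = out.sax.labels[:, :, :, k]
        mask = (frame == RV_POOL).astype(float)
        s = np.sqrt(target[k] / rv[k])
        nr, nc, ns = mask.shape
        rr, cc2 = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        r0 = cr + (rr - cr) / s
        c0 = cc_ + (cc2 - cc_) / s
        new = np.zeros_like(mask)
        for sl in range(ns):
            new[:, :, sl] = ndimage.map_coordinates(
                mask[:, :, sl], [r0, c0], order=0, cval=0.0
            )
        frame[frame == RV_POOL] = BACKGROUND
        frame[(new > 0.5) & (frame == BACKGROUND)] = RV_POOL
    info["path"] = "mask-scaled"
    info["target_sv_ml"] = float(target_sv)


# ---------------------------------------------------------------------------
# curve dataset for the QC classifiers
# ---------------------------------------------------------------------------

VOLUME_PATHOLOGIES = ("nonclosure", "spike", "clipped_plateau")
STRAIN_PATHOLOGIES = ("sign_flip", "spike", "nonclosure")


@dataclass
class CurveDataset:
    """Labelled exemplar curves for training/evaluating curve-shape QC."""

    curves: list  # list of np.ndarray, one cycle each
    times: np.ndarray
    labels: list  # "good" or a pathology name
    kind: str  # "volume" | "strain"

    @property
    def y(self) -> np.ndarray:
        return np.array([0 if l == "good" else 1 for l in self.labels])


def _random_model(rng: np.random.Generator) -> VolumeCurveModel:
    edv = rng.uniform(110.0, 220.0)
    ef = rng.uniform(0.45, 0.68)
    t_es = rng.uniform(0.30, 0.40)
    w_e = rng.uniform(0.26, 0.34)
    w_a = rng.uniform(0.18, 0.24)
    e_peak = rng.uniform(t_es + w_e / 2.0 + 0.01, 0.58)
    a_hi = 1.0 - w_a / 2.0 - 0.005
    a_lo = min(max(0.80, e_peak + w_e / 2.0 + w_a / 2.0 + 0.01), a_hi - 1e-3)
    a_peak = rng.uniform(a_lo, a_hi)
    e_frac = rng.uniform(0.6, 0.8)
    sv = edv * ef
    return VolumeCurveModel(
        edv=edv,
        esv=edv - sv,
        t_es=t_es,
        e_peak_time=e_peak,
        a_peak_time=a_peak,
        e_wave_width=w_e,
        a_wave_width=w_a,
        e_wave_amplitude=e_frac * sv,
        a_wave_amplitude=(1 - e_frac) * sv,
    )


def make_curve_dataset(
    n_good: int,
    n_bad: int,
    seed: int = 0,
    kind: str = "volume",
    n_frames: int = 50,
    rr_interval: float = 1.0,
) -> CurveDataset:
    """Jittered phantom curves ("good") plus QC-relevant pathologies ("bad").

    Volume pathologies: non-closure drift, a single-frame spike, a clipped
    diastolic plateau.  Strain pathologies: sign flip, spike, non-closure.
    ``n_bad = 0`` yields an all-good set.  Bit-exact for a fixed seed.
    """
    if n_good <= 0:
        raise ValueError("n_good must be positive")
    if n_bad < 0:
        raise ValueError("n_bad must be non-negative")
    if kind not in ("volume", "strain"):
        raise ValueError("kind must be 'volume' or 'strain'")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / n_frames
    times = t * rr_interval
    pathologies = VOLUME_PATHOLOGIES if kind == "volume" else STRAIN_PATHOLOGIES

    def base_curve() -> np.ndarray:
        m = _random_model(rng)
        v = m.volume(t)
        if kind == "strain":
            peak = rng.uniform(-24.0, -12.0)
            v = peak * (m.edv - v) / m.sv
            v = v - v[0]
            noise = 0.25
        else:
            noise = 0.8
        return v + rng.normal(0.0, noise, size=n_frames)

    curves, labels = [], []
    for _ in range(n_good):
        curves.append(base_curve())
        labels.append("good")
    for i in range(n_bad):
        v = base_curve()
        amp = np.ptp(v)
        p = pathologies[i % len(pathologies)]
        if p == "nonclosure":
            v = v + np.linspace(0.0, rng.uniform(0.15, 0.30) * (abs(v).max() + amp), n_frames)
        elif p == "spike":
            f = int(rng.integers(2, n_frames - 2))
            v[f] += rng.choice([-1.0, 1.0]) * 1.5 * amp
        elif p == "clipped_plateau":
            v = np.minimum(v, v.max() - 0.3 * amp)
        elif p == "sign_flip":
            v = -v
        curves.append(v)
        labels.append(p)
    return CurveDataset(curves=curves, times=times, labels=labels, kind=kind)
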