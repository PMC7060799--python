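"""Contour sampling, tracking, and Lagrangian strain."""

import numpy as np
import pytest

from cinequant.model import LV_MYO, LV_POOL, LabelledStack, View
from cinequant.phantom import PhantomSpec, VolumeCurveModel, build_phantom
from cinequant.strain import (
    NiftiDisplacementField,
    TrackedContour,
    _sax_contour_pair,
    compute_strain,
    sample_ed_contours,
    strain_curves,
    track,
)


@pytest.fixture(scope="module")
def strain_study_truth():
    spec = PhantomSpec(
        lv=VolumeCurveModel(edv=179.0, esv=77.0), rv=None,
        n_frames=30, voxel_size=(1.0, 1.0), slice_thickness=4.0, slice_gap=1.0,
        lax_voxel=1.0,
    )
    return build_phantom(spec)


def _annulus_stack(r_in=25.0, r_out=35.0):
    n = 90
    yy, xx = np.mgrid[:n, :n]
    r = np.hypot(xx - n / 2, yy - n / 2)
    lab = np.zeros((n, n, 1, 2), dtype=np.uint8)
    lab[(r <= r_in), :] = 0
    pool = r <= r_in
    myo = (r > r_in) & (r <= r_out)
    for f in range(2):
        lab[pool, 0, f] = LV_POOL
        lab[myo, 0, f] = LV_MYO
    return LabelledStack(
        labels=lab, affine=np.eye(4), voxel_size=(1.0, 1.0),
        slice_thickness=8.0, slice_gap=2.0, frame_times=np.array([0.0, 0.5]),
        view=View.SAX,
    )


class TestContourSampling:
    def test_annulus_midwall_radius(self):
        stack = _annulus_stack(25.0, 35.0)
        pair = _sax_contour_pair(stack, 0, n_points=48)
        centre = pair.midwall.mean(axis=0)
        radii = np.linalg.norm(pair.midwall - centre, axis=1)
        assert radii.mean() == pytest.approx(30.0, abs=0.5)

    def test_arc_length_spacing_uniform_within_5_percent(self):
        stack = _annulus_stack()
        pair = _sax_contour_pair(stack, 0, n_points=48)
        for ring in (pair.endo, pair.epi):
            closed = np.vstack([ring, ring[:1]])
            seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
            assert seg.std() / seg.mean() < 0.05

    def test_phantom_yields_three_pairs_and_two_midlines(self, strain_study_truth):
        study, _ = strain_study_truth
        con = sample_ed_contours(study)
        assert len(con.sax) == 3
        assert set(con.lax_midlines) == {"LAX2CH", "LAX4CH"}
        for pair in con.sax:
            assert pair.endo.shape == (48, 3)

    def test_too_few_slices_rejected(self):
        stack = _annulus_stack()
        from cinequant.model import CineStudy, SubjectMeta

        lax = LabelledStack(
            labels=np.zeros((10, 10, 1, 2), dtype=np.uint8), affine=np.eye(4),
            voxel_size=(1.0, 1.0), slice_thickness=6.0, slice_gap=0.0,
            frame_times=np.array([0.0, 0.5]), view=View.LAX2CH,
        )
        lax4 = LabelledStack(
            labels=np.zeros((10, 10, 1, 2), dtype=np.uint8), affine=np.eye(4),
            voxel_size=(1.0, 1.0), slice_thickness=6.0, slice_gap=0.0,
            frame_times=np.array([0.0, 0.5]), view=View.LAX4CH,
        )
        study = CineStudy(sax=stack, lax2ch=lax, lax4ch=lax4, subject=SubjectMeta())
        with pytest.raises(ValueError, match="SAX slices"):
            sample_ed_contours(study)


class _UniformField:
    def __init__(self, d, n_frames):
        self.d = np.asarray(d, dtype=float)
        self.n_frames = n_frames

    def sample(self, points, frame):
        if frame == 0:
            return np.zeros_like(np.atleast_2d(points))
        return np.broadcast_to(self.d, np.atleast_2d(points).shape).copy()


class TestTracking:
    def test_zero_field_keeps_trajectories_constant(self):
        pts = np.random.default_rng(0).normal(size=(12, 3))
        traj = track(pts, field=_UniformField((0, 0, 0), 5), method="fields")
        assert np.allclose(traj.points, pts[None, :, :])

    def test_uniform_translation_shifts_all_points_exactly(self):
        pts = np.random.default_rng(1).normal(size=(7, 3))
        traj = track(pts, field=_UniformField((2.0, -1.0, 0.5), 4), method="fields")
        assert np.allclose(traj.points[2], pts + [2.0, -1.0, 0.5])
        assert np.allclose(traj.points[0], pts)

    def test_dense_nifti_field_interpolates_constant_exactly(self, strain_study_truth):
        study, _ = strain_study_truth
        sax = study.sax
        data = np.zeros(sax.labels.shape[:3] + (3, 3))
        data[..., 1, :] = (1.5, 0.0, -2.0)
        field = NiftiDisplacementField(data, sax)
        pts = np.array([[0.0, 0.0, 30.0], [10.0, -5.0, 50.0]])
        assert np.allclose(field.sample(pts, 1), [[1.5, 0.0, -2.0]] * 2)
        assert np.allclose(field.sample(pts, 0), 0.0)

    def test_phantom_midwall_tracks_analytic_radius(self, strain_study_truth):
        study, truth = strain_study_truth
        con = sample_ed_contours(study)
        pair = con.sax[1]
        traj = track(pair.midwall, field=truth.field, method="fields",
                     n_frames=study.n_frames)
        es = int(np.argmin(truth.lv_analytic))
        centre = traj.points[es].mean(axis=0)
        r_es = np.linalg.norm(traj.points[es] - centre, axis=1).mean()
        z = pair.midwall[0, 2]
        r0 = np.linalg.norm(pair.midwall - pair.midwall.mean(axis=0), axis=1).mean()
        g = truth.lv_geometry
        expected = float(g.midwall_radius(z, g.scale(truth.frame_fracs[es])) / g.midwall_radius(z, 1.0)) * r0
        assert abs(r_es - expected) < 0.5  # half a voxel


class TestStrainCurves:
    @staticmethod
    def _ring(radius, n=48, z=0.0):
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.stack([radius * np.cos(th), radius * np.sin(th), np.full(n, z)], axis=1)

    def _tracked(self, radii_by_frame, thickness=10.0):
        endo = np.stack([self._ring(r) for r in radii_by_frame])
        epi = np.stack([self._ring(r + thickness) for r in radii_by_frame])
        mid = 0.5 * (endo + epi)
        return {
            "endo": TrackedContour(points=endo, kind="endo"),
            "epi": TrackedContour(points=epi, kind="epi"),
            "midwall": TrackedContour(points=mid, kind="midwall"),
        }

    def _lax(self, scale_by_frame, n=48):
        base = np.stack([np.linspace(-40, 40, n), np.zeros(n), np.zeros(n)], axis=1)
        pts = np.stack([base * s for s in scale_by_frame])
        return TrackedContour(points=pts, kind="lax_midline")

    def test_midwall_scaling_by_0p8_gives_minus_20_percent(self):
        # all rings scaled: midwall radius x0.8 at the second frame
        slc = [self._tracked([30.0, 24.0], thickness=0.0)] * 3
        lax = {"LAX2CH": self._lax([1.0, 1.0]), "LAX4CH": self._lax([1.0, 1.0])}
        rep = strain_curves(slc, lax, times=np.array([0.0, 0.35]))
        assert rep.peaks["ecc"] == pytest.approx(-20.0, abs=1e-9)
        assert rep.tpk_ms["ecc"] == pytest.approx(350.0)

    def test_incompressible_ring_thickens_radially(self):
        r_in0, r_out0 = 25.0, 35.0
        r_in1 = 20.0
        r_out1 = np.sqrt(r_out0**2 - r_in0**2 + r_in1**2)  # area preserved
        endo = np.stack([self._ring(r_in0), self._ring(r_in1)])
        epi = np.stack([self._ring(r_out0), self._ring(r_out1)])
        slc = {
            "endo": TrackedContour(points=endo, kind="endo"),
            "epi": TrackedContour(points=epi, kind="epi"),
            "midwall": TrackedContour(points=0.5 * (endo + epi), kind="midwall"),
        }
        lax = {"LAX2CH": self._lax([1.0, 1.0]), "LAX4CH": self._lax([1.0, 1.0])}
        rep = strain_curves([slc], lax, times=np.array([0.0, 0.35]))
        expected = 100.0 * ((r_out1 - r_in1) / (r_out0 - r_in0) - 1.0)
        assert rep.peaks["err"] == pytest.approx(expected, rel=1e-6)
        assert rep.peaks["err"] > 0

    def test_strain_zero_at_ed_exactly(self, strain_study_truth):
        study, truth = strain_study_truth
        rep = compute_strain(study, field=truth.field)
        assert rep.ecc[0] == 0.0
        assert rep.err[0] == 0.0
        assert rep.ell_2ch[0] == 0.0

    def test_strain_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(5)
        radii = [30.0, 26.0, 24.0, 27.0]
        slc = self._tracked(radii)
        # random rotation + translation applied to every frame's contours
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        t = rng.normal(scale=30, size=3)
        moved = {
            k: TrackedContour(points=v.points @ Q.T + t, kind=v.kind)
            for k, v in slc.items()
        }
        lax = {"LAX2CH": self._lax([1, 0.98, 0.97, 0.99]), "LAX4CH": self._lax([1, 1, 1, 1])}
        lax_moved = {
            k: TrackedContour(points=v.points @ Q.T + t, kind=v.kind)
            for k, v in lax.items()
        }
        times = np.array([0.0, 0.2, 0.35, 0.6])
        a = strain_curves([slc] * 3, lax, times)
        b = strain_curves([moved] * 3, lax_moved, times)
        for x, y in ((a.ecc, b.ecc), (a.err, b.err), (a.ell_2ch, b.ell_2ch)):
            assert np.allclose(x, y, atol=1e-9)

    def test_degenerate_contour_rejected(self):
        slc = self._tracked([1.0, 1.0], thickness=0.5)
        lax = {"LAX2CH": self._lax([1, 1]), "LAX4CH": self._lax([1, 1])}
        with pytest.raises(ValueError, match="degenerate"):
            strain_curves([slc], lax, times=np.array([0.0, 0.5]))

    def test_phantom_peak_ecc_matches_analytic(self, strain_study_truth):
        study, truth = strain_study_truth
        con = sample_ed_contours(study)
        rep = compute_strain(study, field=truth.field)
        es = int(np.argmin(truth.lv_analytic))
        zs = [p.midwall[0, 2] for p in con.sax]
        expected = float(np.mean([truth.ecc_midwall(z, es) for z in zs]))
        assert rep.peaks["ecc"] == pytest.approx(expected, abs=1.0)


class TestDemonsTracker:
    def test_builtin_tracker_recovers_contractile_motion_roughly(self):
        spec = PhantomSpec(
            lv=VolumeCurveModel(edv=179.0, esv=77.0), rv=None,
            n_frames=10, voxel_size=(1.5, 1.5), slice_thickness=6.0, slice_gap=0.0,
            lax_voxel=1.5, make_images=True, seed=4,
        )
        study, truth = build_phantom(spec)
        rep = compute_strain(study, method="demons")
        # a simple frame-to-frame demons underestimates, but must see
        # clearly negative circumferential strain at end-systole
        assert rep.peaks["ecc"] < -5.0
        assert rep.ecc[0] == 0.0
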