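"""Phantom generator: analytic curve, voxelization fidelity, artifacts."""

import numpy as np
import pytest

from cinequant.model import LV_MYO, LV_POOL, RV_POOL
from cinequant.phantom import (
    ArtifactSpec,
    PhantomSpec,
    VolumeCurveModel,
    analytic_volume,
    build_phantom,
    inject_artifact,
    make_curve_dataset,
)
from cinequant.volumetrics import cycle_parameters, volume_curve


class TestVolumeCurveModel:
    def test_endpoints_and_end_systole(self):
        m = VolumeCurveModel(edv=179.0, esv=77.0)
        assert analytic_volume(m, 0.0) == pytest.approx(179.0)
        assert analytic_volume(m, m.t_es) == pytest.approx(77.0, abs=0.1)
        assert analytic_volume(m, 1.0) == pytest.approx(179.0, abs=0.1)

    def test_rate_integrates_to_zero_over_cycle(self):
        from scipy.integrate import quad

        m = VolumeCurveModel(edv=150.0, esv=60.0)
        total, _ = quad(lambda t: m.rate(t, rr_interval=1.0), 0.0, 1.0, limit=400)
        assert abs(total) < 1e-6

    def test_minimum_equals_esv(self):
        m = VolumeCurveModel(edv=140.0, esv=55.0)
        t = np.linspace(0, 1, 4001)
        assert analytic_volume(m, t).min() == pytest.approx(55.0, abs=0.1)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"edv": 70.0, "esv": 80.0},  # edv < esv
            {"edv": 100.0, "esv": -5.0},
            {"edv": 150.0, "esv": 60.0, "e_wave_amplitude": 30.0, "a_wave_amplitude": 30.0},
            {"edv": 150.0, "esv": 60.0, "a_peak_time": 0.99, "a_wave_width": 0.3},
        ],
    )
    def test_invalid_models_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VolumeCurveModel(**kwargs)

    def test_closed_form_peaks_match_dense_sampling(self):
        m = VolumeCurveModel(edv=179.0, esv=77.0)
        t = np.linspace(0, 1, 20001)
        r = m.rate(t)
        assert (-r).max() == pytest.approx(m.peak_ejection_rate(), rel=1e-4)
        assert r.max() == pytest.approx(m.peak_early_filling_rate(), rel=1e-4)


class TestBuildPhantom:
    def test_voxelized_edv_within_one_percent_at_1mm(self):
        spec = PhantomSpec(
            lv=VolumeCurveModel(edv=179.0, esv=77.0), rv=None,
            n_frames=2, voxel_size=(1.0, 1.0), slice_thickness=1.0, slice_gap=0.0,
        )
        _, truth = build_phantom(spec)
        assert truth.lv_voxel[0] == pytest.approx(179.0, rel=0.01)

    def test_wall_volume_constant_over_cycle(self, coarse_truth):
        wall = coarse_truth.wall_voxel
        assert np.all(np.abs(wall - wall[0]) < 0.02 * wall[0] + 0.5)

    def test_zero_motion_phantom_has_zero_fields_and_constant_curve(self):
        spec = PhantomSpec(
            lv=VolumeCurveModel(edv=120.0, esv=120.0), rv=None, n_frames=8,
        )
        study, truth = build_phantom(spec)
        pts = np.array([[10.0, 5.0, 30.0], [0.0, 20.0, 60.0], [25.0, 0.0, 10.0]])
        for k in range(8):
            assert np.allclose(truth.field.sample(pts, k), 0.0, atol=1e-12)
        assert np.ptp(truth.lv_voxel) == 0.0

    def test_field_is_zero_at_frame_zero(self, coarse_truth):
        pts = np.array([[5.0, 5.0, 40.0], [-20.0, 10.0, 20.0]])
        assert np.allclose(coarse_truth.field.sample(pts, 0), 0.0, atol=1e-12)

    def test_build_is_deterministic(self, coarse_spec, coarse_study):
        again, _ = build_phantom(coarse_spec)
        assert np.array_equal(again.sax.labels, coarse_study.sax.labels)
        assert np.array_equal(again.lax4ch.labels, coarse_study.lax4ch.labels)

    def test_rv_voxel_curve_tracks_prescription(self, coarse_truth):
        rel = np.abs(coarse_truth.rv_voxel - coarse_truth.rv_analytic) / coarse_truth.rv_analytic
        assert rel.max() < 0.015

    def test_midwall_strain_ground_truth_from_ring_scaling(self):
        # if the mid-wall ring radius scales by r'/r at ES, the analytic
        # circumferential strain is exactly 100 (r'/r - 1)
        spec = PhantomSpec(lv=VolumeCurveModel(edv=179.0, esv=77.0), rv=None)
        _, truth = build_phantom(spec)
        g = truth.lv_geometry
        z = 40.0
        es = int(np.argmin(truth.lv_analytic))
        s = g.scale(truth.frame_fracs[es])
        expected = 100.0 * (g.midwall_radius(z, s) / g.midwall_radius(z, 1.0) - 1.0)
        assert truth.ecc_midwall(z, es) == pytest.approx(float(expected), abs=1e-9)
        assert truth.ecc_midwall(z, 0) == pytest.approx(0.0, abs=1e-12)


class TestArtifacts:
    def test_missing_basal_zero_is_noop(self, coarse_study):
        out = inject_artifact(coarse_study, ArtifactSpec("missing_basal_slices", 0))
        assert np.array_equal(out.sax.labels, coarse_study.sax.labels)
        assert np.allclose(out.sax.affine, coarse_study.sax.affine)

    def test_missing_basal_removes_slices_and_shifts_origin(self, coarse_study):
        out = inject_artifact(coarse_study, ArtifactSpec("missing_basal_slices", 2))
        assert out.sax.n_slices == coarse_study.sax.n_slices - 2
        shift = out.sax.affine[:3, 3] - coarse_study.sax.affine[:3, 3]
        assert np.allclose(shift, coarse_study.sax.affine[:3, 2] * 2)

    def test_removing_all_slices_is_an_error(self, coarse_study):
        art = ArtifactSpec("missing_apical_slices", coarse_study.sax.n_slices)
        with pytest.raises(ValueError, match="all SAX slices"):
            inject_artifact(coarse_study, art)

    def test_rv_sv_mismatch_hits_target_ratio(self, coarse_study):
        out = inject_artifact(coarse_study, ArtifactSpec("rv_sv_mismatch", 0.2), seed=1)
        lv = cycle_parameters(volume_curve(out.sax, "LV"))
        rv = cycle_parameters(volume_curve(out.sax, "RV"))
        assert rv.sv / lv.sv == pytest.approx(0.8, abs=0.02)

    def test_frame_corruption_duplicates_previous_frame(self, coarse_study):
        out = inject_artifact(coarse_study, ArtifactSpec("frame_corruption"), seed=9)
        f = out.provenance["artifacts"][-1]["frame"]
        assert f >= 1
        assert np.array_equal(out.sax.labels[..., f], out.sax.labels[..., f - 1])
        assert not np.array_equal(
            coarse_study.sax.labels[..., f], coarse_study.sax.labels[..., f - 1]
        )

    def test_breathhold_shift_records_applied_vector(self, coarse_study):
        out = inject_artifact(coarse_study, ArtifactSpec("breathhold_shift", 8.0), seed=2)
        info = out.provenance["artifacts"][-1]
        applied = np.hypot(*info["shift_mm"])
        assert applied == pytest.approx(8.0, abs=max(coarse_study.sax.voxel_size))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown artifact kind"):
            ArtifactSpec("gamma_spike", 1.0)


class TestCurveDataset:
    def test_all_good_when_no_bad_requested(self):
        ds = make_curve_dataset(10, 0, seed=0)
        assert all(l == "good" for l in ds.labels)

    def test_spike_pathology_is_a_single_gross_outlier(self):
        from scipy.signal import medfilt

        ds = make_curve_dataset(1, 30, seed=3, kind="volume")
        spikes = [c for c, l in zip(ds.curves, ds.labels) if l == "spike"]
        assert spikes
        for v in spikes:
            trend = medfilt(v, kernel_size=5)
            resid = np.abs(v - trend)
            sd = np.std(np.sort(resid)[:-3])  # robust, spike excluded
            assert resid.max() > 5 * sd
            # the spike dominates: nothing else comes close
            assert np.sum(resid > 0.2 * resid.max()) == 1

    def test_bit_exact_reproducibility(self):
        a = make_curve_dataset(15, 10, seed=11, kind="strain")
        b = make_curve_dataset(15, 10, seed=11, kind="strain")
        assert a.labels == b.labels
        assert all(np.array_equal(x, y) for x, y in zip(a.curves, b.curves))

    def test_strain_sign_flip_pathology_present(self):
        ds = make_curve_dataset(1, 6, seed=2, kind="strain")
        flipped = [c for c, l in zip(ds.curves, ds.labels) if l == "sign_flip"]
        assert flipped and all(np.max(c) > abs(np.min(c)) for c in flipped)
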