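"""Rigid landmark registration: recovery, optimality, refinement, resampling."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pulmoquant.errors import DegenerateGeometryError, PairingError
from pulmoquant.registration import fit_rigid, refine_by_worst_landmark, resample
from pulmoquant.volume import LandmarkSet, RigidTransform, Volume3D


def _random_rigid(rng) -> RigidTransform:
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31 - 1))).as_matrix()
    t = rng.uniform(-10, 10, size=3)
    return RigidTransform(R, t)


def _random_landmarks(rng, n=5) -> LandmarkSet:
    pts = rng.uniform(-15, 15, size=(n, 3))
    return LandmarkSet({f"p{i}": p for i, p in enumerate(pts)}, frame="moving")


class TestFitRigid:
    def test_identical_sets_give_identity(self):
        rng = np.random.default_rng(0)
        m = _random_landmarks(rng)
        rep = fit_rigid(m, m)
        assert np.allclose(rep.transform.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(rep.transform.translation_mm, 0, atol=1e-12)
        assert rep.rms_mm < 1e-12

    def test_pure_translation_recovered(self):
        rng = np.random.default_rng(1)
        m = _random_landmarks(rng)
        f = LandmarkSet({n: m[n] + np.array([5.0, 0, 0]) for n in m.names}, frame="fixed")
        rep = fit_rigid(m, f)
        assert np.allclose(rep.transform.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(rep.transform.translation_mm, [5, 0, 0], atol=1e-12)
        assert rep.rms_mm < 1e-12

    def test_random_rigid_transforms_recovered_exactly(self):
        """100 seeded random transforms from 5 noiseless pairs, RMS < 1e-9 mm."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            m = _random_landmarks(rng)
            true = _random_rigid(rng)
            f = m.transformed(true, frame="fixed")
            rep = fit_rigid(m, f)
            assert rep.rms_mm < 1e-9
            assert np.allclose(rep.transform.rotation, true.rotation, atol=1e-9)
            assert np.allclose(
                rep.transform.translation_mm, true.translation_mm, atol=1e-9
            )

    def test_agrees_with_scipy_align_vectors(self):
        """Independent cross-check of the Kabsch fit on noisy pairs."""
        rng = np.random.default_rng(3)
        m = _random_landmarks(rng, n=6)
        true = _random_rigid(rng)
        f_pts = true.apply(m.as_array()) + rng.normal(0, 0.5, size=(6, 3))
        f = LandmarkSet(dict(zip(m.names, f_pts)), frame="fixed")
        rep = fit_rigid(m, f)

        mc = m.as_array() - m.as_array().mean(axis=0)
        fc = f_pts - f_pts.mean(axis=0)
        R_ref, _ = Rotation.align_vectors(fc, mc)
        assert np.allclose(rep.transform.rotation, R_ref.as_matrix(), atol=1e-9)

    def test_least_squares_optimality_against_random_rivals(self):
        """No rival rigid transform achieves a lower residual RMS."""
        rng = np.random.default_rng(4)
        m = _random_landmarks(rng, n=6)
        true = _random_rigid(rng)
        f_pts = true.apply(m.as_array()) + rng.normal(0, 1.0, size=(6, 3))
        f = LandmarkSet(dict(zip(m.names, f_pts)), frame="fixed")
        rep = fit_rigid(m, f)
        for _ in range(200):
            rival = _random_rigid(rng)
            res = rival.apply(m.as_array()) - f_pts
            rival_rms = np.sqrt((res**2).sum(axis=1).mean())
            assert rep.rms_mm <= rival_rms + 1e-12

    def test_equivariance_under_common_rotation(self):
        """Pre-rotating both sets conjugates the fit and preserves the RMS."""
        rng = np.random.default_rng(5)
        m = _random_landmarks(rng, n=5)
        true = _random_rigid(rng)
        f_pts = true.apply(m.as_array()) + rng.normal(0, 0.3, size=(5, 3))
        f = LandmarkSet(dict(zip(m.names, f_pts)), frame="fixed")
        rep = fit_rigid(m, f)

        Q = _random_rigid(rng)
        mq = m.transformed(Q)
        fq = LandmarkSet(dict(zip(m.names, Q.apply(f_pts))), frame="fixed")
        rep_q = fit_rigid(mq, fq)
        conjugated = Q.compose(rep.transform).compose(Q.inverse())
        assert rep_q.rms_mm == pytest.approx(rep.rms_mm, abs=1e-9)
        assert np.allclose(rep_q.transform.rotation, conjugated.rotation, atol=1e-8)

    def test_degenerate_inputs_rejected(self):
        two = LandmarkSet({"a": (0, 0, 0), "b": (1, 0, 0)})
        with pytest.raises(DegenerateGeometryError):
            fit_rigid(two, two)
        collinear = LandmarkSet({"a": (0, 0, 0), "b": (1, 0, 0), "c": (2, 0, 0)})
        with pytest.raises(DegenerateGeometryError, match="collinear"):
            fit_rigid(collinear, collinear)
        m = LandmarkSet({"a": (0, 0, 0), "b": (1, 0, 0), "c": (0, 1, 0)})
        f = LandmarkSet({"a": (0, 0, 0), "b": (1, 0, 0), "x": (0, 1, 0)})
        with pytest.raises(PairingError):
            fit_rigid(m, f)

    def test_reflection_never_returned(self):
        """A mirrored configuration still yields det(R) = +1."""
        m = LandmarkSet({"a": (1, 0, 0), "b": (0, 1, 0), "c": (0, 0, 1), "d": (0, 0, 0)})
        f = LandmarkSet(
            {"a": (-1, 0, 0), "b": (0, 1, 0), "c": (0, 0, 1), "d": (0, 0, 0)}
        )
        rep = fit_rigid(m, f)
        assert np.linalg.det(rep.transform.rotation) == pytest.approx(1.0)


class TestRefinement:
    def _exact_plus_outlier(self):
        rng = np.random.default_rng(6)
        m = _random_landmarks(rng, n=6)
        true = _random_rigid(rng)
        f_pts = true.apply(m.as_array())
        f_pts[2] += np.array([4.0, -3.0, 2.0])  # corrupt one pick
        f = LandmarkSet(dict(zip(m.names, f_pts)), frame="fixed")
        return m, f, true

    def test_excluding_worst_outlier_restores_exact_fit(self):
        m, f, true = self._exact_plus_outlier()
        rep = fit_rigid(m, f)
        assert rep.rms_mm > 0.5
        assert rep.worst_landmark == "p2"
        refined = refine_by_worst_landmark(rep, exclude=True)
        assert refined.rms_mm < 1e-9
        assert "p2" in refined.excluded
        assert np.allclose(refined.transform.rotation, true.rotation, atol=1e-9)

    def test_replacement_with_corrected_pick(self):
        m, f, true = self._exact_plus_outlier()
        rep = fit_rigid(m, f)
        # re-pick the worst landmark at its true moving position
        corrected = LandmarkSet({"p2": true.inverse().apply(f["p2"])})
        refined = refine_by_worst_landmark(rep, replacement=corrected)
        assert refined.rms_mm < 1e-9

    def test_replacement_with_identical_coordinates_is_idempotent(self):
        rng = np.random.default_rng(7)
        m = _random_landmarks(rng, n=5)
        f = m.transformed(_random_rigid(rng), frame="fixed")
        rep = fit_rigid(m, f)
        same = refine_by_worst_landmark(rep, replacement=m.subset([rep.worst_landmark]))
        assert np.allclose(same.transform.rotation, rep.transform.rotation, atol=1e-12)
        assert same.rms_mm == pytest.approx(rep.rms_mm, abs=1e-12)

    def test_exact_report_refinement_noop_on_rms(self):
        rng = np.random.default_rng(8)
        m = _random_landmarks(rng, n=5)
        f = m.transformed(_random_rigid(rng), frame="fixed")
        rep = fit_rigid(m, f)
        refined = refine_by_worst_landmark(rep, exclude=True)
        assert refined.rms_mm < 1e-9

    def test_exclusion_below_three_rejected(self):
        m = LandmarkSet({"a": (0, 0, 0), "b": (1, 0, 0), "c": (0, 1, 0)})
        rep = fit_rigid(m, m)
        with pytest.raises(DegenerateGeometryError):
            refine_by_worst_landmark(rep, exclude=True)


class TestResample:
    def _vol(self, data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
        return Volume3D(np.asarray(data, float), spacing, origin, modality="PET")

    def test_identity_on_own_grid(self):
        rng = np.random.default_rng(9)
        vol = self._vol(rng.uniform(size=(8, 9, 10)))
        out = resample(vol, RigidTransform.identity(), vol)
        assert np.allclose(out.data, vol.data, atol=1e-12)
        assert out.modality == "PET"

    def test_constant_volume_constant_inside_fill_outside(self):
        vol = self._vol(np.full((10, 10, 10), 7.0))
        t = RigidTransform.from_euler_deg((0, 0, 10), (3, 0, 0))
        out = resample(vol, t, vol, fill=-1.0)
        assert out.data.max() == pytest.approx(7.0)
        assert out.data.min() == pytest.approx(-1.0)
        interior = out.data[4:6, 4:6, 4:6]
        assert np.allclose(interior, 7.0)

    def test_round_trip_bounded_by_interpolation(self):
        rng = np.random.default_rng(10)
        smooth = np.zeros((16, 16, 16))
        smooth[4:12, 4:12, 4:12] = 1.0
        from scipy.ndimage import gaussian_filter

        vol = self._vol(gaussian_filter(smooth, 2.0))
        t = RigidTransform.from_euler_deg((0, 0, 7), (0.4, -0.3, 0.2), centre_mm=(8, 8, 8))
        back = resample(resample(vol, t, vol), t.inverse(), vol)
        core = (slice(4, 12),) * 3
        # two trilinear passes on a sigma-2-smoothed unit step stay within
        # a few percent away from the boundary
        assert np.abs(back.data[core] - vol.data[core]).max() < 0.05
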