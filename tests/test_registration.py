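import numpy as np
import pytest

from articuvel.core import FrameSeries
from articuvel.registration import (CostBreakdown, DisplacementField,
                                    RegParams, TrackedTrajectory,
                                    average_annotations, build_gradients,
                                    cost, propagate_point, register)


def _bilinear_clamped(img, r, c):
    """Scalar bilinear sample with edge clamping (oracle helper)."""
    h, w = img.shape
    r = min(max(r, 0.0), h - 1.0)
    c = min(max(c, 0.0), w - 1.0)
    r0, c0 = int(np.floor(r)), int(np.floor(c))
    r1, c1 = min(r0 + 1, h - 1), min(c0 + 1, w - 1)
    fr, fc = r - r0, c - c0
    return ((1 - fr) * (1 - fc) * img[r0, c0] + (1 - fr) * fc * img[r0, c1]
            + fr * (1 - fc) * img[r1, c0] + fr * fc * img[r1, c1])


def brute_force_cost(u: DisplacementField, frames: np.ndarray,
                     p: RegParams) -> CostBreakdown:
    """Literal scalar-loop implementation of C(u) = S(u) + lam R(u)."""
    nt, h, w = u.shape
    s = 0.0
    for k in range(nt):
        for r in range(h):
            for c in range(w):
                warped = _bilinear_clamped(frames[k], r - u.u_y[k, r, c],
                                           c - u.u_x[k, r, c])
                s += (warped - frames[k + 1, r, c]) ** 2
    reg = 0.0
    for comp in (u.u_x, u.u_y):
        for k in range(nt):
            for r in range(h):
                for c in range(w):
                    dx = comp[k, r, c + 1] - comp[k, r, c] if c + 1 < w else 0.0
                    dy = comp[k, r + 1, c] - comp[k, r, c] if r + 1 < h else 0.0
                    dt = (comp[k + 1, r, c] - comp[k, r, c]) / p.v0 \
                        if k + 1 < nt else 0.0
                    reg += dx * dx + dy * dy + dt * dt
    return CostBreakdown(total=s + p.lam * reg, similarity=s, regularity=reg)


def _blob_frame(h, w, cy, cx, sigma=3.0):
    Y, X = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    return np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * sigma**2))


class TestBuildGradients:
    def test_constant_along_x_in_nullspace(self):
        gx, _, _ = build_gradients((2, 3, 4))
        field = np.tile(np.arange(6).reshape(2, 3, 1), (1, 1, 4)).astype(float)
        assert np.allclose(gx @ field.ravel(), 0.0)

    def test_time_constant_in_gt_nullspace(self):
        _, _, gt = build_gradients((3, 2, 2))
        field = np.tile(np.arange(4).reshape(1, 2, 2), (3, 1, 1)).astype(float)
        assert np.allclose(gt @ field.ravel(), 0.0)

    def test_forward_difference_with_replicated_boundary(self):
        # hand-computed: (1, 2, 4) -> (1, 2, 0)
        gx, _, _ = build_gradients((1, 1, 3))
        np.testing.assert_allclose(gx @ np.array([1.0, 2.0, 4.0]),
                                   [1.0, 2.0, 0.0])

    def test_operator_shapes(self):
        gx, gy, gt = build_gradients((2, 3, 4))
        n = 2 * 3 * 4
        for g in (gx, gy, gt):
            assert g.shape == (n, n)


class TestCost:
    def test_identical_frames_zero_field_is_exact_minimum(self):
        frames = np.tile(_blob_frame(8, 8, 4, 4), (3, 1, 1))
        u = DisplacementField.zeros(2, 8, 8)
        c = cost(u, frames)
        assert c.total == 0.0 and c.similarity == 0.0 and c.regularity == 0.0

    def test_zero_field_gives_plain_ssd(self, rng):
        frames = rng.uniform(0, 1, (3, 5, 5))
        u = DisplacementField.zeros(2, 5, 5)
        c = cost(u, frames)
        ssd = float(np.sum((frames[:-1] - frames[1:]) ** 2))
        assert c.similarity == pytest.approx(ssd, rel=1e-12)
        assert c.regularity == 0.0

    def test_total_is_similarity_plus_lam_regularity(self, rng):
        frames = rng.uniform(0, 1, (4, 6, 6))
        u = DisplacementField(rng.normal(0, 0.5, (3, 6, 6)),
                              rng.normal(0, 0.5, (3, 6, 6)))
        p = RegParams(lam=0.37, v0=1.7)
        c = cost(u, frames, p)
        assert c.total == pytest.approx(c.similarity + p.lam * c.regularity,
                                        rel=1e-12)

    @pytest.mark.parametrize("shape", [(4, 4, 4), (5, 6, 6), (3, 6, 4)])
    def test_brute_force_oracle(self, rng, shape):
        # [DERIVED] scalar-loop oracle on grids up to 6x6x4
        nf, h, w = shape
        frames = rng.uniform(0, 1, (nf, h, w))
        u = DisplacementField(rng.normal(0, 0.8, (nf - 1, h, w)),
                              rng.normal(0, 0.8, (nf - 1, h, w)))
        p = RegParams(lam=0.05, v0=2.0)
        fast = cost(u, frames, p)
        slow = brute_force_cost(u, frames, p)
        assert fast.similarity == pytest.approx(slow.similarity, rel=1e-10)
        assert fast.regularity == pytest.approx(slow.regularity, rel=1e-10)
        assert fast.total == pytest.approx(slow.total, rel=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        frames = rng.uniform(0, 1, (3, 5, 5))
        with pytest.raises(ValueError):
            cost(DisplacementField.zeros(2, 4, 4), frames)


class TestRegister:
    def test_static_series_yields_near_zero_field(self):
        frame = _blob_frame(16, 16, 8, 7)
        series = FrameSeries(np.tile(frame, (3, 1, 1)), 0.02, (1, 1))
        fld = register(series)
        assert max(np.abs(fld.u_x).max(), np.abs(fld.u_y).max()) < 0.05

    def test_known_translation_recovered(self):
        # [DERIVED] known-motion oracle: 1-px x-translation
        f0 = _blob_frame(32, 32, 16, 15, sigma=4.0)
        f1 = _blob_frame(32, 32, 16, 16, sigma=4.0)
        series = FrameSeries(np.stack([f0, f1]), 0.02, (1, 1))
        fld = register(series)
        blob = f0 > 0.3
        assert fld.u_x[0][blob].mean() == pytest.approx(1.0, abs=0.1)
        assert abs(fld.u_y[0][blob].mean()) < 0.1

    def test_cost_not_above_zero_field(self, rng):
        frames = np.stack([_blob_frame(16, 16, 8, 6 + k) for k in range(3)])
        frames += rng.normal(0, 0.01, frames.shape)
        series = FrameSeries(frames, 0.02, (1, 1))
        p = RegParams()
        fld = register(series, p)
        zero = DisplacementField.zeros(2, 16, 16)
        assert cost(fld, frames, p).total <= cost(zero, frames, p).total

    def test_stronger_regularization_does_not_increase_regularity(self):
        frames = np.stack([_blob_frame(16, 16, 8, 6 + k) for k in range(3)])
        series = FrameSeries(frames, 0.02, (1, 1))
        r1 = cost(register(series, RegParams(lam=0.01)), frames).regularity
        r2 = cost(register(series, RegParams(lam=0.1)), frames).regularity
        assert r2 <= r1 + 1e-9

    def test_translation_equivariance(self):
        f0 = _blob_frame(24, 24, 10, 9, sigma=3.0)
        f1 = _blob_frame(24, 24, 10, 10, sigma=3.0)
        shift = 4
        g0, g1 = np.roll(f0, shift, axis=0), np.roll(f1, shift, axis=0)
        t_a = propagate_point((10.0, 9.0), register(FrameSeries(
            np.stack([f0, f1]), 1.0, (1, 1))))
        t_b = propagate_point((10.0 + shift, 9.0), register(FrameSeries(
            np.stack([g0, g1]), 1.0, (1, 1))))
        np.testing.assert_allclose(
            t_b.points - [shift, 0], t_a.points, atol=0.05)

    def test_v0_sensitivity_both_beat_zero_field(self):
        frames = np.stack([_blob_frame(16, 16, 8, 5 + k) for k in range(4)])
        zero = DisplacementField.zeros(3, 16, 16)
        for v0 in (1.0, 4.0):
            p = RegParams(v0=v0)
            fld = register(FrameSeries(frames, 0.02, (1, 1)), p)
            assert cost(fld, frames, p).total < cost(zero, frames, p).total

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            register(FrameSeries(np.zeros((1, 8, 8)), 0.02, (1, 1)))


class TestPropagatePoint:
    def test_zero_field_constant_trajectory(self):
        fld = DisplacementField.zeros(3, 20, 20)
        traj = propagate_point((5.0, 7.0), fld)
        np.testing.assert_allclose(traj.points, [[5, 7]] * 4)

    def test_uniform_field_accumulates(self):
        shape = (3, 20, 20)
        fld = DisplacementField(np.full(shape, 2.0), np.zeros(shape))
        traj = propagate_point((10.0, 10.0), fld)
        np.testing.assert_allclose(traj.points[-1], [10.0, 16.0])

    def test_bilinear_interpolation_between_rows(self):
        # [DERIVED] u_x=1 at row 10, u_x=3 at row 11 -> step 2.0 at row 10.5
        ux = np.zeros((1, 20, 20))
        ux[0, 10, :] = 1.0
        ux[0, 11, :] = 3.0
        fld = DisplacementField(ux, np.zeros_like(ux))
        traj = propagate_point((10.5, 10.0), fld)
        assert traj.points[1, 1] - traj.points[0, 1] == pytest.approx(2.0)

    def test_out_of_bounds_start_rejected(self):
        fld = DisplacementField.zeros(2, 10, 10)
        with pytest.raises(ValueError):
            propagate_point((12.0, 5.0), fld)

    def test_clipping_flag(self):
        shape = (2, 10, 10)
        fld = DisplacementField(np.full(shape, 8.0), np.zeros(shape))
        traj = propagate_point((5.0, 5.0), fld)
        assert traj.clipped
        assert traj.points[:, 1].max() <= 9.0


class TestAverageAnnotations:
    def _traj(self, pts):
        pts = np.asarray(pts, dtype=float)
        return TrackedTrajectory(pts, np.arange(len(pts), dtype=float))

    def test_identical_trajectories_unchanged(self):
        t = self._traj([[1, 2], [3, 4]])
        out = average_annotations([t, t, t])
        np.testing.assert_allclose(out.points, t.points)

    def test_arithmetic_mean(self):
        ts = [self._traj([[0, 0]]), self._traj([[0, 3]]), self._traj([[0, 6]])]
        np.testing.assert_allclose(average_annotations(ts).points, [[0, 3]])

    def test_two_annotations_allowed(self):
        ts = [self._traj([[0, 0]]), self._traj([[2, 4]])]
        np.testing.assert_allclose(average_annotations(ts).points, [[1, 2]])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            average_annotations([self._traj([[0, 0]]),
                                 self._traj([[0, 0], [1, 1]])])
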