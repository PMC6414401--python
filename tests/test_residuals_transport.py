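import numpy as np
import pytest

from shapetraj.diffeo import (
    DeformKernelConfig,
    MomentumSystem,
    build_control_grid,
    flow_mesh,
    gaussian_kernel,
    geodesic_shoot,
    kinetic_norm_sq,
)
from shapetraj.mesh_io import TriMesh
from shapetraj.registration import MatchConfig
from shapetraj.residuals import ResidualRecord, compute_residual
from shapetraj.trajectory import geodesic_regression
from shapetraj.transport import jacobi_transport, transport_all
from shapetraj.varifold import VarifoldKernelConfig
from .conftest import icosphere


@pytest.fixture(scope="module")
def fitted_traj():
    """A moderately curved fitted trajectory on a small ellipsoid."""
    base = icosphere(subdivisions=1, scale=(11.0, 7.0, 6.0))
    cfg = MatchConfig(
        gamma=0.05,
        max_iter=60,
        deform=DeformKernelConfig(lambda_v=11.0, n_steps=9),
        data=VarifoldKernelConfig(lambda_w=5.0),
    )
    grid = build_control_grid(base, cfg.deform)
    pole = base.vertices.mean(axis=0) + np.array([0.0, 7.0, 0.0])
    w = np.exp(-((grid - pole) ** 2).sum(1) / cfg.deform.lambda_v**2)
    beta_true = 2.5 * w[:, None] * np.array([0.1, -0.8, 0.3])
    shapes = []
    for t in np.linspace(0.0, 1.0, 10):
        snap = flow_mesh(
            base, geodesic_shoot(MomentumSystem(grid, t * beta_true), cfg.deform)
        )
        shapes.append((snap, float(t)))
    traj = geodesic_regression(shapes, base, cfg, n_times=10)
    return base, cfg, traj


class TestResiduals:
    def test_snapshot_itself_has_negligible_residual(self, fitted_traj):
        base, cfg, traj = fitted_traj
        s = 6
        rec = compute_residual(
            traj, traj.snapshots[s], float(traj.time_grid[s]), cfg, subject_id="x"
        )
        assert rec.grid_time_index == s
        kn = kinetic_norm_sq(
            MomentumSystem(traj.states[s].points, rec.alpha0), cfg.deform
        )
        assert kn < 1e-4 * base.diameter() ** 2

    def test_recovers_planted_residual_flow(self, fitted_traj):
        base, cfg, traj = fitted_traj
        s = 5
        snap = traj.snapshots[s]
        x_s = traj.states[s].points
        rng = np.random.default_rng(0)
        w = np.exp(
            -((x_s - snap.vertices.mean(0)) ** 2).sum(1) / cfg.deform.lambda_v**2
        )
        alpha_true = 1.2 * w[:, None] * np.array([0.5, 0.3, 0.6])
        subject = flow_mesh(
            snap, geodesic_shoot(MomentumSystem(x_s, alpha_true), cfg.deform)
        )
        rec = compute_residual(traj, subject, float(traj.time_grid[s]), cfg)
        moved = flow_mesh(
            snap, geodesic_shoot(MomentumSystem(x_s, rec.alpha0), cfg.deform)
        )
        rms = np.sqrt(((moved.vertices - subject.vertices) ** 2).sum(1).mean())
        assert rms < 0.2

    def test_mirror_image_perturbations_have_opposite_momenta(self, fitted_traj):
        base, cfg, traj = fitted_traj
        s = 4
        snap = traj.snapshots[s]
        x_s = traj.states[s].points
        w = np.exp(
            -((x_s - snap.vertices.mean(0)) ** 2).sum(1) / cfg.deform.lambda_v**2
        )
        alpha = 1.0 * w[:, None] * np.array([0.4, 0.5, 0.2])
        plus = flow_mesh(
            snap, geodesic_shoot(MomentumSystem(x_s, alpha), cfg.deform)
        )
        minus = flow_mesh(
            snap, geodesic_shoot(MomentumSystem(x_s, -alpha), cfg.deform)
        )
        rp = compute_residual(traj, plus, float(traj.time_grid[s]), cfg)
        rm = compute_residual(traj, minus, float(traj.time_grid[s]), cfg)
        cos = float(
            (rp.alpha0.ravel() @ rm.alpha0.ravel())
            / (np.linalg.norm(rp.alpha0) * np.linalg.norm(rm.alpha0))
        )
        assert cos < -0.8


class TestTransport:
    def test_flat_trajectory_transport_is_identity(self):
        base = icosphere(subdivisions=1, scale=(5.0, 4.0, 3.0))
        cfg = MatchConfig(
            gamma=0.05,
            max_iter=10,
            deform=DeformKernelConfig(lambda_v=8.0, n_steps=5),
            data=VarifoldKernelConfig(lambda_w=3.0),
        )
        shapes = [(base, float(t)) for t in range(6)]
        traj = geodesic_regression(shapes, base, cfg, n_times=6)
        assert np.abs(traj.beta0).max() < 1e-8  # static data: no motion
        traj.beta0[:] = 0.0
        for s in traj.states:
            s.momenta[:] = 0.0
        rng = np.random.default_rng(1)
        theta = rng.normal(size=traj.control_points.shape)
        rec = ResidualRecord("x", 5.0, grid_time_index=5, alpha0=theta, data_term=0.0)
        out = jacobi_transport(traj, rec)
        np.testing.assert_allclose(out, theta, rtol=1e-6, atol=1e-8)

    def test_velocity_direction_is_preserved_along_the_curve(self, fitted_traj):
        # transporting (a multiple of) the curve's own momentum keeps it
        # aligned with the momentum at the destination
        base, cfg, traj = fitted_traj
        s = traj.n_times - 1
        alpha = 0.5 * traj.states[s].momenta
        rec = ResidualRecord("x", 0.0, grid_time_index=s, alpha0=alpha, data_term=0.0)
        out = jacobi_transport(traj, rec)
        ref = 0.5 * traj.states[0].momenta
        cos = float(
            (out.ravel() @ ref.ravel())
            / (np.linalg.norm(out) * np.linalg.norm(ref))
        )
        assert cos > 1 - 1e-3

    def test_epsilon_convergence_is_second_order(self, fitted_traj):
        base, cfg, traj = fitted_traj
        rng = np.random.default_rng(2)
        theta = 0.5 * rng.normal(size=traj.control_points.shape)
        rec = ResidualRecord("x", 0.0, grid_time_index=6, alpha0=theta, data_term=0.0)
        outs = {
            e: jacobi_transport(traj, rec, eps=e) for e in (4e-2, 2e-2, 1e-2)
        }
        d1 = np.linalg.norm(outs[4e-2] - outs[2e-2])
        d2 = np.linalg.norm(outs[2e-2] - outs[1e-2])
        assert d1 < 4 * d2 * 1.5  # O(eps^2): consecutive diffs shrink ~4x
        assert d1 / d2 > 2.0

    def test_transport_preserves_kinetic_norm(self, fitted_traj):
        base, cfg, traj = fitted_traj
        rng = np.random.default_rng(3)
        for s in (3, 6, 9):
            theta = 0.4 * rng.normal(size=traj.control_points.shape)
            rec = ResidualRecord(
                "x", 0.0, grid_time_index=s, alpha0=theta, data_term=0.0
            )
            out = jacobi_transport(traj, rec)
            n_in = kinetic_norm_sq(
                MomentumSystem(traj.states[s].points, theta), traj.kernel
            )
            n_out = kinetic_norm_sq(
                MomentumSystem(traj.states[0].points, out), traj.kernel
            )
            assert n_out == pytest.approx(n_in, rel=0.02)

    def test_transport_is_linear(self, fitted_traj):
        base, cfg, traj = fitted_traj
        rng = np.random.default_rng(4)
        a = 0.1 * rng.normal(size=traj.control_points.shape)
        b = 0.1 * rng.normal(size=traj.control_points.shape)

        def T(v):
            rec = ResidualRecord(
                "x", 0.0, grid_time_index=5, alpha0=v, data_term=0.0
            )
            return jacobi_transport(traj, rec, eps=1e-3)

        lhs = T(2.0 * a + 3.0 * b)
        rhs = 2.0 * T(a) + 3.0 * T(b)
        assert np.linalg.norm(lhs - rhs) < 1e-3 * np.linalg.norm(rhs)

    def test_underflow_epsilon_rejected(self, fitted_traj):
        base, cfg, traj = fitted_traj
        theta = np.ones(traj.control_points.shape)
        rec = ResidualRecord("x", 0.0, grid_time_index=3, alpha0=theta, data_term=0.0)
        with pytest.raises(ValueError, match="eps"):
            jacobi_transport(traj, rec, eps=1e-18)

    def test_transport_all_fills_theta(self, fitted_traj):
        base, cfg, traj = fitted_traj
        recs = [
            ResidualRecord(
                "a", 0.0, grid_time_index=2,
                alpha0=0.1 * np.ones(traj.control_points.shape), data_term=0.0
            ),
            ResidualRecord(
                "b", 0.0, grid_time_index=0,
                alpha0=0.1 * np.ones(traj.control_points.shape), data_term=0.0
            ),
        ]
        transport_all(traj, recs)
        assert all(r.theta0 is not None for r in recs)
        np.testing.assert_allclose(recs[1].theta0, recs[1].alpha0)


def test_residual_data_terms_stay_near_noise_floor(fitted_traj):
    # subjects generated from the trajectory itself plus vertex jitter:
    # residual registration should not fit worse than ~the jitter floor
    base, cfg, traj = fitted_traj
    rng = np.random.default_rng(7)
    from shapetraj.varifold import varifold_sqdist

    data_terms, floors = [], []
    for s in (2, 5, 8):
        snap = traj.snapshots[s]
        jittered = TriMesh(
            snap.vertices + rng.normal(0, 0.15, snap.vertices.shape),
            snap.triangles,
        )
        floors.append(varifold_sqdist(snap, jittered, cfg.data))
        rec = compute_residual(traj, jittered, float(traj.time_grid[s]), cfg)
        data_terms.append(rec.data_term)
    assert np.mean(data_terms) <= 1.5 * np.mean(floors)
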