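import numpy as np
import pytest

from shapetraj.diffeo import (
    DeformKernelConfig,
    MomentumSystem,
    build_control_grid,
    flow_mesh,
    geodesic_shoot,
    kinetic_norm_sq,
)
from shapetraj.mesh_io import SubjectRecord, TriMesh
from shapetraj.registration import MatchConfig
from shapetraj.trajectory import (
    geodesic_regression,
    iterative_centroid,
    select_baseline_subjects,
)
from shapetraj.varifold import VarifoldKernelConfig, varifold_sqdist
from .conftest import icosphere


def make_record(sid, eyo, mesh):
    return SubjectRecord(
        subject_id=sid,
        left_mesh=mesh,
        right_mesh=mesh,
        eyo=eyo,
        group="carrier",
        sex="F",
        site="s",
        family_id="f",
    )


class TestBaselineSelection:
    def test_smallest_eyo_selected(self, unit_sphere):
        recs = [
            make_record(s, e, unit_sphere)
            for s, e in zip("abcd", [-40.0, -39.0, -5.0, 0.0])
        ]
        picked = select_baseline_subjects(recs, 2)
        assert [r.subject_id for r in picked] == ["a", "b"]

    def test_whole_cohort_when_k_equals_n(self, unit_sphere):
        recs = [make_record(s, e, unit_sphere) for s, e in zip("ab", [0.0, 1.0])]
        assert len(select_baseline_subjects(recs, 2)) == 2

    def test_eyo_tie_broken_lexicographically(self, unit_sphere):
        recs = [
            make_record(s, e, unit_sphere)
            for s, e in zip(["z9", "a1", "m5"], [-10.0, -10.0, -40.0])
        ]
        picked = select_baseline_subjects(recs, 2)
        assert [r.subject_id for r in picked] == ["m5", "a1"]


def centroid_cfg():
    return MatchConfig(
        gamma=0.05,
        max_iter=60,
        deform=DeformKernelConfig(lambda_v=12.0, n_steps=5),
        data=VarifoldKernelConfig(lambda_w=2.0),
    )


class TestIterativeCentroid:
    def test_identical_inputs_are_a_fixed_point(self):
        mesh = icosphere(subdivisions=1, scale=(3.0, 2.0, 2.0))
        cfg = centroid_cfg()
        c = iterative_centroid([mesh, mesh.copy(), mesh.copy()], cfg, order_seed=1)
        assert varifold_sqdist(c, mesh, cfg.data) < 1e-8

    def test_two_shape_centroid_is_midpoint(self):
        mesh = icosphere(subdivisions=1, scale=(3.0, 2.0, 2.0))
        other = TriMesh(mesh.vertices + np.array([2.0, 0, 0]), mesh.triangles)
        cfg = centroid_cfg()
        c = iterative_centroid([mesh, other], cfg, order_seed=0)
        mid = mesh.vertices + np.array([1.0, 0, 0])
        rms = np.sqrt(((c.vertices - mid) ** 2).sum(1).mean())
        assert rms < 0.1

    def test_centroid_is_central(self, rng):
        cfg = centroid_cfg()
        base = icosphere(subdivisions=1, scale=(3.0, 2.0, 2.0))
        meshes = []
        for _ in range(6):
            jitter = rng.normal(0, 0.15, base.vertices.shape)
            shift = rng.normal(0, 0.3, 3)
            meshes.append(TriMesh(base.vertices + jitter + shift, base.triangles))
        c = iterative_centroid(meshes, cfg, order_seed=3)
        mean_c = np.mean([varifold_sqdist(c, m, cfg.data) for m in meshes])
        for m in meshes:
            mean_m = np.mean(
                [varifold_sqdist(m, other, cfg.data) for other in meshes]
            )
            assert mean_c <= mean_m + 1e-9


class TestGeodesicRegression:
    def test_static_shapes_need_no_motion(self):
        mesh = icosphere(subdivisions=1, scale=(3.0, 2.0, 2.0))
        cfg = centroid_cfg()
        shapes = [(mesh, t) for t in (-10.0, -5.0, 0.0, 5.0)]
        traj = geodesic_regression(shapes, mesh, cfg, n_times=8)
        kn = kinetic_norm_sq(
            MomentumSystem(traj.control_points, traj.beta0), traj.kernel
        )
        assert kn < 1e-4 * mesh.diameter() ** 2

    def test_rejects_single_time(self):
        mesh = icosphere(subdivisions=1)
        with pytest.raises(ValueError):
            geodesic_regression([(mesh, 0.0), (mesh, 0.0)], mesh, centroid_cfg())

    def test_recovers_known_trajectory(self):
        # inverse crime: sample a ground-truth geodesic at 15 times, no noise
        base = icosphere(subdivisions=2, scale=(11.0, 7.0, 6.0))
        cfg = MatchConfig(
            gamma=0.05,
            max_iter=80,
            deform=DeformKernelConfig(lambda_v=11.0, n_steps=14),
            data=VarifoldKernelConfig(lambda_w=5.0),
        )
        grid = build_control_grid(base, cfg.deform)
        pole = base.vertices.mean(axis=0) + np.array([0.0, 7.0, 0.0])
        w = np.exp(-((grid - pole) ** 2).sum(1) / cfg.deform.lambda_v**2)
        beta_true = 2.0 * w[:, None] * np.array([0.1, -0.8, 0.3])
        times = np.linspace(-40.0, 20.0, 15)
        shapes = []
        for t in times:
            tt = (t + 40.0) / 60.0
            snap = flow_mesh(
                base,
                geodesic_shoot(MomentumSystem(grid, tt * beta_true), cfg.deform),
            )
            shapes.append((snap, float(t)))
        traj = geodesic_regression(shapes, base, cfg, n_times=15)
        truth_end = flow_mesh(
            base, geodesic_shoot(MomentumSystem(grid, beta_true), cfg.deform)
        )
        est_end = traj.snapshots[-1]
        rms = np.sqrt(((est_end.vertices - truth_end.vertices) ** 2).sum(1).mean())
        assert rms < 0.3
        # fitting reduced the data energy by >= 95% vs the static model
        static = sum(
            varifold_sqdist(base, s, cfg.data) for s, _ in shapes
        )
        assert traj.diagnostics["data_term"] <= 0.05 * static
        # geodesic property: kinetic energy constant across snapshots
        H = [kinetic_norm_sq(s, traj.kernel) for s in traj.states]
        assert (max(H) - min(H)) <= 1e-3 * max(H)
        # objective decreased monotonically across accepted iterates
        hist = traj.diagnostics["objective_history"]
        assert all(b <= a + 1e-9 * abs(a) for a, b in zip(hist, hist[1:]))

    def test_time_reversal_mirrors_trajectory(self):
        base = icosphere(subdivisions=1, scale=(6.0, 4.0, 4.0))
        cfg = MatchConfig(
            gamma=0.05,
            max_iter=60,
            deform=DeformKernelConfig(lambda_v=8.0, n_steps=6),
            data=VarifoldKernelConfig(lambda_w=3.0),
        )
        grid = build_control_grid(base, cfg.deform)
        w = np.exp(-((grid - base.vertices.mean(0)) ** 2).sum(1) / 64.0)
        beta_true = 1.0 * w[:, None] * np.array([0.5, 0.2, -0.3])
        times = np.linspace(0.0, 1.0, 7)
        shapes = []
        for t in times:
            snap = flow_mesh(
                base,
                geodesic_shoot(MomentumSystem(grid, t * beta_true), cfg.deform),
            )
            shapes.append((snap, float(t)))
        fwd = geodesic_regression(shapes, base, cfg, n_times=7)
        # reverse time; anchor at the (shared) endpoint shape
        end_mesh = shapes[-1][0]
        rev_shapes = [(s, -t) for s, t in shapes]
        rev = geodesic_regression(rev_shapes, end_mesh, cfg, n_times=7)
        rms = np.sqrt(
            ((rev.snapshots[-1].vertices - fwd.snapshots[0].vertices) ** 2)
            .sum(1)
            .mean()
        )
        assert rms < 0.3


def test_centroid_order_variability_diagnostic(rng):
    from shapetraj.trajectory import centroid_order_variability

    cfg = centroid_cfg()
    base = icosphere(subdivisions=1, scale=(3.0, 2.0, 2.0))
    meshes = [
        TriMesh(base.vertices + rng.normal(0, 0.2, base.vertices.shape), base.triangles)
        for _ in range(4)
    ]
    report = centroid_order_variability(meshes, cfg, order_seeds=(0, 1, 2))
    assert len(report["pairwise_sqdist"]) == 3
    assert report["max_sqdist"] >= 0.0
    assert report["mean_sqdist"] <= report["max_sqdist"] + 1e-12
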