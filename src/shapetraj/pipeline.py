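"""Stage-wise pipeline execution with a persistent run directory.

Each stage writes its outputs plus a provenance record (config hash, seed,
package version) into the run directory and is skipped on re-execution when
its outputs already exist under the same configuration — so an interrupted
run resumes where it stopped and a completed run is a no-op.

Stage order: synth (optional) -> bilateral -> centroid -> regress ->
residuals -> transport -> cluster -> features -> stats.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, features, stats
from .diffeo import DeformKernelConfig, MomentumSystem
from .mesh_io import TriMesh, read_cohort_csv, read_mesh, write_mesh
from .model import CohortShapeModel, PipelineConfig
from .residuals import ResidualRecord, compute_residual
from .trajectory import (
    GeodesicTrajectory,
    geodesic_regression,
    iterative_centroid,
    select_baseline_subjects,
)
from .transport import transport_all

__all__ = ["RunDir", "run_all", "STAGES", "config_from_yaml", "save_momenta", "load_momenta"]

STAGES = (
    "bilateral",
    "centroid",
    "regress",
    "residuals",
    "transport",
    "cluster",
    "features",
    "stats",
)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def config_from_yaml(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("similarity_weights", "eyo_grid"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def save_momenta(path, system: MomentumSystem, meta: dict | None = None) -> None:
    """Two-array container (points, momenta) with a JSON sidecar."""
    path = Path(path)
    np.savez(path, points=system.points, momenta=system.momenta)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta or {}, fh, indent=1)


def load_momenta(path) -> tuple[MomentumSystem, dict]:
    path = Path(path)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        system = MomentumSystem(z["points"], z["momenta"])
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return system, meta


class RunDir:
    """A timestamp-free, resumable run directory keyed by config hash."""

    def __init__(self, path, config: PipelineConfig):
        self.path = Path(path)
        self.path.mkdir(parents=True, exist_ok=True)
        self.config = config
        self.hash = config_hash(config)

    def stage_dir(self, stage: str) -> Path:
        d = self.path / stage
        d.mkdir(exist_ok=True)
        return d

    def _prov_path(self, stage: str) -> Path:
        return self.path / stage / "provenance.json"

    def is_done(self, stage: str) -> bool:
        p = self._prov_path(stage)
        if not p.exists():
            return False
        prov = json.loads(p.read_text())
        return prov.get("config_hash") == self.hash and prov.get("complete", False)

    def mark_done(self, stage: str, extra: dict | None = None) -> None:
        prov = {
            "config_hash": self.hash,
            "seed": self.config.seed,
            "version": __version__,
            "complete": True,
        }
        prov.update(extra or {})
        self._prov_path(stage).write_text(json.dumps(prov, indent=1))

    # -------------------------------------------------------- persistence
    def save_trajectory(self, traj: GeodesicTrajectory) -> None:
        d = self.stage_dir("regress")
        write_mesh(traj.baseline, d / "baseline.ply")
        np.savez(
            d / "trajectory.npz",
            control_points=traj.control_points,
            beta0=traj.beta0,
            time_grid=traj.time_grid,
            state_points=np.stack([s.points for s in traj.states]),
            state_momenta=np.stack([s.momenta for s in traj.states]),
            snapshot_vertices=np.stack([m.vertices for m in traj.snapshots]),
            triangles=traj.baseline.triangles,
        )
        (d / "meta.json").write_text(
            json.dumps(
                {
                    "lambda_v": traj.kernel.lambda_v,
                    "n_steps": traj.kernel.n_steps,
                    "gamma": traj.gamma,
                    "eyo_span": [float(traj.time_grid[0]), float(traj.time_grid[-1])],
                    "seed": self.config.seed,
                    "diagnostics": {
                        k: v
                        for k, v in traj.diagnostics.items()
                        if k != "objective_history"
                    },
                },
                indent=1,
            )
        )

    def load_trajectory(self) -> GeodesicTrajectory:
        d = self.path / "regress"
        meta = json.loads((d / "meta.json").read_text())
        with np.load(d / "trajectory.npz") as z:
            tri = z["triangles"]
            baseline = TriMesh(z["snapshot_vertices"][0], tri, name="baseline")
            states = [
                MomentumSystem(p, m)
                for p, m in zip(z["state_points"], z["state_momenta"])
            ]
            snapshots = [
                TriMesh(v, tri.copy(), name=f"traj_t{s}")
                for s, v in enumerate(z["snapshot_vertices"])
            ]
            return GeodesicTrajectory(
                baseline=baseline,
                control_points=z["control_points"],
                beta0=z["beta0"],
                time_grid=z["time_grid"],
                states=states,
                snapshots=snapshots,
                kernel=DeformKernelConfig(
                    lambda_v=meta["lambda_v"], n_steps=meta["n_steps"]
                ),
                gamma=meta["gamma"],
                diagnostics=meta.get("diagnostics", {}),
            )

    def save_residuals(self, records: list[ResidualRecord]) -> None:
        d = self.stage_dir("residuals")
        np.savez(
            d / "residuals.npz",
            subject_ids=np.array([r.subject_id for r in records]),
            eyos=np.array([r.eyo for r in records]),
            grid_indices=np.array([r.grid_time_index for r in records]),
            alpha0=np.stack([r.alpha0 for r in records]),
            data_terms=np.array([r.data_term for r in records]),
        )

    def load_residuals(self) -> list[ResidualRecord]:
        with np.load(self.path / "residuals" / "residuals.npz") as z:
            records = [
                ResidualRecord(
                    subject_id=str(sid),
                    eyo=float(eyo),
                    grid_time_index=int(gi),
                    alpha0=a,
                    data_term=float(dt),
                )
                for sid, eyo, gi, a, dt in zip(
                    z["subject_ids"],
                    z["eyos"],
                    z["grid_indices"],
                    z["alpha0"],
                    z["data_terms"],
                )
            ]
        theta_path = self.path / "transport" / "theta0.npz"
        if theta_path.exists():
            with np.load(theta_path) as z:
                for rec, th in zip(records, z["theta0"]):
                    rec.theta0 = th
        return records


def run_all(
    cohort_csv,
    out_dir,
    config: PipelineConfig | None = None,
    verbose: bool = True,
    until: str | None = None,
) -> Path:
    """Execute (or resume) the pipeline stages, optionally stopping early.

    ``until`` names the last stage to run (one of ``STAGES``); earlier
    stages are reused from the run directory when their provenance matches.
    """
    config = config or PipelineConfig()
    if until is not None and until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; expected one of {STAGES}")
    run = RunDir(out_dir, config)
    records = read_cohort_csv(cohort_csv)
    model = CohortShapeModel(records, config)
    match_cfg = config.match_config()

    def log(msg):
        if verbose:
            print(msg, flush=True)

    # ---- bilateral subject means
    bdir = run.stage_dir("bilateral")
    if run.is_done("bilateral"):
        log("bilateral: cached")
        means = [
            read_mesh(bdir / f"{r.subject_id}_mean.ply") for r in records
        ]
    else:
        plane = model.mirror_plane()
        means = model.bilateral_means(plane, verbose=verbose)
        for rec, m in zip(records, means):
            write_mesh(m, bdir / f"{rec.subject_id}_mean.ply")
        run.mark_done("bilateral", {"mirror_plane": plane})
        log("bilateral: done")
    if until == "bilateral":
        return run.path

    # ---- baseline centroid
    cdir = run.stage_dir("centroid")
    if run.is_done("centroid"):
        baseline = read_mesh(cdir / "baseline.ply")
        log("centroid: cached")
    else:
        base_recs = select_baseline_subjects(records, min(config.n_baseline, len(records)))
        idx = {r.subject_id: i for i, r in enumerate(records)}
        baseline = iterative_centroid(
            [means[idx[r.subject_id]] for r in base_recs],
            match_cfg,
            order_seed=config.seed,
        )
        write_mesh(baseline, cdir / "baseline.ply")
        run.mark_done("centroid")
        log("centroid: done")
    if until == "centroid":
        return run.path

    # ---- geodesic regression
    if run.is_done("regress"):
        traj = run.load_trajectory()
        log("regress: cached")
    else:
        shapes = [(m, r.eyo) for m, r in zip(means, records)]
        traj = geodesic_regression(shapes, baseline, match_cfg, n_times=config.n_times)
        run.save_trajectory(traj)
        run.mark_done("regress")
        log("regress: done")
    if until == "regress":
        return run.path

    # ---- residual deformations
    if run.is_done("residuals"):
        res_records = run.load_residuals()
        log("residuals: cached")
    else:
        res_records = [
            compute_residual(traj, m, r.eyo, match_cfg, subject_id=r.subject_id)
            for m, r in zip(means, records)
        ]
        run.save_residuals(res_records)
        run.mark_done("residuals")
        log("residuals: done")
    if until == "residuals":
        return run.path

    # ---- parallel transport
    tdir = run.stage_dir("transport")
    if run.is_done("transport") and res_records[0].theta0 is not None:
        log("transport: cached")
    else:
        transport_all(traj, res_records, n_substeps=config.transport_substeps)
        np.savez(
            tdir / "theta0.npz", theta0=np.stack([r.theta0 for r in res_records])
        )
        run.mark_done("transport")
        log("transport: done")
    if until == "transport":
        return run.path

    # ---- clustering
    kdir = run.stage_dir("cluster")
    if run.is_done("cluster"):
        labels = np.load(kdir / "labels.npy")
        sim = features.similarity_matrix(
            traj.control_points,
            traj.beta0,
            weights=config.similarity_weights,
            normalise_dist=config.normalise_dist,
            lambda_v=config.lambda_v,
        )
        cluster_model = features.ClusterModel(
            labels, sim, config.n_clusters, config.seed, config.n_init, np.nan
        )
        log("cluster: cached")
    else:
        sim = features.similarity_matrix(
            traj.control_points,
            traj.beta0,
            weights=config.similarity_weights,
            normalise_dist=config.normalise_dist,
            lambda_v=config.lambda_v,
        )
        cluster_model = features.cluster_parametrisation(
            sim, n_clusters=config.n_clusters, seed=config.seed, n_init=config.n_init
        )
        np.save(kdir / "labels.npy", cluster_model.labels)
        run.mark_done("cluster")
        log("cluster: done")
    if until == "cluster":
        return run.path

    # ---- descriptor table
    fdir = run.stage_dir("features")
    if run.is_done("features"):
        table = pd.read_csv(fdir / "features.csv")
        log("features: cached")
    else:
        nu = np.stack(
            [
                features.cluster_mean_vectors(cluster_model, rec.theta0)
                for rec in res_records
            ]
        )
        meta = pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in records],
                "eyo": [r.eyo for r in records],
                "group": [r.group for r in records],
                "sex": [r.sex for r in records],
                "site": [r.site for r in records],
                "family_id": [r.family_id for r in records],
            }
        )
        table = features.amplitude_and_orientation(nu, meta)
        table.to_csv(fdir / "features.csv", index=False)
        run.mark_done("features")
        log("features: done")
    if until == "features":
        return run.path

    # ---- statistics
    sdir = run.stage_dir("stats")
    if run.is_done("stats"):
        log("stats: cached")
    else:
        stats_table = stats.run_cluster_stats(
            table, config.n_clusters, eyo_grid=config.eyo_grid, alpha=config.alpha
        )
        stats_table.to_csv(sdir / "results.csv", index=False)
        run.mark_done("stats")
        log("stats: done")
    return run.path
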