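"""Cohort-level model object tying the pipeline stages together.

``CohortShapeModel`` holds the data (time-indexed bilateral meshes with
covariates) and the analysis configuration; ``fit`` runs the full chain —
bilateral subject means, iterative-centroid baseline, geodesic regression,
residual extraction, parallel transport, momentum clustering, descriptor
statistics — and returns a ``CohortShapeResults`` with the estimates,
diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import diffeo, features, stats
from .diffeo import DeformKernelConfig
from .mesh_io import SubjectRecord, TriMesh, mirror_mesh, read_cohort_csv
from .registration import MatchConfig, register_bilateral
from .residuals import ResidualRecord, compute_residual
from .trajectory import (
    GeodesicTrajectory,
    geodesic_regression,
    iterative_centroid,
    select_baseline_subjects,
)
from .transport import transport_all
from .varifold import VarifoldKernelConfig

__all__ = ["PipelineConfig", "CohortShapeModel", "CohortShapeResults"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the analysis, with cohort-study defaults.

    Kernel widths are in mm: ``lambda_v`` (deformation; about half the
    length of the structure) and ``lambda_w`` (varifold data term; about
    two voxels).  ``n_times`` is the number of trajectory snapshots over
    the EYO span, ``n_clusters``/``n_init`` the clustering size and number
    of discretisation restarts.
    """

    lambda_v: float = 11.0
    lambda_w: float = 5.0
    gamma: float = 0.1
    n_times: int = 30
    n_steps: int = 11
    n_clusters: int = 10
    n_init: int = 3000
    n_baseline: int = 10
    max_iter: int = 100
    bilateral_rounds: int = 2
    transport_substeps: int = 5
    similarity_weights: tuple[float, float, float] = (5.0, 2.0, 1.0)
    normalise_dist: bool = True
    eyo_grid: tuple[float, ...] = stats.DEFAULT_EYO_GRID
    alpha: float = 0.05
    seed: int = 0

    def match_config(self) -> MatchConfig:
        return MatchConfig(
            gamma=self.gamma,
            max_iter=self.max_iter,
            deform=DeformKernelConfig(lambda_v=self.lambda_v, n_steps=self.n_steps),
            data=VarifoldKernelConfig(lambda_w=self.lambda_w),
        )


class CohortShapeModel:
    """Spatiotemporal shape model for a bilateral, time-indexed cohort."""

    def __init__(
        self, records: list[SubjectRecord], config: PipelineConfig | None = None
    ):
        if not records:
            raise ValueError("empty cohort")
        self.records = list(records)
        self.config = config or PipelineConfig()

    @classmethod
    def from_cohort_csv(
        cls, path, config: PipelineConfig | None = None
    ) -> "CohortShapeModel":
        return cls(read_cohort_csv(path), config=config)

    # ------------------------------------------------------------- stages
    def mirror_plane(self) -> float:
        """Cohort mid-sagittal plane: mean x over all mesh vertices."""
        tot, cnt = 0.0, 0
        for r in self.records:
            for m in (r.left_mesh, r.right_mesh):
                tot += float(m.vertices[:, 0].sum())
                cnt += m.n_vertices
        return tot / cnt

    def bilateral_means(self, plane: float, verbose: bool = False) -> list[TriMesh]:
        """Per-subject mean of the left and mirrored-right shapes."""
        cfg = self.config.match_config()
        means = []
        for i, rec in enumerate(self.records):
            right_m = mirror_mesh(rec.right_mesh, plane)
            grid = diffeo.build_control_grid(rec.left_mesh, cfg.deform)
            mean, _sys = register_bilateral(
                rec.left_mesh,
                right_m,
                init_mid=rec.left_mesh,
                control_points=grid,
                cfg=cfg,
                n_rounds=self.config.bilateral_rounds,
            )
            mean.name = f"{rec.subject_id}_mean"
            means.append(mean)
            if verbose and (i + 1) % 20 == 0:
                print(f"  bilateral means: {i + 1}/{len(self.records)}")
        return means

    def fit(self, seed: int | None = None, verbose: bool = False) -> "CohortShapeResults":
        cfg = self.config
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        match_cfg = cfg.match_config()
        t_start = time.time()
        timings: dict[str, float] = {}

        def tick(name):
            timings[name] = time.time() - t_start
            if verbose:
                print(f"[{timings[name]:7.1f}s] {name} done")

        plane = self.mirror_plane()
        means = self.bilateral_means(plane, verbose=verbose)
        tick("bilateral_means")

        baseline_records = select_baseline_subjects(
            self.records, min(cfg.n_baseline, len(self.records))
        )
        idx = {r.subject_id: i for i, r in enumerate(self.records)}
        baseline_meshes = [means[idx[r.subject_id]] for r in baseline_records]
        baseline = iterative_centroid(baseline_meshes, match_cfg, order_seed=cfg.seed)
        tick("iterative_centroid")

        shapes = [(m, r.eyo) for m, r in zip(means, self.records)]
        traj = geodesic_regression(
            shapes, baseline, match_cfg, n_times=cfg.n_times
        )
        tick("geodesic_regression")

        residual_records: list[ResidualRecord] = []
        for i, (mesh, rec) in enumerate(zip(means, self.records)):
            residual_records.append(
                compute_residual(
                    traj, mesh, rec.eyo, match_cfg, subject_id=rec.subject_id
                )
            )
            if verbose and (i + 1) % 20 == 0:
                print(f"  residuals: {i + 1}/{len(self.records)}")
        tick("residuals")

        transport_all(
            traj, residual_records, n_substeps=cfg.transport_substeps
        )
        tick("transport")

        sim = features.similarity_matrix(
            traj.control_points,
            traj.beta0,
            weights=cfg.similarity_weights,
            normalise_dist=cfg.normalise_dist,
            lambda_v=cfg.lambda_v,
        )
        cluster_model = features.cluster_parametrisation(
            sim, n_clusters=cfg.n_clusters, seed=cfg.seed, n_init=cfg.n_init
        )
        tick("clustering")

        nu = np.stack(
            [
                features.cluster_mean_vectors(cluster_model, rec.theta0)
                for rec in residual_records
            ]
        )
        meta = pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.records],
                "eyo": [r.eyo for r in self.records],
                "group": [r.group for r in self.records],
                "sex": [r.sex for r in self.records],
                "site": [r.site for r in self.records],
                "family_id": [r.family_id for r in self.records],
            }
        )
        table = features.amplitude_and_orientation(nu, meta)
        tick("features")

        stats_table = stats.run_cluster_stats(
            table, cfg.n_clusters, eyo_grid=cfg.eyo_grid, alpha=cfg.alpha
        )
        tick("stats")

        return CohortShapeResults(
            model=self,
            config=cfg,
            mirror_plane=plane,
            mean_shapes=means,
            trajectory=traj,
            residual_records=residual_records,
            cluster_model=cluster_model,
            nu=nu,
            feature_table=table,
            stats_table=stats_table,
            timings=timings,
        )


@dataclass
class CohortShapeResults:
    """Fitted pipeline: estimates, per-stage diagnostics, and test tables."""

    model: CohortShapeModel
    config: PipelineConfig
    mirror_plane: float
    mean_shapes: list[TriMesh]
    trajectory: GeodesicTrajectory
    residual_records: list[ResidualRecord]
    cluster_model: features.ClusterModel
    nu: np.ndarray
    feature_table: pd.DataFrame
    stats_table: pd.DataFrame
    timings: dict = field(default_factory=dict)

    # ------------------------------------------------------------ queries
    def overall_tests(self) -> pd.DataFrame:
        return self.stats_table[
            self.stats_table["test"].isin(["T1_group", "T2_group_by_time"])
        ]

    def at_eyo_tests(self) -> pd.DataFrame:
        return self.stats_table[self.stats_table["test"].str.startswith("at_eyo")]

    def significant_clusters(self, alpha: float | None = None) -> pd.DataFrame:
        alpha = alpha if alpha is not None else self.config.alpha
        ov = self.overall_tests()
        return ov[ov["p_bonferroni"] <= alpha]

    def earliest_significant(self, alpha: float | None = None) -> dict:
        """Earliest corrected-significant grid EYO per (descriptor, cluster)."""
        alpha = alpha if alpha is not None else self.config.alpha
        out: dict[tuple[str, int], float] = {}
        at = self.at_eyo_tests()
        for (desc, k), sub in at.groupby(["descriptor", "cluster"]):
            ts = [
                float(t.split("(")[1].rstrip(")"))
                for t, p in zip(sub["test"], sub["p_bonferroni"])
                if p <= alpha
            ]
            if ts:
                out[(desc, int(k))] = min(ts)
        return out

    def summary(self) -> str:
        cfg = self.config
        n = len(self.model.records)
        carriers = sum(r.group == "carrier" for r in self.model.records)
        lines = [
            "Spatiotemporal shape trajectory analysis",
            "=" * 56,
            f"subjects: {n} ({carriers} carriers, {n - carriers} non-carriers)",
            f"EYO span: [{self.trajectory.time_grid[0]:.1f}, "
            f"{self.trajectory.time_grid[-1]:.1f}] years, "
            f"{cfg.n_times} snapshots",
            f"kernels: lambda_v={cfg.lambda_v} mm, lambda_w={cfg.lambda_w} mm, "
            f"gamma={cfg.gamma}",
            f"control points: {self.trajectory.control_points.shape[0]}, "
            f"clusters: {cfg.n_clusters}",
            f"regression data term: {self.trajectory.diagnostics['data_term']:.4g}",
            "",
            "Wald tests (T1: group, 2 df; T2: group x EYO, 1 df); "
            f"Bonferroni over {2 * cfg.n_clusters} tests",
            "-" * 56,
            f"{'descriptor':<12}{'cluster':>8}{'test':>18}{'chi2':>9}{'p_corr':>10}",
        ]
        for _, row in self.overall_tests().iterrows():
            mark = " *" if row["p_bonferroni"] <= cfg.alpha else ""
            lines.append(
                f"{row['descriptor']:<12}{row['cluster']:>8}{row['test']:>18}"
                f"{row['chi2']:>9.2f}{row['p_bonferroni']:>10.3g}{mark}"
            )
        earliest = self.earliest_significant()
        if earliest:
            lines.append("")
            lines.append("Earliest corrected-significant EYO (5-year grid):")
            for (desc, k), t in sorted(earliest.items()):
                lines.append(f"  {desc} cluster {k}: {t:+.0f} years")
        return "\n".join(lines)

    def plot_group_contrast(self, cluster: int, descriptor: str, ax=None):
        """Group contrast estimate with corrected CI over the EYO grid."""
        import matplotlib.pyplot as plt

        at = self.at_eyo_tests()
        sub = at[(at["cluster"] == cluster) & (at["descriptor"] == descriptor)]
        if sub.empty:
            raise ValueError(
                f"no grid tests for {descriptor} cluster {cluster} "
                "(only stage-one significant descriptors are tested on the grid)"
            )
        ts = [float(t.split("(")[1].rstrip(")")) for t in sub["test"]]
        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(
            ts,
            sub["estimate"],
            yerr=[
                sub["estimate"] - sub["ci_low"],
                sub["ci_high"] - sub["estimate"],
            ],
            fmt="o-",
            capsize=3,
        )
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("EYO (years)")
        ax.set_ylabel(f"{descriptor} contrast (carrier - non-carrier)")
        ax.set_title(f"cluster {cluster}")
        return ax
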