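"""Parallel transport of residual momenta along the regression geodesic.

Residual momenta are anchored at different trajectory times and cannot be
compared directly; they are carried back to the baseline space B0 along the
population geodesic with a Jacobi-field scheme: the transported vector is
the epsilon-derivative of perturbed exponentials, realised here by central
differences,

    J = [ exp_x(delta (-beta + eps theta)) - exp_x(delta (-beta - eps theta)) ] / (2 eps delta)

taken one grid interval (length delta in internal time) at a time along the
time-reversed geodesic.  Stepping interval-by-interval keeps the finite-eps
error uniform across subjects regardless of how far from baseline they sit.

The difference of exponentials measures the transported *velocity* field at
the control points; momenta are converted to and from velocities with the
kernel matrix (w = K a), which makes transport exactly the identity on a
flat (zero-velocity) trajectory and preserves the V-norm up to
discretisation error.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from . import diffeo
from .diffeo import DeformKernelConfig, gaussian_kernel
from .residuals import ResidualRecord
from .trajectory import GeodesicTrajectory

__all__ = ["jacobi_transport", "transport_all"]


def _solve_kernel(K: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Solve K theta = w with a tiny ridge for numerical safety."""
    n = K.shape[0]
    try:
        c = cho_factor(K + 1e-10 * np.eye(n), lower=True)
        return cho_solve(c, w)
    except np.linalg.LinAlgError:
        return np.linalg.solve(K + 1e-8 * np.eye(n), w)


def jacobi_transport(
    traj: GeodesicTrajectory,
    record: ResidualRecord,
    eps: float | None = None,
    n_substeps: int = 5,
) -> np.ndarray:
    """Transport ``record.alpha0`` from its grid time back to index 0.

    Returns theta_i(0) anchored at the baseline control grid.  ``eps`` is
    the central-difference perturbation; the default scales it to the
    relative size of the trajectory and residual momenta.  Convergence is
    O(eps^2).
    """
    theta = np.array(record.alpha0, dtype=np.float64)
    s0 = record.grid_time_index
    if s0 == 0:
        return theta
    T = traj.n_times
    delta = 1.0 / (T - 1)
    lam = traj.kernel.lambda_v
    sub_cfg = DeformKernelConfig(lambda_v=lam, n_steps=n_substeps)

    for s in range(s0, 0, -1):
        x = traj.states[s].points
        beta = traj.states[s].momenta
        theta_norm = float(np.linalg.norm(theta))
        if theta_norm == 0.0:
            return np.zeros_like(theta)
        if eps is None:
            scale = float(np.linalg.norm(beta))
            if scale == 0.0:
                scale = 1.0
            e = 1e-3 * scale / theta_norm
        else:
            e = eps
        if e * theta_norm < 1e3 * np.finfo(float).eps * max(
            1.0, float(np.abs(x).max())
        ):
            raise ValueError(
                "transport perturbation underflows machine precision; "
                "increase eps"
            )
        plus = diffeo.shoot_states(x, delta * (-beta + e * theta), None, sub_cfg)
        minus = diffeo.shoot_states(x, delta * (-beta - e * theta), None, sub_cfg)
        w_new = (plus[-1][0] - minus[-1][0]) / (2.0 * e * delta)
        x_new = traj.states[s - 1].points
        K_new = gaussian_kernel(x_new, x_new, lam)
        theta = _solve_kernel(K_new, w_new)
    return theta


def transport_all(
    traj: GeodesicTrajectory,
    records: list[ResidualRecord],
    eps: float | None = None,
    n_substeps: int = 5,
) -> None:
    """Fill ``theta0`` on every record in place."""
    for rec in records:
        rec.theta0 = jacobi_transport(traj, rec, eps=eps, n_substeps=n_substeps)
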