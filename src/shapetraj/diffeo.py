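"""Control-point / momentum parametrisation of diffeomorphisms.

A deformation is encoded by ``n`` control points ``x_p`` with attached
momentum vectors ``a_p``.  They induce the velocity field

    v(y) = sum_p exp(-|y - x_p|^2 / lambda_v^2) a_p

and the deformation is the time-1 flow of the Hamiltonian system

    dx_p/dt = sum_q K(x_p, x_q) a_q
    da_p/dt = -sum_q (a_p . a_q) grad_1 K(x_p, x_q)

with Gaussian kernel K(x, y) = exp(-|x - y|^2 / lambda_v^2) (no factor 2 in
the denominator).  These are the canonical equations of the kinetic-energy
Hamiltonian H = 1/2 sum_pq (a_p . a_q) K(x_p, x_q); H is conserved along the
flow, which is the main correctness check on the integrator.

Integration is fixed-step RK4.  Exact reverse-mode derivatives through the
discrete RK4 recursion are implemented by hand (``rk4_backprop``); they are
what makes gradient-based estimation of momenta (registration, regression)
possible without an autodiff framework.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist as _cdist

from .mesh_io import TriMesh

__all__ = [
    "DeformKernelConfig",
    "MomentumSystem",
    "GeodesicPath",
    "DivergenceError",
    "velocity_field",
    "geodesic_shoot",
    "flow_mesh",
    "kinetic_norm_sq",
    "kinetic_norm_sq_gradient",
    "build_control_grid",
    "gaussian_kernel",
    "shoot_states",
    "rk4_backprop",
]


class DivergenceError(RuntimeError):
    """Raised when the flow integration produces non-finite state."""


@dataclass(frozen=True)
class DeformKernelConfig:
    """Deformation kernel: width ``lambda_v`` (mm) and RK4 step count."""

    lambda_v: float = 11.0
    n_steps: int = 11

    def __post_init__(self) -> None:
        if not (self.lambda_v > 0):
            raise ValueError("lambda_v must be > 0")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")


@dataclass
class MomentumSystem:
    """Paired control points and momentum vectors (both (n, 3), mm)."""

    points: np.ndarray
    momenta: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        self.momenta = np.atleast_2d(np.asarray(self.momenta, dtype=np.float64))
        if self.points.shape != self.momenta.shape or self.points.shape[1] != 3:
            raise ValueError("points and momenta must both be (n, 3)")
        if self.points.shape[0] < 1:
            raise ValueError("need at least one control point")
        if not (np.isfinite(self.points).all() and np.isfinite(self.momenta).all()):
            raise ValueError("non-finite control points or momenta")

    @property
    def n(self) -> int:
        return self.points.shape[0]


@dataclass
class GeodesicPath:
    """Sequence of (points, momenta) snapshots along a geodesic on [0, 1]."""

    states: list[MomentumSystem]
    kernel: DeformKernelConfig

    @property
    def n_steps(self) -> int:
        return len(self.states) - 1

    @property
    def initial(self) -> MomentumSystem:
        return self.states[0]

    @property
    def final(self) -> MomentumSystem:
        return self.states[-1]


# ------------------------------------------------------------------ kernels

def gaussian_kernel(x: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """K_ij = exp(-|x_i - y_j|^2 / lam^2)."""
    d2 = _cdist(x, y, "sqeuclidean")
    K = d2
    K *= -1.0 / (lam * lam)
    np.exp(K, out=K)
    return K


def velocity_field(
    system: MomentumSystem, query_points: np.ndarray, cfg: DeformKernelConfig
) -> np.ndarray:
    """Evaluate v(y) = sum_p K(y, x_p) a_p at the query points."""
    q = np.atleast_2d(np.asarray(query_points, dtype=np.float64))
    return gaussian_kernel(q, system.points, cfg.lambda_v) @ system.momenta


def kinetic_norm_sq(system: MomentumSystem, cfg: DeformKernelConfig) -> float:
    """Squared V-norm of the initial velocity: sum_pq (a_p . a_q) K(x_p, x_q)."""
    K = gaussian_kernel(system.points, system.points, cfg.lambda_v)
    return float(np.einsum("pq,pd,qd->", K, system.momenta, system.momenta))


def kinetic_norm_sq_gradient(
    system: MomentumSystem, cfg: DeformKernelConfig
) -> np.ndarray:
    """Gradient of the squared V-norm with respect to the momenta: 2 K a."""
    K = gaussian_kernel(system.points, system.points, cfg.lambda_v)
    return 2.0 * K @ system.momenta


# -------------------------------------------------- Hamiltonian RHS and VJP

def _rhs_aux(x, a, q, lam):
    """Time derivative of (x, a, q) plus the kernel matrices for VJP reuse."""
    c = 2.0 / (lam * lam)
    K = gaussian_kernel(x, x, lam)
    dx = K @ a
    W = (a @ a.T) * K
    da = c * (W.sum(axis=1)[:, None] * x - W @ x)
    if q is None:
        return (dx, da, None), (K, None)
    Kqx = gaussian_kernel(q, x, lam)
    dq = Kqx @ a
    return (dx, da, dq), (K, Kqx)


def _rhs(x, a, q, lam):
    return _rhs_aux(x, a, q, lam)[0]


def _rhs_vjp(x, a, q, lam, wx, wa, wq, aux=None):
    """Cotangent of _rhs: given weights on (dx, da, dq), return grads on (x, a, q)."""
    c = 2.0 / (lam * lam)
    K = aux[0] if aux is not None else gaussian_kernel(x, x, lam)
    gx = np.zeros_like(x)
    ga = np.zeros_like(a)
    gq = None if q is None else np.zeros_like(q)

    # dx = K @ a  with cotangent wx
    if wx is not None:
        ga += K @ wx
        S = (wx @ a.T) * K
        T = S + S.T
        gx += c * (T @ x - T.sum(axis=1)[:, None] * x)

    # da_p = c * sum_q (a_p.a_q) K_pq (x_p - x_q)  with cotangent wa
    if wa is not None:
        A = a @ a.T
        u = np.einsum("pd,pd->p", wa, x)
        proj = u[:, None] - wa @ x.T          # V_p . (x_p - x_q)
        Bp = c * K * proj
        ga += Bp @ a + Bp.T @ a
        W = A * K
        gx += c * W.sum(axis=1)[:, None] * wa
        gx -= c * W @ wa
        H = A * Bp                            # = c A K proj
        gx += c * ((H + H.T) @ x - (H.sum(axis=1) + H.sum(axis=0))[:, None] * x)

    # dq = K(q, x) @ a  with cotangent wq
    if wq is not None and q is not None:
        Kqx = aux[1] if aux is not None else gaussian_kernel(q, x, lam)
        ga += Kqx.T @ wq
        S3 = (wq @ a.T) * Kqx
        gq += -c * (S3.sum(axis=1)[:, None] * q - S3 @ x)
        gx += c * (S3.T @ q - S3.sum(axis=0)[:, None] * x)
    return gx, ga, gq


def _add(z, k, h):
    x, a, q = z
    kx, ka, kq = k
    return (x + h * kx, a + h * ka, None if q is None else q + h * kq)


def _rk4_stages(z, h, lam):
    k1, aux1 = _rhs_aux(*z, lam)
    za = _add(z, k1, h / 2)
    k2, aux2 = _rhs_aux(*za, lam)
    zb = _add(z, k2, h / 2)
    k3, aux3 = _rhs_aux(*zb, lam)
    zc = _add(z, k3, h)
    k4, aux4 = _rhs_aux(*zc, lam)
    return (k1, k2, k3, k4), (za, zb, zc), (aux1, aux2, aux3, aux4)


def _rk4_step(z, h, lam):
    (k1, k2, k3, k4), _, _ = _rk4_stages(z, h, lam)
    x, a, q = z
    x1 = x + h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
    a1 = a + h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
    q1 = None if q is None else q + h / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
    return x1, a1, q1


def shoot_states(
    x0: np.ndarray,
    a0: np.ndarray,
    q0: np.ndarray | None,
    cfg: DeformKernelConfig,
    t_final: float = 1.0,
) -> list[tuple]:
    """Integrate the joint system over [0, t_final]; returns all step states.

    The passive points ``q0`` (e.g. mesh vertices) ride on the control-point
    flow without influencing it.
    """
    h = t_final / cfg.n_steps
    z = (
        np.asarray(x0, dtype=np.float64).copy(),
        np.asarray(a0, dtype=np.float64).copy(),
        None if q0 is None else np.asarray(q0, dtype=np.float64).copy(),
    )
    states = [z]
    for step in range(cfg.n_steps):
        z = _rk4_step(z, h, cfg.lambda_v)
        if not all(np.isfinite(part).all() for part in z if part is not None):
            raise DivergenceError(f"non-finite state at integration step {step + 1}")
        states.append(z)
    return states


def rk4_backprop(
    states: list[tuple],
    cfg: DeformKernelConfig,
    terminal_cot: tuple,
    per_step_cots: dict[int, tuple] | None = None,
    t_final: float = 1.0,
) -> tuple:
    """Exact gradient through the RK4 recursion of :func:`shoot_states`.

    ``terminal_cot`` is the (wx, wa, wq) cotangent on the final state;
    ``per_step_cots`` optionally injects additional cotangents at given step
    indices (used by geodesic regression, whose data terms attach to
    intermediate snapshots).  Returns the cotangent on the initial state.
    """
    lam = cfg.lambda_v
    n_steps = len(states) - 1
    h = t_final / n_steps

    def _merge(w, extra):
        if extra is None:
            return w
        wx, wa, wq = w
        ex, ea, eq = extra
        wx = wx if ex is None else (ex if wx is None else wx + ex)
        wa = wa if ea is None else (ea if wa is None else wa + ea)
        wq = wq if eq is None else (eq if wq is None else wq + eq)
        return (wx, wa, wq)

    per_step_cots = per_step_cots or {}
    w = _merge((None, None, None), terminal_cot)
    w = _merge(w, per_step_cots.get(n_steps))
    for step in range(n_steps - 1, -1, -1):
        z = states[step]
        _ks, (za, zb, zc), (aux1, aux2, aux3, aux4) = _rk4_stages(z, h, lam)
        wx, wa, wq = (
            w[0] if w[0] is not None else np.zeros_like(z[0]),
            w[1] if w[1] is not None else np.zeros_like(z[1]),
            None
            if z[2] is None
            else (w[2] if w[2] is not None else np.zeros_like(z[2])),
        )
        w1 = (wx, wa, wq)

        def scaled(wt, s):
            return tuple(None if p is None else s * p for p in wt)

        w_k4 = scaled(w1, h / 6)
        w_zc = _rhs_vjp(*zc, lam, *w_k4, aux=aux4)
        w_k3 = _merge(scaled(w1, 2 * h / 6), scaled(w_zc, h))
        w_zb = _rhs_vjp(*zb, lam, *w_k3, aux=aux3)
        w_k2 = _merge(scaled(w1, 2 * h / 6), scaled(w_zb, h / 2))
        w_za = _rhs_vjp(*za, lam, *w_k2, aux=aux2)
        w_k1 = _merge(scaled(w1, h / 6), scaled(w_za, h / 2))
        w_z = _rhs_vjp(*z, lam, *w_k1, aux=aux1)
        w = _merge(_merge(_merge(_merge(w1, w_za), w_zb), w_zc), w_z)
        w = _merge(w, per_step_cots.get(step))
    return w


# ------------------------------------------------------------ user surface

def geodesic_shoot(
    system: MomentumSystem, cfg: DeformKernelConfig, t_final: float = 1.0
) -> GeodesicPath:
    """Exponential map: integrate the geodesic equations from (x0, a0)."""
    states = shoot_states(system.points, system.momenta, None, cfg, t_final)
    return GeodesicPath(
        states=[MomentumSystem(x, a) for x, a, _ in states], kernel=cfg
    )


def flow_mesh(mesh: TriMesh, path: GeodesicPath) -> TriMesh:
    """Carry mesh vertices through the flow generated by a geodesic path.

    The vertices are re-integrated jointly with the control-point system of
    ``path.initial`` (same RK4 stepping), so the induced time-varying field
    is sampled consistently at every Runge-Kutta stage.
    """
    init = path.initial
    states = shoot_states(init.points, init.momenta, mesh.vertices, path.kernel)
    return TriMesh(states[-1][2], mesh.triangles.copy(), name=mesh.name)


def build_control_grid(mesh: TriMesh, cfg: DeformKernelConfig) -> np.ndarray:
    """Regular control-point grid over the padded bounding box of a mesh.

    Spacing equals ``lambda_v`` and the box is padded by one spacing on each
    side; ordering is deterministic with x varying fastest.
    """
    lo, hi = mesh.bounds()
    lam = cfg.lambda_v
    axes = [np.arange(lo[d] - lam, hi[d] + lam + 1e-9 * lam, lam) for d in range(3)]
    Z, Y, X = np.meshgrid(axes[2], axes[1], axes[0], indexing="ij")
    return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
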