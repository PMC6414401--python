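"""Cluster the trajectory parametrisation and reduce residuals to descriptors.

The control points of the population geodesic, with their regression
momenta beta0(0), are grouped into K clusters by spectral clustering of the
similarity

    s(p, q) = -5 |x_p - x_q|^2 + 2 (cos(beta_p, beta_q) + 1) - | |beta_p|^2 - |beta_q|^2 |

so that a cluster collects nearby control points whose momenta point the
same way with comparable magnitude.  Each subject's transported residual
theta_i(0) is then summarised per cluster by the mean vector nu_{i,k}, and
each mean vector by two decoupled scalars: its amplitude |nu_{i,k}| and an
orientation score O_{i,k} (first principal component of the three axis
angles across subjects, per cluster).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.manifold import spectral_embedding as _spectral_embedding

__all__ = [
    "ClusterModel",
    "similarity_matrix",
    "cluster_parametrisation",
    "cluster_mean_vectors",
    "amplitude_and_orientation",
    "feature_columns",
]

DEFAULT_WEIGHTS = (5.0, 2.0, 1.0)


@dataclass
class ClusterModel:
    """Spectral clustering of the trajectory control points."""

    labels: np.ndarray
    similarity: np.ndarray
    n_clusters: int
    seed: int
    n_init: int
    inertia: float
    embedding: np.ndarray | None = None

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)


def _safe_cosine(beta: np.ndarray) -> np.ndarray:
    """Pairwise cosines; any pair involving a zero vector gets cosine 0."""
    norms = np.linalg.norm(beta, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = beta / safe[:, None]
    cos = unit @ unit.T
    zero = norms == 0
    cos[zero, :] = 0.0
    cos[:, zero] = 0.0
    return np.clip(cos, -1.0, 1.0)


def similarity_matrix(
    control_points: np.ndarray,
    beta0: np.ndarray,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    normalise_dist: bool = True,
    lambda_v: float = 11.0,
) -> np.ndarray:
    """Similarity s(p, q) between momentum-carrying control points.

    With ``normalise_dist`` the pairwise distance is divided by the
    deformation kernel width before squaring, so the three terms stay
    commensurate for any grid spacing; raw millimetre distances are kept
    when it is off.
    """
    x = np.asarray(control_points, dtype=float)
    b = np.asarray(beta0, dtype=float)
    w_d, w_a, w_m = weights
    diff2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
    if normalise_dist:
        diff2 = diff2 / (lambda_v**2)
    cos = _safe_cosine(b)
    mag2 = (b**2).sum(1)
    s = -w_d * diff2 + w_a * (cos + 1.0) - w_m * np.abs(mag2[:, None] - mag2[None, :])
    return 0.5 * (s + s.T)


def _discretize(embedding: np.ndarray, rng: np.random.Generator, max_svd_restarts: int = 5):
    """Yu & Shi rotation/discretisation of a spectral embedding.

    Alternates between snapping the rotated embedding to indicator vectors
    and re-estimating the best rotation by SVD; the random initial rotation
    makes restarts meaningful.
    """
    n, k = embedding.shape
    norms = np.linalg.norm(embedding, axis=1)
    norms[norms == 0] = 1.0
    vecs = embedding / norms[:, None]

    # random orthogonal initial rotation via QR of a Gaussian matrix
    R, _ = np.linalg.qr(rng.normal(size=(k, k)))
    last_obj = 0.0
    labels = None
    for _ in range(30):
        rotated = vecs @ R
        labels = np.argmax(rotated, axis=1)
        indicator = np.zeros((n, k))
        indicator[np.arange(n), labels] = 1.0
        U, S, Vt = np.linalg.svd(vecs.T @ indicator)
        obj = S.sum()
        R = U @ Vt
        if abs(obj - last_obj) < 1e-10:
            break
        last_obj = obj
    return labels


def _inertia(embedding: np.ndarray, labels: np.ndarray, k: int) -> float:
    total = 0.0
    for c in range(k):
        rows = embedding[labels == c]
        if len(rows):
            total += ((rows - rows.mean(axis=0)) ** 2).sum()
    return float(total)


def cluster_parametrisation(
    similarity: np.ndarray,
    n_clusters: int = 10,
    seed: int = 0,
    n_init: int = 3000,
) -> ClusterModel:
    """Normalised-cut spectral clustering with discretisation initialisation.

    Similarities are mapped to positive affinities by ``exp(s / tau)`` with
    ``tau`` the interquartile range of s (scale free); the normalised
    Laplacian embedding into ``n_clusters`` eigenvectors is discretised
    ``n_init`` times from seeded random rotations and the labelling with
    the lowest within-cluster inertia (in embedding space) wins.
    """
    s = np.asarray(similarity, dtype=float)
    n = s.shape[0]
    if n < n_clusters:
        raise ValueError(f"cannot form {n_clusters} clusters from {n} points")
    q75, q25 = np.percentile(s, [75, 25])
    tau = q75 - q25
    if tau <= 0:
        tau = 1.0
    affinity = np.exp((s - s.max()) / tau)  # shift for overflow safety only

    n_comp, _ = connected_components(affinity > 1e-300, directed=False)
    if n_comp > 1:
        raise ValueError(
            "affinity graph is disconnected; use a larger similarity scale tau"
        )

    if n_clusters == n:
        # degenerate request: the optimal normalised cut isolates every point
        labels = np.arange(n)
        return ClusterModel(labels, s, n_clusters, seed, n_init, 0.0)

    embedding = _spectral_embedding(
        affinity,
        n_components=n_clusters,
        norm_laplacian=True,
        drop_first=False,
        random_state=int(seed) % (2**32),
    )
    rng = np.random.default_rng(seed)
    best_labels, best_inertia = None, np.inf
    for _ in range(max(1, n_init)):
        labels = _discretize(embedding, rng)
        if len(np.unique(labels)) < n_clusters:
            continue
        inertia = _inertia(embedding, labels, n_clusters)
        if inertia < best_inertia:
            best_inertia, best_labels = inertia, labels
    if best_labels is None:
        raise RuntimeError(
            "discretisation never produced a labelling with all clusters "
            "non-empty; try more initialisations or fewer clusters"
        )
    return ClusterModel(
        labels=best_labels,
        similarity=s,
        n_clusters=n_clusters,
        seed=seed,
        n_init=n_init,
        inertia=best_inertia,
        embedding=embedding,
    )


def cluster_mean_vectors(model: ClusterModel, theta0: np.ndarray) -> np.ndarray:
    """Per-cluster mean of one subject's transported momenta: (K, 3)."""
    theta0 = np.asarray(theta0, dtype=float)
    out = np.zeros((model.n_clusters, 3))
    for k in range(model.n_clusters):
        rows = model.members(k)
        out[k] = theta0[rows].mean(axis=0)
    return out


def _axis_angles(nu: np.ndarray) -> np.ndarray:
    """Direction angles arccos(nu_a / |nu|) per axis; zero vectors -> pi/2."""
    norms = np.linalg.norm(nu, axis=-1, keepdims=True)
    safe = np.where(norms > 0, norms, 1.0)
    cosines = np.clip(nu / safe, -1.0, 1.0)
    angles = np.arccos(cosines)
    angles = np.where(norms > 0, angles, np.pi / 2)
    return angles


def amplitude_and_orientation(
    nu: np.ndarray, meta: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Reduce per-subject cluster mean vectors to scalar descriptors.

    ``nu`` has shape (N_subjects, K, 3).  Amplitude is the Euclidean norm.
    Orientation: per cluster, the three axis angles of each subject's mean
    vector are centred across subjects and projected on their first
    principal axis; the axis sign is fixed so its largest-magnitude
    component is positive, making the score reproducible.
    """
    nu = np.asarray(nu, dtype=float)
    n_subj, n_clusters, _ = nu.shape
    amp = np.linalg.norm(nu, axis=2)
    ori = np.zeros((n_subj, n_clusters))
    for k in range(n_clusters):
        angles = _axis_angles(nu[:, k, :])
        centred = angles - angles.mean(axis=0)
        if np.allclose(centred, 0.0):
            continue
        _, _, Vt = np.linalg.svd(centred, full_matrices=False)
        axis = Vt[0]
        if axis[np.argmax(np.abs(axis))] < 0:
            axis = -axis
        ori[:, k] = centred @ axis
    cols = {}
    if meta is not None:
        for c in meta.columns:
            cols[c] = np.asarray(meta[c])
    for k in range(n_clusters):
        cols[f"amp_c{k + 1}"] = amp[:, k]
    for k in range(n_clusters):
        cols[f"ori_c{k + 1}"] = ori[:, k]
    return pd.DataFrame(cols)


def feature_columns(n_clusters: int) -> tuple[list[str], list[str]]:
    amps = [f"amp_c{k + 1}" for k in range(n_clusters)]
    oris = [f"ori_c{k + 1}" for k in range(n_clusters)]
    return amps, oris
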