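"""Gaussian-process smoothing of electrode values onto a spherical grid.

Electrode positions and grid points live on a common sphere (the averaged
cortical sphere of radius ``r`` mm); per-electrode scalars (prediction
accuracy, cluster similarity, coverage indicators) are interpolated to the
regular grid with a GP whose kernel is a Gaussian of the great-circle
distance:

    g = K_c^T (K_s + eta I)^{-1} y,
    K_s = exp(-D_s^2 / (2 sigma^2)),   K_c = exp(-D_c^2 / (2 sigma^2)),
    d(u, v) = r * arccos(u^T v).

``sigma`` sets the smoothing length (mm) and ``eta`` regularizes the
electrode kernel (and is required whenever electrodes coincide).
"""
from __future__ import annotations

import numpy as np

from .datatypes import GpConfig, SphereGrid

__all__ = [
    "great_circle_distance",
    "distance_matrix",
    "gp_project",
    "combine_subjects",
    "icosphere_grid",
]


def great_circle_distance(u: np.ndarray, v: np.ndarray, r: float = 1.0) -> float:
    """Great-circle distance ``r * arccos(u^T v)`` between two unit vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero vector has no direction on the sphere")
    c = np.clip((u @ v) / (nu * nv), -1.0, 1.0)
    return float(r * np.arccos(c))


def distance_matrix(P: np.ndarray, Q: np.ndarray, r: float = 1.0) -> np.ndarray:
    """Pairwise great-circle distances between two sets of unit vectors."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    c = np.clip(P @ Q.T, -1.0, 1.0)
    return r * np.arccos(c)


def gp_project(
    values: np.ndarray,
    electrodes: np.ndarray,
    grid: SphereGrid,
    config: GpConfig | None = None,
) -> np.ndarray:
    """Project per-electrode scalars to the grid with the GP smoother.

    Linear in ``values``; with ``eta -> 0`` and distinct electrodes the
    projection interpolates (grid points coincident with electrodes take the
    electrode values exactly).
    """
    if config is None:
        config = GpConfig()
    y = np.asarray(values, dtype=float)
    E = np.asarray(electrodes, dtype=float)
    if E.ndim != 2 or E.shape[1] != 3 or E.shape[0] < 1:
        raise ValueError("electrodes must be an (E, 3) array")
    if y.shape[0] != E.shape[0]:
        raise ValueError("one value per electrode required")
    D_s = distance_matrix(E, E, grid.radius)
    D_c = distance_matrix(E, grid.points, grid.radius)
    K_s = np.exp(-(D_s**2) / (2.0 * config.sigma**2))
    K_c = np.exp(-(D_c**2) / (2.0 * config.sigma**2))
    try:
        alpha = np.linalg.solve(K_s + config.eta * np.eye(E.shape[0]), y)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "electrode kernel is singular (duplicate electrodes with eta=0?); "
            "use eta > 0"
        ) from err
    return K_c.T @ alpha


def combine_subjects(per_subject: list[np.ndarray], mode: str = "mean") -> np.ndarray:
    """Combine per-subject grid projections.

    ``"density"`` sums the projections (coverage maps built from indicator
    values); ``"mean"`` averages, treating NaN entries as missing so a grid
    point is averaged only over subjects that cover it.
    """
    if not per_subject:
        raise ValueError("no subjects to combine")
    shapes = {v.shape for v in map(np.asarray, per_subject)}
    if len(shapes) != 1:
        raise ValueError("all subjects must be on the same grid")
    stack = np.stack([np.asarray(v, dtype=float) for v in per_subject])
    if mode == "density":
        return np.nansum(stack, axis=0)
    if mode == "mean":
        with np.errstate(invalid="ignore"):
            return np.nanmean(stack, axis=0)
    raise ValueError(f"unknown mode: {mode!r}")


def icosphere_grid(order: int = 5, radius: float = 100.0) -> SphereGrid:
    """Subdivided-icosahedron grid of unit vectors (order 5 ~ 10242 vertices)."""
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=order, radius=1.0)
    points = np.asarray(mesh.vertices, dtype=float)
    points /= np.linalg.norm(points, axis=1, keepdims=True)
    return SphereGrid(points=points, radius=radius)
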