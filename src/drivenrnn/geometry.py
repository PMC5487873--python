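"""Reduced-space geometry of trajectories relative to the dynamical skeleton.

The stationary-point family {phi(s)} traces a curve in state space; its
principal components define the low-dimensional frame ("reduced PC-space")
in which both the skeleton and the driven trajectory are visualised. Two
scalar summaries quantify how the trajectory relates to the skeleton:

* ``R`` — radius of the smallest sphere enclosing the projected trajectory
  (how widely the state swings in the skeleton's frame), and
* ``d_phi`` — the maximum over time of the distance between the projected
  state and the projected stationary point phi(S(t)) of the instantaneous
  drive value (how far the state lags behind the moving fixed point).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fixedpoints import ContinuationResult
from .simulate import Trajectory

__all__ = [
    "ProjectedSet",
    "project_onto_stationary_pcs",
    "min_enclosing_sphere",
    "max_instantaneous_distance",
]


@dataclass(frozen=True)
class ProjectedSet:
    """An orthonormal m-dimensional frame fit to the stationary set.

    ``basis`` is N x m with orthonormal columns (the stationary-set PCs),
    ``center`` the mean of the stationary locations; ``skeleton_coords``
    and ``coordinates`` are the stationary curve and the trajectory
    expressed in that frame.
    """

    basis: np.ndarray
    center: np.ndarray
    skeleton_coords: np.ndarray
    coordinates: np.ndarray

    @property
    def m(self) -> int:
        return self.basis.shape[1]

    def project(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.center) @ self.basis


def project_onto_stationary_pcs(
    traj: Trajectory | np.ndarray,
    cont: ContinuationResult,
    m: int = 2,
    which: str = "potentials",
) -> ProjectedSet:
    """Fit PCA on the stationary locations only; express both sets in it.

    The basis is fit exclusively on the skeleton (the set of points visited
    by the stationary point), not on the trajectory, so the frame is a
    property of the vector field rather than of any particular run. The
    comparison is made in membrane-potential coordinates by default, the
    space in which phi(s) lives.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    locs = cont.locations()
    if locs.shape[0] == 0:
        raise ValueError("continuation result is empty")
    center = locs.mean(axis=0)
    _, sv, vt = np.linalg.svd(locs - center, full_matrices=False)
    rank = int(np.sum(sv > sv[0] * 1e-12)) if sv.size else 0
    if m > rank:
        raise ValueError(f"m={m} exceeds stationary-set rank {rank}")
    basis = vt[:m].T
    if isinstance(traj, Trajectory):
        states = traj.potentials if which == "potentials" else traj.rates
    else:
        states = np.atleast_2d(traj)
    return ProjectedSet(
        basis=basis,
        center=center,
        skeleton_coords=(locs - center) @ basis,
        coordinates=(states - center) @ basis,
    )


def _circumball(boundary: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Smallest ball with the given (affinely independent) points on it."""
    if not boundary:
        return np.zeros(0), -1.0
    q0 = boundary[0]
    if len(boundary) == 1:
        return q0.copy(), 0.0
    A = np.array([q - q0 for q in boundary[1:]])
    b = 0.5 * np.sum(A * A, axis=1)
    coef, *_ = np.linalg.lstsq(A @ A.T, b, rcond=None)
    center = q0 + A.T @ coef
    radius = float(np.linalg.norm(center - q0))
    return center, radius


def _welzl(points: np.ndarray, boundary: list[np.ndarray]) -> tuple[np.ndarray, float]:
    # recursion depth bounded by the support size (<= m + 1)
    center, radius = _circumball(boundary)
    if len(boundary) == points.shape[1] + 1:
        return center, radius
    for i in range(points.shape[0]):
        p = points[i]
        if radius < 0 or np.linalg.norm(p - center) > radius * (1 + 1e-12):
            center, radius = _welzl(points[:i], boundary + [p])
    return center, radius


def min_enclosing_sphere(points: np.ndarray, seed: int = 0) -> tuple[np.ndarray, float]:
    """Exact smallest enclosing sphere of a T x m point set.

    Randomised incremental (Welzl move-to-front) algorithm; expected linear
    time for fixed m, with the support set (at most m + 1 points) solved by
    a circumsphere linear system. Radius accurate to ~1e-12 relative.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.shape[0] == 0:
        raise ValueError("need at least one point")
    if pts.shape[0] == 1:
        return pts[0].copy(), 0.0
    rng = np.random.default_rng(seed)
    shuffled = pts[rng.permutation(pts.shape[0])]
    center, radius = _welzl(shuffled, [])
    return center, float(radius)


def max_instantaneous_distance(
    traj: Trajectory,
    cont: ContinuationResult,
    basis: ProjectedSet | None = None,
    m: int = 2,
    pairing: str = "instantaneous",
) -> float:
    """Maximum reduced-space distance between state and moving fixed point.

    At each retained step t the state is paired with phi(S(t)), the
    stationary point of the *instantaneous* drive value (nearest grid
    value); ``pairing="nearest"`` instead pairs with the closest point
    anywhere on the skeleton, a lower bound useful for comparison.
    """
    if basis is None:
        basis = project_onto_stationary_pcs(traj, cont, m=m)
    drive = traj.drive_values()
    lo, hi = cont.s_range
    margin = 1e-9 + (cont.grid[1] - cont.grid[0] if len(cont.grid) > 1 else 0.0)
    if drive.min() < lo - margin or drive.max() > hi + margin:
        raise ValueError(
            f"drive range [{drive.min():.3f}, {drive.max():.3f}] exceeds "
            f"continuation coverage [{lo:.3f}, {hi:.3f}]"
        )
    state_coords = basis.coordinates
    if pairing == "instantaneous":
        idx = np.abs(cont.grid[None, :] - drive[:, None]).argmin(axis=1)
        target = basis.skeleton_coords[idx]
        dists = np.linalg.norm(state_coords - target, axis=1)
    elif pairing == "nearest":
        diff = state_coords[:, None, :] - basis.skeleton_coords[None, :, :]
        dists = np.linalg.norm(diff, axis=2).min(axis=1)
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    return float(dists.max())
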