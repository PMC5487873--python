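"""Stationary points of the frozen-input network and their linearisation.

For a constant input value ``s`` the network follows the autonomous field
``F(x, s) = (1/tau)(-x + W tanh(x) + w s)``; a stationary point phi(s)
solves F(x, s) = 0. The family {phi(s)} over a grid of s values — the
"dynamical skeleton" — is computed by numerical continuation: starting from
the trivial solution phi(0) = 0, s is stepped in small increments and each
root solve is warm-started from the previous solution. Points are classified
from the eigenvalues of the tau-free Jacobian ``W * B - I``: a sink if all
real parts are negative, a source if all positive, a saddle otherwise.

Root solves use a trust-region dogleg-type method (MINPACK's modified
Powell hybrid) with the analytic Jacobian, followed by Newton polishing to
push the residual to the configured stationarity tolerance.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import optimize

from .reservoir import Reservoir, jacobian

__all__ = [
    "StationaryPoint",
    "ContinuationResult",
    "solve_fixed_point",
    "continue_fixed_points",
    "random_restart_search",
    "classify_stationary_point",
    "rotation_plane",
]

#: Default stationarity tolerance on max |F_i|. The ideal criterion of
#: 1e-15 sits at the edge of double precision for hundreds of coupled
#: components; 1e-13 is reliably attainable and is always reported.
DEFAULT_TOL = 1e-13


@dataclass(frozen=True)
class StationaryPoint:
    """A converged root of F(x, s) = 0 with its local linear structure."""

    input_value: float
    location: np.ndarray
    residual_max: float
    eigenvalues: np.ndarray  # sorted by descending real part
    label: str  # "sink" | "saddle" | "source"
    n_unstable: int
    marginal: bool = False
    rotation_basis: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def leading_eigenvalue(self) -> complex:
        """Eigenvalue of largest real part."""
        return complex(self.eigenvalues[0])

    @property
    def leading_by_modulus(self) -> complex:
        return complex(self.eigenvalues[np.argmax(np.abs(self.eigenvalues))])


@dataclass(frozen=True)
class FixedPointFailure:
    """Non-convergence record: best point found and its residual."""

    input_value: float
    best_location: np.ndarray
    residual_max: float


@dataclass
class ContinuationResult:
    grid: np.ndarray
    points: list[StationaryPoint]
    failed: list[float]

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.points):
            raise ValueError("grid and points must align")

    def locations(self) -> np.ndarray:
        """Stationary-point coordinates stacked as len(grid) x N."""
        return np.array([p.location for p in self.points])

    def point_at(self, s: float) -> StationaryPoint:
        """Stationary point at the grid value nearest to ``s``."""
        return self.points[int(np.argmin(np.abs(self.grid - s)))]

    @property
    def s_range(self) -> tuple[float, float]:
        return float(self.grid.min()), float(self.grid.max())

    def to_csv(self, path: str | Path) -> None:
        n = self.points[0].location.size if self.points else 0
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["s", "residual_max", "label", "n_unstable", "eig_re", "eig_im"]
                + [f"phi{i}" for i in range(n)]
            )
            for p in self.points:
                lead = p.leading_eigenvalue
                writer.writerow(
                    [p.input_value, p.residual_max, p.label, p.n_unstable,
                     lead.real, lead.imag] + list(p.location)
                )


def _residual(res: Reservoir, x: np.ndarray, s: float) -> np.ndarray:
    """tau-free stationarity residual -x + W tanh(x) + w s."""
    return -x + res.weights @ np.tanh(x) + res.input_weights * s


def classify_stationary_point(
    eigenvalues: np.ndarray, marginal_tol: float = 0.0
) -> tuple[str, int, bool]:
    """Label a spectrum: sink / saddle / source, plus the unstable count.

    Returns ``(label, n_unstable, marginal)``; ``marginal`` flags real
    parts within ``marginal_tol`` of zero (exact ties by default), for
    which the linearisation is inconclusive.
    """
    eigenvalues = np.asarray(eigenvalues)
    if eigenvalues.size == 0:
        raise ValueError("eigenvalue list must be nonempty")
    re = eigenvalues.real
    n_unstable = int(np.sum(re > marginal_tol))
    n_stable = int(np.sum(re < -marginal_tol))
    marginal = bool(n_unstable + n_stable < eigenvalues.size)
    if n_unstable == 0:
        label = "sink"
    elif n_stable == 0:
        label = "source"
    else:
        label = "saddle"
    return label, n_unstable, marginal


def _make_point(res: Reservoir, s: float, x: np.ndarray, r_max: float) -> StationaryPoint:
    eig = np.linalg.eigvals(jacobian(res, x))
    order = np.argsort(-eig.real)
    eig = eig[order]
    label, n_unstable, marginal = classify_stationary_point(eig)
    return StationaryPoint(
        input_value=float(s),
        location=x.copy(),
        residual_max=float(r_max),
        eigenvalues=eig,
        label=label,
        n_unstable=n_unstable,
        marginal=marginal,
    )


def solve_fixed_point(
    res: Reservoir,
    s: float,
    x0: np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
    max_polish: int = 20,
) -> StationaryPoint | FixedPointFailure:
    """Solve F(x, s) = 0 from a starting point.

    A solve counts as successful only if every residual component is below
    ``tol`` in absolute value; otherwise a :class:`FixedPointFailure`
    carrying the best candidate is returned (never a silent partial
    success).
    """
    if not tol > 0:
        raise ValueError("tol must be positive")
    if x0 is None:
        x0 = np.zeros(res.n)
    x0 = np.asarray(x0, dtype=float)

    sol = optimize.root(
        lambda x: _residual(res, x, s),
        x0,
        jac=lambda x: jacobian(res, x),
        method="hybr",
        options={"xtol": 1e-14},
    )
    x = sol.x
    r = _residual(res, x, s)
    r_max = float(np.max(np.abs(r)))
    # Newton polishing: quadratic convergence near the root pushes the
    # residual to rounding level when the Jacobian is nonsingular.
    for _ in range(max_polish):
        if r_max < tol:
            break
        try:
            step = np.linalg.solve(jacobian(res, x), r)
        except np.linalg.LinAlgError:
            break
        x_new = x - step
        r_new = _residual(res, x_new, s)
        r_new_max = float(np.max(np.abs(r_new)))
        if not np.isfinite(r_new_max) or r_new_max >= r_max:
            break
        x, r, r_max = x_new, r_new, r_new_max
    if r_max < tol:
        return _make_point(res, s, x, r_max)
    return FixedPointFailure(input_value=float(s), best_location=x, residual_max=r_max)


def continue_fixed_points(
    res: Reservoir,
    s_max: float = 1.0,
    delta: float = 0.01,
    tol: float = DEFAULT_TOL,
    max_consecutive_failures: int = 5,
) -> ContinuationResult:
    """Continue phi(s) from the trivial root phi(0) = 0 to +/- s_max.

    Two branches run from s = 0 outward in steps of ``delta``; each solve
    is warm-started from the previous solution. A branch aborts after
    ``max_consecutive_failures`` consecutive failed solves, recording the
    frontier in ``failed``.
    """
    if not delta > 0:
        raise ValueError("delta must be positive")
    n_half = int(round(s_max / delta))

    solved: dict[int, StationaryPoint] = {}
    failed: list[float] = []

    origin = solve_fixed_point(res, 0.0, np.zeros(res.n), tol)
    if isinstance(origin, FixedPointFailure):  # cannot happen: phi(0)=0 exactly
        raise RuntimeError("trivial solution at s=0 did not satisfy tolerance")
    solved[0] = origin

    for direction in (+1, -1):
        x_prev = origin.location
        misses = 0
        for k in range(1, n_half + 1):
            s = direction * k * delta
            out = solve_fixed_point(res, s, x_prev, tol)
            if isinstance(out, FixedPointFailure):
                failed.append(float(s))
                misses += 1
                if misses >= max_consecutive_failures:
                    break
            else:
                solved[direction * k] = out
                x_prev = out.location
                misses = 0

    idx = sorted(solved)
    grid = np.array([k * delta for k in idx])
    return ContinuationResult(
        grid=grid, points=[solved[k] for k in idx], failed=sorted(failed)
    )


def random_restart_search(
    res: Reservoir,
    s: float,
    n_restarts: int = 50,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
    box_halfwidth: float = 1.0,
    dedup_distance: float = 1e-4,
) -> list[StationaryPoint]:
    """Find distinct stationary points at one input value by restarts.

    Initial points are uniform in the hypercube [-box_halfwidth,
    box_halfwidth]^N (the tanh saturation scale). Converged points closer
    than ``dedup_distance`` in Euclidean norm are merged; only points
    meeting the stationarity tolerance are kept, so an empty list is a
    valid (if uninformative) outcome.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    found: list[StationaryPoint] = []
    for _ in range(n_restarts):
        x0 = rng.uniform(-box_halfwidth, box_halfwidth, size=res.n)
        out = solve_fixed_point(res, s, x0, tol)
        if isinstance(out, FixedPointFailure):
            continue
        if all(
            np.linalg.norm(out.location - p.location) >= dedup_distance
            for p in found
        ):
            found.append(out)
    return found


def rotation_plane(
    res: Reservoir, point: StationaryPoint, pair_rank: int = 0, strict: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis of the leading rotation plane at a stationary point.

    Complex-conjugate eigenvalue pairs of the Jacobian correspond, in the
    real Jordan canonical form, to 2x2 rotation-scaling blocks; the plane
    spanned by the real and imaginary parts of the associated eigenvector
    is invariant under the Jacobian and carries the local spiralling.
    ``pair_rank`` selects the complex pair by descending modulus (0 =
    leading). Raises ``ValueError`` if no such pair exists.
    """
    J = jacobian(res, point.location)
    eigvals, eigvecs = np.linalg.eig(J)
    # one representative per conjugate pair: positive imaginary part
    idx = np.where(eigvals.imag > 0)[0]
    if idx.size == 0:
        raise ValueError("no complex-conjugate eigenvalue pair: no rotation plane")
    # leading overall eigenvalue must be complex for pair_rank=0 semantics
    idx = idx[np.argsort(-np.abs(eigvals[idx]))]
    if pair_rank >= idx.size:
        raise ValueError(f"only {idx.size} complex pairs available")
    if pair_rank == 0 and strict:
        lead = np.max(np.abs(eigvals))
        if abs(np.abs(eigvals[idx[0]]) - lead) > 1e-9 * max(lead, 1.0):
            raise ValueError(
                "leading eigenvalue (largest modulus) is real; "
                "request a later pair with pair_rank"
            )
    v = eigvecs[:, idx[pair_rank]]
    basis, _ = np.linalg.qr(np.column_stack([v.real, v.imag]))
    return basis[:, 0], basis[:, 1]
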