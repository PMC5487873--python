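"""Experiment drivers: rho sweeps, skeleton sweeps, and validation fixtures.

The rho sweep measures attractor dimensionality as a function of the
timescale ratio rho for networks of a given size and gain; the skeleton
sweep maps out, per gain and per frozen input value, how many stationary
points exist and of what kind. Fixture signals with known ground-truth
attractor dimensionality (line 1, sinusoid 2, two-frequency torus 3, white
noise unpredictable) validate the estimators end to end.

All drivers derive every RNG stream from ``(master_seed, point index,
replicate index)`` so results are reproducible and independent of
evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dimensionality import EmbeddingConfig, d_knn, d_pca
from .fixedpoints import random_restart_search
from .reservoir import NetworkSpec, build_reservoir
from .simulate import DriveProtocol, SimConfig, discard_transient, simulate

__all__ = [
    "SweepSpec",
    "FixtureSpec",
    "run_rho_sweep",
    "run_skeleton_sweep",
    "make_fixture",
    "estimate_point",
]


def _child_seed(master_seed: int, *key: int) -> int:
    """Deterministic 31-bit seed for one (point, replicate, ...) cell."""
    ss = np.random.SeedSequence(master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class SweepSpec:
    """Configuration of a rho sweep.

    ``network`` is the template whose seed field is ignored (seeds are
    derived per point/replicate from ``master_seed``);
    ``redraw_network_per_point`` redraws recurrent and input weights for
    every (rho, replicate) cell, matching the protocol in which a
    different random network is created for each data point.
    """

    network: NetworkSpec
    rho_values: tuple[float, ...]
    n_replicates: int = 3
    estimators: tuple[str, ...] = ("knn",)
    redraw_network_per_point: bool = True
    master_seed: int = 0
    n_runs_per_estimate: int = 3
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if len(self.rho_values) == 0:
            raise ValueError("rho_values must be nonempty")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        bad = set(self.estimators) - {"pca", "knn"}
        if bad:
            raise ValueError(f"unknown estimators: {sorted(bad)}")


def estimate_point(
    spec: NetworkSpec,
    rho: float,
    estimator: str = "knn",
    seed: int = 0,
    n_runs: int = 3,
    embedding: EmbeddingConfig = EmbeddingConfig(),
    sim: SimConfig = SimConfig(),
    redraw: str = "state",
):
    """Dimensionality estimate for one (network, rho) cell.

    Simulates ``n_runs`` runs under the shared drive protocol, discards
    transients, and applies the requested estimator. With
    ``redraw="state"`` (default) the runs share one reservoir and differ
    only in their random initial state, so the cross-prediction estimator
    keys on the structure the drive imposes on all runs of that network.
    With ``redraw="network"`` every run additionally gets freshly drawn
    recurrent and input weights and shares only the drive — a stricter
    pairing that probes purely drive-locked structure. Returns a
    :class:`~drivenrnn.dimensionality.DimEstimate` for "knn" or a
    ``(mean D_PCA over runs, per-run values)`` tuple for "pca".
    """
    if redraw not in ("network", "state"):
        raise ValueError(f"unknown redraw mode {redraw!r}")
    protocol = DriveProtocol(rho=rho)
    runs = []
    for i in range(n_runs):
        run_seed = seed if redraw == "state" else _child_seed(seed, i)
        net = NetworkSpec(
            n_neurons=spec.n_neurons,
            connection_prob=spec.connection_prob,
            gain=spec.gain,
            seed=run_seed,
        )
        res = build_reservoir(net)
        runs.append(
            discard_transient(simulate(res, protocol, sim, seed_offset=i))
        )
    if estimator == "knn":
        return d_knn(runs, embedding, seed=seed)
    if estimator == "pca":
        vals = [d_pca(r.rates, embedding.variance_threshold) for r in runs]
        return float(np.mean(vals)), vals
    raise ValueError(f"unknown estimator {estimator!r}")


def run_rho_sweep(spec: SweepSpec) -> pd.DataFrame:
    """One row per (rho, replicate, estimator); fully seed-reproducible.

    Failures at individual points are recorded in the ``error`` column and
    the sweep continues.
    """
    rows = []
    fixed_seed = _child_seed(spec.master_seed, 0, 0)
    for pi, rho in enumerate(spec.rho_values):
        for ri in range(spec.n_replicates):
            seed = (
                _child_seed(spec.master_seed, pi, ri)
                if spec.redraw_network_per_point
                else fixed_seed
            )
            for est in spec.estimators:
                row = {
                    "rho": rho,
                    "replicate": ri,
                    "estimator": est,
                    "seed": seed,
                    "value": np.nan,
                    "stderr": np.nan,
                    "saturated": False,
                    "error": "",
                }
                try:
                    out = estimate_point(
                        spec.network,
                        rho,
                        est,
                        seed=seed,
                        n_runs=spec.n_runs_per_estimate,
                        embedding=spec.embedding,
                        sim=spec.sim,
                    )
                    if est == "knn":
                        row["value"] = out.mean
                        row["stderr"] = out.stderr
                        row["saturated"] = out.saturated
                    else:
                        row["value"] = out[0]
                except Exception as exc:  # keep sweeping past bad points
                    row["error"] = f"{type(exc).__name__}: {exc}"
                rows.append(row)
    cols = ["rho", "replicate", "estimator", "seed", "value", "stderr",
            "saturated", "error"]
    return pd.DataFrame(rows, columns=cols)


def sweep_means(table: pd.DataFrame, estimator: str = "knn") -> pd.DataFrame:
    """Per-rho mean and spread of the estimated dimensionality."""
    sub = table[(table["estimator"] == estimator) & (table["error"] == "")]
    return (
        sub.groupby("rho")["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .sort_values("rho", ignore_index=True)
    )


def run_skeleton_sweep(
    g_values,
    template: NetworkSpec,
    s_grid=None,
    n_restarts: int = 50,
    master_seed: int = 0,
    tol: float = 1e-13,
) -> pd.DataFrame:
    """Random-restart stationary-point census per (gain, input value).

    For each gain a fresh network is drawn; at each frozen input value the
    root search runs from ``n_restarts`` random starts and the distinct
    converged points are classified. Returns one row per (g, s) with sink
    and saddle counts and the per-saddle unstable eigenvalue counts.
    """
    if s_grid is None:
        s_grid = np.linspace(-1.0, 1.0, 21)
    rows = []
    for gi, g in enumerate(g_values):
        net = NetworkSpec(
            n_neurons=template.n_neurons,
            connection_prob=template.connection_prob,
            gain=float(g),
            seed=_child_seed(master_seed, gi),
        )
        res = build_reservoir(net)
        for si, s in enumerate(s_grid):
            pts = random_restart_search(
                res, float(s), n_restarts=n_restarts, tol=tol,
                seed=_child_seed(master_seed, gi, si),
            )
            n_sinks = sum(p.label == "sink" for p in pts)
            saddles = [p for p in pts if p.label == "saddle"]
            rows.append(
                {
                    "g": float(g),
                    "s": float(s),
                    "n_found": len(pts),
                    "n_sinks": n_sinks,
                    "n_saddles": len(saddles),
                    "saddle_unstable_counts": tuple(p.n_unstable for p in saddles),
                    "network_seed": net.seed,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FixtureSpec:
    """A synthetic validation signal with known attractor dimensionality.

    kinds: ``sinusoid`` (D=2), ``multisine`` (two incommensurate
    frequencies on a torus, D=3), ``linear_subspace`` (rank-r cloud,
    D_PCA=r), ``white_noise`` (unpredictable, saturates), ``relaxation``
    (exponential decay, D=1).
    """

    kind: str
    length: int = 2000
    n_channels: int = 1
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in {
            "sinusoid", "multisine", "linear_subspace", "white_noise", "relaxation"
        }:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.length < 8:
            raise ValueError("length too short for any embedding test")


def make_fixture(spec: FixtureSpec) -> np.ndarray:
    """Deterministic T x C signal matrix for estimator validation.

    Periodic kinds carry a small observation-noise floor (``noise_sd``,
    relative to the signal's spread, default 2%). A noiseless
    uniformly-sampled periodic series is degenerate for nearest-neighbour
    prediction — exact same-phase recurrences give zero-distance
    neighbours and a perfect one-dimensional forecast regardless of the
    attractor's true dimension — so the noise floor is what makes the
    fixture test geometry rather than grid arithmetic.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.length)
    p = spec.params

    def _noisy(signal: np.ndarray, default_sd: float = 0.02) -> np.ndarray:
        sd = p.get("noise_sd", default_sd)
        if sd == 0:
            return signal
        return signal + sd * signal.std(axis=0) * rng.standard_normal(signal.shape)

    if spec.kind == "sinusoid":
        period = p.get("period", 20.0 * np.pi)  # incommensurate with the grid
        phases = (
            rng.uniform(0, 2 * np.pi, spec.n_channels)
            if p.get("random_phase", False)
            else np.full(spec.n_channels, p.get("phase", 0.0))
        )
        gains = rng.uniform(0.5, 1.5, spec.n_channels)
        base = np.sin(2 * np.pi * t[:, None] / period + phases[None, :])
        return _noisy(base * gains[None, :])
    if spec.kind == "multisine":
        # trajectory on a 2-torus embedded in 3D: two incommensurate angles
        # periods of ~24 and ~34 steps keep the 4-step embedding lag at a
        # substantial phase angle, so the delay map opens up the torus
        f1 = p.get("freq1", 2 * np.pi / 24.0)
        f2 = p.get("freq2", f1 / np.sqrt(2))
        R, r = p.get("major", 2.0), p.get("minor", 1.0)
        phi, theta = f1 * t, f2 * t
        torus = np.column_stack(
            [
                (R + r * np.cos(theta)) * np.cos(phi),
                (R + r * np.cos(theta)) * np.sin(phi),
                r * np.sin(theta),
            ]
        )
        if spec.n_channels > 3:
            mix, _ = np.linalg.qr(rng.standard_normal((spec.n_channels, 3)))
            torus = torus @ mix.T
        else:
            torus = torus[:, : spec.n_channels]
        return _noisy(torus)
    if spec.kind == "linear_subspace":
        rank = p.get("rank", 3)
        latent = rng.standard_normal((spec.length, rank)) * np.linspace(
            2.0, 1.0, rank
        )
        # orthonormal mixing preserves the latent variance spectrum
        mix, _ = np.linalg.qr(rng.standard_normal((spec.n_channels, rank)))
        return latent @ mix.T
    if spec.kind == "white_noise":
        return rng.standard_normal((spec.length, spec.n_channels))
    # relaxation: exponential decay toward zero from random amplitudes
    tau = p.get("tau", spec.length / 5.0)
    amps = rng.uniform(0.5, 2.0, spec.n_channels)
    return np.outer(np.exp(-t / tau), amps)
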