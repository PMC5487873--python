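"""Random firing-rate reservoir construction and its vector field.

The network is the classical continuous-time firing-rate model

    tau dx_i/dt = -x_i + sum_j W_ij tanh(x_j) + w_i s,

with recurrent weights ``W`` drawn on a directed Erdos-Renyi graph
(connection probability ``p``, no self-connections) with nonzero entries
~ N(0, g_G^2), g_G = g / sqrt(p N), and input weights ``w`` ~ N(0, 1).
The gain ``g`` controls the autonomous regime: g < 1 is globally stable,
g >= 1 admits complex (potentially chaotic) dynamics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "NetworkSpec",
    "Reservoir",
    "build_reservoir",
    "vector_field",
    "jacobian",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Generating parameters of a random reservoir.

    Parameters
    ----------
    n_neurons : int
        Network size N (>= 1).
    connection_prob : float
        Erdos-Renyi connection probability p, in (0, 1].
    gain : float
        Global gain g (> 0); nonzero weights have std g / sqrt(p N).
    seed : int
        Master RNG seed. Topology, recurrent weights, input weights and
        initial states are drawn from independent child streams, so each
        component is individually reproducible.
    """

    n_neurons: int
    connection_prob: float
    gain: float
    seed: int

    def __post_init__(self) -> None:
        if int(self.n_neurons) < 1:
            raise ValueError(f"n_neurons must be >= 1, got {self.n_neurons}")
        if not 0.0 < self.connection_prob <= 1.0:
            raise ValueError(
                f"connection_prob must be in (0, 1], got {self.connection_prob}"
            )
        if not self.gain > 0:
            raise ValueError(f"gain must be positive, got {self.gain}")

    @property
    def weight_std(self) -> float:
        """Standard deviation g / sqrt(p N) of nonzero recurrent weights."""
        return self.gain / np.sqrt(self.connection_prob * self.n_neurons)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_neurons": self.n_neurons,
                "connection_prob": self.connection_prob,
                "gain": self.gain,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        d = json.loads(text)
        return cls(
            n_neurons=int(d["n_neurons"]),
            connection_prob=float(d["connection_prob"]),
            gain=float(d["gain"]),
            seed=int(d["seed"]),
        )


@dataclass(frozen=True)
class Reservoir:
    """A realised random network: recurrent and input weights plus spec."""

    weights: np.ndarray
    input_weights: np.ndarray
    spec: NetworkSpec

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def initial_state(self, scale: float = 0.5, seed_offset: int = 0) -> np.ndarray:
        """Draw a random initial membrane-potential vector ~ N(0, scale^2).

        The stream is derived from the spec seed so distinct ``seed_offset``
        values give independent, reproducible initial conditions.
        """
        rng = np.random.default_rng(
            np.random.SeedSequence(self.spec.seed, spawn_key=(3, seed_offset))
        )
        return scale * rng.standard_normal(self.n)

    def save(self, weights_path: str | Path, input_path: str | Path) -> None:
        """Export as plain-text CSV: dense N x N matrix and length-N vector."""
        np.savetxt(weights_path, self.weights, delimiter=",")
        np.savetxt(input_path, self.input_weights, delimiter=",")


def build_reservoir(spec: NetworkSpec) -> Reservoir:
    """Sample a reservoir from its spec.

    Each off-diagonal entry of W is present independently with probability
    p (directed edges); present entries are N(0, (g/sqrt(pN))^2). The
    diagonal is identically zero (no self-connections). Input weights are
    standard normal. Identical specs produce bitwise-identical reservoirs.
    """
    n = spec.n_neurons
    ss = np.random.SeedSequence(spec.seed)
    topo_ss, rec_ss, inp_ss, _state_ss = ss.spawn(4)

    topo_rng = np.random.default_rng(topo_ss)
    rec_rng = np.random.default_rng(rec_ss)
    inp_rng = np.random.default_rng(inp_ss)

    mask = topo_rng.random((n, n)) < spec.connection_prob
    np.fill_diagonal(mask, False)
    weights = np.where(mask, spec.weight_std * rec_rng.standard_normal((n, n)), 0.0)
    input_weights = inp_rng.standard_normal(n)
    return Reservoir(weights=weights, input_weights=input_weights, spec=spec)


def _check_state(res: Reservoir, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (res.n,):
        raise ValueError(f"state has shape {x.shape}, expected ({res.n},)")
    return x


def vector_field(
    res: Reservoir, x: np.ndarray, s: float, tau: float = 1.0
) -> np.ndarray:
    """Velocity (1/tau)(-x + W tanh(x) + w s) of the frozen-input field."""
    x = _check_state(res, x)
    if not tau > 0:
        raise ValueError(f"tau must be positive, got {tau}")
    return (-x + res.weights @ np.tanh(x) + res.input_weights * s) / tau


def jacobian(res: Reservoir, x: np.ndarray) -> np.ndarray:
    """Jacobian W * B - I of the tau-free field -x + W tanh(x) + w s.

    B has identical rows B_ij = 1 - tanh(x_j)^2, so column j of W is scaled
    by the local slope of tanh at x_j. The 1/tau prefactor is a positive
    scalar and does not affect the signs of eigenvalue real parts, hence
    stability classification is tau-independent.
    """
    x = _check_state(res, x)
    slope = 1.0 - np.tanh(x) ** 2
    return res.weights * slope[np.newaxis, :] - np.eye(res.n)
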