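"""Euler integration of the driven network under the pulse-then-sine protocol.

A run consists of a silent lead-in, a short strong pulse that collapses the
state into a small region of state space, and then a unit-amplitude sinusoid
``S(t) = sin(alpha t)``. The drive frequency is held fixed (alpha = 10 by
default, so the forcing period is tau_F = 2*pi/10) and the neuron time
constant is varied instead: tau = rho / alpha, where

    rho = 2*pi * tau / tau_F

is the single dimensionless parameter controlling the response. Varying tau
at fixed alpha is mathematically equivalent to varying the drive frequency,
but keeps the per-step resolution of the sinusoid identical across rho.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .reservoir import Reservoir

__all__ = [
    "DriveProtocol",
    "SimConfig",
    "Trajectory",
    "input_signal",
    "simulate",
    "discard_transient",
]


class IntegrationDivergenceError(RuntimeError):
    """Raised when the Euler state becomes non-finite."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"non-finite state encountered at step {step}")


@dataclass(frozen=True)
class DriveProtocol:
    """Input protocol: pulse parameters and the timescale ratio rho."""

    rho: float
    pulse_amplitude: float = 5.0
    pulse_start_step: int = 200
    pulse_duration_steps: int = 50
    base_angular_freq: float = 10.0

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ValueError(f"rho must be positive, got {self.rho}")
        if self.pulse_start_step < 0 or self.pulse_duration_steps < 0:
            raise ValueError("pulse window must be non-negative")
        if not self.base_angular_freq > 0:
            raise ValueError("base_angular_freq must be positive")

    @property
    def tau(self) -> float:
        """Neuron time constant tau = rho / alpha implied by the ratio rho."""
        return self.rho / self.base_angular_freq

    @property
    def pulse_end_step(self) -> int:
        return self.pulse_start_step + self.pulse_duration_steps


@dataclass(frozen=True)
class SimConfig:
    dt: float = 0.01
    n_steps: int = 3500
    transient_steps: int = 1500
    initial_state_scale: float = 0.5

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not 0 <= self.transient_steps < self.n_steps:
            raise ValueError("transient_steps must lie in [0, n_steps)")


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed membrane potentials and firing rates of one run.

    ``steps`` keeps the absolute step indices of the rows so that the
    instantaneous drive value can be recovered after the transient has been
    discarded.
    """

    times: np.ndarray
    potentials: np.ndarray
    rates: np.ndarray
    protocol: DriveProtocol
    config: SimConfig
    steps: np.ndarray = field(default=None)  # type: ignore[assignment]
    discarded: int = 0

    def __post_init__(self) -> None:
        if self.steps is None:
            object.__setattr__(
                self, "steps", np.arange(self.potentials.shape[0], dtype=int)
            )

    @property
    def n_steps(self) -> int:
        return self.potentials.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.potentials.shape[1]

    def drive_values(self) -> np.ndarray:
        """Instantaneous input S at each retained step."""
        return np.array(
            [input_signal(int(k), self.protocol, self.config.dt) for k in self.steps]
        )

    def to_csv(self, path: str | Path, which: str = "rates") -> None:
        """Write ``time`` plus one column per neuron (plain CSV)."""
        data = self.rates if which == "rates" else self.potentials
        header = "time," + ",".join(f"n{i}" for i in range(self.n_neurons))
        np.savetxt(
            path,
            np.column_stack([self.times, data]),
            delimiter=",",
            header=header,
            comments="",
        )

    def metadata(self) -> dict:
        return {
            "protocol": {
                "rho": self.protocol.rho,
                "pulse_amplitude": self.protocol.pulse_amplitude,
                "pulse_start_step": self.protocol.pulse_start_step,
                "pulse_duration_steps": self.protocol.pulse_duration_steps,
                "base_angular_freq": self.protocol.base_angular_freq,
            },
            "config": {
                "dt": self.config.dt,
                "n_steps": self.config.n_steps,
                "transient_steps": self.config.transient_steps,
                "initial_state_scale": self.config.initial_state_scale,
            },
            "discarded": self.discarded,
            "sinusoid_phase_origin_step": self.protocol.pulse_end_step,
        }


def load_trajectory_csv(path: str | Path) -> np.ndarray:
    """Read the multivariate series (T x N, time column stripped)."""
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return np.atleast_2d(arr)[:, 1:]


def input_signal(step: int, protocol: DriveProtocol, dt: float = 0.01) -> float:
    """Drive value at an integer step: 0, then the pulse, then sin.

    The sinusoid's phase origin sits at the first post-pulse step, so
    S = sin(alpha * (step - pulse_end) * dt) once the pulse has ended.
    """
    if step < 0:
        raise ValueError("step must be >= 0")
    if step < protocol.pulse_start_step:
        return 0.0
    if step < protocol.pulse_end_step:
        return protocol.pulse_amplitude
    t = (step - protocol.pulse_end_step) * dt
    return float(np.sin(protocol.base_angular_freq * t))


def simulate(
    res: Reservoir,
    protocol: DriveProtocol,
    config: SimConfig = SimConfig(),
    x0: np.ndarray | None = None,
    seed_offset: int = 0,
) -> Trajectory:
    """Forward-Euler integration of the driven network.

        x_{k+1} = x_k + (dt / tau) * (-x_k + W tanh(x_k) + w S_k)

    with tau = rho / alpha. Deterministic given (res, protocol, config, x0);
    when ``x0`` is omitted it is drawn reproducibly from the reservoir's
    initial-state stream (zero-mean normal, scale ``initial_state_scale``).
    """
    if x0 is None:
        x0 = res.initial_state(config.initial_state_scale, seed_offset)
    x = np.asarray(x0, dtype=float)
    if x.shape != (res.n,):
        raise ValueError(f"x0 has shape {x.shape}, expected ({res.n},)")

    n_steps = config.n_steps
    h = config.dt / protocol.tau
    W, w = res.weights, res.input_weights

    potentials = np.empty((n_steps, res.n))
    drive = np.array(
        [input_signal(k, protocol, config.dt) for k in range(n_steps)]
    )
    # overflow is handled explicitly via the divergence check below
    with np.errstate(over="ignore", invalid="ignore"):
        for k in range(n_steps):
            potentials[k] = x
            x = x + h * (-x + W @ np.tanh(x) + w * drive[k])
            if not np.all(np.isfinite(x)):
                raise IntegrationDivergenceError(k)

    times = np.arange(n_steps) * config.dt
    return Trajectory(
        times=times,
        potentials=potentials,
        rates=np.tanh(potentials),
        protocol=protocol,
        config=config,
    )


def discard_transient(traj: Trajectory, n: int | None = None) -> Trajectory:
    """Drop the first ``n`` rows (default: the config's transient_steps)."""
    if n is None:
        n = traj.config.transient_steps
    if not 0 <= n < traj.n_steps:
        raise ValueError(f"n must lie in [0, {traj.n_steps}), got {n}")
    return replace(
        traj,
        times=traj.times[n:],
        potentials=traj.potentials[n:],
        rates=traj.rates[n:],
        steps=traj.steps[n:],
        discarded=traj.discarded + n,
    )
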