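"""Shunting (membrane-equation) network dynamics and gated learning laws.

Cells obey the standard shunting form

    dx_i/dt = -A x_i + (B - x_i) E_i - (x_i - C) J_i,

where ``E_i`` is total excitatory input and ``J_i`` total inhibitory input,
so every activity stays inside ``[C, B]`` for any nonnegative input schedule.
Synaptic pathways may be gated by habituative transmitters,

    dz/dt = r (1 - z) - k S z,

a medium-term memory whose steady-state throughput ``S z* = r S / (r + k S)``
still increases monotonically with the presynaptic signal even though the
gate level itself depletes.  Long-term memory lives in adaptive weights
updated by instar (bottom-up filter) and outstar (top-down expectation)
rules, active only while a learning gate is open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np

__all__ = [
    "ShuntingParams",
    "Kernel",
    "SignalFunction",
    "GateState",
    "AdaptiveWeights",
    "step_shunting",
    "equilibrium_feedforward",
    "shunting_equilibrium",
    "step_gate",
    "gate_steady_state",
    "gated_signal",
    "instar_update",
    "outstar_update",
    "winner_take_all",
    "kernel_matrices",
]

ACTIVITY_FLOOR_FRACTION = 1e-6  # "active" means x > 1e-6 * B


@dataclass(frozen=True)
class ShuntingParams:
    """Membrane-equation constants: decay A, ceiling B, floor C, step dt."""

    A: float = 1.0
    B: float = 1.0
    C: float = 0.0
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError(f"decay rate A must be positive, got {self.A}")
        if self.B <= 0:
            raise ValueError(f"excitatory ceiling B must be positive, got {self.B}")
        if self.C > 0:
            raise ValueError(f"inhibitory floor C must be <= 0, got {self.C}")
        if self.dt <= 0 or self.dt * self.A >= 1:
            raise ValueError(
                f"dt must satisfy 0 < dt and dt*A < 1, got dt={self.dt}, A={self.A}"
            )

    @property
    def floor(self) -> float:
        return ACTIVITY_FLOOR_FRACTION * self.B


@dataclass(frozen=True)
class Kernel:
    """On-center off-surround interaction profile over a 1-D map.

    ``surround_width`` may be the string ``"global"`` for uniform surround
    inhibition; otherwise it must exceed the center width.
    """

    center_width: float = 1.0
    center_gain: float = 1.0
    surround_width: float | Literal["global"] = "global"
    surround_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.center_gain < 0 or self.surround_gain < 0:
            raise ValueError("kernel gains must be nonnegative")
        if self.surround_width != "global" and self.surround_width <= self.center_width:
            raise ValueError("off-surround must be wider than on-center")


@dataclass(frozen=True)
class SignalFunction:
    """Pointwise signal function f(x); zero at and below threshold.

    ``sigmoid`` supports winner-take-all contrast enhancement in recurrent
    competition; ``faster_than_linear`` (quadratic above threshold) chooses
    the max; ``linear`` preserves ratios for feedforward relays.
    """

    shape: Literal["linear", "faster_than_linear", "sigmoid"] = "linear"
    threshold: float = 0.0
    gain: float = 1.0

    def __call__(self, x: np.ndarray | float) -> np.ndarray:
        u = np.maximum(np.asarray(x, dtype=float) - self.threshold, 0.0)
        if self.shape == "linear":
            return self.gain * u
        if self.shape == "faster_than_linear":
            return self.gain * u * u
        # sigmoid: f(x) = u^2 / (s^2 + u^2), s = 1/gain
        s = 1.0 / self.gain
        return u * u / (s * s + u * u)


@dataclass
class GateState:
    """Habituative transmitter levels z in [0, 1] per gated pathway."""

    z: np.ndarray
    recovery_rate: float = 1.0
    depletion_rate: float = 1.0

    def __post_init__(self) -> None:
        self.z = np.atleast_1d(np.asarray(self.z, dtype=float))
        if self.recovery_rate <= 0 or self.depletion_rate < 0:
            raise ValueError("recovery rate must be > 0 and depletion rate >= 0")
        if np.any(self.z < 0) or np.any(self.z > 1):
            raise ValueError("gate levels must lie in [0, 1]")


@dataclass
class AdaptiveWeights:
    """LTM trace matrix w[pre, post] with learning rate and hard bounds."""

    w: np.ndarray
    learning_rate: float = 1.0
    w_min: float = 0.0
    w_max: float = 1.0

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError(
                f"learning rate must lie in (0, 1], got {self.learning_rate}"
            )
        if np.any(self.w < self.w_min) or np.any(self.w > self.w_max):
            raise ValueError("weights out of bounds")


def _as_inputs(state: np.ndarray, excit: np.ndarray | float, inhib: np.ndarray | float):
    x = np.atleast_1d(np.asarray(state, dtype=float))
    E = np.broadcast_to(np.asarray(excit, dtype=float), x.shape).copy()
    J = np.broadcast_to(np.asarray(inhib, dtype=float), x.shape).copy()
    if E.shape != x.shape or J.shape != x.shape:
        raise ValueError("state and input dimensions do not match")
    if np.any(E < 0) or np.any(J < 0):
        raise ValueError("shunting inputs must be nonnegative")
    return x, E, J


def step_shunting(
    state: np.ndarray,
    excit_in: np.ndarray | float,
    inhib_in: np.ndarray | float,
    p: ShuntingParams,
) -> np.ndarray:
    """Advance dx/dt = -A x + (B - x) E - (x - C) J by one explicit-Euler step.

    The update is a convex combination of the current state and the
    instantaneous equilibrium (B E + C J)/(A + E + J) whenever
    dt·(A + E + J) <= 1; if any cell violates that bound the step is
    subdivided internally, so activities remain in [C, B] for arbitrary
    nonnegative inputs.
    """
    x, E, J = _as_inputs(state, excit_in, inhib_in)
    total = p.A + E + J
    n_sub = max(1, int(np.ceil(p.dt * float(total.max()))))
    h = p.dt / n_sub
    for _ in range(n_sub):
        x = x + h * (-p.A * x + (p.B - x) * E - (x - p.C) * J)
    return x


def shunting_equilibrium(
    excit_in: np.ndarray | float, inhib_in: np.ndarray | float, p: ShuntingParams
) -> np.ndarray:
    """Fixed point x* = (B E + C J)/(A + E + J) of the shunting equation."""
    E = np.atleast_1d(np.asarray(excit_in, dtype=float))
    J = np.broadcast_to(np.asarray(inhib_in, dtype=float), E.shape)
    return (p.B * E + p.C * J) / (p.A + E + J)


def equilibrium_feedforward(I: np.ndarray, p: ShuntingParams) -> np.ndarray:
    """Divisive contrast normalization: x_i = B I_i / (A + sum_k I_k).

    This is the equilibrium of a feedforward shunting on-center off-surround
    network in which each cell is excited by its own input and inhibited by
    all others; output ratios equal input ratios and total activity <= B.
    """
    I = np.atleast_1d(np.asarray(I, dtype=float))
    if np.any(I < 0):
        raise ValueError("inputs must be nonnegative")
    return p.B * I / (p.A + I.sum())


def step_gate(g: GateState, S: np.ndarray | float, dt: float) -> GateState:
    """Advance dz/dt = r (1 - z) - k S z by dt (substepped for stability)."""
    S_arr = np.broadcast_to(np.asarray(S, dtype=float), g.z.shape)
    if np.any(S_arr < 0):
        raise ValueError("gated signal must be nonnegative")
    rate = g.recovery_rate + g.depletion_rate * S_arr
    n_sub = max(1, int(np.ceil(dt * float(rate.max()))))
    h = dt / n_sub
    z = g.z.copy()
    for _ in range(n_sub):
        z = z + h * (g.recovery_rate * (1.0 - z) - g.depletion_rate * S_arr * z)
    return replace(g, z=z)


def gate_steady_state(g: GateState, S: np.ndarray | float) -> np.ndarray:
    """Closed-form steady state z* = r / (r + k S)."""
    S_arr = np.asarray(S, dtype=float)
    return g.recovery_rate / (g.recovery_rate + g.depletion_rate * S_arr)


def gated_signal(
    S: np.ndarray | float, z: np.ndarray | float, w: np.ndarray | float = 1.0
) -> np.ndarray | float:
    """Effective transmitted signal S·z·w through a habituative gate."""
    S_arr = np.asarray(S, dtype=float)
    z_arr = np.asarray(z, dtype=float)
    if np.any(S_arr < 0):
        raise ValueError("signal must be nonnegative")
    if np.any(z_arr < 0) or np.any(z_arr > 1):
        raise ValueError("gate level must lie in [0, 1]")
    return S_arr * z_arr * np.asarray(w, dtype=float)


def instar_update(
    w: AdaptiveWeights,
    pre: np.ndarray,
    post_winner: Optional[int],
    eta: Optional[float] = None,
) -> AdaptiveWeights:
    """Gated steepest-descent (instar) step on the winner's incoming weights.

    Only column ``post_winner`` of w[pre, post] moves:
    w[:, j] <- w[:, j] + eta (pre - w[:, j]).  A ``None`` winner (no active
    postsynaptic cell) leaves the weights untouched.
    """
    eta = w.learning_rate if eta is None else eta
    if not 0.0 < eta <= 1.0:
        raise ValueError(f"learning rate must lie in (0, 1], got {eta}")
    if post_winner is None:
        return w
    new = w.w.copy()
    pre = np.asarray(pre, dtype=float)
    new[:, post_winner] += eta * (pre - new[:, post_winner])
    np.clip(new, w.w_min, w.w_max, out=new)
    return replace(w, w=new)


def outstar_update(
    w_td: AdaptiveWeights,
    source: int,
    target_pattern: np.ndarray,
    eta: Optional[float] = None,
) -> AdaptiveWeights:
    """Outstar step: only row ``source`` moves toward the sampled pattern.

    With eta = 1 (fast learning) the row equals the attended pattern after
    one resonant update.  eta = 0 is permitted and is a no-op.
    """
    eta = w_td.learning_rate if eta is None else eta
    if eta == 0.0:
        return w_td
    if not 0.0 < eta <= 1.0:
        raise ValueError(f"learning rate must lie in [0, 1], got {eta}")
    new = w_td.w.copy()
    target = np.asarray(target_pattern, dtype=float)
    new[source, :] += eta * (target - new[source, :])
    np.clip(new, w_td.w_min, w_td.w_max, out=new)
    return replace(w_td, w=new)


def winner_take_all(
    x: np.ndarray,
    excluded: frozenset[int] | set[int] = frozenset(),
    floor: float = ACTIVITY_FLOOR_FRACTION,
) -> Optional[int]:
    """Index of the strongest non-excluded cell above the activity floor.

    Ties break toward the lowest index (np.argmax convention).  Returns
    ``None`` when every candidate is at or below the floor or excluded.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("activities must be nonnegative")
    masked = x.copy()
    if excluded:
        masked[list(excluded)] = -np.inf
    j = int(np.argmax(masked))
    if masked[j] <= floor:
        return None
    return j


def kernel_matrices(n: int, kernel: Kernel, spacing: float = 1.0):
    """Dense (excitatory, inhibitory) interaction matrices for an n-cell map.

    Gaussian on-center of width ``center_width``; off-surround either a
    wider Gaussian or uniform ("global"), in map-cell units times
    ``spacing``.
    """
    idx = np.arange(n) * spacing
    d2 = (idx[:, None] - idx[None, :]) ** 2
    E = kernel.center_gain * np.exp(-d2 / (2.0 * kernel.center_width**2))
    if kernel.surround_width == "global":
        J = kernel.surround_gain * np.ones((n, n))
    else:
        J = kernel.surround_gain * np.exp(-d2 / (2.0 * float(kernel.surround_width) ** 2))
    return E, J
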