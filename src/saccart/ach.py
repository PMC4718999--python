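"""Mismatch -> nonspecific arousal -> acetylcholine -> vigilance chain.

Each mismatch between a top-down expectation and the bottom-up input emits
a nonspecific arousal burst proportional to the mismatch magnitude
m = max(0, rho|I| - |X*|).  Repeated mismatches drive cholinergic release
(nucleus basalis), raising an ACh concentration that decays on the
behavioral-episode timescale.  ACh reduces the slow and medium
afterhyperpolarization conductances (boosting the fast one), which shifts
the neuronal input/output transfer function leftward — cells fire at lower
input — and this increased excitability is read out as increased vigilance.

The theory constrains only the directions of these effects; the
functional forms here (exponential conductance decay, threshold
proportional to g_s + g_m, saturating-exponential vigilance) are chosen for
monotonicity, boundedness and closed-form testability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "MismatchEvent",
    "AChState",
    "AHPParams",
    "TransferFunction",
    "arousal_burst",
    "update_ach",
    "ahp_modulation",
    "transfer_shift",
    "vigilance_from_ach",
]

TAU_ACH = 2.0      # s, behavioral-episode decay constant
DELTA_ACH = 0.2    # concentration rise per mismatch event
C_HALF = 1.0       # concentration at which vigilance is halfway to 1

BASELINE_AHP = dict(g_f=1.0, g_m=1.0, g_s=1.0)
THETA0 = 1.0       # baseline transfer-function threshold


@dataclass(frozen=True)
class MismatchEvent:
    """One recorded expectation/input mismatch."""

    time: float
    magnitude: float
    source: Literal["cortical", "collicular"] = "cortical"

    def __post_init__(self) -> None:
        if self.magnitude <= 0:
            raise ValueError("only positive mismatches are recorded")


@dataclass(frozen=True)
class AChState:
    """Cholinergic concentration with first-order decay."""

    concentration: float = 0.0
    delta: float = DELTA_ACH
    tau: float = TAU_ACH

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be nonnegative")
        if self.tau <= 0 or self.delta < 0:
            raise ValueError("tau must be positive and delta nonnegative")


@dataclass(frozen=True)
class AHPParams:
    """Fast / medium / slow afterhyperpolarization conductance scales."""

    g_f: float
    g_m: float
    g_s: float

    def __post_init__(self) -> None:
        if min(self.g_f, self.g_m, self.g_s) < 0:
            raise ValueError("AHP conductances must be nonnegative")


@dataclass(frozen=True)
class TransferFunction:
    """Saturating input/output curve with an AHP-controlled threshold."""

    threshold: float = THETA0
    gain: float = 1.0
    saturation: float = 1.0

    def __call__(self, inp: np.ndarray | float) -> np.ndarray:
        u = np.maximum(np.asarray(inp, dtype=float) - self.threshold, 0.0)
        return self.saturation * (1.0 - np.exp(-self.gain * u))


def arousal_burst(m: float, gain: float = 1.0) -> float:
    """Nonspecific arousal amplitude gain*m, broadcast to all category cells.

    Delivered through habituative gates, a uniform burst boosts the least
    habituated (previously suppressed) cells the most, so it selectively
    silences the currently active cell (see art.dynamic_reset_winner).
    """
    if m < 0:
        raise ValueError("mismatch magnitude must be nonnegative")
    return gain * m


def update_ach(a: AChState, events: Sequence[MismatchEvent], dt: float) -> AChState:
    """Decay concentration over dt, then add delta per mismatch event."""
    c = a.concentration * math.exp(-dt / a.tau) + a.delta * len(events)
    return replace(a, concentration=c)


def ahp_modulation(
    c: float,
    g_f0: float = BASELINE_AHP["g_f"],
    g_m0: float = BASELINE_AHP["g_m"],
    g_s0: float = BASELINE_AHP["g_s"],
) -> AHPParams:
    """ACh diminishes sAHP and mAHP while boosting fAHP.

    g_s(c) = g_s0 e^{-c}, g_m(c) = g_m0 e^{-c} (strictly decreasing, -> 0),
    g_f(c) = g_f0 (2 - e^{-c}) (nondecreasing, bounded by 2 g_f0).
    """
    if c < 0:
        raise ValueError("concentration must be nonnegative")
    damp = math.exp(-c)
    return AHPParams(g_f=g_f0 * (2.0 - damp), g_m=g_m0 * damp, g_s=g_s0 * damp)


def transfer_shift(
    p: AHPParams,
    theta0: float = THETA0,
    g_m0: float = BASELINE_AHP["g_m"],
    g_s0: float = BASELINE_AHP["g_s"],
    gain: float = 1.0,
    saturation: float = 1.0,
) -> TransferFunction:
    """Leftward shift of the transfer function as slow/medium AHP shrink.

    theta = theta0 (g_s + g_m) / (g_s0 + g_m0); gain and saturation fixed,
    so reduced adaptation currents lower the firing threshold and raise the
    output at any fixed input.
    """
    theta = theta0 * (p.g_s + p.g_m) / (g_s0 + g_m0)
    return TransferFunction(threshold=theta, gain=gain, saturation=saturation)


def vigilance_from_ach(c: float, rho_base: float, c_half: float = C_HALF) -> float:
    """Vigilance raised by ACh: rho = rho_base + (1-rho_base)(1 - 2^{-c/c_half}).

    rho(0) = rho_base, strictly increasing in c, halfway to 1 at c = c_half,
    and saturating at 1.
    """
    if not 0.0 < rho_base <= 1.0:
        raise ValueError("baseline vigilance must lie in (0, 1]")
    if c < 0:
        raise ValueError("concentration must be nonnegative")
    return rho_base + (1.0 - rho_base) * (1.0 - math.exp(-c / c_half * math.log(2.0)))
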