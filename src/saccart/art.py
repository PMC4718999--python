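"""ART category learning: resonance, reset, memory search, match tracking.

The attentional system comprises a feature field F1 and a category field F2
joined by a bottom-up adaptive filter and top-down expectations.  An input I
is filtered into category evidence T; the chosen category reads out its
learned expectation V, which selects the attended feature pattern
X* = I AND V (binary mode) or min(I, V) (analog mode).  The orienting system
compares the match against vigilance: the category is reset and search
continues whenever

    rho * |I| - |X*| > 0,

and resonance (attention plus learning) ensues otherwise.  Supervised
predictive errors trigger match tracking: vigilance is raised just above
the current match ratio |X*|/|I|, forcing a search for a better or novel
category with minimal loss of generality.

Category choice uses the Weber-fraction normalization
T_j = |I AND w_j| / (alpha + |w_j|) of ART 1, whose stability and
direct-access theorems the fast-learning mode inherits: templates are
intersections of the exemplars a category has coded, and a familiar
exemplar reaches its category without search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from . import neurodyn
from .neurodyn import GateState, gated_signal

__all__ = [
    "ARTModel",
    "OrientingState",
    "SearchStep",
    "SearchTrace",
    "bottom_up_prime",
    "read_out_expectation",
    "match",
    "vigilance_check",
    "match_track",
    "search",
    "learn",
    "train",
    "dynamic_reset_winner",
    "gated_input_oracle",
]

ALPHA = 0.001          # Weber-fraction choice parameter
EPSILON_MT = 0.001     # match-tracking increment
ATTENTION_FLOOR = 1e-9  # expectation alone may not lift F1 above this


@dataclass
class OrientingState:
    """Vigilance state of the orienting system."""

    rho_base: float = 0.5
    rho: float = 0.5
    match_ratio: float = 1.0
    arousal_flag: bool = False

    def relax(self) -> None:
        """Return vigilance to baseline at the onset of a new input."""
        self.rho = self.rho_base
        self.arousal_flag = False


@dataclass(frozen=True)
class SearchStep:
    category: int
    match_ratio: float
    outcome: Literal["resonate", "reset"]


@dataclass
class SearchTrace:
    """Ordered record of one memory search: resets then a single resonance."""

    steps: list[SearchStep] = field(default_factory=list)
    final_category: Optional[int] = None
    rho_final: float = 0.0

    @property
    def reset_count(self) -> int:
        return sum(1 for s in self.steps if s.outcome == "reset")


class ARTModel:
    """Choice-mode ART network with fast or slow learning.

    Parameters
    ----------
    n_features:
        Dimension of input patterns.
    n_categories:
        Capacity of the category field (committed + uncommitted nodes).
    rho_base:
        Baseline vigilance in (0, 1].
    mode:
        ``"binary"`` (ART 1, the tested core) or ``"analog"``
        (fuzzy min-matching with city-block norms).
    eta:
        Learning rate; 1.0 is one-shot fast learning.
    """

    def __init__(
        self,
        n_features: int,
        n_categories: int = 64,
        rho_base: float = 0.5,
        mode: Literal["binary", "analog"] = "binary",
        eta: float = 1.0,
        alpha: float = ALPHA,
        epsilon: float = EPSILON_MT,
    ) -> None:
        if not 0.0 < rho_base <= 1.0:
            raise ValueError("baseline vigilance must lie in (0, 1]")
        if epsilon <= 0:
            raise ValueError("match-tracking epsilon must be positive")
        self.n_features = n_features
        self.n_categories = n_categories
        self.mode = mode
        self.eta = eta
        self.alpha = alpha
        self.epsilon = epsilon
        # uncommitted rows are "all large": they match anything
        self.w_td = np.ones((n_categories, n_features))
        # uniform small bottom-up weights for uncommitted nodes
        self.w_bu = np.full((n_features, n_categories), 1.0 / (alpha + n_features))
        self.committed: set[int] = set()
        self.labels: dict[int, object] = {}
        self.orienting = OrientingState(rho_base=rho_base, rho=rho_base)
        self.reset_set: set[int] = set()

    # -- core operations ---------------------------------------------------

    def template(self, j: int) -> np.ndarray:
        return self.w_td[j]

    def norm(self, x: np.ndarray) -> float:
        return float(np.sum(x))

    def _check_input(self, I: np.ndarray) -> np.ndarray:
        I = np.asarray(I, dtype=float)
        if I.shape != (self.n_features,):
            raise ValueError(
                f"expected input of dimension {self.n_features}, got {I.shape}"
            )
        if np.any(I < 0):
            raise ValueError("input features must be nonnegative")
        if not np.any(I > 0):
            raise ValueError("a presentable pattern needs a positive component")
        return I


def bottom_up_prime(I: np.ndarray, model: ARTModel) -> np.ndarray:
    """Category evidence T_j = |I AND w_j| / (alpha + |w_j|) for every node.

    Uncommitted nodes carry the all-ones template, so they receive the
    Weber-discounted evidence |I| / (alpha + d) and lose ties against any
    committed node whose template is contained in I.
    """
    I = model._check_input(I)
    overlap = np.minimum(I[:, None], model.w_td.T)  # features x categories
    return overlap.sum(axis=0) / (model.alpha + model.w_td.sum(axis=1))


def read_out_expectation(j: int, model: ARTModel) -> np.ndarray:
    """Top-down expectation V of category j (its learned prototype).

    The expectation is modulatory: without bottom-up input it primes but
    cannot fire F1 (the matched pattern stays at the attentional floor),
    which :func:`match` realizes by intersecting V with I.
    """
    if j in model.reset_set:
        raise ValueError(f"category {j} is reset for this presentation")
    return model.w_td[j].copy()


def match(I: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, float]:
    """Attended pattern X* = min(I, V) and match ratio |X*|/|I|.

    In binary mode min coincides with logical AND.  Mismatched features are
    suppressed by the off-surround of the matching circuit; with no
    bottom-up input the expectation alone cannot activate F1.
    """
    I = np.asarray(I, dtype=float)
    V = np.asarray(V, dtype=float)
    total = float(I.sum())
    if total <= 0:
        raise ValueError("match undefined for an empty input pattern")
    x_star = np.minimum(I, V)
    return x_star, float(x_star.sum()) / total


def vigilance_check(I: np.ndarray, x_star: np.ndarray, rho: float) -> str:
    """``"resonate"`` iff rho |I| - |X*| <= 0, else ``"reset"``.

    With no top-down expectation active, |X*| = |I| and any rho <= 1
    resonates.
    """
    excit = rho * float(np.sum(I))
    inhib = float(np.sum(x_star))
    return "resonate" if excit - inhib <= 0 else "reset"


def reset_category(model: ARTModel, j: int) -> None:
    """Inhibit category j for the remainder of this input presentation."""
    model.reset_set.add(j)


def match_track(rho: float, match_ratio: float, epsilon: float = EPSILON_MT) -> float:
    """Raise vigilance just above the current match ratio.

    The new vigilance rho' = match_ratio + epsilon is the smallest value
    that makes rho'|I| - |X*| positive, i.e. that resets the category which
    just produced a predictive error; it is capped at 1 (a same-exemplar
    label conflict cannot be resolved by vigilance).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return min(match_ratio + epsilon, 1.0)


def search(I: np.ndarray, model: ARTModel, rho: Optional[float] = None) -> SearchTrace:
    """Run one resonance/reset search cycle for input I.

    Categories are tried in nonincreasing order of bottom-up evidence T_j;
    each is matched against vigilance, reset on mismatch, and the first
    resonating category (an uncommitted node always resonates, its all-max
    template matching any input) terminates the search.
    """
    I = model._check_input(I)
    rho = model.orienting.rho if rho is None else rho
    model.reset_set = set()
    trace = SearchTrace()
    while True:
        T = bottom_up_prime(I, model)
        j = neurodyn.winner_take_all(T, excluded=model.reset_set, floor=-np.inf)
        if j is None:
            raise RuntimeError("category capacity exhausted during search")
        V = read_out_expectation(j, model)
        x_star, ratio = match(I, V)
        outcome = vigilance_check(I, x_star, rho)
        trace.steps.append(SearchStep(j, ratio, outcome))  # type: ignore[arg-type]
        if outcome == "resonate":
            trace.final_category = j
            trace.rho_final = rho
            model.orienting.match_ratio = ratio
            return trace
        reset_category(model, j)


def learn(model: ARTModel, j: int, x_star: np.ndarray) -> None:
    """Resonant learning: prune the top-down template toward X*.

    Fast mode (eta = 1): w_td[j] <- X* and the bottom-up column is its
    Weber-normalized image X* / (alpha + |X*|); slow mode takes a convex
    step toward those targets.  Only resonant states may drive learning.
    """
    if j in model.reset_set:
        raise ValueError("learning requires a resonant (non-reset) category")
    x_star = np.asarray(x_star, dtype=float)
    eta = model.eta
    target_bu = x_star / (model.alpha + float(x_star.sum()))
    model.w_td[j] += eta * (x_star - model.w_td[j])
    model.w_bu[:, j] += eta * (target_bu - model.w_bu[:, j])
    model.committed.add(j)


def present(
    model: ARTModel,
    I: np.ndarray,
    label: object = None,
    learning: bool = True,
) -> SearchTrace:
    """Present one exemplar: search, optional supervision, optional learning.

    Supervised mode (label not None): if the resonating category carries a
    different label, match tracking raises vigilance just above the match
    ratio and the search resumes within the same presentation, so the error
    forces either a better committed category or a novel one.
    """
    model.orienting.relax()
    rho = model.orienting.rho
    trace = search(I, model, rho=rho)
    if label is not None:
        while True:
            j = trace.final_category
            assert j is not None
            if j not in model.committed or model.labels.get(j, label) == label:
                break
            ratio = trace.steps[-1].match_ratio
            if ratio >= 1.0:
                # identical exemplar with conflicting labels: unresolvable
                model.orienting.arousal_flag = True
                trace.final_category = None
                return trace
            rho = match_track(rho, ratio, model.epsilon)
            model.orienting.rho = rho
            model.orienting.arousal_flag = True
            reset_category(model, j)
            continuation = search(I, model, rho=rho)
            trace.steps.extend(continuation.steps)
            trace.final_category = continuation.final_category
            trace.rho_final = rho
    if learning and trace.final_category is not None:
        j = trace.final_category
        V = model.w_td[j]
        x_star, _ = match(I, V)
        learn(model, j, x_star)
        if label is not None:
            model.labels[j] = label
    return trace


def train(
    stream: Sequence[np.ndarray] | Iterable[tuple[np.ndarray, object]],
    rho_base: float = 0.5,
    mode: Literal["binary", "analog"] = "binary",
    n_categories: int = 64,
    eta: float = 1.0,
    supervised: bool = False,
    model: Optional[ARTModel] = None,
) -> tuple[ARTModel, list[SearchTrace]]:
    """Train an ART model on an exemplar stream.

    ``stream`` holds either bare patterns (unsupervised) or
    ``(pattern, label)`` pairs (supervised; labels drive match tracking).
    Returns the model and the per-presentation search traces.
    """
    items = list(stream)
    if not items:
        raise ValueError("empty training stream")
    first = items[0]
    if supervised:
        patterns = [np.asarray(p, dtype=float) for p, _ in items]
        labels: list[object] = [lab for _, lab in items]
    else:
        patterns = [np.asarray(p, dtype=float) for p in items]
        labels = [None] * len(items)
    d = patterns[0].shape[0]
    if model is None:
        model = ARTModel(
            n_features=d, n_categories=n_categories, rho_base=rho_base,
            mode=mode, eta=eta,
        )
    traces = [present(model, p, label=lab) for p, lab in zip(patterns, labels)]
    return model, traces


# -- dynamic reset: arousal bursts through habituative gates ----------------

def gated_input_oracle(T: np.ndarray, z: np.ndarray, burst: float) -> int:
    """Direct comparison oracle: argmax of the gated net inputs (T_j + burst) z_j."""
    T = np.asarray(T, dtype=float)
    z = np.asarray(z, dtype=float)
    return int(np.argmax((T + burst) * z))


def dynamic_reset_winner(
    T: np.ndarray,
    gates: GateState,
    burst: float,
    params: Optional[neurodyn.ShuntingParams] = None,
    n_steps: int = 400,
) -> int:
    """Winner after a nonspecific arousal burst, via recurrent competition.

    Every category cell receives its gated specific input plus the same
    uniform burst, also gated: the currently active cell's transmitter is
    the most habituated (lowest z), so the uniform burst amplifies
    previously suppressed cells more and the choice switches to the
    strongest of them.  The winner is read out of a recurrent shunting
    winner-take-all network driven by the gated inputs.
    """
    T = np.asarray(T, dtype=float)
    p = params or neurodyn.ShuntingParams(A=1.0, B=1.0, C=-0.2, dt=0.02)
    net = np.asarray(gated_signal(T + burst, gates.z), dtype=float)
    sig = neurodyn.SignalFunction(shape="sigmoid", threshold=0.0, gain=4.0)
    x = np.zeros_like(net)
    for _ in range(n_steps):
        f = sig(np.maximum(x, 0.0))
        excit = net + 2.0 * f
        inhib = np.full_like(net, 2.0 * f.sum()) - 2.0 * f
        x = neurodyn.step_shunting(x, excit, inhib, p)
    j = neurodyn.winner_take_all(np.maximum(x, 0.0), floor=p.floor)
    if j is None:
        j = int(np.argmax(net))
    return j
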