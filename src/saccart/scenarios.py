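"""Synthetic scenario generators for category-learning and saccade trials.

Every generator is a pure function of its parameters and a seed, so the same
specification reproduces byte-identical fixtures.  Binary feature patterns
with controlled overlap feed the category-learning tests; nested pattern
pairs reproduce the classic concrete-versus-abstract (C inside O) teaching
scenario; target schedules drive the multimodal map training, oddball runs
probe habituative novelty, and bimodal probes exercise multisensory
enhancement and suppression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioSpec",
    "gen_binary_patterns",
    "gen_nested_pair",
    "gen_target_schedule",
    "gen_oddball",
    "gen_bimodal_probe",
    "schedule_to_csv",
    "schedule_from_csv",
    "TRAINED_POSITIONS",
]

TRAINED_POSITIONS = (-30.0, -20.0, -10.0, 0.0, 10.0, 20.0, 30.0)
N_TRAIN_TRIALS = 200


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative description of a synthetic fixture."""

    kind: Literal[
        "binary_patterns", "nested_pair", "target_schedule", "oddball", "bimodal_probe"
    ]
    params: dict = field(default_factory=dict)
    seed: int = 0

    def generate(self):
        fn = {
            "binary_patterns": gen_binary_patterns,
            "nested_pair": gen_nested_pair,
            "target_schedule": gen_target_schedule,
            "oddball": gen_oddball,
            "bimodal_probe": gen_bimodal_probe,
        }[self.kind]
        kwargs = dict(self.params)
        if self.kind != "bimodal_probe":
            kwargs["seed"] = self.seed
        return fn(**kwargs)


def _jaccard_expectation(core: int, private: int, pool: int) -> float:
    """Expected Jaccard overlap of two core+random-private patterns."""
    if private == 0:
        return 1.0 if core > 0 else 0.0
    inter = core + private * private / pool
    union = core + 2 * private - private * private / pool
    return inter / union


def gen_binary_patterns(
    n: int, d: int, overlap: float = 0.4, seed: int = 0
) -> list[np.ndarray]:
    """n binary d-vectors with expected pairwise Jaccard overlap ~ ``overlap``.

    Construction: a shared feature core plus per-pattern random private
    features, with (core, private) sizes chosen by grid search over the
    expected Jaccard.  ``overlap=0`` uses exactly disjoint supports (error
    if d < n), ``overlap=1`` returns identical patterns.
    """
    if n < 1 or d < 2:
        raise ValueError("need n >= 1 and d >= 2")
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if overlap == 0.0:
        size = d // n
        if size < 1:
            raise ValueError(f"cannot fit {n} disjoint patterns in {d} features")
        perm = rng.permutation(d)
        out = []
        for i in range(n):
            p = np.zeros(d)
            p[perm[i * size : (i + 1) * size]] = 1.0
            out.append(p)
        return out
    if overlap == 1.0:
        p = np.zeros(d)
        p[rng.choice(d, size=max(1, d // 2), replace=False)] = 1.0
        return [p.copy() for _ in range(n)]
    best, best_err = None, np.inf
    for core in range(0, d):
        for private in range(0, d - core):
            if core + private == 0 or core + private > d - private:
                continue
            err = abs(_jaccard_expectation(core, private, d - core) - overlap)
            if err < best_err:
                best, best_err = (core, private), err
    assert best is not None
    core, private = best
    core_idx = rng.choice(d, size=core, replace=False)
    pool = np.setdiff1d(np.arange(d), core_idx)
    out = []
    for _ in range(n):
        p = np.zeros(d)
        p[core_idx] = 1.0
        if private:
            p[rng.choice(pool, size=private, replace=False)] = 1.0
        out.append(p)
    return out


def gen_nested_pair(
    d: int = 25, inner_size: int = 12, outer_size: int = 16, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """A strictly nested binary pair: supp(C) a proper subset of supp(O).

    The inner pattern plays the role of a previously learned category (the
    letter C) whose features are all shared by the outer one (the letter O),
    so the unsupervised match ratio of O against C's template is
    inner_size/outer_size.
    """
    if not inner_size < outer_size <= d:
        raise ValueError("need inner_size < outer_size <= d")
    rng = np.random.default_rng(seed)
    outer_idx = rng.choice(d, size=outer_size, replace=False)
    inner_idx = rng.choice(outer_idx, size=inner_size, replace=False)
    c = np.zeros(d)
    c[inner_idx] = 1.0
    o = np.zeros(d)
    o[outer_idx] = 1.0
    return c, o


def gen_target_schedule(
    positions: Sequence[float] = TRAINED_POSITIONS,
    modalities: Sequence[str] = ("auditory", "planned"),
    n_trials: int = N_TRAIN_TRIALS,
    pairing: Literal["colocated", "independent"] = "colocated",
    seed: int = 0,
    salience: float = 1.0,
) -> pd.DataFrame:
    """Training schedule pairing a visual-reactive target with a cue.

    ``colocated`` places the non-visual cue at the visual position every
    trial (the map-learning condition); ``independent`` draws the two
    positions separately (the control that should leave the maps
    unaligned).  Tidy frame: trial, modality, position_deg, salience.
    """
    rng = np.random.default_rng(seed)
    positions = np.asarray(positions, dtype=float)
    rows = []
    for trial in range(n_trials):
        vpos = float(rng.choice(positions))
        cue_mod = str(rng.choice(list(modalities)))
        cpos = vpos if pairing == "colocated" else float(rng.choice(positions))
        rows.append((trial, "visual_reactive", vpos, salience))
        rows.append((trial, cue_mod, cpos, salience))
    return pd.DataFrame(rows, columns=["trial", "modality", "position_deg", "salience"])


def gen_oddball(
    standard_pos: float = 10.0,
    deviant_pos: float = 20.0,
    p_deviant: float = 0.2,
    n: int = 50,
    seed: int = 0,
    modality: str = "visual_reactive",
    salience: float = 1.0,
) -> pd.DataFrame:
    """Spatial oddball schedule: rare deviant position among standards."""
    if not 0.0 <= p_deviant <= 1.0:
        raise ValueError("deviant probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    deviant = rng.random(n) < p_deviant
    rows = [
        (i, modality, deviant_pos if dev else standard_pos, salience, bool(dev))
        for i, dev in enumerate(deviant)
    ]
    return pd.DataFrame(
        rows, columns=["trial", "modality", "position_deg", "salience", "deviant"]
    )


def gen_bimodal_probe(
    offset_deg: float = 0.0,
    salience_v: float = 1.0,
    salience_a: float = 0.8,
) -> pd.DataFrame:
    """Single bimodal trial: visual at 0 degrees, auditory at ``offset_deg``."""
    rows = [
        (0, "visual_reactive", 0.0, salience_v),
        (0, "auditory", float(offset_deg), salience_a),
    ]
    return pd.DataFrame(rows, columns=["trial", "modality", "position_deg", "salience"])


def schedule_to_csv(schedule: pd.DataFrame, path) -> None:
    schedule.to_csv(path, index=False)


def schedule_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
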