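"""Trial-level saccade dynamics: gating, kinematics, wave/decay, novelty.

One trial runs the full loop: targets are instated on the motor-error map
(reactive targets directly, head-centered targets through the learned
transforms), the two-nucleus choice circuit selects a locus, the SNr gate
withholds the command until the winner's activity has exceeded a threshold
for a sustained interval, and the saccade generator — reduced to a
proportional-velocity kinematic plant — executes the movement.  During the
movement the corollary discharge of the changing eye position continuously
updates the motor-error vector, which drags the buildup-cell activity
rostrally across the map (the spreading wave) while off-surround inhibition
from the wave erodes the burst-cell peak at the original target locus (peak
decay).  After landing, a postural gate opens and the vector-associative-map
and cerebellar-gain learning steps run.  Habituative transmitter gates per
map locus deplete with use, so recently chosen positions compete at a
disadvantage against novel ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import neurodyn
from .maps import (
    ChoiceParams,
    HeadCenteredTarget,
    MotorErrorVector,
    SaccartModel,
    SpaceConfig,
    teaching_signal,
)
from .neurodyn import GateState

__all__ = [
    "EyeState",
    "SNrGate",
    "TrialConfig",
    "TrialTrace",
    "saccade_step",
    "corollary_update",
    "update_spreading_wave",
    "update_burst",
    "run_trial",
    "run_schedule",
    "train_saccart",
    "alignment_report",
]


@dataclass
class EyeState:
    """Eye-in-head position and velocity (tonic-cell efference copy)."""

    position: np.ndarray
    velocity: np.ndarray
    moving: bool = False

    def __post_init__(self) -> None:
        self.position = np.atleast_1d(np.asarray(self.position, dtype=float))
        self.velocity = np.atleast_1d(np.asarray(self.velocity, dtype=float))
        if not self.moving and np.any(self.velocity != 0):
            raise ValueError("stationary eye must have zero velocity")


@dataclass
class SNrGate:
    """Inhibitory gate on movement-command release, per channel."""

    open: dict = field(default_factory=lambda: {"reactive": False, "planned": False})

    def any_open(self) -> bool:
        return any(self.open.values())


@dataclass(frozen=True)
class TrialConfig:
    """Timing, plant, gating and habituation constants for one trial.

    Times in seconds, positions in degrees.  The SNr gate opens once the
    choice winner's activity has exceeded ``snr_threshold`` (fraction of the
    shunting ceiling) for ``snr_hold`` consecutive seconds.  The residual
    spreading-wave decay and the peak-decay inhibition rates are per second.
    """

    dt: float = 0.001
    max_duration: float = 0.6
    choice_timeout: float = 0.3
    k_v: float = 50.0                 # plant proportional-velocity rate, 1/s
    stop_tol: float = 0.05            # deg, remaining-drive termination
    min_amplitude: float = 0.5        # deg, commands smaller than this do not move
    snr_threshold: float = 0.2
    snr_hold: float = 0.010
    wave_decay: float = 30.0          # 1/s residual decay of the spreading wave
    pd_passive: float = 2.0           # 1/s passive burst-cell decay
    pd_inhibition: float = 8.0        # 1/s per unit of wave activity
    sparing_sigma: float = 2.0        # cells, on-center sparing around the wave
    gate_recovery: float = 0.5        # 1/s habituative transmitter recovery
    gate_depletion: float = 1.0       # 1/(signal*s) transmitter depletion
    intertrial: float = 0.5           # s of fixation between scheduled trials
    learning: bool = True


@dataclass
class TrialTrace:
    """Complete time-indexed record of one trial."""

    time: list = field(default_factory=list)
    pd: list = field(default_factory=list)
    sw: list = field(default_factory=list)
    choice: list = field(default_factory=list)
    eye: list = field(default_factory=list)
    gate_open: list = field(default_factory=list)
    winner: Optional[int] = None
    landing_error: Optional[float] = None
    choice_latency: Optional[float] = None
    aborted: bool = False
    abort_reason: str = ""
    events: list = field(default_factory=list)

    def log(self, t, pd, sw, choice, eye, gate_open) -> None:
        self.time.append(t)
        self.pd.append(pd.copy())
        self.sw.append(sw.copy())
        self.choice.append(choice.copy())
        self.eye.append(np.atleast_1d(eye).copy())
        self.gate_open.append(bool(gate_open))

    def sw_centroids(self, space: SpaceConfig) -> np.ndarray:
        ecc = np.linalg.norm(space.loci, axis=1)
        out = []
        for a in self.sw:
            s = a.sum()
            out.append(float((a * ecc).sum() / s) if s > 0 else np.nan)
        return np.asarray(out)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame: time, layer, cell, value."""
        rows = []
        for layer, series in (("peak_decay", self.pd), ("spreading_wave", self.sw),
                              ("choice", self.choice)):
            for t, arr in zip(self.time, series):
                for i, v in enumerate(arr):
                    rows.append((t, layer, i, v))
        for t, e in zip(self.time, self.eye):
            rows.append((t, "eye", 0, float(e[0])))
        return pd.DataFrame(rows, columns=["time", "layer", "cell", "value"])


def saccade_step(
    eye: EyeState,
    v: MotorErrorVector,
    gain: np.ndarray | float,
    gate: SNrGate,
    dt: float,
    k_v: float = 50.0,
    stop_tol: float = 0.5,
) -> EyeState:
    """Advance the kinematic plant one step under an SNr-gated command.

    Velocity is proportional to the gained motor error; the movement
    terminates (``moving`` False, zero velocity) when the decoded error
    drops below ``stop_tol`` degrees.  A closed gate leaves the eye
    untouched.
    """
    if not gate.any_open():
        return eye
    drive = v.signed + np.atleast_1d(np.asarray(gain, dtype=float))
    if np.linalg.norm(drive) < stop_tol:
        return EyeState(position=eye.position, velocity=np.zeros_like(eye.position),
                        moving=False)
    vel = k_v * drive
    return EyeState(position=eye.position + dt * vel, velocity=vel, moving=True)


def corollary_update(
    h_target: np.ndarray | float, eye: EyeState, model: Optional[SaccartModel] = None,
    h_locus: Optional[int] = None,
) -> MotorErrorVector:
    """Recompute the motor-error vector from the current eye position.

    For a calibrated head-centered locus the adaptive read-out W[h] is used;
    otherwise the target position itself stands in (a perfectly calibrated
    read-out).  The decoded error shrinks as an accurate movement proceeds.
    """
    if model is not None and h_locus is not None:
        return model.compute_motor_error_vector(h_locus, eye.position)
    h = np.atleast_1d(np.asarray(h_target, dtype=float))
    return MotorErrorVector.from_signed(h - eye.position)


def update_spreading_wave(
    sw: np.ndarray,
    v_now: MotorErrorVector,
    space: SpaceConfig,
    dt: float,
    wave_decay: float = 30.0,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Shift the buildup-cell bump to the locus of the current motor error.

    Residual activity at previously visited loci decays at ``wave_decay``,
    leaving a rostrally propagating wave as the error shrinks toward zero
    (the foveal pole).
    """
    sw = sw * np.exp(-wave_decay * dt)
    locus = space.locus_of(v_now.signed)
    sw[locus] = max(sw[locus], amplitude)
    return sw


def update_burst(
    pd_layer: np.ndarray,
    sw: np.ndarray,
    space: SpaceConfig,
    dt: float,
    pd_passive: float = 2.0,
    pd_inhibition: float = 8.0,
    sparing_sigma: float = 2.0,
) -> np.ndarray:
    """Erode burst-cell peaks away from the wave; spare the aligned locus.

    The spreading wave's off-surround inhibits burst cells at all other map
    positions, so activity at the original target locus decays once the
    wave departs; the cell under the wave is spared by the resonant
    on-center.  With no wave, only the passive decay acts.  The update is a
    multiplicative decay, so no burst activity ever increases.
    """
    total = sw.sum()
    if total <= 0:
        return pd_layer * np.exp(-pd_passive * dt)
    center = int(np.argmax(sw))
    dcells = np.linalg.norm(space.loci - space.loci[center], axis=1) / space.spacing
    sparing = np.exp(-(dcells**2) / (2.0 * sparing_sigma**2))
    rate = (pd_passive + pd_inhibition * total) * (1.0 - sparing)
    return pd_layer * np.exp(-rate * dt)


def _choice_step(model: SaccartModel, x: np.ndarray, bu: np.ndarray,
                 hole: np.ndarray) -> np.ndarray:
    cp = model.choice_params
    p = cp.shunt
    xr = np.maximum(x, 0.0)
    n1 = np.minimum(xr / p.B, 1.0)
    excit = bu * (1.0 + cp.fb_gain * n1)
    broad = cp.n2_drive(bu.sum(), xr.sum())
    inhib = cp.contrast * cp.inh_gain * broad * (1.0 - hole)
    return neurodyn.step_shunting(x, excit, inhib, p)


def run_trial(
    targets: Sequence[HeadCenteredTarget],
    model: SaccartModel,
    config: Optional[TrialConfig] = None,
    eye0: np.ndarray | float = 0.0,
    gates: Optional[GateState] = None,
) -> TrialTrace:
    """Execute one full saccade trial and return its trace.

    Phases: (1) choice — bottom-up instatement gated by habituative
    transmitter, two-nucleus competition, SNr threshold-hold gating;
    (2) movement — gained command, proportional-velocity plant, corollary
    updating, spreading wave and peak decay; (3) fixation — postural-gate
    learning (VAM and cerebellar gain) and transmitter depletion.
    """
    cfg = config or TrialConfig()
    space = model.space
    e0 = np.atleast_1d(np.asarray(eye0, dtype=float)).astype(float)
    trace = TrialTrace()

    z = gates.z if gates is not None else np.ones(space.n_loci)
    bu = np.zeros(space.n_loci)
    pd_layer = np.zeros(space.n_loci)
    for t in targets:
        drive = model.map_drive(t, e0)
        bu += drive * z
        if t.modality == "visual_reactive":
            pd_layer += drive * z

    if bu.max(initial=0.0) <= model.choice_params.shunt.floor:
        trace.aborted = True
        trace.abort_reason = "no suprathreshold map input"
        return trace

    hole_center = int(np.argmax(bu))
    dcells = (
        np.linalg.norm(space.loci - space.loci[hole_center], axis=1) / space.spacing
    )
    cp = model.choice_params
    hole = cp.hole_depth * np.exp(-(dcells**2) / (2.0 * cp.hole_sigma**2))

    # phase 1: choice + SNr gating
    x = np.zeros(space.n_loci)
    gate = SNrGate()
    sw = np.zeros(space.n_loci)
    eye = EyeState(position=e0.copy(), velocity=np.zeros_like(e0))
    t_now = 0.0
    hold = 0.0
    winner = None
    n_choice = int(round(cfg.choice_timeout / cfg.dt))
    for _ in range(n_choice):
        x = _choice_step(model, x, bu, hole)
        xr = np.maximum(x, 0.0)
        j = int(np.argmax(xr))
        if xr[j] > cfg.snr_threshold * cp.shunt.B:
            hold += cfg.dt
        else:
            hold = 0.0
        trace.log(t_now, pd_layer, sw, xr, eye.position, gate.any_open())
        t_now += cfg.dt
        if hold >= cfg.snr_hold:
            winner = j
            break
    if winner is None:
        trace.aborted = True
        trace.abort_reason = "SNr gate never opened (target unreachable)"
        return trace

    trace.winner = winner
    trace.choice_latency = t_now
    trace.events.append(("choice", t_now, winner))
    gate.open["reactive"] = True

    # phase 2: movement
    v0 = MotorErrorVector.from_signed(space.position_of(winner))
    h_eff = e0 + v0.signed                      # head-centered goal of the command
    command = model.command(v0, winner)
    endpoint = e0 + model.plant_gain * command  # ballistic plant endpoint
    sw = update_spreading_wave(sw, v0, space, 0.0, cfg.wave_decay)
    if np.linalg.norm(command) >= cfg.min_amplitude:
        eye = EyeState(position=e0.copy(), velocity=np.zeros_like(e0), moving=True)
        n_max = int(round(cfg.max_duration / cfg.dt))
        for _ in range(n_max):
            remaining = endpoint - eye.position
            if np.linalg.norm(remaining) < cfg.stop_tol:
                # residual plant drive settles the eye onto the endpoint
                eye = EyeState(position=endpoint.copy(),
                               velocity=np.zeros_like(e0), moving=False)
                break
            vel = cfg.k_v * remaining
            eye = EyeState(position=eye.position + cfg.dt * vel, velocity=vel,
                           moving=True)
            v_now = MotorErrorVector.from_signed(h_eff - eye.position)
            sw = update_spreading_wave(sw, v_now, space, cfg.dt, cfg.wave_decay)
            pd_layer = update_burst(pd_layer, sw, space, cfg.dt, cfg.pd_passive,
                                    cfg.pd_inhibition, cfg.sparing_sigma)
            x = _choice_step(model, x, bu, hole)
            trace.log(t_now, pd_layer, sw, np.maximum(x, 0.0), eye.position, True)
            t_now += cfg.dt
        eye = EyeState(position=eye.position, velocity=np.zeros_like(e0), moving=False)
    trace.events.append(("land", t_now, float(eye.position[0])))

    # phase 3: post-saccadic fixation — postural gate opens, learning runs
    landing_err = h_eff - eye.position
    trace.landing_error = float(np.linalg.norm(landing_err))
    if cfg.learning:
        for t in targets:
            h = t.pos_array(space.d)
            h_locus = space.locus_of(h)
            if t.modality == "visual_reactive":
                model.cerebellar_gain_update(winner, landing_err)
            else:
                model.vam_learn(h_locus, eye.position, postural_gate=True)

    # habituative transmitter depletion over the trial
    if gates is not None:
        stepped = neurodyn.step_gate(
            GateState(z=z, recovery_rate=cfg.gate_recovery,
                      depletion_rate=cfg.gate_depletion),
            S=bu,
            dt=t_now if t_now > 0 else cfg.dt,
        )
        gates.z = stepped.z
    return trace


def run_schedule(
    schedule: pd.DataFrame,
    model: SaccartModel,
    config: Optional[TrialConfig] = None,
    gates: Optional[GateState] = None,
) -> list[TrialTrace]:
    """Run a target schedule trial by trial, with intertrial gate recovery.

    ``schedule`` is tidy: one row per cue with columns trial, modality,
    position_deg, salience; all cues sharing a trial index are presented
    simultaneously.
    """
    cfg = config or TrialConfig()
    traces = []
    for _, group in schedule.groupby("trial", sort=True):
        targets = [
            HeadCenteredTarget(r.modality, float(r.position_deg), float(r.salience))
            for r in group.itertuples()
        ]
        traces.append(run_trial(targets, model, cfg, gates=gates))
        if gates is not None and cfg.intertrial > 0:
            stepped = neurodyn.step_gate(
                GateState(z=gates.z, recovery_rate=cfg.gate_recovery,
                          depletion_rate=cfg.gate_depletion),
                S=0.0,
                dt=cfg.intertrial,
            )
            gates.z = stepped.z
    return traces


def train_saccart(
    model: SaccartModel,
    schedule: pd.DataFrame,
    config: Optional[TrialConfig] = None,
) -> list[TrialTrace]:
    """Train all SACCART stages on a (visual, cue) pairing schedule.

    Each trial instates its targets, chooses, saccades and then runs the
    post-saccadic learning: cerebellar gain and VAM from the landing error,
    vector-to-map instar on the nucleus-1 winner for the non-visual cue, and
    map-to-map learning against the Gaussian teacher centered on the
    visually activated locus, masked by the choice competition.
    """
    cfg = config or TrialConfig()
    traces = []
    for _, group in schedule.groupby("trial", sort=True):
        targets = [
            HeadCenteredTarget(r.modality, float(r.position_deg), float(r.salience))
            for r in group.itertuples()
        ]
        e0 = np.zeros(model.space.d)
        visual = [t for t in targets if t.modality == "visual_reactive"]
        others = [t for t in targets if t.modality != "visual_reactive"]
        # pre-saccadic motor-error vector of the head-centered cue
        pre_v = {}
        for t in others:
            h_locus = model.space.locus_of(t.pos_array(model.space.d))
            pre_v[t] = MotorErrorVector.from_signed(model.vam_w[h_locus] - e0)
        tr = run_trial(targets, model, cfg, eye0=e0)
        traces.append(tr)
        if tr.aborted or tr.winner is None:
            continue
        if visual and others:
            pd_locus = model.space.locus_of(visual[0].retinal(e0))
            teacher = teaching_signal(pd_locus, model.space, model.sigma_g)
            mask = model.competition_mask(tr.winner)
            for t in others:
                n1 = model.vector_to_map_choose_and_learn(pre_v[t])
                model.map_to_map_learn(n1, teacher, mask)
    return traces


def alignment_report(
    model: SaccartModel,
    positions: Sequence[float],
    modality: str = "auditory",
) -> pd.DataFrame:
    """Compare the SC winner for non-visual vs. visual cues position by position."""
    rows = []
    for p in positions:
        vis = model.choose([HeadCenteredTarget("visual_reactive", p)])
        oth = model.choose([HeadCenteredTarget(modality, p)])
        rows.append(
            dict(
                position_deg=p,
                visual_winner=vis.winner,
                other_winner=oth.winner,
                aligned=(vis.winner is not None and vis.winner == oth.winner),
            )
        )
    return pd.DataFrame(rows)
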