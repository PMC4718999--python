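"""SACCART coordinate transforms and the multimodal saccade-map choice circuit.

Visual-reactive targets arrive retinotopically and excite a motor-error map
directly; visually-attentive, auditory and planned targets are represented
head-centered and must be transformed into the same map.  The stages:

1.  Vector associative map (VAM): an adaptive head-centered read-out minus
    the efference copy of eye position yields an opponent-coded motor-error
    vector; post-saccadic learning under a postural gate nulls the read-out
    error, so the transform converges to the identity h -> h.
2.  Cerebellar gain: an additive per-locus correction to the reactive
    movement command, adapted from the post-saccadic landing error, that
    compensates a miscalibrated oculomotor plant.
3.  Vector-to-map SOM: the motor-error vector selects (and instar-tunes) a
    cell of the first choice nucleus, one per map locus.
4.  Map-to-map learning: the selected cell learns, against a Gaussian
    teaching signal centered on the visually activated locus, where its
    vector lives on the visual-reactive motor-error map; competition masks
    learning away from the winning neighborhood.
5.  Choice circuit: the deep-map layer receives bottom-up drive; nucleus 1
    returns topographic, purely modulatory on-center feedback (no positive
    feedback in excess of the feedforward drive) and nucleus 2 returns
    broad, anti-topographic inhibition sparing a neighborhood of its
    strongest input.  The loop contrast-normalizes, suppresses losers below
    the activity floor, and selects the locus of strongest evidence —
    amplified by spatially convergent multimodal input and reduced by
    spatially competing input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from . import neurodyn
from .neurodyn import ShuntingParams

__all__ = [
    "SpaceConfig",
    "HeadCenteredTarget",
    "MotorErrorVector",
    "TopoMap",
    "ChoiceParams",
    "ChoiceResult",
    "SaccartModel",
    "reactive_map_input",
    "teaching_signal",
    "choice_circuit",
    "multimodal_combine",
]

MODALITIES = ("visual_reactive", "visual_attentive", "auditory", "planned")

SIGMA_G = 3.0        # Gaussian teacher width, map cells
SIGMA_SOM = 3.5      # vector-space responsibility width, degrees
PLANT_GAIN = 0.8     # miscalibrated oculomotor plant
LAMBDA_VAM = 0.5
LAMBDA_GAIN = 0.3
ETA_M2M = 0.1
READOUT_GAIN = 2.0   # map-to-map read-out gain ahead of synaptic saturation


@dataclass(frozen=True)
class SpaceConfig:
    """Geometry of the motor-error / head-centered maps."""

    d: Literal[1, 2] = 1
    extent: float = 40.0          # degrees, map covers [-extent, extent] per axis
    n_cells: int = 41             # per axis

    def __post_init__(self) -> None:
        if self.d not in (1, 2):
            raise ValueError("dimensionality must be 1 or 2")
        if self.n_cells < 11:
            raise ValueError("need at least 11 cells per axis")

    @property
    def axis(self) -> np.ndarray:
        return np.linspace(-self.extent, self.extent, self.n_cells)

    @property
    def spacing(self) -> float:
        return 2.0 * self.extent / (self.n_cells - 1)

    @property
    def loci(self) -> np.ndarray:
        """(n_loci, d) preferred motor-error vectors, rostral (small) to caudal."""
        if self.d == 1:
            return self.axis[:, None]
        xx, yy = np.meshgrid(self.axis, self.axis, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel()])

    @property
    def n_loci(self) -> int:
        return self.n_cells**self.d

    def locus_of(self, position: np.ndarray | float) -> int:
        """Index of the map cell whose preferred vector is nearest."""
        pos = np.atleast_1d(np.asarray(position, dtype=float))
        return int(np.argmin(np.sum((self.loci - pos[None, :]) ** 2, axis=1)))

    def position_of(self, locus: int) -> np.ndarray:
        return self.loci[locus]

    def cell_distances(self) -> np.ndarray:
        """Pairwise locus distances in map-cell units."""
        diff = self.loci[:, None, :] - self.loci[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1)) / self.spacing


@dataclass(frozen=True)
class HeadCenteredTarget:
    """A movement target tagged by modality, in head-centered degrees."""

    modality: str
    position: float | tuple[float, float]
    salience: float = 1.0

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.salience < 0:
            raise ValueError("salience must be nonnegative")

    def pos_array(self, d: int = 1) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.position, dtype=float))[:d]

    def retinal(self, eye: np.ndarray) -> np.ndarray:
        """Retinotopic position h - e (meaningful for visual_reactive)."""
        return self.pos_array(len(np.atleast_1d(eye))) - np.atleast_1d(eye)


@dataclass(frozen=True)
class MotorErrorVector:
    """Opponent (agonist/antagonist) coding of a signed error per axis."""

    agonist: np.ndarray
    antagonist: np.ndarray

    @classmethod
    def from_signed(cls, v: np.ndarray | float) -> "MotorErrorVector":
        v = np.atleast_1d(np.asarray(v, dtype=float))
        return cls(agonist=np.maximum(v, 0.0), antagonist=np.maximum(-v, 0.0))

    @property
    def signed(self) -> np.ndarray:
        return self.agonist - self.antagonist

    @property
    def amplitude(self) -> float:
        return float(np.linalg.norm(self.signed))

    def opponent(self) -> np.ndarray:
        """Concatenated nonnegative channel vector (agonist then antagonist)."""
        return np.concatenate([self.agonist, self.antagonist])


@dataclass
class TopoMap:
    """One layer of a discretized motor-error map."""

    layer: Literal["peak_decay", "spreading_wave", "nucleus1", "nucleus2"]
    space: SpaceConfig
    activity: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.activity is None:
            self.activity = np.zeros(self.space.n_loci)
        self.activity = np.asarray(self.activity, dtype=float)
        if np.any(self.activity < 0):
            raise ValueError("map activities must be nonnegative")

    def centroid_eccentricity(self) -> float:
        """Activity-weighted mean eccentricity of preferred vectors (degrees)."""
        total = self.activity.sum()
        if total <= 0:
            return 0.0
        ecc = np.linalg.norm(self.space.loci, axis=1)
        return float((self.activity * ecc).sum() / total)


def reactive_map_input(
    retinal_position: np.ndarray | float,
    space: SpaceConfig,
    salience: float = 1.0,
    width_cells: float = 0.0,
) -> TopoMap:
    """Topographic instatement of a retinal error on the peak-decay layer.

    Default bump width is a single cell (delta input); positions outside the
    map extent are clipped to the nearest edge locus.
    """
    pos = np.atleast_1d(np.asarray(retinal_position, dtype=float))
    clipped = np.clip(pos, -space.extent, space.extent)
    if not np.allclose(clipped, pos):
        import warnings

        warnings.warn("target outside map extent; clipped", stacklevel=2)
    locus = space.locus_of(clipped)
    act = np.zeros(space.n_loci)
    if width_cells <= 0:
        act[locus] = salience
    else:
        d = np.linalg.norm(space.loci - space.loci[locus], axis=1) / space.spacing
        act = salience * np.exp(-(d**2) / (2.0 * width_cells**2))
    return TopoMap(layer="peak_decay", space=space, activity=act)


def teaching_signal(pd_locus: int, space: SpaceConfig, sigma_g: float = SIGMA_G) -> np.ndarray:
    """Gaussian teacher over the spreading-wave layer, centered at pd_locus.

    Learning is maximal at the peak and falls off along the flanks; widths
    are in map-cell units.
    """
    d = np.linalg.norm(space.loci - space.loci[pd_locus], axis=1) / space.spacing
    return np.exp(-(d**2) / (2.0 * sigma_g**2))


# -- choice circuit ----------------------------------------------------------

@dataclass(frozen=True)
class ChoiceParams:
    """Two-nucleus resonant choice-circuit constants.

    ``fb_gain`` scales the nucleus-1 modulatory on-center (multiplies, never
    exceeds, the feedforward drive).  Nucleus-2 inhibition is broad with a
    Gaussian exemption of width ``hole_sigma`` (cells) and depth
    ``hole_depth`` < 1 around its strongest input, so even the winner feels
    competing inputs.  ``contrast`` scales the inhibitory strength (the knob
    the optional cholinergic coupling moves).
    """

    shunt: ShuntingParams = ShuntingParams(A=1.0, B=1.0, C=-1.0, dt=0.02)
    fb_gain: float = 1.0
    inh_gain: float = 1.0
    hole_sigma: float = 2.5
    hole_depth: float = 0.9
    n2_recurrent: float = 0.6
    n2_norm: float = 0.1
    contrast: float = 1.0
    n_steps: int = 400
    record_every: int = 10

    def n2_drive(self, bu_total: float, x_total: float) -> float:
        """Divisively normalized broad drive to nucleus 2."""
        s = bu_total + self.n2_recurrent * x_total
        return s / (1.0 + self.n2_norm * s)


@dataclass
class ChoiceResult:
    winner: Optional[int]
    activity: np.ndarray
    winner_activity: float
    trace: np.ndarray  # (n_snapshots, n_loci)


def choice_circuit(
    bottom_up: np.ndarray, space: SpaceConfig, params: Optional[ChoiceParams] = None
) -> ChoiceResult:
    """Resolve competing map inputs to a single above-floor winner.

    Converges to the locus of strongest bottom-up evidence; losers are
    driven below the activity floor by the anti-topographic nucleus-2
    inhibition, and total activity is divisively normalized by the shunting
    ceiling.  Ties break toward the lowest index.
    """
    params = params or ChoiceParams()
    p = params.shunt
    bu = np.asarray(bottom_up, dtype=float)
    if np.any(bu < 0):
        raise ValueError("bottom-up input must be nonnegative")
    if bu.max(initial=0.0) <= p.floor:
        return ChoiceResult(None, np.zeros_like(bu), 0.0, np.zeros((1, bu.size)))
    # nucleus-2 hole centered on its strongest (feedforward) input
    hole_center = int(np.argmax(bu))
    d = np.linalg.norm(space.loci - space.loci[hole_center], axis=1) / space.spacing
    hole = params.hole_depth * np.exp(-(d**2) / (2.0 * params.hole_sigma**2))
    x = np.zeros_like(bu)
    snaps = []
    for t in range(params.n_steps):
        xr = np.maximum(x, 0.0)
        n1 = np.minimum(xr / p.B, 1.0)                     # topographic feedback
        excit = bu * (1.0 + params.fb_gain * n1)            # modulatory on-center
        broad = params.n2_drive(bu.sum(), xr.sum())         # nucleus-2 drive
        inhib = params.contrast * params.inh_gain * broad * (1.0 - hole)
        x = neurodyn.step_shunting(x, excit, inhib, p)
        if t % params.record_every == 0:
            snaps.append(np.maximum(x, 0.0))
    xr = np.maximum(x, 0.0)
    snaps.append(xr)
    winner = neurodyn.winner_take_all(xr, floor=p.floor)
    w_act = float(xr[winner]) if winner is not None else 0.0
    return ChoiceResult(winner, xr, w_act, np.asarray(snaps))


def multimodal_combine(
    visual_in: np.ndarray,
    other_in: np.ndarray,
    space: SpaceConfig,
    params: Optional[ChoiceParams] = None,
) -> dict:
    """Compare bimodal vs. unimodal equilibrium choice-circuit responses.

    Spatially convergent inputs amplify the winner above either unimodal
    response; spatially competing inputs reduce it below the stronger
    unimodal response.
    """
    v = choice_circuit(visual_in, space, params)
    o = choice_circuit(other_in, space, params)
    both = choice_circuit(np.asarray(visual_in) + np.asarray(other_in), space, params)
    uni_max = max(v.winner_activity, o.winner_activity)
    return {
        "visual": v,
        "other": o,
        "bimodal": both,
        "enhanced": both.winner_activity > uni_max,
        "suppressed": both.winner_activity < uni_max,
    }


# -- the trainable model -----------------------------------------------------

class SaccartModel:
    """All adaptive stages of the multimodal saccade map, on one geometry.

    State per map locus: the VAM head-centered read-out (with a trained
    mask), the additive cerebellar gain, one nucleus-1 SOM prototype in
    motor-error space, and a row of map-to-map weights onto the
    spreading-wave layer.
    """

    def __init__(
        self,
        space: Optional[SpaceConfig] = None,
        sigma_g: float = SIGMA_G,
        sigma_som: float = SIGMA_SOM,
        plant_gain: float = PLANT_GAIN,
        choice_params: Optional[ChoiceParams] = None,
    ) -> None:
        self.space = space or SpaceConfig()
        self.sigma_g = sigma_g
        self.sigma_som = sigma_som
        self.plant_gain = plant_gain
        self.choice_params = choice_params or ChoiceParams()
        n = self.space.n_loci
        d = self.space.d
        # VAM read-out per head-map locus (degrees); untrained cells read 0
        self.vam_w = np.zeros((n, d))
        self.vam_trained = np.zeros(n, dtype=bool)
        # additive cerebellar gain per motor-error locus (degrees)
        self.gain = np.zeros((n, d))
        # SOM prototypes: anatomical topography, refined by instar learning
        self.som_proto = self.space.loci.copy()
        # map-to-map weights: nucleus-1 cell -> spreading-wave profile
        self.m2m = np.zeros((n, n))
        self.m2m_trained = np.zeros(n, dtype=bool)

    # VAM ------------------------------------------------------------------

    def compute_motor_error_vector(
        self, h_locus: int, eye: np.ndarray | float
    ) -> MotorErrorVector:
        """Opponent-coded v = W[h_locus] - e (corollary-discharge subtraction)."""
        e = np.atleast_1d(np.asarray(eye, dtype=float))
        return MotorErrorVector.from_signed(self.vam_w[h_locus] - e)

    def vam_learn(
        self,
        h_locus: int,
        e_final: np.ndarray | float,
        postural_gate: bool,
        lam: float = LAMBDA_VAM,
    ) -> None:
        """Null the read-out error against the post-saccadic eye position.

        Active only while the postural gate is open (fixation after the
        movement); drives W[h] toward the eye position that foveated h.
        """
        if not postural_gate:
            return
        e = np.atleast_1d(np.asarray(e_final, dtype=float))
        self.vam_w[h_locus] += lam * (e - self.vam_w[h_locus])
        self.vam_trained[h_locus] = True

    def vam_read(self, h: np.ndarray | float) -> np.ndarray:
        """Population read-out of the head-centered transform at any h.

        Exact at calibrated (trained) loci; between them the read-out
        interpolates linearly over the trained samples (1-D) or by
        Gaussian-weighted averaging (2-D).  With nothing trained, reads 0.
        """
        h = np.atleast_1d(np.asarray(h, dtype=float))
        if not self.vam_trained.any():
            return np.zeros(self.space.d)
        nearest = self.space.locus_of(h)
        if self.vam_trained[nearest] and np.allclose(
            self.space.loci[nearest], h, atol=1e-9
        ):
            return self.vam_w[nearest].copy()
        tr = np.flatnonzero(self.vam_trained)
        if self.space.d == 1:
            xs = self.space.loci[tr, 0]
            order = np.argsort(xs)
            return np.array(
                [np.interp(h[0], xs[order], self.vam_w[tr, 0][order])]
            )
        w = np.exp(
            -np.sum((self.space.loci[tr] - h) ** 2, axis=1) / (2.0 * self.sigma_som**2)
        )
        return (w[:, None] * self.vam_w[tr]).sum(axis=0) / w.sum()

    # cerebellum -------------------------------------------------------------

    def command(self, v: MotorErrorVector, locus: int) -> np.ndarray:
        """Movement command: motor-error vector plus the learned gain."""
        return v.signed + self.gain[locus]

    def cerebellar_gain_update(
        self, locus: int, landing_error: np.ndarray | float, lam: float = LAMBDA_GAIN
    ) -> None:
        """Adapt the additive gain from the visual landing error.

        Overshoot (negative error) decreases the gain; repeated trials drive
        the landing error geometrically to zero.
        """
        err = np.atleast_1d(np.asarray(landing_error, dtype=float))
        self.gain[locus] += lam * err

    # vector-to-map SOM --------------------------------------------------------

    def som_responsibilities(self, v: MotorErrorVector) -> np.ndarray:
        """Graded nucleus-1 activation: Gaussian proximity to each prototype.

        Unnormalized, so the cell whose prototype matches the vector fires
        at full strength and flanking cells fire at their tuning overlap.
        """
        d2 = np.sum((self.som_proto - v.signed[None, :]) ** 2, axis=1)
        return np.exp(-d2 / (2.0 * self.sigma_som**2))

    def vector_to_map_choose_and_learn(
        self, v: MotorErrorVector, eta: float = 0.1
    ) -> int:
        """Nearest-prototype choice; instar step on the winner only.

        eta = 0 performs the choice without learning.  Ties break toward the
        lowest index.
        """
        d2 = np.sum((self.som_proto - v.signed[None, :]) ** 2, axis=1)
        winner = int(np.argmin(d2))
        if eta > 0.0:
            self.som_proto[winner] += eta * (v.signed - self.som_proto[winner])
        return winner

    # map-to-map ---------------------------------------------------------------

    def map_to_map_learn(
        self,
        active_n1_cell: int,
        teacher: np.ndarray,
        competition_mask: Optional[np.ndarray] = None,
        eta: float = ETA_M2M,
    ) -> None:
        """Move the active cell's row toward the masked Gaussian teacher.

        The competition mask (1 inside the winning neighborhood, 0 outside)
        suppresses learning at loci silenced by the choice competition.
        """
        teacher = np.asarray(teacher, dtype=float)
        mask = (
            np.ones_like(teacher)
            if competition_mask is None
            else np.asarray(competition_mask, dtype=float)
        )
        row = self.m2m[active_n1_cell]
        row += eta * mask * (teacher - row)
        np.clip(row, 0.0, 1.0, out=row)
        if mask.any() and teacher.max() > 0:
            self.m2m_trained[active_n1_cell] = True

    def competition_mask(self, winner_locus: int) -> np.ndarray:
        """Learning window: open within sigma_g cells of the choice winner."""
        d = (
            np.linalg.norm(self.space.loci - self.space.loci[winner_locus], axis=1)
            / self.space.spacing
        )
        return (d <= self.sigma_g).astype(float)

    # performance ---------------------------------------------------------------

    def nonvisual_drive(
        self, target: HeadCenteredTarget, eye: np.ndarray | float = 0.0
    ) -> np.ndarray:
        """Spreading-wave drive for an auditory / attentive / planned target.

        Head-centered position -> VAM motor-error vector -> graded nucleus-1
        responsibilities -> learned map-to-map read-out, scaled by salience.
        """
        h = target.pos_array(self.space.d)
        v = MotorErrorVector.from_signed(self.vam_read(h) - np.atleast_1d(eye))
        a = self.som_responsibilities(v)
        # smooth synaptic saturation: overlapping learned rows of flanking
        # nucleus-1 cells cannot drive a locus beyond its ceiling, and the
        # strictly monotone transform preserves the location of the peak
        drive = 1.0 - np.exp(-READOUT_GAIN * (a @ self.m2m))
        return target.salience * drive

    def map_drive(
        self, target: HeadCenteredTarget, eye: np.ndarray | float = 0.0
    ) -> np.ndarray:
        """Bottom-up map drive for a target of any modality."""
        if target.modality == "visual_reactive":
            return reactive_map_input(
                target.retinal(np.atleast_1d(eye)), self.space, target.salience
            ).activity
        return self.nonvisual_drive(target, eye)

    def choose(
        self, targets: Sequence[HeadCenteredTarget], eye: np.ndarray | float = 0.0,
        gates: Optional[np.ndarray] = None,
    ) -> ChoiceResult:
        """Instate all targets, optionally gate by habituative transmitter, choose."""
        bu = np.zeros(self.space.n_loci)
        for t in targets:
            bu += self.map_drive(t, eye)
        if gates is not None:
            bu = bu * gates
        return choice_circuit(bu, self.space, self.choice_params)
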