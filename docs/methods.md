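# Methods

## Dynamics core

Every cell obeys the shunting membrane equation

    dx_i/dt = −A x_i + (B − x_i) E_i − (x_i − C) J_i,

with decay rate `A`, excitatory ceiling `B`, inhibitory floor `C ≤ 0`,
total excitatory input `E_i ≥ 0` and total inhibitory input `J_i ≥ 0`.
Because the explicit-Euler update is a convex combination of the current
state and the instantaneous equilibrium `(BE + CJ)/(A + E + J)` whenever
`dt·(A + E + J) ≤ 1`, the integrator subdivides any step that violates that
bound; activities therefore remain in `[C, B]` for arbitrary nonnegative
input schedules, not just for inputs the caller promises to keep small.
Feedforward on-center off-surround networks settle at the divisive
normalization `x_i = B·I_i/(A + ΣI)`, which preserves input ratios and
bounds total activity by `B`; closed-form equilibria are used as oracles
against long-run integration in the tests (agreement to 1e-6 over 100
random parameter draws).

Habituative transmitter gates follow `dz/dt = r(1 − z) − k·S·z` with
recovery rate `r` and depletion rate `k`. The steady-state throughput
`S·z* = rS/(r + kS)` is strictly increasing in `S` although `z*` is
strictly decreasing — depression does not invert the rank order of inputs,
it compresses it. Long-term memory uses instar updates (only the winning
postsynaptic cell's incoming weights move toward the presynaptic pattern;
error contracts by exactly `1 − η` per presentation) and outstar updates
(only the sampling source's outgoing weights move toward the active
pattern; `η = 1` is one-shot fast learning).

## Category learning

Choice uses the Weber-fraction evidence `T_j = |I ∧ w_j|/(α + |w_j|)` with
`α = 0.001`; uncommitted categories carry the all-ones template ("matches
anything", loses ties to any committed subset template). Matching is
`X* = min(I, V)` (logical AND in the binary core); reset occurs iff
`ρ|I| − |X*| > 0`; with no expectation active `|X*| = |I|` and any `ρ ≤ 1`
resonates. Fast learning prunes the template to the intersection of the
exemplars its category has coded, which is what makes cyclic presentation
self-stabilizing (weights quiesce, familiar exemplars reach their category
with zero resets). Match tracking sets `ρ = |X*|/|I| + ε` with `ε = 0.001`
and is capped at 1; an identical exemplar carrying two different labels is
flagged and skipped, since no vigilance can separate it. Vigilance relaxes
to baseline at each new input onset; persistent vigilance lives in the
cholinergic layer below.

Reset is realized two ways. The bookkeeping mode (the tested contract)
maintains a per-presentation reset set. The dynamic mode delivers a uniform
arousal burst through the habituative gates into a recurrent shunting
winner-take-all field: the currently active cell is the most habituated
(lowest `z`), so the same burst amplifies previously suppressed cells more
and the choice switches to the strongest of them. The oracle is the direct
comparison of gated net inputs `(T_j + burst)·z_j`; on randomized 5-cell
instances whose gate asymmetry exceeds 0.15 the dynamic winner matches the
oracle and deserts the active cell in 100% of 1,000 instances.

## The cholinergic chain

Mismatch events of magnitude `m = max(0, ρ|I| − |X*|)` drive a nonspecific
arousal burst `gain·m` and increment an ACh concentration that decays with
`τ = 2 s` (the behavioral-episode scale), `δ = 0.2` per event. The theory
constrains only directions of effect, so the functional forms are chosen
for monotonicity, boundedness, and closed-form testability:

- `g_s(c) = g_s0·e^{−c}`, `g_m(c) = g_m0·e^{−c}` (slow/medium AHP fall),
  `g_f(c) = g_f0·(2 − e^{−c})` (fast AHP rises, bounded);
- transfer threshold `θ = θ0·(g_s + g_m)/(g_s0 + g_m0)` — the leftward
  shift: less adaptation current, lower threshold, more output at any fixed
  input;
- vigilance `ρ = ρ_base + (1 − ρ_base)(1 − 2^{−c/c_half})`, `c_half = 1`:
  baseline at zero ACh, halfway to 1 at `c_half`, saturating at 1.

Each link is monotone, so the chain is: more mismatch → more ACh → lower
threshold → higher vigilance → at least as many categories on the same
stream. An optional flag maps `c` onto the saccade-map choice-contrast
parameter (the collicular analog is exposed as a switchable hypothesis, off
by default).

## The multimodal saccade map

Geometry: 1-D azimuth by default, 41 cells over ±40° (2°/cell); every
mechanism is written against locus arrays with explicit positions, and a 2-D
grid is supported (tested at the unit level; the behavioral suite is 1-D).
Signed motor errors are opponent-coded as rectified
(agonist, antagonist) pairs so all activities stay nonnegative.

**VAM.** `v = W[h_locus] − e`; after an accurate movement the postural gate
opens and `W[h] ← W[h] − λ(W[h] − e_final)` with `λ = 0.5`, so `W[h] → h`
and the motor error at fixation is zero. Continuous positions are read out
exactly at calibrated loci and by linear interpolation across calibrated
samples in between (population decoding over the head-centered map); with
nothing calibrated the read-out is zero, which is the "miscalibrated before
learning" regime.

**Cerebellar gain.** The plant is deliberately miscalibrated
(`plant_gain = 0.8`). The cerebellar correction is additive per locus:
command `= v + g[locus]`, `g ← g + λ·landing_error` with `λ = 0.3`, so the
landing error contracts by `1 − λ·plant_gain = 0.76` per trial at any
eccentricity and post-training saccades land within 0.011° at all trained
eccentricities. (A multiplicative gain with the same additive update law
diverges for eccentricities above `2/(λ·plant_gain)` ≈ 8°, which is why the
correction is additive.)

**Vector-to-map.** One nucleus-1 cell per map locus; prototypes are
initialized at each locus's preferred vector (the map's anatomical
topography) and refined by instar learning on the winner
(nearest prototype, lowest index on ties). At performance time the nucleus-1
population responds gradedly — Gaussian tuning of width `σ_som = 3.5°` —
which is what lets untrained vectors interpolate between trained cells.

**Map-to-map.** After each training trial the winning nucleus-1 cell's row
moves toward a Gaussian teacher of width `σ_G = 3` cells centered on the
visually activated locus, masked to the winning neighborhood
(`η = 0.1`). The read-out is `1 − exp(−2·Σ_j a_j w_j)`: a smooth synaptic
saturation. Three numerical choices here matter and were fixed by analysis
before freezing: (i) `σ_G = 3` cells — the training grid spaces positions 5
cells apart, and a mixture of Gaussians interpolating between two trained
cells is unimodal only for `σ ≥ 2.5` cells, so a narrower teacher makes
interpolation structurally impossible; (ii) the saturation must be strictly
monotone — a hard clip creates plateaus whose argmax sits at the plateau
edge and destroys alignment; (iii) the read-out gain 2 sets converged
auditory drives high enough to open the SNr gate. With these, auditory and
planned winners match visual winners at 100% of trained positions (seeds
1–3), untrained midpoints read out within one cell, and a control trained
on independently drawn cue pairs shows 0% alignment.

**Choice circuit.** The deep layer receives bottom-up drive `bu`; nucleus 1
returns topographic, purely modulatory feedback (excitation
`bu·(1 + x/B)` — no bottom-up input, no feedback, and the feedback never
exceeds the feedforward drive); nucleus 2 receives the broad drive
`S = Σbu + 0.6·Σx`, divisively saturated as `S/(1 + 0.1·S)`, and returns
inhibition `(1 − 0.9·G(d; 2.5 cells))·S_sat` — broad, anti-topographic, with
a Gaussian exemption around its strongest input. The hole depth 0.9 < 1 is
deliberate: a winner completely exempt from inhibition would be blind to
spatially competing inputs, contradicting multisensory suppression. The
floor `C = −1` lets losers be driven below the activity floor (with `C = 0`
a losing cell with positive input keeps a strictly positive equilibrium).
At equilibrium the winner is the locus of strongest bottom-up evidence
(ties to the lowest index), spatially convergent bimodal input raises the
winner's activity above either unimodal response (measured ratio 1.26),
20°-separated input lowers it below the stronger unimodal response (0.93),
and total activity stays below `B` for spatially resolved targets. Targets
closer than the sparing hole merge into a single bump — the saccadic
averaging regime, where two equal targets separated by less than `2σ_G`
select a winner strictly between them.

**Trial dynamics.** dt = 1 ms, trials ≤ 600 ms. The SNr gate opens when the
choice winner exceeds `0.2·B` for 10 consecutive ms (converged non-visual
drives equilibrate near `0.25·B`, visual deltas near `0.55·B`, so the
threshold admits all modalities while habituated inputs still open it
later — the latency difference the oddball test measures). The saccade
generator is a proportional-velocity kinematic plant toward the ballistic
endpoint `e0 + plant_gain·command`; on termination the residual drive
settles the eye onto the endpoint. During the movement the corollary
discharge recomputes `v = h − e` each step; the spreading-wave layer
carries a unit bump at the locus of the current error with residual decay
30 s⁻¹ (the visible wave), and the burst layer decays at
`(2 + 8·ΣSW)·(1 − G(d; 2 cells))` s⁻¹ — spared while the wave sits on it,
eroded once the wave departs, never increasing. Habituative map gates
(`r = 0.5 s⁻¹`, `k = 1.0`) deplete with use over each trial and recover
during the 0.5 s intertrial interval, settling near `z ≈ 0.6` under
repeated stimulation — enough to lose a tie against a fresh locus but not
enough to silence responding.

## Synthetic scenarios

Generators are pure functions of parameters and seed. Binary pattern sets
control expected pairwise Jaccard overlap by a shared core plus random
private features, with core/private sizes found by grid search over the
closed-form expectation (`overlap = 0` uses exactly disjoint supports;
requested overlap is met within ±0.1 empirically). The nested pair draws
`supp(C) ⊂ supp(O)` with |C| = 12, |O| = 16 in d = 25, giving the 0.75
match ratio the match-tracking scenario turns on. Target schedules pair
each visual-reactive target with a co-located (training) or independently
drawn (control) auditory/planned cue, 200 trials over
{−30, …, +30}° in 10° steps; the oddball schedule draws deviants as
Bernoulli trials. These fixtures exercise the mechanisms under idealized
conditions — noiseless binary features, point targets on a grid, a linear
plant; passing tests demonstrate the circuit logic, not robustness to
sensory noise, eccentricity-dependent plant nonlinearity, or naturalistic
feature statistics, none of which the generators emulate.

## Numerical and scope notes

- All randomness flows through explicitly passed seeds
  (`numpy.random.default_rng`); same config + seed reproduces outputs
  byte-identically.
- Ties break toward the lowest index everywhere a choice is made; the
  "active" floor is `1e-6·B`.
- The total-activity bound of the choice circuit applies to spatially
  resolved targets (separations beyond the sparing hole). Multiple
  high-salience deltas packed inside one hole behave as a single broadened
  target whose plateau can exceed `B` in sum though never per cell.
- The spiking/laminar biophysics behind the arousal and AHP machinery is
  abstracted to the functional chain (conductance scales, transfer-function
  threshold); receptor pharmacology is out of scope.
- Saccade-generator biophysics is reduced to the kinematic plant; no head
  movement, no oblique-saccade curvature, no microsaccades.
- Map-to-map learning is switched off during test trials (the default
  treats it as developmental rather than continuous).
- Whether collicular reset shares the nucleus-basalis arousal pathway is
  left as a switchable hypothesis (`ChoiceParams.contrast` coupling), off
  by default.
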