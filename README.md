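# saccart

A rate-based neural-circuit simulator for cholinergically modulated
decision-making, in two coupled halves:

1. **Category learning (ART).** Bottom-up inputs choose a recognition
   category; the category reads out a learned top-down expectation; the
   attended pattern `X* = I ∧ V` is compared against the **vigilance**
   criterion `ρ|I| − |X*| ≤ 0`. A good enough match yields resonance
   (attention + fast learning of the pruned prototype); a mismatch emits a
   nonspecific arousal burst that resets the category and drives memory
   search. Supervised predictive errors invoke **match tracking**:
   `ρ ← |X*|/|I| + ε`, the smallest vigilance rise that corrects the error.
   Mismatches also release acetylcholine, which suppresses slow/medium
   afterhyperpolarization currents, shifts the neuronal transfer function
   leftward, and raises vigilance — novelty makes learning more concrete.

2. **Saccadic target choice (SACCART).** A discretized motor-error map of
   the deeper superior colliculus / optic tectum receives visual-reactive
   targets topographically, while auditory, visually-attentive and planned
   targets arrive head-centered and must be transformed: a vector
   associative map (VAM) subtracts the eye-position efference copy from an
   adaptive head-centered read-out (calibrated to the identity `h ↦ h` by
   post-saccadic learning under a postural gate), a self-organizing map
   assigns each motor-error vector a cell of a topographic choice nucleus,
   and map-to-map weights learned against a Gaussian teacher centered on the
   visually activated locus align all modalities on one map. A two-nucleus
   circuit — modulatory topographic on-center feedback (nucleus 1) and broad
   anti-topographic inhibition sparing the strongest locus (nucleus 2) —
   resolves the competition; the SNr gate releases the winning command after
   a threshold-hold; a kinematic plant executes the saccade while corollary
   discharge drags a spreading wave of buildup-cell activity rostrally and
   erodes the burst-cell peak. Habituative transmitter gates penalize
   recently chosen positions, so novel targets win ties.

All cells obey shunting (membrane-equation) dynamics
`dx/dt = −Ax + (B−x)E − (x−C)J`; all synaptic depression follows the
habituative gate `dz/dt = r(1−z) − kSz`; learning is instar/outstar gated
steepest descent. Everything is deterministic given a seed.

## Worked example

```bash
python examples/02_match_tracking.py
```

```
unsupervised: 1 category, O matched C's prototype at ratio 0.75
supervised:   2 categories, vigilance match-tracked to 0.751
```

A 12-feature pattern is learned, then a 16-feature pattern containing it is
presented. Unsupervised at vigilance 0.5, the larger pattern matches the
stored prototype at ratio 12/16 = 0.75 and the two merge into one category.
With distinct supervised labels, the predictive error raises vigilance to
exactly 0.751 = 0.75 + ε — just enough to reset the offending category —
and the outer pattern is given its own category.

```bash
python examples/04_train_saccade_map.py
```

```
alignment: 100% of trained positions
non-colocated control alignment: 0%
```

After 200 trials pairing a visual target with a co-located auditory or
planned cue, a sound selects the same collicular locus as a light at the
same position at every trained position, and untrained positions in between
read out within one map cell of the topographically correct locus. The
control trained on independently drawn positions learns no alignment.

The other examples show the vigilance dial (`01`), the ACh → excitability →
vigilance chain (`03`), and a full saccade trial with the spreading
wave, burst-peak decay and habituative novelty (`05`).

A thin CLI wraps the same library calls:

```bash
saccart train-art --seed 3 --out runs/art --override rho_base=0.8
saccart train-saccart --seed 1 --out runs/map
saccart run-trial runs/map/model.h5 --position 10 --out runs/trial
saccart sweep rho_base 0.1,0.3,0.5,0.7,0.9 --seed 3 --out runs/sweep
```

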