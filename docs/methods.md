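# Methods

## The model

`npsim` simulates perception-based action selection in priming experiments
as a layered, noise-free dynamical system advanced in discrete steps of
1 ms. Every cognitive representation — a feature instance, a semantic
concept, a response — is one scalar activation that relaxes toward a
(moving) fixed point with asymmetric per-step gains: a rise rate when
actively driven, a decay rate when input is withdrawn
(`x ← x + τ·(target − x)`). The abstraction is validated separately by the
`spiking` module: the trial-averaged population rate of a recurrent
integrate-and-fire cluster rises and decays approximately exponentially,
which is the justification for collapsing each assembly onto one variable.

Information flows front to back within every step:

1. **Feature layers** (color, shape, word; location is supported by the
   architecture but not used by the shipped paradigms). A displayed feature
   receives input one unit above baseline, with a *residual overshoot* at
   onset (`F = F̂ + f`) that relaxes back to the unit level. Perceptual
   input reaches the layers `t_recognition` = 50 steps after display onset
   and persists `t_afterimage` = 30 steps past offset. The target-defining
   instance (green) receives a linearly growing amplification `A` (slope
   α); in inhibition mode the distractor-defining instance (red) instead
   accumulates suppression `I` (slope k) that persists and ramps down after
   the response, which is what drives the representation below baseline
   (inhibitory rebound).
2. **Feature bindings.** Objects are tuples of feature instances held by a
   pool of at most 7 binding slots. A perceived object's slot grows toward
   the maximum strength `b̂`; unperceived slots decay; a new object claims a
   free slot or overwrites the weakest slot not currently perceived.
   Bindings mediate activation exchange: each member feature drifts toward
   the mean of the other members at a rate equal to the binding strength —
   this is how the color boost reaches the target's shape.
3. **Semantic layer.** A task-defined gating function maps feature
   activations to concept drives. The gate passes only activations above a
   perceptual floor midway between baseline and unit input, so
   sub-perceptual residuals of earlier trials do not re-enter the
   competition. An adaptive threshold tracks a scaled sum of supra-baseline
   activations (`ν_sθ` chosen so its fixed point falls between the two
   strongest concepts) and thereby singles out the winner.
4. **Action layer.** Response activations (including the formal no-action
   `a0`, driven toward 1 whenever no stimulus is shown) race against their
   own adaptive threshold. The naming task passes only the winning concept
   forward, with a drive that grows with the winner's lead over the
   runner-up (or the semantic threshold, if higher) and saturates; the
   comparison task converts the winner's threshold margin into evidence
   for *yes* (word and picture channel agree) or *no*. A trial's decision
   is the first step at which exactly one action exceeds the threshold;
   the reaction time adds a fixed motor stage `t_motor` = 80 ms. If the
   unique winner is `a0` nothing happens; if no unique winner emerges
   before the timeout the trial is recorded as an omission.
5. **Episodic memory.** When a response is made, the entire state
   (features, bindings, semantics, actions) is stored as a trace whose
   strength starts at `ê` and decays freely. Each step, every trace's
   *retrieval strength* compares the current subjective percept — the
   objects in the strongest bindings — with the stored values: percept
   significance (mean supra-baseline activation per relevant feature
   dimension) times the mean of the inverse per-object mismatches
   (feature differences plus binding-strength differences scaled by
   `1/b̂`), regularised by ε so that an exact repeat yields a large but
   finite strength. Retrieval drags present activations toward the stored
   ones with weight `r_k·e_k`. Only real responses are reinstated in the
   action layer; the formal no-action is bookkeeping, not a motor
   representation. An old/new classifier locates `r_k` against a prototype
   similarity curve with a shrinking uncertainty band; under the
   temporal-discrimination semaphore the classification gates synaptic
   transmission (old displays close the direct route and boost retrieval,
   Eq.-style anti-symmetric modulation).

Seven binary semaphores switch these mechanisms to express the classic
theories: distractor inhibition (all off), global threshold (boost +
broadening/forced decay), episodic retrieval (full-state retrieval, boost),
response retrieval (action-only retrieval), temporal discrimination
(retrieval gated by the old/new verdict). 2⁷ = 128 configurations exist;
the five presets are fixed rows of that table.

## Parameters

Layer rates (per step = per ms), published profile for the voicekey naming
task: ρ_f = 0.01, δ_f = 0.003 (features); ρ_b = 0.008, δ_b = 0.005,
b̂ = 0.05, 7 slots (bindings); τ_sθ = 0.002, ν_sθ = 0.51 (semantic
threshold); ρ_a = 0.004, δ_a = 0.002, τ_aθ = 0.002, ν_aθ = 0.5 (actions);
ê = 0.002, δ_e = 0.003 (memory); α = 0.0005 (amplification slope);
baseline F̌ = 1; t_recognition/t_afterimage/t_motor = 50/30/80. The
comparison-task profile differs as published (ρ_f = 0.009, ρ_b = 0.0096,
ν_sθ = 0.4131, channel gains σ_shape→s = 0.1, σ_word→s = 0.12, σ_s→a = 1,
ρ_a = 0.0036, ν_aθ = 0.6, broadening β = 0.00155, forced decay
φ = 0.00011).

Several quantities the published profiles do not pin down are shipped as
package defaults, chosen once by calibrating the voicekey run against its
published condition means and then frozen:

- **semantic rates** ρ_s = 0.01, δ_s = 0.003 (mirroring the feature rates);
- **unit input** F̂ = 2 (one unit above baseline — a visible stimulus keeps
  driving its features rather than fading to baseline);
- **semantic channel gain** 0.1 for the naming task (the identity map fixes
  the wiring, not the gain; a modest gain keeps threshold excursions small
  enough to recover between trials);
- **readout margin** s_margin = 0.026 and action-drive gain σ_s→a = 1.2,
  which set the steepness of the winner readout and hence the absolute RT
  level;
- **similarity regulariser** ε = 0.2, which caps the retrieval pole for
  nearly identical percepts and thereby sets the retrieval magnitude;
- **response–stimulus interval** 1400 steps (1.4 s of blank screen between
  response and next onset; 1.2 s for the comparison profile);
- **inhibition slope** k = α (symmetry default; free in fitting);
- **discrimination prototype** ď = 0.05, d̂ = 1.2, τ_d = 0.01, ǔ = 1.0,
  τ_u = 0.012, placing the prototype between typical control and repeat
  similarity levels so intermediate similarity stays unclassified longest;
- **memory capacity** 3 traces — the directly preceding trial dominates,
  with headroom;
- gate modulation depths 0.2 and blocking rate τ_block = 0.01 (engaged
  only by the discrimination semaphores).

## Trial sequences (the synthetic data)

The generator builds *continuous* chains — every display is simultaneously
the probe of the previous trial and the prime of the next, as in the
experimental procedure it emulates. Requested priming conditions (CO, DT,
TT, TD, DD, DDTT, DTTD; with s/r response-relation suffixes in the
comparison task) appear exactly `n_per_condition` times in seeded-shuffled
order, and object identities are chosen greedily (with seeded tie-breaks
and whole-sequence retries) so that every object serves as target and as
distractor equally often to within one appearance. It emulates the
*design* of such experiments, not their noise: the model is deterministic,
so per-condition standard deviations reflect sequence-position
heterogeneity only, and passing tests say nothing about fits to
trial-level human variability.

## Numerical choices

Forward-Euler per-step updates in the feed-forward order listed above;
memory weights enter with a one-step lag. No clipping to [0, 1] anywhere —
sub-baseline and supra-unit excursions are meaningful. All floats are
written with 12 significant digits; runs are reproducible bit for bit from
the echoed configuration. Omissions enter fitting as the timeout latency
rather than propagating as missing values. The finite-difference fitter
normalises parameters to their bounds, descends with backtracking line
search, falls back to single-coordinate moves when the combined direction
fails, and restarts from fixed quasi-random points because the RT surface
has several basins separated by decision-channel switches.

## Known limitations

- The calibration reproduces the published control RT and
  attended-repetition benefit of the voicekey run, and the published
  sign structure for TD and DD, but the ignored-repetition (DT) condition
  comes out as a small net *benefit* rather than the published ~24 ms
  cost: with similarity-scaled retrieval, dragging the repeated object's
  semantic state toward its stored value helps a rising target more than
  the reinstated old response hinders it, at every parameter setting we
  explored. The DT cost appears to require either a much stronger
  response-conflict channel or role-specific retrieval that the printed
  equations do not provide.
- Cross-trial residual activation (afterimages, decaying thresholds,
  response persistence) is a genuine model feature; even with all
  theory mechanisms switched off the conditions differ by a few
  milliseconds at the shipped response–stimulus interval. These couplings
  decay at printed rates and cannot be removed without also removing the
  memory trace.
- The comparison-task fit reproduces the published error level for the
  inhibition preset, but the response-relation main effect (repeat slower
  than switch in the empirical control cells) is outside what the
  mechanisms express; the fit compensates through the response-layer
  parameters.
- One step is identified with 1 ms throughout; that mapping is an
  interpretation of the published latency constants, not a measured
  quantity.
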