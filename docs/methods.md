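# Methods

`stroopeffort` simulates and inverts a discrete-state active-inference model
of the Stroop task, in which cognitive effort is an information-theoretic
quantity: the divergence between what an agent habitually intends to do and
what it context-sensitively believes it should do.

## Generative model

The model is a two-level (deep temporal) partially observed Markov decision
process.  Each level is a categorical generative model with the usual
components: likelihoods `A` (outcomes given the joint hidden state),
transitions `B` (column-stochastic, per factor and action), log-preferences
`C` over outcomes, initial-state priors `D`, and habit potentials `E` over
policies.

**Fast level (within one presentation).**  Hidden-state factors: written
word (4), font colour (4), task sequence (instruction / viewing / response),
instruction (2), response modality (2), and correctness (2).  Outcome
modalities — instruction cue, word text, font colour, verbal response — each
carry an explicit *null* level for phases in which they are not generated
(the cue only during the instruction phase; word and colour during viewing
and responding; the verbal response only at the response step, driven by the
written word when the modality is "word" and by the font colour when it is
"colour").  The correctness factor influences no outcome; it exists to be
predicted.  Instruction presentations last one step, stimulus presentations
two (viewing, response).

**Slow level (across presentations).**  Factors: narrative (instructional
context → response context), instruction, and response modality — the only
controlled factor.  The two policies are constant mental actions: *respond
via the word* or *respond via the colour*.  Slow outcomes set the fast
level's initial states; the correctness channel (correct iff instruction and
modality agree) is the only preference-bearing outcome.

**Demand and motivation.**  Two log-scale parameters:

```
E = exp(e) · (−0.85, +0.85)      habit potential (demand)
C = exp(c) · (+1, −1)            correctness preference (motivation)
```

At `e = 0` the habitual prior `softmax(−E)` expects word-reading 84.5% of
the time; at `c = 0` being correct is `e² ≈ 7.39` times more probable than
being incorrect under the prior preference.

## Belief updating

Beliefs are updated by a free-energy gradient flow on log-potentials `v`,
`v ← v + κ(ln q* − v)` with step `κ = 1/4` and 16 recorded iterations per
observation epoch.  Because the target of the flow — the exact smoothing
posterior `q*` of the joint hidden-state chain, computed by forward/backward
message passing on the flattened joint space — does not depend on the
iterate, the flow contracts geometrically onto it and the engine returns the
fixed point itself.  Posteriors are therefore exact (they agree with
brute-force enumeration to machine precision on small models), while the
recorded iterates provide the sub-epoch dynamics from which synthetic
electrophysiology is derived.

Policies are scored by expected free energy

```
G_π = Σ_τ Σ_m [ o_πτ · (ln o_πτ − C_m) ] + H · s_πτ
```

with predicted outcomes `o = A·s` (the linear push-forward; the literal
expected-log form is available as a mode), `C` stored as log-preferences
(negated inside the risk term, so preferred outcomes lower `G`), and `H` the
conditional outcome entropy of the likelihood.  `G` decomposes per time step
into a preference term and a mutual information between states and outcomes;
the recombination is checked against the direct form to 1e−8.  Probabilities
are floored at 1e−16 inside logarithms; joint states flatten in declaration
order with the last factor fastest; ties in any argmax break to the lowest
index.

## Cognitive effort

For each decision,

```
P_E = Cat(softmax(−E)),   P_G = Cat(softmax(−G − E)),   ξ = KL[P_G ‖ P_E].
```

`ξ ≥ 0`, vanishes when `G` is constant across policies, and is invariant to
constant shifts of `G` or `E`.  Because `G` depends only on the instruction
belief (pinned by the initial cue) and not on the upcoming stimulus, `ξ` is
exactly equal for congruent and incongruent decisions within a session —
effort and trial difficulty dissociate.  Note an intrinsic ceiling: for a
binary policy set with an 85/15 habit, `ξ ≤ ln(1/0.155) ≈ 1.86` nats
whatever `G` is.  At baseline the simulated means are ≈ 1.77 nats
(colour-naming) and ≈ 0.17 nats (word-reading): colour-naming demands an
order of magnitude more effort, with the same between-condition ordering as
larger reported magnitudes that would require a richer policy space or a
rescaled habit (both expressible through `StroopParams`).

The demand × preference surface treats a single binary decision in which the
habit opposes the preferred policy: demand `d` is the habitual probability
of the dispreferred policy and preference strength `ψ` separates the two
expected free energies by `2ψ`.  Effort rises with demand and then collapses
as the habit becomes immovable; the probability of overcoming the habit
declines monotonically with demand.

## Overt behaviour

Responses are sampled from `u = softmax(λ ln(A) s)` over the four colour
words, where `s` is the Bayesian model average of policy-conditioned
predictions and `λ = 1/4` is the action precision (lower → more random).
Reaction times are `r = ½ exp(n + H[u])` with `n ~ N(0, 1/256)`: confident
predictions are answered in ~0.5 time units, uncertain ones more slowly.

**Session dynamics.**  The per-decision policy posterior is
`π_t = softmax(−E − G_t − F_t)` where two quantities beyond the printed
habit/risk trade-off are needed to obtain the reported sequential
phenomena:

* **Planning depth.**  `G_t` accumulates the correctness risk over the next
  `planning_horizon` presentations (default 3).  Depth 1 puts the baseline
  decision near a coin flip (≈48% errors on incongruent colour-naming),
  whose error bursts cancel the congruency sequence effect; accumulating
  over the whole remaining session saturates the posterior and abolishes
  errors (and with them the Stroop effect).  Depth 3 reproduces the
  reported regime: ≈18% errors confined to incongruent colour-naming
  trials, congruent trials at ceiling, and the characteristic RT orderings.
* **Leaky response evidence.**  Each observed response is scored under each
  policy with the same precision-`λ` likelihood that generated it
  (`u_π = softmax(λ ln(A s_π))`), and the log-evidence accumulator `F`
  retains a fraction `evidence_decay = 0.5` per presentation.  Incongruent
  responses discriminate the policies (and hence sharpen `π`); congruent
  responses are uninformative, so beliefs relax toward the habit across
  congruent stretches.  This produces the congruency sequence effect —
  errors on incongruent trials are more likely after congruent than after
  incongruent trials — and lets the agent recover after an error rather
  than locking into the wrong modality (raw deterministic likelihoods
  would make a single response decisive at the log-floor scale).

Effort is computed from `(G_t, E)` alone, per its definition; `F` only
shapes action selection.  Correctness is scored against the generating
process's instruction, not the agent's belief.  One seed stream drives
stimulus generation and an independent derived stream drives response/RT
sampling, so identical stimuli can be replayed across parameter settings.

## Synthetic electrophysiology

Each represented population's belief (state probability, or policy
probability) is treated as a normalised firing rate on the iteration grid
(16 bins per observation epoch).  Rasters sample each bin as an independent
Bernoulli draw per replication (default 16).  Local field potentials are
the first differences of the rates smoothed with a Gaussian kernel of 2 bins
(a symmetric FIR filter; no phase distortion).  Evoked responses are
time-locked averages over stimulus presentations, by default for the
slow-level response-modality populations, with amplitude summarised as the
maximum absolute deflection in the trial window.

Error trials evoke markedly larger responses than correct trials in the
same condition (the error-related-negativity analogue; an error swings the
policy belief across its whole range).  A limitation: the congruent >
incongruent amplitude ordering sometimes reported empirically does *not*
emerge from the leaky-accumulator dynamics — near the pinned policy belief,
a re-pinning update on an incongruent trial is at least as large as one
presentation's leak on a congruent trial — and reproducing it would require
policy beliefs to hover mid-range, which is precisely the regime that
destroys the congruency sequence effect.  The package reports both
averages; it does not claim the ordering.

## Phenotyping (the inverse problem)

The fused log likelihood replays the scheme at candidate `(c, e)`, forcing
the recorded responses and stimuli:

```
L(c, e) = Σ_τ ln u_τ[o_τ]  −  Σ_τ (1/256) (ln r_τ + u_τ·ln u_τ + ln 2)².
```

The RT residual weight 1/256 deliberately *down-weights* reaction times
relative to the exact Gaussian log-density of the generative noise (which
would give 128): log-RTs are observed with sd 1/16, and at full weight they
would dominate the posterior and invert the robust finding that choice data
carry most of the phenotypic information.  The exact-density weight is
available via `rt_weight`.

Posteriors over `(c, e)` are Gaussian, obtained by variational Laplace:
damped Gauss–Newton ascent on the log-joint with central-difference
gradients and curvature (step 1e−3), eigenvalue-floored at 1e−8; the free
energy (Laplace log-evidence) is non-decreasing over accepted steps.
Priors are `N(0, 1/126)` on each parameter.  The posterior over `c − e`
propagates the covariance; in practice `c` and `e` are strongly
posteriorly correlated — behaviour constrains roughly `2exp(c) − 1.7exp(e)`
— so the contrast `c − e` is recovered with smaller normalised error than
either parameter alone.  Bayesian model reduction re-evaluates evidence and
posteriors under reduced priors in closed form (precision-space identity)
and is exact and compositional; pruned coefficients get a reduced prior
variance of 1e−8.  Information gain is `KL[posterior ‖ prior]` (a
`direction` flag gives the reverse).

The behaviour-on-priors regressions use the design `[1, c, e, ce, c², e²]`
with a softmax link for proportion correct (second logit fixed at 1) and an
identity link for log mean RT, coefficient priors `N(0, I)` and
log-precision prior `N(4, 1)`; all 64 on/off coefficient subsets are scored
by model reduction and a column's inclusion probability sums the posterior
probabilities of models containing it.

The recovery experiment simulates one session per `(c, e)` on a shared
stimulus stream — any difference in demand is a property of the subject,
not the task — over a default 5 × 5 grid,
`c, e ∈ {−0.5, −0.25, 0, 0.25, 0.5}` (rows concatenated), and fits each
dataset with both, choice-only and RT-only data terms.

## What the simulations do and do not show

The generator emulates a single-session, four-colour Stroop design with an
instruction cue followed by 63 stimuli and a 50% congruency schedule.  It
does not model neutral stimuli, response omissions, learning of the model
parameters, task switching, or within-subject fatigue; reaction times have
no irreducible motor component (their floor is the 0.5-unit constant).
Passing tests therefore establish internal consistency of the scheme and
the direction of its behavioural and informational effects under these
idealised conditions, not quantitative fidelity to any empirical data set.

Default problem sizes — 64 presentations per session, 20–200 seeded
sessions for behavioural statistics, 25 recovery datasets — were chosen so
that every reported statistic is stable across seeds while a full
reproduction runs in minutes on one core.
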