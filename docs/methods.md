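# Methods

## Model and assumptions

The simulator implements ensembles of projective-simulation (PS) agents on a
1D ring.  A PS agent's memory is a two-layer percept→action graph whose edge
weights `h` define the policy by row normalisation; learning is strictly
reward-driven via the glow eligibility trace

```
g(t+1) = (1 − η) g(t) + 1{edge traversed},      h ← h + R·g on reward.
```

The glow matrix is updated every round; `h` is updated only at the round in
which the agent reaches a food site, at most once per trial.  Glow is reset
to zero at the start of every trial (trial-scoped eligibility; letting it
carry over was tested and changes no reported observable beyond ~5%).

Assumptions inherited by every result:

* **Discrete kinematics.** Speed is exactly one position per round; the only
  actions are keep-heading and reverse.  Step lengths are therefore native
  positive integers and the discrete versions of all step-length models are
  the correct ones (no binning).
* **Sequential updating.** Agents act in a fixed label order within each
  global round; each agent perceives the already-updated state of agents
  that acted before it in the same round.
* **Reorientation noise.** Each agent's heading is re-randomised (uniform
  ±1, i.e. flipped with probability 1/2) every `s_r` rounds, with a per-agent
  phase drawn uniformly at trial (or run) start.  The noise is applied right
  before the agent's own round, so an agent embedded in a swarm can
  re-stabilise its heading within the same round it was scrambled.
* **Perception.** The front region is displacements +1..+V_R along the
  heading, the back region −1..−V_R.  A region's class is its neighbour
  count (none / <3 / ≥3) and the majority motion (receding vs approaching),
  with an exact tie classified as approaching.  Agents co-located with the
  focal agent sit on the boundary between the two regions and are counted in
  **both**, classified by orientation the same way as that region's
  neighbours (same heading = receding in front, approaching behind).

The co-location rule deserves a note because it is the one genuinely open
modelling choice with macroscopic consequences.  If co-located agents are
invisible, a maximally packed swarm erases its own perceived density
gradients: edge agents still see a hard asymmetry and reflect inward, but
nothing opposes compression, and cohesive training collapses the swarm to
near-zero width.  Counting co-located agents in both regions makes a packed
swarm look dense from everywhere, which self-limits compression; with this
rule the cohesive ensembles equilibrate at finite width while the
aligned-swarm regime is essentially unaffected.  The tie-break direction was
also tested both ways; "approaching" gives slightly better aligned-swarm
statistics and is kept.

## Parameters

| symbol | meaning | default | units |
| --- | --- | --- | --- |
| `W` | world size | 500 (8000 for open-world stability runs) | positions |
| `N` | agents per ensemble | 60 | — |
| `V_R` | visual range per side | 6 | positions |
| `s_r` | reorientation period | 5 | rounds |
| `η` | glow damping | 0.2 | — |
| `R` | reward | 1 | — |
| `n` | rounds per trial | 50 | rounds |
| trials | training length | 10^4 | — |
| `d_F` | food distance from the initial-region centre `C = V_R` | 2–21 | positions |

The defaults are the standard training conditions; they are not tuned.
Agents start uniformly on the inclusive window `{0 .. 2 V_R}` so that
`C = V_R = 6`, and food sits at `(C ± d_F) mod W`.

## Free runs and trajectory analysis

Trained weights are frozen (no food, no reward; noise stays on) and the
ensemble walks `10^5` rounds in `W = 500`, or 5000 rounds in `W = 8000` when
the question is whether the swarm survives in an effectively open world.
Positions are recorded unwrapped; wrapped coordinates are recovered mod `W`.

* **MSD.** One time origin per trajectory (the run start), averaged over
  agents; the diffusion exponent is the least-squares slope of log₂ MSD vs
  log₂ lag over the dyadic lags 2..1024 by default.  For cohesive swarms the
  MSD is normal-diffusive only below the swarm-confinement scale (lags ≲ 32);
  beyond it the displacement is the swarm centre's own slow wander and the
  apparent slope drops.  The window is therefore an explicit argument
  everywhere, and the cohesive-regime check fits the pre-confinement window.
* **Steps.** Maximal same-direction runs in temporal order, including the
  boundary-truncated first and last runs (at `S ≳ 10^4` steps per trajectory
  their effect is negligible).
* **MLE.**
  * BW: closed form `λ̂ = ln(ℓ̄/(ℓ̄−1))`.
  * CRW: EM on the count representation (the iid likelihood depends only on
    length counts), multi-restart; closed-form weighted-geometric M-step.
  * CCRW: Baum–Welch with scaled forward/backward passes and the same
    closed-form geometric M-step; 10 restarts (informed start from the CRW
    fit plus log-uniform random rates in [10⁻³, 2] and uniform transition
    probabilities), a cheap pass on a 5000-step prefix followed by a tight
    polish (tolerance 10⁻⁸ on the log-likelihood, ≤1000 iterations) on the
    full sequence.  Rates are clipped to [10⁻⁶, 10], probabilities to
    [10⁻⁶, 1−10⁻⁶]; the intensive state is the larger rate (labels swapped
    at the end if needed).
  * PL: 1D bounded maximisation of `−μ Σln ℓ − S ln ζ(μ,1)` on
    μ ∈ (1, 20], with ζ the Hurwitz zeta from scipy.
  * Degenerate samples (all steps length 1) return an infinite-rate/exponent
    sentinel with a warning rather than an error.
* **Identifiability.** The CCRW initial-state probability `δ` carries one
  observation's worth of information per sequence; its MLE is boundary-valued
  with O(1) standard error.  It is reported but should not be interpreted.
* **Selection.** AIC `= 2k − 2 ln L̂`, Akaike weights, BIC
  `= k ln S − 2 ln L̂` with k = 1, 3, 5, 1 for BW, CRW, CCRW, PL.  The BIC
  winner must beat every rival by more than 10; otherwise the comparison is
  reported as inconclusive.
* **GOF.** For iid models, a likelihood-ratio (G) statistic of binned counts
  against the fitted pmf (single-length bins pooled from the right until
  each expected count reaches 5, plus an open tail), calibrated by
  parametric bootstrap with refitting (default 200 replicates).  For the
  CCRW, one-step-ahead forecast cdfs from the forward recursion give
  discrete mid-pseudo-residuals `u_t = (F_t(ℓ_t) + F_t(ℓ_t − 1))/2`, tested
  for uniformity by KS.  Because the data are discrete the residuals retain
  atoms, so `D_KS` has a floor well above the continuous KS scale even under
  a perfect model; it is a comparative, not absolute, measure here.

## Synthetic generators

`psforage.synth` provides exact samplers for all four step-length models
(geometric draws; the CCRW simulates its mode chain; the power law uses the
zipf sampler, which shares the Hurwitz-zeta normalisation) and deterministic
fixture policies (`uniform`, `always_go`, `pure_aligner`, `pure_cohesive`)
with probability-~1 edges realised as 10⁶:1 weight ratios.  These fixtures
exercise the world and the metrics without any training.  What passing tests
on them show is that the machinery — kinematics, perception, metrics,
likelihoods, selection — is correct under known ground truth; they do not
show that real animal trajectories follow any of these models, and the
trained-agent results themselves are statements about this model world, not
about field data.

## Problem sizes used in tests and the acceptance script

The agent loop is JIT-compiled (≈2×10⁶ agent-rounds/s on one CPU), so the
package uses the full study conditions rather than scaled-down ones wherever
they appear: training runs are 10⁴ trials of 50 rounds × 60 agents, and
trajectory analyses use 10⁵-round free runs.  Monte-Carlo baselines use
250–1000 trials; the model-selection fractions in the reproduction script
use 300 trajectories (five ensembles) per regime, because whole ensembles
shift their trajectory statistics together and ensemble-level variance
dominates the binomial error; the test suite uses one ensemble (60
trajectories) per regime with correspondingly wider bands.  Metric-recorded
trainings (which log per-trial order parameter and neighbour counts) use
1000–2000 trials, past the point where those curves plateau.

## Known limitations

* The nearby-food (`d_F = 4`) swarm equilibrates ~35% wider than the
  reference values this package aims to regenerate (extent ≈ 23 vs 17, hence mean neighbours ≈ 28 vs 35; the two numbers are
  mutually consistent through the uniform density profile).  Every other
  collective observable — the `d_F = 2` regime, the aligned regime, step
  rates, policy tables, selection fractions — agrees closely.  The width is
  sensitive to the exact softness of the learned edge-turning responses;
  trial-scoped vs persistent glow, stopping at food, the tie-break
  direction, and longer training were all tested and none closes the gap.
* The BIC selection fractions carry strong ensemble-level variance: a single
  ensemble's 60 trajectories move together, so estimates from one or two
  ensembles swing by ±7 percentage points between seeds.  Averaged over five
  ensembles they agree with the reference fractions (≈86% CCRW aligned,
  ≈88% BW cohesive vs 85%/90%).
* One-dimensional world only; homogeneous agents; no perception of food or
  landmarks; no explicit evolutionary operators.  The two-layer ECM has no
  clip composition or forgetting.
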