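# Methods

## The model

`cultlink` simulates cultural change in a well-mixed population of `N`
individuals. Each individual carries `h` cultural traits (loci-like
dimensions of a repertoire), each holding one of `k` discrete variants
(allele-like), plus a private, symmetric *link graph* over its traits.
Links are the model's central object: when a trait is demonstrated, every
trait connected to it — directly or indirectly — in the demonstrator's link
graph is demonstrated with it, and the whole connected component (the
*package*) is offered for copying as a unit. Links themselves transmit,
break and form, so linkage patterns differ between individuals and evolve.

Pay-offs are multiplicative across traits. Variant `j` of trait `i` pays
`1 − ((j−1)/(k−1))·s_i`, so variant 1 is always best, variant `k` worst, and
a neutral trait has `s_i = 0`. An individual's pay-off is the product of its
variant pay-offs.

One timestep, synchronously for all individuals:

1. **Partner choice.** Every individual chooses an interaction partner other
   than itself: uniformly (unbiased), proportionally to total pay-off
   (pay-off-biased), or with weight `1 − s_κ(1 − q_r)` where `q_r` is the
   population frequency of the candidate's variant (conformist-biased;
   defined for a single trait). The conformist weight is a linear discount
   of rare-variant carriers: `s_κ = 0` recovers unbiased choice, `s_κ = 1`
   weights candidates by their variant's frequency. All weights are
   evaluated on the frozen start-of-step state and renormalized over the
   `N−1` non-self candidates.
2. **Package transmission.** The focal individual picks one of its `h`
   traits uniformly at random; the partner's connected component of that
   trait is the package. Each in-package variant is copied with probability
   `c`, blindly with respect to pay-offs. Links follow a fixed outcome
   table: an in-package link both individuals share is kept; one only the
   partner has is acquired with probability `1 − b`; one only the focal has
   is broken; every focal link joining a package trait to an outside trait
   is lost; links fully outside the package are untouched.
3. **Link formation.** Each currently unlinked trait pair of each individual
   links with probability `a`.
4. **Innovation.** Each trait of each individual switches, with probability
   `μ`, to one of the other `k − 1` variants chosen uniformly (transition
   rate `μ/(k−1)` between any ordered variant pair).

All reads in stages 1–2 come from the start-of-step snapshot, so an
individual's influence within a timestep depends only on its start-of-step
state. Population size is fixed; there is no demographic turnover, spatial
structure, pay-off synergy between linked traits, or directed link
formation — links form at random.

A *fixed-package* control mode replaces stage 2: each focal copies exactly
`n` distinct traits sampled uniformly, ignoring links entirely (with `n = 0`
no transmission; `n = h` every trait offered). It isolates the package-*size*
effect from the package-*composition* dynamics.

## Scenarios and run structure

A standard replicate runs a 5000-timestep unbiased burn-in followed by 2000
timesteps under the scenario's mode, recording per-trait variant counts and
the population link frequency after every step. Scenarios:

* **neutral** — unbiased throughout; the equifinality baseline.
* **payoff** — post phase pay-off-biased with selection `s1` (and
  optionally `s2`) imposed; no other intervention. Used for the biased
  comparison distributions.
* **hitchhike_neutral / hitchhike_functional** — at the end of burn-in a
  single, uniformly chosen innovator receives variant 1 at trait 1 while
  all others are set to variant `k`; trait 2 is relabelled so the innovator
  carries the rarest variant as label `k` (the *associated variant*), with
  the remaining labels ranking the other variants by decreasing count (ties
  to the lower original label; the innovator's trait-2 variant is
  overwritten with the rarest before relabelling). This is the most
  challenging starting point for hitchhiking, hence conservative. The post
  phase is pay-off-biased with `s1 = 0.9` and `s2 = 0` (neutral associated
  variant) or `s2 ∈ {0.1, 0.2}` (detrimental).
* **conformist** — a single trait (`h = 1`), conformist-biased for the
  whole run with no burn-in phase; by default the run length equals
  burn-in + post of the other scenarios so all scenarios share one horizon.
* **fixed_package** — the control mode above, unbiased.

Every run is reproducible from `(seed_base, combination index, replicate
index)` via `numpy.random.SeedSequence` spawning; a single PCG64 generator
drives each replicate with a fixed draw order.

## Statistics

* **Pairwise difference** `π = 1 − Σ_j n_j(n_j−1)/(N(N−1))` from variant
  counts `n_j` — exactly the probability that two individuals sampled
  without replacement differ at the trait (a small-sample-corrected
  Simpson/heterozygosity index). The counts interpretation (rather than
  proportions) is forced by that sampling definition.
* **Wright–Fisher references.** The closed form
  `π^WF ≈ 2Nμ(k−1)/(k−1+2Nμk)` for the standard k-allele Wright–Fisher
  model, and its rescaling with `μ_eff = μ·h/(nc)` for this model, where a
  trait is successfully transmitted only every `h/(nc)` timesteps on
  average while innovation ticks every step. The *unscaled* form matches
  the fully-linked / `n = h` case; the `n = 1` scaling matches linkless
  runs. Both forms are approximations, and the rescaled one carries a
  known bias: mapping `h/(nc)` staggered timesteps onto one synchronous
  Wright–Fisher generation ignores that a pair of lineages each update
  once per effective generation and coalesce with probability `~1/(N−1)`
  per update — roughly twice the Wright–Fisher rate — so the matching
  reference really has `N_e ≈ N/(2 − nc/h)`. At `n = h` the correction
  factor is `2 − c ≈ 1`, and the unscaled form is accurate; at `n = 1` the
  printed scaling overestimates equilibrium diversity by ~0.004 at
  `N = 1000` and ~0.017 at `N = 200` — larger than three standard errors of
  a 100-replicate mean, which is why the corresponding agreement check
  fails as stated while the `n = h` check passes. A direct Wright–Fisher
  simulation (multinomial resampling plus innovation, vectorized across
  replicates) provides the reference *distribution* for the overlap
  analyses.
* **Link frequency** — realized links over `h(h−1)/2` possible, averaged
  over individuals. **Package-size variance** — variance of connected-
  component sizes over all `N·h` (individual, trait) pairs; zero in both
  the linkless and fully-linked limits, peaked at intermediate linkage. The
  per-(individual, trait) convention weights a component of size `m` by its
  `m` member traits, mirroring the package-choice probability; a
  per-component convention would differ.
* **Area of overlap** between two π samples: `∫ min(f_x, f_y)` on [0, 1].
  Default estimator: shared 100-bin histogram (transparent and
  deterministic). Alternative (`method="kde"`): Gaussian kernel densities
  reflected at the support boundaries, integrated on a 1001-point grid.
  With O(100) replicates per sample the 100-bin histogram underestimates
  overlap badly (sparse-bin noise enters as `Σ|p̂_x−p̂_y|/2`, ~0.2 for
  identical distributions), so all headline overlap numbers are computed
  with the KDE estimator; the histogram default is kept for large-sample
  use and for its transparency. Method metadata is recorded in every
  result.
* **Sweep detection.** On the post-burn-in clock (index 0 = the adjusted
  state, frequency `1/N`), the sweep ends at the earliest step whose
  trait-1 variant-1 frequency does not exceed the previous one
  (non-strict), censored at the horizon if the rise never pauses. The
  associated variant *hitchhikes* when its frequency strictly exceeds 0.5
  at sweep end; the majority duration counts consecutive post-sweep steps
  strictly above 0.5, censored durations entering the mean at their
  observed (lower-bound) value with the censored fraction reported. The
  mean duration is reported only when hitchhiking occurs in more than 5% of
  replicates.

## Numerical and design choices

* The dynamics are jitted (numba) with one shared kernel per rule; the
  public per-operation functions and the replicate driver call the same
  kernels, so unit tests exercise production code. Uniform draws are
  batched per stage and consumed positionally; a linkless-pair shortcut in
  the transmit stage is draw-for-draw identical to the general path.
* Partner sampling uses exact inverse-CDF sampling with the focal's own
  mass excised (no rejection); if every non-self weight is zero (possible
  in degenerate pay-off states with some `s_i = 1`), choice falls back to
  uniform and a warning is logged.
* Package membership is computed on the *partner's* link graph: a
  demonstrator can only bundle what its own links connect.
* Shared in-package links are kept with certainty (not re-broken with
  probability `b`): the outcome-table reading, preferred over the looser
  prose reading; flagged as a sensitivity candidate.
* Variant copying and link acquisition are independent Bernoulli events; a
  link can be acquired even when copying of an endpoint variant failed.
* `k = 4` is assumed by the sweep adjustment only in the sense that the
  worst variant is labelled `k`; any `k ≥ 2` works.
* Innovation reuses the event-test uniform, rescaled, to pick the
  replacement variant (exact, saves one stream per step).
* The two-individual oracle enumerates every stochastic branch of a
  timestep exactly (partner choice is forced at `N = 2`); it is restricted
  to `h ≤ 2`, `k ≤ 3` to keep state spaces enumerable. A noteworthy exact
  consequence it verifies: at `c = 1`, `μ = 0` two distinct individuals
  *swap* variants forever under synchronous updating — fixation requires
  `c < 1`.

## What the synthetic conditions do and do not show

All inputs are simulated; there is no external data. The generator's
defaults are the study conditions themselves (`N = 1000`, `h = 5`, `k = 4`,
`μ = 0.01`, `c = 0.99`, `b = 0.1`, linked condition `a = 0.01`; burn-in
5000 + 2000 post timesteps; conformist strengths 0.03/0.048, pay-off
comparison strengths 0.07/0.24, hitchhiking `s1 = 0.9`). Passing tests show
the implementation reproduces the model's published behaviour at those
conditions — equilibrium diversity, equifinality overlaps, hitchhiking
gradients — not that the model describes any real cultural system: the
population is well-mixed, traits are non-epistatic, links form at random,
and innovation is undirected.

Desk-scale problem sizes (the package's own reproduction defaults): 100
replicates per simulated condition (60 for the flanking hitchhike-gradient
conditions, whose between-condition differences are an order of magnitude
above noise), 1000 for the cheap Wright–Fisher reference, hitchhike runs
truncated to 500 post-burn-in steps (sweeps end within tens of steps; only
sweep-end quantities are consumed), and reduced-`N` (200) variants for the
Wright–Fisher-agreement and fixed-package checks. The fixed-package runs
use 3500 timesteps (several relaxation times at `N = 200`; equilibrium
means indistinguishable from the 7000-step convention) with 150 replicates
at `n ≤ 3` rising to 600 at `n ∈ {4, 5}`: as `n → h` the traits become
fully correlated and behave as a single trait with `θ ≈ 4`, whose broad
stationary law (between-replicate sd ~0.1) must be averaged over while the
adjacent-mean gaps shrink to a few thousandths — the `n = 4` vs `n = 5`
ordering sits at the edge of what any desk-scale replicate count resolves.
With 100 replicates the KDE overlap estimates carry a sampling error of
roughly ±0.03–0.05.

Observed behaviour at the study conditions worth recording: the diversity
dip in `a` is deepest around `a ≈ 0.005–0.01` (mean link frequency ~0.08–
0.13); by `a = 0.05` the mean link frequency reaches ~0.5 and the mean π has
climbed most of the way back toward the Wright–Fisher expectation, crossing
it from below between `a = 0.02` and `a = 0.05`. The equifinality and
hitchhiking analyses therefore use the `a = 0.01` linked condition
throughout.

## Known limitations

* The closed-form Wright–Fisher references are approximations; agreement
  tests are calibrated at scales where their bias is inside three standard
  errors of the replicate mean.
* Overlap estimates with O(100) replicates inherit KDE bandwidth bias; the
  printed reference values were themselves estimated from finite samples by
  an unspecified density method. One published overlap (the hitchhiking
  associated variant against pay-off-biased transmission at `s1 = 0.24`)
  is not reproduced under this implementation's reading of the rules:
  reproducing it would require the associated variant's sweep-end π
  distribution to concentrate near 0.5 (near-universal hitchhiking at the
  linked condition), whereas under the printed rules the sweep completes in
  ~16 steps and the sweeping lineage carries the trait1–trait2 link only
  ~13% of the time, leaving a substantial no-hitchhike mode near the
  neutral equilibrium. Run-length, estimator-convention and
  breakage-rule variants were all examined without closing the gap while
  preserving the other five overlap values.
* Majority-duration means mix censored and uncensored observations
  (censored at their observed value, fraction reported) rather than using a
  survival estimator; durations at these conditions are far from the
  horizon, so the distinction is minor.
* The static-link model variant and epistatic/synergistic pay-offs are out
  of scope.
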