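# Methods

## Psychophysical model

An observer's answer on a two-interval contrast-oddball trial is driven by
an internal decision variable z ~ Normal(ΔC + b, σ²), where ΔC is the
contrast difference in percent (second interval minus first at the oddball
location), b is a response bias toward "second" and σ the internal noise,
both in contrast-percent. The observer answers "second" iff z > 0, so the
choice rate is the cumulative Gaussian H((ΔC + b)/σ), and sensitivity is
summarised by the maximum slope s = 1/√(2πσ²). There are deliberately no
lapse or guess-rate parameters: the model is exactly (b, σ).

Per-trial confidence is defined as the normalised decision variable
c = z/σ. This is the quantity the Weighted Confidence Sharing (WCS) rule
assumes the members exchange: the dyad answers by the sign of c₁ + c₂.
Because c₁ + c₂ is again Gaussian in ΔC, WCS implies the closed-form dyad
parameters

- b_dyad = (σ₂b₁ + σ₁b₂)/(σ₁ + σ₂),
- σ_dyad = √2 σ₁σ₂/(σ₁ + σ₂),
- s_dyad = (s₁ + s₂)/√2,

an improvement line s_dyad/s_max = √2/2 (1 + s_min/s_max), and a break-even
member ratio √2 − 1 ≈ 0.414. Note that whenever the members agree, the sign
of c₁ + c₂ equals their common choice, so under WCS generation the dyad's
final answers follow the dyad psychometric function on *all* trials, not
just conflicts — which is why the default dyad fit includes agreement
trials (a flag restricts it to disagreements for sensitivity analyses).

The rival rules are implemented from the standard formulations: Coin Flip
(conflicts decided at random; s_dyad = (s₁+s₂)/2), Behaviour & Feedback
(defer to the member with smaller σ; s_dyad = s_max) and Direct Signal
Sharing (inverse-variance combination of the raw z's; s_dyad = √(s₁²+s₂²)).
Predictions from these carry `formula_source="cited-source"` to mark that
their closed forms come from the literature that introduced them rather
than being derived here. DSS ≥ WCS ≥ CF holds for every slope pair
(root-mean-square ≥ ... ≥ mean, divided/multiplied by the same constants),
with equality of DSS and WCS only for equal members.

## Fitting

`fit_psychometric` estimates (b, σ) from per-level choice proportions.
The default is unweighted least squares on proportions — the classic
curve-fitting approach for this design — with binomial maximum likelihood
as the statistically preferred option. The search is bounded to
σ ∈ [0.1, 100] and b ∈ [−50, 50] contrast-%, initialised from a
probit-transformed linear regression (proportions clamped to (10⁻³,
1−10⁻³) for the initialiser only; the objective itself uses the raw
proportions). All-identical response sets have no finite σ and raise
"non-identifiable". Degenerate proportions of exactly 0 or 1 are kept as-is
for least squares; the likelihood handles them natively.

A practical identifiability note: a single 8-block session (128 trials,
16 per signed level) pins σ to roughly 12–15% median relative error for
σ ∈ [3, 20] — observers whose σ approaches the largest design contrast
(15%) produce nearly linear response profiles over the sampled range. The
recovery test therefore checks the <10% criterion at 32 blocks, where the
estimator reaches ~7%.

## Synthetic experiment generator

The generator emulates the study design it is meant to exercise: 8 blocks
of 16 trials, oddball contrast levels {11.5, 13.5, 17, 25}% against a 10%
baseline (so |ΔC| ∈ {1.5, 3.5, 7, 15}), every timing × level combination
exactly twice per block, order shuffled. All randomness flows through one
`numpy.random.Generator` seeded by a single integer, making runs byte-
reproducible.

Response times follow rt = rt_offset + (rt_gain/|c|)·LogNormal(0, 0.35):
faster when confident, with multiplicative jitter so the high-confidence
limit is exactly rt_offset. Defaults rt_offset = 0.30 s, rt_gain = 0.45 s
give individual decision times of roughly 0.5–1.5 s for mid-range
confidence, a plausible scale for speeded two-choice responses.

Group-phase trajectories are produced by a simple motor model chosen for
transparency rather than biomechanical fidelity. Each handle is an
overdamped unit (damping 2 N·s/unit) driven by the member's applied force
plus a coupling spring (default 4 N/unit) to the partner's handle; the
displayed cursor is the mean of the two positions. Compliant (finite-
stiffness) coupling is essential: with perfectly rigid coupling the two
handle series coincide and the leader/follower velocity contrast
degenerates. The Leader — the member whose choice won — tracks a
minimum-jerk reference from 0 to ±1 with a proportional gain that grows
with |confidence| (1.5 N/unit × (1 + 0.5|c|), capped at 12 N), starting at
its onset time (same law as rt). The Follower first drives toward its own
side (excursion 0.25, below the largest first-crossing threshold swept) for
`follower_yield_delay` = 0.45 s after its own onset, then yields: it stops
driving and is dragged through the spring while applying a small viscous
braking force (0.8 N·s/unit) against the motion. The braking term is what
makes follower mechanical work reliably negative — a fully passive follower
does near-zero net work because its early own-side push is positive work
that cancels the later drag. A trial ends when the combined cursor has
stayed beyond |x| ≥ 0.9 (our validation-zone choice) for 1 s. Positions are
clipped to [−1, 1]; sampling is 100 Hz by default (the logging rate is a
free choice).

What the generator reproduces, by construction or in expectation: leaders
start earlier, apply larger peak force and positive work; followers resist
then yield, doing non-positive work; first-crossing accuracy is
non-decreasing in the threshold; the leader's pre-crossing pace is closer
to the dyad's post-crossing pace than the follower's. What it does **not**
emulate: force-feedback negotiation dynamics (oscillatory "haggling"),
fatigue and learning across blocks, asymmetric handedness or seating
effects, broken or re-initiated movements, and realistic magnitudes of
forces, work or decision times. Quantities like the ~88–96% first-crossing
accuracy row or 0.75 N vs 0.43 N force contrast observed with human dyads
are therefore qualitative targets only (direction and ordering), never
numbers the simulator is tuned to; on clean synthetic trajectories several
predictors saturate at 100%.

## Feature extraction choices

- Peak force uses |f| (magnitude), since "highest force applied" carries no
  sign convention.
- First-crossing ties (both handles exiting the zone at the same sample)
  go to the larger displacement, then the lower member index.
- The velocity analysis splits each trajectory at the first crossing of a
  reference threshold, default 0.05 (the smallest swept value); VeloL and
  VeloF are each member's own mean |Δx|/Δt before the split and VeloD the
  combined cursor's after it. A flag computes VeloL/VeloF from the combined
  cursor instead (grouped by leader identity) as a robustness check.
- Mechanical work normalises by the number of summed increments, counting
  all samples of the group phase, moving or not.
- Disagreement trials lacking a matching trajectory are skipped and
  counted, never silently dropped.

## Cohort statistics

Dyad-vs-best comparisons are paired: a one-sample t-test on
s_dyad − s_max within a similarity class (df = n − 1), matching the
degrees-of-freedom pattern of per-dyad designs. The similarity threshold is
0.4 with ties classed "similar" (the exact break-even point √2 − 1 rounds
to 0.4; the strict-inequality formulation leaves the boundary undefined, so
a tie rule had to be chosen). The observed-vs-WCS comparison is likewise a
one-sample test on per-dyad slope differences. The improvement-vs-ratio
relation is ordinary least squares with standard-error formulas from the
usual normal-equations theory (statsmodels); the over-weighting coefficient
γ = α/β of the weighted-WCS variant is estimated by least squares with the
intercept pinned at √2/2, because the weighted model changes only the
slope. Degenerate inputs (all-zero differences, constant ratios, classes
with fewer than two dyads) raise or return explicit degenerate results
rather than NaNs. Raw p-values are reported without multiple-testing
correction, as is conventional for this handful of planned contrasts.

## Problem sizes in the test suite

Monte-Carlo checks run at sizes chosen to make their expectations sharp:
choice-rate calibration at n = 10⁵ draws against 3 binomial standard
errors; parameter recovery on a 3×3 grid of (σ₁, σ₂) with 6 replicate
40-block experiments per cell, compared within 3 Monte-Carlo standard
errors plus a 2% allowance for the small-sample bias of the fitted slope;
directional cohort tests with 8–14 dyads and 12–40 blocks each. The
low-ratio ("different") cohort uses 40 blocks per dyad because its expected
deficit (~15% of s_max) is comparable to single-session fit noise.

## Known limitations

- The trajectory model is phenomenological; its constants (gains, damping,
  braking) are plausibility choices, not fitted to human data.
- Only two-member groups are supported throughout.
- The weighted-WCS variant is treated at the level of the improvement line
  (γ estimation); no trial-level weighted decision rule is simulated.
- Imported logs must already be normalised to the [−1, 1] position
  convention; the reader validates but does not rescale.
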