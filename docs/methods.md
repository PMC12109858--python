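# Methods

This note documents the models implemented in `edsense`, the defaults
they ship with, what the synthetic-learner generator does and does not
emulate, and the design choices made where the design was genuinely
open.

## Skill topology

Skills are nodes of a DAG; an edge A → B means mastering A is a
necessary condition for mastering B. Each skill has an operation
(addition, subtraction, multiplication), a number range (0–10, 0–100,
0–1000), a difficulty rank that must strictly increase along every
prerequisite path within one operation, and variant tags (worked
*support*, *bridging to 10* — i.e. a carry or borrow past ten —,
*mental*).

The default roster contains 38 skills. The published description of the
tool fixes the count, the three number ranges, the variant vocabulary
and the 0–100 addition chain (2,1 with support → 2,1 → 2,1 with
bridging to 10 → 2,2 → …) but does not enumerate the full list, so the
roster is a documented reconstruction: six skills per range per
operation for addition and subtraction (36), the subtraction chain
mirroring addition skill-for-skill with "bridging" meaning a required
borrow, plus *Multiplication 1,1* and *Multiplication 2,2* attached
below *Addition 2,2*. In the 0–10 block the only operand shape is
single-digit/single-digit, so its six skills are the
{support, plain, mental} × {non-bridging, bridging} variant grid; the
single-digit subtraction bridging skill draws teen minuends (12 − 5),
the canonical "bridging down through 10" item. The roster is data, not
code: it round-trips through the JSON schema and a DAGitty-style text
dialect, and users can supply their own.

Topological order breaks ties by (difficulty_rank, id) so that every
session and serialization is deterministic.

## Student model

Per-skill latent binary mastery K_t, maximum-entropy prior
P(K_0 = 1) = 0.5 (no information about the learner at intake).

* **Transition** (per practice step): P(K_t=1 | K_{t−1}=1) = `p_retain`
  (default 0.9), P(K_t=1 | K_{t−1}=0) = `p_acquire` (default 0.1).
  These are the published conditional probabilities; both configurable.
* **Emission**: the source material conditions on hints H, attempts A,
  corrects C, wrongs W and specific wrongs SW but states no functional
  form, so the emission model is this package's design: classic
  knowledge-tracing slip/guess Bernoulli products,
  P(obs | K=1) = (1−s)^C · s^W and P(obs | K=0) = g^C · (1−g)^W, with
  s = 0.10, g = 0.20 by default. SW is folded into W (a specific wrong
  is a wrong). An optional `hint_discount` d < 1 shrinks the effective
  correct count to C·d^H, making hinted successes less informative;
  it defaults to 1 (off) because no hint model is published.
* **Forward update**: the published normalization step is ill-formed as
  printed (its denominator re-multiplies the transition messages); the
  implementation performs the standard normalized two-term forward
  update p′ ∝ emission(obs | K=1)·M with M = p_retain·p +
  p_acquire·(1−p), which the surrounding derivation evidently intends.
  This repair is deliberate and tested.
* **Memory of five**: posteriors are computed from the last ≤ 5
  observations only. Implemented as a sliding window with re-anchoring:
  the forward recursion is re-run from the 0.5 prior over the retained
  window on every update. Until the window first overflows this is
  identical to the incremental Bayes update; afterwards it forgets
  evidence older than five steps without inventing a decay model. The
  window length is configurable. Property tests verify the filter
  equals brute-force marginalization over all 2^(T+1) latent paths to
  1e−12.
* **Cross-skill propagation** is a damped one-hop heuristic (default
  λ = 0.5): a skill's posterior lifts each direct precursor to
  max(own, λ·p) and caps each direct successor at min(own, 1−λ·(1−p)).
  The source states that neighbour skills influence each other but
  gives no mechanism; full belief propagation is deliberately out of
  scope, and `run_session` does not apply propagation implicitly — it
  is an explicit API call.

A consequence of the five-step window worth knowing: with defaults the
posterior after an unbroken run of correct answers plateaus near 0.97
rather than approaching 1, because only five observations ever count.

## Controller

State: current skill, posterior lower/upper thresholds initialized to
PLT = 0, PUT = 1 (as printed in the control algorithm), and a sample
counter. Per step: play a task, update the posterior, then

* p > PUT → advance to the easiest direct successor;
* p < PLT → remediate to the precursor with the lowest posterior
  (ties by id);
* otherwise stay.

The printed pseudocode routes the high-mastery branch to a *precursor*,
contradicting the surrounding prose ("moves them forward"); the default
`mastery_advance` semantics follow the prose, and the literal
transposed behaviour is available as `semantics="as_printed"`.

Out-of-band events adapt the crossed threshold by
`adapt_amount / n_samples` (default amount 0.1; n_samples counted from
1 to avoid the printed division by zero on the first step), clamped so
0 ≤ PLT ≤ PUT ≤ 1 always. Note that with the printed initialization
PLT = 0, PUT = 1 no posterior is ever out of band, so under defaults
progression is driven entirely by the mastery-stop rule; the band
machinery becomes active whenever a session is configured with a
non-degenerate initial band.

Because no stopping rule is published, a skill is **retired** when its
posterior stays ≥ `mastery_stop` (default 0.95, reachable under the
five-observation window) for `consecutive_stop` (default 2) consecutive
tasks. On retirement the session resumes at the easiest unfinished
skill in topological order — this guarantees full roster coverage and
makes the hardest skill the last to retire. The session ends when the
final skill in topological order is retired, or at a step cap (default
500) that guarantees termination; capped logs are marked truncated, not
raised as errors.

## Buggy rules

The five dyscalculia error cases are executable functions, each checked
against its published worked example:

1. **Operation misattribution** (semantic memory): multiply instead of
   add/subtract; 3 + 5 = 15. (The second printed illustration,
   32 + 7 = 109, matches no stated rule — the product is 224 — and is
   classified as a generic wrong answer.)
2. **No-carry concatenation** (visuospatial): each column summed
   independently, all column-sum digits concatenated; 28 + 14 = 312.
3. **Digit collapse** (procedural): every digit of both operands summed
   into one number; 92 + 43 = 18.
4. **Carry omission** (procedural): per-column sums keep only the units
   digit; 39 + 25 = 54.
5. **Zero absorption** (semantic): any column containing a zero yields
   zero. The prose describes a whole-result-zero misconception but the
   printed example (26 + 20 = 40) is column-level, so the column rule
   is the default and the whole-result variant sits behind
   `zero_absorbs_all=True`.

Subtraction uses the borrow-omission mirrors of rules 2–4 (column-wise
absolute difference, digit-difference collapse). Classification
precedence for ambiguous answers is Case 1 → Case 5, fixed and
documented; rules can coincide with the true answer (no-carry on a
carry-free sum), and correctness always wins.

Task generation draws operands uniformly (rejection sampling) from each
skill's constraint set: digit widths from the skill name, the range
bound, carry-free columns for non-bridging variants, units digits
summing past ten (or a required borrow) for bridging variants, and
non-negative subtraction results.

## Simulated learners

Each synthetic learner has: a latent per-skill mastery map (everyone
starts all-unlearned — the intervention begins at the floor of the
topology); `learn_rate`, the probability an unlearned skill becomes
learned after one practice opportunity (typical 0.4–0.7, dyscalculic
0.1–0.3); slip 0.05–0.15 and guess 0.15–0.25; an error profile over
the five cases keyed to memory subtype (semantic → Cases 1/5,
visuospatial → Case 2, procedural → Cases 3/4, typical → mostly
unstructured errors); and a lognormal response-time model
log-RT ~ N(μ0 + Δμ·rank, σ²) with μ0 = 2.5 log-seconds (≈ 12 s),
Δμ = 0.05–0.12 per difficulty rank and σ = 0.5, so harder skills are
systematically slower. Hints and attempts default to 0 and 1 — no
distribution for them is published. None of these values are fitted to
real children; they were chosen once as plausible magnitudes for
primary-school arithmetic practice.

The default cohort is 50 learners, half dyscalculic, one full adaptive
session each (≈ 170–500 steps). On that cohort the tracer's posteriors
separate the latent mastery state well: ranking accuracy (AUC) ≈ 0.93
and Brier score ≈ 0.11 at seed 7, against an uninformed baseline of
0.5 / 0.25. Calibration is scored **per practice step** — the posterior
after absorbing a step's evidence against the latent state that
generated that response — because adaptive sessions end with every
visited skill mastered, which would leave an end-of-session comparison
with no unmastered class at all.

What the generator does *not* emulate: affective states, fatigue and
drift within a session, forgetting (mastery never un-flips), real
response-time distributions, hint-seeking behaviour, and any empirical
prevalence of the five error cases (none is published; the subtype
weights are stated defaults, not estimates). Passing cohort tests
therefore show that the engine is self-consistent and discriminating
under its own generative assumptions — not that it is calibrated to
real dyscalculic children.

## Analytics

* **Dispersion**: sample variance (n−1 divisor) and SD per skill. The
  divisor is unstated in the source; the reproducible surface — the
  speed–accuracy correlations computed from the published dispersion
  table — is divisor-agnostic.
* **Pearson correlation** with the packaged 11-row pre-assessment
  dispersion table as default input: r = −0.5176 between the speed and
  accuracy variance columns, r = −0.5034 between the SD columns. The
  `se` field of the result is the regression standard error of
  estimate, s_y·√((1−r²)(n−1)/(n−2)), clearly labelled as such: the
  published "standard error" column matches no standard correlation SE
  formula (the regression SEE gives 368.5 / 5.48 against the printed
  488.7 / 7.99) and is not asserted anywhere.
* **Welch's ANOVA** implements the Welch (1951) statistic directly
  (precision weights w_i = n_i/s_i², weighted grand mean, the
  (k²−1)/(3A) Satterthwaite-type df2). It is validated against an
  independently coded textbook oracle to 1e−8 and against
  `pingouin.welch_anova`; under equal sizes and equal sample variances
  it stays within 5% of the classic one-way F. The published
  response-time F values depend on unpublished raw data and are not
  reproduction targets.
* **Power analysis** searches N upward from 2, at each N computing the
  two-tailed critical t at df = N−1 and the rejection probability of a
  noncentral t with δ = d_z·√N. For d_z = 0.56, α = 0.05, target 0.95
  it returns N = 44, δ = 3.7146, t_crit = 2.0167, achieved power
  0.9526 — verified against statsmodels and a 100,000-rep Monte-Carlo
  of the paired t test. Tail terms that underflow the noncentral-t CDF
  at extreme noncentrality are treated as zero.
* **Session summaries** mirror the sample-dataset metric table layout
  (mean/min/max/count of correct, wrong and specific-wrong answers per
  skill level and per 10-question block, plus special-case counts) on
  simulated logs; the published table's values come from unpublished
  raw data and are format references only.

No multiple-testing correction is applied anywhere (none is described
for the original analyses), and p-values never drive automated
decisions.

## Numerical and testing notes

* All randomness flows through `numpy.random.Generator` seeds; sessions
  and cohorts are bit-for-bit reproducible under a fixed seed.
* The DBN filter is compared to the path-sum oracle at 1e−12; emission
  underflow is not a concern at window length 5 with per-step counts.
* Hypothesis property tests run derandomized so the suite is
  deterministic.
* Cohort-level tests use 50 learners × ≤ 500 steps, sized so the whole
  suite completes in seconds while keeping ≈ 18,000 posterior/state
  pairs in the calibration check.

## Known limitations

* The 38-skill roster is a reconstruction; only its count, ranges,
  variant vocabulary and the 0–100 addition slice are anchored.
* The emission model and all simulator distributions are package
  choices, not published quantities.
* Propagation across the DAG is heuristic; no joint inference over the
  whole graph is performed.
* No parameter learning: slip/guess/transition values are fixed
  configuration, not estimated from data.
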