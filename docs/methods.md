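# Methods

This note documents the models, parameter choices and numerical conventions
behind `torcourse`, in the order the pipeline runs them.

## Experimental design generator

A session consists of `n_blocks × trials_per_block` trials (default 8 × 30 =
240). A fraction `filler_fraction` (default 0.20, i.e. 48 trials) are filler
trials; the remaining 192 main trials cross cue informativity (informative /
non-informative) with interrupting-task presence (present / absent), 48 per
cell, with speed- and lane-change tasks split equally within every cell. Main
trials start from a middle lane at 80 or 100 km/h so that both responses are
meaningful; lane fillers start on an outer lane (forced inward change) and
speed fillers at 60 or 120 km/h (forced acceleration / deceleration). Filler
trials exist to break one-to-one stimulus–response mappings and are never
analyzed.

Balance is enforced at the session level, not per block. Counterbalanced
attributes (cue-onset jitter from {2,…,7} s, video version 1–4, LDT stimulus
class word/pseudoword) are cycled through each design cell and then shuffled,
so they are as even as the integer counts allow without being confounded with
serial position. Exact balance is required only where the counts permit it:
the main-trial count must divide by 8 (2 × 2 cells × 2 tasks) and the filler
count by 2 (task parity); filler condition labels cycle through the 2 × 2
crossing. Unsatisfiable configurations are rejected with the first violated
constraint named.

Randomization uses one stream per participant, seeded by (master seed,
participant index), so any participant's sequence is reproducible in
isolation. Whether condition repetitions should be constrained is left open;
the sequences are plain random permutations.

## Behavioral simulator

Take-over RTs follow, in ms,

    rt = mu * exp(N(-sigma^2/2, sigma)),
    mu = base + intercept_p + a * t_cond^(-b)
         + benefit_p * 1[non-informative]
         + shift * 1[LDT present]
         + amplitude * 1[informative, LDT present, onset <= t_cond <= offset]

with `t_cond` the trial's ordered position within its own condition cell —
deliberately the same axis the effect-course analysis uses, so the planted
truth and the analysis are aligned. `intercept_p ~ N(0, participant_sd)` and
`benefit_p ~ N(benefit, benefit_sd)` vary across participants. The
`benefit_sd` term (default 25 ms) is needed to give the paired effect sizes a
realistic scale: without between-participant effect heterogeneity, d_z at 45
participants and ~96 trials per level would be implausibly large. The
modulation window is hard-edged by default so that recovery tests have an
unambiguous truth; its amplitude raises informative-cue RTs under
interruption only, shrinking the informativity benefit there without touching
the non-informative baseline.

Defaults (base 520 ms, a = 150, b = 0.35, benefit 45 ms, amplitude 35 ms on
ordered trials 7–23, LDT base 695 ms with a 30 ms slowing after informative
cues, take-over error rates ≈ 0.7–1.1%, LDT error rates ≈ 3.4–3.9%, omission
rate 0.5%) emulate a session whose observed statistics sit where published
task-cuing / take-over work puts them: take-over means near 575/600 ms for
informative/non-informative cues, LDT means near 760–790 ms, a session-average
interaction of amplitude × 17/48 ≈ 12 ms, and contrast effect sizes of
|d| ≈ 0.3–1.3.

Noise family: multiplicative log-normal with E[noise] = 1, so `mu` is the
expected RT and the distribution is right-skewed as empirical RT
distributions are. `residual_sigma` (default 0.15, i.e. a trial SD of ~90 ms
at a 600 ms mean) is a reporting-scale calibration, not an inferential claim:
it is chosen so the printed effect sizes above are attainable. Larger values
interact visibly with the ±2 SD exclusion rule (next section): trimming a
right-skewed distribution at bounds pooled across conditions removes more
mass from the slower condition's right tail and attenuates condition
differences — at sigma 0.25 the post-exclusion informativity benefit shrinks
from 45 to ~22 ms. This attenuation is a real property of the rule worth
knowing about when comparing generative parameters with post-exclusion
estimates.

RTs are truncated at the 2.5 s response deadline; omissions (probability
`omission_rate`) are coded as missing values, never as the deadline. Setting
`residual_sigma = 0` gives the exact noise-free limit used by tests.
`expected_informativity_course` returns the closed-form noise-free
informative − non-informative difference at any ordered trial
(−benefit outside the window; −benefit + amplitude inside it under
interruption), the oracle for recovery tests. `simulate_null_dataset` zeroes
every condition and modulation term for type-I-error calibration.

What the generator does *not* emulate: sequential dependencies beyond the
practice curve (no autocorrelated fluctuations in attention), speed–accuracy
trade-offs (errors are independent coin flips, not fast guesses),
jitter/video effects on RT, and block-boundary effects. Passing tests
therefore certify the pipeline's statistical machinery under a plausible RT
model, not the behavior of any particular empirical dataset.

## Exclusion cascade

Participant level (first): a participant is excluded when their mean RT over
responded trials is more than `participant_outlier_k` (default 3) SDs *slower*
than the sample mean in *both* the take-over and the interrupting task —
one-sided and conjunctive. Sample mean/SD are computed over participant-level
means, filler trials included.

Trial level, in this order, on main trials:

1. omissions (no response before the deadline);
2. RT outliers outside the individual's mean ± `trial_outlier_k` (default 2)
   SDs, with mean/SD per participant × task family (take-over vs. LDT),
   pooled across conditions, on responded main trials *including errors* — a
   `outlier_per_condition` switch computes them per cell for sensitivity
   checks;
3. for RT analysis sets only, error trials;
4. carry-over (take-over sets only, default on): trials whose within-trial
   interrupting LDT was answered incorrectly, omitted, or was an LDT-bounds
   RT outlier.

The ordering matters — outlier bounds are computed before error removal — and
is pinned by a test. A constant RT series has no outliers (a zero-SD guard
also absorbs one-ulp float noise in group means). Note that the ±2 SD rule is
not idempotent by construction: trimming shrinks the SD, so re-running the
cascade on its own output can remove further trials; the pipeline applies it
exactly once, and the tested invariants are monotonicity (retained ⊆ input)
and report conservation (per participant, removals by each rule plus retained
trials reconstruct the main-trial count for every analysis set).

Participants left with an empty analysis cell are retained with a logged
warning; the statistics modules drop them pairwise.

## Mean-level inference

Condition means are computed per participant, pooling the speed and lane
tasks; RT means from the RT sets, error rates from the ER sets. The paired t
is classical (two-sided, df = n−1) with d_z = mean difference / SD of paired
differences = t/√n. The 2 × 2 within-subject ANOVA is an explicit
sums-of-squares decomposition in which each effect is tested against its own
participant-by-effect error term; with two levels per factor each F(1, n−1)
equals the squared paired t on the corresponding contrast scores (asserted to
1e−9 in tests, and cross-checked against `pingouin.rm_anova`). Simple
informativity effects are reported at each interruption level.

Two standardized effect sizes are reported side by side because they answer
different questions and can differ by a factor of several: d_z (difference
scaled by the *paired-difference* SD) and d_av (difference scaled by the
average of the two condition SDs). Published ANOVA-context Cohen's d values
are often of the d_av kind; both are labeled explicitly in every output
table.

Degenerate inputs: zero-variance differences with a nonzero mean yield an
infinite-t flag rather than an exception; identical inputs yield t = 0,
p = 1.

## Effect-course analysis

Per participant and condition, RTs are ordered by session occurrence and
smoothed with a centered moving average of odd width `window` (default 11,
about one fifth of the 48 trials available per cell). Edge windows truncate
to the available neighbors, so the output has the input's length and the
course starts at ordered trial 1. The analyzed length is the minimum number
of ordered trials available in both conditions across participants —
exclusions make condition series unequal in length, and the minimum rule
keeps the paired t at every index a complete-cases test on the same
participants.

At each ordered index a paired t across participants compares the two
smoothed series. Clusters are maximal runs of adjacent indices individually
significant at `sample_alpha` (default 0.1, used only for cluster formation)
*with the same t sign*; the cluster mass T is the sum of member t-values.
Inference is by permutation: each participant's two condition series are
exchanged with a fair coin, and the smooth → t → cluster stage is re-run.
Because the exchange unit is the whole series, an exchange is exactly a sign
flip of that participant's difference vector, which is how the permutations
are executed (the per-index second moment is invariant under sign flips, so
only the flipped means need recomputation — this makes 5000 permutations
cheap). The per-permutation statistic is the maximum |mass| over that
permutation's clusters, giving family-wise control; a pooled variant
(ranking an observed cluster within all permutation clusters) is available
behind `max_cluster_rule=False` for sensitivity analysis. The reported
p-value is (exceedances + 1)/(n_permutations + 1), so p is floored at
1/(n_permutations + 1) and never zero; the +1 correction differs from the raw
proportion by at most 1/5001 at the default.

The interaction ("difference of effect courses") analysis forms, per
participant, (informative − non-informative | LDT absent) − (same | LDT
present) from the smoothed series truncated to the common analyzed length,
tests it against zero index-wise, and permutes by per-participant sign flips
of the interaction score. Under the generator's convention the planted
modulation produces a *negative* interaction course inside the truth window.

Calibration and recovery are verified by simulation in the test suite: under
the global null the family-wise cluster rejection rate over 500 simulated
sessions (45 participants, 48 trials/condition, window 11, sample alpha 0.1,
1000 permutations — scaled down from the default 5000 to keep the run within
a test session) falls inside the exact binomial 95% band around 0.05; with
the default modulation planted on ordered trials 7–23, the most-massive
significant interaction cluster overlaps the truth window at Jaccard ≥ 0.5 in
at least 80% of 100 replicates. Smoothing with an 11-trial window blurs the
window edges by up to ±5 trials, which the Jaccard criterion tolerates.

## Orchestration

`run_full_analysis` executes design → (simulate | load) → exclusion cascade →
mean-level statistics → the three effect-course analyses (informativity with
the LDT absent, with it present, and their difference). One master seed
derives all stage seeds through a `SeedSequence`, so the full run and every
stage are individually reproducible; every output table carries the
configuration echo and seed in `#` header comments. Reanalysis of an external
deposit goes through `read_dataset`, which validates the schema (required
columns named in errors, dense 1-based trial indices, no RT beyond the
deadline) and accepts a column-mapping for other naming conventions rather
than guessing.

## Known limitations

- The generator's dispersion and error-rate defaults are reporting-scale
  calibrations, not estimates; no inferential claim about any empirical
  dataset follows from them.
- The ±2 SD exclusion rule attenuates true condition differences under
  skewed noise (quantified above); analyses of generative parameters should
  compare against noise-free simulations, not post-exclusion estimates.
- The analyzed-length rule (minimum across participants) and the centered
  smoothing are documented choices; trailing smoothing or fixed trims would
  shift cluster bounds by a few trials.
- Cluster-based permutation inference licenses statements about the presence
  of an effect somewhere within a cluster, not about its exact boundaries.
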