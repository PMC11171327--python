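# Methods

## Scope and data model

The package evaluates treatment efficacy in xenograft studies where each
animal contributes a weekly tumor-volume series starting at treatment
day 0 (enrollment requires a tumor of at least 100 mm³), and in vitro
potency experiments contribute concentration–response plates. All
volumes are mm³, times are days, and a recorded volume of exactly 0
encodes an unmeasurable (disappeared) tumor.

## Time to event

The event is tumor volume reaching 400% of the day-0 value, i.e. 4·V0 —
a *quadrupling*, not a 400% increase. The first reading at or above the
threshold defines the event interval; the crossing time is interpolated
on the log-volume scale, which is exact when growth is exponential
within the interval. Consequences of this convention, chosen for
first-hitting-time semantics:

- later dips below the threshold do not rescind an event;
- the event time is invariant to a common rescaling of all volumes;
- if a tumor regrows from an unmeasurable reading straight past the
  threshold, the previous volume is replaced by a configurable floor
  (default 1 mm³) so the logarithm is defined. The floor biases the
  interpolated time slightly early, which is the conservative direction
  for a treated arm.

Animals that never quadruple are censored at their last observed day; no
extrapolation beyond the observation window is attempted.

## Response classification

Rules are applied with precedence MCR > CR > PR > SD > PD so every
trajectory of ≥2 readings receives exactly one category:

| category | rule |
|---|---|
| MCR | ≥3 consecutive unmeasurable readings, each strictly after the last treatment day |
| CR  | ≥2 unmeasurable readings in total (any positions), MCR not met |
| PR  | min V_t/V0 ≤ 0.5 |
| SD  | final V_t/V0 ≤ 1.25 |
| PD  | otherwise |

Two clauses required interpretation. First, "unmeasurable up to two
times consecutively or intermittently any number of times" is read as a
plurality requirement: a single isolated unmeasurable reading is not a
CR and falls through to PR/SD/PD. Second, the literal PR wording
("measurable tumor throughout") combined with literal SD/PD
preconditions ("<50% regression throughout") would leave a
single-zero trajectory with no category; the precedence chain above
makes the rule set total while agreeing with every worked example. The
measurability threshold `measurable_min` defaults to 0 mm³ — only an
exactly-zero record counts as disappeared — because no detection limit
is part of the classification definition; it is configurable
(`--measurable-min`) for data that encode a limit explicitly.

"End of study" for the SD/PD growth test is each animal's last available
reading, including series terminated early at quadrupling.

A treatment group's single call is the median of its per-animal
ordinals, with a non-integer median rounded down (toward the worse
category). Median aggregation is the established convention for
single-call-per-model reporting; pessimistic rounding avoids crediting a
group with a response half its animals did not achieve. Objective
response = PR, CR or MCR.

## Survival statistics

Kaplan–Meier, median EFS and the log-rank test are implemented from
their definitions because they are the analysis contract of the
pipeline; `lifelines` serves as an independent oracle in the tests.
Conventions: censorings tied with events occur after the events (the
standard risk-set convention); the median is the first time S(t) ≤ 0.5
(left endpoint of a flat step at exactly 0.5); the log-rank statistic
uses the hypergeometric variance with the multiplicity correction
(n−d)/(n−1) at tied event times, referred to χ²(1), two-sided. Reported
p-values are floored at 1e-16 and flagged, so a literal zero is never
printed. At 10 animals per arm the χ² reference is mildly
anticonservative (empirical type-I rate ≈6% at nominal 5%,
indistinguishable from `lifelines` on the same draws); this is a
property of the asymptotic test, not of the implementation.

## Dose–response and potentiation

The 4PL model `s(c) = bottom + (top−bottom)/(1+(c/IC50)^h)` is fit by
bounded least squares (`scipy.optimize.curve_fit`). Initialization:
top/bottom from the dose-averaged extreme signals; IC50 by log-linear
interpolation of the dose bracket containing the half-signal; Hill slope
multi-started over {0.5, 1, 2}, keeping the lowest RSS. Constraints:
bottom ≥ 0, h ∈ (0.1, 10]; fits pinned at these bounds are flagged
rather than rejected. At least four distinct positive concentrations are
required; zero-dose wells anchor the top asymptote through the residuals
but are excluded from the power term. Flat plates return
`converged=False` instead of raising.

Potentiation is the IC50 ratio `IC50_alone / IC50_combo`; the same ratio
contract, separately labeled, quantifies the additional shift from a
resistance-pathway modulator (e.g. an MGMT inhibitor added to an
existing combination). No formal synergy index (Bliss, Loewe) is
computed — the design varies one drug against a fixed sensitizer
concentration, for which the fold shift is the meaningful summary.

## Biomarker correlation

Response categories are encoded on the plotting scale 1=MCR … 5=PD and
treated as numeric for Pearson's r, matching how such correlations are
reported; Spearman's rho accompanies it as the rank-robust check. The
two-sided p comes from t = r√(n−2)/√(1−r²) with n−2 df; the 95% CI uses
the Fisher z-transform. For the frequently quoted pair (r = 0.88,
n = 6) this computation gives p ≈ 0.021; published figures sometimes
print slightly smaller values for the same pair, which cannot be
reproduced from the two-sided t formula and may reflect a one-sided test
or unrounded inputs. `pearson_p_from_r` exists precisely to audit such
pairs. With n = 6 the permutation distribution has granularity 1/720, so
t-based and permutation p-values agree only to ~0.01–0.02; the tests
budget for that discreteness.

## RNA-seq utilities

Read pairs aligned to both the graft (human) and host (mouse) genomes
are compared lexicographically — alignment score (higher wins), mismatch
count (lower wins), matched-segment length (higher wins), each summed
over mates — and assigned human-only / mouse-only / common / unaligned;
pairs whose three metrics all tie within a tolerance (default 0: exact
ties only) are "common". Human-only and common reads are retained for
quantification. The tolerance default is explicit configuration, not an
inferred constant: the assignment criteria come with no published
thresholds.

FPKM = counts·10⁹/(length·library size). The BH step-up adjustment is
implemented directly (the cross-check against
`statsmodels.multipletests` lives in the tests); note BH adjustment is
order-preserving and bounded by [max p, 1] but *not* idempotent — 
re-adjusting an adjusted vector inflates it again. The
differential-expression filter takes an externally produced per-gene
statistics table (any DE engine; a negative-binomial model is
deliberately out of scope) and applies the three strict criteria
|log2FC| > 1, mean FPKM > 1, adjusted p < 0.05.

## Synthetic data

The generator emulates the study design, not any particular dataset.
Noise-free volumes follow a piecewise-exponential model: regression at
rate `k_regress ≤ 0` for `effect_days`, regrowth at `k_regrow`
afterwards; an arm with `effect_days = 0` grows at `k_control`
throughout. Day 0 is treatment start; pre-enrollment growth is not
modeled. Measured volume multiplies the model by lognormal noise
`exp(N(0, cv²))` — multiplicative because caliper error scales with
tumor size — with cv defaulting to 0.15, a free parameter chosen as a
realistic caliper repeatability, not a literature value. Volumes below a
detection limit (default 10 mm³, a generator-side construct) are
recorded as exactly 0; series stop at the first reading ≥4·V0 (the
termination rule) or at the horizon (84 days ≈ 12 weeks). Per-animal
randomness derives from the cohort seed and the (arm, animal) index
pair, so cohorts are reproducible and order-independent.

Five parameter archetypes (one per category) are provided; noise-free
they classify exactly as intended, and at cv = 0.15 with 10 animals/arm
the group call matches the archetype in ≈98–99% of cohorts. The weakest
archetype is SD, whose final-volume criterion sits nearest its 1.25
boundary — as in real studies, where SD/PD distinctions are the most
noise-sensitive.

What the generator does not emulate: inter-animal growth-rate
heterogeneity, measurement dropout, toxicity-related deaths, drug
pharmacokinetics, and correlated longitudinal noise. Passing recovery
tests therefore demonstrates correctness of the analysis rules under the
stated model, not robustness to every pathology of real caliper data.

## Problem sizes

The verification runs use 100 random grids for event-time accuracy, 500
cohorts (5 arms × 10 animals) for classification recovery, exhaustive
event/censor patterns to n = 8 plus 2000 null replicates for the
survival stack, 500 plate simulations (8 doses × 3 replicates, cv 0.05)
for IC50 bias and 200 two-plate designs for potentiation, 1000 random
vectors (length ≤ 12) for BH, 4500 synthetic read pairs, and 10⁴
permutations for the correlation audit.

## Known limitations

- The classifier requires ≥2 readings and refuses single-point series.
- Log-linear interpolation is exact only under within-interval
  exponential growth; sharp regrowth spikes bias the event time late.
- The 4PL fitter assumes a decreasing signal; increasing dose–response
  curves need their signal negated.
- Median-of-ordinals group calls ignore per-animal event times; a group
  can earn PR while individual animals progressed.
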