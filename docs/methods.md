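# Methods

## Scope and model

`rhdnipt` models the evaluation of a triplicate three-exon real-time
PCR NIPT-RhD assay against newborn cord-blood serology. It has two
halves: a generative half (synthetic cohort + assay physics) that
emulates the study conditions of a 2968-pregnancy routine performance
evaluation, and an analytic half (interpretation, concordance,
accuracy) that is exact arithmetic over whatever records it is given —
simulated or reconstructed from printed counts.

## Synthetic cohort

One pregnancy carries: gestational age at sampling, maternal age,
1–3 fetuses with *RHD* genotype class and sex, a maternal non-coding
*RHD* variant flag, follow-up availability, and (downstream) a
mislabeling flag. Default rates are the study's printed margins:
twins 199/2968, triplets 7/2968, follow-up 0.777, per-fetus D-antigen
positivity 1475/2244, weak D 13/1475 of positives, partial D-variants
9/2968 of positives, maternal variants 15/2968, vanishing twin 1/2968,
mislabeling 1/1000.

**Gestational age.** The study prints only a range (5+6–40+0), a
median (12+6) and a first-trimester fraction (50.9% before 14+0).
Those three pins are mutually tight: the median at day 90 together
with 50.9% below day 98 leaves exactly 0.9% of mass in [90, 98), which
no smooth unimodal-bulk-plus-uniform-tail family can produce (a
uniform tail over [90, 280] alone puts ≥2% there). We therefore define
the distribution directly by a piecewise quantile function — a
Beta(3, 1.5)-shaped booking bulk on [41, 90) with mass 0.5 (mode near
11–12 weeks), a uniform bridge on [90, 98) with mass 0.009, and a
linearly decreasing tail on [98, 280] with mass 0.491 — so all three
printed summaries hold by construction, at any configured
`first_trimester_frac > 0.5`. Degenerate configurations (equal
min/max, or pins outside the range) fall back to a point mass or a
uniform draw.

**Zygosity.** Fetal genotypes are drawn independently within a
pregnancy except with probability 0.3 (configurable) the fetuses share
one genotype, a stand-in for monozygosity; plurality and genotype are
otherwise independent. **Vanishing twin.** With probability 1/2968 an
extra fetus is added, flagged vanished: it contributes cfDNA at a
decayed level (default 0.5 of a live fetus) but is excluded from the
serology reference — the mechanism behind a vanished-co-twin false
positive. **Follow-up** is missing completely at random, reflecting
delivery elsewhere rather than outcome-dependent loss.

## Assay physics

Per replicate well, template molecules are Poisson with mean
`total_cfdna · plasma_per_replicate · ff_target`, each detected
independently with probability `detection_prob_per_copy`; a well is
positive when ≥1 molecule is detected, and
`ct = ct_intercept − ct_slope·log10(detected) + N(0, ct_noise_sd)`.
This limiting-dilution model yields the gestational-age sensitivity
gradient without further machinery. Defaults (chosen once, as the
package's calibration of the study conditions):

| parameter | default | rationale |
|---|---|---|
| total cfDNA | 1000 GE/mL | typical plasma cfDNA load |
| plasma per replicate | 0.33 mL | ~2 mL extraction split across wells |
| fetal fraction | log-normal, median 4% at 12+6, doubling per 10 weeks (`ff_slope = ln2/70`), log-sd 0.6, capped at 0.3 | median and slope are standard cffDNA figures; the spread and cap were set so the simulated cohort reproduces the study's ~97.3% conclusive rate with all four inconclusive reasons at roughly their printed frequencies |
| detection per copy | 0.5 | PCR efficiency below single-molecule certainty |
| ct intercept / slope / noise | 38 / 3.32 / 0.3 | 3.32 cycles per log10 is perfect doubling; intercept is the single-copy ct |
| spurious call | 0.002 per well | keeps 1–2-call RhD-negative samples occurring |
| SRY / RASSF1A efficiency | 1.0 / 0.4 | the methylation-sensitive digest loses template; 0.4 places the fetal-marker failure rate near its printed frequency (27/2968) |

The fetal-fraction cap at 0.3 matters for the maternal-variant rule: a
maternal *RHD* gene adds template at maternal scale (not multiplied by
the fetal fraction), giving ct ≈ 30.6 versus ≥ 32.4 for purely fetal
signal, so the ct threshold of 32 separates the two; without the cap,
rare very-high-ff samples would cross it.

**Mislabeling** swaps the assay observations of two records and flags
both; a record already involved in a swap is not drawn again, so the
operation is a permutation (and two records at swap probability 1
exchange exactly once). **IPC failures** are supported
(`ipc_fail_prob`, default 0) and only flagged, never resimulated.

## Interpretation

Precedence: (1) maternal-variant suspicion — ≥7 calls and median
positive-well ct below 32; (2) 7–9 calls → positive; (3) 3–6 calls
with every exon all-or-none, at least one full and one empty →
D-variant suspected; (4) other 3–6 → inconclusive call count; (5) 0–2
calls → negative if any fetal marker has ≥2 of 3 calls (configurable),
else inconclusive for unconfirmed fetal DNA. Design choices where the
reporting practice leaves room: the maternal flag requires the full
positive band (maternal template amplifies everywhere, so a low-ct
3–6 sample is better explained by dropout); the D-variant pattern
requires strict exon-level all-or-none (scattered positivity is
stochastic dropout); the marker gate applies only to the 0–2 band (a
positive *RHD* result is not gated — the maternal-variant rule already
guards it). The six categories are mutually exclusive and exhaustive
over all 512 call matrices × ct regimes × marker states, verified by
full enumeration against an independently written flat-rule oracle.

## Concordance and accuracy

Only records with a conclusive NIPT report and a known reference enter
the 2×2 table; weak D and partial D newborns count as
reference-positive. The early-gestation subset keeps samples before
140 days (20+0), i.e. through 19+6 completed weeks, which reproduces
the study's printed 1756/488 split. Wilson score intervals are
computed from the closed form with the normal quantile at full double
precision (no continuity correction, no multiplicity adjustment);
display rounding is round-half-up at two percent decimals. The
interval is clipped to [0, 1] and forced to contain p̂ against
floating-point rounding at the k = 0 and k = n boundaries.

**Known display discrepancy.** The published sensitivity CI lower
bounds (99.61% overall, 99.50% early) differ by one display digit from
standard Wilson under round-half-up, which gives 99.6170 → 99.62 and
99.5065 → 99.51. Every other printed bound reproduces exactly. The
implementation does not contort to match those two digits; the
acceptance tests pin our values and document the difference.

## Synthetic-record reconstruction

`rhdnipt.datasets.records_from_counts` rebuilds per-pregnancy
comparison records from the study's printed margins (individual-level
data were never published): early records at day 90, late at day 150,
the single false negative at 13+4 (day 95), fully concordant multiples
placed among the early true calls. It reproduces the overall, early
and multiples strata and the participant flow exactly, but gestational
ages and the co-assignment of plurality with error status within
strata are synthetic.

## What the simulation does and does not show

Passing simulation tests show that the pipeline's rules and statistics
behave correctly under the stated physics: genotype recovery is exact
when error processes are off and detection is saturated; the positive
band rate is monotone in fetal fraction; the conclusive rate and
inconclusive-reason mix at n = 2968 land near the printed values. They
do not validate the physics against raw instrument data — real
fetal-fraction distributions are heavier-tailed and
gestation-dependent in ways the two-parameter log-normal cannot
capture; ct noise is not homoscedastic; maternal variants vary in copy
number; and the second-sample confirmation policy of routine practice
is deliberately out of scope (first-test results only).

## Problem sizes and numerical choices

Tests run the full pipeline at the study's n = 2968 once and at
n ≤ 1500 elsewhere; Monte-Carlo checks use 3 000–10 000 replicates per
condition, and the Wilson-versus-bisection oracle covers every k at
every n ≤ 200 to 10⁻¹⁰ (120 vectorized bisection iterations). The
coverage property uses 200 replicate cohorts with 1000
reference-positives at a known 1% misreport rate — a size at which the
exact Wilson coverage (computed from the binomial pmf) is 96.4%,
comfortably above the 93% assertion. Master seed derivation is
`master, master+1, master+2` for cohort, assay and mislabeling stages.
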