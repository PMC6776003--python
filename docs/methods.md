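# Methods

## Residency model

The unit of analysis is a presence/absence record on one subject's
sampling schedule, an ordered list of integer day offsets (calendar dates
in metadata are parsed as ISO-8601 and converted to offsets from the
subject's first sample; all arithmetic is on integer days, which avoids
timezone and calendar ambiguity).

**Episodes.** Presence dates are partitioned into maximal runs in which
consecutive detections are no more than `gap_limit_days` (default 30)
apart. The rule looks only at the day-difference between detections:
intervening sampled absences do not break an episode, because an absence
in a collected sample is indistinguishable from a missed collection at
the modelling level adopted here. The alternative semantics (an observed
absence interrupts an episode) would make residency depend on collection
compliance; it was considered and rejected, and the gap rule is the
single knob governing loss. Each episode carries its flanking sample
dates (the latest sample strictly before the first detection, the
earliest strictly after the last) and censoring flags when those do not
exist.

**Span estimators.** For an episode with detections spanning
[first, last], prior sample p and next sample s:

- `min` = last − first — time the organism was certainly present;
- `ave` = s − first — first detection to the sample just after loss;
- `max` = s − p — the full window in which presence cannot be excluded.

When p or s is missing (episode touches the study boundary) the observed
boundary date substitutes, so `ave`/`max` degrade toward `min` and never
extrapolate beyond sampled time. Min ≤ Ave ≤ Max holds per episode by
construction and is property-tested on random series.

**Classification.** Resident iff any episode span under the chosen
estimator is ≥ `residency_threshold_days` (default 14; the comparison is
≥, so exactly 14 days qualifies). Total residence time sums the spans of
qualifying episodes — when a taxon is lost and re-establishes, both
resident episodes count toward its percent-of-study residence.
Always-resident additionally requires a *single* episode (an interior
loss with an over-limit gap disqualifies) whose estimator-specific
residence interval — starting at p for `max`, at the first detection
otherwise; ending at s for `ave`/`max`, at the last detection for `min` —
covers the whole sampled period. Under `max` an absence at the very first
sample is therefore forgiven, which is what makes always-resident counts
grow along min → ave → max.

Defaults: threshold 14 d (≥ 3× the 0.7–4 d transit-time upper bound),
gap 30 d, rarefaction depth 10 000 reads, dataset-wide minimum 100 reads
per retained taxon, presence = ≥ 1 count after processing. The threshold
and gap limit are independent parameters. Whether presence is scored on
rarefied or raw counts is the caller's choice (`--no-rarefy` in the CLI);
rarefied is the default pipeline order, raw counts are used in the
noise-free recovery tests where rarefaction dropout is not the property
under test.

## Cohort summaries

Summary tables count resident / transient / always-resident taxa per
subject and estimator; only taxa observed at least once in a subject
enter that subject's denominator. The cohort Average row averages the
count cells arithmetically and rounds to the nearest integer, ties away
from zero; percentage cells are computed from the (rounded) counts in
their own row — the Average percentages are ratios of averaged counts,
not averages of subject percentages. The two conventions differ at one
reproduced cell, and the ratio convention is the one that matches the
published table this code reproduces.

The core-resident-microbiome curve N(x) counts taxa always-resident in at
least x of the S subjects (taxon identifiers are assumed comparable
across subjects, i.e. produced by a joint clustering run). It is fit with
the one-phase decay N(x) = (y0 − c)·exp(−k·(x−1)) + c by
Levenberg–Marquardt least squares, anchored at x = 1 so y0 is the fitted
N(1); initialisation y0 = N(1), c = N(S), k = 1. The plateau test is a
Wald t statistic c/SE(c) on n − 3 df. A constant curve leaves k
unidentifiable and is returned flagged rather than fitted. Note the ±2 SE
interval has exact coverage P(|t_{n−3}| ≤ 2), which is ≈ 0.90 at n = 8
and ≈ 0.935 at n = 16; the parameter-recovery simulations therefore use
16-point curves, where the interval's nominal level approximately holds.

## Diversity

Bray–Curtis (1 − 2Σmin/(Σa+Σb)) and inverse Simpson (1/Σp²) are computed
directly and cross-checked against independent library implementations in
the tests. The dissimilarity-vs-time trend uses all sample pairs (lag =
day difference) by default, with a first-sample-anchored alternative —
both conventions exist in the literature, so the choice is exposed rather
than hidden. Within/between-subject contrasts pool both subjects' within
distributions and use the two-sided Wilcoxon rank-sum test. The
participant-wise comparison of consecutive-sample turnover is a global
Kruskal–Wallis followed by Dunn's pairwise z tests on pooled mid-ranks
with tie correction and Holm adjustment (the correction method is
configurable); compact letters are the maximal cliques of the
non-significant-pair graph, ordered by group mean.

## Clones

Clones are fingerprint-defined and subject-scoped; identical identifiers
in different subjects are different clones and are never compared. Clone
residency reuses the taxon episode machinery verbatim on the clone's
observation dates (a date not on the subject's schedule is an input
error). The candidate screen flags (subject, group-label) series spanning
≥ the residency threshold as worth fingerprinting and conservatively
counts one transient clone per sample for sub-threshold labels.

Residence-time comparisons use log10(observed days + 1) where observed
days is the sum of *all* episode spans, with no residency-threshold
gating: the comparison plots transients at their short spans rather than
at zero. The +1 offset keeps single-observation clones (0 observed days)
on the scale; it is configurable since the published analogue of this
plot does not state its offset. Groups with ≤ 6 members pool into
"Other"; the published pooling counted isolates, this package sees
clones, so the threshold applies to clone counts. The omnibus test is
one-way ANOVA on log10 days; pairwise contrasts use t statistics on the
pooled within-group variance with Holm–Šidák adjustment.

Beyond-study clones are those observed at the subject's first sample,
last sample, or both. The 2×2 association of {long-lived groups} ×
{beyond-study} is tested by χ² (no Yates correction by default; a warning
fires when an expected count is < 5) and {long-lived} × {resident} by a
two-sided Fisher's exact test computed by exact integer hypergeometric
enumeration — probabilities at fixed margins share a common denominator,
so the "no more probable than observed" comparison is done on integer
numerators with no floating-point tie tolerance.

## Concordance and power

Culture is the gold standard. TP/FP/FN/TN counts are tallied per sample;
PPV, NPV and accuracy with zero denominators are reported as missing with
a warning, never coerced. Colony-sampling power is the upper tail of
Binomial(n, p) (exact, default) or Poisson(np) (rare-events form) at
`min_events`; both are provided because rare-events phrasing ("lambda")
suggests Poisson while the exact binomial is never wrong. The inverse
(`required_picks`) bisects on the monotone power function.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes: 8
subjects; spans uniform on 245–849 days; collections on a jittered grid
targeting a median 8-day interval (integer jitter ±2 d), each planned
collection missed with probability 0.1; 180–250 taxa per subject split
35% always-resident / 45% episodic / 20% transient; episodic colonization
durations lognormal with log-mean 4 (≈ 55 d) and log-sd 1, placed
uniformly (1–2 intervals per taxon, non-overlapping); transients occupy a
single sampled day. Counts: each taxon has a lognormal baseline
(log-sd 1.5) and an AR(1) log-abundance process (ρ = 0.8, innovation
sd 0.5 — chosen to give the small consecutive Bray–Curtis turnover that
motivates the analysis); present taxa's exponentiated log-abundances are
normalised and 20 000 reads drawn multinomially per sample, so columns
sum exactly to the read depth.

Detection is idealised: a present taxon always leaves ≥ 1 read (reads are
reassigned from the most abundant taxon if the multinomial draw left it
at zero) unless hit by the per-observation false-negative probability
(default 0). This makes the generator's presence pattern equal the truth
intervals restricted to sampled days at zero noise — recovery tests are
sharp — at the cost of realism: real 16S data has abundance-dependent
dropout, a detection floor near 10^6 CFU/g, compositional coupling, and
phylogenetic correlation, none of which are modelled. Passing recovery
tests therefore validate the *calling machinery*, not detection
performance on real sequencing data. A planted core (`core_taxa_count`)
gives `CORE_*` taxa shared across subjects; all other taxa are
subject-private.

Clone series: per group, residence durations are 10^Normal(mean, sd)
days (defaults: long-lived groups A/B2.3/F at log10 means 2.0/1.9/1.8,
short-lived A.1/B1/E at 0.9/1.0/0.8, sd 0.4 — a within-group spread of
roughly 1.5 decades, matching the scatter such data show), windows placed
uniformly, and each sampled day inside the window observed with
probability 0.8. Unobserved clones stay in the ground truth.

All randomness flows through one explicitly threaded numpy Generator;
the same seed reproduces a cohort bit-for-bit.

## Recovery guarantees and measured rates

For a true colonization interval of length L inside the sampled period
with maximum inter-sample gap g ≤ the gap limit, the first detection is
at most g after the interval opens and the sample following the last
detection falls strictly beyond it, so the `ave` span exceeds L − g:
L ≥ τ + g guarantees a resident call under `ave` (and `max`). No such
bound holds under `min` (worst case observes only L − 2g), which is why
sensitivity is stated for `ave` and single-day-transient specificity for
`min` — both are measured at 100% on noise-free cohorts. With a 10%
per-observation false-negative rate, resident/transient agreement with
truth is measured (not assumed) at ≈ 96% by the acceptance script.

## Problem sizes

The test suite and acceptance script use: 1000 random series for the
ordering and segmentation-oracle checks; 200 replicates for plateau
recovery; 500 replicates for the 0.5-log10 clone ANOVA power (15 clones
per group, sd 0.4 log10 days, log10 means 2.0 vs 1.5 — levels where
duration clipping at the study span and sampling discretisation are
negligible); full default cohorts for label recovery; and all 132 470
2×2 tables with total ≤ 40 for the Fisher check. The analysis drivers
run one default cohort at seed 42.

## Known limitations

- Censoring is flagged, not modelled: no survival-analysis treatment of
  boundary episodes.
- The gap rule never consults observed absences; organisms redetected
  within 30 days are assumed continuously present.
- Rarefaction dropout can demote a low-abundance always-resident taxon;
  the pipeline exposes the unrarefied path but does not correct for this.
- The screen for candidate resident clones is a conservative
  reconstruction of a step-wise triage whose exact decision rules are
  not published; it is labelled as such.
- Abundance-weighted residency, phylogenetic structure and covariates
  (diet, antibiotics) are out of scope.
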