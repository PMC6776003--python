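# gutresidency

Episode-based residency analysis for longitudinal gut-microbiome time
series — who actually *lives* in a gut, who is just passing through, and
how confidently can either be said from irregular stool sampling?

Community-level 16S surveys often report a stable "core" of taxa that are
never lost, while cultivation studies of the same guts see bacterial
clones turning over within months. This package implements the analysis
machinery needed to examine that tension on presence/absence time series:
an operational residency definition applied identically to sequence-level
taxa (OTUs/ASVs) and to cultured, fingerprint-defined clones, plus the
cohort summaries, core-microbiome decay test, clone-group comparisons,
diagnostic-concordance and colony-sampling-power calculations that hang
off it. A seeded synthetic-cohort generator with exported ground truth
backs every stochastic claim with a recovery test.

## The residency model

A subject is sampled on days $d_1 < d_2 < \dots < d_n$. For each taxon
(or clone) the detection record is segmented into **episodes**: maximal
runs of detections in which consecutive detections are at most
$g = 30$ days apart. A longer silence means the organism is presumed
lost; if it reappears it starts a new episode and must qualify again.

Because sampling is discrete, an episode's true duration is only
bracketed. Three estimators convert an episode with first/last detections
$f, \ell$ and flanking sample days $p < f$ and $s > \ell$ into a span:

$$\mathrm{Min} = \ell - f \le \mathrm{Ave} = s - f \le \mathrm{Max} = s - p$$

falling back to the observed boundary when a flanking sample does not
exist. A taxon is **resident** if some episode's span reaches the
threshold $\tau = 14$ days (at least three times the upper bound of the
0.7–4 day healthy-adult gut transit time — anything shorter could just be
washing through), **transient** otherwise, and **always resident** when a
single episode's residence interval covers the entire sampled study
period. The three estimators give the characteristic ordering of resident
and always-resident counts, Min ≤ Ave ≤ Max.

On top of this core the package provides:

- per-subject/cohort summary tables and percentile-rank residency
  profiles (`cohort`);
- the core-resident-microbiome test: $N(x)$ = number of taxa
  always-resident in ≥ x subjects, fit with
  $N(x) = (y_0 - c)\,e^{-k(x-1)} + c$ and a Wald test of the plateau
  $c = 0$ (`cohort`);
- Bray–Curtis / inverse-Simpson diversity, consecutive-sample turnover
  series, time trends, within/between-subject contrasts,
  Kruskal–Wallis + Dunn with compact letters (`diversity`);
- clone screening, residence-time ANOVA on $\log_{10}$ days with
  Holm–Šidák contrasts, beyond-study χ² and resident-vs-transient
  Fisher's exact test by exact enumeration (`clones`);
- culture-vs-sequencing confusion statistics (PPV/NPV/accuracy) and
  binomial/Poisson colony-sampling power (`concordance`);
- the synthetic cohort generator (`simulate`) and TSV readers/writers,
  <100-read filtering and exact rarefaction (`datamodel`, `io`).

## Worked example

How many colonies must be picked per stool sample to detect a clone at 2%
relative abundance at least once with 80% power?

```bash
$ gutresidency power --n 84 --rate 0.02 --min-events 1
0.8168
```

84 picks give power 0.817 (binomial; the Poisson rare-events model gives
0.814), and scanning shows 80 picks is the minimum reaching 0.8.

The analysis drivers under `analysis/` run the full pipeline on the
synthetic cohort (eight subjects, spans 245–849 days, median 8 days
between samples, 180–250 taxa each). For example:

```bash
$ python analysis/02_residency_summary.py
synthetic cohort average row:
  178 taxa; resident 87% (min) <= 90% (ave) <= 98% (max); always resident 42/42/42%
published eight-participant average row (recomputed from its printed per-participant cells):
  41 samples, 430 days, 203 OTUs; min resident 154 (76%), always 69 (34%); ave resident 175 (86%)
```

The first line is the simulated cohort: most observed taxa qualify as
residents under some estimator and the resident fraction grows from the
conservative Min to the generous Max estimator, as it must. The second
line re-derives a published cohort-average row exactly from its printed
per-participant cells, anchoring the summary arithmetic.

```bash
$ python analysis/03_core_microbiome_decay.py
no_planted_core: N(x) = [590, 0, 0, 0, 0, 0, 0, 0]
  decay fit degenerate (curve collapses immediately); no shared core by construction
planted_core_12: N(x) = [568, 12, 12, 12, 12, 12, 11, 9]
  ave-estimator plateau = 11.33 +/- 0.49 (p = 2.94e-06, R^2 = 1.0000)
```

With no taxa shared between subjects the always-resident overlap curve
collapses at x = 2; planting a 12-taxon shared core makes the fitted
plateau come back significantly non-zero and close to 12 (one core taxon
drops below detection in two subjects after rarefaction).

Drivers `01`–`06` cover cohort generation, residency summaries, the decay
test, community turnover, clone comparisons and diagnostic concordance;
each writes tidy tables under `results/` and prints what it found.

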