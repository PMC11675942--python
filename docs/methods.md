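# Methods

## Setting and data model

Spontaneous adverse-event reporting systems (FAERS being the canonical one)
collect voluntary reports of suspected drug–event associations. They have
no denominator: only *relative reporting* is identified, which is why all
four methods here are disproportionality statistics, comparisons of how
often an event is reported with a target drug versus a comparator pool.

The in-memory unit is a normalized table with one row per
(report, drug, event) combination. Readers exist for delimited text in
that layout and for a minimal FAERS-style "$"-delimited ASCII dialect
(DEMO/DRUG/REAC/OUTC/INDI with the small stable column subset the pipeline
needs; quarterly schema drift is deliberately out of scope). Drug names
are normalized case-insensitively over generic names plus the US brand
names of the class; age codes YR/DEC/MON/DY convert to years by
1, 10, 1/12 and 1/365.25.

The inclusion pipeline applies, in fixed order: deduplication (keep the
maximum case version per case, then collapse exact duplicates; a
full-record-only mode exists because reporting systems differ in their
versioning discipline), primary-suspect role, the four retained drugs,
the gastrointestinal system-organ class, US reports, exclusion of
combination-therapy reports, listwise exclusion on configurable missing
fields (default: drug, event term, country — demographics may be missing
in retained reports), and an optional year window. "Combination therapy"
is operationalized strictly: a report whose primary/secondary-suspect
rows span more than one distinct drug. Every stage logs
(in, excluded, out) and the log is validated for conservation
(`in = excluded + out`, chained across stages).

## Contingency tables and the comparator

The 2×2 table for (drug, event) uses the *within-class* comparator — the
other three retained drugs pooled. That choice is not aesthetic: it is the
only comparator arithmetically consistent with the packaged published
statistics (verified cell-by-cell). Counting is event-level by default
(one count per report-drug-event row); case-level counting is available
behind a flag. Serious-outcome tables (disability, life-threatening,
hospitalization, death — CTCAE grades: disability/hospitalization → 3,
life-threatening → 4, death → 5) use the
same per-drug GI-report totals as denominators, which reproduces the
published death and disability rows exactly.

## The four statistics

* **ROR** `(a·d)/(b·c)`; CI `exp(ln ROR ± z·√(1/a+1/b+1/c+1/d))`.
* **PRR** `[a/(a+b)]/[c/(c+d)]`; delta-method variance
  `1/a − 1/(a+b) + 1/c − 1/(c+d)`. The published intervals deviate from
  this variance by ≈0.3%, so PRR intervals are property-tested rather
  than exact-tested.
* **χ²** Pearson with Yates continuity correction by default (the
  convention of the classical PRR criterion).
* **BCPNN IC.** Headline variant: the closed-form shrinkage IC,
  `IC = log₂((a+½)/(E+½))`, `E = (a+b)(a+c)/N`, with the percentile
  approximation `IC025 = IC − 3.3(a+½)^−½ − 2(a+½)^−3/2`. Second variant:
  the two-layer Beta-prior model (margins Beta(1,1) from α=β=2, joint cell
  weight γ₁₁=1 with γ scaled so the prior IC is centred on zero); its
  posterior mean and variance of `IC = log₂(p_xy/(p_x p_y))` are computed
  *exactly* from digamma/trigamma moments of log-Beta variables, and
  `IC025 = E(IC) − z·√V(IC)`. Tests check both variants against
  independent numerical quadrature to 1e-6. The published IC025 values
  match neither standard parameterization and are therefore excluded from
  exact reproduction — both variants are reported instead.
* **Adjusted logistic regression.** One observation per report; outcome =
  event mentioned; exposure = target drug vs pooled comparator; age
  continuous and mean-centered, sex with female reference. Fitting is
  Newton–Raphson maximum likelihood (statsmodels `Logit`); rows missing a
  covariate are dropped listwise for this method only. Complete separation
  is detected and *reported*, not silently penalized; a Firth
  (Jeffreys-prior) penalized fit is available behind a flag for separated
  or sparse data. Without covariates the drug coefficient equals ln ROR
  exactly — the identity used throughout the tests.

**Critical value.** All 95% intervals use z = 1.96 rather than
Φ⁻¹(0.975) ≈ 1.959964. The difference is visible at three printed decimals
on sparse tables, and 1.96 is what reproduces the packaged published
intervals; it is also the near-universal convention in the
pharmacovigilance formula literature.

**Zero cells.** Haldane–Anscombe +0.5 on all four cells for ROR/PRR, with
the result flagged `corrected`; corrected cells are excluded from exact
reproduction (the source analysis evidently used a different, unstated
correction). Degenerate margins make a statistic non-estimable, which
surfaces as a reason code, never an exception, in signal evaluation.

**Signal rules** (defaults, configurable): ROR CI low > 1 and a ≥ 3;
PRR ≥ 2 and χ² ≥ 4 and a ≥ 3; IC025 > 0; β > 0 and p < 0.05.

## The packaged count fixture and its audit

The package carries the published per-drug GI-report totals
(4401/4126/4075/3966, total 16,568), per-event per-drug case counts, and
the printed ROR/PRR/IC025/β values, each entry with a provenance note.
During packaging every printed ROR/PRR cell was recomputed from the
printed counts; cells disagreeing beyond 0.0005 at three decimals are
recorded in a `known_discrepant_cells` list inside the resource. The audit
found:

- the semaglutide vomiting case count (2298) is inconsistent with its own
  printed ROR (which implies ≈1198); because the erratic count also
  contaminates the comparator cells of the other three drugs, the whole
  row is flagged;
- the life-threatening and hospitalization rows are transposed (for three
  of the four drugs the printed values match exactly after swapping the
  rows; the dulaglutide cells match neither orientation);
- nearly all dulaglutide cells, and the liraglutide/dulaglutide diarrhea
  pair (consistent with swapped case counts), fail to reproduce;
- the liraglutide/semaglutide peptic-ulcer cells reflect a different
  zero-cell correction; one exenatide nausea CI digit differs.

The reproduction command surfaces every such cell as
`excluded_known_discrepancy`; the 199 remaining printed cells reproduce
exactly. The incomplete inflammatory-bowel-disease row (three of four
counts unprinted) raises on table construction — no imputation.

## Synthetic data

The generator emulates the analyzed cohort's structure: four drugs with
multinomial shares 26.6/24.9/24.6/23.9%, 62% female, age bands
18–44/45–54/55–64/65+ with shares 10/19.8/32/38.2% (uniform within band,
65+ capped at 90), 65% consumer reports, indication mix ≈89/3/8%
diabetes/obesity/weight-loss, reporting years uniform over each drug's
marketing era (2007/2010/2014/2017 onward), serious-outcome probabilities
20.3/1.2/1.2/0.8% (hospitalization/life-threatening/death/disability),
and per-event baselines defaulting to the pooled event proportions of the
packaged fixture.

Events are drawn independently per report given covariates. The effect
parameter θ(drug, event) multiplies the reporting *odds*:
`logit p = logit(baseline) + ln θ (+ confounding terms)`. The odds-scale
definition makes the ROR against the pooled comparator estimate θ exactly,
so parameter recovery is unbiased by construction rather than only in the
rare-event limit; it also needs no probability clipping. Optional
confounding: per-event log-odds slopes in age (per decade, centered at 55)
and sex, and an age tilt on drug assignment — together these create the
classic situation where the crude ROR is biased and the adjusted
regression recovers ln θ, which is the acceptance surface for the
adjustment stage.

`expected_tables` returns exact expected 2×2 cell means by integrating
the event probabilities over the covariate law (Gauss–Legendre with 16
nodes per age band, exact over sex), including under confounding and
tilted assignment; the generator is validated against it by Monte-Carlo
means over replicate seeds.

What the generator does **not** emulate: within-report event correlation
(symptom clusters), reporting-delay dynamics, secular trends in reporting,
country mixtures, real FAERS duplication patterns (only an optional exact-
duplicate injection rate for exercising deduplication), or free-text drug
names. Passing tests therefore demonstrate estimator correctness and
calibration under the stated model, not robustness to those real-data
features.

## Problem sizes and numerical choices

Simulation-based checks use 50,000 reports per replicate with a 5%
baseline — counts comparable to the real cohort's pancreatitis row — with
50 replicates per effect size for recovery (tolerance ±0.1 on the log
scale on the median) and 200 replicates of 10,000 reports × 12 drug-event
pairs for null CI coverage (0.95 ± 0.02). Exact-reproduction comparisons
use tolerance 0.0005 after rounding to 3 decimals, because the printed
values are rounded, not truncated (verified: 1.5533 → 1.553,
3.0964 → 3.096). Logistic fits run to log-likelihood tolerance 1e-8 with
at most 50 Newton steps; estimates with |β| > 15 are classified as
separation. Display percentages round half-up to one decimal.

## Known limitations

- The published adjusted β values cannot be reproduced: they require the
  report-level covariate data behind the original extraction. The package
  reproduces the *identity* linking β to ln ROR in the covariate-free case
  and validates adjustment by simulation instead.
- The published class-level ROR against a non-GLP-1 background (0.56 /
  2.63) is not reproduced; its comparator population is unspecified. The
  analysis accepts a user-supplied external background table for that
  style of contrast.
- MedDRA is licensed; event terms and system organ classes are opaque
  strings here, with a flat configurable GI term list standing in for the
  full hierarchy.
- Disproportionality statistics are signal-detection tools. Nothing here
  estimates incidence or establishes causation.
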