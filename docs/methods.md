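# Methods

## Scope and data model

The unit of analysis is an individual with phased haplotype labels at four
independently segregating loci: the MHC (labels classified into the five
CEH groups `AP < 0 < c1 < ER < H+`, ordered by nominal disease risk) and
three non-MHC regions (`d1`, `d2`, `d3`) reduced to binary risk / non-risk
haplotypes.  An MHC *genotype* is the unordered pair of group
assignments (15 values); non-MHC genotypes are risk-copy counts 0/1/2.
Classification is total: labels absent from the catalog fall into the
neutral group `0`, which is defined residually (a strict mode turns this
into an error).  The five group codes themselves are accepted as labels so
cohorts phased at group resolution — including simulated ones — classify
as written.

Genotypes are collapsed into risk categories for the stratified tables:
one `H+`/`ER` copy beside `0` is *single-copy risk*; two copies from
{`H+`, `ER`, `c1`} are *double-copy risk*; `(AP,0)` and `(AP,AP)` are the
protective analogues; `(0,0)` and `(0,c1)` are *neutral* (a lone `c1`
carries little excess risk — its effect is treated as recessive);
mixed protective/risk pairs are *other*.

## Association statistics

All effect estimates are Woolf odds ratios, `OR = ad/bc`, with log-scale
standard error `√(1/a+1/b+1/c+1/d)` and Wald intervals.  Two ORs are
compared with `z = [ln OR₁ − ln OR₂]/√(SE₁²+SE₂²)`; because a shared
reference group cancels from the ratio, these comparisons are independent
of the reference chosen, and ORs are re-referenced by the chain rule
`OR(a vs c) = OR(a vs b)·OR(b vs c)` (exact at the count level, which the
tests verify in rational arithmetic).  Zero cells raise a degenerate-table
error by default; an optional Haldane–Anscombe correction adds 0.5 to all
cells and flags the result.  Multiple testing uses Benjamini–Hochberg,
applied per output family (one matrix or table per call) with a
global-family mode in the pipeline.  Hardy–Weinberg checks use the
asymptotic chi-square with allele frequencies estimated by counting,
df = #genotype cells − #alleles, and pooling of cells with expected count
below 1.

Estimates marginal below 15 exposed representations are flagged `na`
(display bands additionally distinguish 15–49 from ≥50).  At prevalence
≈ 0.003 the rare-disease approximation (OR ≈ RR) is accurate to well under
1% for the effect sizes involved, and ORs are treated as relative risks
throughout the model evaluation.

A documented caveat: recomputing the published women-vs-men single-copy z
from the *rounded* printed ORs and CIs (3.0, 2.8–3.2 vs 2.6, 2.4–2.8)
gives z ≈ 2.75 rather than the reported 2.4; the original computation
evidently used unrounded values, so that number is not treated as a
recomputable quantity.

## The two matrix analyses

**Combination matrix.**  Columns are MHC genotypes in increasing-risk
order; rows are non-MHC copy-count combinations.  Each cell is the OR of
the row's combination versus the zero-copy reference *within the column's
MHC stratum*, so the cell isolates what the non-MHC copies add on a fixed
MHC background, and cells are invariant to individuals outside the
stratum.  "Within the loci involved" means the reference is pinned to zero
copies only at loci the row constrains (a strict mode pins all three).
z tests `ln OR` against 0 and is binned into the five shading bands
(|z| < 1, 1–2, 2–3, 3–4, ≥ 4).

**Transition matrix.**  The replacement OR `OR(C, X→Y)` is simply the
case-control OR between genotypes `(C,Y)` and `(C,X)`.  The cell at column
`(a→b)`, row `(c→d)` is `ln[OR(c,a→b)/OR(d,a→b)]`; because genotype counts
are unordered this identically equals `ln[OR(a,c→d)/OR(b,c→d)]`, and the
implementation computes both readings and asserts agreement to machine
precision (skipped only when a zero-cell correction, which breaks the
algebra, was applied).  z comes from the two replacement ORs' log-scale
comparison.  If haplotype effects combined multiplicatively with no
interaction, every cell would be ≈ 0.

## Additive vs multiplicative accumulation

Components are relative risks versus the `(AP,AP)` baseline
(`R_b = R_AP = 1`).  Expectations for a combination are
`1 + Σ(R_i − 1)` (additive) and `Π R_i` (multiplicative); each observed
combination's OR versus the baseline is compared with both on the ln
scale, rows rarer than 15 are dropped, and the verdict is the majority of
decisive rows (`additive_fraction` reports the share).

**Why each component carries two values.**  A case–control cohort
identifies a component only relative to a reference, and a single number
cannot be simultaneously the component's additive excess and its
multiplicative factor once a background risk intervenes.  The estimators
are therefore model-consistent by scale:

* *MHC haplotype X* (default "zero" route): from
  `OR((0,X) vs (0,0))` re-referenced through
  `r₀₀ = OR((0,0) vs (AP,AP))`.  On the additive scale
  `R_X = OR·r₀₀ − (r₀₀+1)/2 + 1` (subtracting the neutral companion's
  excess, using `r₀₀ = 1 + 2(R₀−1)`); on the multiplicative scale
  `R_X = OR·√r₀₀` (using `r₀₀ = R₀²`).  An alternative "ap" route
  estimates `OR((AP,X) vs (AP,AP))` directly — unbiased on both scales at
  once, but very noisy in realistic cohorts because the `(AP,AP)` stratum
  is rare (~20 expected individuals, ~2 expected cases at the default
  cohort sizes), which is also why the default observed-risk route chains
  through the well-populated `(0,0)` stratum.
* *Non-MHC locus, k copies*: from the within-`(0,0)`-stratum OR of k vs 0
  copies; multiplicative scale uses the ratio as is (backgrounds cancel),
  additive scale converts the excess to the baseline scale,
  `1 + r₀₀(OR − 1)`.

Two consequences, both deliberate.  First, every *definitional* row — the
`(0,X)` genotypes and the `(0,0)`-stratum non-MHC combinations that anchor
the components — satisfies both expectations identically, ties, and drops
out of the verdict, so the verdict rests entirely on genuinely combined
genotypes.  Second, re-referencing the whole evaluation from `(AP,AP)` to
`(0,0)` rescales every observation and both expectations by the same
bridge OR, leaving per-row outcomes unchanged (exactly, for all rows not
carrying a baseline haplotype — the baseline's own component is pinned at
1 by definition, so rows containing it are reference-dependent by
construction).  When the configured baseline falls below the 15-count
floor the evaluation automatically re-references to `(0,0)` and records
`baseline_used`; with `baseline_fallback=False` it raises instead.

Zero-cell correction defaults **on** inside this module (off elsewhere): a
single empty cell in a sparse baseline stratum should degrade one
estimate, not void the whole evaluation.

## The cohort generator

The generator draws haplotypes independently per locus (so genotypes are
Hardy–Weinberg by construction and loci segregate independently), composes
a genotype relative risk from per-copy components under the configured
rule, applies per-genotype MHC overrides, converts risk to penetrance by a
single scale factor solved analytically so the expected population
prevalence equals the configured value, assigns disease by Bernoulli
draws, and accumulates freshly drawn individuals until the case and
control quotas fill.  Configured RRs therefore hold exactly by
construction, not asymptotically.  Sex is 50/50 and independent of
genotype; an optional multiplier scales female penetrance for single-copy-
risk genotypes only (the normalisation accounts for it).  Output is
byte-identical for identical config and seed.

### Default parameter derivations

Stated conditions: non-MHC risk-haplotype frequencies 0.02 / 0.23 / 0.41;
prevalence 0.003; cohort sizes 11,376 cases and 18,872 controls.  Values
the source material states only indirectly, derived once:

* `H+` frequency 0.12251 from the 23% control carrier rate
  (`1−(1−p)² = 0.23`);
* `ER` frequency 0.02874 from `H+` constituting 81% of control risk
  haplotypes;
* `AP` frequency 0.04344 from an ~8.5% carrier rate (8% in women, 9% in
  men);
* `c1` frequency 0.062 — the highest-frequency single CEH, set to the
  reported ceiling for any CEH combination's control frequency;
* per-copy haplotype RRs calibrated so the cohort reproduces
  `(0,H+)` vs `(0,0)` = 3.0, `(0,ER)` vs `(0,0)` = 2.0 (a chosen value:
  "extended risk" sits below `H+` and no ER OR is printed) and
  `(AP,AP)` vs `(0,0)` = 0.13 under the chosen composition;
* non-MHC per-copy RRs (1.35, 1.25, 1.20) — plausible haplotype-level
  effect sizes for the strongest non-MHC MS loci, which are not printed.

The `study_like_config` preset additionally overrides MHC genotypes to the
published non-additive pattern: `(0,c1)` ≈ 1.09 (from 3.0/2.74),
`(c1,c1)` = 2.5 (reported as significantly elevated without a printed OR),
`(c1,H+)` ≈ 4.02 and `(H+,H+)` = 6.51 (from the replacement ORs 3.67 and
2.17), `(AP,H+)` ≈ 1.92 (from the replacement OR 3.4) — all as ORs versus
`(0,0)` before rescaling to the baseline-1 scale.  The optional sex effect
multiplies female single-copy-risk penetrance by 3.0/2.6 ≈ 1.15,
reproducing the observed female *excess* for that category (the
female/male OR ratio), not the absolute printed per-sex levels.

### What the generator does and does not emulate

It emulates the statistical skeleton the analyses assume: independent
segregation, HWE, rare disease, known composition of risk, a sparse
protective baseline.  It does **not** emulate linkage disequilibrium
between loci, population stratification or geographic heterogeneity,
genotyping/phasing error, label-level CEH diversity within groups, family
structure, or environmental covariates.  Passing tests therefore
demonstrate that the estimators recover known structure under the model's
own assumptions — not that those assumptions hold in any real cohort.

## Numerical and testing choices

* Problem sizes: the acceptance suites use 200 cohorts of 5,000 + 8,000
  for CI-coverage of configured RRs, 100 cohorts per composition at the
  default sizes for model discrimination, 500 small cohorts (3,000
  controls) for HWE p-value uniformity (KS at α = 0.01), and 2×10⁶
  population draws for the prevalence check — sizes at which each check's
  Monte-Carlo error is small against its tolerance.
* Degenerate inputs: overlapping exposure/reference predicates are logic
  errors; empty references, zero cells (without correction) and absent
  reference genotypes raise degenerate-table errors that the matrix
  builders convert to `na` cells; monomorphic loci cannot support an HWE
  test.
* Ties in `closer_model` are declared below 10⁻⁹ absolute ln-distance
  difference; genotype display order is lexicographic in the group risk
  order.
* All randomness flows from a single integer seed per config; derived
  seeds stay below 2³¹.

## Known limitations

* Component estimation assumes the two MHC haplotypes' effects and the
  non-MHC effects are identified from the `(0,·)` strata; strong
  interactions involving the neutral group itself would bias components on
  both scales.
* The additive/multiplicative verdict is a descriptive majority over
  combinations, not a formal model-selection statistic, matching the
  analysis it implements; no likelihood or information criterion is
  computed.
* The `(AP,AP)` baseline is intrinsically sparse at realistic frequencies;
  quantities referenced to it (e.g. a recovered `(AP,AP)` OR) carry large
  sampling error at the default cohort sizes, and the evaluation's
  baseline fallback exists precisely for this regime.
* Covariate adjustment (logistic regression, principal components) is out
  of scope; cohorts are analysed as given.
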