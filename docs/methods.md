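# Methods

## Scope and data model

The unit of analysis is a health facility offering childbirth services,
observed once. Facilities belong to one of two tiers — hospitals
(assessed against an expanded item list covering comprehensive
emergency obstetric and newborn care) and health centres/clinics — and
every analysis is stratified by tier; scores are never compared across
tiers, and PCA models are fitted per tier.

Raw item responses take five values: yes, no, don't know, missing, not
applicable. Before aggregation, yes → 1 and no/don't-know/missing → 0.
Not-applicable responses (items asked only of government-managed
facilities) are handled per aggregation purpose: for the additive
methods the cell is excluded and the denominator adjusted; for PCA the
cell is coded 0 so the matrix stays dense. These coding rules are the
contract of `survey_io.code_responses` and everything downstream
assumes them.

## Index definitions

Three item-selection frameworks ship as YAML registries:

| framework | health-centre items | hospital items | domains |
|---|---|---|---|
| SARA tracer | 15 | 22 | 3 |
| DHS indicators | 30 | 33 | 5 + 1 excluded |
| WHO standards | 44 | 52 | 4 |

The hospital list always nests the health-centre list. The DHS
"guidelines, staff training and supervision" domain is carried in the
item list (it counts for simple addition and PCA) but excluded from
domain-weighted aggregation. WHO-standards items additionally map to
one of the five WHO quality standards (three provision-of-care, two
cross-cutting). The per-framework totals are fixed and validated at
load time; the split of items across domains within a framework, and
the item labels, are editorial approximations — downstream code is
agnostic to both, and the registry format accepts replacements. The
three framework item sets are kept disjoint because an item definition
carries exactly one readiness domain, and the frameworks partition
their items along different domain structures.

Five items (two DHS general-requirements, three WHO staffing/systems)
are conditional on managing authority: not applicable for private
facilities.

## Aggregation methods

*Simple addition.* score = Σ available / Σ applicable, equal item
weights. Scores are exact rationals in floating point (a single
correctly rounded division), so exact equality is safe for tie
grouping.

*Domain-weighted addition.* Per-domain availability fraction, then the
unweighted mean over domains, excluding (i) configured weighting
exclusions and (ii) domains left without applicable items — the
domain-level analogue of the item-level denominator adjustment.

*Principal components.* Eigendecomposition of the item correlation
matrix (standardized 0/1 items). The correlation rather than covariance
choice makes first-component variance shares equal λ₁/p, consistent
with the eigenvalue and variance-share ranges the construct is reported
with. The first eigenvector's sign is fixed by a positive loading sum
(tie-broken by the largest-magnitude loading), so higher score = more
ready. Raw projections are min–max rescaled over the scored cohort:
some facility scores exactly 0 and some exactly 1 *by construction*,
and scores are cohort-relative. Zero-variance items make the
correlation undefined; the fitter refuses them by default and offers an
explicit drop-with-warning mode (used by the pipeline, where a
universally available item in a given cohort is expected and benign).

Floor/ceiling detection uses exact equality for additive scores and a
1e-9 tolerance for PCA scores (whose endpoints are exact only up to
the rescaling arithmetic).

## Item diagnostics

*Availability* is the share of facilities with the item present among
facilities where it applies. Items with availability strictly above
0.97 are screened out as near-universal (they cannot discriminate);
0.97 exactly is retained. Item-variation reporting classifies items as
rare (availability < 0.40, strict) or widely available (≥ 0.90); the
wide threshold is inclusive, following the reporting table convention
this output mirrors (the accompanying prose says "> 90%", the table
header "≥ 90%"; the table is the artifact reproduced). Variation
percentages are integer-rounded half-to-even.

*2PL item response model.* P(y=1|θ) = 1/(1+exp(−a(θ−b))) with
θ ~ N(0,1), fitted per readiness domain by marginal maximum likelihood:
EM with 21-point Gauss–Hermite quadrature. The E-step computes each
facility's posterior over quadrature nodes (respecting the
applicability mask); the M-step maximises the expected complete-data
log-likelihood per item with bounded L-BFGS-B, a ∈ [0.05, 10],
b ∈ [−6, 6]. Convergence when the largest parameter change drops below
1e-4, capped at 500 iterations (non-convergence is flagged, not
raised). The marginal log-likelihood is nondecreasing across
iterations, which the tests assert. Starting values: a = 1,
b = −logit(availability). Recovery at the cohort sizes used for
selection (hundreds of facilities) is adequate for ranking items;
truth-correlations exceed 0.9 by n = 2000 (see
`analysis/05_irt_recovery.py`). No 3PL, no graded responses, no DIF
analysis. The discrimination cutoff used when filtering candidate items
is a configuration knob (default a ≥ 0.65) — an editorial default, as
item selection in practice mixes statistical with conceptual criteria.

*Internal consistency.* Cronbach's alpha with sample variances;
undefined (NaN with a warning) when the total score is constant.
Interitem correlation is the Pearson (phi) correlation of 0/1 items;
zero-variance items are dropped with a warning and reported.

## Comparison battery

Summaries use population moments for skewness and kurtosis (kurtosis
non-excess, normal = 3, matching the convention of the statistical
environment this kind of table is usually produced in) and the sample
SD for the coefficient of variation. Reported percentages round
half-to-even at one decimal via exact decimal arithmetic: 34/160 →
21.2, 50/160 → 31.2 (both .x25 cases round to the even digit).

Ranking ties: "next highest score" means the second-largest *distinct*
score value, with facilities counted by exact equality. Average ranks
(for correlations), dense ranks and ordinal ranks are all emitted,
since different ranking displays use different conventions.

Bland–Altman agreement uses per-facility differences a − b with limits
at mean ± exactly 2·SD (sample SD), plus the count outside the limits
and the Spearman correlation of the two score sets. Spearman is
computed in-package (average ranks, Pearson of ranks, two-sided
t-approximation with n−2 df; exact ±1 short-circuit for concordant or
reversed rankings) and cross-checked against an independent
implementation in the tests. Facilities missing delivery volume are
deleted pairwise from volume correlations only. No multiple-testing
adjustment is applied anywhere.

## Synthetic cohort generator

The generator emulates the study conditions the pipeline assumes:

- 160 hospitals and 246 health centres/clinics; latent readiness
  θ ~ N(1, 1) for hospitals and N(0, 1) for health centres (direction
  chosen so hospital medians exceed health-centre medians, as observed);
- item responses Bernoulli(sigmoid(a(θ−b))) with a ~ Uniform(0.5, 2.5)
  and b ~ Normal(per-domain shift, 1);
- don't-know and missing overwrite responses completely at random at
  0.5% each (observed: below 1% combined categories);
- private facilities (3.8% of hospitals, 6.1% of health centres, the
  observed managing-authority split) receive not-applicable on the five
  conditional items, putting per-item NA rates inside the observed
  3%–8% band;
- monthly delivery volume = round(exp(3.0 + 0.5·θ + N(0, 1.5²))). With
  these defaults the latent volume–trait correlation is ≈ 0.32, which
  lands observed score–volume Spearman correlations in the 0.15–0.40
  range reported for real facilities.

`preset_paper_like` fixes per-domain difficulty shifts once — SARA
domains easiest (shifts −1.4 to −1.8), DHS intermediate, WHO-standards
mixed including genuinely hard system items (shifts −0.3 to −1.2) — so
that the qualitative regime of the real comparison emerges: the short
easy SARA index shows ceiling percentages in the tens of percent for
hospitals and frequent top-rank ties, the 52-item WHO index stays below
10% ceiling, and all volume correlations are positive.

What the generator does **not** emulate: multi-factor trait structure
(a single trait per tier with domain difficulty shifts is the simplest
structure consistent with a one-dimensional readiness construct;
interdomain correlations in real data are freer), survey sampling
design and regional clustering, informative missingness, response bias
in self-reported items, and the true item-overlap map between
frameworks. Passing tests therefore demonstrate the *pipeline's*
correctness and the direction of item-count/ceiling/tie effects, not
calibrated real-world magnitudes: on synthetic cohorts the first
principal component explains more variance (≈ 15–25%) than is typical
of real facility data, precisely because the generator is cleanly
unidimensional.

## Problem sizes and runtime choices

Test and acceptance runs use the defaults above: full 406-facility
cohorts for pipeline checks, 20 paired replicates for the regime
comparisons, n = 2000 × 10 items for the headline IRT recovery and
n = 500 vs 4000 × 6 items × 20 replicates for the recovery-improves-
with-n property. The EM fitter handles these in well under a second
each; the entire suite runs in seconds on one CPU.

## Known limitations

- Registry labels and domain splits are representative, not the
  verbatim instrument items; analyses that depend on specific item
  identities should replace the shipped YAML.
- PCA scores are cohort-relative (min–max within tier); they cannot be
  compared across cohorts or monitored over time without refitting.
- The 2PL fitter assumes a standard-normal trait per domain and
  conditional independence of items given the trait.
- Whether the original scores standardized items before PCA is an
  inference from the printed variance shares; the correlation-matrix
  choice is flagged for sensitivity analysis rather than certain.
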