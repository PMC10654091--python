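# Methods

This note records the statistical procedures implemented in vaxbiome,
the defaults and why they were chosen, what the synthetic cohort does
and does not emulate, and the numerical corner cases.

## Outcome construction

Titer processing runs outlier removal → classification → min-max
normalization → median composites.

* **Outlier rule.** A value is removed iff |v − mean| > 3·SD within its
  (antigen, time point) group, with mean and SD (sample SD, n−1
  denominator) computed once over the full group *including* the
  candidate. The pass is deliberately single-shot, not iterative: an
  iterative pass would keep shrinking the SD and remove further values,
  and the pipeline asserts it is applied exactly once. Groups of size 1
  are untestable and retained. The inequality is strict; a value
  exactly at the fence stays.
* **Classification.** LVR iff ≥ 4 of the six DTaP/Hib titers are
  strictly below threshold ("below" is strict; a titer exactly at
  threshold counts as protected). Classification uses the *measured*
  titers, not the outlier-filtered ones: the threshold rule is a
  per-subject criterion, and removing a population-level outlier can
  only destroy a decidable label. With missing antigens the label is
  LVR when ≥ 4 of the measured values are below threshold, NVR only
  when all six were measured, and `unknown` otherwise — missingness
  must not manufacture normal responders.
* **Normalization.** Min-max within (antigen, time point) preserves
  rank order and distribution shape while putting antigens with
  different units on one scale. A degenerate all-equal group maps to
  0.5 (midpoint keeps downstream medians unbiased) with a logged
  warning.
* **Composites.** Per-subject medians over available antigens: all 19
  (cross-vaccine), the 6 DTaP/Hib, the 13 PCV. A composite with no
  available antigens is missing, never imputed.

## Exposure model and testing

Cumulative oral exposure is the size of the union of exposed calendar
days from oral courses before the cutoff (day 365 by default), so
overlapping prescriptions never double count and the value cannot
exceed the cutoff. "Use at birth" means any systemic (oral/IM/IV)
course starting in days 0–7; the window width is a config knob since
"at birth" has no canonical bound. Topical courses are excluded from
all exposure variables.

The zero-inflated Poisson fit profiles π out analytically — at the MLE
the fitted zero mass equals the empirical zero fraction whenever
feasible, giving π̂(λ) = (p₀ − e^(−λ))/(1 − e^(−λ)) clipped to [0, 1] —
and maximizes the 1-D profile likelihood in λ by bounded scalar search
(tolerance 1e-10, upper bound 2× the positive-count mean). Data with
no zeros sit on the π = 0 boundary where λ̂ is the sample mean; all-zero
data are flagged degenerate (π → 1) rather than silently fit. The
two-group omnibus test refers 2·(ll_a + ll_b − ll_pooled) to χ²(2);
degenerate component fits flag the result. The post-hoc decomposition
uses Fisher exact on exposed/unexposed for the zero component and a
Wilcoxon rank-sum restricted to strictly positive counts for the count
component (the count-component test is a documented choice; nothing
deeper than "compare exposure intensity among the exposed" is implied).

**Hypothesis roster.** The default grouped screen tests 10 hypotheses:
cumulative oral days at 2 mo/4 mo/6 mo/1 yr (ZIP omnibus LRT between
responder groups), recent use within 7 days of the 2 mo/4 mo/6 mo
time points, current use at 2 mo/4 mo, and use at birth (all Fisher
exact on 2×2 tables). The roster is configuration, not dogma — the
grouped correction works for any grouping.

**Double FDR.** Stage 1 takes each group's minimum raw p as its
representative and BH-adjusts across groups; stage 2 BH-adjusts within
each group; the final adjusted p of a hypothesis is the maximum of its
within-group value and its group's stage-1 value. This guarantees
adjusted ≥ raw, collapses to plain BH for a single group, and controls
discovery at both levels. Decisions default to q = 0.1.

## Community metrics

Rarefaction subsamples without replacement (multivariate
hypergeometric draws from a seeded generator), drops samples below
depth, and conserves the depth exactly. Default depths are 10,000
reads for amplicon tables and 2.5 million for shotgun KO tables;
synthetic runs use 5,000 so that desk-scale tests stay fast — these
are stated problem sizes of the package's own test fixtures, not
recommendations for real data.

Shannon diversity uses log base 2 (bits); the base is configurable and
Pielou evenness H/log₂S is base-invariant. Evenness is undefined
(missing) at richness 1. Diversity formulas are evaluated through
scikit-bio; Bray-Curtis through scikit-bio's distance machinery.

Gene→KO aggregation divides a gene's count equally among its m mapped
KO groups (count/m each), conserving mapped mass to < 1e-9 per sample;
unmapped genes are dropped and tallied. Fractional KO counts are kept
as reals — downstream rank-based tests are scale-free, so re-rounding
would only lose information.

## Association screen

Samples map to nominal time points through closed age windows (2 mo =
[46, 75], 4 mo = [107, 137], 6 mo = [168, 198], 1 yr = [335, 395]
days); the windows are configuration with declared defaults, chosen to
sit halfway to the neighbouring well visits. With several samples of
one subject in a window, the one nearest the window center wins (ties
break to the earlier sample).

Categorical tests are Mann-Whitney U: exact two-sided p by full
enumeration of group relabelings for combined n ≤ 12 (tie-safe),
normal approximation with tie correction above. The approximation is
within 0.02 of the exact null for splits with both groups ≥ 4; for
extreme splits (1/11) the exact null is so coarse that gaps reach
~0.115 — which is exactly why the exact path exists at small n.
Continuous tests are Spearman's ρ with tie-aware ranks, pairwise
deletion of missing values, and a minimum of 4 complete pairs;
constant vectors yield a missing result rather than a number.

BH families are (assay × time point × outcome); family keys are
carried on every result row and never mixed. Nominal selection for
enrichment takes raw p < 0.05 from a single family, optionally
filtered by association sign (both pooled and signed modes exist
because enrichment inputs can reasonably be either).

## Enrichment

One-sided over-representation p: P(X ≥ k) for X ~ Hypergeom(N, K, n)
with N detected KOs, K of them in the module, n significant, k
significant in the module. Modules are intersected with the detected
universe first; modules with K < 5 are excluded before testing; BH
runs across exactly the modules tested. A significant set that is not
a subset of the detected universe raises — that situation always means
an upstream family mix-up. `gene_ratio` = k/n (module share of the
significant set); k/K is also emitted.

## Synthetic cohort

The generator emulates the *structure* of a two-year infant cohort:

* 101 subjects, 72 with year-1 titer assessment and 56 with year-2
  (both rates configurable), ~5% of assessed subjects missing the PCV
  panel;
* 19 log-normal titers with a block correlation matrix —
  intra-PCV 0.75, intra-DTaP/Hib 0.45, cross-block 0.25 by default
  (positive semi-definiteness is validated with an error naming the
  offending parameters);
* responder labels assigned *exactly* (round(n·rate) subjects, a
  stratified design choice that makes label arithmetic deterministic
  and keeps the empirical rate trivially inside any binomial band),
  then enforced by a closed loop that multiplicatively shifts a
  subject's six DTaP/Hib titers until the threshold classifier emits
  the intended label — labels therefore agree with the classifier by
  construction and leak into no feature except the planted ones;
* ZIP exposure days per responder group (defaults π = 0.47/0.50,
  λ = 10/28 days for NVR/LVR), realized as non-overlapping oral
  courses so the union-of-days variable equals the drawn total;
  at-birth course probabilities 2/60 and 3/12; topical/IM/IV courses
  at per-subject Poisson rates (0.55/0.07/0.07) chosen to give roughly
  a 74/20/3/3% course mix;
* well visits at days 7–730 with ±10-day jitter, 15% per-visit
  dropout and 85% per-assay capture;
* Dirichlet-multinomial count tables (concentration 200 around
  log-normal base abundances) at desk-scale depths;
* planted signals: the designated KO module's members get a
  log-abundance shift proportional to the subject's latent response
  score (the standardized mean per-antigen z-score of log titers at
  1 year). The shift per unit effect (constant 1.1) was calibrated
  once so the *realized* Spearman correlation with the cross-vaccine
  composite ≈ the configured Spearman-scale effect near |ρ| = 0.5;
  large configured effects saturate below 1 because the composite is
  itself a noisy readout of the latent score. One metabolite carries a
  signed effect the same way.

What it does **not** emulate: real taxonomic or functional abundance
distributions, per-antigen titer marginals of any actual cohort
(config-driven log-normals only), antibiotic indication/confounding,
breastfeeding or daycare covariates, batch effects, or sequencing
error. Passing recovery tests therefore demonstrates that the
*statistics* behave as specified under the declared generative model —
not that the pipeline would reach identical conclusions on any real
cohort.

All randomness flows from one root seed through named substreams per
stage (labels, titers, exposures, visits, each feature table,
metabolites, modules), so any single table is reproducible in
isolation and identical seeds give byte-identical files.

## Numerical choices and degenerate inputs

* Sample SD everywhere uses the n−1 denominator (small-group
  convention).
* ZIP LRT statistics are clipped at 0 (floating-point jitter around
  identical fits), and fits at boundaries are flagged, not hidden.
* Empty exposure logs skip the exposure stage with an explicit notice;
  the remaining stages complete.
* Empty cohorts (n = 0) write header-only tables.
* Mann-Whitney/Spearman with an empty group, constant input or too few
  pairs return missing results that are logged and excluded from BH
  families rather than propagated as numbers.

## Problem sizes of the shipped checks

The package's own test battery uses: ZIP parameter recovery at
n = 5000 (20 replicates), LRT null calibration over 1000 simulations
at n = 30 per group, power over 200 simulations at n = 36 vs 6,
exhaustive Fisher-vs-enumeration over all 135,750 2×2 tables with
total ≤ 40, planted-module recovery over 20 replicate cohorts of 72
subjects (~60 complete cases at the 2-month window), and Monte-Carlo
rarefaction means over several hundred seeds. These sizes are the
package's declared experimental conditions for its own validation.
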