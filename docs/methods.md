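# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the design decisions behind `sizerange`, in the spirit of a
statistical software methods appendix.

## The response and its data model

The unit of observation is a *reported maximum size*: the largest linear
dimension (length, height, width, or diameter) published for a species by
one source. All sizes are converted to centimetres at ingest (μm ×10⁻⁴,
mm ×0.1, m ×100) and all logarithms are base 10. A species enters the
analysis only with at least two reports; species with one report are
excluded with a logged warning. **No quality control is applied at ingest** —
duplicated identical reports count toward the report count, and implausible
values are kept — because quantifying and flagging errors downstream is the
point of the pipeline, and silent cleaning would bias every estimate of
reporting variation.

Per species the pipeline records the smallest, largest and mean reported
maximum, the report count and its four-level categorisation (2, 3, 4–5, ≥6),
and the range statistic

    maxsize_range = log10(largest) − log10(smallest)   [orders of magnitude],

set to exactly 0 (no log round-off) when all reports are equal. The
**species mean** defaults to the arithmetic mean of log10 sizes — the
geometric mean on the raw scale — because every downstream analysis operates
on the log scale; a `mean_mode="raw_arithmetic"` switch gives the plain
arithmetic mean instead.

The four-level count categorisation exists because report counts are
extremely skewed (median 2); treating count as continuous makes the high
tail dominate the interaction terms.

Magnitude classes are disjoint half-open bins — zero, (0, 0.5), [0.5, 1),
[1, 2], and strictly >2 — with cumulative counts (>0.5, >1, >2) reported
alongside so either bin convention can be audited.

Habitat is collapsed to benthic / pelagic / unspecified; unknown or missing
tokens map to unspecified. The invertebrate flag defaults to
`phylum != Chordata` (overridable by an explicit column), matching the
skeletal composition of the modelled phyla.

## The gamma hurdle regression

`maxsize_range` is zero for roughly 38% of species and strictly positive,
heavily right-skewed otherwise. The hurdle model factorises the likelihood
into a binomial (logit) component for whether the range is non-zero, fit to
all species, and a gamma (log link) component for the positive magnitudes,
fit to the positive subset. Because the likelihood factorises exactly, the
two components are maximised independently and the total log-likelihood is
their sum; the suite asserts this factorisation numerically.

**Orientation.** The zero component internally models P(range > 0), so a
positive coefficient means *more* variation. Reports emit both orientations
(P(nonzero) and P(zero), signs flipped) with explicit labels, since
published coefficient tables for this kind of model are often printed in the
opposite orientation and silent sign conventions are a classic source of
misreading.

**Fitting.** The logistic component is fit by Newton scoring (IRLS) with
step-halving on likelihood decrease; convergence requires the maximum
absolute score below 1e-8, with a guard flagging complete separation when
any coefficient passes magnitude 30 on the logit scale. For the gamma
component, the mean-coefficient score α·Xᵀ(y/μ − 1) does not involve the
shape, so β is fit by Fisher scoring first; the shape α then solves
log α − ψ(α) = mean(y/μ − log(y/μ)) − 1 by Newton steps (ψ the digamma
function). The shape is full maximum likelihood, *not* a moment or deviance
estimator, and is counted as one parameter — once for the whole hurdle — in
the AICc bookkeeping, giving k = 2·26 + 1 = 53 for the largest predictor
set. A zero-variance response drives the shape past a guard of 1e8 and
flags non-convergence rather than raising. The expected information is
block-diagonal in (β, α), which supplies the covariance for Wald tests.
Near the optimum the likelihood can be flat at float precision while the
score still shrinks, so iteration continues as long as step-halving finds
any acceptable step; this is what lets the score identities hold to 1e-6
in the tests.

**Model competition.** Seven predictor sets are competed:
phylum+habitat, phylum, skeleton+habitat, invertebrate+habitat, habitat,
skeleton, invertebrate — each with log10(smallest), count class, and the
interactions of log10(smallest) with every factor, identically in both
components. Phylum, skeleton, and invertebrate status are highly collinear
(skeletal type is essentially conserved within phyla), which is why they are
never combined in one model. AICc uses n = the number of species entering
the zero component. Comparing fits on different species sets is an error.

**Reference levels.** Treatment coding against count class 2, phylum
Annelida, habitat benthic (configurable). When a conventional default
reference is absent from a (filtered or simulated) cohort, the first
lexicographic observed level is used instead; an *explicitly* configured
reference that is unobserved is an error.

**Post hoc comparisons.** Estimated marginal means cross the requested
factors' levels, average non-requested factors with equal weights, and hold
continuous covariates at their observed mean (overridable). Standard errors
follow from the component covariance by the delta rule. All pairwise
contrasts are Tukey-adjusted via the studentized-range distribution with
infinite degrees of freedom: p = P(Q_{m,∞} ≥ |z|·√2), which reduces to the
unadjusted two-sided normal p at m = 2. Wald flags are reported at 0.05 and
at a stricter multiplicity-corrected threshold whose default, 0.009, is
treated as configurable data rather than derived, since the appropriate
Bonferroni divisor depends on how many model terms one counts.

## Distribution-level analyses

* **Largest-vs-smallest OLS** on log10 scale with a t test of the slope
  against 1 (n − 2 df); a slope below 1 means proportionally more reporting
  variation in smaller species. With an exact fit the test is degenerate and
  the t ratio is reported as 0 (or ±∞ if the slope differs from the null).
* **D'Agostino (1970) skewness test**: biased moment skewness
  g1 = m₃/m₂^{3/2} and its normalizing transformation to z. The
  transformation is evaluated directly (not via a library call) so that an
  exactly symmetric sample maps to z = 0; library implementations commonly
  substitute y = 1 when y = 0, which is a hidden discontinuity at the null.
* **Two-sample KS** with ties handled by evaluating at all pooled jump
  points and the asymptotic p (sample sizes here are in the thousands;
  exact small-sample enumeration is used only as a test oracle).
* **Centered-variance F test**: both samples mean-centered (literally the
  sample mean, not a robust centre), F = s²_a/s²_b, two-sided p by doubling
  the smaller F tail.
* **Spearman correlation** as Pearson on average-tie ranks.
* **Taxonomic hierarchy**: at genus/family/order level the range is the
  log10 ratio of the largest to smallest member species' size, using
  `maxsize_largest` as the species size metric by default (comparing the
  "largest and smallest species" most naturally compares their maxima;
  switchable to the species mean); single-species taxa are excluded.
  Because taxa only merge going up the hierarchy, mean ranges are
  necessarily non-decreasing from genus to order — asserted as a property
  test, and the quantitative intra- vs inter-specific gap is the scientific
  result.

## Rank-stability randomization

Each randomization draws one reported maximum per species, uniformly over
that species' recorded reports *including duplicates* (duplicates encode how
often a value is reported; a `distinct_only` switch draws over unique values
instead), ranks species ascending with average ranks for ties, and compares
two independent rankings per pair by Spearman rho and by per-species
absolute rank displacement. 1000 pairs by default, a single seeded
generator per call, bitwise reproducible. The species attaining the maximum
displacement is recorded per pair (ties broken by lowest species id; pairs
in which nothing moves record no mover), and `top_movers` sorts species by
times-largest-mover then mean displacement. The two rankings of a pair are
drawn independently — "pairs of rankings" read literally — rather than by a
leave-one-out scheme.

## The synthetic-cohort generator

The generator is the package's stand-in for the study conditions, with full
ground truth. Its species-level process **is** the hurdle model: covariates
drawn from stated frequencies, P(range > 0) = inverse-logit of a linear
predictor, positive ranges Gamma(shape, mean = exp(linear predictor)).
Measurement records then realise each species' range exactly — one report at
the true maximum, one at the bottom of the range, extras uniform on the
log10 interval — so that re-summarising the records reproduces the
generator's own truth to 1e-12 when error injection is off (asserted).
Reports are written in a natural unit for each species' scale (μm/mm/cm/m),
exercising unit conversion on every round trip.

The **default study-condition preset** (versioned YAML shipped with the package) fixes
the study conditions: phylum and habitat frequencies proportional to the
published per-phylum species tallies (eight phyla, Chordata and Mollusca
dominating); count classes 60/24/13.2/2.8% giving a median count of 2 and
2.8% of species above 5 reports; log10(smallest) normal with mean 0.60 and
sd 0.895 (the published minimum-size distribution moments); zero-component
slopes taken from the published zero-inflation coefficient table in the
P(nonzero) orientation, with the intercept calibrated once, numerically, so
the marginal zero fraction is ≈ 0.38; conditional-component coefficients
chosen to match the qualitative published pattern (range decreasing in
size, increasing in report count, highest in Annelida/Cnidaria/
Echinodermata, lowest in Nematoda and pelagic species) with the intercept
set so the magnitude-class prevalences land in the reported regime (~5% of
species above half an order, ~1% above one order); gamma shape 1.2 (strong
right skew); gross-error rates 0.2% unit slips and 0.1% colony-vs-module
confusions, putting ~0.2% of species above two orders — the reported
prevalence of extreme ranges.

Injected errors multiply one report by 10/100/1000 (either direction; unit
slips) or divide one report by 10^U(2, 3.5) (zooid-vs-colony), and are
recorded in a ground-truth ledger with the resulting range, enabling recall
scoring of the extreme-range flag.

**What the generator does not emulate:** correlation between covariates
(real phyla have strongly habitat- and size-structured memberships — drawn
independently here), phylogenetic correlation among species, source-level
effects (the same database mis-reporting many species), and real taxonomies
(the synthetic order/family/genus nesting is balanced and arbitrary).
Passing tests therefore demonstrate correctness of the estimators and the
pipeline under the stated generating process, not robustness to the full
messiness of real compilations. At the default scale (5000 species vs the
study's ~27,000) sample-size-dependent statistics — skewness z, rank
displacement counts — are proportionally smaller; the suite and the
acceptance script use this scale to keep full runs in seconds.

## Extreme-range audit

Every species is classified into the magnitude bins; species above two
orders form the hand-check shortlist. Advisory cause tags: a
largest/smallest ratio within 5% of a power of ten (≥10) suggests a unit
slip; a >2-order range with at least three reports all clustered within
half an order of the bottom except a single large outlier suggests
colony-vs-module confusion; everything else is `unknown`. A
width-vs-length tag exists in the vocabulary but is never auto-assigned —
distinguishing it from genuine shape variation needs morphology the table
does not carry. Tags are annotations only; no record is ever dropped, and
tallies are recomputable from the written per-species table (asserted).

## Pipeline and reproducibility

`run_pipeline` executes ingest (or simulation) → summaries → ≥100-species
phylum filter → model competition → post hoc contrasts → distribution tests
→ hierarchy → rank stability → audit, writing CSV/JSON outputs and a
manifest (config hash, seed, stage row counts). Reruns with the same config
and seed are bitwise identical in all non-timestamp outputs; no output
depends on iteration order of unordered containers (species are always
processed in sorted-id order). Any stage error halts the run with the stage
identity, preserving earlier outputs.

## Known limitations

* The hurdle fitters assume a dense design; no sparse or very-wide support.
* The Tukey adjustment uses infinite-df studentized range (appropriate at
  these sample sizes), not finite-df.
* The KS p-value is asymptotic; do not trust it below a few dozen
  observations per sample.
* The generator's covariate independence means collinearity diagnostics on
  synthetic cohorts are optimistic relative to real data.
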