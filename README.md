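# sizerange

**Auditing intraspecific variation in reported maximum body sizes of marine
metazoans.**

Trait databases routinely carry several published "maximum size" values for
the same species — holotype measurements, regional inventories, secondary
compilations — and these reports can disagree by anything from rounding noise
to three orders of magnitude (a unit slip, or a bryozoan colony recorded
alongside a single zooid). `sizerange` implements, as a tested and reusable
pipeline, the statistical audit of that variation: how big it is, what
predicts it, and how much it matters for comparative macroecology. It is
aimed at researchers who assemble or consume large body-size compilations and
want to quantify — rather than hand-vet — the reliability of a single
"maximum size per species" number.

## The statistics at the core

For a species with reported maxima $x_1, \dots, x_n$ (cm, largest linear
dimension, $n \ge 2$), the range statistic is

$$\text{maxsize}_{range} = \log_{10}(\text{maxsize}_{largest}) - \log_{10}(\text{maxsize}_{smallest}),$$

measured in orders of magnitude and exactly zero when all reports agree.
Across species this response is zero-inflated (~38% of species) and heavily
right-skewed, so it is modelled with a **zero-inflated gamma hurdle
regression**:

* **zero component** — binomial GLM, logit link, for $P(\text{range} > 0)$,
  fit to all species;
* **conditional component** — gamma GLM, log link, for the positive ranges
  only, with shape estimated by full maximum likelihood.

Both components share the predictor set
`log10(smallest) + count class + variable + interactions with log10(smallest)`,
where `variable` is phylum, habitat, skeleton, or invertebrate status (alone
or with habitat). Candidate models are competed by **AICc**
($-2\ell + 2k + 2k(k+1)/(n-k-1)$, the gamma shape counted once), and post hoc
group comparisons use **estimated marginal means with Tukey-adjusted
pairwise contrasts** (studentized-range tail, infinite df).

Around the regression sit the cohort-level audits: largest-vs-smallest OLS
with a slope-versus-1 t test, D'Agostino skewness tests, KS / centered-F /
Spearman comparisons of the minimum/mean/maximum size distributions,
intra- versus interspecific ranges up the taxonomic hierarchy, a
**rank-stability randomization** (1000 pairs of rankings, each drawing one
reported maximum per species), and magnitude-class flagging of extreme
species with advisory cause tags.

Because the deposited compilation is external, the package ships a
**synthetic-cohort generator** whose default preset reproduces the study
conditions (zero fraction ≈ 0.38, covariate frequencies proportional to the
published per-phylum tallies, median report count 2, rare injected gross
errors) with full ground truth, so every stage runs — and is tested —
without a download.

## Worked example

```bash
python analysis/01_simulate_cohort.py 1   # seed 1
python analysis/02_summarize_sizes.py
python analysis/03_fit_hurdle_models.py
python analysis/05_rank_stability.py 1
```

which prints (abridged):

```
wrote 13408 measurement records for 5000 species to results/cohort
  zero-variation fraction: 0.376
...
AICc model competition:
               model  df        aicc  delta_aicc
      phylum+habitat  53 2891.632774    0.000000
    skeleton+habitat  33 2961.270514   69.637740
...
best model: phylum+habitat (k=53, gamma shape=1.122)
...
rank stability over 1000 ranking pairs (5000 species):
  mean Spearman rho:            0.9828
  median rank displacement:     11 places
```

Reading: the predictor set with phylum and habitat (plus size, count class,
and size interactions; 53 parameters across the two hurdle components) wins
the AICc competition decisively, and the across-species body-size ranking is
almost indifferent to which report is drawn per species — the typical
species moves ~11 rank places out of 5000, while species carrying gross
reporting errors move thousands.

The same stages are available as a CLI
(`sizerange simulate|summarize|fit|compare|distributions|hierarchy|rank-stability|audit|run`)
and as library functions (`sizerange.hurdle_glm.fit_hurdle`,
`sizerange.rank_stability.rank_stability`, ...).

## Layout

```
src/sizerange/        library: trait_table, synthetic_cohort, hurdle_glm,
                      distribution_tests, rank_stability, audit, cli
analysis/             numbered narrative drivers writing under results/
tests/                pytest suite (unit, property, and acceptance tests)
scripts/acceptance.py headline-quantity recomputation
docs/methods.md       model, generator, and design documentation
```
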