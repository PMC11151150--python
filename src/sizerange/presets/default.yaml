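# Default synthetic cohort preset (version 1).
#
# Covariate frequencies are proportional to the study's per-phylum and
# per-habitat species tallies; report-count classes give a median count of 2
# and ~2.8% of species with more than 5 reports.  The zero component is on
# the logit scale for P(range > 0) with slopes matching the magnitude and
# sign structure of the fitted zero-inflation model (size, count, phylum and
# habitat effects plus size interactions); its intercept is calibrated so the
# marginal zero-range fraction is ~0.38.  The conditional component mean
# (log scale) makes positive ranges small on average (~0.2 orders of
# magnitude, putting roughly 5% of species above half an order and 1-2%
# above a full order), decreasing in size, increasing in report count,
# highest in Annelida/Cnidaria/Echinodermata and lowest in Nematoda and
# pelagic species.
# Gross-error rates put roughly 0.2% of species off by a decade or more.

phylum_freqs:
  Annelida: 0.013897
  Arthropoda: 0.095376
  Bryozoa: 0.008691
  Chordata: 0.479630
  Cnidaria: 0.025925
  Echinodermata: 0.008581
  Mollusca: 0.343478
  Nematoda: 0.024422

habitat_freqs:
  benthic: 0.770819
  pelagic: 0.195666
  unspecified: 0.033515

count_class_freqs:
  c2: 0.600
  c3: 0.240
  c4_5: 0.132
  c6plus: 0.028

log10_smallest_dist: [0.601, 0.895]

zero_coefs:
  intercept: 1.610
  log10_smallest: -0.61
  count_class[c3]: 0.34
  count_class[c4_5]: 0.60
  count_class[c6plus]: 0.97
  phylum[Arthropoda]: -1.38
  phylum[Bryozoa]: -0.54
  phylum[Chordata]: -0.91
  phylum[Cnidaria]: -0.27
  phylum[Echinodermata]: 0.10
  phylum[Mollusca]: -0.92
  phylum[Nematoda]: -1.96
  habitat[pelagic]: -0.53
  habitat[unspecified]: 0.31
  log10_smallest:count_class[c3]: 0.03
  log10_smallest:count_class[c4_5]: 0.08
  log10_smallest:count_class[c6plus]: 0.03
  log10_smallest:phylum[Arthropoda]: 0.21
  log10_smallest:phylum[Bryozoa]: -0.36
  log10_smallest:phylum[Chordata]: 0.10
  log10_smallest:phylum[Cnidaria]: 0.11
  log10_smallest:phylum[Echinodermata]: -0.34
  log10_smallest:phylum[Mollusca]: 0.14
  log10_smallest:phylum[Nematoda]: 0.28
  log10_smallest:habitat[pelagic]: 0.41
  log10_smallest:habitat[unspecified]: 0.0

cond_coefs:
  intercept: -1.05
  log10_smallest: -0.15
  count_class[c3]: 0.10
  count_class[c4_5]: 0.20
  count_class[c6plus]: 0.35
  phylum[Arthropoda]: -0.50
  phylum[Bryozoa]: 0.30
  phylum[Chordata]: -0.60
  phylum[Cnidaria]: -0.05
  phylum[Echinodermata]: -0.05
  phylum[Mollusca]: -0.50
  phylum[Nematoda]: -0.90
  habitat[pelagic]: -0.40
  habitat[unspecified]: 0.30
  log10_smallest:count_class[c3]: 0.02
  log10_smallest:count_class[c4_5]: 0.03
  log10_smallest:count_class[c6plus]: 0.05
  log10_smallest:phylum[Arthropoda]: -0.10
  log10_smallest:phylum[Bryozoa]: -0.15
  log10_smallest:phylum[Chordata]: 0.10
  log10_smallest:phylum[Cnidaria]: 0.05
  log10_smallest:phylum[Echinodermata]: -0.10
  log10_smallest:phylum[Mollusca]: 0.08
  log10_smallest:phylum[Nematoda]: 0.12
  log10_smallest:habitat[pelagic]: 0.15
  log10_smallest:habitat[unspecified]: -0.15

gamma_shape: 1.2

unit_factor_rate: 0.002
colony_factor_rate: 0.001
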