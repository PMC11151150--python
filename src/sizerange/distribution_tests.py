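"""Distribution-level comparisons of species size summaries.

These are the cohort-wide analyses: the largest-versus-smallest reported
maximum regression with a slope-versus-one test, skewness tests on the range
statistic, and pairwise comparisons (Kolmogorov-Smirnov, centered-variance F,
Spearman) of the per-species minimum/mean/maximum size distributions, plus
the intra- versus interspecific range comparison across taxonomic levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trait_table import SpeciesAnnotation, SpeciesSizeSummary, _as_annotation_map

__all__ = [
    "SlopeTestResult",
    "DistributionComparison",
    "TaxonLevel",
    "TaxonRange",
    "ols_slope_test",
    "dagostino_skewness_test",
    "ecdf",
    "ks_two_sample",
    "variance_ratio_test_centered",
    "spearman",
    "compare_size_distributions",
    "taxon_interspecific_ranges",
]


@dataclass(frozen=True)
class SlopeTestResult:
    """OLS fit with a t test of the slope against a null value."""

    slope: float
    intercept: float
    se_slope: float
    null_slope: float
    t_ratio: float
    df: int
    p_value: float
    adj_r2: float


def ols_slope_test(x, y, null_slope: float = 1.0) -> SlopeTestResult:
    """Ordinary least squares of y on x with a slope-vs-null t test.

    The t ratio is (slope - null_slope) / se(slope) on n - 2 degrees of
    freedom, two-sided.  Adjusted R^2 uses the standard small-sample
    correction 1 - (1 - R^2)(n - 1)/(n - 2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("x is constant; slope undefined")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - intercept - slope * x
    df = n - 2
    sigma2 = float(resid @ resid) / df
    se_slope = math.sqrt(sigma2 / sxx)
    if se_slope == 0.0:  # exact fit: the test is degenerate
        t = 0.0 if slope == null_slope else math.copysign(math.inf, slope - null_slope)
    else:
        t = (slope - null_slope) / se_slope
    p = float(2 * stats.t.sf(abs(t), df))
    syy = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / syy if syy > 0 else float("nan")
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df
    return SlopeTestResult(slope, intercept, se_slope, null_slope, t, df, p, adj_r2)


def dagostino_skewness_test(values) -> tuple[float, float, float]:
    """Sample skewness with the D'Agostino (1970) normality z test.

    Returns (g1, z, two-sided p) where g1 = m3 / m2^(3/2) is the biased
    moment skewness and z its normalizing transformation.  The
    transformation is evaluated directly so that an exactly symmetric sample
    yields z = 0 (a perfectly-symmetric input is mapped to the null's
    centre, with no zero-guard substitution).
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 9:
        raise ValueError("skewness z transformation requires n >= 9")
    if np.all(v == v[0]):
        raise ValueError("constant sample: skewness undefined")
    g1 = float(stats.skew(v, bias=True))
    y = g1 * math.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = (
        3.0 * (n**2 + 27 * n - 70) * (n + 1) * (n + 3)
        / ((n - 2) * (n + 5) * (n + 7) * (n + 9))
    )
    w2 = -1.0 + math.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / math.sqrt(math.log(math.sqrt(w2)))
    alpha = math.sqrt(2.0 / (w2 - 1.0))
    z = delta * math.asinh(y / alpha)
    p = float(2 * stats.norm.sf(abs(z)))
    return g1, float(z), p


def ecdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF: sorted unique support and fractions.

    Returns (support, F) with F[i] the fraction of the sample <= support[i];
    F reaches exactly 1 at the sample maximum.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    support, counts = np.unique(v, return_counts=True)
    return support, np.cumsum(counts) / v.size


def ecdf_at(values, query) -> np.ndarray:
    """Evaluate the ECDF of a sample at arbitrary query points."""
    v = np.sort(np.asarray(values, dtype=float))
    return np.searchsorted(v, np.asarray(query, dtype=float), side="right") / v.size


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p).

    D is the supremum of |ECDF_a - ECDF_b| over the pooled support; ties are
    handled by evaluating at every pooled jump point.  The p-value uses the
    asymptotic Kolmogorov distribution with effective sample size
    n_a n_b / (n_a + n_b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def variance_ratio_test_centered(a, b) -> tuple[float, float]:
    """F test for equal variances on mean-centered samples.

    F = s_a^2 / s_b^2 with n-1 denominators; the two-sided p doubles the
    smaller tail of F_(n_a-1, n_b-1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per sample")
    va = float(np.var(a - a.mean(), ddof=1))
    vb = float(np.var(b - b.mean(), ddof=1))
    if va == 0 or vb == 0:
        raise ValueError("zero variance in a sample; F undefined")
    F = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    p = 2.0 * min(stats.f.cdf(F, dfa, dfb), stats.f.sf(F, dfa, dfb))
    return F, float(min(p, 1.0))


def spearman(a, b) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties, t-approximation p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("constant ranks: correlation undefined")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


@dataclass(frozen=True)
class DistributionComparison:
    """All pairwise statistics between two size distributions."""

    label_a: str
    label_b: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    ks_D: float
    ks_p: float
    f_stat: float
    f_p: float
    spearman_rho: float
    spearman_p: float


def compare_size_distributions(
    summaries: Sequence[SpeciesSizeSummary],
) -> list[DistributionComparison]:
    """Compare the log10 smallest/mean/largest maximum-size distributions.

    Produces the three pairwise comparisons (mean vs minimum, mean vs
    maximum, minimum vs maximum) across species, each with KS, centered-F and
    Spearman statistics plus per-sample mean (sd).
    """
    if not summaries:
        raise ValueError("no summaries to compare")
    cols = {
        "minimum": np.array([s.log10_smallest for s in summaries]),
        "mean": np.array([s.log10_mean for s in summaries]),
        "maximum": np.array([s.log10_largest for s in summaries]),
    }
    pairs = [("mean", "minimum"), ("mean", "maximum"), ("minimum", "maximum")]
    out = []
    for la, lb in pairs:
        a, b = cols[la], cols[lb]
        if np.array_equal(a, b):
            D, ks_p = 0.0, 1.0
            F, f_p = 1.0, 1.0
            rho, s_p = 1.0, 0.0
        else:
            D, ks_p = ks_two_sample(a, b)
            F, f_p = variance_ratio_test_centered(a, b)
            rho, s_p = spearman(a, b)
        out.append(
            DistributionComparison(
                label_a=la,
                label_b=lb,
                mean_a=float(a.mean()),
                sd_a=float(a.std(ddof=1)),
                mean_b=float(b.mean()),
                sd_b=float(b.std(ddof=1)),
                ks_D=D,
                ks_p=ks_p,
                f_stat=F,
                f_p=f_p,
                spearman_rho=rho,
                spearman_p=s_p,
            )
        )
    return out


class TaxonLevel(str, Enum):
    ORDER = "order"
    FAMILY = "family"
    GENUS = "genus"
    SPECIES = "species"


@dataclass(frozen=True)
class TaxonRange:
    """Size range (orders of magnitude) within one taxon at one level."""

    taxon: str
    level: TaxonLevel
    n_members: int
    range: float


def taxon_interspecific_ranges(
    summaries: Sequence[SpeciesSizeSummary],
    annotations,
    level: TaxonLevel | str,
    metric: str = "maxsize_largest",
) -> list[TaxonRange]:
    """Within-taxon size ranges at a taxonomic level.

    At order/family/genus level the range is the log10 ratio of the largest
    to the smallest member species' size (interspecific); taxa with fewer
    than two species are excluded.  At species level it returns each species'
    own intraspecific maxsize_range.  ``metric`` selects the species size
    used for interspecific ranges (``maxsize_largest`` by default, or
    ``maxsize_mean``).
    """
    level = TaxonLevel(level)
    if metric not in ("maxsize_largest", "maxsize_mean"):
        raise ValueError(f"unknown species size metric {metric!r}")
    if level is TaxonLevel.SPECIES:
        return [
            TaxonRange(taxon=str(s.aphia_id), level=level, n_members=1, range=s.maxsize_range)
            for s in summaries
        ]
    ann = _as_annotation_map(annotations)
    attr = {"order": "order_", "family": "family_", "genus": "genus"}[level.value]
    groups: dict[str, list[float]] = {}
    for s in summaries:
        a = ann.get(s.aphia_id)
        if a is None:
            raise KeyError(f"species {s.aphia_id} has no annotation")
        taxon = getattr(a, attr)
        if taxon is None:
            raise ValueError(f"annotation for species {s.aphia_id} lacks the {level.value} level")
        groups.setdefault(taxon, []).append(getattr(s, metric))
    out = []
    for taxon in sorted(groups):
        sizes = groups[taxon]
        if len(sizes) < 2:
            continue
        out.append(
            TaxonRange(
                taxon=taxon,
                level=level,
                n_members=len(sizes),
                range=math.log10(max(sizes)) - math.log10(min(sizes)),
            )
        )
    return out
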