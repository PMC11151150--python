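"""Zero-inflated gamma hurdle regression for the size-range statistic.

The response maxsize_range is zero for a large fraction of species (many
species have identical reported maxima) and strictly positive, heavily
right-skewed otherwise.  A hurdle model factorises the likelihood into

* a **zero component**: binomial GLM with logit link for the probability
  that a species has a *non-zero* range, fit to all species, and
* a **conditional component**: gamma GLM with log link for the magnitude of
  the range, fit to the positive-range species only,

with identical predictor sets on both sides.  Because the likelihood
factorises, the two components are maximised independently; the total
log-likelihood is their sum.  The gamma shape is estimated by full maximum
likelihood and counted as one parameter in the AICc.

Orientation note: the zero component here models P(range > 0).  Reports can
be read in either orientation by flipping coefficient signs; reporters emit
both labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, expit, gammaln, polygamma
from scipy.stats import norm, studentized_range

from .trait_table import SpeciesAnnotation, SpeciesSizeSummary, _as_annotation_map

__all__ = [
    "ModelSpec",
    "DesignMatrix",
    "ComponentFit",
    "HurdleFit",
    "EmmResult",
    "ContrastResult",
    "covariate_frame",
    "build_design",
    "fit_logistic",
    "fit_gamma_loglink",
    "fit_hurdle",
    "aicc",
    "compare_models",
    "estimated_marginal_means",
    "pairwise_contrasts",
    "marginal_effect_curves",
    "CANDIDATE_SPECS",
    "hurdle_report",
]

#: default reference levels: the levels absent from the fitted-coefficient lists
DEFAULT_REFERENCES = {
    "count_class": "c2",
    "phylum": "Annelida",
    "habitat": "benthic",
    "skeleton": "none",
    "invertebrate": "False",
}

_COEF_GUARD = 30.0  # logit-scale magnitude beyond which separation is declared
_MAX_ITER = 200
_SCORE_TOL = 1e-8


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model formula: response ~ continuous + factors + interactions."""

    response: str = "maxsize_range"
    continuous_terms: tuple[str, ...] = ("log10_smallest",)
    factor_terms: tuple[str, ...] = ()
    interaction_terms: tuple[tuple[str, str], ...] = ()
    reference_levels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for cont, fact in self.interaction_terms:
            if cont not in self.continuous_terms:
                raise ValueError(f"interaction references undeclared continuous term {cont!r}")
            if fact not in self.factor_terms:
                raise ValueError(f"interaction references undeclared factor {fact!r}")

    def reference_for(self, factor: str) -> str | None:
        return {**DEFAULT_REFERENCES, **self.reference_levels}.get(factor)


def standard_spec(*factors: str, count: bool = True) -> ModelSpec:
    """The study's standard formula: range ~ log10_smallest + count + factors
    + log10_smallest:count + log10_smallest:each factor."""
    facts = (("count_class",) if count else ()) + tuple(factors)
    return ModelSpec(
        factor_terms=facts,
        interaction_terms=tuple(("log10_smallest", f) for f in facts),
    )


#: the candidate predictor sets competed by AICc
CANDIDATE_SPECS: dict[str, ModelSpec] = {
    "phylum+habitat": standard_spec("phylum", "habitat"),
    "phylum": standard_spec("phylum"),
    "skeleton+habitat": standard_spec("skeleton", "habitat"),
    "invertebrate+habitat": standard_spec("invertebrate", "habitat"),
    "habitat": standard_spec("habitat"),
    "skeleton": standard_spec("skeleton"),
    "invertebrate": standard_spec("invertebrate"),
}


@dataclass(frozen=True)
class DesignMatrix:
    """Dense design matrix with treatment-coded factors and metadata."""

    X: np.ndarray
    columns: tuple[str, ...]
    species_ids: tuple[int, ...]
    factor_levels: Mapping[str, tuple[str, ...]]  # observed levels, reference first
    spec: ModelSpec

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]


def covariate_frame(
    summaries: Sequence[SpeciesSizeSummary],
    annotations,
) -> pd.DataFrame:
    """Assemble the per-species covariate table used by every model."""
    ann = _as_annotation_map(annotations)
    rows = []
    for s in summaries:
        a = ann[s.aphia_id]
        rows.append(
            {
                "aphia_id": s.aphia_id,
                "maxsize_range": s.maxsize_range,
                "log10_smallest": s.log10_smallest,
                "count_class": s.count_class.value,
                "phylum": a.phylum,
                "habitat": a.habitat.value,
                "skeleton": a.skeleton.value,
                "invertebrate": str(a.is_invertebrate),
            }
        )
    return pd.DataFrame(rows)


def build_design(data: pd.DataFrame, spec: ModelSpec) -> DesignMatrix:
    """Build the treatment-coded design matrix for a model spec.

    Column order is deterministic: intercept, continuous terms in spec order,
    then each factor's non-reference levels in plain lexicographic order, then
    interaction columns (continuous value times factor dummy) last.
    """
    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    factor_levels: dict[str, tuple[str, ...]] = {}
    dummies: dict[str, list[tuple[str, np.ndarray]]] = {}

    for term in spec.continuous_terms:
        cols.append(np.asarray(data[term], dtype=float))
        names.append(term)

    for factor in spec.factor_terms:
        values = data[factor].astype(str)
        observed = sorted(values.unique())
        if len(observed) < 2:
            raise ValueError(f"factor {factor!r} is constant (single level {observed})")
        if factor in spec.reference_levels:
            ref = spec.reference_levels[factor]
            if ref not in observed:
                raise ValueError(
                    f"reference level {ref!r} for factor {factor!r} not observed "
                    f"(observed: {observed})"
                )
        else:
            # conventional default reference, falling back to the first
            # observed level when the conventional one is absent
            ref = DEFAULT_REFERENCES.get(factor)
            if ref not in observed:
                ref = observed[0]
        levels = [ref] + [lv for lv in observed if lv != ref]
        factor_levels[factor] = tuple(levels)
        dummies[factor] = []
        for lv in levels[1:]:
            d = (values == lv).to_numpy(dtype=float)
            cols.append(d)
            names.append(f"{factor}[{lv}]")
            dummies[factor].append((lv, d))

    for cont, factor in spec.interaction_terms:
        x = np.asarray(data[cont], dtype=float)
        for lv, d in dummies[factor]:
            cols.append(x * d)
            names.append(f"{cont}:{factor}[{lv}]")

    return DesignMatrix(
        X=np.column_stack(cols),
        columns=tuple(names),
        species_ids=tuple(int(i) for i in data["aphia_id"]),
        factor_levels=factor_levels,
        spec=spec,
    )


@dataclass(frozen=True)
class ComponentFit:
    """One GLM component: coefficients, covariance, log-likelihood."""

    coefs: np.ndarray
    vcov: np.ndarray
    loglik: float
    converged: bool
    columns: tuple[str, ...]
    n_iter: int
    shape: float | None = None  # gamma shape; None for the binomial component
    shape_se: float | None = None

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))


def fit_logistic(design: DesignMatrix, is_nonzero: np.ndarray) -> ComponentFit:
    """Logistic regression by Newton scoring (IRLS).

    Converges when the max absolute score falls below 1e-8.  Coefficients
    diverging past magnitude
    30 on the logit scale flag non-convergence (complete separation) rather
    than returning silently.
    """
    X = design.X
    y = np.asarray(is_nonzero, dtype=float)
    if y.min() == y.max():
        raise ValueError("need at least one success and one failure")
    n, k = X.shape
    beta = np.zeros(k)
    ll = _logistic_ll(X, y, beta)
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        p = expit(X @ beta)
        score = X.T @ (y - p)
        w = p * (1 - p)
        info = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # step-halving on likelihood decrease
        beta, ll, moved = _half_steps(lambda b: _logistic_ll(X, y, b), beta, step, ll)
        if np.max(np.abs(beta)) > _COEF_GUARD:
            converged = False
            break
        score_norm = np.max(np.abs(X.T @ (y - expit(X @ beta))))
        if score_norm < _SCORE_TOL:
            converged = True
            break
        if not moved:
            # no acceptable step remains: numerically stationary
            converged = score_norm < 1e-6
            break
    p = expit(X @ beta)
    w = np.clip(p * (1 - p), 1e-12, None)
    info = X.T @ (X * w[:, None])
    vcov = np.linalg.pinv(info)
    return ComponentFit(
        coefs=beta,
        vcov=vcov,
        loglik=_logistic_ll(X, y, beta),
        converged=converged,
        columns=design.columns,
        n_iter=it,
    )


def _logistic_ll(X, y, beta) -> float:
    eta = X @ beta
    # log(1+exp(eta)) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _half_steps(ll_fn, beta, step, ll, max_halves: int = 30):
    """Accept the longest fraction of the step that does not decrease ll.

    Near the optimum ll can be flat at float precision while the score still
    shrinks, so equal-ll candidates are accepted; the caller stops when the
    step no longer moves the coefficients at all.
    """
    import numpy as _np

    for j in range(max_halves):
        cand = beta + step / (2**j)
        cand_ll = ll_fn(cand)
        if math.isfinite(cand_ll) and cand_ll >= ll - 1e-12:
            return cand, cand_ll, not _np.array_equal(cand, beta)
    return beta, ll, False


def fit_gamma_loglink(design: DesignMatrix, positive_ranges: np.ndarray) -> ComponentFit:
    """Gamma GLM with log link, shape by full maximum likelihood.

    The mean model is mu = exp(X beta).  For the gamma family the score for
    beta, alpha * X'(y/mu - 1), does not involve the shape, so beta is fit by
    Fisher scoring first and the shape alpha then solves

        log(alpha) - psi(alpha) = mean(y/mu - log(y/mu)) - 1

    by Newton steps on log(alpha) (psi = digamma).  The expected information
    is block-diagonal in (beta, alpha), which gives the covariance.  An
    essentially zero-variance response drives alpha past a guard of 1e8 and
    flags non-convergence.
    """
    X = design.X
    y = np.asarray(positive_ranges, dtype=float)
    if np.any(y <= 0):
        raise ValueError("gamma component requires strictly positive responses")
    n, k = X.shape
    beta = np.zeros(k)
    beta[0] = math.log(y.mean())
    dev_ll = lambda b: -np.sum(np.log(_mu(X, b)) + y / _mu(X, b))  # shape-free part
    ll = dev_ll(beta)
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        mu = _mu(X, beta)
        score = X.T @ (y / mu - 1.0)
        info = X.T @ X  # expected information / alpha
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        beta, ll, moved = _half_steps(dev_ll, beta, step, ll)
        score_norm = np.max(np.abs(X.T @ (y / _mu(X, beta) - 1.0)))
        if score_norm < _SCORE_TOL:
            converged = True
            break
        if not moved:
            converged = score_norm < 1e-6
            break

    mu = _mu(X, beta)
    ratio = y / mu
    target = float(np.mean(ratio - np.log(ratio))) - 1.0
    alpha, alpha_ok = _solve_gamma_shape(target)
    if not alpha_ok:
        converged = False

    loglik = float(
        n * (alpha * math.log(alpha) - gammaln(alpha))
        + np.sum(-alpha * np.log(mu) + (alpha - 1) * np.log(y) - alpha * ratio)
    )
    vcov = np.linalg.pinv(X.T @ X) / alpha
    shape_info = n * (polygamma(1, alpha) - 1.0 / alpha)
    shape_se = 1.0 / math.sqrt(shape_info) if shape_info > 0 else float("inf")
    return ComponentFit(
        coefs=beta,
        vcov=vcov,
        loglik=loglik,
        converged=converged,
        columns=design.columns,
        n_iter=it,
        shape=alpha,
        shape_se=shape_se,
    )


def _mu(X, beta):
    return np.exp(np.clip(X @ beta, -700, 700))


def _solve_gamma_shape(target: float, guard: float = 1e8) -> tuple[float, bool]:
    """Solve log(a) - digamma(a) = target for a > 0 (target > 0)."""
    if target <= 1e-12:  # zero-variance response: shape diverges
        return guard, False
    # log(a) - psi(a) ~ 1/(2a) for large a gives a bracketing start
    a = max(1.0 / (2.0 * target), 1e-6)
    for _ in range(100):
        f = math.log(a) - float(digamma(a)) - target
        fprime = 1.0 / a - float(polygamma(1, a))
        step = f / fprime
        new_a = a - step
        if new_a <= 0:
            new_a = a / 2.0
        if new_a > guard:
            return guard, False
        if abs(new_a - a) < 1e-12 * (a + 1.0):
            return new_a, True
        a = new_a
    return a, abs(math.log(a) - float(digamma(a)) - target) < 1e-8


@dataclass(frozen=True)
class HurdleFit:
    """Joint result of the two independently-fitted hurdle components."""

    zero: ComponentFit
    cond: ComponentFit
    zero_design: DesignMatrix
    cond_design: DesignMatrix
    n_obs: int
    n_positive: int
    data: pd.DataFrame

    @property
    def loglik_total(self) -> float:
        return self.zero.loglik + self.cond.loglik

    @property
    def k_params(self) -> int:
        # one dispersion (gamma shape) counted once in total
        return len(self.zero.coefs) + len(self.cond.coefs) + 1

    @property
    def aicc(self) -> float:
        return aicc(self.loglik_total, self.k_params, self.n_obs)

    @property
    def converged(self) -> bool:
        return self.zero.converged and self.cond.converged


def fit_hurdle(
    summaries: Sequence[SpeciesSizeSummary],
    annotations,
    spec: ModelSpec,
) -> HurdleFit:
    """Fit the two-part hurdle model with identical predictors in both parts.

    The zero component is fit to all species with the indicator range > 0;
    the conditional gamma component to the positive-range subset only.
    """
    data = covariate_frame(summaries, annotations)
    zero_design = build_design(data, spec)
    is_nonzero = (data["maxsize_range"].to_numpy() > 0).astype(float)
    if is_nonzero.min() == is_nonzero.max():
        # every species on one side of the hurdle: the binomial component is
        # degenerate; flag it and let the conditional fit stand alone
        k = zero_design.k
        zero_fit = ComponentFit(
            coefs=np.full(k, np.nan),
            vcov=np.full((k, k), np.nan),
            loglik=0.0,
            converged=False,
            columns=zero_design.columns,
            n_iter=0,
        )
    else:
        zero_fit = fit_logistic(zero_design, is_nonzero)

    pos = data[data["maxsize_range"] > 0].reset_index(drop=True)
    cond_design = build_design(pos, spec)
    cond_fit = fit_gamma_loglink(cond_design, pos["maxsize_range"].to_numpy())
    return HurdleFit(
        zero=zero_fit,
        cond=cond_fit,
        zero_design=zero_design,
        cond_design=cond_design,
        n_obs=len(data),
        n_positive=len(pos),
        data=data,
    )


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike criterion: -2 ll + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def compare_models(fits: Sequence[HurdleFit], labels: Sequence[str]) -> pd.DataFrame:
    """Rank hurdle fits by AICc (ascending) with delta-AICc and df columns."""
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) > 1:
        raise ValueError(f"fits are on different species sets (n_obs {sorted(n_obs)})")
    ids = {f.zero_design.species_ids for f in fits}
    if len(ids) > 1:
        raise ValueError("fits are on different species sets")
    table = pd.DataFrame(
        {
            "model": list(labels),
            "df": [f.k_params for f in fits],
            "aicc": [f.aicc for f in fits],
            "loglik": [f.loglik_total for f in fits],
            "converged": [f.converged for f in fits],
        }
    ).sort_values("aicc", kind="mergesort", ignore_index=True)
    table["delta_aicc"] = table["aicc"] - table["aicc"].iloc[0]
    return table


@dataclass(frozen=True)
class EmmResult:
    """Estimated marginal mean for one cell of the reference grid."""

    levels: tuple[tuple[str, str], ...]  # ((factor, level), ...)
    estimate_link: float
    se: float
    estimate_response: float
    grid_vector: np.ndarray  # averaged design row, for contrast covariances


@dataclass(frozen=True)
class ContrastResult:
    """One pairwise difference of EMMs on the link scale."""

    pair: tuple[tuple[tuple[str, str], ...], tuple[tuple[str, str], ...]]
    difference: float
    se: float
    z: float
    p_adjusted: float
    p_unadjusted: float


def _component(fit: HurdleFit, component: str) -> tuple[ComponentFit, DesignMatrix, pd.DataFrame]:
    if component == "zero":
        return fit.zero, fit.zero_design, fit.data
    if component == "conditional":
        pos = fit.data[fit.data["maxsize_range"] > 0].reset_index(drop=True)
        return fit.cond, fit.cond_design, pos
    raise ValueError(f"unknown component {component!r}")


def _grid_row(
    design: DesignMatrix,
    cont_values: Mapping[str, float],
    factor_values: Mapping[str, str],
) -> np.ndarray:
    """Design row for one fully-specified covariate combination."""
    spec = design.spec
    row = np.zeros(len(design.columns))
    row[0] = 1.0
    idx = {name: i for i, name in enumerate(design.columns)}
    for term in spec.continuous_terms:
        row[idx[term]] = cont_values[term]
    for factor in spec.factor_terms:
        lv = factor_values[factor]
        name = f"{factor}[{lv}]"
        if name in idx:
            row[idx[name]] = 1.0
        elif lv != design.factor_levels[factor][0]:
            raise ValueError(f"unknown level {lv!r} for factor {factor!r}")
    for cont, factor in spec.interaction_terms:
        lv = factor_values[factor]
        name = f"{cont}:{factor}[{lv}]"
        if name in idx:
            row[idx[name]] = cont_values[cont]
    return row


def estimated_marginal_means(
    fit: HurdleFit,
    component: str,
    factors: Sequence[str],
    at: Mapping[str, float] | None = None,
) -> list[EmmResult]:
    """EMMs for the requested factors of one hurdle component.

    The reference grid crosses the requested factors' levels; non-requested
    factors are averaged with equal weight over their observed levels, and
    continuous covariates are held at ``at`` (default: the observed mean in
    the component's data).  Standard errors come from the component
    covariance by the delta rule; the response-scale value applies the
    inverse link (logistic or exp).
    """
    comp, design, data = _component(fit, component)
    spec = design.spec
    for f in factors:
        if f not in spec.factor_terms:
            raise ValueError(f"factor {f!r} not in model ({spec.factor_terms})")
    at = dict(at or {})
    cont_values = {
        term: at.get(term, float(data[term].mean())) for term in spec.continuous_terms
    }
    others = [f for f in spec.factor_terms if f not in factors]

    import itertools

    results = []
    req_level_sets = [design.factor_levels[f] for f in factors]
    other_level_sets = [design.factor_levels[f] for f in others]
    for req_combo in itertools.product(*req_level_sets):
        rows = []
        for other_combo in itertools.product(*other_level_sets):
            fv = dict(zip(factors, req_combo)) | dict(zip(others, other_combo))
            rows.append(_grid_row(design, cont_values, fv))
        L = np.mean(rows, axis=0)
        est = float(L @ comp.coefs)
        se = float(math.sqrt(L @ comp.vcov @ L))
        resp = float(expit(est)) if component == "zero" else math.exp(est)
        results.append(
            EmmResult(
                levels=tuple(zip(factors, req_combo)),
                estimate_link=est,
                se=se,
                estimate_response=resp,
                grid_vector=L,
            )
        )
    return results


def pairwise_contrasts(
    emms: Sequence[EmmResult],
    fit: HurdleFit,
    component: str,
    adjust: str = "tukey",
) -> list[ContrastResult]:
    """All pairwise EMM differences with Tukey (studentized-range) adjustment.

    With m means, the adjusted p for a difference with statistic z is
    P(Q_{m,inf} >= |z| * sqrt(2)); for m = 2 this reduces to the unadjusted
    two-sided normal p.
    """
    if len(emms) < 2:
        raise ValueError("need at least two EMMs to contrast")
    if adjust not in ("tukey", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    comp, _, _ = _component(fit, component)
    m = len(emms)
    out = []
    for i in range(m):
        for j in range(i + 1, m):
            a, b = emms[i], emms[j]
            d = a.estimate_link - b.estimate_link
            L = a.grid_vector - b.grid_vector
            se = float(math.sqrt(L @ comp.vcov @ L))
            z = d / se if se > 0 else 0.0
            p_un = float(2 * norm.sf(abs(z)))
            if adjust == "tukey":
                p_adj = float(studentized_range.sf(abs(z) * math.sqrt(2.0), m, np.inf))
            else:
                p_adj = p_un
            out.append(
                ContrastResult(
                    pair=(a.levels, b.levels),
                    difference=d,
                    se=se,
                    z=z,
                    p_adjusted=min(max(p_adj, p_un), 1.0),
                    p_unadjusted=p_un,
                )
            )
    return out


def marginal_effect_curves(
    fit: HurdleFit,
    over: str,
    by: str,
    grid: np.ndarray | None = None,
    component: str = "zero",
) -> pd.DataFrame:
    """Predicted curves along a continuous term, one per factor level.

    For the zero component the curve is P(nonzero range); for the
    conditional component it is the expected positive range.  Non-plotted
    factors sit at their reference level; the default grid spans the observed
    range of the continuous term in 100 steps.
    """
    comp, design, data = _component(fit, component)
    spec = design.spec
    if over not in spec.continuous_terms:
        raise ValueError(f"{over!r} is not a continuous model term")
    if by not in spec.factor_terms:
        raise ValueError(f"{by!r} is not a factor in the model")
    if grid is None:
        x = data[over]
        grid = np.linspace(float(x.min()), float(x.max()), 100)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty prediction grid")

    rows = []
    for lv in design.factor_levels[by]:
        for g in grid:
            fv = {f: design.factor_levels[f][0] for f in spec.factor_terms}
            fv[by] = lv
            cv = {t: float(data[t].mean()) for t in spec.continuous_terms}
            cv[over] = float(g)
            L = _grid_row(design, cv, fv)
            eta = float(L @ comp.coefs)
            pred = float(expit(eta)) if component == "zero" else math.exp(eta)
            rows.append({by: lv, over: float(g), "linear_predictor": eta, "prediction": pred})
    return pd.DataFrame(rows)


def hurdle_report(fit: HurdleFit, alpha_bonferroni: float = 0.009) -> dict:
    """Coefficient report for both components, in both orientations.

    Wald z tests with two significance flags: the conventional 0.05 level and
    a stricter multiplicity-corrected level (default 0.009).  The zero
    component is reported both as P(nonzero) (the internal orientation) and as
    P(zero) (signs flipped), clearly labelled.
    """

    def table(comp: ComponentFit, flip: bool = False) -> list[dict]:
        sign = -1.0 if flip else 1.0
        out = []
        for name, b, se in zip(comp.columns, comp.coefs, comp.se()):
            z = b / se if se > 0 else float("nan")
            p = float(2 * norm.sf(abs(z)))
            out.append(
                {
                    "term": name,
                    "estimate": sign * float(b),
                    "std_error": float(se),
                    "z": sign * float(z),
                    "p": p,
                    "significant_05": p < 0.05,
                    "significant_bonferroni": p < alpha_bonferroni,
                }
            )
        return out

    return {
        "zero_component_p_nonzero": table(fit.zero),
        "zero_component_p_zero": table(fit.zero, flip=True),
        "conditional_component": table(fit.cond),
        "gamma_shape": fit.cond.shape,
        "gamma_shape_se": fit.cond.shape_se,
        "loglik_zero": fit.zero.loglik,
        "loglik_cond": fit.cond.loglik,
        "loglik_total": fit.loglik_total,
        "k_params": fit.k_params,
        "n_obs": fit.n_obs,
        "n_positive": fit.n_positive,
        "aicc": fit.aicc,
        "converged": fit.converged,
        "alpha_bonferroni": alpha_bonferroni,
    }
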