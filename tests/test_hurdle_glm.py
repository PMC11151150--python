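"""Hurdle GLM: design coding, fitter oracles, AICc, marginal means, contrasts."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats
from scipy.special import expit, gammaln

from sizerange import hurdle_glm as hg, synthetic_cohort as sc


def frame(n, rng, levels=("a", "b"), factor="habitat"):
    """Small covariate frame with one factor and one continuous term."""
    return pd.DataFrame(
        {
            "aphia_id": np.arange(1, n + 1),
            "log10_smallest": rng.normal(size=n),
            factor: rng.choice(list(levels), size=n),
        }
    )


class TestBuildDesign:
    def test_column_count_small(self):
        rng = np.random.default_rng(0)
        data = frame(10, rng)
        spec = hg.ModelSpec(factor_terms=("habitat",), reference_levels={"habitat": "a"})
        d = hg.build_design(data, spec)
        assert d.columns == ("intercept", "log10_smallest", "habitat[b]")
        assert d.X.shape == (10, 3)
        assert np.all(d.X[:, 0] == 1.0)

    def test_full_formula_column_count_closed_form(self, small_cohort):
        """Predictor set with 8 phyla, 3 habitats, 4 count classes and both
        size interactions: 1 + 1 + (3+7+2) + (3+7+2) = 26 columns per
        component, i.e. 2*26 + 1 = 53 parameters for the whole hurdle."""
        data = hg.covariate_frame(small_cohort.summaries, small_cohort.annotations)
        d = hg.build_design(data, hg.standard_spec("phylum", "habitat"))
        n_levels = {"count_class": 4, "phylum": 8, "habitat": 3}
        expected = 1 + 1 + sum(v - 1 for v in n_levels.values()) * 2
        assert d.k == expected == 26

    def test_missing_reference_level_is_error(self):
        rng = np.random.default_rng(1)
        data = frame(10, rng, levels=("x", "y"))
        spec = hg.ModelSpec(factor_terms=("habitat",), reference_levels={"habitat": "absent"})
        with pytest.raises(ValueError, match="reference level"):
            hg.build_design(data, spec)

    def test_constant_factor_is_error_naming_it(self):
        rng = np.random.default_rng(2)
        data = frame(10, rng, levels=("only",))
        spec = hg.ModelSpec(factor_terms=("habitat",), reference_levels={"habitat": "only"})
        with pytest.raises(ValueError, match="habitat"):
            hg.build_design(data, spec)

    def test_interaction_must_reference_declared_terms(self):
        with pytest.raises(ValueError, match="interaction"):
            hg.ModelSpec(factor_terms=(), interaction_terms=(("log10_smallest", "habitat"),))


def intercept_design(n):
    data = pd.DataFrame({"aphia_id": np.arange(n), "log10_smallest": np.zeros(n)})
    return hg.build_design(data, hg.ModelSpec(continuous_terms=(), factor_terms=()))


class TestLogistic:
    def test_intercept_only_closed_form(self):
        d = intercept_design(10)
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], dtype=float)
        fit = hg.fit_logistic(d, y)
        assert fit.converged
        assert fit.coefs[0] == pytest.approx(math.log(0.3 / 0.7), abs=1e-8)

    def test_score_identities_at_convergence(self, small_cohort):
        data = hg.covariate_frame(small_cohort.summaries, small_cohort.annotations)
        design = hg.build_design(data, hg.standard_spec("habitat"))
        y = (data["maxsize_range"] > 0).to_numpy(dtype=float)
        fit = hg.fit_logistic(design, y)
        p = expit(design.X @ fit.coefs)
        score = design.X.T @ (y - p)
        assert np.max(np.abs(score)) < 1e-6
        # the intercept score identity: fitted probabilities sum to successes
        assert p.sum() == pytest.approx(y.sum(), abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_likelihood_maximizer(self, seed):
        """Two/three-parameter fits agree with a generic optimizer to 1e-6."""
        rng = np.random.default_rng(seed)
        n = 50
        data = frame(n, rng)
        spec = hg.ModelSpec(factor_terms=("habitat",), reference_levels={"habitat": "a"})
        design = hg.build_design(data, spec)
        beta_true = np.array([0.3, 0.8, -0.5])
        y = (rng.random(n) < expit(design.X @ beta_true)).astype(float)
        if y.min() == y.max():
            pytest.skip("degenerate draw")
        fit = hg.fit_logistic(design, y)

        def nll(b):
            eta = design.X @ b
            return -(y @ eta - np.logaddexp(0, eta).sum())

        res = optimize.minimize(nll, np.zeros(3), method="BFGS", tol=1e-12)
        res = optimize.minimize(
            nll, res.x, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12}
        )
        assert np.max(np.abs(fit.coefs - res.x)) < 1e-6

    def test_complete_separation_flagged(self):
        data = pd.DataFrame(
            {"aphia_id": np.arange(20), "log10_smallest": np.linspace(-1, 1, 20)}
        )
        design = hg.build_design(data, hg.ModelSpec())
        y = (data["log10_smallest"] > 0).to_numpy(dtype=float)
        fit = hg.fit_logistic(design, y)
        assert not fit.converged

    def test_all_same_outcome_rejected(self):
        d = intercept_design(5)
        with pytest.raises(ValueError):
            hg.fit_logistic(d, np.ones(5))


class TestGamma:
    def test_intercept_only_mean(self):
        rng = np.random.default_rng(3)
        y = rng.gamma(2.0, 1.5, size=200)
        d = intercept_design(200)
        fit = hg.fit_gamma_loglink(d, y)
        assert fit.converged
        assert math.exp(fit.coefs[0]) == pytest.approx(y.mean(), rel=1e-10)

    def test_shape_matches_profile_likelihood_grid(self):
        """ML shape agrees with a 1-D profile-likelihood search to 1e-4."""
        rng = np.random.default_rng(4)
        y = rng.gamma(1.7, 0.2, size=300)
        d = intercept_design(300)
        fit = hg.fit_gamma_loglink(d, y)

        mu = y.mean()  # intercept-only ML mean

        def nll_shape(a):
            return -(
                300 * (a * math.log(a) - gammaln(a))
                + np.sum(-a * math.log(mu) + (a - 1) * np.log(y) - a * y / mu)
            )

        grid = np.linspace(0.5, 5.0, 451)
        a0 = grid[np.argmin([nll_shape(a) for a in grid])]
        res = optimize.minimize_scalar(
            nll_shape, bracket=(a0 - 0.01, a0, a0 + 0.01), options={"xtol": 1e-12}
        )
        assert fit.shape == pytest.approx(res.x, abs=1e-4)

    def test_gamma_score_identity(self, small_cohort):
        data = hg.covariate_frame(small_cohort.summaries, small_cohort.annotations)
        pos = data[data["maxsize_range"] > 0].reset_index(drop=True)
        design = hg.build_design(pos, hg.standard_spec("habitat"))
        fit = hg.fit_gamma_loglink(design, pos["maxsize_range"].to_numpy())
        mu = np.exp(design.X @ fit.coefs)
        score = design.X.T @ (pos["maxsize_range"].to_numpy() / mu - 1.0)
        assert np.max(np.abs(score)) < 1e-6

    def test_constant_response_flags_nonconvergence(self):
        d = intercept_design(20)
        fit = hg.fit_gamma_loglink(d, np.full(20, 3.0))
        assert not fit.converged
        assert math.exp(fit.coefs[0]) == pytest.approx(3.0, rel=1e-10)

    def test_nonpositive_response_rejected(self):
        d = intercept_design(3)
        with pytest.raises(ValueError):
            hg.fit_gamma_loglink(d, np.array([1.0, 0.0, 2.0]))

    def test_cross_check_against_reference_glm(self):
        """Mean coefficients agree with an established GLM implementation."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        data = frame(200, rng)
        spec = hg.ModelSpec(factor_terms=("habitat",), reference_levels={"habitat": "a"})
        design = hg.build_design(data, spec)
        y = rng.gamma(2.0, np.exp(design.X @ np.array([-1.0, 0.3, 0.5])) / 2.0)
        fit = hg.fit_gamma_loglink(design, y)
        ref = sm.GLM(y, design.X, family=sm.families.Gamma(sm.families.links.Log())).fit()
        assert np.max(np.abs(fit.coefs - ref.params)) < 1e-6


class TestHurdle:
    def test_loglik_total_is_component_sum(self, small_cohort):
        fit = hg.fit_hurdle(
            small_cohort.summaries, small_cohort.annotations, hg.standard_spec("habitat")
        )
        assert fit.loglik_total == pytest.approx(fit.zero.loglik + fit.cond.loglik)
        assert fit.k_params == len(fit.zero.coefs) + len(fit.cond.coefs) + 1

    def test_reference_recoding_leaves_fit_invariant(self, small_cohort):
        """Changing the treatment reference changes coefficients, not fits."""
        spec_a = hg.standard_spec("habitat")
        spec_b = hg.ModelSpec(
            factor_terms=spec_a.factor_terms,
            interaction_terms=spec_a.interaction_terms,
            reference_levels={"habitat": "pelagic", "count_class": "c3"},
        )
        fa = hg.fit_hurdle(small_cohort.summaries, small_cohort.annotations, spec_a)
        fb = hg.fit_hurdle(small_cohort.summaries, small_cohort.annotations, spec_b)
        pa = expit(fa.zero_design.X @ fa.zero.coefs)
        # align rows: same species order by construction
        pb = expit(fb.zero_design.X @ fb.zero.coefs)
        assert np.max(np.abs(pa - pb)) < 1e-8
        assert fa.aicc == pytest.approx(fb.aicc, abs=1e-6)

    def test_no_zero_species_boundary(self):
        truth = sc.default_truth(n_species=600, seed=21).replace(
            zero_coefs={"intercept": 25.0}, unit_factor_rate=0.0, colony_factor_rate=0.0
        )
        cohort = sc.simulate_cohort(truth)
        assert all(s.maxsize_range > 0 for s in cohort.summaries)
        fit = hg.fit_hurdle(cohort.summaries, cohort.annotations, hg.standard_spec("habitat"))
        assert not fit.zero.converged  # degenerate binomial side, flagged
        assert np.all(np.isnan(fit.zero.coefs))
        # the conditional side equals a plain gamma fit on the same data
        data = hg.covariate_frame(cohort.summaries, cohort.annotations)
        design = hg.build_design(data, hg.standard_spec("habitat"))
        alone = hg.fit_gamma_loglink(design, data["maxsize_range"].to_numpy())
        assert np.allclose(fit.cond.coefs, alone.coefs)
        assert fit.loglik_total == pytest.approx(alone.loglik)

    def test_parameter_recovery_single_seed(self, small_cohort):
        """Every generating coefficient within ~4 SE at n=1500 (single seed)."""
        truth = small_cohort.truth
        fit = hg.fit_hurdle(
            small_cohort.summaries, small_cohort.annotations, hg.standard_spec("phylum", "habitat")
        )
        for comp, coefs in (("zero", truth.zero_coefs), ("cond", truth.cond_coefs)):
            f = fit.zero if comp == "zero" else fit.cond
            se = f.se()
            for i, c in enumerate(f.columns):
                z = (f.coefs[i] - coefs.get(c, 0.0)) / se[i]
                assert abs(z) < 4.5, f"{comp} {c}: z={z:.2f}"


class TestAicc:
    def test_closed_formula(self):
        assert hg.aicc(-50.0, 2, 100) == pytest.approx(104 + 12 / 97)

    def test_approaches_aic_for_large_n(self):
        aic = -2 * (-50.0) + 2 * 3
        assert abs(hg.aicc(-50.0, 3, 10**9) - aic) < 1e-6

    def test_undefined_below_n_k_plus_one(self):
        with pytest.raises(ValueError):
            hg.aicc(-1.0, 5, 6)

    def test_ranking_matches_recomputation(self, small_cohort):
        labels = ["habitat", "invertebrate"]
        fits = [
            hg.fit_hurdle(
                small_cohort.summaries,
                small_cohort.annotations,
                hg.CANDIDATE_SPECS[l],
            )
            for l in labels
        ]
        table = hg.compare_models(fits, labels)
        recomputed = sorted(
            (hg.aicc(f.loglik_total, f.k_params, f.n_obs), l) for f, l in zip(fits, labels)
        )
        assert list(table["model"]) == [l for _, l in recomputed]
        assert table["delta_aicc"].iloc[0] == 0.0

    def test_identical_fits_tie_at_zero_delta(self, small_cohort):
        f = hg.fit_hurdle(small_cohort.summaries, small_cohort.annotations, hg.standard_spec("habitat"))
        table = hg.compare_models([f, f], ["a", "b"])
        assert np.allclose(table["delta_aicc"], 0.0)

    def test_different_species_sets_rejected(self, small_cohort):
        f1 = hg.fit_hurdle(small_cohort.summaries, small_cohort.annotations, hg.standard_spec("habitat"))
        f2 = hg.fit_hurdle(
            small_cohort.summaries[:-50], small_cohort.annotations, hg.standard_spec("habitat")
        )
        with pytest.raises(ValueError):
            hg.compare_models([f1, f2], ["a", "b"])


@pytest.fixture(scope="module")
def fit(small_cohort):
    return hg.fit_hurdle(
        small_cohort.summaries, small_cohort.annotations, hg.standard_spec("phylum", "habitat")
    )


class TestEmmsAndContrasts:

    def test_emm_matches_explicit_grid_average(self, fit):
        """EMMs equal a hand-constructed equal-weight average of predictions."""
        emms = hg.estimated_marginal_means(fit, "conditional", ["habitat"])
        design = fit.cond_design
        data = fit.data[fit.data["maxsize_range"] > 0]
        at = {"log10_smallest": float(data["log10_smallest"].mean())}
        for emm in emms:
            habitat = dict(emm.levels)["habitat"]
            preds = []
            for ph, cc in itertools.product(
                design.factor_levels["phylum"], design.factor_levels["count_class"]
            ):
                row = hg._grid_row(
                    design, at, {"phylum": ph, "count_class": cc, "habitat": habitat}
                )
                preds.append(float(row @ fit.cond.coefs))
            assert emm.estimate_link == pytest.approx(np.mean(preds), abs=1e-10)

    def test_intercept_only_emm_is_inverse_linked_intercept(self, small_cohort):
        spec = hg.ModelSpec(
            continuous_terms=(), factor_terms=("habitat",), interaction_terms=()
        )
        f = hg.fit_hurdle(small_cohort.summaries, small_cohort.annotations, spec)
        emms = hg.estimated_marginal_means(f, "zero", ["habitat"])
        for e in emms:
            assert e.estimate_response == pytest.approx(float(expit(e.estimate_link)))

    def test_unknown_factor_rejected(self, fit):
        with pytest.raises(ValueError):
            hg.estimated_marginal_means(fit, "zero", ["skeleton"])

    def test_contrasts_antisymmetric_and_bounded(self, fit):
        emms = hg.estimated_marginal_means(fit, "zero", ["habitat"])
        contrasts = hg.pairwise_contrasts(emms, fit, "zero")
        assert len(contrasts) == 3
        for c in contrasts:
            assert c.p_adjusted >= c.p_unadjusted - 1e-12
            assert 0 <= c.p_adjusted <= 1

    def test_tukey_reduces_to_normal_for_two_means(self, fit):
        emms = hg.estimated_marginal_means(fit, "zero", ["habitat"])[:2]
        (c,) = hg.pairwise_contrasts(emms, fit, "zero")
        assert c.p_adjusted == pytest.approx(c.p_unadjusted, rel=1e-6)

    def test_tukey_matches_numeric_integration(self, fit):
        """Adjusted p equals the integrated studentized-range tail (m=4)."""
        emms = hg.estimated_marginal_means(fit, "zero", ["count_class"])
        assert len(emms) == 4
        contrasts = hg.pairwise_contrasts(emms, fit, "zero")

        def tail(q, m):
            # P(range of m iid standard normals > q)
            z = np.linspace(-10, 10, 4001)
            phi = stats.norm.pdf(z)
            inner = (stats.norm.cdf(z) - stats.norm.cdf(z - q)) ** (m - 1)
            return 1.0 - m * np.trapezoid(phi * inner, z)

        for c in contrasts[:3]:
            q = abs(c.z) * math.sqrt(2.0)
            assert c.p_adjusted == pytest.approx(tail(q, 4), abs=1e-6)

    def test_single_emm_rejected(self, fit):
        emms = hg.estimated_marginal_means(fit, "zero", ["habitat"])[:1]
        with pytest.raises(ValueError):
            hg.pairwise_contrasts(emms, fit, "zero")


class TestMarginalEffectCurves:
    def test_curves_equal_direct_linear_predictor(self, small_cohort):
        fit = hg.fit_hurdle(
            small_cohort.summaries, small_cohort.annotations, hg.standard_spec("habitat")
        )
        grid = np.linspace(-2, 2, 7)
        curves = hg.marginal_effect_curves(fit, "log10_smallest", "habitat", grid, "zero")
        design = fit.zero_design
        for _, row in curves.iterrows():
            fv = {f: design.factor_levels[f][0] for f in design.spec.factor_terms}
            fv["habitat"] = row["habitat"]
            L = hg._grid_row(design, {"log10_smallest": row["log10_smallest"]}, fv)
            assert row["linear_predictor"] == pytest.approx(float(L @ fit.zero.coefs), abs=1e-12)
            assert row["prediction"] == pytest.approx(float(expit(L @ fit.zero.coefs)), abs=1e-12)

    def test_positive_slope_gives_monotone_probability(self, small_cohort):
        fit = hg.fit_hurdle(
            small_cohort.summaries, small_cohort.annotations, hg.standard_spec("habitat")
        )
        curves = hg.marginal_effect_curves(fit, "log10_smallest", "habitat", None, "zero")
        for _, grp in curves.groupby("habitat"):
            diffs = np.diff(grp.sort_values("log10_smallest")["prediction"])
            assert np.all(diffs <= 0) or np.all(diffs >= 0)  # monotone per level

    def test_empty_grid_rejected(self, small_cohort):
        fit = hg.fit_hurdle(
            small_cohort.summaries, small_cohort.annotations, hg.standard_spec("habitat")
        )
        with pytest.raises(ValueError):
            hg.marginal_effect_curves(fit, "log10_smallest", "habitat", np.array([]), "zero")
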