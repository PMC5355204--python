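import itertools

import numpy as np
import pandas as pd
import pytest

from sealmove.mixedlm import _group_stats, fit_lmm
from sealmove.modelavg import (
    AICcModelAverager,
    FittedModel,
    ModelSpec,
    aicc,
    aicc_weights,
    build_candidate_set,
    design_matrix,
    fit_candidates,
    model_average,
    transform_response,
)


def _make_fit(terms, beta, se, ll, k=4, n=60):
    spec = ModelSpec(tuple(terms))
    fm = FittedModel(spec, dict(beta), dict(se), ll, k, n)
    fm.aicc = aicc(ll, k, n)
    return fm


class TestAICc:
    def test_hand_computed_value(self):
        assert aicc(-100, 3, 50) == pytest.approx(206.5217, abs=1e-4)

    def test_asymptotic_aic_limit(self):
        assert aicc(-100, 3, 10**9) == pytest.approx(206.0, abs=1e-6)

    def test_monotone_penalty(self):
        assert aicc(-100, 4, 50) > aicc(-100, 3, 50)

    def test_undefined_small_n(self):
        with pytest.raises(ValueError):
            aicc(-10, 5, 6)

    def test_weights_examples(self):
        np.testing.assert_allclose(aicc_weights([100.0]), [1.0])
        w = aicc_weights([100.0, 102.0])
        np.testing.assert_allclose(w, [0.7311, 0.2689], atol=1e-4)

    def test_weights_sum_to_one(self, rng):
        for _ in range(20):
            w = aicc_weights(rng.uniform(100, 300, rng.integers(1, 15)))
            assert w.sum() == pytest.approx(1.0)


class TestCandidateSets:
    def test_distance_set_contents(self):
        specs = build_candidate_set("distance")
        names = {s.name for s in specs}
        assert "null" in names and "species" in names
        assert all("species:month" not in s.terms for s in specs)

    def test_hierarchy_rule(self):
        for analysis in ("ud", "dive", "distance"):
            for s in build_candidate_set(analysis):
                if "species:month" in s.terms:
                    assert {"species", "month"} <= set(s.terms)
        with pytest.raises(ValueError, match="main effects"):
            ModelSpec(("species", "species:month"))

    def test_sizes_match_combinatorial_oracle(self):
        mains = ["species", "month", "sex", "mass"]
        # brute force: every nonempty subset up to the size cap, plus the
        # interaction added wherever species and month co-occur
        def count(max_terms, with_interaction):
            n = 1  # null
            for r in range(1, max_terms + 1):
                for combo in itertools.combinations(mains, r):
                    n += 1
                    if with_interaction and {"species", "month"} <= set(combo):
                        n += 1
            return n

        assert len(build_candidate_set("ud")) == count(4, True) == 20
        assert len(build_candidate_set("dive")) == count(4, True) == 20
        assert len(build_candidate_set("distance")) == count(3, False) == 15

    def test_unknown_analysis_rejected(self):
        with pytest.raises(ValueError, match="unknown analysis"):
            build_candidate_set("banana")

    def test_correlation_structure_per_analysis(self):
        assert build_candidate_set("ud")[0].correlation == "none"
        assert build_candidate_set("distance")[0].correlation == "ar1"
        assert build_candidate_set("dive")[0].correlation == "car1"


class TestTransforms:
    def test_log_requires_positive(self):
        with pytest.raises(ValueError):
            transform_response([1.0, -2.0], "log")
        np.testing.assert_allclose(transform_response([1.0, np.e], "log"),
                                   [0.0, 1.0])

    def test_logit_boundary_clip(self):
        y = np.array([0.0, 0.5, 1.0])
        n = np.array([10.0, 10.0, 10.0])
        z = transform_response(y, "logit", n)
        p = 1 / (1 + np.exp(-z))
        np.testing.assert_allclose(p, [1 / 40, 0.5, 39 / 40])

    def test_month_reference_is_september(self):
        df = pd.DataFrame({"month": [10, 9, 11], "mass": [1.0, 2, 3]})
        X, names = design_matrix(df, ("month",))
        assert names == ["(Intercept)", "month[10]", "month[11]"]
        # September rows carry only the intercept
        np.testing.assert_allclose(X[1], [1.0, 0.0, 0.0])


class TestAveraging:
    def test_degenerate_identical_models(self):
        fits = [_make_fit(("species",), {"(Intercept)": 1.0, "species[s]": 2.0},
                          {"(Intercept)": 0.1, "species[s]": 0.2}, ll)
                for ll in (-100.0, -100.0)]
        avg = model_average(fits)
        assert avg["species[s]"].beta == pytest.approx(2.0)
        # identical estimates: no between-model variance inflation
        half_width = avg["species[s]"].ci_upper - avg["species[s]"].beta
        assert half_width == pytest.approx(1.96 * 0.2)

    def test_weighted_mean_example(self):
        # two models with renormalized weights (0.75, 0.25): AICc gap of
        # 2*ln(3) gives exactly a 3:1 weight ratio
        gap = 2.0 * np.log(3.0)
        fits = [
            _make_fit(("mass",), {"mass": 1.0}, {"mass": 0.1}, -100.0),
            _make_fit(("mass",), {"mass": 3.0}, {"mass": 0.1}, -100.0 - gap / 2),
        ]
        avg = model_average(fits, coverage=1.0)
        assert avg["mass"].beta == pytest.approx(0.75 * 1.0 + 0.25 * 3.0)

    def test_single_dominant_model_reduces_to_it(self):
        fits = [
            _make_fit(("species",), {"species[s]": 1.5}, {"species[s]": 0.1},
                      -90.0),
            _make_fit((), {"(Intercept)": 0.0}, {"(Intercept)": 0.1}, -110.0),
        ]
        avg = model_average(fits, coverage=0.95)
        assert avg["species[s]"].beta == pytest.approx(1.5)
        assert avg["species[s]"].significant

    def test_term_absent_from_selection_not_emitted(self):
        fits = [
            _make_fit((), {"(Intercept)": 0.0}, {"(Intercept)": 0.1}, -90.0),
            _make_fit(("mass",), {"(Intercept)": 0.0, "mass": 1.0},
                      {"(Intercept)": 0.1, "mass": 0.5}, -115.0),
        ]
        avg = model_average(fits, coverage=0.95)
        assert "mass" not in avg


class TestMixedModelFits:
    def test_dual_route_likelihood_pieces(self, rng):
        """Analytic O(n) Woodbury/tridiagonal stats vs dense linear algebra."""
        for corr in ("none", "ar1", "car1"):
            n = 30
            y = rng.normal(size=n)
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            t = np.sort(rng.uniform(0, 40, n))
            gamma2, rho = 0.6, 0.55
            a, b, c, ld = _group_stats(y, X, t, corr, gamma2, rho)
            if corr == "none":
                R = np.eye(n)
            elif corr == "ar1":
                idx = np.arange(n)
                R = rho ** np.abs(np.subtract.outer(idx, idx))
            else:
                R = rho ** np.abs(np.subtract.outer(t, t))
            W = gamma2 * np.ones((n, n)) + R
            Wi = np.linalg.inv(W)
            np.testing.assert_allclose(a, X.T @ Wi @ X, rtol=1e-8)
            np.testing.assert_allclose(b, X.T @ Wi @ y, rtol=1e-8)
            assert c == pytest.approx(y @ Wi @ y)
            assert ld == pytest.approx(np.linalg.slogdet(W)[1])

    def test_matches_statsmodels_random_intercept(self, rng):
        import statsmodels.api as sm
        g = np.repeat(np.arange(10), 20)
        x = rng.normal(size=200)
        y = (1.0 + 0.5 * x + rng.normal(0, 0.7, 10)[g]
             + rng.normal(0, 1.0, 200))
        X = np.column_stack([np.ones(200), x])
        ours = fit_lmm(y, X, g)
        ref = sm.MixedLM(y, X, groups=g).fit(reml=False)
        np.testing.assert_allclose(ours.beta, ref.fe_params, atol=1e-4)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-4)

    def test_null_model_single_animal_intercept_is_mean(self, rng):
        y = rng.normal(3.0, 1.0, 40)
        fit = fit_lmm(y, np.ones((40, 1)), np.zeros(40), correlation="none")
        assert fit.beta[0] == pytest.approx(y.mean(), abs=1e-6)

    def test_ar1_structure_detected_by_aicc(self, rng):
        wins = 0
        n_rep = 15
        for _ in range(n_rep):
            g = np.repeat(np.arange(8), 40)
            y = []
            for _g in range(8):
                e = [rng.normal()]
                for _i in range(39):
                    e.append(0.8 * e[-1] + np.sqrt(1 - 0.64) * rng.normal())
                y.append(np.asarray(e) + rng.normal(0, 0.5))
            y = np.concatenate(y)
            X = np.ones((len(y), 1))
            f_ar = fit_lmm(y, X, g, correlation="ar1")
            f_id = fit_lmm(y, X, g, correlation="none")
            if aicc(f_ar.loglik, f_ar.k, f_ar.n) < aicc(f_id.loglik, f_id.k,
                                                        f_id.n):
                wins += 1
        assert wins >= 0.9 * n_rep

    def test_fit_candidates_recovers_species_effect(self, rng):
        n_animals, m = 16, 30
        rows = []
        for i in range(n_animals):
            sp = "harbor" if i % 2 else "spotted"
            b = rng.normal(0, 0.2)
            for j in range(m):
                mu = 0.2 + (1.0 if sp == "spotted" else 0.0) + b
                rows.append((f"a{i}", sp, "F" if i % 3 else "M", 40 + i,
                             9 + (j // 10), float(j * 6),
                             mu + rng.normal(0, 0.5)))
        df = pd.DataFrame(rows, columns=["animal_id", "species", "sex", "mass",
                                         "month", "t_hr", "resp"])
        fits = fit_candidates(df, build_candidate_set("dive"), "resp",
                              transform=None, time_col="t_hr")
        assert len(fits) == 20
        avg = model_average(fits)
        est = avg["species[spotted]"]
        assert est.ci_lower < 1.0 < est.ci_upper
        assert est.significant

    def test_estimator_api(self, rng):
        df = pd.DataFrame({
            "animal_id": np.repeat([f"a{i}" for i in range(8)], 12),
            "species": np.repeat(["harbor", "spotted"] * 4, 12),
            "sex": np.repeat(["F", "M"] * 4, 12),
            "mass": np.repeat(rng.uniform(30, 70, 8), 12),
            "month": np.tile(np.repeat([9, 10, 11, 12], 3), 8),
            "area": rng.lognormal(3.0, 0.5, 96),
        })
        est = AICcModelAverager(analysis="ud", response="area",
                                transform="log").fit(df)
        assert est.selection_table_["weight"].sum() == pytest.approx(1.0)
        assert {"term", "beta", "significant"} <= set(est.averaged_table_.columns)
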