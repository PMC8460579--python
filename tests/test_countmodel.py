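"""Poisson GLM / GLMM estimation, information criteria, and the LRT."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special

from binocsync.countmodel import (
    PoissonCountModel,
    build_design,
    fit_poisson_glm,
    fit_poisson_glmm,
    format_table,
    information_criteria,
    likelihood_ratio,
    lrt_compare,
)
from binocsync.simulate import simulate_count_table


def counts_frame(counts, regions=None):
    n = len(counts)
    return pd.DataFrame(
        {
            "participant_id": ["P1"] * n,
            "group": ["g"] * n,
            "article_id": ["A1"] * n,
            "page_id": [str(i + 1) for i in range(n)],
            "region": regions or ["middle"] * n,
            "count": counts,
        }
    )


# ---------------------------------------------------------------------------
# design matrix


def test_design_treatment_coding_middle_reference():
    df = counts_frame([1, 2, 3], ["left", "middle", "right"])
    d = build_design(df, region_effect=True, random_factors=())
    assert d.xnames == ["intercept", "region[left]", "region[right]"]
    np.testing.assert_array_equal(
        d.X, np.array([[1, 1, 0], [1, 0, 0], [1, 0, 1]], dtype=float)
    )


def test_design_permutation_equivariance():
    df = counts_frame([1, 2, 3, 4], ["left", "middle", "right", "left"])
    d1 = build_design(df, True, ())
    perm = [2, 0, 3, 1]
    d2 = build_design(df.iloc[perm].reset_index(drop=True), True, ())
    np.testing.assert_array_equal(d1.X[perm], d2.X)
    np.testing.assert_array_equal(d1.y[perm], d2.y)


def test_design_missing_region_level_errors():
    df = counts_frame([1, 2], ["middle", "middle"])
    with pytest.raises(ValueError, match="left"):
        build_design(df, region_effect=True, random_factors=())


def test_page_factor_keyed_within_article():
    df = counts_frame([1, 2, 3, 4])
    df["article_id"] = ["A1", "A1", "A2", "A2"]
    df["page_id"] = ["1", "2", "1", "2"]
    d = build_design(df, False, ("page",), page_within_article=True)
    assert d.factors[0].n_levels == 4
    d2 = build_design(df, False, ("page",), page_within_article=False)
    assert d2.factors[0].n_levels == 2


# ---------------------------------------------------------------------------
# GLM


def test_glm_intercept_only_closed_form():
    res = fit_poisson_glm(counts_frame([3, 5, 4]), region_effect=False)
    assert res.params["intercept"] == pytest.approx(np.log(4), abs=1e-6)
    assert res.converged


def test_glm_constant_counts_zero_slopes():
    df = counts_frame([7, 7, 7, 7, 7, 7], ["left", "middle", "right"] * 2)
    res = fit_poisson_glm(df)
    assert res.params["intercept"] == pytest.approx(np.log(7), abs=1e-8)
    assert abs(res.params["region[left]"]) < 1e-8
    assert abs(res.params["region[right]"]) < 1e-8


def test_glm_loglik_gradient_and_deviance_monotone():
    rng = np.random.default_rng(2)
    df, _ = simulate_count_table(
        {"left": 0.3, "right": -0.2}, {}, n_participants=10, n_pages=3, seed=2
    )
    res = fit_poisson_glm(df)
    d = res.model.design
    eta = d.X @ res.params.to_numpy()
    # loglik equals a direct evaluation of the Poisson log-likelihood
    direct = float(np.sum(df["count"] * eta - np.exp(eta))
                   - special.gammaln(df["count"] + 1).sum())
    assert res.loglik == pytest.approx(direct, abs=1e-8)
    # score is zero at the MLE
    grad = d.X.T @ (d.y - np.exp(eta))
    assert np.max(np.abs(grad)) < 1e-5
    # IRLS deviance trace decreases monotonically to convergence
    hist = np.array(res.deviance_history)
    assert np.all(np.diff(hist) <= 1e-8)


def test_glm_matches_statsmodels():
    import statsmodels.api as sm

    df, _ = simulate_count_table(
        {"left": 0.5, "right": -0.3}, {}, n_participants=20, n_pages=2, seed=9
    )
    mine = fit_poisson_glm(df)
    d = mine.model.design
    ref = sm.GLM(d.y, d.X, family=sm.families.Poisson()).fit()
    np.testing.assert_allclose(mine.params.to_numpy(), ref.params, atol=1e-6)
    np.testing.assert_allclose(mine.bse.to_numpy(), ref.bse, atol=1e-6)
    assert mine.loglik == pytest.approx(ref.llf, abs=1e-6)


# ---------------------------------------------------------------------------
# GLMM


@pytest.fixture(scope="module")
def lme4_fixture_counts():
    """Deterministic table whose glmer reference fit is frozen below."""
    df, _ = simulate_count_table(
        {"left": 0.4, "right": -0.2},
        {"participant": 0.3, "page": 0.15},
        n_participants=8, n_articles=2, n_pages=3, intercept=1.0, seed=42,
    )
    return df


def test_glmm_matches_frozen_glmer_reference(lme4_fixture_counts):
    """Crossed random-intercept fit against a frozen lme4::glmer oracle.

    Reference values computed once with glmer(count ~ region + (1|participant)
    + (1|article) + (1|page), family=poisson) on this exact table.
    """
    full = fit_poisson_glmm(lme4_fixture_counts)
    null = fit_poisson_glmm(lme4_fixture_counts, region_effect=False)
    assert null.loglik == pytest.approx(-292.032567, abs=0.01)
    assert full.loglik == pytest.approx(-278.246498, abs=0.01)
    assert full.params["intercept"] == pytest.approx(0.9488618, abs=0.005)
    assert full.params["region[left]"] == pytest.approx(0.4236803, abs=0.005)
    assert full.params["region[right]"] == pytest.approx(-0.1620441, abs=0.005)
    assert full.bse["intercept"] == pytest.approx(0.1234109, abs=0.01)
    assert full.bse["region[left]"] == pytest.approx(0.1137403, abs=0.01)
    assert full.random_sds["participant"] == pytest.approx(0.1777276, abs=0.01)
    assert full.random_sds["page"] == pytest.approx(0.1409259, abs=0.01)
    assert full.random_sds["article"] == pytest.approx(0.0, abs=0.01)
    lrt = lrt_compare(null, full)
    assert lrt.chisq == pytest.approx(27.572, abs=0.05)
    assert lrt.df == 2


def test_glmm_laplace_close_to_exact_quadrature(lme4_fixture_counts):
    """Single-factor Laplace loglik vs brute-force adaptive quadrature."""
    res = fit_poisson_glmm(lme4_fixture_counts, random_factors=("participant",))
    d = res.model.design
    beta = res.params.to_numpy()
    sigma = res.random_sds["participant"]
    assert sigma > 0
    eta0 = d.X @ beta
    codes = d.factors[0].codes
    exact = 0.0
    for g in range(d.factors[0].n_levels):
        mask = codes == g
        y, e0 = d.y[mask], eta0[mask]
        shift = float(np.sum(y * e0 - np.exp(e0) - special.gammaln(y + 1)))

        def integrand(b):
            eta = e0 + b
            ll = np.sum(y * eta - np.exp(eta) - special.gammaln(y + 1))
            return np.exp(ll - shift) * np.exp(-b**2 / (2 * sigma**2)) / (
                sigma * np.sqrt(2 * np.pi)
            )

        val, _ = integrate.quad(integrand, -8 * sigma, 8 * sigma, limit=200)
        exact += np.log(val) + shift
    assert res.loglik == pytest.approx(exact, abs=0.05)


def test_glmm_boundary_reduces_to_glm():
    df, _ = simulate_count_table(
        {"left": 0.3, "right": -0.1}, {}, n_participants=36,
        n_articles=3, n_pages=4, intercept=np.log(4), seed=0,
    )
    glm = fit_poisson_glm(df)
    glmm = fit_poisson_glmm(df)
    assert all(v == 0.0 for v in glmm.random_variances.values())
    np.testing.assert_allclose(
        glm.params.to_numpy(), glmm.params.to_numpy(), atol=1e-4
    )
    # boundary still counts toward k: 3 fixed + 3 variance components
    assert glmm.k_params == 6


def test_glmm_recovers_planted_effects():
    df, _ = simulate_count_table(
        {"left": 0.46, "right": -0.13}, {"participant": 0.23},
        n_participants=36, n_articles=1, n_pages=60, intercept=0.5, seed=21,
    )
    res = fit_poisson_glmm(df, random_factors=("participant",))
    assert res.params["region[left]"] == pytest.approx(0.46, abs=3 * res.bse["region[left]"])
    assert res.params["region[right]"] == pytest.approx(-0.13, abs=3 * res.bse["region[right]"])
    assert res.random_sds["participant"] == pytest.approx(0.23, abs=0.10)


def test_glmm_nested_loglik_ordering_and_identities(lme4_fixture_counts):
    null = fit_poisson_glmm(lme4_fixture_counts, region_effect=False)
    full = fit_poisson_glmm(lme4_fixture_counts)
    assert full.loglik >= null.loglik - 1e-6
    for res in (null, full):
        aic, bic = information_criteria(res.loglik, res.k_params, res.nobs)
        assert res.aic == pytest.approx(aic)
        assert res.bic == pytest.approx(bic)
        np.testing.assert_allclose(
            res.zvalues.to_numpy(),
            res.params.to_numpy() / res.bse.to_numpy(),
        )


def test_single_level_factor_dropped_with_warning():
    df, _ = simulate_count_table({}, {}, n_participants=4, n_articles=1,
                                 n_pages=2, seed=1)
    with pytest.warns(UserWarning, match="single level"):
        res = fit_poisson_glmm(df, random_factors=("participant", "article"))
    assert "article" not in res.random_variances
    assert res.k_params == 3 + 1


# ---------------------------------------------------------------------------
# LRT and reporting


def test_lrt_identities():
    same = likelihood_ratio(-100.0, -100.0, df=2)
    assert same.chisq == 0.0 and same.p == 1.0
    lrt = likelihood_ratio(-8252.810, -8198.181, df=2)
    assert lrt.chisq == pytest.approx(109.258, abs=1e-9)
    assert lrt.p < 1e-20


def test_lrt_requires_nesting(lme4_fixture_counts):
    full = fit_poisson_glmm(lme4_fixture_counts)
    other = fit_poisson_glmm(lme4_fixture_counts, random_factors=("participant",))
    with pytest.raises(ValueError, match="nested"):
        lrt_compare(full, other)
    with pytest.raises(ValueError, match="extra parameters"):
        lrt_compare(full, full)


def test_format_table_shape_and_boundary_footnote(lme4_fixture_counts):
    null = fit_poisson_glmm(lme4_fixture_counts, region_effect=False)
    full = fit_poisson_glmm(lme4_fixture_counts)
    table = format_table(null, full, title="fixture")
    for needle in ("null model", "sides of screen", "Log likelihood",
                   "Akaike inf. crit.", "Bayesian inf. crit.", "Observations",
                   "region[left]", "Constant"):
        assert needle in table

    df0, _ = simulate_count_table({"left": 0.3, "right": -0.1}, {},
                                  n_participants=36, n_articles=3, n_pages=4,
                                  intercept=np.log(4), seed=0)
    n0 = fit_poisson_glmm(df0, region_effect=False)
    f0 = fit_poisson_glmm(df0)
    assert "All random intercepts were equal to zero." in format_table(n0, f0)


def test_results_json_round_trip(tmp_path, lme4_fixture_counts):
    import json

    from binocsync.events import write_fit_json

    res = fit_poisson_glmm(lme4_fixture_counts, random_factors=("participant",))
    path = tmp_path / "fit.json"
    write_fit_json(res, path)
    back = json.loads(path.read_text())
    assert back["estimates"]["region[left]"]["est"] == pytest.approx(
        res.params["region[left]"]
    )
    assert back["aic"] == pytest.approx(res.aic)
    assert back["n_obs"] == res.nobs


def test_summary_mentions_key_quantities(lme4_fixture_counts):
    res = fit_poisson_glmm(lme4_fixture_counts)
    text = res.summary()
    assert "Log likelihood" in text and "AIC" in text
    assert "region[left]" in text and "participant" in text
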