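"""Censored mixed regression, truncated-normal correction, residual averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.optimize import minimize
from scipy.stats import norm

from pedscan.phenotype import (
    CensoredFit,
    PhenotypeError,
    build_adjusted_phenotype,
    conditional_expectation_censored,
    fit_censored_exam,
    validate_exam_records,
)
from pedscan.simulate import SimConfig, SimTruth, simulate_pedigrees, simulate_phenotypes


def _fam_of(peds):
    return {m.individual_id: p.family_id for p in peds for m in p.members}


@pytest.fixture(scope="module")
def uncensored_data():
    cfg = SimConfig(n_pedigrees=30, h2=0.0, qtl_frac=0.0, tau=6.0,
                    total_sd=12.0, censor_prob=0.0, seed=10)
    peds = simulate_pedigrees(cfg.n_pedigrees, cfg.template)
    df = simulate_phenotypes(peds, SimTruth(), cfg, seed=11)
    return peds, df[df["exam"] == 1].reset_index(drop=True)


def test_uncensored_fit_matches_linear_mixed_model(uncensored_data):
    """With no medicated records the censored likelihood reduces to the
    normal one: coefficients match statsmodels MixedLM (ML) to 1e-4."""
    import statsmodels.api as sm

    peds, df = uncensored_data
    fam_of = _fam_of(peds)
    fit = fit_censored_exam(df, fam_of)
    assert fit.n_censored == 0

    from pedscan.phenotype import design_matrix

    X = design_matrix(df)
    groups = df["id"].map(fam_of)
    ref = sm.MixedLM(df["sbp"].to_numpy(), X, groups=groups).fit(
        reml=False, method="powell", maxiter=2000
    )
    assert ref.converged
    got = fit.beta.to_numpy()
    want = np.asarray(ref.fe_params)
    assert np.abs(got - want).max() / np.abs(want).max() < 1e-4
    # variance components agree too (looser: different optimizers)
    assert fit.sigma ** 2 == pytest.approx(float(ref.scale), rel=1e-2)


def test_censored_fit_beats_naive_on_censored_data():
    """With 30% right-censoring the censored ML keeps the intercept close
    to truth while an uncensored fit of the same records is biased down."""
    cfg = SimConfig(n_pedigrees=40, h2=0.0, qtl_frac=0.0, tau=5.0,
                    total_sd=15.0, censor_quantile=0.7, censor_prob=1.0, seed=5)
    peds = simulate_pedigrees(cfg.n_pedigrees, cfg.template)
    df = simulate_phenotypes(peds, SimTruth(), cfg, seed=6)
    d1 = df[df["exam"] == 1].reset_index(drop=True)
    fam_of = _fam_of(peds)
    fit = fit_censored_exam(d1, fam_of)
    naive = fit_censored_exam(d1.assign(med="no"), fam_of)
    truth_int = cfg.mean_sbp
    assert abs(fit.beta["intercept"] - truth_int) < abs(
        naive.beta["intercept"] - truth_int
    )


def test_tau_zero_matches_single_level_tobit():
    """tau ~ 0 data: random intercept collapses and the fit agrees with an
    independently coded single-level tobit ML."""
    cfg = SimConfig(n_pedigrees=30, h2=0.0, qtl_frac=0.0, tau=0.0,
                    total_sd=15.0, censor_quantile=0.7, censor_prob=1.0, seed=8)
    peds = simulate_pedigrees(cfg.n_pedigrees, cfg.template)
    df = simulate_phenotypes(peds, SimTruth(), cfg, seed=9)
    d1 = df[df["exam"] == 1].reset_index(drop=True)
    fit = fit_censored_exam(d1, _fam_of(peds))
    assert fit.tau < 0.15 * fit.sigma  # near the boundary

    from pedscan.phenotype import design_matrix

    X = design_matrix(d1)
    y = d1["sbp"].to_numpy(float)
    cens = (d1["med"] == "yes").to_numpy()

    def nll(params):
        beta, lsig = params[:-1], params[-1]
        s = np.exp(lsig)
        z = (y - X @ beta) / s
        ll = np.where(cens, norm.logsf(z), norm.logpdf(z) - lsig)
        return -ll.sum()

    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    ref = minimize(nll, np.r_[beta0, np.log(15.0)], method="BFGS")
    assert np.abs(fit.beta.to_numpy() - ref.x[:-1]).max() < 0.2
    assert fit.sigma == pytest.approx(float(np.exp(ref.x[-1])), rel=2e-2)


def test_conditional_expectation_closed_form():
    # y = mu: E[Y | Y > mu] = mu + sigma * sqrt(2/pi)
    got = conditional_expectation_censored(100.0, 100.0, 10.0)
    assert got == pytest.approx(100.0 + 10.0 * np.sqrt(2.0 / np.pi), abs=1e-9)


def test_conditional_expectation_quadrature_oracle():
    y, mu, sigma = 140.0, 120.0, 15.0
    num, _ = integrate.quad(
        lambda t: t * norm.pdf(t, mu, sigma), y, mu + 60 * sigma
    )
    den = norm.sf(y, mu, sigma)
    want = num / den
    got = conditional_expectation_censored(y, mu, sigma)
    assert got == pytest.approx(want, abs=1e-8)


def test_conditional_expectation_tail_contraction():
    # far above the mean the correction shrinks toward y_obs:
    # asymptotically Y* ~ y_obs + sigma^2/(y_obs - mu) = 221 here
    with pytest.warns(RuntimeWarning):
        got = conditional_expectation_censored(220.0, 120.0, 10.0)
    assert 220.0 < got < 221.05


@settings(max_examples=200, deadline=None)
@given(
    y=st.floats(80, 200),
    mu=st.floats(90, 150),
    dy=st.floats(0.01, 20),
    dmu=st.floats(0.01, 20),
)
def test_conditional_expectation_monotone(y, mu, dy, dmu):
    s = 12.0
    base = conditional_expectation_censored(y, mu, s)
    assert conditional_expectation_censored(y + dy, mu, s) > base
    assert conditional_expectation_censored(y, mu + dmu, s) > base


def _dummy_fit(exam, sigma=10.0):
    return CensoredFit(
        exam_index=exam,
        beta=pd.Series([120.0, 0.0, 0.0, 0.0],
                       index=["intercept", "sex", "age", "smoke"]),
        sigma=sigma, tau=0.0, ranef={}, loglik=0.0, converged=True,
    )


def _recs(rows):
    return pd.DataFrame(
        rows, columns=["id", "exam", "sbp", "age", "sex", "smoke", "med"]
    )


def test_adjusted_phenotype_mean_and_counts():
    fits = {e: _dummy_fit(e) for e in (1, 2, 3, 4)}
    fam_of = {"a": "F", "b": "F", "c": "F"}
    recs = _recs(
        [
            ("a", 1, 125.0, 0, "male", "no", "no"),
            ("a", 2, 115.0, 0, "male", "no", "no"),
            ("a", 3, 120.0, 0, "male", "no", "no"),
            ("a", 4, 999.0, 0, "male", "no", "no"),  # exam 4 ignored
            ("b", 2, 130.0, 0, "male", "no", "no"),
            ("c", 4, 140.0, 0, "male", "no", "no"),  # only exam 4 -> skipped
        ]
    )
    out, skipped = build_adjusted_phenotype(fits, recs, fam_of)
    out = out.set_index("id")
    assert out.loc["a", "R"] == pytest.approx(0.0)
    assert out.loc["a", "n_exams_used"] == 3
    assert out.loc["b", "R"] == pytest.approx(10.0)
    assert out.loc["b", "n_exams_used"] == 1
    assert "c" not in out.index
    assert skipped == ["c"]


def test_adjusted_phenotype_medicated_exceeds_naive():
    fits = {1: _dummy_fit(1)}
    fam_of = {"a": "F", "b": "F"}
    recs = _recs(
        [
            ("a", 1, 130.0, 0, "male", "no", "yes"),
            ("b", 1, 130.0, 0, "male", "no", "no"),
        ]
    )
    out, _ = build_adjusted_phenotype(fits, recs, fam_of)
    out = out.set_index("id")
    assert out.loc["a", "R"] > out.loc["b", "R"]  # Y* > Y
    assert out.loc["b", "R"] == pytest.approx(10.0)


def test_validate_rejects_duplicates_and_bad_exams():
    recs = _recs([("a", 1, 120.0, 0, "male", "no", "no"),
                  ("a", 1, 121.0, 0, "male", "no", "no")])
    with pytest.raises(PhenotypeError, match="duplicate"):
        validate_exam_records(recs)
    recs2 = _recs([("a", 7, 120.0, 0, "male", "no", "no")])
    with pytest.raises(PhenotypeError, match="1..4"):
        validate_exam_records(recs2)
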