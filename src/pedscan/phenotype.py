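"""Censoring-aware phenotype adjustment for longitudinal blood pressure.

Antihypertensive medication lowers observed systolic blood pressure (SBP),
so a treated measurement is a *lower bound* on the underlying untreated
value.  Each exam is modelled separately by a censored normal (tobit)
regression with a pedigree random intercept:

    Y = X beta + u_ped + eps,   eps ~ N(0, sigma^2),  u_ped ~ N(0, tau^2)

where the likelihood contribution of an unmedicated record is the normal
density and that of a medicated record is the right-tail survival
probability P(Y_underlying > y_obs), assuming noninformative censoring.
The random intercept is integrated out by Gauss-Hermite quadrature.

For a medicated record the underlying value is replaced by the truncated
normal conditional expectation Y* = E[Y | Y > y_obs]; residuals Y - Yhat
(unmedicated) or Y* - Yhat (medicated) are averaged over exams 1-3 into the
adjusted phenotype R used by all downstream genetic analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp
from scipy.stats import norm

COVARIATES = ("sex", "age", "smoke")
DESIGN_COLUMNS = ("intercept",) + COVARIATES
ADJUST_EXAMS = (1, 2, 3)  # exam 4, when present, is ignored by design


class PhenotypeError(ValueError):
    pass


class CensoredFitError(RuntimeError):
    """Censored-regression optimization failed to converge after restarts."""


@dataclass
class CensoredFit:
    """One exam's censored mixed-regression ML fit."""

    exam_index: int
    beta: pd.Series  # indexed by DESIGN_COLUMNS, mmHg per unit
    sigma: float  # residual s.d., mmHg
    tau: float  # pedigree random-intercept s.d., mmHg
    ranef: dict[str, float]  # family -> posterior-mode random intercept, mmHg
    loglik: float
    converged: bool
    tau_boundary: bool = False
    n_records: int = 0
    n_censored: int = 0

    def fitted(self, df: pd.DataFrame, fam_of: Mapping[str, str]) -> np.ndarray:
        """Model mean Xb + u_ped for each row (covariates + random effect)."""
        X = design_matrix(df)
        u = np.array([self.ranef.get(fam_of[i], 0.0) for i in df["id"]])
        return X @ self.beta.to_numpy() + u

    def report(self) -> dict:
        return {
            "exam": self.exam_index,
            "coefficients": {k: float(v) for k, v in self.beta.items()},
            "sigma": self.sigma,
            "tau": self.tau,
            "loglik": self.loglik,
            "converged": self.converged,
            "tau_boundary": self.tau_boundary,
            "n_records": self.n_records,
            "n_censored": self.n_censored,
        }


def _coerce01(s: pd.Series, one_values: tuple) -> np.ndarray:
    return s.map(lambda v: 1.0 if v in one_values else 0.0).to_numpy()


def design_matrix(df: pd.DataFrame) -> np.ndarray:
    """Fixed-effect design: intercept, sex (female=1), age (years), smoking."""
    return np.column_stack(
        [
            np.ones(len(df)),
            _coerce01(df["sex"], ("female", "F", "f", 2, "2"))
            if df["sex"].dtype == object
            else (df["sex"].to_numpy(float)),
            df["age"].to_numpy(float),
            _coerce01(df["smoke"], ("yes", "Y", "y", 1, "1", True))
            if df["smoke"].dtype == object
            else df["smoke"].to_numpy(float),
        ]
    )


def validate_exam_records(df: pd.DataFrame, max_exam: int = 4) -> None:
    required = {"id", "exam", "sbp", "age", "sex", "smoke", "med"}
    missing = required - set(df.columns)
    if missing:
        raise PhenotypeError(f"exam table missing columns {sorted(missing)}")
    if df.duplicated(["id", "exam"]).any():
        dup = df[df.duplicated(["id", "exam"])].iloc[0]
        raise PhenotypeError(
            f"duplicate record for individual {dup['id']!r} exam {dup['exam']}"
        )
    if not df["exam"].between(1, max_exam).all():
        raise PhenotypeError(f"exam indices must lie in 1..{max_exam}")
    if (df["sbp"] <= 0).any():
        raise PhenotypeError("non-positive SBP values")


def conditional_expectation_censored(
    y_obs, mu, sigma, alpha_max: float = 8.0
):
    """Truncated-normal mean E[Y | Y > y_obs] for Y ~ N(mu, sigma^2).

    Returns ``mu + sigma * phi(a) / (1 - Phi(a))`` with ``a = (y_obs - mu) /
    sigma`` (the inverse Mills ratio), evaluated in log space for stability.
    ``mu`` is the full model mean: covariate effects plus the pedigree
    random effect.  Standardized observations beyond ``alpha_max`` are far
    in the upper tail; they are handled by the same stable formula but a
    warning is emitted since the correction degenerates to ~y_obs there.
    """
    y_obs = np.asarray(y_obs, float)
    mu = np.asarray(mu, float)
    if np.any(np.asarray(sigma) <= 0):
        raise PhenotypeError("sigma must be positive")
    alpha = (y_obs - mu) / sigma
    if np.any(alpha > alpha_max):
        warnings.warn(
            "censored observation(s) beyond %.1f residual s.d.; conditional "
            "expectation is numerically ~y_obs there" % alpha_max,
            RuntimeWarning,
        )
    mills = np.exp(norm.logpdf(alpha) - norm.logsf(alpha))
    out = mu + sigma * mills
    # mathematically out > y_obs; guard rounding in the extreme tail
    return np.maximum(out, y_obs + np.finfo(float).tiny)


def _grouped(df: pd.DataFrame, fam_of: Mapping[str, str]):
    fam = df["id"].map(lambda i: fam_of[i])
    order = np.argsort(fam.to_numpy(), kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    fam = fam.iloc[order].reset_index(drop=True)
    starts = np.flatnonzero(np.r_[True, fam.to_numpy()[1:] != fam.to_numpy()[:-1]])
    fams = fam.to_numpy()[starts]
    return df, starts, fams


def fit_censored_exam(
    records: pd.DataFrame,
    fam_of: Mapping[str, str],
    n_quad: int = 20,
    n_restarts: int = 3,
    seed: int = 0,
) -> CensoredFit:
    """ML fit of the censored mixed regression for one exam's records.

    ``records`` holds one exam's rows (columns id, exam, sbp, age, sex,
    smoke, med); ``fam_of`` maps individual to family.  The pedigree random
    intercept is integrated out with ``n_quad``-point Gauss-Hermite
    quadrature; optimization restarts from perturbed starts on
    non-convergence.
    """
    if records["exam"].nunique() > 1:
        raise PhenotypeError("fit_censored_exam expects records from a single exam")
    fams_present = {fam_of[i] for i in records["id"]}
    if len(fams_present) < 2:
        raise PhenotypeError("need records from at least 2 pedigrees")
    exam = int(records["exam"].iloc[0])
    df, starts, fams = _grouped(records, fam_of)
    y = df["sbp"].to_numpy(float)
    X = design_matrix(df)
    cens = df["med"].map(
        lambda v: v in ("yes", "Y", "y", 1, "1", True, 1.0)
    ).to_numpy(bool)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise PhenotypeError("design matrix is rank-deficient")

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    logw = np.log(weights) - 0.5 * np.log(np.pi)

    # start values from OLS on uncensored records
    ok = ~cens if (~cens).sum() >= X.shape[1] + 1 else np.ones(len(y), bool)
    beta0, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
    resid0 = y[ok] - X[ok] @ beta0
    sigma0 = max(float(np.std(resid0)), 1.0)

    def negloglik(params: np.ndarray) -> float:
        beta = params[:-2]
        sigma, tau = params[-2], params[-1]
        u = np.sqrt(2.0) * tau * nodes  # (K,)
        z = (y[:, None] - (X @ beta)[:, None] - u[None, :]) / sigma  # (n, K)
        lc = np.where(
            cens[:, None], norm.logsf(z), norm.logpdf(z) - np.log(sigma)
        )
        per_fam = np.add.reduceat(lc, starts, axis=0)  # (n_fam, K)
        return -float(logsumexp(per_fam + logw[None, :], axis=1).sum())

    p = X.shape[1]
    bounds = [(None, None)] * p + [(1e-3 * sigma0, None), (0.0, None)]
    rng = np.random.default_rng(seed)
    starts_list = [np.r_[beta0, sigma0, 0.5 * sigma0]]
    for _ in range(n_restarts):
        starts_list.append(
            np.r_[
                beta0 * rng.uniform(0.8, 1.2, p),
                sigma0 * rng.uniform(0.5, 2.0),
                sigma0 * rng.uniform(0.05, 1.0),
            ]
        )
    best = None
    trace = []
    for x0 in starts_list:
        res = minimize(
            negloglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 1000},
        )
        trace.append((res.success, float(res.fun)))
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-9):
            best = res
        if best is not None and best.success:
            break
    if best is None or not np.isfinite(best.fun):
        raise CensoredFitError(f"exam {exam}: optimization failed; trace={trace}")

    beta = best.x[:p]
    sigma = float(best.x[p])
    tau = float(best.x[p + 1])
    tau_boundary = tau < 1e-4 * sigma

    # posterior-mode random intercepts given the MLEs
    ranef: dict[str, float] = {}
    ends = np.r_[starts[1:], len(y)]
    for f, s0, s1 in zip(fams, starts, ends):
        if tau_boundary:
            ranef[f] = 0.0
            continue
        yy, xx, cc = y[s0:s1], X[s0:s1], cens[s0:s1]

        def neg_post(u: float) -> float:
            z = (yy - xx @ beta - u) / sigma
            ll = np.where(cc, norm.logsf(z), norm.logpdf(z) - np.log(sigma))
            return -(ll.sum() - 0.5 * u * u / tau ** 2)

        opt = minimize_scalar(neg_post, bounds=(-8 * tau, 8 * tau), method="bounded")
        ranef[f] = float(opt.x)
    for f in fams_present:
        ranef.setdefault(f, 0.0)

    return CensoredFit(
        exam_index=exam,
        beta=pd.Series(beta, index=list(DESIGN_COLUMNS)),
        sigma=sigma,
        tau=tau,
        ranef=ranef,
        loglik=-float(best.fun),
        converged=bool(best.success),
        tau_boundary=tau_boundary,
        n_records=len(y),
        n_censored=int(cens.sum()),
    )


@dataclass
class AdjustedPhenotype:
    individual_id: str
    R: float
    n_exams_used: int


def build_adjusted_phenotype(
    fits: Mapping[int, CensoredFit],
    records: pd.DataFrame,
    fam_of: Mapping[str, str],
) -> tuple[pd.DataFrame, list[str]]:
    """Adjusted phenotype R: mean censoring-corrected residual over exams 1-3.

    Per record the residual is ``Y - Yhat`` (unmedicated) or ``Y* - Yhat``
    (medicated), with Yhat the fitted covariate + random-effect mean from
    that exam's :class:`CensoredFit`.  Individuals with no record in exams
    1-3 are excluded and returned in the skip report.  Returns a frame with
    columns id, R, n_exams_used.
    """
    validate_exam_records(records)
    use = records[records["exam"].isin(ADJUST_EXAMS)].copy()
    for exam in sorted(use["exam"].unique()):
        if exam not in fits:
            raise PhenotypeError(f"no censored fit supplied for exam {exam}")
    skipped = sorted(set(records["id"]) - set(use["id"]))

    parts = []
    for exam, df in use.groupby("exam"):
        fit = fits[int(exam)]
        yhat = fit.fitted(df, fam_of)
        y = df["sbp"].to_numpy(float)
        med = df["med"].map(
            lambda v: v in ("yes", "Y", "y", 1, "1", True, 1.0)
        ).to_numpy(bool)
        resid = y - yhat
        if med.any():
            ystar = conditional_expectation_censored(y[med], yhat[med], fit.sigma)
            resid[med] = ystar - yhat[med]
        parts.append(pd.DataFrame({"id": df["id"].to_numpy(), "resid": resid}))
    out = (
        pd.concat(parts)
        .groupby("id", sort=True)["resid"]
        .agg(R="mean", n_exams_used="size")
        .reset_index()
    )
    out["n_exams_used"] = out["n_exams_used"].astype(int)
    return out, skipped


def write_adjusted(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def read_exam_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str})
    validate_exam_records(df)
    return df
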