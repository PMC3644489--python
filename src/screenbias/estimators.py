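"""Binary-outcome regression machinery shared by every analysis.

Implements, from first principles, the four primitives the method
comparison rests on:

* maximum-likelihood logistic regression via iteratively reweighted
  least squares (IRLS), with optional observation weights;
* a cluster-robust (sandwich) covariance treating subjects as nested
  within physicians — point estimates are identical to ordinary
  logistic regression, only the variance changes, which is exactly the
  independence-working-correlation GEE used for clustered binary data;
* marginal standardization (g-computation): predict every subject's
  outcome probability with exposure set to 1 and to 0, average each,
  and report the difference as an absolute risk reduction (ARR) in
  percentage points, with a delta-method or cluster-bootstrap CI;
* the c-statistic (concordance probability) via an O(n log n) rank
  computation with half-credit for ties.

Sign convention: ARR = 100 * (mean risk exposed - mean risk
unexposed); negative values mean the exposure is protective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats
from scipy.special import expit, logit

__all__ = [
    "DesignSpec",
    "FitResult",
    "RiskEstimate",
    "SeparationError",
    "RankDeficiencyError",
    "NotConvergedError",
    "build_design_matrix",
    "fit_logistic",
    "c_statistic",
    "unadjusted_risk_difference",
    "marginal_arr",
    "proportion_ci",
]

Z975 = stats.norm.ppf(0.975)

#: reference levels (absorbed into the intercept) for each categorical
REFERENCE_LEVELS = {
    "age_group": "50-59",
    "sex": "M",
    "income_quintile": 1,
    "rural": False,
    "comorbidity": "not_hospitalized",
}

_CATEGORY_LEVELS = {
    "age_group": ["50-59", "60-69", "70-74"],
    "sex": ["M", "F"],
    "income_quintile": [1, 2, 3, 4, 5],
    "comorbidity": ["not_hospitalized", "hosp_no_comorbidity", "comorbid"],
}


class SeparationError(RuntimeError):
    """Coefficients diverged: the data are (quasi-)separated."""


class RankDeficiencyError(RuntimeError):
    """The design matrix is rank deficient."""


class NotConvergedError(RuntimeError):
    """IRLS did not converge within the iteration budget."""


@dataclass(frozen=True)
class DesignSpec:
    """What to regress on what, and how to cluster.

    ``covariates`` are names of the standard subject covariates (dummy
    expansion with fixed reference levels); ``extra_terms`` are numeric
    columns entered linearly (e.g. the instrument, or a predicted
    exposure probability); ``exposure`` is the binary term toggled by
    marginal standardization.
    """

    outcome: str
    exposure: str | None = "exposed"
    covariates: Sequence[str] = ()
    extra_terms: Sequence[str] = ()
    cluster: str = "pcp_id"
    weights: str | None = None

    def __post_init__(self) -> None:
        names = list(self.covariates) + list(self.extra_terms)
        if self.exposure:
            names.append(self.exposure)
        if len(set(names)) != len(names):
            raise ValueError(f"duplicated terms in design: {names}")


@dataclass
class FitResult:
    """A fitted binary-outcome model."""

    design: DesignSpec
    params: pd.Series
    cov_model: pd.DataFrame
    cov_cluster: pd.DataFrame
    n_obs: int
    n_clusters: int
    converged: bool
    n_iter: int
    loglik: float
    c_statistic: float

    def se(self, robust: bool = True) -> pd.Series:
        cov = self.cov_cluster if robust else self.cov_model
        return pd.Series(np.sqrt(np.diag(cov)), index=self.params.index)

    def predict(self, rows: pd.DataFrame, override: dict | None = None) -> np.ndarray:
        """Predicted probabilities, optionally overriding term values."""
        X = build_design_matrix(self.design, rows, override=override)
        return expit(np.clip(X.to_numpy() @ self.params.to_numpy(), -30, 30))


@dataclass
class RiskEstimate:
    """Per-method arm risks (%) and absolute risk reduction (pp)."""

    method: str
    p_unexposed: float
    p_exposed: float
    arr: float
    ci_unexposed: tuple = (np.nan, np.nan)
    ci_exposed: tuple = (np.nan, np.nan)
    ci_arr: tuple = (np.nan, np.nan)
    n: int = 0
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "p_unexposed": self.p_unexposed,
            "p_unexposed_lo": self.ci_unexposed[0],
            "p_unexposed_hi": self.ci_unexposed[1],
            "p_exposed": self.p_exposed,
            "p_exposed_lo": self.ci_exposed[0],
            "p_exposed_hi": self.ci_exposed[1],
            "arr": self.arr,
            "arr_lo": self.ci_arr[0],
            "arr_hi": self.ci_arr[1],
            "n": self.n,
            **self.extra,
        }


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def build_design_matrix(
    design: DesignSpec, rows: pd.DataFrame, override: dict | None = None
) -> pd.DataFrame:
    """Expand covariates to dummies (fixed reference levels) plus intercept."""
    override = override or {}
    n = len(rows)
    cols: dict[str, np.ndarray] = {"const": np.ones(n)}

    if design.exposure:
        if design.exposure in override:
            cols[design.exposure] = np.full(n, float(override[design.exposure]))
        else:
            cols[design.exposure] = rows[design.exposure].to_numpy(dtype=float)

    for cov in design.covariates:
        values = rows[cov]
        if cov == "rural":
            cols["rural"] = values.to_numpy(dtype=float)
            continue
        levels = _CATEGORY_LEVELS[cov]
        ref = REFERENCE_LEVELS[cov]
        for lev in levels:
            if lev == ref:
                continue
            cols[f"{cov}[{lev}]"] = (values == lev).to_numpy(dtype=float)

    for term in design.extra_terms:
        if term in override:
            cols[term] = np.full(n, float(override[term]))
        else:
            cols[term] = rows[term].to_numpy(dtype=float)

    return pd.DataFrame(cols, index=rows.index)


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy()
    _, R, piv = sla.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = diag <= tol
    if bad.any():
        aliased = [X.columns[piv[i]] for i in np.flatnonzero(bad)]
        raise RankDeficiencyError(f"design matrix is rank deficient; aliased columns: {aliased}")


# ---------------------------------------------------------------------------
# IRLS logistic fit
# ---------------------------------------------------------------------------

def fit_logistic(
    design: DesignSpec,
    rows: pd.DataFrame,
    weights: np.ndarray | None = None,
    max_iter: int = 50,
    score_tol: float = 1e-8,
    deviance_rtol: float = 1e-10,
    coef_bound: float = 30.0,
) -> FitResult:
    """Maximum-likelihood logistic regression with sandwich variances.

    Convergence is declared when the maximum absolute score falls below
    ``score_tol`` or the relative deviance change falls below
    ``deviance_rtol``.  Coefficients exceeding ``coef_bound`` in
    absolute value raise :class:`SeparationError`.
    """
    y = rows[design.outcome].to_numpy(dtype=float)
    if not (0 < y.sum() < len(y)):
        raise ValueError(
            f"outcome {design.outcome!r} needs at least one event and one non-event"
        )
    X_df = build_design_matrix(design, rows)
    _check_rank(X_df)
    X = X_df.to_numpy()
    n, k = X.shape

    if weights is None and design.weights is not None:
        weights = rows[design.weights].to_numpy(dtype=float)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or (w < 0).any():
        raise ValueError("weights must be a nonnegative vector matching rows")

    beta = np.zeros(k)
    beta[0] = logit(np.clip(np.average(y, weights=w), 1e-10, 1 - 1e-10))
    deviance = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30.0, 30.0)
        p = expit(eta)
        score = X.T @ (w * (y - p))
        irls_w = w * p * (1.0 - p)
        A = X.T @ (X * irls_w[:, None])
        try:
            delta = np.linalg.solve(A, score)
        except np.linalg.LinAlgError as err:  # flat likelihood
            raise SeparationError(f"information matrix singular at iteration {it}") from err
        beta = beta + delta
        if np.abs(beta).max() > coef_bound:
            raise SeparationError(
                "coefficients diverged (|coef| > "
                f"{coef_bound}); data are likely separated"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            ll_terms = y * np.log(p) + (1 - y) * np.log1p(-p)
        new_dev = -2.0 * float(np.sum(w * np.where(np.isfinite(ll_terms), ll_terms, -700)))
        if np.abs(score).max() < score_tol or (
            np.isfinite(deviance)
            and abs(deviance - new_dev) <= deviance_rtol * (abs(new_dev) + 1e-300)
        ):
            deviance = new_dev
            converged = True
            break
        deviance = new_dev

    eta = np.clip(X @ beta, -30.0, 30.0)
    p = expit(eta)
    irls_w = w * p * (1.0 - p)
    A = X.T @ (X * irls_w[:, None])
    A_inv = np.linalg.inv(A)

    # cluster-summed score outer product
    resid = (w * (y - p))[:, None] * X
    clusters = rows[design.cluster].to_numpy()
    order = np.argsort(clusters, kind="stable")
    sorted_c = clusters[order]
    boundaries = np.flatnonzero(np.r_[True, sorted_c[1:] != sorted_c[:-1]])
    G = np.add.reduceat(resid[order], boundaries, axis=0)
    B = G.T @ G
    cov_cluster = A_inv @ B @ A_inv

    with np.errstate(divide="ignore"):
        ll = float(np.sum(w * (y * np.log(np.clip(p, 1e-300, 1)) + (1 - y) * np.log(np.clip(1 - p, 1e-300, 1)))))

    cols = list(X_df.columns)
    return FitResult(
        design=design,
        params=pd.Series(beta, index=cols),
        cov_model=pd.DataFrame(A_inv, index=cols, columns=cols),
        cov_cluster=pd.DataFrame(cov_cluster, index=cols, columns=cols),
        n_obs=n,
        n_clusters=len(boundaries),
        converged=converged,
        n_iter=it,
        loglik=ll,
        c_statistic=c_statistic(p, y),
    )


# ---------------------------------------------------------------------------
# discrimination
# ---------------------------------------------------------------------------

def c_statistic(scores: np.ndarray, outcomes: np.ndarray) -> float:
    """Concordance probability, ties counted half.

    Equals the probability that a randomly chosen event subject is
    scored above a randomly chosen non-event subject.  Computed from
    midranks in O(n log n); identical to brute-force enumeration over
    all case-control pairs.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("c-statistic undefined: both outcome classes must be present")
    ranks = stats.rankdata(scores)  # midranks handle ties as half-credit
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


# ---------------------------------------------------------------------------
# risk estimates
# ---------------------------------------------------------------------------

def proportion_ci(k: float, n: float) -> tuple[float, float, float]:
    """Wald proportion and 95% CI, on the percent scale."""
    p = k / n
    half = Z975 * np.sqrt(p * (1 - p) / n)
    return 100 * p, 100 * (p - half), 100 * (p + half)


def unadjusted_risk_difference(
    rows: pd.DataFrame, outcome: str, exposure: str = "exposed"
) -> RiskEstimate:
    """Arm proportions with Wald CIs and their unpooled-variance difference."""
    exposed = rows[exposure].to_numpy(dtype=bool)
    y = rows[outcome].to_numpy(dtype=float)
    n1, n0 = int(exposed.sum()), int((~exposed).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both exposure arms must be nonempty")
    k1, k0 = float(y[exposed].sum()), float(y[~exposed].sum())
    p1, lo1, hi1 = proportion_ci(k1, n1)
    p0, lo0, hi0 = proportion_ci(k0, n0)
    v1 = (k1 / n1) * (1 - k1 / n1) / n1
    v0 = (k0 / n0) * (1 - k0 / n0) / n0
    arr = p1 - p0
    half = 100 * Z975 * np.sqrt(v1 + v0)
    return RiskEstimate(
        method="unadjusted",
        p_unexposed=p0,
        p_exposed=p1,
        arr=arr,
        ci_unexposed=(lo0, hi0),
        ci_exposed=(lo1, hi1),
        ci_arr=(arr - half, arr + half),
        n=n1 + n0,
    )


def marginal_arr(
    fit: FitResult,
    rows: pd.DataFrame,
    method: str = "adjusted_logistic",
    ci: str = "delta",
    n_boot: int = 200,
    seed: int = 0,
) -> RiskEstimate:
    """Marginal standardization of a fitted model to an ARR.

    Every subject's outcome probability is predicted with the exposure
    term set to 1, then to 0; each is averaged over the population, and
    the ARR is the difference (x100).  ``ci="delta"`` propagates the
    cluster-robust coefficient covariance through the averaged
    predictions; ``ci="bootstrap"`` resamples physicians with
    replacement and refits (percentile interval, seeded).
    """
    if not fit.converged:
        raise NotConvergedError("marginal standardization requires a converged fit")
    if not fit.design.exposure:
        raise ValueError("the fitted design has no exposure term")

    X1 = build_design_matrix(fit.design, rows, override={fit.design.exposure: 1}).to_numpy()
    X0 = build_design_matrix(fit.design, rows, override={fit.design.exposure: 0}).to_numpy()
    beta = fit.params.to_numpy()
    p1 = expit(np.clip(X1 @ beta, -30, 30))
    p0 = expit(np.clip(X0 @ beta, -30, 30))
    m1, m0 = float(p1.mean()), float(p0.mean())
    arr = 100.0 * (m1 - m0)

    V = fit.cov_cluster.to_numpy()
    g1 = (p1 * (1 - p1)) @ X1 / len(rows)
    g0 = (p0 * (1 - p0)) @ X0 / len(rows)
    se1 = float(np.sqrt(g1 @ V @ g1))
    se0 = float(np.sqrt(g0 @ V @ g0))
    gd = g1 - g0
    se_arr = float(np.sqrt(gd @ V @ gd))

    est = RiskEstimate(
        method=method,
        p_unexposed=100 * m0,
        p_exposed=100 * m1,
        arr=arr,
        ci_unexposed=(100 * (m0 - Z975 * se0), 100 * (m0 + Z975 * se0)),
        ci_exposed=(100 * (m1 - Z975 * se1), 100 * (m1 + Z975 * se1)),
        ci_arr=(arr - 100 * Z975 * se_arr, arr + 100 * Z975 * se_arr),
        n=len(rows),
        extra={"ci_method": ci, "c_statistic": fit.c_statistic},
    )

    if ci == "bootstrap":
        rng = np.random.default_rng(seed)
        cluster_ids = rows[fit.design.cluster].to_numpy()
        unique = np.unique(cluster_ids)
        groups = rows.groupby(fit.design.cluster, sort=False)
        frames = {cid: g for cid, g in groups}
        draws = []
        for _ in range(n_boot):
            chosen = rng.choice(unique, size=len(unique), replace=True)
            boot = pd.concat([frames[c] for c in chosen], ignore_index=True)
            try:
                bfit = fit_logistic(fit.design, boot)
            except (SeparationError, RankDeficiencyError, ValueError):
                continue
            b1 = build_design_matrix(bfit.design, boot, override={fit.design.exposure: 1}).to_numpy()
            b0 = build_design_matrix(bfit.design, boot, override={fit.design.exposure: 0}).to_numpy()
            bb = bfit.params.to_numpy()
            draws.append(100.0 * float(expit(np.clip(b1 @ bb, -30, 30)).mean()
                                       - expit(np.clip(b0 @ bb, -30, 30)).mean()))
        if draws:
            lo, hi = np.percentile(draws, [2.5, 97.5])
            est.ci_arr = (float(lo), float(hi))
            est.extra["n_boot_ok"] = len(draws)
    return est
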