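"""Physician-preference instrumental-variable estimation.

The instrument is each PCP's discretionary-colonoscopy rate (procedures
per 100 eligible patients that are outpatient, screening-kind and not
followed by a CRC diagnosis within three years).  Because a
discretionary colonoscopy cannot, by definition, occur in a patient who
develops CRC near the procedure, the rate moves a patient's chance of
being scoped without being independently associated with their cancer
risk — it affects the outcome only through the exposure.

Estimation is two-stage predictor substitution with logistic stages:

1. regress exposure on the instrument plus the measured covariates
   (cluster-robust); strength diagnostics are the partial F-statistic
   of the instrument from an auxiliary linear first stage, the
   likelihood-ratio chi-square, and the first-stage odds ratio;
2. regress the outcome on the *predicted* exposure probability plus
   covariates (cluster-robust), and marginally standardize by
   evaluating the second-stage model at predicted exposure 1 vs 0 for
   every subject.

Second-stage variances treat the first stage as fixed; a seeded
physician-level bootstrap over both stages is available for honest
intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import COVARIATES
from .estimators import (
    DesignSpec,
    FitResult,
    RiskEstimate,
    build_design_matrix,
    fit_logistic,
    marginal_arr,
    SeparationError,
    RankDeficiencyError,
)

__all__ = ["IVStrength", "IVResult", "first_stage", "second_stage", "iv_arr"]

PREDICTED_EXPOSURE = "predicted_exposure"


@dataclass
class IVStrength:
    """First-stage instrument-strength diagnostics."""

    partial_f: float
    lr_chi2: float
    odds_ratio: float


@dataclass
class IVResult:
    first_stage: FitResult
    strength: IVStrength
    second_stage: FitResult
    estimate: RiskEstimate


def first_stage(
    rows: pd.DataFrame, covariates=tuple(COVARIATES)
) -> tuple[FitResult, IVStrength]:
    """Logistic fit of exposure on instrument + covariates, with diagnostics.

    The partial F is the squared t-statistic of the instrument in an
    auxiliary ordinary-least-squares (linear probability) first stage —
    the conventional weak-instrument diagnostic; the likelihood-ratio
    chi-square compares logistic first stages with and without the
    instrument.
    """
    instrument = rows["instrument"].to_numpy(dtype=float)
    if np.ptp(instrument) == 0:
        raise ValueError("instrument has no variation")

    design = DesignSpec(
        outcome="exposed", exposure=None, covariates=covariates, extra_terms=("instrument",)
    )
    fit = fit_logistic(design, rows)

    reduced = DesignSpec(outcome="exposed", exposure=None, covariates=covariates)
    fit_reduced = fit_logistic(reduced, rows)
    lr_chi2 = 2.0 * (fit.loglik - fit_reduced.loglik)

    partial_f = _linear_partial_f(design, rows)
    strength = IVStrength(
        partial_f=partial_f,
        lr_chi2=float(lr_chi2),
        odds_ratio=float(np.exp(fit.params["instrument"])),
    )
    return fit, strength


def _linear_partial_f(design: DesignSpec, rows: pd.DataFrame) -> float:
    X = build_design_matrix(design, rows).to_numpy()
    y = rows[design.outcome].to_numpy(dtype=float)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    cols = list(build_design_matrix(design, rows).columns)
    j = cols.index("instrument")
    se = np.sqrt(sigma2 * XtX_inv[j, j])
    t = beta[j] / se
    return float(t * t)


def second_stage(
    rows: pd.DataFrame,
    fs_fit: FitResult,
    outcome: str,
    covariates=tuple(COVARIATES),
    ci: str = "delta",
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[FitResult, RiskEstimate]:
    """Outcome on predicted exposure probability + covariates.

    The marginal ARR evaluates the fitted second-stage model at
    predicted exposure 1 vs 0 for every subject and averages — the
    predicted probability plays the role the binary exposure plays in
    the standard model, but now ranges over (0, 1).
    """
    if not fs_fit.converged:
        raise RuntimeError("first stage did not converge")
    work = rows.copy()
    work[PREDICTED_EXPOSURE] = fs_fit.predict(rows)
    p_range = float(np.ptp(work[PREDICTED_EXPOSURE].to_numpy()))
    if p_range < 0.05:
        warnings.warn(
            f"predicted-exposure range {p_range:.4f} < 0.05: the exposure "
            "contrast is weakly identified",
            stacklevel=2,
        )
    design = DesignSpec(
        outcome=outcome, exposure=PREDICTED_EXPOSURE, covariates=covariates
    )
    fit = fit_logistic(design, work)
    est = marginal_arr(fit, work, method="iv_two_stage", ci="delta")
    est.extra["predicted_exposure_range"] = p_range

    if ci == "bootstrap":
        est.ci_arr = _bootstrap_ci(rows, outcome, covariates, n_boot, seed) or est.ci_arr
        est.extra["ci_method"] = "bootstrap"
    return fit, est


def _bootstrap_ci(rows, outcome, covariates, n_boot, seed):
    """Physician-cluster bootstrap over both stages (percentile CI)."""
    rng = np.random.default_rng(seed)
    frames = {cid: g for cid, g in rows.groupby("pcp_id", sort=False)}
    cids = np.array(list(frames))
    draws = []
    for _ in range(n_boot):
        chosen = rng.choice(cids, size=len(cids), replace=True)
        boot = pd.concat([frames[c] for c in chosen], ignore_index=True)
        try:
            fs, _ = first_stage(boot, covariates)
            work = boot.copy()
            work[PREDICTED_EXPOSURE] = fs.predict(boot)
            design = DesignSpec(
                outcome=outcome, exposure=PREDICTED_EXPOSURE, covariates=covariates
            )
            fit = fit_logistic(design, work)
        except (SeparationError, RankDeficiencyError, ValueError, RuntimeError):
            continue
        X1 = build_design_matrix(design, work, override={PREDICTED_EXPOSURE: 1}).to_numpy()
        X0 = build_design_matrix(design, work, override={PREDICTED_EXPOSURE: 0}).to_numpy()
        b = fit.params.to_numpy()
        draws.append(
            100.0
            * float(
                expit(np.clip(X1 @ b, -30, 30)).mean()
                - expit(np.clip(X0 @ b, -30, 30)).mean()
            )
        )
    if not draws:
        return None
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return (float(lo), float(hi))


def iv_arr(
    rows: pd.DataFrame,
    outcome: str,
    covariates=tuple(COVARIATES),
    ci: str = "delta",
    n_boot: int = 200,
    seed: int = 0,
) -> IVResult:
    """Run both stages and package the result."""
    fs, strength = first_stage(rows, covariates)
    ss, est = second_stage(
        rows, fs, outcome, covariates=covariates, ci=ci, n_boot=n_boot, seed=seed
    )
    est.extra.update(
        {
            "partial_f": strength.partial_f,
            "lr_chi2": strength.lr_chi2,
            "first_stage_or": strength.odds_ratio,
        }
    )
    return IVResult(first_stage=fs, strength=strength, second_stage=ss, estimate=est)
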