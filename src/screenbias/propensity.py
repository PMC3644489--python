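"""Propensity-score analyses: stratification, weighting, matching.

The propensity score is the modelled probability of receiving a
colonoscopy given the measured covariates (age group, sex, income
quintile, comorbidity, rural residence).  Three designs consume it:

* **quintile stratification** — compare arm-specific event rates within
  five equal score strata and pool the stratum risk differences with
  stratum-size weights;
* **inverse-probability-of-treatment weighting (IPTW)** — weight
  exposed subjects by 1/PS and unexposed by 1/(1-PS) (unstabilized),
  then fit a weighted, covariate-adjusted outcome model and marginally
  standardize;
* **greedy 1:1 matching** — match exposed to unexposed without
  replacement on the score at 5 decimal places, then 4, ... down to 1,
  the standard digit-greedy procedure, with balance diagnostics
  (standardized differences), McNemar tests and Kaplan-Meier curves on
  the matched sample.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import COVARIATES
from .estimators import (
    DesignSpec,
    FitResult,
    RiskEstimate,
    Z975,
    fit_logistic,
    marginal_arr,
)

__all__ = [
    "PropensityResult",
    "MatchedSample",
    "derive_propensity",
    "quintile_stratified_rates",
    "iptw_weights",
    "iptw_arr",
    "greedy_match",
    "standardized_difference",
    "balance_table",
    "mcnemar_test",
    "km_cumulative",
    "matched_arr",
]

SCORE_CLIP = 1e-6


@dataclass
class PropensityResult:
    """Per-subject scores (same row order as the input) plus the fit."""

    scores: np.ndarray
    fit: FitResult


@dataclass
class MatchedSample:
    """1:1 matched pairs (without replacement)."""

    pairs: pd.DataFrame  # treated_id, control_id, distance, digits
    n_unmatched_treated: int


def derive_propensity(rows: pd.DataFrame) -> PropensityResult:
    """Fit the propensity model and return clipped fitted probabilities."""
    design = DesignSpec(outcome="exposed", exposure=None, covariates=COVARIATES)
    fit = fit_logistic(design, rows)
    scores = np.clip(fit.predict(rows), SCORE_CLIP, 1 - SCORE_CLIP)
    return PropensityResult(scores=scores, fit=fit)


# ---------------------------------------------------------------------------
# quintile stratification
# ---------------------------------------------------------------------------

def quintile_stratified_rates(
    rows: pd.DataFrame,
    scores: np.ndarray,
    outcome: str,
    n_strata: int = 5,
) -> tuple[pd.DataFrame, RiskEstimate]:
    """Event rates per score stratum and the pooled risk difference.

    Strata are equal-count rank splits (ties resolved by stable rank,
    sizes within +-1), so constant scores still produce five usable
    strata.  The pooled ARR is the stratum-size-weighted mean of the
    stratum ARRs; strata missing an arm are excluded from pooling and
    flagged in the table.
    """
    n = len(rows)
    if n < n_strata:
        raise ValueError(f"need at least {n_strata} rows")
    order = np.argsort(scores, kind="stable")
    stratum = np.empty(n, dtype=int)
    stratum[order] = (np.arange(n) * n_strata) // n

    exposed = rows["exposed"].to_numpy(dtype=bool)
    y = rows[outcome].to_numpy(dtype=float)

    records = []
    for s in range(n_strata):
        m = stratum == s
        e, u = m & exposed, m & ~exposed
        n1, n0 = int(e.sum()), int(u.sum())
        rate1 = float(y[e].mean()) if n1 else np.nan
        rate0 = float(y[u].mean()) if n0 else np.nan
        records.append(
            {
                "stratum": s + 1,
                "n": int(m.sum()),
                "n_exposed": n1,
                "n_unexposed": n0,
                "rate_exposed_pct": 100 * rate1,
                "rate_unexposed_pct": 100 * rate0,
                "both_arms": bool(n1 and n0),
            }
        )
    table = pd.DataFrame(records)
    usable = table[table["both_arms"]]
    if usable.empty:
        raise ValueError("every stratum is missing an exposure arm")

    wts = usable["n"].to_numpy(dtype=float)
    wts = wts / wts.sum()
    diffs = (usable["rate_exposed_pct"] - usable["rate_unexposed_pct"]).to_numpy()
    arr = float(wts @ diffs)
    # unpooled binomial variance per stratum, combined with the same weights
    var = 0.0
    p1_bar = 0.0
    p0_bar = 0.0
    for w, (_, r) in zip(wts, usable.iterrows()):
        p1 = r["rate_exposed_pct"] / 100
        p0 = r["rate_unexposed_pct"] / 100
        var += w**2 * (p1 * (1 - p1) / r["n_exposed"] + p0 * (1 - p0) / r["n_unexposed"])
        p1_bar += w * p1
        p0_bar += w * p0
    half = 100 * Z975 * np.sqrt(var)
    est = RiskEstimate(
        method="ps_quintile",
        p_unexposed=100 * p0_bar,
        p_exposed=100 * p1_bar,
        arr=arr,
        ci_arr=(arr - half, arr + half),
        n=int(usable["n"].sum()),
        extra={"n_strata_used": int(len(usable))},
    )
    return table, est


# ---------------------------------------------------------------------------
# IPTW
# ---------------------------------------------------------------------------

def iptw_weights(scores: np.ndarray, exposed: np.ndarray) -> np.ndarray:
    """Unstabilized inverse-probability-of-treatment weights."""
    scores = np.asarray(scores, dtype=float)
    exposed = np.asarray(exposed, dtype=bool)
    if ((scores <= 0) | (scores >= 1)).any():
        raise ValueError("propensity scores must lie strictly inside (0, 1)")
    return np.where(exposed, 1.0 / scores, 1.0 / (1.0 - scores))


def iptw_arr(
    rows: pd.DataFrame,
    scores: np.ndarray,
    outcome: str,
    covariates: tuple = tuple(COVARIATES),
    ci: str = "delta",
    seed: int = 0,
) -> RiskEstimate:
    """PS-weighted, covariate-adjusted outcome model, marginally standardized.

    Weights enter the IRLS working weights and are treated as fixed by
    the cluster-robust variance.  Extreme-weight diagnostics (max and
    99th percentile) are attached to the estimate.
    """
    w = iptw_weights(scores, rows["exposed"].to_numpy(dtype=bool))
    design = DesignSpec(outcome=outcome, exposure="exposed", covariates=covariates)
    fit = fit_logistic(design, rows, weights=w)
    est = marginal_arr(fit, rows, method="ps_iptw", ci=ci, seed=seed)
    est.extra.update(
        {
            "max_weight": float(w.max()),
            "p99_weight": float(np.percentile(w, 99)),
            "sum_weights_exposed": float(w[rows["exposed"].to_numpy(dtype=bool)].sum()),
            "sum_weights_unexposed": float(w[~rows["exposed"].to_numpy(dtype=bool)].sum()),
        }
    )
    return est


# ---------------------------------------------------------------------------
# greedy matching
# ---------------------------------------------------------------------------

def greedy_match(
    scores: np.ndarray,
    exposed: np.ndarray,
    seed: int = 0,
    ids: np.ndarray | None = None,
    digits: range = range(5, 0, -1),
    caliper: float | None = None,
) -> MatchedSample:
    """Digit-based greedy 1:1 matching without replacement.

    Pass *d* matches treated subjects to the nearest still-available
    control whose score agrees on the first *d* decimal places; passes
    run from 5 digits down to 1.  Within a pass, treated subjects are
    processed in a seeded-random order derived from their (sorted) ids,
    so permuting input row order changes nothing.  Unmatched treated
    subjects are allowed and counted.  ``caliper``, if given, bounds
    the raw score distance of any accepted pair.
    """
    scores = np.asarray(scores, dtype=float)
    exposed = np.asarray(exposed, dtype=bool)
    if ids is None:
        ids = np.arange(len(scores))
    ids = np.asarray(ids)

    # canonical order: sort both arms by id, then seeded shuffle of treated
    t_idx = np.flatnonzero(exposed)
    c_idx = np.flatnonzero(~exposed)
    t_idx = t_idx[np.argsort(ids[t_idx], kind="stable")]
    c_idx = c_idx[np.argsort(ids[c_idx], kind="stable")]
    rng = np.random.default_rng(seed)
    t_order = t_idx[rng.permutation(len(t_idx))]

    matched_treated: list[int] = []
    matched_control: list[int] = []
    distances: list[float] = []
    pass_digits: list[int] = []
    available_t = list(t_order)

    # controls kept in per-key sorted lists, rebuilt each pass
    for d in digits:
        if not available_t or not len(c_idx):
            break
        # bucket entries sorted by (score, id) so ties resolve by lowest id
        buckets: dict[float, list[tuple[float, int, int]]] = {}
        for ci in c_idx:
            key = round(scores[ci], d)
            buckets.setdefault(key, []).append((scores[ci], int(ids[ci]), ci))
        for key in buckets:
            buckets[key].sort()
        still: list[int] = []
        for ti in available_t:
            key = round(scores[ti], d)
            bucket = buckets.get(key)
            if not bucket:
                still.append(ti)
                continue
            pos = bisect_left(bucket, (scores[ti],))
            best = None
            for cand in (pos - 1, pos):
                if 0 <= cand < len(bucket):
                    dist = abs(bucket[cand][0] - scores[ti])
                    if best is None or dist < best[0] or (
                        dist == best[0] and bucket[cand][1] < ids[best[1]]
                    ):
                        best = (dist, bucket[cand][2], cand)
            if best is None or (caliper is not None and best[0] > caliper):
                still.append(ti)
                continue
            matched_treated.append(ti)
            matched_control.append(best[1])
            distances.append(best[0])
            pass_digits.append(d)
            bucket.pop(best[2])
        available_t = still
        c_idx = np.array(
            sorted(set(c_idx) - set(matched_control)), dtype=int
        )

    pairs = pd.DataFrame(
        {
            "treated_id": ids[matched_treated] if matched_treated else np.array([], dtype=ids.dtype),
            "control_id": ids[matched_control] if matched_control else np.array([], dtype=ids.dtype),
            "distance": np.array(distances, dtype=float),
            "digits": np.array(pass_digits, dtype=int),
        }
    )
    return MatchedSample(pairs=pairs, n_unmatched_treated=len(available_t))


# ---------------------------------------------------------------------------
# balance diagnostics
# ---------------------------------------------------------------------------

def standardized_difference(p1: float, p2: float) -> float:
    """Standardized difference (%) between two proportions.

    ``100 * |p1 - p2| / sqrt((p1(1-p1) + p2(1-p2)) / 2)``; defined as 0
    when both variances vanish with equal proportions.
    """
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("proportions must lie in [0, 1]")
    pooled = (p1 * (1 - p1) + p2 * (1 - p2)) / 2.0
    if pooled == 0:
        if p1 == p2:
            return 0.0
        return float("inf")
    return 100.0 * abs(p1 - p2) / float(np.sqrt(pooled))


def balance_table(rows: pd.DataFrame, covariates=tuple(COVARIATES)) -> pd.DataFrame:
    """Per covariate level: arm proportions, chi-square p, std. difference.

    The chi-square p-value is reported per covariate (as customary in
    baseline tables) but balance decisions rest on the standardized
    difference alone.
    """
    exposed = rows["exposed"].to_numpy(dtype=bool)
    records = []
    for cov in covariates:
        values = rows[cov]
        levels = sorted(values.unique(), key=str)
        contingency = pd.crosstab(values, exposed)
        if contingency.shape[1] == 2 and (contingency.to_numpy() > 0).all():
            chi2_p = float(stats.chi2_contingency(contingency)[1])
        else:
            chi2_p = np.nan
        for lev in levels:
            ind = (values == lev).to_numpy()
            p1 = float(ind[exposed].mean())
            p0 = float(ind[~exposed].mean())
            records.append(
                {
                    "covariate": cov,
                    "level": lev,
                    "prop_exposed": p1,
                    "prop_unexposed": p0,
                    "chi2_p": chi2_p,
                    "std_diff_pct": standardized_difference(p1, p0),
                }
            )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# paired tests and survival curves
# ---------------------------------------------------------------------------

@dataclass
class McNemarResult:
    statistic: float
    p_value: float
    b: int  # treated-only events
    c: int  # control-only events
    exact: bool = False


def mcnemar_test(
    treated_outcomes: np.ndarray, control_outcomes: np.ndarray
) -> McNemarResult:
    """McNemar test on paired binary outcomes.

    Chi-square form ``(b - c)^2 / (b + c)`` on the discordant counts;
    the exact binomial p-value is used when ``b + c < 25``.  With no
    discordant pairs the statistic is 0 and p = 1 by convention.
    """
    t = np.asarray(treated_outcomes, dtype=bool)
    c_arr = np.asarray(control_outcomes, dtype=bool)
    if t.shape != c_arr.shape:
        raise ValueError("paired outcome vectors must have equal length")
    b = int((t & ~c_arr).sum())
    c = int((~t & c_arr).sum())
    if b + c == 0:
        return McNemarResult(statistic=0.0, p_value=1.0, b=b, c=c)
    stat = (b - c) ** 2 / (b + c)
    if b + c < 25:
        p = float(stats.binomtest(b, b + c, 0.5).pvalue)
        return McNemarResult(statistic=stat, p_value=p, b=b, c=c, exact=True)
    return McNemarResult(statistic=stat, p_value=float(stats.chi2.sf(stat, 1)), b=b, c=c)


def km_cumulative(
    event_year: np.ndarray,
    censor_year: np.ndarray,
    horizon: int,
) -> pd.DataFrame:
    """Product-limit cumulative event probability on a yearly grid.

    ``event_year`` is NaN for subjects who never have the event;
    ``censor_year`` is the year after which the subject is no longer
    observed (e.g. other-cause death), NaN meaning observed to the
    horizon.  Events and censorings in the same year count the event
    first.  Returns columns year, n_at_risk, n_events, cum_incidence.
    """
    event_year = np.asarray(event_year, dtype=float)
    censor_year = np.asarray(censor_year, dtype=float)
    n = len(event_year)
    censor = np.where(np.isnan(censor_year), horizon, np.minimum(censor_year, horizon))
    has_event = ~np.isnan(event_year) & (event_year <= censor)

    surv = 1.0
    records = []
    for year in range(1, horizon + 1):
        at_risk = int(
            ((~has_event) & (censor >= year)).sum()
            + (has_event & (event_year >= year)).sum()
        )
        d = int((has_event & (event_year == year)).sum())
        if at_risk > 0:
            surv *= 1.0 - d / at_risk
        records.append(
            {
                "year": year,
                "n_at_risk": at_risk,
                "n_events": d,
                "cum_incidence": 1.0 - surv,
            }
        )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# matched analysis
# ---------------------------------------------------------------------------

def matched_arr(
    matched: MatchedSample,
    rows: pd.DataFrame,
    outcome: str,
) -> tuple[RiskEstimate, pd.DataFrame]:
    """Arm risks and ARR over matched pairs, plus subgroup table.

    The ARR variance uses the paired-difference formula, and the
    McNemar p-value is attached.  Subgroups (sex-by-age and income
    quintile, defined by the treated member) with no pairs are omitted.
    """
    if len(matched.pairs) == 0:
        raise ValueError("no matched pairs")
    by_id = rows.set_index("subject_id")
    t_rows = by_id.loc[matched.pairs["treated_id"].to_numpy()]
    c_rows = by_id.loc[matched.pairs["control_id"].to_numpy()]
    yt = t_rows[outcome].to_numpy(dtype=bool)
    yc = c_rows[outcome].to_numpy(dtype=bool)

    est = _paired_estimate(yt, yc, "ps_matched")

    groups: list[tuple[str, np.ndarray]] = []
    sex = t_rows["sex"].to_numpy()
    age = t_rows["age_group"].to_numpy()
    for s in ("M", "F"):
        groups.append((f"sex={s}", sex == s))
        for a in ("50-59", "60-69", "70-74"):
            groups.append((f"sex={s},age={a}", (sex == s) & (age == a)))
    inc = t_rows["income_quintile"].to_numpy()
    for q in range(1, 6):
        groups.append((f"income_q{q}", inc == q))

    records = []
    for label, mask in groups:
        if not mask.any():
            continue
        sub = _paired_estimate(yt[mask], yc[mask], label)
        records.append(
            {
                "subgroup": label,
                "n_pairs": int(mask.sum()),
                "rate_exposed_pct": sub.p_exposed,
                "rate_unexposed_pct": sub.p_unexposed,
                "arr": sub.arr,
                "mcnemar_p": sub.extra["mcnemar_p"],
            }
        )
    return est, pd.DataFrame(records)


def _paired_estimate(yt: np.ndarray, yc: np.ndarray, method: str) -> RiskEstimate:
    n = len(yt)
    p1, p0 = float(yt.mean()), float(yc.mean())
    arr = 100.0 * (p1 - p0)
    diffs = yt.astype(float) - yc.astype(float)
    se = float(np.sqrt(np.var(diffs, ddof=1) / n)) if n > 1 else np.nan
    test = mcnemar_test(yt, yc)
    _, lo1, hi1 = (100 * p1, *_wald(p1, n))
    _, lo0, hi0 = (100 * p0, *_wald(p0, n))
    return RiskEstimate(
        method=method,
        p_unexposed=100 * p0,
        p_exposed=100 * p1,
        arr=arr,
        ci_unexposed=(lo0, hi0),
        ci_exposed=(lo1, hi1),
        ci_arr=(arr - 100 * Z975 * se, arr + 100 * Z975 * se),
        n=n,
        extra={"mcnemar_p": test.p_value, "mcnemar_statistic": test.statistic},
    )


def _wald(p: float, n: int) -> tuple[float, float]:
    half = Z975 * np.sqrt(p * (1 - p) / n)
    return 100 * (p - half), 100 * (p + half)
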