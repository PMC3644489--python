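"""Synthetic screening registry generation.

Produces a seeded population of screen-eligible subjects nested within
primary-care physicians (PCPs), with the three structural features that
make observational screening studies hard to analyse:

* **clustering** — colonoscopy uptake varies across PCPs through a
  latent referral propensity, which later serves as the source of the
  physician-preference instrument;
* **confounding** — measured covariates and an unmeasured subject-level
  factor ``u`` shift both uptake and cancer risk;
* **exposure measurement error** — cancers arising during the exposure
  window trigger *diagnostic* colonoscopies, so in a naively constructed
  cohort the procedure appears to cause the disease it detects.

Time is a discrete annual clock: colonoscopies occur in years 1-5,
incident colorectal cancer (CRC) is followed through year 12 and CRC
death through year 10.

All draws are vectorised and flow from a single seed through one
independent substream per generation stage, so enlarging the subject
population does not perturb the physician draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import AGE_GROUPS, COMORBIDITY_LEVELS, GeneratorConfig

__all__ = [
    "RegistrySnapshot",
    "generate_pcps",
    "generate_subjects",
    "assign_exposure",
    "simulate_outcomes",
    "generate_registry",
    "exposure_linear_predictor",
    "true_marginal_arr",
    "validate_registry",
]

# stage tags for the per-stage RNG substreams
_STAGE_PCPS = 1
_STAGE_COVARIATES = 2
_STAGE_EXPOSURE = 3
_STAGE_OUTCOMES = 4

LOGIT_CLIP = 30.0

INCIDENCE_END_YEAR = 12
MORTALITY_END_YEAR = 10
EXPOSURE_WINDOW_END = 5
#: CRC deaths occur 0-2 years after diagnosis (uniform), capped at year 12.
MAX_DEATH_LAG = 2

EVENT_COLUMNS = [
    "screening_year",
    "diagnostic_year",
    "diagnostic_inpatient",
    "crc_dx_year",
    "crc_death_year",
    "other_death_year",
]


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(stage,)))


@dataclass
class RegistrySnapshot:
    """A complete generated registry: config + physicians + subjects."""

    config: GeneratorConfig
    pcps: pd.DataFrame
    subjects: pd.DataFrame

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.json").write_text(self.config.to_json())
        self.pcps.to_csv(outdir / "pcps.csv", index=False)
        export_subjects(self.subjects).to_csv(outdir / "subjects.csv", index=False)

    @classmethod
    def load(cls, indir: str | Path) -> "RegistrySnapshot":
        indir = Path(indir)
        config = GeneratorConfig.from_json((indir / "config.json").read_text())
        pcps = pd.read_csv(indir / "pcps.csv")
        subjects = pd.read_csv(indir / "subjects.csv")
        for col in EVENT_COLUMNS:
            if col == "diagnostic_inpatient":
                subjects[col] = subjects[col].fillna(0).astype(bool)
            else:
                subjects[col] = subjects[col].astype("Int64")
        subjects["rural"] = subjects["rural"].astype(bool)
        return cls(config=config, pcps=pcps, subjects=subjects)


def export_subjects(subjects: pd.DataFrame) -> pd.DataFrame:
    """Flatten subjects for CSV export.

    The latent confounder is deliberately dropped: analysis inputs must
    never contain it (it exists only to create unmeasured confounding).
    """
    out = subjects.drop(columns=["confounder_u"], errors="ignore").copy()
    out["rural"] = out["rural"].astype(int)
    out["diagnostic_inpatient"] = out["diagnostic_inpatient"].astype(int)
    return out


# ---------------------------------------------------------------------------
# generation stages
# ---------------------------------------------------------------------------

def generate_pcps(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the physician panel: latent referral propensity and panel size.

    Panel sizes are gamma-Poisson (negative binomial) with mean
    ``mean_panel`` and variance ``mean_panel * (1 + panel_dispersion)``;
    dispersion 0 gives pure Poisson.  The latent referral propensity is
    normal on the logit scale.
    """
    config.validate()
    rng = _stage_rng(config.seed, _STAGE_PCPS)
    n = config.n_pcps
    if config.panel_dispersion > 0:
        shape = config.mean_panel / config.panel_dispersion
        lam = rng.gamma(shape=shape, scale=config.panel_dispersion, size=n)
    else:
        lam = np.full(n, float(config.mean_panel))
    panel = rng.poisson(lam)
    panel = np.maximum(panel, 0)
    propensity = config.pcp_propensity_mu + config.pcp_propensity_sigma * rng.standard_normal(n)
    return pd.DataFrame(
        {
            "pcp_id": np.arange(n, dtype=np.int64),
            "propensity_logit": propensity,
            "n_eligible": panel.astype(np.int64),
            "discretionary_rate": np.full(n, np.nan),
        }
    )


def generate_subjects(config: GeneratorConfig, pcps: pd.DataFrame) -> pd.DataFrame:
    """Draw subject covariates and the latent confounder; no events yet."""
    config.validate()
    if len(pcps) == 0:
        raise ValueError("pcps must be nonempty")
    rng = _stage_rng(config.seed, _STAGE_COVARIATES)
    freqs = config.covariate_freqs
    n = int(pcps["n_eligible"].sum())
    pcp_id = np.repeat(pcps["pcp_id"].to_numpy(), pcps["n_eligible"].to_numpy())

    age = rng.choice(
        np.array(AGE_GROUPS), size=n, p=[freqs.age_group[a] for a in AGE_GROUPS]
    )
    sex = np.where(rng.random(n) < freqs.female, "F", "M")
    income = rng.choice(
        np.arange(1, 6), size=n, p=[freqs.income_quintile[q] for q in range(1, 6)]
    )
    rural = rng.random(n) < freqs.rural
    comorbidity = rng.choice(
        np.array(COMORBIDITY_LEVELS),
        size=n,
        p=[freqs.comorbidity[c] for c in COMORBIDITY_LEVELS],
    )
    u = rng.standard_normal(n)

    return pd.DataFrame(
        {
            "subject_id": np.arange(n, dtype=np.int64),
            "pcp_id": pcp_id,
            "age_group": age,
            "sex": sex,
            "income_quintile": income.astype(np.int64),
            "rural": rural,
            "comorbidity": comorbidity,
            "confounder_u": u,
        }
    )


def exposure_linear_predictor(
    config: GeneratorConfig, subjects: pd.DataFrame, propensity_logit: np.ndarray
) -> np.ndarray:
    """Logit-scale uptake predictor, clipped to avoid overflow."""
    b = config.beta_exposure
    lp = (
        b.intercept
        + b.instrument * propensity_logit
        + b.age_60_69 * (subjects["age_group"] == "60-69").to_numpy()
        + b.age_70_74 * (subjects["age_group"] == "70-74").to_numpy()
        + b.female * (subjects["sex"] == "F").to_numpy()
        + b.income_q2 * (subjects["income_quintile"] == 2).to_numpy()
        + b.income_q3 * (subjects["income_quintile"] == 3).to_numpy()
        + b.income_q4 * (subjects["income_quintile"] == 4).to_numpy()
        + b.income_q5 * (subjects["income_quintile"] == 5).to_numpy()
        + b.rural * subjects["rural"].to_numpy()
        + b.comorbidity_hosp * (subjects["comorbidity"] == "hosp_no_comorbidity").to_numpy()
        + b.comorbidity_multi * (subjects["comorbidity"] == "comorbid").to_numpy()
        + b.confounder * subjects["confounder_u"].to_numpy()
    )
    return np.clip(lp, -LOGIT_CLIP, LOGIT_CLIP)


def assign_exposure(
    config: GeneratorConfig, pcps: pd.DataFrame, subjects: pd.DataFrame
) -> pd.DataFrame:
    """Draw colonoscopy events.

    Two independent processes:

    * screening colonoscopy (at most one per subject), with probability
      ``inverse-logit`` of the uptake predictor, in a uniform year 1-5,
      always outpatient;
    * incipient ("window") CRC with probability ``window_crc_rate``,
      diagnosed in a uniform year 1-5; such a case receives a diagnostic
      colonoscopy in its diagnosis year with probability
      ``p_diagnostic_given_window_crc``.  This is the measurement-error
      mechanism: the disease causes the procedure.
    """
    rng = _stage_rng(config.seed, _STAGE_EXPOSURE)
    n = len(subjects)
    prop = pcps.set_index("pcp_id")["propensity_logit"]
    prop_per_subject = prop.loc[subjects["pcp_id"]].to_numpy()

    p_screen = expit(exposure_linear_predictor(config, subjects, prop_per_subject))
    screened = rng.random(n) < p_screen
    screening_year_draw = rng.integers(1, EXPOSURE_WINDOW_END + 1, size=n)

    window_crc = rng.random(n) < config.window_crc_rate
    window_dx_year_draw = rng.integers(1, EXPOSURE_WINDOW_END + 1, size=n)
    diagnostic = window_crc & (rng.random(n) < config.p_diagnostic_given_window_crc)

    out = subjects.copy()
    out["screening_year"] = pd.array(
        np.where(screened, screening_year_draw, 0), dtype="Int64"
    )
    out.loc[~screened, "screening_year"] = pd.NA
    out["diagnostic_year"] = pd.array(
        np.where(diagnostic, window_dx_year_draw, 0), dtype="Int64"
    )
    out.loc[~diagnostic, "diagnostic_year"] = pd.NA
    out["diagnostic_inpatient"] = False
    out["crc_dx_year"] = pd.array(np.where(window_crc, window_dx_year_draw, 0), dtype="Int64")
    out.loc[~window_crc, "crc_dx_year"] = pd.NA
    return out


def simulate_outcomes(config: GeneratorConfig, subjects: pd.DataFrame) -> pd.DataFrame:
    """Draw follow-up CRC, CRC death and other-cause death.

    Follow-up CRC (years 6-12, disjoint from window CRC) has per-subject
    probability ``inverse-logit(logit(baseline) + log(rr)*screened +
    gamma*u)`` where the baseline is the age-by-sex 7-year risk.  A CRC
    case dies of CRC with probability ``p_death_given_crc_5y``, 0-2
    years after diagnosis.  Other-cause death is an annual geometric
    hazard independent of exposure and cancer.
    """
    rng = _stage_rng(config.seed, _STAGE_OUTCOMES)
    n = len(subjects)
    out = subjects.copy()

    p_follow = _followup_crc_prob(
        config,
        subjects,
        screened=subjects["screening_year"].notna().to_numpy(),
    )
    has_window_crc = subjects["crc_dx_year"].notna().to_numpy()
    follow_crc = (~has_window_crc) & (rng.random(n) < p_follow)
    follow_year = rng.integers(EXPOSURE_WINDOW_END + 1, INCIDENCE_END_YEAR + 1, size=n)

    dx_year = out["crc_dx_year"].to_numpy(dtype="float64", na_value=np.nan)
    dx_year = np.where(follow_crc, follow_year, dx_year)
    is_case = ~np.isnan(dx_year)

    dies = is_case & (rng.random(n) < config.p_death_given_crc_5y)
    lag = rng.integers(0, MAX_DEATH_LAG + 1, size=n)
    death_year = np.minimum(dx_year + lag, INCIDENCE_END_YEAR)

    if config.p_other_death > 0:
        other_year = rng.geometric(config.p_other_death, size=n).astype("float64")
        other_year[other_year > INCIDENCE_END_YEAR] = np.nan
    else:
        other_year = np.full(n, np.nan)

    out["crc_dx_year"] = _to_int64(dx_year, is_case)
    out["crc_death_year"] = _to_int64(death_year, dies)
    out["other_death_year"] = _to_int64(other_year, ~np.isnan(other_year))
    return out


def _to_int64(values: np.ndarray, mask: np.ndarray) -> pd.arrays.IntegerArray:
    arr = pd.array(np.where(mask, np.nan_to_num(values), 0).astype(np.int64), dtype="Int64")
    arr[~mask] = pd.NA
    return arr


def _followup_crc_prob(
    config: GeneratorConfig, subjects: pd.DataFrame, screened: np.ndarray
) -> np.ndarray:
    base = np.array(
        [
            config.baseline_risk_7y[(a, s)]
            for a, s in zip(subjects["age_group"], subjects["sex"])
        ]
    )
    lp = (
        logit(np.clip(base, 1e-12, 1 - 1e-12))
        + np.log(config.rr_colonoscopy) * screened.astype(float)
        + config.gamma_confounder * subjects["confounder_u"].to_numpy()
    )
    return expit(np.clip(lp, -LOGIT_CLIP, LOGIT_CLIP))


def generate_registry(config: GeneratorConfig) -> RegistrySnapshot:
    """Run all stages; deterministic given ``config`` (incl. its seed)."""
    pcps = generate_pcps(config)
    subjects = generate_subjects(config, pcps)
    subjects = assign_exposure(config, pcps, subjects)
    subjects = simulate_outcomes(config, subjects)
    return RegistrySnapshot(config=config, pcps=pcps, subjects=subjects)


# ---------------------------------------------------------------------------
# counterfactual truth
# ---------------------------------------------------------------------------

def true_marginal_arr(
    config: GeneratorConfig,
    subjects: pd.DataFrame,
    outcome: str = "incidence",
    subset: np.ndarray | pd.Index | None = None,
) -> float:
    """Exact counterfactual marginal ARR of screening, in percentage points.

    Evaluates every subject's follow-up outcome probability under
    screening set to 1 and to 0 — holding the subject's covariates and
    latent confounder fixed — and returns ``100 * (mean p1 - mean p0)``.
    This is the exact expectation of a common-random-numbers
    counterfactual simulation, and is the recovery target for all
    estimators.  ``subset`` (boolean mask or index into ``subjects``)
    restricts the population, e.g. to a matched sample's treated
    subjects for an average-treatment-effect-on-the-treated target.

    Only the follow-up cancer process responds to screening; window CRC
    (and its diagnostic colonoscopy) is exposure-independent by design,
    so subjects are weighted by their probability of being at risk of
    follow-up CRC, which cancels in the difference.
    """
    if subset is not None:
        subset = np.asarray(subset)
        subjects = subjects[subset] if subset.dtype == bool else subjects.loc[subset]
    p1 = _followup_crc_prob(config, subjects, screened=np.ones(len(subjects), dtype=bool))
    p0 = _followup_crc_prob(config, subjects, screened=np.zeros(len(subjects), dtype=bool))
    if outcome == "incidence":
        scale = 1.0
    elif outcome == "mortality":
        scale = config.p_death_given_crc_5y * _p_death_counted()
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    return 100.0 * scale * float(np.mean(p1) - np.mean(p0))


def _p_death_counted() -> float:
    """P(CRC death year <= mortality horizon | follow-up CRC case).

    Diagnosis year uniform on 6..12, death lag uniform on 0..2.
    """
    years = np.arange(EXPOSURE_WINDOW_END + 1, INCIDENCE_END_YEAR + 1)
    lags = np.arange(0, MAX_DEATH_LAG + 1)
    counted = (years[:, None] + lags[None, :]) <= MORTALITY_END_YEAR
    return counted.mean()


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------

def validate_registry(snapshot: RegistrySnapshot) -> None:
    """Check every structural invariant of a generated registry.

    Raises ``AssertionError`` naming the first violated invariant.
    """
    subj = snapshot.subjects
    assert subj["subject_id"].is_unique, "subject ids must be unique"
    assert subj["pcp_id"].isin(snapshot.pcps["pcp_id"]).all(), "orphan pcp_id"

    dx = subj["crc_dx_year"]
    death = subj["crc_death_year"]
    has_death = death.notna()
    assert dx[has_death].notna().all(), "CRC death without CRC diagnosis"
    assert (death[has_death] >= dx[has_death]).all(), "CRC death before diagnosis"

    diag = subj["diagnostic_year"].notna()
    assert (dx[diag] <= EXPOSURE_WINDOW_END).all(), (
        "diagnostic colonoscopy requires a window CRC diagnosis"
    )
    assert (subj.loc[diag, "diagnostic_year"] == dx[diag]).all(), (
        "diagnostic colonoscopy must occur in the diagnosis year"
    )
    sy = subj["screening_year"].dropna()
    assert sy.between(1, EXPOSURE_WINDOW_END).all(), "screening year outside window"
    assert subj["crc_dx_year"].dropna().between(1, INCIDENCE_END_YEAR).all()
    assert subj["crc_death_year"].dropna().between(1, INCIDENCE_END_YEAR).all()
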