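"""Cohort construction: eligibility filters, instrument, analysis rows.

Two cohort designs are supported, mirroring the two ways an
administrative-data screening study can be assembled:

* the **unselected cohort** takes every generated subject and measures
  exposure and outcome over the same calendar window, so diagnostic
  colonoscopies performed *because of* an incipient cancer count as
  exposure — the source of the paradoxical harm signal;
* the **restricted cohort** keeps only subjects alive and cancer-free
  at the end of the exposure window, and only patients of physicians
  with a meaningful screening practice (>= 10 eligible patients and an
  any-colonoscopy referral rate strictly above 3%), so exposure
  measurement is separated in time from outcome ascertainment.

The physician-preference instrument — each PCP's discretionary
colonoscopies per 100 eligible patients — is always computed on the
full pre-restriction panel, so restriction cannot leak outcome
information into the instrument.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import RegistrySnapshot

__all__ = [
    "CohortSpec",
    "Cohort",
    "EmptyCohortError",
    "AllPCPsExcludedError",
    "classify_discretionary",
    "compute_pcp_instrument",
    "compute_referral_rates",
    "build_unselected_cohort",
    "build_restricted_cohort",
    "build_cohort",
]

logger = logging.getLogger(__name__)

COVARIATES = ["age_group", "sex", "income_quintile", "rural", "comorbidity"]

ROW_COLUMNS = [
    "subject_id",
    "pcp_id",
    "exposed",
    "crc_incident",
    "crc_death",
    *COVARIATES,
    "instrument",
]


class EmptyCohortError(ValueError):
    """No subjects remain after applying the cohort filters."""


class AllPCPsExcludedError(ValueError):
    """Every physician failed the panel-size or referral-rate filter."""


@dataclass(frozen=True)
class CohortSpec:
    """Filters and follow-up windows defining a cohort."""

    cohort_kind: str = "restricted"  # {"unselected", "restricted"}
    min_pcp_eligible: int = 10
    min_referral_rate_pct: float = 3.0
    referral_rate_basis: str = "any"  # {"any", "discretionary"}
    discretionary_lookahead_years: int = 3
    exposure_window_end: int = 5
    incidence_end_year: int = 12
    mortality_end_year: int = 10

    def __post_init__(self) -> None:
        if self.cohort_kind not in ("unselected", "restricted"):
            raise ValueError(f"unknown cohort_kind {self.cohort_kind!r}")
        if not (0.0 <= self.min_referral_rate_pct <= 100.0):
            raise ValueError("min_referral_rate_pct must be in [0, 100]")
        if self.discretionary_lookahead_years < 0:
            raise ValueError("discretionary_lookahead_years must be >= 0")
        if self.referral_rate_basis not in ("any", "discretionary"):
            raise ValueError(f"unknown referral_rate_basis {self.referral_rate_basis!r}")
        if not (
            self.exposure_window_end
            <= self.mortality_end_year
            <= self.incidence_end_year
        ):
            raise ValueError("follow-up windows must be ordered")


@dataclass
class Cohort:
    """Analysis-ready cohort: one flat row per subject plus flow counts."""

    spec: CohortSpec
    rows: pd.DataFrame
    counts: dict = field(default_factory=dict)

    def save(self, csv_path: str | Path) -> None:
        csv_path = Path(csv_path)
        out = self.rows.copy()
        for col in ("exposed", "crc_incident", "crc_death", "rural"):
            out[col] = out[col].astype(int)
        out.to_csv(csv_path, index=False)
        sidecar = csv_path.with_suffix(".counts.json")
        sidecar.write_text(
            json.dumps({"spec": asdict(self.spec), "counts": self.counts}, indent=2)
        )

    @classmethod
    def load(cls, csv_path: str | Path) -> "Cohort":
        csv_path = Path(csv_path)
        rows = pd.read_csv(csv_path)
        for col in ("exposed", "crc_incident", "crc_death", "rural"):
            rows[col] = rows[col].astype(bool)
        sidecar = csv_path.with_suffix(".counts.json")
        spec = CohortSpec()
        counts: dict = {}
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            spec = CohortSpec(**meta.get("spec", {}))
            counts = meta.get("counts", {})
        return cls(spec=spec, rows=rows, counts=counts)


# ---------------------------------------------------------------------------
# discretionary classification and the instrument
# ---------------------------------------------------------------------------

def classify_discretionary(
    subjects: pd.DataFrame, lookahead_years: int = 3
) -> pd.DataFrame:
    """Flag each colonoscopy event as discretionary or not.

    A colonoscopy is *discretionary* iff it is a screening-kind
    outpatient procedure with no CRC diagnosis at the time of the
    procedure or within ``lookahead_years`` years after it.  Diagnostic
    colonoscopies are never discretionary (they are, by construction,
    associated with a concurrent CRC diagnosis).

    Returns a frame aligned with ``subjects`` with boolean columns
    ``screening_discretionary`` and ``diagnostic_discretionary``.
    """
    sy = subjects["screening_year"]
    dx = subjects["crc_dx_year"]
    no_crc_near = dx.isna() | (dx < sy) | (dx > sy + lookahead_years)
    screening_disc = (sy.notna() & no_crc_near).fillna(False).astype(bool)
    return pd.DataFrame(
        {
            "screening_discretionary": screening_disc.to_numpy(),
            "diagnostic_discretionary": np.zeros(len(subjects), dtype=bool),
        },
        index=subjects.index,
    )


def compute_pcp_instrument(
    pcps: pd.DataFrame, subjects: pd.DataFrame, spec: CohortSpec | None = None
) -> pd.DataFrame:
    """Fill each PCP's discretionary-colonoscopy rate per 100 eligible.

    ``n_eligible`` is recomputed as the count of linked subjects.  PCPs
    with an empty panel get an *undefined* rate (NaN) and
    ``instrument_defined = False``; the undefined rate is never coerced
    to a number.
    """
    spec = spec or CohortSpec()
    flags = classify_discretionary(subjects, spec.discretionary_lookahead_years)
    disc_count = (
        pd.Series(flags["screening_discretionary"].to_numpy(), index=subjects["pcp_id"])
        .groupby(level=0)
        .sum()
    )
    n_linked = subjects.groupby("pcp_id").size()

    out = pcps.copy()
    out["n_eligible"] = out["pcp_id"].map(n_linked).fillna(0).astype(np.int64)
    counts = out["pcp_id"].map(disc_count).fillna(0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = 100.0 * counts / out["n_eligible"].to_numpy()
    rate[out["n_eligible"] == 0] = np.nan
    out["discretionary_rate"] = rate
    out["instrument_defined"] = out["n_eligible"] > 0
    return out


def compute_referral_rates(
    pcps: pd.DataFrame, subjects: pd.DataFrame, spec: CohortSpec
) -> pd.Series:
    """Per-PCP colonoscopy referral rate (%) used by the restriction filter.

    By default the rate counts *any* colonoscopy (screening or
    diagnostic) among linked subjects; ``referral_rate_basis =
    "discretionary"`` counts only discretionary procedures.
    """
    if spec.referral_rate_basis == "discretionary":
        flags = classify_discretionary(subjects, spec.discretionary_lookahead_years)
        event = flags["screening_discretionary"].to_numpy()
    else:
        event = (
            subjects["screening_year"].notna() | subjects["diagnostic_year"].notna()
        ).to_numpy()
    counts = pd.Series(event, index=subjects["pcp_id"]).groupby(level=0).sum()
    n_linked = subjects.groupby("pcp_id").size()
    rate = 100.0 * counts / n_linked
    return rate.reindex(pcps["pcp_id"]).astype(float)


# ---------------------------------------------------------------------------
# cohort builders
# ---------------------------------------------------------------------------

def _assemble_rows(
    subjects: pd.DataFrame,
    exposed: pd.Series,
    incident: pd.Series,
    death: pd.Series,
    instrument: pd.Series,
) -> pd.DataFrame:
    rows = pd.DataFrame(
        {
            "subject_id": subjects["subject_id"].to_numpy(),
            "pcp_id": subjects["pcp_id"].to_numpy(),
            "exposed": exposed.to_numpy(dtype=bool),
            "crc_incident": incident.to_numpy(dtype=bool),
            "crc_death": death.to_numpy(dtype=bool),
        }
    )
    for cov in COVARIATES:
        rows[cov] = subjects[cov].to_numpy()
    rows["instrument"] = instrument.to_numpy(dtype=float)
    return rows


def _drop_missing_covariates(rows: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    missing = rows[COVARIATES].isna().any(axis=1)
    n_missing = int(missing.sum())
    if n_missing:
        logger.info("dropping %d rows with missing covariates", n_missing)
        rows = rows[~missing].reset_index(drop=True)
    return rows, n_missing


def _base_counts(rows: pd.DataFrame) -> dict:
    return {
        "n_subjects": int(len(rows)),
        "n_exposed": int(rows["exposed"].sum()),
        "n_incident": int(rows["crc_incident"].sum()),
        "n_deaths": int(rows["crc_death"].sum()),
    }


def build_unselected_cohort(
    registry: RegistrySnapshot, spec: CohortSpec | None = None
) -> Cohort:
    """All generated subjects; exposure and outcomes measured concurrently.

    Exposure is *any* colonoscopy (screening or diagnostic) during the
    window; incidence counts every CRC diagnosis through
    ``incidence_end_year`` including window cancers.  A subject whose
    only colonoscopy is the diagnostic one triggered by their own
    cancer is therefore exposed *and* incident — the measurement-error
    mechanism this design fails to exclude.
    """
    spec = spec or CohortSpec(cohort_kind="unselected")
    subj = registry.subjects
    if len(subj) == 0:
        raise EmptyCohortError("registry contains no subjects")

    pcps = compute_pcp_instrument(registry.pcps, subj, spec)
    instrument = subj["pcp_id"].map(pcps.set_index("pcp_id")["discretionary_rate"])

    exposed = subj["screening_year"].notna() | subj["diagnostic_year"].notna()
    incident = subj["crc_dx_year"].notna() & (
        subj["crc_dx_year"] <= spec.incidence_end_year
    )
    death = subj["crc_death_year"].notna() & (
        subj["crc_death_year"] <= spec.mortality_end_year
    )

    rows = _assemble_rows(subj, exposed, incident.fillna(False), death.fillna(False), instrument)
    rows, n_missing = _drop_missing_covariates(rows)
    counts = _base_counts(rows)
    counts.update(
        {
            "n_pcps_retained": int(pcps["instrument_defined"].sum()),
            "n_pcps_excluded": int((~pcps["instrument_defined"]).sum()),
            "n_dropped_missing_covariates": n_missing,
        }
    )
    return Cohort(spec=spec, rows=rows, counts=counts)


def build_restricted_cohort(
    registry: RegistrySnapshot, spec: CohortSpec | None = None
) -> Cohort:
    """Subjects alive and CRC-free at the end of the exposure window,
    nested in physicians with ``>= min_pcp_eligible`` eligible patients
    and a referral rate strictly above ``min_referral_rate_pct``.

    Outcomes are counted from year ``exposure_window_end + 1`` onward,
    so exposure measurement precedes outcome ascertainment; by
    construction no retained colonoscopy is associated with a window
    cancer.
    """
    spec = spec or CohortSpec(cohort_kind="restricted")
    subj = registry.subjects
    if len(subj) == 0:
        raise EmptyCohortError("registry contains no subjects")

    # instrument and referral rates on the full pre-restriction panel
    pcps = compute_pcp_instrument(registry.pcps, subj, spec)
    referral = compute_referral_rates(registry.pcps, subj, spec)
    pcp_meta = pcps.set_index("pcp_id")
    referral.index = pcps["pcp_id"]

    pcp_ok = (
        pcp_meta["instrument_defined"]
        & (pcp_meta["n_eligible"] >= spec.min_pcp_eligible)
        & (referral > spec.min_referral_rate_pct)
    )
    if not pcp_ok.any():
        raise AllPCPsExcludedError(
            f"all {len(pcp_ok)} PCPs excluded "
            f"(min panel {spec.min_pcp_eligible}, referral rate > "
            f"{spec.min_referral_rate_pct}%)"
        )

    w_end = spec.exposure_window_end
    prior_crc = subj["crc_dx_year"].notna() & (subj["crc_dx_year"] <= w_end)
    prior_death = (
        subj["other_death_year"].notna() & (subj["other_death_year"] <= w_end)
    ) | (subj["crc_death_year"].notna() & (subj["crc_death_year"] <= w_end))
    subj_pcp_ok = subj["pcp_id"].map(pcp_ok).astype(bool)

    keep = ~prior_crc & ~prior_death & subj_pcp_ok
    kept = subj[keep]
    if len(kept) == 0:
        raise EmptyCohortError("no subjects remain after restriction filters")

    instrument = kept["pcp_id"].map(pcp_meta["discretionary_rate"])
    exposed = kept["screening_year"].notna() | kept["diagnostic_year"].notna()
    incident = kept["crc_dx_year"].notna() & (
        kept["crc_dx_year"].between(w_end + 1, spec.incidence_end_year)
    )
    death = kept["crc_death_year"].notna() & (
        kept["crc_death_year"].between(w_end + 1, spec.mortality_end_year)
    )

    rows = _assemble_rows(
        kept, exposed.fillna(False), incident.fillna(False), death.fillna(False), instrument
    )
    rows, n_missing = _drop_missing_covariates(rows)
    counts = _base_counts(rows)
    counts.update(
        {
            "n_pcps_retained": int(pcp_ok.sum()),
            "n_pcps_excluded": int((~pcp_ok).sum()),
            "n_excluded_window_crc": int(prior_crc.sum()),
            "n_excluded_prior_death": int((~prior_crc & prior_death).sum()),
            "n_excluded_pcp_filter": int(
                (~prior_crc & ~prior_death & ~subj_pcp_ok).sum()
            ),
            "n_dropped_missing_covariates": n_missing,
        }
    )
    return Cohort(spec=spec, rows=rows, counts=counts)


def build_cohort(registry: RegistrySnapshot, spec: CohortSpec) -> Cohort:
    """Dispatch on ``spec.cohort_kind``."""
    if spec.cohort_kind == "unselected":
        return build_unselected_cohort(registry, spec)
    return build_restricted_cohort(registry, spec)
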