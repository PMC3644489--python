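"""Shared fixtures and independent reference implementations.

The reference implementations here are deliberately naive (brute-force
pair enumeration, stepwise matching, closed-form 2x2 algebra): they are
the oracles the fast production code is checked against and must stay
independent of it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import screenbias as sb
from screenbias.cohort import COVARIATES

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# session-scoped default-calibration run (shared by several tests)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_registry() -> sb.RegistrySnapshot:
    """Default calibration at ~200,000 subjects / 2,000 physicians."""
    return sb.generate_registry(sb.default_config(seed=1))


@pytest.fixture(scope="session")
def unselected_cohort(default_registry) -> sb.Cohort:
    return sb.build_unselected_cohort(default_registry)


@pytest.fixture(scope="session")
def restricted_cohort(default_registry) -> sb.Cohort:
    return sb.build_restricted_cohort(default_registry)


@pytest.fixture(scope="session")
def restricted_propensity(restricted_cohort) -> sb.PropensityResult:
    return sb.derive_propensity(restricted_cohort.rows)


@pytest.fixture(scope="session")
def restricted_matched(restricted_cohort, restricted_propensity) -> sb.MatchedSample:
    rows = restricted_cohort.rows
    return sb.greedy_match(
        restricted_propensity.scores,
        rows["exposed"].to_numpy(dtype=bool),
        seed=1,
        ids=rows["subject_id"].to_numpy(),
    )


@pytest.fixture(scope="session")
def small_registry() -> sb.RegistrySnapshot:
    """Small default-calibration registry for cheap structural tests."""
    return sb.generate_registry(sb.default_config(seed=5, n_pcps=100))


# ---------------------------------------------------------------------------
# independent reference implementations (oracles)
# ---------------------------------------------------------------------------

def brute_force_c_statistic(scores, outcomes) -> float:
    """All case-control pairs, ties counted half."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    cases = scores[y]
    controls = scores[~y]
    total = 0.0
    for s1 in cases:
        for s0 in controls:
            if s1 > s0:
                total += 1.0
            elif s1 == s0:
                total += 0.5
    return total / (len(cases) * len(controls))


def reference_greedy_match(scores, exposed, seed, ids):
    """Stepwise digit-greedy matching, written for clarity not speed.

    Mirrors the contract: passes at 5..1 decimals; within a pass the
    treated are visited in a seeded-random order over the id-sorted
    treated list; each treated takes the nearest available control
    agreeing on the rounded score, ties to the lowest control id.
    """
    scores = np.asarray(scores, dtype=float)
    exposed = np.asarray(exposed, dtype=bool)
    ids = np.asarray(ids)
    t_idx = sorted(np.flatnonzero(exposed), key=lambda i: ids[i])
    c_avail = set(np.flatnonzero(~exposed))
    rng = np.random.default_rng(seed)
    order = [t_idx[i] for i in rng.permutation(len(t_idx))]
    pairs = []
    unmatched = list(order)
    for d in range(5, 0, -1):
        next_unmatched = []
        for ti in unmatched:
            key = round(scores[ti], d)
            cands = [ci for ci in c_avail if round(scores[ci], d) == key]
            if not cands:
                next_unmatched.append(ti)
                continue
            best = min(cands, key=lambda ci: (abs(scores[ci] - scores[ti]), ids[ci]))
            pairs.append((ids[ti], ids[best]))
            c_avail.discard(best)
        unmatched = next_unmatched
    return pairs, len(unmatched)


def two_by_two_log_or(a, b, c, d) -> float:
    """log odds ratio of a 2x2 table [[a, b], [c, d]] (events/non-events)."""
    return float(np.log((a * d) / (b * c)))


def make_binary_rows(
    n: int, seed: int, n_clusters: int = 20, x_effect: float = 0.8, e_effect: float = -0.5
) -> pd.DataFrame:
    """Small generic clustered binary dataset for regression oracles."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    e = rng.random(n) < 0.4
    cluster = rng.integers(0, n_clusters, n)
    re = rng.standard_normal(n_clusters)[cluster] * 0.3
    from scipy.special import expit

    p = expit(-1.0 + x_effect * x + e_effect * e + re)
    y = rng.random(n) < p
    return pd.DataFrame(
        {
            "crc_incident": y,
            "exposed": e,
            "x": x,
            "pcp_id": cluster,
        }
    )


@pytest.fixture
def covariate_names():
    return list(COVARIATES)
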