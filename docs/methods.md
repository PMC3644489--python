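# Methods

## What the simulation emulates

`screenbias` models the estimation problem of a population-based
retrospective cohort study of screening colonoscopy and colorectal
cancer (CRC), built on linked administrative data: subjects aged 50–74
nested within primary-care physicians (PCPs), a 5-year exposure window
in which colonoscopies occur, and outcome follow-up of 7 years for CRC
incidence and 5 years for CRC mortality after the window. Time is a
discrete annual clock, years 1–12; the exposure window is years 1–5,
incidence is counted through year 12 and mortality through year 10.
Calendar dates, billing codes and record linkage are deliberately out
of scope: the generator emits subjects who are already screen-eligible
and stably attached to one PCP, because upstream eligibility scrubbing
does not interact with the estimator comparison the package exists for.

Three structural features carry all the scientific content:

1. **Clustering.** Each PCP has a latent referral propensity
   `z_j ~ N(μ, σ²)` on the logit scale (default σ = 0.5). Subjects of
   enthusiastic referrers are scoped more often regardless of their own
   characteristics. This is both a nuisance (within-physician
   correlation, handled by sandwich variances) and a resource (the
   physician-preference instrument).
2. **Confounding.** Measured covariates (age group, sex, neighbourhood
   income quintile, rural residence, 3-level comorbidity) and one
   unmeasured standard-normal confounder `u` load on uptake; age, sex
   and `u` load on outcome risk.
3. **Exposure measurement error.** Incipient ("window") cancers arise
   during years 1–5 at a small exposure-independent rate and receive a
   diagnostic colonoscopy with high probability in the diagnosis year.
   In a cohort that measures exposure and outcome concurrently, these
   procedures make colonoscopy look carcinogenic.

Window cancer and follow-up cancer are disjoint processes, and window
cancer ignores screening exposure. This is the minimal mechanism that
produces the concurrent-measurement artifact while keeping the
restricted-cohort estimand clean: among subjects cancer-free at the end
of the window, the only exposure effect is the causal one.

### Outcome model

Follow-up CRC (diagnosis year uniform on 6–12) has per-subject
probability

    logit p = logit(π(age, sex)) + log(RR)·screened + γ·u

where π is the age-by-sex 7-year baseline risk and RR is the true
causal risk ratio of screening (default 0.65). A CRC case dies of CRC
with probability `p_death_given_crc_5y` (default 0.30), 0–2 years after
diagnosis (capped at year 12); mortality is counted through year 10, so
late-diagnosed cases cannot contribute a counted death — which is why
observed mortality is roughly one sixth of incidence rather than 30%.
Other-cause death is an annual geometric hazard (default 1.5%/year),
independent of everything else; it censors Kaplan–Meier curves and
removes subjects from the restricted cohort if it occurs during the
window.

### Default calibration

Defaults are chosen once to make the synthetic registry resemble the
published marginal structure of provincial screening data for this age
band, and are not tuned beyond that: ~7.3% of the unselected cohort and
~8% of the restricted cohort exposed over five years; ~1.3% seven-year
incidence; a 54.3% female share; covariate–uptake odds ratios derived
from published baseline-characteristics contrasts (uptake peaks at ages
60–69, rises with income, and is dominated by prior hospital contact —
the comorbidity coefficients of +2.8 and +2.4 reproduce the
three-digit standardized differences such tables show). The latent
confounder defaults to mild loadings (0.3 on each side), giving the
realistic regime where covariate adjustment moves the answer slightly
and the instrument moves it more. With these defaults the true marginal
ARR for incidence is about −0.48 percentage points, and the
unadjusted restricted-cohort contrast lands near −0.5 pp.

The per-stage random streams are derived from one seed (independent
substreams for physicians, covariates, exposure, outcomes), so
regeneration is bit-reproducible and enlarging the population does not
perturb the physician draws.

### The counterfactual truth

`true_marginal_arr` evaluates every subject's follow-up outcome
probability under screening set to 1 and to 0, holding covariates and
`u` fixed, and averages — the exact expectation of a
common-random-numbers counterfactual simulation (a test verifies the
simulated version agrees). The `subset` argument restricts the
population, which matters for matching: a 1:1 matched contrast targets
the effect in the *treated* population (older, more comorbid, hence a
larger absolute effect), so matched estimates are compared against the
truth computed over the matched treated subjects, while regression,
IPTW and quintile pooling are compared against the full-cohort truth.

## Cohort construction

The **unselected cohort** includes everyone; exposure is any
colonoscopy (screening or diagnostic) in years 1–5; incidence counts
any diagnosis through year 12, including window cancers.

The **restricted cohort** drops subjects with a window cancer or any
death in years 1–5, then drops patients of PCPs with fewer than 10
eligible patients or an any-colonoscopy referral rate not strictly
above 3%. Boundary conventions are literal: a panel of 9 is excluded; a
rate of exactly 3.0% is excluded. Outcomes are counted from year 6.
The referral-rate filter uses all colonoscopies by default
(`referral_rate_basis="discretionary"` is available), since the
filter's purpose — identifying physicians who actually refer — differs
from the instrument's.

The **instrument** (discretionary colonoscopies per 100 eligible
patients; discretionary = outpatient, screening-kind, no CRC diagnosis
at the procedure or within 3 years after) is always computed on the
full pre-restriction panel, so restriction cannot leak outcome
information into it. Empty panels get an undefined rate and an
exclusion flag, never a number.

## Estimators

* **Logistic regression** is iteratively reweighted least squares
  written in-house (it is the machinery under test), with optional
  observation weights. Convergence: max |score| < 1e-8 or relative
  deviance change < 1e-10, 50-iteration cap; linear predictors are
  clipped at ±30; coefficients exceeding ±30 raise a separation error;
  rank deficiency is detected by pivoted QR and reported with the
  aliased column names. Point estimates equal ordinary ML; clustering
  is handled by the plain cluster-summed sandwich covariance
  (independence-working-correlation GEE). No small-sample correction is
  applied — with ~2,000 clusters the G/(G−1) factor is negligible, and
  the plain form makes the one-cluster-per-observation case equal HC0
  exactly; the statsmodels comparison test accounts for the known
  factor.
* **Marginal standardization (g-computation)** predicts every subject
  under exposure 1 and 0 and averages; the ARR confidence interval is a
  delta-method propagation of the cluster-robust coefficient
  covariance through the averaged predictions (a seeded physician-level
  bootstrap is available by flag — the CI construction for averaged
  predictions is a genuinely open choice and both are exposed).
  Percentages are reported at full precision and formatted to two
  decimals in tables.
* **Propensity-score methods**: quintile stratification uses
  rank-based equal-count strata (ties cannot distort sizes beyond ±1)
  and pools stratum risk differences with stratum-size weights,
  excluding and flagging one-armed strata. IPTW uses unstabilized
  weights 1/PS and 1/(1−PS) (scores clipped to [1e-6, 1−1e-6]) inside
  a weighted, covariate-adjusted outcome fit treated as fixed by the
  sandwich variance; extreme-weight diagnostics are attached. Matching
  is the standard digit-greedy procedure — passes at 5 down to 1
  decimal places, nearest available control at each precision, without
  replacement, no caliper by default (flag available) — with treated
  order randomized by seed over the id-sorted list, so results are
  invariant to input row order. With the default (fully categorical)
  propensity model the scores take ~180 distinct values and digit
  matching becomes exact covariate-pattern matching, which is why
  post-matching standardized differences are essentially zero.
* **McNemar** uses the chi-square form on discordant counts with an
  exact binomial p-value when b + c < 25, and p = 1 by convention with
  no discordant pairs. The paired ARR variance is the paired-difference
  formula.
* **Kaplan–Meier** curves are computed on the yearly grid by the
  product-limit formula, events before censorings within a year;
  checked against lifelines.
* **Instrumental variable**: two-stage predictor substitution with
  logistic stages — exposure on instrument + covariates, then outcome
  on the *predicted* exposure probability + covariates, both with
  physician-cluster-robust variance; the marginal ARR evaluates the
  second stage at predicted exposure 1 vs 0. This follows the
  applied-epidemiology formulation rather than linear 2SLS; an
  auxiliary linear first stage exists only to supply the conventional
  partial-F diagnostic (squared OLS t of the instrument), reported
  alongside the likelihood-ratio chi-square and first-stage odds ratio.
  Second-stage variance treats the first stage as fixed; a seeded
  two-stage cluster bootstrap is available. A warning is issued when
  the predicted-exposure spread is below 0.05 (weakly identified
  contrast). The estimate applies to the instrument's marginal
  population; no LATE decomposition is attempted.

## Study sizes used by the test suite

The scientific end-to-end tests run at sizes chosen to make their
Monte-Carlo error small relative to the effects under test while
keeping the suite fast: the reversal and balance checks use one default
registry of ~200,000 subjects / 2,000 physicians; the
measured-confounding recovery uses 20 replicates of ~50,000 subjects;
the instrument recovery uses 20 replicates of ~100,000 subjects.

For the instrument experiment the physician panels are set to a mean of
250 eligible patients (400 physicians) rather than the default 100
(2,000 physicians). This is a substantive modelling point, not a
convenience: a preference instrument defined as a *rate on the
physician's own panel* inherits two finite-panel contaminations —
pure sampling noise, and a panel-composition term (panels whose
patients happen to carry more of the unmeasured confounder have both
higher realized rates and higher risk). Both shrink as 1/panel-size.
With 100-patient panels the contamination measurably attenuates the IV
estimate toward the confounded answer; with hundreds of patients per
panel — the realistic regime for the full provincial panels such
instruments are computed on — the instrument is clean and the IV
estimate recovers the counterfactual truth where covariate adjustment
fails. The discretionary-rate definition (excluding procedures followed
by a CRC diagnosis within 3 years) demonstrably improves instrument
validity over a raw colonoscopy rate in this simulation, matching its
design rationale.

## What passing tests do and do not show

The generator draws covariates independently of each other, uses a
single latent confounder, one screening colonoscopy per subject at
most, exposure-independent window cancers, and annual time steps.
Passing recovery tests therefore shows the estimators are implemented
correctly and behave as theory predicts *under this data-generating
process*; it does not certify performance on real registries, where
covariates are dependent, confounding is multivariate, exposure
misclassification is richer (incomplete procedures, repeat exams,
FOBT/sigmoidoscopy pathways), and physician assignment itself is
outcome-related. Known limitations, in addition: two-stage predictor
substitution with logistic stages is not strictly consistent under
strong effect heterogeneity (its residual bias is visible only at
precision beyond these study sizes); the IPTW weights are unstabilized
by design fidelity and can be extreme when scores approach 1; and the
Wilcoxon signed-rank comparison of matched survival curves used in
some published analyses has no unambiguous censored-data definition
and is not implemented — McNemar on fixed-horizon indicators is used
instead.
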