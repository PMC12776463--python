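"""Synthetic confounded cohorts with known ground-truth treatment effects.

Real MCI-to-AD cohorts built from clinical data warehouses are access
restricted, so every estimator in this package is validated against simulated
cohorts whose true potential outcomes are known by construction.  The
generator emulates the three features that make observational drug-effect
estimation hard:

* **confounded assignment** — treatment probability is a logistic function of
  the same comorbidities and age that drive the outcome;
* **heterogeneous incidence effects** — the treatment effect on the log-odds
  of conversion varies with effect-modifier covariates;
* **treatment-shifted conversion times** — months to conversion follow a
  linear model with a treatment delay, observed only for converters.

Both potential outcomes per endpoint share one uniform draw per patient
(common random numbers), so per-patient true effects are well defined without
cross-world noise.  Continuous covariates enter every linear predictor
standardized by their specified mean and standard deviation, keeping
coefficients unit-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import CohortTable

__all__ = [
    "OutcomeModel",
    "TimeModel",
    "CohortSpec",
    "SyntheticTruth",
    "SyntheticCohort",
    "generate_cohort",
    "oracle_true_effects",
    "standard_spec",
    "easy_spec",
    "make_event_fixture",
    "FIXTURE_DRUG",
    "FIXTURE_EXPECTED_COUNTS",
    "write_truth",
    "read_truth",
]


@dataclass
class OutcomeModel:
    """Logistic model for incidence: logit P = intercept + x'beta + t*(effect + x'modifiers)."""

    intercept: float
    coefficients: dict[str, float] = field(default_factory=dict)
    treatment_effect: float = 0.0
    modifiers: dict[str, float] = field(default_factory=dict)


@dataclass
class TimeModel:
    """Linear model for months to conversion with a treatment delay.

    E[months] = max(0, baseline + x'shifts + t*(delay + x'delay_modifiers));
    factual labels add truncated Gaussian noise (sd in months).
    """

    baseline: float
    coefficients: dict[str, float] = field(default_factory=dict)
    treatment_delay: float = 0.0
    delay_modifiers: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 6.0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class CohortSpec:
    n: int
    binary_covariates: list[tuple[str, float]]
    continuous_covariates: list[tuple[str, float, float]]
    propensity: dict[str, float]  # per-covariate log-odds plus "intercept"
    incidence_model: OutcomeModel
    time_model: TimeModel
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be at least 2")
        for name, p in self.binary_covariates:
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence of {name} must be in (0, 1)")
        for name, _, sd in self.continuous_covariates:
            if sd <= 0:
                raise ValueError(f"sd of {name} must be positive")

    @property
    def covariate_names(self) -> list[str]:
        return [n for n, _ in self.binary_covariates] + [n for n, _, _ in self.continuous_covariates]

    @property
    def covariate_kinds(self) -> list[str]:
        return (["binary"] * len(self.binary_covariates)
                + ["continuous"] * len(self.continuous_covariates))


@dataclass
class SyntheticTruth:
    """Generator-side truth: propensities, potential outcomes, per-patient effects."""

    propensity: np.ndarray
    po_inc_1: np.ndarray
    po_inc_0: np.ndarray
    po_time_1: np.ndarray
    po_time_0: np.ndarray
    true_ite_inc: np.ndarray
    true_ite_time: np.ndarray


@dataclass
class SyntheticCohort:
    cohort: CohortTable
    truth: SyntheticTruth


def _linear_predictor(xstd: np.ndarray, names: list[str],
                      coefficients: dict[str, float]) -> np.ndarray:
    lp = np.zeros(xstd.shape[0])
    for name, coef in coefficients.items():
        if name == "intercept":
            lp += coef
            continue
        if name not in names:
            raise KeyError(f"coefficient on unknown covariate {name!r}")
        lp += coef * xstd[:, names.index(name)]
    return lp


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a cohort and its ground truth; deterministic given the spec seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    names = spec.covariate_names
    cols = []
    for _, prev in spec.binary_covariates:
        cols.append((rng.random(n) < prev).astype(float))
    for _, mean, sd in spec.continuous_covariates:
        cols.append(rng.normal(mean, sd, n))
    X = np.column_stack(cols)

    # standardized view used by every linear predictor
    Xstd = X.copy()
    offset = len(spec.binary_covariates)
    for j, (_, mean, sd) in enumerate(spec.continuous_covariates):
        Xstd[:, offset + j] = (X[:, offset + j] - mean) / sd

    propensity = expit(_linear_predictor(Xstd, names, spec.propensity))
    t = (rng.random(n) < propensity).astype(int)
    if t.sum() == 0 or t.sum() == n:
        raise ValueError(
            f"degenerate assignment: {t.sum()} treated of {n}; adjust the propensity model"
        )

    im = spec.incidence_model
    base_logit = im.intercept + _linear_predictor(Xstd, names, im.coefficients)
    effect = im.treatment_effect + _linear_predictor(Xstd, names, im.modifiers)
    po_inc_0 = expit(base_logit)
    po_inc_1 = expit(base_logit + effect)
    u_inc = rng.random(n)  # common random numbers across the two worlds
    y_inc_pot = {0: (u_inc < po_inc_0).astype(int), 1: (u_inc < po_inc_1).astype(int)}

    tm = spec.time_model
    base_time = tm.baseline + _linear_predictor(Xstd, names, tm.coefficients)
    delay = tm.treatment_delay + _linear_predictor(Xstd, names, tm.delay_modifiers)
    po_time_0 = np.maximum(0.0, base_time)
    po_time_1 = np.maximum(0.0, base_time + delay)
    noise = rng.normal(0.0, tm.noise_sd, n)  # shared across worlds
    y_time_pot = {0: np.maximum(0.0, po_time_0 + noise),
                  1: np.maximum(0.0, po_time_1 + noise)}

    y_inc = np.where(t == 1, y_inc_pot[1], y_inc_pot[0])
    y_time_factual = np.where(t == 1, y_time_pot[1], y_time_pot[0])
    observed = y_inc == 1
    y_time = np.where(observed, y_time_factual, np.nan)

    cohort = CohortTable(
        [f"P{i:06d}" for i in range(n)], X, names, spec.covariate_kinds,
        t, y_inc, y_time, observed,
    )
    truth = SyntheticTruth(
        propensity=propensity, po_inc_1=po_inc_1, po_inc_0=po_inc_0,
        po_time_1=po_time_1, po_time_0=po_time_0,
        true_ite_inc=po_inc_1 - po_inc_0, true_ite_time=po_time_1 - po_time_0,
    )
    return SyntheticCohort(cohort, truth)


def oracle_true_effects(sc: SyntheticCohort,
                        strata: np.ndarray | None = None):
    """True average treatment effects from the generator's potential outcomes.

    Returns ``(ate_inc, ate_time)``, or a dict keyed by stratum label when
    ``strata`` (one label per patient) is given.
    """
    if sc.truth is None:
        raise ValueError("cohort carries no ground truth")
    ti, tt = sc.truth.true_ite_inc, sc.truth.true_ite_time
    if strata is None:
        return float(ti.mean()), float(tt.mean())
    strata = np.asarray(strata)
    return {lab: (float(ti[strata == lab].mean()), float(tt[strata == lab].mean()))
            for lab in np.unique(strata)}


# ------------------------------------------------------------- standard specs

def standard_spec(n: int = 4000, seed: int = 7,
                  confounding_scale: float = 1.0) -> CohortSpec:
    """The package's reference study conditions: a confounded cohort with a
    heterogeneous protective effect on incidence and a homogeneous +4-month
    conversion delay.

    Comorbidity prevalences follow typical MCI-cohort figures (diabetes,
    hypertension, obesity, stroke, depression, traumatic brain injury), plus a
    null marker with no role in any model.  ``confounding_scale`` multiplies
    the propensity coefficients shared with the outcome model, providing a
    knob from randomized (0) to strongly confounded assignment.
    """
    s = confounding_scale
    return CohortSpec(
        n=n,
        seed=seed,
        binary_covariates=[
            ("diabetes", 0.30), ("hypertension", 0.50), ("obesity", 0.25),
            ("stroke", 0.10), ("depression", 0.20), ("tbi", 0.05),
            ("marker_null", 0.30),
        ],
        continuous_covariates=[("age", 72.0, 8.0)],
        propensity={"intercept": -0.5, "diabetes": 0.8 * s, "hypertension": 0.5 * s,
                    "depression": 0.4 * s, "age": 0.6 * s},
        incidence_model=OutcomeModel(
            intercept=-1.3,
            coefficients={"diabetes": 0.8, "hypertension": 0.4, "obesity": 0.2,
                          "stroke": 0.6, "depression": 0.3, "tbi": 0.5, "age": 0.9},
            treatment_effect=-0.9,
            modifiers={"diabetes": 0.4, "depression": -0.5},
        ),
        time_model=TimeModel(
            baseline=30.0,
            coefficients={"age": -4.0, "diabetes": -3.0, "hypertension": -1.5},
            treatment_delay=4.0,
            noise_sd=6.0,
        ),
    )


def easy_spec(n: int = 2000, seed: int = 11) -> CohortSpec:
    """A well-separated outcome model (near-randomized assignment, strong
    covariate signal) used to check factual predictive performance."""
    return CohortSpec(
        n=n,
        seed=seed,
        binary_covariates=[("diabetes", 0.30), ("hypertension", 0.50),
                           ("stroke", 0.10), ("depression", 0.20)],
        continuous_covariates=[("age", 72.0, 8.0)],
        propensity={"intercept": 0.0, "diabetes": 0.2},
        incidence_model=OutcomeModel(
            intercept=-0.8,
            coefficients={"age": 2.5, "diabetes": 2.0, "stroke": 1.5,
                          "hypertension": 1.0, "depression": 0.8},
            treatment_effect=-1.0,
        ),
        time_model=TimeModel(
            baseline=30.0, coefficients={"age": -5.0}, treatment_delay=4.0,
            noise_sd=4.0,
        ),
    )


def write_truth(truth: SyntheticTruth, path: str) -> None:
    pd.DataFrame({
        "propensity": truth.propensity,
        "po_inc_1": truth.po_inc_1, "po_inc_0": truth.po_inc_0,
        "po_time_1": truth.po_time_1, "po_time_0": truth.po_time_0,
        "true_ite_inc": truth.true_ite_inc, "true_ite_time": truth.true_ite_time,
    }).to_csv(path, index=False)


def read_truth(path: str) -> SyntheticTruth:
    df = pd.read_csv(path)
    return SyntheticTruth(**{c: df[c].to_numpy() for c in df.columns})


# ------------------------------------------------------------- event fixture

FIXTURE_DRUG = "DRUG_A"

#: Expected outcome of piping the fixture through build_treatment_cohort with
#: default eligibility parameters (3-year washout, 3 refills, 3 visits).
FIXTURE_EXPECTED_COUNTS = {
    "included_treated": 4,
    "included_control": 4,
    "no_mci": 0,
    "age_under_min": 1,
    "prior_dementia": 1,
    "insufficient_followup": 1,
    "insufficient_visits": 1,
    "insufficient_refills": 1,
    "washout_exposure": 1,
}


def make_event_fixture() -> pd.DataFrame:
    """A deterministic 14-patient longitudinal event table.

    Eight clean patients (four treated, four control) survive the default
    eligibility filters; six others each violate exactly one rule, in the
    order the rules are evaluated (see FIXTURE_EXPECTED_COUNTS).  C04 carries
    an exposure 4 years after MCI onset: a control under the default 3-year
    washout, excluded under a 5-year washout.
    """
    rows: list[tuple[str, str, str, str]] = []

    def ev(pid, date, kind, code=""):
        rows.append((pid, date, kind, code))

    def clean_spine(pid, birth="1950-01-01"):
        ev(pid, birth, "birth")
        ev(pid, "2015-06-01", "diagnosis", "MCI")
        ev(pid, "2015-07-01", "visit")
        ev(pid, "2016-01-05", "visit")
        ev(pid, "2016-06-02", "visit")

    def refills(pid, dates=("2015-08-01", "2015-09-01", "2015-10-01")):
        for d in dates:
            ev(pid, d, "prescription", FIXTURE_DRUG)

    # clean treated
    clean_spine("T01"); refills("T01")
    clean_spine("T02"); refills("T02"); ev("T02", "2017-03-01", "diagnosis", "AD")
    clean_spine("T03"); refills("T03"); ev("T03", "2014-01-01", "diagnosis", "HYPERTENSION")
    clean_spine("T04"); refills("T04"); ev("T04", "2015-06-01", "diagnosis", "DIABETES")

    # clean controls
    clean_spine("C01"); ev("C01", "2016-02-01", "diagnosis", "OBESITY")  # post-baseline, no flag
    clean_spine("C02"); ev("C02", "2016-09-01", "diagnosis", "AD")
    clean_spine("C03")
    ev("C03", "2013-05-01", "diagnosis", "DEPRESSION")
    ev("C03", "2015-05-01", "diagnosis", "STROKE")
    clean_spine("C04"); ev("C04", "2019-07-01", "prescription", FIXTURE_DRUG)

    # one-rule violators
    clean_spine("X_AGE", birth="1970-01-01"); refills("X_AGE")  # 45 at first MCI
    clean_spine("X_PRIOR"); refills("X_PRIOR")
    ev("X_PRIOR", "2014-01-01", "diagnosis", "AD")
    ev("X_FU", "1950-01-01", "birth")
    ev("X_FU", "2015-06-01", "diagnosis", "MCI")
    for d in ("2015-07-01", "2015-08-01", "2015-09-01"):
        ev("X_FU", d, "visit")
    ev("X_FU", "2015-12-01", "visit")  # last event < 1 year after MCI
    ev("X_VISITS", "1950-01-01", "birth")
    ev("X_VISITS", "2015-06-01", "diagnosis", "MCI")
    ev("X_VISITS", "2015-07-01", "visit")
    ev("X_VISITS", "2015-09-01", "visit")  # only 2 visits
    refills("X_VISITS")
    ev("X_VISITS", "2016-08-01", "prescription", FIXTURE_DRUG)
    clean_spine("X_REFILLS")
    refills("X_REFILLS", dates=("2015-08-01", "2015-09-01"))  # only 2 refills
    clean_spine("X_WASHOUT")
    ev("X_WASHOUT", "2016-03-01", "diagnosis", "AD")
    ev("X_WASHOUT", "2016-06-01", "prescription", FIXTURE_DRUG)  # after AD, inside washout

    df = pd.DataFrame(rows, columns=["patient_id", "date", "kind", "code"])
    df["date"] = pd.to_datetime(df["date"])
    return df.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)
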