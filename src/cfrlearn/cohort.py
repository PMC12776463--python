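"""Cohort data model, CSV round trip, and target-trial cohort construction.

The central container is :class:`CohortTable`: one row per patient with
baseline covariates, a binary treatment indicator, a binary incidence outcome
(conversion from mild cognitive impairment, MCI, to Alzheimer's disease, AD),
and a months-to-conversion label observed only for converters.

:func:`build_treatment_cohort` assembles such a table from a longitudinal
event log (diagnoses, prescriptions, visits) by applying eligibility filters
in a fixed order, attributing every exclusion to exactly one first-failing
rule:

1. an MCI diagnosis exists;
2. age at first MCI is at least ``min_age_years``;
3. no AD or other dementia diagnosis strictly before first MCI;
4. follow-up (last event minus first MCI) spans at least ``min_followup_years``;
5. at least ``min_visits`` clinical visits on/after first MCI;
6. arm membership: treated patients start the drug after first MCI and before
   any AD diagnosis with at least ``min_refills`` prescriptions; controls have
   no exposure inside the ``control_washout_years`` window following MCI onset.

Months are counted as floor(days / 30.44), a documented convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_KINDS",
    "EligibilityParams",
    "CohortTable",
    "build_treatment_cohort",
    "read_cohort",
    "write_cohort",
    "read_events",
    "write_events",
]

EVENT_KINDS = ("birth", "diagnosis", "prescription", "visit")
DAYS_PER_MONTH = 30.44
MCI, AD, DEMENTIA_OTHER = "MCI", "AD", "DEMENTIA_OTHER"
_SPECIAL_CODES = {MCI, AD, DEMENTIA_OTHER}


@dataclass
class EligibilityParams:
    min_age_years: float = 50.0
    min_followup_years: float = 1.0
    min_visits: int = 3
    min_refills: int = 3
    control_washout_years: float = 3.0

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CohortTable:
    """Per-patient covariates, treatment, and dual outcomes.

    ``y_time`` is meaningful only where ``time_observed`` is True (converters);
    elsewhere it is NaN.
    """

    patient_ids: list[str]
    X: np.ndarray
    covariate_names: list[str]
    covariate_kinds: list[str]
    t: np.ndarray
    y_inc: np.ndarray
    y_time: np.ndarray
    time_observed: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.t = np.asarray(self.t, dtype=np.int64)
        self.y_inc = np.asarray(self.y_inc, dtype=np.int64)
        self.y_time = np.asarray(self.y_time, dtype=np.float64)
        self.time_observed = np.asarray(self.time_observed, dtype=bool)
        self.validate()

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    def validate(self) -> None:
        n, X = self.n, self.X
        if X.shape != (n, len(self.covariate_names)):
            raise ValueError("covariate matrix shape does not match names/rows")
        if len(self.covariate_kinds) != len(self.covariate_names):
            raise ValueError("covariate kinds must match names")
        for arr, name in ((self.t, "t"), (self.y_inc, "y_inc")):
            bad = np.where(~np.isin(arr, (0, 1)))[0]
            if bad.size:
                raise ValueError(f"column {name} must be 0/1; bad value at row {bad[0]}")
        for j, (cname, kind) in enumerate(zip(self.covariate_names, self.covariate_kinds)):
            if kind not in ("binary", "continuous"):
                raise ValueError(f"unknown covariate kind {kind!r} for column {cname}")
            if kind == "binary":
                bad = np.where(~np.isin(X[:, j], (0.0, 1.0)))[0]
                if bad.size:
                    raise ValueError(f"binary column {cname} has non-0/1 value at row {bad[0]}")
        if not np.all(np.isfinite(X)):
            raise ValueError("covariates contain non-finite values")
        obs = self.time_observed
        bad = np.where(obs & (self.y_inc == 0))[0]
        if bad.size:
            raise ValueError(f"y_time observed where y_inc = 0 at row {bad[0]}")
        bad = np.where(obs & ~(self.y_time >= 0))[0]
        if bad.size:
            raise ValueError(f"y_time must be >= 0 where observed; bad row {bad[0]}")
        if np.any(~obs & ~np.isnan(self.y_time)):
            raise ValueError("y_time must be NaN where unobserved")

    def subset(self, idx: np.ndarray) -> "CohortTable":
        idx = np.asarray(idx)
        return CohortTable(
            [self.patient_ids[i] for i in idx], self.X[idx],
            list(self.covariate_names), list(self.covariate_kinds),
            self.t[idx], self.y_inc[idx], self.y_time[idx], self.time_observed[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"patient_id": self.patient_ids, "t": self.t, "y_inc": self.y_inc})
        df["y_time"] = [f"{v:g}" if o else "" for v, o in zip(self.y_time, self.time_observed)]
        for j, name in enumerate(self.covariate_names):
            df[name] = self.X[:, j]
        return df


# --------------------------------------------------------------------- CSV IO

def write_cohort(cohort: CohortTable, path: str) -> None:
    """Write the cohort CSV plus a sidecar `<path>.meta.json` covariate manifest."""
    cohort.validate()
    cohort.to_frame().to_csv(path, index=False)
    meta = {"covariates": dict(zip(cohort.covariate_names, cohort.covariate_kinds))}
    with open(f"{path}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_cohort(path: str) -> CohortTable:
    """Load and validate a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = ["patient_id", "t", "y_inc", "y_time"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    try:
        with open(f"{path}.meta.json") as fh:
            kinds_map = json.load(fh)["covariates"]
    except FileNotFoundError:
        kinds_map = {}
    cov_names = [c for c in df.columns if c not in required]
    kinds = [kinds_map.get(c, _infer_kind(df[c])) for c in cov_names]
    y_time = pd.to_numeric(df["y_time"], errors="coerce").to_numpy(dtype=float)
    observed = ~np.isnan(y_time)
    neg = np.where(observed & (y_time < 0))[0]
    if neg.size:
        raise ValueError(f"negative y_time at row {neg[0]}, column y_time")
    return CohortTable(
        df["patient_id"].tolist(), df[cov_names].to_numpy(dtype=float),
        cov_names, kinds, df["t"].to_numpy(), df["y_inc"].to_numpy(),
        y_time, observed,
    )


def _infer_kind(col: pd.Series) -> str:
    vals = pd.unique(col.dropna())
    return "binary" if set(np.asarray(vals, dtype=float)) <= {0.0, 1.0} else "continuous"


def read_events(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "kind": str, "code": str})
    df["date"] = pd.to_datetime(df["date"])
    bad = ~df["kind"].isin(EVENT_KINDS)
    if bad.any():
        raise ValueError(f"unknown event kind {df.loc[bad, 'kind'].iloc[0]!r}")
    return df


def write_events(events: pd.DataFrame, path: str) -> None:
    out = events.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


# ---------------------------------------------------- cohort from event table

def build_treatment_cohort(
    events: pd.DataFrame, drug: str, params: EligibilityParams | None = None,
) -> tuple[CohortTable, dict[str, int]]:
    """Apply eligibility filters to a longitudinal event table.

    Returns the cohort plus an exclusion report mapping each first-failing
    rule to its patient count (with ``included_treated`` / ``included_control``
    tallies).  Raises if either arm ends up empty, naming the tally.
    """
    params = params or EligibilityParams()
    events = events.copy()
    events["date"] = pd.to_datetime(events["date"])
    report = {k: 0 for k in (
        "no_mci", "age_under_min", "prior_dementia", "insufficient_followup",
        "insufficient_visits", "insufficient_refills", "washout_exposure",
    )}
    rows = []
    for pid, g in events.sort_values(["patient_id", "date"]).groupby("patient_id", sort=True):
        rule, row = _evaluate_patient(pid, g, drug, params)
        if rule is not None:
            report[rule] += 1
        else:
            rows.append(row)
    n_treated = sum(1 for r in rows if r["t"] == 1)
    n_control = len(rows) - n_treated
    report["included_treated"] = n_treated
    report["included_control"] = n_control
    if n_treated == 0 or n_control == 0:
        raise ValueError(f"empty {'treated' if n_treated == 0 else 'control'} arm; "
                         f"exclusion tally: {report}")

    # baseline comorbidity flags: diagnosis codes on/before first MCI
    comorbidities = sorted({c for r in rows for c in r["baseline_codes"]})
    names = comorbidities + ["age"]
    kinds = ["binary"] * len(comorbidities) + ["continuous"]
    X = np.zeros((len(rows), len(names)))
    for i, r in enumerate(rows):
        for c in r["baseline_codes"]:
            X[i, comorbidities.index(c)] = 1.0
        X[i, -1] = r["age"]
    cohort = CohortTable(
        [r["pid"] for r in rows], X, names, kinds,
        np.array([r["t"] for r in rows]),
        np.array([r["y_inc"] for r in rows]),
        np.array([r["y_time"] for r in rows], dtype=float),
        np.array([r["y_inc"] == 1 for r in rows]),
    )
    return cohort, report


def _evaluate_patient(pid, g, drug, params):
    dx = g[g["kind"] == "diagnosis"]
    mci_dates = dx.loc[dx["code"] == MCI, "date"]
    if mci_dates.empty:
        return "no_mci", None
    first_mci = mci_dates.min()

    birth = g.loc[g["kind"] == "birth", "date"]
    if birth.empty:
        raise ValueError(f"patient {pid} has no birth record")
    age = (first_mci - birth.iloc[0]).days / 365.25
    if age < params.min_age_years:
        return "age_under_min", None

    dementia = dx[dx["code"].isin((AD, DEMENTIA_OTHER))]
    if (dementia["date"] < first_mci).any():
        return "prior_dementia", None

    followup_days = (g["date"].max() - first_mci).days
    if followup_days < params.min_followup_years * 365.25:
        return "insufficient_followup", None

    n_visits = int(((g["kind"] == "visit") & (g["date"] >= first_mci)).sum())
    if n_visits < params.min_visits:
        return "insufficient_visits", None

    ad_dates = dx.loc[(dx["code"] == AD) & (dx["date"] > first_mci), "date"]
    first_ad = ad_dates.min() if not ad_dates.empty else None

    rx = g.loc[(g["kind"] == "prescription") & (g["code"] == drug), "date"]
    post_mci_rx = rx[rx > first_mci]
    initiated = (
        not rx.empty and rx.min() > first_mci
        and (first_ad is None or rx.min() < first_ad)
    )
    if initiated and len(post_mci_rx) >= params.min_refills:
        t = 1
    else:
        washout_end = first_mci + pd.Timedelta(days=params.control_washout_years * 365.25)
        in_washout = rx[(rx >= first_mci) & (rx <= washout_end)]
        if in_washout.empty:
            t = 0
        elif initiated:
            return "insufficient_refills", None
        else:
            return "washout_exposure", None

    y_inc = int(first_ad is not None)
    y_time = float(int((first_ad - first_mci).days / DAYS_PER_MONTH)) if y_inc else np.nan
    baseline_codes = set(
        dx.loc[(dx["date"] <= first_mci) & ~dx["code"].isin(_SPECIAL_CODES), "code"]
    )
    return None, {"pid": pid, "t": t, "y_inc": y_inc, "y_time": y_time,
                  "age": age, "baseline_codes": baseline_codes}
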