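"""Individualized and average treatment effects with interpretability summaries.

For the incidence endpoint the individualized treatment effect (ITE) is the
predicted risk difference tau_inc = Yhat_inc(1) - Yhat_inc(0): negative values
indicate benefit (lower conversion risk under treatment).  For the time
endpoint tau_time = Yhat_time(1) - Yhat_time(0): positive values indicate a
conversion delay under treatment.  The average treatment effect (ATE) is the
mean ITE over the cohort, with a seeded nonparametric percentile bootstrap for
its confidence interval.

Directional feature effects intervene on one binary covariate at a time —
set present versus absent with everything else held fixed — and average the
change in the treated-arm risk prediction.  Pairwise interactions extend this
to a double difference (departure from additivity of two features on treated
risk).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .model import CounterfactualModel

__all__ = [
    "compute_ite",
    "ensemble_ite",
    "ate_with_ci",
    "bootstrap_ci",
    "directional_effect",
    "directional_effects",
    "pairwise_interaction",
    "interaction_matrix",
    "subgroup_summary",
]


def compute_ite(model: CounterfactualModel, X: np.ndarray,
                endpoint: str = "incidence") -> np.ndarray:
    """Per-patient treatment-effect predictions, row-aligned with X."""
    pred = model.predict_counterfactual(X)
    if endpoint == "incidence":
        return pred.y_inc_1 - pred.y_inc_0
    if endpoint == "time":
        return pred.y_time_1 - pred.y_time_0
    raise ValueError(f"unknown endpoint {endpoint!r}; use 'incidence' or 'time'")


def ensemble_ite(models: list[CounterfactualModel], X: np.ndarray,
                 endpoint: str = "incidence") -> np.ndarray:
    """Average the per-patient effect predictions of a seed ensemble."""
    if not models:
        raise ValueError("ensemble must contain at least one model")
    return np.mean([compute_ite(m, X, endpoint) for m in models], axis=0)


def bootstrap_ci(tau: np.ndarray, level: float = 0.95, n_boot: int = 200,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean of tau.

    Protocol: with rng = default_rng(seed), draw an (n_boot, n) index matrix
    uniformly with replacement in one call, take row means, and return the
    (1-level)/2 and (1+level)/2 quantiles (linear interpolation).
    """
    tau = np.asarray(tau, dtype=float)
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, tau.size, size=(n_boot, tau.size))
    means = tau[idx].mean(axis=1)
    lo = (1.0 - level) / 2.0
    return (float(np.quantile(means, lo)), float(np.quantile(means, 1.0 - lo)))


def ate_with_ci(model: CounterfactualModel, cohort: CohortTable,
                level: float = 0.95, n_boot: int = 200, seed: int = 0,
                endpoint: str = "incidence") -> dict[str, float]:
    """ATE with a prediction-level bootstrap CI (fixed fitted model).

    Resamples patients (hence their predicted ITEs) with replacement; the
    model itself is not refit, so the interval reflects cohort sampling
    variability of the point estimate, not refitting variability.
    """
    tau = compute_ite(model, cohort.X, endpoint)
    lo, hi = bootstrap_ci(tau, level=level, n_boot=n_boot, seed=seed)
    return {"ate": float(tau.mean()), "ci_low": lo, "ci_high": hi,
            "level": level, "n_boot": n_boot}


def _require_binary(model: CounterfactualModel, j: int) -> None:
    if model.covariate_kinds[j] != "binary":
        raise ValueError(
            f"covariate {model.covariate_names[j]!r} is continuous; directional "
            "effects are defined for binary covariates — supply a binarized column"
        )


def _feature_index(model: CounterfactualModel, feature: int | str) -> int:
    if isinstance(feature, str):
        try:
            return model.covariate_names.index(feature)
        except ValueError:
            raise KeyError(f"unknown covariate {feature!r}") from None
    return int(feature)


def _treated_risk(model: CounterfactualModel, X: np.ndarray) -> np.ndarray:
    return model.predict_counterfactual(X).y_inc_1


def directional_effect(model: CounterfactualModel, X: np.ndarray,
                       feature: int | str) -> float:
    """DE_j: mean change in treated risk when feature j is set 1 versus 0.

    Positive values mean presence of the feature raises predicted risk under
    treatment; negative values mean a protective association under treatment.
    """
    j = _feature_index(model, feature)
    _require_binary(model, j)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    X1, X0 = X.copy(), X.copy()
    X1[:, j], X0[:, j] = 1.0, 0.0
    return float(np.mean(_treated_risk(model, X1) - _treated_risk(model, X0)))


def directional_effects(model: CounterfactualModel, X: np.ndarray) -> pd.Series:
    """DE_j for every binary covariate, as a named series."""
    out = {name: directional_effect(model, X, j)
           for j, name in enumerate(model.covariate_names)
           if model.covariate_kinds[j] == "binary"}
    return pd.Series(out, name="directional_effect")


def pairwise_interaction(model: CounterfactualModel, X: np.ndarray,
                         feature_j: int | str, feature_k: int | str) -> float:
    """Double-difference interaction of two binary features on treated risk.

    I_jk = mean[ Y(1)|j=1,k=1 - Y(1)|j=1,k=0 - Y(1)|j=0,k=1 + Y(1)|j=0,k=0 ];
    zero when the two features act additively on the prediction, symmetric in
    (j, k) by construction.
    """
    j = _feature_index(model, feature_j)
    k = _feature_index(model, feature_k)
    if j == k:
        raise ValueError("pairwise interaction requires two distinct features")
    _require_binary(model, j)
    _require_binary(model, k)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    total = 0.0
    for vj, vk, sign in ((1, 1, 1), (1, 0, -1), (0, 1, -1), (0, 0, 1)):
        Xi = X.copy()
        Xi[:, j], Xi[:, k] = vj, vk
        total += sign * np.mean(_treated_risk(model, Xi))
    return float(total)


def interaction_matrix(model: CounterfactualModel, X: np.ndarray) -> pd.DataFrame:
    """Symmetric matrix of pairwise interactions over binary covariates.

    The diagonal is left NaN (no self-interaction is defined).
    """
    binary = [name for name, kind in zip(model.covariate_names, model.covariate_kinds)
              if kind == "binary"]
    mat = pd.DataFrame(np.nan, index=binary, columns=binary)
    for a in range(len(binary)):
        for b in range(a + 1, len(binary)):
            v = pairwise_interaction(model, X, binary[a], binary[b])
            mat.iloc[a, b] = mat.iloc[b, a] = v
    return mat


def subgroup_summary(tau: np.ndarray, labels: np.ndarray,
                     benefit_threshold: float = 0.0) -> pd.DataFrame:
    """Per-subgroup ITE summaries.

    benefit probability = fraction with tau < -threshold (risk reduction);
    harm probability = fraction with tau > +threshold; variability is the
    within-group SD.  Group means, weighted by size, reproduce the overall
    ATE exactly.
    """
    tau = np.asarray(tau, dtype=float)
    labels = np.asarray(labels)
    if tau.shape[0] != labels.shape[0]:
        raise ValueError("tau and labels must align")
    rows = []
    for lab in pd.unique(labels):
        g = tau[labels == lab]
        rows.append({
            "group": lab, "n": g.size, "mean_ite": float(g.mean()),
            "sd_ite": float(g.std(ddof=0)),
            "benefit_prob": float(np.mean(g < -benefit_threshold)),
            "harm_prob": float(np.mean(g > benefit_threshold)),
        })
    return pd.DataFrame(rows)
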