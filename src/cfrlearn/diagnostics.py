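"""Balance and predictive-performance diagnostics.

Covariate balance between arms is summarized by the absolute standardized
mean difference (SMD) with the pooled-variance convention, both on raw
covariates and per-dimension on learned embeddings, and by the two-sample
Kolmogorov-Smirnov (KS) distance per latent dimension (summarized as the mean
over dimensions).  Factual predictive performance is scored with AUC, Brier
score, time RMSE, the concordance index over observed conversion times, and
the Spearman rank correlation.  A stratified k-fold harness reports mean and
standard deviation across folds, mirroring how representation-balancing
methods are usually benchmarked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index
from scipy.stats import ks_2samp, spearmanr
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .cohort import CohortTable
from .ipm import IPMConfig
from .model import CounterfactualModel, ModelConfig
from .training import TrainConfig, train

__all__ = [
    "BalanceReport",
    "covariate_smd",
    "balance_report",
    "latent_ks",
    "evaluate_predictions",
    "crossval_evaluate",
]


def covariate_smd(values_treated: np.ndarray, values_control: np.ndarray) -> float:
    """Absolute standardized mean difference with pooled sample variances.

    |mean_T - mean_C| / sqrt((var_T + var_C) / 2), variances with ddof = 1.
    When both arms are constant: 0 if the constants agree, inf otherwise
    (the difference is not standardizable).
    """
    a = np.asarray(values_treated, dtype=float)
    b = np.asarray(values_control, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both arms must be nonempty")
    va = a.var(ddof=1) if a.size > 1 else 0.0
    vb = b.var(ddof=1) if b.size > 1 else 0.0
    pooled = np.sqrt((va + vb) / 2.0)
    gap = abs(a.mean() - b.mean())
    if pooled == 0.0:
        return 0.0 if gap == 0.0 else float("inf")
    return float(gap / pooled)


def latent_ks(z_treated: np.ndarray, z_control: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-dimension two-sample KS statistics and their mean."""
    a = np.atleast_2d(np.asarray(z_treated, dtype=float))
    b = np.atleast_2d(np.asarray(z_control, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both arms must be nonempty")
    stats = np.array([ks_2samp(a[:, j], b[:, j]).statistic for j in range(a.shape[1])])
    return stats, float(stats.mean())


@dataclass
class BalanceReport:
    covariate_smd: pd.Series
    mean_covariate_smd: float
    latent_smd: np.ndarray
    mean_latent_smd: float
    latent_ks: np.ndarray
    mean_latent_ks: float
    n_treated: int
    n_control: int

    def to_dict(self) -> dict:
        return {
            "covariate_smd": self.covariate_smd.to_dict(),
            "mean_covariate_smd": self.mean_covariate_smd,
            "latent_smd": self.latent_smd.tolist(),
            "mean_latent_smd": self.mean_latent_smd,
            "latent_ks": self.latent_ks.tolist(),
            "mean_latent_ks": self.mean_latent_ks,
            "n_treated": self.n_treated, "n_control": self.n_control,
        }


def balance_report(cohort: CohortTable,
                   model: CounterfactualModel | None = None) -> BalanceReport:
    """Raw-covariate SMDs plus, when a model is given, latent SMD/KS."""
    treated = cohort.t == 1
    smds = pd.Series({
        name: covariate_smd(cohort.X[treated, j], cohort.X[~treated, j])
        for j, name in enumerate(cohort.covariate_names)
    })
    if model is not None:
        z = model.encode(cohort.X)
        zt, zc = z[treated], z[~treated]
        lsmd = np.array([covariate_smd(zt[:, j], zc[:, j]) for j in range(z.shape[1])])
        ks_stats, mean_ks = latent_ks(zt, zc)
    else:
        lsmd = np.array([])
        ks_stats, mean_ks = np.array([]), float("nan")
    return BalanceReport(
        covariate_smd=smds, mean_covariate_smd=float(smds.mean()),
        latent_smd=lsmd,
        mean_latent_smd=float(lsmd.mean()) if lsmd.size else float("nan"),
        latent_ks=ks_stats, mean_latent_ks=mean_ks,
        n_treated=int(treated.sum()), n_control=int((~treated).sum()),
    )


def evaluate_predictions(model: CounterfactualModel, cohort: CohortTable) -> dict[str, float]:
    """Factual prediction metrics; counterfactual outputs are never scored.

    AUC is NaN (undefined) when only one outcome class is present; the time
    metrics are NaN with fewer than two observed conversion times.
    """
    pred = model.predict_counterfactual(cohort.X)
    p_factual, t_factual = pred.factual(cohort.t)
    y = cohort.y_inc
    auc = float(roc_auc_score(y, p_factual)) if len(np.unique(y)) == 2 else float("nan")
    brier = float(np.mean((p_factual - y) ** 2))
    obs = cohort.time_observed
    if obs.sum() >= 2:
        yt, yp = cohort.y_time[obs], t_factual[obs]
        rmse = float(np.sqrt(np.mean((yp - yt) ** 2)))
        cindex = float(concordance_index(yt, yp)) if np.unique(yt).size > 1 else float("nan")
        rho = float(spearmanr(yt, yp).statistic) if np.unique(yt).size > 1 else float("nan")
    else:
        rmse = cindex = rho = float("nan")
    return {"auc": auc, "brier": brier, "time_rmse": rmse,
            "c_index": cindex, "spearman": rho}


def crossval_evaluate(cohort: CohortTable, model_config: ModelConfig | None = None,
                      train_config: TrainConfig | None = None,
                      ipm_config: IPMConfig | None = None,
                      k: int = 10, seed: int = 0):
    """Stratified k-fold cross-validation of factual metrics and balance.

    Folds are stratified jointly on (treatment, incidence).  One model per
    fold with identical configs; metrics and latent balance are computed on
    the held-out fold.  Returns (per-fold DataFrame, {metric: (mean, sd)}).
    """
    tc = train_config or TrainConfig()
    strata = 2 * cohort.t + cohort.y_inc
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr_idx, te_idx) in enumerate(skf.split(cohort.X, strata)):
        tr, te = cohort.subset(tr_idx), cohort.subset(te_idx)
        if len(np.unique(tr.t)) < 2:
            raise ValueError(f"fold {fold} training split lacks one arm")
        model, _ = train(tr, model_config, tc, ipm_config)
        metrics = evaluate_predictions(model, te)
        rep = balance_report(te, model)
        rows.append({"fold": fold, **metrics,
                     "mean_latent_smd": rep.mean_latent_smd,
                     "mean_latent_ks": rep.mean_latent_ks})
    df = pd.DataFrame(rows)
    summary = {c: (float(np.nanmean(df[c])), float(np.nanstd(df[c])))
               for c in df.columns if c != "fold"}
    return df, summary
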