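"""Multi-task factual losses, balance-penalized training, and grid selection.

The objective combines a factual binary cross-entropy on conversion incidence
(L_inc), a factual squared error on months-to-conversion over converters only
(L_time), and a distributional balance penalty on the latent batch (L_ipm):

    L_pred  = lambda_inc * L_inc / r_inc + lambda_time * L_time / r_time
    L_total = L_pred + alpha * L_ipm

where r_inc, r_time are exponential running means of the raw losses on the
training split, bringing the two endpoints to comparable magnitude.  Only the
head matching each patient's assigned arm receives gradient from the factual
terms; the encoder receives gradient from all three.

Optimization is Adam (learning rate 2e-3, weight decay 1e-4, batch size 128)
with gradients clipped to a global L2 norm of 1.0.  The balance weight alpha
is scanned over {0.1, 0.5, 1.0, 2.0, 10.0} and the endpoint weights over a
small validation grid, scored by a composite objective that rewards incidence
discrimination (AUC) and calibration (Brier), and penalizes time RMSE and
residual latent imbalance.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .cohort import CohortTable
from .ipm import EmptyArmError, IPMConfig, ipm_distance, ipm_with_grad
from .model import CounterfactualModel, ModelConfig, softplus
from .nn import Adam, clip_gradients

__all__ = [
    "TrainConfig",
    "LossBundle",
    "CompositeObjective",
    "factual_losses",
    "total_loss",
    "train",
    "select_hyperparameters",
    "stratified_split",
]


@dataclass
class TrainConfig:
    learning_rate: float = 2e-3
    weight_decay: float = 1e-4
    batch_size: int = 128
    grad_clip_l2: float = 1.0
    epochs: int = 200
    alpha: float = 1.0
    lambda_inc: float = 1.0
    lambda_time: float = 1.0
    alpha_grid: tuple[float, ...] = (0.1, 0.5, 1.0, 2.0, 10.0)
    lambda_grid: tuple[tuple[float, float], ...] = ((1, 0.25), (1, 0.5), (1, 1), (1, 2))
    rescale_ema_decay: float = 0.99
    rescale_warmup_steps: int = 50
    validation_fraction: float = 0.2
    early_stopping_patience: int = 20
    lr_schedule: str = "cosine"  # "cosine" (decay to 0 over epochs) or "constant"
    seed: int = 0

    def __post_init__(self):
        for name in ("learning_rate", "batch_size", "grad_clip_l2", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.alpha_grid:
            raise ValueError("alpha_grid must be nonempty")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")


@dataclass
class LossBundle:
    L_inc: float
    L_time: float
    L_pred: float
    L_ipm: float
    L_total: float
    lambda_inc: float
    lambda_time: float
    alpha: float


def factual_losses(y_inc_1, y_inc_0, y_time_1, y_time_0,
                   t, y_inc, y_time, mask) -> tuple[float, float]:
    """Factual BCE over all rows and factual MSE over observed-time rows.

    Predictions are probabilities / months (post-link).  L_time is 0 when the
    batch contains no observed conversion time.
    """
    t = np.asarray(t, dtype=float)
    y_inc = np.asarray(y_inc, dtype=float)
    if np.any((y_inc != 0) & (y_inc != 1)):
        raise ValueError("y_inc must be 0/1")
    p = np.clip(t * y_inc_1 + (1 - t) * y_inc_0, 1e-12, 1 - 1e-12)
    l_inc = float(-np.mean(y_inc * np.log(p) + (1 - y_inc) * np.log(1 - p)))
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        return l_inc, 0.0
    yt_hat = (t * y_time_1 + (1 - t) * y_time_0)[mask]
    l_time = float(np.mean((yt_hat - np.asarray(y_time, dtype=float)[mask]) ** 2))
    return l_inc, l_time


def total_loss(l_inc: float, l_time: float, l_ipm: float,
               lambda_inc: float, lambda_time: float, alpha: float,
               r_inc: float = 1.0, r_time: float = 1.0) -> LossBundle:
    """Compose the rescaled multi-task prediction loss and the balance penalty."""
    l_pred = lambda_inc * l_inc / r_inc + lambda_time * l_time / r_time
    return LossBundle(l_inc, l_time, l_pred, l_ipm, l_pred + alpha * l_ipm,
                      lambda_inc, lambda_time, alpha)


def stratified_split(t: np.ndarray, y_inc: np.ndarray, fraction: float,
                     seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic validation split stratified jointly on (t, y_inc)."""
    rng = np.random.default_rng(seed)
    strata = 2 * np.asarray(t) + np.asarray(y_inc)
    val = []
    for s in np.unique(strata):
        idx = np.where(strata == s)[0]
        idx = idx[rng.permutation(len(idx))]
        k = max(1, int(round(fraction * len(idx)))) if len(idx) > 1 else 0
        val.extend(idx[:k])
    val = np.sort(np.array(val, dtype=int))
    train_idx = np.setdiff1d(np.arange(len(t)), val)
    return train_idx, val


def _batch_gradients(model: CounterfactualModel, X, t, y_inc, y_time, mask,
                     lambda_inc, lambda_time, alpha, r_inc, r_time,
                     ipm_config: IPMConfig, rng) -> tuple[LossBundle, bool]:
    """Forward/backward for one minibatch; fills parameter gradients.

    Returns the (rescaled) loss bundle and whether the IPM term was skipped
    because one arm was empty in the batch.
    """
    B = X.shape[0]
    t = np.asarray(t, dtype=float)
    z = model.encode(X, train=True, rng=rng)
    raw = {name: model.heads[name].forward(z, train=True) for name in model.heads}

    logit_f = t * raw["inc_1"].ravel() + (1 - t) * raw["inc_0"].ravel()
    l_inc = float(np.mean(np.logaddexp(0.0, logit_f) - y_inc * logit_f))
    g_logit = (expit(logit_f) - y_inc) / B * (lambda_inc / r_inc)

    dz = np.zeros_like(z)
    dz += model.heads["inc_1"].backward((g_logit * t)[:, None])
    dz += model.heads["inc_0"].backward((g_logit * (1 - t))[:, None])

    l_time = 0.0
    n_obs = int(np.sum(mask))
    if n_obs > 0:
        raw_f = t * raw["time_1"].ravel() + (1 - t) * raw["time_0"].ravel()
        resid = (softplus(raw_f) - np.where(mask, y_time, 0.0)) * mask
        l_time = float(np.sum(resid ** 2) / n_obs)
        if lambda_time > 0:
            g_raw = 2.0 * resid * expit(raw_f) / n_obs * (lambda_time / r_time)
            dz += model.heads["time_1"].backward((g_raw * t)[:, None])
            dz += model.heads["time_0"].backward((g_raw * (1 - t))[:, None])

    l_ipm, skipped = 0.0, False
    treated = t == 1
    if alpha > 0:
        try:
            l_ipm, gt, gc = ipm_with_grad(z[treated], z[~treated], ipm_config)
            dz[treated] += alpha * gt
            dz[~treated] += alpha * gc
        except EmptyArmError:
            skipped = True
    elif treated.any() and (~treated).any():
        l_ipm = ipm_distance(z[treated], z[~treated], ipm_config)

    model.encoder.backward(dz)
    return total_loss(l_inc, l_time, l_ipm, lambda_inc, lambda_time, alpha,
                      r_inc, r_time), skipped


def evaluate_split(model: CounterfactualModel, cohort: CohortTable,
                   ipm_config: IPMConfig, lambda_inc, lambda_time, alpha,
                   r_inc=1.0, r_time=1.0) -> LossBundle:
    """Raw losses of a split in evaluation mode, with a full-data IPM."""
    pred = model.predict_counterfactual(cohort.X)
    l_inc, l_time = factual_losses(pred.y_inc_1, pred.y_inc_0, pred.y_time_1,
                                   pred.y_time_0, cohort.t, cohort.y_inc,
                                   cohort.y_time, cohort.time_observed)
    z = model.encode(cohort.X)
    treated = cohort.t == 1
    try:
        l_ipm = ipm_distance(z[treated], z[~treated], ipm_config)
    except EmptyArmError:
        l_ipm = 0.0
    return total_loss(l_inc, l_time, l_ipm, lambda_inc, lambda_time, alpha,
                      r_inc, r_time)


def train(cohort: CohortTable, model_config: ModelConfig | None = None,
          train_config: TrainConfig | None = None,
          ipm_config: IPMConfig | None = None,
          ) -> tuple[CounterfactualModel, pd.DataFrame]:
    """Fit the encoder and heads; returns the model and the per-epoch history.

    Deterministic given the configs and seeds.  Early stopping monitors the
    validation total loss with the configured patience and restores the best
    checkpoint.  Divergence (non-finite loss) aborts with the last good
    checkpoint and a warning.
    """
    tc = train_config or TrainConfig()
    ic = ipm_config or IPMConfig()
    if cohort.t.sum() == 0 or cohort.t.sum() == cohort.n:
        raise ValueError("training requires both a treated and a control arm")
    if tc.lambda_time > 0 and cohort.time_observed.sum() == 0:
        raise ValueError("lambda_time > 0 requires at least one observed conversion time")

    mc = model_config or ModelConfig(input_dim=cohort.X.shape[1], seed=tc.seed)
    model = CounterfactualModel(mc, cohort.covariate_names, cohort.covariate_kinds)

    tr_idx, va_idx = stratified_split(cohort.t, cohort.y_inc, tc.validation_fraction, tc.seed)
    tr, va = cohort.subset(tr_idx), cohort.subset(va_idx)
    model.set_standardization(tr.X)

    optimizer = Adam(model.params, lr=tc.learning_rate, weight_decay=tc.weight_decay)
    rng = np.random.default_rng(tc.seed + 1)
    r_inc_ema, r_time_ema = None, None
    # monitor rescalers are frozen at the end of warm-up so the validation
    # total loss stays comparable across epochs (the per-step EMA keeps
    # adapting for gradient scaling)
    r_monitor: tuple[float, float] | None = None
    step = 0
    skipped_batches = 0
    history: list[dict] = []
    best = (np.inf, None, -1)  # (val L_total, params snapshot, epoch)

    for epoch in range(1, tc.epochs + 1):
        if tc.lr_schedule == "cosine":
            optimizer.lr = tc.learning_rate * 0.5 * (1 + np.cos(np.pi * (epoch - 1) / tc.epochs))
        order = rng.permutation(tr.n)
        diverged = False
        for start in range(0, tr.n, tc.batch_size):
            idx = order[start:start + tc.batch_size]
            if step < tc.rescale_warmup_steps or r_inc_ema is None:
                r_inc = 1.0
            else:
                r_inc = max(r_inc_ema, 1e-8)
            if step < tc.rescale_warmup_steps or r_time_ema is None:
                r_time = 1.0
            else:
                r_time = max(r_time_ema, 1e-8)
            if step == tc.rescale_warmup_steps and r_monitor is None:
                r_monitor = (r_inc, r_time)
            optimizer.zero_grad()
            bundle, skipped = _batch_gradients(
                model, tr.X[idx], tr.t[idx], tr.y_inc[idx], tr.y_time[idx],
                tr.time_observed[idx], tc.lambda_inc, tc.lambda_time, tc.alpha,
                r_inc, r_time, ic, rng)
            skipped_batches += int(skipped)
            if not np.isfinite(bundle.L_total):
                diverged = True
                break
            optimizer.add_weight_decay()
            clip_gradients(model.params, tc.grad_clip_l2)
            optimizer.step()
            d = tc.rescale_ema_decay
            r_inc_ema = bundle.L_inc if r_inc_ema is None else d * r_inc_ema + (1 - d) * bundle.L_inc
            if bundle.L_time > 0 or tr.time_observed[idx].sum() > 0:
                r_time_ema = (bundle.L_time if r_time_ema is None
                              else d * r_time_ema + (1 - d) * bundle.L_time)
            step += 1
        if diverged:
            warnings.warn("training diverged; restoring last good checkpoint",
                          RuntimeWarning, stacklevel=2)
            break

        r_inc, r_time = r_monitor if r_monitor is not None else (1.0, 1.0)
        tr_b = evaluate_split(model, tr, ic, tc.lambda_inc, tc.lambda_time, tc.alpha, r_inc, r_time)
        va_b = evaluate_split(model, va, ic, tc.lambda_inc, tc.lambda_time, tc.alpha, r_inc, r_time)
        history.append({
            "epoch": epoch,
            "train_L_inc": tr_b.L_inc, "train_L_time": tr_b.L_time,
            "train_L_ipm": tr_b.L_ipm, "train_L_total": tr_b.L_total,
            "val_L_inc": va_b.L_inc, "val_L_time": va_b.L_time,
            "val_L_ipm": va_b.L_ipm, "val_L_total": va_b.L_total,
        })
        if va_b.L_total < best[0]:
            best = (va_b.L_total, _snapshot(model), epoch)
        elif epoch - best[2] >= tc.early_stopping_patience:
            break

    if best[1] is not None:
        _restore(model, best[1])
    if skipped_batches:
        warnings.warn(f"{skipped_batches} minibatches had an empty arm; "
                      "IPM penalty skipped for those steps", RuntimeWarning, stacklevel=2)
    return model, pd.DataFrame(history)


def _snapshot(model):
    return ([p.value.copy() for p in model.params],
            copy.deepcopy(model._state_arrays()))


def _restore(model, snap):
    values, arrays = snap
    for p, v in zip(model.params, values):
        p.value[...] = v
    from .nn import BatchNorm
    bn = [l for l in model.encoder.layers if isinstance(l, BatchNorm)]
    for i, layer in enumerate(bn):
        layer.running_mean[...] = arrays[f"bn_{i}_mean"]
        layer.running_var[...] = arrays[f"bn_{i}_var"]


def train_ensemble(cohort: CohortTable, model_config: ModelConfig | None = None,
                   train_config: TrainConfig | None = None,
                   ipm_config: IPMConfig | None = None,
                   n_models: int = 3) -> list[CounterfactualModel]:
    """Fit a small seed ensemble on the same cohort.

    Each member uses the same configs with a distinct derived seed
    (seed + 1000 k); averaging their effect predictions damps optimizer and
    initialization noise in the point estimates.
    """
    tc = train_config or TrainConfig()
    models = []
    for k in range(n_models):
        tck = TrainConfig(**{**asdict(tc), "seed": tc.seed + 1000 * k})
        mck = model_config
        if mck is not None:
            mck = ModelConfig(**{**asdict(mck), "seed": tck.seed})
        models.append(train(cohort, mck, tck, ipm_config)[0])
    return models


# ----------------------------------------------------- hyperparameter search

@dataclass
class CompositeObjective:
    """Validation score: w_auc*AUC - w_cal*Brier - w_rmse*nRMSE - w_ipm*nIPM.

    RMSE is normalized by the standard deviation of observed conversion times
    on the validation split; the IPM is computed between arms after per-
    dimension standardization of the pooled validation embeddings, making
    both terms scale-free.
    """

    w_auc: float = 1.0
    w_cal: float = 0.5
    w_rmse: float = 1.0
    w_ipm: float = 0.5

    def evaluate(self, model: CounterfactualModel, val: CohortTable,
                 ipm_config: IPMConfig) -> dict[str, float]:
        pred = model.predict_counterfactual(val.X)
        p_factual, t_factual = pred.factual(val.t)
        if len(np.unique(val.y_inc)) < 2:
            auc = np.nan
        else:
            auc = float(roc_auc_score(val.y_inc, p_factual))
        brier = float(np.mean((p_factual - val.y_inc) ** 2))
        obs = val.time_observed
        if obs.sum() >= 2 and np.std(val.y_time[obs]) > 0:
            rmse = float(np.sqrt(np.mean((t_factual[obs] - val.y_time[obs]) ** 2)))
            nrmse = rmse / float(np.std(val.y_time[obs]))
        else:
            nrmse = 0.0
        z = model.encode(val.X)
        sd = z.std(axis=0)
        z = (z - z.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        treated = val.t == 1
        try:
            nipm = ipm_distance(z[treated], z[~treated], ipm_config)
        except EmptyArmError:
            nipm = 0.0
        value = (self.w_auc * (auc if np.isfinite(auc) else 0.0)
                 - self.w_cal * brier - self.w_rmse * nrmse - self.w_ipm * nipm)
        return {"auc": auc, "brier": brier, "nrmse": nrmse, "nipm": nipm,
                "objective": value}


def select_hyperparameters(cohort: CohortTable,
                           model_config: ModelConfig | None = None,
                           train_config: TrainConfig | None = None,
                           ipm_config: IPMConfig | None = None,
                           objective: CompositeObjective | None = None,
                           staged: bool = True):
    """Choose (lambda_inc, lambda_time) and alpha on the validation split.

    Staged search (default): scan the lambda grid at alpha = 1, keep the
    maximizer of the composite objective, then scan the alpha grid at the
    selected lambdas.  Ties break toward the smaller alpha, then the smaller
    lambda_time.  Returns (alpha*, (lambda_inc*, lambda_time*), fitted model,
    grid report).
    """
    tc = train_config or TrainConfig()
    ic = ipm_config or IPMConfig()
    obj = objective or CompositeObjective()
    report: list[dict] = []

    def run_cell(alpha, lam):
        cell_tc = TrainConfig(**{**asdict(tc), "alpha": alpha,
                                 "lambda_inc": lam[0], "lambda_time": lam[1]})
        model, _ = train(cohort, model_config, cell_tc, ic)
        _, va_idx = stratified_split(cohort.t, cohort.y_inc, tc.validation_fraction, tc.seed)
        scores = obj.evaluate(model, cohort.subset(va_idx), ic)
        report.append({"alpha": alpha, "lambda_inc": lam[0], "lambda_time": lam[1], **scores})
        return model, scores["objective"]

    def argmax(cells):
        finite = [(o, a, lam, m) for (o, a, lam, m) in cells if np.isfinite(o)]
        if not finite:
            raise RuntimeError(f"every grid cell diverged; report: {report}")
        # maximize objective; ties -> smaller alpha, then smaller lambda_time
        return max(finite, key=lambda c: (c[0], -c[1], -c[2][1]))

    if staged:
        lam_cells = []
        for lam in tc.lambda_grid:
            m, o = run_cell(1.0, tuple(lam))
            lam_cells.append((o, 1.0, tuple(lam), m))
        _, _, lam_star, _ = argmax(lam_cells)
        a_cells = []
        for alpha in tc.alpha_grid:
            m, o = run_cell(alpha, lam_star)
            a_cells.append((o, alpha, lam_star, m))
        _, alpha_star, lam_star, model = argmax(a_cells)
    else:
        cells = []
        for alpha in tc.alpha_grid:
            for lam in tc.lambda_grid:
                m, o = run_cell(alpha, tuple(lam))
                cells.append((o, alpha, tuple(lam), m))
        _, alpha_star, lam_star, model = argmax(cells)
    return alpha_star, lam_star, model, pd.DataFrame(report)
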