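"""Loss arithmetic, split construction, and small end-to-end training runs."""

import numpy as np
import pandas as pd
import pytest

from cfrlearn.ipm import IPMConfig
from cfrlearn.model import ModelConfig
from cfrlearn.synthetic import generate_cohort, standard_spec
from cfrlearn.training import (CompositeObjective, TrainConfig, factual_losses,
                               select_hyperparameters, stratified_split,
                               total_loss, train)


def test_factual_losses_hand_values():
    """One treated row at prediction 0.5 gives BCE ln 2; a constant +2
    residual gives time MSE 4."""
    l_inc, _ = factual_losses(np.array([0.5]), np.array([0.9]),
                              np.array([10.0]), np.array([10.0]),
                              t=np.array([1]), y_inc=np.array([1]),
                              y_time=np.array([np.nan]), mask=np.array([False]))
    assert l_inc == pytest.approx(np.log(2), abs=1e-12)
    y_time = np.array([10.0, 20.0, 30.0])
    _, l_time = factual_losses(np.full(3, 0.5), np.full(3, 0.5),
                               y_time + 2.0, y_time + 7.0,
                               t=np.ones(3, dtype=int), y_inc=np.ones(3, dtype=int),
                               y_time=y_time, mask=np.ones(3, dtype=bool))
    assert l_time == pytest.approx(4.0, abs=1e-12)


def test_factual_losses_select_assigned_arm_only():
    """Control rows must be scored by the control head, not the treated one."""
    l_inc, _ = factual_losses(np.array([0.99]), np.array([0.5]),
                              np.zeros(1), np.zeros(1),
                              t=np.array([0]), y_inc=np.array([0]),
                              y_time=np.array([np.nan]), mask=np.array([False]))
    assert l_inc == pytest.approx(np.log(2), abs=1e-12)


def test_factual_losses_empty_mask_and_bad_labels():
    l_inc, l_time = factual_losses(np.array([0.4]), np.array([0.4]),
                                   np.array([5.0]), np.array([5.0]),
                                   t=np.array([1]), y_inc=np.array([0]),
                                   y_time=np.array([np.nan]), mask=np.array([False]))
    assert l_time == 0.0
    with pytest.raises(ValueError, match="0/1"):
        factual_losses(np.array([0.4]), np.array([0.4]), np.array([5.0]),
                       np.array([5.0]), np.array([1]), np.array([2]),
                       np.array([np.nan]), np.array([False]))


def test_total_loss_hand_arithmetic():
    """L_inc=0.6, L_time=9, r=(0.6,9), lambda=(1,1), alpha=2, L_ipm=0.25
    composes to exactly 2.5; alpha=0 collapses to L_pred."""
    b = total_loss(0.6, 9.0, 0.25, 1.0, 1.0, 2.0, r_inc=0.6, r_time=9.0)
    assert b.L_total == pytest.approx(2.5, abs=1e-12)
    assert b.L_pred == pytest.approx(2.0, abs=1e-12)
    b0 = total_loss(0.6, 9.0, 0.25, 1.0, 1.0, 0.0, r_inc=0.6, r_time=9.0)
    assert b0.L_total == b0.L_pred


def test_stratified_split_covers_all_strata_deterministically():
    rng = np.random.default_rng(0)
    t = (rng.random(400) < 0.4).astype(int)
    y = (rng.random(400) < 0.3).astype(int)
    tr1, va1 = stratified_split(t, y, 0.2, seed=5)
    tr2, va2 = stratified_split(t, y, 0.2, seed=5)
    np.testing.assert_array_equal(va1, va2)
    assert len(np.intersect1d(tr1, va1)) == 0
    assert len(tr1) + len(va1) == 400
    for s in range(4):
        mask = (2 * t + y) == s
        if mask.sum() > 1:
            assert np.isin(np.where(mask)[0], va1).any()


@pytest.fixture(scope="module")
def small_run():
    sc = generate_cohort(standard_spec(n=800, seed=7))
    tc = TrainConfig(epochs=15, early_stopping_patience=15, seed=3, alpha=1.0,
                     rescale_warmup_steps=10)
    model, hist = train(sc.cohort, None, tc, IPMConfig(kind="mmd_linear"))
    return sc, tc, model, hist


def test_training_reduces_total_loss(small_run):
    _, _, _, hist = small_run
    assert hist["train_L_total"].iloc[-1] < hist["train_L_total"].iloc[0]


def test_training_is_reproducible(small_run):
    sc, tc, model, hist = small_run
    model2, hist2 = train(sc.cohort, None, tc, IPMConfig(kind="mmd_linear"))
    pd.testing.assert_frame_equal(hist, hist2)
    a = model.predict_counterfactual(sc.cohort.X[:5])
    b = model2.predict_counterfactual(sc.cohort.X[:5])
    np.testing.assert_array_equal(a.y_inc_1, b.y_inc_1)
    np.testing.assert_array_equal(a.y_time_0, b.y_time_0)


def test_lambda_time_zero_freezes_time_heads():
    sc = generate_cohort(standard_spec(n=500, seed=11))
    tc = TrainConfig(epochs=3, seed=1, alpha=0.0, lambda_time=0.0,
                     early_stopping_patience=5)
    mc = ModelConfig(input_dim=sc.cohort.X.shape[1], seed=1)
    model, _ = train(sc.cohort, mc, tc, IPMConfig(kind="mmd_linear"))
    fresh = ModelConfig(input_dim=sc.cohort.X.shape[1], seed=1)
    from cfrlearn.model import CounterfactualModel
    ref = CounterfactualModel(fresh, sc.cohort.covariate_names,
                              sc.cohort.covariate_kinds)
    # time-head parameters keep only the weight-decay shrinkage (no loss
    # gradient); weight decay affects decayed slots, so biases are untouched
    for name in ("time_1", "time_0"):
        for p_trained, p_ref in zip(model.heads[name].params, ref.heads[name].params):
            if not p_trained.decay:
                np.testing.assert_array_equal(p_trained.value, p_ref.value)


def test_single_arm_cohort_rejected():
    sc = generate_cohort(standard_spec(n=300, seed=5))
    c = sc.cohort.subset(np.where(sc.cohort.t == 1)[0])
    with pytest.raises(ValueError, match="arm"):
        train(c, None, TrainConfig(epochs=1), IPMConfig())


def test_grid_selection_single_cell_and_tie_breaks():
    sc = generate_cohort(standard_spec(n=600, seed=13))
    tc = TrainConfig(epochs=4, seed=2, alpha_grid=(0.5,), lambda_grid=((1, 1),),
                     early_stopping_patience=5)
    alpha, lam, model, report = select_hyperparameters(
        sc.cohort, None, tc, IPMConfig(kind="mmd_linear"))
    assert alpha == 0.5
    assert lam == (1, 1)
    # staged search: one lambda row (alpha=1) + one alpha row
    assert len(report) == 2
    assert {"auc", "brier", "nrmse", "nipm", "objective"} <= set(report.columns)


def test_composite_objective_finite_on_validation():
    sc = generate_cohort(standard_spec(n=500, seed=17))
    tc = TrainConfig(epochs=3, seed=1, early_stopping_patience=5)
    model, _ = train(sc.cohort, None, tc, IPMConfig(kind="mmd_linear"))
    from cfrlearn.training import stratified_split
    _, va = stratified_split(sc.cohort.t, sc.cohort.y_inc, 0.2, 1)
    scores = CompositeObjective().evaluate(model, sc.cohort.subset(va),
                                           IPMConfig(kind="mmd_linear"))
    assert np.isfinite(scores["objective"])
    assert 0 <= scores["auc"] <= 1


def test_stronger_penalty_lowers_validation_imbalance():
    """Training with a large balance weight yields a smaller validation
    IPM than training without it, same seed."""
    from cfrlearn.training import evaluate_split
    sc = generate_cohort(standard_spec(n=800, seed=23, confounding_scale=1.5))
    vals = {}
    for alpha in (0.0, 10.0):
        tc = TrainConfig(epochs=25, early_stopping_patience=10**6, seed=4,
                         alpha=alpha)
        model, _ = train(sc.cohort, None, tc, IPMConfig(kind="mmd_linear"))
        _, va = stratified_split(sc.cohort.t, sc.cohort.y_inc, 0.2, 4)
        bundle = evaluate_split(model, sc.cohort.subset(va),
                                IPMConfig(kind="mmd_linear"), 1, 1, alpha)
        vals[alpha] = bundle.L_ipm
    assert vals[10.0] < vals[0.0]
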