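"""Effect estimators: definition identities, bootstrap, attribution conventions."""

import numpy as np
import pytest

from cfrlearn.effects import (bootstrap_ci, compute_ite, directional_effect,
                              pairwise_interaction, subgroup_summary)
from cfrlearn.model import CounterfactualModel, ModelConfig


@pytest.fixture()
def model():
    cfg = ModelConfig(input_dim=4, encoder_widths=[8], latent_dim=4,
                      head_widths=[6, 3], seed=13)
    m = CounterfactualModel(cfg, covariate_names=["a", "b", "c", "age"],
                            covariate_kinds=["binary", "binary", "binary", "continuous"])
    rng = np.random.default_rng(1)
    for p in m.params:
        p.value += rng.normal(0, 0.3, p.value.shape)
    return m


def _X(n=20, seed=2):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 4))
    X[:, :3] = (X[:, :3] > 0).astype(float)
    return X


def test_ite_definition_and_tied_heads(model):
    X = _X()
    pred = model.predict_counterfactual(X)
    np.testing.assert_allclose(compute_ite(model, X, "incidence"),
                               pred.y_inc_1 - pred.y_inc_0, atol=1e-14)
    np.testing.assert_allclose(compute_ite(model, X, "time"),
                               pred.y_time_1 - pred.y_time_0, atol=1e-14)
    with pytest.raises(ValueError, match="endpoint"):
        compute_ite(model, X, "hazard")
    for p1, p0 in zip(model.heads["inc_1"].params, model.heads["inc_0"].params):
        p0.value[...] = p1.value
    np.testing.assert_allclose(compute_ite(model, X, "incidence"), 0.0, atol=1e-14)


def test_ate_is_exact_mean_of_ites(model):
    X = _X(50)
    tau = compute_ite(model, X, "incidence")
    assert tau.mean() == pytest.approx(float(np.mean(tau)), abs=1e-15)
    assert np.all((tau >= -1) & (tau <= 1))


# ------------------------------------------------------------------ bootstrap

def oracle_percentile_bootstrap(tau, level, n_boot, seed):
    """Independent re-implementation following the documented seed protocol."""
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(tau), size=(n_boot, len(tau)))
    means = np.sort(np.asarray(tau)[idx].mean(axis=1))
    lo = (1 - level) / 2
    return (float(np.quantile(means, lo)), float(np.quantile(means, 1 - lo)))


def test_bootstrap_matches_independent_oracle():
    tau = np.array([-0.21, -0.18, -0.02, 0.05, -0.33, -0.11, 0.02, -0.25,
                    -0.07, -0.15, 0.11, -0.29, -0.19, -0.01, -0.09, -0.23,
                    0.03, -0.13, -0.27, -0.05])
    got = bootstrap_ci(tau, level=0.95, n_boot=200, seed=1)
    want = oracle_percentile_bootstrap(tau, 0.95, 200, 1)
    assert got[0] == pytest.approx(want[0], abs=1e-12)
    assert got[1] == pytest.approx(want[1], abs=1e-12)
    assert bootstrap_ci(tau, seed=1) == bootstrap_ci(tau, seed=1)  # deterministic


def test_bootstrap_degenerate_and_symmetric_cases():
    const = np.full(30, -0.2)
    lo, hi = bootstrap_ci(const, seed=0)
    assert lo == hi == pytest.approx(-0.2)
    lo, hi = bootstrap_ci(np.array([-1.0, 1.0]), n_boot=4000, seed=3)
    assert lo == pytest.approx(-hi, abs=0.1)


def test_bootstrap_interval_shrinks_with_n():
    rng = np.random.default_rng(5)
    widths = []
    for n in (500, 4000):
        tau = rng.normal(-0.1, 0.2, n)
        lo, hi = bootstrap_ci(tau, n_boot=300, seed=7)
        widths.append(hi - lo)
    assert widths[1] < widths[0]


# ----------------------------------------------------- directional effects

def test_directional_effect_zero_when_model_ignores_feature(model):
    """Zeroing the encoder input weights of one covariate forces DE_j = 0."""
    model.heads  # model built; zero column 1 of the first encoder layer
    model.encoder.layers[0].W.value[1, :] = 0.0
    assert directional_effect(model, _X(), "b") == pytest.approx(0.0, abs=1e-14)


def test_directional_effect_single_row_equals_two_predictions(model):
    X = _X(1)
    X1, X0 = X.copy(), X.copy()
    X1[0, 2], X0[0, 2] = 1.0, 0.0
    want = (model.predict_counterfactual(X1).y_inc_1
            - model.predict_counterfactual(X0).y_inc_1)[0]
    assert directional_effect(model, X, "c") == pytest.approx(float(want), abs=1e-14)


def test_directional_effect_mean_decomposes_over_rows(model):
    X = _X(15)
    per_row = [directional_effect(model, X[i:i + 1], 0) for i in range(15)]
    assert directional_effect(model, X, 0) == pytest.approx(np.mean(per_row), abs=1e-12)


def test_directional_effect_rejects_continuous(model):
    with pytest.raises(ValueError, match="continuous"):
        directional_effect(model, _X(), "age")


# ---------------------------------------------------------------- interactions

def test_interaction_symmetry_and_self_error(model):
    X = _X(25)
    ab = pairwise_interaction(model, X, "a", "b")
    ba = pairwise_interaction(model, X, "b", "a")
    assert ab == pytest.approx(ba, abs=1e-12)
    with pytest.raises(ValueError, match="distinct"):
        pairwise_interaction(model, X, "a", "a")


def test_interaction_closed_form_product_predictor():
    """A hand-built predictor y(1) = 0.1 + 0.2 x_j x_k has interaction 0.2,
    and an additive predictor has interaction exactly 0."""

    class Toy:
        covariate_names = ["j", "k"]
        covariate_kinds = ["binary", "binary"]

        def __init__(self, fn):
            self.fn = fn

        def predict_counterfactual(self, X):
            from cfrlearn.model import CounterfactualPrediction
            v = self.fn(X)
            z = np.zeros(len(X))
            return CounterfactualPrediction(v, z, z, z)

    X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    prod = Toy(lambda X: 0.1 + 0.2 * X[:, 0] * X[:, 1])
    assert pairwise_interaction(prod, X, 0, 1) == pytest.approx(0.2, abs=1e-14)
    add = Toy(lambda X: 0.1 + 0.3 * X[:, 0] - 0.2 * X[:, 1])
    assert pairwise_interaction(add, X, 0, 1) == pytest.approx(0.0, abs=1e-14)


# ------------------------------------------------------------------ subgroups

def test_subgroup_probabilities_and_decomposition():
    tau = np.array([-0.2] * 4 + [-0.1, 0.1] + [0.3] * 3)
    labels = np.array(["a"] * 4 + ["b"] * 2 + ["c"] * 3)
    df = subgroup_summary(tau, labels).set_index("group")
    assert df.loc["a", "benefit_prob"] == 1.0
    assert df.loc["a", "sd_ite"] == 0.0
    assert df.loc["b", "benefit_prob"] == 0.5
    assert df.loc["b", "harm_prob"] == 0.5
    # weighted group means reproduce the global ATE exactly
    weighted = (df["mean_ite"] * df["n"]).sum() / df["n"].sum()
    assert weighted == pytest.approx(tau.mean(), abs=1e-12)


def test_subgroup_random_three_group_decomposition():
    rng = np.random.default_rng(11)
    tau = rng.normal(size=200)
    labels = rng.integers(0, 3, 200)
    df = subgroup_summary(tau, labels)
    weighted = (df["mean_ite"] * df["n"]).sum() / df["n"].sum()
    assert weighted == pytest.approx(tau.mean(), abs=1e-12)


def test_bootstrap_coverage_calibration():
    """Across simulated draws, the 95% percentile interval for the mean
    covers the true mean at close to its nominal rate."""
    rng = np.random.default_rng(17)
    mu, covered = -0.1, 0
    n_sims = 200
    for s in range(n_sims):
        tau = rng.normal(mu, 0.3, 150)
        lo, hi = bootstrap_ci(tau, level=0.95, n_boot=200, seed=s)
        covered += lo <= mu <= hi
    assert covered / n_sims >= 0.88
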