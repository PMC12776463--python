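"""Encoder and dual prediction network for counterfactual outcome estimation.

The network maps baseline covariates ``x`` to a latent embedding ``z = Phi(x)``
through an MLP with batch normalization, ReLU and dropout, then evaluates four
outcome heads on the shared embedding: an incidence head and a months-to-
conversion head for each treatment condition.  Incidence heads end in a
logistic link so predictions live in (0, 1); time heads end in a softplus link
so predicted months are nonnegative by construction rather than by clipping.

Each head is a two-layer MLP with its own parameters, so perturbing the
treated-condition heads can never change control-condition predictions.

At inference dropout is disabled and batch norm uses running statistics, so
counterfactual predictions are deterministic functions of the covariates.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit

from .nn import BatchNorm, Dropout, Linear, Param, ReLU, Sequential

__all__ = ["ModelConfig", "CounterfactualPrediction", "CounterfactualModel"]


@dataclass
class ModelConfig:
    input_dim: int
    encoder_widths: list[int] = field(default_factory=lambda: [64, 64])
    latent_dim: int = 32
    head_widths: list[int] = field(default_factory=lambda: [32, 16])
    dropout_rate: float = 0.1
    use_batch_norm: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.input_dim < 1:
            raise ValueError("input_dim must be positive")
        if any(w < 1 for w in self.encoder_widths) or self.latent_dim < 1:
            raise ValueError("encoder widths and latent_dim must be positive")
        if len(self.head_widths) != 2 or any(w < 1 for w in self.head_widths):
            raise ValueError("heads are two-layer MLPs: head_widths needs exactly 2 positive entries")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class CounterfactualPrediction:
    """The four potential-outcome predictions per patient.

    ``y_inc_1`` / ``y_inc_0``: incidence probability under treatment / control.
    ``y_time_1`` / ``y_time_0``: expected months to conversion under each arm.
    """

    y_inc_1: np.ndarray
    y_inc_0: np.ndarray
    y_time_1: np.ndarray
    y_time_0: np.ndarray

    def factual(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Select the predictions matching each patient's assigned arm."""
        t = np.asarray(t, dtype=float)
        y_inc = t * self.y_inc_1 + (1 - t) * self.y_inc_0
        y_time = t * self.y_time_1 + (1 - t) * self.y_time_0
        return y_inc, y_time


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


HEAD_NAMES = ("inc_1", "inc_0", "time_1", "time_0")


class CounterfactualModel:
    """Encoder plus four outcome heads, with covariate standardization baked in.

    Continuous covariates are standardized with training-split statistics
    stored on the model, so callers always pass raw covariates.
    """

    def __init__(self, config: ModelConfig, covariate_names: list[str] | None = None,
                 covariate_kinds: list[str] | None = None):
        self.config = config
        d = config.input_dim
        self.covariate_names = covariate_names or [f"x{i}" for i in range(d)]
        self.covariate_kinds = covariate_kinds or ["continuous"] * d
        if len(self.covariate_names) != d or len(self.covariate_kinds) != d:
            raise ValueError("covariate names/kinds must match input_dim")
        self.std_mean = np.zeros(d)
        self.std_scale = np.ones(d)
        rng = np.random.default_rng(config.seed)

        layers: list = []
        prev = d
        for w in config.encoder_widths:
            layers.append(Linear(prev, w, rng))
            if config.use_batch_norm:
                layers.append(BatchNorm(w))
            layers.append(ReLU())
            if config.dropout_rate > 0:
                layers.append(Dropout(config.dropout_rate))
            prev = w
        layers.append(Linear(prev, config.latent_dim, rng))
        self.encoder = Sequential(layers)

        def make_head() -> Sequential:
            h1, h2 = config.head_widths
            return Sequential([
                Linear(config.latent_dim, h1, rng),
                ReLU(),
                Linear(h1, h2, rng),
                ReLU(),
                Linear(h2, 1, rng),
            ])

        self.heads = {name: make_head() for name in HEAD_NAMES}

    # ------------------------------------------------------------------ params
    @property
    def params(self) -> list[Param]:
        out = list(self.encoder.params)
        for name in HEAD_NAMES:
            out.extend(self.heads[name].params)
        return out

    def set_standardization(self, X_train: np.ndarray) -> None:
        """Store per-column standardization for continuous covariates."""
        X_train = np.asarray(X_train, dtype=np.float64)
        cont = np.array([k == "continuous" for k in self.covariate_kinds])
        mean = np.zeros(X_train.shape[1])
        scale = np.ones(X_train.shape[1])
        if cont.any():
            mean[cont] = X_train[:, cont].mean(axis=0)
            sd = X_train[:, cont].std(axis=0, ddof=0)
            scale[cont] = np.where(sd > 0, sd, 1.0)
        self.std_mean, self.std_scale = mean, scale

    def standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"covariate matrix has {X.shape[1]} columns, model expects {self.config.input_dim}"
            )
        return (X - self.std_mean) / self.std_scale

    # ----------------------------------------------------------------- forward
    def encode(self, X: np.ndarray, train: bool = False,
               rng: np.random.Generator | None = None) -> np.ndarray:
        """Embed raw covariates into the latent space."""
        return self.encoder.forward(self.standardize(X), train=train, rng=rng)

    def head_raw(self, z: np.ndarray, train: bool = False) -> dict[str, np.ndarray]:
        """Pre-link head outputs (logits for incidence, pre-softplus for time)."""
        return {name: self.heads[name].forward(z, train=train).ravel()
                for name in HEAD_NAMES}

    def predict_counterfactual(self, X: np.ndarray) -> CounterfactualPrediction:
        """Evaluate all four heads in evaluation mode on the shared embedding."""
        z = self.encode(X, train=False)
        raw = self.head_raw(z, train=False)
        return CounterfactualPrediction(
            y_inc_1=expit(raw["inc_1"]),
            y_inc_0=expit(raw["inc_0"]),
            y_time_1=softplus(raw["time_1"]),
            y_time_0=softplus(raw["time_0"]),
        )

    # ----------------------------------------------------------- serialization
    def _state_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.params):
            arrays[f"param_{i}"] = p.value
        bn = [l for l in self.encoder.layers if isinstance(l, BatchNorm)]
        for i, layer in enumerate(bn):
            arrays[f"bn_{i}_mean"] = layer.running_mean
            arrays[f"bn_{i}_var"] = layer.running_var
        arrays["std_mean"] = self.std_mean
        arrays["std_scale"] = self.std_scale
        return arrays

    def save(self, path: str) -> None:
        """Write a model artifact directory: parameter blob + JSON manifest."""
        os.makedirs(path, exist_ok=True)
        np.savez(os.path.join(path, "parameters.npz"), **self._state_arrays())
        manifest = {
            "config": asdict(self.config),
            "covariate_names": self.covariate_names,
            "covariate_kinds": self.covariate_kinds,
            "format_version": 1,
        }
        with open(os.path.join(path, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "CounterfactualModel":
        with open(os.path.join(path, "manifest.json")) as fh:
            manifest = json.load(fh)
        config = ModelConfig(**manifest["config"])
        model = cls(config, manifest["covariate_names"], manifest["covariate_kinds"])
        with np.load(os.path.join(path, "parameters.npz")) as data:
            for i, p in enumerate(model.params):
                p.value[...] = data[f"param_{i}"]
            bn = [l for l in model.encoder.layers if isinstance(l, BatchNorm)]
            for i, layer in enumerate(bn):
                layer.running_mean[...] = data[f"bn_{i}_mean"]
                layer.running_var[...] = data[f"bn_{i}_var"]
            model.std_mean = data["std_mean"]
            model.std_scale = data["std_scale"]
        return model
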