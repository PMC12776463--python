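"""Run configuration: YAML round trip for every component's settings.

A run config is a single YAML document with optional sections ``simulate``,
``eligibility``, ``model``, ``train``, ``ipm``, ``tree`` and ``objective``
plus a global ``seed`` and ``output_dir``.  Unknown keys are rejected at any
level, so typos fail loudly instead of silently using defaults.

Each pipeline stage derives its own seed from the global seed and the stage
name, so inserting a stage never shifts the randomness of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields, asdict

import yaml

from .cohort import EligibilityParams
from .ipm import IPMConfig
from .model import ModelConfig
from .synthetic import CohortSpec, OutcomeModel, TimeModel, easy_spec, standard_spec
from .training import CompositeObjective, TrainConfig
from .uplift import TreeConfig

__all__ = ["RunConfig", "load_config", "derive_seed", "cohort_spec_from_dict",
           "cohort_spec_to_dict"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: CRC-32 of "stage:seed", kept below 2^31."""
    return zlib.crc32(f"{stage}:{global_seed}".encode()) % (2**31)


def _from_dict(cls, data: dict | None, name: str):
    data = data or {}
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {name!r} section: {sorted(unknown)}")
    return cls(**data)


def cohort_spec_from_dict(data: dict) -> CohortSpec:
    allowed = {"n", "seed", "preset", "confounding_scale", "covariates",
               "propensity", "incidence_model", "time_model"}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in 'simulate' section: {sorted(unknown)}")
    preset = data.get("preset")
    if preset is not None:
        maker = {"standard": standard_spec, "easy": easy_spec}.get(preset)
        if maker is None:
            raise ValueError(f"unknown simulate preset {preset!r}")
        kwargs = {k: data[k] for k in ("n", "seed", "confounding_scale") if k in data}
        if preset == "easy":
            kwargs.pop("confounding_scale", None)
        return maker(**kwargs)
    cov = data.get("covariates", {})
    return CohortSpec(
        n=data["n"],
        seed=data.get("seed", 0),
        binary_covariates=[tuple(c) for c in cov.get("binary", [])],
        continuous_covariates=[tuple(c) for c in cov.get("continuous", [])],
        propensity=dict(data.get("propensity", {})),
        incidence_model=_from_dict(OutcomeModel, data.get("incidence_model"),
                                   "incidence_model"),
        time_model=_from_dict(TimeModel, data.get("time_model"), "time_model"),
    )


def cohort_spec_to_dict(spec: CohortSpec) -> dict:
    return {
        "n": spec.n, "seed": spec.seed,
        "covariates": {
            "binary": [list(c) for c in spec.binary_covariates],
            "continuous": [list(c) for c in spec.continuous_covariates],
        },
        "propensity": dict(spec.propensity),
        "incidence_model": asdict(spec.incidence_model),
        "time_model": asdict(spec.time_model),
    }


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "runs/out"
    simulate: CohortSpec | None = None
    eligibility: EligibilityParams = field(default_factory=EligibilityParams)
    model: dict = field(default_factory=dict)  # ModelConfig kwargs minus input_dim
    train: TrainConfig = field(default_factory=TrainConfig)
    ipm: IPMConfig = field(default_factory=IPMConfig)
    tree: TreeConfig = field(default_factory=TreeConfig)
    objective: CompositeObjective = field(default_factory=CompositeObjective)
    drug: str | None = None

    def model_config(self, input_dim: int) -> ModelConfig:
        return _from_dict(ModelConfig, {"input_dim": input_dim, **self.model}, "model")

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)


_SECTIONS = {"seed", "output_dir", "simulate", "eligibility", "model", "train",
             "ipm", "tree", "objective", "drug"}


def load_config(path_or_dict: str | dict) -> RunConfig:
    if isinstance(path_or_dict, dict):
        data = path_or_dict
    else:
        with open(path_or_dict) as fh:
            data = yaml.safe_load(fh) or {}
    unknown = set(data) - _SECTIONS
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    model = data.get("model", {})
    if "input_dim" in model:
        raise ValueError("model.input_dim is derived from the cohort, not configured")
    tr = dict(data.get("train", {}))
    if "lambda_grid" in tr:
        tr["lambda_grid"] = tuple(tuple(p) for p in tr["lambda_grid"])
    if "alpha_grid" in tr:
        tr["alpha_grid"] = tuple(tr["alpha_grid"])
    return RunConfig(
        seed=data.get("seed", 0),
        output_dir=data.get("output_dir", "runs/out"),
        simulate=(cohort_spec_from_dict(data["simulate"])
                  if data.get("simulate") else None),
        eligibility=_from_dict(EligibilityParams, data.get("eligibility"), "eligibility"),
        model=dict(model),
        train=_from_dict(TrainConfig, tr, "train"),
        ipm=_from_dict(IPMConfig, data.get("ipm"), "ipm"),
        tree=_from_dict(TreeConfig, data.get("tree"), "tree"),
        objective=_from_dict(CompositeObjective, data.get("objective"), "objective"),
        drug=data.get("drug"),
    )
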