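"""YAML configuration for the end-to-end pipeline.

A config declares either a dataset path or a generative spec (never both),
the phenotypes, an optional model-ladder definition, and run options.
Example::

    phenotypes:
      - {name: dheas, scale: continuous}
      - {name: cwp, scale: binary, prevalence: 0.1962}
    generate:
      n_mz: 219
      n_dz: 244
      paths:
        A: [[0.86, 0.0], [0.3, 0.7]]
        E: [[0.51, 0.0], [0.2, 0.6]]
      age: {mean: 58.39, sd: 11.08, slopes: [0.0, 0.0]}
      missing: {twin: 0.05, value: 0.0}
    ladder:
      include_saturated: false
      ip_cp_sets: [1]
      reduced:
        cholesky_AE_reduced: ["A[2,2]"]
    options: {seed: 1, n_starts: 2, bootstrap: 200}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .fiml import FitOptions
from .models import PhenotypeSpec
from .simulate import GenerativeSpec

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    phenotypes: tuple[PhenotypeSpec, ...]
    dataset_path: Path | None = None
    generate: GenerativeSpec | None = None
    ladder: dict = field(default_factory=dict)
    seed: int = 0
    n_boot: int = 1000
    shared_target: str | None = None
    fit_options: FitOptions = field(default_factory=FitOptions)
    include_age: bool = True

    def __post_init__(self):
        if (self.dataset_path is None) == (self.generate is None):
            raise ValueError(
                "config must provide exactly one of dataset path / generative spec"
            )


def _parse_phenotypes(items) -> tuple[PhenotypeSpec, ...]:
    out = []
    for it in items:
        out.append(
            PhenotypeSpec(
                name=it["name"],
                scale=it.get("scale", "continuous"),
                prevalence=it.get("prevalence"),
            )
        )
    return tuple(out)


def _parse_generate(section, phenotypes) -> GenerativeSpec:
    paths = {c: np.asarray(m, dtype=float) for c, m in section["paths"].items()}
    age = section.get("age", {})
    missing = section.get("missing", {})
    return GenerativeSpec(
        n_mz=int(section["n_mz"]),
        n_dz=int(section["n_dz"]),
        phenotypes=phenotypes,
        paths=paths,
        trait_means=section.get("trait_means"),
        trait_sds=section.get("trait_sds"),
        age_mean=float(age.get("mean", 58.39)),
        age_sd=float(age.get("sd", 11.08)),
        age_slopes=age.get("slopes"),
        missing_twin_prob=float(missing.get("twin", 0.0)),
        missing_value_prob=float(missing.get("value", 0.0)),
        seed=int(section.get("seed", 0)),
    )


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    phenotypes = _parse_phenotypes(raw["phenotypes"])
    opts_raw = raw.get("options", {})
    fit_opts = FitOptions(
        n_starts=int(opts_raw.get("n_starts", 5)),
        seed=int(opts_raw.get("seed", 0)),
        qmc_points=int(opts_raw.get("qmc_points", 2048)),
        maxiter=int(opts_raw.get("maxiter", 2000)),
    )
    generate = None
    if "generate" in raw:
        generate = _parse_generate(raw["generate"], phenotypes)
        generate.seed = int(opts_raw.get("seed", generate.seed))
    return PipelineConfig(
        phenotypes=phenotypes,
        dataset_path=Path(raw["dataset"]) if "dataset" in raw else None,
        generate=generate,
        ladder=raw.get("ladder", {}),
        seed=int(opts_raw.get("seed", 0)),
        n_boot=int(opts_raw.get("bootstrap", 1000)),
        shared_target=raw.get("shared_target"),
        fit_options=fit_opts,
        include_age=bool(raw.get("include_age", True)),
    )
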