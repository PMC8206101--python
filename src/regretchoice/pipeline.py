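"""Orchestration: run the simulate -> fit -> ANOVA -> report chain.

`run_full` executes the whole two-stage analysis on a simulated or ingested
dataset and returns a :class:`RunReport` whose payload is JSON-ready and
reproducible byte-for-byte from the embedded configuration and seed.
Dataset I/O (:func:`read_dataset`, :func:`write_dataset`) is re-exported
from :mod:`regretchoice.dataset`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .choice_model import ModelSpec, fit_condition, extract_subject_coefficients
from .dataset import CONDITIONS, Dataset, read_dataset, write_dataset
from .rating_model import fit_rating_condition, extract_rating_coefficients
from .simulate import SimulationConfig, simulate_dataset
from .stage2 import AnovaResult, anova_by_coefficient, coefficient_table
from .task import points_to_gbp

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig", "RunReport", "run_full", "bonus_draw",
    "read_dataset", "write_dataset",
]

MODES = ("simulate", "fit", "full", "power", "type1")


@dataclass(frozen=True)
class PipelineConfig:
    """What to run and on what data.

    ``mode='full'`` simulates (or ingests, if ``input_path`` is set) and
    runs both stage-1 families and all stage-2 ANOVAs.  The seed governs
    every random draw and is echoed into each output artefact.
    """

    seed: int
    mode: str = "full"
    simulation: SimulationConfig | None = None
    input_path: str | None = None
    dialect: str = "native"
    column_map: Mapping[str, str] | None = None
    model_spec: ModelSpec = field(default_factory=ModelSpec)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulation", None)
        seed = raw.pop("seed")
        if sim is not None:
            sim = SimulationConfig(seed=sim.pop("seed", seed), **sim)
        spec = raw.pop("model_spec", None)
        kwargs = dict(raw)
        if spec is not None:
            kwargs["model_spec"] = ModelSpec(
                fixed=tuple(spec.get("fixed", ModelSpec().fixed)),
                random=tuple(spec.get("random", ModelSpec().random)),
            )
        return cls(seed=seed, simulation=sim, **kwargs)


@dataclass
class RunReport:
    """All stage outputs plus provenance; ``payload()`` is JSON-ready."""

    choice_models: dict
    rating_models: dict
    choice_coefficients: "object"        # long DataFrame
    rating_coefficients: "object"
    anovas: dict[str, AnovaResult]
    provenance: dict

    def payload(self) -> dict:
        return {
            "provenance": self.provenance,
            "choice_models": self.choice_models,
            "rating_models": self.rating_models,
            "anova": {name: res.to_dict() for name, res in self.anovas.items()},
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.payload(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def run_full(config: PipelineConfig) -> RunReport:
    """Simulate or ingest, fit both stage-1 families per cell, run stage 2.

    Produces four choice fits, four rating fits, and five ANOVA tables
    (dEV, dSD, AR from choices; b_reg, b_dis from ratings).  Stage errors
    propagate with the stage name attached; completed stage outputs are kept
    on the report object.
    """
    if config.input_path is not None:
        dataset = read_dataset(config.input_path, config.dialect, config.column_map)
    else:
        sim = config.simulation or SimulationConfig(seed=config.seed)
        dataset = simulate_dataset(sim)

    choice_models, rating_models = {}, {}
    for cond in CONDITIONS:
        key = "/".join(cond)
        try:
            choice_models[key] = fit_condition(dataset, cond, config.model_spec)
        except Exception as exc:
            raise RuntimeError(f"stage 1 (choice, {key}) failed: {exc}") from exc
        try:
            rating_models[key] = fit_rating_condition(dataset, cond)
        except Exception as exc:
            raise RuntimeError(f"stage 1 (rating, {key}) failed: {exc}") from exc

    choice_coefs = coefficient_table(dataset, config.model_spec)
    rating_rows = []
    for cond in CONDITIONS:
        coefs = extract_rating_coefficients(rating_models["/".join(cond)])
        for name in ("b_reg", "b_dis"):
            rating_rows.append(
                coefs[[name]].rename(columns={name: "value"}).reset_index().assign(
                    beneficiary=cond[0], audience=cond[1], coefficient=name)
            )
    rating_coefs = pd.concat(rating_rows, ignore_index=True)

    anovas = {}
    try:
        anovas.update(anova_by_coefficient(choice_coefs))
        anovas.update(anova_by_coefficient(rating_coefs))
    except Exception as exc:
        raise RuntimeError(f"stage 2 (ANOVA) failed: {exc}") from exc

    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "dataset": _jsonable(dataset.provenance),
        "model_spec": {"fixed": list(config.model_spec.fixed),
                       "random": list(config.model_spec.random)},
    }
    return RunReport(
        choice_models={k: m.report() for k, m in choice_models.items()},
        rating_models={k: m.report() for k, m in rating_models.items()},
        choice_coefficients=choice_coefs,
        rating_coefficients=rating_coefs,
        anovas=anovas,
        provenance=provenance,
    )


def bonus_draw(dataset: Dataset, subject_id, rng: np.random.Generator) -> float:
    """The performance bonus: two random trials, one per audience condition.

    Picks one of the subject's trials with the partner present and one with
    the partner absent, converts each obtained outcome to GBP and returns
    the sum (0 to 5 GBP under the anchor conversions).
    """
    sub = dataset.df[dataset.df["subject_id"] == subject_id]
    total = 0.0
    for audience in ("present", "absent"):
        trials = sub[sub["audience"] == audience]
        if len(trials) == 0:
            raise ValueError(f"subject {subject_id} has no audience-{audience} trials")
        row = trials.iloc[int(rng.integers(0, len(trials)))]
        total += points_to_gbp(float(row["obtained"]))
    return total


def _jsonable(obj):
    """Drop non-serialisable entries (e.g. the truth DataFrame) from provenance."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items() if not hasattr(v, "to_csv")}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
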