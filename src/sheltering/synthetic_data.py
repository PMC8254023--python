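"""Experiment-shaped synthetic datasets with known ground truth.

The generator emulates the structure of the binary-choice experiment: three
conditions (15 all-naive trials of 10 individuals, 19 all-conditioned trials,
35 mixed trials of 4 naive + 6 conditioned), occupancies recorded every
10 minutes for 3 hours plus a 24-hour snapshot, and dynamics produced by the
package's own joining/leaving hazards with the retained parameter estimates.
Every dataset comes with a ground-truth manifest (true parameters, per-trial
seeds, final states) so downstream calibration checks never have to infer
the generating process.

Null variants switch off the social retention (``sigma = 0``) or the odour
preference (``mu_ps = 0.5``) for type-I-error calibration of the resampling
tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import CONDITIONED_PARAMS, NAIVE_PARAMS, GroupComposition, ModelParams
from .simulator import EXPERIMENT_GRID_MIN, simulate_trials

__all__ = [
    "ConditionSpec",
    "ExperimentDesign",
    "default_design",
    "generate_experiment",
    "generate_null_dataset",
    "write_experiment",
]


@dataclass(frozen=True)
class ConditionSpec:
    label: str
    n_naive: int
    n_conditioned: int
    n_trials: int


@dataclass(frozen=True)
class ExperimentDesign:
    """Trial layout, recording grid, parameters and master seed of a dataset."""

    conditions: tuple[ConditionSpec, ...]
    times_min: tuple[int, ...]
    params_by_type: Mapping[str, ModelParams]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("design needs at least one condition")
        if not self.times_min:
            raise ValueError("design needs a recording grid")
        if list(self.times_min) != sorted(set(self.times_min)):
            raise ValueError("recording grid must be strictly increasing")


def default_design(
    seed: int = 0,
    params_by_type: Mapping[str, ModelParams] | None = None,
    times_min: Sequence[int] = EXPERIMENT_GRID_MIN,
) -> ExperimentDesign:
    """The experiment's own layout: naive 10/0 x 15, conditioned 0/10 x 19,
    mixed 4/6 x 35 trials, recorded at 0-180 min every 10 min plus 24 h."""
    if params_by_type is None:
        params_by_type = {"naive": NAIVE_PARAMS, "conditioned": CONDITIONED_PARAMS}
    return ExperimentDesign(
        conditions=(
            ConditionSpec("naive", 10, 0, 15),
            ConditionSpec("conditioned", 0, 10, 19),
            ConditionSpec("mixed", 4, 6, 35),
        ),
        times_min=tuple(int(t) for t in times_min),
        params_by_type=dict(params_by_type),
        seed=int(seed),
    )


def generate_experiment(
    design: ExperimentDesign,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Simulate the full design; returns per-condition trial tables + manifest.

    Each condition draws its trials from a child stream of the design's
    master seed, so regeneration with the same design is byte-identical.
    """
    duration = design.times_min[-1] * 60
    children = np.random.SeedSequence(design.seed).spawn(len(design.conditions))
    tables: dict[str, pd.DataFrame] = {}
    manifest: dict = {
        "seed": design.seed,
        "times_min": list(design.times_min),
        "params_by_type": {k: p.to_dict() for k, p in design.params_by_type.items()},
        "conditions": [],
    }
    for spec, child in zip(design.conditions, children):
        comp = GroupComposition(spec.n_naive, spec.n_conditioned, design.params_by_type)
        cond_seed = int(child.generate_state(1, dtype=np.uint32)[0])
        trials = simulate_trials(
            comp,
            spec.n_trials,
            duration,
            seed=cond_seed,
            record_times_min=design.times_min,
            condition=spec.label,
            trial_prefix=spec.label,
        )
        tables[spec.label] = pd.concat(
            [t.to_frame() for t in trials], ignore_index=True
        )
        manifest["conditions"].append(
            {
                "label": spec.label,
                "n_naive": spec.n_naive,
                "n_conditioned": spec.n_conditioned,
                "n_trials": spec.n_trials,
                "seed": cond_seed,
                "trial_seeds": [t.seed for t in trials],
                "final_states": [
                    [int(t.pooled()[-1, 0]), int(t.pooled()[-1, 1])] for t in trials
                ],
            }
        )
    return tables, manifest


def generate_null_dataset(
    design: ExperimentDesign,
    social: bool = False,
    symmetric: bool = False,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Generate a dataset under a null constraint applied to every type.

    ``social=False`` removes the social retention (``sigma = 0``: nonsocial,
    binomial shelter choice at stationarity); ``symmetric=True`` removes the
    odour preference (``mu_ps = 0.5``).  Both may be combined.
    """
    params = {}
    for label, p in design.params_by_type.items():
        kwargs = p.to_dict()
        if not social:
            kwargs["sigma"] = 0.0
        if symmetric:
            kwargs["mu_ps"] = 0.5
        params[label] = ModelParams(**kwargs)
    null_design = dataclasses.replace(design, params_by_type=params)
    tables, manifest = generate_experiment(null_design)
    manifest["null"] = {"social": social, "symmetric": symmetric}
    return tables, manifest


def write_experiment(
    tables: Mapping[str, pd.DataFrame], manifest: dict, out_dir: str | Path
) -> None:
    """Write one CSV per condition plus the ground-truth ``manifest.json``."""
    from .io import write_trials

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for label, table in tables.items():
        write_trials(table, out / f"{label}.csv")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
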