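"""Behavioural rates of the two-shelter aggregation model.

Individuals explore a binary-choice arena containing an odorous shelter
(PS, peanut-butter scented) and an odorless control shelter (CS).  Per
one-second time step, an individual outside the shelters joins the PS with
probability ``J_ps = theta * mu_ps`` and the CS with ``J_cs = theta * mu_cs``,
where ``theta`` is the global per-second probability of finding a shelter
while exploring and ``mu_ps + mu_cs = 1`` splits it by shelter quality.  A
sheltered individual leaves with probability ``Q = rho * exp(-sigma*(X-1))``
where ``X`` is the shelter's current occupancy: conspecifics retain each
other, and ``sigma`` (the social strength) sets how fast the leaving
probability collapses as the aggregate grows.

Two behavioural types are distinguished: *naive* individuals keep their
spontaneous attraction to the odour (``mu_ps > 0.5``) and explore quickly,
while aversively *conditioned* individuals have lost the preference and
explore more slowly.  ``rho`` and ``sigma`` are shared across types and
shelters (the minimal assumption retained by the model), but each type
carries its own copy so the assumption is relaxable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = [
    "PS",
    "CS",
    "ModelParams",
    "GroupComposition",
    "ShelterState",
    "NAIVE_PARAMS",
    "CONDITIONED_PARAMS",
    "joining_probability",
    "leaving_probability",
    "load_params",
    "dump_params",
]

PS = "PS"
CS = "CS"


class ParameterError(ValueError):
    """Raised when behavioural parameters violate their constraints."""


@dataclass(frozen=True)
class ModelParams:
    """Per-type behavioural rates.

    Parameters
    ----------
    theta : float
        Per-second probability of an outside individual finding a shelter
        (s^-1).  Interpreted as a Bernoulli probability per 1-s step, hence
        restricted to [0, 1].
    mu_ps : float
        Relative response to the odorous shelter, in [0, 1].  ``mu_cs`` is
        always stored as ``1 - mu_ps``.
    rho : float
        Per-second leaving probability of a solitary sheltered individual
        (s^-1), in [0, 1].
    sigma : float
        Social-strength coefficient (per sheltered conspecific), >= 0.
    """

    theta: float
    mu_ps: float
    rho: float
    sigma: float
    mu_cs: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= 1.0):
            raise ParameterError(f"theta must lie in [0, 1], got {self.theta!r}")
        if not (0.0 <= self.mu_ps <= 1.0):
            raise ParameterError(f"mu_ps must lie in [0, 1], got {self.mu_ps!r}")
        if not (0.0 <= self.rho <= 1.0):
            raise ParameterError(f"rho must lie in [0, 1], got {self.rho!r}")
        if not (self.sigma >= 0.0):
            raise ParameterError(f"sigma must be >= 0, got {self.sigma!r}")
        object.__setattr__(self, "mu_cs", 1.0 - self.mu_ps)

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "mu_ps": self.mu_ps,
            "rho": self.rho,
            "sigma": self.sigma,
        }


#: Retained parameter estimates for untrained individuals.
NAIVE_PARAMS = ModelParams(theta=1e-3, mu_ps=0.63, rho=0.002, sigma=1.19)

#: Retained parameter estimates for aversively conditioned individuals.
CONDITIONED_PARAMS = ModelParams(theta=3.703e-4, mu_ps=0.445, rho=0.002, sigma=1.19)


@dataclass(frozen=True)
class GroupComposition:
    """Counts of each behavioural type plus their parameter sets.

    ``params_by_type`` must provide exactly one :class:`ModelParams` for each
    of the labels ``"naive"`` and ``"conditioned"`` that has a nonzero count.
    """

    n_naive: int
    n_conditioned: int
    params_by_type: Mapping[str, ModelParams]

    def __post_init__(self) -> None:
        if self.n_naive < 0 or self.n_conditioned < 0:
            raise ParameterError("type counts must be non-negative")
        if self.total < 1:
            raise ParameterError("group must contain at least one individual")
        for label, n in (("naive", self.n_naive), ("conditioned", self.n_conditioned)):
            if n > 0 and label not in self.params_by_type:
                raise ParameterError(f"missing ModelParams for type {label!r}")
        for label, p in self.params_by_type.items():
            if not isinstance(p, ModelParams):
                raise ParameterError(f"params for {label!r} is not a ModelParams")

    @property
    def total(self) -> int:
        return self.n_naive + self.n_conditioned

    def counts(self) -> dict[str, int]:
        return {"naive": self.n_naive, "conditioned": self.n_conditioned}


@dataclass
class ShelterState:
    """Pooled occupancy of the two shelters at one instant."""

    x_ps: int
    x_cs: int
    n_out: int

    def __post_init__(self) -> None:
        if min(self.x_ps, self.x_cs, self.n_out) < 0:
            raise ParameterError("occupancies must be non-negative")

    @property
    def total(self) -> int:
        return self.x_ps + self.x_cs + self.n_out


def joining_probability(params: ModelParams, shelter: str) -> float:
    """Per-second probability that an outside individual joins *shelter*.

    ``J_ps = theta * mu_ps`` and ``J_cs = theta * mu_cs``; the two sum to
    ``theta`` exactly.
    """
    if shelter == PS:
        return params.theta * params.mu_ps
    if shelter == CS:
        return params.theta * params.mu_cs
    raise ValueError(f"shelter must be {PS!r} or {CS!r}, got {shelter!r}")


def leaving_probability(params: ModelParams, occupancy: int) -> float:
    """Per-second probability that a sheltered individual leaves.

    ``Q = rho * exp(-sigma * (X - 1))`` with ``X`` the shelter's occupancy
    (including the focal individual, so ``X >= 1``).  Social retention makes
    this strictly decreasing in ``X`` when ``sigma > 0``.
    """
    if occupancy < 1:
        raise ValueError(f"occupancy must be >= 1 (focal individual inside), got {occupancy}")
    return params.rho * math.exp(-params.sigma * (occupancy - 1))


# --- parameter file round-trip -------------------------------------------------

def load_params(path: str | Path) -> dict[str, ModelParams]:
    """Read a ``{type: {theta, mu_ps, rho, sigma}}`` mapping from JSON or YAML."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yml", ".yaml"}:
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise ParameterError(f"{path}: expected a mapping of type -> parameters")
    out: dict[str, ModelParams] = {}
    for label, entry in raw.items():
        try:
            out[label] = ModelParams(
                theta=float(entry["theta"]),
                mu_ps=float(entry["mu_ps"]),
                rho=float(entry["rho"]),
                sigma=float(entry["sigma"]),
            )
        except (KeyError, TypeError) as exc:
            raise ParameterError(f"{path}: invalid entry for type {label!r}: {exc}") from exc
    return out


def dump_params(params_by_type: Mapping[str, ModelParams], path: str | Path) -> None:
    """Write a parameter mapping as JSON (the canonical on-disk form)."""
    payload = {label: p.to_dict() for label, p in params_by_type.items()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
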