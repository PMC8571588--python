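"""Prior specifications for ABC parameter draws.

Uniform and log-uniform marginals with finite ordered bounds, plus
structural constraints (e.g. ordered divergence times) enforced by
rejection against a template's ``feasible`` predicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Uniform:
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.low) and np.isfinite(self.high) and self.low < self.high):
            raise ValueError("bounds must be finite and ordered")

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.low, self.high))


@dataclass(frozen=True)
class LogUniform:
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high and np.isfinite(self.high)):
            raise ValueError("log-uniform bounds must be positive, finite, ordered")

    def sample(self, rng: np.random.Generator) -> float:
        return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))


@dataclass
class PriorSpec:
    """Named independent marginals; structural constraints live with the
    scenario template's ``feasible`` predicate."""

    marginals: dict[str, Uniform | LogUniform]

    @property
    def names(self) -> list[str]:
        return list(self.marginals)

    def sample(self, rng: np.random.Generator, feasible=None, max_tries: int = 10000) -> dict:
        """Draw one parameter set, rejecting draws a predicate refuses."""
        for _ in range(max_tries):
            params = {k: d.sample(rng) for k, d in self.marginals.items()}
            if feasible is None or feasible(params):
                return params
        raise RuntimeError("could not draw feasible parameters; constraints too tight")

    def to_dict(self) -> dict:
        return {
            k: {
                "distribution": type(d).__name__.lower(),
                "low": d.low,
                "high": d.high,
            }
            for k, d in self.marginals.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        marg = {}
        for k, spec in d.items():
            kind = spec["distribution"]
            if kind == "uniform":
                marg[k] = Uniform(spec["low"], spec["high"])
            elif kind == "loguniform":
                marg[k] = LogUniform(spec["low"], spec["high"])
            else:
                raise ValueError(f"unknown distribution {kind!r}")
        return cls(marg)
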