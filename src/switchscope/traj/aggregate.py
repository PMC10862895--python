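"""Replica aggregation: mean and standard error of the mean across replicas."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ..errors import AggregationError

__all__ = ["ReplicaAggregate", "aggregate_replicas", "format_mean_sem"]

_SCALAR_KEY = "value"


@dataclass(frozen=True)
class ReplicaAggregate:
    """Per-key mean and s.e.m. (sample SD / sqrt(n)) over replicas."""

    means: dict
    sems: dict
    n_replicas: int

    @property
    def mean(self) -> float:
        if len(self.means) != 1:
            raise AggregationError("aggregate has multiple keys; access by key")
        return next(iter(self.means.values()))

    @property
    def sem(self) -> float:
        if len(self.sems) != 1:
            raise AggregationError("aggregate has multiple keys; access by key")
        return next(iter(self.sems.values()))

    def to_dict(self) -> dict:
        return {
            "n_replicas": self.n_replicas,
            "stats": {str(k): {"mean": self.means[k], "sem": self.sems[k]}
                      for k in self.means},
        }


def aggregate_replicas(values: Sequence) -> ReplicaAggregate:
    """Aggregate per-replica scalars or per-replica key->value mappings.

    Requires >= 2 replicas (the s.e.m. is undefined otherwise) and, for
    mapping input, identical key sets across replicas.
    """
    if len(values) < 2:
        raise AggregationError("need >= 2 replicas to compute an s.e.m.")
    if isinstance(values[0], Mapping):
        keys = set(values[0])
        for i, v in enumerate(values):
            if not isinstance(v, Mapping) or set(v) != keys:
                missing = sorted(keys.symmetric_difference(set(v)))
                raise AggregationError(
                    f"replica {i} key mismatch; differing keys: {missing}")
        per_key = {k: np.array([v[k] for v in values], dtype=float) for k in keys}
    else:
        per_key = {_SCALAR_KEY: np.asarray(values, dtype=float)}

    n = len(values)
    means = {k: float(np.mean(a)) for k, a in per_key.items()}
    sems = {k: float(np.std(a, ddof=1) / math.sqrt(n)) for k, a in per_key.items()}
    return ReplicaAggregate(means, sems, n)


def format_mean_sem(mean: float, sem: float, as_percent: bool = True,
                    decimals: int = 1) -> str:
    """Render ``mean +/- sem`` in the conventional ``97.4±1.4%`` style.

    With ``as_percent`` the inputs are fractions and scaled by 100.
    """
    scale = 100.0 if as_percent else 1.0
    suffix = "%" if as_percent else ""
    return f"{mean * scale:.{decimals}f}±{sem * scale:.{decimals}f}{suffix}"
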