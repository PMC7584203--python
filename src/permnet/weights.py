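"""Trajectory weights for de-biasing the non-uniform assembly sampling.

A single assembly run reaches its final matrix through a sequence of donor
transfers; at each step the move is drawn uniformly from the ``n_e`` feasible
(row, recipient) choices.  The product of the ``n_e`` along the run is the
trajectory weight ``w(t)``; conditional on the initial permutation, the run's
probability is ``1 / w(t)``.  Averaging a metric ``Q`` over samples with
weights ``w`` therefore recovers (up to the trajectory-count degeneracy of
each final matrix) the unbiased ensemble mean:

    <Q> = sum_j w_j Q_j / sum_j w_j.

Weights grow multiplicatively and overflow floats quickly, so the log of the
weight is always maintained; the exact big-integer product is additionally
kept for small instances.  Inert shuffles are not covered by the weight
formula (they are probability-preserving randomisations, not donor
transfers), so any run touched by shuffling is flagged ``shuffle_tainted``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "TrajectoryWeight",
    "EnsembleSample",
    "accumulate_step_weight",
    "weighted_mean",
]


@dataclass
class TrajectoryWeight:
    """Multiplicative weight of one assembly trajectory.

    ``log_weight`` is always maintained; ``exact_weight`` (a Python int, so
    arbitrary precision) only while ``track_exact`` is set - typically for
    small instances where the product stays enumerable.
    """

    log_weight: float = 0.0
    exact_weight: Optional[int] = 1
    shuffle_tainted: bool = False
    track_exact: bool = field(default=True, repr=False)

    def __post_init__(self):
        if not self.track_exact:
            self.exact_weight = None

    def accumulate(self, n_available: int) -> "TrajectoryWeight":
        """Record one transfer step that had ``n_available`` feasible moves."""
        if n_available < 1:
            raise ValidationError("n_available must be >= 1 (the chosen move existed)")
        self.log_weight += math.log(n_available)
        if self.exact_weight is not None:
            self.exact_weight *= int(n_available)
        return self

    @property
    def n_steps_consistent(self) -> bool:
        """Big-integer and log bookkeeping agree (when both are kept)."""
        if self.exact_weight is None:
            return True
        return math.isclose(
            self.log_weight,
            math.log(self.exact_weight),
            rel_tol=1e-12,
            abs_tol=1e-12,
        )


def accumulate_step_weight(acc: TrajectoryWeight, n_available: int) -> TrajectoryWeight:
    """Functional alias for :meth:`TrajectoryWeight.accumulate`."""
    return acc.accumulate(n_available)


@dataclass
class EnsembleSample:
    """One final matrix with its trajectory weight and attached metric values."""

    matrix: np.ndarray
    weight: TrajectoryWeight
    metrics: dict = field(default_factory=dict)


def weighted_mean(
    samples: Sequence[EnsembleSample],
    metric: Callable[[np.ndarray], float] | str,
    warn_tainted: bool = True,
) -> float:
    """Importance-weighted ensemble mean ``sum w_j Q_j / sum w_j``.

    ``metric`` is either a callable evaluated on each sample's matrix or the
    key of a value already attached in ``sample.metrics``.  The sum is
    computed in log space (log-sum-exp shift by the maximum log weight), so
    it is stable even when exact weights would overflow a float.
    """
    samples = list(samples)
    if not samples:
        raise ValidationError("weighted_mean requires at least one sample")
    if warn_tainted and any(s.weight.shuffle_tainted for s in samples):
        warnings.warn(
            "some trajectories involved inert shuffles; their weights cover "
            "only the donor-transfer steps and the estimate may be biased",
            stacklevel=2,
        )
    if callable(metric):
        q = np.array([float(metric(s.matrix)) for s in samples])
    else:
        q = np.array([float(s.metrics[metric]) for s in samples])
    logw = np.array([s.weight.log_weight for s in samples])
    w = np.exp(logw - logw.max())
    return float(np.sum(w * q) / np.sum(w))
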