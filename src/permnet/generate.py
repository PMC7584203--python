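"""Synthetic bi-degree sequence generation.

Draws correlated (k_in, k_out) pairs via a Gaussian copula so the rank
correlation between a node's in- and out-degree is controllable, then
repairs the (generically unequal) totals by unit adjustments within bounds -
the repaired sequence always passes the degree-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .errors import ValidationError
from .sequences import BiDegreeSequence

__all__ = ["DegreeSequenceSpec", "generate_degree_sequences"]


@dataclass(frozen=True)
class DegreeSequenceSpec:
    """Recipe for a synthetic bi-degree sequence.

    Attributes
    ----------
    n_nodes
        Number of nodes N.
    distribution
        Marginal of both degree sequences: ``"uniform"`` or ``"power_law"``
        (discrete, ``P(k) ~ k^-exponent``) on ``[k_min, k_max]``.
    k_min, k_max
        Inclusive degree bounds; for binary assemblies keep ``k_max <= N``.
    exponent
        Power-law exponent (ignored for the uniform marginal).
    rho
        Target Spearman rank correlation between a node's in- and
        out-degree, in [-1, 1].
    seed
        Seed used when no generator is supplied.
    """

    n_nodes: int
    distribution: str = "uniform"
    k_min: int = 1
    k_max: int = 10
    exponent: float = 2.5
    rho: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValidationError("n_nodes must be >= 1")
        if self.distribution not in ("uniform", "power_law"):
            raise ValidationError(f"unknown distribution: {self.distribution!r}")
        if not (0 <= self.k_min <= self.k_max):
            raise ValidationError("need 0 <= k_min <= k_max")
        if not (-1 <= self.rho <= 1):
            raise ValidationError("rho must be in [-1, 1]")
        if self.distribution == "power_law" and self.k_min < 1:
            raise ValidationError("power_law marginal requires k_min >= 1")


def _marginal_quantile(u: np.ndarray, spec: DegreeSequenceSpec) -> np.ndarray:
    support = np.arange(spec.k_min, spec.k_max + 1)
    if spec.distribution == "uniform":
        idx = np.minimum((u * support.size).astype(np.int64), support.size - 1)
        return support[idx]
    pmf = support.astype(np.float64) ** (-spec.exponent)
    cdf = np.cumsum(pmf / pmf.sum())
    return support[np.searchsorted(cdf, u, side="left")]


def _repair_sums(
    k_in: np.ndarray, k_out: np.ndarray, spec: DegreeSequenceSpec, rng
) -> None:
    """Unit increments/decrements on k_out at random nodes until sums match."""
    diff = int(k_in.sum() - k_out.sum())
    guard = 0
    while diff != 0:
        if diff > 0:
            candidates = np.nonzero(k_out < spec.k_max)[0]
            step = 1
        else:
            candidates = np.nonzero(k_out > spec.k_min)[0]
            step = -1
        if candidates.size == 0:
            raise ValidationError(
                "cannot repair degree totals within [k_min, k_max]"
            )
        take = min(abs(diff), candidates.size)
        chosen = rng.choice(candidates, size=take, replace=False)
        k_out[chosen] += step
        diff -= step * take
        guard += 1
        if guard > 10_000:  # pragma: no cover - defensive
            raise ValidationError("degree-sum repair did not terminate")


def generate_degree_sequences(
    spec: DegreeSequenceSpec, rng: Optional[np.random.Generator] = None
) -> BiDegreeSequence:
    """Draw a bi-degree sequence according to ``spec``.

    The Gaussian copula uses the Pearson correlation ``2 sin(pi rho / 6)``
    that induces Spearman rank correlation ``rho`` on the latent normals;
    discretisation to the marginal support weakens it slightly for narrow
    degree ranges.  The result always satisfies ``sum k_in == sum k_out``.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    r = 2 * np.sin(np.pi * spec.rho / 6)
    z = rng.multivariate_normal(
        [0.0, 0.0], [[1.0, r], [r, 1.0]], size=spec.n_nodes
    )
    u = stats.norm.cdf(z)
    k_in = _marginal_quantile(u[:, 0], spec).astype(np.int64)
    k_out = _marginal_quantile(u[:, 1], spec).astype(np.int64)
    _repair_sums(k_in, k_out, spec, rng)
    return BiDegreeSequence(k_in, k_out)
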