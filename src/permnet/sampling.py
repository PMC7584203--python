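"""Exhaustive small-instance oracles and trajectory sampling helpers.

For instances small enough to enumerate (a handful of nodes), this module
provides ground truth against which the stochastic assembler is checked:

* :func:`enumerate_realisations` - every matrix realising the bi-degree
  sequence under the mode's constraints, by brute force;
* :func:`exact_assembly_distribution` - the exact probability with which the
  assembly pipeline produces each final matrix, obtained by expanding every
  equally-likely initial row permutation and every donor-transfer branch with
  exact rational arithmetic;
* :func:`sample_trajectories` - repeated full assembly runs collected as
  weighted ensemble samples for the importance-weighted estimator.

The trajectory expansion mirrors :func:`permnet.assembly.donor_sweep`
exactly: donors in ascending column order, one transfer per donor per sweep,
uniform choice among the feasible (row, recipient) moves, no inert shuffling.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from .assembly import (
    AssemblyConfig,
    ResidualState,
    assemble,
    feasible_moves,
)
from .errors import ValidationError
from .sequences import BiDegreeSequence
from .weights import EnsembleSample, TrajectoryWeight, weighted_mean  # noqa: F401

__all__ = [
    "enumerate_realisations",
    "enumerate_initial_permutations",
    "exact_assembly_distribution",
    "distribution_from_start",
    "sample_trajectories",
    "ExactDistribution",
    "matrix_key",
]

MatrixKey = Tuple[Tuple[int, ...], ...]


def matrix_key(a: np.ndarray) -> MatrixKey:
    """Hashable canonical identity of an integer matrix."""
    return tuple(tuple(int(x) for x in row) for row in np.asarray(a))


def _row_candidates(k: int, n: int, binary: bool, forbid_diag: Optional[int]):
    """All admissible arrangements of ``k`` edge units over ``n`` cells."""
    if binary:
        for cols in itertools.combinations(range(n), k):
            if forbid_diag is not None and forbid_diag in cols:
                continue
            row = [0] * n
            for c in cols:
                row[c] = 1
            yield tuple(row)
    else:
        # weak compositions of k into n parts
        for cuts in itertools.combinations(range(k + n - 1), n - 1):
            row = []
            prev = -1
            for c in cuts:
                row.append(c - prev - 1)
                prev = c
            row.append(k + n - 2 - prev)
            if forbid_diag is not None and row[forbid_diag] > 0:
                continue
            yield tuple(row)


def enumerate_realisations(
    seq: BiDegreeSequence,
    config: Optional[AssemblyConfig] = None,
    max_nodes: int = 4,
) -> List[np.ndarray]:
    """Brute-force list of all matrices with row sums k_in and column sums k_out.

    Matrices are returned in lexicographic order of their flattened rows so
    the ordering is stable across runs.  Refuses instances above
    ``max_nodes`` (the search is exponential in N^2).
    """
    config = config or AssemblyConfig()
    n = seq.n_nodes
    if n > max_nodes:
        raise ValidationError(
            f"exhaustive enumeration capped at N={max_nodes} (got N={n})"
        )
    if not seq.assemblable:
        return []
    binary = not config.multi_mode
    out: List[np.ndarray] = []

    def recurse(i: int, colsum: Tuple[int, ...], rows: Tuple[Tuple[int, ...], ...]):
        if i == n:
            if all(c == t for c, t in zip(colsum, seq.k_out)):
                out.append(np.array(rows, dtype=np.int64))
            return
        forbid = None if config.allow_self_loops else i
        for row in _row_candidates(int(seq.k_in[i]), n, binary, forbid):
            new = tuple(c + r for c, r in zip(colsum, row))
            if any(c > t for c, t in zip(new, seq.k_out)):
                continue
            recurse(i + 1, new, rows + (row,))

    recurse(0, (0,) * n, ())
    out.sort(key=lambda m: tuple(m.ravel()))
    return out


def enumerate_initial_permutations(
    seq: BiDegreeSequence, config: Optional[AssemblyConfig] = None
) -> List[np.ndarray]:
    """Every equally-likely row-permuted precursor (binary mode).

    Each row of the precursor carries ``k_in_i`` ones; a uniform permutation
    of the row's cells makes every arrangement of every row equally probable,
    so the joint space is the product of per-row combinations - e.g.
    3 * 3 * 3 = 27 starts for ``k_in = [1, 2, 1]``.
    """
    config = config or AssemblyConfig()
    if config.multi_mode:
        raise ValidationError("initial-permutation enumeration is binary-mode only")
    n = seq.n_nodes
    per_row = [list(_row_candidates(int(k), n, True, None)) for k in seq.k_in]
    return [np.array(rows, dtype=np.int64) for rows in itertools.product(*per_row)]


@dataclass
class ExactDistribution:
    """Exact production probabilities of the assembly pipeline."""

    probabilities: Dict[MatrixKey, Fraction]
    failed: Fraction
    #: per initial permutation: final-matrix -> conditional probability
    incidence: List[Dict[MatrixKey, Fraction]] = field(default_factory=list)
    starts: List[np.ndarray] = field(default_factory=list)

    @property
    def total(self) -> Fraction:
        return sum(self.probabilities.values(), start=Fraction(0)) + self.failed

    def as_floats(self) -> Dict[MatrixKey, float]:
        return {k: float(v) for k, v in self.probabilities.items()}


def distribution_from_start(
    a1: np.ndarray,
    seq: BiDegreeSequence,
    config: Optional[AssemblyConfig] = None,
) -> Tuple[Dict[MatrixKey, Fraction], Fraction]:
    """Exact conditional distribution of final matrices from one start.

    Expands every donor-transfer trajectory out of ``a1`` with branch
    probability ``1/n_e`` at each step.  Mass on trajectories that dead-end
    (a full sweep with donors left but no feasible transfer) is returned
    separately as ``failed``.
    """
    config = config or AssemblyConfig()
    if config.multi_mode:
        raise ValidationError("the trajectory oracle is binary-mode only")
    target = seq.k_out
    mass: Dict[MatrixKey, Fraction] = {}
    failed = Fraction(0)

    def sweep(a, residual, donors, transferred, prob):
        nonlocal failed
        if not donors:
            if all(v == 0 for v in residual):
                key = matrix_key(a)
                mass[key] = mass.get(key, Fraction(0)) + prob
            elif not transferred:
                failed += prob
            else:
                start_sweep(a, residual, prob)
            return
        d, rest = donors[0], donors[1:]
        state = ResidualState(np.array(residual))
        rows, recips = feasible_moves(np.array(a), d, state, config)
        if rows.size == 0:
            sweep(a, residual, rest, transferred, prob)
            return
        branch = prob / int(rows.size)
        for r, c in zip(rows, recips):
            b = [list(row) for row in a]
            b[r][d] -= 1
            b[r][c] += 1
            res = list(residual)
            res[d] -= 1
            res[c] += 1
            sweep(
                tuple(tuple(row) for row in b),
                tuple(res),
                rest,
                True,
                branch,
            )

    def start_sweep(a, residual, prob):
        donors = [i for i, v in enumerate(residual) if v > 0]
        sweep(a, residual, donors, False, prob)

    a1 = np.asarray(a1)
    residual = tuple(int(v) for v in (a1.sum(axis=0) - target))
    if all(v == 0 for v in residual):
        return {matrix_key(a1): Fraction(1)}, Fraction(0)
    start_sweep(matrix_key(a1), residual, Fraction(1))
    return mass, failed


def exact_assembly_distribution(
    seq: BiDegreeSequence,
    config: Optional[AssemblyConfig] = None,
    max_nodes: int = 4,
) -> ExactDistribution:
    """Exact distribution over final matrices for the full pipeline.

    Averages :func:`distribution_from_start` over every equally-likely
    initial permutation with exact rational arithmetic; the returned masses
    (plus any failed mass) sum to exactly 1.
    """
    config = config or AssemblyConfig()
    if seq.n_nodes > max_nodes:
        raise ValidationError(
            f"exhaustive trajectory expansion capped at N={max_nodes}"
        )
    starts = enumerate_initial_permutations(seq, config)
    p_start = Fraction(1, len(starts))
    probs: Dict[MatrixKey, Fraction] = {}
    failed = Fraction(0)
    incidence: List[Dict[MatrixKey, Fraction]] = []
    for a1 in starts:
        mass, f = distribution_from_start(a1, seq, config)
        incidence.append(mass)
        failed += p_start * f
        for k, v in mass.items():
            probs[k] = probs.get(k, Fraction(0)) + p_start * v
    return ExactDistribution(
        probabilities=probs, failed=failed, incidence=incidence, starts=starts
    )


def sample_trajectories(
    seq: BiDegreeSequence,
    config: Optional[AssemblyConfig] = None,
    n_samples: int = 1000,
    rng: Optional[np.random.Generator] = None,
    metric: Optional[Callable[[np.ndarray], float]] = None,
    metric_name: str = "Q",
) -> List[EnsembleSample]:
    """Collect ``n_samples`` converged assembly runs as weighted samples.

    A single RNG drives all runs so the ensemble is reproducible from one
    seed.  If ``metric`` is given it is evaluated once per distinct final
    matrix (cached by matrix identity) and attached to each sample.
    """
    config = config or AssemblyConfig()
    rng = rng if rng is not None else config.rng()
    cache: Dict[MatrixKey, float] = {}
    samples: List[EnsembleSample] = []
    for _ in range(n_samples):
        result = assemble(seq, config, rng)
        metrics = {}
        if metric is not None:
            key = matrix_key(result.matrix)
            if key not in cache:
                cache[key] = float(metric(result.matrix))
            metrics[metric_name] = cache[key]
        samples.append(
            EnsembleSample(matrix=result.matrix, weight=result.weight, metrics=metrics)
        )
    return samples
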