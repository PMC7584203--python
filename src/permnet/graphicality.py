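"""Graphicality pre-tests for bi-degree sequences.

A bi-degree sequence ``(k_in, k_out)`` is *graphic* when a binary adjacency
matrix exists whose row sums are ``k_in`` and column sums ``k_out``
(self-loops permitted: the diagonal is unconstrained).  The classical
Gale-Ryser/Fulkerson criterion settles this with ``N - 1`` inequalities after
sorting ``k_in`` non-increasing:

    sum_i min(k_out_i, j)  >=  sum_{i<=j} k_in_i      for j = 1 .. N-1,

together with equal degree totals.  The test is run once, before assembly;
it does not guarantee the stochastic assembly will succeed, only that a
realisation exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ValidationError
from .sequences import BiDegreeSequence

__all__ = [
    "check_degree_sums",
    "gale_ryser_graphic",
    "assert_assemblable",
    "GaleRyserResult",
    "AssemblyDiagnosis",
]


def check_degree_sums(seq: BiDegreeSequence) -> bool:
    """True iff ``sum(k_in) == sum(k_out)``.

    This is necessary in every mode: each directed edge is counted once in
    each total. Pure; does not mutate ``seq``.
    """
    if not isinstance(seq, BiDegreeSequence):
        seq = BiDegreeSequence(*seq)
    return seq.assemblable


@dataclass(frozen=True)
class GaleRyserResult:
    """Outcome of the binary-realisability test."""

    graphic: bool
    #: smallest violated inequality index j (1-based), or None
    first_violated: Optional[int]
    reason: str

    def __bool__(self) -> bool:
        return self.graphic


def gale_ryser_graphic(seq: BiDegreeSequence) -> GaleRyserResult:
    """Gale-Ryser test for existence of a binary realisation (loops allowed).

    ``k_in`` is sorted non-increasing on a copy (the input order is never
    touched); ``k_out`` enters only through ``sum min(k_out_i, j)``, which is
    order-free.  Degrees exceeding ``N`` are rejected up front: with 0/1
    entries no row or column sum can exceed the node count.

    Returns
    -------
    GaleRyserResult
        ``graphic`` flag plus, on inequality failure, the smallest violating
        ``j`` (1-based).  A degree-exceeds-N rejection reports
        ``first_violated=None`` so it is distinguishable from an inequality
        failure.
    """
    if not check_degree_sums(seq):
        return GaleRyserResult(
            False, None,
            f"degree sums differ: sum(k_in)={int(seq.k_in.sum())} != "
            f"sum(k_out)={int(seq.k_out.sum())}",
        )
    n = seq.n_nodes
    if n == 0:
        return GaleRyserResult(True, None, "empty sequence")
    if seq.k_in.max(initial=0) > n or seq.k_out.max(initial=0) > n:
        return GaleRyserResult(
            False, None,
            "degree exceeds N: not realisable with binary entries",
        )
    kin_sorted = np.sort(seq.k_in)[::-1]
    lhs_prev = np.cumsum(kin_sorted)  # right side: sum_{i<=j} k_in_i
    kout = seq.k_out
    for j in range(1, n):
        lhs = int(np.minimum(kout, j).sum())
        if lhs < lhs_prev[j - 1]:
            return GaleRyserResult(
                False, j,
                f"Gale-Ryser inequality violated at j={j}: "
                f"{lhs} < {int(lhs_prev[j - 1])}",
            )
    return GaleRyserResult(True, None, "graphic")


@dataclass(frozen=True)
class AssemblyDiagnosis:
    """Pass/fail gate evaluated once before assembly starts."""

    ok: bool
    reason: str
    mode: str  # "binary" | "multi"

    def __bool__(self) -> bool:
        return self.ok


def assert_assemblable(seq: BiDegreeSequence, config=None) -> AssemblyDiagnosis:
    """Mode-aware feasibility gate, run once before assembly.

    Binary mode (``multi_target_proportion == 0``) requires the full
    Gale-Ryser criterion.  Multi-edge mode only requires equal degree totals:
    any row of ``k_in_i`` units fits in at most ``N`` columns with unlimited
    multiplicity, so no stronger condition applies.

    Passing this gate does not guarantee the stochastic assembly converges;
    rare dead-ends surface at runtime as :class:`~permnet.errors.AssemblyFailure`.
    """
    from .assembly import AssemblyConfig  # local import: no cycle at module load

    if config is None:
        config = AssemblyConfig()
    multi = config.multi_target_proportion > 0
    mode = "multi" if multi else "binary"
    if not check_degree_sums(seq):
        return AssemblyDiagnosis(
            False,
            f"degree sums differ: sum(k_in)={int(seq.k_in.sum())} != "
            f"sum(k_out)={int(seq.k_out.sum())}",
            mode,
        )
    if multi:
        return AssemblyDiagnosis(True, "degree sums equal (multi-edge mode)", mode)
    gr = gale_ryser_graphic(seq)
    if not gr.graphic:
        return AssemblyDiagnosis(False, gr.reason, mode)
    if not config.allow_self_loops:
        forced = seq.n_nodes and (
            seq.k_in.max(initial=0) >= seq.n_nodes
            or seq.k_out.max(initial=0) >= seq.n_nodes
        )
        if forced:
            return AssemblyDiagnosis(
                False,
                "a degree equals N: every binary realisation needs a "
                "self-loop, which the configuration forbids",
                mode,
            )
        # No closed-form pre-test is applied for the loop-free case beyond
        # the forced-diagonal check; assembly may still fail at runtime with
        # a diagnostic trace.
    return AssemblyDiagnosis(True, gr.reason, mode)


def require_assemblable(seq: BiDegreeSequence, config=None) -> AssemblyDiagnosis:
    """Like :func:`assert_assemblable` but raises on failure."""
    diag = assert_assemblable(seq, config)
    if not diag.ok:
        raise ValidationError(diag.reason)
    return diag
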