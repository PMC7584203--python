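"""The permutation method: assemble a digraph matching an exact bi-degree sequence.

Pipeline
--------
1. *Precursor*: pack each node's ``k_in_i`` edge units into the leftmost cells
   of its row (multiplicities > 1 allocated first when a multi-edge proportion
   is targeted).  Row sums equal ``k_in`` from this point on and are never
   altered again.
2. *Permute*: shuffle each row's cells independently and uniformly.  Column
   sums (realised out-degrees) are now random and generally wrong.
3. *Donor loops*: classify columns by the sign of their out-degree residual
   (donor ``> 0`` / recipient ``< 0`` / inert ``== 0``) and repeatedly move
   surplus edge units within a row from a donor column to a recipient column.
   Each performed transfer reduces ``sum |residual|`` by exactly 2.  When a
   sweep performs too few transfers relative to the number of donors visited,
   degree-preserving checkerboard swaps through inert columns ("inert
   shuffling") randomise the matrix to unlock further transfers - a simulated
   annealing move that leaves every row and column sum untouched.

Convergence means the L2 norm of the out-degree residual fell below
``epsilon`` (default 0.5: residuals are integers, so this is exact matching).

Donor columns are visited in ascending index order every sweep.  The order is
deliberately deterministic: the trajectory-weight machinery and the exhaustive
small-instance oracle in :mod:`permnet.sampling` enumerate exactly the
branching generated by uniform *move* choice under this fixed visiting order,
so sampled frequencies converge to the oracle's exact distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

import numpy as np

from .errors import ValidationError, AssemblyFailure
from .graphicality import assert_assemblable
from .sequences import BiDegreeSequence
from .weights import TrajectoryWeight

__all__ = [
    "AssemblyConfig",
    "ResidualState",
    "AssemblyTrace",
    "AssemblyResult",
    "build_precursor",
    "permute_rows",
    "out_degree_residual",
    "feasible_moves",
    "transfer_edge",
    "donor_sweep",
    "inert_shuffle",
    "assemble",
]


@dataclass
class AssemblyConfig:
    """Tunable knobs of the assembly procedure.

    Attributes
    ----------
    allow_self_loops
        Permit non-zero diagonal entries (edges from a node to itself).
    multi_target_proportion
        Fraction in ``[0, 1)`` of edge units that should be multi-edges
        (units beyond the first on an ordered node pair).  0 means a binary
        matrix.
    inert_activation_ratio
        Inert shuffling triggers after a sweep whose ratio of performed
        transfers to donors visited falls *below* this threshold.
        0 disables shuffling entirely; 1 shuffles after every imperfect sweep.
    epsilon
        Convergence tolerance on the residual L2 norm.  Any value below 1
        means exact integer matching while tolerating float round-off.
    max_donor_loops
        Hard cap on donor sweeps before giving up.
    shuffles_per_activation
        Checkerboard swaps attempted per activation; ``"auto"`` performs one
        per inert column, capped at 1000.
    stall_sweeps
        Consecutive sweeps with zero transfers and zero successful shuffles
        before the run is declared stalled.
    no_transfer_limit
        Hard safety limit: consecutive transfer-free sweeps (even with
        shuffles still succeeding) before the run is declared stalled.
    seed
        Seed for the single RNG governing all randomness of a run.
    debug_checks
        Re-verify row-sum conservation after every sweep (slow; for tests).
    """

    allow_self_loops: bool = True
    multi_target_proportion: float = 0.0
    inert_activation_ratio: float = 0.5
    epsilon: float = 0.5
    max_donor_loops: int = 100_000
    shuffles_per_activation: Union[int, str] = "auto"
    stall_sweeps: int = 50
    no_transfer_limit: int = 1000
    seed: Optional[int] = None
    debug_checks: bool = False

    def __post_init__(self):
        if not (0 <= self.multi_target_proportion < 1):
            raise ValidationError("multi_target_proportion must be in [0, 1)")
        if not (0 <= self.inert_activation_ratio <= 1):
            raise ValidationError("inert_activation_ratio must be in [0, 1]")
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be positive")
        if self.max_donor_loops < 1:
            raise ValidationError("max_donor_loops must be >= 1")
        if self.shuffles_per_activation != "auto" and (
            not isinstance(self.shuffles_per_activation, (int, np.integer))
            or self.shuffles_per_activation < 1
        ):
            raise ValidationError("shuffles_per_activation must be 'auto' or >= 1")

    @property
    def multi_mode(self) -> bool:
        return self.multi_target_proportion > 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


class ResidualState:
    """Out-degree residual bookkeeping: realised minus target column sums."""

    def __init__(self, residual: np.ndarray):
        self.residual = np.asarray(residual, dtype=np.int64)

    @property
    def r_out(self) -> float:
        """L2 norm of the residual vector - the convergence metric."""
        return float(np.linalg.norm(self.residual))

    @property
    def sum_abs(self) -> int:
        return int(np.abs(self.residual).sum())

    @property
    def donors(self) -> np.ndarray:
        """Columns with surplus outbound edges (residual > 0), ascending."""
        return np.nonzero(self.residual > 0)[0]

    @property
    def recipients(self) -> np.ndarray:
        return np.nonzero(self.residual < 0)[0]

    @property
    def inerts(self) -> np.ndarray:
        return np.nonzero(self.residual == 0)[0]

    def apply_transfer(self, donor: int, recipient: int) -> None:
        self.residual[donor] -= 1
        self.residual[recipient] += 1


@dataclass
class AssemblyTrace:
    """Per-sweep diagnostics of one assembly run."""

    r_out: List[float] = field(default_factory=list)
    transfers_done: List[int] = field(default_factory=list)
    transfers_possible: List[int] = field(default_factory=list)
    shuffles: List[int] = field(default_factory=list)
    failed_loops: int = 0  # cumulative sweeps with zero transfers
    status: str = "running"  # converged | stalled | loop-limit
    multi_target_count: int = 0
    multi_achieved_count: int = 0

    def record(self, r_out: float, done: int, possible: int, shuffles: int) -> None:
        self.r_out.append(r_out)
        self.transfers_done.append(done)
        self.transfers_possible.append(possible)
        self.shuffles.append(shuffles)
        if done == 0:
            self.failed_loops += 1

    @property
    def n_sweeps(self) -> int:
        return len(self.r_out)

    @property
    def multi_shortfall(self) -> int:
        """Multi-edge units the precursor could not place without breaking k_in."""
        return self.multi_target_count - self.multi_achieved_count

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "loop": np.arange(1, self.n_sweeps + 1),
                "r_out": self.r_out,
                "transfers": self.transfers_done,
                "possible": self.transfers_possible,
                "shuffles": self.shuffles,
            }
        )


@dataclass
class AssemblyResult:
    """A converged assembly: final matrix, its trajectory weight, diagnostics."""

    matrix: np.ndarray
    weight: TrajectoryWeight
    trace: AssemblyTrace

    @property
    def multi_edge_proportion(self) -> float:
        from .metrics import multi_edge_proportion

        return multi_edge_proportion(self.matrix)


# ---------------------------------------------------------------------------
# precursor construction


def _slot_allocate(caps: np.ndarray, amount: int, rng) -> np.ndarray:
    """Distribute ``amount`` units over rows, uniformly over capacity slots."""
    amount = min(amount, int(caps.sum()))
    if amount == 0:
        return np.zeros_like(caps)
    slots = np.repeat(np.arange(caps.size), caps)
    chosen = rng.choice(slots.size, size=amount, replace=False)
    return np.bincount(slots[chosen], minlength=caps.size)


def _multiplicity_counts(
    k_in: np.ndarray, m_target: int, max_occupied: int, rng: np.random.Generator
) -> np.ndarray:
    """Number of multi-edge units to fold into each row.

    Row ``i`` can absorb at most ``k_in_i - 1`` units (all its edge units on
    a single cell) and must absorb at least ``k_in_i - max_occupied`` (only
    ``max_occupied`` cells are available, e.g. N - 1 without self-loops).
    Beyond those floors, conversions are drawn uniformly without replacement
    from per-row capacity slots - but rows are concentrated down to a single
    occupied cell only as a last resort: a row whose whole in-degree sits in
    one cell can never donate or shuffle under the like-type rule, so such
    rows are created only when the target is otherwise unreachable.
    """
    occupied_floor = np.where(k_in > 0, 1, 0)
    floors = np.maximum(k_in - max_occupied, 0)
    m = floors.astype(np.int64).copy()
    remaining = m_target - int(m.sum())
    if remaining <= 0:
        return m  # target missed from above; the degrees are inviolate
    # soft capacity keeps >= 2 occupied cells in every row that has >= 2 units
    soft_caps = np.maximum(np.minimum(k_in - 2, k_in - occupied_floor) - floors, 0)
    soft = _slot_allocate(soft_caps, remaining, rng)
    m += soft
    remaining -= int(soft.sum())
    if remaining > 0:
        hard_caps = np.maximum(k_in - 1, 0) - m
        m += _slot_allocate(hard_caps, remaining, rng)
    return m


def build_precursor(
    seq: BiDegreeSequence,
    config: Optional[AssemblyConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Left-packed matrix satisfying ``k_in`` exactly (column sums arbitrary).

    Binary mode: row ``i`` holds ``k_in_i`` ones in its leftmost cells.
    Multi mode: solo units are converted into multiplicity increments on
    randomly chosen occupied cells until the target multi-edge count
    ``round(p * sum k_in)`` is met or no row can absorb more; the row sums
    are inviolate, so an infeasible target is missed by the smallest possible
    shortfall rather than met.
    """
    config = config or AssemblyConfig()
    n = seq.n_nodes
    k_in = seq.k_in

    def row_positions(i: int, count: int) -> np.ndarray:
        if config.allow_self_loops:
            return np.arange(count)
        cols = np.arange(count + 1)
        return cols[cols != i][:count]

    if not config.multi_mode:
        if config.allow_self_loops:
            return (np.arange(n)[None, :] < k_in[:, None]).astype(np.int64)
        a = np.zeros((n, n), dtype=np.int64)
        for i in range(n):
            a[i, row_positions(i, int(k_in[i]))] = 1
        return a
    rng = rng if rng is not None else config.rng()
    m_target = int(round(config.multi_target_proportion * seq.n_edges))
    max_occupied = n if config.allow_self_loops else n - 1
    m_per_row = _multiplicity_counts(k_in, m_target, max_occupied, rng)
    a = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        occupied = int(k_in[i] - m_per_row[i])
        if occupied == 0:
            continue
        # distribute the extra units uniformly over the occupied cells
        extra = rng.multinomial(int(m_per_row[i]), np.full(occupied, 1.0 / occupied))
        a[i, row_positions(i, occupied)] = 1 + extra
    return a


def permute_rows(
    a: np.ndarray, rng: np.random.Generator, skip_diagonal: bool = False
) -> np.ndarray:
    """Independently and uniformly permute the cells of every row.

    Implemented as an argsort of iid uniforms per row (a vectorised
    Fisher-Yates equivalent); returns a new array, row sums unchanged.  With
    ``skip_diagonal`` the diagonal cell of each row is pinned (used in
    no-self-loop mode, where it must stay empty) and the remaining N - 1
    cells are permuted uniformly.
    """
    if not skip_diagonal:
        keys = rng.random(a.shape)
        order = np.argsort(keys, axis=1)
        return np.take_along_axis(a, order, axis=1)
    out = a.copy()
    n = a.shape[1]
    idx = np.arange(n)
    for i in range(a.shape[0]):
        off = idx[idx != i]
        out[i, off] = a[i, off][rng.permutation(n - 1)]
    return out


def out_degree_residual(a: np.ndarray, seq: BiDegreeSequence) -> ResidualState:
    """Realised column sums minus target ``k_out``."""
    return ResidualState(a.sum(axis=0) - seq.k_out)


# ---------------------------------------------------------------------------
# edge transfers


def _move_ok(a, row, donor, recipient, config) -> bool:
    if a[row, donor] < 1:
        return False
    if not config.allow_self_loops and row == recipient:
        return False
    if not config.multi_mode:
        return a[row, recipient] == 0
    # like-type rule: solo units land on empty cells, surplus units of a
    # multi cell land on occupied cells - either way m(A) is unchanged
    if a[row, donor] == 1:
        return a[row, recipient] == 0
    return a[row, recipient] >= 1


def feasible_moves(
    a: np.ndarray,
    donor: int,
    state: ResidualState,
    config: AssemblyConfig,
) -> Tuple[np.ndarray, np.ndarray]:
    """All (row, recipient) moves that shift one unit out of ``donor``.

    A move relocates one edge unit within ``row`` from column ``donor`` to a
    recipient column, so the row sum (in-degree) is conserved by
    construction.  Feasibility additionally requires the binary cap or the
    like-type multi rule, and respects the self-loop policy.
    """
    rows = np.nonzero(a[:, donor])[0]
    recips = state.recipients
    if rows.size == 0 or recips.size == 0:
        return rows[:0], recips[:0]
    sub = a[np.ix_(rows, recips)]
    if not config.multi_mode:
        feas = sub == 0
    else:
        solo = (a[rows, donor] == 1)[:, None]
        feas = np.where(solo, sub == 0, sub >= 1)
    if not config.allow_self_loops:
        feas &= rows[:, None] != recips[None, :]
    rr, cc = np.nonzero(feas)
    return rows[rr], recips[cc]


def transfer_edge(
    a: np.ndarray,
    donor: int,
    recipient: int,
    row: int,
    config: AssemblyConfig,
    state: Optional[ResidualState] = None,
) -> bool:
    """Move one edge unit within ``row`` from ``donor`` to ``recipient``.

    Returns False (matrix untouched) when the move is infeasible.  A
    performed transfer decreases the donor residual and increases the
    recipient residual by one each, so ``sum |residual|`` drops by exactly 2.
    """
    if state is not None and not (
        state.residual[donor] > 0 and state.residual[recipient] < 0
    ):
        return False
    if not _move_ok(a, row, donor, recipient, config):
        return False
    a[row, donor] -= 1
    a[row, recipient] += 1
    if state is not None:
        state.apply_transfer(donor, recipient)
    return True


def donor_sweep(
    a: np.ndarray,
    state: ResidualState,
    config: AssemblyConfig,
    rng: np.random.Generator,
    weight: Optional[TrajectoryWeight] = None,
) -> Tuple[int, int]:
    """One loop over all donor columns, at most one transfer each.

    Donors are visited in ascending index order (see module docstring).  For
    each donor the full feasible (row, recipient) set is enumerated; its size
    ``n_e`` is recorded into the trajectory weight and one move is drawn
    uniformly.  Donors with no feasible move are skipped.

    Returns
    -------
    (transfers_done, donors_visited)
        Numerator and denominator of the inert-shuffle activation ratio.
    """
    donors = state.donors
    done = 0
    for d in donors:
        if state.residual[d] <= 0:  # saturated earlier in this sweep? (cannot
            continue  # happen for donors, kept for safety)
        rows, recips = feasible_moves(a, int(d), state, config)
        n_e = rows.size
        if n_e == 0:
            continue
        pick = int(rng.integers(n_e))
        if weight is not None:
            weight.accumulate(n_e)
        a[rows[pick], d] -= 1
        a[rows[pick], recips[pick]] += 1
        state.apply_transfer(int(d), int(recips[pick]))
        done += 1
    return done, int(donors.size)


def inert_shuffle(
    a: np.ndarray,
    state: ResidualState,
    config: AssemblyConfig,
    rng: np.random.Generator,
    max_proposals_per_swap: int = 30,
) -> int:
    """Degree-preserving checkerboard swaps routed through inert columns.

    Picks rows ``r1 != r2`` and columns ``c1`` (inert) and ``c2`` (donor or
    recipient) with occupied cells at ``(r1, c1)`` and ``(r2, c2)``, then
    swaps one unit diagonally: both row sums and both column sums are
    unchanged, so the residual vector is untouched.  The move only
    re-randomises *where* edges sit, which can unlock transfers for stuck
    donors - a simulated-annealing-like kick.

    Returns the number of swaps actually performed (0 when nothing feasible
    was found within the proposal budget).
    """
    inerts = state.inerts
    active = np.nonzero(state.residual != 0)[0]
    if inerts.size == 0 or active.size == 0:
        return 0
    if config.shuffles_per_activation == "auto":
        n_swaps = min(int(inerts.size), 1000)
    else:
        n_swaps = int(config.shuffles_per_activation)
    performed = 0
    for _ in range(n_swaps):
        for _ in range(max_proposals_per_swap):
            c1 = int(inerts[rng.integers(inerts.size)])
            c2 = int(active[rng.integers(active.size)])
            rows1 = np.nonzero(a[:, c1])[0]
            rows2 = np.nonzero(a[:, c2])[0]
            if rows1.size == 0 or rows2.size == 0:
                continue
            r1 = int(rows1[rng.integers(rows1.size)])
            r2 = int(rows2[rng.integers(rows2.size)])
            if r1 == r2:
                continue
            if not config.allow_self_loops and (r1 == c2 or r2 == c1):
                continue
            if not (
                _move_ok(a, r1, c1, c2, config) and _move_ok(a, r2, c2, c1, config)
            ):
                continue
            a[r1, c1] -= 1
            a[r1, c2] += 1
            a[r2, c2] -= 1
            a[r2, c1] += 1
            performed += 1
            break
    return performed


# ---------------------------------------------------------------------------
# full pipeline


def assemble(
    seq: BiDegreeSequence,
    config: Optional[AssemblyConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> AssemblyResult:
    """Run the full permutation-method pipeline on ``seq``.

    Raises
    ------
    ValidationError
        If the pre-assembly graphicality gate fails.
    AssemblyFailure
        If the run stalls or exhausts ``max_donor_loops``; the exception
        carries the :class:`AssemblyTrace` for post-mortem.
    """
    config = config or AssemblyConfig()
    rng = rng if rng is not None else config.rng()
    diag = assert_assemblable(seq, config)
    if not diag.ok:
        raise ValidationError(diag.reason)

    a = build_precursor(seq, config, rng)
    trace = AssemblyTrace()
    if config.multi_mode:
        trace.multi_target_count = int(
            round(config.multi_target_proportion * seq.n_edges)
        )
        trace.multi_achieved_count = int(np.maximum(a - 1, 0).sum())
    a = permute_rows(a, rng, skip_diagonal=not config.allow_self_loops)
    state = out_degree_residual(a, seq)
    weight = TrajectoryWeight(track_exact=seq.n_nodes <= 64)

    stall = 0
    no_transfer = 0
    while state.r_out >= config.epsilon:
        if trace.n_sweeps >= config.max_donor_loops:
            trace.status = "loop-limit"
            raise AssemblyFailure(
                f"no convergence within {config.max_donor_loops} donor loops "
                f"(r_out={state.r_out:.3f})",
                trace=trace,
            )
        done, visited = donor_sweep(a, state, config, rng, weight)
        shuffles = 0
        if (
            state.r_out >= config.epsilon
            and done / max(visited, 1) < config.inert_activation_ratio
        ):
            shuffles = inert_shuffle(a, state, config, rng)
            if shuffles:
                weight.shuffle_tainted = True
        trace.record(state.r_out, done, visited, shuffles)
        if config.debug_checks:
            _assert_invariants(a, seq, config)
        no_transfer = no_transfer + 1 if done == 0 else 0
        stall = stall + 1 if (done == 0 and shuffles == 0) else 0
        if stall >= config.stall_sweeps or no_transfer >= config.no_transfer_limit:
            trace.status = "stalled"
            raise AssemblyFailure(
                f"stalled: {max(stall, no_transfer)} consecutive sweeps "
                f"without transfers (r_out={state.r_out:.3f})",
                trace=trace,
            )

    trace.status = "converged"
    _assert_invariants(a, seq, config)
    return AssemblyResult(matrix=a, weight=weight, trace=trace)


def _assert_invariants(a: np.ndarray, seq: BiDegreeSequence, config: AssemblyConfig):
    if not np.array_equal(a.sum(axis=1), seq.k_in):
        raise AssertionError("internal error: k_in conservation violated")
    if not config.multi_mode and a.max(initial=0) > 1:
        raise AssertionError("internal error: binary cap violated")
    if not config.allow_self_loops and np.any(np.diag(a) != 0):
        raise AssertionError("internal error: self-loop created in no-loop mode")
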