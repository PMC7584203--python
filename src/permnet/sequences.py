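"""Bi-degree sequences: the paired in/out integer degree targets of a digraph.

Convention used throughout the package: the adjacency matrix ``A`` stores in
``A[i, j]`` the number of edges *from node j into node i*, so row sums are
realised in-degrees and column sums realised out-degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


def _as_degree_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValidationError(f"{name} must contain integers")
    arr = arr.astype(np.int64)
    if arr.size and arr.min() < 0:
        raise ValidationError(f"{name} must be non-negative")
    return arr


@dataclass(frozen=True)
class BiDegreeSequence:
    """Paired in/out degree targets for ``N`` nodes.

    Parameters
    ----------
    k_in, k_out
        Equal-length sequences of non-negative integers. ``k_in[i]`` is the
        number of inbound edges node ``i`` must receive, ``k_out[i]`` the
        number of outbound edges it must emit.

    Notes
    -----
    A sequence can only be realised at all (in any mode) when the two sums
    agree: every directed edge contributes one unit to each total.
    """

    k_in: np.ndarray = field()
    k_out: np.ndarray = field()

    def __post_init__(self):
        object.__setattr__(self, "k_in", _as_degree_array(self.k_in, "k_in"))
        object.__setattr__(self, "k_out", _as_degree_array(self.k_out, "k_out"))
        if self.k_in.shape != self.k_out.shape:
            raise ValidationError(
                f"k_in and k_out must have equal length "
                f"(got {self.k_in.size} and {self.k_out.size})"
            )

    @property
    def n_nodes(self) -> int:
        return int(self.k_in.size)

    @property
    def n_edges(self) -> int:
        """Total number of edge units prescribed by ``k_in``."""
        return int(self.k_in.sum())

    @property
    def assemblable(self) -> bool:
        """Necessary condition for realisability: equal degree totals."""
        return bool(self.k_in.sum() == self.k_out.sum())

    def permuted(self, perm) -> "BiDegreeSequence":
        """Relabel nodes by ``perm`` (applied to both sequences)."""
        perm = np.asarray(perm)
        return BiDegreeSequence(self.k_in[perm], self.k_out[perm])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"BiDegreeSequence(N={self.n_nodes}, edges={self.n_edges}, "
            f"assemblable={self.assemblable})"
        )
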