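"""Network summary statistics: ANND, spectral radius, multi-edge proportion,
and the Kuramoto order parameter.

Adjacency convention: ``A[i, j]`` counts edges from node ``j`` into node
``i`` (rows inbound, columns outbound).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .errors import ValidationError

__all__ = [
    "AnndResult",
    "annd",
    "spectral_radius",
    "multi_edge_proportion",
    "kuramoto_order",
]


@dataclass
class AnndResult:
    """Per-node average nearest-neighbour degree plus per-degree-class summary.

    ``values[i]`` is NaN for nodes with zero denominator degree (no
    neighbours in the requested orientation); such nodes are excluded from
    the class summary.  ``by_degree`` maps each occupied integer degree class
    to ``(mean, std, count)`` of the per-node values in that class.
    """

    values: np.ndarray
    degrees: np.ndarray
    variant: str
    weighted: bool
    by_degree: Dict[int, Tuple[float, float, int]]

    @property
    def undefined_nodes(self) -> np.ndarray:
        return np.nonzero(np.isnan(self.values))[0]


def annd(a: np.ndarray, variant: str = "out", weighted: bool = False) -> AnndResult:
    """Average nearest-neighbour degree of every node.

    For the working orientation matrix ``M`` the per-node value is

        annd_i = ( sum_{j != i} sum_{k != j} M_ij M_jk ) / sum_j M_ij ,

    i.e. the degree-weighted mean (loop-corrected) degree of node ``i``'s
    neighbours one step away.  ``variant="out"`` applies the formula to ``A``
    as stored, ``variant="in"`` to its transpose (the two index orientations
    of the directed definition); ``variant="undirected"`` symmetrises the
    support first.  The binary form uses the 0/1 support of ``A``; the
    weighted form uses the multiplicities themselves as weights with the same
    per-node strength normalisation, so the two coincide on binary matrices.

    Class means in ``by_degree`` group nodes by the same orientation's
    degree (the denominator), as integers; for the weighted variant the
    grouping degree is the integer strength.
    """
    a = np.asarray(a)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("annd requires a square matrix")
    if variant not in ("out", "in", "undirected"):
        raise ValidationError(f"unknown ANND variant: {variant!r}")
    if variant == "undirected":
        support = ((a + a.T) > 0).astype(np.int64)
        m = support if not weighted else (a + a.T)
    else:
        m = a if variant == "out" else a.T
        if not weighted:
            m = (m > 0).astype(np.int64)
    m = m.astype(np.float64)
    deg = m.sum(axis=1)
    # sum_{k != j} M_jk = row sum minus the diagonal of the neighbour row
    s = deg - np.diag(m)
    numer = m @ s - np.diag(m) * s  # subtract the j = i term
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(deg > 0, numer / deg, np.nan)

    by_degree: Dict[int, Tuple[float, float, int]] = {}
    ok = deg > 0
    for d in np.unique(deg[ok]):
        sel = ok & (deg == d)
        vals = values[sel]
        by_degree[int(d)] = (float(vals.mean()), float(vals.std()), int(sel.sum()))
    return AnndResult(
        values=values,
        degrees=deg,
        variant=variant,
        weighted=weighted,
        by_degree=by_degree,
    )


def spectral_radius(a: np.ndarray) -> float:
    """Largest eigenvalue modulus of the adjacency matrix."""
    a = np.asarray(a, dtype=np.float64)
    if a.size == 0:
        return 0.0
    return float(np.max(np.abs(np.linalg.eigvals(a))))


def multi_edge_proportion(a: np.ndarray) -> float:
    """Fraction of edge units that are multi-edges: sum max(a_ij - 1, 0) / sum a_ij.

    A multi-edge is any connection between an ordered node pair beyond the
    first. Binary matrices give 0; an empty matrix gives 0 by convention.
    """
    a = np.asarray(a)
    total = int(a.sum())
    if total == 0:
        return 0.0
    return float(np.maximum(a - 1, 0).sum() / total)


def kuramoto_order(phases) -> complex:
    """Complex Kuramoto order parameter ``(1/N) sum_j exp(i theta_j)``.

    Magnitude 1 means full synchrony, 0 an incoherent (balanced) phase
    distribution.
    """
    phases = np.asarray(phases, dtype=np.float64)
    if phases.size == 0:
        raise ValidationError("kuramoto_order requires at least one phase")
    return complex(np.mean(np.exp(1j * phases)))
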