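"""Plain-text readers and writers.

Degree sequences: one integer per line, or two-column TSV ``node_id<TAB>degree``
(lines starting with ``#`` are comments).

Adjacency matrices: Matrix Market coordinate integer general (1-based, via
scipy) or a 3-column edge-list TSV ``source<TAB>target<TAB>count`` with a
``# N=<nodes>`` header comment; node indices in the TSV are 1-based.  With
the package convention ``A[i, j]`` = edges from j into i, an edge line
``(s, t, c)`` stores ``A[t-1, s-1] = c``.  Writing then reading reproduces
the matrix exactly.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Union

import numpy as np
import scipy.io
import scipy.sparse as sp

from .errors import ValidationError
from .sequences import BiDegreeSequence

__all__ = [
    "read_degree_sequence",
    "write_degree_sequence",
    "read_bidegree",
    "read_adjacency",
    "write_adjacency",
]

PathLike = Union[str, Path]


def read_degree_sequence(path: PathLike) -> np.ndarray:
    """Read one degree per line, or (node_id, degree) TSV pairs in node order."""
    path = Path(path)
    values = {}
    plain = []
    two_col = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) not in (1, 2):
            raise ValidationError(
                f"{path}:{lineno}: expected 1 or 2 columns, got {len(parts)}"
            )
        if two_col is None:
            two_col = len(parts) == 2
        elif two_col != (len(parts) == 2):
            raise ValidationError(f"{path}:{lineno}: inconsistent column count")
        try:
            numbers = [int(p) for p in parts]
        except ValueError:
            raise ValidationError(
                f"{path}:{lineno}: non-integer degree entry {line!r}"
            ) from None
        if two_col:
            node, deg = numbers
            if node in values:
                raise ValidationError(f"{path}:{lineno}: duplicate node id {node}")
            values[node] = deg
        else:
            plain.append(numbers[0])
    if two_col:
        order = sorted(values)
        arr = np.array([values[k] for k in order], dtype=np.int64)
    else:
        arr = np.array(plain, dtype=np.int64)
    if arr.size and arr.min() < 0:
        raise ValidationError(f"{path}: negative degree")
    return arr


def write_degree_sequence(path: PathLike, degrees) -> None:
    Path(path).write_text("\n".join(str(int(d)) for d in degrees) + "\n")


def read_bidegree(kin_path: PathLike, kout_path: PathLike) -> BiDegreeSequence:
    return BiDegreeSequence(
        read_degree_sequence(kin_path), read_degree_sequence(kout_path)
    )


def write_adjacency(path: PathLike, a: np.ndarray, fmt: str = "edge_list_tsv") -> None:
    """Write an adjacency matrix; ``fmt`` is ``edge_list_tsv`` or ``matrix_market``."""
    a = np.asarray(a)
    path = Path(path)
    if fmt == "matrix_market":
        coo = sp.coo_matrix(a.astype(np.int64))
        # scipy writes 1-based coordinate integer general for int matrices;
        # hand it an open handle so it cannot append its own .mtx suffix
        with open(path, "wb") as fh:
            scipy.io.mmwrite(fh, coo, field="integer")
        return
    if fmt != "edge_list_tsv":
        raise ValidationError(f"unknown adjacency format: {fmt!r}")
    buf = _io.StringIO()
    buf.write(f"# N={a.shape[0]}\n")
    buf.write("# source\ttarget\tcount (1-based; A[target, source] = count)\n")
    rows, cols = np.nonzero(a)
    for i, j in zip(rows, cols):
        buf.write(f"{j + 1}\t{i + 1}\t{int(a[i, j])}\n")
    path.write_text(buf.getvalue())


def read_adjacency(path: PathLike, fmt: str | None = None) -> np.ndarray:
    """Read an adjacency matrix, auto-detecting the format when not given."""
    path = Path(path)
    if fmt is None:
        head = path.read_text().lstrip()[:14].lower()
        fmt = "matrix_market" if head.startswith("%%matrixmarket") else "edge_list_tsv"
    if fmt == "matrix_market":
        with open(path, "rb") as fh:
            mat = scipy.io.mmread(fh)
        if sp.issparse(mat):
            mat = mat.toarray()
        arr = np.asarray(mat)
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValidationError(f"{path}: non-integer adjacency entries")
        arr = arr.astype(np.int64)
        if arr.size and arr.min() < 0:
            raise ValidationError(f"{path}: negative adjacency entries")
        return arr
    if fmt != "edge_list_tsv":
        raise ValidationError(f"unknown adjacency format: {fmt!r}")
    n = None
    edges = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if stripped.startswith("N="):
                try:
                    n = int(stripped[2:].split()[0])
                except ValueError:
                    raise ValidationError(
                        f"{path}:{lineno}: malformed N header"
                    ) from None
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValidationError(
                f"{path}:{lineno}: expected 3 columns (source, target, count)"
            )
        try:
            s, t, c = (int(p) for p in parts)
        except ValueError:
            raise ValidationError(f"{path}:{lineno}: non-integer entry") from None
        if c < 0:
            raise ValidationError(f"{path}:{lineno}: negative edge count")
        edges.append((lineno, s, t, c))
    if n is None:
        n = max((max(s, t) for _, s, t, _ in edges), default=0)
    a = np.zeros((n, n), dtype=np.int64)
    for lineno, s, t, c in edges:
        if not (1 <= s <= n and 1 <= t <= n):
            raise ValidationError(
                f"{path}:{lineno}: node index out of range 1..{n}"
            )
        a[t - 1, s - 1] = c
    return a
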