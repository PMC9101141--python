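"""Reader/writer for the GAL spatial-weights exchange format.

GAL is the plain-text adjacency format used by GeoDa and the spatial
econometrics toolchain: a header line carrying the number of areal units,
then for each unit a line ``<id> <degree>`` followed by a line listing the
ids of its neighbors.  Only binary symmetric contiguity is representable,
which is exactly what the intrinsic CAR prior consumes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import scipy.sparse as sp

__all__ = ["read_gal", "write_gal"]


def read_gal(path: str | Path) -> tuple[list[str], sp.csr_array]:
    """Read a GAL file.

    Returns
    -------
    ids : list of str
        Unit identifiers in file order.
    adjacency : scipy.sparse.csr_array
        Symmetric binary adjacency aligned with ``ids``.

    Raises
    ------
    ValueError
        If the file is malformed, references unknown ids, or encodes an
        asymmetric neighbor relation.
    """
    tokens_per_line = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                tokens_per_line.append(line.split())
    if not tokens_per_line:
        raise ValueError(f"empty GAL file: {path}")

    header = tokens_per_line[0]
    # GeoDa headers are "0 n shapefile key"; minimal headers are just "n".
    n = int(header[1]) if len(header) >= 2 else int(header[0])

    ids: list[str] = []
    neighbor_ids: dict[str, list[str]] = {}
    i = 1
    while i < len(tokens_per_line):
        unit, degree = tokens_per_line[i][0], int(tokens_per_line[i][1])
        neigh: list[str] = []
        i += 1
        while len(neigh) < degree:
            if i >= len(tokens_per_line):
                raise ValueError(f"GAL file truncated in neighbor list of unit {unit}")
            neigh.extend(tokens_per_line[i])
            i += 1
        if len(neigh) != degree:
            raise ValueError(f"unit {unit}: declared degree {degree}, got {len(neigh)} neighbors")
        ids.append(unit)
        neighbor_ids[unit] = neigh
    if len(ids) != n:
        raise ValueError(f"GAL header declares {n} units, file lists {len(ids)}")

    index = {u: j for j, u in enumerate(ids)}
    rows, cols = [], []
    for u, neigh in neighbor_ids.items():
        for v in neigh:
            if v not in index:
                raise ValueError(f"unit {u} lists unknown neighbor id {v}")
            rows.append(index[u])
            cols.append(index[v])
    adj = sp.csr_array(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)
    )
    if (adj != adj.T).nnz:
        raise ValueError("asymmetric adjacency: some edge (a,b) lacks its reverse (b,a)")
    if adj.diagonal().any():
        raise ValueError("self-neighbor found (nonzero diagonal)")
    return ids, adj


def write_gal(path: str | Path, ids, adjacency: sp.csr_array) -> None:
    """Write a symmetric binary adjacency as a GAL file."""
    adjacency = sp.csr_array(adjacency)
    n = adjacency.shape[0]
    if len(ids) != n:
        raise ValueError("ids length does not match adjacency order")
    with open(path, "w") as fh:
        fh.write(f"{n}\n")
        indptr, indices = adjacency.indptr, adjacency.indices
        for i, unit in enumerate(ids):
            neigh = indices[indptr[i] : indptr[i + 1]]
            fh.write(f"{unit} {len(neigh)}\n")
            fh.write(" ".join(str(ids[j]) for j in neigh) + "\n")
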