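"""Adjacency-structure utilities shared by the generator and the sampler."""

from __future__ import annotations

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = ["validate_adjacency", "is_connected", "laplacian", "color_classes"]


def validate_adjacency(adj: sp.sparray, require_connected: bool = True) -> sp.csr_array:
    """Check symmetry, zero diagonal, binary weights and (optionally) connectivity.

    Returns the adjacency as csr. Raises ValueError on any violation.
    """
    adj = sp.csr_array(adj)
    if adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if (adj != adj.T).nnz:
        raise ValueError("adjacency must be symmetric")
    if adj.diagonal().any():
        raise ValueError("adjacency must have a zero diagonal")
    if adj.nnz and not np.all(adj.data == 1):
        raise ValueError("adjacency must be binary (0/1 contiguity)")
    if require_connected and not is_connected(adj):
        raise ValueError("adjacency graph is disconnected (single component required)")
    return adj


def is_connected(adj: sp.sparray) -> bool:
    ncomp, _ = sp.csgraph.connected_components(sp.csr_matrix(adj), directed=False)
    return ncomp == 1


def laplacian(adj: sp.sparray) -> sp.csr_array:
    """Combinatorial graph Laplacian L = D - A (the intrinsic CAR precision kernel)."""
    adj = sp.csr_array(adj, dtype=float)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    return sp.csr_array(sp.diags(deg) - adj)


def color_classes(adj: sp.sparray) -> list[np.ndarray]:
    """Greedy proper coloring; vertices within a class are mutually non-adjacent.

    Sites in one class have conditionally independent full conditionals under a
    Markov random field, so single-site Metropolis updates can be applied to a
    whole class in one vectorized step.
    """
    g = nx.from_scipy_sparse_array(sp.csr_matrix(adj))
    coloring = nx.greedy_color(g, strategy="largest_first")
    ncolors = max(coloring.values()) + 1
    classes = [[] for _ in range(ncolors)]
    for node, c in coloring.items():
        classes[c].append(node)
    return [np.array(sorted(c), dtype=np.intp) for c in classes]
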