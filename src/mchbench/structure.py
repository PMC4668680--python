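"""Structure (scaled precision) matrices for the intrinsic Gaussian
Markov random field priors of the mortality model.

All three builders return the *structure* matrix: the precision divided by
its scalar precision parameter.  ICAR is the graph Laplacian (rank n-1 on a
connected graph); RW1 is the second-difference tridiagonal matrix (rank
T-1); their space-time interaction is the Kronecker product with null-space
dimension n + T - 1.
"""

from __future__ import annotations

import numpy as np

from .graphs import RegionGraph

__all__ = ["build_icar_precision", "build_rw1_precision", "build_interaction_precision"]


def build_icar_precision(graph: RegionGraph) -> np.ndarray:
    """Intrinsic CAR structure matrix: degree on the diagonal, -1 for
    neighbours.  Rows sum to zero; rank is n-1 (connectivity is enforced
    by RegionGraph)."""
    n = graph.n_regions
    K = np.zeros((n, n))
    for a, b in graph.edges:
        K[a, b] = K[b, a] = -1.0
        K[a, a] += 1.0
        K[b, b] += 1.0
    return K


def build_rw1_precision(T: int) -> np.ndarray:
    """First-order random-walk structure matrix on T time points.

    The quadratic form x'Rx equals the sum of squared successive
    differences of x; rank T-1.
    """
    if T < 2:
        raise ValueError("RW1 needs at least 2 time points")
    R = np.zeros((T, T))
    i = np.arange(T - 1)
    R[i, i] += 1.0
    R[i + 1, i + 1] += 1.0
    R[i, i + 1] -= 1.0
    R[i + 1, i] -= 1.0
    return R


def build_interaction_precision(graph: RegionGraph, T: int) -> np.ndarray:
    """Space-time interaction structure: kron(RW1, ICAR).

    Element ordering: cell (region i, year t) maps to flat index
    ``t * n_regions + i`` (year-major blocks).  Null-space dimension is
    n + T - 1: vectors constant in time for each region, plus vectors
    constant in space for each year, overlapping in the global constant.
    """
    return np.kron(build_rw1_precision(T), build_icar_precision(graph))
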