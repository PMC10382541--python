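"""Boundary-matrix reduction over GF(2), numba-compiled.

The persistence pairing is computed dimension by dimension from the top
down ("twist"/clearing order): the pivot rows found while reducing the
degree-(p+1) boundary matrix are positive p-simplices whose columns in the
degree-p matrix are cleared.  Columns are stored as sorted index arrays in
a growable flat buffer; column addition is symmetric difference.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["reduce_boundary", "h0_merge_events"]


@njit(cache=True)
def _symdiff(a, na, b_buf, s, e, out):
    """Symmetric difference of sorted a[:na] and b_buf[s:e] into out."""
    i, j, k = 0, s, 0
    while i < na and j < e:
        x, y = a[i], b_buf[j]
        if x < y:
            out[k] = x
            i += 1
            k += 1
        elif y < x:
            out[k] = y
            j += 1
            k += 1
        else:
            i += 1
            j += 1
    while i < na:
        out[k] = a[i]
        i += 1
        k += 1
    while j < e:
        out[k] = b_buf[j]
        j += 1
        k += 1
    return k


@njit(cache=True)
def reduce_boundary(facets, n_rows, cleared):
    """Reduce one boundary matrix; columns must be in filtration order.

    facets : (n_cols, w) int64 — row indices of each column's boundary
    cleared : (n_cols,) bool — columns known to reduce to zero (skipped)

    Returns ``pivots`` (n_cols,) int64: the pivot row of each reduced
    column, or -1 where the column reduced to zero (or was cleared).
    """
    n_cols, w = facets.shape
    pivots = np.full(n_cols, -1, np.int64)
    if n_cols == 0:
        return pivots
    claimed = np.full(n_rows, -1, np.int64)     # row -> claiming column
    # flat storage for reduced columns
    cap = 4 * n_cols * w + 64
    buf = np.empty(cap, np.int64)
    col_s = np.zeros(n_cols, np.int64)
    col_e = np.zeros(n_cols, np.int64)
    pos = 0
    work = np.empty(n_rows + 1, np.int64)
    tmp = np.empty(n_rows + 1, np.int64)
    for j in range(n_cols):
        if cleared[j]:
            continue
        nw = w
        for t in range(w):
            work[t] = facets[j, t]
        work[:nw].sort()
        while nw > 0:
            piv = work[nw - 1]
            other = claimed[piv]
            if other < 0:
                claimed[piv] = j
                pivots[j] = piv
                break
            nw = _symdiff(work, nw, buf, col_s[other], col_e[other], tmp)
            work, tmp = tmp, work
        if pos + nw > cap:
            newcap = max(2 * cap, pos + nw)
            newbuf = np.empty(newcap, np.int64)
            newbuf[:pos] = buf[:pos]
            buf = newbuf
            cap = newcap
        for t in range(nw):
            buf[pos + t] = work[t]
        col_s[j] = pos
        col_e[j] = pos + nw
        pos += nw
    return pivots


@njit(cache=True)
def _find(parent, x):
    root = x
    while parent[root] != root:
        root = parent[root]
    while parent[x] != root:            # path compression
        parent[x], x = root, parent[x]
    return root


@njit(cache=True)
def h0_merge_events(edge_vertices, n_vertices):
    """Union-find over edges in filtration order.

    Returns a boolean array ``merges`` (True where the edge joins two
    components, i.e. the edge is negative and kills an H0 class; False
    where it creates a 1-cycle, i.e. is positive).
    """
    n_edges = edge_vertices.shape[0]
    parent = np.arange(n_vertices)
    merges = np.zeros(n_edges, np.bool_)
    for i in range(n_edges):
        a = _find(parent, edge_vertices[i, 0])
        b = _find(parent, edge_vertices[i, 1])
        if a != b:
            parent[a] = b
            merges[i] = True
    return merges
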