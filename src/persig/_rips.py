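"""Vietoris-Rips simplex enumeration up to tetrahedra, numba-compiled.

All filtration values are on the RADIUS scale: a simplex enters at half
its diameter (largest pairwise distance), so Rips and Cech diagrams of the
same cloud are directly comparable.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["enum_edges", "enum_triangles", "enum_tetrahedra", "adjacency"]


@njit(cache=True)
def enum_edges(dm, t_dist):
    """All pairs i<j with distance <= t_dist, in lexicographic order."""
    n = dm.shape[0]
    cnt = 0
    for i in range(n):
        for j in range(i + 1, n):
            if dm[i, j] <= t_dist:
                cnt += 1
    verts = np.empty((cnt, 2), np.int64)
    vals = np.empty(cnt, np.float64)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            if dm[i, j] <= t_dist:
                verts[k, 0] = i
                verts[k, 1] = j
                vals[k] = 0.5 * dm[i, j]
                k += 1
    return verts, vals


@njit(cache=True)
def adjacency(edge_verts, n):
    """CSR adjacency (both directions, neighbor lists sorted ascending)."""
    m = edge_verts.shape[0]
    deg = np.zeros(n + 1, np.int64)
    for e in range(m):
        deg[edge_verts[e, 0] + 1] += 1
        deg[edge_verts[e, 1] + 1] += 1
    indptr = np.cumsum(deg)
    fill = indptr[:-1].copy()
    indices = np.empty(2 * m, np.int64)
    for e in range(m):                    # lex edge order => sorted lists
        i, j = edge_verts[e, 0], edge_verts[e, 1]
        indices[fill[i]] = j
        fill[i] += 1
        indices[fill[j]] = i
        fill[j] += 1
    return indptr, indices


@njit(cache=True)
def _common_after(indptr, indices, a, b, floor, out):
    """Common neighbors of a and b strictly greater than floor."""
    ia, ea = indptr[a], indptr[a + 1]
    ib, eb = indptr[b], indptr[b + 1]
    k = 0
    while ia < ea and ib < eb:
        x, y = indices[ia], indices[ib]
        if x < y:
            ia += 1
        elif y < x:
            ib += 1
        else:
            if x > floor:
                out[k] = x
                k += 1
            ia += 1
            ib += 1
    return k


@njit(cache=True)
def enum_triangles(dm, edge_verts, indptr, indices):
    n = dm.shape[0]
    m = edge_verts.shape[0]
    scratch = np.empty(n, np.int64)
    cnt = 0
    for e in range(m):
        cnt += _common_after(indptr, indices, edge_verts[e, 0],
                             edge_verts[e, 1], edge_verts[e, 1], scratch)
    verts = np.empty((cnt, 3), np.int64)
    vals = np.empty(cnt, np.float64)
    pos = 0
    for e in range(m):
        i, j = edge_verts[e, 0], edge_verts[e, 1]
        nc = _common_after(indptr, indices, i, j, j, scratch)
        for t in range(nc):
            k = scratch[t]
            verts[pos, 0] = i
            verts[pos, 1] = j
            verts[pos, 2] = k
            v = dm[i, j]
            if dm[i, k] > v:
                v = dm[i, k]
            if dm[j, k] > v:
                v = dm[j, k]
            vals[pos] = 0.5 * v
            pos += 1
    return verts, vals


@njit(cache=True)
def enum_tetrahedra(dm, tri_verts, indptr, indices):
    n = dm.shape[0]
    m = tri_verts.shape[0]
    scratch = np.empty(n, np.int64)
    cnt = 0
    for t in range(m):
        i, j, k = tri_verts[t, 0], tri_verts[t, 1], tri_verts[t, 2]
        nc = _common_after(indptr, indices, j, k, k, scratch)
        for s in range(nc):
            # scratch[s] is adjacent to j and k; require adjacency to i too
            if _is_adjacent(indptr, indices, i, scratch[s]):
                cnt += 1
    verts = np.empty((cnt, 4), np.int64)
    vals = np.empty(cnt, np.float64)
    pos = 0
    for t in range(m):
        i, j, k = tri_verts[t, 0], tri_verts[t, 1], tri_verts[t, 2]
        nc = _common_after(indptr, indices, j, k, k, scratch)
        for s in range(nc):
            l = scratch[s]
            if _is_adjacent(indptr, indices, i, l):
                verts[pos, 0] = i
                verts[pos, 1] = j
                verts[pos, 2] = k
                verts[pos, 3] = l
                v = dm[i, j]
                for (a, b) in ((i, k), (i, l), (j, k), (j, l), (k, l)):
                    if dm[a, b] > v:
                        v = dm[a, b]
                vals[pos] = 0.5 * v
                pos += 1
    return verts, vals


@njit(cache=True)
def _is_adjacent(indptr, indices, a, b):
    lo, hi = indptr[a], indptr[a + 1]
    while lo < hi:                       # binary search in sorted list
        mid = (lo + hi) // 2
        if indices[mid] < b:
            lo = mid + 1
        else:
            hi = mid
    return lo < indptr[a + 1] and indices[lo] == b
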