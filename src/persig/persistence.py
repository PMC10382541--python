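"""Persistence diagrams from point clouds.

:func:`compute_diagram` is the production path: Vietoris-Rips complexes
by numba-compiled neighbor enumeration and GF(2) boundary reduction, Cech
filtrations as Delaunay-alpha complexes in R^2/R^3 (identical diagrams,
far cheaper) with a genuine minimal-enclosing-ball Cech construction for
small clouds in higher dimension.  All scales are RADII: a Rips simplex
enters at half its diameter, a Cech simplex at its enclosing-ball radius,
so the two filtrations of the same cloud are directly comparable.

A full (untruncated) Rips diagram in degree k >= 1 is obtained by
truncating at the enclosing radius min_i max_j d(i, j): beyond it the
complex is a cone, hence contractible, and no feature of positive degree
survives.  For clouds too large for that, a finite ``threshold`` computes
the partial filtration and reports still-open cycles with death = inf,
feeding the infinite-cycle testing machinery.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from . import _rips
from ._alpha import build_alpha
from ._reduction import h0_merge_events, reduce_boundary
from .diagrams import PersistenceDiagram, validate_distance_matrix
from .oracle import naive_cech_persistence, naive_rips_persistence
from .samplers import PointCloud

__all__ = ["compute_diagram", "rips_auto_threshold", "enclosing_radius",
           "naive_rips_persistence", "naive_cech_persistence"]

#: simplex budget for a single reduction (memory guard)
DEFAULT_MAX_SIMPLICES = 30_000_000


def enclosing_radius(dm: np.ndarray) -> float:
    """Radius beyond which the Rips complex is a cone (min_i max_j d/2)."""
    return 0.5 * float(np.min(np.max(dm, axis=1)))


def _as_geometry(data, filtration):
    """Return (points or None, distance matrix or None, n)."""
    if isinstance(data, PointCloud):
        pts = data.points
        return pts, None, pts.shape[0]
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError("input must be an n x d coordinate matrix, a "
                         "PointCloud, or a square distance matrix")
    if (arr.shape[0] == arr.shape[1]
            and np.allclose(np.diag(arr), 0.0)
            and np.allclose(arr, arr.T)):
        if filtration == "cech":
            raise ValueError("the Cech/alpha construction needs coordinates, "
                             "not a distance matrix")
        return None, validate_distance_matrix(arr), arr.shape[0]
    if not np.all(np.isfinite(arr)):
        raise ValueError("coordinates must be finite")
    return arr, None, arr.shape[0]


# ---------------------------------------------------------------------------
# generic simplexwise assembly

def _sorted_dim(verts, vals, n):
    """Sort one dimension's simplices by (value, lexicographic vertices)."""
    key = np.zeros(len(vals), dtype=np.int64)
    for c in range(verts.shape[1]):
        key = key * n + verts[:, c]
    order = np.lexsort((key, vals))
    return verts[order], vals[order], key[order]


def _facet_rows(verts, keys_prev, perm_prev, n):
    """Indices (into the sorted previous dimension) of each simplex's facets."""
    m, w = verts.shape
    out = np.empty((m, w), dtype=np.int64)
    for s in range(w):
        sub = np.delete(verts, s, axis=1)
        fkey = np.zeros(m, dtype=np.int64)
        for c in range(sub.shape[1]):
            fkey = fkey * n + sub[:, c]
        pos = np.searchsorted(keys_prev, fkey)
        out[:, s] = perm_prev[pos]
    return out


def _persist(simp, vals, n_points, max_degree, filtration, threshold):
    """Reduce a filtration given per-dimension simplices/values (radii)."""
    dims = sorted(simp)
    top = dims[-1] if dims else 0
    sverts, svals, skeys, perm_bykey = {}, {}, {}, {}
    for p in dims:
        v, w, key = _sorted_dim(simp[p], vals[p], n_points)
        sverts[p], svals[p] = v, w
        ksort = np.argsort(key)
        skeys[p] = key[ksort]          # keys ascending, for searchsorted
        perm_bykey[p] = ksort          # key rank -> filtration index
    rows_deg, rows_b, rows_d = [], [], []

    # H0 via union-find over edges in filtration order
    merges = np.zeros(0, dtype=bool)
    if 1 in sverts and len(svals[1]):
        merges = h0_merge_events(sverts[1], n_points)
        death0 = svals[1][merges]
        rows_deg += [0] * len(death0)
        rows_b += [0.0] * len(death0)
        rows_d += list(death0)
        n_inf0 = n_points - int(merges.sum())
    else:
        n_inf0 = n_points
    rows_deg += [0] * n_inf0
    rows_b += [0.0] * n_inf0
    rows_d += [np.inf] * n_inf0

    cleared_next = None                 # pivot-row mask for dim p, from p+1
    for p in range(top, 1, -1):
        m_p = len(svals.get(p, []))
        m_f = len(svals.get(p - 1, []))
        if m_p == 0:
            cleared_next = None
            continue
        facets = _facet_rows(sverts[p], skeys[p - 1], perm_bykey[p - 1],
                             n_points)
        cleared = (cleared_next if cleared_next is not None
                   else np.zeros(m_p, dtype=bool))
        piv = reduce_boundary(facets, m_f, cleared)
        paired = piv >= 0
        rows_deg += [p - 1] * int(paired.sum())
        rows_b += list(svals[p - 1][piv[paired]])
        rows_d += list(svals[p][paired])
        if p <= max_degree:             # essential p-cycles
            ess = (~paired) & (~cleared)
            rows_deg += [p] * int(ess.sum())
            rows_b += list(svals[p][ess])
            rows_d += [np.inf] * int(ess.sum())
        cleared_f = np.zeros(m_f, dtype=bool)
        cleared_f[piv[paired]] = True
        cleared_next = cleared_f
    # essential 1-cycles: positive edges never paired by a triangle
    if max_degree >= 1 and 1 in sverts and len(svals[1]):
        positive = ~merges
        if cleared_next is not None:
            positive = positive & (~cleared_next)
        rows_deg += [1] * int(positive.sum())
        rows_b += list(svals[1][positive])
        rows_d += [np.inf] * int(positive.sum())

    return PersistenceDiagram(np.array(rows_deg, dtype=np.int64),
                              np.array(rows_b, dtype=float),
                              np.array(rows_d, dtype=float),
                              filtration, threshold, n_points)


# ---------------------------------------------------------------------------
# Rips

def _rips_filtration(dm, max_degree, t_dist, max_simplices):
    n = dm.shape[0]
    edge_v, edge_val = _rips.enum_edges(dm, t_dist)
    simp, vals = {1: edge_v}, {1: edge_val}
    if max_degree >= 1 and len(edge_val):
        indptr, indices = _rips.adjacency(edge_v, n)
        tri_v, tri_val = _rips.enum_triangles(dm, edge_v, indptr, indices)
        if len(tri_val) > max_simplices:
            raise MemoryError(
                f"{len(tri_val)} triangles exceed the simplex budget "
                f"({max_simplices}); lower the threshold")
        simp[2], vals[2] = tri_v, tri_val
        if max_degree >= 2 and len(tri_val):
            tet_v, tet_val = _rips.enum_tetrahedra(dm, tri_v, indptr, indices)
            if len(tet_val) > max_simplices:
                raise MemoryError(
                    f"{len(tet_val)} tetrahedra exceed the simplex budget "
                    f"({max_simplices}); lower the threshold")
            simp[3], vals[3] = tet_v, tet_val
    return simp, vals


def _rips_diagram(dm, max_degree, threshold, max_simplices):
    if max_degree > 2:
        raise NotImplementedError(
            "the fast Rips path supports max_degree <= 2; use the naive "
            "backend for higher degrees on small inputs")
    full = np.isinf(threshold)
    t_radius = enclosing_radius(dm) if full else float(threshold)
    simp, vals = _rips_filtration(dm, max_degree, 2.0 * t_radius,
                                  max_simplices)
    dgm = _persist(simp, vals, dm.shape[0], max_degree, "rips",
                   np.inf if full else t_radius)
    if full:
        # beyond the enclosing radius the complex is a cone: no positive-
        # degree cycle may remain open
        open_k = (dgm.degrees >= 1) & ~dgm.finite_mask
        if open_k.any():
            raise AssertionError("essential cycle past the enclosing radius")
    return dgm


def rips_auto_threshold(dm, max_degree=1, start=None, grow=1.5,
                        max_simplices=DEFAULT_MAX_SIMPLICES,
                        stop_essential=0):
    """Grow a Rips truncation radius until at most ``stop_essential``
    cycles of degree 1..max_degree remain open (or the cone radius or the
    simplex budget is reached).  Returns the final diagram.

    The result is a truncated diagram whose threshold is recorded; it is
    complete up to that radius but late-born features past it (rare for
    noise clouds, systematic for essential signal) stay open.
    """
    r_cone = enclosing_radius(dm)
    if start is None:
        nn = np.partition(dm + np.diag(np.full(len(dm), np.inf)), 0, axis=1)
        start = 3.0 * float(np.median(nn[:, 0]))
    tau = min(0.5 * start, r_cone)      # radius scale
    while True:
        try:
            dgm = _rips_diagram(dm, max_degree, tau, max_simplices)
        except MemoryError:
            raise
        n_open = int(((dgm.degrees >= 1) & ~dgm.finite_mask).sum())
        if n_open <= stop_essential or tau >= r_cone:
            return dgm
        tau = min(grow * tau, r_cone)


# ---------------------------------------------------------------------------
# public API

def compute_diagram(data, filtration: str = "rips", max_degree: int = 1,
                    threshold: float = np.inf, backend: str = "auto",
                    max_simplices: int = DEFAULT_MAX_SIMPLICES
                    ) -> PersistenceDiagram:
    """Persistence diagram of a point cloud (or distance matrix, Rips only).

    Parameters
    ----------
    data : PointCloud, (n, d) array, or square distance matrix
    filtration : 'rips' or 'cech'
    max_degree : highest homology degree reported
    threshold : truncation radius; ``inf`` computes the full diagram
    backend : 'auto', 'fast' (numba Rips / alpha), or 'naive' (the
        small-instance reduction oracle)
    """
    if filtration not in ("rips", "cech"):
        raise ValueError("filtration must be 'rips' or 'cech'")
    if max_degree < 0:
        raise ValueError("max_degree must be >= 0")
    pts, dm, n = _as_geometry(data, filtration)

    if backend == "naive":
        if filtration == "rips":
            if dm is None:
                dm = squareform(pdist(pts))
            return naive_rips_persistence(dm, max_degree, threshold)
        return naive_cech_persistence(pts, max_degree, threshold)
    if backend not in ("auto", "fast"):
        raise ValueError(f"unknown backend {backend!r}")

    if filtration == "rips":
        if dm is None:
            dm = squareform(pdist(pts))
        else:
            dm = validate_distance_matrix(dm)
        if isinstance(threshold, str):
            if threshold != "auto":
                raise ValueError("threshold must be a radius, inf or 'auto'")
            return rips_auto_threshold(dm, max_degree,
                                       max_simplices=max_simplices)
        return _rips_diagram(dm, max_degree, threshold, max_simplices)

    # Cech
    d = pts.shape[1]
    if d in (2, 3) and n > d + 1:
        simp, vals = build_alpha(pts)
        if np.isfinite(threshold):
            simp = {p: v[vals[p] <= threshold] for p, v in simp.items()}
            vals = {p: w[w <= threshold] for p, w in vals.items()}
            simp = {p: v for p, v in simp.items() if len(v)}
            vals = {p: w for p, w in vals.items() if len(w)}
            if not simp:
                simp, vals = {1: np.empty((0, 2), np.int64)}, {1: np.empty(0)}
        # alpha needs faces only up to max_degree+1; extra dims are harmless
        return _persist(simp, vals, n, max_degree, "cech",
                        threshold if np.isfinite(threshold) else np.inf)
    return naive_cech_persistence(pts, max_degree, threshold)
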