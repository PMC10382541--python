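"""Delaunay-alpha filtration for point clouds in R^2 and R^3.

The alpha complex is the Delaunay triangulation filtered by (squared)
circumradii with the standard Gabriel-propagation rule: a simplex whose
minimal circumball is empty enters at its circumradius, otherwise it
inherits the smallest value among its cofaces.  Its persistence diagram is
identical to the Cech filtration's for points in general position, at a
tiny fraction of the cost.  Values are returned on the radius scale
(square roots of the squared-radius filtration).
"""

from __future__ import annotations


import numpy as np
from scipy.spatial import Delaunay, QhullError

__all__ = ["build_alpha"]


def _circumspheres(points, simplices):
    """Batched circumcenter and squared circumradius of k-simplices."""
    v = points[simplices]                     # (m, k+1, d)
    rel = v[:, 1:, :] - v[:, :1, :]           # (m, k, d)
    gram = 2.0 * np.einsum("mkd,mld->mkl", rel, rel)
    rhs = np.einsum("mkd,mkd->mk", rel, rel)
    try:
        x = np.linalg.solve(gram, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        x = np.empty_like(rhs)
        for i in range(len(gram)):            # sliver fallback
            x[i] = np.linalg.lstsq(gram[i], rhs[i], rcond=None)[0]
    centers = v[:, 0, :] + np.einsum("mk,mkd->md", x, rel)
    r2 = np.einsum("md,md->m", centers - v[:, 0, :], centers - v[:, 0, :])
    return centers, r2


def build_alpha(points):
    """Build the alpha filtration of a 2-D or 3-D point cloud.

    Returns ``(simplices, values)`` where ``simplices[p]`` is an
    ``(m_p, p+1)`` array of vertex ids (rows sorted) for p = 1..d and
    ``values[p]`` the matching filtration radii.  Vertices (p = 0) all
    enter at radius 0 and are implicit.
    """
    points = np.asarray(points, dtype=float)
    n, d = points.shape
    if d not in (2, 3):
        raise ValueError("alpha construction implemented for d in {2, 3}")
    if n <= d:
        raise ValueError("need at least d+1 points for a Delaunay complex")
    try:
        tri = Delaunay(points)
    except QhullError:
        # degenerate inputs (e.g. cospherical/collinear): joggle
        tri = Delaunay(points, qhull_options="QJ")
    top = np.sort(tri.simplices, axis=1).astype(np.int64)   # (m, d+1)

    simplices: dict[int, np.ndarray] = {d: np.unique(top, axis=0)}
    facet_idx: dict[int, np.ndarray] = {}
    opposite: dict[int, np.ndarray] = {}
    for p in range(d, 1, -1):
        sp = simplices[p]                      # (m_p, p+1)
        m_p = sp.shape[0]
        cols = np.arange(p + 1)
        faces = np.stack([sp[:, np.delete(cols, s)] for s in range(p + 1)],
                         axis=1)               # (m_p, p+1, p)
        opp = sp.copy()                        # slot s drops vertex s
        uniq, inv = np.unique(faces.reshape(-1, p), axis=0,
                              return_inverse=True)
        simplices[p - 1] = uniq
        facet_idx[p] = inv.reshape(m_p, p + 1)
        opposite[p] = opp

    # squared circumradii and Gabriel propagation, top dimension downward
    cent: dict[int, np.ndarray] = {}
    r2: dict[int, np.ndarray] = {}
    for p in range(1, d + 1):
        cent[p], r2[p] = _circumspheres(points, simplices[p])
    val2: dict[int, np.ndarray] = {d: r2[d]}
    for p in range(d, 1, -1):
        fidx = facet_idx[p]                    # (m_p, p+1)
        m_f = simplices[p - 1].shape[0]
        cof_min = np.full(m_f, np.inf)
        np.minimum.at(cof_min, fidx.ravel(), np.repeat(val2[p], p + 1))
        # Gabriel test: is the opposite vertex inside the facet's circumball?
        ov = points[opposite[p]]               # (m_p, p+1, d)
        diff = ov - cent[p - 1][fidx]
        dist2 = np.einsum("msd,msd->ms", diff, diff)
        bad = np.zeros(m_f, dtype=bool)
        np.logical_or.at(bad, fidx.ravel(), (dist2 < r2[p - 1][fidx]).ravel())
        val2[p - 1] = np.where(bad, cof_min, np.minimum(cof_min, r2[p - 1]))

    out_s = {p: simplices[p] for p in range(1, d + 1)}
    out_v = {p: np.sqrt(np.maximum(val2[p], 0.0)) for p in range(1, d + 1)}
    return out_s, out_v
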