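"""Self-contained small-instance persistence oracle.

A deliberately simple, independent implementation of persistent homology:
enumerate every simplex up to the requested dimension, sort simplexwise,
and run the textbook column reduction of the boundary matrix over GF(2)
with Python sets.  It shares no code with the production path in
:mod:`persig.persistence` and serves as its correctness reference on small
inputs (capped at 64 points).

Also hosts the genuine Cech construction: filtration value of a simplex =
radius of the minimal enclosing ball of its vertices (brute-force support
enumeration), usable in any ambient dimension for small n.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .diagrams import PersistenceDiagram, validate_distance_matrix

__all__ = ["naive_rips_persistence", "naive_cech_persistence",
           "miniball_radius", "reduce_simplexwise"]

NAIVE_CAP = 64


def _circumsphere(pts):
    """Center/radius of the sphere through affinely independent points."""
    rel = pts[1:] - pts[0]
    gram = 2.0 * rel @ rel.T
    rhs = np.einsum("kd,kd->k", rel, rel)
    x = np.linalg.solve(gram, rhs)
    center = pts[0] + x @ rel
    return center, float(np.linalg.norm(center - pts[0]))


def miniball_radius(points) -> float:
    """Radius of the smallest ball enclosing a (small) point set.

    Brute force over candidate support subsets: the minimal enclosing ball
    is the circumsphere-in-affine-hull of some subset of at most d+1
    points lying on its boundary.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    k, d = pts.shape
    if k == 1:
        return 0.0
    best = np.inf
    for size in range(1, min(k, d + 1) + 1):
        for support in combinations(range(k), size):
            sub = pts[list(support)]
            if size == 1:
                center, r = sub[0], 0.0
            else:
                try:
                    center, r = _circumsphere(sub)
                except np.linalg.LinAlgError:
                    continue
            if r < best and np.all(
                    np.linalg.norm(pts - center, axis=1) <= r + 1e-9 * (1 + r)):
                best = r
    return float(best)


def reduce_simplexwise(simplices, max_degree):
    """Textbook GF(2) column reduction over a sorted simplexwise filtration.

    ``simplices``: list of ``(value, vertex_tuple)`` sorted by
    (value, dimension, vertices).  Returns ``(pairs, essential)`` where
    pairs are ``(degree, birth, death)`` and essential are ``(degree,
    birth)`` for unpaired cycle-creating simplices, both restricted to
    degrees <= max_degree.
    """
    index = {verts: i for i, (_, verts) in enumerate(simplices)}
    cols: dict[int, set] = {}
    low: dict[int, int] = {}
    positive: list[int] = []
    for j, (_, verts) in enumerate(simplices):
        if len(verts) == 1:
            col = set()
        else:
            col = {index[verts[:s] + verts[s + 1:]]
                   for s in range(len(verts))}
        while col:
            piv = max(col)
            if piv not in low:
                low[piv] = j
                break
            col ^= cols[low[piv]]
        cols[j] = col
        if not col:
            positive.append(j)
    paired = set(low)
    pairs, essential = [], []
    for piv, j in low.items():
        k = len(simplices[piv][1]) - 1
        if k <= max_degree:
            pairs.append((k, simplices[piv][0], simplices[j][0]))
    for j in positive:
        if j not in paired:
            k = len(simplices[j][1]) - 1
            if k <= max_degree:
                essential.append((k, simplices[j][0]))
    return pairs, essential


def _assemble(pairs, essential, filtration, threshold, n):
    rows = [(k, b, d) for k, b, d in pairs]
    rows += [(k, b, np.inf) for k, b in essential]
    rows.sort()
    deg = np.array([r[0] for r in rows], dtype=np.int64)
    b = np.array([r[1] for r in rows], dtype=float)
    d = np.array([r[2] for r in rows], dtype=float)
    return PersistenceDiagram(deg, b, d, filtration, threshold, n)


def naive_rips_persistence(dm, max_degree: int = 1,
                           threshold: float = np.inf) -> PersistenceDiagram:
    """Rips persistence by full enumeration and boundary reduction.

    Correctness oracle only: the input is capped at 64 points.  Filtration
    values are radii (half the simplex diameter).  ``threshold`` is a
    radius; simplices entering after it are omitted and unpaired cycles
    are reported with death = inf.
    """
    dm = validate_distance_matrix(dm)
    n = dm.shape[0]
    if n > NAIVE_CAP:
        raise ValueError(f"naive oracle capped at {NAIVE_CAP} points")
    full = np.isinf(threshold)
    # past the enclosing radius the complex is a cone over the minimizing
    # vertex, so the filtration may be truncated there without losing any
    # feature of positive persistence
    cut = 0.5 * float(np.min(np.max(dm, axis=1))) if full and n > 1 \
        else threshold
    simplices = []
    for size in range(1, max_degree + 3):
        for verts in combinations(range(n), size):
            val = 0.0 if size == 1 else 0.5 * max(
                dm[a, b] for a, b in combinations(verts, 2))
            if val <= cut:
                simplices.append((val, verts))
    simplices.sort(key=lambda s: (s[0], len(s[1]), s[1]))
    pairs, essential = reduce_simplexwise(simplices, max_degree)
    if full:
        essential = [(k, b) for k, b in essential if k == 0]
    return _assemble(pairs, essential, "rips", threshold, n)


def naive_cech_persistence(points, max_degree: int = 1,
                           threshold: float = np.inf) -> PersistenceDiagram:
    """Cech persistence with minimal-enclosing-ball filtration values.

    Valid in any ambient dimension; capped at 64 points.  For points in
    general position this agrees with the Delaunay-alpha diagram.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n > NAIVE_CAP:
        raise ValueError(f"naive oracle capped at {NAIVE_CAP} points")
    simplices = []
    for size in range(1, max_degree + 3):
        for verts in combinations(range(n), size):
            val = miniball_radius(pts[list(verts)])
            if val <= threshold:
                simplices.append((val, verts))
    simplices.sort(key=lambda s: (s[0], len(s[1]), s[1]))
    pairs, essential = reduce_simplexwise(simplices, max_degree)
    return _assemble(pairs, essential, "cech", threshold, n)
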