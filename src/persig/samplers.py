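"""Synthetic point-cloud generators.

Every sampling model used in the universality experiments is implemented
here with seedable randomness: iid samples on manifolds (torus, Klein
bottle, projective plane, sphere, ...) and from product distributions
(uniform box, beta, normal, Cauchy), more intricate spaces (pentagon
linkage configuration space, Henneberg surface, stratified plane-in-cube),
non-iid clouds (Brownian path, Lorenz trajectory), surface-mesh sampling,
time-delay embeddings of scalar signals, and the noisy figure-eight used
in the hypothesis-testing demonstration.

All samplers consume a single integer seed through
:func:`numpy.random.default_rng`, so identical ``(model, params, n, seed)``
yield bit-identical clouds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "PointCloud",
    "ModelSpec",
    "MODEL_NAMES",
    "sample",
    "sample_eight",
    "sample_mesh",
    "delay_embed",
    "read_series",
]

_REJECTION_CAP = 10_000  # batches; exceeded only for mis-parameterized models


@dataclass(frozen=True)
class PointCloud:
    """An n x d coordinate matrix with provenance metadata."""

    points: np.ndarray
    model: str = "unknown"
    params: Mapping[str, float] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim == 1:
            pts = pts[:, None]
        if pts.ndim != 2 or pts.shape[0] < 1 or pts.shape[1] < 1:
            raise ValueError("points must be an n x d matrix with n, d >= 1")
        if not np.all(np.isfinite(pts)):
            raise ValueError("all coordinates must be finite")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    def rescaled(self, c: float) -> "PointCloud":
        """Return a copy with all coordinates multiplied by ``c > 0``."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return PointCloud(self.points * c, self.model,
                          dict(self.params), self.seed)


#: models accepted by :func:`sample`, with their default parameters
_DEFAULTS: dict[str, dict[str, float]] = {
    "box": {"d": 2},
    "ball": {"d": 2},
    "annulus": {"d": 2, "r_in": 0.5, "r_out": 1.0},
    "sphere": {"d": 2},          # d-sphere embedded in R^{d+1}
    "beta": {"d": 2, "beta_a": 2.0, "beta_b": 2.0},
    "normal": {"d": 2},
    "cauchy": {"d": 2},
    "torus": {"R1": 2.0, "R2": 1.0},
    "klein": {},
    "projective": {},
    "linkage": {},
    "henneberg": {},
    "stratified": {"p": 0.5},
    "brownian": {"d": 2},
    "lorenz": {"sigma": 45.0, "rho": 54.0, "beta": 10.0, "dt": 0.1,
               "method": "rk4", "substeps": 100},
}

MODEL_NAMES = tuple(sorted(_DEFAULTS))


@dataclass(frozen=True)
class ModelSpec:
    """A named sampling model with validated parameters.

    ``dim`` is the ambient/product dimension for the models that take one
    (box, ball, annulus, sphere, beta, normal, cauchy, brownian); embedded
    manifolds (torus, klein, projective, linkage, henneberg, stratified,
    lorenz) have a fixed ambient dimension and ignore it.
    """

    name: str
    dim: int | None = None
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in _DEFAULTS:
            raise ValueError(
                f"unknown model {self.name!r}; choose from {MODEL_NAMES}")
        merged = dict(_DEFAULTS[self.name])
        unknown = set(self.params) - set(merged)
        if unknown:
            raise ValueError(
                f"unknown parameter(s) {sorted(unknown)} for model "
                f"{self.name!r}")
        merged.update(self.params)
        if self.dim is not None:
            if "d" not in _DEFAULTS[self.name]:
                raise ValueError(
                    f"model {self.name!r} has a fixed ambient dimension")
            merged["d"] = int(self.dim)
        if "d" in merged and merged["d"] < 1:
            raise ValueError("dimension must be >= 1")
        if self.name == "torus" and not merged["R1"] > merged["R2"] > 0:
            raise ValueError("torus requires R1 > R2 > 0")
        if self.name == "annulus" and not 0 < merged["r_in"] < merged["r_out"]:
            raise ValueError("annulus requires 0 < r_in < r_out")
        if self.name == "stratified" and not 0 <= merged["p"] <= 1:
            raise ValueError("stratified mixture probability must be in [0,1]")
        object.__setattr__(self, "params", merged)


def sample(spec: ModelSpec | str, n: int, seed: int | None = None,
           **params) -> PointCloud:
    """Draw ``n`` points from a synthetic model.

    ``spec`` may be a :class:`ModelSpec` or a model name (extra keyword
    arguments then become model parameters).  Identical ``(spec, n, seed)``
    produce bit-identical output.
    """
    if isinstance(spec, str):
        d = params.pop("d", None)
        spec = ModelSpec(spec, dim=d, params=params)
    elif params:
        raise TypeError("pass parameters inside the ModelSpec")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pts = _SAMPLERS[spec.name](rng, n, spec.params)
    return PointCloud(pts, spec.name, dict(spec.params), seed)


# ---------------------------------------------------------------------------
# iid models

def _box(rng, n, p):
    return rng.uniform(0.0, 1.0, size=(n, int(p["d"])))


def _rejection(rng, n, d, half_width, accept):
    """Rejection-sample ``n`` points from [-h, h]^d given an accept mask fn."""
    out = np.empty((n, d))
    got = 0
    for _ in range(_REJECTION_CAP):
        m = max(2 * (n - got), 16)
        cand = rng.uniform(-half_width, half_width, size=(m, d))
        keep = cand[accept(cand)]
        take = min(n - got, keep.shape[0])
        out[got:got + take] = keep[:take]
        got += take
        if got == n:
            return out
    raise RuntimeError("rejection sampling failed to converge "
                       "(mis-parameterized model?)")


def _ball(rng, n, p):
    d = int(p["d"])
    return _rejection(rng, n, d, 1.0,
                      lambda c: np.einsum("ij,ij->i", c, c) <= 1.0)


def _annulus(rng, n, p):
    d = int(p["d"])
    lo, hi = p["r_in"], p["r_out"]

    def accept(c):
        r2 = np.einsum("ij,ij->i", c, c)
        return (r2 >= lo * lo) & (r2 <= hi * hi)

    return _rejection(rng, n, d, hi, accept)


def _sphere(rng, n, p):
    d = int(p["d"])
    g = rng.standard_normal((n, d + 1))
    return g / np.linalg.norm(g, axis=1, keepdims=True)


def _beta(rng, n, p):
    return rng.beta(p["beta_a"], p["beta_b"], size=(n, int(p["d"])))


def _normal(rng, n, p):
    return rng.standard_normal((n, int(p["d"])))


def _cauchy(rng, n, p):
    return rng.standard_cauchy((n, int(p["d"])))


def _torus(rng, n, p):
    r1, r2 = p["R1"], p["R2"]
    phi = rng.uniform(0.0, 2 * np.pi, n)
    theta = rng.uniform(0.0, 2 * np.pi, n)
    rad = r1 + r2 * np.cos(phi)
    return np.column_stack([rad * np.cos(theta), rad * np.sin(theta),
                            r2 * np.sin(phi)])


def _klein(rng, n, p):
    phi = rng.uniform(0.0, 2 * np.pi, n)
    theta = rng.uniform(0.0, 2 * np.pi, n)
    return np.column_stack([
        (1 + np.cos(theta)) * np.cos(phi),
        (1 + np.cos(theta)) * np.sin(phi),
        np.sin(theta) * np.cos(phi / 2),
        np.sin(theta) * np.sin(phi / 2),
    ])


def _projective(rng, n, p):
    g = rng.standard_normal((n, 3))
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    u, v, w = g.T
    return np.column_stack([u * v, u * w, v * v - w * w, 2 * v * w])


def linkage_vertices(phi, theta, s):
    """Vertices p3, p4, p5 of a unit pentagon linkage with p1=(0,0), p2=(1,0).

    ``s`` in {+1, -1} selects between the two intersection points of the
    unit circles about p3 and p5 that locate p4.  Raises ``ValueError``
    when no pentagon exists (``|p3 - p5| > 2``).
    """
    p5 = np.array([np.cos(phi), np.sin(phi)])
    p3 = np.array([1 + np.cos(theta), np.sin(theta)])
    gap = p3 - p5
    dist = float(np.hypot(*gap))
    if dist > 2 or dist == 0.0:
        raise ValueError("no valid pentagon for these angles")
    q = 0.5 * (p3 + p5)
    h = 0.5 * dist                     # |q - p5|
    perp = np.array([q[1] - p5[1], p5[0] - q[0]])
    p4 = q + s * (np.sqrt(1.0 - h * h) / h) * perp
    return p3, p4, p5


def _linkage(rng, n, p):
    out = np.empty((n, 6))
    got = 0
    for _ in range(_REJECTION_CAP):
        m = max(2 * (n - got), 16)
        phi = rng.uniform(0.0, 2 * np.pi, m)
        theta = rng.uniform(0.0, 2 * np.pi, m)
        s = np.where(rng.random(m) < 0.5, 1.0, -1.0)
        p5 = np.column_stack([np.cos(phi), np.sin(phi)])
        p3 = np.column_stack([1 + np.cos(theta), np.sin(theta)])
        dist = np.linalg.norm(p3 - p5, axis=1)
        ok = (dist <= 2.0) & (dist > 0.0)
        p3, p5, s, dist = p3[ok], p5[ok], s[ok], dist[ok]
        q = 0.5 * (p3 + p5)
        h = 0.5 * dist
        perp = np.column_stack([q[:, 1] - p5[:, 1], p5[:, 0] - q[:, 0]])
        p4 = q + (s * np.sqrt(1.0 - h * h) / h)[:, None] * perp
        block = np.column_stack([p3, p4, p5])
        take = min(n - got, block.shape[0])
        out[got:got + take] = block[:take]
        got += take
        if got == n:
            return out
    raise RuntimeError("rejection sampling failed to converge")


def _henneberg(rng, n, p):
    phi = rng.uniform(0.0, 2 * np.pi, n)
    theta = rng.uniform(0.0, 2 * np.pi, n)
    return np.column_stack([
        2 * np.cos(theta) * np.sinh(phi)
        - (2.0 / 3.0) * np.cos(3 * theta) * np.sinh(3 * phi),
        2 * np.sin(theta) * np.sinh(phi)
        + (2.0 / 3.0) * np.sin(3 * theta) * np.sinh(3 * phi),
        2 * np.cos(2 * theta) * np.cosh(2 * phi),
    ])


def _stratified(rng, n, p):
    # a plane [-1,1]^2 x {0} inside the cube [-1,1]^3; the lower stratum
    # is chosen with probability p
    pts = rng.uniform(-1.0, 1.0, size=(n, 3))
    on_plane = rng.random(n) < p["p"]
    pts[on_plane, 2] = 0.0
    return pts


# ---------------------------------------------------------------------------
# non-iid models

def _brownian(rng, n, p):
    z = rng.standard_normal((n, int(p["d"])))
    return np.cumsum(z, axis=0)


def _lorenz_rhs(x, sigma, rho, beta):
    return np.array([
        sigma * (x[1] - x[0]),
        x[0] * (rho - x[2]) - x[1],
        x[0] * x[1] - beta * x[2],
    ])


def _lorenz(rng, n, p):
    # dt is the SAMPLING interval of the trajectory; the integrator takes
    # `substeps` internal fixed steps per sample, because at these stiff
    # parameter values a single explicit step of size 0.1 is unstable
    sigma, rho, beta, dt = p["sigma"], p["rho"], p["beta"], p["dt"]
    method = p.get("method", "rk4")
    substeps = int(p.get("substeps", 100))
    h = dt / substeps
    x = rng.uniform(0.0, 1.0, 3)
    out = np.empty((n, 3))
    out[0] = x
    for i in range(1, n):
        for _ in range(substeps):
            if method == "euler":
                x = x + h * _lorenz_rhs(x, sigma, rho, beta)
            else:
                k1 = _lorenz_rhs(x, sigma, rho, beta)
                k2 = _lorenz_rhs(x + 0.5 * h * k1, sigma, rho, beta)
                k3 = _lorenz_rhs(x + 0.5 * h * k2, sigma, rho, beta)
                k4 = _lorenz_rhs(x + h * k3, sigma, rho, beta)
                x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        out[i] = x
    return out


_SAMPLERS = {
    "box": _box, "ball": _ball, "annulus": _annulus, "sphere": _sphere,
    "beta": _beta, "normal": _normal, "cauchy": _cauchy, "torus": _torus,
    "klein": _klein, "projective": _projective, "linkage": _linkage,
    "henneberg": _henneberg, "stratified": _stratified,
    "brownian": _brownian, "lorenz": _lorenz,
}


# ---------------------------------------------------------------------------
# figure eight

def sample_eight(n: int, neck_width: float = 0.1, noise_sigma: float = 0.0075,
                 seed: int | None = None) -> PointCloud:
    """Sample a noisy figure eight: a wedge of two unit circles.

    Points are drawn uniformly on the unit circles centered at (-1, 0) and
    (1, 0) (tangent at the origin); points landing within ``neck_width/2``
    of the origin are discarded and redrawn, opening a gap of width
    ``neck_width`` at the neck, and isotropic Gaussian jitter of scale
    ``noise_sigma`` is then added.
    """
    if not 0 < neck_width < 2:
        raise ValueError("neck_width must lie in (0, 2)")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty((n, 2))
    got = 0
    for _ in range(_REJECTION_CAP):
        m = max(2 * (n - got), 16)
        side = np.where(rng.random(m) < 0.5, -1.0, 1.0)
        ang = rng.uniform(0.0, 2 * np.pi, m)
        pts = np.column_stack([side + np.cos(ang), np.sin(ang)])
        pts = pts[np.hypot(pts[:, 0], pts[:, 1]) >= neck_width / 2]
        take = min(n - got, pts.shape[0])
        out[got:got + take] = pts[:take]
        got += take
        if got == n:
            break
    else:
        raise RuntimeError("rejection sampling failed to converge")
    out += noise_sigma * rng.standard_normal((n, 2))
    return PointCloud(out, "eight",
                      {"neck_width": neck_width, "noise_sigma": noise_sigma},
                      seed)


# ---------------------------------------------------------------------------
# mesh surfaces

def sample_mesh(mesh, n: int, seed: int | None = None) -> PointCloud:
    """Sample ``n`` points uniformly from a triangulated surface.

    ``mesh`` is a ``trimesh.Trimesh`` or a path to an ASCII OFF/PLY file.
    A triangle is chosen with probability proportional to its area and a
    point is placed uniformly inside it via barycentric coordinates.
    """
    import trimesh

    if not isinstance(mesh, trimesh.Trimesh):
        mesh = trimesh.load_mesh(str(mesh), process=False)
    if n < 1:
        raise ValueError("n must be >= 1")
    tri = np.asarray(mesh.triangles, dtype=float)
    areas = np.asarray(mesh.area_faces, dtype=float)
    ok = areas > 0
    if tri.shape[0] == 0 or not ok.any():
        raise ValueError("mesh has no nondegenerate triangle")
    tri, areas = tri[ok], areas[ok]
    rng = np.random.default_rng(seed)
    idx = rng.choice(tri.shape[0], size=n, p=areas / areas.sum())
    u = rng.random(n)
    v = rng.random(n)
    flip = u + v > 1          # reflect into the lower barycentric triangle
    u[flip], v[flip] = 1 - u[flip], 1 - v[flip]
    a, b, c = tri[idx, 0], tri[idx, 1], tri[idx, 2]
    pts = a + u[:, None] * (b - a) + v[:, None] * (c - a)
    return PointCloud(pts, "mesh", {"n_triangles": tri.shape[0]}, seed)


# ---------------------------------------------------------------------------
# time series

def delay_embed(series, embed_dim: int, stride: int = 3, lag: int = 7,
                n: int | None = None) -> PointCloud:
    """Time-delay embedding of a scalar signal into R^embed_dim.

    Row ``i`` (0-based) is ``(V[i*stride], V[i*stride + lag], ...,
    V[i*stride + (embed_dim-1)*lag])``.  When ``n`` is omitted the maximal
    number of rows fitting in the series is used.
    """
    v = np.asarray(series, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise ValueError("series values must be finite")
    if embed_dim < 1 or stride < 1 or lag < 1:
        raise ValueError("embed_dim, stride and lag must be positive")
    span = (embed_dim - 1) * lag
    n_max = (len(v) - 1 - span) // stride + 1
    if n is None:
        n = n_max
    if n < 1 or n > n_max:
        raise ValueError(
            f"series too short: at most {max(n_max, 0)} rows available")
    starts = np.arange(n) * stride
    idx = starts[:, None] + np.arange(embed_dim) * lag
    return PointCloud(v[idx], "delay_embed",
                      {"embed_dim": embed_dim, "stride": stride, "lag": lag},
                      None)


def read_series(path) -> np.ndarray:
    """Read a scalar signal from single-column text or a PCM WAV file."""
    path = str(path)
    if path.lower().endswith(".wav"):
        from scipy.io import wavfile
        _, data = wavfile.read(path)
        data = np.asarray(data, dtype=float)
        if data.ndim > 1:       # use the first channel
            data = data[:, 0]
        return data
    return np.loadtxt(path, dtype=float).ravel()
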