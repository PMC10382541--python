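"""Persistence-diagram containers and plain-text I/O.

A diagram is a multiset of features ``(degree k, birth b, death d)`` on a
common radius scale, together with the filtration type that produced it
and the computation threshold tau (``inf`` for a full filtration).  Death
may be ``inf`` for essential ("infinite") cycles of a thresholded
computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PersistenceDiagram",
    "read_diagram",
    "write_diagram",
    "select_noise_candidates",
    "validate_distance_matrix",
]


@dataclass
class PersistenceDiagram:
    """Multiset of (degree, birth, death) features on the radius scale."""

    degrees: np.ndarray
    births: np.ndarray
    deaths: np.ndarray
    filtration: str = "rips"
    threshold: float = np.inf
    n_points: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.degrees = np.asarray(self.degrees, dtype=np.int64).ravel()
        self.births = np.asarray(self.births, dtype=float).ravel()
        self.deaths = np.asarray(self.deaths, dtype=float).ravel()
        if not (len(self.degrees) == len(self.births) == len(self.deaths)):
            raise ValueError("degrees, births and deaths must align")
        if np.any(self.births < 0):
            raise ValueError("births must be nonnegative")
        if np.any(self.deaths < self.births):
            raise ValueError("every death must be >= its birth")
        if self.filtration not in ("rips", "cech"):
            raise ValueError("filtration must be 'rips' or 'cech'")

    def __len__(self) -> int:
        return len(self.births)

    def of_degree(self, k: int) -> "PersistenceDiagram":
        return self._mask(self.degrees == k)

    def _mask(self, m) -> "PersistenceDiagram":
        return PersistenceDiagram(self.degrees[m], self.births[m],
                                  self.deaths[m], self.filtration,
                                  self.threshold, self.n_points,
                                  dict(self.meta))

    @property
    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.deaths)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"degree": self.degrees, "birth": self.births,
                             "death": self.deaths})

    def as_multiset(self, decimals: int = 9):
        """Order-free representation for comparisons, rounded."""
        rows = sorted(zip(self.degrees.tolist(),
                          np.round(self.births, decimals).tolist(),
                          np.round(self.deaths, decimals).tolist()))
        return tuple(map(tuple, rows))


def write_diagram(dgm: PersistenceDiagram, path) -> None:
    """Write ``degree,birth,death`` CSV; ``inf`` marks essential cycles."""
    df = dgm.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")


def read_diagram(path, filtration: str = "rips",
                 threshold: float = np.inf) -> PersistenceDiagram:
    """Read a ``degree,birth,death`` CSV written by :func:`write_diagram`.

    Malformed rows (negative birth, death < birth) are rejected with the
    offending row number.
    """
    df = pd.read_csv(path)
    need = {"degree", "birth", "death"}
    if not need.issubset(df.columns):
        raise ValueError(f"diagram file must have columns {sorted(need)}")
    births = df["birth"].to_numpy(dtype=float)
    deaths = df["death"].to_numpy(dtype=float)
    for i, (b, d) in enumerate(zip(births, deaths)):
        if not np.isfinite(b) or b < 0:
            raise ValueError(f"row {i + 1}: invalid birth {b}")
        if d < b:
            raise ValueError(f"row {i + 1}: death {d} precedes birth {b}")
    return PersistenceDiagram(df["degree"].to_numpy(dtype=np.int64),
                              births, deaths, filtration, threshold)


def select_noise_candidates(dgm: PersistenceDiagram, k: int):
    """Split the degree-``k`` features into testable finite and infinite parts.

    Zero-persistence pairs (death == birth) and zero-birth features are
    dropped: the death/birth ratio is undefined or uninformative for them.
    Degree 0 is rejected because every component is born at radius 0.
    """
    if k < 1:
        raise ValueError("significance testing requires degree k >= 1")
    sub = dgm.of_degree(k)
    keep = (sub.births > 0) & (sub.deaths > sub.births)
    sub = sub._mask(keep)
    return sub._mask(sub.finite_mask), sub._mask(~sub.finite_mask)


def validate_distance_matrix(dm: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Check symmetry, zero diagonal and nonnegativity; return as float array."""
    dm = np.asarray(dm, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.all(np.isfinite(dm)):
        raise ValueError("distances must be finite")
    if np.any(np.abs(np.diag(dm)) > tol):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(np.abs(dm - dm.T) > tol):
        raise ValueError("distance matrix must be symmetric")
    if np.any(dm < 0):
        raise ValueError("distances must be nonnegative")
    return 0.5 * (dm + dm.T)
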