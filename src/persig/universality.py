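"""The universal null for persistence values.

Persistence of a k-cycle (k >= 1) is measured multiplicatively,
pi = death/birth.  The diagram's pi-values are mapped to

    ell = A * loglog(pi) + B,      A = 1 (Rips) or 1/2 (Cech),
    B   = -lambda - A * Lbar,

where Lbar is the diagram mean of loglog(pi) and lambda the
Euler-Mascheroni constant.  For noise generated by a very wide class of
sampling models the ell-values empirically follow a single parameter-free
law, the left-skewed Gumbel distribution F(x) = 1 - exp(-exp(x)) — the
universal null against which individual cycles are tested.

The centering makes mean(ell) = -lambda identically, and because loglog
turns powers of pi into additive shifts absorbed by B, the ell-values are
invariant to pi -> pi^c — hence to radius-vs-diameter or
radius-vs-squared-radius scale conventions of persistence software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .diagrams import PersistenceDiagram, select_noise_candidates

__all__ = [
    "EULER_MASCHERONI",
    "TransformParams",
    "LGumbel",
    "pi_values",
    "lifetimes",
    "ell_transform",
    "ell_of_pi",
    "ell_inverse",
    "ks_gof",
    "ecdf_qq",
    "diagram_pi_values",
]

#: Euler-Mascheroni constant, hard-coded to 20 digits
EULER_MASCHERONI = 0.57721566490153286061

_A_BY_FILTRATION = {"rips": 1.0, "cech": 0.5}


@dataclass(frozen=True)
class TransformParams:
    """Constants of the ell-transform for one diagram."""

    A: float
    Lbar: float

    @property
    def B(self) -> float:
        return -EULER_MASCHERONI - self.A * self.Lbar

    @classmethod
    def from_filtration(cls, filtration: str, Lbar: float):
        try:
            return cls(_A_BY_FILTRATION[filtration], float(Lbar))
        except KeyError:
            raise ValueError("filtration must be 'rips' or 'cech'") from None


def pi_values(births, deaths) -> np.ndarray:
    """Multiplicative persistence pi = death/birth, order preserved."""
    b = np.asarray(births, dtype=float)
    d = np.asarray(deaths, dtype=float)
    if np.any(b <= 0):
        raise ValueError("pi requires birth > 0 (exclude degree-0 features)")
    if np.any(~np.isfinite(d)):
        raise ValueError("pi requires finite death (pre-filter essential "
                         "cycles)")
    return d / b


def lifetimes(births, deaths) -> np.ndarray:
    """Additive persistence Delta = death - birth."""
    return np.asarray(deaths, dtype=float) - np.asarray(births, dtype=float)


def diagram_pi_values(dgm: PersistenceDiagram, k: int) -> np.ndarray:
    """pi-values of the finite degree-k features of a diagram."""
    finite, _ = select_noise_candidates(dgm, k)
    return pi_values(finite.births, finite.deaths)


def ell_transform(pis, filtration: str = "rips",
                  params: TransformParams | None = None):
    """Map pi-values to ell-values; returns ``(ell, TransformParams)``.

    ``B`` is estimated from the data (its mean loglog pi) unless explicit
    ``params`` are injected, e.g. for simulation studies with a known
    normalization.  pi-values numerically at or below 1 carry no usable
    persistence and are dropped with a warning.
    """
    pis = np.asarray(pis, dtype=float).ravel()
    if pis.size == 0:
        raise ValueError("need at least one pi-value")
    usable = pis > 1.0 + 1e-12
    if not usable.all():
        warnings.warn(f"dropping {int((~usable).sum())} pi-value(s) <= 1 "
                      "(zero persistence)", stacklevel=2)
        pis = pis[usable]
        if pis.size == 0:
            raise ValueError("no pi-value exceeds 1")
    ll = np.log(np.log(pis))
    if params is None:
        params = TransformParams.from_filtration(filtration, ll.mean())
    return params.A * ll + params.B, params


def ell_of_pi(pi, params: TransformParams) -> np.ndarray:
    """ell-value of given pi under fixed transform constants."""
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 1):
        raise ValueError("pi must exceed 1")
    return params.A * np.log(np.log(pi)) + params.B


def ell_inverse(y, params: TransformParams):
    """Invert the ell-map: the pi-value whose ell-value is ``y``."""
    if params.A == 0:
        raise ValueError("params.A must be nonzero")
    y = np.asarray(y, dtype=float)
    inner = (y - params.B) / params.A
    if np.any(inner > 700) or np.any(np.exp(np.minimum(inner, 700)) > 700):
        raise OverflowError("ell-value out of invertible range")
    return np.exp(np.exp(inner))


class LGumbel:
    """The left-skewed Gumbel law, F(x) = 1 - exp(-exp(x)).

    Parameter-free; the mirror image of the standard (right-skewed)
    Gumbel.  Its mean is -lambda (lambda the Euler-Mascheroni constant),
    matching the centering mean(ell) = -lambda enforced by the
    ell-transform.
    """

    @staticmethod
    def cdf(x):
        return -np.expm1(-np.exp(np.asarray(x, dtype=float)))

    @staticmethod
    def pdf(x):
        x = np.asarray(x, dtype=float)
        return np.exp(x - np.exp(x))

    @staticmethod
    def quantile(q):
        q = np.asarray(q, dtype=float)
        if np.any(q <= 0) or np.any(q >= 1):
            raise ValueError("quantile argument must lie in (0, 1)")
        return np.log(-np.log1p(-q))

    @staticmethod
    def mean(method: str = "quadrature") -> float:
        """E[X] = -lambda; 'quadrature' integrates x f(x) numerically."""
        if method == "exact":
            return -EULER_MASCHERONI
        with np.errstate(over="ignore"):
            val, _ = integrate.quad(lambda x: x * np.exp(x - np.exp(x)),
                                    -np.inf, np.inf)
        return val

    @staticmethod
    def rvs(size, rng):
        return LGumbel.quantile(rng.uniform(size=size))


def ks_gof(ells):
    """One-sample Kolmogorov-Smirnov test of ell-values against LGumbel.

    Returns ``(D, p)`` with D the sup-distance between the ECDF and the
    LGumbel CDF and p from the asymptotic Kolmogorov distribution.  Note
    that B having been estimated from the same diagram makes the test
    mildly conservative.
    """
    ells = np.asarray(ells, dtype=float).ravel()
    if ells.size < 5:
        raise ValueError("need at least 5 values for a KS test")
    res = stats.kstest(ells, stats.gumbel_l.cdf, mode="asymp")
    return float(res.statistic), float(res.pvalue)


def ecdf_qq(values):
    """ECDF and LGumbel QQ tables for plotting.

    Returns ``(ecdf, qq)``: ``ecdf`` has columns (sorted value, F_hat),
    ``qq`` has columns (theoretical quantile at (i - 1/2)/m, empirical
    quantile).
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if v.size == 0:
        raise ValueError("need at least one value")
    m = v.size
    ecdf = np.column_stack([v, np.arange(1, m + 1) / m])
    probs = (np.arange(1, m + 1) - 0.5) / m
    qq = np.column_stack([LGumbel.quantile(probs), v])
    return ecdf, qq
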