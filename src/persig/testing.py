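"""Per-cycle hypothesis tests and the infinite-cycle threshold search.

Under the universal null, the ell-value of a noise cycle follows the
left-skewed Gumbel law, so an observed ell = x has p-value
P(ell >= x | noise) = exp(-exp(x)).  Cycles are tested simultaneously
with a Bonferroni correction at level alpha / |dgm_k|; the surviving set
is the signal part dgm_S(alpha) of the diagram.

Cycles still open at a truncation radius tau ("infinite" cycles) admit
only the bound p <= exp(-exp(ell(tau/b))): the unknown death exceeds tau,
so pi > tau/b.  The iterative search raises tau just far enough —
tau <- min(I) * pi_min(alpha/|D|) — to decide each undecided cycle,
avoiding computation of the much larger filtration up to the true deaths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagrams import PersistenceDiagram, select_noise_candidates
from .persistence import compute_diagram, enclosing_radius
from .samplers import PointCloud
from .universality import (TransformParams, ell_inverse, ell_of_pi,
                           ell_transform, pi_values)

__all__ = ["p_value", "pi_min", "infinite_p_bound", "signal_features",
           "find_infinite_threshold", "full_report", "SignificanceReport",
           "InfiniteSearchTrace"]


def p_value(ell):
    """p-value of an observed ell-value under the LGumbel null."""
    ell = np.asarray(ell, dtype=float)
    with np.errstate(over="ignore"):
        return np.exp(-np.exp(ell))


def pi_min(x: float, params: TransformParams):
    """Smallest pi whose p-value falls below ``x`` (0 < x < 1)."""
    x = float(x)
    if not 0 < x < 1:
        raise ValueError("x must lie in (0, 1)")
    return float(ell_inverse(np.log(np.log(1.0 / x)), params))


def infinite_p_bound(b, tau, params: TransformParams):
    """Upper bound on the p-value of a cycle born at ``b``, still open at
    ``tau``: its pi exceeds tau/b, so p < exp(-exp(ell(tau/b)))."""
    b = np.asarray(b, dtype=float)
    if np.any(b <= 0) or np.any(tau < b):
        raise ValueError("need 0 < b <= tau")
    ratio = tau / b
    if np.any(ratio <= 1):
        raise ValueError("tau/b must exceed 1")
    return p_value(ell_of_pi(ratio, params))


@dataclass
class SignificanceReport:
    """Per-feature test results for the degree-k features of one diagram."""

    degree: int
    filtration: str
    alpha: float
    births: np.ndarray
    deaths: np.ndarray               # inf for bound-only (open) cycles
    pis: np.ndarray                  # tau/b lower bound where death is inf
    ells: np.ndarray
    p_values: np.ndarray             # upper bound where bound_only
    bound_only: np.ndarray
    significant: np.ndarray
    params: TransformParams
    n_tested: int
    threshold: float = np.inf
    meta: dict = field(default_factory=dict)

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.n_tested

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "birth": self.births, "death": self.deaths, "pi": self.pis,
            "ell": self.ells, "p_value": self.p_values,
            "bound_only": self.bound_only, "significant": self.significant,
        })
        return df.sort_values("p_value", kind="stable").reset_index(drop=True)

    def to_dict(self) -> dict:
        return {
            "degree": self.degree, "filtration": self.filtration,
            "alpha": self.alpha, "n_tested": self.n_tested,
            "bonferroni_threshold": self.bonferroni_threshold,
            "threshold": (None if np.isinf(self.threshold)
                          else self.threshold),
            "A": self.params.A, "B": self.params.B,
            "n_significant": self.n_significant,
            "features": self.to_frame().to_dict(orient="records"),
        }


def signal_features(dgm: PersistenceDiagram, k: int = 1,
                    filtration: str | None = None, alpha: float = 0.05,
                    params: TransformParams | None = None
                    ) -> SignificanceReport:
    """Test every degree-k cycle of a diagram at Bonferroni level
    alpha/|dgm_k|.

    |dgm_k| counts all tested features, finite and (for truncated
    diagrams) still-open ones; the latter receive p-value upper bounds and
    are flagged ``bound_only``.  The transform constant B is estimated
    from the finite features of this diagram unless ``params`` is given.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    filtration = filtration or dgm.filtration
    finite, infinite = select_noise_candidates(dgm, k)
    if len(finite):
        # features whose ratio is 1 up to roundoff carry no usable
        # persistence; drop them like exact zero-persistence pairs
        usable = pi_values(finite.births, finite.deaths) > 1.0 + 1e-12
        finite = finite._mask(usable)
    m = len(finite) + len(infinite)
    if m == 0:
        return SignificanceReport(
            k, filtration, alpha, np.empty(0), np.empty(0), np.empty(0),
            np.empty(0), np.empty(0), np.empty(0, bool), np.empty(0, bool),
            params or TransformParams.from_filtration(filtration, 0.0), 1,
            dgm.threshold)
    if len(finite) == 0:
        raise ValueError("no finite degree-k feature to estimate the "
                         "transform from; raise the threshold")
    pis_f = pi_values(finite.births, finite.deaths)
    ells_f, params = ell_transform(pis_f, filtration, params)
    p_f = p_value(ells_f)
    if len(infinite):
        if not np.isfinite(dgm.threshold):
            raise ValueError("open cycles in an untruncated diagram")
        ratio = dgm.threshold / infinite.births
        ells_i = ell_of_pi(ratio, params)
        p_i = p_value(ells_i)
    else:
        ratio = np.empty(0)
        ells_i = np.empty(0)
        p_i = np.empty(0)
    births = np.concatenate([finite.births, infinite.births])
    deaths = np.concatenate([finite.deaths, np.full(len(infinite), np.inf)])
    pis = np.concatenate([pis_f, ratio])
    ells = np.concatenate([ells_f, ells_i])
    ps = np.concatenate([p_f, p_i])
    bound = np.concatenate([np.zeros(len(finite), bool),
                            np.ones(len(infinite), bool)])
    sig = ps < alpha / m
    return SignificanceReport(k, filtration, alpha, births, deaths, pis,
                              ells, ps, bound, sig, params, m,
                              dgm.threshold)


@dataclass
class InfiniteSearchTrace:
    """Per-iteration state of the threshold search."""

    taus: list = field(default_factory=list)
    diagram_sizes: list = field(default_factory=list)
    undecided: list = field(default_factory=list)    # birth sets I
    pi_mins: list = field(default_factory=list)
    final_tau: float = np.nan
    converged: bool = False

    def to_dict(self) -> dict:
        return {
            "iterations": [
                {"tau": t, "diagram_size": s, "undecided_births": list(u),
                 "pi_min": pm}
                for t, s, u, pm in zip(self.taus, self.diagram_sizes,
                                       self.undecided, self.pi_mins)],
            "final_tau": self.final_tau, "converged": self.converged,
        }


def find_infinite_threshold(pc, k: int = 1, filtration: str = "rips",
                            alpha: float = 0.05, tau0: float | None = None,
                            tau_max: float | None = None, pick: str = "min",
                            max_iter: int = 60, **compute_kw):
    """Iterative threshold search deciding the significance of open cycles.

    Starting from tau0, repeatedly computes the truncated diagram D =
    dgm_k(tau), finds the open cycles whose significance is still
    undecided (tau/b < pi_min(alpha/|D|)) and raises tau to
    ``pick(I) * pi_min(alpha/|D|)`` until none remain.  ``pick`` is the
    earliest-born cycle ('min', fewest extra simplices per step) or the
    latest-born ('max', fewer iterations).  tau is capped at the cloud's
    enclosing radius, beyond which the complex is a cone and no cycle
    stays open.

    Returns ``(trace, report)`` where the report tests the final diagram.
    """
    if pick not in ("min", "max"):
        raise ValueError("pick must be 'min' or 'max'")
    from scipy.spatial.distance import pdist, squareform
    pts = pc.points if isinstance(pc, PointCloud) else np.asarray(pc, float)
    dm = squareform(pdist(pts))
    r_cone = enclosing_radius(dm)
    if tau_max is None:
        tau_max = r_cone
    if tau0 is None:
        # start just above the connectivity radius (half the longest
        # minimum-spanning-tree edge): below it, latent cycles of the
        # underlying space need not be born yet and cannot be examined
        from scipy.sparse.csgraph import minimum_spanning_tree
        longest = minimum_spanning_tree(dm).max()
        # 1.5x the connectivity radius: cycles bounded by gaps comparable
        # to the sparsest region are typically born by then; for latent
        # cycles known to be born later, pass tau0 explicitly
        tau0 = min(0.75 * float(longest), tau_max)
    if tau0 <= 0 or tau_max < tau0:
        raise ValueError("need 0 < tau0 <= tau_max")
    tau = float(tau0)
    trace = InfiniteSearchTrace()
    dgm = None
    for _ in range(max_iter):
        dgm = compute_diagram(pts, filtration, max_degree=k, threshold=tau,
                              **compute_kw)
        finite, infinite = select_noise_candidates(dgm, k)
        if len(finite) == 0:           # too sparse to estimate B yet
            tau = min(2.0 * tau, tau_max)
            trace.taus.append(tau)
            trace.diagram_sizes.append(len(infinite))
            trace.undecided.append(list(infinite.births))
            trace.pi_mins.append(np.nan)
            continue
        m = len(finite) + len(infinite)
        _, params = ell_transform(pi_values(finite.births, finite.deaths),
                                  filtration)
        pm = pi_min(alpha / m, params)
        undecided = infinite.births[tau / infinite.births < pm]
        trace.taus.append(tau)
        trace.diagram_sizes.append(m)
        trace.undecided.append(list(undecided))
        trace.pi_mins.append(pm)
        if len(undecided) == 0:
            trace.converged = True
            break
        b_pick = undecided.min() if pick == "min" else undecided.max()
        # nudge strictly past the boundary so tau*/b clears pi_min even
        # after floating-point roundoff
        new_tau = b_pick * pm * (1.0 + 1e-9)   # > tau since tau/b < pi_min
        if new_tau >= tau_max:
            if tau >= tau_max:
                break
            new_tau = tau_max
        tau = float(new_tau)
    trace.final_tau = tau
    report = signal_features(dgm, k, filtration, alpha)
    return trace, report


def full_report(pc, k: int = 1, filtration: str = "rips",
                alpha: float = 0.05, threshold: float = np.inf,
                **compute_kw):
    """End-to-end: diagram -> ell-values -> finite tests + infinite search.

    With an infinite threshold the full diagram is computed and only
    finite cycles are tested.  With a finite threshold, any cycle still
    open triggers the iterative threshold search starting there; with
    threshold='auto' the search starts from a small data-driven radius so
    that signal cycles are decided via the tau/b bound without ever
    building the filtration out to their deaths.

    Returns ``(report, trace_or_None)``.
    """
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError("threshold must be a radius, inf or 'auto'")
        trace, report = find_infinite_threshold(pc, k, filtration, alpha,
                                                tau0=None, **compute_kw)
        return report, trace
    dgm = compute_diagram(pc, filtration, max_degree=k, threshold=threshold,
                          **compute_kw)
    _, infinite = select_noise_candidates(dgm, k)
    if len(infinite) and np.isfinite(dgm.threshold):
        trace, report = find_infinite_threshold(
            pc, k, filtration, alpha, tau0=float(dgm.threshold),
            **compute_kw)
        return report, trace
    return signal_features(dgm, k, filtration, alpha), None
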