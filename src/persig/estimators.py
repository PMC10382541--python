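"""scikit-learn style front ends.

`SignificantCycles` wraps the whole pipeline (diagram -> ell-values ->
Bonferroni tests) as an estimator whose ``fit`` ingests an (n, d)
coordinate matrix, so it composes with sklearn model selection and
pipelines; `EllTransform` exposes the pi -> ell normalization as a
transformer.  Both delegate to the functional API.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .testing import full_report
from .universality import ell_transform

__all__ = ["SignificantCycles", "EllTransform"]


class SignificantCycles(BaseEstimator):
    """Detect statistically significant k-cycles in a point cloud.

    Parameters
    ----------
    degree : homology degree tested (1 = loops, 2 = cavities)
    filtration : 'cech' (Delaunay-alpha in R^2/R^3) or 'rips'
    alpha : family-wise error level for the Bonferroni-corrected tests
    threshold : truncation radius; ``inf`` computes the full filtration,
        a finite value triggers the iterative search for cycles still
        open at it

    Attributes (after ``fit``)
    --------------------------
    report_ : SignificanceReport with per-cycle pi, ell, p-value, verdict
    trace_ : InfiniteSearchTrace or None
    significant_ : boolean mask over the tested cycles
    n_significant_ : number of signal cycles at level alpha
    """

    def __init__(self, degree: int = 1, filtration: str = "cech",
                 alpha: float = 0.05, threshold: float = np.inf,
                 backend: str = "auto"):
        self.degree = degree
        self.filtration = filtration
        self.alpha = alpha
        self.threshold = threshold
        self.backend = backend

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be an (n, d) coordinate matrix")
        report, trace = full_report(X, self.degree, self.filtration,
                                    self.alpha, self.threshold,
                                    backend=self.backend)
        self.report_ = report
        self.trace_ = trace
        self.significant_ = report.significant
        self.p_values_ = report.p_values
        self.n_significant_ = report.n_significant
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X=None):
        """Significance verdicts for the cycles found during ``fit``."""
        check_is_fitted(self, "report_")
        return self.significant_


class EllTransform(TransformerMixin, BaseEstimator):
    """Normalize pi-values (or birth-death pairs) to universal ell-values.

    ``fit`` estimates the diagram-dependent offset B from the training
    values; ``transform`` applies ell = A loglog(pi) + B.  Input is a
    column of pi-values or an (m, 2) array of (birth, death) pairs.
    """

    def __init__(self, filtration: str = "cech"):
        self.filtration = filtration

    @staticmethod
    def _pis(X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 2:
            return X[:, 1] / X[:, 0]
        return X.ravel()

    def fit(self, X, y=None):
        _, self.params_ = ell_transform(self._pis(X), self.filtration)
        return self

    def transform(self, X):
        check_is_fitted(self, "params_")
        ells, _ = ell_transform(self._pis(X), self.filtration,
                                params=self.params_)
        return ells[:, None]
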