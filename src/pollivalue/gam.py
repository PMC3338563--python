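"""Penalized B-spline additive models (P-splines) with GCV smoothing selection.

The trend-surface regressions in this package need univariate smooths,
a bivariate temperature x precipitation interaction surface, and an
optional bivariate coordinate smooth.  They are fitted here as
penalized regression splines in the Eilers-Marx style: cubic B-spline
bases with equally spaced knots, second-order difference penalties on
the coefficients (tensor products of marginal bases and Kronecker-sum
penalties for bivariate terms), and smoothing parameters chosen by
minimizing the generalized cross-validation score

    GCV(lambda) = n * RSS / (n - tr(H))^2 .

The second-difference penalty leaves constant and linear functions
unpenalized, so exactly linear signals are recovered without bias.
Each smooth is centered against the training data so the global
intercept is identifiable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline
from scipy.linalg import block_diag
from sklearn.base import BaseEstimator, RegressorMixin

_DEGREE = 3
_PENALTY_ORDER = 2


def _knots(lo: float, hi: float, nbasis: int) -> np.ndarray:
    """Augmented knot vector for ``nbasis`` cubic B-splines on [lo, hi]."""
    if nbasis < _DEGREE + 1:
        raise ValueError(f"need at least {_DEGREE + 1} basis functions, got {nbasis}")
    if hi <= lo:
        hi = lo + 1.0  # degenerate predictor: constant column, penalty handles it
    interior = np.linspace(lo, hi, nbasis - _DEGREE + 1)
    return np.r_[[lo] * _DEGREE, interior, [hi] * _DEGREE]


def _basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    x = np.clip(x, knots[0], knots[-1])  # constant extrapolation outside training range
    return BSpline.design_matrix(x, knots, _DEGREE, extrapolate=False).toarray()


def _diff_penalty(nbasis: int) -> np.ndarray:
    d = np.diff(np.eye(nbasis), n=_PENALTY_ORDER, axis=0)
    return d.T @ d


class _Smooth1D:
    def __init__(self, col: str, k: int):
        self.col, self.k = col, int(k)

    @property
    def name(self) -> str:
        return f"s({self.col})"

    def prepare(self, X: pd.DataFrame):
        x = X[self.col].to_numpy(float)
        self.knots_ = _knots(x.min(), x.max(), self.k)
        self.penalty_ = _diff_penalty(self.k)
        B = _basis(x, self.knots_)
        self.center_ = B.mean(axis=0)
        return B - self.center_

    def design(self, X: pd.DataFrame):
        return _basis(X[self.col].to_numpy(float), self.knots_) - self.center_


class _Smooth2D:
    """Tensor-product smooth of two predictors with a Kronecker-sum penalty."""

    def __init__(self, col1: str, col2: str, k: int):
        self.col1, self.col2, self.k = col1, col2, int(k)

    @property
    def name(self) -> str:
        return f"te({self.col1},{self.col2})"

    def prepare(self, X: pd.DataFrame):
        x1 = X[self.col1].to_numpy(float)
        x2 = X[self.col2].to_numpy(float)
        self.knots1_ = _knots(x1.min(), x1.max(), self.k)
        self.knots2_ = _knots(x2.min(), x2.max(), self.k)
        p1 = _diff_penalty(self.k)
        p2 = _diff_penalty(self.k)
        eye = np.eye(self.k)
        self.penalty_ = np.kron(p1, eye) + np.kron(eye, p2)
        B = self._tensor(x1, x2)
        self.center_ = B.mean(axis=0)
        return B - self.center_

    def _tensor(self, x1, x2):
        b1 = _basis(x1, self.knots1_)
        b2 = _basis(x2, self.knots2_)
        return (b1[:, :, None] * b2[:, None, :]).reshape(len(x1), -1)

    def design(self, X: pd.DataFrame):
        return self._tensor(X[self.col1].to_numpy(float), X[self.col2].to_numpy(float)) - self.center_


def _make_smooth(term):
    kind = term[0]
    if kind == "s":
        return _Smooth1D(term[1], term[2])
    if kind == "te":
        return _Smooth2D(term[1], term[2], term[3])
    raise ValueError(f"unknown smooth term {term!r}; use ('s', col, k) or ('te', col1, col2, k)")


class TrendSurfaceGAM(BaseEstimator, RegressorMixin):
    """Gaussian additive model with penalized spline smooths.

    Parameters
    ----------
    terms
        Tuple of smooth specifications: ``("s", column, k)`` for a
        univariate cubic P-spline with ``k`` basis functions, or
        ``("te", col1, col2, k)`` for a tensor-product surface with
        ``k`` basis functions per margin (k*k coefficients).
    optimize_lambda
        If True (default), smoothing parameters are chosen by GCV
        (Nelder-Mead on log-lambda); otherwise ``lam0`` is used as-is.
    lam0
        Initial (or fixed) smoothing parameter for every term.

    Attributes
    ----------
    coef_, intercept_ : fitted coefficients
    lam_ : per-term smoothing parameters chosen by GCV
    edf_ : total effective degrees of freedom (trace of the hat matrix)
    explained_variance_ : in-sample 1 - RSS/TSS
    gcv_ : GCV score at the optimum
    term_table_ : per-term edf and approximate F-test p-values
    """

    def __init__(self, terms=(), optimize_lambda: bool = True, lam0: float = 1.0):
        self.terms = terms
        self.optimize_lambda = optimize_lambda
        self.lam0 = lam0

    # -- internals -----------------------------------------------------
    def _assemble(self, lam: np.ndarray):
        """Full penalty matrix for smoothing parameters ``lam``."""
        blocks = [np.zeros((1, 1))]  # intercept: unpenalized
        for lam_t, sm in zip(lam, self._smooths):
            blocks.append(lam_t * sm.penalty_)
        return block_diag(*blocks)

    def _solve(self, lam: np.ndarray):
        A = self._xtx + self._assemble(lam)
        beta = np.linalg.solve(A, self._xty)
        # tr(H) = tr(A^-1 XtX); RSS from the normal-equation identities
        edf = float(np.trace(np.linalg.solve(A, self._xtx)))
        rss = float(self._yty - 2 * beta @ self._xty + beta @ self._xtx @ beta)
        rss = max(rss, 0.0)
        return beta, edf, rss

    def _gcv(self, log_lam: np.ndarray) -> float:
        lam = np.exp(np.clip(log_lam, -25.0, 25.0))
        try:
            _, edf, rss = self._solve(lam)
        except np.linalg.LinAlgError:
            return np.inf
        n = self._n
        denom = max(n - edf, 1e-8)
        return n * rss / denom**2

    # -- estimator API -------------------------------------------------
    def fit(self, X: pd.DataFrame, y):
        if not self.terms:
            raise ValueError("no smooth terms specified")
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self._smooths = [_make_smooth(t) for t in self.terms]
        cols = [np.ones((len(X), 1))]
        self._slices = []
        start = 1
        for sm in self._smooths:
            B = sm.prepare(X)
            cols.append(B)
            self._slices.append(slice(start, start + B.shape[1]))
            start += B.shape[1]
        Xd = np.hstack(cols)
        n, p = Xd.shape
        if n < 2 * p:
            raise ValueError(f"too few rows ({n}) for {p} coefficients; reduce basis sizes")
        self._n = n
        self._xtx = Xd.T @ Xd
        self._xty = Xd.T @ y
        self._yty = float(y @ y)

        lam = np.full(len(self._smooths), float(self.lam0))
        if self.optimize_lambda:
            res = optimize.minimize(
                self._gcv,
                np.log(lam),
                method="Nelder-Mead",
                options={"maxiter": 200 * len(lam), "xatol": 1e-2, "fatol": 1e-10},
            )
            lam = np.exp(np.clip(res.x, -25.0, 25.0))
        self.lam_ = lam
        beta, edf, rss = self._solve(lam)
        self.intercept_ = float(beta[0])
        self.coef_ = beta
        self.edf_ = edf
        tss = float(np.sum((y - y.mean()) ** 2))
        self.explained_variance_ = 1.0 - rss / tss if tss > 0 else 0.0
        self.gcv_ = n * rss / max(n - edf, 1e-8) ** 2
        self.n_obs_ = n
        self._rss = rss
        self.term_table_ = self._term_tests(y, rss, edf)
        return self

    def _term_tests(self, y, rss_full, edf_full) -> pd.DataFrame:
        """Approximate per-term F-tests by refitting without each term."""
        rows = []
        n = self._n
        scale = rss_full / max(n - edf_full, 1.0)
        for i, sm in enumerate(self._smooths):
            sl = self._slices[i]
            keep = np.r_[np.arange(0, sl.start), np.arange(sl.stop, self._xtx.shape[0])]
            xtx_r = self._xtx[np.ix_(keep, keep)]
            xty_r = self._xty[keep]
            pen_r = self._assemble(self.lam_)[np.ix_(keep, keep)]
            A = xtx_r + pen_r
            beta_r = np.linalg.solve(A, xty_r)
            edf_r = float(np.trace(np.linalg.solve(A, xtx_r)))
            rss_r = max(float(self._yty - 2 * beta_r @ xty_r + beta_r @ xtx_r @ beta_r), 0.0)
            edf_t = max(edf_full - edf_r, 1e-8)
            fstat = max(rss_r - rss_full, 0.0) / edf_t / max(scale, 1e-300)
            pval = float(stats.f.sf(fstat, edf_t, max(n - edf_full, 1.0)))
            rows.append({"term": sm.name, "edf": edf_t, "F": fstat, "p_value": pval})
        return pd.DataFrame(rows)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        out = np.full(len(X), self.intercept_)
        for sm, sl in zip(self._smooths, self._slices):
            out = out + sm.design(X) @ self.coef_[sl]
        return out
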