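"""Sparse recovery of neural weights from the underdetermined screen system.

The screen yields one phenotype per line but covers ~3x more neuron
classes than lines, so M w = P is underdetermined.  Weights are inferred
by L1-penalized least squares

.. math:: J(w) = \\frac{1}{2n}\\lVert P - Mw \\rVert_2^2 + \\lambda \\lVert w \\rVert_1

with n the number of lines, no intercept (phenotypes are differences with
zero baseline) and no column standardization (the design is binary; scaling
would distort weight interpretability).  The penalty strength is swept over
six orders of magnitude; the reported solution is taken at the elbow where
the chi-squared error (mean squared residual) begins to increase.  Stability
is quantified by resampling replicates within each line x condition,
rebuilding the gated phenotype vector, and re-solving.

Every returned solution carries a KKT optimality certificate:
``(1/n) M_j^T (P - Mw) = lambda * sign(w_j)`` on the active set and
``|(1/n) M_j^T (P - Mw)| <= lambda`` off it, within ``kkt_tol``.

The two estimators follow scikit-learn conventions (``fit``/``predict``,
``get_params``, trailing-underscore fitted attributes) and compose with
sklearn model-selection tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso
from sklearn.utils.validation import check_is_fitted

from .matrix import MeasurementMatrix
from .screen import PhenotypeVector, build_phenotype_vector, phenotypes_from_table


class ConvergenceError(RuntimeError):
    """Solver failed to reach a KKT-certified optimum."""


def _as_arrays(M, P):
    """Coerce (MeasurementMatrix | ndarray, PhenotypeVector | ndarray)."""
    if isinstance(M, MeasurementMatrix):
        if isinstance(P, PhenotypeVector) and P.line_ids != M.line_ids:
            raise ValueError("phenotype vector and matrix disagree on line ids")
        X = M.values
    else:
        X = np.asarray(M, dtype=float)
    y = P.values if isinstance(P, PhenotypeVector) else np.asarray(P, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError(f"incompatible shapes: M {X.shape}, P {y.shape}")
    return X, y


#: A neuron counts as selected when its weight is within a factor of five of
#: the dominant weight.  On binary promoter designs the lasso path carries
#: persistent small nonzero coefficients (correlated columns soaking up
#: residual structure and gate-leaked replicate noise); those sit an order
#: of magnitude below the leading weights and are background, not circuit.
SUPPORT_REL_TOL = 0.2


def _support(weights: np.ndarray, rel_tol: float = SUPPORT_REL_TOL) -> np.ndarray:
    """Indices with |w| above ``rel_tol * max|w|`` (empty for w == 0)."""
    scale = np.max(np.abs(weights)) if weights.size else 0.0
    if scale == 0:
        return np.array([], dtype=int)
    return np.nonzero(np.abs(weights) > rel_tol * scale)[0]


def kkt_violation(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                  lam: float) -> float:
    """Largest violation of the lasso KKT conditions (0 for an exact optimum)."""
    n = X.shape[0]
    g = X.T @ (y - X @ w) / n
    active = w != 0
    viol = 0.0
    if active.any():
        viol = float(np.max(np.abs(g[active] - lam * np.sign(w[active]))))
    if (~active).any():
        viol = max(viol, float(np.max(np.abs(g[~active]) - lam)))
    return max(viol, 0.0)


def _cd_fit(X, y, alpha, max_iter, tol, warm_from=None) -> np.ndarray:
    """One coordinate-descent lasso fit; convergence is judged by the
    caller's KKT certificate, so sklearn's own warning is suppressed."""
    est = Lasso(alpha=alpha, fit_intercept=False, max_iter=max_iter,
                tol=tol, warm_start=warm_from is not None)
    if warm_from is not None:
        est.coef_ = np.asarray(warm_from, dtype=float).copy()
        est.intercept_ = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return est.coef_.copy()


def lam_max(M, P) -> float:
    """Smallest penalty at which the all-zero solution is optimal."""
    X, y = _as_arrays(M, P)
    return float(np.max(np.abs(X.T @ y)) / X.shape[0])


@dataclass(frozen=True)
class WeightSolution:
    """Per-neuron weights at one penalty, with fit error and support."""

    weights: np.ndarray
    lam: float
    chi2: float  # mean squared residual
    support: np.ndarray  # indices of (numerically) nonzero weights
    neuron_ids: tuple | None = None

    @property
    def l1_norm(self) -> float:
        return float(np.sum(np.abs(self.weights)))

    def support_ids(self) -> tuple:
        if self.neuron_ids is None:
            return tuple(int(i) for i in self.support)
        return tuple(self.neuron_ids[i] for i in self.support)


@dataclass(frozen=True)
class SparsitySweep:
    """Solutions along a log-spaced penalty grid."""

    lam_grid: np.ndarray
    solutions: tuple

    def __post_init__(self):
        grid = np.asarray(self.lam_grid, dtype=float)
        object.__setattr__(self, "lam_grid", grid)
        object.__setattr__(self, "solutions", tuple(self.solutions))
        if len(grid) != len(self.solutions):
            raise ValueError("one solution per grid point required")
        if len(grid) and np.any(np.diff(grid) <= 0):
            raise ValueError("penalty grid must be strictly increasing")

    @property
    def chi2(self) -> np.ndarray:
        return np.array([s.chi2 for s in self.solutions])

    @property
    def l1_norms(self) -> np.ndarray:
        return np.array([s.l1_norm for s in self.solutions])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lam": self.lam_grid, "chi2": self.chi2,
                             "l1_norm": self.l1_norms})


class ScreenLasso(BaseEstimator, RegressorMixin):
    """L1-penalized solver for M w = P at a fixed penalty.

    Parameters
    ----------
    alpha : float
        Penalty strength (the lambda of the objective above).
    max_iter, tol : int, float
        Coordinate-descent budget and stopping tolerance.
    kkt_tol : float
        Maximum admissible KKT violation of the returned solution,
        measured relative to the data's gradient scale
        ``max(1, lambda_max)`` so the certificate is unit-independent.

    Attributes
    ----------
    coef_ : ndarray of shape (n_neurons,)
        Inferred weights (signed; negative = inhibition promotes the
        opposite behavior).
    chi2_ : float
        Mean squared residual of the fit.
    support_ : ndarray
        Indices of nonzero weights.
    """

    def __init__(self, alpha: float = 1.0, max_iter: int = 100_000,
                 tol: float = 1e-12, kkt_tol: float = 1e-6,
                 support_rel_tol: float = SUPPORT_REL_TOL):
        self.alpha = alpha
        self.max_iter = max_iter
        self.tol = tol
        self.kkt_tol = kkt_tol
        self.support_rel_tol = support_rel_tol

    def fit(self, X, y):
        X, y = _as_arrays(X, y)
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        scale = max(1.0, float(np.max(np.abs(X.T @ y)) / X.shape[0])) if y.size else 1.0
        if self.alpha == 0:
            # minimum-norm least squares; coordinate descent is undefined here
            coef = np.linalg.lstsq(X, y, rcond=None)[0]
        else:
            coef = _cd_fit(X, y, self.alpha, self.max_iter, self.tol)
            if kkt_violation(X, y, coef, self.alpha) > self.kkt_tol * scale:
                # one retry with a larger budget before giving up
                coef = _cd_fit(X, y, self.alpha, 20 * self.max_iter,
                               self.tol / 100, warm_from=coef)
        viol = kkt_violation(X, y, coef, self.alpha)
        if viol > self.kkt_tol * scale:
            raise ConvergenceError(
                f"KKT violation {viol:.3e} exceeds tolerance "
                f"{self.kkt_tol * scale:.3e} at alpha={self.alpha:.3e} "
                f"(n={X.shape[0]}, p={X.shape[1]})")
        self.coef_ = coef
        self.kkt_violation_ = viol
        self.chi2_ = float(np.mean((y - X @ coef) ** 2))
        self.support_ = _support(coef, self.support_rel_tol)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        X, _ = _as_arrays(X, np.zeros(np.asarray(X.values if isinstance(
            X, MeasurementMatrix) else X).shape[0]))
        return X @ self.coef_


class ElbowScreenLasso(BaseEstimator, RegressorMixin):
    """Lasso with penalty chosen at the chi-squared elbow of a log sweep.

    Sweeps ``n_points`` log-spaced penalties over ``span`` orders of
    magnitude below ``lam_hi`` (defaults to the data's lambda_max), then
    keeps the largest penalty whose chi-squared error stays within
    ``rel_tol`` of the low-penalty floor, relative to the full chi-squared
    range — the point where error "begins to increase".

    Attributes (after fit): ``coef_``, ``lam_``, ``chi2_``, ``support_``,
    ``sweep_`` (the full :class:`SparsitySweep`).
    """

    def __init__(self, lam_lo: float | None = None, lam_hi: float | None = None,
                 n_points: int = 60, span: float = 1e6, rel_tol: float = 0.001,
                 max_iter: int = 100_000, tol: float = 1e-12,
                 kkt_tol: float = 1e-6,
                 support_rel_tol: float = SUPPORT_REL_TOL):
        self.lam_lo = lam_lo
        self.lam_hi = lam_hi
        self.n_points = n_points
        self.span = span
        self.rel_tol = rel_tol
        self.max_iter = max_iter
        self.tol = tol
        self.kkt_tol = kkt_tol
        self.support_rel_tol = support_rel_tol

    def _grid(self, X, y) -> np.ndarray:
        hi = self.lam_hi if self.lam_hi is not None else max(
            float(np.max(np.abs(X.T @ y)) / X.shape[0]), 1e-300)
        lo = self.lam_lo if self.lam_lo is not None else hi / self.span
        if not 0 < lo < hi:
            raise ValueError(f"invalid penalty range [{lo}, {hi}]")
        if self.n_points < 2:
            raise ValueError("n_points must be at least 2")
        return np.logspace(np.log10(lo), np.log10(hi), self.n_points)

    def fit(self, X, y):
        neuron_ids = X.neuron_ids if isinstance(X, MeasurementMatrix) else None
        X, y = _as_arrays(X, y)
        grid = self._grid(X, y)
        scale = max(1.0, float(np.max(np.abs(X.T @ y)) / X.shape[0])) if y.size else 1.0
        # warm-start from the sparse end of the path; each solution still
        # carries its own KKT certificate, so the result is start-independent
        sols: list = [None] * len(grid)
        coef = None
        for gi in range(len(grid) - 1, -1, -1):
            lam = float(grid[gi])
            coef = _cd_fit(X, y, lam, self.max_iter, self.tol, warm_from=coef)
            if kkt_violation(X, y, coef, lam) > self.kkt_tol * scale:
                est = ScreenLasso(alpha=lam, max_iter=self.max_iter,
                                  tol=self.tol, kkt_tol=self.kkt_tol).fit(X, y)
                coef = est.coef_
            sols[gi] = WeightSolution(
                weights=coef, lam=lam,
                chi2=float(np.mean((y - X @ coef) ** 2)),
                support=_support(coef, self.support_rel_tol),
                neuron_ids=neuron_ids)
        self.sweep_ = SparsitySweep(lam_grid=grid, solutions=tuple(sols))
        self.lam_, chosen = select_elbow(self.sweep_, rel_tol=self.rel_tol)
        self.coef_ = chosen.weights
        self.chi2_ = chosen.chi2
        self.support_ = chosen.support
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        X, _ = _as_arrays(X, np.zeros(np.asarray(X.values if isinstance(
            X, MeasurementMatrix) else X).shape[0]))
        return X @ self.coef_


def lasso_solve(M, P, lam: float, kkt_tol: float = 1e-6) -> WeightSolution:
    """Solve the penalized system at one penalty; KKT-certified."""
    neuron_ids = M.neuron_ids if isinstance(M, MeasurementMatrix) else None
    est = ScreenLasso(alpha=lam, kkt_tol=kkt_tol).fit(M, P)
    return WeightSolution(weights=est.coef_, lam=float(lam), chi2=est.chi2_,
                          support=est.support_, neuron_ids=neuron_ids)


def brute_force_solve(M, P, lam: float, max_columns: int = 14) -> WeightSolution:
    """Exact minimizer of the lasso objective by support/sign enumeration.

    For every candidate support S and sign pattern s the stationarity
    system ``(1/n) M_S^T M_S w_S = (1/n) M_S^T P - lam * s`` is solved;
    a candidate whose solution is sign-consistent and satisfies the
    off-support KKT bound is the global optimum (the objective is convex).
    Exponential in the column count — a test oracle, not a solver.
    """
    X, y = _as_arrays(M, P)
    n, p = X.shape
    if p > max_columns:
        raise ValueError(f"{p} columns exceed the brute-force limit {max_columns}")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    neuron_ids = M.neuron_ids if isinstance(M, MeasurementMatrix) else None

    def finish(w):
        return WeightSolution(weights=w, lam=float(lam),
                              chi2=float(np.mean((y - X @ w) ** 2)),
                              support=_support(w), neuron_ids=neuron_ids)

    if lam == 0:
        return finish(np.linalg.lstsq(X, y, rcond=None)[0])

    G = X.T @ X / n
    b = X.T @ y / n
    tol = 1e-9 * max(1.0, float(np.max(np.abs(b))))

    # empty support
    if np.max(np.abs(b)) <= lam + tol:
        return finish(np.zeros(p))

    best_w, best_J = None, np.inf
    for k in range(1, p + 1):
        for S in combinations(range(p), k):
            S = list(S)
            A = G[np.ix_(S, S)]
            try:
                Ainv = np.linalg.inv(A)
            except np.linalg.LinAlgError:
                continue  # dependent columns; optimum covered by another support
            signs = np.array(
                [[1.0 if (m >> i) & 1 else -1.0 for i in range(k)]
                 for m in range(2 ** k)])
            cand = (Ainv @ (b[S][:, None] - lam * signs.T)).T  # (2^k, k)
            ok = np.all(np.sign(cand) == signs, axis=1)
            for wS in cand[ok]:
                w = np.zeros(p)
                w[S] = wS
                grad = b - G @ w
                off = np.setdiff1d(np.arange(p), S)
                if off.size and np.max(np.abs(grad[off])) > lam + tol:
                    J = 0.5 * float(np.mean((y - X @ w) ** 2)) + lam * np.sum(np.abs(w))
                    if J < best_J:
                        best_w, best_J = w, J
                    continue
                return finish(w)  # full KKT certificate -> global optimum
    if best_w is not None:  # pragma: no cover - safety net for degenerate input
        return finish(best_w)
    raise ConvergenceError("brute-force enumeration found no stationary point")


def sparsity_sweep(M, P, lam_lo: float | None = None,
                   lam_hi: float | None = None,
                   n_points: int = 60, **kwargs) -> SparsitySweep:
    """One KKT-certified solution per point of a log-spaced penalty grid.

    The default grid spans six orders of magnitude up to the data's
    lambda_max (where the solution is exactly zero).
    """
    est = ElbowScreenLasso(lam_lo=lam_lo, lam_hi=lam_hi, n_points=n_points,
                           **kwargs).fit(M, P)
    return est.sweep_


def select_elbow(sweep: SparsitySweep, rel_tol: float = 0.001) -> tuple:
    """Largest penalty before the chi-squared error begins to increase.

    Returns ``(lam, solution)`` for the largest grid penalty whose chi2
    does not exceed ``chi2_min + rel_tol * (chi2_max - chi2_min)``.  A
    flat chi2 curve yields the largest (sparsest) penalty.
    """
    if not len(sweep.solutions):
        raise ValueError("empty sweep")
    chi2 = sweep.chi2
    lo, hi = float(chi2.min()), float(chi2.max())
    if hi == lo:
        i = len(sweep.solutions) - 1
    else:
        i = int(np.nonzero(chi2 <= lo + rel_tol * (hi - lo))[0].max())
    return float(sweep.lam_grid[i]), sweep.solutions[i]


@dataclass(frozen=True)
class BootstrapReport:
    """Per-neuron bootstrap medians, percentile intervals, selection rates."""

    neuron_ids: tuple
    median: np.ndarray
    lo: np.ndarray  # 2.5th percentile
    hi: np.ndarray  # 97.5th percentile
    selection_frequency: np.ndarray
    lam: float
    n_boot: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "neuron_id": list(self.neuron_ids), "median_weight": self.median,
            "ci_lo": self.lo, "ci_hi": self.hi,
            "selection_frequency": self.selection_frequency,
        })


def _welch_pvalues(mean_p, var_p, n_p, mean_m, var_m, n_m):
    """Vectorized Welch two-sided p-values with zero-variance conventions."""
    diff = mean_p - mean_m
    se2 = var_p / n_p + var_m / n_m
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        dof = se2 ** 2 / ((var_p / n_p) ** 2 / (n_p - 1)
                          + (var_m / n_m) ** 2 / (n_m - 1))
        pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    degenerate = se2 == 0
    pvals = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), pvals)
    return diff, pvals


def bootstrap_weights(M: MeasurementMatrix, replicate_table: pd.DataFrame,
                      metric: str, alpha: float, lam: float, n_boot: int,
                      seed: int, reselect_lambda: bool = False,
                      **elbow_kwargs) -> BootstrapReport:
    """Stability of the inferred weights under replicate resampling.

    Each bootstrap draw resamples the replicates of every line x condition
    with replacement, re-runs the significance gate to rebuild the
    phenotype vector, and re-solves the penalized system at the fixed
    penalty ``lam`` (or re-selects the elbow per draw with
    ``reselect_lambda``).  Reports per-neuron median weight, 2.5/97.5
    percentile interval, and the fraction of draws selecting the neuron.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    rng = np.random.default_rng(seed)
    line_ids = M.line_ids
    plus, minus = [], []
    for lid in line_ids:
        sub = replicate_table[(replicate_table["line_id"] == lid)
                              & (replicate_table["metric"] == metric)]
        p = sub.loc[sub["condition"] == "plusATR", "value"].to_numpy(float)
        m = sub.loc[sub["condition"] == "minusATR", "value"].to_numpy(float)
        if len(p) < 2 or len(m) < 2:
            raise ValueError(f"line {lid}: need >= 2 replicates per condition")
        plus.append(p)
        minus.append(m)

    n_lines = len(line_ids)
    mean_p = np.empty((n_boot, n_lines))
    var_p = np.empty((n_boot, n_lines))
    mean_m = np.empty((n_boot, n_lines))
    var_m = np.empty((n_boot, n_lines))
    n_p = np.empty(n_lines)
    n_m = np.empty(n_lines)
    for i in range(n_lines):
        rp = plus[i][rng.integers(0, len(plus[i]), size=(n_boot, len(plus[i])))]
        rm = minus[i][rng.integers(0, len(minus[i]), size=(n_boot, len(minus[i])))]
        mean_p[:, i], var_p[:, i] = rp.mean(axis=1), rp.var(axis=1, ddof=1)
        mean_m[:, i], var_m[:, i] = rm.mean(axis=1), rm.var(axis=1, ddof=1)
        n_p[i], n_m[i] = len(plus[i]), len(minus[i])

    diffs, pvals = _welch_pvalues(mean_p, var_p, n_p, mean_m, var_m, n_m)
    values = np.where(pvals <= alpha, diffs, 0.0)

    weights = np.empty((n_boot, M.n_neurons))
    for d in range(n_boot):
        if reselect_lambda:
            est = ElbowScreenLasso(**elbow_kwargs).fit(M.values, values[d])
            weights[d] = est.coef_
        else:
            weights[d] = ScreenLasso(alpha=lam).fit(M.values, values[d]).coef_
    scale = np.max(np.abs(weights), axis=1, keepdims=True)
    active = np.abs(weights) > SUPPORT_REL_TOL * np.where(scale > 0, scale, 1.0)
    sel = active.mean(axis=0)
    qs = np.percentile(weights, [2.5, 50.0, 97.5], axis=0)
    return BootstrapReport(neuron_ids=M.neuron_ids, median=qs[1], lo=qs[0],
                           hi=qs[2], selection_frequency=sel, lam=float(lam),
                           n_boot=n_boot, seed=seed)
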