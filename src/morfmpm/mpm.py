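"""Minimax probability machine (MPM) training, scoring and calibration.

The MPM finds the hyperplane W^T x = b minimizing the worst-case
misclassification probability over all class distributions with the given
means and covariances (mu_1, R_1), (mu_2, R_2). After fixing the scale of
W with the constraint W^T (mu_1 - mu_2) = 1, the problem is

    min_W  sqrt(W^T R_1 W) + sqrt(W^T R_2 W)   s.t.  W^T (mu_1 - mu_2) = 1,

a second-order-cone program solved here by iterative least squares: the
constraint is eliminated by the substitution W = w0 + F u (w0 the
minimum-norm solution, F an orthonormal null-space basis), and each
iteration minimizes the locally weighted quadratic
W^T R_1 W / g_1 + W^T R_2 W / g_2 with g_k the current norms. The margin
and offset follow from the optimum:

    kappa* = 1 / (sqrt(W^T R_1 W) + sqrt(W^T R_2 W)),
    b*     = W^T mu_2 + kappa* sqrt(W^T R_2 W)
           = W^T mu_1 - kappa* sqrt(W^T R_1 W),

and alpha = kappa^2 / (1 + kappa^2) lower-bounds the worst-case per-class
accuracy. Class 1 is the MoRF class; a residue is called MoRF when its
score W^T x - b exceeds the threshold (default 0).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from .io_formats import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_RIDGE = 1e-6
CONSTRAINT_TOL = 1e-8
DEFAULT_OBJECTIVE_TOL = 1e-9
DEFAULT_MAX_ITER = 1000


class ConvergenceError(RuntimeError):
    """Solver failed to converge; carries the last objective value."""

    def __init__(self, message: str, last_objective: float) -> None:
        super().__init__(message)
        self.last_objective = last_objective


@dataclass
class ClassStats:
    """Mean vector and ridge-regularized unbiased covariance of one class."""

    mu: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).ravel()
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        d = self.mu.size
        if self.R.shape != (d, d):
            raise ValidationError("covariance shape does not match mean")
        if not np.allclose(self.R, self.R.T, atol=1e-10):
            raise ValidationError("covariance must be symmetric")


@dataclass
class MPMModel:
    """A trained MPM: hyperplane, margin, and the preprocessing needed to
    apply it (per-column standardization, dropped columns, feature/window
    provenance). ``solve_mpm`` produces one with an identity standardizer;
    ``fit`` fills in the trained statistics."""

    W: np.ndarray
    b: float
    kappa: float
    mean: np.ndarray = None
    sd: np.ndarray = None
    kept_columns: np.ndarray = None
    feature_names: tuple = ()
    window_sizes: tuple = ()
    objective: float = float("nan")
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float).ravel()
        d = self.W.size
        if self.mean is None:
            self.mean = np.zeros(d)
        if self.sd is None:
            self.sd = np.ones(d)
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.sd = np.asarray(self.sd, dtype=float).ravel()
        if self.kept_columns is None:
            self.kept_columns = np.arange(d)
        self.kept_columns = np.asarray(self.kept_columns, dtype=int).ravel()

    @property
    def worst_case_misclassification(self) -> float:
        """Upper bound 1 - kappa^2/(1+kappa^2) on the per-class error of
        any distribution matching the training moments."""
        return 1.0 - self.kappa**2 / (1.0 + self.kappa**2)

    @property
    def n_input_columns(self) -> int:
        return int(self.kept_columns.max()) + 1 if self.kept_columns.size else 0

    def score(self, X: np.ndarray) -> np.ndarray:
        return score(self, X)

    def to_dict(self) -> dict:
        return {
            "W": self.W.tolist(),
            "b": self.b,
            "kappa": self.kappa,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "kept_columns": self.kept_columns.tolist(),
            "feature_names": list(self.feature_names),
            "window_sizes": list(self.window_sizes),
            "objective": self.objective,
            "n_iter": self.n_iter,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MPMModel":
        return cls(
            W=np.array(payload["W"], dtype=float),
            b=float(payload["b"]),
            kappa=float(payload["kappa"]),
            mean=np.array(payload["mean"], dtype=float),
            sd=np.array(payload["sd"], dtype=float),
            kept_columns=np.array(payload["kept_columns"], dtype=int),
            feature_names=tuple(payload.get("feature_names", ())),
            window_sizes=tuple(payload.get("window_sizes", ())),
            objective=float(payload.get("objective", float("nan"))),
            n_iter=int(payload.get("n_iter", 0)),
        )


def class_stats(X: np.ndarray, y: np.ndarray, ridge: float = DEFAULT_RIDGE) -> tuple:
    """Per-class means and unbiased covariances, ridge-regularized with
    delta = ridge * mean(diag(R)) (or ridge alone when the class is
    degenerate) so R + delta*I is always positive definite.

    Class 1 (y == 1) is the MoRF class and is returned first.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    if X.shape[0] != y.size:
        raise ValidationError("X and y disagree on the number of samples")
    out = []
    for cls in (1, 0):
        Xi = X[y == cls]
        if Xi.shape[0] < 2:
            raise ValidationError(
                f"class {cls} needs at least 2 samples, got {Xi.shape[0]}"
            )
        mu = Xi.mean(axis=0)
        R = np.cov(Xi, rowvar=False, ddof=1)
        R = np.atleast_2d(R)
        mean_diag = float(np.trace(R)) / R.shape[0]
        delta = ridge * (mean_diag if mean_diag > 0 else 1.0)
        out.append(ClassStats(mu=mu, R=R + delta * np.eye(R.shape[0])))
    return out[0], out[1]


def _norms(W: np.ndarray, R1: np.ndarray, R2: np.ndarray) -> tuple:
    g1 = float(np.sqrt(max(W @ R1 @ W, 0.0)))
    g2 = float(np.sqrt(max(W @ R2 @ W, 0.0)))
    return g1, g2


def solve_mpm(
    stats1: ClassStats,
    stats2: ClassStats,
    tol: float = DEFAULT_OBJECTIVE_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> MPMModel:
    """Solve the constrained sum-of-norms problem by iterative least
    squares and recover kappa and b from the optimum.

    Raises on an infeasible constraint (mu_1 == mu_2) or non-convergence.
    """
    mu1, R1 = stats1.mu, stats1.R
    mu2, R2 = stats2.mu, stats2.R
    a = mu1 - mu2
    a_norm2 = float(a @ a)
    if a_norm2 <= 1e-24:
        raise ValidationError("mu_1 == mu_2: the MPM constraint is infeasible")

    w0 = a / a_norm2  # minimum-norm solution of a^T W = 1
    F = null_space(a[None, :])  # d x (d-1) orthonormal basis of {W : a^T W = 0}

    W = w0.copy()
    g1, g2 = _norms(W, R1, R2)
    objective = g1 + g2
    n_iter = 0
    converged = F.shape[1] == 0  # 1-D problem: w0 is the only feasible point
    eps = 1e-15
    while not converged and n_iter < max_iter:
        G = R1 / max(g1, eps) + R2 / max(g2, eps)
        # minimize (w0 + F u)^T G (w0 + F u) over u
        lhs = F.T @ G @ F
        rhs = -(F.T @ (G @ w0))
        u = np.linalg.lstsq(lhs, rhs, rcond=None)[0]
        W = w0 + F @ u
        g1, g2 = _norms(W, R1, R2)
        new_objective = g1 + g2
        n_iter += 1
        if abs(objective - new_objective) <= tol * max(abs(objective), 1e-300):
            objective = new_objective
            converged = True
        else:
            objective = new_objective
    if not converged:
        raise ConvergenceError(
            f"iterative least squares did not converge in {max_iter} iterations",
            last_objective=objective,
        )

    residual = abs(float(W @ a) - 1.0)
    if residual > CONSTRAINT_TOL:
        raise ConvergenceError(
            f"constraint residual {residual:.3g} exceeds {CONSTRAINT_TOL}",
            last_objective=objective,
        )
    kappa = 1.0 / objective
    b_from_2 = float(W @ mu2) + kappa * g2
    b_from_1 = float(W @ mu1) - kappa * g1
    if abs(b_from_1 - b_from_2) > CONSTRAINT_TOL:
        raise ConvergenceError(
            f"offset expressions disagree by {abs(b_from_1 - b_from_2):.3g}",
            last_objective=objective,
        )
    model = MPMModel(
        W=W, b=b_from_2, kappa=kappa, objective=objective, n_iter=n_iter,
    )
    logger.debug(
        "MPM solved: kappa=%.4g, worst-case misclassification bound=%.4g",
        kappa, model.worst_case_misclassification,
    )
    return model


def fit(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: tuple = (),
    window_sizes: tuple = (),
    ridge: float = DEFAULT_RIDGE,
    tol: float = DEFAULT_OBJECTIVE_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> MPMModel:
    """Standardize columns, estimate class moments (class 1 = MoRF), solve,
    and package the model with its preprocessing.

    Zero-variance columns cannot be standardized and are dropped with a
    warning; their indices are recorded so scoring stays aligned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    if X.ndim != 2:
        raise ValidationError("X must be 2-D")
    sd_all = X.std(axis=0, ddof=0)
    kept = np.flatnonzero(sd_all > 0)
    if kept.size == 0:
        raise ValidationError("all feature columns are constant")
    if kept.size < X.shape[1]:
        dropped = sorted(set(range(X.shape[1])) - set(kept.tolist()))
        logger.warning("dropping constant feature column(s) %s", dropped)
    mean = X[:, kept].mean(axis=0)
    sd = sd_all[kept]
    Z = (X[:, kept] - mean) / sd
    stats1, stats2 = class_stats(Z, y, ridge=ridge)
    model = solve_mpm(stats1, stats2, tol=tol, max_iter=max_iter)
    model.mean = mean
    model.sd = sd
    model.kept_columns = kept
    model.feature_names = tuple(feature_names)
    model.window_sizes = tuple(window_sizes)
    return model


def score(model: MPMModel, X: np.ndarray) -> np.ndarray:
    """Per-row scores s = W^T z - b on standardized features; the MoRF
    call is s > threshold (default threshold 0)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.kept_columns.size and X.shape[1] <= model.kept_columns.max():
        raise ValidationError(
            f"model expects at least {model.n_input_columns} feature columns, "
            f"got {X.shape[1]}"
        )
    Z = (X[:, model.kept_columns] - model.mean) / model.sd
    return Z @ model.W - model.b


def calibrate_thresholds(scores: np.ndarray, labels: np.ndarray, fpr_targets) -> dict:
    """For each target FPR, the smallest threshold whose achieved FPR
    (with the strict ``score > threshold`` call rule) does not exceed it.

    Returns ``{target: (threshold, achieved_tpr, achieved_fpr)}``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).ravel()
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    neg = scores[labels == 0]
    pos = scores[labels == 1]
    if neg.size == 0:
        raise ValidationError("threshold calibration needs negative residues")
    candidates = np.concatenate(([scores.min() - 1.0], np.unique(scores)))
    neg_sorted = np.sort(neg)
    pos_sorted = np.sort(pos)
    # achieved rates at each candidate threshold, via rank lookups
    fprs = (neg.size - np.searchsorted(neg_sorted, candidates, side="right")) / neg.size
    out = {}
    for target in fpr_targets:
        if not (0 <= target <= 1):
            raise ValidationError(f"FPR target {target} outside [0, 1]")
        idx = int(np.argmax(fprs <= target))  # fprs is non-increasing; first hit
        t = float(candidates[idx])
        tpr = (
            float((pos.size - np.searchsorted(pos_sorted, t, side="right")) / pos.size)
            if pos.size else float("nan")
        )
        out[float(target)] = (t, tpr, float(fprs[idx]))
    return out
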