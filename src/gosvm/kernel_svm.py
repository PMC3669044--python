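"""Radial-basis kernel SVM with class-imbalance diagonal augmentation.

The classifier works entirely in the dual on a precomputed kernel.  The RBF
width σ is set heuristically to the median, over positive training points,
of the Euclidean distance to each one's nearest negative training point.
Class imbalance is countered by augmenting each training point's kernel
self-similarity by λ·|C|/N (|C| the size of the point's class, N the
training-set size, λ = m/2 with m the median of the pre-augmentation
diagonal).  The augmentation realizes a 2-norm soft margin with
class-dependent regularization, so the dual is a *hard-margin* problem on
the augmented kernel: nonnegative multipliers with no upper box constraint.
Cross-kernel blocks used for prediction are never augmented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

SUPPORT_TOL = 1e-8  # relative threshold for support-vector membership


class SvmConvergenceError(RuntimeError):
    """Solver failed to satisfy the KKT conditions; carries the residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (KKT residual {residual:.3e})")
        self.residual = residual


@dataclass
class KernelMatrix:
    """A kernel block with its construction metadata.

    ``lam``/``m``/``class_sizes`` are populated once the training diagonal
    has been augmented; ``augmented`` distinguishes the two states.
    """

    values: np.ndarray
    sigma: float
    lam: float | None = None
    m: float | None = None
    class_sizes: tuple[int, int] | None = None
    augmented: bool = False


@dataclass
class SvmModel:
    """Dual SVM solution: f(x) = Σ_i α_i y_i K(x, x_i) + b."""

    alphas: np.ndarray
    bias: float
    labels: np.ndarray
    support_indices: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        amax = float(self.alphas.max()) if self.alphas.size else 0.0
        self.support_indices = np.flatnonzero(self.alphas > SUPPORT_TOL * max(amax, 1e-300))


def sigma_heuristic(X: np.ndarray, labels: np.ndarray) -> float:
    """Median over positives of the distance to the nearest negative.

    With an even number of positives the median is the mean of the two
    central values.  If the median is zero (a positive coincides with a
    negative) the smallest strictly positive nearest-neighbour distance is
    used instead; if every distance is zero the heuristic is undefined.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    pos = X[y > 0]
    neg = X[y < 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("sigma heuristic needs both classes")
    nearest = cdist(pos, neg).min(axis=1)
    sigma = float(np.median(nearest))
    if sigma == 0.0:
        nonzero = nearest[nearest > 0]
        if nonzero.size == 0:
            raise ValueError("all positive points coincide with negatives; sigma undefined")
        sigma = float(nonzero.min())
    return sigma


def rbf_kernel(X_a: np.ndarray, X_b: np.ndarray, sigma: float) -> np.ndarray:
    """K(x, y) = exp(−‖x−y‖² / σ²)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    sq = cdist(np.atleast_2d(X_a), np.atleast_2d(X_b), metric="sqeuclidean")
    return np.exp(-sq / (sigma * sigma))


def augment_diagonal(kernel: KernelMatrix, labels: np.ndarray) -> KernelMatrix:
    """Add λ·|C|/N to each training point's diagonal entry.

    m is the median of the pre-augmentation diagonal (1 for RBF) and λ = m/2.
    Off-diagonal entries are untouched.
    """
    K = np.asarray(kernel.values, dtype=float)
    y = np.asarray(labels)
    n = K.shape[0]
    if K.shape[0] != K.shape[1]:
        raise ValueError("augmentation applies to a square training kernel")
    if y.shape[0] != n:
        raise ValueError("labels length does not match kernel size")
    n_pos = int((y > 0).sum())
    n_neg = n - n_pos
    m = float(np.median(np.diag(K)))
    lam = m / 2.0
    class_size = np.where(y > 0, n_pos, n_neg)
    K_aug = K.copy()
    K_aug[np.diag_indices(n)] += lam * class_size / n
    return KernelMatrix(
        values=K_aug, sigma=kernel.sigma, lam=lam, m=m,
        class_sizes=(n_pos, n_neg), augmented=True,
    )


def train_svm(
    kernel: KernelMatrix | np.ndarray,
    labels: np.ndarray,
    *,
    max_iter: int = 1000,
    kkt_tol: float = 1e-6,
) -> SvmModel:
    """Solve the hard-margin dual on the augmented kernel by active sets.

    maximize Σα − ½ ΣΣ α_i α_j y_i y_j K(i,j),  α ≥ 0,  Σ α_i y_i = 0.

    Because the augmented kernel is strictly positive definite the dual is
    strictly concave and the active-set iteration (drop the most negative
    free multiplier, add the most violated margin) terminates at the unique
    KKT point.  The bias is the average of y_i − Σ_j α_j y_j K(i, j) over
    support vectors.
    """
    K = kernel.values if isinstance(kernel, KernelMatrix) else np.asarray(kernel, float)
    y = np.asarray(labels, dtype=float)
    n = y.size
    if K.shape != (n, n):
        raise ValueError("kernel/labels size mismatch")
    if not ((y > 0).any() and (y < 0).any()):
        raise ValueError("both classes required")
    Q = K * np.outer(y, y)
    free = np.ones(n, dtype=bool)
    alpha = np.zeros(n)
    bias = 0.0
    for _ in range(max_iter):
        idx = np.flatnonzero(free)
        k = idx.size
        A = np.empty((k + 1, k + 1))
        A[:k, :k] = Q[np.ix_(idx, idx)]
        A[:k, k] = y[idx]
        A[k, :k] = y[idx]
        A[k, k] = 0.0
        rhs = np.zeros(k + 1)
        rhs[:k] = 1.0
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        a_free, bias = sol[:k], float(sol[k])
        if a_free.min() < -1e-10:
            free[idx[int(np.argmin(a_free))]] = False
            continue
        alpha = np.zeros(n)
        alpha[idx] = np.clip(a_free, 0.0, None)
        margins = Q @ alpha + y * bias  # y_i f(x_i)
        outside = np.flatnonzero(~free)
        if outside.size and margins[outside].min() < 1.0 - 1e-10:
            free[outside[int(np.argmin(margins[outside]))]] = True
            continue
        break
    else:
        resid = _kkt_residual(Q, y, alpha, bias)
        raise SvmConvergenceError("active-set iteration cap reached", resid)

    model = SvmModel(alphas=alpha, bias=bias, labels=y)
    # average the bias over support vectors (y_i f(x_i) = 1 on each)
    sv = model.support_indices
    if sv.size:
        model.bias = float(np.mean(y[sv] - (K[np.ix_(sv, np.arange(n))] @ (alpha * y))))
    resid = _kkt_residual(Q, y, alpha, model.bias)
    if resid > kkt_tol:
        raise SvmConvergenceError("solution violates KKT conditions", resid)
    return model


def _kkt_residual(Q: np.ndarray, y: np.ndarray, alpha: np.ndarray, bias: float) -> float:
    margins = Q @ alpha + y * bias
    active = alpha > SUPPORT_TOL * max(float(alpha.max()), 1e-300)
    r_eq = abs(float(alpha @ y))
    r_sv = float(np.abs(margins[active] - 1.0).max()) if active.any() else 0.0
    r_margin = float(np.clip(1.0 - margins[~active], 0.0, None).max()) if (~active).any() else 0.0
    return max(r_eq, r_sv, r_margin)


def dual_objective(kernel: KernelMatrix | np.ndarray, labels: np.ndarray, alphas: np.ndarray) -> float:
    """Σα − ½ αᵀ (yyᵀ ∘ K) α, the quantity the dual maximizes."""
    K = kernel.values if isinstance(kernel, KernelMatrix) else np.asarray(kernel, float)
    y = np.asarray(labels, dtype=float)
    Q = K * np.outer(y, y)
    return float(alphas.sum() - 0.5 * alphas @ Q @ alphas)


def discriminants(model: SvmModel, K_cross: np.ndarray) -> np.ndarray:
    """f(x) = Σ_i α_i y_i K(x, x_i) + b for each cross-kernel row.

    ``K_cross`` is test × train on the *un-augmented* kernel: augmentation
    affects only training self-similarities.
    """
    K_cross = np.atleast_2d(np.asarray(K_cross, dtype=float))
    if K_cross.shape[1] != model.alphas.size:
        raise ValueError("cross-kernel columns must index the training set")
    return K_cross @ (model.alphas * model.labels) + model.bias
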