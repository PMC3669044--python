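"""Sigmoid calibration of SVM discriminant values into posterior probabilities.

The posterior model is p(y=1 | x) = 1 / (1 + exp(a·f(x) + b)).  Under this
parameterization a is *negative* when larger discriminants mean the positive
class.  The parameters are fitted by maximum likelihood against smoothed
targets t = (N₊+1)/(N₊+2) for positives and t = 1/(N₋+2) for negatives —
the smoothing keeps the objective well-conditioned even when the calibration
fold is perfectly separated.  The optimizer is a damped Newton iteration on
the cross-entropy written in an overflow-safe log1p/exp form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GRAD_TOL = 1e-8
MAX_ITER = 100


@dataclass(frozen=True)
class CalibrationTargets:
    """Smoothed regression targets for the calibration fold."""

    t: np.ndarray
    n_pos: int
    n_neg: int


@dataclass
class SigmoidFit:
    """Fitted sigmoid parameters; p(f) = 1/(1+exp(a·f + b))."""

    a: float
    b: float
    converged: bool
    final_nll: float


def platt_targets(labels: np.ndarray) -> CalibrationTargets:
    """Targets (N₊+1)/(N₊+2) for y=+1 and 1/(N₋+2) for y=−1."""
    y = np.asarray(labels)
    n_pos = int((y > 0).sum())
    n_neg = int((y < 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("calibration fold must contain both classes")
    t_pos = (n_pos + 1.0) / (n_pos + 2.0)
    t_neg = 1.0 / (n_neg + 2.0)
    t = np.where(y > 0, t_pos, t_neg)
    return CalibrationTargets(t=t, n_pos=n_pos, n_neg=n_neg)


def _nll_grad_hess(f: np.ndarray, t: np.ndarray, a: float, b: float):
    """Cross-entropy, gradient and Hessian in (a, b); stable for large |z|."""
    z = a * f + b
    # nll_i = log(1+e^z) − (1−t) z, folded to avoid overflow
    nll = float(np.sum(np.where(z > 0, t * z + np.log1p(np.exp(-np.abs(z))),
                                (t - 1.0) * z + np.log1p(np.exp(-np.abs(z))))))
    p = np.empty_like(z)  # p = sigmoid(−z)
    hi = z >= 0
    ez = np.exp(-z[hi])
    p[hi] = ez / (1.0 + ez)
    ez = np.exp(z[~hi])
    p[~hi] = 1.0 / (1.0 + ez)
    d = t - p
    grad = np.array([float(d @ f), float(d.sum())])
    w = p * (1.0 - p)
    hess = np.array([[float(w @ (f * f)), float(w @ f)],
                     [float(w @ f), float(w.sum())]])
    return nll, grad, hess


def fit_sigmoid(f: np.ndarray, targets: CalibrationTargets) -> SigmoidFit:
    """Newton fit of (a, b) with backtracking line search.

    Starts at a=0, b=log((N₋+1)/(N₊+1)).  Accepted steps strictly decrease
    the objective; iteration stops when the gradient norm falls below 1e−8
    or after 100 iterations (flagged unconverged, best iterate returned).
    """
    f = np.asarray(f, dtype=float)
    if f.size < 2:
        raise ValueError("need at least two discriminant values")
    if np.ptp(f) == 0.0:
        raise ValueError("all discriminant values identical; slope is unidentifiable")
    t = np.asarray(targets.t, dtype=float)
    if t.shape != f.shape:
        raise ValueError("targets/discriminants length mismatch")

    a, b = 0.0, float(np.log((targets.n_neg + 1.0) / (targets.n_pos + 1.0)))
    nll, grad, hess = _nll_grad_hess(f, t, a, b)
    converged = False
    for _ in range(MAX_ITER):
        if np.hypot(*grad) <= GRAD_TOL:
            converged = True
            break
        # damped Newton direction; tiny ridge guards near-singular Hessians
        try:
            step = np.linalg.solve(hess + 1e-12 * np.eye(2), -grad)
        except np.linalg.LinAlgError:
            step = -grad
        # near the minimum the objective decrease falls below roundoff while
        # the gradient still shrinks quadratically, so accept steps that do
        # not increase the objective beyond numerical noise
        noise = 1e-12 * max(1.0, abs(nll))
        stepsize = 1.0
        improved = False
        for _bt in range(50):
            a_new, b_new = a + stepsize * step[0], b + stepsize * step[1]
            nll_new, grad_new, hess_new = _nll_grad_hess(f, t, a_new, b_new)
            if nll_new <= nll + noise:
                moved = (a_new != a) or (b_new != b)
                a, b, nll, grad, hess = a_new, b_new, nll_new, grad_new, hess_new
                improved = moved
                break
            stepsize *= 0.5
        if not improved:
            converged = np.hypot(*grad) <= GRAD_TOL
            break
    else:
        converged = np.hypot(*grad) <= GRAD_TOL
    return SigmoidFit(a=a, b=b, converged=bool(converged), final_nll=nll)


def apply_sigmoid(fit: SigmoidFit, f: np.ndarray) -> np.ndarray:
    """Elementwise p = 1/(1+exp(a·f + b)); values lie strictly in (0, 1)."""
    z = fit.a * np.asarray(f, dtype=float) + fit.b
    out = np.empty_like(z, dtype=float)
    hi = z >= 0
    ez = np.exp(-z[hi])
    out[hi] = ez / (1.0 + ez)
    ez = np.exp(z[~hi])
    out[~hi] = 1.0 / (1.0 + ez)
    tiny = np.finfo(float).tiny
    return np.clip(out, tiny, 1.0 - np.finfo(float).epsneg)
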