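"""Independent brute-force oracles used to validate the estimators.

These deliberately avoid the package's Newton machinery: the joint
likelihood is maximized by multi-resolution coordinate-wise grid search,
and score equations are solved by dense scanning, so agreement with the
package is evidence about the estimators rather than a tautology.
"""
from __future__ import annotations

import numpy as np


def binary_loglik(X: np.ndarray, theta: np.ndarray, b: np.ndarray) -> float:
    """Joint dichotomous Rasch log-likelihood for complete binary data."""
    eta = theta[:, None] - b[None, :]
    return float(
        np.sum(np.where(X == 1, -np.logaddexp(0.0, -eta), -np.logaddexp(0.0, eta)))
    )


def grid_jmle(
    X: np.ndarray,
    *,
    span: float = 10.0,
    final_step: float = 5e-5,
) -> tuple[np.ndarray, np.ndarray]:
    """Maximize the joint likelihood by coordinate-wise grid refinement.

    Scans each person and item parameter over a lattice centered on its
    current value, halving-by-five the lattice step down to
    ``final_step`` (effectively a [-span, span] grid search at that
    resolution), then centers item difficulties to mean zero.
    """
    X = np.asarray(X, dtype=float)
    n, i_ = X.shape
    theta = np.zeros(n)
    b = np.zeros(i_)
    step = 1.0
    offsets = np.arange(-10, 11)
    while True:
        moved = True
        while moved:
            moved = False
            for p in range(n):
                grid = np.clip(theta[p] + step * offsets, -span, span)
                eta = grid[:, None] - b[None, :]
                ll = np.where(
                    X[p][None, :] == 1,
                    -np.logaddexp(0.0, -eta),
                    -np.logaddexp(0.0, eta),
                ).sum(axis=1)
                best = grid[np.argmax(ll)]
                if best != theta[p]:
                    theta[p] = best
                    moved = True
            for j in range(i_):
                grid = np.clip(b[j] + step * offsets, -span, span)
                eta = theta[:, None] - grid[None, :]
                ll = np.where(
                    X[:, j][:, None] == 1,
                    -np.logaddexp(0.0, -eta),
                    -np.logaddexp(0.0, eta),
                ).sum(axis=0)
                best = grid[np.argmax(ll)]
                if best != b[j]:
                    b[j] = best
                    moved = True
        if step <= final_step:
            break
        step /= 5.0
    center = b.mean()
    return theta - center, b - center


def scan_score_equation(
    b: np.ndarray,
    tau: np.ndarray,
    target: float,
    *,
    lo: float = -12.0,
    hi: float = 12.0,
    step: float = 1e-4,
) -> float:
    """Dense scan for the theta whose expected score is closest to target."""
    from scipy.special import expit

    grid = np.arange(lo, hi + step, step)
    best_theta = np.nan
    best_err = np.inf
    for chunk in np.array_split(grid, max(1, grid.size // 200_000)):
        expected = expit(
            chunk[:, None, None] - b[None, :, None] - tau[None, None, :]
        ).sum(axis=(1, 2))
        err = np.abs(expected - target)
        k = int(np.argmin(err))
        if err[k] < best_err:
            best_err = float(err[k])
            best_theta = float(chunk[k])
    return best_theta


def scan_binary_score_equation(
    b: np.ndarray, target: float, *, step: float = 1e-5
) -> float:
    """Dense scan of the dichotomous person score equation."""
    return scan_score_equation(
        np.asarray(b, dtype=float), np.zeros(1), target, step=step
    )
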