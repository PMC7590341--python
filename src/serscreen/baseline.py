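"""Adaptive iteratively reweighted penalized least-squares (AirPLS) baseline removal.

SERS spectra of food extracts ride on a large fluorescence background
that the nanoparticle substrate amplifies together with the analyte
signal.  AirPLS estimates that background as the smooth curve ``z``
minimizing a weighted least-squares fit to the spectrum plus a
roughness penalty, then re-weights iteratively: points lying *above*
the current baseline are treated as signal (weight 0) while points
below it pull the baseline down with exponentially growing weights.
The inner solve is a Whittaker smoother — the penalized normal
equations ``(W + lam * D'D) z = W y`` with ``D`` the k-th order finite
difference operator — solved here in symmetric banded form (bandwidth
k), which keeps a 1,024-channel correction essentially instantaneous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import solveh_banded

__all__ = [
    "AirplsConfig",
    "BaselineFit",
    "DegenerateSystemError",
    "whittaker_smooth",
    "airpls_baseline",
]


class DegenerateSystemError(ValueError):
    """The penalized least-squares system has no unique solution."""


@dataclass(frozen=True)
class AirplsConfig:
    """Controls for the AirPLS iteration.

    lam
        Smoothness penalty; larger values give stiffer baselines.
    max_iter
        Iteration cap; the loop may stop earlier on the tolerance.
    tol_ratio
        Stop once the mass of negative residuals falls below this
        fraction of the total absolute signal.
    diff_order
        Order of the finite-difference roughness penalty (1 or 2).
    endpoint_weighting
        "exp": the two endpoints get weight exp(t*max|d-|/s) each
        iteration, anchoring the baseline at the spectrum edges;
        "zero": endpoints are treated like any other point.
    """

    lam: float = 100.0
    max_iter: int = 15
    tol_ratio: float = 0.001
    diff_order: int = 2
    endpoint_weighting: str = "exp"

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not (0 < self.tol_ratio < 1):
            raise ValueError("tol_ratio must be in (0, 1)")
        if self.diff_order not in (1, 2):
            raise ValueError("diff_order must be 1 or 2")
        if self.endpoint_weighting not in ("exp", "zero"):
            raise ValueError("endpoint_weighting must be 'exp' or 'zero'")


@dataclass
class BaselineFit:
    """Result of an AirPLS run: baseline, corrected signal, diagnostics."""

    baseline: np.ndarray
    corrected: np.ndarray
    n_iter: int
    converged: bool
    residual_negative_mass: float
    weights_history: list = field(default_factory=list, repr=False)


def _difference_penalty(n: int, diff_order: int) -> sp.spmatrix:
    d = sp.eye(n, format="csc")
    for _ in range(diff_order):
        d = d[1:] - d[:-1]
    return (d.T @ d).tocsc()


def whittaker_smooth(
    y: np.ndarray, w: np.ndarray, lam: float, diff_order: int = 2
) -> np.ndarray:
    """Solve the weighted Whittaker smoother.

    Returns the ``z`` minimizing ``sum_i w_i (y_i - z_i)^2 +
    lam * sum_j ((D^k z)_j)^2`` via the banded Cholesky solve of
    ``(W + lam * D'D) z = W y``.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    n = len(y)
    if len(w) != n:
        raise ValueError(f"weight length {len(w)} != signal length {n}")
    if n < diff_order + 1:
        raise ValueError(f"need at least {diff_order + 1} points, got {n}")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(w)):
        raise ValueError("non-finite input to whittaker_smooth")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if not np.any(w > 0):
        raise DegenerateSystemError("all weights zero: baseline undetermined")

    a = sp.diags(w) + lam * _difference_penalty(n, diff_order)
    a = a.tocsc()
    # upper banded storage for solveh_banded: ab[k-d, d:] holds superdiagonal d
    k = diff_order
    ab = np.zeros((k + 1, n))
    for d in range(k + 1):
        ab[k - d, d:] = a.diagonal(d)
    try:
        return solveh_banded(ab, w * y, lower=False)
    except np.linalg.LinAlgError as exc:  # too few anchored points for the penalty order
        raise DegenerateSystemError(f"singular penalized system: {exc}") from exc


def airpls_baseline(y: np.ndarray, cfg: AirplsConfig = AirplsConfig()) -> BaselineFit:
    """Estimate and subtract a baseline by adaptive iterative reweighting.

    Weights start at 1 everywhere.  Each iteration fits the Whittaker
    baseline ``z``, forms the residual ``d = y - z`` and the negative
    residual mass ``s = sum |d[d < 0]|``; the loop stops when ``s``
    drops below ``tol_ratio * sum|y|`` (converged) or at ``max_iter``.
    Otherwise points at or above the baseline get weight 0 and points
    below get ``exp(t * |d_i| / s)``, endpoints per the config.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite input to airpls_baseline")
    n = len(y)
    w = np.ones(n)
    abs_total = np.abs(y).sum()
    z = np.zeros(n)
    s = np.inf
    converged = False
    history: list[np.ndarray] = []

    t = 0
    for t in range(1, cfg.max_iter + 1):
        history.append(w.copy())
        z = whittaker_smooth(y, w, cfg.lam, cfg.diff_order)
        d = y - z
        neg = d < 0
        s = float(np.abs(d[neg]).sum())
        if s == 0.0 or s < cfg.tol_ratio * abs_total:
            converged = True
            break
        if t == cfg.max_iter:
            break
        w = np.zeros(n)
        w[neg] = np.exp(t * np.abs(d[neg]) / s)
        if cfg.endpoint_weighting == "exp":
            peak_w = np.exp(t * np.abs(d[neg]).max() / s)
            w[0] = peak_w
            w[-1] = peak_w

    return BaselineFit(
        baseline=z,
        corrected=y - z,
        n_iter=t,
        converged=converged,
        residual_negative_mass=s,
        weights_history=history,
    )
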