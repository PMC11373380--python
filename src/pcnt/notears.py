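"""Linear-SEM structure learning by continuous acyclicity-constrained optimization.

Minimizes the penalized least-squares score

    (1/2n) ||X - XW||_F^2 + lambda1 ||W||_1

subject to the smooth acyclicity constraint h(W) = tr(exp(W o W)) - d = 0,
solved with an augmented Lagrangian whose bound-constrained subproblems use
L-BFGS-B on the split W = W+ - W-. A boolean edge mask (e.g. derived from a
PC-learned CPDAG) restricts the support: forbidden entries are held exactly
at zero by fixing their bounds, so constraint satisfaction is structural,
not approximate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.optimize as sopt

from .graph import (
    CPDAG,
    ConstraintMask,
    ExpressionMatrix,
    WeightedGraph,
    break_cycles_by_weight,
    threshold_graph,
)

logger = logging.getLogger(__name__)


@dataclass
class NotearsConfig:
    """Tuning parameters of the augmented-Lagrangian solver.

    lambda1: L1 penalty on the weights (sparsity).
    max_dual_iter: cap on outer dual updates.
    h_tol: acyclicity tolerance declaring convergence.
    rho_max: cap on the quadratic penalty before giving up.
    w_threshold: final pruning of small weights; kept deliberately small
        because top-k edge selection downstream does the real sparsification.
    lbfgs_maxiter: iteration cap for each L-BFGS-B subproblem.
    """

    lambda1: float = 0.1
    max_dual_iter: int = 100
    h_tol: float = 1e-8
    rho_max: float = 1e16
    w_threshold: float = 0.05
    lbfgs_maxiter: int = 1000

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.w_threshold < 0:
            raise ValueError("lambda1 and w_threshold must be non-negative")
        if self.h_tol <= 0 or self.rho_max <= 0 or self.max_dual_iter < 1:
            raise ValueError("h_tol, rho_max, max_dual_iter must be positive")


def acyclicity_h(W: np.ndarray) -> tuple[float, np.ndarray]:
    """Smooth acyclicity measure h(W) = tr(exp(W o W)) - d and its gradient.

    h is zero exactly when the support of W is acyclic; the gradient is
    exp(W o W)^T o 2W.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {W.shape}")
    with np.errstate(over="ignore", invalid="ignore"):
        E = sla.expm(W * W)
    if not np.isfinite(E).all():
        # overflow during a line-search trial step: report a huge finite
        # constraint value so the step is rejected without NaN propagation
        return 1e12, 2.0 * W
    h = float(np.trace(E)) - W.shape[0]
    grad = E.T * (2.0 * W)
    return h, grad


def least_squares_loss(W: np.ndarray, x: ExpressionMatrix) -> tuple[float, np.ndarray]:
    """Half mean squared residual of X - XW and its gradient in W."""
    X = x.values
    n, d = X.shape
    if W.shape != (d, d):
        raise ValueError(f"W shape {W.shape} does not match {d} genes")
    R = X - X @ W
    loss = 0.5 / n * float((R * R).sum())
    grad = -1.0 / n * X.T @ R
    return loss, grad


def build_constraint_mask(c: CPDAG) -> ConstraintMask:
    """Translate a CPDAG into hard edge permissions.

    A directed edge i -> j permits only that direction; an undirected edge
    permits both (the optimizer resolves the orientation); a non-adjacent
    pair permits neither.
    """
    amat = c.amat
    allowed = (amat == 1)
    np.fill_diagonal(allowed, False)
    return ConstraintMask(allowed)


@dataclass
class NotearsFit:
    """Solver output: the pruned graph plus convergence diagnostics."""

    graph: WeightedGraph
    W_raw: np.ndarray
    h_final: float
    rho_final: float
    n_dual_iter: int
    converged: bool
    objective: float
    #: per accepted subproblem: (objective at warm start, objective at solution)
    objective_trace: list[tuple[float, float]] = field(default_factory=list)


def fit_notears(
    x: ExpressionMatrix,
    mask: ConstraintMask | None = None,
    cfg: NotearsConfig | None = None,
) -> NotearsFit:
    """Solve the constrained NOTEARS program on (standardized) data.

    Entries where ``mask`` is false are excluded from the optimization by
    zero bounds on both halves of the split, so they are exactly zero in the
    output. With no mask only the diagonal is excluded.
    """
    cfg = cfg or NotearsConfig()
    d = x.n_genes
    if mask is not None and mask.n_genes != d:
        raise ValueError("mask dimension does not match data")
    allowed = mask.allowed if mask is not None else ~np.eye(d, dtype=bool)

    if not allowed.any():
        return NotearsFit(
            graph=WeightedGraph(np.zeros((d, d)), list(x.gene_ids)),
            W_raw=np.zeros((d, d)),
            h_final=0.0,
            rho_final=1.0,
            n_dual_iter=0,
            converged=True,
            objective=least_squares_loss(np.zeros((d, d)), x)[0],
        )

    free = allowed.ravel()
    bounds = [(0.0, None) if f else (0.0, 0.0) for f in free] * 2

    def unpack(theta: np.ndarray) -> np.ndarray:
        return (theta[: d * d] - theta[d * d :]).reshape(d, d)

    # Gram form of the least-squares score: for n >> d this makes each
    # objective evaluation O(d^3) instead of O(n d^2)
    n = x.n_samples
    S = x.values.T @ x.values / n
    tr_S = float(np.trace(S))

    def gram_loss(W: np.ndarray) -> tuple[float, np.ndarray]:
        SW = S @ W
        loss = 0.5 * (tr_S - 2.0 * float(np.trace(SW)) + float((W * SW).sum()))
        return loss, SW - S

    rho, dual_alpha, h_val = 1.0, 0.0, np.inf
    theta = np.zeros(2 * d * d)
    objective_trace: list[tuple[float, float]] = []
    n_iter = 0
    converged = False

    for n_iter in range(1, cfg.max_dual_iter + 1):

        def objective(t: np.ndarray) -> tuple[float, np.ndarray]:
            W = unpack(t)
            loss, g_loss = gram_loss(W)
            h, g_h = acyclicity_h(W)
            obj = loss + 0.5 * rho * h * h + dual_alpha * h + cfg.lambda1 * t.sum()
            gW = g_loss + (rho * h + dual_alpha) * g_h
            g = np.concatenate([gW.ravel(), -gW.ravel()]) + cfg.lambda1
            return obj, g

        h_old = h_val
        while True:
            start_obj = objective(theta)[0]
            sol = sopt.minimize(
                objective,
                theta,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": cfg.lbfgs_maxiter},
            )
            theta_new = sol.x
            h_val, _ = acyclicity_h(unpack(theta_new))
            if h_val > 0.25 * h_old and rho < cfg.rho_max:
                rho *= 10.0
            else:
                break
        theta = theta_new
        objective_trace.append((float(start_obj), float(sol.fun)))
        dual_alpha += rho * h_val
        if h_val <= cfg.h_tol:
            converged = True
            break
        if rho >= cfg.rho_max:
            break

    if not converged:
        warnings.warn(
            f"augmented Lagrangian stopped with h={h_val:.3e} > h_tol="
            f"{cfg.h_tol:.0e} (rho={rho:.1e}); returning best iterate",
            stacklevel=2,
        )

    W_raw = unpack(theta)
    # Long cycles of near-threshold weights contribute less to h(W) than
    # h_tol can detect (a k-cycle of weights w adds about (w^2)^k/(k-1)!),
    # so a converged solution may still be cyclic after small-weight pruning;
    # deleting the weakest edge per cycle restores the DAG invariant while
    # touching only edges the optimizer already drove near zero.
    graph = threshold_graph(WeightedGraph(W_raw.copy(), list(x.gene_ids)), cfg.w_threshold)
    graph = break_cycles_by_weight(graph)
    loss_final = least_squares_loss(W_raw, x)[0]
    return NotearsFit(
        graph=graph,
        W_raw=W_raw,
        h_final=h_val,
        rho_final=rho,
        n_dual_iter=n_iter,
        converged=converged,
        objective=loss_final,
        objective_trace=objective_trace,
    )
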