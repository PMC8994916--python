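"""ADMM solver for the penalized mark-pair likelihood.

The objective

    min_{Z >= 0}  -log L(Z, G) + lambda1 ||Z||_* + lambda2 ||Z||_1

is split with two auxiliary copies Z1 (nuclear block) and Z2 (L1 block) and
solved by scaled-dual ADMM:

    Z   <- argmin_{Z>=0} -log L(Z) + rho/2 (||Z - Z1 + U1||^2 + ||Z - Z2 + U2||^2)
    Z1  <- SVD soft-threshold of (Z + U1) at lambda1/rho
    Z2  <- entrywise soft-threshold of (Z + U2) at lambda2/rho
    U1  <- U1 + Z - Z1 ;  U2 <- U2 + Z - Z2

The Z block has no closed form and is solved by projected gradient descent
with Armijo backtracking, warm-started across outer iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datamodel import ContactRecords, MarkAssignment, MarkPairMatrix
from .model import (
    BinnedDataTerm,
    ObjectiveSpec,
    UnbinnedDataTerm,
    penalty_value,
)

logger = logging.getLogger(__name__)


class DivergenceError(RuntimeError):
    """ADMM residuals grew persistently instead of contracting."""


@dataclass
class ADMMState:
    """Solver state and diagnostics after :func:`admm_fit`."""

    Z: np.ndarray
    Z1: np.ndarray
    Z2: np.ndarray
    U1: np.ndarray
    U2: np.ndarray
    rho: float
    iterations: int = 0
    primal_residual: float = np.inf
    dual_residual: float = np.inf
    converged: bool = False
    objective_trace: list[float] = field(default_factory=list)

    def diagnostics(self) -> dict:
        Z = self.Z
        return {
            "iterations": self.iterations,
            "converged": self.converged,
            "primal_residual": float(self.primal_residual),
            "dual_residual": float(self.dual_residual),
            "rho": self.rho,
            "objective": self.objective_trace[-1] if self.objective_trace else None,
            "rank": int(np.linalg.matrix_rank(Z, tol=1e-8)),
            "nnz": int(np.sum(np.abs(Z) > 1e-8)),
            "objective_trace": [float(v) for v in self.objective_trace],
        }


# ---------------------------------------------------------------------------
# proximal operators


def nuclear_prox(Q: np.ndarray, alpha: float) -> np.ndarray:
    """argmin_Y alpha*||Y||_* + 1/2 ||Y - Q||_F^2  (singular-value shrinkage)."""
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    Q = np.asarray(Q, dtype=float)
    if alpha == 0:
        return Q.copy()
    U, s, Vt = np.linalg.svd(Q, full_matrices=False)
    return (U * np.maximum(s - alpha, 0.0)) @ Vt


def l1_prox(Q: np.ndarray, tau: float) -> np.ndarray:
    """Entrywise soft-threshold: 0 inside the dead zone |q| < tau, else shrink."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    Q = np.asarray(Q, dtype=float)
    return np.sign(Q) * np.maximum(np.abs(Q) - tau, 0.0)


# ---------------------------------------------------------------------------
# projected gradient with Armijo backtracking


def _project_nonneg(Z: np.ndarray) -> np.ndarray:
    return np.maximum(Z, 0.0)


def _projected_gradient(
    value_and_grad,
    Z0: np.ndarray,
    max_iter: int = 200,
    grad_tol: float = 1e-6,
    max_halvings: int = 50,
    armijo_c: float = 1e-4,
    project=_project_nonneg,
) -> np.ndarray:
    """Minimize a smooth function over a box (default: nonnegative orthant).

    Accepts a step when the Armijo sufficient-decrease condition holds;
    halves the step otherwise.  Never returns a point with a larger
    objective than the start.
    """
    Z = project(np.asarray(Z0, dtype=float))
    f, g = value_and_grad(Z)
    step = 1.0
    for _ in range(max_iter):
        # projected-gradient optimality measure
        if np.linalg.norm(Z - project(Z - g)) <= grad_tol * max(
            1.0, np.linalg.norm(Z)
        ):
            break
        accepted = False
        t = step
        for _ in range(max_halvings):
            cand = project(Z - t * g)
            delta = cand - Z
            if not delta.any():
                break
            f_cand, g_cand = value_and_grad(cand)
            if f_cand <= f + armijo_c * float(np.sum(g * delta)):
                Z, f, g = cand, f_cand, g_cand
                step = min(t * 2.0, 1e6)
                accepted = True
                break
            t *= 0.5
        if not accepted:
            pg = np.linalg.norm(Z - project(Z - g))
            if pg > 1000.0 * grad_tol * max(1.0, np.linalg.norm(Z)):
                logger.warning(
                    "projected gradient: line search stalled away from optimum "
                    "(pg-norm %.3g); returning iterate", pg
                )
            break
    return (Z + Z.T) / 2.0


def z_update(
    state: ADMMState,
    data_term: UnbinnedDataTerm,
    max_inner: int = 200,
    grad_tol: float = 1e-6,
) -> np.ndarray:
    """Solve the likelihood block of the ADMM splitting.

    Minimizes -log L(Z) + rho/2 (||Z - Z1 + U1||^2 + ||Z - Z2 + U2||^2) over
    Z >= 0, warm-started at the current Z; the result is symmetrized.
    """
    rho = state.rho
    P1 = state.Z1 - state.U1
    P2 = state.Z2 - state.U2

    def value_and_grad(Z: np.ndarray) -> tuple[float, np.ndarray]:
        f, g = data_term.value_and_grad(Z)
        d1 = Z - P1
        d2 = Z - P2
        f += 0.5 * rho * (float(np.sum(d1 * d1)) + float(np.sum(d2 * d2)))
        g = g + rho * (d1 + d2)
        return f, g

    return _projected_gradient(
        value_and_grad, state.Z, max_iter=max_inner, grad_tol=grad_tol
    )


# ---------------------------------------------------------------------------
# outer loops


def admm_fit(
    contacts: ContactRecords,
    assignment: MarkAssignment,
    spec: ObjectiveSpec,
    rho: float = 1.0,
    tol: float = 1e-4,
    max_iter: int = 500,
    inner_max_iter: int = 200,
    inner_grad_tol: float = 1e-6,
    scope: str = "within-chromosome",
    pairs: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    init: float = 0.01,
    check_divergence: bool = True,
) -> tuple[MarkPairMatrix, ADMMState]:
    """Fit the mark-pair matrix by ADMM on the unbinned Bernoulli likelihood.

    Stops when max(||Z-Z1||_F, ||Z-Z2||_F) / max(1, ||Z||_F) < tol, or at
    ``max_iter``.  ``pairs``/``labels`` restrict the likelihood to an
    explicit pair subset (cross-validation); otherwise the non-edge sum runs
    over all in-scope pairs via the aggregate identity.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    m = assignment.n_marks
    data_term = UnbinnedDataTerm(
        contacts,
        assignment,
        scope=scope,
        pairs=pairs,
        labels=labels,
        clamp_eps=spec.clamp_eps,
    )
    Z = np.full((m, m), float(init))
    state = ADMMState(Z=Z, Z1=Z.copy(), Z2=Z.copy(), U1=np.zeros((m, m)),
                      U2=np.zeros((m, m)), rho=rho)
    worst_recent = None
    for it in range(1, max_iter + 1):
        state.Z = z_update(
            state, data_term, max_inner=inner_max_iter, grad_tol=inner_grad_tol
        )
        Z1_old, Z2_old = state.Z1, state.Z2
        state.Z1 = nuclear_prox(state.Z + state.U1, spec.lambda1 / rho)
        state.Z2 = l1_prox(state.Z + state.U2, spec.lambda2 / rho)
        state.U1 = state.U1 + state.Z - state.Z1
        state.U2 = state.U2 + state.Z - state.Z2
        r1 = np.linalg.norm(state.Z - state.Z1)
        r2 = np.linalg.norm(state.Z - state.Z2)
        state.primal_residual = max(r1, r2)
        state.dual_residual = rho * max(
            np.linalg.norm(state.Z1 - Z1_old), np.linalg.norm(state.Z2 - Z2_old)
        )
        state.iterations = it
        state.objective_trace.append(
            data_term.value(state.Z) + penalty_value(state.Z, spec)
        )
        # primal residual alone is blind to progress of the likelihood block
        # (with small penalties Z1 tracks Z exactly), so require the dual
        # residual to settle as well
        znorm = max(1.0, np.linalg.norm(state.Z))
        scaled = max(state.primal_residual, state.dual_residual) / znorm
        if scaled < tol:
            state.converged = True
            break
        if check_divergence:
            if worst_recent is None or it % 20 == 0:
                if worst_recent is not None and state.primal_residual > 10.0 * worst_recent:
                    raise DivergenceError(
                        f"ADMM residual grew 10x over 20 iterations "
                        f"(residual={state.primal_residual:.3g})"
                    )
                worst_recent = state.primal_residual
    X = MarkPairMatrix.from_z(np.maximum(state.Z, 0.0), assignment.catalog)
    return X, state


def fit_binned(
    contacts: ContactRecords,
    assignment: MarkAssignment,
    spec: ObjectiveSpec,
    restarts: int = 5,
    seed: int = 0,
    max_iter: int = 500,
    grad_tol: float = 1e-6,
    scope: str = "within-chromosome",
) -> tuple[MarkPairMatrix, dict]:
    """Fit the binned (Poisson / Le Cam) model by multistart projected gradient.

    The count likelihood is optimized directly in X with box constraints
    0 <= x < 1; the nuclear and L1 penalties are evaluated on the
    transformed matrix Z = -log(1 - X) via subgradients.  The problem is
    treated as potentially multimodal, so the best of ``restarts`` random
    starts is returned.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    data_term = BinnedDataTerm(
        contacts, assignment, scope=scope, clamp_eps=spec.clamp_eps
    )
    m = assignment.n_marks
    rng = np.random.default_rng(seed)
    x_cap = 1.0 - 1e-9

    def project(X: np.ndarray) -> np.ndarray:
        return np.clip(X, 0.0, x_cap)

    def value_and_grad(X: np.ndarray) -> tuple[float, np.ndarray]:
        f, g = data_term.value_and_grad(X)
        if spec.lambda1 > 0 or spec.lambda2 > 0:
            Z = -np.log1p(-X)
            dz_dx = 1.0 / (1.0 - X)
            if spec.lambda1 > 0:
                U, s, Vt = np.linalg.svd(Z, full_matrices=False)
                f += spec.lambda1 * float(s.sum())
                g = g + spec.lambda1 * (U @ Vt) * dz_dx  # nuclear subgradient
            if spec.lambda2 > 0:
                f += spec.lambda2 * float(np.abs(Z).sum())
                g = g + spec.lambda2 * np.sign(Z) * dz_dx
        return f, g

    best = None
    best_obj = np.inf
    objs = []
    for _ in range(restarts):
        X0 = rng.uniform(0.0, 0.2, size=(m, m))
        X0 = (X0 + X0.T) / 2.0
        Xf = _projected_gradient(
            value_and_grad, X0, max_iter=max_iter, grad_tol=grad_tol,
            project=project,
        )
        obj, _ = value_and_grad(Xf)
        objs.append(float(obj))
        if obj < best_obj:
            best_obj, best = float(obj), Xf
    X = MarkPairMatrix(np.clip(best, 0.0, x_cap), assignment.catalog)
    return X, {"objective": best_obj, "restart_objectives": objs}
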