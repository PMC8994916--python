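"""Generative model: edge probabilities, likelihoods, and the penalized objective.

Unbinned model
--------------
Every unordered site pair (u, v) interacts independently with probability

    P(u ~ v | X) = 1 - prod_{m,n} (1 - x_mn)^{c^u_m c^v_n}
                 = 1 - exp(-C_u^T Z C_v),   x_mn = 1 - exp(-z_mn)

where ``C_u`` is the binary mark vector at site u.  On the z-scale the
negative log-likelihood of the observed contact graph is convex, and the
fitted objective adds nuclear-norm (low rank / block structure) and L1
(sparsity) penalties:

    min_{Z >= 0}  -log L(Z, G) + lambda1 ||Z||_* + lambda2 ||Z||_1

Binned model
------------
With counts aggregated into bins the per-pair count follows a
Poisson-binomial over ``T = C_u^T 1 C_v`` slots with probabilities drawn
from X; it is approximated (Le Cam) by Poisson(lambda_uv) with
``lambda_uv = C_u^T X C_v``.

The non-edge sum over all pairs never loops over O(n^2) pairs: with
``S = sum_u C_u`` and ``T = sum_u C_u C_u^T`` (per chromosome),

    sum_{u<v} C_u^T Z C_v = (S^T Z S - trace(T Z)) / 2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .datamodel import ContactRecords, MarkAssignment, MarkPairMatrix

logger = logging.getLogger(__name__)

NONEDGE_SCOPES = ("within-chromosome", "genome-wide")


@dataclass(frozen=True)
class ObjectiveSpec:
    """Penalty weights and numerical safety for the fitted objective."""

    lambda1: float = 0.1  # nuclear-norm (low-rank) weight
    lambda2: float = 0.1  # L1 (sparsity) weight
    clamp_eps: float = 1e-10

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalty weights must be nonnegative")
        if self.clamp_eps <= 0:
            raise ValueError("clamp_eps must be positive")


# ---------------------------------------------------------------------------
# elementwise transforms


def transform_z_to_x(Z: np.ndarray) -> np.ndarray:
    """x = 1 - exp(-z), elementwise."""
    Z = np.asarray(Z, dtype=float)
    if np.any(Z < 0):
        raise ValueError("Z must be nonnegative")
    return -np.expm1(-Z)


def transform_x_to_z(X: np.ndarray) -> np.ndarray:
    """z = -log(1 - x), elementwise; inverse of :func:`transform_z_to_x`."""
    X = np.asarray(X, dtype=float)
    if np.any(X < 0) or np.any(X >= 1):
        raise ValueError("X must lie in [0, 1)")
    return -np.log1p(-X)


def edge_probability(
    c_u: np.ndarray, c_v: np.ndarray, X: MarkPairMatrix | np.ndarray
) -> float:
    """Probability that sites with mark vectors ``c_u``, ``c_v`` interact.

    Sites sharing several active mark pairs receive several independent
    chances to interact, hence the survival-product form.  Any ``x_mn = 1``
    on an active pair yields probability exactly 1 (the z-scale limit).
    """
    Xa = X.X if isinstance(X, MarkPairMatrix) else np.asarray(X, dtype=float)
    c_u = np.asarray(c_u, dtype=float)
    c_v = np.asarray(c_v, dtype=float)
    weights = np.outer(c_u, c_v)
    active = weights > 0
    if np.any(Xa[active] >= 1.0):
        logger.warning("edge_probability: x=1 on an active mark pair (z infinite)")
        return 1.0
    s = -np.sum(weights[active] * np.log1p(-Xa[active]))
    return float(-np.expm1(-s))


# ---------------------------------------------------------------------------
# unbinned likelihood


class UnbinnedDataTerm:
    """Precomputed negative log-likelihood (and gradient) of a contact graph.

    Two modes:

    * aggregate (default): edges are the observed contacts; the non-edge sum
      runs over every other unordered pair in scope (within-chromosome or
      genome-wide), computed via the aggregate identity in O(|E| + n m^2).
    * explicit pairs: ``pairs`` is an (iu, iv) array and ``labels`` marks
      which of those pairs are edges; only the listed pairs contribute
      (used by cross-validation on pair subsets).
    """

    def __init__(
        self,
        contacts: ContactRecords,
        assignment: MarkAssignment,
        scope: str = "within-chromosome",
        pairs: np.ndarray | None = None,
        labels: np.ndarray | None = None,
        clamp_eps: float = 1e-10,
    ) -> None:
        if scope not in NONEDGE_SCOPES:
            raise ValueError(f"scope must be one of {NONEDGE_SCOPES}")
        A = assignment.counts
        self.m = A.shape[1]
        self.clamp_eps = clamp_eps
        if pairs is not None:
            if labels is None:
                raise ValueError("labels must accompany explicit pairs")
            pairs = np.asarray(pairs)
            labels = np.asarray(labels, dtype=bool)
            if labels.shape[0] != pairs.shape[0]:
                raise ValueError("labels and pairs must have equal length")
            self._Au_pos = A[pairs[labels, 0]]
            self._Av_pos = A[pairs[labels, 1]]
            Au_neg = A[pairs[~labels, 0]]
            Av_neg = A[pairs[~labels, 1]]
            # sum over explicit non-edges of sym(C_u C_v^T)
            G = Au_neg.T @ Av_neg
            self._agg = (G + G.T) / 2.0
        else:
            self._Au_pos = A[contacts.iu]
            self._Av_pos = A[contacts.iv]
            groups = (
                {"all": np.arange(A.shape[0])}
                if scope == "genome-wide"
                else assignment.index.chromosome_groups()
            )
            agg = np.zeros((self.m, self.m))
            for rows in groups.values():
                Ac = A[rows]
                S = Ac.sum(axis=0)
                agg += 0.5 * (np.outer(S, S) - Ac.T @ Ac)
            # remove the edge pairs from the all-pair aggregate
            G = self._Au_pos.T @ self._Av_pos
            self._agg = agg - (G + G.T) / 2.0
        zero_edge = (self._Au_pos.sum(axis=1) == 0) | (self._Av_pos.sum(axis=1) == 0)
        if np.any(zero_edge):
            logger.warning(
                "%d edge(s) join mark-free sites; their terms are clamped",
                int(zero_edge.sum()),
            )

    def _edge_s(self, Z: np.ndarray) -> np.ndarray:
        return np.einsum("ij,jk,ik->i", self._Au_pos, Z, self._Av_pos)

    def value(self, Z: np.ndarray) -> float:
        """Negative log-likelihood at symmetric Z >= 0."""
        s = np.maximum(self._edge_s(Z), self.clamp_eps)
        edge_ll = np.log(-np.expm1(-s)).sum()
        nonedge = float(np.sum(self._agg * Z))
        return -edge_ll + nonedge

    def value_and_grad(self, Z: np.ndarray) -> tuple[float, np.ndarray]:
        s = np.maximum(self._edge_s(Z), self.clamp_eps)
        one_m_exp = -np.expm1(-s)  # 1 - e^{-s}
        value = -np.log(one_m_exp).sum() + float(np.sum(self._agg * Z))
        # d/dZ of -log(1-e^{-s}) summed over edges: -(e^{-s}/(1-e^{-s})) sym(CuCv^T)
        w = np.exp(-s) / one_m_exp
        G = self._Au_pos.T @ (w[:, None] * self._Av_pos)
        grad = self._agg - (G + G.T) / 2.0
        return value, grad


def log_likelihood_unbinned(
    Z: np.ndarray,
    contacts: ContactRecords,
    assignment: MarkAssignment,
    scope: str = "within-chromosome",
    clamp_eps: float = 1e-10,
) -> float:
    """Log-likelihood of the contact graph at Z (aggregate non-edge sum)."""
    term = UnbinnedDataTerm(contacts, assignment, scope=scope, clamp_eps=clamp_eps)
    return -term.value(np.asarray(Z, dtype=float))


def objective(
    Z: np.ndarray,
    contacts: ContactRecords,
    assignment: MarkAssignment,
    spec: ObjectiveSpec,
    scope: str = "within-chromosome",
) -> float:
    """Penalized negative log-likelihood: -log L + l1*||Z||_* + l2*||Z||_1."""
    Z = np.asarray(Z, dtype=float)
    nll = -log_likelihood_unbinned(
        Z, contacts, assignment, scope=scope, clamp_eps=spec.clamp_eps
    )
    return nll + penalty_value(Z, spec)


def penalty_value(Z: np.ndarray, spec: ObjectiveSpec) -> float:
    nuclear = float(np.linalg.svd(Z, compute_uv=False).sum())
    return spec.lambda1 * nuclear + spec.lambda2 * float(np.abs(Z).sum())


# ---------------------------------------------------------------------------
# binned (count) model


def poisson_binomial_pmf(slot_probs: np.ndarray, k: int) -> float:
    """Exact Poisson-binomial pmf by dynamic-programming convolution.

    ``slot_probs`` are the success probabilities of the independent contact
    slots between two bins (the multiset {x_mn repeated c^u_m c^v_n times}).
    O(T * k) time; returns 0 for k > T.
    """
    p = np.asarray(slot_probs, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("slot probabilities must lie in [0, 1]")
    if k < 0:
        raise ValueError("k must be nonnegative")
    if k > len(p):
        return 0.0
    return float(poisson_binomial_pmf_vector(p)[k])


def poisson_binomial_pmf_vector(slot_probs: np.ndarray) -> np.ndarray:
    """Full pmf over k = 0..T for the given slot probabilities."""
    p = np.asarray(slot_probs, dtype=float)
    pmf = np.zeros(len(p) + 1)
    pmf[0] = 1.0
    for i, pi in enumerate(p):
        pmf[1 : i + 2] = pmf[1 : i + 2] * (1 - pi) + pmf[: i + 1] * pi
        pmf[0] *= 1 - pi
    return pmf


def lecam_poisson_pmf(lambda_uv: float, k: int) -> float:
    """Poisson(lambda) pmf — the Le Cam approximation of the slot model."""
    if lambda_uv < 0:
        raise ValueError("lambda must be nonnegative")
    if k < 0:
        return 0.0
    if lambda_uv == 0:
        return 1.0 if k == 0 else 0.0
    return float(math.exp(k * math.log(lambda_uv) - lambda_uv - gammaln(k + 1)))


def pair_slot_probs(
    c_u: np.ndarray, c_v: np.ndarray, X: np.ndarray
) -> np.ndarray:
    """Multiset of slot probabilities {x_mn repeated c^u_m c^v_n times}."""
    counts = np.outer(np.asarray(c_u, dtype=int), np.asarray(c_v, dtype=int))
    reps = counts.ravel()
    return np.repeat(np.asarray(X, dtype=float).ravel(), reps)


class BinnedDataTerm:
    """Negative Poisson (Le Cam) log-likelihood of binned counts in X."""

    def __init__(
        self,
        contacts: ContactRecords,
        assignment: MarkAssignment,
        scope: str = "within-chromosome",
        clamp_eps: float = 1e-10,
    ) -> None:
        if scope not in NONEDGE_SCOPES:
            raise ValueError(f"scope must be one of {NONEDGE_SCOPES}")
        A = assignment.counts
        self.clamp_eps = clamp_eps
        self._Au = A[contacts.iu]
        self._Av = A[contacts.iv]
        self._k = contacts.counts.astype(float)
        self._log_k_fact = gammaln(self._k + 1.0)
        groups = (
            {"all": np.arange(A.shape[0])}
            if scope == "genome-wide"
            else assignment.index.chromosome_groups()
        )
        agg = np.zeros((A.shape[1], A.shape[1]))
        for rows in groups.values():
            Ac = A[rows]
            S = Ac.sum(axis=0)
            agg += 0.5 * (np.outer(S, S) - Ac.T @ Ac)
        self._agg = agg  # sum over ALL in-scope pairs of sym(CuCv^T)

    def _lam(self, X: np.ndarray) -> np.ndarray:
        return np.einsum("ij,jk,ik->i", self._Au, X, self._Av)

    def value(self, X: np.ndarray) -> float:
        lam = np.maximum(self._lam(X), self.clamp_eps)
        ll = float(np.sum(self._k * np.log(lam) - self._log_k_fact))
        # -sum_all_pairs lambda_uv via the aggregate; observed-pair lambdas
        # are inside the aggregate already
        ll -= float(np.sum(self._agg * X))
        return -ll

    def value_and_grad(self, X: np.ndarray) -> tuple[float, np.ndarray]:
        """Negative log-likelihood and its gradient in X."""
        lam = np.maximum(self._lam(X), self.clamp_eps)
        value = -float(np.sum(self._k * np.log(lam) - self._log_k_fact)) + float(
            np.sum(self._agg * X)
        )
        w = self._k / lam
        G = self._Au.T @ (w[:, None] * self._Av)
        grad = self._agg - (G + G.T) / 2.0
        return value, grad


def log_likelihood_binned(
    X: np.ndarray,
    contacts: ContactRecords,
    assignment: MarkAssignment,
    scope: str = "within-chromosome",
    clamp_eps: float = 1e-10,
) -> float:
    """Poisson (Le Cam) log-likelihood of binned counts at probability matrix X."""
    term = BinnedDataTerm(contacts, assignment, scope=scope, clamp_eps=clamp_eps)
    return -term.value(np.asarray(X, dtype=float))
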