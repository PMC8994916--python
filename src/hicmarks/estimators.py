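"""Estimator front-ends over the ADMM and multistart solvers.

These follow scikit-learn conventions — constructor stores hyperparameters
untouched, ``fit`` returns ``self``, fitted attributes end in an underscore,
``get_params``/``set_params``/``clone`` work — but take the package's domain
objects (a :class:`~hicmarks.datamodel.MarkAssignment` and a
:class:`~hicmarks.datamodel.ContactRecords`) rather than 2-D feature
arrays, since the model is fit to a graph, not a sample matrix.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .datamodel import ContactRecords, MarkAssignment, ValidationError
from .model import ObjectiveSpec
from .optimize import admm_fit, fit_binned


class MarkPairDecomposer(BaseEstimator):
    """Decompose an unbinned contact graph into mark-pair probabilities.

    Fits the convex penalized Bernoulli likelihood by ADMM with nuclear-norm
    (weight ``lambda1``) and L1 (weight ``lambda2``) penalties on the
    transformed matrix Z, where X = 1 - exp(-Z).

    Parameters
    ----------
    lambda1, lambda2 : float
        Low-rank and sparsity penalty weights.
    rho : float
        ADMM penalty parameter.
    tol, max_iter : float, int
        Outer-loop stopping rule.
    inner_max_iter, inner_grad_tol : int, float
        Projected-gradient budget for the likelihood block.
    nonedge_scope : str
        ``"within-chromosome"`` (default) or ``"genome-wide"`` — which pairs
        count as non-edges in the likelihood.

    Attributes
    ----------
    X_ : MarkPairMatrix
        Fitted symmetric probability matrix.
    Z_ : ndarray
        Its transform.
    state_ : ADMMState
        Solver diagnostics.
    catalog_ : MarkCatalog
    """

    def __init__(
        self,
        lambda1: float = 0.1,
        lambda2: float = 0.1,
        rho: float = 1.0,
        tol: float = 1e-4,
        max_iter: int = 500,
        inner_max_iter: int = 200,
        inner_grad_tol: float = 1e-6,
        nonedge_scope: str = "within-chromosome",
        clamp_eps: float = 1e-10,
    ) -> None:
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.rho = rho
        self.tol = tol
        self.max_iter = max_iter
        self.inner_max_iter = inner_max_iter
        self.inner_grad_tol = inner_grad_tol
        self.nonedge_scope = nonedge_scope
        self.clamp_eps = clamp_eps

    def fit(
        self,
        assignment: MarkAssignment,
        contacts: ContactRecords,
        pairs: np.ndarray | None = None,
        labels: np.ndarray | None = None,
    ) -> "MarkPairDecomposer":
        if assignment.index.binned or contacts.binned:
            raise ValidationError(
                "MarkPairDecomposer expects unbinned inputs; see "
                "BinnedMarkPairDecomposer"
            )
        spec = ObjectiveSpec(
            lambda1=self.lambda1, lambda2=self.lambda2, clamp_eps=self.clamp_eps
        )
        X, state = admm_fit(
            contacts,
            assignment,
            spec,
            rho=self.rho,
            tol=self.tol,
            max_iter=self.max_iter,
            inner_max_iter=self.inner_max_iter,
            inner_grad_tol=self.inner_grad_tol,
            scope=self.nonedge_scope,
            pairs=pairs,
            labels=labels,
        )
        self.X_ = X
        self.Z_ = X.Z
        self.state_ = state
        self.catalog_ = assignment.catalog
        return self

    def predict_proba(
        self, assignment: MarkAssignment, pairs: np.ndarray
    ) -> np.ndarray:
        """Contact probability for each (u, v) row-index pair."""
        check_is_fitted(self, "X_")
        from .evaluate import predict_probabilities

        return predict_probabilities(self.X_, assignment, pairs)

    def score(
        self,
        assignment: MarkAssignment,
        contacts: ContactRecords,
        neg_ratio: int = 10,
        seed: int = 0,
    ) -> float:
        """Link-prediction ROC AUC against a seeded negative sample."""
        check_is_fitted(self, "X_")
        from .evaluate import roc_auc, sample_negative_pairs

        neg = sample_negative_pairs(
            contacts, assignment, ratio=neg_ratio, seed=seed, scope=self.nonedge_scope
        )
        pos = np.column_stack([contacts.iu, contacts.iv])
        pairs = np.vstack([pos, neg])
        truth = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
        auc, _ = roc_auc(self.predict_proba(assignment, pairs), truth)
        return auc


class BinnedMarkPairDecomposer(BaseEstimator):
    """Decompose binned contact counts under the Poisson (Le Cam) model.

    The count likelihood is optimized on the z-scale by projected gradient
    with Armijo backtracking from ``restarts`` random starts (the binned
    problem is treated as potentially multimodal); the best objective wins.
    """

    def __init__(
        self,
        lambda1: float = 0.1,
        lambda2: float = 0.1,
        restarts: int = 5,
        max_iter: int = 500,
        grad_tol: float = 1e-6,
        nonedge_scope: str = "within-chromosome",
        clamp_eps: float = 1e-10,
        random_state: int = 0,
    ) -> None:
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.restarts = restarts
        self.max_iter = max_iter
        self.grad_tol = grad_tol
        self.nonedge_scope = nonedge_scope
        self.clamp_eps = clamp_eps
        self.random_state = random_state

    def fit(
        self, assignment: MarkAssignment, contacts: ContactRecords
    ) -> "BinnedMarkPairDecomposer":
        spec = ObjectiveSpec(
            lambda1=self.lambda1, lambda2=self.lambda2, clamp_eps=self.clamp_eps
        )
        X, info = fit_binned(
            contacts,
            assignment,
            spec,
            restarts=self.restarts,
            seed=self.random_state,
            max_iter=self.max_iter,
            grad_tol=self.grad_tol,
            scope=self.nonedge_scope,
        )
        self.X_ = X
        self.Z_ = X.Z
        self.fit_info_ = info
        self.catalog_ = assignment.catalog
        return self

    def predict_expected_counts(
        self, assignment: MarkAssignment, pairs: np.ndarray
    ) -> np.ndarray:
        """Poisson mean count lambda_uv = C_u^T X C_v for each pair."""
        check_is_fitted(self, "X_")
        pairs = np.asarray(pairs)
        A = assignment.counts
        return np.einsum(
            "ij,jk,ik->i", A[pairs[:, 0]], self.X_.X, A[pairs[:, 1]]
        )
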