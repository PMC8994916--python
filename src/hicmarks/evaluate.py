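"""Prediction and downstream evaluation.

Covers link-prediction ROC/AUC, distance-decay null baselines, A/B
compartment calls from the leading eigenvector, Normalized Variation of
Information between partitions, TAD-boundary confusion counts, stability
correlations between fitted matrices, nested cross-validation over the
penalty grid, and in-silico perturbations (mark masking, region deletion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score, roc_curve

from .datamodel import (
    ContactRecords,
    MarkAssignment,
    MarkPairMatrix,
    ValidationError,
)
from .model import ObjectiveSpec, edge_probability
from .optimize import admm_fit

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = tuple(product((0.01, 0.1, 0.5), repeat=2))


@dataclass(frozen=True)
class BaselineParams:
    """Distance-decay null model: P(contact) = clip(alpha * d^{-beta}, 0, 1)."""

    alpha: float
    beta: float

    def predict(self, distances: np.ndarray) -> np.ndarray:
        d = np.asarray(distances, dtype=float)
        if np.any(d <= 0):
            raise ValidationError("distances must be positive")
        return np.clip(self.alpha * d ** (-self.beta), 0.0, 1.0)


@dataclass(frozen=True)
class PartitionLabels:
    """Per-bin integer cluster labels over a contiguous index."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "labels", np.asarray(self.labels, dtype=np.int64).ravel()
        )

    def __len__(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# prediction


def predict_probabilities(
    X: MarkPairMatrix,
    assignment: MarkAssignment,
    pairs: np.ndarray,
) -> np.ndarray:
    """Score site pairs under the fitted model.

    Unbinned assignments give Bernoulli contact probabilities; binned
    assignments give the Poisson expected count ``lambda_uv = C_u^T X C_v``.
    """
    pairs = np.asarray(pairs)
    A = assignment.counts
    Au, Av = A[pairs[:, 0]], A[pairs[:, 1]]
    if assignment.index.binned:
        return np.einsum("ij,jk,ik->i", Au, X.X, Av)
    s = np.einsum("ij,jk,ik->i", Au, X.Z, Av)
    return -np.expm1(-s)


def roc_auc(
    scores: np.ndarray, truth: np.ndarray
) -> tuple[float, np.ndarray]:
    """AUC plus ROC points (threshold, FPR, TPR), ties rank-averaged."""
    truth = np.asarray(truth)
    if len(np.unique(truth)) < 2:
        only = int(np.unique(truth)[0])
        raise ValidationError(f"truth contains a single class ({only})")
    fpr, tpr, thr = roc_curve(truth, scores)
    auc = float(roc_auc_score(truth, scores))
    return auc, np.column_stack([thr, fpr, tpr])


def fit_distance_decay(
    distances: np.ndarray, labels: np.ndarray, beta: float = 1.0
) -> BaselineParams:
    """Fit the scale alpha of the distance-decay null by Bernoulli MLE.

    beta is held fixed (conventionally 1, 1.5, or 2); alpha is found by a
    bounded 1-D search on the clipped-probability likelihood.
    """
    d = np.asarray(distances, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.any(d <= 0):
        raise ValidationError("distances must be positive")
    base = d ** (-beta)
    eps = 1e-12

    def nll(log_alpha: float) -> float:
        p = np.clip(np.exp(log_alpha) * base, eps, 1.0 - eps)
        return -float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))

    if not np.any(y > 0):
        return BaselineParams(alpha=0.0, beta=beta)
    res = minimize_scalar(nll, bounds=(-40.0, 40.0), method="bounded")
    return BaselineParams(alpha=float(np.exp(res.x)), beta=beta)


# ---------------------------------------------------------------------------
# partitions and boundaries


def compartment_calls(matrix: np.ndarray) -> PartitionLabels:
    """Two-way A/B partition from the leading eigenvector's sign pattern.

    The input contact (or predicted-probability) matrix is converted to its
    row correlation matrix first; the eigenvector of largest-magnitude
    eigenvalue is taken, and zero entries join the positive class.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1] or M.shape[0] < 2:
        raise ValidationError("matrix must be square with >= 2 bins")
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValidationError("matrix must be symmetric")
    if np.any(M.std(axis=1) == 0):
        raise ValidationError("degenerate input: constant row(s)")
    C = np.corrcoef(M)
    evals, evecs = np.linalg.eigh(C)
    lead = evecs[:, np.argmax(np.abs(evals))]
    return PartitionLabels((lead >= 0).astype(np.int64))


def nvi(p: PartitionLabels | np.ndarray, q: PartitionLabels | np.ndarray) -> float:
    """Normalized Variation of Information in [0, 1]; 0 means identical.

    VI(p, q) = H(p) + H(q) - 2 I(p; q) with natural-log entropies over the
    joint contingency table, normalized by log n.
    """
    pl = p.labels if isinstance(p, PartitionLabels) else np.asarray(p).ravel()
    ql = q.labels if isinstance(q, PartitionLabels) else np.asarray(q).ravel()
    if len(pl) != len(ql):
        raise ValidationError("partitions must cover the same index")
    n = len(pl)
    if n < 2:
        return 0.0

    def entropy(counts: np.ndarray) -> float:
        f = counts / n
        f = f[f > 0]
        return -float(np.sum(f * np.log(f)))

    _, pi = np.unique(pl, return_inverse=True)
    _, qi = np.unique(ql, return_inverse=True)
    joint = np.zeros((pi.max() + 1, qi.max() + 1))
    np.add.at(joint, (pi, qi), 1.0)
    h_p = entropy(joint.sum(axis=1))
    h_q = entropy(joint.sum(axis=0))
    h_pq = entropy(joint.ravel())
    mutual = h_p + h_q - h_pq
    vi = h_p + h_q - 2.0 * mutual
    return float(max(vi, 0.0) / np.log(n))


def boundary_confusion(
    true_boundaries: np.ndarray,
    pred_boundaries: np.ndarray,
    tol_bins: int = 0,
) -> dict:
    """Confusion counts between true and predicted boundary positions.

    A true boundary is a TP when an unmatched predicted boundary lies within
    ``tol_bins`` (greedy nearest-first, each prediction matched once).
    """
    t = np.asarray(sorted(true_boundaries), dtype=np.int64)
    p = np.asarray(sorted(pred_boundaries), dtype=np.int64)
    candidates = []
    for i, tb in enumerate(t):
        for j, pb in enumerate(p):
            d = abs(int(tb) - int(pb))
            if d <= tol_bins:
                candidates.append((d, i, j))
    candidates.sort()
    matched_t: set[int] = set()
    matched_p: set[int] = set()
    for _, i, j in candidates:
        if i not in matched_t and j not in matched_p:
            matched_t.add(i)
            matched_p.add(j)
    tp = len(matched_t)
    fn = len(t) - tp
    fp = len(p) - len(matched_p)
    tpr = tp / len(t) if len(t) else 0.0
    return {
        "TP": tp,
        "FP": fp,
        "FN": fn,
        "TPR": tpr,
        "FNR": 1.0 - tpr if len(t) else 0.0,
    }


def stability_correlation(X_a: MarkPairMatrix, X_b: MarkPairMatrix) -> float:
    """Spearman rank correlation of upper-triangle (incl. diagonal) entries."""
    if X_a.catalog.names != X_b.catalog.names:
        raise ValidationError("matrices must share the same mark catalog")
    rho, _ = spearmanr(X_a.upper_triangle(), X_b.upper_triangle())
    return float(rho)


# ---------------------------------------------------------------------------
# negative sampling and cross-validation


def sample_negative_pairs(
    contacts: ContactRecords,
    assignment: MarkAssignment,
    ratio: int = 10,
    seed: int = 0,
    scope: str = "within-chromosome",
) -> np.ndarray:
    """Seeded uniform sample of non-edge pairs, ``ratio`` x the edge count."""
    rng = np.random.default_rng(seed)
    n = assignment.n_sites
    edge_set = contacts.pair_set()
    groups = (
        {"all": np.arange(n)}
        if scope == "genome-wide"
        else assignment.index.chromosome_groups()
    )
    group_list = list(groups.values())
    sizes = np.array([len(g) * (len(g) - 1) // 2 for g in group_list], dtype=float)
    if sizes.sum() <= len(edge_set):
        raise ValidationError("no non-edges available to sample")
    target = min(int(ratio * max(len(contacts), 1)), int(sizes.sum() - len(edge_set)))
    probs = sizes / sizes.sum()
    edge_keys = {u * n + v for u, v in edge_set}
    chosen: set[int] = set()
    for _ in range(200):
        if len(chosen) >= target:
            break
        batch = max(4 * (target - len(chosen)), 1024)
        gi = rng.choice(len(group_list), size=batch, p=probs)
        for g in np.unique(gi):
            rows = group_list[g]
            if len(rows) < 2:
                continue
            k = int(np.sum(gi == g))
            a = rows[rng.integers(0, len(rows), size=k)]
            b = rows[rng.integers(0, len(rows), size=k)]
            u = np.minimum(a, b)
            v = np.maximum(a, b)
            ok = u < v
            for key in (u[ok] * n + v[ok]).tolist():
                if key not in edge_keys:
                    chosen.add(key)
                    if len(chosen) >= target:
                        break
            if len(chosen) >= target:
                break
    keys = np.array(sorted(chosen), dtype=np.int64)
    return np.column_stack([keys // n, keys % n]).astype(np.intp)


def _fit_and_auc(
    assignment: MarkAssignment,
    contacts: ContactRecords,
    train_pairs: np.ndarray,
    train_labels: np.ndarray,
    test_pairs: np.ndarray,
    test_labels: np.ndarray,
    lam: tuple[float, float],
    admm_kwargs: dict,
) -> float:
    spec = ObjectiveSpec(lambda1=lam[0], lambda2=lam[1])
    X, _ = admm_fit(
        contacts,
        assignment,
        spec,
        pairs=train_pairs,
        labels=train_labels,
        **admm_kwargs,
    )
    scores = predict_probabilities(X, assignment, test_pairs)
    auc, _ = roc_auc(scores, test_labels)
    return auc


def cv_select_lambda(
    contacts: ContactRecords,
    assignment: MarkAssignment,
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID,
    k: int = 2,
    seed: int = 0,
    neg_ratio: int = 10,
    admm_kwargs: dict | None = None,
) -> tuple[tuple[float, float], dict]:
    """Single-level k-fold selection of (lambda1, lambda2) by validation AUC.

    Folds partition the scored pairs (edges plus a seeded non-edge sample);
    ties break toward the larger (more regularized) penalty pair.
    """
    admm_kwargs = dict(admm_kwargs or {})
    grid = sorted({(float(a), float(b)) for a, b in lambda_grid})
    rng = np.random.default_rng(seed)
    neg = sample_negative_pairs(contacts, assignment, ratio=neg_ratio, seed=seed)
    pos = np.column_stack([contacts.iu, contacts.iv]).astype(np.intp)
    pairs = np.vstack([pos, neg])
    labels = np.concatenate(
        [np.ones(len(pos), dtype=bool), np.zeros(len(neg), dtype=bool)]
    )
    perm = rng.permutation(len(pairs))
    folds = [perm[i::k] for i in range(k)]
    best_lam, best_auc, detail = None, -np.inf, {}
    for lam in grid:
        aucs = []
        for f in range(k):
            val = folds[f]
            tr = np.concatenate([folds[g] for g in range(k) if g != f])
            aucs.append(
                _fit_and_auc(
                    assignment, contacts, pairs[tr], labels[tr],
                    pairs[val], labels[val], lam, admm_kwargs,
                )
            )
        mean_auc = float(np.mean(aucs))
        detail[lam] = mean_auc
        if mean_auc >= best_auc:  # >= : larger lambda wins ties
            best_auc, best_lam = mean_auc, lam
    return best_lam, {"grid_auc": detail, "best_auc": best_auc}


def nested_cv(
    contacts: ContactRecords,
    assignment: MarkAssignment,
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID,
    outer_k: int = 5,
    inner_k: int = 4,
    mode: str = "same-chromosome",
    seed: int = 0,
    neg_ratio: int = 10,
    admm_kwargs: dict | None = None,
) -> dict:
    """Nested cross-validation over the (lambda1, lambda2) grid.

    Outer folds are random partitions of the scored pairs (edges plus a
    seeded sample of non-edges), or whole chromosomes in
    leave-one-chromosome-out mode.  Inner folds pick the penalty pair with
    the best mean validation AUC; ties break toward the larger (more
    regularized) pair.  Deterministic under a fixed seed.
    """
    if outer_k < 2 or inner_k < 2:
        raise ValidationError("outer_k and inner_k must both be >= 2")
    if mode not in ("same-chromosome", "leave-one-chromosome-out"):
        raise ValidationError(f"unknown mode {mode!r}")
    admm_kwargs = dict(admm_kwargs or {})
    grid = sorted({(float(a), float(b)) for a, b in lambda_grid})
    rng = np.random.default_rng(seed)

    neg = sample_negative_pairs(contacts, assignment, ratio=neg_ratio, seed=seed)
    pos = np.column_stack([contacts.iu, contacts.iv]).astype(np.intp)
    pairs = np.vstack([pos, neg])
    labels = np.concatenate(
        [np.ones(len(pos), dtype=bool), np.zeros(len(neg), dtype=bool)]
    )

    if mode == "leave-one-chromosome-out":
        chroms = assignment.index.chroms
        pair_chrom = chroms[pairs[:, 0]]
        fold_keys = sorted(set(pair_chrom.tolist()))
        if len(fold_keys) < 2:
            raise ValidationError("leave-one-chromosome-out needs >= 2 chromosomes")
        outer_folds = [np.nonzero(pair_chrom == c)[0] for c in fold_keys]
    else:
        perm = rng.permutation(len(pairs))
        outer_folds = [perm[i::outer_k] for i in range(outer_k)]
        fold_keys = list(range(outer_k))

    def pick_lambda(train_idx: np.ndarray) -> tuple[float, float]:
        inner_perm = rng.permutation(train_idx)
        inner_folds = [inner_perm[i::inner_k] for i in range(inner_k)]
        best_lam, best_auc = None, -np.inf
        for lam in grid:
            aucs = []
            for f in range(inner_k):
                val = inner_folds[f]
                tr = np.concatenate([inner_folds[g] for g in range(inner_k) if g != f])
                try:
                    aucs.append(
                        _fit_and_auc(
                            assignment, contacts, pairs[tr], labels[tr],
                            pairs[val], labels[val], lam, admm_kwargs,
                        )
                    )
                except ValidationError:
                    continue  # degenerate single-class fold
            mean_auc = float(np.mean(aucs)) if aucs else -np.inf
            # >= so that later (larger) lambda pairs win ties
            if mean_auc >= best_auc:
                best_auc, best_lam = mean_auc, lam
        return best_lam

    per_fold = []
    for key, test_idx in zip(fold_keys, outer_folds):
        train_idx = np.setdiff1d(np.arange(len(pairs)), test_idx)
        lam = pick_lambda(train_idx)
        auc = _fit_and_auc(
            assignment, contacts, pairs[train_idx], labels[train_idx],
            pairs[test_idx], labels[test_idx], lam, admm_kwargs,
        )
        per_fold.append({"fold": key, "lambda": lam, "auc": auc})

    chosen = max(
        ((sum(1 for f in per_fold if f["lambda"] == lam), lam) for lam in grid
         if any(f["lambda"] == lam for f in per_fold))
    )[1]
    return {
        "chosen_lambda": chosen,
        "folds": per_fold,
        "mean_auc": float(np.mean([f["auc"] for f in per_fold])),
        "pairs": pairs,
        "labels": labels,
    }


# ---------------------------------------------------------------------------
# perturbations


def mask_marks(
    assignment: MarkAssignment,
    region: tuple[str, int, int],
    marks: list[str] | str = "all",
) -> MarkAssignment:
    """Zero selected mark columns for sites inside [start, end) of a region."""
    chrom, start, end = region
    out = assignment.copy()
    in_region = (
        (assignment.index.chroms == chrom)
        & (assignment.index.positions >= start)
        & (assignment.index.positions < end)
    )
    if marks == "all":
        cols = np.arange(assignment.n_marks)
    else:
        cols = np.array([assignment.catalog.index_of(m) for m in marks], dtype=np.intp)
    out.counts[np.ix_(np.nonzero(in_region)[0], cols)] = 0
    return out


def delete_region(
    assignment: MarkAssignment,
    contacts: ContactRecords,
    region: tuple[str, int, int],
) -> tuple[MarkAssignment, ContactRecords]:
    """Excise a region: drop its sites and contacts, shift downstream
    coordinates left by the region length, and rejoin the flanks."""
    chrom, start, end = region
    if end < start:
        raise ValidationError("region end must be >= start")
    idx = assignment.index
    inside = (
        (idx.chroms == chrom) & (idx.positions >= start) & (idx.positions < end)
    )
    keep = ~inside
    keep_rows = np.nonzero(keep)[0]
    new_pos = idx.positions[keep].copy()
    shift = (idx.chroms[keep] == chrom) & (idx.positions[keep] >= end)
    new_pos[shift] -= end - start
    from .datamodel import SiteIndex  # local import to avoid cycle at module load

    new_index = SiteIndex(idx.chroms[keep].copy(), new_pos, resolution=idx.resolution)
    new_assign = MarkAssignment(
        assignment.counts[keep_rows], assignment.catalog, new_index
    )
    old_to_new = -np.ones(len(idx), dtype=np.intp)
    old_to_new[keep_rows] = np.arange(len(keep_rows))
    cu, cv = old_to_new[contacts.iu], old_to_new[contacts.iv]
    ok = (cu >= 0) & (cv >= 0)
    new_contacts = ContactRecords(
        cu[ok], cv[ok], contacts.counts[ok], new_index, contacts.binned
    )
    return new_assign, new_contacts
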