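"""Forward simulator of the generative model.

Builds a ground-truth mark-pair probability matrix (sparse, optionally with
block/community structure), samples mark assignments and contact graphs from
it, and writes fixture bundles through the package's file formats.  The
simulated genome is a single pseudo-chromosome with sites spaced 4 kb apart
(typical restriction-fragment scale); there is deliberately no
distance-dependent contact decay — the generative model has none, which is
exactly what makes distance-decay baselines a fair null to beat.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import io as hio
from .datamodel import (
    ContactRecords,
    MarkAssignment,
    MarkCatalog,
    MarkPairMatrix,
    SiteIndex,
    SyntheticTruth,
    ValidationError,
)
from .model import pair_slot_probs, poisson_binomial_pmf_vector

SITE_SPACING = 4000  # bp between simulated restriction sites

CONTACT_MODES = ("unbinned", "binned-exact", "binned-lecam")


def make_truth(
    n_marks: int,
    sparsity: float = 0.35,
    block_structure: list[list[int]] | None = None,
    seed: int = 0,
    n_sites: int = 500,
    n_chroms: int = 1,
    density_range: tuple[float, float] = (0.05, 0.3),
    within_block: tuple[float, float] = (0.3, 0.7),
    background: tuple[float, float] = (0.05, 0.4),
) -> SyntheticTruth:
    """Ground-truth X with a requested nonzero fraction.

    ``sparsity`` is the fraction of (unordered) mark pairs with nonzero
    interaction probability.  With ``block_structure`` the nonzero mass is
    placed preferentially within the given mark groups (high within-group
    probabilities, occasional low off-group entries), yielding the
    sparse-plus-low-rank structure the penalties target.
    """
    if not 0.0 <= sparsity <= 1.0:
        raise ValidationError("sparsity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    X = np.zeros((n_marks, n_marks))
    r, c = np.triu_indices(n_marks)
    n_pairs = len(r)
    n_nonzero = int(round(sparsity * n_pairs))
    if n_nonzero > 0:
        if block_structure:
            in_block = np.zeros(n_pairs, dtype=bool)
            for group in block_structure:
                gs = set(group)
                in_block |= np.array(
                    [ri in gs and ci in gs for ri, ci in zip(r, c)]
                )
            order = np.concatenate(
                [
                    rng.permutation(np.nonzero(in_block)[0]),
                    rng.permutation(np.nonzero(~in_block)[0]),
                ]
            )
            pick = order[:n_nonzero]
            vals = np.where(
                in_block[pick],
                rng.uniform(*within_block, size=n_nonzero),
                rng.uniform(*background, size=n_nonzero),
            )
        else:
            pick = rng.choice(n_pairs, size=n_nonzero, replace=False)
            vals = rng.uniform(*background, size=n_nonzero)
        X[r[pick], c[pick]] = vals
        X[c[pick], r[pick]] = vals
    catalog = MarkCatalog(tuple(f"mark{i:02d}" for i in range(n_marks)))
    density = rng.uniform(*density_range, size=n_marks)
    return SyntheticTruth(
        X_true=MarkPairMatrix(X, catalog),
        n_sites=n_sites,
        mark_density=density,
        seed=seed,
        block_structure=block_structure,
        params={
            "sparsity": sparsity,
            "n_chroms": n_chroms,
            "density_range": list(density_range),
            "within_block": list(within_block),
            "background": list(background),
        },
    )


def _site_index(n_sites: int, n_chroms: int = 1, binned: bool = False,
                resolution: int | None = None) -> SiteIndex:
    per = n_sites // n_chroms
    sizes = [per + (1 if i < n_sites % n_chroms else 0) for i in range(n_chroms)]
    chroms = np.concatenate(
        [np.full(s, f"chrS{i + 1}", dtype=object) for i, s in enumerate(sizes)]
    )
    pos = np.concatenate(
        [np.arange(s, dtype=np.int64) * SITE_SPACING + SITE_SPACING // 2
         for s in sizes]
    )
    return SiteIndex(chroms, pos, resolution=resolution if binned else None)


def sample_assignment(
    truth: SyntheticTruth, binned: bool = False, seed: int | None = None
) -> MarkAssignment:
    """Sample a mark assignment: Bernoulli indicators (unbinned) or Poisson
    counts with the same per-mark rates (binned)."""
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    n, density = truth.n_sites, truth.mark_density
    n_chroms = int(truth.params.get("n_chroms", 1))
    if binned:
        index = _site_index(n, n_chroms, binned=True, resolution=SITE_SPACING)
        counts = rng.poisson(np.broadcast_to(density, (n, len(density))))
    else:
        index = _site_index(n, n_chroms)
        counts = (rng.random((n, len(density))) < density).astype(np.int64)
    return MarkAssignment(counts, truth.X_true.catalog, index)


def sample_contacts(
    truth: SyntheticTruth,
    assignment: MarkAssignment,
    mode: str = "unbinned",
    seed: int | None = None,
    block_size: int = 2000,
) -> ContactRecords:
    """Sample the contact graph pair-independently from the truth matrix.

    ``unbinned``: each pair is an edge with the survival-product probability.
    ``binned-exact``: per-pair count sampled slot-by-slot (Poisson-binomial).
    ``binned-lecam``: per-pair count ~ Poisson(C_u^T X C_v).
    """
    if mode not in CONTACT_MODES:
        raise ValidationError(f"mode must be one of {CONTACT_MODES}")
    rng = np.random.default_rng(truth.seed + 2 if seed is None else seed)
    A = assignment.counts
    X = truth.X_true.X
    binned = mode != "unbinned"
    iu_all, iv_all, k_all = [], [], []
    # pairs are sampled within chromosomes (the likelihood's default scope)
    for rows_c in assignment.index.chromosome_groups().values():
        Ac = A[rows_c]
        nc = len(rows_c)
        for start in range(0, nc, block_size):
            rows = np.arange(start, min(start + block_size, nc))
            if mode == "unbinned":
                Z = truth.X_true.Z
                S = (Ac[rows] @ Z) @ Ac.T  # s_uv for block rows x all in chrom
                P = -np.expm1(-S)
                draw = rng.random(P.shape) < P
                bu, bv = np.nonzero(draw)
                keep = rows[bu] < bv  # strict upper triangle, u < v
                iu_all.append(rows_c[rows[bu][keep]])
                iv_all.append(rows_c[bv[keep]])
                k_all.append(np.ones(int(keep.sum()), dtype=np.int64))
            elif mode == "binned-lecam":
                lam = (Ac[rows] @ X) @ Ac.T
                counts = rng.poisson(lam)
                bu, bv = np.nonzero(counts > 0)
                keep = rows[bu] < bv
                iu_all.append(rows_c[rows[bu][keep]])
                iv_all.append(rows_c[bv[keep]])
                k_all.append(counts[bu, bv][keep])
            else:  # binned-exact: slot-by-slot Bernoulli per pair
                for u in rows:
                    for v in range(u + 1, nc):
                        slots = pair_slot_probs(Ac[u], Ac[v], X)
                        if len(slots) == 0:
                            continue
                        k = int((rng.random(len(slots)) < slots).sum())
                        if k > 0:
                            iu_all.append(np.array([rows_c[u]]))
                            iv_all.append(np.array([rows_c[v]]))
                            k_all.append(np.array([k], dtype=np.int64))
    if iu_all:
        iu = np.concatenate(iu_all)
        iv = np.concatenate(iv_all)
        k = np.concatenate(k_all)
    else:
        iu = iv = np.empty(0, dtype=np.intp)
        k = np.empty(0, dtype=np.int64)
    return ContactRecords(iu, iv, k, assignment.index, binned)


FIXTURE_SIZES = {
    # name -> (n_marks, n_sites, n_chroms, density_range, within_block, background)
    # medium mirrors a 16-mark catalog at a few thousand sites across several
    # pseudo-chromosomes; its interaction probabilities are scaled down so the
    # contact graph stays realistically sparse for the larger catalog
    "tiny": (3, 8, 1, (0.3, 0.7), (0.3, 0.7), (0.05, 0.4)),
    "small": (6, 500, 1, (0.05, 0.3), (0.3, 0.7), (0.05, 0.4)),
    "medium": (16, 3000, 6, (0.02, 0.12), (0.1, 0.3), (0.02, 0.1)),
}


def make_fixture_suite(seed: int, directory: str | Path | None = None) -> dict:
    """Generate the (tiny, small, medium) datasets with truth attached.

    Each bundle has an unbinned assignment and contact graph sampled from a
    sparse block-structured truth; when ``directory`` is given everything is
    also written through the package file formats plus a truth sidecar.
    """
    suite = {}
    for name, (n_marks, n_sites, n_chroms, dens, within, bg) in FIXTURE_SIZES.items():
        blocks = _default_blocks(n_marks)
        truth = make_truth(
            n_marks,
            sparsity=0.35,
            block_structure=blocks,
            seed=seed + {"tiny": 11, "small": 12, "medium": 13}[name],
            n_sites=n_sites,
            n_chroms=n_chroms,
            density_range=dens,
            within_block=within,
            background=bg,
        )
        assignment = sample_assignment(truth)
        contacts = sample_contacts(truth, assignment, mode="unbinned")
        suite[name] = {"truth": truth, "assignment": assignment, "contacts": contacts}
        if directory is not None:
            d = Path(directory) / name
            d.mkdir(parents=True, exist_ok=True)
            hio.write_contacts(contacts, d / "contacts.tsv")
            hio.write_assignment_beds(assignment, d / "peaks")
            hio.write_mark_pair_matrix(truth.X_true, d / "X_true.tsv")
            with open(d / "truth_config.json", "w") as fh:
                json.dump(
                    {
                        "seed": truth.seed,
                        "n_sites": truth.n_sites,
                        "mark_density": truth.mark_density.tolist(),
                        "block_structure": truth.block_structure,
                        **truth.params,
                    },
                    fh,
                    indent=2,
                    sort_keys=True,
                )
    return suite


def _default_blocks(n_marks: int) -> list[list[int]]:
    half = n_marks // 2
    return [list(range(half)), list(range(half, n_marks))]


def exact_pmf_for_pair(
    truth: SyntheticTruth, c_u: np.ndarray, c_v: np.ndarray
) -> np.ndarray:
    """Poisson-binomial pmf of the count between two bins under the truth."""
    return poisson_binomial_pmf_vector(pair_slot_probs(c_u, c_v, truth.X_true.X))
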