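"""Domain containers for the mark-pair contact decomposition.

The model operates on three objects: a catalog of chromatin marks, an index
of genomic sites (restriction sites, or fixed-width bins after binning), and
the contact graph between those sites.  The fitted quantity is a symmetric
matrix ``X`` of mark-pair interaction probabilities, carried together with
its unconstrained transform ``Z`` where ``x = 1 - exp(-z)`` entrywise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass(frozen=True)
class MarkCatalog:
    """Ordered catalog of chromatin-mark identifiers.

    The order is fixed for the lifetime of a fitted model: rows and columns
    of every mark-pair matrix are addressed by this order.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(self.names)
        if len(set(names)) != len(names):
            raise ValidationError("mark names must be unique")
        object.__setattr__(self, "names", names)

    def __len__(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class SiteIndex:
    """Ordered genomic sites (restriction sites) or bins.

    Coordinates are 0-based; bins are half-open ``[start, start+resolution)``.
    ``resolution`` is ``None`` for unbinned (point) sites.
    """

    chroms: np.ndarray  # object array of chromosome names, len n
    positions: np.ndarray  # int array: site position, or bin start
    resolution: int | None = None

    def __post_init__(self) -> None:
        chroms = np.asarray(self.chroms, dtype=object)
        positions = np.asarray(self.positions, dtype=np.int64)
        if chroms.shape != positions.shape:
            raise ValidationError("chroms and positions must have equal length")
        seen = set(zip(chroms.tolist(), positions.tolist()))
        if len(seen) != len(positions):
            raise ValidationError("site coordinates must be unique per chromosome")
        object.__setattr__(self, "chroms", chroms)
        object.__setattr__(self, "positions", positions)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def binned(self) -> bool:
        return self.resolution is not None

    def lookup(self) -> dict[tuple[str, int], int]:
        """Map (chrom, position) -> row index."""
        return {
            (c, int(p)): i
            for i, (c, p) in enumerate(zip(self.chroms, self.positions))
        }

    def chromosome_groups(self) -> dict[str, np.ndarray]:
        """Row indices per chromosome, in index order."""
        groups: dict[str, list[int]] = {}
        for i, c in enumerate(self.chroms):
            groups.setdefault(c, []).append(i)
        return {c: np.asarray(ix, dtype=np.intp) for c, ix in groups.items()}


@dataclass
class MarkAssignment:
    """Per-site (or per-bin) mark count matrix over a catalog.

    ``counts`` is ``|sites| x |marks|`` nonnegative integers; binary in the
    unbinned case (a mark either is or is not near a restriction site),
    sums of member-site indicators after binning.
    """

    counts: np.ndarray
    catalog: MarkCatalog
    index: SiteIndex

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.index), len(self.catalog)):
            raise ValidationError(
                f"counts must be |sites| x |marks| = {len(self.index)} x {len(self.catalog)}"
            )
        if np.any(counts < 0):
            raise ValidationError("mark counts must be nonnegative")
        if not self.index.binned and np.any(counts > 1):
            raise ValidationError("unbinned mark indicators must be binary")
        self.counts = counts.astype(np.float64)

    @property
    def n_sites(self) -> int:
        return len(self.index)

    @property
    def n_marks(self) -> int:
        return len(self.catalog)

    def copy(self) -> "MarkAssignment":
        return MarkAssignment(self.counts.copy(), self.catalog, self.index)


@dataclass
class ContactRecords:
    """Undirected contact graph over a site index.

    Pairs are stored once with ``u < v`` (row-index order); counts are
    positive integers.  In unbinned mode counts are interpreted as
    presence/absence.
    """

    iu: np.ndarray  # int row indices, iu < iv elementwise
    iv: np.ndarray
    counts: np.ndarray
    index: SiteIndex
    binned: bool = False

    def __post_init__(self) -> None:
        iu = np.asarray(self.iu, dtype=np.intp)
        iv = np.asarray(self.iv, dtype=np.intp)
        counts = np.asarray(self.counts, dtype=np.int64)
        if not (iu.shape == iv.shape == counts.shape):
            raise ValidationError("iu, iv, counts must have equal length")
        if np.any(iu == iv):
            raise ValidationError("self-pairs are not allowed")
        if np.any(counts <= 0):
            raise ValidationError("contact counts must be positive")
        swap = iu > iv
        iu2 = np.where(swap, iv, iu)
        iv2 = np.where(swap, iu, iv)
        # merge duplicates
        order = np.lexsort((iv2, iu2))
        iu2, iv2, counts = iu2[order], iv2[order], counts[order]
        if len(iu2):
            key = iu2 * (len(self.index) + 1) + iv2
            uniq, start = np.unique(key, return_index=True)
            summed = np.add.reduceat(counts, start)
            iu2, iv2, counts = iu2[start], iv2[start], summed
        self.iu, self.iv, self.counts = iu2, iv2, counts

    def __len__(self) -> int:
        return len(self.iu)

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())

    def pair_set(self) -> set[tuple[int, int]]:
        return set(zip(self.iu.tolist(), self.iv.tolist()))

    def copy(self) -> "ContactRecords":
        return ContactRecords(
            self.iu.copy(), self.iv.copy(), self.counts.copy(), self.index, self.binned
        )


@dataclass
class MarkPairMatrix:
    """Symmetric matrix of mark-pair interaction probabilities.

    ``X`` holds probabilities in [0, 1); ``Z = -log(1 - X)`` is the
    transform on which the penalized likelihood is convex.
    """

    X: np.ndarray
    catalog: MarkCatalog

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=np.float64)
        m = len(self.catalog)
        if X.shape != (m, m):
            raise ValidationError(f"X must be {m} x {m}")
        if not np.allclose(X, X.T, atol=1e-8):
            raise ValidationError("X must be symmetric")
        if np.any(X < 0) or np.any(X >= 1):
            raise ValidationError("X entries must lie in [0, 1)")
        self.X = (X + X.T) / 2.0

    @property
    def Z(self) -> np.ndarray:
        return -np.log1p(-self.X)

    @classmethod
    def from_z(cls, Z: np.ndarray, catalog: MarkCatalog) -> "MarkPairMatrix":
        Z = np.asarray(Z, dtype=np.float64)
        if np.any(Z < 0):
            raise ValidationError("Z entries must be nonnegative")
        return cls(-np.expm1(-Z), catalog)

    def upper_triangle(self, include_diagonal: bool = True) -> np.ndarray:
        m = self.X.shape[0]
        r, c = np.triu_indices(m, k=0 if include_diagonal else 1)
        return self.X[r, c]


@dataclass
class SyntheticTruth:
    """Ground truth bundle produced by the forward simulator."""

    X_true: MarkPairMatrix
    n_sites: int
    mark_density: np.ndarray  # per-mark Bernoulli rate (unbinned) / Poisson rate (binned)
    seed: int
    block_structure: list[list[int]] | None = None
    params: dict = field(default_factory=dict)
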