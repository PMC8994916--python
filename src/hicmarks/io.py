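"""Readers, writers, and preprocessing for peaks, contacts, and matrices.

File conventions
----------------
* peaks: BED3+ (tab-separated, 0-based half-open; extra columns ignored)
* contacts: whitespace-separated ``chromA posA chromB posB [count]``
* mark-pair matrix: labeled tab-separated square matrix, header row and
  first column carry mark names
* config: flat YAML key-value file
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    ContactRecords,
    MarkAssignment,
    MarkCatalog,
    MarkPairMatrix,
    SiteIndex,
    ValidationError,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised for malformed input lines, naming the offending line number."""


# ---------------------------------------------------------------------------
# readers


def read_peaks_bed(path: str | Path, mark_name: str = "") -> list[tuple[str, int, int]]:
    """Read BED3+ peak intervals, returning sorted (chrom, start, end) tuples."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValidationError(
                    f"{path}:{lineno}: interval end {end} <= start {start}"
                )
            intervals.append((chrom, start, end))
    intervals.sort(key=lambda t: (t[0], t[1], t[2]))
    return intervals


def read_contacts(
    path: str | Path, binned: bool = False, resolution: int | None = None
) -> ContactRecords:
    """Read a contact-pair file into :class:`ContactRecords`.

    Lines are ``chromA posA chromB posB [count]`` (count defaults to 1).
    Pairs are normalized to u < v by (chrom, pos); duplicates are summed;
    self-pairs are dropped with a warning.
    """
    rec: list[tuple[str, int, str, int, int]] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) not in (4, 5):
                raise ParseError(f"{path}:{lineno}: expected 4 or 5 fields")
            try:
                ca, pa, cb, pb = fields[0], int(fields[1]), fields[2], int(fields[3])
                count = int(fields[4]) if len(fields) == 5 else 1
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field") from exc
            if count < 0:
                raise ValidationError(f"{path}:{lineno}: negative count {count}")
            if count == 0:
                continue
            if (ca, pa) == (cb, pb):
                dropped += 1
                continue
            rec.append((ca, pa, cb, pb, count))
    if dropped:
        logger.warning("read_contacts: dropped %d self-pair line(s)", dropped)
    coords = sorted({(c, p) for r in rec for c, p in ((r[0], r[1]), (r[2], r[3]))})
    index = SiteIndex(
        np.array([c for c, _ in coords], dtype=object),
        np.array([p for _, p in coords], dtype=np.int64),
        resolution=resolution if binned else None,
    )
    if not rec:
        empty = np.empty(0, dtype=np.intp)
        return ContactRecords(empty, empty, np.empty(0, dtype=np.int64), index, binned)
    look = index.lookup()
    iu = np.array([look[(r[0], r[1])] for r in rec], dtype=np.intp)
    iv = np.array([look[(r[2], r[3])] for r in rec], dtype=np.intp)
    counts = np.array([r[4] for r in rec], dtype=np.int64)
    return ContactRecords(iu, iv, counts, index, binned)


def write_contacts(contacts: ContactRecords, path: str | Path) -> None:
    index = contacts.index
    with open(path, "w") as fh:
        for u, v, c in zip(contacts.iu, contacts.iv, contacts.counts):
            fh.write(
                f"{index.chroms[u]}\t{index.positions[u]}\t"
                f"{index.chroms[v]}\t{index.positions[v]}\t{c}\n"
            )


def write_assignment_beds(
    assignment: MarkAssignment, directory: str | Path, width: int = 1
) -> list[Path]:
    """Write one BED file per mark; a site with indicator/count > 0 becomes a
    ``width``-bp interval starting at the site position (count in column 5)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    index = assignment.index
    for j, name in enumerate(assignment.catalog.names):
        p = directory / f"{name}.bed"
        with open(p, "w") as fh:
            for i in np.nonzero(assignment.counts[:, j] > 0)[0]:
                pos = int(index.positions[i])
                fh.write(
                    f"{index.chroms[i]}\t{pos}\t{pos + width}\t{name}\t"
                    f"{int(assignment.counts[i, j])}\n"
                )
        paths.append(p)
    return paths


def write_mark_pair_matrix(matrix: MarkPairMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        matrix.X, index=list(matrix.catalog.names), columns=list(matrix.catalog.names)
    )
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_mark_pair_matrix(path: str | Path) -> MarkPairMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: row and column mark labels differ")
    return MarkPairMatrix(df.to_numpy(dtype=float), MarkCatalog(tuple(df.columns)))


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a key-value mapping")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# preprocessing


def map_marks_to_sites(
    peaks: dict[str, list[tuple[str, int, int]]],
    sites: SiteIndex,
    max_dist: int = 100,
) -> MarkAssignment:
    """Assign each mark to every site within ``max_dist`` bp of one of its peaks.

    Distance is 0 when the site position lies inside the half-open peak
    interval, otherwise the gap to the nearest peak edge; the threshold is
    inclusive.  Chromosomes present in peaks but absent from sites are
    skipped with a warning.
    """
    if sites.binned:
        raise ValidationError("map_marks_to_sites expects unbinned (point) sites")
    if max_dist < 0:
        raise ValidationError("max_dist must be >= 0")
    catalog = MarkCatalog(tuple(peaks.keys()))
    counts = np.zeros((len(sites), len(catalog)), dtype=np.int64)
    groups = sites.chromosome_groups()
    for j, (mark, intervals) in enumerate(peaks.items()):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivals in by_chrom.items():
            if chrom not in groups:
                logger.warning(
                    "map_marks_to_sites: chromosome %r in peaks for %s absent from sites",
                    chrom,
                    mark,
                )
                continue
            rows = groups[chrom]
            pos = sites.positions[rows]
            starts = np.array([s for s, _ in ivals])
            ends = np.array([e for _, e in ivals])
            # gap(site, [s, e)): 0 inside, else distance to the nearest edge
            gap = np.maximum(
                starts[None, :] - pos[:, None], pos[:, None] - ends[None, :]
            )
            gap = np.maximum(gap, 0)
            hit = (gap <= max_dist).any(axis=1)
            counts[rows[hit], j] = 1
    return MarkAssignment(counts, catalog, sites)


def _bin_index(
    sites: SiteIndex, resolution: int
) -> tuple[SiteIndex, np.ndarray]:
    """Binned index plus a site -> bin-row map."""
    bins = sorted(
        {(c, int(p) // resolution * resolution) for c, p in zip(sites.chroms, sites.positions)}
    )
    binned = SiteIndex(
        np.array([c for c, _ in bins], dtype=object),
        np.array([s for _, s in bins], dtype=np.int64),
        resolution=resolution,
    )
    look = binned.lookup()
    site_to_bin = np.array(
        [
            look[(c, int(p) // resolution * resolution)]
            for c, p in zip(sites.chroms, sites.positions)
        ],
        dtype=np.intp,
    )
    return binned, site_to_bin


def bin_assignment(assignment: MarkAssignment, resolution: int) -> MarkAssignment:
    """Aggregate unbinned mark indicators into per-bin counts."""
    if assignment.index.binned:
        raise ValidationError("assignment is already binned")
    binned, site_to_bin = _bin_index(assignment.index, resolution)
    counts = np.zeros((len(binned), assignment.n_marks), dtype=np.int64)
    np.add.at(counts, site_to_bin, assignment.counts.astype(np.int64))
    return MarkAssignment(counts, assignment.catalog, binned)


def bin_contacts(contacts: ContactRecords, resolution: int) -> ContactRecords:
    """Aggregate unbinned contacts onto a bin grid, summing member-pair counts.

    Pairs whose two ends fall in the same bin are dropped (the likelihood is
    over distinct node pairs); the dropped total is logged.
    """
    if contacts.binned:
        raise ValidationError("contacts are already binned")
    binned, site_to_bin = _bin_index(contacts.index, resolution)
    bu = site_to_bin[contacts.iu]
    bv = site_to_bin[contacts.iv]
    intra = bu == bv
    n_intra = int(contacts.counts[intra].sum())
    if n_intra:
        logger.info("bin_contacts: dropped %d intra-bin contact count(s)", n_intra)
    keep = ~intra
    if not keep.any():
        empty = np.empty(0, dtype=np.intp)
        return ContactRecords(empty, empty, np.empty(0, dtype=np.int64), binned, True)
    return ContactRecords(bu[keep], bv[keep], contacts.counts[keep], binned, True)


def rpkm_log_binarize(
    values: np.ndarray, threshold: float = 0.5, log_base: float = math.e
) -> np.ndarray:
    """Binarize a per-bin signal matrix: average replicates, log(1+x), threshold.

    ``values`` is bins x replicates (or 1-D for a single replicate); the
    threshold is inclusive.  Replicate averaging precedes the log transform.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValidationError("signal values must be nonnegative")
    mean = values if values.ndim == 1 else values.mean(axis=1)
    logged = np.log1p(mean) / math.log(log_base)
    return (logged >= threshold).astype(np.int64)
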