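import numpy as np
import pytest

from hicmarks.datamodel import (
    ContactRecords,
    MarkAssignment,
    MarkCatalog,
    SiteIndex,
)
from hicmarks.synthetic import make_fixture_suite


@pytest.fixture(scope="session")
def fixture_suite():
    """The standard (tiny, small, medium) synthetic bundles, one generation."""
    return make_fixture_suite(1)


@pytest.fixture
def simple_sites():
    """Three unbinned sites on one chromosome."""
    return SiteIndex(
        np.array(["chr1", "chr1", "chr1"], dtype=object),
        np.array([0, 1000, 2000]),
    )


@pytest.fixture
def one_mark_assignment(simple_sites):
    cat = MarkCatalog(("m",))
    return MarkAssignment(np.array([[1], [1], [1]]), cat, simple_sites)


def make_random_instance(seed, n_sites=12, n_marks=3, density=0.5, edge_rate=0.2,
                         n_chroms=1):
    """Small random assignment + contact graph (not drawn from the model);
    used where only structural validity matters."""
    rng = np.random.default_rng(seed)
    per = n_sites // n_chroms
    chroms = np.concatenate(
        [np.full(per, f"chr{i}", dtype=object) for i in range(n_chroms)]
    )
    pos = np.concatenate([np.arange(per) * 1000 for _ in range(n_chroms)])
    index = SiteIndex(chroms, pos)
    counts = (rng.random((len(chroms), n_marks)) < density).astype(int)
    cat = MarkCatalog(tuple(f"m{i}" for i in range(n_marks)))
    assignment = MarkAssignment(counts, cat, index)
    iu, iv = [], []
    groups = index.chromosome_groups()
    for rows in groups.values():
        for a in range(len(rows)):
            for b in range(a + 1, len(rows)):
                if rng.random() < edge_rate:
                    iu.append(rows[a])
                    iv.append(rows[b])
    if not iu:
        iu, iv = [0], [1]
    contacts = ContactRecords(
        np.array(iu), np.array(iv), np.ones(len(iu), dtype=np.int64), index
    )
    return assignment, contacts
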