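import numpy as np
import pandas as pd
import pytest

from pycape.cross_io import Cross
from pycape.eigentraits import EigentraitBasis, NormalizationRecord


def make_basis(E, sample_index=None, phen_names=None):
    """Wrap an arbitrary ET matrix in an EigentraitBasis for scan tests."""
    E = np.asarray(E, dtype=float)
    n, k = E.shape
    if sample_index is None:
        sample_index = pd.Index([str(i + 1) for i in range(n)])
    if phen_names is None:
        phen_names = [f"p{i + 1}" for i in range(k)]
    return EigentraitBasis(
        left_vectors=E,
        singular_values=np.ones(k),
        right_vectors=np.eye(k),
        phenotype_names=list(phen_names),
        sample_index=sample_index,
        normalization=NormalizationRecord(),
        selected=tuple(range(k)),
    )


def make_cross(genotype_cols: dict, phen=None, chromosomes=None, positions=None):
    """Build a small Cross from genotype column vectors."""
    G = pd.DataFrame({k: np.asarray(v, dtype=float)
                      for k, v in genotype_cols.items()})
    n = len(G)
    G.index = pd.Index([str(i + 1) for i in range(n)], name="individual")
    if phen is None:
        rng = np.random.default_rng(0)
        phen = pd.DataFrame(rng.standard_normal((n, 2)),
                            index=G.index, columns=["p1", "p2"])
    else:
        phen = pd.DataFrame(phen, index=G.index)
    markers = list(G.columns)
    chrom = chromosomes or {m: "1" for m in markers}
    pos = positions or {m: float(i) for i, m in enumerate(markers)}
    mmap = pd.DataFrame(
        {"chromosome": [chrom[m] for m in markers],
         "position": [pos[m] for m in markers]},
        index=pd.Index(markers, name="marker"),
    )
    cross = Cross(phenotypes=phen, genotypes=G, map=mmap)
    cross.validate()
    return cross


@pytest.fixture(scope="session")
def edge_cross():
    from pycape.simdata import make_fixture
    return make_fixture("one_directed_edge", 3)


@pytest.fixture(scope="session")
def example_like_cross():
    from pycape.simdata import make_fixture
    return make_fixture("example_like", 7)
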