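import random

import pytest

import rfsolve as rf
from rfsolve.bipartition import Bipartition


@pytest.fixture
def e1_sources():
    """Three quartet sources on {a..e} with a unique perfect supertree."""
    return [
        rf.parse_newick("((a,b),(c,d));"),
        rf.parse_newick("((a,b),(c,e));"),
        rf.parse_newick("((b,c),(d,e));"),
    ]


@pytest.fixture
def e1_index(e1_sources):
    return rf.build_taxon_index(e1_sources)


@pytest.fixture
def e2_sources():
    """The three mutually incompatible quartets on {a,b,c,d}."""
    return [
        rf.parse_newick("((a,b),(c,d));"),
        rf.parse_newick("((a,c),(b,d));"),
        rf.parse_newick("((a,d),(b,c));"),
    ]


@pytest.fixture
def e2_index(e2_sources):
    return rf.build_taxon_index(e2_sources)


def all_bipartitions(index):
    """Every nontrivial bipartition of the full taxon set."""
    full = index.full_mask
    out = []
    for m in range(1, full):
        if not m & 1:  # canonical side holds the lowest taxon
            continue
        c = full ^ m
        if m.bit_count() >= 2 and c.bit_count() >= 2:
            out.append(Bipartition.of(m, c))
    return out


def random_labels(n):
    return [f"x{i:02d}" for i in range(n)]


def random_tree(n, seed):
    return rf.random_binary_tree(random_labels(n), random.Random(seed))


def random_instance(seed, n=None, k=None, nni=None):
    """Seeded (model, sources, index) triple at oracle-checkable size."""
    n = n if n is not None else [5, 6, 7][seed % 3]
    k = k if k is not None else [3, 5][(seed // 3) % 2]
    nni = nni if nni is not None else (seed // 6) % 3
    model = rf.simulate_model_tree(n, seed)
    cfg = rf.SimulationConfig(
        n_taxa=n,
        scaffold_density=0.8,
        n_clade_trees=k - 1,
        nni_perturbations=nni,
        seed=seed,
    )
    sources = rf.simulate_sources(model, cfg)
    return model, sources, rf.build_taxon_index(sources)
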