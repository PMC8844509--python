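import numpy as np
import pytest

import phylogd as pg

# single master seed for the whole suite; derived streams are spawned
MASTER_SEED = 42


@pytest.fixture(scope="session")
def abc_tree():
    """((A,B),C) species tree: ids 0=A 1=B 2=(A,B) 3=C 4=root."""
    return pg.parse_newick("((A:1,B:1):1,C:2);", kind="species")


@pytest.fixture(scope="session")
def balanced8():
    return pg.default_species_tree()


def make_caterpillar(n_tips: int) -> "pg.SpeciesTree":
    nwk = "t1"
    for i in range(2, n_tips + 1):
        nwk = f"({nwk}:1,t{i}:1)"
    return pg.parse_newick(nwk + ";", kind="species")


@pytest.fixture(scope="session")
def caterpillar31():
    """31 tips -> exactly 30 internal nodes (including the root)."""
    return make_caterpillar(31)


def tuple_to_gene_newick(tree, counter=None) -> str:
    """Nested species tuples -> gene-tree newick with unique gene ids."""
    if counter is None:
        counter = {"i": 0}

    def walk(node):
        if isinstance(node, str):
            counter["i"] += 1
            return f"{node}|g{counter['i']}"
        return "(" + ",".join(walk(c) for c in node) + ")100"

    return walk(tree) + ";"


def rng_for(*key) -> np.random.Generator:
    """Deterministic generator derived from the suite master seed."""
    import zlib

    ss = np.random.SeedSequence(
        [MASTER_SEED] + [zlib.crc32(repr(k).encode()) for k in key])
    return np.random.default_rng(ss)
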