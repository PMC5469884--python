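import numpy as np
import pandas as pd
import pytest

from microeuk.io import CountTable, Lineage
from microeuk.simulate import paper_shaped_fixture


@pytest.fixture
def small_table() -> CountTable:
    # 2 OTUs x 2 samples; library sizes (4, 6)
    return CountTable(
        pd.DataFrame([[1, 2], [3, 4]], index=["otu1", "otu2"], columns=["s1", "s2"])
    )


@pytest.fixture
def toy_taxonomy() -> dict:
    def lin(otu, s):
        ranks = tuple(s.split(";"))
        from microeuk.io import load_major_group_map, resolve_major_group

        return Lineage(otu, ranks, resolve_major_group(ranks, load_major_group_map()))

    return {
        "otu1": lin("otu1", "Eukaryota;Alveolata;Ciliophora;Spirotrichea;x;x;g;sp1"),
        "otu2": lin("otu2", "Eukaryota;Rhizaria;Cercozoa;Filosa;x;x;g;sp2"),
        "otu3": lin("otu3", "Eukaryota;Opisthokonta;Metazoa;Arthropoda;x;x;g;sp3"),
    }


@pytest.fixture(scope="session")
def survey_fixture():
    """Small survey-shaped synthetic dataset shared across tests."""
    return paper_shaped_fixture(seed=7, n_otus_per_group=12)


def random_table(rng: np.random.Generator, n_otus=None, n_samples=None) -> CountTable:
    n_otus = n_otus or int(rng.integers(2, 21))
    n_samples = n_samples or int(rng.integers(2, 7))
    counts = rng.integers(0, 30, size=(n_otus, n_samples))
    # avoid all-zero samples
    for j in range(n_samples):
        if counts[:, j].sum() == 0:
            counts[rng.integers(0, n_otus), j] = 1
    return CountTable(
        pd.DataFrame(
            counts,
            index=[f"o{i}" for i in range(n_otus)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )


def random_tree(rng: np.random.Generator, tip_names):
    from skbio import TreeNode

    nodes = [TreeNode(name=n, length=float(rng.exponential(1.0))) for n in tip_names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(length=float(rng.exponential(1.0)), children=[a, b]))
    nodes[0].length = None
    return nodes[0]
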