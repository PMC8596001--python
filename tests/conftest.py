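import numpy as np
import pandas as pd
import pytest

from termevol import Phylogeny, SimConfig, simulate_bd_tree


@pytest.fixture
def cherry3():
    """3-tip ultrametric: ((A:1,B:1):1,C:2);"""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def fossil3():
    """3-tip non-ultrametric: C is a fossil ending at depth 1."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:1);")


def random_tree(seed, n_extant=6, death=0.5, retention=0.5):
    cfg = SimConfig(n_extant=n_extant, death=death, fossil_retention=retention,
                    seed=seed)
    return simulate_bd_tree(cfg, seed)


@pytest.fixture
def random_tree_factory():
    return random_tree


@pytest.fixture
def species_records():
    """A small hand-built trait table: 3 modern genera, 1 fossil species."""
    rows = []
    for genus, widths in [("Alpha", [1.0, 1.2, 1.4]), ("Beta", [2.0]),
                          ("Gamma", [0.8, 0.9])]:
        for i, w in enumerate(widths):
            rows.append(dict(species=f"{genus}_sp{i+1}", genus=genus,
                             family="Fam", caste="imago", head_width_mm=w,
                             status="modern"))
    rows.append(dict(species="Fossilus_antiquus", genus="Fossilus",
                     family="Fam", caste="imago", head_width_mm=1.5,
                     status="fossil"))
    return pd.DataFrame(rows)


def vcv_bruteforce(tree):
    """Shared root-path length per tip pair, by explicit path enumeration."""
    paths = []
    for t in tree.tips:
        path = []
        v = int(t)
        while v != 0:
            path.append(v)
            v = int(tree.parent[v])
        paths.append(set(path))
    n = tree.n_tips
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            C[i, j] = sum(tree.blen[v] for v in paths[i] & paths[j])
    return C
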