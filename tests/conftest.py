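import itertools

import numpy as np
import pytest
from hypothesis import settings

import syntenycamp as sc

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def human_annotation():
    return sc.builtin_fixture("human_table1")


@pytest.fixture(scope="session")
def enhancer_blocks():
    return sc.builtin_fixture("enhancers_table2")


@pytest.fixture(scope="session")
def fig1_tree():
    return sc.builtin_fixture("species_tree_fig1")


@pytest.fixture(scope="session")
def fig1_presence():
    return sc.builtin_fixture("species_presence_fig1")


def random_binary_tree(rng: np.random.Generator, n_leaves: int, labels=None) -> sc.SpeciesTree:
    """Random rooted binary tree by sequential joins (unit branch lengths)."""
    if labels is None:
        labels = [f"L{i}" for i in range(n_leaves)]
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return sc.SpeciesTree.from_newick(nodes[0] + ";")


def exhaustive_dollo_min_losses(tree: sc.SpeciesTree, present, absent):
    """Independent oracle: minimum loss count over all single-gain placements.

    Enumerates every candidate gain edge whose clade covers all present
    leaves, then every subset of strictly-descendant edges (smallest
    first) until one explains the observations.
    """
    present, absent = frozenset(present), frozenset(absent)
    best = None
    for gain in tree.clades():
        if not present <= gain:
            continue
        below = [c for c in tree.clades() if c < gain]
        found = None
        for k in range(len(below) + 1):
            for combo in itertools.combinations(below, k):
                losses = set(combo)
                consistent = True
                for leaf in gain:
                    lost = any(frozenset([leaf]) <= e for e in losses)
                    if leaf in present and lost:
                        consistent = False
                    elif leaf in absent and not lost:
                        consistent = False
                    if not consistent:
                        break
                if consistent:
                    found = k
                    break
            if found is not None:
                break
        if found is not None and (best is None or found < best):
            best = found
    return best


def brute_force_duplications(cluster_tree: sc.SpeciesTree, species_tree: sc.SpeciesTree, leaf_map):
    """Independent duplication oracle via path-to-root LCA intersection."""

    def species_lca(species_set):
        paths = []
        for s in species_set:
            paths.append(set(species_tree.path_to_root(frozenset([s]))))
        common = set.intersection(*paths)
        return min(common, key=len)

    dups = set()
    for clade in cluster_tree.clades():
        if cluster_tree.is_leaf(clade):
            continue
        img = species_lca({leaf_map[l] for l in clade})
        for child in cluster_tree.children(clade):
            if species_lca({leaf_map[l] for l in child}) == img:
                dups.add(clade)
                break
    return dups
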