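from __future__ import annotations

import random

import pytest

from synterec.io_formats import read_tree
from synterec.reconciliation import SlicedTree
from synterec.trees import DatedSpeciesTree, GeneTree, TreeNode


def species(newick: str) -> DatedSpeciesTree:
    return read_tree(newick, kind="species")


def gene(newick: str, species_map=None) -> GeneTree:
    return read_tree(newick, kind="gene", species_map=species_map)


@pytest.fixture
def three_taxon():
    """((A,B) at age 1, C) at age 2 — the canonical toy chronogram."""
    t = species("((A:1,B:1):1,C:2);")
    return t, SlicedTree(t)


def random_chronogram(rng: random.Random, n_taxa: int) -> DatedSpeciesTree:
    """Random coalescent-style ultrametric tree with distinct node ages."""
    nodes = [TreeNode(f"T{i}") for i in range(n_taxa)]
    ages = {id(n): 0.0 for n in nodes}
    age = 0.0
    while len(nodes) > 1:
        age += rng.uniform(0.2, 1.0)
        i, j = rng.sample(range(len(nodes)), 2)
        a, b = nodes[i], nodes[j]
        parent = TreeNode()
        a.length = age - ages[id(a)]
        b.length = age - ages[id(b)]
        parent.add_child(a)
        parent.add_child(b)
        ages[id(parent)] = age
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return DatedSpeciesTree(nodes[0])


def random_gene_tree(rng: random.Random, taxa: list[str], n_leaves: int) -> GeneTree:
    """Random gene tree whose leaves draw species uniformly from ``taxa``."""
    leaves = []
    for i in range(n_leaves):
        sp = rng.choice(taxa)
        leaves.append(TreeNode(f"{sp}_{i}"))
    nodes = list(leaves)
    while len(nodes) > 1:
        i, j = rng.sample(range(len(nodes)), 2)
        parent = TreeNode()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return GeneTree(nodes[0])
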