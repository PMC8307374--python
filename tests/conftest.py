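"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import numpy as np
import dendropy
import pytest

from pttsminer.align import DistanceMatrix


def random_binary_tree(rng: np.random.Generator, n_leaves: int,
                       rooted: bool = False) -> dendropy.Tree:
    """Random binary tree with branch lengths drawn from U(0.05, 1)."""
    labels = [f"t{i}" for i in range(n_leaves)]
    tns = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=tns.get_taxon(lab)) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = round(float(rng.uniform(0.05, 1.0)), 6)
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[0]
    tree.is_rooted = rooted
    return tree


def additive_matrix_from_tree(tree: dendropy.Tree) -> DistanceMatrix:
    """Exact leaf-to-leaf path-length matrix of a tree (additive by
    construction)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[i], taxa[j])
    return DistanceMatrix(labels=tuple(labels), values=d)


def robinson_foulds(a: dendropy.Tree, b: dendropy.Tree) -> int:
    """Unrooted RF distance between two trees over the same leaf set."""
    tns = dendropy.TaxonNamespace()
    a2 = dendropy.Tree.get(data=a.as_string(schema="newick"), schema="newick",
                           taxon_namespace=tns)
    b2 = dendropy.Tree.get(data=b.as_string(schema="newick"), schema="newick",
                           taxon_namespace=tns)
    for t in (a2, b2):  # compare as unrooted splits
        t.is_rooted = False
        t.deroot()
        t.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a2, b2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
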