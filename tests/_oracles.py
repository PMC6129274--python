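"""Independent oracles used by the tests.

Everything here recomputes expected values by a route independent of the
package's propagation kernel: explicit path enumeration on trees and
random HOG construction that bypasses the OrthoXML layer.
"""
from __future__ import annotations

import numpy as np

from qtlprio.orthology import (GENE_LEAF, ORTHOLOG_GROUP, PARALOG_GROUP,
                               HOGNode, edge_factor, iter_nodes)
from qtlprio.propagation import PropagationParams


def random_hog(rng: np.random.Generator, max_leaves: int = 30,
               p_paralog: float = 0.4, min_leaves: int = 2) -> HOGNode:
    """A random HOG tree with 2..max_leaves gene leaves and random
    ortholog/paralog internal nodes (root kept an ortholog group)."""
    n = int(rng.integers(min_leaves, max_leaves + 1))
    counter = [0]

    def build(size: int, root: bool) -> HOGNode:
        if size == 1:
            counter[0] += 1
            return HOGNode(GENE_LEAF, gene_id=f"g{counter[0]}")
        n_parts = int(rng.integers(2, min(size, 4) + 1))
        cuts = sorted(rng.choice(np.arange(1, size), size=n_parts - 1, replace=False))
        sizes = np.diff([0, *cuts, size])
        kind = ORTHOLOG_GROUP if root or rng.random() >= p_paralog else PARALOG_GROUP
        return HOGNode(kind, children=[build(int(s), False) for s in sizes])

    return build(n, True)


def parent_map(tree: HOGNode) -> dict[HOGNode, HOGNode]:
    parents: dict[HOGNode, HOGNode] = {}
    for node in iter_nodes(tree):
        for child in node.children:
            parents[child] = node
    return parents


def path_edges(tree: HOGNode, a: HOGNode, b: HOGNode) -> list[HOGNode]:
    """Parents of every edge crossed on the a -> LCA -> b path."""
    parents = parent_map(tree)

    def ancestry(node: HOGNode) -> list[HOGNode]:
        chain = [node]
        while chain[-1] in parents:
            chain.append(parents[chain[-1]])
        return chain

    up_a = ancestry(a)
    up_b = ancestry(b)
    set_a = {id(n): i for i, n in enumerate(up_a)}
    lca_i_b = next(i for i, n in enumerate(up_b) if id(n) in set_a)
    lca = up_b[lca_i_b]
    lca_i_a = set_a[id(lca)]
    # each edge's factor is determined by the parent it hangs from
    edges = [parents[n] for n in up_a[:lca_i_a]]
    edges += [parents[n] for n in up_b[:lca_i_b]]
    return edges


def single_seed_finals(tree: HOGNode, seeded_gene: str, seed: float,
                       params: PropagationParams) -> dict[str, float]:
    """Brute-force expected final scores when exactly one leaf is seeded:
    seed times the product of edge factors along the leaf-to-leaf path."""
    leaves = [n for n in iter_nodes(tree) if n.is_leaf]
    source = next(l for l in leaves if l.gene_id == seeded_gene)
    finals: dict[str, float] = {}
    for leaf in leaves:
        if leaf is source:
            finals[leaf.gene_id] = seed
            continue
        product = 1.0
        for parent in path_edges(tree, source, leaf):
            product *= edge_factor(parent, params.decay, params.paralog_mode)
        finals[leaf.gene_id] = seed * product
    return finals
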