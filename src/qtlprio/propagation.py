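"""Score propagation through HOG trees (the core kernel).

Per-trait seed scores sit at the gene leaves.  They are pushed up the tree
— each internal node sums its children's scores, each crossing decayed by
the edge factor — and then pulled back down, each node taking the maximum
of its own up-phase score and the decayed score arriving from its parent.
The decay is 20% per edge by default; edges below a duplication node decay
twice over (the paralogy penalty).  The result is a post-propagation score
for every gene in the tree, never smaller than its own seed.

Traits are opaque labels: each trait's scores propagate independently.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .orthology import HOGNode, edge_factor, iter_nodes

__all__ = ["PropagationParams", "ScoreState", "up_propagate", "down_propagate", "propagate"]


@dataclass(frozen=True)
class PropagationParams:
    """Kernel parameters.

    decay:
        Fraction of score lost per edge, default 0.2.
    paralog_mode:
        ``squared_decay`` (default): paralog edges multiply by (1-d)**2;
        ``doubled_rate``: by 1-2d.
    """

    decay: float = 0.2
    paralog_mode: str = "squared_decay"

    def __post_init__(self) -> None:
        if not 0.0 <= self.decay < 1.0:
            raise ValueError(f"decay must be in [0, 1), got {self.decay}")
        if self.paralog_mode not in ("squared_decay", "doubled_rate"):
            raise ValueError(f"unknown paralog_mode {self.paralog_mode!r}")

    def factor(self, parent: HOGNode) -> float:
        return edge_factor(parent, self.decay, self.paralog_mode)


class ScoreState:
    """Per-node scores for one trait at one propagation phase.

    Keys are :class:`HOGNode` objects (identity-hashed); ``phase`` is one of
    ``"seeded"``, ``"up"``, ``"final"``.
    """

    def __init__(self, scores: dict[HOGNode, float], phase: str):
        self.scores = scores
        self.phase = phase

    def __getitem__(self, node: HOGNode) -> float:
        return self.scores.get(node, 0.0)


def _postorder(tree: HOGNode) -> list[HOGNode]:
    order = list(iter_nodes(tree))
    order.reverse()  # reversed pre-order visits children before parents
    return order


def up_propagate(
    tree: HOGNode, seeds: Mapping[str, float], params: PropagationParams | None = None
) -> ScoreState:
    """Push leaf seeds to the root: post-order; an internal node's score is
    the sum over children of ``child_score * edge_factor``.

    ``seeds`` maps gene_id -> non-negative seed; unseeded leaves score 0.
    """
    params = params or PropagationParams()
    for gene, seed in seeds.items():
        if seed < 0:
            raise ValueError(f"negative seed {seed} for gene {gene!r}")
    scores: dict[HOGNode, float] = {}
    for node in _postorder(tree):
        if node.is_leaf:
            scores[node] = seeds.get(node.gene_id, 0.0)
        else:
            factor = params.factor(node)
            scores[node] = factor * sum(scores[c] for c in node.children)
    return ScoreState(scores, "up")


def down_propagate(
    tree: HOGNode, up_state: ScoreState, params: PropagationParams | None = None
) -> ScoreState:
    """Pull scores from the root: pre-order; each child's final score is
    ``max(own up score, parent final * edge_factor)``.  The root's final
    score is its up score.
    """
    params = params or PropagationParams()
    finals: dict[HOGNode, float] = {tree: up_state[tree]}
    for node in iter_nodes(tree):
        if node.is_leaf:
            continue
        factor = params.factor(node)
        parent_final = finals[node]
        for child in node.children:
            finals[child] = max(up_state[child], parent_final * factor)
    return ScoreState(finals, "final")


def propagate(
    trees: Iterable[HOGNode],
    seeds: Mapping[str, float],
    params: PropagationParams | None = None,
    genes_of_interest: Iterable[str] | None = None,
) -> dict[str, float]:
    """Run up- then down-propagation over a HOG forest for one trait.

    Returns gene_id -> final score for every gene of an evaluated tree plus
    every seeded gene.  Genes in no tree keep their seed (a singleton is its
    own HOG).  When ``genes_of_interest`` is given, only trees containing a
    seeded gene or a gene of interest are evaluated — the rest cannot
    change any requested score.
    """
    params = params or PropagationParams()
    interest = set(genes_of_interest) if genes_of_interest is not None else None
    relevant = set(seeds) if interest is None else interest | set(seeds)
    finals: dict[str, float] = {g: s for g, s in seeds.items()}
    for tree in trees:
        leaves = [n for n in iter_nodes(tree) if n.is_leaf]
        if not any(leaf.gene_id in relevant for leaf in leaves):
            continue
        up = up_propagate(tree, seeds, params)
        final = down_propagate(tree, up, params)
        for leaf in leaves:
            finals[leaf.gene_id] = final[leaf]
    return finals
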