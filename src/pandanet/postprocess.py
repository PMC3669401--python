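"""Condition-specific edge and node extraction.

After running the refinement on several conditions, the interesting biology
usually lives in the edges that are strong in exactly one condition: take the
top-k edges of each network, intersect/difference the sets, and flag nodes
whose adjacency is dominated by condition-unique edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .netio import LabeledBipartiteNetwork

__all__ = ["EdgeSet", "top_k_edges", "condition_unique_edges", "condition_specific_nodes"]


@dataclass
class EdgeSet:
    """An ordered set of (TF, gene, weight) triples for one condition.

    Ordered by descending weight, ties broken lexicographically by (TF, gene);
    no duplicate (TF, gene) pairs.
    """

    condition: str
    edges: list[tuple[str, str, float]]
    tf_universe: frozenset = field(default_factory=frozenset)
    gene_universe: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        pairs = [(t, g) for t, g, _ in self.edges]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (TF, gene) pairs in edge set")
        self.edges = sorted(self.edges, key=lambda e: (-e[2], e[0], e[1]))

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return {(t, g) for t, g, _ in self.edges}

    def __len__(self) -> int:
        return len(self.edges)


def top_k_edges(network: LabeledBipartiteNetwork, k: int, condition: str = "") -> EdgeSet:
    """The k highest-weight TF->gene pairs, deterministic under weight ties.

    Ties at the k-th weight are resolved lexicographically by (TF, gene).
    """
    n_pairs = network.weights.size
    if not (0 < k <= n_pairs):
        raise ValueError(f"k must lie in (0, {n_pairs}], got {k}")
    triples = [
        (t, g, float(network.weights[i, j]))
        for i, t in enumerate(network.tf_labels)
        for j, g in enumerate(network.gene_labels)
    ]
    triples.sort(key=lambda e: (-e[2], e[0], e[1]))
    return EdgeSet(
        condition=condition,
        edges=triples[:k],
        tf_universe=frozenset(network.tf_labels),
        gene_universe=frozenset(network.gene_labels),
    )


def condition_unique_edges(edge_sets) -> tuple[dict[str, EdgeSet], EdgeSet]:
    """Split edge sets into per-condition unique edges and the common core.

    An edge is unique to a condition when it appears in that condition's set
    and in no other; the common set is the intersection of all sets.  Edges
    shared by some but not all conditions land in neither.
    """
    edge_sets = list(edge_sets)
    if len(edge_sets) < 2:
        raise ValueError("need at least 2 edge sets")
    universes = {(es.tf_universe, es.gene_universe) for es in edge_sets if es.tf_universe}
    if len(universes) > 1:
        raise ValueError("edge sets come from different label universes")
    pair_maps = [{(t, g): w for t, g, w in es.edges} for es in edge_sets]
    all_pairs = [set(m) for m in pair_maps]
    common_pairs = set.intersection(*all_pairs)
    uniques: dict[str, EdgeSet] = {}
    for es, mine, m in zip(edge_sets, all_pairs, pair_maps):
        others = set.union(*[o for o in all_pairs if o is not mine])
        uniq = mine - others
        uniques[es.condition] = EdgeSet(
            condition=es.condition,
            edges=[(t, g, m[(t, g)]) for t, g in uniq],
            tf_universe=es.tf_universe,
            gene_universe=es.gene_universe,
        )
    ref = pair_maps[0]
    common = EdgeSet(
        condition="common",
        edges=[(t, g, ref[(t, g)]) for t, g in common_pairs],
        tf_universe=edge_sets[0].tf_universe,
        gene_universe=edge_sets[0].gene_universe,
    )
    return uniques, common


def condition_specific_nodes(
    unique: EdgeSet,
    full: EdgeSet,
    min_fraction: float = 0.5,
    min_edges: int = 2,
) -> list[dict]:
    """Nodes whose adjacency is dominated by condition-unique edges.

    TFs and genes are scored separately.  A node is reported when at least
    ``min_edges`` of its adjacent edges are unique and the unique fraction of
    its total adjacency is >= ``min_fraction``.  Sorted by fraction then
    unique degree, descending.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must lie in (0, 1]")
    if not unique.pairs <= full.pairs:
        raise ValueError("unique edge set is not a subset of the full edge set")

    def _degrees(es: EdgeSet, axis: int) -> dict[str, int]:
        d: dict[str, int] = {}
        for e in es.edges:
            d[e[axis]] = d.get(e[axis], 0) + 1
        return d

    out = []
    for axis, kind in ((0, "TF"), (1, "gene")):
        u_deg = _degrees(unique, axis)
        f_deg = _degrees(full, axis)
        for node, ud in u_deg.items():
            td = f_deg[node]
            frac = ud / td
            if ud >= min_edges and frac >= min_fraction:
                out.append(
                    {
                        "node": node,
                        "kind": kind,
                        "unique_degree": ud,
                        "total_degree": td,
                        "fraction": frac,
                    }
                )
    out.sort(key=lambda r: (-r["fraction"], -r["unique_degree"], r["node"]))
    return out
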