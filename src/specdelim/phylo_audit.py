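"""Midpoint rooting and per-cluster monophyly auditing.

Optimal clusters need not be monophyletic in the optimal phylogeny; this
module roots a branch-length tree at the midpoint of its longest
leaf-to-leaf path (so no outgroup is required) and reports, for every
cluster of a partition, whether the leaves under the cluster's most recent
common ancestor are exactly the cluster's members.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import pandas as pd

from .errors import TreeError
from .io_formats import UNASSIGNED, Partition

__all__ = ["midpoint_root", "monophyly_report", "write_monophyly_report", "is_rooted_binary_base"]


def _leaf_map(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    out = {}
    for leaf in tree.leaf_node_iter():
        out[leaf.taxon.label] = leaf
    return out


def _ancestor_chain(node: dendropy.Node) -> list[dendropy.Node]:
    chain = [node]
    while chain[-1].parent_node is not None:
        chain.append(chain[-1].parent_node)
    return chain


def _path_edges(a: dendropy.Node, b: dendropy.Node):
    """Edges on the a->b path as (edge, child_end_is_near_a) tuples."""
    up_a = _ancestor_chain(a)
    up_b = _ancestor_chain(b)
    set_a = set(id(n) for n in up_a)
    mrca = next(n for n in up_b if id(n) in set_a)
    edges = []
    for n in up_a:
        if n is mrca:
            break
        edges.append((n.edge, True))  # walking child -> parent
    down = []
    for n in up_b:
        if n is mrca:
            break
        down.append((n.edge, False))  # walking parent -> child
    edges.extend(reversed(down))
    return edges


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Returns a new tree; the input is not modified. The two maximally distant
    leaves end up equidistant from the root. Ties for the longest path are
    broken toward the lexicographically smallest leaf-name pair, so the
    operation is deterministic; on an already-midpoint-rooted tree it leaves
    topology and root position unchanged.
    """
    tree = tree.clone(depth=1)
    leaves = _leaf_map(tree)
    if len(leaves) < 2:
        raise TreeError("midpoint rooting needs at least 2 leaves")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in leaves}
    names = sorted(leaves)
    best = None  # (distance, name_a, name_b)
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            dist = pdm.patristic_distance(taxa[na], taxa[nb])
            if best is None or dist > best[0] + 1e-15:
                best = (dist, na, nb)
    dist, na, nb = best
    if dist <= 0:
        raise TreeError("all leaf-to-leaf distances are zero; midpoint undefined")
    half = dist / 2.0
    edges = _path_edges(leaves[na], leaves[nb])
    cum = 0.0
    target = None
    for edge, child_near in edges:
        length = edge.length or 0.0
        if cum + length >= half - 1e-12 and length > 0:
            from_child = (half - cum) if child_near else (cum + length - half)
            from_child = min(max(from_child, 0.0), length)
            target = (edge, from_child)
            break
        cum += length
    if target is None:  # numerical fallback: use the last positive edge
        for edge, child_near in reversed(edges):
            if (edge.length or 0.0) > 0:
                target = (edge, 0.0 if child_near else edge.length)
                break
    edge, from_child = target
    child = edge.head_node
    parent = edge.tail_node
    new_node = dendropy.Node()
    parent.remove_child(child)
    parent.add_child(new_node)
    new_node.edge.length = edge.length - from_child
    new_node.add_child(child)
    child.edge.length = from_child
    tree.reroot_at_node(new_node, update_bipartitions=False)
    tree.suppress_unifurcations()
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


def is_rooted_binary_base(tree: dendropy.Tree) -> bool:
    """True when the seed node has exactly two children (a rooted tree)."""
    return len(tree.seed_node.child_nodes()) == 2


def monophyly_report(tree: dendropy.Tree, partition: Partition) -> pd.DataFrame:
    """Per-cluster monophyly verdicts against a (rooted) tree.

    A cluster is monophyletic iff the leaf set under its members' MRCA
    equals the cluster exactly; singletons are trivially monophyletic.
    Unrooted input (trifurcating base) is midpoint-rooted first.
    UNASSIGNED specimens are ignored. Raises :class:`TreeError` listing any
    cluster member missing from the tree.
    """
    if not is_rooted_binary_base(tree):
        tree = midpoint_root(tree)
    elif not tree.is_rooted:
        tree = tree.clone(depth=1)
        tree.is_rooted = True
    leaves = _leaf_map(tree)
    missing = sorted(set(partition.assigned_ids()) - set(leaves))
    if missing:
        raise TreeError(f"partition IDs missing from tree: {missing}")
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in leaves}
    rows = []
    for label, members in sorted(partition.blocks().items()):
        if len(members) == 1:
            rows.append((label, 1, True, 1, 0))
            continue
        mrca = tree.mrca(taxa=[taxa[m] for m in members])
        under = sum(1 for _ in mrca.leaf_iter())
        rows.append((label, len(members), under == len(members), under, under - len(members)))
    return pd.DataFrame(
        rows,
        columns=["cluster", "size", "monophyletic", "mrca_leaf_count", "n_intruders"],
    )


def write_monophyly_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)
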