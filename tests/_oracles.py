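"""Independent brute-force oracles used to cross-check the fast
implementations.  Deliberately naive: explicit per-branch descendant sets
via dendropy, pure-Python loops, no shared code with the package."""

from __future__ import annotations

import dendropy


def branch_leaf_sets(newick: str) -> list[tuple[float, frozenset[str]]]:
    """(length, descendant-leaf-label set) for every non-root edge."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    branches = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        leaves = frozenset(
            leaf.taxon.label for leaf in node.leaf_iter() if leaf.taxon is not None
        )
        branches.append((float(node.edge.length or 0.0), leaves))
    return branches


def bray_curtis_bruteforce(x, y) -> float:
    shared = sum(min(a, b) for a, b in zip(x, y))
    total = sum(x) + sum(y)
    return 1.0 - 2.0 * shared / total


def unweighted_unifrac_bruteforce(newick, taxon_ids, x, y) -> float:
    present_x = {t for t, v in zip(taxon_ids, x) if v > 0}
    present_y = {t for t, v in zip(taxon_ids, y) if v > 0}
    unique = 0.0
    union = 0.0
    for length, leaves in branch_leaf_sets(newick):
        on_x = bool(leaves & present_x)
        on_y = bool(leaves & present_y)
        if on_x or on_y:
            union += length
            if on_x != on_y:
                unique += length
    return unique / union if union else 0.0


def weighted_unifrac_bruteforce(newick, taxon_ids, x, y, normalized=True) -> float:
    tx, ty = sum(x), sum(y)
    px = {t: v / tx for t, v in zip(taxon_ids, x)}
    py = {t: v / ty for t, v in zip(taxon_ids, y)}
    raw = 0.0
    norm = 0.0
    for length, leaves in branch_leaf_sets(newick):
        ax = sum(px.get(t, 0.0) for t in leaves)
        ay = sum(py.get(t, 0.0) for t in leaves)
        raw += length * abs(ax - ay)
        norm += length * (ax + ay)
    if not normalized:
        return raw
    return raw / norm if norm else 0.0
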