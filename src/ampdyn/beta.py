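"""Beta diversity: Bray-Curtis, unweighted UniFrac, normalized weighted
UniFrac, and full pairwise matrix assembly.

UniFrac works on a per-branch decomposition of the rooted input tree.  For a
branch (edge above a node) with length b, let p_s be the fraction of sample
s's reads descending through that branch.  Then

    unweighted  = sum_{branches unique to one sample} b  /  sum_{branches with
                  any present descendant} b            (presence/absence only)
    weighted    = sum b * |p_x - p_y|, divided (normalized form, the default)
                  by sum b * (p_x + p_y)  so values land on [0, 1].

The tree is used exactly as given: its root is the root, polytomies stay,
and zero-length branches contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alpha import rarefy
from .io_formats import CommunityTable, DistanceMatrix, PhyloTree


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """BC = 1 - 2 * sum min(x_i, y_i) / (sum x + sum y), on counts or
    relative abundances alike."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors differ in length")
    total = x.sum() + y.sum()
    if total == 0:
        raise ValueError("Bray-Curtis undefined for two empty samples")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / total)


@dataclass
class _BranchDecomposition:
    """Branch lengths and a branch x taxon incidence matrix for one tree,
    restricted to a fixed taxon ordering.  Precomputed once per matrix."""

    lengths: np.ndarray  # (n_branches,)
    incidence: np.ndarray  # (n_branches, n_taxa) bool: taxon descends through branch

    @classmethod
    def build(cls, tree: PhyloTree, taxon_ids: list[str]) -> "_BranchDecomposition":
        index = {t: i for i, t in enumerate(taxon_ids)}
        leaf_names = set(tree.leaf_names)
        missing = [t for t in taxon_ids if t not in leaf_names]
        if missing:
            raise ValueError(f"taxa not found as tree leaves: {missing[:5]}")
        lengths: list[float] = []
        rows: list[np.ndarray] = []
        # postorder so each node's descendant set is the union of its children's
        masks: dict[int, np.ndarray] = {}
        for node in tree.tree.postorder(include_self=True):
            if node.is_tip():
                mask = np.zeros(len(taxon_ids), dtype=bool)
                if node.name in index:
                    mask[index[node.name]] = True
            else:
                mask = np.zeros(len(taxon_ids), dtype=bool)
                for child in node.children:
                    mask |= masks[id(child)]
            masks[id(node)] = mask
            if node.parent is not None:  # the root has no branch above it
                lengths.append(float(node.length or 0.0))
                rows.append(mask)
        return cls(np.asarray(lengths), np.asarray(rows))

    def branch_proportions(self, proportions: np.ndarray) -> np.ndarray:
        """Map taxon proportions (taxa x samples) to per-branch descending
        fractions (branches x samples)."""
        return self.incidence.astype(float) @ proportions


def _as_proportions(x: np.ndarray, label: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError(f"sample {label} is empty")
    return x / total


def unweighted_unifrac(
    tree: PhyloTree, x: np.ndarray, y: np.ndarray, taxon_ids: list[str]
) -> float:
    """Fraction of observed branch length unique to one of the two samples;
    depends only on presence/absence."""
    dec = _BranchDecomposition.build(tree, list(taxon_ids))
    return _unweighted_from_decomposition(dec, np.asarray(x) > 0, np.asarray(y) > 0)


def _unweighted_from_decomposition(
    dec: _BranchDecomposition, present_x: np.ndarray, present_y: np.ndarray
) -> float:
    on_x = dec.incidence @ present_x > 0
    on_y = dec.incidence @ present_y > 0
    union = float(dec.lengths[on_x | on_y].sum())
    if union == 0:
        return 0.0
    unique = float(dec.lengths[on_x ^ on_y].sum())
    return unique / union


def weighted_unifrac(
    tree: PhyloTree,
    x: np.ndarray,
    y: np.ndarray,
    taxon_ids: list[str],
    normalized: bool = True,
) -> float:
    """Abundance-weighted branch-length displacement between two samples.

    Raw form: sum_b b * |p_x - p_y|.  Normalized (default) divides by
    sum_b b * (p_x + p_y), bounding the value on [0, 1]."""
    dec = _BranchDecomposition.build(tree, list(taxon_ids))
    px = dec.branch_proportions(_as_proportions(x, "x")[:, None])[:, 0]
    py = dec.branch_proportions(_as_proportions(y, "y")[:, None])[:, 0]
    raw = float((dec.lengths * np.abs(px - py)).sum())
    if not normalized:
        return raw
    norm = float((dec.lengths * (px + py)).sum())
    if norm == 0:
        return 0.0
    return raw / norm


def distance_matrix(
    table: CommunityTable,
    metric: str,
    tree: PhyloTree | None = None,
    subsample_depth: int | None = None,
    seed: int = 0,
) -> DistanceMatrix:
    """All pairwise distances for one metric, optionally after rarefying
    every sample once to a fixed depth (subsample first, then distances —
    one seed-controlled draw per sample)."""
    if metric not in ("bray_curtis", "unifrac_unweighted", "unifrac_weighted"):
        raise ValueError(f"unknown metric {metric!r}")
    counts = table.counts.copy()
    if subsample_depth is not None:
        rng = np.random.default_rng(seed)
        counts = np.column_stack(
            [rarefy(counts[:, j], subsample_depth, rng) for j in range(table.n_samples)]
        )
    n = table.n_samples
    values = np.zeros((n, n))
    if metric == "bray_curtis":
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = bray_curtis(counts[:, i], counts[:, j])
    else:
        if tree is None:
            raise ValueError("UniFrac metrics require a tree")
        dec = _BranchDecomposition.build(tree, table.taxon_ids)
        totals = counts.sum(axis=0).astype(float)
        if (totals == 0).any():
            empty = [s for s, t in zip(table.sample_ids, totals) if t == 0]
            raise ValueError(f"empty samples: {empty}")
        if metric == "unifrac_unweighted":
            on = dec.incidence @ (counts > 0) > 0  # branches x samples
            lengths = dec.lengths[:, None]
            for i in range(n):
                for j in range(i + 1, n):
                    union = float(lengths[on[:, i] | on[:, j]].sum())
                    unique = float(lengths[on[:, i] ^ on[:, j]].sum())
                    values[i, j] = values[j, i] = unique / union if union else 0.0
        else:
            bp = dec.branch_proportions(counts / totals)  # branches x samples
            for i in range(n):
                for j in range(i + 1, n):
                    raw = float((dec.lengths * np.abs(bp[:, i] - bp[:, j])).sum())
                    norm = float((dec.lengths * (bp[:, i] + bp[:, j])).sum())
                    values[i, j] = values[j, i] = raw / norm if norm else 0.0
    values = np.clip(values, 0.0, 1.0)
    return DistanceMatrix(list(table.sample_ids), values, metric)
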