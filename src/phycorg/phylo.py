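"""Light phylogenetic summaries: concatenated shared-gene supermatrices,
p-distances, neighbor-joining trees and RSCU cluster trees.

These are sanity-check tools — quick topology summaries over synthetic or
real panels — not a replacement for full Bayesian inference, which is out
of scope by design.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
import skbio

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.d) != 0) or np.any(self.d < 0):
            raise ValueError("need zero diagonal and non-negative entries")


@dataclass
class SummaryTree:
    taxa: list[str]
    newick: str

    def tree(self) -> skbio.TreeNode:
        return skbio.TreeNode.read([self.newick])

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartition halves (both sides of each split)."""
        t = self.tree()
        all_tips = frozenset(x.name for x in t.tips())
        out = set()
        for node in t.non_tips(include_self=False):
            side = frozenset(x.name for x in node.tips())
            if 1 < len(side) < len(all_tips) - 1:
                out.add(side)
                out.add(all_tips - side)
        return out


def concat_shared_pcgs(panel: dict[str, dict[str, str]]
                       ) -> tuple[dict[str, str],
                                  list[tuple[str, int, int]]]:
    """Concatenate the genes shared by every taxon, in alphabetical gene
    order.  Returns the per-taxon supermatrix and a partition map of
    (gene, start, end) 1-based inclusive coordinates."""
    shared = set.intersection(*(set(genes) for genes in panel.values()))
    if not shared:
        raise ValueError("no gene shared by all taxa")
    order = sorted(shared)
    rows = {t: [] for t in sorted(panel)}
    partitions = []
    pos = 0
    for gene in order:
        lens = {len(panel[t][gene]) for t in panel}
        if len(lens) != 1:
            raise ValueError(f"gene {gene} rows are not aligned")
        (glen,) = lens
        partitions.append((gene, pos + 1, pos + glen))
        pos += glen
        for t in rows:
            rows[t].append(panel[t][gene])
    return {t: "".join(parts) for t, parts in rows.items()}, partitions


def p_distance(supermatrix: dict[str, str]) -> DistanceMatrix:
    """Pairwise mismatch fraction over columns where both rows are
    ungapped."""
    taxa = sorted(supermatrix)
    arrs = {t: np.frombuffer(supermatrix[t].encode(), dtype="S1")
            for t in taxa}
    n = len(taxa)
    d = np.zeros((n, n))
    gap = np.bytes_("-")
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[taxa[i]], arrs[taxa[j]]
            ok = (a != gap) & (b != gap)
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {taxa[i]} and {taxa[j]}")
            d[i, j] = d[j, i] = float((a[ok] != b[ok]).sum()) / m
    return DistanceMatrix(taxa, d)


def nj_tree(dm: DistanceMatrix) -> SummaryTree:
    """Saitou–Nei neighbor joining (via scikit-bio) with Newick output.

    Panels of fewer than 4 taxa yield the degenerate cherry/star tree with
    a warning.
    """
    n = len(dm.taxa)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        log.warning("NJ on 2 taxa: returning a single cherry")
        h = dm.d[0, 1] / 2
        nwk = f"({dm.taxa[0]}:{h:.6f},{dm.taxa[1]}:{h:.6f});"
        return SummaryTree(list(dm.taxa), nwk)
    if n == 3:
        log.warning("NJ on 3 taxa: returning the star tree")
        a, b, c = dm.d[0, 1], dm.d[0, 2], dm.d[1, 2]
        x = (a + b - c) / 2
        y = (a + c - b) / 2
        z = (b + c - a) / 2
        nwk = (f"({dm.taxa[0]}:{max(x, 0):.6f},{dm.taxa[1]}:{max(y, 0):.6f},"
               f"{dm.taxa[2]}:{max(z, 0):.6f});")
        return SummaryTree(list(dm.taxa), nwk)
    sk_dm = skbio.DistanceMatrix(dm.d, ids=dm.taxa)
    tree = skbio.tree.nj(sk_dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    nwk = str(tree).strip()
    return SummaryTree(list(dm.taxa), nwk)


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    root, _ = hierarchy.to_tree(Z, rd=True)

    def rec(node, parent_height: float) -> str:
        blen = max((parent_height - node.dist) / 2, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{blen:.6f}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{blen:.6f}"

    return f"({rec(root.left, root.dist)},{rec(root.right, root.dist)});"


def rscu_cluster(rscu_vectors: dict[str, dict[str, float]]) -> SummaryTree:
    """Average-linkage hierarchical clustering of per-taxon RSCU vectors.

    Distances are Euclidean over the codons defined (non-missing) in both
    members of each pair, so unobserved synonymous families are skipped
    pairwise rather than imputed as zero.
    """
    taxa = sorted(rscu_vectors)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vi, vj = rscu_vectors[taxa[i]], rscu_vectors[taxa[j]]
            shared = sorted(set(vi) & set(vj))
            if not shared:
                raise ValueError(
                    f"no shared codons between {taxa[i]} and {taxa[j]}")
            d[i, j] = d[j, i] = math.sqrt(
                sum((vi[c] - vj[c]) ** 2 for c in shared))
    Z = hierarchy.linkage(squareform(d), method="average")
    return SummaryTree(taxa, _linkage_to_newick(Z, taxa))
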