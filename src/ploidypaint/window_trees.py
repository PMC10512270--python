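"""Windowed neighbor-joining genealogies and rooted sister classification.

The haplotype matrix is cut into consecutive, non-overlapping 50-SNP
windows per contig; each window yields a neighbor-joining (NJ) tree of
uncorrected (p) distances, and the rooted sister group of the focal
"other" and "lupina" haplotypes is recorded after rooting on a designated
outgroup lineage.  Windows whose first-to-last SNP span exceeds a
physical threshold (default 10 kb) are flagged discarded, since such
windows tend to run across long missing tracts.

The NJ agglomeration follows the Saitou-Nei Q-criterion with a
deterministic tie rule (the joined pair with the lexicographically
smallest leaf labels wins) and negative branch lengths clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .ancestry_paint import HaplotypeMatrix


@dataclass
class TopologyClass:
    """Rooted sister groups of the two focal haplotypes in one window."""

    sister_other: frozenset[str]
    sister_lupina: frozenset[str]
    other_lupina_sisters: bool

    @staticmethod
    def _fmt(s: frozenset[str]) -> str:
        return ",".join(sorted(s))

    def as_row(self) -> dict:
        return {
            "sister_other": self._fmt(self.sister_other),
            "sister_lupina": self._fmt(self.sister_lupina),
            "other_lupina_sisters": self.other_lupina_sisters,
        }


@dataclass
class WindowTree:
    """One 50-SNP window's genealogy and bookkeeping."""

    contig: str
    start_pos0: int
    end_pos0: int  # position of the window's last SNP (inclusive)
    n_snps: int
    tree: TreeNode | None
    discarded: bool = False
    reason: str = ""
    topology: TopologyClass | None = None

    @property
    def span_bp(self) -> int:
        return self.end_pos0 - self.start_pos0


def pairwise_p_distance(
    matrix: HaplotypeMatrix, columns: Sequence[int] | None = None
) -> pd.DataFrame:
    """Uncorrected p-distances between all haplotypes.

    The distance of a pair is the proportion of differing alleles over
    their pairwise-complete columns (cells missing in either haplotype
    are skipped).  A pair with no complete column raises a ``ValueError``
    naming the pair.
    """
    sub = matrix.alleles if columns is None else matrix.alleles.iloc[:, list(columns)]
    if sub.shape[1] == 0:
        raise ValueError("empty window")
    labels = list(sub.index)
    arr = sub.to_numpy(dtype=object)
    present = np.array([[c is not None and c == c for c in row] for row in arr])
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = present[i] & present[j]
            if not ok.any():
                raise ValueError(
                    f"no shared genotyped column for pair ({labels[i]!r}, {labels[j]!r})"
                )
            diff = np.mean(arr[i, ok] != arr[j, ok])
            d[i, j] = d[j, i] = diff
    return pd.DataFrame(d, index=labels, columns=labels)


def nj_tree(d: pd.DataFrame) -> TreeNode:
    """Neighbor-joining tree from a symmetric distance matrix.

    Standard Saitou-Nei agglomeration; ties in the Q-matrix are broken
    by the lexicographically smallest (sorted) pair of minimum leaf
    labels, so the result is independent of input row order.  Negative
    branch lengths are clamped to zero.  Requires at least 4 taxa.
    """
    if not np.allclose(d.to_numpy(), d.to_numpy().T):
        raise ValueError("distance matrix must be symmetric")
    labels = list(d.index)
    if len(labels) < 4:
        raise ValueError("neighbor joining here requires at least 4 taxa")
    # deterministic start order
    order = sorted(range(len(labels)), key=lambda i: labels[i])
    nodes = [TreeNode(name=labels[i]) for i in order]
    keys = [labels[i] for i in order]  # min leaf label per active node
    D = d.to_numpy()[np.ix_(order, order)].astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                tie_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, tie_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = float(li), float(lj)
        parent.extend([ni, nj_])
        new_d = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)], new_d[keep]])
        D = np.hstack([D, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # final three nodes join at an unrooted trifurcation
    (a, b, c) = nodes
    la = max(0.5 * (D[0, 1] + D[0, 2] - D[1, 2]), 0.0)
    lb = max(0.5 * (D[0, 1] + D[1, 2] - D[0, 2]), 0.0)
    lc = max(0.5 * (D[0, 2] + D[1, 2] - D[0, 1]), 0.0)
    a.length, b.length, c.length = float(la), float(lb), float(lc)
    root = TreeNode()
    root.extend([a, b, c])
    return root


def window_genealogies(
    matrix: HaplotypeMatrix,
    window_snps: int = 50,
    max_span_bp: int = 10_000,
) -> list[WindowTree]:
    """Cut the matrix into consecutive 50-SNP windows and infer NJ trees.

    Trailing windows with fewer than ``window_snps`` columns are
    dropped.  Windows whose first-to-last SNP span exceeds
    ``max_span_bp``, or in which some haplotype pair shares no genotyped
    column, are emitted flagged ``discarded`` (without a tree) and
    should be excluded from summaries.
    """
    if window_snps < 1:
        raise ValueError("window_snps must be positive")
    out: list[WindowTree] = []
    sites = matrix.sites
    for contig in dict.fromkeys(sites["contig"]):
        idx = np.flatnonzero((sites["contig"] == contig).to_numpy())
        for w0 in range(0, len(idx) - window_snps + 1, window_snps):
            cols = idx[w0 : w0 + window_snps]
            start = int(sites["pos0"].iloc[cols[0]])
            end = int(sites["pos0"].iloc[cols[-1]])
            wt = WindowTree(
                contig=contig,
                start_pos0=start,
                end_pos0=end,
                n_snps=window_snps,
                tree=None,
            )
            if end - start > max_span_bp:
                wt.discarded, wt.reason = True, "span"
            else:
                try:
                    dm = pairwise_p_distance(matrix, cols)
                except ValueError:
                    wt.discarded, wt.reason = True, "missing"
                else:
                    wt.tree = nj_tree(dm)
            out.append(wt)
    return out


def classify_sister(
    tree: TreeNode | WindowTree,
    other_label: str = "other",
    lupina_label: str = "lupina",
    outgroup: str = "columbiana",
) -> TopologyClass:
    """Rooted sister groups of the focal haplotypes.

    The (unrooted) genealogy is rooted on the branch leading to the
    outgroup tip; the sister of a focal haplotype is the leaf set of the
    other child(ren) of its smallest containing clade.  Classification
    depends only on the topology, never on branch lengths.
    """
    if isinstance(tree, WindowTree):
        if tree.tree is None:
            raise ValueError("window has no tree (discarded)")
        tree = tree.tree
    # undirected adjacency over the skbio tree
    adj: dict[TreeNode, list[TreeNode]] = {}
    for node in tree.traverse(include_self=True):
        adj.setdefault(node, [])
        for child in node.children:
            adj[node].append(child)
            adj.setdefault(child, []).append(node)
    tips = {n.name: n for n in adj if len(adj[n]) == 1 and n.name is not None}
    if outgroup not in tips:
        raise ValueError(f"outgroup {outgroup!r} not found in tree")
    for focal in (other_label, lupina_label):
        if focal not in tips:
            raise ValueError(f"focal haplotype {focal!r} not found in tree")

    # orient all edges away from the outgroup tip
    parent: dict[TreeNode, TreeNode | None] = {tips[outgroup]: None}
    stack = [tips[outgroup]]
    while stack:
        node = stack.pop()
        for nb in adj[node]:
            if nb not in parent:
                parent[nb] = node
                stack.append(nb)

    def leafset(node: TreeNode, skip: TreeNode) -> frozenset[str]:
        """Leaf names reachable from ``node`` without crossing ``skip``."""
        seen, stack_, leaves = {skip, node}, [node], []
        while stack_:
            cur = stack_.pop()
            nbs = [nb for nb in adj[cur] if nb not in seen]
            if len(adj[cur]) == 1 and cur.name is not None:
                leaves.append(cur.name)
            for nb in nbs:
                seen.add(nb)
                stack_.append(nb)
        return frozenset(leaves)

    def sister(focal: str) -> frozenset[str]:
        tip = tips[focal]
        p = parent[tip]
        sisters: set[str] = set()
        for nb in adj[p]:
            if nb is tip or nb is parent[p]:
                continue
            sisters |= leafset(nb, p)
        return frozenset(sisters)

    s_other = sister(other_label)
    s_lupina = sister(lupina_label)
    return TopologyClass(
        sister_other=s_other,
        sister_lupina=s_lupina,
        other_lupina_sisters=(lupina_label in s_other) or (other_label in s_lupina),
    )


def classification_table(
    windows: list[WindowTree],
    other_label: str = "other",
    lupina_label: str = "lupina",
    outgroup: str = "columbiana",
) -> pd.DataFrame:
    """Per-window sister classification as a tidy frame; discarded
    windows keep their flag and carry empty sister fields."""
    rows = []
    for wt in windows:
        base = {
            "contig": wt.contig,
            "start_pos0": wt.start_pos0,
            "end_pos0": wt.end_pos0,
            "n_snps": wt.n_snps,
            "discarded": wt.discarded,
            "reason": wt.reason,
        }
        if not wt.discarded:
            topo = classify_sister(wt, other_label, lupina_label, outgroup)
            wt.topology = topo
            base.update(topo.as_row())
        else:
            base.update(
                {"sister_other": "", "sister_lupina": "", "other_lupina_sisters": False}
            )
        rows.append(base)
    return pd.DataFrame(rows)


def write_newick(windows: list[WindowTree], path) -> None:
    """Write non-discarded window trees as one newick per line."""
    with open(path, "w") as fh:
        for wt in windows:
            if wt.tree is not None:
                fh.write(str(wt.tree).strip() + "\n")
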