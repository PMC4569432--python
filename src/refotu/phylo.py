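"""Pairwise V1-V2 similarity, neighbor-joining trees and bootstrap support.

Distances for tree building are 1 - pairwise identity from the shared
alignment kernel (p-distance on aligned columns; no substitution-model
correction).  Neighbor joining follows Saitou & Nei with deterministic
tie-breaking (smallest index pair) and negative branch lengths clamped to
zero.  Bootstrap support resamples multiple-alignment columns with
replacement and counts recovered bipartitions; the multiple alignment is
produced by MAFFT.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .alignment import AlignmentKernel, DEFAULT_KERNEL

_NEWICK_KWARGS = dict(
    schema="newick",
    suppress_rooting=True,
    unquoted_underscores=True,
)


@dataclass
class PhyloTree:
    """Branch-length tree with unique leaf labels, Newick-serialisable."""

    tree: dendropy.Tree
    negative_branch_deficit: float = 0.0   # total length clamped away in NJ
    supports: dict[frozenset, int] = field(default_factory=dict)

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        t = dendropy.Tree.get(data=text, schema="newick",
                              preserve_underscores=True)
        return cls(tree=t)

    def newick(self) -> str:
        return self.tree.as_string(**_NEWICK_KWARGS).strip() + "\n"

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def midpoint_root(self) -> "PhyloTree":
        self.tree.reroot_at_midpoint(update_bipartitions=False)
        return self

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each encoded as the leaf side not containing
        the lexicographically smallest label (root-invariant)."""
        labels = sorted(self.leaf_labels)
        ref = labels[0]
        all_labels = frozenset(labels)
        out: set[frozenset] = set()
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node is self.tree.seed_node:
                continue
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            side = all_labels - below if ref in below else below
            if 1 < len(side) < len(labels) - 1:
                out.add(side)
        return out


def pairwise_identity(named_seqs: Sequence[tuple[str, str]],
                      kernel: AlignmentKernel | None = None) -> pd.DataFrame:
    """Symmetric identity-fraction matrix over the given sequences."""
    if len(named_seqs) < 2:
        raise ValueError("need at least two sequences")
    for name, seq in named_seqs:
        if not seq:
            raise ValueError(f"empty sequence: {name}")
    kernel = kernel or DEFAULT_KERNEL
    names = [n for n, _ in named_seqs]
    n = len(names)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            # query the shorter so reference end gaps stay free
            a, b = named_seqs[i][1], named_seqs[j][1]
            q, t = (a, b) if len(a) <= len(b) else (b, a)
            m[i, j] = m[j, i] = kernel.align(q, t).identity
    return pd.DataFrame(m, index=names, columns=names)


def nj_tree(distances: pd.DataFrame) -> PhyloTree:
    """Saitou-Nei neighbor joining over a symmetric distance matrix.

    Ties in the Q criterion break on the smallest (i, j) label-order index
    pair; negative branch lengths are clamped to zero and the clamped total
    is reported on the result.
    """
    d = distances.to_numpy(dtype=float)
    labels = [str(c) for c in distances.columns]
    if d.shape[0] != d.shape[1] or list(distances.index) != list(distances.columns):
        raise ValueError("distance matrix must be square with matching labels")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix is not symmetric")
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two taxa")

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(node)
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    if n == 2:
        root = nodes[0]
        nodes[1].edge.length = clamp(d[0, 1])
        root.add_child(nodes[1])
        tree.seed_node = root
        return PhyloTree(tree=tree, negative_branch_deficit=deficit)

    active = list(range(n))
    dist = d.copy()
    while len(active) > 3:
        m = len(active)
        r = dist[np.ix_(active, active)].sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * dist[active[ai], active[aj]] - r[ai] - r[aj]
                if best is None or q < best[0] - 1e-12:
                    best = (q, ai, aj)
        _q, ai, aj = best
        i, j = active[ai], active[aj]
        dij = dist[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        nodes[i].edge.length = clamp(li)
        nodes[j].edge.length = clamp(lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # grow the matrix with the new node's distances
        new = np.zeros(dist.shape[0])
        for kx in active:
            if kx in (i, j):
                continue
            new[kx] = 0.5 * (dist[i, kx] + dist[j, kx] - dij)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, :-1] = new
        dist[:-1, -1] = new
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    root = dendropy.Node()
    li = 0.5 * (dist[i, j] + dist[i, k] - dist[j, k])
    lj = 0.5 * (dist[i, j] + dist[j, k] - dist[i, k])
    lk = 0.5 * (dist[i, k] + dist[j, k] - dist[i, j])
    for node, length in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.edge.length = clamp(length)
        root.add_child(node)
    tree.seed_node = root
    return PhyloTree(tree=tree, negative_branch_deficit=deficit)


# ---------------------------------------------------------------------------
# multiple alignment + bootstrap


def mafft_align(named_seqs: Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
    """Multiple alignment via MAFFT (deterministic for a fixed input)."""
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "in.fasta"
        with open(fasta, "w") as fh:
            for name, seq in named_seqs:
                fh.write(f">{name}\n{seq}\n")
        proc = subprocess.run(
            ["mafft", "--retree", "2", "--quiet", str(fasta)],
            capture_output=True, text=True, check=True)
    out: list[tuple[str, str]] = []
    name, chunks = None, []
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            if name is not None:
                out.append((name, "".join(chunks).upper()))
            name, chunks = line[1:].split()[0], []
        else:
            chunks.append(line.strip())
    if name is not None:
        out.append((name, "".join(chunks).upper()))
    order = {n: i for i, (n, _s) in enumerate(named_seqs)}
    return sorted(out, key=lambda t: order[t[0]])


def p_distance_matrix(alignment: Sequence[tuple[str, str]],
                      columns: np.ndarray | None = None) -> pd.DataFrame:
    """Pairwise mismatch fraction over columns where both sequences have a
    base (gap columns are excluded pair-by-pair)."""
    names = [n for n, _ in alignment]
    arr = np.array([list(s) for _n, s in alignment], dtype="U1")
    if columns is not None:
        arr = arr[:, columns]
    n = len(names)
    gap = (arr == "-") | (arr == ".")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = ~(gap[i] | gap[j])
            nv = int(valid.sum())
            if nv == 0:
                d[i, j] = d[j, i] = 1.0
                continue
            mism = int((arr[i, valid] != arr[j, valid]).sum())
            d[i, j] = d[j, i] = mism / nv
    return pd.DataFrame(d, index=names, columns=names)


def bootstrap_support(alignment: Sequence[tuple[str, str]],
                      n_reps: int = 1000, seed: int = 0) -> PhyloTree:
    """NJ tree from the full alignment with bipartition bootstrap counts.

    Columns are resampled with replacement ``n_reps`` times; each replicate
    rebuilds a p-distance NJ tree and every bipartition of the base tree
    gains one count per replicate containing it.  Supports land in the
    internal node labels of the returned tree.
    """
    ncol = len(alignment[0][1])
    if ncol < 2:
        raise ValueError("alignment must have at least two columns")
    if len({len(s) for _n, s in alignment}) != 1:
        raise ValueError("alignment rows differ in length")
    base = nj_tree(p_distance_matrix(alignment))
    counts: dict[frozenset, int] = {bp: 0 for bp in base.bipartitions()}
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    for _rep in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_tree = nj_tree(p_distance_matrix(alignment, columns=cols))
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    base.supports = counts
    _annotate_supports(base, counts)
    return base


def _annotate_supports(ptree: PhyloTree, counts: dict[frozenset, int]) -> None:
    labels = sorted(ptree.leaf_labels)
    ref = labels[0]
    all_labels = frozenset(labels)
    for node in ptree.tree.preorder_node_iter():
        if node.is_leaf() or node is ptree.tree.seed_node:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = all_labels - below if ref in below else below
        if side in counts:
            node.label = str(counts[side])
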