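"""Between-sample community structure: UniFrac, PCoA, ANOSIM, group distances.

UniFrac measures the phylogenetic branch length unique to either of two
communities: the unweighted form contrasts presence/absence of each branch's
descendants relative to the branch length spanned by the union, the weighted
form sums branch lengths weighted by the difference in descending read
fractions (normalised by the maximum attainable value by default).
Ordination is classical PCoA (double-centred eigendecomposition); group
separation is tested with rank-based ANOSIM under label permutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .mapping import AbundanceTable
from .phylo import PhyloTree
from .simdata import substream


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame      # samples x axes
    explained: np.ndarray          # fraction of positive-eigenvalue variance
    negative_eigenvalue_mass: float
    degenerate: bool = False


def _edge_structure(table: AbundanceTable, ptree: PhyloTree):
    leaves = set(ptree.leaf_labels)
    missing = [c for c in table.counts.index if c not in leaves]
    if missing:
        raise ValueError(f"clusters absent from the tree: {missing[:5]}")
    cluster_pos = {c: i for i, c in enumerate(table.counts.index)}
    lengths, masks = [], []
    for node in ptree.tree.preorder_node_iter():
        if node is ptree.tree.seed_node:
            continue
        length = node.edge.length or 0.0
        if length < 0:
            raise ValueError("negative branch length in UniFrac tree")
        mask = np.zeros(len(cluster_pos), dtype=bool)
        for leaf in node.leaf_iter():
            if leaf.taxon.label in cluster_pos:
                mask[cluster_pos[leaf.taxon.label]] = True
        if mask.any():
            lengths.append(length)
            masks.append(mask)
    return np.array(lengths), np.array(masks)


def unifrac(table: AbundanceTable, ptree: PhyloTree, weighted: bool = False,
            normalized: bool = True) -> pd.DataFrame:
    """Pairwise UniFrac distances between the table's samples."""
    lengths, masks = _edge_structure(table, ptree)
    counts = table.counts.to_numpy(dtype=float)
    samples = list(table.counts.columns)
    totals = counts.sum(axis=0)
    frac = np.divide(counts, np.where(totals == 0, 1, totals))
    edge_frac = masks @ frac                 # branch x sample descending mass
    edge_present = masks @ (counts > 0)      # branch x sample presence count
    n = len(samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if weighted:
                raw = float(lengths @ np.abs(edge_frac[:, i] - edge_frac[:, j]))
                if normalized:
                    denom = float(lengths @ (edge_frac[:, i] + edge_frac[:, j]))
                    raw = raw / denom if denom > 0 else 0.0
                d[i, j] = d[j, i] = raw
            else:
                a = edge_present[:, i] > 0
                b = edge_present[:, j] > 0
                union = float(lengths @ (a | b))
                unique = float(lengths @ (a ^ b))
                d[i, j] = d[j, i] = unique / union if union > 0 else 0.0
    return pd.DataFrame(d, index=samples, columns=samples)


def pcoa(distances: pd.DataFrame, n_axes: int | None = None) -> OrdinationResult:
    """Classical scaling of a symmetric distance matrix.

    Negative eigenvalues (non-Euclidean input) are dropped and their absolute
    mass reported; explained fractions are relative to the positive spectrum.
    """
    d = distances.to_numpy(dtype=float)
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix is not symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    neg_mass = float(np.abs(evals[evals < -1e-10]).sum())
    if not pos.any():
        coords = pd.DataFrame(np.zeros((n, 1)), index=distances.index,
                              columns=["PC1"])
        return OrdinationResult(coords, np.array([0.0]), neg_mass,
                                degenerate=True)
    lam = evals[pos]
    vec = evecs[:, pos]
    coords = vec * np.sqrt(lam)
    if n_axes is not None:
        coords = coords[:, :n_axes]
        lam_show = lam[:n_axes]
    else:
        lam_show = lam
    frame = pd.DataFrame(coords, index=distances.index,
                         columns=[f"PC{i+1}" for i in range(coords.shape[1])])
    return OrdinationResult(frame, lam_show / lam.sum(), neg_mass)


def anosim(distances: pd.DataFrame, groups: pd.Series, n_perm: int = 10000,
           seed: int = 0, exhaustive: bool = False) -> tuple[float, float]:
    """ANOSIM R and its permutation tail probability.

    R = (mean between-group rank - mean within-group rank) / (M / 2) with
    M = n(n-1)/2; p = (1 + #{permuted R >= observed}) / (1 + n_perm).  With
    ``exhaustive`` every ordering of the label vector is enumerated (small n
    only) and p is the exact tail fraction #{R_perm >= R_obs} / n!.
    """
    if n_perm < 1 and not exhaustive:
        raise ValueError("n_perm must be >= 1")
    labels = groups.reindex(distances.index)
    if labels.isna().any():
        raise ValueError("missing group labels for some samples")
    counts = labels.value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("ANOSIM needs >= 2 groups with >= 2 samples each")
    d = distances.to_numpy(dtype=float)
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])
    m = len(ranks)
    lab = labels.to_numpy()

    def r_stat(lv: np.ndarray) -> float:
        within = lv[iu[0]] == lv[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    observed = r_stat(lab)
    if exhaustive:
        from itertools import permutations
        total = exceed = 0
        for perm in permutations(lab):
            total += 1
            if r_stat(np.array(perm)) >= observed - 1e-12:
                exceed += 1
        return float(observed), exceed / total
    rng = substream(seed, "anosim")
    exceed = 0
    for _ in range(n_perm):
        if r_stat(rng.permutation(lab)) >= observed - 1e-12:
            exceed += 1
    return float(observed), (1 + exceed) / (1 + n_perm)


def group_distance_summary(distances: pd.DataFrame, groups: pd.Series,
                           n_perm: int = 10000, seed: int = 0) -> pd.DataFrame:
    """Mean +/- sd of pairwise distances within and between groups.

    Significance of each pair-class difference uses a sample-label
    permutation test (pairs sharing a sample are dependent, so a t-test on
    pairs would be anti-conservative).
    """
    labels = groups.reindex(distances.index)
    d = distances.to_numpy(dtype=float)
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = d[iu]
    lab = labels.to_numpy()

    def classes(lv):
        return np.array(["-".join(sorted((lv[i], lv[j])))
                         for i, j in zip(*iu)])

    cls = classes(lab)
    rows = []
    names = sorted(set(cls))
    for name in names:
        sel = cls == name
        rows.append((name, int(sel.sum()), float(vals[sel].mean()),
                     float(vals[sel].std(ddof=1)) if sel.sum() > 1 else 0.0))
    out = pd.DataFrame(rows, columns=["pair_class", "n_pairs", "mean", "sd"]
                       ).set_index("pair_class")

    rng = substream(seed, "group-distances")
    for a, b in combinations(names, 2):
        obs = abs(vals[cls == a].mean() - vals[cls == b].mean())
        exceed = 0
        for _ in range(n_perm):
            pc = classes(rng.permutation(lab))
            if abs(vals[pc == a].mean() - vals[pc == b].mean()) >= obs - 1e-12:
                exceed += 1
        out.loc[a, f"p_vs_{b}"] = (1 + exceed) / (1 + n_perm)
    return out
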