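"""Mutation sharing across branches and sample trees.

A mutation's branch presence set is topology-concordant when it equals the
complete tip set of one node of the physical branching tree — exactly what
meristematic propagation through axillary meristems predicts.  Sample
relatedness is summarised by neighbour joining on presence/absence Hamming
distances, and layer-versus-branch similarity by a permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .countio import MutationCall
from .synthetic import split_sample_id
from .topology import TreeTopology


def presence_matrix(
    calls: Sequence[MutationCall], samples: Sequence[str]
) -> pd.DataFrame:
    """Binary mutations x samples matrix (1 = called/genotyped present)."""
    data = {
        c.id: [1 if s in c.samples else 0 for s in samples] for c in calls
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=list(samples))


def branch_presence_sets(calls: Sequence[MutationCall]) -> pd.DataFrame:
    """Partition of the catalog by branch presence set.

    Returns one row per distinct branch set with its mutation count and
    per-layer counts; attrs carry single/multi-branch tallies.
    """
    rows: dict[frozenset, dict] = {}
    for c in calls:
        r = rows.setdefault(
            c.branch_set, {"branch_set": c.branch_set, "n": 0, "L1": 0, "L2": 0, "shared": 0, "leaf": 0}
        )
        r["n"] += 1
        r[c.layer] += 1
    df = pd.DataFrame(rows.values())
    if df.empty:
        df = pd.DataFrame(columns=["branch_set", "n", "L1", "L2", "shared", "leaf"])
    df = df.sort_values("n", ascending=False).reset_index(drop=True)
    n_multi = sum(1 for c in calls if len(c.branch_set) > 1)
    df.attrs["n_mutations"] = len(calls)
    df.attrs["n_multi_branch"] = n_multi
    df.attrs["multi_branch_fraction"] = n_multi / len(calls) if calls else 0.0
    return df


def topology_concordant(branch_set: frozenset[str] | set[str], topology: TreeTopology) -> bool:
    """True iff the branch set is the complete tip set of some topology node."""
    return topology.is_clade(branch_set)


def pairwise_distances(matrix: pd.DataFrame) -> pd.DataFrame:
    """Unweighted Hamming distance: number of mutations present in exactly
    one of the two samples."""
    x = matrix.to_numpy(dtype=int)
    diff = (x[:, :, None] != x[:, None, :]).sum(axis=0)
    return pd.DataFrame(diff, index=matrix.columns, columns=matrix.columns)


@dataclass
class SampleTree:
    """Unrooted tree over samples with non-negative edge lengths."""

    newick: str
    tips: tuple[str, ...]

    def to_topology(self) -> TreeTopology:
        return TreeTopology.from_newick(self.newick)


def neighbor_joining(dist: pd.DataFrame) -> SampleTree:
    """Saitou-Nei neighbour joining with lowest-index tie-breaking.

    Exact (including edge lengths) on additive distance matrices.  Negative
    branch-length estimates are kept as computed so additivity is preserved.
    """
    labels = list(dist.columns)
    n = len(labels)
    if n < 2:
        raise ValueError("need >=2 samples")
    d = dist.to_numpy(dtype=float).copy()
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    nodes = [f"{l}" for l in labels]  # current newick fragment per node
    if n == 2:
        return SampleTree(f"({nodes[0]}:{d[0, 1] / 2:.17g},{nodes[1]}:{d[0, 1] / 2:.17g});", tuple(labels))
    active = list(range(n))
    frags = {i: nodes[i] for i in active}
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break on the flattened argmin
        ai, aj = divmod(int(np.argmin(q)), m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        new = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for ak in active:
            if ak in (i, j):
                continue
            d[new, ak] = d[ak, new] = 0.5 * (d[i, ak] + d[j, ak] - dij)
        frags[new] = f"({frags[i]}:{li:.17g},{frags[j]}:{lj:.17g})"
        active = [a for a in active if a not in (i, j)] + [new]
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    newick = f"({frags[i]}:{li:.17g},{frags[j]}:{lj:.17g},{frags[k]}:{lk:.17g});"
    return SampleTree(newick, tuple(labels))


def layer_vs_branch_similarity(
    dist: pd.DataFrame,
    metadata: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean within-layer distance minus mean within-branch distance.

    Negative values mean samples cluster by meristem layer rather than by
    branch.  The permutation null shuffles layer labels within each branch;
    the one-tailed p is the fraction of permutations at least as negative.
    ``metadata`` needs columns sample, branch, layer.
    """
    meta = metadata.set_index("sample").loc[list(dist.columns)]
    layers = meta["layer"].to_numpy()
    branches = meta["branch"].to_numpy()
    if len(set(layers)) < 2 or len(set(branches)) < 2:
        raise ValueError("need >=2 layers and >=2 branches")
    dmat = dist.to_numpy(dtype=float)

    def stat(layer_labels: np.ndarray) -> float:
        n = len(layer_labels)
        wl, wb = [], []
        for i in range(n):
            for j in range(i + 1, n):
                if layer_labels[i] == layer_labels[j] and branches[i] != branches[j]:
                    wl.append(dmat[i, j])
                if branches[i] == branches[j] and layer_labels[i] != layer_labels[j]:
                    wb.append(dmat[i, j])
        if not wl or not wb:
            return 0.0
        return float(np.mean(wl) - np.mean(wb))

    observed = stat(layers)
    rng = np.random.default_rng(seed)
    count = 0
    branch_groups = {b: np.where(branches == b)[0] for b in set(branches)}
    for _ in range(n_permutations):
        perm = layers.copy()
        for idx in branch_groups.values():
            perm[idx] = perm[rng.permutation(idx)]
        if stat(perm) <= observed:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return observed, p


def subtree_restriction(
    calls: Sequence[MutationCall], topology: TreeTopology, node: str
) -> list[MutationCall]:
    """Keep mutations whose branch set lies entirely within the subtree of
    ``node`` (used to analyse sharing free of tree-wide fixed mutations)."""
    tips = topology.subtree_tips(node)
    return [c for c in calls if c.branch_set and c.branch_set <= tips]
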