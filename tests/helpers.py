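"""Shared test utilities: hand-built count tables and additive matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd

from msm.countio import AlleleCountTable, _ALLELE_COLS


def make_table(sample_id: str, sites: list[dict]) -> AlleleCountTable:
    """Build a count table from site specs.

    Each spec: {chrom, pos, ref, depth, alleles: {allele: count | (count,
    plus, minus, baseq)}}.  The reference allele row is added automatically
    with the residual depth unless given explicitly.
    """
    rows = []
    for s in sites:
        alleles = dict(s.get("alleles", {}))
        listed = 0
        for allele, spec in alleles.items():
            if isinstance(spec, int):
                spec = (spec, spec - spec // 2, spec // 2, 37.0)
            count, plus, minus, baseq = spec
            listed += count if allele != s["ref"] else 0
            rows.append(
                (s["chrom"], s["pos"], s["ref"], s["depth"], allele,
                 count, plus, minus, baseq, 60.0)
            )
        if s["ref"] not in alleles:
            rc = s["depth"] - listed
            rows.append(
                (s["chrom"], s["pos"], s["ref"], s["depth"], s["ref"],
                 rc, rc - rc // 2, rc // 2, 37.0, 60.0)
            )
    return AlleleCountTable(sample_id, pd.DataFrame(rows, columns=_ALLELE_COLS))


def background_sites(n: int, depth: int = 300, chrom: str = "chr9", start: int = 1000) -> list[dict]:
    """Clean reference-only sites (for depth-range and percentile context)."""
    return [
        {"chrom": chrom, "pos": start + 10 * i, "ref": "A", "depth": depth, "alleles": {}}
        for i in range(n)
    ]


def random_additive_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    """Tip-tip distances of a random binary tree with edges in [0.5, 2]."""
    children: dict[int, tuple[int, int]] = {}
    edge: dict[int, float] = {}
    ids = list(range(n))
    nxt = n
    while len(ids) > 1:
        i, j = sorted(rng.choice(len(ids), 2, replace=False))
        a, b = ids[i], ids[j]
        children[nxt] = (a, b)
        edge[a] = float(rng.uniform(0.5, 2.0))
        edge[b] = float(rng.uniform(0.5, 2.0))
        ids = [x for x in ids if x not in (a, b)] + [nxt]
        nxt += 1
    root = ids[0]

    def leaf_paths(x, acc):
        """Node path from root to each leaf; each entry owns its edge."""
        if x < n:
            return {x: acc}
        l, r = children[x]
        out = {}
        out.update(leaf_paths(l, acc + [l]))
        out.update(leaf_paths(r, acc + [r]))
        return out

    paths = leaf_paths(root, [])
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            pa, pb = paths[a], paths[b]
            common = 0
            for x, y in zip(pa, pb):
                if x == y:
                    common += 1
                else:
                    break
            dist = sum(edge[x] for x in pa[common:]) + sum(edge[x] for x in pb[common:])
            d[a, b] = d[b, a] = dist
    return d


def newick_tip_distances(newick: str) -> dict[tuple[str, str], float]:
    import io

    from skbio import TreeNode

    t = TreeNode.read(io.StringIO(newick))
    dm = t.tip_tip_distances()
    out = {}
    for a in dm.ids:
        for b in dm.ids:
            out[(a, b)] = dm[a, b]
    return out
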