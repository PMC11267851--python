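"""Targeted re-genotyping of known mutation sites.

Bulk: presence under a sweep of minimal read-support cutoffs, optionally
jointly over sample sets (a mutation counts as positively genotyped only
when every member sample supports it).  Single cell: per-cluster tallies
of cells with mutant-allele reads, a cell being mutant with >=1 mutant
read (matching the binary colouring used for expression figures and the
low per-cell coverage of scRNA data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .countio import AlleleCountTable, MutationCall
from .synthetic import split_sample_id


def _site_lookup(table: AlleleCountTable) -> tuple[dict, dict]:
    counts = table.df.set_index(["chrom", "pos", "allele"])["count"].to_dict()
    depths = (
        table.df.drop_duplicates(["chrom", "pos"]).set_index(["chrom", "pos"])["depth"].to_dict()
    )
    return counts, depths


def genotype_calls(
    calls: Sequence[MutationCall],
    tables: Mapping[str, AlleleCountTable],
) -> pd.DataFrame:
    """Alt count / depth / AF of every call in every sample (long form).
    Sites absent from a table count as 0 reads."""
    lookups = {sid: _site_lookup(t) for sid, t in tables.items()}
    rows = []
    for c in calls:
        for sid, (counts, depths) in lookups.items():
            alt = counts.get((c.chrom, c.pos, c.token or c.alt), 0)
            depth = depths.get((c.chrom, c.pos), 0)
            rows.append(
                {
                    "id": c.id,
                    "sample": sid,
                    "alt_count": int(alt),
                    "depth": int(depth),
                    "af": alt / depth if depth else 0.0,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class GenotypeSweep:
    """Percentage of mutations positively genotyped per read-support cutoff.

    ``summary`` columns: cutoff, set, percent; ``presence`` is the
    per-mutation boolean table behind it."""

    summary: pd.DataFrame
    presence: pd.DataFrame


def genotype_sweep(
    calls: Sequence[MutationCall],
    tables: Mapping[str, AlleleCountTable],
    sample_sets: Mapping[str, Callable[[str], list[str]]],
    cutoffs: Sequence[int] = tuple(range(1, 21)),
) -> GenotypeSweep:
    """Sweep the minimal read support required to genotype known mutations.

    ``sample_sets`` maps a set name to a function branch -> sample ids;
    only branches in which a mutation was originally identified are
    queried, and a joint set supports the mutation at cutoff k only if
    every member sample in every such branch has >= k alternate reads.
    """
    geno = genotype_calls(calls, tables)
    counts = geno.set_index(["id", "sample"])["alt_count"].to_dict()
    rows, pres_rows = [], []
    for set_name, members in sample_sets.items():
        for k in cutoffs:
            n_pos = 0
            for c in calls:
                sids = [s for b in sorted(c.branch_set) for s in members(b)]
                queried = [s for s in sids if s in tables]
                ok = bool(queried) and all(counts.get((c.id, s), 0) >= k for s in queried)
                pres_rows.append(
                    {"id": c.id, "set": set_name, "cutoff": k, "present": ok}
                )
                n_pos += ok
            rows.append(
                {
                    "cutoff": k,
                    "set": set_name,
                    "percent": 100.0 * n_pos / len(calls) if calls else 0.0,
                }
            )
    return GenotypeSweep(pd.DataFrame(rows), pd.DataFrame(pres_rows))


def af_concordance(
    calls: Sequence[MutationCall],
    table_pairs: Mapping[str, tuple[AlleleCountTable, AlleleCountTable]],
    private_af: float = 0.02,
) -> pd.DataFrame:
    """Per-site AF pairs between two tissues of the same branch.

    ``table_pairs`` maps branch -> (table_a, table_b).  Sites with solid AF
    in one member and near-zero (< ``private_af``) in the other are flagged
    private; shared mutations are expected to show very similar AFs.
    """
    rows = []
    for branch, (ta, tb) in table_pairs.items():
        ca, da = _site_lookup(ta)
        cb, db = _site_lookup(tb)
        for c in calls:
            if branch not in c.branch_set:
                continue
            key = (c.chrom, c.pos, c.token or c.alt)
            depth_a = da.get(key[:2], 0)
            depth_b = db.get(key[:2], 0)
            af_a = ca.get(key, 0) / depth_a if depth_a else 0.0
            af_b = cb.get(key, 0) / depth_b if depth_b else 0.0
            private = (af_a < private_af) != (af_b < private_af)
            rows.append(
                {
                    "id": c.id,
                    "branch": branch,
                    "af_a": af_a,
                    "af_b": af_b,
                    "delta": abs(af_a - af_b),
                    "private": private,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ClusterGenotype:
    """Per-mutation, per-cluster cell tallies (mutant = >=1 mutant read)."""

    tallies: pd.DataFrame  # id, cluster, layer, mutant_cells, wildtype_cells
    mutant_barcodes: dict[str, list[str]]
    uncovered: list[str]  # mutation ids with zero coverage in all cells


def cluster_genotype(
    sc_counts: pd.DataFrame,
    cluster_map: pd.DataFrame,
    calls: Sequence[MutationCall],
    branches: Sequence[str] | None = None,
) -> ClusterGenotype:
    """Tally cells with mutant vs wild-type reads per expression cluster.

    Barcodes absent from the cluster map are dropped with a warning (they
    cannot be assigned to a layer); mutations without any covered cell are
    reported as uncovered rather than silently omitted.
    """
    cmap = cluster_map.set_index("barcode")
    unknown = set(sc_counts["barcode"]) - set(cmap.index)
    if unknown:
        warnings.warn(f"dropping {len(unknown)} barcodes absent from the cluster map")
        sc_counts = sc_counts[~sc_counts["barcode"].isin(unknown)]
    if branches is not None:
        keep = cmap[cmap["branch"].isin(branches)].index
        sc_counts = sc_counts[sc_counts["barcode"].isin(keep)]
    rows = []
    mutant_barcodes: dict[str, list[str]] = {}
    uncovered = []
    clusters = cluster_map[["cluster", "layer"]].drop_duplicates()
    for c in calls:
        at_site = sc_counts[
            (sc_counts["chrom"] == c.chrom) & (sc_counts["pos"] == c.pos)
        ]
        if at_site.empty:
            uncovered.append(c.id)
            continue
        token = c.token or c.alt
        per_cell = at_site.groupby("barcode").apply(
            lambda g: bool((g["allele"] == token).any() and (g["count"][g["allele"] == token] > 0).any()),
            include_groups=False,
        )
        mutant_barcodes[c.id] = sorted(per_cell[per_cell].index)
        cell_layer = cmap.loc[per_cell.index]
        tally = pd.DataFrame(
            {"mutant": per_cell.to_numpy(), "cluster": cell_layer["cluster"].to_numpy(),
             "layer": cell_layer["layer"].to_numpy()}
        )
        agg = tally.groupby(["cluster", "layer"])["mutant"].agg(["sum", "count"]).reset_index()
        for _, r in clusters.iterrows():
            hit = agg[(agg["cluster"] == r["cluster"])]
            mut = int(hit["sum"].iloc[0]) if len(hit) else 0
            tot = int(hit["count"].iloc[0]) if len(hit) else 0
            rows.append(
                {
                    "id": c.id,
                    "cluster": r["cluster"],
                    "layer": r["layer"],
                    "mutant_cells": mut,
                    "wildtype_cells": tot - mut,
                }
            )
    return ClusterGenotype(pd.DataFrame(rows), mutant_barcodes, uncovered)


def layer_tallies(cluster_geno: ClusterGenotype) -> pd.DataFrame:
    """Collapse cluster tallies to layers (id x layer mutant/wild-type)."""
    if cluster_geno.tallies.empty:
        return pd.DataFrame(columns=["id", "layer", "mutant_cells", "wildtype_cells"])
    return (
        cluster_geno.tallies.groupby(["id", "layer"], as_index=False)[
            ["mutant_cells", "wildtype_cells"]
        ].sum()
    )
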