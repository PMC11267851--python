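"""Somatic mutation calling from layer-enriched allelic count tables.

Five pipelines turn candidate sites (>=3 alternate reads) into calls:

1. layer-specific mutations in a single branch, by allele-frequency
   contrast between the L1 and L2 samples of that branch;
2. layer-specific mutations shared between branches, by log2 fold-change
   between the mean layer AFs across branches;
3. layer-specific mutations in a single branch with moderate read support,
   by within-branch AF fold-change;
4. mutations shared between layers, called across all fruit samples at
   once with noise filters replacing the layer contrast;
5. a leaf pipeline for bulk (layer-mixed) leaf samples.

All filters are pure per-site predicates so the final selection equals the
conjunction of the published filter set; percentile-based thresholds are
derived from the branch's own AF-difference background.  Calls are merged
into one catalog with targeted re-genotyping standing in for the manual
re-checking of every sample at every called position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .countio import AlleleCountTable, FilterConfig, MutationCall, SampleEvidence
from .depth import DepthRange
from .synthetic import split_sample_id
from .topology import TreeTopology

HetSites = set[tuple[str, int]]


@dataclass
class BranchSamplePair:
    """The L1 and L2 count tables of one branch (plus optional leaf)."""

    branch: str
    l1: AlleleCountTable
    l2: AlleleCountTable
    leaf: AlleleCountTable | None = None

    def __post_init__(self) -> None:
        if self.l1 is None or self.l2 is None:
            raise ValueError(f"branch {self.branch}: both layer tables are required")


def anchored_alleles(ref_base: str, token: str) -> tuple[str, str]:
    """Convert a count-table allele token to VCF-style anchored ref/alt."""
    if token.startswith("+"):
        return ref_base, ref_base + token[1:]
    if token.startswith("-"):
        return ref_base + token[1:], ref_base
    return ref_base, token


def variant_class(token: str) -> str:
    return "indel" if token[:1] in "+-" else "SNV"


def site_frame(tables: dict[str, AlleleCountTable]) -> pd.DataFrame:
    """Joint per-site frame across samples.

    One row per site in the union of the tables, with a single consensus
    alternate allele (highest pooled read count, ties alphabetical) and per
    sample columns ``depth_S, alt_S, af_S, plus_S, minus_S, baseq_S``.
    Samples without the position contribute zero depth and zero reads.
    """
    longs = []
    for label, t in tables.items():
        d = t.df.copy()
        d["label"] = label
        longs.append(d)
    allrows = pd.concat(longs, ignore_index=True) if longs else pd.DataFrame(columns=["chrom", "pos"])
    if allrows.empty:
        return pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
    sites = allrows.drop_duplicates(["chrom", "pos"])[["chrom", "pos", "ref"]]
    alts = allrows[(allrows["allele"] != allrows["ref"]) & (allrows["count"] > 0)]
    pooled = (
        alts.groupby(["chrom", "pos", "allele"], as_index=False)["count"].sum()
        .sort_values(["chrom", "pos", "count", "allele"], ascending=[True, True, False, True])
        .drop_duplicates(["chrom", "pos"])
        .rename(columns={"allele": "alt"})[["chrom", "pos", "alt"]]
    )
    frame = sites.merge(pooled, on=["chrom", "pos"], how="left")
    frame["alt"] = frame["alt"].fillna("")
    for label, t in tables.items():
        depth = t.df.drop_duplicates(["chrom", "pos"])[["chrom", "pos", "depth"]]
        frame = frame.merge(
            depth.rename(columns={"depth": f"depth_{label}"}), on=["chrom", "pos"], how="left"
        )
        onalt = t.df.rename(columns={"allele": "alt"})[
            ["chrom", "pos", "alt", "count", "plus", "minus", "baseq"]
        ]
        frame = frame.merge(
            onalt.rename(
                columns={
                    "count": f"alt_{label}",
                    "plus": f"plus_{label}",
                    "minus": f"minus_{label}",
                    "baseq": f"baseq_{label}",
                }
            ),
            on=["chrom", "pos", "alt"],
            how="left",
        )
        frame[f"depth_{label}"] = frame[f"depth_{label}"].fillna(0).astype(int)
        for c in (f"alt_{label}", f"plus_{label}", f"minus_{label}"):
            frame[c] = frame[c].fillna(0).astype(int)
        frame[f"baseq_{label}"] = frame[f"baseq_{label}"].fillna(60.0)
        frame[f"af_{label}"] = frame[f"alt_{label}"] / frame[f"depth_{label}"].clip(lower=1)
    return frame.sort_values(["chrom", "pos"]).reset_index(drop=True)


def _not_het(frame: pd.DataFrame, het_sites: HetSites) -> pd.Series:
    keys = list(zip(frame["chrom"], frame["pos"]))
    return pd.Series([k not in het_sites for k in keys], index=frame.index)


def _noise_ok(frame: pd.DataFrame, label: str, cfg: FilterConfig) -> pd.Series:
    """True where the sample's alternate evidence is clean: reads on both
    strands (when any), adequate base quality, depth below the repeat cap."""
    has_alt = frame[f"alt_{label}"] > 0
    strand_bias = has_alt & ((frame[f"plus_{label}"] == 0) | (frame[f"minus_{label}"] == 0))
    low_qual = has_alt & (frame[f"baseq_{label}"] < cfg.min_base_quality)
    repeat = frame[f"depth_{label}"] > cfg.repeat_depth_cap
    return ~(strand_bias | low_qual | repeat)


def _evidence(frame_row: pd.Series, label: str) -> SampleEvidence:
    d = int(frame_row[f"depth_{label}"])
    a = int(frame_row[f"alt_{label}"])
    return SampleEvidence(alt_count=a, depth=d, af=a / d if d else 0.0)


def _make_call(row, branch_set, layer, pipeline, sample_labels, flags=()):
    ref, alt = anchored_alleles(row["ref"], row["alt"])
    return MutationCall(
        id=f"{pipeline}:{row['chrom']}:{row['pos']}",
        chrom=row["chrom"],
        pos=int(row["pos"]),
        ref=ref,
        alt=alt,
        token=row["alt"],
        var_class=variant_class(row["alt"]),
        layer=layer,
        branch_set=frozenset(branch_set),
        samples={lab: _evidence(row, lab) for lab in sample_labels},
        pipelines=(pipeline,),
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# pipeline 1: layer-specific, single branch, AF difference


def pipeline1_layer_specific(
    pair: BranchSamplePair,
    het_sites: HetSites,
    ranges: dict[str, DepthRange],
    cfg: FilterConfig,
) -> list[MutationCall]:
    s1, s2 = pair.l1.sample_id, pair.l2.sample_id
    frame = site_frame({s1: pair.l1, s2: pair.l2})
    if frame.empty:
        return []
    cand = (frame[f"alt_{s1}"] >= cfg.min_alt_reads_candidate) | (
        frame[f"alt_{s2}"] >= cfg.min_alt_reads_candidate
    )
    f1 = _not_het(frame, het_sites)
    f2 = pd.Series(
        ranges[s1].contains(frame[f"depth_{s1}"].to_numpy())
        & ranges[s2].contains(frame[f"depth_{s2}"].to_numpy()),
        index=frame.index,
    )
    het1 = frame[f"af_{s1}"].between(cfg.het_af_lo, cfg.het_af_hi)
    het2 = frame[f"af_{s2}"].between(cfg.het_af_lo, cfg.het_af_hi)
    f3 = ~(het1 & het2)
    af_diff = (frame[f"af_{s1}"] - frame[f"af_{s2}"]).abs()
    f4 = af_diff >= cfg.af_diff_min
    focal_is_l1 = frame[f"af_{s1}"] >= frame[f"af_{s2}"]
    noise1, noise2 = _noise_ok(frame, s1, cfg), _noise_ok(frame, s2, cfg)
    f5 = noise1.where(focal_is_l1, noise2)

    # adaptive AF-difference threshold: the upper percentile of the branch's
    # sub-threshold (noise) AF-difference distribution, i.e. the technical
    # AF scatter between the two layer samples after removing phased het
    # sites, bad-depth sites and germline-like hets
    background = f1 & f2 & f3 & ~f4
    thr = (
        float(np.percentile(af_diff[background], cfg.af_diff_percentile))
        if background.any()
        else 0.0
    )
    alt_focal = frame[f"alt_{s1}"].where(focal_is_l1, frame[f"alt_{s2}"])
    selected = cand & f1 & f2 & f3 & f4 & f5 & (alt_focal >= cfg.strong_alt_reads) & (
        af_diff > thr
    )

    calls = []
    for _, row in frame[selected].iterrows():
        layer = "L1" if row[f"af_{s1}"] >= row[f"af_{s2}"] else "L2"
        calls.append(_make_call(row, [pair.branch], layer, "pipeline1", [s1, s2]))
    return calls


# ---------------------------------------------------------------------------
# pipelines 2 and 3: fold-change based


def _fruit_frame(pairs: dict[str, BranchSamplePair]) -> tuple[pd.DataFrame, dict]:
    tables = {}
    for b, pair in pairs.items():
        tables[pair.l1.sample_id] = pair.l1
        tables[pair.l2.sample_id] = pair.l2
    return site_frame(tables), tables


def _candidate_branches(frame, pairs, ranges, cfg) -> dict[str, pd.Series]:
    """Branch-level candidacy: >=3 alternate reads in either layer AND both
    layer samples inside their optimal depth range (a branch whose coverage
    is unusable at the site simply does not count as supporting it)."""
    out = {}
    for b, pair in pairs.items():
        s1, s2 = pair.l1.sample_id, pair.l2.sample_id
        cand = (frame[f"alt_{s1}"] >= cfg.min_alt_reads_candidate) | (
            frame[f"alt_{s2}"] >= cfg.min_alt_reads_candidate
        )
        in_range = pd.Series(
            ranges[s1].contains(frame[f"depth_{s1}"].to_numpy())
            & ranges[s2].contains(frame[f"depth_{s2}"].to_numpy()),
            index=frame.index,
        )
        out[b] = cand & in_range
    return out


def _pseudo_af(frame, labels) -> pd.Series:
    """Depth-aware pseudo-AF (half a read at the site's mean depth) guarding
    the fold-change against zero denominators."""
    mean_depth = sum(frame[f"depth_{l}"] for l in labels) / len(labels)
    return 0.5 / mean_depth.clip(lower=1.0)


def pipeline2_shared_across_branches(
    pairs: dict[str, BranchSamplePair],
    het_sites: HetSites,
    ranges: dict[str, DepthRange],
    cfg: FilterConfig,
) -> list[MutationCall]:
    if len(pairs) < 2:
        raise ValueError("pipeline 2 needs >=2 branches")
    frame, tables = _fruit_frame(pairs)
    if frame.empty:
        return []
    cand_b = _candidate_branches(frame, pairs, ranges, cfg)
    n_cand = sum(c.astype(int) for c in cand_b.values())
    f1 = _not_het(frame, het_sites)
    f2 = pd.Series(True, index=frame.index)  # range handled inside candidacy
    f3 = n_cand >= 2
    f4 = pd.Series(False, index=frame.index)
    for sid in tables:
        f4 |= frame[f"alt_{sid}"] > cfg.strong_alt_reads
    l1_labels = [p.l1.sample_id for p in pairs.values()]
    l2_labels = [p.l2.sample_id for p in pairs.values()]
    m1 = sum(frame[f"af_{l}"] for l in l1_labels) / len(l1_labels)
    m2 = sum(frame[f"af_{l}"] for l in l2_labels) / len(l2_labels)
    ps = _pseudo_af(frame, list(tables))
    lfc = np.log2((m1 + ps) / (m2 + ps))
    f5 = lfc.abs() >= cfg.log2fc_min
    selected = f1 & f2 & f3 & f4 & f5

    calls = []
    for idx, row in frame[selected].iterrows():
        branches = sorted(b for b in pairs if cand_b[b][idx])
        layer = "L1" if m1[idx] >= m2[idx] else "L2"
        labels = [l for b in branches for l in (pairs[b].l1.sample_id, pairs[b].l2.sample_id)]
        calls.append(_make_call(row, branches, layer, "pipeline2", labels))
    return calls


def pipeline3_foldchange_single_branch(
    pairs: dict[str, BranchSamplePair],
    het_sites: HetSites,
    ranges: dict[str, DepthRange],
    cfg: FilterConfig,
) -> list[MutationCall]:
    """Within-branch fold-change calls for sites candidate in exactly one
    branch (the single-branch complement of pipeline 2)."""
    frame, tables = _fruit_frame(pairs)
    if frame.empty:
        return []
    cand_b = _candidate_branches(frame, pairs, ranges, cfg)
    n_cand = sum(c.astype(int) for c in cand_b.values())
    f1 = _not_het(frame, het_sites)
    single = n_cand == 1
    calls = []
    for b, pair in pairs.items():
        s1, s2 = pair.l1.sample_id, pair.l2.sample_id
        strong = (frame[f"alt_{s1}"] > cfg.strong_alt_reads) | (
            frame[f"alt_{s2}"] > cfg.strong_alt_reads
        )
        ps = _pseudo_af(frame, [s1, s2])
        lfc = np.log2((frame[f"af_{s1}"] + ps) / (frame[f"af_{s2}"] + ps))
        selected = f1 & single & cand_b[b] & strong & (lfc.abs() >= cfg.log2fc_min)
        for _, row in frame[selected].iterrows():
            layer = "L1" if row[f"af_{s1}"] >= row[f"af_{s2}"] else "L2"
            calls.append(_make_call(row, [b], layer, "pipeline3", [s1, s2]))
    return calls


# ---------------------------------------------------------------------------
# pipeline 4: shared between layers


def pipeline4_shared_between_layers(
    tables: dict[str, AlleleCountTable],
    het_sites: HetSites,
    cfg: FilterConfig,
) -> list[MutationCall]:
    """Layer-agnostic calling across all fruit samples at once.

    Because the layer contrast is unavailable, germline-like noise is
    removed by requiring the site NOT to carry alternate reads in every
    sample, to stay under the repeat depth cap, and to be supported on
    both strands.
    """
    frame = site_frame(tables)
    if frame.empty:
        return []
    labels = list(tables)
    f1 = _not_het(frame, het_sites)
    strong = pd.Series(False, index=frame.index)
    for sid in labels:
        strong |= (frame[f"alt_{sid}"] >= cfg.strong_alt_reads) & (
            frame[f"af_{sid}"] >= cfg.leaf_min_af
        )
    f2 = strong
    everywhere = pd.Series(True, index=frame.index)
    for sid in labels:
        everywhere &= frame[f"alt_{sid}"] >= 1
    f3 = ~everywhere
    max_depth = pd.concat([frame[f"depth_{sid}"] for sid in labels], axis=1).max(axis=1)
    f4 = max_depth <= cfg.repeat_depth_cap
    tot_plus = sum(frame[f"plus_{sid}"] for sid in labels)
    tot_minus = sum(frame[f"minus_{sid}"] for sid in labels)
    tot_alt = sum(frame[f"alt_{sid}"] for sid in labels)
    f5 = ~((tot_alt > 0) & ((tot_plus == 0) | (tot_minus == 0)))
    selected = f1 & f2 & f3 & f4 & f5

    by_branch: dict[str, list[str]] = {}
    for sid in labels:
        by_branch.setdefault(split_sample_id(sid)[0], []).append(sid)
    calls = []
    for idx, row in frame[selected].iterrows():
        branches = sorted(
            b
            for b, sids in by_branch.items()
            if any(row[f"alt_{s}"] >= cfg.min_alt_reads_candidate for s in sids)
        )
        if not branches:
            continue
        labs = [s for b in branches for s in by_branch[b]]
        calls.append(_make_call(row, branches, "shared", "pipeline4", labs))
    return calls


# ---------------------------------------------------------------------------
# leaf pipeline


def leaf_pipeline(
    leaf_tables: dict[str, AlleleCountTable],
    het_sites: HetSites,
    ranges: dict[str, DepthRange],
    cfg: FilterConfig,
) -> list[MutationCall]:
    """Mutation calling in bulk leaf samples (a layer mixture), requiring
    >=20 alternate reads at AF >= 0.25 plus clean strand/quality evidence."""
    calls = []
    for sid, table in leaf_tables.items():
        branch, _ = split_sample_id(sid)
        frame = site_frame({sid: table})
        if frame.empty:
            continue
        cand = frame[f"alt_{sid}"] >= cfg.min_alt_reads_candidate
        f1 = _not_het(frame, het_sites)
        f2 = pd.Series(
            ranges[sid].contains(frame[f"depth_{sid}"].to_numpy()), index=frame.index
        )
        f3 = (frame[f"alt_{sid}"] >= cfg.strong_alt_reads) & (
            frame[f"af_{sid}"] >= cfg.leaf_min_af
        )
        f4 = _noise_ok(frame, sid, cfg)
        for _, row in frame[cand & f1 & f2 & f3 & f4].iterrows():
            calls.append(_make_call(row, [branch], "leaf", "leaf", [sid]))
    return calls


# ---------------------------------------------------------------------------
# merge and reconcile


def _resolve_layer(labels: set[str]) -> tuple[str, bool]:
    fruit = labels & {"L1", "L2"}
    if len(fruit) == 2:
        return "shared", True
    if len(fruit) == 1:
        return next(iter(fruit)), False
    if "shared" in labels:
        return "shared", False
    return "leaf", False


def regenotype_site(
    table: AlleleCountTable, chrom: str, pos: int, token: str
) -> SampleEvidence:
    """Targeted lookup of one allele at one position (absent site = 0 reads)."""
    rows = table.df[(table.df["chrom"] == chrom) & (table.df["pos"] == pos)]
    if rows.empty:
        return SampleEvidence(alt_count=0, depth=0, af=0.0)
    depth = int(rows["depth"].iloc[0])
    hit = rows[rows["allele"] == token]
    alt = int(hit["count"].iloc[0]) if len(hit) else 0
    return SampleEvidence(alt_count=alt, depth=depth, af=alt / depth if depth else 0.0)


def merge_and_reconcile(
    calls: list[MutationCall],
    tables: dict[str, AlleleCountTable],
    topology: TreeTopology,
    cfg: FilterConfig,
) -> list[MutationCall]:
    """Collapse pipeline outputs into one catalog and re-check every sample.

    Duplicate calls (same chrom/pos/alt) are merged; a layer-specific label
    from pipelines 1-3 takes precedence over pipeline 4's layer-agnostic
    'shared' label, and genuinely conflicting L1-vs-L2 labels become
    'shared' with a warning.  Every call is then re-genotyped in every
    sample with relaxed thresholds; supported presences extend the call's
    branch set with recorded provenance.
    """
    # precompute per-sample site index for fast targeted lookup
    site_idx: dict[str, pd.DataFrame] = {}
    for sid, t in tables.items():
        site_idx[sid] = t.df.set_index(["chrom", "pos", "allele"])["count"].to_dict()
    depth_idx = {
        sid: t.df.drop_duplicates(["chrom", "pos"]).set_index(["chrom", "pos"])["depth"].to_dict()
        for sid, t in tables.items()
    }

    grouped: dict[tuple, list[MutationCall]] = {}
    for c in calls:
        grouped.setdefault(c.key, []).append(c)

    merged = []
    for key in sorted(grouped):
        group = grouped[key]
        first = group[0]
        labels = {c.layer for c in group}
        layer, conflict = _resolve_layer(labels)
        if conflict:
            warnings.warn(
                f"conflicting layer labels at {first.chrom}:{first.pos}; set to shared"
            )
        branch_set = frozenset().union(*(c.branch_set for c in group))
        samples: dict[str, SampleEvidence] = {}
        for c in group:
            for sid, ev in c.samples.items():
                samples.setdefault(sid, ev)
        flags = set()
        for c in group:
            flags.update(c.flags)
        if conflict:
            flags.add("layer_conflict")
        # targeted re-genotyping in every sample
        for sid, t in tables.items():
            if sid in samples:
                continue
            depth = depth_idx[sid].get((first.chrom, first.pos), 0)
            alt = site_idx[sid].get((first.chrom, first.pos, first.token), 0)
            af = alt / depth if depth else 0.0
            if alt >= cfg.regenotype_min_alt and af >= cfg.regenotype_min_af:
                samples[sid] = SampleEvidence(
                    alt_count=alt, depth=depth, af=af, added_by="regenotype"
                )
        # presence must survive the evidence re-check: the merged call keeps
        # only samples meeting the relaxed presence rule (measurement rows
        # for the non-carrying layer and stray error reads drop out), and a
        # branch is carried only if one of its samples remains
        present = {
            sid: ev
            for sid, ev in samples.items()
            if ev.alt_count >= cfg.regenotype_min_alt and ev.af >= cfg.regenotype_min_af
        }
        if present:
            samples = present
            branch_set = frozenset(split_sample_id(sid)[0] for sid in present)
        merged.append(
            MutationCall(
                id="",  # assigned below
                chrom=first.chrom,
                pos=first.pos,
                ref=first.ref,
                alt=first.alt,
                token=first.token,
                var_class=first.var_class,
                layer=layer,
                branch_set=branch_set,
                samples=samples,
                pipelines=tuple(p for c in group for p in c.pipelines),
                curated=True,
                flags=tuple(flags),
            )
        )
    merged.sort(key=lambda c: (c.chrom, c.pos, c.alt))
    for i, c in enumerate(merged, 1):
        c.id = f"SM{i}"
    return merged
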