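"""Loss-of-heterozygosity detection.

An LOH tract converts a heterozygous locus to homozygosity in one meristem
layer.  Two independent signals are required before a call is made:

* an allele-frequency shift at phased inter-haplotype variants — one layer
  leaves the heterozygous band while the other stays in it; and
* haplotype-switch reads — reads (or read pairs) covering two phased
  variants within 1 kb whose observed alleles come from different parental
  haplotypes, marking the edge of the converted tract.

Switch evidence seen in both layers of a branch is treated as a shared
artefact (mapping error, collapsed repeat) and discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import BranchSamplePair
from .countio import AlleleCountTable, FilterConfig, MutationCall, SampleEvidence
from .depth import DepthRange
from .synthetic import TISSUE_MAIN_LAYER, split_sample_id


@dataclass(frozen=True)
class SwitchEvidence:
    """A run of phased-variant pairs with haplotype-switching reads in
    exactly one layer of a branch; coordinates are the outermost phased
    sites involved."""

    chrom: str
    start: int
    end: int
    branch: str
    layer: str
    n_switch: int


def af_shift_candidates(
    pair: BranchSamplePair,
    phased: pd.DataFrame,
    ranges: dict[str, DepthRange],
    cfg: FilterConfig,
) -> pd.DataFrame:
    """Phased het sites whose AF leaves the heterozygous band in exactly one
    layer.

    Removes sites that are heterozygous in both layers (0.35 <= AF <= 0.6),
    low-AF in both (<= 0.1, i.e. not a usable het site), have an absolute
    between-layer AF difference below 0.25, or sit below the sample's own
    optimal depth range.  Returns columns chrom, pos, ref, alt, branch,
    layer (the shifted layer), af_l1, af_l2.
    """
    s1, s2 = pair.l1.sample_id, pair.l2.sample_id
    key = phased[["chrom", "pos", "allele_a", "allele_b"]]

    def per_layer(table: AlleleCountTable) -> pd.DataFrame:
        df = table.df.merge(key, on=["chrom", "pos"])
        b = df[df["allele"] == df["allele_b"]][["chrom", "pos", "count"]]
        depth = df.drop_duplicates(["chrom", "pos"])[["chrom", "pos", "depth"]]
        out = key.merge(depth, on=["chrom", "pos"], how="left").merge(
            b.rename(columns={"count": "b_count"}), on=["chrom", "pos"], how="left"
        )
        out["depth"] = out["depth"].fillna(0).astype(int)
        out["b_count"] = out["b_count"].fillna(0).astype(int)
        out["af"] = out["b_count"] / out["depth"].clip(lower=1)
        return out

    t1, t2 = per_layer(pair.l1), per_layer(pair.l2)
    m = key.copy()
    m["af_l1"], m["depth_l1"] = t1["af"], t1["depth"]
    m["af_l2"], m["depth_l2"] = t2["af"], t2["depth"]
    het1 = m["af_l1"].between(cfg.loh_het_lo, cfg.loh_het_hi)
    het2 = m["af_l2"].between(cfg.loh_het_lo, cfg.loh_het_hi)
    low_both = (m["af_l1"] <= cfg.loh_low_af) & (m["af_l2"] <= cfg.loh_low_af)
    diff_ok = (m["af_l1"] - m["af_l2"]).abs() >= cfg.af_diff_min
    depth_ok = (m["depth_l1"] >= ranges[s1].lo) & (m["depth_l2"] >= ranges[s2].lo)
    keep = ~(het1 & het2) & ~low_both & diff_ok & depth_ok
    out = m[keep].copy()
    # the shifted layer is the one farther from the heterozygous expectation
    d1 = (out["af_l1"] - 0.5).abs()
    d2 = (out["af_l2"] - 0.5).abs()
    out["layer"] = np.where(d1 >= d2, "L1", "L2")
    out["branch"] = pair.branch
    out = out.rename(columns={"allele_a": "ref", "allele_b": "alt"})
    return out[["chrom", "pos", "ref", "alt", "branch", "layer", "af_l1", "af_l2"]].reset_index(
        drop=True
    )


def detect_switch_reads(
    observations: pd.DataFrame,
    phased: pd.DataFrame,
    cfg: FilterConfig,
) -> list[SwitchEvidence]:
    """Find phased-pair runs with >= cfg.loh_min_switch_reads switching
    reads in exactly one layer of a branch.

    ``observations`` has one row per read: sample, chrom, pos1, pos2,
    hap1, hap2.  Pairs farther apart than cfg.loh_pair_window are ignored;
    adjacent qualifying pairs are merged into one region whose coordinates
    are the outermost phased sites involved.
    """
    if observations.empty:
        return []
    obs = observations[
        (observations["pos2"] - observations["pos1"]) <= cfg.loh_pair_window
    ].copy()
    if obs.empty:
        return []
    obs["switch"] = obs["hap1"] != obs["hap2"]
    counts = (
        obs.groupby(["sample", "chrom", "pos1", "pos2"], as_index=False)["switch"].sum()
    )
    counts["branch"] = counts["sample"].map(lambda s: split_sample_id(s)[0])
    counts["layer"] = counts["sample"].map(
        lambda s: TISSUE_MAIN_LAYER.get(split_sample_id(s)[1])
    )
    hits = counts[counts["switch"] >= cfg.loh_min_switch_reads]

    # discard pairs that switch in both layers of the same branch
    both = hits.groupby(["branch", "chrom", "pos1", "pos2"])["layer"].nunique()
    shared_pairs = set(both[both > 1].index)
    evidence: list[SwitchEvidence] = []
    for (branch, layer, chrom), grp in hits.groupby(["branch", "layer", "chrom"]):
        grp = grp[
            ~grp.apply(lambda r: (branch, chrom, r["pos1"], r["pos2"]) in shared_pairs, axis=1)
        ]
        if grp.empty:
            continue
        grp = grp.sort_values("pos1")
        cur_start, cur_end, cur_n = None, None, 0
        for _, r in grp.iterrows():
            if cur_start is None or r["pos1"] > cur_end:
                if cur_start is not None:
                    evidence.append(
                        SwitchEvidence(chrom, int(cur_start), int(cur_end), branch, layer, int(cur_n))
                    )
                cur_start, cur_end, cur_n = r["pos1"], r["pos2"], r["switch"]
            else:  # chained pair
                cur_end = max(cur_end, r["pos2"])
                cur_n += r["switch"]
        if cur_start is not None:
            evidence.append(
                SwitchEvidence(chrom, int(cur_start), int(cur_end), branch, layer, int(cur_n))
            )
    evidence.sort(key=lambda e: (e.chrom, e.start, e.branch, e.layer))
    return evidence


def call_loh(
    candidates: pd.DataFrame,
    evidence: list[SwitchEvidence],
    window: int = 1000,
) -> list[MutationCall]:
    """Intersect AF-shift candidates with switch-read regions into tracts.

    Switch reads mark the edges of a converted tract while the AF shift
    covers its interior, so per branch/layer/chromosome both evidence
    types are chained whenever they lie within ``window`` bp of each
    other; each maximal chain containing at least one AF-shift candidate
    and at least one switch region becomes a single LOH call anchored at
    its first candidate locus."""
    calls: list[MutationCall] = []
    if candidates.empty or not evidence:
        return calls
    cand_groups: dict[tuple, list] = {}
    for _, r in candidates.iterrows():
        cand_groups.setdefault((r["branch"], r["layer"], r["chrom"]), []).append(r)
    sw_groups: dict[tuple, list[SwitchEvidence]] = {}
    for ev in evidence:
        sw_groups.setdefault((ev.branch, ev.layer, ev.chrom), []).append(ev)

    def emit(chrom, branch, layer, cands):
        first = min(cands, key=lambda r: r["pos"])
        calls.append(
            MutationCall(
                id=f"LOH:{chrom}:{first['pos']}",
                chrom=chrom,
                pos=int(first["pos"]),
                ref=str(first["ref"]),
                alt=str(first["alt"]),
                token=str(first["alt"]),
                var_class="LOH",
                layer=layer,
                branch_set=frozenset([branch]),
                samples={},
                pipelines=("loh",),
                curated=True,
            )
        )

    for key in sorted(sw_groups, key=str):
        branch, layer, chrom = key
        cands = sorted(cand_groups.get(key, []), key=lambda r: r["pos"])
        if not cands:
            continue
        regions = sorted(sw_groups[key], key=lambda e: (e.start, e.end))
        used = [False] * len(regions)
        # consecutive switch regions bracket a tract: one call if AF-shift
        # candidates lie between them
        i = 0
        while i + 1 < len(regions):
            lo, hi = regions[i].start, regions[i + 1].end
            between = [r for r in cands if lo - window <= r["pos"] <= hi + window]
            if between:
                emit(chrom, branch, layer, between)
                used[i] = used[i + 1] = True
                i += 2
            else:
                i += 1
        # unpaired edge (e.g. tract at a chromosome end): nearby candidates
        for i, ev in enumerate(regions):
            if used[i]:
                continue
            near = [
                r for r in cands if ev.start - window <= r["pos"] <= ev.end + window
            ]
            if near:
                emit(chrom, branch, layer, near)
    calls.sort(key=lambda c: (c.chrom, c.pos))
    for i, c in enumerate(calls, 1):
        c.id = f"LOH{i}"
    return calls
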