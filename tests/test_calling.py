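import numpy as np
import pytest

from helpers import background_sites, make_table
from msm.calling import (
    BranchSamplePair,
    anchored_alleles,
    leaf_pipeline,
    merge_and_reconcile,
    pipeline1_layer_specific,
    pipeline2_shared_across_branches,
    pipeline3_foldchange_single_branch,
    pipeline4_shared_between_layers,
    site_frame,
    variant_class,
)
from msm.countio import FilterConfig
from msm.depth import DepthRange
from msm.topology import TreeTopology

RANGES = {
    f"{b}.{t}": DepthRange(f"{b}.{t}", 150, 460)
    for b in ("B1", "B2", "B3", "B4")
    for t in ("L1-fruit", "L2-fruit", "leaf")
}
TOP4 = TreeTopology.from_newick("((B1,(B2,B3)),B4);")


def _pair(branch, l1_sites, l2_sites, n_bg=60):
    bg = background_sites(n_bg)
    l1 = make_table(f"{branch}.L1-fruit", l1_sites + bg)
    l2 = make_table(f"{branch}.L2-fruit", l2_sites + bg)
    return BranchSamplePair(branch, l1, l2)


def _site(pos, alt_count, depth=300, chrom="chr1", ref="A", alt="T", **kw):
    alleles = {alt: alt_count} if alt_count else {}
    alleles.update(kw.get("extra", {}))
    return {"chrom": chrom, "pos": pos, "ref": ref, "depth": depth, "alleles": alleles}


def test_anchored_alleles_and_class():
    assert anchored_alleles("A", "T") == ("A", "T")
    assert anchored_alleles("A", "+AT") == ("A", "AAT")
    assert anchored_alleles("A", "-CG") == ("ACG", "A")
    assert variant_class("T") == "SNV"
    assert variant_class("+AT") == "indel"


def test_pipeline1_calls_clear_layer_specific_site(cfg):
    pair = _pair("B1", [_site(500, 141)], [_site(500, 0)])
    calls = pipeline1_layer_specific(pair, set(), RANGES, cfg)
    assert len(calls) == 1
    c = calls[0]
    assert (c.chrom, c.pos, c.layer, c.branch_set) == ("chr1", 500, "L1", {"B1"})


@pytest.mark.parametrize(
    "af1,af2",
    [
        (0.45, 0.44),  # small AF difference
        (0.50, 0.50),  # heterozygous in both layers
    ],
)
def test_pipeline1_excludes_filtered_sites(cfg, af1, af2):
    pair = _pair("B1", [_site(500, int(300 * af1))], [_site(500, int(300 * af2))])
    assert pipeline1_layer_specific(pair, set(), RANGES, cfg) == []


def test_pipeline1_excludes_het_sites_and_noise(cfg):
    pair = _pair("B1", [_site(500, 141)], [_site(500, 0)])
    assert pipeline1_layer_specific(pair, {("chr1", 500)}, RANGES, cfg) == []
    # single-strand alternate support
    pair = _pair(
        "B1",
        [{"chrom": "chr1", "pos": 500, "ref": "A", "depth": 300,
          "alleles": {"T": (141, 141, 0, 37.0)}}],
        [_site(500, 0)],
    )
    assert pipeline1_layer_specific(pair, set(), RANGES, cfg) == []


def test_pipeline2_shared_across_branches(cfg):
    pairs = {}
    for b in ("B1", "B2", "B3"):
        pairs[b] = _pair(b, [_site(700, 141)], [_site(700, 0)])
    pairs["B4"] = _pair("B4", [_site(700, 0)], [_site(700, 0)])
    calls = pipeline2_shared_across_branches(pairs, set(), RANGES, cfg)
    assert len(calls) == 1
    assert calls[0].branch_set == {"B1", "B2", "B3"}
    assert calls[0].layer == "L1"


def test_pipeline2_requires_strong_support_somewhere(cfg):
    pairs = {
        b: _pair(b, [_site(700, 15)], [_site(700, 0)]) for b in ("B1", "B2")
    }
    assert pipeline2_shared_across_branches(pairs, set(), RANGES, cfg) == []


def test_pipeline2_skips_single_branch_sites(cfg):
    pairs = {
        "B1": _pair("B1", [_site(700, 141)], [_site(700, 0)]),
        "B2": _pair("B2", [_site(700, 0)], [_site(700, 0)]),
    }
    assert pipeline2_shared_across_branches(pairs, set(), RANGES, cfg) == []


def test_pipeline3_single_branch_foldchange(cfg):
    pairs = {
        "B2": _pair("B2", [_site(900, 0, depth=306)], [_site(900, 95, depth=306)]),
        "B3": _pair("B3", [_site(900, 0)], [_site(900, 0)]),
    }
    calls = pipeline3_foldchange_single_branch(pairs, set(), RANGES, cfg)
    assert len(calls) == 1
    assert calls[0].layer == "L2" and calls[0].branch_set == {"B2"}


def test_pipeline3_excludes_low_foldchange_and_multibranch(cfg):
    # AF 0.20 vs 0.30: |log2 fc| < 1
    pairs = {
        "B2": _pair("B2", [_site(900, 60)], [_site(900, 90)]),
        "B3": _pair("B3", [_site(900, 0)], [_site(900, 0)]),
    }
    assert pipeline3_foldchange_single_branch(pairs, set(), RANGES, cfg) == []
    # candidate in a second branch
    pairs = {
        "B2": _pair("B2", [_site(900, 0, depth=306)], [_site(900, 95, depth=306)]),
        "B3": _pair("B3", [_site(900, 4)], [_site(900, 0)]),
    }
    assert pipeline3_foldchange_single_branch(pairs, set(), RANGES, cfg) == []


def test_pipeline4_shared_between_layers(cfg):
    tables = {}
    for b in ("B1", "B2", "B3", "B4"):
        for t in ("L1-fruit", "L2-fruit"):
            n = 135 if b == "B4" else 0
            tables[f"{b}.{t}"] = make_table(
                f"{b}.{t}", [_site(1100, n)] + background_sites(20)
            )
    calls = pipeline4_shared_between_layers(tables, set(), cfg)
    assert len(calls) == 1
    assert calls[0].layer == "shared" and calls[0].branch_set == {"B4"}


def test_pipeline4_excludes_germline_like_and_repeats(cfg):
    # alternate allele in every sample: germline-like noise
    tables = {
        f"{b}.{t}": make_table(f"{b}.{t}", [_site(1100, 150)] + background_sites(20))
        for b in ("B1", "B2")
        for t in ("L1-fruit", "L2-fruit")
    }
    assert pipeline4_shared_between_layers(tables, set(), cfg) == []
    # depth above the repeat cap
    tables = {}
    for b in ("B1", "B2"):
        for t in ("L1-fruit", "L2-fruit"):
            n = 270 if b == "B1" else 0
            tables[f"{b}.{t}"] = make_table(
                f"{b}.{t}", [_site(1100, n, depth=600)] + background_sites(20)
            )
    assert pipeline4_shared_between_layers(tables, set(), cfg) == []


def test_leaf_pipeline_thresholds(cfg):
    ranges = dict(RANGES)
    # an L1-origin mutation is invisible in bulk leaf: AF ~0.045 -> 13 reads
    t_low = make_table("B1.leaf", [_site(1300, 13)] + background_sites(50))
    # an L2-origin mutation at leaf AF ~0.39 is called
    t_ok = make_table("B2.leaf", [_site(1300, 117)] + background_sites(50))
    # strand-biased site is rejected
    t_bias = make_table(
        "B3.leaf",
        [{"chrom": "chr1", "pos": 1300, "ref": "A", "depth": 300,
          "alleles": {"T": (117, 117, 0, 37.0)}}] + background_sites(50),
    )
    calls = leaf_pipeline(
        {"B1.leaf": t_low, "B2.leaf": t_ok, "B3.leaf": t_bias}, set(), ranges, cfg
    )
    assert [(c.branch_set, c.layer) for c in calls] == [({"B2"}, "leaf")]


def test_merge_collapses_duplicates_and_records_pipelines(cfg):
    pair = _pair("B1", [_site(500, 141)], [_site(500, 0)])
    pairs = {"B1": pair, "B2": _pair("B2", [_site(500, 0)], [_site(500, 0)])}
    p1 = pipeline1_layer_specific(pair, set(), RANGES, cfg)
    p3 = pipeline3_foldchange_single_branch(pairs, set(), RANGES, cfg)
    assert len(p1) == 1 and len(p3) == 1
    tables = {p.l1.sample_id: p.l1 for p in pairs.values()}
    tables.update({p.l2.sample_id: p.l2 for p in pairs.values()})
    merged = merge_and_reconcile(p1 + p3, tables, TOP4, cfg)
    assert len(merged) == 1
    assert set(merged[0].pipelines) == {"pipeline1", "pipeline3"}
    assert merged[0].id == "SM1"


def test_merge_regenotyping_extends_branch_set(cfg):
    pair = _pair("B2", [_site(500, 141)], [_site(500, 0)])
    calls = pipeline1_layer_specific(pair, set(), RANGES, cfg)
    # B3's L1 sample has 8 alternate reads at AF 0.1: presence is added
    t_b3 = make_table("B3.L1-fruit", [_site(500, 8, depth=80)] + background_sites(10))
    tables = {
        "B2.L1-fruit": pair.l1, "B2.L2-fruit": pair.l2, "B3.L1-fruit": t_b3,
    }
    merged = merge_and_reconcile(calls, tables, TOP4, cfg)
    assert merged[0].branch_set == {"B2", "B3"}
    assert merged[0].samples["B3.L1-fruit"].added_by == "regenotype"


def test_merge_empty_input(cfg):
    assert merge_and_reconcile([], {}, TOP4, cfg) == []


def test_merge_conflicting_layers_become_shared(cfg):
    a = _pair("B1", [_site(500, 141)], [_site(500, 0)])
    b = _pair("B2", [_site(500, 0)], [_site(500, 141)])
    calls = pipeline1_layer_specific(a, set(), RANGES, cfg)
    calls += pipeline1_layer_specific(b, set(), RANGES, cfg)
    assert {c.layer for c in calls} == {"L1", "L2"}
    tables = {t.sample_id: t for p in (a, b) for t in (p.l1, p.l2)}
    with pytest.warns(UserWarning, match="conflicting layer"):
        merged = merge_and_reconcile(calls, tables, TOP4, cfg)
    assert merged[0].layer == "shared"
    assert "layer_conflict" in merged[0].flags


# ---------------------------------------------------------------------------
# brute-force oracle equivalence on random sites


def _random_tables(n_sites, seed):
    """Random 3-branch, 2-layer tables exercising every filter."""
    rng = np.random.default_rng(seed)
    branches = ("B1", "B2", "B3")
    sites = {}
    for i in range(n_sites):
        pos = 1000 + i
        per_sample = {}
        for b in branches:
            for t in ("L1-fruit", "L2-fruit"):
                depth = int(rng.choice([80, 200, 300, 350, 600]))
                kind = rng.random()
                if kind < 0.45:
                    alt = 0
                elif kind < 0.6:
                    alt = int(rng.integers(1, 6))
                elif kind < 0.8:
                    alt = int(rng.integers(6, 25))
                else:
                    alt = int(rng.integers(25, min(depth, 200)))
                plus = int(rng.choice([0, alt // 2, alt]))
                baseq = float(rng.choice([25.0, 37.0]))
                per_sample[f"{b}.{t}"] = (depth, alt, plus, alt - plus, baseq)
        sites[pos] = per_sample
    tables = {}
    for sid in [f"{b}.{t}" for b in branches for t in ("L1-fruit", "L2-fruit")]:
        specs = []
        for pos, per_sample in sites.items():
            depth, alt, plus, minus, baseq = per_sample[sid]
            alleles = {"T": (alt, plus, minus, baseq)} if alt else {}
            specs.append(
                {"chrom": "chr1", "pos": pos, "ref": "A", "depth": depth,
                 "alleles": alleles}
            )
        tables[sid] = make_table(sid, specs)
    het = {("chr1", 1000 + i) for i in rng.choice(n_sites, n_sites // 10, replace=False)}
    return tables, sites, het


def _oracle_pipeline1(sites, het, rng_lo, rng_hi, branch, cfg):
    """Independent per-site predicate conjunction for pipeline 1."""
    s1, s2 = f"{branch}.L1-fruit", f"{branch}.L2-fruit"
    rows = {}
    for pos, per in sites.items():
        d1, a1, p1, m1, q1 = per[s1]
        d2, a2, p2, m2, q2 = per[s2]
        af1, af2 = a1 / d1, a2 / d2
        rows[pos] = (d1, a1, p1, m1, q1, d2, a2, p2, m2, q2, af1, af2)
    passing_background = []
    for pos, r in rows.items():
        d1, a1, *_, d2, a2, _, _, _, q2, af1, af2 = (
            r[0], r[1], r[2], r[3], r[4], r[5], r[6], r[7], r[8], r[9], r[10], r[11],
        )
        f1 = ("chr1", pos) not in het
        f2 = rng_lo <= r[0] <= rng_hi and rng_lo <= r[5] <= rng_hi
        f3 = not (0.3 <= r[10] <= 0.65 and 0.3 <= r[11] <= 0.65)
        f4 = abs(r[10] - r[11]) >= 0.25
        if f1 and f2 and f3 and not f4:
            passing_background.append(abs(r[10] - r[11]))
    thr = float(np.percentile(passing_background, 99)) if passing_background else 0.0
    selected = set()
    for pos, r in rows.items():
        d1, a1, p1, m1, q1, d2, a2, p2, m2, q2, af1, af2 = r
        cand = a1 >= cfg.min_alt_reads_candidate or a2 >= cfg.min_alt_reads_candidate
        f1 = ("chr1", pos) not in het
        f2 = rng_lo <= d1 <= rng_hi and rng_lo <= d2 <= rng_hi
        f3 = not (0.3 <= af1 <= 0.65 and 0.3 <= af2 <= 0.65)
        f4 = abs(af1 - af2) >= 0.25
        if af1 >= af2:
            fa, fp, fm, fq, fd = a1, p1, m1, q1, d1
        else:
            fa, fp, fm, fq, fd = a2, p2, m2, q2, d2
        noisy = (fa > 0 and (fp == 0 or fm == 0)) or (fa > 0 and fq < 30) or (
            d1 > 500 or d2 > 500
        )
        if (cand and f1 and f2 and f3 and f4 and not noisy
                and fa >= 20 and abs(af1 - af2) > thr):
            selected.add(pos)
    return selected


def test_pipeline1_equals_bruteforce_on_random_sites(cfg):
    tables, sites, het = _random_tables(400, seed=5)
    ranges = {sid: DepthRange(sid, 150, 460) for sid in tables}
    for branch in ("B1", "B2", "B3"):
        pair = BranchSamplePair(
            branch, tables[f"{branch}.L1-fruit"], tables[f"{branch}.L2-fruit"]
        )
        got = {c.pos for c in pipeline1_layer_specific(pair, het, ranges, cfg)}
        want = _oracle_pipeline1(sites, het, 150, 460, branch, cfg)
        assert got == want


def test_pipeline4_equals_bruteforce_on_random_sites(cfg):
    tables, sites, het = _random_tables(400, seed=6)
    got = {c.pos for c in pipeline4_shared_between_layers(tables, het, cfg)}
    want = set()
    for pos, per in sites.items():
        f1 = ("chr1", pos) not in het
        strong = any(a >= 20 and a / d >= 0.25 for d, a, _, _, _ in per.values())
        everywhere = all(a >= 1 for _, a, _, _, _ in per.values())
        depth_ok = max(d for d, *_ in per.values()) <= 500
        tot_alt = sum(a for _, a, _, _, _ in per.values())
        tot_plus = sum(p for _, _, p, _, _ in per.values())
        tot_minus = sum(m for _, _, _, m, _ in per.values())
        strands_ok = not (tot_alt > 0 and (tot_plus == 0 or tot_minus == 0))
        # a call also needs a supported branch
        has_branch = any(
            per[f"{b}.L1-fruit"][1] >= 3 or per[f"{b}.L2-fruit"][1] >= 3
            for b in ("B1", "B2", "B3")
        )
        if f1 and strong and not everywhere and depth_ok and strands_ok and has_branch:
            want.add(pos)
    assert got == want


def test_pipelines23_equal_bruteforce_on_random_sites(cfg):
    tables, sites, het = _random_tables(400, seed=7)
    ranges = {sid: DepthRange(sid, 150, 460) for sid in tables}
    pairs = {
        b: BranchSamplePair(b, tables[f"{b}.L1-fruit"], tables[f"{b}.L2-fruit"])
        for b in ("B1", "B2", "B3")
    }
    got2 = {c.pos for c in pipeline2_shared_across_branches(pairs, het, ranges, cfg)}
    got3 = {c.pos for c in pipeline3_foldchange_single_branch(pairs, het, ranges, cfg)}
    want2, want3 = set(), set()
    for pos, per in sites.items():
        f1 = ("chr1", pos) not in het
        cand = {}
        for b in ("B1", "B2", "B3"):
            d1, a1, *_ = per[f"{b}.L1-fruit"]
            d2, a2, *_ = per[f"{b}.L2-fruit"]
            cand[b] = (a1 >= 3 or a2 >= 3) and 150 <= d1 <= 460 and 150 <= d2 <= 460
        n_cand = sum(cand.values())
        strong_any = any(a > 20 for _, a, _, _, _ in per.values())
        afs1 = [per[f"{b}.L1-fruit"][1] / per[f"{b}.L1-fruit"][0] for b in cand]
        afs2 = [per[f"{b}.L2-fruit"][1] / per[f"{b}.L2-fruit"][0] for b in cand]
        ps = 0.5 / np.mean([d for d, *_ in per.values()])
        lfc = abs(np.log2((np.mean(afs1) + ps) / (np.mean(afs2) + ps)))
        if f1 and n_cand >= 2 and strong_any and lfc >= cfg.log2fc_min:
            want2.add(pos)
        if f1 and n_cand == 1:
            b = next(k for k, v in cand.items() if v)
            d1, a1, *_ = per[f"{b}.L1-fruit"]
            d2, a2, *_ = per[f"{b}.L2-fruit"]
            psb = 0.5 / np.mean([d1, d2])
            lfcb = abs(np.log2((a1 / d1 + psb) / (a2 / d2 + psb)))
            if (a1 > 20 or a2 > 20) and lfcb >= cfg.log2fc_min:
                want3.add(pos)
    assert got2 == want2
    assert got3 == want3
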