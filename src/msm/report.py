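"""End-to-end orchestration and run reporting.

``run_all`` drives every stage on one configuration — simulate, depth
ranges, the five calling pipelines, merge, LOH, spectra, sharing/tree
analysis, genotyping sweep — writing stage outputs plus a machine-readable
summary and a manifest (config snapshot, seeds, per-stage counts), so each
reported number is traceable to a stage output file.

``catalog_percentages`` does the bookkeeping arithmetic for a published-
style catalog summary (sharing/layer/spectrum percentages from raw
tallies).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .calling import (
    BranchSamplePair,
    leaf_pipeline,
    merge_and_reconcile,
    pipeline1_layer_specific,
    pipeline2_shared_across_branches,
    pipeline3_foldchange_single_branch,
    pipeline4_shared_between_layers,
)
from .countio import FilterConfig, write_bam_readcount, write_calls_tsv, write_calls_vcf
from .depth import depth_ranges
from .genotyping import genotype_sweep
from .loh import af_shift_candidates, call_loh, detect_switch_reads
from .spectra import spectrum_summary
from .synthetic import (
    LOHEvent,
    MixtureModel,
    NoiseModel,
    SyntheticGenome,
    TISSUES,
    make_phased_variants,
    sample_id,
    simulate_counts,
    simulate_phased_reads,
    simulate_truth,
)
from .topology import DEFAULT_NEWICK, TreeTopology
from .tree import (
    branch_presence_sets,
    neighbor_joining,
    pairwise_distances,
    presence_matrix,
    topology_concordant,
)


def catalog_percentages(
    n_total: int,
    n_layer_specific: int,
    n_shared_layers: int,
    n_l1: int,
    n_l2: int,
    n_snv: int,
    n_indel: int,
    n_indel_2bp_at: int,
    n_multi_branch: int,
    n_multi_concordant: int,
    n_leaf_total: int,
    n_fruit_leaf_shared: int,
    n_l2_in_leaf: int,
    n_l1_in_leaf: int,
    n_l2_union_organs: int,
    n_l2_shared_organs: int,
) -> dict[str, float]:
    """Standard summary percentages for a layer-resolved somatic catalog.

    All values are plain ratios of the supplied tallies, on a 0-100 scale.
    """

    def pct(a: int, b: int) -> float:
        return 100.0 * a / b if b else 0.0

    return {
        "pct_layer_specific": pct(n_layer_specific, n_total),
        "pct_shared_between_layers": pct(n_shared_layers, n_total),
        "pct_l1_of_layer_specific": pct(n_l1, n_layer_specific),
        "pct_l2_of_layer_specific": pct(n_l2, n_layer_specific),
        "pct_multi_branch": pct(n_multi_branch, n_total),
        "pct_multi_branch_concordant": pct(n_multi_concordant, n_multi_branch),
        "pct_indels_2bp_at": pct(n_indel_2bp_at, n_indel),
        "pct_leaf_shared_with_fruit": pct(n_fruit_leaf_shared, n_leaf_total),
        "pct_fruit_shared_with_leaf": pct(n_fruit_leaf_shared, n_total),
        "pct_l1_found_in_leaf": pct(n_l1_in_leaf, n_l1),
        "pct_l2_found_in_leaf": pct(n_l2_in_leaf, n_l2),
        "pct_l2_meristematic": pct(n_l2_shared_organs, n_l2_union_organs),
    }


#: Catalog tallies of the layer-resolved apricot fruit-tree study that this
#: pipeline re-implements, used as the worked example for the arithmetic
#: above: 205 small mutations in fruits (193 layer-specific: 123 in L1 and
#: 70 in L2; 84 SNVs, 109 indels of which 76 are 2-bp AT-repeat slips), 64
#: present in multiple branches (60 concordant with the topology), 70 leaf
#: mutations of which 60 were shared with the adjacent fruit, 49 of the 70
#: L2 mutations recovered in leaves and none of the 123 L1 mutations, and
#: 60 of the 92 mutations seen in L2 or leaf shared between both organs.
WORKED_EXAMPLE_TALLIES = dict(
    n_total=205,
    n_layer_specific=193,
    n_shared_layers=12,
    n_l1=123,
    n_l2=70,
    n_snv=84,
    n_indel=109,
    n_indel_2bp_at=76,
    n_multi_branch=64,
    n_multi_concordant=60,
    n_leaf_total=70,
    n_fruit_leaf_shared=60,
    n_l2_in_leaf=49,
    n_l1_in_leaf=0,
    n_l2_union_organs=92,
    n_l2_shared_organs=60,
)


def catalog_summary(calls, topology: TreeTopology) -> dict:
    """Counts by layer, sharing classes and concordance for a catalog."""
    by_layer = {l: sum(1 for c in calls if c.layer == l) for l in ("L1", "L2", "shared", "leaf")}
    sharing = branch_presence_sets(calls)
    multi = [c for c in calls if len(c.branch_set) > 1]
    concord = sum(1 for c in multi if topology_concordant(c.branch_set, topology))
    return {
        "n_calls": len(calls),
        "by_layer": by_layer,
        "n_multi_branch": len(multi),
        "n_multi_branch_concordant": concord,
        "n_single_branch": len(calls) - len(multi),
        "n_branch_sets": int(len(sharing)),
    }


@dataclass
class RunResult:
    catalog: list
    loh_calls: list
    truth: object
    tables: dict
    summary: dict
    manifest: dict


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: dict | None = None, outdir: str | Path | None = None) -> RunResult:
    """Run the full pipeline on a simulated dataset.

    Recognised config keys (all optional): seed, newick, rate_l1, rate_l2,
    p_shared, n_pregraft_l1, n_pregraft_l2, n_organ_per_sample, mean_depth,
    error_rate, n_background, n_loh_events, filter (FilterConfig fields).
    Deterministic given the seed.
    """
    config = dict(config or {})
    seed = int(config.get("seed", 0))
    cfg = FilterConfig(**config.get("filter", {}))
    topology = TreeTopology.from_newick(config.get("newick", DEFAULT_NEWICK))
    genome = SyntheticGenome(seed=seed * 10 + 1)
    truth = simulate_truth(
        topology,
        rate_l1=config.get("rate_l1", 4.0),
        rate_l2=config.get("rate_l2", 2.0),
        p_shared=config.get("p_shared", 0.06),
        n_pregraft_l1=config.get("n_pregraft_l1", 21),
        n_pregraft_l2=config.get("n_pregraft_l2", 1),
        n_organ_per_sample=config.get("n_organ_per_sample", 1),
        seed=seed * 10 + 2,
        genome=genome,
    )
    mixture = MixtureModel()
    noise = NoiseModel(
        mean_depth=config.get("mean_depth", 300.0),
        error_rate=config.get("error_rate", 1e-3),
        seed=seed * 10 + 3,
    )
    samples = [(b, t) for b in topology.tips for t in TISSUES]
    tables = simulate_counts(
        truth, mixture, noise, samples, n_background=config.get("n_background", 5000)
    )
    ranges = depth_ranges(tables)
    pairs = {
        b: BranchSamplePair(
            b,
            tables[sample_id(b, "L1-fruit")],
            tables[sample_id(b, "L2-fruit")],
            tables[sample_id(b, "leaf")],
        )
        for b in topology.tips
    }
    het_sites: set = set()
    calls = []
    per_pipeline = {}
    for b, pair in pairs.items():
        calls += pipeline1_layer_specific(pair, het_sites, ranges, cfg)
    per_pipeline["pipeline1"] = len(calls)
    c2 = pipeline2_shared_across_branches(pairs, het_sites, ranges, cfg)
    c3 = pipeline3_foldchange_single_branch(pairs, het_sites, ranges, cfg)
    fruit_tables = {
        t.sample_id: t for p in pairs.values() for t in (p.l1, p.l2)
    }
    c4 = pipeline4_shared_between_layers(fruit_tables, het_sites, cfg)
    leaf_tables = {sample_id(b, "leaf"): tables[sample_id(b, "leaf")] for b in topology.tips}
    cleaf = leaf_pipeline(leaf_tables, het_sites, ranges, cfg)
    per_pipeline.update(pipeline2=len(c2), pipeline3=len(c3), pipeline4=len(c4), leaf=len(cleaf))
    catalog = merge_and_reconcile(calls + c2 + c3 + c4 + cleaf, tables, topology, cfg)

    # LOH stage on simulated phased reads
    n_loh = int(config.get("n_loh_events", 1))
    phased = make_phased_variants(genome, seed=seed * 10 + 4)
    events = [
        LOHEvent(chrom="chr1", start=50_000 + 20_000 * i, end=58_000 + 20_000 * i,
                 branch=topology.tips[i % len(topology.tips)], layer="L1")
        for i in range(n_loh)
    ]
    loh_noise = NoiseModel(mean_depth=noise.mean_depth, error_rate=noise.error_rate,
                           seed=seed * 10 + 5)
    fruit_samples = [(b, t) for b in topology.tips for t in ("L1-fruit", "L2-fruit")]
    obs, ph_tables = simulate_phased_reads(events, phased, loh_noise, fruit_samples, mixture)
    ph_ranges = depth_ranges(ph_tables)
    cand_frames = [
        af_shift_candidates(
            BranchSamplePair(b, ph_tables[sample_id(b, "L1-fruit")],
                             ph_tables[sample_id(b, "L2-fruit")]),
            phased, ph_ranges, cfg,
        )
        for b in topology.tips
    ]
    candidates = pd.concat(cand_frames, ignore_index=True) if cand_frames else pd.DataFrame()
    evidence = detect_switch_reads(obs, phased, cfg)
    loh_calls = call_loh(candidates, evidence)

    spectrum = spectrum_summary(catalog, genome)
    summary = catalog_summary(catalog, topology)
    ts_pct, tv_pct = spectrum.ts_tv_percent()
    summary["spectrum"] = {
        "n_snv": spectrum.n_snv,
        "n_indel": spectrum.n_indel,
        "transitions_pct": ts_pct,
        "transversions_pct": tv_pct,
        "cpg_transitions": spectrum.cpg_transitions,
    }
    summary["n_loh_calls"] = len(loh_calls)
    summary["per_pipeline"] = per_pipeline
    summary["n_truth"] = len(truth)

    sample_ids = [sample_id(b, t) for b in topology.tips for t in ("L1-fruit", "L2-fruit")]
    fruit_calls = [c for c in catalog if c.layer in ("L1", "L2", "shared")]
    nj_newick = ""
    if fruit_calls:
        pm = presence_matrix(fruit_calls, sample_ids)
        nj_newick = neighbor_joining(pairwise_distances(pm)).newick
    summary["nj_newick"] = nj_newick

    sweep = genotype_sweep(
        [c for c in catalog if c.layer == "L1"],
        tables,
        {
            "L1": lambda b: [sample_id(b, "L1-fruit")],
            "L1+leaf": lambda b: [sample_id(b, "L1-fruit"), sample_id(b, "leaf")],
        },
    )

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in config.items()},
        "filter": cfg.to_dict(),
        "stage_counts": {
            "truth_mutations": len(truth),
            "samples": len(tables),
            **per_pipeline,
            "catalog": len(catalog),
            "loh": len(loh_calls),
        },
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        truth.write_tsv(outdir / "truth.tsv")
        (outdir / "topology.nwk").write_text(topology.to_newick() + "\n")
        counts_dir = outdir / "counts"
        counts_dir.mkdir(exist_ok=True)
        for sid, t in tables.items():
            write_bam_readcount(t, counts_dir / f"{sid}.counts.tsv")
        write_calls_tsv(catalog, outdir / "catalog.tsv")
        write_calls_vcf(
            sorted(catalog + loh_calls, key=lambda c: (c.chrom, c.pos, c.alt)),
            outdir / "catalog.vcf",
        )
        sweep.summary.to_csv(outdir / "genotype_sweep.tsv", sep="\t", index=False)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
        manifest["checksums"] = {
            p.name: _checksum(p) for p in sorted(outdir.glob("*.tsv"))
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return RunResult(
        catalog=catalog, loh_calls=loh_calls, truth=truth, tables=tables,
        summary=summary, manifest=manifest,
    )
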