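# msm — layer-aware somatic mutation analysis

Plant shoot apical meristems are organised in nearly independent cell
layers: the tunica layers L1 and L2 and the corpus L3.  A somatic mutation
arising in one layer of a meristem is propagated — in that layer only —
into every branch and organ that later develops from it.  Bulk sequencing
mixes the layers and hides most of this mosaicism; sequencing layer-enriched
tissue (fruit peel ≈ L1, fruit flesh ≈ L2, bulk leaf ≈ an L1/L2/L3 mixture
with L1 under-represented) exposes it.

`msm` is a tested re-implementation of that analysis for people studying
genomic mosaicism in trees and clonally propagated crops.  From per-sample
allelic read counts (bam-readcount text dialect) it provides:

* **Calling** — four fruit pipelines (single-branch AF contrast between
  layers, cross-branch sharing, within-branch fold-change, layer-shared)
  plus a bulk-leaf pipeline, merged into one catalog with targeted
  re-genotyping replacing manual re-checking.  Candidate sites need ≥3
  alternate reads; confident calls need 20 reads, AF contrast ≥0.25 or
  |log2 fold-change| ≥1, clean strand/quality evidence and depth inside
  each sample's optimal range (0.05/0.95 quantiles).
* **LOH** — loss-of-heterozygosity tracts from an allele-frequency shift at
  phased inter-haplotype variants *and* ≥10 haplotype-switch reads between
  phased sites ≤1 kb apart, in exactly one layer of a branch.
* **Spectra** — transitions/transversions, the 96 canonical
  pyrimidine-centred trinucleotide contexts, CpG transitions, signed indel
  sizes, and region enrichment (one-tailed Fisher exact test on
  callable-length-normalised counts, Benjamini–Hochberg adjusted).
* **Tree analysis** — branch presence sets, topology concordance (a branch
  set is concordant when it is a clade of the physical tree), Hamming
  distances, deterministic Saitou–Nei neighbour joining, and a permutation
  test for layer-versus-branch clustering.
* **Genotyping** — bulk read-support sweeps over known sites and
  per-cluster genotyping of single-cell allelic counts.
* **Simulation** — a two-layer meristem lineage simulator (`msm.synthetic`)
  that generates ground-truth catalogs on a branching topology and emits
  realistic count tables, phased-read observations and single-cell counts,
  so every stage runs and is testable with no external data.

## Worked example

Run the whole pipeline on a simulated tree (seven branches `B1..B7`, two
layers, 300× depth, the default topology `((B1,(B2,B3)),B4,(B5,(B6,B7)))`):

```bash
msm all --seed 1 --outdir demo/
```

or equivalently `msm.report.run_all({"seed": 1}, "demo/")`.  With seed 1
this prints (abridged):

```json
{
  "n_calls": 94,
  "by_layer": {"L1": 59, "L2": 23, "shared": 3, "leaf": 9},
  "n_multi_branch": 42,
  "n_multi_branch_concordant": 42,
  "spectrum": {"n_snv": 47, "n_indel": 47,
               "transitions_pct": 68.1, "cpg_transitions": 6},
  "n_loh_calls": 1,
  "n_truth": 98
}
```

Reading this: of 98 simulated mutations, 94 were recovered; the catalog is
dominated by L1 calls (the higher-load layer), every one of the 42
mutations found in more than one branch sits on a clade of the branching
topology (meristematic propagation), the point-mutation spectrum is
transition-biased, and the one planted LOH event was recovered.  `demo/`
holds the catalog (TSV and VCF with `LAYER`/`BRANCHES`/`PIPELINE` INFO
keys), per-sample count tables, the genotyping sweep, a JSON summary and a
manifest with config, seeds and per-stage counts.

Step-wise subcommands (`msm simulate`, `msm call`, `msm depth-range`,
`msm tree`, `msm genotype`, `msm sc-genotype`, `msm validate`,
`msm convert`) operate on files and compose the same way; see `--help`.

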