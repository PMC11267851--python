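"""Mutation spectra and genomic-region enrichment.

Point mutations are summarised in the canonical pyrimidine-centred
notation (six substitution classes C>A..T>G; 96 trinucleotide contexts),
indels by signed size, and region enrichment by a one-tailed Fisher exact
test on callable-length-normalised counts with Benjamini-Hochberg
adjustment across region classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .countio import MutationCall

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

#: Default tail per region class: transposable elements / repeats are
#: tested for excess, genic classes for depletion.
DEFAULT_TAILS = {
    "CDS": "less",
    "UTR": "less",
    "intron": "less",
    "TE": "greater",
    "repeat": "greater",
    "intergenic": "greater",
}

#: Priority when region annotations overlap (most specific first).
REGION_PRIORITY = ("CDS", "UTR", "intron", "TE", "repeat", "intergenic")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_snv(ref: str, alt: str, triplet: str) -> tuple[str, str, bool]:
    """Canonical substitution class, canonical triplet, and CpG flag.

    Purine-centred mutations are reverse-complemented so the mutated base
    is always a pyrimidine; the CpG flag marks C>T transitions at a CG
    dinucleotide (the methylation-associated class).
    """
    for b in (ref, alt):
        if b not in "ACGT":
            raise ValueError(f"non-ACGT allele {b!r}")
    if any(b not in "ACGT" for b in triplet) or len(triplet) != 3:
        raise ValueError(f"invalid triplet {triplet!r}")
    if triplet[1] != ref:
        raise ValueError(f"triplet {triplet} centre does not match ref {ref}")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    if ref in "AG":  # purine-centred: flip to the pyrimidine strand
        ref, alt, triplet = revcomp(ref), revcomp(alt), revcomp(triplet)
    cls = f"{ref}>{alt}"
    cpg = cls == "C>T" and triplet[2] == "G"
    return cls, triplet, cpg


@dataclass
class SpectrumSummary:
    transitions: int = 0
    transversions: int = 0
    substitution_counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in SUBSTITUTION_CLASSES}
    )
    triplet_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    cpg_transitions: int = 0
    indel_sizes: dict[int, int] = field(default_factory=dict)

    @property
    def n_snv(self) -> int:
        return self.transitions + self.transversions

    @property
    def n_indel(self) -> int:
        return sum(self.indel_sizes.values())

    def ts_tv_percent(self) -> tuple[float, float]:
        n = self.n_snv
        if n == 0:
            return 0.0, 0.0
        return 100 * self.transitions / n, 100 * self.transversions / n


def indel_size(ref: str, alt: str) -> int:
    """Signed size of an anchored indel: insertions positive, deletions
    negative."""
    return len(alt) - len(ref)


def spectrum_summary(calls: Sequence[MutationCall], genome) -> SpectrumSummary:
    """Tally substitution classes, triplet contexts, CpG transitions and
    indel sizes for a catalog.  ``genome`` must provide
    ``triplet(chrom, pos) -> str | None`` for flank lookup."""
    out = SpectrumSummary()
    for c in calls:
        if c.var_class == "SNV":
            triplet = genome.triplet(c.chrom, c.pos)
            if triplet is None:
                warnings.warn(f"{c.id}: no flanking bases at contig edge; skipped")
                continue
            cls, canon, cpg = classify_snv(c.ref, c.alt, triplet)
            if (c.ref, c.alt) in TRANSITIONS:
                out.transitions += 1
            else:
                out.transversions += 1
            out.substitution_counts[cls] += 1
            out.triplet_counts[(cls, canon)] = out.triplet_counts.get((cls, canon), 0) + 1
            if cpg:
                out.cpg_transitions += 1
        elif c.var_class == "indel":
            size = indel_size(c.ref, c.alt)
            out.indel_sizes[size] = out.indel_sizes.get(size, 0) + 1
    return out


def assign_region(chrom: str, pos: int, regions: pd.DataFrame) -> str:
    """Region class of a position under the priority CDS > UTR > intron >
    TE > repeat > intergenic; unannotated positions are intergenic."""
    hits = regions[
        (regions["chrom"] == chrom) & (regions["start"] <= pos) & (regions["end"] >= pos)
    ]
    if hits.empty:
        return "intergenic"
    classes = set(hits["region"])
    for cls in REGION_PRIORITY:
        if cls in classes:
            return cls
    return sorted(classes)[0]


def region_enrichment(
    calls: Sequence[MutationCall],
    regions: pd.DataFrame,
    callable_lengths: Mapping[str, int],
    tails: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region-class mutation enrichment against a uniform null.

    Each region class is tested with a one-tailed Fisher exact test on the
    2x2 table (mutations in/out of the class vs callable bases in/out);
    p-values are Benjamini-Hochberg adjusted across classes.  Frequencies
    are mutations per callable base.
    """
    tails = dict(DEFAULT_TAILS, **(tails or {}))
    lengths = {k: int(v) for k, v in callable_lengths.items()}
    zero = [k for k, v in lengths.items() if v <= 0]
    if zero:
        warnings.warn(f"regions with zero callable length excluded: {zero}")
        for k in zero:
            del lengths[k]
    total_len = sum(lengths.values())
    obs = {k: 0 for k in lengths}
    for c in calls:
        cls = assign_region(c.chrom, c.pos, regions)
        if cls in obs:
            obs[cls] += 1
    n_total = sum(obs.values())
    rows = []
    for cls in lengths:
        k_in, l_in = obs[cls], lengths[cls]
        k_out, l_out = n_total - k_in, total_len - l_in
        tail = tails.get(cls, "two-sided")
        table = [[k_in, k_out], [l_in - k_in, l_out - k_out]]
        _, p = fisher_exact(table, alternative=tail)
        rows.append(
            {
                "region": cls,
                "observed": k_in,
                "callable_length": l_in,
                "frequency": k_in / l_in,
                "tail": tail,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        _, p_adj, _, _ = multipletests(df["p"], alpha=alpha, method="fdr_bh")
        df["p_adjusted"] = np.maximum(p_adj, df["p"])
        df["significant"] = df["p_adjusted"] < alpha
    return df
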