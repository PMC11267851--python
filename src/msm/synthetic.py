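"""Synthetic two-layer meristem lineage simulator.

Plant shoot apical meristems are organised in cell layers (tunica L1/L2,
corpus L3) that stay largely separate while branches and organs develop.
A somatic mutation arising in one layer of a meristem node is therefore
expected in the same layer of every branch descending from that node, and
tissue samples are mixtures of layers (fruit peel is almost pure L1, flesh
almost pure L2, bulk leaf is dominated by mesophyll/L2 with epidermis/L1
under-represented).

This module generates ground-truth mutation catalogs on a branching
topology and emits per-sample allelic count tables (plus read-level phased
haplotype observations for LOH and per-barcode single-cell counts) with
binomial sequencing noise, so every downstream stage of the pipeline can be
exercised without external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .countio import AlleleCountTable, _ALLELE_COLS
from .topology import TreeTopology

TISSUES = ("L1-fruit", "L2-fruit", "leaf")

#: Dominant meristem layer of each tissue type (used for organ-level
#: mutations and for deciding which sample carries an LOH event).
TISSUE_MAIN_LAYER = {"L1-fruit": "L1", "L2-fruit": "L2", "leaf": "L2"}

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def sample_id(branch: str, tissue: str) -> str:
    return f"{branch}.{tissue}"


def split_sample_id(sid: str) -> tuple[str, str]:
    branch, tissue = sid.split(".", 1)
    return branch, tissue


# ---------------------------------------------------------------------------
# genome


class SyntheticGenome:
    """Random reference sequence with optional AT-dinucleotide hotspots.

    The hotspots emulate the microsatellite context in which most somatic
    indels occur; indel truth mutations are preferentially placed there.
    """

    def __init__(
        self,
        chrom_lengths: dict[str, int] | None = None,
        seed: int = 0,
        n_at_hotspots: int = 200,
        hotspot_repeats: int = 5,
    ):
        self.chrom_lengths = dict(chrom_lengths or {"chr1": 1_000_000, "chr2": 1_000_000})
        rng = np.random.default_rng(seed)
        self._seq: dict[str, np.ndarray] = {}
        self.at_hotspots: list[tuple[str, int]] = []
        run = hotspot_repeats * 2
        for chrom, length in self.chrom_lengths.items():
            seq = rng.choice(_BASES, size=length)
            n_hot = max(0, int(round(n_at_hotspots * length / sum(self.chrom_lengths.values()))))
            if n_hot:
                starts = rng.choice(
                    np.arange(10, length - run - 10), size=n_hot, replace=False
                )
                starts.sort()
                for s in starts:
                    seq[s : s + run] = np.where(
                        np.arange(run) % 2 == 0, b"A", b"T"
                    ).astype("S1")
                    self.at_hotspots.append((chrom, int(s) + 1))  # 1-based start
            self._seq[chrom] = seq

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self._seq[chrom][pos - 1].decode()

    def slice(self, chrom: str, start: int, end: int) -> str:
        """1-based closed interval."""
        return self._seq[chrom][start - 1 : end].tobytes().decode()

    def triplet(self, chrom: str, pos: int) -> str | None:
        if pos < 2 or pos > self.chrom_lengths[chrom] - 1:
            return None
        return self.slice(chrom, pos - 1, pos + 1)


# ---------------------------------------------------------------------------
# models


@dataclass
class MixtureModel:
    """Per-tissue meristem-layer cell proportions.

    Defaults: fruit peel is 95% L1, fruit flesh 98% L2, and bulk leaf is
    8.9% L1 (epidermis), 78.2% L2 (mesophyll), 7.2% L3 (vascular) with the
    remainder unassigned — the leaf proportions observed in single-cell
    expression data of the same system.
    """

    fractions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "L1-fruit": {"L1": 0.95, "L2": 0.05},
            "L2-fruit": {"L1": 0.02, "L2": 0.98},
            "leaf": {"L1": 0.089, "L2": 0.782, "L3": 0.072, "other": 0.057},
        }
    )

    def __post_init__(self) -> None:
        for tissue, fr in self.fractions.items():
            if any(not 0.0 <= v <= 1.0 for v in fr.values()):
                raise ValueError(f"{tissue}: layer fractions must be within [0, 1]")
            if abs(sum(fr.values()) - 1.0) > 1e-9:
                raise ValueError(f"{tissue}: layer fractions must sum to 1")

    def fraction(self, tissue: str, layers: Iterable[str]) -> float:
        if tissue not in self.fractions:
            raise KeyError(f"mixture model has no tissue {tissue!r}")
        fr = self.fractions[tissue]
        return sum(fr.get(l, 0.0) for l in layers)


@dataclass
class NoiseModel:
    """Sequencing depth and error model.

    Depth is negative-binomial around ``mean_depth`` (the study's samples
    were sequenced at 198-422x, so 300x is the default); overdispersion is
    what makes a per-sample optimal depth range meaningful.
    """

    mean_depth: float = 300.0
    depth_dispersion: float = 10.0  # NB size parameter; larger = tighter
    error_rate: float = 1e-3
    seed: int = 0
    #: fraction of background positions in repeat-like (coverage-collapsed)
    #: or dropout regions; these are what the optimal-depth-range filter is
    #: meant to remove
    frac_repeat: float = 0.04
    frac_dropout: float = 0.04
    repeat_depth_multiplier: float = 3.0
    dropout_depth_multiplier: float = 0.25

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if not 0.0 <= self.error_rate <= 0.01:
            raise ValueError("error_rate must be within [0, 0.01]")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be > 0")
        if self.frac_repeat + self.frac_dropout > 1:
            raise ValueError("pathological site fractions exceed 1")

    def draw_depths(
        self, rng: np.random.Generator, n: int, multiplier: np.ndarray | float = 1.0
    ) -> np.ndarray:
        if self.mean_depth == 0:
            return np.zeros(n, dtype=int)
        r = self.depth_dispersion
        mean = self.mean_depth * np.broadcast_to(np.asarray(multiplier, dtype=float), (n,))
        p = r / (r + np.maximum(mean, 1e-9))
        return rng.negative_binomial(r, p)

    def site_class_multipliers(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Per-site depth multipliers shared across samples (repeat pileups
        and dropout regions are properties of the locus, not the sample)."""
        u = rng.random(n)
        mult = np.ones(n)
        mult[u < self.frac_repeat] = self.repeat_depth_multiplier
        mult[(u >= self.frac_repeat) & (u < self.frac_repeat + self.frac_dropout)] = (
            self.dropout_depth_multiplier
        )
        return mult


# ---------------------------------------------------------------------------
# truth


@dataclass(frozen=True)
class TruthMutation:
    id: str
    chrom: str
    pos: int
    ref: str
    alt: str  # anchored VCF-style alleles
    token: str  # bam-readcount allele token (base, +SEQ or -SEQ)
    var_class: str  # SNV | indel
    origin_layer: str  # L1 | L2 | both
    origin_node: str  # topology node, "pre-graft" or "organ:<sample_id>"
    branch_set: frozenset[str]


@dataclass
class TruthSet:
    mutations: list[TruthMutation]
    topology: TreeTopology
    genome: SyntheticGenome

    def __len__(self) -> int:
        return len(self.mutations)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": m.id,
                    "chrom": m.chrom,
                    "pos": m.pos,
                    "ref": m.ref,
                    "alt": m.alt,
                    "token": m.token,
                    "class": m.var_class,
                    "origin_layer": m.origin_layer,
                    "origin_node": m.origin_node,
                    "branch_set": ",".join(sorted(m.branch_set)),
                }
                for m in self.mutations
            ]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _draw_positions(
    genome: SyntheticGenome, rng: np.random.Generator, n: int, used: set[tuple[str, int]]
) -> list[tuple[str, int]]:
    chroms = list(genome.chrom_lengths)
    weights = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    out = []
    while len(out) < n:
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        pos = int(rng.integers(3, genome.chrom_lengths[chrom] - 2))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            out.append((chrom, pos))
    return out


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _make_snv(genome, rng, chrom, pos, p_transition: float = 0.6):
    """Random SNV with a transition bias (plant somatic spectra are
    dominated by C:G>T:A changes)."""
    ref = genome.base(chrom, pos)
    if rng.random() < p_transition:
        alt = _TRANSITION[ref]
    else:
        alt = rng.choice([b for b in "ACGT" if b != ref and b != _TRANSITION[ref]])
    return ref, str(alt), str(alt), "SNV"


def _make_indel(genome, rng, chrom, pos, at_fraction: float):
    """Anchored indel; with probability ``at_fraction`` a 2-bp AT-slip event."""
    anchor = genome.base(chrom, pos)
    if rng.random() < at_fraction:
        unit = "AT" if anchor != "T" else "TA"
        if rng.random() < 0.5:
            return anchor, anchor + unit, "+" + unit, "indel"
        nxt = genome.slice(chrom, pos + 1, pos + 2)
        return anchor + nxt, anchor, "-" + nxt, "indel"
    size = int(rng.integers(1, 4))
    if rng.random() < 0.5:
        ins = "".join(rng.choice(list("ACGT"), size=size))
        return anchor, anchor + ins, "+" + ins, "indel"
    removed = genome.slice(chrom, pos + 1, pos + size)
    return anchor + removed, anchor, "-" + removed, "indel"


def simulate_truth(
    topology: TreeTopology,
    rate_l1: float = 4.0,
    rate_l2: float = 2.0,
    p_shared: float = 0.06,
    n_pregraft_l1: int = 21,
    n_pregraft_l2: int = 1,
    n_organ_per_sample: int = 1,
    seed: int = 0,
    genome: SyntheticGenome | None = None,
    p_indel: float = 0.56,
    at_indel_fraction: float = 0.7,
    organ_samples: Sequence[str] | None = None,
) -> TruthSet:
    """Generate a ground-truth mutation catalog on the meristem lineage.

    Per topology node, Poisson(rate) mutations arise in each layer (L1
    accumulates mutations faster than L2); each is propagated to all tips
    below its origin node.  A fraction ``p_shared`` of mutations are shared
    between layers, placed either at a single branch or at the root (half
    of observed layer-shared mutations sit at one branch).  ``pre-graft``
    mutations were fixed in the grafted cutting and appear in every branch;
    organ mutations arose during organ development and are private to one
    sample.
    """
    if rate_l1 < 0 or rate_l2 < 0:
        raise ValueError("mutation rates must be >= 0")
    if rate_l1 < rate_l2:
        raise ValueError("rate_l1 must be >= rate_l2 (L1 carries the higher load)")
    if not 0.0 <= p_shared <= 1.0:
        raise ValueError("p_shared must be within [0, 1]")
    if not topology.tips:
        raise ValueError("topology has no tips")
    genome = genome or SyntheticGenome(seed=seed)
    rng = np.random.default_rng(seed)
    if organ_samples is None:
        organ_samples = [sample_id(b, "leaf") for b in topology.tips]

    all_tips = frozenset(topology.tips)
    plan: list[tuple[str, str, frozenset[str]]] = []  # (layer, origin_node, branch_set)
    for node in topology.nodes:
        tips = topology.subtree_tips(node)
        for layer, rate in (("L1", rate_l1), ("L2", rate_l2)):
            for _ in range(rng.poisson(rate)):
                if p_shared > 0 and rng.random() < p_shared:
                    # layer-shared mutation: single branch or root
                    if rng.random() < 0.5:
                        tip = topology.tips[rng.integers(len(topology.tips))]
                        plan.append(("both", tip, frozenset([tip])))
                    else:
                        plan.append(("both", topology.nodes[0], all_tips))
                else:
                    plan.append((layer, node, tips))
    for _ in range(n_pregraft_l1):
        plan.append(("L1", "pre-graft", all_tips))
    for _ in range(n_pregraft_l2):
        plan.append(("L2", "pre-graft", all_tips))
    for sid in organ_samples:
        branch, tissue = split_sample_id(sid)
        if branch not in all_tips:
            raise ValueError(f"organ sample {sid!r} not on a topology tip")
        for _ in range(n_organ_per_sample):
            plan.append(
                (TISSUE_MAIN_LAYER[tissue], f"organ:{sid}", frozenset([branch]))
            )

    used: set[tuple[str, int]] = set()
    positions = _draw_positions(genome, rng, len(plan), used)
    mutations = []
    for i, ((layer, node, tips), (chrom, pos)) in enumerate(zip(plan, positions), 1):
        if rng.random() < p_indel:
            ref, alt, token, cls = _make_indel(genome, rng, chrom, pos, at_indel_fraction)
        else:
            ref, alt, token, cls = _make_snv(genome, rng, chrom, pos)
        mutations.append(
            TruthMutation(
                id=f"T{i}", chrom=chrom, pos=pos, ref=ref, alt=alt, token=token,
                var_class=cls, origin_layer=layer, origin_node=node, branch_set=tips,
            )
        )
    mutations.sort(key=lambda m: (m.chrom, m.pos))
    return TruthSet(mutations=mutations, topology=topology, genome=genome)


# ---------------------------------------------------------------------------
# bulk counts


def carrier_layers(mut: TruthMutation) -> tuple[str, ...]:
    return ("L1", "L2") if mut.origin_layer == "both" else (mut.origin_layer,)


def expected_af(mut: TruthMutation, tissue: str, mixture: MixtureModel) -> float:
    """Closed-form expected alternate allele frequency in a carrier sample.

    A heterozygous mutation carried by a fraction f of the sample's cells
    has expected AF = 0.5 * f.
    """
    return 0.5 * mixture.fraction(tissue, carrier_layers(mut))


def _carrier_fraction(mut: TruthMutation, sid: str, mixture: MixtureModel) -> float:
    branch, tissue = split_sample_id(sid)
    if mut.origin_node.startswith("organ:"):
        return (
            mixture.fraction(tissue, carrier_layers(mut))
            if mut.origin_node == f"organ:{sid}"
            else 0.0
        )
    if branch not in mut.branch_set:
        return 0.0
    return mixture.fraction(tissue, carrier_layers(mut))


def simulate_counts(
    truth: TruthSet,
    mixture: MixtureModel,
    noise: NoiseModel,
    samples: Sequence[tuple[str, str]],
    n_background: int = 5000,
    base_quality: float = 37.0,
    map_quality: float = 60.0,
) -> dict[str, AlleleCountTable]:
    """Emit per-sample allele count tables at truth + background positions.

    At a mutation site the expected alternate fraction is 0.5 times the
    fraction of the sample's cells that belong to the origin layer(s) and
    descend from the origin node; everywhere else alternate reads arise
    only from the per-base error rate.  Strand counts split ~50/50.

    Truth mutations sit at normal-coverage (callable) loci; a configurable
    fraction of background sites gets repeat-like or dropout coverage
    (consistent across samples), which is what the per-sample optimal
    depth range is meant to exclude.
    """
    tips = set(truth.topology.tips)
    for branch, tissue in samples:
        if branch not in tips:
            raise ValueError(f"sample branch {branch!r} is not a topology tip")
        if tissue not in mixture.fractions:
            raise ValueError(f"mixture model missing tissue {tissue!r}")
    rng = np.random.default_rng(noise.seed)

    used = {(m.chrom, m.pos) for m in truth.mutations}
    background = _draw_positions(truth.genome, rng, n_background, used)
    bg_mult = noise.site_class_multipliers(rng, len(background))
    sites = [
        (m.chrom, m.pos, truth.genome.base(m.chrom, m.pos), m.token, 1.0)
        for m in truth.mutations
    ]
    sites += [
        (c, p, truth.genome.base(c, p), "", float(m))
        for (c, p), m in zip(background, bg_mult)
    ]
    sites.sort(key=lambda s: (s[0], s[1]))
    n_sites = len(sites)
    site_chrom = np.array([s[0] for s in sites])
    site_pos = np.array([s[1] for s in sites], dtype=int)
    site_ref = np.array([s[2] for s in sites])
    site_token = np.array([s[3] for s in sites], dtype=object)
    site_mult = np.array([s[4] for s in sites])

    mut_by_pos = {(m.chrom, m.pos): m for m in truth.mutations}
    err = noise.error_rate
    tables: dict[str, AlleleCountTable] = {}
    for branch, tissue in samples:
        sid = sample_id(branch, tissue)
        fracs = np.zeros(n_sites)
        for i in range(n_sites):
            m = mut_by_pos.get((site_chrom[i], site_pos[i]))
            if m is not None:
                fracs[i] = _carrier_fraction(m, sid, mixture)
        p_alt = 0.5 * fracs
        p_alt = p_alt * (1 - err) + (1 - p_alt) * err / 3.0
        depths = noise.draw_depths(rng, n_sites, multiplier=site_mult)
        alt = rng.binomial(depths, p_alt)
        err_pool = rng.binomial(np.maximum(depths - alt, 0), err)
        e1 = rng.binomial(err_pool, 1 / 3)
        e2 = rng.binomial(err_pool - e1, 1 / 2)
        e3 = err_pool - e1 - e2
        ref_count = depths - alt - err_pool

        rows: list[tuple] = []
        for i in range(n_sites):
            d = int(depths[i])
            if d == 0:
                continue
            ref = site_ref[i]
            others = [b for b in "ACGT" if b != ref]
            token = site_token[i]
            if token == "":
                # background site: alt reads are errors on a random base
                errs = [int(alt[i]) + int(e1[i]), int(e2[i]), int(e3[i])]
            else:
                errs = [int(e1[i]), int(e2[i]), int(e3[i])]
            alleles = [(ref, int(ref_count[i]))]
            if token != "" and alt[i] > 0:
                alleles.append((token, int(alt[i])))
            for b, e in zip(others, errs):
                if e > 0 and b != token:
                    alleles.append((b, e))
            for allele, count in alleles:
                plus = int(rng.binomial(count, 0.5))
                rows.append(
                    (site_chrom[i], int(site_pos[i]), ref, d, allele, count,
                     plus, count - plus, base_quality, map_quality)
                )
        tables[sid] = AlleleCountTable(sid, pd.DataFrame(rows, columns=_ALLELE_COLS))
    return tables


# ---------------------------------------------------------------------------
# phased reads / LOH


@dataclass(frozen=True)
class LOHEvent:
    """A loss-of-heterozygosity tract: one haplotype's alleles replace the
    other's over [start, end] in one layer of one branch."""

    chrom: str
    start: int
    end: int
    branch: str
    layer: str = "L1"
    retained: str = "A"  # which parental haplotype survives

    def __post_init__(self) -> None:
        if self.retained not in ("A", "B"):
            raise ValueError("retained haplotype must be 'A' or 'B'")
        if self.end < self.start:
            raise ValueError("event end < start")


def make_phased_variants(
    genome: SyntheticGenome,
    spacing: int = 500,
    chrom: str = "chr1",
    start: int = 1,
    end: int = 200_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Evenly spaced phased inter-haplotype variants (columns: chrom, pos,
    allele_a, allele_b).  Haplotype A is the reference-carrying parent."""
    rng = np.random.default_rng(seed)
    positions = np.arange(start + spacing, min(end, genome.chrom_lengths[chrom]), spacing)
    rows = []
    for pos in positions:
        a = genome.base(chrom, int(pos))
        b = str(rng.choice([x for x in "ACGT" if x != a]))
        rows.append((chrom, int(pos), a, b))
    return pd.DataFrame(rows, columns=["chrom", "pos", "allele_a", "allele_b"])


def simulate_phased_reads(
    truth_loh: Sequence[LOHEvent],
    phased: pd.DataFrame,
    noise: NoiseModel,
    samples: Sequence[tuple[str, str]],
    mixture: MixtureModel | None = None,
    span_reads: int = 30,
    pair_window: int = 1000,
) -> tuple[pd.DataFrame, dict[str, AlleleCountTable]]:
    """Read-level haplotype observations at phased variant pairs plus allele
    count tables at the phased sites.

    In a carrier sample, read pairs spanning an event boundary all switch
    haplotype (the converted molecules change parental identity at the
    tract edge) and allele frequencies inside the tract collapse towards
    the retained haplotype.  Elsewhere, haplotype mis-assignments occur at
    the per-base error rate only.
    """
    mixture = mixture or MixtureModel()
    rng = np.random.default_rng(noise.seed)
    phased = phased.sort_values(["chrom", "pos"]).reset_index(drop=True)

    for ev in truth_loh:
        inside = phased[
            (phased["chrom"] == ev.chrom)
            & (phased["pos"] >= ev.start - pair_window)
            & (phased["pos"] <= ev.end + pair_window)
        ]
        if len(inside) < 2:
            warnings.warn(
                f"LOH event {ev.chrom}:{ev.start}-{ev.end} has no phased pair "
                f"within {pair_window} bp; it is unobservable"
            )

    pairs = []
    for chrom, grp in phased.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        for i in range(len(pos) - 1):
            if pos[i + 1] - pos[i] <= pair_window:
                pairs.append((chrom, int(pos[i]), int(pos[i + 1])))

    def carrier(ev: LOHEvent, sid: str) -> bool:
        branch, tissue = split_sample_id(sid)
        return branch == ev.branch and TISSUE_MAIN_LAYER.get(tissue) == ev.layer

    obs_rows = []
    err = noise.error_rate
    haps = np.array(["A", "B"])
    for branch, tissue in samples:
        sid = sample_id(branch, tissue)
        for chrom, p1, p2 in pairs:
            boundary = None
            inside_ev = None
            for ev in truth_loh:
                if ev.chrom != chrom or not carrier(ev, sid):
                    continue
                in1 = ev.start <= p1 <= ev.end
                in2 = ev.start <= p2 <= ev.end
                if in1 != in2:
                    boundary = ev
                elif in1 and in2:
                    inside_ev = ev
            if boundary is not None:
                lost = "B" if boundary.retained == "A" else "A"
                inside_first = boundary.start <= p1 <= boundary.end
                h1 = boundary.retained if inside_first else lost
                h2 = lost if inside_first else boundary.retained
                for _ in range(span_reads):
                    obs_rows.append((sid, chrom, p1, p2, h1, h2))
            elif inside_ev is not None:
                for _ in range(span_reads):
                    obs_rows.append((sid, chrom, p1, p2, inside_ev.retained, inside_ev.retained))
            else:
                true_h = haps[rng.integers(0, 2, size=span_reads)]
                flip1 = rng.random(span_reads) < err
                flip2 = rng.random(span_reads) < err
                for k in range(span_reads):
                    h1 = true_h[k] if not flip1[k] else ("B" if true_h[k] == "A" else "A")
                    h2 = true_h[k] if not flip2[k] else ("B" if true_h[k] == "A" else "A")
                    obs_rows.append((sid, chrom, p1, p2, h1, h2))
    obs = pd.DataFrame(obs_rows, columns=["sample", "chrom", "pos1", "pos2", "hap1", "hap2"])

    # allele count tables at phased sites (alternate allele = haplotype B)
    tables: dict[str, AlleleCountTable] = {}
    n = len(phased)
    for branch, tissue in samples:
        sid = sample_id(branch, tissue)
        af_b = np.full(n, 0.5)
        for ev in truth_loh:
            if not carrier(ev, sid):
                continue
            purity = mixture.fraction(tissue, (ev.layer,))
            mask = (
                (phased["chrom"] == ev.chrom)
                & (phased["pos"] >= ev.start)
                & (phased["pos"] <= ev.end)
            ).to_numpy()
            target = 1.0 if ev.retained == "B" else 0.0
            af_b[mask] = purity * target + (1 - purity) * 0.5
        depths = noise.draw_depths(rng, n)
        p = af_b * (1 - err) + (1 - af_b) * err
        b_counts = rng.binomial(depths, p)
        rows = []
        for i in range(n):
            d = int(depths[i])
            if d == 0:
                continue
            chrom = phased.at[i, "chrom"]
            pos = int(phased.at[i, "pos"])
            a, b = phased.at[i, "allele_a"], phased.at[i, "allele_b"]
            nb = int(b_counts[i])
            for allele, count in ((a, d - nb), (b, nb)):
                if count == 0 and allele != a:
                    continue
                plus = int(rng.binomial(count, 0.5))
                rows.append((chrom, pos, a, d, allele, count, plus, count - plus, 37.0, 60.0))
        tables[sid] = AlleleCountTable(sid, pd.DataFrame(rows, columns=_ALLELE_COLS))
    return obs, tables


# ---------------------------------------------------------------------------
# single-cell counts


def simulate_single_cell_counts(
    truth: TruthSet,
    clusters: pd.DataFrame,
    expression_rate: float | dict[str, float] = 0.05,
    seed: int = 0,
    contamination: float = 0.0,
    mutant_cells: dict[str, dict[str, int]] | None = None,
) -> pd.DataFrame:
    """Per-barcode allelic counts at mutation sites.

    ``clusters`` needs columns barcode, cluster, layer, branch.  A cell
    covers a site with probability ``expression_rate``; a covered cell of
    the mutation's origin layer (in a carrier branch) yields a mutant read
    with probability 0.5 (heterozygous expression), other layers only via
    ``contamination``.  ``mutant_cells`` switches a mutation to exact mode:
    {mutation_id: {layer: n}} cells receive a mutant read deterministically
    (with matched wild-type cells of the same layer).
    """
    required = {"barcode", "cluster", "layer", "branch"}
    if not required <= set(clusters.columns):
        raise ValueError(f"cluster map needs columns {sorted(required)}")
    bad = set(clusters["layer"]) - {"L1", "L2", "L3", "other"}
    if bad:
        raise ValueError(f"unknown cluster layer labels {sorted(bad)}")
    if clusters["barcode"].duplicated().any():
        raise ValueError("duplicate barcodes in cluster map")
    rng = np.random.default_rng(seed)
    rows = []
    for m in truth.mutations:
        rate = (
            expression_rate.get(m.id, 0.0)
            if isinstance(expression_rate, dict)
            else expression_rate
        )
        forced = (mutant_cells or {}).get(m.id)
        carriers = set(carrier_layers(m))
        cells = clusters[clusters["branch"].isin(m.branch_set)]
        if forced is not None:
            for layer, n_mut in forced.items():
                pool = cells[cells["layer"] == layer]["barcode"].tolist()
                if n_mut > len(pool):
                    raise ValueError(
                        f"{m.id}: requested {n_mut} {layer} mutant cells, "
                        f"only {len(pool)} barcodes available"
                    )
                chosen = list(rng.choice(pool, size=n_mut, replace=False)) if n_mut else []
                for bc in chosen:
                    rows.append((bc, m.chrom, m.pos, m.token or m.alt, 1))
                wt_pool = [b for b in pool if b not in set(chosen)]
                n_wt = min(n_mut, len(wt_pool))
                for bc in rng.choice(wt_pool, size=n_wt, replace=False) if n_wt else []:
                    rows.append((bc, m.chrom, m.pos, m.ref[0], 1))
            continue
        if rate <= 0:
            continue
        covered = rng.random(len(cells)) < rate
        for (_, cell), cov in zip(cells.iterrows(), covered):
            if not cov:
                continue
            if cell["layer"] in carriers:
                is_mut = rng.random() < 0.5
            else:
                is_mut = rng.random() < contamination
            allele = (m.token or m.alt) if is_mut else m.ref[0]
            rows.append((cell["barcode"], m.chrom, m.pos, allele, 1))
    return pd.DataFrame(rows, columns=["barcode", "chrom", "pos", "allele", "count"])


def write_single_cell_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def make_cluster_map(
    branches: Sequence[str],
    cells_per_branch: int = 200,
    layer_proportions: dict[str, float] | None = None,
    n_clusters: dict[str, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic barcode->cluster map mirroring a leaf expression atlas:
    L2 (mesophyll) dominates, L1 (epidermis) and L3 (vascular) are small."""
    props = layer_proportions or {"L1": 0.089, "L2": 0.782, "L3": 0.072, "other": 0.057}
    nclust = n_clusters or {"L1": 2, "L2": 6, "L3": 4, "other": 3}
    rng = np.random.default_rng(seed)
    layers = list(props)
    p = np.array([props[l] for l in layers])
    p = p / p.sum()
    rows = []
    for branch in branches:
        draws = rng.choice(len(layers), size=cells_per_branch, p=p)
        for i, li in enumerate(draws):
            layer = layers[li]
            cluster = f"{layer}_c{int(rng.integers(nclust[layer]))}"
            rows.append((f"{branch}_BC{i:05d}", cluster, layer, branch))
    return pd.DataFrame(rows, columns=["barcode", "cluster", "layer", "branch"])
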