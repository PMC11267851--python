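"""Input/output for the pipeline's tabular formats and the run configuration.

The entry point of the whole analysis is per-sample allelic read counts in
the bam-readcount text dialect (one line per position, one ``base:count:...``
field per observed allele).  Internally all coordinates are 1-based and
closed; BED input is converted at the boundary.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .topology import TreeTopology

_ALLELE_COLS = ["chrom", "pos", "ref", "depth", "allele", "count", "plus", "minus", "baseq", "mapq"]

VALID_LAYERS = ("L1", "L2", "shared", "leaf")
VALID_CLASSES = ("SNV", "indel", "LOH", "complex")


def _valid_allele(tok: str) -> bool:
    if tok in ("A", "C", "G", "T", "N", "="):
        return True
    if len(tok) > 1 and tok[0] in "+-":
        return all(c in "ACGTN" for c in tok[1:])
    return False


class AlleleCountTable:
    """Per-sample, per-position allele read counts (1-based positions).

    Stored long-form: one row per (position, allele).  The reference allele
    is listed like any other so that depth bookkeeping stays explicit.
    """

    def __init__(self, sample_id: str, df: pd.DataFrame):
        self.sample_id = sample_id
        if df.empty:
            df = pd.DataFrame(columns=_ALLELE_COLS)
        missing = set(_ALLELE_COLS) - set(df.columns)
        if missing:
            raise ValueError(f"allele count table missing columns {sorted(missing)}")
        df = df[_ALLELE_COLS].copy()
        df = df.sort_values(["chrom", "pos", "allele"], kind="mergesort").reset_index(drop=True)
        if len(df):
            if (df["count"] > df["depth"]).any():
                raise ValueError("allele count exceeds total depth")
            sites = df[["chrom", "pos", "ref"]].drop_duplicates()
            dup = sites.duplicated(["chrom", "pos"])
            if dup.any():
                bad = sites[dup].iloc[0]
                raise ValueError(
                    f"conflicting reference alleles at {bad.chrom}:{bad.pos} "
                    "(possible 0-based/1-based mix-up)"
                )
        self.df = df

    def __len__(self) -> int:
        return len(self.df[["chrom", "pos"]].drop_duplicates())

    @property
    def empty(self) -> bool:
        return self.df.empty

    def depths(self) -> pd.Series:
        """Per-site total depth (one value per position)."""
        return self.df.drop_duplicates(["chrom", "pos"]).set_index(["chrom", "pos"])["depth"]

    def site_stats(self, multiallelic_min: int = 3) -> pd.DataFrame:
        """Per-site summary with the best-supported alternate allele.

        Columns: chrom, pos, ref, depth, ref_count, alt, alt_count,
        alt_plus, alt_minus, alt_baseq, af, multiallelic.  Sites with no
        alternate reads get alt="" and alt_count=0.  When several alternate
        alleles are observed the highest-count one is kept (ties broken
        alphabetically) and the site is flagged multiallelic if the runner-up
        has >= ``multiallelic_min`` reads.
        """
        df = self.df
        sites = df.drop_duplicates(["chrom", "pos"])[["chrom", "pos", "ref", "depth"]]
        refs = df[df["allele"] == df["ref"]][["chrom", "pos", "count"]].rename(
            columns={"count": "ref_count"}
        )
        alts = df[(df["allele"] != df["ref"]) & (df["count"] > 0)].copy()
        alts = alts.sort_values(
            ["chrom", "pos", "count", "allele"],
            ascending=[True, True, False, True],
            kind="mergesort",
        )
        best = alts.drop_duplicates(["chrom", "pos"]).rename(
            columns={
                "allele": "alt",
                "count": "alt_count",
                "plus": "alt_plus",
                "minus": "alt_minus",
                "baseq": "alt_baseq",
                "mapq": "alt_mapq",
            }
        )[["chrom", "pos", "alt", "alt_count", "alt_plus", "alt_minus", "alt_baseq", "alt_mapq"]]
        # runner-up alternate allele per site (alts already sorted by count)
        second = (
            alts[alts.duplicated(["chrom", "pos"])]
            .drop_duplicates(["chrom", "pos"])[["chrom", "pos", "count"]]
        )
        out = sites.merge(refs, on=["chrom", "pos"], how="left")
        out = out.merge(best, on=["chrom", "pos"], how="left")
        out["ref_count"] = out["ref_count"].fillna(0).astype(int)
        out["alt"] = out["alt"].fillna("")
        for c in ("alt_count", "alt_plus", "alt_minus"):
            out[c] = out[c].fillna(0).astype(int)
        out["af"] = np.where(out["depth"] > 0, out["alt_count"] / out["depth"].clip(lower=1), 0.0)
        if len(second):
            sec = second.rename(columns={"count": "second_count"})
            out = out.merge(sec, on=["chrom", "pos"], how="left")
            out["multiallelic"] = out["second_count"].fillna(0) >= multiallelic_min
            out = out.drop(columns=["second_count"])
        else:
            out["multiallelic"] = False
        return out.reset_index(drop=True)


def read_bam_readcount(path: str | Path, sample_id: str | None = None) -> AlleleCountTable:
    """Parse a bam-readcount dialect file.

    Line layout: ``chrom  pos  ref  depth  allele:count:mapq:baseq:plus:minus ...``
    Malformed lines raise with the 1-based line number.
    """
    path = Path(path)
    rows: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path.name}:{lineno}: expected >=4 tab-separated fields")
            chrom, pos_s, ref, depth_s = parts[:4]
            try:
                pos = int(pos_s)
                depth = int(depth_s)
            except ValueError:
                raise ValueError(f"{path.name}:{lineno}: non-integer pos/depth") from None
            if pos < 1:
                raise ValueError(f"{path.name}:{lineno}: position {pos} is not 1-based")
            for tok in parts[4:]:
                bits = tok.split(":")
                if len(bits) != 6:
                    raise ValueError(f"{path.name}:{lineno}: malformed allele field {tok!r}")
                allele = bits[0]
                if not _valid_allele(allele):
                    raise ValueError(f"{path.name}:{lineno}: unknown allele token {allele!r}")
                try:
                    count, plus, minus = int(bits[1]), int(bits[4]), int(bits[5])
                    mapq, baseq = float(bits[2]), float(bits[3])
                except ValueError:
                    raise ValueError(f"{path.name}:{lineno}: non-numeric counts in {tok!r}") from None
                rows.append((chrom, pos, ref, depth, allele, count, plus, minus, baseq, mapq))
    df = pd.DataFrame(rows, columns=_ALLELE_COLS)
    return AlleleCountTable(sample_id or path.stem, df)


def write_bam_readcount(table: AlleleCountTable, path: str | Path) -> None:
    df = table.df.copy()
    # reference allele first, then alternates alphabetically
    df["_reffirst"] = (df["allele"] != df["ref"]).astype(int)
    df = df.sort_values(["chrom", "pos", "_reffirst", "allele"], kind="mergesort")
    with open(path, "w") as fh:
        cur_key = None
        fields: list[str] = []
        for r in df.itertuples(index=False):
            key = (r.chrom, r.pos, r.ref, r.depth)
            if key != cur_key:
                if cur_key is not None:
                    fh.write("\t".join([cur_key[0], str(cur_key[1]), cur_key[2],
                                        str(cur_key[3])] + fields) + "\n")
                cur_key, fields = key, []
            fields.append(
                f"{r.allele}:{int(r.count)}:{r.mapq:g}:{r.baseq:g}:{int(r.plus)}:{int(r.minus)}"
            )
        if cur_key is not None:
            fh.write("\t".join([cur_key[0], str(cur_key[1]), cur_key[2],
                                str(cur_key[3])] + fields) + "\n")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class FilterConfig:
    """All numeric thresholds of the calling and LOH pipelines.

    Defaults follow the published filter set for layer-enriched deep
    sequencing (~200-420x): candidate sites need >=3 alternate reads, a
    confident call 20; heterozygous background is AF 0.3-0.65; layer
    contrast needs an AF difference >=0.25 or a log2 fold-change >=1.
    """

    min_alt_reads_candidate: int = 3
    strong_alt_reads: int = 20
    het_af_lo: float = 0.3
    het_af_hi: float = 0.65
    af_diff_min: float = 0.25
    af_diff_percentile: float = 99.0
    loh_het_lo: float = 0.35
    loh_het_hi: float = 0.6
    loh_low_af: float = 0.1
    loh_min_switch_reads: int = 10
    loh_pair_window: int = 1000
    repeat_depth_cap: int = 500
    leaf_min_af: float = 0.25
    min_base_quality: float = 30.0
    min_map_quality: float = 10.0
    log2fc_min: float = 1.0
    # relaxed thresholds for targeted re-genotyping during catalog merging
    regenotype_min_alt: int = 5
    regenotype_min_af: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "het_af_lo", "het_af_hi", "af_diff_min", "loh_het_lo",
            "loh_het_hi", "loh_low_af", "leaf_min_af", "regenotype_min_af",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not self.het_af_lo < self.het_af_hi:
            raise ValueError("het_af_lo must be < het_af_hi")
        if not self.loh_het_lo < self.loh_het_hi:
            raise ValueError("loh_het_lo must be < loh_het_hi")
        for name in (
            "min_alt_reads_candidate", "strong_alt_reads", "loh_min_switch_reads",
            "loh_pair_window", "repeat_depth_cap", "regenotype_min_alt",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.af_diff_percentile <= 100:
            raise ValueError("af_diff_percentile must be in (0, 100]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# mutation calls


@dataclass
class SampleEvidence:
    alt_count: int
    depth: int
    af: float
    added_by: str | None = None  # set when presence came from re-genotyping

    def __post_init__(self) -> None:
        if self.depth > 0:
            expected = self.alt_count / self.depth
            if abs(self.af - expected) > 1e-6:
                self.af = expected


@dataclass
class MutationCall:
    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    var_class: str  # SNV | indel | LOH | complex
    layer: str  # L1 | L2 | shared | leaf
    branch_set: frozenset[str]
    samples: dict[str, SampleEvidence] = field(default_factory=dict)
    pipelines: tuple[str, ...] = ()
    curated: bool = False
    flags: tuple[str, ...] = ()
    #: raw count-table allele token (e.g. "T", "+AT", "-A"); kept for
    #: targeted re-genotyping lookups
    token: str = ""

    def __post_init__(self) -> None:
        if self.var_class not in VALID_CLASSES:
            raise ValueError(f"invalid variant class {self.var_class!r}")
        if self.layer not in VALID_LAYERS:
            raise ValueError(f"invalid layer {self.layer!r}")
        self.branch_set = frozenset(self.branch_set)
        self.pipelines = tuple(sorted(set(self.pipelines)))
        self.flags = tuple(sorted(set(self.flags)))

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)


def _sorted_calls(calls: Sequence[MutationCall]) -> list[MutationCall]:
    ordered = sorted(calls, key=lambda c: (c.chrom, c.pos, c.alt))
    if list(ordered) != list(calls):
        warnings.warn("calls were not coordinate-sorted; sorting on write")
    return ordered


def write_calls_tsv(calls: Sequence[MutationCall], path: str | Path) -> None:
    cols = [
        "id", "chrom", "pos", "ref", "alt", "token", "var_class", "layer",
        "branch_set", "pipelines", "curated", "flags", "samples",
    ]
    rows = []
    for c in _sorted_calls(calls):
        rows.append(
            {
                "id": c.id,
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "token": c.token,
                "var_class": c.var_class,
                "layer": c.layer,
                "branch_set": ",".join(sorted(c.branch_set)),
                "pipelines": ",".join(c.pipelines),
                "curated": int(c.curated),
                "flags": ",".join(c.flags),
                "samples": json.dumps(
                    {
                        s: [e.alt_count, e.depth, round(e.af, 6), e.added_by]
                        for s, e in sorted(c.samples.items())
                    }
                ),
            }
        )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> list[MutationCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    calls = []
    for _, r in df.iterrows():
        samples = {
            s: SampleEvidence(alt_count=v[0], depth=v[1], af=v[2], added_by=v[3])
            for s, v in json.loads(r["samples"]).items()
        }
        calls.append(
            MutationCall(
                id=r["id"],
                chrom=r["chrom"],
                pos=int(r["pos"]),
                ref=r["ref"],
                alt=r["alt"],
                token=str(r.get("token", "")),
                var_class=r["var_class"],
                layer=r["layer"],
                branch_set=frozenset(x for x in str(r["branch_set"]).split(",") if x),
                samples=samples,
                pipelines=tuple(x for x in str(r["pipelines"]).split(",") if x),
                curated=bool(int(r["curated"])),
                flags=tuple(x for x in str(r["flags"]).split(",") if x),
            )
        )
    return calls


def write_calls_vcf(calls: Sequence[MutationCall], path: str | Path) -> None:
    """Write the catalog as VCF 4.2 with LAYER/BRANCHES/PIPELINE/CLASS INFO keys."""
    header = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=LAYER,Number=1,Type=String,Description="Meristem layer assignment">',
        '##INFO=<ID=BRANCHES,Number=.,Type=String,Description="Branches carrying the mutation">',
        '##INFO=<ID=PIPELINE,Number=.,Type=String,Description="Source calling pipelines">',
        '##INFO=<ID=CLASS,Number=1,Type=String,Description="Variant class">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        for c in _sorted_calls(calls):
            ref, alt = c.ref, c.alt
            info = (
                f"LAYER={c.layer};BRANCHES={','.join(sorted(c.branch_set))};"
                f"PIPELINE={','.join(c.pipelines) or '.'};CLASS={c.var_class}"
            )
            fh.write(f"{c.chrom}\t{c.pos}\t{c.id}\t{ref}\t{alt}\t.\tPASS\t{info}\n")


# ---------------------------------------------------------------------------
# topology / regions


def load_topology(path: str | Path) -> TreeTopology:
    with open(path) as fh:
        return TreeTopology.from_newick(fh.read())


def load_regions(path: str | Path) -> pd.DataFrame:
    """Read a BED-like region annotation (chrom, start, end, class).

    BED is half-open 0-based; the returned frame is 1-based closed
    (columns chrom, start, end, region).
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "region"],
        dtype={"chrom": str, "region": str},
    )
    if (df["end"] <= df["start"]).any():
        raise ValueError("BED interval with end <= start")
    df["start"] = df["start"] + 1  # to 1-based closed
    return df


def load_callable_lengths(path: str | Path) -> dict[str, int]:
    """TSV of (region class, callable bases)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["region", "length"])
    return dict(zip(df["region"], df["length"].astype(int)))


def callable_lengths_from_regions(regions: pd.DataFrame) -> dict[str, int]:
    lengths = regions.assign(length=regions["end"] - regions["start"] + 1)
    return lengths.groupby("region")["length"].sum().astype(int).to_dict()
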