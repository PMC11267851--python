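"""Per-sample optimal read-depth ranges and candidate-site selection.

Repetitive or collapsed regions attract excess coverage and deleted or
poorly mappable regions too little; restricting calls to the central part
of a sample's depth distribution removes both failure modes.  The range is
formalised as symmetric depth quantiles (defaults 0.05/0.95), a
reproducible stand-in for picking the range off the depth histogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .countio import AlleleCountTable, FilterConfig


@dataclass(frozen=True)
class DepthRange:
    sample_id: str
    lo: int
    hi: int
    method: str = "quantile"

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"invalid depth range [{self.lo}, {self.hi}]")

    def contains(self, depth) -> np.ndarray | bool:
        return (depth >= self.lo) & (depth <= self.hi)


def select_depth_range(
    table: AlleleCountTable, lo_quantile: float = 0.05, hi_quantile: float = 0.95
) -> DepthRange:
    """Depth-distribution quantiles of the sample, excluding zero-depth rows.

    A degenerate (constant-depth) distribution is widened to [d-1, d] with
    a warning so the range stays a proper interval.
    """
    if table.empty:
        raise ValueError("cannot derive a depth range from an empty table")
    if not 0 <= lo_quantile < hi_quantile <= 1:
        raise ValueError("need 0 <= lo_quantile < hi_quantile <= 1")
    depths = table.depths().to_numpy()
    depths = depths[depths > 0]
    if depths.size == 0:
        raise ValueError("all rows have zero depth")
    lo = int(np.quantile(depths, lo_quantile, method="lower"))
    hi = int(np.quantile(depths, hi_quantile, method="lower"))
    if lo >= hi:
        warnings.warn(
            f"{table.sample_id}: degenerate depth distribution (all ~{hi}); "
            "using [hi-1, hi]"
        )
        lo = hi - 1
    return DepthRange(table.sample_id, lo, hi)


def depth_ranges(
    tables: dict[str, AlleleCountTable],
    lo_quantile: float = 0.05,
    hi_quantile: float = 0.95,
    overrides: dict[str, tuple[int, int]] | None = None,
) -> dict[str, DepthRange]:
    """Per-sample ranges, with optional manual per-sample overrides."""
    out = {}
    for sid, table in tables.items():
        if overrides and sid in overrides:
            lo, hi = overrides[sid]
            out[sid] = DepthRange(sid, lo, hi, method="manual")
        else:
            out[sid] = select_depth_range(table, lo_quantile, hi_quantile)
    return out


def candidate_sites(table: AlleleCountTable, cfg: FilterConfig) -> pd.DataFrame:
    """Sites whose best alternate allele has >= cfg.min_alt_reads_candidate
    reads — the entry criterion for all downstream mutation calling."""
    stats = table.site_stats()
    return stats[stats["alt_count"] >= cfg.min_alt_reads_candidate].reset_index(drop=True)
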