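"""Kimura 2-parameter divergence and repeat landscapes.

A repeat landscape is a histogram of the genome fraction occupied by TE
copies, binned by the K2P divergence of each copy from its family
consensus.  Low-divergence bins reflect recent insertion bursts; the right
tail holds old, degenerating copies.  Landscapes can be stratified by
genome compartment (gene-rich A vs repeat-rich B) and compared with a
paired t-test over per-bin genome percentages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tecurate.seqio import CopyAlignment, GenomicInterval

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 1.0
DEFAULT_MAX_PERCENT = 50.0


class K2PSaturated(ValueError):
    """Raised when substitution proportions exceed the K2P domain."""


def kimura_k2p(p: float, q: float) -> float:
    """Kimura 2-parameter distance in substitutions per site.

    ``p`` is the observed transition proportion and ``q`` the transversion
    proportion.  K = -1/2 * ln((1 - 2p - q) * sqrt(1 - 2q)).  Raises
    :class:`K2PSaturated` outside the valid domain (either log argument
    non-positive).
    """
    if p < 0 or q < 0:
        raise ValueError("p and q must be >= 0")
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise K2PSaturated(f"saturated: p={p}, q={q}")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def copy_divergence(copy: CopyAlignment) -> Optional[float]:
    """Percent K2P divergence of one copy, or None when saturated."""
    if copy.aligned_sites == 0:
        return None
    p = copy.transitions / copy.aligned_sites
    q = copy.transversions / copy.aligned_sites
    try:
        return 100.0 * kimura_k2p(p, q)
    except K2PSaturated:
        return None


@dataclass(frozen=True)
class CompartmentMap:
    """A/B compartment intervals; non-overlapping within a sequence."""

    intervals: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        by_seq: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            if iv.label not in {"A", "B"}:
                raise ValueError(f"compartment label must be A or B, got {iv.label!r}")
            by_seq.setdefault(iv.seqid, []).append(iv)
        for ivs in by_seq.values():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                if a.end > b.start:
                    raise ValueError("compartment intervals overlap")

    def assign(self, interval: GenomicInterval) -> Optional[str]:
        """Compartment of an interval, by its midpoint; None if outside."""
        mid = interval.midpoint
        for iv in self.intervals:
            if iv.seqid == interval.seqid and iv.start <= mid < iv.end:
                return iv.label
        return None

    @classmethod
    def from_bed_intervals(
        cls, intervals: Iterable[GenomicInterval]
    ) -> "CompartmentMap":
        return cls(tuple(intervals))


@dataclass
class LandscapeTable:
    """Per-bin genome percentages, long format.

    ``table`` columns: group (family or superfamily), compartment ("all"
    when unstratified), bin_low, bin_high, percent.
    """

    table: pd.DataFrame
    genome_size: int
    bin_width: float = DEFAULT_BIN_WIDTH
    saturated_copies: int = 0
    unassigned_copies: int = 0

    def percentages(
        self, group: Optional[str] = None, compartment: str = "all"
    ) -> pd.Series:
        """Per-bin percent for one stratum, indexed by bin_low, dense."""
        t = self.table
        if group is not None:
            t = t[t["group"] == group]
        t = t[t["compartment"] == compartment]
        agg = t.groupby("bin_low")["percent"].sum()
        n_bins = int(round(DEFAULT_MAX_PERCENT / self.bin_width))
        idx = np.arange(n_bins) * self.bin_width
        return agg.reindex(idx, fill_value=0.0)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def build_landscape(
    copies: Sequence[CopyAlignment],
    genome_size: int,
    bin_width: float = DEFAULT_BIN_WIDTH,
    group_by: str = "family",
    compartments: Optional[CompartmentMap] = None,
    max_percent: float = DEFAULT_MAX_PERCENT,
) -> LandscapeTable:
    """Aggregate copies into a repeat landscape.

    Each copy contributes its genomic span (bp) to the divergence bin
    ``floor(K% / bin_width)`` of its group; bin totals are expressed as
    percent of ``genome_size``.  With a compartment map, copies are
    stratified by the compartment containing their midpoint; copies outside
    every compartment go to an "unassigned" stratum.  Saturated copies are
    excluded and counted.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    rows: list[tuple[str, str, float, float, int]] = []
    n_sat = 0
    n_unassigned = 0
    for copy in copies:
        k = copy_divergence(copy)
        if k is None:
            n_sat += 1
            continue
        k = min(k, max_percent - 1e-9)
        bin_low = math.floor(k / bin_width) * bin_width
        # family labels may carry a '#Order/Superfamily' suffix
        if group_by == "superfamily" and "#" in copy.family:
            group = copy.family.split("#", 1)[1]
        else:
            group = copy.family.split("#", 1)[0]
        if compartments is None:
            comp = "all"
        else:
            comp = compartments.assign(copy.copy_interval)
            if comp is None:
                comp = "unassigned"
                n_unassigned += 1
        rows.append((group, comp, bin_low, bin_low + bin_width, len(copy.copy_interval)))
    if n_sat:
        logger.warning("excluded %d saturated copies from landscape", n_sat)
    if n_unassigned:
        logger.warning("%d copies outside every compartment", n_unassigned)
    df = pd.DataFrame(
        rows, columns=["group", "compartment", "bin_low", "bin_high", "bp"]
    )
    if df.empty:
        table = pd.DataFrame(
            columns=["group", "compartment", "bin_low", "bin_high", "percent"]
        )
    else:
        agg = (
            df.groupby(["group", "compartment", "bin_low", "bin_high"], as_index=False)
            ["bp"].sum()
        )
        agg["percent"] = agg["bp"] / genome_size * 100.0
        table = agg.drop(columns="bp").sort_values(
            ["group", "compartment", "bin_low"], ignore_index=True
        )
    return LandscapeTable(
        table=table,
        genome_size=genome_size,
        bin_width=bin_width,
        saturated_copies=n_sat,
        unassigned_copies=n_unassigned,
    )


@dataclass(frozen=True)
class PairedTestResult:
    """Paired t-test between compartment landscapes."""

    t: float
    df: int
    p_value: float
    mean_difference: float  # mean(B - A) over the tested bins
    higher: str  # "A", "B", or "equal"
    n_bins: int
    degenerate: bool = False


def compare_compartments(
    landscape: LandscapeTable,
    group: Optional[str] = None,
    bin_range: Optional[tuple[float, float]] = None,
) -> PairedTestResult:
    """Paired t-test of per-bin percentages between A and B compartments.

    Pairs (A_i, B_i) over divergence bins (optionally restricted to
    ``bin_range``, inclusive of bin_low in [lo, hi)); two-sided p from the
    t distribution on n-1 df.  All-zero differences yield t=0, p=1 flagged
    degenerate.  ``higher`` reports the direction of the mean difference.
    """
    a = landscape.percentages(group, "A")
    b = landscape.percentages(group, "B")
    if bin_range is not None:
        lo, hi = bin_range
        mask = (a.index >= lo) & (a.index < hi)
        a, b = a[mask], b[mask]
    if len(a) < 2:
        raise ValueError("need at least 2 bins for a paired test")
    d = b.to_numpy() - a.to_numpy()
    n = len(d)
    mean_d = float(np.mean(d))
    if np.allclose(d, 0.0):
        return PairedTestResult(0.0, n - 1, 1.0, 0.0, "equal", n, degenerate=True)
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        # constant nonzero difference: direction certain, t unbounded
        t_stat = math.inf if mean_d > 0 else -math.inf
        p = 0.0
    else:
        t_stat = mean_d / (sd / math.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t_stat), df=n - 1)
    higher = "B" if mean_d > 0 else ("A" if mean_d < 0 else "equal")
    return PairedTestResult(
        t=float(t_stat), df=n - 1, p_value=float(p),
        mean_difference=mean_d, higher=higher, n_bins=n,
    )
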