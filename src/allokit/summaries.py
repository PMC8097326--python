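"""Assembly statistics, printed-ratio reporting and small summary formulas.

Ratios are rounded half-even at the requested decimal count, matching the
convention of the reported percentages this module reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import GeneModel, ValidationError


@dataclass
class AssemblyStats:
    n_sequences: int
    total_bp: int
    n50: int
    n90: int
    l50: int
    l90: int
    longest: int
    gap_bp: int
    missing_pct: float


@dataclass
class RGRInput:
    """Paired measurements (same units) at two times, in days."""

    m1: float
    m2: float
    t1: float
    t2: float

    def __post_init__(self) -> None:
        if self.m1 <= 0 or self.m2 <= 0:
            raise ValidationError("measurements must be positive")
        if self.t2 <= self.t1:
            raise ValidationError("t2 must exceed t1")


def _nx(sorted_desc: np.ndarray, cumulative: np.ndarray, total: int,
        x: int) -> tuple[int, int]:
    threshold = x / 100.0 * total
    idx = int(np.searchsorted(cumulative, threshold, side="left"))
    return int(sorted_desc[idx]), idx + 1


def assembly_stats(lengths: Sequence[int], gap_lengths: Sequence[int] | int = 0,
                   ) -> AssemblyStats:
    """N50/N90, L50/L90 and the missing-bases percentage.

    Nx is the length of the sequence at which the cumulative
    sorted-descending length first reaches x% of the total; Lx is the count
    of sequences up to that point.  Missing bases (%) = gap length / total
    assembly size x 100, rounded to two decimals.
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    if lengths.size == 0:
        raise ValidationError("empty sequence length list")
    if (lengths <= 0).any():
        raise ValidationError("sequence lengths must be positive")
    gap_bp = int(gap_lengths) if np.isscalar(gap_lengths) else int(sum(gap_lengths))
    sorted_desc = np.sort(lengths)[::-1]
    cumulative = np.cumsum(sorted_desc)
    total = int(cumulative[-1])
    n50, l50 = _nx(sorted_desc, cumulative, total, 50)
    n90, l90 = _nx(sorted_desc, cumulative, total, 90)
    return AssemblyStats(
        n_sequences=len(lengths), total_bp=total, n50=n50, n90=n90,
        l50=l50, l90=l90, longest=int(sorted_desc[0]), gap_bp=gap_bp,
        missing_pct=proportion_report(gap_bp, total, 2))


def proportion_report(numerator: float, denominator: float,
                      decimals: int = 2) -> float:
    """100 x numerator / denominator, rounded half-even."""
    if denominator <= 0:
        raise ValidationError("denominator must be positive")
    value = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_EVEN))


# ---------------------------------------------------------------------------
# TE density near genes (metagene profile)
# ---------------------------------------------------------------------------

def _merge_intervals(intervals: np.ndarray) -> np.ndarray:
    if len(intervals) == 0:
        return intervals.reshape(0, 2)
    order = np.lexsort((intervals[:, 1], intervals[:, 0]))
    merged = [list(intervals[order[0]])]
    for start, end in intervals[order[1:]]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return np.asarray(merged)


def _covered_bp(merged: np.ndarray, lo: int, hi: int) -> int:
    """Overlap of [lo, hi) with merged, sorted, non-overlapping intervals."""
    if hi <= lo or len(merged) == 0:
        return 0
    overlap = np.minimum(merged[:, 1], hi) - np.maximum(merged[:, 0], lo)
    return int(overlap[overlap > 0].sum())


def te_density_near_genes(genes: Sequence[GeneModel], te_intervals: pd.DataFrame,
                          flank_bp: int = 3000, n_bins: int = 10,
                          ) -> dict[str, np.ndarray]:
    """Mean TE-covered fraction in bins across upstream flank, gene body
    and downstream flank, averaged per genome label.

    The gene body is length-normalized to ``n_bins`` metagene bins; each
    flank contributes ``n_bins`` fixed-width bins.  Profiles follow gene
    orientation (upstream first).  Flanks running past the chromosome
    start are clipped at position 1.
    """
    merged_by_chrom = {
        str(chrom): _merge_intervals(grp[["start", "end"]].to_numpy(dtype=np.int64))
        for chrom, grp in te_intervals.groupby("chrom")}
    profiles: dict[str, list[np.ndarray]] = {}
    for gene in genes:
        merged = merged_by_chrom.get(gene.chrom, np.zeros((0, 2), dtype=np.int64))
        g_lo, g_hi = gene.start - 1, gene.end  # 0-based half-open
        up_edges = np.linspace(max(0, g_lo - flank_bp), g_lo, n_bins + 1)
        body_edges = np.linspace(g_lo, g_hi, n_bins + 1)
        down_edges = np.linspace(g_hi, g_hi + flank_bp, n_bins + 1)
        profile = []
        for edges in (up_edges, body_edges, down_edges):
            for lo, hi in zip(edges[:-1], edges[1:]):
                lo_i, hi_i = int(round(lo)), int(round(hi))
                width = hi_i - lo_i
                profile.append(_covered_bp(merged, lo_i, hi_i) / width
                               if width > 0 else 0.0)
        profile = np.asarray(profile)
        if gene.strand == "-":
            profile = profile[::-1]
        profiles.setdefault(gene.genome_label, []).append(profile)
    return {label: np.mean(rows, axis=0) for label, rows in profiles.items()}


# ---------------------------------------------------------------------------
# read-level repeat classification
# ---------------------------------------------------------------------------

def is_repeat_read(aln_length: float, read_length: float,
                   min_aln: float = 100.0, min_cov_pct: float = 70.0) -> bool:
    """A read is a repeat read if its best alignment to the repeat library
    is over 100 bp or covers over 70% of the read."""
    if read_length <= 0:
        raise ValidationError("read_length must be positive")
    return aln_length > min_aln or 100.0 * aln_length / read_length > min_cov_pct


def classify_repeat_reads(reads: pd.DataFrame, min_aln: float = 100.0,
                          min_cov_pct: float = 70.0) -> float:
    """Fraction (0-1) of reads classified as repeat.

    ``reads`` needs ``aln_length`` and ``read_length`` columns (the best
    alignment per read against the repeat library).
    """
    if len(reads) == 0:
        raise ValidationError("no reads supplied")
    flags = [is_repeat_read(float(r.aln_length), float(r.read_length),
                            min_aln, min_cov_pct)
             for r in reads.itertuples()]
    return float(np.mean(flags))


def relative_growth_rate(rgr: RGRInput) -> float:
    """RGR = (ln M2 - ln M1) / (T2 - T1), per day."""
    return float((np.log(rgr.m2) - np.log(rgr.m1)) / (rgr.t2 - rgr.t1))


def stained_fraction(n_stained: int, n_total: int) -> float:
    """Percent of plump, deeply stained pollen grains."""
    if n_total < 1:
        raise ValidationError("n_total must be at least 1")
    if not 0 <= n_stained <= n_total:
        raise ValidationError("n_stained outside [0, n_total]")
    return 100.0 * n_stained / n_total
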