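"""Windowed read-depth homoeologous-exchange (HE) caller.

An HE replaces a chromosomal segment of one subgenome with the homologous
segment of the other.  When reads of the allopolyploid are mapped to the
two parental references, the event shows up as reciprocal depth evidence:
a run of double-coverage windows (75-150x at a 50x genome mean) on the
donor side and a run of near-zero windows (0-25x) on the receiving side.
Candidate segments are linked across small gaps, gated on long-read mapped
fraction, and confirmed by pairing duplicated with deleted segments through
linked syntenic blocks plus a sequence-identity check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import AnalysisThresholds, DepthTrack, GeneModel, genes_by_id
from .synteny import SyntenyBlock

logger = logging.getLogger(__name__)

WINDOW_LABELS = ("deleted", "normal", "duplicated", "outlier", "partial")


@dataclass(frozen=True)
class WindowLabel:
    chrom: str
    window_index: int
    depth: float
    label: str


@dataclass
class DepthSegment:
    """A linked run of same-kind depth windows; the unit of HE calling."""

    chrom: str
    start_window: int
    end_window: int
    kind: str
    mean_depth: float
    mapped_fraction: float = float("nan")

    def bp_span(self, window_bp: int) -> tuple[int, int]:
        """0-based half-open bp interval covered by the segment."""
        return self.start_window * window_bp, (self.end_window + 1) * window_bp

    def overlaps(self, other: "DepthSegment") -> bool:
        return (self.chrom == other.chrom
                and self.start_window <= other.end_window
                and other.start_window <= self.end_window)


@dataclass
class HECall:
    """A duplicated segment paired (or not) with its homologous deletion."""

    segment_dup: DepthSegment
    dup_subgenome: str
    segment_del: DepthSegment | None = None
    del_subgenome: str | None = None
    direction: str = "unresolved"
    identity_pct: float | None = None
    confirmed: bool = False


def classify_depth_windows(track: DepthTrack,
                           thresholds: AnalysisThresholds | None = None,
                           observed_mean: float | None = None,
                           ) -> list[WindowLabel]:
    """Label each window as deleted / normal / duplicated / outlier.

    The depth bands are tied to the study's ~50x genome mean; when
    ``observed_mean`` is supplied the bands are scaled by
    ``observed_mean / mean_depth``.  Band endpoints are inclusive.  Trailing
    partial windows are labeled ``partial`` and excluded from segments.
    """
    thresholds = thresholds or AnalysisThresholds()
    scale = 1.0 if observed_mean is None else observed_mean / thresholds.mean_depth
    dup_lo, dup_hi = (x * scale for x in thresholds.he_dup_range)
    del_lo, del_hi = (x * scale for x in thresholds.he_del_range)
    labels = []
    for i, depth in enumerate(track.values):
        depth = float(depth)
        if track.last_partial and i == track.n_windows - 1:
            label = "partial"
        elif del_lo <= depth <= del_hi:
            label = "deleted"
        elif dup_lo <= depth <= dup_hi:
            label = "duplicated"
        elif depth > dup_hi:
            label = "outlier"
        else:
            label = "normal"
        labels.append(WindowLabel(track.chrom, i, depth, label))
    return labels


def link_windows(labels: Sequence[WindowLabel], kind: str,
                 max_gap: int | None = None,
                 thresholds: AnalysisThresholds | None = None,
                 ) -> list[DepthSegment]:
    """Merge same-kind windows separated by at most ``max_gap`` others.

    Segment bounds are the outermost same-kind windows; the mean depth is
    taken over the same-kind windows only.  Linking is idempotent.
    """
    thresholds = thresholds or AnalysisThresholds()
    if max_gap is None:
        max_gap = thresholds.he_link_gap_windows
    picked = [l for l in labels if l.label == kind]
    if not picked:
        return []
    segments: list[DepthSegment] = []
    run: list[WindowLabel] = [picked[0]]
    for label in picked[1:]:
        if label.window_index - run[-1].window_index - 1 <= max_gap:
            run.append(label)
        else:
            segments.append(_make_segment(run, kind))
            run = [label]
    segments.append(_make_segment(run, kind))
    return segments


def _make_segment(run: Sequence[WindowLabel], kind: str) -> DepthSegment:
    return DepthSegment(run[0].chrom, run[0].window_index, run[-1].window_index,
                        kind, float(np.mean([l.depth for l in run])))


def call_candidate_he(segment: DepthSegment,
                      mapped_fraction: Mapping[tuple[str, int], float],
                      thresholds: AnalysisThresholds | None = None,
                      ) -> bool | None:
    """Gate a segment on long-read mapped fraction (> 30%, strict).

    ``mapped_fraction`` maps (chrom, window_index) to the percent of the
    window covered by mapped long-read alignment.  Returns None (segment
    skipped) when no window of the segment has data.
    """
    thresholds = thresholds or AnalysisThresholds()
    values = [mapped_fraction[(segment.chrom, i)]
              for i in range(segment.start_window, segment.end_window + 1)
              if (segment.chrom, i) in mapped_fraction]
    if not values:
        logger.warning("segment %s:%d-%d has no mapped-fraction data; skipped",
                       segment.chrom, segment.start_window, segment.end_window)
        return None
    segment.mapped_fraction = float(np.mean(values))
    return segment.mapped_fraction > thresholds.he_min_mapped_fraction


def filter_candidates(segments: Sequence[DepthSegment],
                      mapped_fraction: Mapping[tuple[str, int], float],
                      thresholds: AnalysisThresholds | None = None,
                      ) -> list[DepthSegment]:
    return [s for s in segments
            if call_candidate_he(s, mapped_fraction, thresholds)]


def mapped_fraction_table(df: pd.DataFrame) -> dict[tuple[str, int], float]:
    """Index a (chrom, window_index, mapped_pct) frame for segment gating."""
    return {(str(r.chrom), int(r.window_index)): float(r.mapped_pct)
            for r in df.itertuples()}


# ---------------------------------------------------------------------------
# confirmation through linked syntenic blocks
# ---------------------------------------------------------------------------

def _block_spans(block: SyntenyBlock, by_id_a: Mapping[str, GeneModel],
                 by_id_b: Mapping[str, GeneModel]) -> tuple[int, int, int, int]:
    a_genes = [by_id_a[a.gene_a] for a in block.anchors]
    b_genes = [by_id_b[a.gene_b] for a in block.anchors]
    return (min(g.start for g in a_genes), max(g.end for g in a_genes),
            min(g.start for g in b_genes), max(g.end for g in b_genes))


def link_blocks(blocks: Sequence[SyntenyBlock], genes_a: Sequence[GeneModel],
                genes_b: Sequence[GeneModel], max_gap_bp: int,
                ) -> list[SyntenyBlock]:
    """Merge same-chromosome-pair blocks separated by < ``max_gap_bp``."""
    by_id_a, by_id_b = genes_by_id(genes_a), genes_by_id(genes_b)
    grouped: dict[tuple[str, str], list[SyntenyBlock]] = {}
    for block in blocks:
        grouped.setdefault((block.chrom_a, block.chrom_b), []).append(block)
    merged: list[SyntenyBlock] = []
    for key in sorted(grouped):
        members = sorted(grouped[key],
                         key=lambda b: _block_spans(b, by_id_a, by_id_b)[0])
        current = members[0]
        cur_span = _block_spans(current, by_id_a, by_id_b)
        for nxt in members[1:]:
            nxt_span = _block_spans(nxt, by_id_a, by_id_b)
            gap_a = nxt_span[0] - cur_span[1]
            if gap_a < max_gap_bp:
                current = SyntenyBlock(current.block_id, current.chrom_a,
                                       current.chrom_b,
                                       current.anchors + nxt.anchors,
                                       current.orientation)
                cur_span = (cur_span[0], max(cur_span[1], nxt_span[1]),
                            min(cur_span[2], nxt_span[2]),
                            max(cur_span[3], nxt_span[3]))
            else:
                merged.append(current)
                current, cur_span = nxt, nxt_span
        merged.append(current)
    return merged


def _homologous_interval(blocks: Sequence[SyntenyBlock], chrom: str,
                         lo: int, hi: int, dup_side: str,
                         by_id_a: Mapping[str, GeneModel],
                         by_id_b: Mapping[str, GeneModel],
                         pad: int) -> tuple[str, int, int] | None:
    """Map a bp interval on one side of the blocks to the other side.

    The interval on the opposite subgenome is spanned by the partner genes
    of the anchors overlapping [lo, hi] (nearest flanking anchors if none
    overlap), padded by one window.
    """
    for block in blocks:
        own_chrom = block.chrom_a if dup_side == "a" else block.chrom_b
        if own_chrom != chrom:
            continue
        own_genes = [(by_id_a if dup_side == "a" else by_id_b)[
            a.gene_a if dup_side == "a" else a.gene_b] for a in block.anchors]
        other_genes = [(by_id_b if dup_side == "a" else by_id_a)[
            a.gene_b if dup_side == "a" else a.gene_a] for a in block.anchors]
        span_lo = min(g.start for g in own_genes)
        span_hi = max(g.end for g in own_genes)
        if hi < span_lo or lo > span_hi:
            continue
        inside = [og for g, og in zip(own_genes, other_genes)
                  if g.end >= lo and g.start <= hi]
        if not inside:
            before = [og for g, og in zip(own_genes, other_genes) if g.end < lo]
            after = [og for g, og in zip(own_genes, other_genes) if g.start > hi]
            inside = before[-1:] + after[:1]
        if not inside:
            continue
        other_chrom = block.chrom_b if dup_side == "a" else block.chrom_a
        return (other_chrom,
                max(0, min(g.start for g in inside) - 1 - pad),
                max(g.end for g in inside) + pad)
    return None


def _identity_for(identity: pd.DataFrame | None, dup_sub: str,
                  dup_chrom: str, dup_lo: int, dup_hi: int,
                  del_chrom: str, del_lo: int, del_hi: int) -> float | None:
    """Look up percent identity for a paired (duplicated, deleted) region."""
    if identity is None:
        return None
    if dup_sub == "SubC":
        c = (dup_chrom, dup_lo, dup_hi)
        h = (del_chrom, del_lo, del_hi)
    else:
        c = (del_chrom, del_lo, del_hi)
        h = (dup_chrom, dup_lo, dup_hi)
    for row in identity.itertuples():
        if (str(row.chrom_c) == c[0] and row.end_c >= c[1] and row.start_c <= c[2]
                and str(row.chrom_h) == h[0] and row.end_h >= h[1]
                and row.start_h <= h[2]):
            return float(row.pct_identity)
    return None


def confirm_he(dup_segments: Mapping[str, Sequence[DepthSegment]],
               del_segments: Mapping[str, Sequence[DepthSegment]],
               blocks: Sequence[SyntenyBlock],
               genes_c: Sequence[GeneModel], genes_h: Sequence[GeneModel],
               identity: pd.DataFrame | None = None,
               thresholds: AnalysisThresholds | None = None,
               ) -> list[HECall]:
    """Pair candidate duplicated segments with homologous deletions.

    ``dup_segments`` / ``del_segments`` map subgenome label (SubC/SubH) to
    candidate segments on that subgenome.  Blocks are SubC(a) <-> SubH(b)
    synteny; blocks closer than 20 kb are linked first.  A duplicated
    segment whose homologous interval overlaps a deleted segment on the
    other subgenome becomes an HE call; its direction points from the
    deleted subgenome's parent toward the duplicated subgenome (deletion on
    SubH means CC content replaced HH: direction CC_to_HH).  The call is
    confirmed only when a sequence-identity record covers the region pair.
    """
    thresholds = thresholds or AnalysisThresholds()
    by_id_c, by_id_h = genes_by_id(genes_c), genes_by_id(genes_h)
    linked = link_blocks(blocks, genes_c, genes_h, thresholds.block_link_gap_bp)
    window_bp = thresholds.he_window_bp
    calls: list[HECall] = []
    other = {"SubC": "SubH", "SubH": "SubC"}
    for dup_sub in ("SubC", "SubH"):
        for dup in dup_segments.get(dup_sub, []):
            lo, hi = dup.bp_span(window_bp)
            target = _homologous_interval(
                linked, dup.chrom, lo, hi, "a" if dup_sub == "SubC" else "b",
                by_id_c, by_id_h, window_bp)
            call = HECall(dup, dup_sub)
            if target is not None:
                t_chrom, t_lo, t_hi = target
                for del_seg in del_segments.get(other[dup_sub], []):
                    d_lo, d_hi = del_seg.bp_span(window_bp)
                    if del_seg.chrom == t_chrom and d_hi > t_lo and d_lo < t_hi:
                        call.segment_del = del_seg
                        call.del_subgenome = other[dup_sub]
                        call.direction = ("CC_to_HH" if call.del_subgenome == "SubH"
                                          else "HH_to_CC")
                        ident = _identity_for(identity, dup_sub, dup.chrom, lo,
                                              hi, del_seg.chrom, d_lo, d_hi)
                        if ident is not None:
                            call.identity_pct = ident
                            call.confirmed = True
                        break
            calls.append(call)
    return calls
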