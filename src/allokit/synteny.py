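"""Synteny block chaining and 1:1 ortholog/homeolog pair calling.

Filtered homology hits are first reduced to near-best 1:1 pairs with a
cscore screen, then chained per chromosome pair into collinear blocks by
dynamic programming on gene-order ranks.  A block needs at least four
anchor pairs and tolerates rank gaps of at most 20 genes on either side,
with inversions handled by chaining the second genome's ranks negated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .core_io import (AnalysisThresholds, GeneModel, ValidationError,
                      genes_by_id)


@dataclass(frozen=True)
class AnchorPair:
    """A retained 1:1 homology hit placed on both gene orders."""

    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int
    score: float


@dataclass
class SyntenyBlock:
    """An ordered chain of anchor pairs between two chromosomes."""

    block_id: str
    chrom_a: str
    chrom_b: str
    anchors: list[AnchorPair] = field(default_factory=list)
    orientation: str = "same"

    @property
    def score(self) -> float:
        return sum(a.score for a in self.anchors)

    @property
    def rank_span_a(self) -> tuple[int, int]:
        return self.anchors[0].rank_a, self.anchors[-1].rank_a


def screen_one_to_one(hits: pd.DataFrame, cscore_min: float = 0.9) -> pd.DataFrame:
    """Apply the cscore filter followed by a strict 1:1 best-partner screen.

    A hit (q, s) survives the cscore filter iff its score is at least
    ``cscore_min`` times the best score involving either q or s.  Among the
    survivors each gene keeps only its best-scoring partner, so no gene
    appears in more than one retained pair; ties break lexicographically.
    """
    if len(hits) == 0:
        return hits.copy()
    best_q = hits.groupby("query_id")["bitscore"].transform("max")
    best_s = hits.groupby("subject_id")["bitscore"].transform("max")
    survivors = hits[hits["bitscore"] >= cscore_min * pd.concat(
        [best_q, best_s], axis=1).max(axis=1)]
    ordered = survivors.sort_values(
        ["bitscore", "query_id", "subject_id"],
        ascending=[False, True, True], kind="mergesort")
    used_q: set[str] = set()
    used_s: set[str] = set()
    keep_index = []
    for row in ordered.itertuples():
        if row.query_id in used_q or row.subject_id in used_s:
            continue
        used_q.add(row.query_id)
        used_s.add(row.subject_id)
        keep_index.append(row.Index)
    return hits.loc[sorted(keep_index)].reset_index(drop=True)


def _best_chain(anchors: Sequence[AnchorPair], inverted: bool,
                max_gap: int, min_len: int) -> list[int] | None:
    """Highest-scoring collinear chain of length >= ``min_len``.

    Anchors must be sorted by rank_a.  rank_b must strictly increase along
    the chain (decrease when ``inverted``) and consecutive anchors may
    differ by at most ``max_gap`` in both rank coordinates.  The dynamic
    program tracks chain length capped at ``min_len`` so the returned
    chain maximizes score subject to the length floor (None if no valid
    chain exists).  Returns indices into ``anchors``.
    """
    n = len(anchors)
    if n == 0:
        return None
    sign = -1 if inverted else 1
    neg = float("-inf")
    # dp[i][l]: best score of a chain ending at i whose length, capped at
    # min_len, is l
    dp = [[neg] * (min_len + 1) for _ in range(n)]
    parent: list[list[tuple[int, int] | None]] = [
        [None] * (min_len + 1) for _ in range(n)]
    for i in range(n):
        ai = anchors[i]
        dp[i][1] = ai.score
        for j in range(i - 1, -1, -1):
            aj = anchors[j]
            if ai.rank_a - aj.rank_a > max_gap:
                break
            if ai.rank_a <= aj.rank_a:
                continue
            db = sign * (ai.rank_b - aj.rank_b)
            if db <= 0 or db > max_gap:
                continue
            for l in range(1, min_len + 1):
                if dp[j][l] == neg:
                    continue
                nl = min(l + 1, min_len)
                cand = dp[j][l] + ai.score
                if cand > dp[i][nl]:
                    dp[i][nl] = cand
                    parent[i][nl] = (j, l)
    end = max(range(n), key=lambda i: (dp[i][min_len], -i))
    if dp[end][min_len] == neg:
        return None
    chain = []
    state: tuple[int, int] | None = (end, min_len)
    while state is not None:
        chain.append(state[0])
        state = parent[state[0]][state[1]]
    chain.reverse()
    return chain


def chain_hits(hits: pd.DataFrame, genes_a: Sequence[GeneModel],
               genes_b: Sequence[GeneModel],
               thresholds: AnalysisThresholds | None = None,
               ) -> list[SyntenyBlock]:
    """Chain 1:1-screened hits into maximal syntenic blocks.

    Blocks are extracted greedily per (chrom_a, chrom_b): the best-scoring
    chain found in either orientation is emitted, its anchors removed, and
    the search repeated until no chain of ``min_anchor_pairs`` remains.
    """
    thresholds = thresholds or AnalysisThresholds()
    by_id_a = genes_by_id(genes_a)
    by_id_b = genes_by_id(genes_b)
    anchors_by_pair: dict[tuple[str, str], list[AnchorPair]] = {}
    for row in hits.itertuples():
        if row.query_id not in by_id_a:
            raise ValidationError(f"hit query {row.query_id!r} missing from annotation A")
        if row.subject_id not in by_id_b:
            raise ValidationError(f"hit subject {row.subject_id!r} missing from annotation B")
        ga, gb = by_id_a[row.query_id], by_id_b[row.subject_id]
        anchors_by_pair.setdefault((ga.chrom, gb.chrom), []).append(
            AnchorPair(ga.gene_id, gb.gene_id, ga.rank, gb.rank, float(row.bitscore)))

    blocks: list[SyntenyBlock] = []
    counter = 0
    for (chrom_a, chrom_b) in sorted(anchors_by_pair):
        remaining = sorted(anchors_by_pair[(chrom_a, chrom_b)],
                           key=lambda a: (a.rank_a, a.rank_b))
        while len(remaining) >= thresholds.min_anchor_pairs:
            best: list[int] | None = None
            best_key = None
            best_orient = "same"
            for inverted in (False, True):
                chain = _best_chain(remaining, inverted,
                                    thresholds.block_gap_genes,
                                    thresholds.min_anchor_pairs)
                if chain is None:
                    continue
                key = (sum(remaining[i].score for i in chain), len(chain),
                       -min(chain))
                if best is None or key > best_key:
                    best, best_key, best_orient = chain, key, (
                        "inverted" if inverted else "same")
            if best is None:
                break
            counter += 1
            blocks.append(SyntenyBlock(
                f"block_{counter:04d}", chrom_a, chrom_b,
                [remaining[i] for i in best], best_orient))
            chosen = set(best)
            remaining = [a for i, a in enumerate(remaining) if i not in chosen]
    return blocks


def call_ortholog_pairs(blocks: Iterable[SyntenyBlock]) -> dict[str, str]:
    """Union of all block anchors as a bijective gene_a -> gene_b map."""
    pairs: dict[str, str] = {}
    seen_b: set[str] = set()
    for block in blocks:
        for anchor in block.anchors:
            if anchor.gene_a in pairs or anchor.gene_b in seen_b:
                raise ValidationError(
                    f"gene {anchor.gene_a}/{anchor.gene_b} occurs in two blocks")
            pairs[anchor.gene_a] = anchor.gene_b
            seen_b.add(anchor.gene_b)
    return pairs
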