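"""Multi-filter lost-gene decision procedure with depth confirmation.

The filter order is fixed: potential-loss calling from synteny, rescue of
mis-annotated genes, partial/pseudogene classification, read-depth
confirmation, and exclusion of parental genotype differences.  Confirmed
losses are then tracked across the generation series (F1, S0, S4..S13)
and each loss event attributed to hybridization, genome duplication or
ongoing diploidization.

Boundary semantics are strict throughout: a gene at exactly 1.0x depth or
exactly 5% gene-body breadth is NOT lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (AnalysisThresholds, GeneModel, ValidationError,
                      genes_by_id, per_base_depth)
from .synteny import SyntenyBlock

logger = logging.getLogger(__name__)

LOSS_STATES = ("retained", "potential_loss", "rescued_misannotation",
               "partial_loss", "pseudogene", "dna_loss_candidate",
               "confirmed_loss", "genotype_difference")


@dataclass
class GeneCoverage:
    """Mean read depth and breadth of coverage over one gene body."""

    gene_id: str
    depth_fold: float
    breadth_pct: float

    def __post_init__(self) -> None:
        if self.depth_fold < 0 or not 0 <= self.breadth_pct <= 100:
            raise ValidationError(f"implausible coverage for {self.gene_id}")


@dataclass
class LossRecord:
    """A candidate lost gene and its progress through the filter chain."""

    gene_id: str
    ancestral_genome: str
    in_block: bool = True
    state: str = "retained"
    depth_fold: float | None = None
    breadth_pct: float | None = None
    presence: dict[str, bool] = field(default_factory=dict)
    attribution: str = "none"
    restored: bool = False
    unstable: bool = False
    # derived-genome interval spanned by the five nearest anchored
    # neighbors on each side; None for out-of-block candidates
    window_chrom: str | None = None
    window_start: int | None = None
    window_end: int | None = None


def _covered_lost(depth: float, breadth: float, thresholds: AnalysisThresholds) -> bool:
    return depth < thresholds.loss_depth_max and breadth < thresholds.loss_breadth_max


def find_potential_losses(blocks: Sequence[SyntenyBlock],
                          pair_map: Mapping[str, str],
                          ancestral_genes: Sequence[GeneModel],
                          derived_genes: Sequence[GeneModel],
                          hits: pd.DataFrame,
                          thresholds: AnalysisThresholds | None = None,
                          ) -> list[LossRecord]:
    """Call potential losses of ancestral genes against a derived subgenome.

    A blocked ancestral gene is a potential loss iff it is unpaired and has
    no homolog (in ``hits``) among the derived genes lying between the
    derived-side positions of its five nearest anchored neighbors on each
    side.  Every ancestral gene outside all blocks is a potential loss with
    ``in_block=False``.
    """
    thresholds = thresholds or AnalysisThresholds()
    window_pairs = thresholds.homolog_search_window_pairs
    derived_by_id = genes_by_id(derived_genes)
    hits_by_query: dict[str, list[str]] = {}
    for row in hits.itertuples():
        hits_by_query.setdefault(row.query_id, []).append(row.subject_id)

    blocks_by_chrom: dict[str, list[SyntenyBlock]] = {}
    for block in blocks:
        blocks_by_chrom.setdefault(block.chrom_a, []).append(block)

    records: list[LossRecord] = []
    for gene in ancestral_genes:
        label = gene.genome_label
        if gene.gene_id in pair_map:
            records.append(LossRecord(gene.gene_id, label, state="retained"))
            continue
        covering = [b for b in blocks_by_chrom.get(gene.chrom, [])
                    if b.anchors[0].rank_a <= gene.rank <= b.anchors[-1].rank_a]
        if not covering:
            records.append(LossRecord(gene.gene_id, label, in_block=False,
                                      state="potential_loss"))
            continue
        rec = LossRecord(gene.gene_id, label, in_block=True, state="potential_loss")
        homolog_found = False
        for block in covering:
            upstream = [a for a in block.anchors if a.rank_a < gene.rank][-window_pairs:]
            downstream = [a for a in block.anchors if a.rank_a > gene.rank][:window_pairs]
            neighbor_genes = [derived_by_id[a.gene_b] for a in upstream + downstream]
            lo = min(g.start for g in neighbor_genes)
            hi = max(g.end for g in neighbor_genes)
            if rec.window_chrom is None:
                rec.window_chrom, rec.window_start, rec.window_end = block.chrom_b, lo, hi
            for subject in hits_by_query.get(gene.gene_id, []):
                target = derived_by_id.get(subject)
                if (target is not None and target.chrom == block.chrom_b
                        and target.end >= lo and target.start <= hi):
                    homolog_found = True
                    break
            if homolog_found:
                break
        if homolog_found:
            rec.state = "retained"
        records.append(rec)
    return records


def rescue_misannotation(records: Iterable[LossRecord],
                         rescue_candidates: pd.DataFrame | None,
                         thresholds: AnalysisThresholds | None = None,
                         ) -> list[LossRecord]:
    """Rescue potential losses explained by newly predicted derived genes.

    ``rescue_candidates`` rows describe re-predicted derived gene models
    aligned back to the candidate: ``lost_gene_id, predicted_gene_id,
    pct_identity, query_cov_pct, subject_cov_pct, chrom, start, end``.
    A candidate is rescued when identity >= 95%, BOTH coverages >= 90% and
    the predicted gene lies within the five-anchor neighborhood (candidates
    without a window, i.e. outside blocks, carry no positional constraint).
    """
    thresholds = thresholds or AnalysisThresholds()
    records = list(records)
    if rescue_candidates is None or len(rescue_candidates) == 0:
        return records
    by_lost: dict[str, list] = {}
    for row in rescue_candidates.itertuples():
        by_lost.setdefault(str(row.lost_gene_id), []).append(row)
    for rec in records:
        if rec.state != "potential_loss":
            continue
        for row in by_lost.get(rec.gene_id, []):
            if (row.pct_identity < thresholds.rescue_identity_min
                    or row.query_cov_pct < thresholds.rescue_coverage_min
                    or row.subject_cov_pct < thresholds.rescue_coverage_min):
                continue
            if rec.window_chrom is not None:
                if (row.chrom != rec.window_chrom or row.end < rec.window_start
                        or row.start > rec.window_end):
                    continue
            rec.state = "rescued_misannotation"
            break
    return records


def classify_partial_or_pseudogene(records: Iterable[LossRecord],
                                   cds_report: pd.DataFrame,
                                   ) -> list[LossRecord]:
    """Split surviving candidates into partial losses, pseudogenes and
    clean DNA-loss candidates.

    ``cds_report`` gives, per candidate gene, whether a homologous derived
    region exists and its ``has_start``, ``has_stop`` and ``frameshift``
    status.  Candidates whose homologous region lacks a start or stop codon
    are partial losses; frameshifted regions are pseudogenes; candidates
    with no homologous region at all fall through to DNA-loss.
    """
    records = list(records)
    report = cds_report.set_index(cds_report["gene_id"].astype(str))
    for rec in records:
        if rec.state != "potential_loss":
            continue
        if rec.gene_id not in report.index:
            raise ValidationError(f"cds report missing candidate {rec.gene_id}")
        row = report.loc[rec.gene_id]
        if bool(row["has_region"]):
            if not bool(row["has_start"]) or not bool(row["has_stop"]):
                rec.state = "partial_loss"
                continue
            if bool(row["frameshift"]):
                rec.state = "pseudogene"
                continue
        rec.state = "dna_loss_candidate"
    return records


def gene_coverage(genes: Sequence[GeneModel], depth_df: pd.DataFrame,
                  chrom_lengths: Mapping[str, int] | None = None,
                  ) -> dict[str, GeneCoverage]:
    """Per-gene mean depth and breadth from raw bedGraph records."""
    arrays = per_base_depth(depth_df, chrom_lengths)
    out: dict[str, GeneCoverage] = {}
    for gene in genes:
        if gene.chrom not in arrays or gene.end > len(arrays[gene.chrom]):
            raise ValidationError(
                f"gene {gene.gene_id} outside depth track bounds on {gene.chrom}")
        body = arrays[gene.chrom][gene.start - 1:gene.end]
        out[gene.gene_id] = GeneCoverage(
            gene.gene_id, float(body.mean()), float(100.0 * (body > 0).mean()))
    return out


def validate_loss_by_depth(records: Iterable[LossRecord],
                           coverage: Mapping[str, GeneCoverage],
                           thresholds: AnalysisThresholds | None = None,
                           ) -> list[LossRecord]:
    """Confirm DNA-loss candidates with read coverage of the new genome.

    Only candidates with depth < 1x AND gene-body breadth < 5% become
    confirmed losses; all others revert to retained (false positives).
    """
    thresholds = thresholds or AnalysisThresholds()
    records = list(records)
    for rec in records:
        if rec.state != "dna_loss_candidate":
            continue
        if rec.gene_id not in coverage:
            raise ValidationError(f"no coverage for candidate {rec.gene_id}")
        cov = coverage[rec.gene_id]
        rec.depth_fold, rec.breadth_pct = cov.depth_fold, cov.breadth_pct
        rec.state = ("confirmed_loss"
                     if _covered_lost(cov.depth_fold, cov.breadth_pct, thresholds)
                     else "retained")
    return records


def exclude_genotype_differences(records: Iterable[LossRecord],
                                 parental_coverage: Mapping[str, GeneCoverage] | None,
                                 thresholds: AnalysisThresholds | None = None,
                                 ) -> list[LossRecord]:
    """Reclassify confirmed losses also absent from the true parent line.

    A gene absent from the resequenced actual parent as well (same
    <1x / <5% rule) reflects a genotype difference between parent
    accessions, not a polyploidization loss.
    """
    thresholds = thresholds or AnalysisThresholds()
    records = list(records)
    if parental_coverage is None:
        logger.warning("no parental resequencing coverage supplied; "
                       "genotype-difference exclusion skipped")
        return records
    for rec in records:
        if rec.state != "confirmed_loss":
            continue
        cov = parental_coverage.get(rec.gene_id)
        if cov is not None and _covered_lost(cov.depth_fold, cov.breadth_pct, thresholds):
            rec.state = "genotype_difference"
    return records


def build_presence_matrix(gene_ids: Sequence[str],
                          coverage_by_generation: Mapping[str, Mapping[str, GeneCoverage]],
                          generations: Sequence[str],
                          thresholds: AnalysisThresholds | None = None,
                          ) -> pd.DataFrame:
    """Boolean genes x generations matrix of read-coverage presence.

    A gene is present in a generation unless its depth and breadth both
    fall below the loss cutoffs.  Missing generation samples are omitted
    with a warning.
    """
    thresholds = thresholds or AnalysisThresholds()
    columns = []
    data = {}
    for gen in generations:
        if gen not in coverage_by_generation:
            logger.warning("generation %s has no coverage sample; column omitted", gen)
            continue
        cov = coverage_by_generation[gen]
        col = []
        for gid in gene_ids:
            if gid not in cov:
                raise ValidationError(f"generation {gen} lacks coverage for {gid}")
            c = cov[gid]
            col.append(not _covered_lost(c.depth_fold, c.breadth_pct, thresholds))
        columns.append(gen)
        data[gen] = col
    return pd.DataFrame(data, index=list(gene_ids), columns=columns, dtype=bool)


def attribute_loss_events(presence: pd.DataFrame,
                          ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Attribute each ever-absent gene to a formation stage.

    Absence already in F1 means the loss accompanied interspecific
    hybridization (flagged ``restored`` if the gene is back by S0);
    first absence at S0 points to genome duplication; first absence at a
    later selfed generation S_n to ongoing diploidization.  Sporadic
    patterns beyond the F1->S0 restoration are attributed by first absence
    and flagged unstable.
    """
    rows = []
    counts: dict[str, int] = {}
    gens = list(presence.columns)
    for gene_id, row in presence.iterrows():
        absent = ~row.to_numpy(dtype=bool)
        if not absent.any():
            rows.append((gene_id, "none", False, False))
            continue
        first = int(np.argmax(absent))
        stage_gen = gens[first]
        restored = False
        unstable = False
        if stage_gen == "F1":
            attribution = "hybridization"
            if len(gens) > 1 and bool(row.iloc[1]):
                restored = True
                unstable = absent[2:].any()
            else:
                unstable = (~absent[1:]).any()
        elif stage_gen == "S0":
            attribution = "duplication"
            unstable = (~absent[first:]).any()
        else:
            attribution = f"diploidization({stage_gen})"
            unstable = (~absent[first:]).any()
        counts[attribution] = counts.get(attribution, 0) + 1
        rows.append((gene_id, attribution, restored, unstable))
    result = pd.DataFrame(rows, columns=["gene_id", "attribution",
                                         "restored", "unstable"])
    return result.set_index("gene_id"), counts
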