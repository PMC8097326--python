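"""Synthetic allopolyploid data generator with a ground-truth ledger.

The generator emulates the study design every pipeline stage consumes:
two diploid parents (a CC-like and a more TE-rich HH-like genome) sharing
an ancestral gene order; an allotetraploid whose SubC/SubH subgenomes copy
the parental orders with injected, stage-stamped gene losses (F1, S0,
S4..S13, plus a restored-at-S0 subset), homoeologous exchanges with
direction, misannotation/partial/pseudogene cases and parental genotype
differences; depth tracks at a ~50x mean for every generation; cp-genome
variants appearing at defined generations; candidate structural variants;
and homeolog expression with configurable dominance effects.

Every emission is a plain-text standard format and every injected event is
recorded in a :class:`GroundTruth` ledger so recovery can be scored.  A
fixed seed fully determines all outputs (byte-identical files).

Read depth is emitted as read-length-sized chunks whose mean depth is
drawn as Poisson(chunk_len * coverage) / chunk_len - at every windowed or
gene-body mean the pipeline computes this is distributionally identical to
per-base Poisson coverage, while keeping text tracks compact.  Regions
deleted from the tetraploid emit no coverage at all by default (a
``contamination_depth`` knob adds sparse stray reads); see the methods
note for why a vanishing residual is the realistic condition under the
strict <1x depth / <5% breadth confirmation rule.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (GENERATIONS, GeneModel, ValidationError, assign_ranks,
                      write_annotation, write_bed3, write_bedgraph,
                      write_cp_vcf, write_hits, write_table, CpVariant)
from .variants import filter_true_svs

#: generation series plus the deeply sequenced reference generation
SAMPLES = GENERATIONS + ("S14",)

FILES = {
    "cc_gff": "cc.gff3", "hh_gff": "hh.gff3",
    "subc_gff": "subc.gff3", "subh_gff": "subh.gff3",
    "te_cc": "te_cc.bed", "te_hh": "te_hh.bed",
    "te_subc": "te_subc.bed", "te_subh": "te_subh.bed",
    "hits_cc_subc": "hits_cc_subc.tsv", "hits_hh_subh": "hits_hh_subh.tsv",
    "hits_subc_subh": "hits_subc_subh.tsv", "hits_cc_hh": "hits_cc_hh.tsv",
    "chrom_lengths": "chrom_lengths.tsv",
    "cds_report": "cds_report.tsv",
    "rescue": "rescue_candidates.tsv",
    "mapfrac": "mapped_fraction.tsv",
    "identity": "identity_regions.tsv",
    "expression": "expression.tsv",
    "sv": "sv_candidates.tsv",
    "ground_truth": "ground_truth.json",
}


def depth_file(sample: str, genome: str) -> str:
    return f"depth_{sample}_{genome}.bedgraph"


def cp_file(sample: str) -> str:
    return f"cp_{sample}.vcf"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset (seed-deterministic)."""

    seed: int = 0
    n_chrom_c: int = 2
    n_chrom_h: int = 2
    genes_per_chrom: int = 250
    gene_len_range: tuple[int, int] = (600, 1200)
    spacing_range: tuple[int, int] = (900, 1500)
    te_fraction_c: float = 0.30
    te_fraction_h: float = 0.45
    te_len_range: tuple[int, int] = (300, 3000)
    noise_paralogs: int = 10
    # stage-stamped DNA losses per subgenome; SubH loses more (fractionation
    # bias) and most losses accompany hybridization
    loss_counts_c: dict[str, int] = field(
        default_factory=lambda: {"F1": 4, "S0": 1, "S5": 1, "S8": 1, "S10": 1})
    loss_counts_h: dict[str, int] = field(
        default_factory=lambda: {"F1": 10, "S0": 5, "S4": 2, "S6": 2, "S7": 1,
                                 "S9": 1, "S13": 1})
    n_restored_c: int = 0
    n_restored_h: int = 2
    n_misannotated: int = 4
    n_partial: int = 3
    n_pseudo: int = 3
    n_genotype_diff: int = 2
    # (direction, replaced length in bp); CC-biased conversion
    he_events: tuple[tuple[str, int], ...] = (
        ("CC_to_HH", 30000), ("CC_to_HH", 25000), ("CC_to_HH", 35000),
        ("HH_to_CC", 25000), ("HH_to_CC", 30000))
    n_sv: int = 40
    sv_small_fraction: float = 0.3
    sv_softclip_prob: float = 0.85
    sv_parental_prob: float = 0.25
    n_cp_snp: int = 195
    cp_snp_f1: int = 144
    n_cp_indel: int = 100
    cp_indel_f1: int = 73
    cp_len: int = 155000
    cp_anomaly_rate: float = 0.0
    depth_mean: float = 50.0
    depth_chunk_bp: int = 150
    contamination_depth: float = 0.0
    mapped_fraction_pct: float = 80.0
    expr_mean: float = 100.0
    expr_dispersion: float = 0.1
    expr_fold: float = 4.0
    bias_fraction_c: float = 0.15
    bias_fraction_h: float = 0.10
    not_expressed_fraction: float = 0.05
    expr_reps: int = 3

    @property
    def n_genes(self) -> int:
        return self.n_chrom_c * self.genes_per_chrom

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValidationError("no genes configured")
        for name in ("loss_counts_c", "loss_counts_h"):
            for stage in getattr(self, name):
                if stage not in GENERATIONS:
                    raise ValidationError(f"unknown loss stage {stage!r}")
        if self.cp_snp_f1 > self.n_cp_snp or self.cp_indel_f1 > self.n_cp_indel:
            raise ValidationError("F1-stamped cp counts exceed totals")


@dataclass
class GroundTruth:
    """Ledger of every injected event, for scoring recovery."""

    losses: list[dict] = field(default_factory=list)
    misannotated: list[dict] = field(default_factory=list)
    partial: list[dict] = field(default_factory=list)
    pseudogenes: list[dict] = field(default_factory=list)
    genotype_diff: list[dict] = field(default_factory=list)
    he_events: list[dict] = field(default_factory=list)
    cp_stages: list[dict] = field(default_factory=list)
    sv_verdicts: list[dict] = field(default_factory=list)
    expression_classes: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as handle:
            return cls(**json.load(handle))


# ---------------------------------------------------------------------------
# parents
# ---------------------------------------------------------------------------

@dataclass
class ParentGenomes:
    genes_cc: list[GeneModel]
    genes_hh: list[GeneModel]
    te_cc: pd.DataFrame
    te_hh: pd.DataFrame
    chrom_lengths: dict[str, int]
    cc_index: dict[int, GeneModel]
    hh_index: dict[int, GeneModel]


def _chrom_names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1:02d}" for i in range(n)]


def _place_genes(rng: np.random.Generator, indices: Sequence[int], chrom: str,
                 id_prefix: str, label: str, cfg: SimulationConfig,
                 ) -> tuple[list[GeneModel], int]:
    genes = []
    pos = int(rng.integers(*cfg.spacing_range))
    for idx in indices:
        length = int(rng.integers(*cfg.gene_len_range))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"{id_prefix}{idx:05d}", chrom, pos,
                               pos + length - 1, strand, label))
        pos += length + int(rng.integers(*cfg.spacing_range))
    return genes, pos


def _place_tes(rng: np.random.Generator, chrom: str, length: int,
               fraction: float, cfg: SimulationConfig) -> list[tuple[str, int, int]]:
    mean_te = float(np.mean(cfg.te_len_range))
    mean_gap = mean_te * (1.0 - fraction) / fraction
    rows = []
    pos = rng.exponential(mean_gap)
    while pos < length:
        te_len = int(rng.integers(*cfg.te_len_range))
        rows.append((chrom, int(pos), int(min(pos + te_len, length))))
        pos += te_len + rng.exponential(mean_gap)
    return rows


def simulate_parents(cfg: SimulationConfig, rng: np.random.Generator,
                     ) -> ParentGenomes:
    """Two parent annotations sharing an ancestral gene order, plus TEs."""
    n = cfg.n_genes
    split_c = np.array_split(np.arange(n), cfg.n_chrom_c)
    split_h = np.array_split(np.arange(n), cfg.n_chrom_h)
    chroms_c = _chrom_names("C", cfg.n_chrom_c)
    chroms_h = _chrom_names("H", cfg.n_chrom_h)
    chrom_lengths: dict[str, int] = {}
    genes_cc: list[GeneModel] = []
    genes_hh: list[GeneModel] = []
    te_rows_c: list[tuple[str, int, int]] = []
    te_rows_h: list[tuple[str, int, int]] = []
    for chrom, indices in zip(chroms_c, split_c):
        genes, length = _place_genes(rng, indices, chrom, "CsaG", "CC", cfg)
        genes_cc.extend(genes)
        chrom_lengths[chrom] = length
        te_rows_c.extend(_place_tes(rng, chrom, length, cfg.te_fraction_c, cfg))
    for chrom, indices in zip(chroms_h, split_h):
        genes, length = _place_genes(rng, indices, chrom, "ChyG", "HH", cfg)
        genes_hh.extend(genes)
        chrom_lengths[chrom] = length
        te_rows_h.extend(_place_tes(rng, chrom, length, cfg.te_fraction_h, cfg))
    assign_ranks(genes_cc)
    assign_ranks(genes_hh)
    cc_index = {int(g.gene_id[4:]): g for g in genes_cc}
    hh_index = {int(g.gene_id[4:]): g for g in genes_hh}
    return ParentGenomes(
        genes_cc, genes_hh,
        pd.DataFrame(te_rows_c, columns=["chrom", "start", "end"]),
        pd.DataFrame(te_rows_h, columns=["chrom", "start", "end"]),
        chrom_lengths, cc_index, hh_index)


# ---------------------------------------------------------------------------
# tetraploid with injected events
# ---------------------------------------------------------------------------

def _subgenome_chrom(parent_chrom: str) -> str:
    # C01 -> Chc01, H03 -> Chh03
    return ("Chc" if parent_chrom.startswith("C") else "Chh") + parent_chrom[1:]


@dataclass
class Tetraploid:
    genes_subc: list[GeneModel]
    genes_subh: list[GeneModel]
    truth: GroundTruth
    # ancestral index -> event kind on each subgenome
    removed_c: dict[int, str]
    removed_h: dict[int, str]
    he_regions: list[dict]
    chrom_lengths: dict[str, int]


def _expand_stages(counts: Mapping[str, int]) -> list[str]:
    ordered = sorted(counts, key=GENERATIONS.index)
    stages: list[str] = []
    for stage in ordered:
        stages.extend([stage] * counts[stage])
    return stages


def _pick_he_regions(cfg: SimulationConfig, parents: ParentGenomes,
                     rng: np.random.Generator, used: set[int]) -> list[dict]:
    margin = 8
    regions = []
    for direction, length in cfg.he_events:
        recv_index = parents.hh_index if direction == "CC_to_HH" else parents.cc_index
        donor_index = parents.cc_index if direction == "CC_to_HH" else parents.hh_index
        placed = False
        for _ in range(500):
            j0 = int(rng.integers(margin, cfg.n_genes - margin))
            # extend until the replaced span reaches the requested length
            j1 = j0
            start_gene = recv_index[j0]
            while (j1 + 1 < cfg.n_genes
                   and recv_index[j1 + 1].chrom == start_gene.chrom
                   and recv_index[j1].end - start_gene.start + 1 < length):
                j1 += 1
            span = recv_index[j1].end - start_gene.start + 1
            block = set(range(j0 - 1, j1 + 2))
            same_chrom = (recv_index[j0 - 1].chrom == recv_index[j1 + 1].chrom ==
                          start_gene.chrom and
                          donor_index[j0 - 1].chrom == donor_index[j1 + 1].chrom ==
                          donor_index[j0].chrom)
            if span < length or not same_chrom or block & used:
                continue
            used |= block
            recv_lo = (recv_index[j0 - 1].end + start_gene.start) // 2
            recv_hi = (recv_index[j1].end + recv_index[j1 + 1].start) // 2
            donor_lo = (donor_index[j0 - 1].end + donor_index[j0].start) // 2
            donor_hi = (donor_index[j1].end + donor_index[j1 + 1].start) // 2
            if direction == "CC_to_HH":
                region = {"direction": direction, "idx_lo": j0, "idx_hi": j1,
                          "chrom_c": _subgenome_chrom(donor_index[j0].chrom),
                          "c_lo": donor_lo, "c_hi": donor_hi,
                          "chrom_h": _subgenome_chrom(start_gene.chrom),
                          "h_lo": recv_lo, "h_hi": recv_hi}
            else:
                region = {"direction": direction, "idx_lo": j0, "idx_hi": j1,
                          "chrom_c": _subgenome_chrom(start_gene.chrom),
                          "c_lo": recv_lo, "c_hi": recv_hi,
                          "chrom_h": _subgenome_chrom(donor_index[j0].chrom),
                          "h_lo": donor_lo, "h_hi": donor_hi}
            regions.append(region)
            placed = True
            break
        if not placed:
            raise ValidationError(
                f"could not place HE event {direction} of {length} bp "
                f"without overlapping earlier events")
    return regions


def simulate_allopolyploid(parents: ParentGenomes, cfg: SimulationConfig,
                           rng: np.random.Generator) -> Tetraploid:
    """Derive SubC/SubH annotations with injected, ledgered events."""
    margin = 8
    used: set[int] = set()
    # keep chromosome ends anchored so five-neighbor windows always exist
    interior: list[int] = []
    boundary: set[int] = set()
    for index in (parents.cc_index, parents.hh_index):
        by_chrom: dict[str, list[int]] = {}
        for idx, gene in index.items():
            by_chrom.setdefault(gene.chrom, []).append(idx)
        for idxs in by_chrom.values():
            idxs.sort()
            boundary |= set(idxs[:margin] + idxs[-margin:])
    interior = [i for i in range(cfg.n_genes) if i not in boundary]

    he_regions = _pick_he_regions(cfg, parents, rng, used)

    stages_c = _expand_stages(cfg.loss_counts_c)
    stages_h = _expand_stages(cfg.loss_counts_h)
    n_mis_c = cfg.n_misannotated // 2
    n_mis_h = cfg.n_misannotated - n_mis_c
    n_part_c = cfg.n_partial // 2
    n_part_h = cfg.n_partial - n_part_c
    n_pseudo_c = cfg.n_pseudo // 2
    n_pseudo_h = cfg.n_pseudo - n_pseudo_c
    needed = (len(stages_c) + len(stages_h) + cfg.n_misannotated
              + cfg.n_partial + cfg.n_pseudo + cfg.n_genotype_diff)
    pool = np.array(sorted(set(interior) - used), dtype=int)
    if len(pool) < needed:
        raise ValidationError("genome too small for the configured events")
    chosen = list(rng.choice(pool, size=needed, replace=False))

    def take(k: int) -> list[int]:
        out = [int(i) for i in chosen[:k]]
        del chosen[:k]
        return out

    loss_idx_c = take(len(stages_c))
    loss_idx_h = take(len(stages_h))
    mis_c, mis_h = take(n_mis_c), take(n_mis_h)
    part_c, part_h = take(n_part_c), take(n_part_h)
    pseudo_c, pseudo_h = take(n_pseudo_c), take(n_pseudo_h)
    geno_c = take(cfg.n_genotype_diff)

    truth = GroundTruth()
    removed_c: dict[int, str] = {}
    removed_h: dict[int, str] = {}

    def register(indices, stages, sub, index, removed, n_restored):
        f1_seen = 0
        for idx, stage in zip(indices, stages):
            restored = stage == "F1" and f1_seen < n_restored
            if stage == "F1":
                f1_seen += 1
            truth.losses.append({"gene_id": index[idx].gene_id,
                                 "subgenome": sub, "stage": stage,
                                 "restored": restored})
            removed[idx] = "loss"

    register(loss_idx_c, stages_c, "SubC", parents.cc_index, removed_c,
             cfg.n_restored_c)
    register(loss_idx_h, stages_h, "SubH", parents.hh_index, removed_h,
             cfg.n_restored_h)
    for idx in mis_c:
        removed_c[idx] = "misannotated"
        truth.misannotated.append({"gene_id": parents.cc_index[idx].gene_id,
                                   "subgenome": "SubC"})
    for idx in mis_h:
        removed_h[idx] = "misannotated"
        truth.misannotated.append({"gene_id": parents.hh_index[idx].gene_id,
                                   "subgenome": "SubH"})
    for idx in part_c:
        removed_c[idx] = "partial"
        truth.partial.append({"gene_id": parents.cc_index[idx].gene_id,
                              "subgenome": "SubC"})
    for idx in part_h:
        removed_h[idx] = "partial"
        truth.partial.append({"gene_id": parents.hh_index[idx].gene_id,
                              "subgenome": "SubH"})
    for idx in pseudo_c:
        removed_c[idx] = "pseudogene"
        truth.pseudogenes.append({"gene_id": parents.cc_index[idx].gene_id,
                                  "subgenome": "SubC"})
    for idx in pseudo_h:
        removed_h[idx] = "pseudogene"
        truth.pseudogenes.append({"gene_id": parents.hh_index[idx].gene_id,
                                  "subgenome": "SubH"})
    for idx in geno_c:
        removed_c[idx] = "genotype_diff"
        truth.genotype_diff.append({"gene_id": parents.cc_index[idx].gene_id,
                                    "subgenome": "SubC"})
    truth.he_events = [dict(r) for r in he_regions]

    transplanted_on_c = {i for r in he_regions if r["direction"] == "HH_to_CC"
                         for i in range(r["idx_lo"], r["idx_hi"] + 1)}
    transplanted_on_h = {i for r in he_regions if r["direction"] == "CC_to_HH"
                         for i in range(r["idx_lo"], r["idx_hi"] + 1)}

    genes_subc: list[GeneModel] = []
    genes_subh: list[GeneModel] = []
    for idx in range(cfg.n_genes):
        cc, hh = parents.cc_index[idx], parents.hh_index[idx]
        if idx not in removed_c:
            prefix = "ChcT" if idx in transplanted_on_c else "ChcG"
            genes_subc.append(GeneModel(f"{prefix}{idx:05d}",
                                        _subgenome_chrom(cc.chrom), cc.start,
                                        cc.end, cc.strand, "SubC"))
        if idx not in removed_h:
            prefix = "ChhT" if idx in transplanted_on_h else "ChhG"
            genes_subh.append(GeneModel(f"{prefix}{idx:05d}",
                                        _subgenome_chrom(hh.chrom), hh.start,
                                        hh.end, hh.strand, "SubH"))
    assign_ranks(genes_subc)
    assign_ranks(genes_subh)

    chrom_lengths = dict(parents.chrom_lengths)
    for chrom, length in parents.chrom_lengths.items():
        chrom_lengths[_subgenome_chrom(chrom)] = length
    return Tetraploid(genes_subc, genes_subh, truth, removed_c, removed_h,
                      he_regions, chrom_lengths)


# ---------------------------------------------------------------------------
# homology hit tables
# ---------------------------------------------------------------------------

def _hit_rows(pairs, rng, identity_range, bitscore_range, evalue):
    rows = []
    for query, subject, qlen in pairs:
        identity = float(rng.uniform(*identity_range))
        bitscore = float(rng.uniform(*bitscore_range))
        aln = max(1, int(qlen * 0.9))
        rows.append((query, subject, round(identity, 2), aln,
                     int(aln * (100 - identity) / 100), 0, 1, aln, 1, aln,
                     evalue, round(bitscore, 1)))
    return rows


def _noise_rows(rng, cfg, queries, subjects):
    if cfg.noise_paralogs == 0 or not queries or not subjects:
        return []
    rows = []
    for _ in range(cfg.noise_paralogs):
        q = queries[int(rng.integers(len(queries)))]
        s = subjects[int(rng.integers(len(subjects)))]
        rows.extend(_hit_rows([(q.gene_id, s.gene_id, q.length)], rng,
                              (70, 80), (80, 150), 1e-8))
    return rows


def build_hit_tables(parents: ParentGenomes, tetra: Tetraploid,
                     cfg: SimulationConfig, rng: np.random.Generator,
                     ) -> dict[str, pd.DataFrame]:
    from .core_io import HIT_COLUMNS

    subc_by_idx = {int(g.gene_id[4:]): g for g in tetra.genes_subc}
    subh_by_idx = {int(g.gene_id[4:]): g for g in tetra.genes_subh}
    event_free_c = [g for i, g in sorted(parents.cc_index.items())
                    if i not in tetra.removed_c]
    event_free_h = [g for i, g in sorted(parents.hh_index.items())
                    if i not in tetra.removed_h]

    tables: dict[str, list] = {}
    rows = []
    for idx in sorted(subc_by_idx):
        cc = parents.cc_index[idx]
        sub = subc_by_idx[idx]
        transplant = sub.gene_id.startswith("ChcT")
        rows.extend(_hit_rows(
            [(cc.gene_id, sub.gene_id, cc.length)], rng,
            (92, 96) if transplant else (98.5, 99.9),
            (450, 600) if transplant else (700, 900), 1e-50))
    rows.extend(_noise_rows(rng, cfg, event_free_c, tetra.genes_subc))
    tables["hits_cc_subc"] = rows

    rows = []
    for idx in sorted(subh_by_idx):
        hh = parents.hh_index[idx]
        sub = subh_by_idx[idx]
        transplant = sub.gene_id.startswith("ChhT")
        rows.extend(_hit_rows(
            [(hh.gene_id, sub.gene_id, hh.length)], rng,
            (92, 96) if transplant else (98.5, 99.9),
            (450, 600) if transplant else (700, 900), 1e-50))
    rows.extend(_noise_rows(rng, cfg, event_free_h, tetra.genes_subh))
    tables["hits_hh_subh"] = rows

    rows = []
    for idx in range(cfg.n_genes):
        if idx in subc_by_idx and idx in subh_by_idx:
            c, h = subc_by_idx[idx], subh_by_idx[idx]
            transplant = c.gene_id[3] == "T" or h.gene_id[3] == "T"
            rows.extend(_hit_rows(
                [(c.gene_id, h.gene_id, c.length)], rng,
                (98, 99.9) if transplant else (92, 96), (450, 650), 1e-40))
    rows.extend(_noise_rows(rng, cfg, tetra.genes_subc, tetra.genes_subh))
    tables["hits_subc_subh"] = rows

    rows = []
    for idx in range(cfg.n_genes):
        cc, hh = parents.cc_index[idx], parents.hh_index[idx]
        rows.extend(_hit_rows([(cc.gene_id, hh.gene_id, cc.length)], rng,
                              (92, 96), (450, 650), 1e-40))
    rows.extend(_noise_rows(rng, cfg, parents.genes_cc, parents.genes_hh))
    tables["hits_cc_hh"] = rows

    return {name: pd.DataFrame(rows, columns=HIT_COLUMNS)
            for name, rows in tables.items()}


# ---------------------------------------------------------------------------
# depth tracks
# ---------------------------------------------------------------------------

def _loss_absent(sample: str, stage: str, restored: bool) -> bool:
    if restored:
        return sample in ("F1", "S14")
    if sample == "S14":
        return True
    return SAMPLES.index(sample) >= SAMPLES.index(stage)


def _depth_events(parents: ParentGenomes, tetra: Tetraploid,
                  cfg: SimulationConfig, genome: str, sample: str,
                  ) -> dict[str, list[tuple[int, int, float]]]:
    """Coverage-rate intervals (0-based half-open) deviating from the mean."""
    events: dict[str, list[tuple[int, int, float]]] = {}

    def add(chrom: str, lo: int, hi: int, rate: float) -> None:
        events.setdefault(chrom, []).append((lo, hi, rate))

    index = parents.cc_index if genome == "CC" else parents.hh_index
    by_id = {g.gene_id: g for g in index.values()}
    sub = "SubC" if genome == "CC" else "SubH"
    for loss in tetra.truth.losses:
        if loss["subgenome"] != sub:
            continue
        gene = by_id[loss["gene_id"]]
        if _loss_absent(sample, loss["stage"], loss["restored"]):
            add(gene.chrom, gene.start - 1, gene.end, 0.0)
    for entry in tetra.truth.genotype_diff:
        if entry["subgenome"] == sub:
            gene = by_id[entry["gene_id"]]
            add(gene.chrom, gene.start - 1, gene.end, 0.0)
    if sample != "F1":  # exchanges arise with genome doubling
        for region in tetra.he_regions:
            # deleted on the receiving subgenome, doubled on the donor side
            if region["direction"] == "CC_to_HH":
                del_chrom, del_lo, del_hi = region["chrom_h"], region["h_lo"], region["h_hi"]
                dup_chrom, dup_lo, dup_hi = region["chrom_c"], region["c_lo"], region["c_hi"]
            else:
                del_chrom, del_lo, del_hi = region["chrom_c"], region["c_lo"], region["c_hi"]
                dup_chrom, dup_lo, dup_hi = region["chrom_h"], region["h_lo"], region["h_hi"]
            if genome == "CC" and del_chrom.startswith("Chc"):
                add("C" + del_chrom[3:], del_lo, del_hi, 0.0)
            if genome == "HH" and del_chrom.startswith("Chh"):
                add("H" + del_chrom[3:], del_lo, del_hi, 0.0)
            if genome == "CC" and dup_chrom.startswith("Chc"):
                add("C" + dup_chrom[3:], dup_lo, dup_hi, 2.0 * cfg.depth_mean)
            if genome == "HH" and dup_chrom.startswith("Chh"):
                add("H" + dup_chrom[3:], dup_lo, dup_hi, 2.0 * cfg.depth_mean)
    return events


def _emit_depth(rng: np.random.Generator, chrom_lengths: Mapping[str, int],
                events: Mapping[str, Sequence[tuple[int, int, float]]],
                cfg: SimulationConfig) -> pd.DataFrame:
    chunk = cfg.depth_chunk_bp
    out_chrom, out_start, out_end, out_val = [], [], [], []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        pieces = []
        pos = 0
        for lo, hi, rate in sorted(events.get(chrom, [])):
            if lo < pos:
                raise ValidationError(f"overlapping depth events on {chrom}")
            if lo > pos:
                pieces.append((pos, lo, cfg.depth_mean))
            pieces.append((lo, hi, rate))
            pos = hi
        if pos < length:
            pieces.append((pos, length, cfg.depth_mean))
        for lo, hi, rate in pieces:
            if rate <= 0:
                if cfg.contamination_depth > 0:
                    n_reads = rng.poisson(
                        (hi - lo) * cfg.contamination_depth / chunk)
                    for _ in range(int(n_reads)):
                        start = int(rng.integers(lo, max(lo + 1, hi - chunk)))
                        out_chrom.append(chrom)
                        out_start.append(start)
                        out_end.append(min(start + chunk, hi))
                        out_val.append(1.0)
                continue
            starts = np.arange(lo, hi, chunk)
            ends = np.minimum(starts + chunk, hi)
            widths = ends - starts
            values = rng.poisson(rate * widths) / widths
            out_chrom.extend([chrom] * len(starts))
            out_start.extend(starts.tolist())
            out_end.extend(ends.tolist())
            out_val.extend(values.tolist())
    return pd.DataFrame({"chrom": out_chrom, "start": out_start,
                         "end": out_end, "value": out_val})


def simulate_depth_tracks(parents: ParentGenomes, tetra: Tetraploid,
                          cfg: SimulationConfig, rng: np.random.Generator,
                          ) -> dict[tuple[str, str], pd.DataFrame]:
    """Depth bedGraph frames keyed by (sample, reference genome).

    Samples cover the generation series plus S14; the two parental
    resequencing controls are keyed ("parent", "CC"/"HH").  Genotype
    differences are the only events absent from the parental controls.
    """
    tracks: dict[tuple[str, str], pd.DataFrame] = {}
    for genome in ("CC", "HH"):
        lengths = {c: l for c, l in parents.chrom_lengths.items()
                   if c.startswith(genome[0])}
        for sample in SAMPLES:
            events = _depth_events(parents, tetra, cfg, genome, sample)
            tracks[(sample, genome)] = _emit_depth(rng, lengths, events, cfg)
        parent_events: dict[str, list[tuple[int, int, float]]] = {}
        if genome == "CC":
            for entry in tetra.truth.genotype_diff:
                gene = next(g for g in parents.genes_cc
                            if g.gene_id == entry["gene_id"])
                parent_events.setdefault(gene.chrom, []).append(
                    (gene.start - 1, gene.end, 0.0))
        tracks[("parent", genome)] = _emit_depth(rng, lengths, parent_events, cfg)
    return tracks


def rename_to_subgenome(df: pd.DataFrame) -> pd.DataFrame:
    """Relabel parent chromosome names to their subgenome equivalents."""
    out = df.copy()
    out["chrom"] = out["chrom"].map(_subgenome_chrom)
    return out


# ---------------------------------------------------------------------------
# auxiliary evidence tables
# ---------------------------------------------------------------------------

def build_cds_report(parents: ParentGenomes, tetra: Tetraploid) -> pd.DataFrame:
    status = {}
    for gene in parents.genes_cc + parents.genes_hh:
        status[gene.gene_id] = {"gene_id": gene.gene_id, "has_region": True,
                                "has_start": True, "has_stop": True,
                                "frameshift": False}
    for entry in tetra.truth.losses + tetra.truth.genotype_diff:
        status[entry["gene_id"]]["has_region"] = False
    for entry in tetra.truth.partial:
        status[entry["gene_id"]]["has_stop"] = False
    for entry in tetra.truth.pseudogenes:
        status[entry["gene_id"]]["frameshift"] = True
    return pd.DataFrame([status[g] for g in sorted(status)])


def build_rescue_table(parents: ParentGenomes, tetra: Tetraploid,
                       rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    index = {g.gene_id: g for g in parents.genes_cc + parents.genes_hh}
    for k, entry in enumerate(tetra.truth.misannotated):
        gene = index[entry["gene_id"]]
        rows.append({
            "lost_gene_id": gene.gene_id,
            "predicted_gene_id": f"pred{k:03d}",
            "pct_identity": round(float(rng.uniform(96, 99)), 2),
            "query_cov_pct": round(float(rng.uniform(92, 98)), 2),
            "subject_cov_pct": round(float(rng.uniform(92, 98)), 2),
            "chrom": _subgenome_chrom(gene.chrom),
            "start": gene.start, "end": gene.end})
    # decoy alignments for two true losses, below the identity cutoff
    for k, entry in enumerate(tetra.truth.losses[:2]):
        gene = index[entry["gene_id"]]
        rows.append({
            "lost_gene_id": gene.gene_id,
            "predicted_gene_id": f"decoy{k:03d}",
            "pct_identity": round(float(rng.uniform(85, 92)), 2),
            "query_cov_pct": round(float(rng.uniform(92, 98)), 2),
            "subject_cov_pct": round(float(rng.uniform(92, 98)), 2),
            "chrom": _subgenome_chrom(gene.chrom),
            "start": gene.start, "end": gene.end})
    return pd.DataFrame(rows, columns=["lost_gene_id", "predicted_gene_id",
                                       "pct_identity", "query_cov_pct",
                                       "subject_cov_pct", "chrom", "start",
                                       "end"])


def build_mapped_fraction(tetra: Tetraploid, cfg: SimulationConfig,
                          rng: np.random.Generator,
                          window_bp: int = 5000) -> pd.DataFrame:
    rows = []
    for chrom in sorted(tetra.chrom_lengths):
        if not chrom.startswith("Ch"):
            continue
        n_windows = -(-tetra.chrom_lengths[chrom] // window_bp)
        values = np.clip(rng.normal(cfg.mapped_fraction_pct, 3.0, n_windows),
                         60.0, 95.0)
        for i, value in enumerate(values):
            rows.append((chrom, i, round(float(value), 2)))
    return pd.DataFrame(rows, columns=["chrom", "window_index", "mapped_pct"])


def build_identity_table(tetra: Tetraploid, rng: np.random.Generator,
                         ) -> pd.DataFrame:
    rows = []
    for region in tetra.he_regions:
        rows.append({
            "chrom_c": region["chrom_c"], "start_c": region["c_lo"],
            "end_c": region["c_hi"], "chrom_h": region["chrom_h"],
            "start_h": region["h_lo"], "end_h": region["h_hi"],
            "pct_identity": round(float(rng.uniform(97.0, 99.5)), 2)})
    return pd.DataFrame(rows, columns=["chrom_c", "start_c", "end_c",
                                       "chrom_h", "start_h", "end_h",
                                       "pct_identity"])


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _nb_mean(rng: np.random.Generator, mean: float, dispersion: float,
             reps: int) -> float:
    if mean <= 0:
        return 0.0
    n = 1.0 / dispersion
    p = n / (n + mean)
    return float(rng.negative_binomial(n, p, size=reps).mean())


def simulate_expression(tetra: Tetraploid, cfg: SimulationConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Homeolog expression table with a ledgered dominance structure.

    Each emitted value is the mean of ``expr_reps`` negative-binomial
    replicate draws, emulating replicated normalized expression estimates.
    """
    subc_by_idx = {int(g.gene_id[4:]): g for g in tetra.genes_subc}
    subh_by_idx = {int(g.gene_id[4:]): g for g in tetra.genes_subh}
    shared = sorted(set(subc_by_idx) & set(subh_by_idx))
    n = len(shared)
    n_ne = int(round(cfg.not_expressed_fraction * n))
    n_c = int(round(cfg.bias_fraction_c * n))
    n_h = int(round(cfg.bias_fraction_h * n))
    classes = (["not_expressed"] * n_ne + ["C_dominant"] * n_c
               + ["H_dominant"] * n_h + ["neutral"] * (n - n_ne - n_c - n_h))
    order = rng.permutation(n)
    rows = []
    for slot, pair_pos in enumerate(order):
        idx = shared[pair_pos]
        cls = classes[slot]
        if cls == "not_expressed":
            mean_c = mean_h = 0.2
        elif cls == "C_dominant":
            mean_c, mean_h = cfg.expr_mean * cfg.expr_fold, cfg.expr_mean
        elif cls == "H_dominant":
            mean_c, mean_h = cfg.expr_mean, cfg.expr_mean * cfg.expr_fold
        else:
            mean_c = mean_h = cfg.expr_mean
        pair_id = f"pair{idx:05d}"
        tetra.truth.expression_classes[pair_id] = cls
        rows.append({
            "pair_id": pair_id,
            "gene_c": subc_by_idx[idx].gene_id,
            "gene_h": subh_by_idx[idx].gene_id,
            "expr_c": round(_nb_mean(rng, mean_c, cfg.expr_dispersion,
                                     cfg.expr_reps), 4),
            "expr_h": round(_nb_mean(rng, mean_h, cfg.expr_dispersion,
                                     cfg.expr_reps), 4)})
    return pd.DataFrame(sorted(rows, key=lambda r: r["pair_id"]),
                        columns=["pair_id", "gene_c", "gene_h",
                                 "expr_c", "expr_h"])


# ---------------------------------------------------------------------------
# chloroplast timeline
# ---------------------------------------------------------------------------

def simulate_cp_timeline(tetra: Tetraploid, cfg: SimulationConfig,
                         rng: np.random.Generator) -> list[CpVariant]:
    """cp-genome variants appearing at stamped stages and persisting."""
    bases = "ACGT"
    n_total = cfg.n_cp_snp + cfg.n_cp_indel
    positions = np.sort(rng.choice(
        np.arange(200, cfg.cp_len - 200), size=n_total, replace=False))
    type_order = rng.permutation(
        ["SNP"] * cfg.n_cp_snp + ["indel"] * cfg.n_cp_indel)

    def stage_list(total: int, n_f1: int) -> list[str]:
        rest = total - n_f1
        n_s0 = rest // 2
        later = rest - n_s0
        stages = ["F1"] * n_f1 + ["S0"] * n_s0
        selfed = [g for g in GENERATIONS if g not in ("F1", "S0")]
        for i in range(later):
            stages.append(selfed[i % len(selfed)])
        return stages

    snp_stages = list(rng.permutation(stage_list(cfg.n_cp_snp, cfg.cp_snp_f1)))
    indel_stages = list(rng.permutation(stage_list(cfg.n_cp_indel,
                                                   cfg.cp_indel_f1)))
    variants = []
    for pos, vtype in zip(positions, type_order):
        stage = snp_stages.pop() if vtype == "SNP" else indel_stages.pop()
        if vtype == "SNP":
            ref = bases[int(rng.integers(4))]
            alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
        else:
            anchor = bases[int(rng.integers(4))]
            extra = "".join(bases[int(b)] for b in rng.integers(0, 4, size=int(
                rng.integers(1, 50))))
            if rng.random() < 0.5:
                ref, alt = anchor, anchor + extra
            else:
                ref, alt = anchor + extra, anchor
        first = GENERATIONS.index(stage)
        presence = {}
        for i, sample in enumerate(GENERATIONS):
            present = i >= first
            if (present and i > first and cfg.cp_anomaly_rate > 0
                    and rng.random() < cfg.cp_anomaly_rate):
                present = False
            presence[sample] = present
        variants.append(CpVariant(int(pos), ref, alt, vtype, presence))
        tetra.truth.cp_stages.append({"pos": int(pos), "vtype": vtype,
                                      "stage": stage})
    return variants


# ---------------------------------------------------------------------------
# structural variants
# ---------------------------------------------------------------------------

SV_TYPES = ("insertion", "deletion", "inversion", "translocation",
            "transposition")


def simulate_svs(tetra: Tetraploid, cfg: SimulationConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    sub_chroms = sorted(c for c in tetra.chrom_lengths if c.startswith("Ch"))
    rows = []
    for k in range(cfg.n_sv):
        chrom = sub_chroms[int(rng.integers(len(sub_chroms)))]
        if rng.random() < cfg.sv_small_fraction:
            length = int(rng.integers(5, 26))
        else:
            length = int(rng.integers(26, 5001))
        start = int(rng.integers(1, tetra.chrom_lengths[chrom] - length))
        rows.append({
            "sv_id": f"sv{k:03d}", "chrom": chrom, "start": start,
            "end": start + length,
            "sv_type": SV_TYPES[int(rng.integers(len(SV_TYPES)))],
            "length": length,
            "softclip_support": bool(rng.random() < cfg.sv_softclip_prob),
            "parental_support": bool(rng.random() < cfg.sv_parental_prob)})
    df = pd.DataFrame(rows, columns=["sv_id", "chrom", "start", "end",
                                     "sv_type", "length", "softclip_support",
                                     "parental_support"])
    verdicts = filter_true_svs(df)
    tetra.truth.sv_verdicts = [
        {"sv_id": r.sv_id, "verdict": r.verdict} for r in verdicts.itertuples()]
    return df


# ---------------------------------------------------------------------------
# one-call emission
# ---------------------------------------------------------------------------

def simulate_all(cfg: SimulationConfig, outdir: str | Path) -> GroundTruth:
    """Generate and write every pipeline input plus the ground-truth ledger."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    parents = simulate_parents(cfg, rng)
    tetra = simulate_allopolyploid(parents, cfg, rng)
    hit_tables = build_hit_tables(parents, tetra, cfg, rng)
    depth = simulate_depth_tracks(parents, tetra, cfg, rng)
    mapfrac = build_mapped_fraction(tetra, cfg, rng)
    identity = build_identity_table(tetra, rng)
    expression = simulate_expression(tetra, cfg, rng)
    cp_variants = simulate_cp_timeline(tetra, cfg, rng)
    svs = simulate_svs(tetra, cfg, rng)
    rescue = build_rescue_table(parents, tetra, rng)

    write_annotation(parents.genes_cc, outdir / FILES["cc_gff"])
    write_annotation(parents.genes_hh, outdir / FILES["hh_gff"])
    write_annotation(tetra.genes_subc, outdir / FILES["subc_gff"])
    write_annotation(tetra.genes_subh, outdir / FILES["subh_gff"])
    write_bed3(parents.te_cc, outdir / FILES["te_cc"])
    write_bed3(parents.te_hh, outdir / FILES["te_hh"])
    write_bed3(rename_to_subgenome(parents.te_cc), outdir / FILES["te_subc"])
    write_bed3(rename_to_subgenome(parents.te_hh), outdir / FILES["te_subh"])
    for name, table in hit_tables.items():
        write_hits(table, outdir / FILES[name])
    lengths_df = pd.DataFrame(sorted(tetra.chrom_lengths.items()),
                              columns=["chrom", "length"])
    write_table(lengths_df, outdir / FILES["chrom_lengths"])
    write_table(build_cds_report(parents, tetra), outdir / FILES["cds_report"])
    write_table(rescue, outdir / FILES["rescue"])
    write_table(mapfrac, outdir / FILES["mapfrac"])
    write_table(identity, outdir / FILES["identity"])
    write_table(expression, outdir / FILES["expression"])
    write_table(svs, outdir / FILES["sv"])
    for (sample, genome), df in depth.items():
        write_bedgraph(df, outdir / depth_file(sample, genome))
        if sample == "S14":
            sub = "SubC" if genome == "CC" else "SubH"
            write_bedgraph(rename_to_subgenome(df),
                           outdir / depth_file(sample, sub))
    for sample in GENERATIONS:
        write_cp_vcf(cp_variants, sample, outdir / cp_file(sample),
                     contig="cp_HH", contig_length=cfg.cp_len)
    tetra.truth.to_json(outdir / FILES["ground_truth"])
    return tetra.truth


# ---------------------------------------------------------------------------
# recovery scoring against the ledger
# ---------------------------------------------------------------------------

def expected_attribution(stage: str) -> str:
    if stage == "F1":
        return "hybridization"
    if stage == "S0":
        return "duplication"
    return f"diploidization({stage})"


def score_recovery(results: Mapping, truth: GroundTruth,
                   window_bp: int = 5000) -> dict:
    """Score pipeline results against the ground-truth ledger.

    Returns confirmed-loss recall/precision, stage-attribution accuracy
    over recovered losses, HE recall and direction accuracy, cp F1
    fractions and expression-bias class agreement.
    """
    confirmed = {r.gene_id for records in results["loss_records"].values()
                 for r in records if r.state == "confirmed_loss"}
    true_losses = {entry["gene_id"] for entry in truth.losses}
    tp = len(confirmed & true_losses)
    scores: dict = {
        "loss_recall": tp / len(true_losses) if true_losses else 1.0,
        "loss_precision": tp / len(confirmed) if confirmed else 1.0,
        "n_true_losses": len(true_losses),
        "n_confirmed": len(confirmed),
    }

    attribution = results["attribution"]
    n_ok = 0
    for entry in truth.losses:
        gid = entry["gene_id"]
        if gid not in confirmed or gid not in attribution.index:
            continue
        row = attribution.loc[gid]
        if (row["attribution"] == expected_attribution(entry["stage"])
                and bool(row["restored"]) == bool(entry["restored"])):
            n_ok += 1
    scores["stage_accuracy"] = n_ok / tp if tp else 1.0

    matched = direction_ok = 0
    for event in truth.he_events:
        if event["direction"] == "CC_to_HH":
            dup_sub, chrom, lo, hi = "SubC", event["chrom_c"], event["c_lo"], event["c_hi"]
        else:
            dup_sub, chrom, lo, hi = "SubH", event["chrom_h"], event["h_lo"], event["h_hi"]
        hit = None
        for call in results["he_calls"]:
            if not call.confirmed or call.dup_subgenome != dup_sub:
                continue
            s_lo, s_hi = call.segment_dup.bp_span(window_bp)
            if call.segment_dup.chrom == chrom and s_hi > lo and s_lo < hi:
                hit = call
                break
        if hit is not None:
            matched += 1
            if hit.direction == event["direction"]:
                direction_ok += 1
    scores["he_recall"] = matched / len(truth.he_events) if truth.he_events else 1.0
    scores["he_matched"] = matched
    scores["he_direction_accuracy"] = (direction_ok / matched) if matched else 1.0

    if "cp_partition" in results:
        scores["cp_fraction_f1"] = dict(results["cp_partition"].fraction_f1)

    predictions = {p.pair_id: p.bias_class for p in results["expression_pairs"]}
    if truth.expression_classes:
        agree = sum(1 for pid, cls in truth.expression_classes.items()
                    if predictions.get(pid) == cls)
        scores["expression_class_recovery"] = agree / len(truth.expression_classes)
        biased = [pid for pid, cls in truth.expression_classes.items()
                  if cls in ("C_dominant", "H_dominant")]
        if biased:
            scores["expression_bias_recovery"] = sum(
                1 for pid in biased if predictions.get(pid) ==
                truth.expression_classes[pid]) / len(biased)
    return scores
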