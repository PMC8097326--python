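"""Shared domain types and readers/writers for the formats the pipeline touches.

Coordinate conventions are localized here: gene annotations are GFF3-style
1-based inclusive; depth tracks are bedGraph-style 0-based half-open.  All
writers emit deterministic column and line order so that identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class AllokitError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(AllokitError):
    """Input violates a documented contract."""


class ParseError(ValidationError):
    """A file could not be parsed; the message names the offending line."""


GENOME_LABELS = ("CC", "HH", "SubC", "SubH")

#: Sample order of the generation series: the unduplicated interspecific
#: hybrid (F1), the first doubled generation (S0) and selfed generations.
GENERATIONS = ("F1", "S0", "S4", "S5", "S6", "S7", "S8", "S9", "S10", "S11", "S12", "S13")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene with 1-based inclusive coordinates and a per-chromosome rank."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    genome_label: str
    rank: int = -1
    attributes: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class DepthTrack:
    """Fixed-window mean fold-coverage along one chromosome.

    ``values[i]`` is the length-weighted mean depth of window ``i``.  A
    trailing window shorter than ``window_size`` keeps its true length for
    weighted statistics and is flagged via ``last_partial``.
    """

    chrom: str
    window_size: int
    values: np.ndarray
    origin: str = ""
    chrom_length: int = 0
    last_partial: bool = False

    @property
    def n_windows(self) -> int:
        return len(self.values)

    def window_span(self, index: int) -> tuple[int, int]:
        """0-based half-open bp interval of window ``index``."""
        start = index * self.window_size
        return start, min(start + self.window_size, self.chrom_length)


@dataclass
class CpVariant:
    """A chloroplast-genome variant with per-sample presence calls."""

    pos: int
    ref: str
    alt: str
    vtype: str
    presence: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"
        if self.vtype != expected:
            raise ValidationError(
                f"variant at {self.pos}: vtype {self.vtype} inconsistent with "
                f"alleles {self.ref}>{self.alt}")
        if self.vtype == "indel":
            span = max(len(self.ref), len(self.alt))
            if not 2 <= span <= 50:
                raise ValidationError(
                    f"indel at {self.pos}: allele span {span} outside the "
                    f"2-50 bp calling contract")


@dataclass
class AnalysisThresholds:
    """Every numeric cutoff the pipeline consumes, with study defaults."""

    block_gap_genes: int = 20
    min_anchor_pairs: int = 4
    cscore_min: float = 0.90
    homolog_search_window_pairs: int = 5
    rescue_identity_min: float = 95.0
    rescue_coverage_min: float = 90.0
    loss_depth_max: float = 1.0
    loss_breadth_max: float = 5.0
    he_window_bp: int = 5000
    he_dup_range: tuple[float, float] = (75.0, 150.0)
    he_del_range: tuple[float, float] = (0.0, 25.0)
    mean_depth: float = 50.0
    he_link_gap_windows: int = 10
    he_min_mapped_fraction: float = 30.0
    block_link_gap_bp: int = 20000
    expr_fold_min: float = 2.0
    sv_min_len: int = 25
    repeat_read_min_aln: int = 100
    repeat_read_min_cov: float = 70.0

    def validate(self) -> None:
        for name in ("block_gap_genes", "min_anchor_pairs", "cscore_min",
                     "homolog_search_window_pairs", "rescue_identity_min",
                     "rescue_coverage_min", "loss_depth_max", "loss_breadth_max",
                     "he_window_bp", "mean_depth", "he_link_gap_windows",
                     "he_min_mapped_fraction", "block_link_gap_bp",
                     "expr_fold_min", "sv_min_len", "repeat_read_min_aln",
                     "repeat_read_min_cov"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be positive")
        dup_lo, dup_hi = self.he_dup_range
        del_lo, del_hi = self.he_del_range
        if not (del_lo < del_hi and dup_lo < dup_hi):
            raise ValidationError("depth ranges must be non-empty")
        if del_hi >= dup_lo:
            raise ValidationError("duplicated and deleted depth ranges overlap")


# ---------------------------------------------------------------------------
# GFF3 gene annotations
# ---------------------------------------------------------------------------

_ID_RE = re.compile(r"(?:^|;)ID=([^;]+)")


def load_annotation(path: str | Path, genome_label: str) -> list[GeneModel]:
    """Read gene features from a GFF3 file.

    Returns genes sorted by (chrom, start) with ``rank`` assigned by start
    position per chromosome.  Coordinates stay 1-based inclusive.  Unknown
    attributes are preserved opaquely for lossless round-tripping.
    """
    if genome_label not in GENOME_LABELS:
        raise ValidationError(f"unknown genome label {genome_label!r}")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(parts)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates") from exc
            match = _ID_RE.search(attrs)
            if match is None:
                raise ParseError(f"{path}: line {lineno}: gene feature lacks ID=")
            gene_id = match.group(1)
            if gene_id in seen:
                raise ValidationError(
                    f"{path}: line {lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            try:
                genes.append(GeneModel(gene_id, seqid, start, end, strand,
                                       genome_label, attributes=attrs))
            except ValidationError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return assign_ranks(genes)


def assign_ranks(genes: Iterable[GeneModel]) -> list[GeneModel]:
    """Sort genes by (chrom, start) and number them 0.. per chromosome."""
    ordered = sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    counters: dict[str, int] = {}
    for gene in ordered:
        gene.rank = counters.get(gene.chrom, 0)
        counters[gene.chrom] = gene.rank + 1
    return ordered


def write_annotation(genes: Sequence[GeneModel], path: str | Path) -> None:
    ordered = sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for g in ordered:
            attrs = g.attributes if g.attributes else f"ID={g.gene_id}"
            handle.write(
                f"{g.chrom}\tallokit\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")


def genes_by_id(genes: Iterable[GeneModel]) -> dict[str, GeneModel]:
    return {g.gene_id: g for g in genes}


# ---------------------------------------------------------------------------
# bedGraph depth
# ---------------------------------------------------------------------------

def load_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph file into a validated (chrom, start, end, value) frame.

    Intervals are 0-based half-open and must be non-overlapping with
    non-negative values.
    """
    rows: list[tuple[str, int, int, float]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            parts = stripped.split("\t")
            if len(parts) != 4:
                raise ParseError(
                    f"{path}: line {lineno}: expected 4 columns, got {len(parts)}")
            try:
                chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: malformed record") from exc
            if value < 0:
                raise ValidationError(f"{path}: line {lineno}: negative depth {value}")
            if start >= end:
                raise ValidationError(f"{path}: line {lineno}: empty interval")
            rows.append((chrom, start, end, value))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    for chrom, grp in df.groupby("chrom", sort=False):
        if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
            raise ValidationError(f"{path}: overlapping intervals on {chrom}")
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    ordered = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    with open(path, "w") as handle:
        for chrom, start, end, value in ordered.itertuples(index=False):
            handle.write(f"{chrom}\t{int(start)}\t{int(end)}\t{float(value)!r}\n")


def per_base_depth(df: pd.DataFrame,
                   chrom_lengths: Mapping[str, int] | None = None,
                   ) -> dict[str, np.ndarray]:
    """Expand bedGraph records into per-base depth arrays (gaps are depth 0)."""
    out: dict[str, np.ndarray] = {}
    chroms = set(df["chrom"].unique())
    if chrom_lengths:
        chroms |= set(chrom_lengths)
    for chrom in sorted(chroms):
        grp = df[df["chrom"] == chrom]
        max_end = int(grp["end"].max()) if len(grp) else 0
        length = int(chrom_lengths[chrom]) if chrom_lengths and chrom in chrom_lengths else max_end
        if max_end > length:
            raise ValidationError(
                f"records on {chrom} extend to {max_end} past declared length {length}")
        arr = np.zeros(length, dtype=float)
        for _, start, end, value in grp.itertuples(index=False):
            arr[start:end] = value
        out[chrom] = arr
    return out


def window_depth(df: pd.DataFrame, window_size: int,
                 chrom_lengths: Mapping[str, int] | None = None,
                 origin: str = "") -> dict[str, DepthTrack]:
    """Aggregate bedGraph records to fixed windows by length-weighted mean."""
    if window_size <= 0:
        raise ValidationError("window_size must be positive")
    tracks: dict[str, DepthTrack] = {}
    for chrom, arr in per_base_depth(df, chrom_lengths).items():
        length = len(arr)
        if length == 0:
            tracks[chrom] = DepthTrack(chrom, window_size, np.zeros(0), origin, 0, False)
            continue
        n_windows = -(-length // window_size)
        starts = np.arange(n_windows) * window_size
        sums = np.add.reduceat(arr, starts)
        widths = np.minimum(starts + window_size, length) - starts
        tracks[chrom] = DepthTrack(chrom, window_size, sums / widths, origin,
                                   length, length % window_size != 0)
    return tracks


def load_depth(path: str | Path, window_size: int,
               chrom_lengths: Mapping[str, int] | None = None,
               origin: str = "") -> dict[str, DepthTrack]:
    """Read a bedGraph file and aggregate it to fixed-size windows."""
    return window_depth(load_bedgraph(path), window_size, chrom_lengths, origin)


# ---------------------------------------------------------------------------
# tabular homology hits (outfmt-6 dialect)
# ---------------------------------------------------------------------------

HIT_COLUMNS = ["query_id", "subject_id", "pct_identity", "aln_length",
               "mismatches", "gap_opens", "q_start", "q_end", "s_start",
               "s_end", "evalue", "bitscore"]


def load_hits(path: str | Path, evalue_max: float = 1e-5) -> pd.DataFrame:
    """Read a 12-column tabular hit file.

    Hits are retained only if ``evalue <= evalue_max`` (mirroring the
    all-against-all alignment cutoff) and self-hits are dropped.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=HIT_COLUMNS)
    if df.shape[1] != 12:
        raise ParseError(f"{path}: expected 12 columns, got {df.shape[1]}")
    df.columns = HIT_COLUMNS
    df["query_id"] = df["query_id"].astype(str)
    df["subject_id"] = df["subject_id"].astype(str)
    if ((df["pct_identity"] < 0) | (df["pct_identity"] > 100)).any():
        raise ValidationError(f"{path}: pct_identity outside [0, 100]")
    if (df["aln_length"] < 1).any():
        raise ValidationError(f"{path}: alignment length < 1")
    if (df["evalue"] < 0).any():
        raise ValidationError(f"{path}: negative e-value")
    keep = (df["evalue"] <= evalue_max) & (df["query_id"] != df["subject_id"])
    return df[keep].reset_index(drop=True)


def write_hits(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=HIT_COLUMNS)


# ---------------------------------------------------------------------------
# chloroplast variants (minimal VCF subset via pysam)
# ---------------------------------------------------------------------------

def write_cp_vcf(variants: Sequence[CpVariant], sample: str, path: str | Path,
                 contig: str = "cp", contig_length: int = 160000) -> None:
    """Write the variants present in ``sample`` as a single-sample VCF."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={contig_length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for var in sorted(variants, key=lambda v: (v.pos, v.ref, v.alt)):
            if not var.presence.get(sample, False):
                continue
            rec = out.new_record(contig=contig, start=var.pos - 1,
                                 alleles=(var.ref, var.alt))
            rec.samples[sample]["GT"] = (1, 1)
            out.write(rec)


def read_cp_vcfs(sample_paths: Sequence[tuple[str, str | Path]]) -> list[CpVariant]:
    """Merge per-sample VCFs into CpVariant records with presence maps.

    A variant is present in a sample when that sample's file carries a
    record with a non-reference genotype (records without genotypes count
    as present).
    """
    import pysam

    order = [sample for sample, _ in sample_paths]
    presence: dict[tuple[int, str, str], dict[str, bool]] = {}
    for sample, path in sample_paths:
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                for alt in rec.alts or ():
                    called = True
                    if rec.samples:
                        called = any(
                            any(allele not in (None, 0) for allele in s.get("GT", ()))
                            for s in rec.samples.values())
                    if called:
                        presence.setdefault((rec.pos, rec.ref, alt), {})[sample] = True
    variants = []
    for (pos, ref, alt), seen in sorted(presence.items()):
        vtype = "SNP" if len(ref) == 1 and len(alt) == 1 else "indel"
        variants.append(CpVariant(pos, ref, alt, vtype,
                                  {s: seen.get(s, False) for s in order}))
    return variants


# ---------------------------------------------------------------------------
# plain TSV tables
# ---------------------------------------------------------------------------

def load_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    """Read a header-carrying TSV and check for required columns."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(required))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_bed3(path: str | Path) -> pd.DataFrame:
    """Read a headerless 3-column BED (chrom, start, end; 0-based half-open)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    if (df["start"] >= df["end"]).any():
        raise ValidationError(f"{path}: empty or inverted BED interval")
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_bed3(df: pd.DataFrame, path: str | Path) -> None:
    df.sort_values(["chrom", "start", "end"], kind="mergesort").to_csv(
        path, sep="\t", header=False, index=False,
        columns=["chrom", "start", "end"])


def load_chrom_lengths(path: str | Path) -> dict[str, int]:
    df = load_table(path, ["chrom", "length"])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))
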