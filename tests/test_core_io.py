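import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allokit.core_io import (CpVariant, ParseError, ValidationError,
                             load_annotation, load_bedgraph, load_depth,
                             load_hits, read_cp_vcfs, window_depth,
                             write_annotation, write_bedgraph, write_cp_vcf,
                             write_hits, GeneModel, HIT_COLUMNS)


# --- GFF3 annotations -------------------------------------------------------

def _write_gff(path, rows):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, start, end, gid in rows:
            fh.write(f"{chrom}\tsrc\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}\n")


def test_empty_annotation_gives_empty_collection(tmp_path):
    path = tmp_path / "empty.gff3"
    path.write_text("##gff-version 3\n")
    assert load_annotation(path, "CC") == []


def test_ranks_assigned_by_start_and_restart_per_chromosome(tmp_path):
    # interleaved chromosomes in file order; the sort-then-enumerate oracle
    # says ranks follow start position within each chromosome
    rows = [("chr2", 50, 80, "d"), ("chr1", 500, 900, "b"),
            ("chr1", 100, 200, "a"), ("chr2", 400, 600, "e")]
    path = tmp_path / "genes.gff3"
    _write_gff(path, rows)
    genes = load_annotation(path, "CC")
    ranks = {g.gene_id: (g.chrom, g.rank) for g in genes}
    assert ranks == {"a": ("chr1", 0), "b": ("chr1", 1),
                     "d": ("chr2", 0), "e": ("chr2", 1)}


def test_annotation_round_trip_identical(tmp_path):
    path = tmp_path / "genes.gff3"
    _write_gff(path, [("chr1", 100, 200, "a"), ("chr1", 500, 900, "b")])
    genes = load_annotation(path, "SubC")
    out = tmp_path / "copy.gff3"
    write_annotation(genes, out)
    again = load_annotation(out, "SubC")
    assert [(g.gene_id, g.chrom, g.start, g.end, g.strand, g.rank)
            for g in genes] == [(g.gene_id, g.chrom, g.start, g.end,
                                 g.strand, g.rank) for g in again]


def test_malformed_gff_line_errors_with_line_number(tmp_path):
    path = tmp_path / "bad.gff3"
    path.write_text("chr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=a\nchr1\tbroken\n")
    with pytest.raises(ParseError, match="line 2"):
        load_annotation(path, "CC")


def test_duplicate_gene_id_rejected(tmp_path):
    path = tmp_path / "dup.gff3"
    _write_gff(path, [("chr1", 1, 10, "a"), ("chr1", 20, 30, "a")])
    with pytest.raises(ValidationError, match="duplicate"):
        load_annotation(path, "CC")


# --- bedGraph depth ---------------------------------------------------------

def test_single_full_window(tmp_path):
    path = tmp_path / "d.bedgraph"
    path.write_text("chr1\t0\t5000\t50\n")
    tracks = load_depth(path, 5000)
    assert tracks["chr1"].values.tolist() == [50.0]


def test_length_weighted_window_mean(tmp_path):
    path = tmp_path / "d.bedgraph"
    path.write_text("chr1\t0\t2500\t100\nchr1\t2500\t5000\t0\n")
    tracks = load_depth(path, 5000)
    assert tracks["chr1"].values.tolist() == [50.0]


def test_gap_means_zero_depth(tmp_path):
    path = tmp_path / "d.bedgraph"
    path.write_text("")
    tracks = load_depth(path, 5000, chrom_lengths={"chr1": 10000})
    assert tracks["chr1"].values.tolist() == [0.0, 0.0]
    assert not tracks["chr1"].last_partial


def test_overlapping_and_negative_records_rejected(tmp_path):
    overlap = tmp_path / "o.bedgraph"
    overlap.write_text("chr1\t0\t100\t5\nchr1\t50\t150\t5\n")
    with pytest.raises(ValidationError, match="overlap"):
        load_bedgraph(overlap)
    neg = tmp_path / "n.bedgraph"
    neg.write_text("chr1\t0\t100\t-3\n")
    with pytest.raises(ValidationError, match="negative"):
        load_bedgraph(neg)


def test_trailing_partial_window_flagged(tmp_path):
    path = tmp_path / "d.bedgraph"
    path.write_text("chr1\t0\t7500\t10\n")
    tracks = load_depth(path, 5000)
    track = tracks["chr1"]
    assert track.last_partial and track.n_windows == 2
    assert track.values.tolist() == [10.0, 10.0]


@settings(max_examples=40, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 50), st.integers(1, 30),
                          st.floats(0, 100, allow_nan=False)),
                min_size=0, max_size=12),
       st.integers(2, 17))
def test_window_aggregation_conserves_coverage_mass(intervals, window):
    # lay intervals end to end so they never overlap
    rows, pos = [], 0
    for gap, span, value in intervals:
        pos += gap
        rows.append(("chr1", pos, pos + span, value))
        pos += span
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    tracks = window_depth(df, window, chrom_lengths={"chr1": max(pos, 1)})
    track = tracks["chr1"]
    widths = [track.window_span(i)[1] - track.window_span(i)[0]
              for i in range(track.n_windows)]
    mass = float(np.dot(track.values, widths))
    expected = sum((e - s) * v for _, s, e, v in rows)
    assert mass == pytest.approx(expected, rel=1e-6, abs=1e-6)


def test_bedgraph_round_trip_identical(tmp_path):
    df = pd.DataFrame([("chr1", 0, 150, 47 / 150), ("chr1", 150, 300, 0.5)],
                      columns=["chrom", "start", "end", "value"])
    path = tmp_path / "rt.bedgraph"
    write_bedgraph(df, path)
    again = load_bedgraph(path)
    pd.testing.assert_frame_equal(df, again)


# --- homology hits ----------------------------------------------------------

def test_hit_filtering(tmp_path):
    rows = [
        ("g1", "h1", 95.0, 300, 10, 0, 1, 300, 1, 300, 1e-20, 500.0),
        ("g1", "g1", 100.0, 300, 0, 0, 1, 300, 1, 300, 0.0, 600.0),  # self
        ("g2", "h2", 90.0, 200, 20, 0, 1, 200, 1, 200, 1e-3, 80.0),  # weak
    ]
    path = tmp_path / "hits.tsv"
    write_hits(pd.DataFrame(rows, columns=HIT_COLUMNS), path)
    hits = load_hits(path)
    assert hits["query_id"].tolist() == ["g1"]
    assert hits["subject_id"].tolist() == ["h1"]
    assert hits["bitscore"].tolist() == [500.0]


def test_hit_wrong_column_count(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("g1\th1\t90\n")
    with pytest.raises(ParseError, match="12 columns"):
        load_hits(path)


# --- cp variant VCFs --------------------------------------------------------

def test_cp_vcf_round_trip_presence(tmp_path):
    variants = [
        CpVariant(100, "A", "T", "SNP", {"F1": True, "S0": True}),
        CpVariant(500, "G", "GAT", "indel", {"F1": False, "S0": True}),
    ]
    paths = []
    for sample in ("F1", "S0"):
        path = tmp_path / f"{sample}.vcf"
        write_cp_vcf(variants, sample, path, contig="cp", contig_length=1000)
        paths.append((sample, path))
    merged = read_cp_vcfs(paths)
    assert [(v.pos, v.ref, v.alt, v.vtype, v.presence) for v in merged] == [
        (100, "A", "T", "SNP", {"F1": True, "S0": True}),
        (500, "G", "GAT", "indel", {"F1": False, "S0": True})]


def test_cp_variant_type_contract():
    with pytest.raises(ValidationError):
        CpVariant(1, "A", "T", "indel", {})
    with pytest.raises(ValidationError):
        CpVariant(1, "A", "A" + "T" * 60, "indel", {})  # > 50 bp span


def test_gene_model_invariants():
    with pytest.raises(ValidationError):
        GeneModel("g", "chr1", 10, 5, "+", "CC")
    with pytest.raises(ValidationError):
        GeneModel("g", "chr1", 1, 5, "?", "CC")
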