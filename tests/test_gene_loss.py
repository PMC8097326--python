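import numpy as np
import pandas as pd
import pytest

from allokit.core_io import AnalysisThresholds, GeneModel, HIT_COLUMNS, assign_ranks
from allokit.gene_loss import (GeneCoverage, LossRecord, attribute_loss_events,
                               build_presence_matrix,
                               classify_partial_or_pseudogene,
                               exclude_genotype_differences,
                               find_potential_losses, gene_coverage,
                               rescue_misannotation, validate_loss_by_depth)
from allokit.core_io import ValidationError
from allokit.synteny import chain_hits, call_ortholog_pairs, screen_one_to_one

TH = AnalysisThresholds()


def build_toy(n=9, missing=(5,)):
    """n ancestral genes; derived genome lacks the ``missing`` ranks."""
    genes_a = assign_ranks([
        GeneModel(f"a{i}", "cA", 1000 * (i + 1), 1000 * (i + 1) + 500, "+", "CC")
        for i in range(n)])
    genes_b = assign_ranks([
        GeneModel(f"b{i}", "cB", 1000 * (i + 1), 1000 * (i + 1) + 500, "+", "SubC")
        for i in range(n) if i not in missing])
    rows = [(f"a{i}", f"b{i}", 95.0, 300, 5, 0, 1, 300, 1, 300, 1e-30, 500.0)
            for i in range(n) if i not in missing]
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    screened = screen_one_to_one(hits, TH.cscore_min)
    blocks = chain_hits(screened, genes_a, genes_b, TH)
    pairs = call_ortholog_pairs(blocks)
    return genes_a, genes_b, blocks, pairs, hits


def test_unpaired_gene_inside_block_is_potential_loss():
    genes_a, genes_b, blocks, pairs, hits = build_toy()
    records = {r.gene_id: r for r in find_potential_losses(
        blocks, pairs, genes_a, genes_b, hits, TH)}
    assert records["a5"].state == "potential_loss"
    assert records["a5"].in_block
    # window spans the derived neighbors of the missing gene
    assert records["a5"].window_chrom == "cB"
    assert all(records[f"a{i}"].state == "retained" for i in range(9) if i != 5)


def test_fully_anchored_genome_has_no_potential_losses():
    genes_a, genes_b, blocks, pairs, hits = build_toy(missing=())
    records = find_potential_losses(blocks, pairs, genes_a, genes_b, hits, TH)
    assert all(r.state == "retained" for r in records)


def test_gene_with_homolog_in_window_is_retained():
    # the derived homolog exists inside the window even though unpaired
    genes_a, genes_b, blocks, pairs, hits = build_toy()
    extra = pd.DataFrame(
        [("a5", "b4", 95.0, 300, 5, 0, 1, 300, 1, 300, 1e-30, 100.0)],
        columns=HIT_COLUMNS)
    records = {r.gene_id: r for r in find_potential_losses(
        blocks, pairs, genes_a, genes_b, pd.concat([hits, extra]), TH)}
    assert records["a5"].state == "retained"


def test_gene_on_blockless_chromosome_is_out_of_block_loss():
    genes_a, genes_b, blocks, pairs, hits = build_toy()
    orphan = GeneModel("a_orphan", "cX", 100, 700, "+", "CC")
    records = {r.gene_id: r for r in find_potential_losses(
        blocks, pairs, assign_ranks(genes_a + [orphan]), genes_b, hits, TH)}
    assert records["a_orphan"].state == "potential_loss"
    assert not records["a_orphan"].in_block
    assert records["a_orphan"].window_chrom is None


# --- rescue -----------------------------------------------------------------

def rescue_row(**kw):
    row = dict(lost_gene_id="a5", predicted_gene_id="p1", pct_identity=96.0,
               query_cov_pct=92.0, subject_cov_pct=95.0, chrom="cB",
               start=5500, end=6200)
    row.update(kw)
    return pd.DataFrame([row])


def candidate(window=("cB", 2000, 11500)):
    rec = LossRecord("a5", "CC", state="potential_loss")
    if window:
        rec.window_chrom, rec.window_start, rec.window_end = window
    return rec


@pytest.mark.parametrize("override, rescued", [
    ({}, True),                                 # 96% id, both covs >= 90
    ({"pct_identity": 90.0}, False),            # identity below 95
    ({"query_cov_pct": 85.0}, False),           # query coverage below 90
    ({"chrom": "cZ"}, False),                   # outside the anchor window
])
def test_rescue_rule(override, rescued):
    rec = rescue_misannotation([candidate()], rescue_row(**override), TH)[0]
    assert (rec.state == "rescued_misannotation") == rescued


def test_rescue_without_candidates_is_noop():
    rec = rescue_misannotation([candidate()], None, TH)[0]
    assert rec.state == "potential_loss"


# --- partial / pseudogene ---------------------------------------------------

def report(gene="a5", has_region=True, has_start=True, has_stop=True,
           frameshift=False):
    return pd.DataFrame([{"gene_id": gene, "has_region": has_region,
                          "has_start": has_start, "has_stop": has_stop,
                          "frameshift": frameshift}])


@pytest.mark.parametrize("kw, state", [
    (dict(has_start=False), "partial_loss"),
    (dict(has_stop=False), "partial_loss"),
    (dict(frameshift=True), "pseudogene"),
    (dict(has_region=False), "dna_loss_candidate"),
    (dict(), "dna_loss_candidate"),  # intact region falls through to DNA loss
])
def test_partial_pseudogene_classification(kw, state):
    rec = classify_partial_or_pseudogene([candidate()], report(**kw))[0]
    assert rec.state == state


def test_missing_cds_report_is_an_error():
    with pytest.raises(ValidationError, match="missing"):
        classify_partial_or_pseudogene([candidate()], report(gene="other"))


# --- coverage ---------------------------------------------------------------

def depth_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def test_gene_coverage_uniform_zero_and_split():
    gene = GeneModel("g", "chr1", 101, 200, "+", "CC")  # 100 bp body
    full = gene_coverage([gene], depth_df([("chr1", 0, 300, 50.0)]))
    assert (full["g"].depth_fold, full["g"].breadth_pct) == (50.0, 100.0)
    empty = gene_coverage([gene], depth_df([]), {"chr1": 300})
    assert (empty["g"].depth_fold, empty["g"].breadth_pct) == (0.0, 0.0)
    half = gene_coverage([gene], depth_df([("chr1", 100, 150, 2.0)]),
                         {"chr1": 300})
    assert (half["g"].depth_fold, half["g"].breadth_pct) == (1.0, 50.0)


def test_gene_outside_track_bounds_is_an_error():
    gene = GeneModel("g", "chr2", 1, 100, "+", "CC")
    with pytest.raises(ValidationError, match="outside"):
        gene_coverage([gene], depth_df([("chr1", 0, 300, 50.0)]))


# --- depth confirmation with strict boundaries ------------------------------

def dna_candidate():
    rec = LossRecord("a5", "CC", state="dna_loss_candidate")
    return rec


@pytest.mark.parametrize("depth, breadth, state", [
    (0.5, 2.0, "confirmed_loss"),
    (50.0, 100.0, "retained"),
    (0.8, 10.0, "retained"),      # breadth fails the AND rule
    (1.0, 2.0, "retained"),       # exactly 1.0x is NOT < 1x
    (0.5, 5.0, "retained"),       # exactly 5% is NOT < 5%
    (0.999, 4.999, "confirmed_loss"),
])
def test_depth_confirmation_boundaries(depth, breadth, state):
    cov = {"a5": GeneCoverage("a5", depth, breadth)}
    assert validate_loss_by_depth([dna_candidate()], cov, TH)[0].state == state


def test_genotype_difference_exclusion():
    confirmed = LossRecord("a5", "CC", state="confirmed_loss")
    present_in_parent = {"a5": GeneCoverage("a5", 50.0, 100.0)}
    absent_in_parent = {"a5": GeneCoverage("a5", 0.0, 0.0)}
    assert exclude_genotype_differences(
        [confirmed], present_in_parent, TH)[0].state == "confirmed_loss"
    confirmed = LossRecord("a5", "CC", state="confirmed_loss")
    assert exclude_genotype_differences(
        [confirmed], absent_in_parent, TH)[0].state == "genotype_difference"
    confirmed = LossRecord("a5", "CC", state="confirmed_loss")
    assert exclude_genotype_differences(
        [confirmed], None, TH)[0].state == "confirmed_loss"


# --- presence matrix and attribution ----------------------------------------

GENS = ["F1", "S0", "S4", "S5", "S6"]


def coverage_series(pattern):
    """pattern: present flags per generation for one gene 'g'."""
    return {gen: {"g": GeneCoverage("g", 50.0 if flag else 0.0,
                                    100.0 if flag else 0.0)}
            for gen, flag in zip(GENS, pattern)}


@pytest.mark.parametrize("pattern, row", [
    ([1, 1, 1, 1, 1], [True] * 5),
    ([0, 0, 0, 0, 0], [False] * 5),
    ([0, 1, 0, 0, 0], [False, True, False, False, False]),
])
def test_presence_matrix_rows(pattern, row):
    matrix = build_presence_matrix(["g"], coverage_series(pattern), GENS, TH)
    assert matrix.loc["g"].tolist() == row


def test_presence_matrix_omits_missing_generation():
    cov = coverage_series([1, 1, 1, 1, 1])
    del cov["S4"]
    matrix = build_presence_matrix(["g"], cov, GENS, TH)
    assert list(matrix.columns) == ["F1", "S0", "S5", "S6"]


def matrix(rows):
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                        columns=GENS, dtype=bool)


def test_attribution_rules():
    m = matrix([
        [0, 0, 0, 0, 0],   # absent from F1 onward -> hybridization
        [0, 1, 1, 1, 1],   # absent in F1, back at S0 -> restored
        [1, 0, 0, 0, 0],   # lost with duplication
        [1, 1, 1, 0, 0],   # first absent at S5 -> diploidization(S5)
        [1, 1, 1, 1, 1],   # never absent
        [1, 1, 0, 1, 0],   # sporadic: first absence S4, flagged unstable
    ])
    result, counts = attribute_loss_events(m)
    assert result.loc["g0", "attribution"] == "hybridization"
    assert not result.loc["g0", "restored"]
    assert result.loc["g1", "attribution"] == "hybridization"
    assert result.loc["g1", "restored"]
    assert result.loc["g2", "attribution"] == "duplication"
    assert result.loc["g3", "attribution"] == "diploidization(S5)"
    assert result.loc["g4", "attribution"] == "none"
    assert result.loc["g5", "attribution"] == "diploidization(S4)"
    assert result.loc["g5", "unstable"]
    # stage counts conserve the number of ever-absent genes
    assert sum(counts.values()) == 5


def test_attribution_of_empty_matrix():
    result, counts = attribute_loss_events(matrix([]))
    assert result.empty and counts == {}
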