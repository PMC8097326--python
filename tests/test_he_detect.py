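import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allokit.core_io import (AnalysisThresholds, DepthTrack, GeneModel,
                             HIT_COLUMNS, assign_ranks)
from allokit.he_detect import (DepthSegment, WindowLabel, call_candidate_he,
                               classify_depth_windows, confirm_he,
                               link_windows)
from allokit.synteny import chain_hits, screen_one_to_one

from .oracles import link_runs_bruteforce

TH = AnalysisThresholds()


def track(values, window=5000, partial=False):
    length = window * len(values) - (window // 2 if partial else 0)
    return DepthTrack("Chc01", window, np.asarray(values, dtype=float),
                      "S14", length, partial)


# --- window classification --------------------------------------------------

@pytest.mark.parametrize("depth, label", [
    (100.0, "duplicated"),
    (50.0, "normal"),
    (10.0, "deleted"),
    (75.0, "duplicated"),   # band endpoints are inclusive
    (150.0, "duplicated"),
    (25.0, "deleted"),
    (0.0, "deleted"),
    (150.1, "outlier"),
    (25.1, "normal"),
    (74.9, "normal"),
])
def test_depth_band_classification(depth, label):
    labels = classify_depth_windows(track([depth]), TH)
    assert labels[0].label == label


def test_trailing_partial_window_excluded():
    labels = classify_depth_windows(track([100.0, 100.0], partial=True), TH)
    assert [l.label for l in labels] == ["duplicated", "partial"]
    assert link_windows(labels, "duplicated", thresholds=TH)[0].end_window == 0


def test_band_scaling_follows_observed_mean():
    # at a 100x sample mean the duplicated band doubles to 150-300
    labels = classify_depth_windows(track([200.0]), TH, observed_mean=100.0)
    assert labels[0].label == "duplicated"


# --- window linking ---------------------------------------------------------

def labels_at(indices, kind="duplicated", n=40):
    out = []
    for i in range(n):
        label = kind if i in indices else "normal"
        out.append(WindowLabel("Chc01", i, 100.0 if label == kind else 50.0,
                               label))
    return out


def test_gap_of_four_windows_links_into_one_segment():
    segments = link_windows(labels_at({1, 2, 3, 8, 9, 10}), "duplicated",
                            thresholds=TH)
    assert [(s.start_window, s.end_window) for s in segments] == [(1, 10)]


def test_gap_beyond_ten_windows_splits_segments():
    segments = link_windows(labels_at({1, 2, 3, 15, 16, 17}), "duplicated",
                            thresholds=TH)
    assert [(s.start_window, s.end_window) for s in segments] == [(1, 3), (15, 17)]


def test_no_labeled_windows_no_segments():
    assert link_windows(labels_at(set()), "duplicated", thresholds=TH) == []


@settings(max_examples=50, deadline=None)
@given(st.sets(st.integers(0, 60)), st.integers(0, 12))
def test_linking_matches_run_merge_enumeration_and_is_idempotent(idx, gap):
    labels = labels_at(idx, n=61)
    segments = link_windows(labels, "duplicated", max_gap=gap)
    spans = [(s.start_window, s.end_window) for s in segments]
    assert spans == link_runs_bruteforce(sorted(idx), gap)
    # idempotence: relinking the segment windows changes nothing
    relabeled = labels_at({i for lo, hi in spans for i in range(lo, hi + 1)
                           if i in idx}, n=61)
    again = link_windows(relabeled, "duplicated", max_gap=gap)
    assert [(s.start_window, s.end_window) for s in again] == spans


# --- mapped-fraction gating -------------------------------------------------

@pytest.mark.parametrize("fraction, accepted", [
    (80.0, True),
    (10.0, False),
    (30.0, False),   # strict > 30
    (30.01, True),
])
def test_candidate_gating_on_mapped_fraction(fraction, accepted):
    seg = DepthSegment("Chc01", 2, 4, "duplicated", 100.0)
    mapfrac = {("Chc01", i): fraction for i in range(2, 5)}
    assert call_candidate_he(seg, mapfrac, TH) is accepted


def test_segment_without_mapfrac_data_skipped():
    seg = DepthSegment("Chc01", 2, 4, "duplicated", 100.0)
    assert call_candidate_he(seg, {}, TH) is None


# --- false candidates under uniform coverage --------------------------------

def test_uniform_poisson_coverage_yields_no_candidate_segments():
    """2000 windows of 5 kb at a 50x mean: the Poisson window-mean spread
    (sd ~ 0.1x) never reaches the 25x/75x class edges."""
    rng = np.random.default_rng(0)
    for _ in range(5):
        values = rng.poisson(50.0 * 5000, size=2000) / 5000
        labels = classify_depth_windows(track(list(values)), TH)
        n_bad = sum(1 for l in labels if l.label != "normal")
        assert n_bad <= 1


# --- confirmation through blocks --------------------------------------------

def toy_confirmation(block_gap_bp=0, identity=True):
    """20 homeolog anchors; windows 8-13 on SubC duplicated, same span on
    SubH deleted.  Optionally split the block in two parts ~15 kb apart."""
    genes_c = assign_ranks([
        GeneModel(f"c{i}", "Chc01", 4000 * i + 1000, 4000 * i + 3000, "+", "SubC")
        for i in range(20)])
    genes_h = assign_ranks([
        GeneModel(f"h{i}", "Chh01", 4000 * i + 1000, 4000 * i + 3000, "+", "SubH")
        for i in range(20)])
    hits = pd.DataFrame(
        [(f"c{i}", f"h{i}", 94.0, 300, 5, 0, 1, 300, 1, 300, 1e-30, 500.0)
         for i in range(20)], columns=HIT_COLUMNS)
    blocks = chain_hits(screen_one_to_one(hits, 0.9), genes_c, genes_h, TH)
    dup = DepthSegment("Chc01", 8, 13, "duplicated", 100.0)
    dele = DepthSegment("Chh01", 8, 13, "deleted", 0.5)
    identity_df = pd.DataFrame([{
        "chrom_c": "Chc01", "start_c": 40000, "end_c": 70000,
        "chrom_h": "Chh01", "start_h": 40000, "end_h": 70000,
        "pct_identity": 99.0}]) if identity else pd.DataFrame(
            columns=["chrom_c", "start_c", "end_c", "chrom_h", "start_h",
                     "end_h", "pct_identity"])
    return blocks, dup, dele, identity_df


def test_reciprocal_segments_confirm_with_direction():
    blocks, dup, dele, identity = toy_confirmation()
    calls = confirm_he({"SubC": [dup]}, {"SubH": [dele]}, blocks,
                       *_toy_genes(), identity, TH)
    assert len(calls) == 1
    call = calls[0]
    assert call.confirmed
    assert call.direction == "CC_to_HH"  # deletion on SubH: CC replaced HH
    assert call.identity_pct == 99.0


def test_duplication_without_homologous_deletion_is_unresolved():
    blocks, dup, _, identity = toy_confirmation()
    calls = confirm_he({"SubC": [dup]}, {"SubH": []}, blocks,
                       *_toy_genes(), identity, TH)
    assert calls[0].direction == "unresolved"
    assert not calls[0].confirmed


def test_missing_identity_row_leaves_call_unconfirmed():
    blocks, dup, dele, identity = toy_confirmation(identity=False)
    calls = confirm_he({"SubC": [dup]}, {"SubH": [dele]}, blocks,
                       *_toy_genes(), identity, TH)
    assert calls[0].direction == "CC_to_HH"
    assert not calls[0].confirmed


def _two_part_blocks(gap_bp):
    """Two four-anchor blocks on the same chromosome pair, ``gap_bp`` apart."""
    from allokit.synteny import AnchorPair, SyntenyBlock

    genes_c, genes_h = [], []
    blocks = []
    offset = 1000
    for part in range(2):
        anchors = []
        for i in range(4):
            idx = part * 4 + i
            start = offset + 3000 * i
            genes_c.append(GeneModel(f"c{idx}", "Chc01", start, start + 2000,
                                     "+", "SubC"))
            genes_h.append(GeneModel(f"h{idx}", "Chh01", start, start + 2000,
                                     "+", "SubH"))
            anchors.append(AnchorPair(f"c{idx}", f"h{idx}", idx, idx, 500.0))
        blocks.append(SyntenyBlock(f"b{part}", "Chc01", "Chh01", anchors))
        offset += 3000 * 3 + 2000 + gap_bp
    return blocks, assign_ranks(genes_c), assign_ranks(genes_h)


@pytest.mark.parametrize("gap_bp, n_merged", [(15000, 1), (25000, 2)])
def test_blocks_within_20kb_are_linked(gap_bp, n_merged):
    from allokit.he_detect import link_blocks

    blocks, genes_c, genes_h = _two_part_blocks(gap_bp)
    merged = link_blocks(blocks, genes_c, genes_h, TH.block_link_gap_bp)
    assert len(merged) == n_merged
    if n_merged == 1:
        assert len(merged[0].anchors) == 8


def _toy_genes():
    genes_c = assign_ranks([
        GeneModel(f"c{i}", "Chc01", 4000 * i + 1000, 4000 * i + 3000, "+", "SubC")
        for i in range(20)])
    genes_h = assign_ranks([
        GeneModel(f"h{i}", "Chh01", 4000 * i + 1000, 4000 * i + 3000, "+", "SubH")
        for i in range(20)])
    return genes_c, genes_h


def test_recovered_directions_reflect_cc_biased_conversion(pipeline_results):
    """With a CC-biased conversion mix, more SubH regions are replaced."""
    results, truth = pipeline_results
    directions = [c.direction for c in results["he_calls"] if c.confirmed]
    assert directions.count("CC_to_HH") > directions.count("HH_to_CC")
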