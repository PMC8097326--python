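"""Homeolog expression-bias classification and genome-wide dominance summary.

Each syntenic homeolog pair (one copy on SubC, one on SubH) is classified
by a twofold rule on pseudocounted normalized expression; the genome-wide
summary counts classes, bins log2 expression of the dominant copies and
compares the two dominant sets with a two-sided rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AnalysisThresholds, ValidationError

BIAS_CLASSES = ("C_dominant", "H_dominant", "neutral", "not_expressed")


@dataclass
class HomeologExpression:
    pair_id: str
    gene_c: str
    gene_h: str
    expr_c: float
    expr_h: float
    bias_class: str = "neutral"


@dataclass
class DominanceSummary:
    counts: dict[str, int]
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]
    statistic: float | None
    p_value: float | None


def classify_homeolog_pair(expr_c: float, expr_h: float,
                           fold_min: float = 2.0,
                           pseudocount: float = 1.0,
                           expression_floor: float = 1.0) -> str:
    """Classify one homeolog pair by the fold rule.

    Pairs in which both copies fall below the expression floor are
    ``not_expressed``.  Otherwise the pseudocounted ratio decides:
    >= fold_min is C-dominant, <= 1/fold_min is H-dominant (exactly
    ``fold_min``-fold counts as biased), anything between is neutral.
    """
    if expr_c < 0 or expr_h < 0:
        raise ValidationError("negative expression value")
    if expr_c < expression_floor and expr_h < expression_floor:
        return "not_expressed"
    ratio = (expr_c + pseudocount) / (expr_h + pseudocount)
    if ratio >= fold_min:
        return "C_dominant"
    if ratio <= 1.0 / fold_min:
        return "H_dominant"
    return "neutral"


def classify_pairs(expression: pd.DataFrame,
                   thresholds: AnalysisThresholds | None = None,
                   pseudocount: float = 1.0,
                   expression_floor: float = 1.0) -> list[HomeologExpression]:
    """Classify a (pair_id, gene_c, gene_h, expr_c, expr_h) table."""
    thresholds = thresholds or AnalysisThresholds()
    out = []
    for row in expression.itertuples():
        cls = classify_homeolog_pair(float(row.expr_c), float(row.expr_h),
                                     thresholds.expr_fold_min, pseudocount,
                                     expression_floor)
        out.append(HomeologExpression(str(row.pair_id), str(row.gene_c),
                                      str(row.gene_h), float(row.expr_c),
                                      float(row.expr_h), cls))
    return out


def summarize_dominance(pairs: Sequence[HomeologExpression],
                        bins: np.ndarray | None = None) -> DominanceSummary:
    """Count classes, bin dominant-copy expression, and rank-test dominance.

    The histograms give log2(expr+1) of the dominant copy for C- and
    H-dominant pairs.  The two dominant sets are compared with a two-sided
    Wilcoxon rank-sum (Mann-Whitney) test; the test is skipped (None) when
    either class is empty.  Class counts always conserve the total.
    """
    if bins is None:
        bins = np.arange(0.0, 16.5, 0.5)
    counts = {cls: 0 for cls in BIAS_CLASSES}
    dominant = {"C_dominant": [], "H_dominant": []}
    for pair in pairs:
        counts[pair.bias_class] += 1
        if pair.bias_class == "C_dominant":
            dominant["C_dominant"].append(pair.expr_c)
        elif pair.bias_class == "H_dominant":
            dominant["H_dominant"].append(pair.expr_h)
    histograms = {
        cls: np.histogram(np.log2(np.asarray(vals, dtype=float) + 1.0), bins=bins)
        for cls, vals in dominant.items()}
    statistic = p_value = None
    if dominant["C_dominant"] and dominant["H_dominant"]:
        res = stats.mannwhitneyu(dominant["C_dominant"], dominant["H_dominant"],
                                 alternative="two-sided")
        statistic, p_value = float(res.statistic), float(res.pvalue)
    return DominanceSummary(counts, histograms, statistic, p_value)
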