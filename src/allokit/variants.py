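"""Generation-wise partition of chloroplast variants and SV filtering.

The chloroplast genome is maternally inherited, so cp variants relative to
the maternal parent time-stamp genomic change along the generation series:
a variant first seen in the F1 homoploid hybrid reflects hybridization,
first seen in S0 genome duplication, and first seen in a later selfed
generation ongoing diploidization.  Structural variants pass a size filter
(>25 bp), require soft-clip read support, and are discarded as genotype
differences when the actual parent line's reads also support them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .core_io import AnalysisThresholds, CpVariant, ValidationError

SV_VERDICTS = ("too_small", "unverified", "genotype_difference", "true_sv")


@dataclass
class StagePartition:
    """Stage-wise variant counts; anomalous variants bucket separately."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    anomalous: dict[str, int] = field(default_factory=dict)
    fraction_f1: dict[str, float] = field(default_factory=dict)
    assignments: pd.DataFrame | None = None

    def total(self, vtype: str) -> int:
        return sum(self.counts.get(vtype, {}).values()) + self.anomalous.get(vtype, 0)


def _stage_label(sample: str) -> str:
    if sample == "F1":
        return "hybridization"
    if sample == "S0":
        return "duplication"
    return f"diploidization({sample})"


def partition_by_first_appearance(variants: Sequence[CpVariant],
                                  sample_order: Sequence[str],
                                  ) -> StagePartition:
    """Assign each variant the stage of its first presence.

    Variants that disappear after first appearing and then return are
    flagged anomalous (individual differences within a generation) and
    counted in their own bucket so that stage counts + anomalous equal the
    total per variant type.  ``fraction_f1`` is the percent of variants of
    each type first present in F1.
    """
    rows = []
    partition = StagePartition()
    for var in variants:
        present = [bool(var.presence.get(s, False)) for s in sample_order]
        if not any(present):
            raise ValidationError(
                f"variant at {var.pos} absent from every sample")
        first = present.index(True)
        anomalous = False
        seen_absent = False
        for flag in present[first:]:
            if not flag:
                seen_absent = True
            elif seen_absent:
                anomalous = True
                break
        stage = _stage_label(sample_order[first])
        rows.append((var.pos, var.ref, var.alt, var.vtype, stage, anomalous))
        if anomalous:
            partition.anomalous[var.vtype] = partition.anomalous.get(var.vtype, 0) + 1
        else:
            by_type = partition.counts.setdefault(var.vtype, {})
            by_type[stage] = by_type.get(stage, 0) + 1
    df = pd.DataFrame(rows, columns=["pos", "ref", "alt", "vtype", "stage",
                                     "anomalous"])
    partition.assignments = df
    for vtype, grp in df.groupby("vtype"):
        n_f1 = int((grp["stage"] == "hybridization").sum())
        partition.fraction_f1[vtype] = 100.0 * n_f1 / len(grp)
    return partition


def filter_true_svs(candidates: pd.DataFrame,
                    thresholds: AnalysisThresholds | None = None,
                    ) -> pd.DataFrame:
    """Apply the SV decision rules in order and add a ``verdict`` column.

    Length <= 25 bp -> too_small; no soft-clip breakpoint support ->
    unverified; supported by actual-parent-line reads ->
    genotype_difference; everything else is a true SV accumulated after
    the allopolyploidization event.
    """
    thresholds = thresholds or AnalysisThresholds()
    verdicts = []
    for row in candidates.itertuples():
        if int(row.length) <= thresholds.sv_min_len:
            verdicts.append("too_small")
        elif not bool(row.softclip_support):
            verdicts.append("unverified")
        elif bool(row.parental_support):
            verdicts.append("genotype_difference")
        else:
            verdicts.append("true_sv")
    out = candidates.copy()
    out["verdict"] = verdicts
    return out
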