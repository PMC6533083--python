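"""Deterministic calculators for the bench assays around the pipeline.

Covers double-delta-Ct relative expression, ChIP-qPCR percent input and
fold enrichment over a negative-control locus, the promoter/intron
enrichment ratio, and caliper tumor volumes with per-animal relative change.
Amplification efficiency is fixed at 2.0 per cycle (no efficiency
correction); replicate Ct values are averaged arithmetically on the Ct
scale before any delta is taken.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import ChipQpcrTable, QpcrTable, TumorMeasurement


def relative_expression(qpcr: QpcrTable, control_condition: str) -> pd.DataFrame:
    """Fold change per (condition, target) by the 2^(-ddCt) method.

    dCt = mean Ct(target) - mean Ct(reference) within a condition;
    ddCt = dCt(condition) - dCt(control); fold = 2^(-ddCt). The control
    condition's fold is exactly 1 by construction.
    """
    mean_ct: dict[tuple[str, str], float] = {}
    ref_of: dict[tuple[str, str], str] = {}
    for r in qpcr.records:
        mean_ct[(r.condition, r.target)] = r.mean_ct
        ref_of[(r.condition, r.target)] = r.reference
    if control_condition not in {c for c, _ in mean_ct}:
        raise ValueError(f"control condition {control_condition!r} absent")

    def delta_ct(condition: str, target: str) -> float:
        ref = ref_of[(condition, target)]
        if (condition, target) not in mean_ct:
            raise ValueError(f"no record for target {target!r} in {condition!r}")
        if (condition, ref) not in mean_ct:
            raise ValueError(
                f"no reference-gene ({ref!r}) record in condition {condition!r}"
            )
        return mean_ct[(condition, target)] - mean_ct[(condition, ref)]

    rows = []
    for condition, target in sorted(mean_ct):
        ref = ref_of[(condition, target)]
        if target == ref:
            continue
        if (control_condition, target) not in mean_ct:
            raise ValueError(
                f"target {target!r} has no control-condition record"
            )
        ddct = delta_ct(condition, target) - delta_ct(control_condition, target)
        rows.append((condition, target, float(2.0 ** (-ddct))))
    return pd.DataFrame(rows, columns=["condition", "target", "fold"])


def percent_input(chip: ChipQpcrTable) -> pd.DataFrame:
    """ChIP recovery as percent of (dilution-adjusted) input chromatin.

    The input Ct is first adjusted for the fraction of chromatin it was
    measured on: adjusted Ct = Ct_input - log2(1 / input_fraction). Then
    percent input = 100 * 2^(adjusted Ct - Ct_IP).
    """
    rows = []
    for r in chip.records:
        adj = r.ct_input - np.log2(1.0 / r.input_fraction)
        rows.append((r.locus, float(100.0 * 2.0 ** (adj - r.ct_ip))))
    return pd.DataFrame(rows, columns=["locus", "percent_input"])


def fold_enrichment(chip: ChipQpcrTable, negative_locus: str) -> pd.DataFrame:
    """Percent input at each locus relative to a negative-control locus."""
    pi = percent_input(chip).set_index("locus")["percent_input"]
    if negative_locus not in pi.index:
        raise ValueError(f"negative-control locus {negative_locus!r} absent")
    ref = pi[negative_locus]
    if ref == 0:
        raise ValueError("zero percent input at the negative-control locus")
    out = (pi / ref).rename("fold_over_negative").reset_index()
    return out


def region_ratio(
    enrichment: pd.DataFrame,
    promoter_loci: Sequence[str],
    intron_loci: Sequence[str],
) -> float:
    """Mean enrichment over promoter loci divided by mean over intron loci."""
    if not len(promoter_loci) or not len(intron_loci):
        raise ValueError("both region lists must be non-empty")
    table = enrichment.set_index("locus")["fold_over_negative"]
    for locus in [*promoter_loci, *intron_loci]:
        if locus not in table.index:
            raise ValueError(f"locus {locus!r} absent from enrichment table")
    intron_mean = float(table[list(intron_loci)].mean())
    if intron_mean == 0:
        raise ValueError("zero mean enrichment over intron loci")
    return float(table[list(promoter_loci)].mean()) / intron_mean


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumor volume V = L * W^2 * 0.52 (mm^3), with L >= W enforced."""
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("measurements must be positive")
    L, W = max(length_mm, width_mm), min(length_mm, width_mm)
    return L * W * W * 0.52


def relative_volume_change(
    measurements: Iterable[TumorMeasurement],
) -> pd.DataFrame:
    """Per-animal ratio of final to initial tumor volume.

    Measurements are sorted by day within each animal; every animal needs
    at least two timepoints.
    """
    by_animal: dict[str, list[TumorMeasurement]] = {}
    for m in measurements:
        by_animal.setdefault(m.animal, []).append(m)
    rows = []
    for animal in sorted(by_animal):
        series = sorted(by_animal[animal], key=lambda m: m.day)
        if len(series) < 2:
            raise ValueError(f"animal {animal!r} has a single timepoint")
        groups = {m.group for m in series}
        if len(groups) != 1:
            raise ValueError(f"animal {animal!r} spans multiple groups")
        v0 = tumor_volume(series[0].length_mm, series[0].width_mm)
        v1 = tumor_volume(series[-1].length_mm, series[-1].width_mm)
        rows.append((animal, series[0].group, v1 / v0))
    return pd.DataFrame(rows, columns=["animal", "group", "relative_change"])


def group_volume_summary(per_animal: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of relative change per treatment group."""
    return (
        per_animal.groupby("group", as_index=False)["relative_change"]
        .agg(mean_change="mean", sd_change="std", n="count")
    )
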