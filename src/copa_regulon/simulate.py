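"""Synthetic-data generators for every input the pipeline consumes.

The generators emulate the statistical structure the analyses assume:

* a multi-lineage cell-line expression compendium with a small planted
  regulon that is strongly elevated only in one target lineage;
* knockout perturbation tables from a known directed network in which the
  anchor activates all members but one;
* Hill-curve dose-response surfaces with a tunable excess over the
  Bliss-independence expectation;
* a 180-compound imaging-screen plate with planted marker suppressors;
* qPCR Ct tables consistent with 2-fold-per-cycle chemistry.

Every generator is a pure function of its spec plus a seed.

The compendium background is hierarchical log-normal: each gene draws a
baseline level (log2 mean 3, log2 sd 1.5 across genes) and each sample
then scatters around that baseline with a smaller within-gene log2 sd.
Dropout zeros at rate 0.3 mimic RPKM sparsity and exercise the
undefined-fold path of the outlier statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .types import (
    CONTROL_LABEL,
    DoseMatrix,
    ExpressionCompendium,
    PerturbationTable,
    QpcrRecord,
    QpcrTable,
    ScreenPlate,
    ValidationError,
    Well,
)

#: the default planted regulon: anchor first, then the other members
DEFAULT_REGULON = (
    "PAX8", "CDH6", "CLDN16", "FGF18", "FOLR1",
    "SLC34A2", "SOX17", "SPON1", "WNT7A",
)


def _child_seed(seed: int, stream: str) -> np.random.Generator:
    """Derive an independent, deterministic generator per named stream."""
    ss = np.random.SeedSequence([int(seed) % (2 ** 31), *map(ord, stream)])
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class CompendiumSpec:
    """Parameters of the planted-outlier expression compendium."""

    n_lineages: int = 25
    samples_per_lineage: int = 25
    n_background_genes: int = 2000
    regulon_genes: tuple[str, ...] = DEFAULT_REGULON
    anchor: str = "PAX8"
    target_lineage: str = "ovary"
    outlier_log2_fold: float = 7.0
    background_log2_mean: float = 3.0
    background_log2_sd: float = 1.5
    within_gene_log2_sd: float = 0.5
    dropout_rate: float = 0.3
    dropout_log2_ceiling: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_lineages < 1 or self.samples_per_lineage < 1:
            raise ValidationError("need >= 1 lineage and >= 1 sample per lineage")
        if self.n_background_genes < 1:
            raise ValidationError("need >= 1 background gene")
        if self.outlier_log2_fold < 0:
            raise ValidationError("outlier_log2_fold must be >= 0")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.anchor not in self.regulon_genes:
            raise ValidationError("anchor must be a regulon gene")

    def background_gene_ids(self) -> tuple[str, ...]:
        width = len(str(self.n_background_genes))
        ids = tuple(f"BG{i + 1:0{width}d}" for i in range(self.n_background_genes))
        if set(ids) & set(self.regulon_genes):
            raise ValidationError("regulon genes must be disjoint from background")
        return ids

    def lineage_names(self) -> tuple[str, ...]:
        others = tuple(
            f"lineage_{i + 1:02d}" for i in range(self.n_lineages - 1)
        )
        return (self.target_lineage, *others)


def simulate_compendium(spec: CompendiumSpec) -> ExpressionCompendium:
    """Log-normal background with the regulon elevated in the target lineage.

    Regulon genes' values in target-lineage samples are multiplied by
    2**outlier_log2_fold before dropout is applied.
    """
    rng = _child_seed(spec.seed, "compendium")
    gene_ids = (*spec.regulon_genes, *spec.background_gene_ids())
    n_genes = len(gene_ids)
    n_samples = spec.n_lineages * spec.samples_per_lineage

    lineage_of_sample = np.repeat(spec.lineage_names(), spec.samples_per_lineage)
    sample_ids = tuple(
        f"{lin}_s{i % spec.samples_per_lineage + 1:02d}"
        for i, lin in enumerate(lineage_of_sample)
    )

    baseline = rng.normal(spec.background_log2_mean, spec.background_log2_sd,
                          size=n_genes)
    # Regulon genes represent typically-expressed lineage genes: their
    # baseline is pinned at the background log-mean so the planted contrast
    # is exactly the specified fold over a typical gene's level.
    baseline[: len(spec.regulon_genes)] = spec.background_log2_mean
    noise = rng.normal(0.0, spec.within_gene_log2_sd, size=(n_genes, n_samples))
    log2x = baseline[:, None] + noise
    in_target = lineage_of_sample == spec.target_lineage
    log2x[: len(spec.regulon_genes), in_target] += spec.outlier_log2_fold
    values = np.exp2(log2x)
    if spec.dropout_rate > 0:
        # Zeros come from lowly/moderately expressed measurements: cells
        # above the ceiling (abundant transcripts) are never dropped.
        ceiling = spec.dropout_log2_ceiling
        if ceiling is None:
            ceiling = spec.background_log2_mean + 2.0 * spec.background_log2_sd
        eligible = log2x < ceiling
        drop = (rng.random((n_genes, n_samples)) < spec.dropout_rate) & eligible
        values[drop] = 0.0

    lineages = dict(zip(sample_ids, lineage_of_sample))
    return ExpressionCompendium(
        gene_ids=gene_ids, sample_ids=sample_ids, values=values,
        lineages=lineages,
    )


@dataclass(frozen=True)
class NetworkSpec:
    """Ground-truth directed network behind a perturbation experiment.

    The anchor activates every gene in ``activated``; ``independent``
    members belong to the regulon but carry no anchor edge. By default the
    anchor drives all other members except FOLR1.
    """

    anchor: str = "PAX8"
    activated: tuple[str, ...] = tuple(
        g for g in DEFAULT_REGULON if g not in ("PAX8", "FOLR1")
    )
    independent: tuple[str, ...] = ("FOLR1",)
    knockdown_effect: float = 0.3
    noise_log2_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        members = set(self.activated) | set(self.independent)
        if not members:
            raise ValidationError("network needs at least one non-anchor member")
        if self.anchor in members:
            raise ValidationError("anchor cannot be its own target")
        if set(self.activated) & set(self.independent):
            raise ValidationError("activated and independent sets must be disjoint")
        if not (0.0 < self.knockdown_effect < 1.0):
            raise ValidationError("knockdown_effect must be in (0, 1)")

    def genes(self) -> tuple[str, ...]:
        return (self.anchor, *self.activated, *self.independent)

    def planted_edges(self) -> frozenset[tuple[str, str, str]]:
        """(source, target, sign) triples of the ground-truth network."""
        return frozenset(
            (self.anchor, t, "activation") for t in self.activated
        )


def simulate_perturbations(spec: NetworkSpec) -> PerturbationTable:
    """Relative expression after individually knocking out each member.

    Knocking out the anchor lowers itself and its activated targets to
    ``knockdown_effect``; knocking out any other member lowers only that
    member. Multiplicative log2-normal replicate noise applies everywhere.
    """
    rng = _child_seed(spec.seed, "perturbations")
    genes = spec.genes()
    n = len(genes)
    rel = np.ones((n, n))
    anchor_idx = 0
    for ti, t in enumerate(genes):
        if t == spec.anchor or t in spec.activated:
            rel[anchor_idx, ti] = spec.knockdown_effect
    for ki in range(1, n):
        rel[ki, ki] = spec.knockdown_effect
    if spec.noise_log2_sd > 0:
        rel *= np.exp2(rng.normal(0.0, spec.noise_log2_sd, size=rel.shape))
    return PerturbationTable(knockout_ids=genes, measured_ids=genes, rel_expr=rel)


def hill_inhibition(dose: np.ndarray, ec50: float, hill: float) -> np.ndarray:
    """Fractional inhibition of a monotherapy Hill curve (0 at dose 0)."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        f = dose ** hill / (ec50 ** hill + dose ** hill)
    return np.where(dose == 0, 0.0, f)


def simulate_dose_surface(
    ec50_a: float = 1.0,
    hill_a: float = 1.0,
    ec50_b: float = 50.0,
    hill_b: float = 1.0,
    doses_a: Sequence[float] = (0, 0.25, 0.5, 1, 2, 4, 8),
    doses_b: Sequence[float] = (0, 12.5, 25, 50, 100, 200, 400),
    bliss_excess_delta: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    drug_a: str = "drug_a",
    drug_b: str = "drug_b",
) -> DoseMatrix:
    """Hill-curve monotherapies with a planted excess over Bliss independence.

    ``bliss_excess_delta`` is added to the expected inhibition only in
    strictly-combination cells (both doses > 0) and the result is clamped
    into [0, 1] before Gaussian noise; viability = 1 - inhibition, clipped
    to be non-negative.
    """
    if ec50_a <= 0 or ec50_b <= 0 or hill_a <= 0 or hill_b <= 0:
        raise ValidationError("EC50s and Hill slopes must be positive")
    if not (-1.0 <= bliss_excess_delta <= 1.0):
        raise ValidationError("bliss_excess_delta must be in [-1, 1]")
    rng = _child_seed(seed, "dose")
    da = np.asarray(doses_a, dtype=float)
    db = np.asarray(doses_b, dtype=float)
    f_a = hill_inhibition(da, ec50_a, hill_a)
    f_b = hill_inhibition(db, ec50_b, hill_b)
    expected = f_a[:, None] + f_b[None, :] - f_a[:, None] * f_b[None, :]
    combo = (da[:, None] > 0) & (db[None, :] > 0)
    inhibition = np.clip(expected + bliss_excess_delta * combo, 0.0, 1.0)
    if noise_sd > 0:
        inhibition = inhibition + rng.normal(0.0, noise_sd, size=inhibition.shape)
    viability = np.clip(1.0 - inhibition, 0.0, None)
    return DoseMatrix(doses_a=da, doses_b=db, viability=viability,
                      drug_a=drug_a, drug_b=drug_b)


def simulate_screen(
    n_compounds: int = 180,
    n_hits: int = 15,
    suppression_factor: float = 0.2,
    noise_sd: float = 0.05,
    n_control_wells: int = 16,
    seed: int = 0,
    baseline_ratio: float = 0.5,
) -> tuple[ScreenPlate, tuple[str, ...]]:
    """Screen plate with planted marker suppressors; returns (plate, hit ids).

    Control and non-hit wells carry a marker/nuclear ratio around
    ``baseline_ratio``; hit wells' marker signal is multiplied by
    ``suppression_factor``. ``noise_sd`` is the log2 sd of multiplicative
    well-to-well noise on the ratio; nuclear intensities vary independently
    and cancel out of the ratio by construction.
    """
    if not (0 < n_hits <= n_compounds):
        raise ValidationError("need 0 < n_hits <= n_compounds")
    if not (0.0 < suppression_factor < 1.0):
        raise ValidationError("suppression_factor must be in (0, 1)")
    if n_control_wells < 1:
        raise ValidationError("need >= 1 control well")
    rng = _child_seed(seed, "screen")
    width = len(str(n_compounds))
    compounds = [f"CPD{i + 1:0{width}d}" for i in range(n_compounds)]
    hits = tuple(sorted(map(str, rng.choice(compounds, size=n_hits, replace=False))))
    wells = []
    labels = [CONTROL_LABEL] * n_control_wells + compounds
    for i, compound in enumerate(labels):
        nuclear = rng.uniform(500.0, 2000.0)
        ratio = baseline_ratio
        if compound in hits:
            ratio *= suppression_factor
        if noise_sd > 0:
            ratio *= float(np.exp2(rng.normal(0.0, noise_sd)))
        wells.append(Well(f"W{i + 1:03d}", compound, ratio * nuclear, nuclear))
    return ScreenPlate(wells=tuple(wells)), hits


def simulate_qpcr(
    true_fold_changes: Mapping[str, Mapping[str, float]],
    ct_noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    reference: str = "GAPDH",
    control_condition: str = "control",
    base_ct: float = 24.0,
    reference_ct: float = 18.0,
) -> QpcrTable:
    """Ct tables encoding known fold changes via 2-fold-per-cycle chemistry.

    ``true_fold_changes`` maps condition -> target -> fold change relative
    to the control condition. A target's Ct shifts by -log2(fold); the
    reference gene is constant across conditions. The control condition is
    generated implicitly with all folds 1.
    """
    for cond, folds in true_fold_changes.items():
        for target, fold in folds.items():
            if fold <= 0:
                raise ValidationError(
                    f"fold change must be > 0 ({cond!r}, {target!r})"
                )
    rng = _child_seed(seed, "qpcr")
    targets = sorted({t for folds in true_fold_changes.values() for t in folds})

    def cts(center: float) -> tuple[float, ...]:
        if ct_noise_sd > 0:
            return tuple(center + rng.normal(0.0, ct_noise_sd)
                         for _ in range(n_replicates))
        return tuple(center for _ in range(n_replicates))

    records = []
    conditions = [control_condition] + sorted(
        c for c in true_fold_changes if c != control_condition
    )
    for cond in conditions:
        for target in targets:
            fold = true_fold_changes.get(cond, {}).get(target, 1.0)
            if cond == control_condition:
                fold = 1.0
            records.append(QpcrRecord(cond, target, reference,
                                      cts(base_ct - float(np.log2(fold)))))
        records.append(QpcrRecord(cond, reference, reference, cts(reference_ct)))
    return QpcrTable(records=tuple(records))
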