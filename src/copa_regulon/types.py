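"""Core domain containers for the outlier/regulon pipeline.

Each container is a thin, validated wrapper around numpy arrays or plain
records. Validation happens at construction time so that every downstream
operation can assume its invariants (non-negative expression, unique
identifiers, matching dimensions, positive denominators, ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: compound label that marks a control (e.g. DMSO) well on a screen plate
CONTROL_LABEL = "CONTROL"


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes}")


@dataclass(frozen=True)
class ExpressionCompendium:
    """Gene x sample expression matrix (RPKM-like units) with lineage labels.

    Parameters
    ----------
    gene_ids, sample_ids
        Unique, case-sensitive identifiers for matrix rows / columns.
    values
        Non-negative, finite matrix of shape ``(len(gene_ids), len(sample_ids))``.
    lineages
        Mapping from each sample id to its lineage (tissue-of-origin) label.
        Every sample in the matrix must be annotated.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    lineages: Mapping[str, str]

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(map(str, self.gene_ids)))
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(values)):
            g, s = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite expression at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if np.any(values < 0):
            g, s = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative expression ({values[g, s]}) at gene "
                f"{self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )
        missing = [s for s in self.sample_ids if s not in self.lineages]
        if missing:
            raise ValidationError(f"samples without lineage annotation: {missing}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def lineage_labels(self) -> np.ndarray:
        """Lineage label per sample, in matrix column order."""
        return np.array([self.lineages[s] for s in self.sample_ids])

    def samples_in_lineage(self, lineage: str) -> list[str]:
        return [s for s in self.sample_ids if self.lineages[s] == lineage]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids),
                            columns=list(self.sample_ids))


@dataclass(frozen=True)
class OutlierCalls:
    """Per (gene, sample) fold statistics and the joint outlier flag.

    ``row_fold`` / ``col_fold`` are NaN where the corresponding median
    denominator was zero; such cells are never outliers.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    row_fold: np.ndarray
    col_fold: np.ndarray
    is_outlier: np.ndarray
    row_cutoff: float
    col_cutoff: float

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        rf = np.asarray(self.row_fold, dtype=float)
        cf = np.asarray(self.col_fold, dtype=float)
        flag = np.asarray(self.is_outlier, dtype=bool)
        object.__setattr__(self, "row_fold", rf)
        object.__setattr__(self, "col_fold", cf)
        object.__setattr__(self, "is_outlier", flag)
        shape = (len(self.gene_ids), len(self.sample_ids))
        if rf.shape != shape or cf.shape != shape or flag.shape != shape:
            raise ValidationError("fold/flag matrices do not match id lists")
        if self.row_cutoff <= 0 or self.col_cutoff <= 0:
            raise ValidationError("cutoffs must be positive")
        bad = flag & ~(
            np.nan_to_num(rf, nan=-np.inf) > self.row_cutoff
        ) | flag & ~(np.nan_to_num(cf, nan=-np.inf) > self.col_cutoff)
        if np.any(bad):
            g, s = np.argwhere(bad)[0]
            raise ValidationError(
                f"outlier flag without supporting folds at "
                f"({self.gene_ids[g]!r}, {self.sample_ids[s]!r})"
            )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with one row per (gene, sample)."""
        genes = np.repeat(self.gene_ids, len(self.sample_ids))
        samples = np.tile(self.sample_ids, len(self.gene_ids))
        return pd.DataFrame({
            "gene": genes,
            "sample": samples,
            "row_fold": self.row_fold.ravel(),
            "col_fold": self.col_fold.ravel(),
            "is_outlier": self.is_outlier.ravel(),
        })


@dataclass(frozen=True)
class PerturbationTable:
    """Knockout target x measured gene relative expression (1 = unchanged)."""

    knockout_ids: tuple[str, ...]
    measured_ids: tuple[str, ...]
    rel_expr: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "knockout_ids", tuple(self.knockout_ids))
        object.__setattr__(self, "measured_ids", tuple(self.measured_ids))
        rel = np.asarray(self.rel_expr, dtype=float)
        object.__setattr__(self, "rel_expr", rel)
        _check_unique(self.knockout_ids, "knockout ids")
        _check_unique(self.measured_ids, "measured ids")
        if rel.shape != (len(self.knockout_ids), len(self.measured_ids)):
            raise ValidationError("rel_expr shape does not match id lists")
        if not np.all(np.isfinite(rel)) or np.any(rel <= 0):
            raise ValidationError("relative expression must be positive and finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rel_expr, index=list(self.knockout_ids),
                            columns=list(self.measured_ids))


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    sign: str  # "activation" | "repression"
    magnitude: float  # |log2 fold change|, > 0

    def __post_init__(self):
        if self.sign not in ("activation", "repression"):
            raise ValidationError(f"invalid edge sign {self.sign!r}")
        if self.source == self.target:
            raise ValidationError(f"self-edge on {self.source!r}")
        if not self.magnitude > 0:
            raise ValidationError("edge magnitude must be positive")


@dataclass(frozen=True)
class RegulonNetwork:
    """Directed, signed regulatory network inferred from perturbations."""

    nodes: frozenset[str]
    edges: frozenset[Edge]

    def __post_init__(self):
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "edges", frozenset(self.edges))
        for e in self.edges:
            if e.source not in self.nodes or e.target not in self.nodes:
                raise ValidationError(f"edge {e} references unknown node")

    def activation_out_degree(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for e in self.edges:
            if e.sign == "activation":
                deg[e.source] += 1
        return deg

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(
            (e.source, e.target, e.sign, e.magnitude) for e in self.edges
        )
        return pd.DataFrame(rows, columns=["source", "target", "sign", "magnitude"])


@dataclass(frozen=True)
class DoseMatrix:
    """Combination viability surface over two ascending dose grids.

    Rows index drug A doses, columns drug B doses; each axis starts at 0
    (the untreated anchor lives at ``viability[0, 0]``). NaN cells are
    permitted (unmeasured high-dose corners) and are skipped downstream.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    viability: np.ndarray
    drug_a: str = "drug_a"
    drug_b: str = "drug_b"
    n_clamped: int = 0

    def __post_init__(self):
        da = np.asarray(self.doses_a, dtype=float)
        db = np.asarray(self.doses_b, dtype=float)
        v = np.asarray(self.viability, dtype=float)
        object.__setattr__(self, "doses_a", da)
        object.__setattr__(self, "doses_b", db)
        object.__setattr__(self, "viability", v)
        for name, d in (("drug A", da), ("drug B", db)):
            if d.ndim != 1 or len(d) == 0:
                raise ValidationError(f"{name} dose axis must be a non-empty vector")
            if np.any(d < 0):
                raise ValidationError(f"{name} doses must be non-negative")
            if d[0] != 0:
                raise ValidationError(f"{name} dose axis must start at 0")
            if len(d) > 1 and not np.all(np.diff(d) > 0):
                raise ValidationError(f"{name} doses must be strictly increasing")
        if v.shape != (len(da), len(db)):
            raise ValidationError(
                f"viability shape {v.shape} does not match dose axes "
                f"({len(da)} x {len(db)})"
            )
        if np.isnan(v[0, 0]):
            raise ValidationError("untreated anchor viability[0, 0] is missing")
        if np.any(np.nan_to_num(v, nan=0.0) < 0):
            raise ValidationError("viability must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.viability, index=self.doses_a, columns=self.doses_b)


@dataclass(frozen=True)
class Well:
    well_id: str
    compound_id: str  # CONTROL_LABEL for control wells
    marker_intensity: float
    nuclear_intensity: float

    def __post_init__(self):
        if not np.isfinite(self.marker_intensity) or self.marker_intensity < 0:
            raise ValidationError(
                f"well {self.well_id!r}: marker intensity must be >= 0"
            )
        if not np.isfinite(self.nuclear_intensity) or self.nuclear_intensity <= 0:
            raise ValidationError(
                f"well {self.well_id!r}: nuclear intensity must be > 0"
            )


@dataclass(frozen=True)
class ScreenPlate:
    """Per-well aggregate marker and nuclear-stain intensities."""

    wells: tuple[Well, ...]

    def __post_init__(self):
        object.__setattr__(self, "wells", tuple(self.wells))
        _check_unique([w.well_id for w in self.wells], "well ids")
        if not any(w.compound_id == CONTROL_LABEL for w in self.wells):
            raise ValidationError("plate has no control wells")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(w.well_id, w.compound_id, w.marker_intensity, w.nuclear_intensity)
             for w in self.wells],
            columns=["well_id", "compound_id", "marker_intensity",
                     "nuclear_intensity"],
        )


@dataclass(frozen=True)
class QpcrRecord:
    condition: str
    target: str
    reference: str
    cts: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "cts", tuple(float(c) for c in self.cts))
        if len(self.cts) == 0:
            raise ValidationError(
                f"({self.condition}, {self.target}): needs >= 1 Ct replicate"
            )
        for c in self.cts:
            if not (0.0 <= c <= 45.0):
                raise ValidationError(
                    f"({self.condition}, {self.target}): Ct {c} outside [0, 45]"
                )

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.cts))


@dataclass(frozen=True)
class QpcrTable:
    records: tuple[QpcrRecord, ...]

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise ValidationError("empty qPCR table")

    def conditions(self) -> list[str]:
        return sorted({r.condition for r in self.records})

    def to_frame(self) -> pd.DataFrame:
        n = max(len(r.cts) for r in self.records)
        rows = []
        for r in self.records:
            cts = list(r.cts) + [np.nan] * (n - len(r.cts))
            rows.append([r.condition, r.target, r.reference, *cts])
        return pd.DataFrame(
            rows,
            columns=["condition", "target", "reference"]
            + [f"ct_{i + 1}" for i in range(n)],
        )


@dataclass(frozen=True)
class ChipRecord:
    locus: str
    ct_ip: float
    ct_input: float
    input_fraction: float

    def __post_init__(self):
        if not (np.isfinite(self.ct_ip) and np.isfinite(self.ct_input)):
            raise ValidationError(f"locus {self.locus!r}: Ct values must be finite")
        if not (0.0 < self.input_fraction <= 1.0):
            raise ValidationError(
                f"locus {self.locus!r}: input fraction must be in (0, 1]"
            )


@dataclass(frozen=True)
class ChipQpcrTable:
    records: tuple[ChipRecord, ...]

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise ValidationError("empty ChIP-qPCR table")
        _check_unique([r.locus for r in self.records], "loci")


@dataclass(frozen=True)
class TumorMeasurement:
    """A single caliper measurement; length/width are canonicalized L >= W."""

    animal: str
    group: str
    day: float
    length_mm: float
    width_mm: float

    def __post_init__(self):
        if self.length_mm <= 0 or self.width_mm <= 0:
            raise ValidationError(
                f"animal {self.animal!r} day {self.day}: measurements must be > 0"
            )
        if self.width_mm > self.length_mm:
            L, W = self.width_mm, self.length_mm
            object.__setattr__(self, "length_mm", L)
            object.__setattr__(self, "width_mm", W)
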