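"""Readers and writers for the pipeline's tabular formats.

TSV is the canonical dialect; CSV is accepted on read by sniffing the
delimiter of the header line. Floats are serialized at ``repr`` precision so
that write/read round trips are lossless well past 12 significant digits.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .types import (
    ChipQpcrTable,
    ChipRecord,
    DoseMatrix,
    ExpressionCompendium,
    OutlierCalls,
    PerturbationTable,
    QpcrRecord,
    QpcrTable,
    ScreenPlate,
    TumorMeasurement,
    ValidationError,
    Well,
)


def _sniff_sep(path: str | os.PathLike) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_annotation(path: str | os.PathLike) -> dict[str, str]:
    """Read a sample_id -> lineage table (columns: sample_id, lineage)."""
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip", dtype=str)
    for col in ("sample_id", "lineage"):
        if col not in df.columns:
            raise ValidationError(f"annotation file lacks column {col!r}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in annotation: {dupes}")
    return dict(zip(df["sample_id"], df["lineage"]))


def read_expression_matrix(
    path: str | os.PathLike, annotation_path: str | os.PathLike
) -> ExpressionCompendium:
    """Read a gene x sample matrix plus its lineage annotation.

    The matrix file has gene ids in the first column and sample ids in the
    header. Missing cells are an error: the outlier statistic's medians are
    undefined under missingness.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip", index_col=0)
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise ValidationError(f"missing value in expression matrix at gene {gene!r}")
    lineages = read_annotation(annotation_path)
    return ExpressionCompendium(
        gene_ids=tuple(df.index.astype(str)),
        sample_ids=tuple(df.columns.astype(str)),
        values=df.to_numpy(dtype=float),
        lineages=lineages,
    )


def write_expression_matrix(
    compendium: ExpressionCompendium,
    path: str | os.PathLike,
    annotation_path: str | os.PathLike | None = None,
) -> None:
    df = compendium.to_frame()
    df.index.name = "gene_id"
    write_table(df.reset_index(), path)
    if annotation_path is not None:
        ann = pd.DataFrame(
            {"sample_id": list(compendium.sample_ids),
             "lineage": [compendium.lineages[s] for s in compendium.sample_ids]}
        )
        write_table(ann, annotation_path)


def read_perturbation_table(path: str | os.PathLike) -> PerturbationTable:
    """Read a knockout x measured-gene relative-expression table.

    Replicate rows sharing a knockout id are averaged on the log2 scale
    (geometric mean on the fold-change scale) before validation.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip", index_col=0)
    values = df.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)) or np.any(values <= 0):
        raise ValidationError("relative expression must be positive and finite")
    log2 = np.log2(df)
    merged = log2.groupby(level=0, sort=False).mean()
    return PerturbationTable(
        knockout_ids=tuple(merged.index.astype(str)),
        measured_ids=tuple(merged.columns.astype(str)),
        rel_expr=np.exp2(merged.to_numpy()),
    )


def read_dose_matrix(
    path: str | os.PathLike, drug_a: str = "drug_a", drug_b: str = "drug_b"
) -> DoseMatrix:
    """Read a dose-combination viability grid.

    First row holds drug B doses, first column drug A doses; cell [0, 0] of
    the file is a label or empty. Missing viability cells are tolerated only
    off the untreated anchor and become NaN.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip", index_col=0)
    return DoseMatrix(
        doses_a=df.index.to_numpy(dtype=float),
        doses_b=df.columns.to_numpy(dtype=float),
        viability=df.to_numpy(dtype=float),
        drug_a=drug_a,
        drug_b=drug_b,
    )


def read_screen_plate(path: str | os.PathLike) -> ScreenPlate:
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    needed = ["well_id", "compound_id", "marker_intensity", "nuclear_intensity"]
    for col in needed:
        if col not in df.columns:
            raise ValidationError(f"screen plate file lacks column {col!r}")
    wells = [
        Well(str(r.well_id), str(r.compound_id), float(r.marker_intensity),
             float(r.nuclear_intensity))
        for r in df.itertuples(index=False)
    ]
    return ScreenPlate(wells=tuple(wells))


def read_qpcr_table(path: str | os.PathLike) -> QpcrTable:
    """Read a qPCR Ct table (condition, target, reference, ct_1..ct_n)."""
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    ct_cols = [c for c in df.columns if c.startswith("ct_")]
    if not ct_cols:
        raise ValidationError("qPCR table has no ct_* columns")
    records = []
    for r in df.itertuples(index=False):
        cts = [getattr(r, c) for c in ct_cols]
        cts = [float(c) for c in cts if pd.notna(c)]
        records.append(QpcrRecord(str(r.condition), str(r.target),
                                  str(r.reference), tuple(cts)))
    return QpcrTable(records=tuple(records))


def read_chip_table(path: str | os.PathLike) -> ChipQpcrTable:
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    records = [
        ChipRecord(str(r.locus), float(r.ct_ip), float(r.ct_input),
                   float(r.input_fraction))
        for r in df.itertuples(index=False)
    ]
    return ChipQpcrTable(records=tuple(records))


def read_tumor_measurements(path: str | os.PathLike) -> list[TumorMeasurement]:
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    return [
        TumorMeasurement(str(r.animal), str(r.group), float(r.day),
                         float(r.length_mm), float(r.width_mm))
        for r in df.itertuples(index=False)
    ]


def _format_cell(x) -> str:
    if isinstance(x, (float, np.floating)):
        return repr(float(x))
    if isinstance(x, (bool, np.bool_)):
        return "True" if x else "False"
    return str(x)


def write_table(result, path: str | os.PathLike) -> None:
    """Write a result as a deterministic TSV.

    Accepts a DataFrame or any domain object exposing ``to_frame()``
    (OutlierCalls, PerturbationTable, networks, plates, ...). Column order is
    whatever the frame defines; floats are serialized with ``repr`` so values
    survive a round trip to >= 12 significant digits.
    """
    if hasattr(result, "to_frame") and not isinstance(result, pd.DataFrame):
        df = result.to_frame()
    elif isinstance(result, pd.DataFrame):
        df = result
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_format_cell(x) for x in row) + "\n")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a ``write_table`` TSV (generic)."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
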