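"""Image-screen analytics: marker/nuclear ratios, plate normalization, hit ranking.

The unit of analysis is the well: an aggregate marker intensity (e.g. a
transcription-factor immunofluorescence signal) and an aggregate nuclear
stain intensity. Compounds that suppress the marker drive the per-well
marker/nuclear ratio down; hits are the k compounds with the lowest
control-normalized ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import CONTROL_LABEL, ScreenPlate


def well_ratio(plate: ScreenPlate) -> pd.DataFrame:
    """Per-well marker/nuclear intensity ratio."""
    df = plate.to_frame()
    df["ratio"] = df["marker_intensity"] / df["nuclear_intensity"]
    return df[["well_id", "compound_id", "ratio"]]


def normalize_plate(ratios: pd.DataFrame) -> pd.DataFrame:
    """Divide each well's ratio by the median control-well ratio."""
    control = ratios.loc[ratios["compound_id"] == CONTROL_LABEL, "ratio"]
    if control.empty:
        raise ValueError("no control wells on plate")
    ref = float(control.median())
    if ref <= 0:
        raise ValueError("median control ratio must be > 0")
    out = ratios.copy()
    out["normalized_ratio"] = out["ratio"] / ref
    return out


def rank_hits(normalized: pd.DataFrame, k: int = 15) -> pd.DataFrame:
    """Rank compounds by ascending normalized ratio; mark the top k selected.

    Control wells are excluded; compounds with several wells are summarized
    by their mean ratio. Ties are broken lexicographically by compound id.
    """
    col = "normalized_ratio" if "normalized_ratio" in normalized.columns else "ratio"
    compounds = (
        normalized.loc[normalized["compound_id"] != CONTROL_LABEL]
        .groupby("compound_id", as_index=False)
        .agg(raw_ratio=("ratio", "mean"), normalized_ratio=(col, "mean"))
    )
    if k > len(compounds):
        raise ValueError(f"k={k} exceeds number of compounds ({len(compounds)})")
    compounds = compounds.sort_values(
        ["normalized_ratio", "compound_id"], kind="mergesort"
    ).reset_index(drop=True)
    compounds.insert(0, "rank", np.arange(1, len(compounds) + 1))
    compounds["selected"] = compounds["rank"] <= k
    return compounds[["rank", "compound_id", "raw_ratio", "normalized_ratio",
                      "selected"]]
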