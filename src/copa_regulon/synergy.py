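"""Bliss-independence scoring of drug-combination dose matrices.

Effects are expressed as fraction inhibition f = 1 - normalized viability.
Under Bliss independence the expected combined inhibition is
f_AB = f_A + f_B - f_A * f_B, with the monotherapy inhibitions taken from
the observed 0-dose margins (no curve fitting). Excess over the expectation
is the synergy score: positive = synergistic, negative = antagonistic. The
scalar summary is the mean excess over strictly-combination cells (both
doses > 0); the maximum excess and its dose coordinates are also reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .types import DoseMatrix

logger = logging.getLogger(__name__)


def normalize_viability(dose_matrix: DoseMatrix) -> DoseMatrix:
    """Divide all cells by the untreated anchor and clamp into [0, 1].

    The number of cells clamped is logged and carried on the returned
    matrix's ``n_clamped`` field.
    """
    anchor = dose_matrix.viability[0, 0]
    if not anchor > 0:
        raise ValueError("untreated anchor viability must be > 0")
    v = dose_matrix.viability / anchor
    clamped = int(np.nansum((v < 0) | (v > 1)))
    if clamped:
        logger.info("normalize_viability: clamped %d cell(s) into [0, 1]", clamped)
    v = np.clip(v, 0.0, 1.0)
    return DoseMatrix(
        doses_a=dose_matrix.doses_a,
        doses_b=dose_matrix.doses_b,
        viability=v,
        drug_a=dose_matrix.drug_a,
        drug_b=dose_matrix.drug_b,
        n_clamped=clamped,
    )


@dataclass(frozen=True)
class BlissResult:
    """Expected/observed inhibition surfaces and the excess over independence."""

    doses_a: np.ndarray
    doses_b: np.ndarray
    observed_inhibition: np.ndarray
    expected_inhibition: np.ndarray
    excess: np.ndarray
    summary_score: float
    drug_a: str = "drug_a"
    drug_b: str = "drug_b"

    def max_excess(self) -> tuple[float, float, float]:
        """(max excess, dose_a, dose_b) over defined combination cells."""
        ex = self.excess.copy()
        ex[0, :] = -np.inf
        ex[:, 0] = -np.inf
        ex[np.isnan(ex)] = -np.inf
        i, j = np.unravel_index(np.argmax(ex), ex.shape)
        return float(self.excess[i, j]), float(self.doses_a[i]), float(self.doses_b[j])

    def excess_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.excess, index=self.doses_a, columns=self.doses_b)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, da in enumerate(self.doses_a):
            for j, db in enumerate(self.doses_b):
                rows.append((da, db, self.observed_inhibition[i, j],
                             self.expected_inhibition[i, j], self.excess[i, j]))
        return pd.DataFrame(rows, columns=[
            "dose_a", "dose_b", "observed_inhibition", "expected_inhibition",
            "excess"])


def bliss_excess(dose_matrix: DoseMatrix, normalize: bool = True) -> BlissResult:
    """Excess inhibition over the Bliss-independence expectation.

    Monotherapy inhibitions come from the matrix's own 0-dose row/column,
    which must be fully observed. NaN combination cells propagate to NaN
    excess and are excluded from the summary mean.
    """
    dm = normalize_viability(dose_matrix) if normalize else dose_matrix
    inhibition = 1.0 - dm.viability
    f_a = inhibition[:, 0]
    f_b = inhibition[0, :]
    if np.any(np.isnan(f_a)) or np.any(np.isnan(f_b)):
        raise ValueError("monotherapy margins contain missing values")
    expected = f_a[:, None] + f_b[None, :] - f_a[:, None] * f_b[None, :]
    excess = inhibition - expected
    combo = excess[1:, 1:]
    summary = float(np.nanmean(combo)) if combo.size else 0.0
    return BlissResult(
        doses_a=dm.doses_a,
        doses_b=dm.doses_b,
        observed_inhibition=inhibition,
        expected_inhibition=expected,
        excess=excess,
        summary_score=summary,
        drug_a=dm.drug_a,
        drug_b=dm.drug_b,
    )


def synergy_report(results: Mapping[str, BlissResult]) -> pd.DataFrame:
    """One summary row per drug pair, ordered deterministically by name."""
    if not results:
        raise ValueError("no results to report")
    rows = []
    for name in sorted(results):
        res = results[name]
        mx, da, db = res.max_excess()
        rows.append((name, res.drug_a, res.drug_b, res.summary_score, mx, da, db))
    return pd.DataFrame(rows, columns=[
        "pair", "drug_a", "drug_b", "summary_score", "max_excess",
        "dose_a_at_max", "dose_b_at_max"])
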