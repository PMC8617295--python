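"""Quantitative sensory testing (QST) scores.

Raw modal pain thresholds — cold (CPT, °C), heat (HPT, °C) and mechanical
(MPT, mN; log-transformed before use) — are turned into cohort z-scores with
the sign fixed so that *higher always means more pain-sensitive*: a sensitive
person feels cold pain at a higher temperature (z kept) but heat and
mechanical pain at lower intensities (z negated).  The modality-independent
composite is the arithmetic mean of the three signed z-scores.

Z-scores use the analyzed cohort's own mean and population (1/n) sd.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from gradpain.errors import DataError

log = logging.getLogger(__name__)


def _zscore(x: np.ndarray, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise DataError(f"need at least 3 subjects to z-score {what}")
    if not np.all(np.isfinite(x)):
        raise DataError(f"non-finite {what} values")
    sd = x.std()  # population convention
    if sd <= 0:
        raise DataError(f"all subjects identical on {what}: zero standard deviation")
    return (x - x.mean()) / sd


def modal_scores(cpt: np.ndarray, hpt: np.ndarray, mpt: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-subject modal sensitivity z-scores (z_cold, z_heat, z_mech).

    z_cold = z(CPT); z_heat = −z(HPT); z_mech = −z(ln MPT).
    """
    mpt = np.asarray(mpt, dtype=np.float64)
    if np.any(mpt <= 0):
        bad = np.where(mpt <= 0)[0]
        raise DataError(f"nonpositive mechanical threshold for subject index(es) {bad.tolist()}")
    z_cold = _zscore(np.asarray(cpt, float), "CPT")
    z_heat = -_zscore(np.asarray(hpt, float), "HPT")
    z_mech = -_zscore(np.log(mpt), "log MPT")
    return z_cold, z_heat, z_mech


def composite_score(z_cold: np.ndarray, z_heat: np.ndarray, z_mech: np.ndarray) -> np.ndarray:
    """Modality-independent composite = mean of the three signed z-scores."""
    z = np.column_stack([z_cold, z_heat, z_mech]).astype(np.float64)
    if not np.all(np.isfinite(z)):
        raise DataError("missing or non-finite modal score")
    return z.mean(axis=1)


def score_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Score a cohort table with columns cpt_C, hpt_C, mpt_mN.

    Subjects with a missing modality are excluded (logged); the returned copy
    gains z_cold, z_heat, z_mech and composite columns.
    """
    required = ["cpt_C", "hpt_C", "mpt_mN"]
    missing_cols = [c for c in required if c not in table.columns]
    if missing_cols:
        raise DataError(f"cohort table missing column(s) {missing_cols}")
    complete = table[required].notna().all(axis=1)
    if not complete.all():
        log.warning("score_cohort: excluding %d subject(s) with missing modalities", int((~complete).sum()))
    out = table.loc[complete].copy()
    z_cold, z_heat, z_mech = modal_scores(out["cpt_C"].to_numpy(), out["hpt_C"].to_numpy(), out["mpt_mN"].to_numpy())
    out["z_cold"] = z_cold
    out["z_heat"] = z_heat
    out["z_mech"] = z_mech
    out["composite"] = composite_score(z_cold, z_heat, z_mech)
    return out
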