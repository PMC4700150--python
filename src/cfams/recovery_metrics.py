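"""Root-mean-square deviation between theoretical and estimated loadings.

RMSD_k = sqrt( sum_i (lam_ik(t) - lam_ik(e))^2 / p_k ) over the p_k items
defining factor k, computed on standardized loadings.  It is 0 for a perfect
pattern-magnitude match and 2 when all loadings are unity with opposite
signs; values below 0.20 are read as satisfactory recovery.  The study's
dependent variable is the weak factor's RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population_models import WEAK_FACTOR, FactorModelSpec

#: RMSD below this is read as satisfactory recovery.
SATISFACTORY_THRESHOLD = 0.20


@dataclass(frozen=True)
class RecoveryScore:
    factor_id: int
    rmsd: float
    satisfactory: bool


def rmsd(theoretical, estimated) -> float:
    """Root mean square deviation between two loading vectors."""
    t = np.asarray(theoretical, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if t.shape != e.shape or t.ndim != 1 or t.size < 1:
        raise ValueError("loading vectors must be 1-D and of equal length")
    return float(np.sqrt(np.mean((t - e) ** 2)))


def classify_recovery(value: float) -> bool:
    """True iff the RMSD indicates satisfactory recovery (< 0.20)."""
    if not 0.0 <= value <= 2.0:
        raise ValueError(f"RMSD {value} outside [0, 2]")
    return value < SATISFACTORY_THRESHOLD


def score_factor(
    spec: FactorModelSpec, standardized_loadings: np.ndarray, factor_id: int
) -> RecoveryScore:
    """RMSD of one factor over its defining items."""
    items = spec.factor_items[factor_id]
    value = rmsd(spec.Lambda[items, factor_id], standardized_loadings[items, factor_id])
    return RecoveryScore(
        factor_id=factor_id,
        rmsd=value,
        satisfactory=value < SATISFACTORY_THRESHOLD if value <= 2.0 else False,
    )


def weak_factor_rmsd(spec: FactorModelSpec, standardized_loadings: np.ndarray) -> float:
    """RMSD of the model's weak factor (the study's dependent variable)."""
    return score_factor(spec, standardized_loadings, WEAK_FACTOR[spec.model_id]).rmsd
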