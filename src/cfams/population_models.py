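"""Population models, mean-structure constraint patterns, and the study design grid.

Three generating factor models are built in: a one-factor model whose single
factor is weak (all twelve loadings 0.30), a two-factor model with one strong
(0.80) and one weak (0.30) factor, and a three-factor model (0.95 / 0.70 /
0.30).  All models have p = 12 observed indicators with simple structure, unit
observed variances, item intercepts tau and factor means kappa.  The
experimental design crosses estimation method, sample size, mean-structure
constraint and (for multi-factor models) factor correlation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from itertools import product
from typing import Sequence

import numpy as np
import yaml

MODEL_IDS = ("1F", "2F", "3F")
METHODS = ("ML", "ULS")
SAMPLE_SIZES = (100, 300, 500)
FACTOR_CORRELATIONS = (0.0, 0.5)

#: constraint levels available per model; "NONE" is the covariance-only CFA.
CONSTRAINTS = {
    "1F": ("NONE", "C1", "C2", "C3"),
    "2F": ("NONE", "C1", "C2", "C3", "C4"),
    "3F": ("NONE", "C1", "C2", "C3", "C4", "C5"),
}

# (block size, loading) per factor, in item order.
_BLOCKS = {
    "1F": ((12, 0.30),),
    "2F": ((7, 0.80), (5, 0.30)),
    "3F": ((5, 0.95), (4, 0.70), (3, 0.30)),
}
_TAU = {
    "1F": (3.0,) * 12,
    "2F": (8.0,) * 7 + (3.0,) * 5,
    "3F": (9.5,) * 5 + (7.0,) * 4 + (3.0,) * 3,
}
_KAPPA = {"1F": (6.0,), "2F": (12.0, 6.0), "3F": (12.0, 8.0, 6.0)}

#: index of the weak factor (all loadings 0.30) in each model.
WEAK_FACTOR = {"1F": 0, "2F": 1, "3F": 2}


@dataclass(frozen=True)
class FactorModelSpec:
    """A fully specified population factor model.

    Lambda is p x q with simple structure (one nonzero loading per row), Phi
    has unit diagonal, ThetaDelta is the diagonal of unique variances chosen
    so that the implied observed variances are 1, tau are item intercepts and
    kappa factor means.
    """

    model_id: str
    Lambda: np.ndarray
    Phi: np.ndarray
    ThetaDelta: np.ndarray  # diagonal entries, length p
    tau: np.ndarray
    kappa: np.ndarray
    factor_correlation: float = 0.0

    @property
    def p(self) -> int:
        return self.Lambda.shape[0]

    @property
    def q(self) -> int:
        return self.Lambda.shape[1]

    @property
    def factor_items(self) -> list[np.ndarray]:
        """Item indices loading on each factor, per the simple structure."""
        return [np.flatnonzero(self.Lambda[:, j]) for j in range(self.q)]

    @property
    def marker_items(self) -> np.ndarray:
        """First item of each factor; used as scaling marker under C1."""
        return np.array([idx[0] for idx in self.factor_items])

    def validate(self) -> None:
        lam, phi = self.Lambda, self.Phi
        if not np.all((lam != 0).sum(axis=1) == 1):
            raise ValueError("each row of Lambda must have exactly one nonzero loading")
        if not np.allclose(np.diag(phi), 1.0):
            raise ValueError("Phi must have unit diagonal")
        if np.any(self.ThetaDelta <= 0):
            raise ValueError("unique variances must be positive")
        sigma, _ = build_population_moments(self)
        if np.linalg.eigvalsh(sigma)[0] <= 0:
            raise ValueError("implied covariance matrix is not positive definite")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("Lambda", "Phi", "ThetaDelta", "tau", "kappa"):
            d[k] = np.asarray(d[k]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FactorModelSpec":
        return cls(
            model_id=d["model_id"],
            Lambda=np.asarray(d["Lambda"], dtype=float),
            Phi=np.asarray(d["Phi"], dtype=float),
            ThetaDelta=np.asarray(d["ThetaDelta"], dtype=float),
            tau=np.asarray(d["tau"], dtype=float),
            kappa=np.asarray(d["kappa"], dtype=float),
            factor_correlation=float(d.get("factor_correlation", 0.0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FactorModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FactorModelSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def __eq__(self, other) -> bool:
        if not isinstance(other, FactorModelSpec):
            return NotImplemented
        return (
            self.model_id == other.model_id
            and self.factor_correlation == other.factor_correlation
            and all(
                np.array_equal(getattr(self, k), getattr(other, k))
                for k in ("Lambda", "Phi", "ThetaDelta", "tau", "kappa")
            )
        )


def make_model(model_id: str, factor_correlation: float = 0.0) -> FactorModelSpec:
    """Build one of the registered generating models.

    Parameters
    ----------
    model_id : {"1F", "2F", "3F"}
    factor_correlation : float
        Common correlation for all factor pairs (0 or 0.50 in the study
        design); ignored for the one-factor model.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    blocks = _BLOCKS[model_id]
    q = len(blocks)
    p = sum(n for n, _ in blocks)
    lam = np.zeros((p, q))
    row = 0
    for j, (n, value) in enumerate(blocks):
        lam[row : row + n, j] = value
        row += n
    if model_id == "1F":
        factor_correlation = 0.0
    phi = np.full((q, q), factor_correlation)
    np.fill_diagonal(phi, 1.0)
    common = np.diag(lam @ phi @ lam.T)
    spec = FactorModelSpec(
        model_id=model_id,
        Lambda=lam,
        Phi=phi,
        ThetaDelta=1.0 - common,
        tau=np.asarray(_TAU[model_id]),
        kappa=np.asarray(_KAPPA[model_id]),
        factor_correlation=factor_correlation,
    )
    spec.validate()
    return spec


def build_population_moments(spec: FactorModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied covariance Sigma = Lambda Phi Lambda' + ThetaDelta and
    mean vector mu = tau + Lambda kappa."""
    sigma = spec.Lambda @ spec.Phi @ spec.Lambda.T + np.diag(spec.ThetaDelta)
    mu = spec.tau + spec.Lambda @ spec.kappa
    if np.linalg.eigvalsh(sigma)[0] <= 0:
        raise ValueError("implied covariance matrix is not positive definite")
    return sigma, mu


@dataclass(frozen=True)
class ConstraintPattern:
    """Which mean-structure parameters are free under a design constraint.

    tau_free[i] is True when item i's intercept is estimated; fixed intercepts
    are held at 0.  All factor means kappa are always estimated.  Under C1
    (the saturated mean structure) one marker loading per factor is fixed at
    unity and the factor variances are freed; under every other pattern the
    factor variances are fixed at 1 and all pattern loadings are free.
    """

    model_id: str
    constraint_id: str
    tau_free: np.ndarray  # bool, length p
    marker_lambda_fixed: bool  # True only for C1

    @property
    def n_free_nu(self) -> int:
        q = len(_KAPPA[self.model_id])
        return int(self.tau_free.sum()) + q

    @property
    def saturated(self) -> bool:
        return self.n_free_nu >= len(self.tau_free)

    @property
    def identification_fixes(self) -> list[tuple[str, float]]:
        fixes = [(f"tau[{i}]", 0.0) for i in np.flatnonzero(~self.tau_free)]
        if self.marker_lambda_fixed:
            spec = make_model(self.model_id)
            fixes += [
                (f"lambda[{i},{j}]", 1.0) for j, i in enumerate(spec.marker_items)
            ]
        else:
            fixes += [
                (f"phi[{j},{j}]", 1.0) for j in range(len(_KAPPA[self.model_id]))
            ]
        return fixes


def constraint_pattern(model_id: str, constraint_id: str) -> ConstraintPattern:
    """Mean-structure constraint patterns of the study design.

    C1: saturated — marker loading fixed at 1 and its intercept at 0 per
        factor, all remaining intercepts and all factor means free.
    C2: tau-equivalent — every intercept fixed at 0, factor means free.
    C3..C5: intercepts of one factor's items (plus each factor's marker) fixed
        at 0, the rest free.  In the one-factor model C3 fixes the intercepts
        of every other item.  The last constraint of each multi-factor model
        zeroes the weak factor's intercepts.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    if constraint_id not in CONSTRAINTS[model_id] or constraint_id == "NONE":
        raise ValueError(f"constraint {constraint_id!r} not defined for {model_id}")
    spec = make_model(model_id)
    p = spec.p
    markers = spec.marker_items
    free = np.ones(p, dtype=bool)
    free[markers] = False
    if constraint_id == "C2":
        free[:] = False
    elif constraint_id == "C3" and model_id == "1F":
        free[:] = False
        free[1::2] = True
    elif constraint_id != "C1":
        # Ck (k>=3) zeroes the intercepts of factor k-3's items.
        factor = int(constraint_id[1]) - 3
        free[spec.factor_items[factor]] = False
    return ConstraintPattern(
        model_id=model_id,
        constraint_id=constraint_id,
        tau_free=free,
        marker_lambda_fixed=constraint_id == "C1",
    )


@dataclass(frozen=True)
class DesignCell:
    """One cell of the factorial design."""

    model_id: str
    method: str
    N: int
    constraint_id: str
    factor_correlation: float | None = None

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.constraint_id not in CONSTRAINTS[self.model_id]:
            raise ValueError(
                f"constraint {self.constraint_id!r} invalid for {self.model_id}"
            )
        if self.model_id == "1F":
            if self.factor_correlation is not None:
                raise ValueError("1F cells carry no factor-correlation level")
        elif self.factor_correlation not in FACTOR_CORRELATIONS:
            raise ValueError("factor_correlation must be 0 or 0.5")

    @property
    def label(self) -> str:
        co = "" if self.factor_correlation is None else f"-CO{self.factor_correlation}"
        return f"{self.model_id}-{self.method}-N{self.N}-{self.constraint_id}{co}"

    def spec(self) -> FactorModelSpec:
        return make_model(self.model_id, self.factor_correlation or 0.0)


def design_cells(model_ids: Sequence[str] = MODEL_IDS) -> list[DesignCell]:
    """Enumerate the design: 24 (1F) + 60 (2F) + 72 (3F) = 156 cells."""
    cells = []
    for model_id in model_ids:
        cos = (None,) if model_id == "1F" else FACTOR_CORRELATIONS
        for method, n, cid, co in product(
            METHODS, SAMPLE_SIZES, CONSTRAINTS[model_id], cos
        ):
            cells.append(DesignCell(model_id, method, n, cid, co))
    return cells


def make_design(
    reps_per_cell: int, model_ids: Sequence[str] = MODEL_IDS
) -> list[tuple[DesignCell, int]]:
    """Full crossing of the design cells with replication indices."""
    if reps_per_cell < 1:
        raise ValueError("reps_per_cell must be >= 1")
    return [(cell, r) for cell in design_cells(model_ids) for r in range(reps_per_cell)]
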