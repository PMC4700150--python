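"""Fisher-information calculus for the gain from modeling means.

For the normal-theory ML estimator of the covariance-structure parameters
theta, the asymptotic covariance of sqrt(n)(theta_hat - theta) is V = Ic^-1,
with Ic the covariance-structure information.  Adding a mean structure
mu = tau + Lambda kappa contributes

* added information about the loadings, (kappa kappa') (x) Sigma^-1 on the
  vec(Lambda) block (zero on the Phi and ThetaDelta blocks);
* cross information between theta and the mean parameters nu = (tau, kappa);
* the nu-block information [[Sigma^-1, Sigma^-1 Lambda],
                            [Lambda' Sigma^-1, Lambda' Sigma^-1 Lambda]].

The net information about theta is the Schur complement
Istar - I_theta_nu I_nu_nu^-1 I_nu_theta; it is positive semi-definite, and
strictly nonzero exactly when the mean structure is not saturated and kappa
is nonzero.  The asymptotic relative efficiency (ARE) of a loading estimate
is the ratio of its asymptotic variance with the mean structure to that
without; values below 1 favor modeling the means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cfa_estimation import Parameterization, dsigma_stack, mean_jacobian
from .population_models import (
    ConstraintPattern,
    FactorModelSpec,
    build_population_moments,
)


def _resolve(spec: FactorModelSpec, constraint: ConstraintPattern | None):
    """Parameterization, true parameter vector, implied Sigma^-1 and the
    model matrices at the truth, in the constraint's identification."""
    par = Parameterization(spec, constraint)
    x = par.true_values()
    Lam, Phi, delta, tau, kappa = par.unpack(x)
    Sigma = Lam @ Phi @ Lam.T + np.diag(delta)
    Sinv = np.linalg.inv(Sigma)
    return par, x, Lam, Phi, delta, kappa, Sigma, Sinv


def info_cov_only(
    spec: FactorModelSpec, constraint: ConstraintPattern | None = None
) -> np.ndarray:
    """Covariance-structure information Ic on the free theta coordinates:
    Ic_jk = 1/2 tr(Sigma^-1 dSigma_j Sigma^-1 dSigma_k), so that Ic^-1 is the
    asymptotic covariance of sqrt(n)(theta_hat - theta)."""
    par, _, Lam, Phi, _, _, _, Sinv = _resolve(spec, constraint)
    D = dsigma_stack(par, Lam, Phi)
    E = Sinv @ D  # stack of Sigma^-1 dSigma_j
    Ic = 0.5 * np.einsum("aij,bji->ab", E, E)
    if np.linalg.eigvalsh(Ic)[0] <= 1e-10:
        raise np.linalg.LinAlgError(
            "covariance-structure information is singular: model under-identified"
        )
    return Ic


def added_information(
    spec: FactorModelSpec, constraint: ConstraintPattern | None = None
) -> np.ndarray:
    """Added information about theta from the mean structure:
    (kappa kappa') (x) Sigma^-1 on the loading block, zero elsewhere, reduced
    to the free theta coordinates."""
    if constraint is None:
        par, x, Lam, Phi, delta, kappa, Sigma, Sinv = _resolve(spec, None)
        kappa = spec.kappa
    else:
        par, x, Lam, Phi, delta, kappa, Sigma, Sinv = _resolve(spec, constraint)
    Jt = mean_jacobian(par, Lam, kappa)[:, : par.n_theta]
    return Jt.T @ Sinv @ Jt


@dataclass
class InformationBlocks:
    """The information partition for one constraint pattern."""

    Ic: np.ndarray
    Istar: np.ndarray
    Ithetanu: np.ndarray
    Inunu: np.ndarray
    param: Parameterization

    @property
    def full(self) -> np.ndarray:
        """Joint information for (theta, nu)."""
        top = np.hstack([self.Ic + self.Istar, self.Ithetanu])
        bottom = np.hstack([self.Ithetanu.T, self.Inunu])
        return np.vstack([top, bottom])


def information_blocks(
    spec: FactorModelSpec, constraint: ConstraintPattern
) -> InformationBlocks:
    par, x, Lam, Phi, delta, kappa, Sigma, Sinv = _resolve(spec, constraint)
    D = dsigma_stack(par, Lam, Phi)
    E = Sinv @ D
    Ic = 0.5 * np.einsum("aij,bji->ab", E, E)
    J = mean_jacobian(par, Lam, kappa)
    JS = J.T @ Sinv @ J
    nt = par.n_theta
    return InformationBlocks(
        Ic=Ic,
        Istar=JS[:nt, :nt],
        Ithetanu=JS[:nt, nt:],
        Inunu=JS[nt:, nt:],
        param=par,
    )


def net_information(spec: FactorModelSpec, constraint: ConstraintPattern) -> np.ndarray:
    """Net information about theta from the mean structure:
    Istar - I_theta_nu I_nu_nu^-1 I_nu_theta (positive semi-definite; the
    zero matrix when the mean structure is saturated or kappa = 0)."""
    blocks = information_blocks(spec, constraint)
    if np.linalg.eigvalsh(blocks.Inunu)[0] <= 1e-12:
        raise np.linalg.LinAlgError("mean structure not identified (singular Inunu)")
    return blocks.Istar - blocks.Ithetanu @ np.linalg.solve(
        blocks.Inunu, blocks.Ithetanu.T
    )


@dataclass
class AsymptoticCovariances:
    """Asymptotic covariances of sqrt(n)(theta_hat - theta) without and with
    the mean structure."""

    V_cov_only: np.ndarray
    V_meancov: np.ndarray
    param: Parameterization


def asymptotic_covariances(
    spec: FactorModelSpec, constraint: ConstraintPattern
) -> AsymptoticCovariances:
    blocks = information_blocks(spec, constraint)
    net = blocks.Istar - blocks.Ithetanu @ np.linalg.solve(
        blocks.Inunu, blocks.Ithetanu.T
    )
    return AsymptoticCovariances(
        V_cov_only=np.linalg.inv(blocks.Ic),
        V_meancov=np.linalg.inv(blocks.Ic + net),
        param=blocks.param,
    )


def analytic_are(spec: FactorModelSpec, constraint: ConstraintPattern) -> np.ndarray:
    """Per-free-loading analytic ARE: diag(V_meancov)/diag(V_cov_only) on the
    loading coordinates.  All ratios are 1 under a saturated mean structure
    and strictly below 1 otherwise (for nonzero kappa)."""
    cov = asymptotic_covariances(spec, constraint)
    idx = cov.param.loading_index
    return np.diag(cov.V_meancov)[idx] / np.diag(cov.V_cov_only)[idx]


def empirical_are(
    estimates_with_means: np.ndarray,
    estimates_without: np.ndarray,
    N: int | None = None,
    min_replicates: int = 30,
) -> np.ndarray:
    """Monte Carlo ARE: per-loading ratio of across-replicate variances of
    sqrt(N)-scaled loading estimates, mean-structure model over
    covariance-only model.  The sqrt(N) factors cancel when both sets share
    one sample size, so N only matters for mixed-N inputs (not used here).

    Warns when either replicate set has fewer than ``min_replicates`` rows.
    """
    a = np.asarray(estimates_with_means, dtype=float)
    b = np.asarray(estimates_without, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[1] != b.shape[1]:
        raise ValueError("replicate sets must cover the same loadings")
    if min(len(a), len(b)) < min_replicates:
        warnings.warn(
            f"ARE from fewer than {min_replicates} valid replicates is unstable",
            stacklevel=2,
        )
    return a.var(axis=0, ddof=1) / b.var(axis=0, ddof=1)
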