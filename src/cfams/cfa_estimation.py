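"""Fitting CFA and CFA-MS models by ML and ULS.

The free-parameter vector is laid out as theta = [free loadings, free factor
(co)variances, unique variances] followed, when a mean structure is estimated,
by nu = [free intercepts, factor means].  Two equivalent identifications are
supported: unit factor variances (diag Phi = 1, all pattern loadings free)
and marker scaling (first loading of each factor fixed at 1, factor variances
free, the form in which the saturated constraint C1 is stated).  Fitting
always uses the unit-variance coordinates — the marker metric has a
degenerate ridge (factor variance to 0, loadings unbounded) when the marker
loading is weak — while the marker coordinates remain available for the
efficiency calculus and reparameterization checks; standardized solutions
are identical either way.

Optimization is Fisher scoring: damped Newton steps on the untransformed
parameters using the expected (information-matrix) Hessian, with analytic
gradients and a step-halving line search, capped at 250 iterations;
convergence is a relative discrepancy decrease below 1e-6.  A fit that hits
the cap or whose line search stalls is flagged non-convergent.  Unique
variances are left unconstrained so that Heywood cases (estimated unique
variance <= 0) can be detected at the optimum and screened out, as is done in
parameter-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .population_models import ConstraintPattern, FactorModelSpec
from .synthetic_data import SampleMoments

#: iteration cap shared by ML and ULS fits.
MAX_ITERATIONS = 250
#: convergence test: relative decrease of the discrepancy below this value.
FTOL = 1e-6
_PENALTY = 1e10  # objective value returned when implied Sigma is not PD


class Parameterization:
    """Bijection between the free-parameter vector and (Lambda, Phi,
    ThetaDelta, tau, kappa) under a given identification."""

    def __init__(
        self,
        spec: FactorModelSpec,
        constraint: ConstraintPattern | None = None,
        marker_scaling: bool | None = None,
    ):
        """marker_scaling=None follows the constraint's declared
        identification (marker loadings fixed at 1 under C1).  Passing False
        selects the equivalent unit-factor-variance coordinates instead —
        the same model manifold, reparameterized — which is what the fitting
        routine uses: the marker metric has a degenerate ridge (factor
        variance to 0, loadings unbounded) when the marker loading is weak.
        """
        self.spec = spec
        self.constraint = constraint
        self.include_means = constraint is not None
        if marker_scaling is None:
            marker_fixed = bool(constraint and constraint.marker_lambda_fixed)
        else:
            marker_fixed = bool(marker_scaling)
        self.marker_fixed = marker_fixed
        p, q = spec.p, spec.q
        self.p, self.q = p, q

        rows, cols = np.nonzero(spec.Lambda)
        self.Lam0 = np.zeros((p, q))
        if marker_fixed:
            markers = spec.marker_items
            self.Lam0[markers, np.arange(q)] = 1.0
            keep = ~np.isin(rows, markers)
            rows, cols = rows[keep], cols[keep]
        self.lam_rows, self.lam_cols = rows, cols
        n_lam = len(rows)
        self.phi_i, self.phi_j = np.triu_indices(q, k=1)
        n_phid = q if marker_fixed else 0
        n_phio = len(self.phi_i)
        self.n_theta = n_lam + n_phid + n_phio + p

        if self.include_means:
            self.tau_free = np.flatnonzero(constraint.tau_free)
            n_nu = len(self.tau_free) + q
        else:
            self.tau_free = np.empty(0, dtype=int)
            n_nu = 0
        self.n_nu = n_nu
        self.n_params = self.n_theta + n_nu

        i = 0
        self.sl_lam = slice(i, i + n_lam); i += n_lam
        self.sl_phid = slice(i, i + n_phid); i += n_phid
        self.sl_phio = slice(i, i + n_phio); i += n_phio
        self.sl_delta = slice(i, i + p); i += p
        self.sl_tau = slice(i, i + len(self.tau_free)); i += len(self.tau_free)
        self.sl_kappa = slice(i, i + (q if self.include_means else 0))

    # -- vector <-> matrices ------------------------------------------------
    def unpack(self, x):
        q = self.q
        Lam = self.Lam0.copy()
        Lam[self.lam_rows, self.lam_cols] = x[self.sl_lam]
        Phi = np.eye(q) if not self.marker_fixed else np.diag(x[self.sl_phid])
        Phi = Phi.copy()
        off = x[self.sl_phio]
        Phi[self.phi_i, self.phi_j] = off
        Phi[self.phi_j, self.phi_i] = off
        delta = x[self.sl_delta]
        if self.include_means:
            tau = np.zeros(self.p)
            tau[self.tau_free] = x[self.sl_tau]
            kappa = x[self.sl_kappa]
        else:
            tau = np.zeros(self.p)
            kappa = np.zeros(q)
        return Lam, Phi, delta, tau, kappa

    def pack(self, Lam, Phi, delta, tau=None, kappa=None):
        x = np.empty(self.n_params)
        x[self.sl_lam] = np.asarray(Lam)[self.lam_rows, self.lam_cols]
        if self.marker_fixed:
            x[self.sl_phid] = np.diag(Phi)
        x[self.sl_phio] = np.asarray(Phi)[self.phi_i, self.phi_j]
        x[self.sl_delta] = delta
        if self.include_means:
            x[self.sl_tau] = np.asarray(tau)[self.tau_free]
            x[self.sl_kappa] = kappa
        return x

    def start_values(self, moments: SampleMoments | None = None):
        """Structure-agnostic starting point.

        Covariance side: loadings 0.5, unique variances 0.5, factor
        covariances 0 (variances 0.5 when free).  Mean side: kappa starts at
        the least-squares solution of the fixed-intercept items' mean
        equations (those items must reproduce xbar through Lambda kappa
        alone), then the free intercepts absorb the remaining sample means.
        Starting the means near their feasible region keeps the initial
        discrepancy from being dominated by the mean term, which otherwise
        drags the loadings toward poor local optima.
        """
        x = np.zeros(self.n_params)
        x[self.sl_lam] = 0.5
        if self.marker_fixed:
            x[self.sl_phid] = 0.5
        x[self.sl_delta] = 0.5
        if self.include_means and moments is not None:
            Lam0 = self.Lam0.copy()
            Lam0[self.lam_rows, self.lam_cols] = 0.5
            fixed = np.setdiff1d(np.arange(self.p), self.tau_free)
            if len(fixed):
                kappa0, *_ = np.linalg.lstsq(Lam0[fixed], moments.xbar[fixed],
                                             rcond=None)
            else:  # no intercept fixed: means are saturated, any kappa works
                kappa0 = np.zeros(self.q)
            x[self.sl_kappa] = kappa0
            x[self.sl_tau] = (moments.xbar - Lam0 @ kappa0)[self.tau_free]
        return x

    def true_values(self):
        """The population parameters expressed in this identification.

        Under marker scaling the loadings, factor covariances and factor
        means are rescaled (lam* = lam/lam_m, phi*_jk = lam_mj lam_mk phi_jk);
        under any mean-structure constraint the free kappa and tau absorb the
        population means exactly (the generating models are consistent with
        every constraint pattern by construction).
        """
        spec = self.spec
        Lam, Phi = spec.Lambda.copy(), spec.Phi.copy()
        mu = spec.tau + Lam @ spec.kappa
        if self.marker_fixed:
            lm = Lam[spec.marker_items, np.arange(self.q)]
            Lam = Lam / lm
            Phi = Phi * np.outer(lm, lm)
        if self.include_means:
            lam_m = Lam[spec.marker_items, np.arange(self.q)]
            kappa = mu[spec.marker_items] / lam_m
            tau = mu - Lam @ kappa
        else:
            tau, kappa = None, None
        return self.pack(Lam, Phi, spec.ThetaDelta, tau, kappa)

    @property
    def loading_index(self):
        """Coordinates of the free loadings within the parameter vector."""
        return np.arange(self.sl_lam.start, self.sl_lam.stop)

    def parameter_names(self):
        names = [f"lambda[{i},{j}]" for i, j in zip(self.lam_rows, self.lam_cols)]
        if self.marker_fixed:
            names += [f"phi[{j},{j}]" for j in range(self.q)]
        names += [f"phi[{i},{j}]" for i, j in zip(self.phi_i, self.phi_j)]
        names += [f"theta_delta[{i}]" for i in range(self.p)]
        names += [f"tau[{i}]" for i in self.tau_free]
        if self.include_means:
            names += [f"kappa[{j}]" for j in range(self.q)]
        return names


@dataclass
class ParameterSet:
    """Covariance-structure parameters theta and mean-structure parameters nu
    in the coordinates of a :class:`Parameterization`."""

    theta: np.ndarray
    nu: np.ndarray
    param: Parameterization

    @classmethod
    def from_vector(cls, x, param: Parameterization):
        return cls(theta=x[: param.n_theta], nu=x[param.n_theta :], param=param)

    @property
    def x(self):
        return np.concatenate([self.theta, self.nu])

    def matrices(self):
        return self.param.unpack(self.x)


# -- discrepancy functions --------------------------------------------------

def _implied(par: Parameterization, x):
    Lam, Phi, delta, tau, kappa = par.unpack(x)
    Sigma = Lam @ Phi @ Lam.T + np.diag(delta)
    mu = tau + Lam @ kappa if par.include_means else None
    return Lam, Phi, delta, Sigma, mu


def _chain_grad(par, Lam, Phi, G, g_mu, kappa):
    """Map the matrix gradients dF/dSigma (G, symmetric) and dF/dmu (g_mu)
    onto the free-parameter vector."""
    grad = np.empty(par.n_params)
    GLP = 2.0 * G @ Lam @ Phi
    if par.include_means and g_mu is not None:
        GLP = GLP + np.outer(g_mu, kappa)
    grad[par.sl_lam] = GLP[par.lam_rows, par.lam_cols]
    LGL = Lam.T @ G @ Lam
    if par.marker_fixed:
        grad[par.sl_phid] = np.diag(LGL)
    grad[par.sl_phio] = 2.0 * LGL[par.phi_i, par.phi_j]
    grad[par.sl_delta] = np.diag(G)
    if par.include_means and g_mu is not None:
        grad[par.sl_tau] = g_mu[par.tau_free]
        grad[par.sl_kappa] = Lam.T @ g_mu
    return grad


def dsigma_stack(par: Parameterization, Lam, Phi) -> np.ndarray:
    """Derivatives of Sigma with respect to each free theta coordinate,
    stacked as (n_theta, p, p)."""
    p = par.p
    D = np.zeros((par.n_theta, p, p))
    LP = Lam @ Phi
    k = 0
    for i, j in zip(par.lam_rows, par.lam_cols):
        D[k, i, :] += LP[:, j]
        D[k, :, i] += LP[:, j]
        k += 1
    if par.marker_fixed:
        for j in range(par.q):
            D[k] = np.outer(Lam[:, j], Lam[:, j])
            k += 1
    for i, j in zip(par.phi_i, par.phi_j):
        D[k] = np.outer(Lam[:, i], Lam[:, j]) + np.outer(Lam[:, j], Lam[:, i])
        k += 1
    for i in range(p):
        D[k, i, i] = 1.0
        k += 1
    return D


def mean_jacobian(par: Parameterization, Lam, kappa) -> np.ndarray:
    """d mu / d (free parameters), p x n_params (zero without mean structure)."""
    J = np.zeros((par.p, par.n_params))
    sl = par.sl_lam.start
    for k, (i, j) in enumerate(zip(par.lam_rows, par.lam_cols)):
        J[i, sl + k] = kappa[j]
    if par.include_means:
        for k, i in enumerate(par.tau_free):
            J[i, par.sl_tau.start + k] = 1.0
        J[:, par.sl_kappa] = Lam
    return J


def _expected_hessian(x, par, method: str):
    """Expected (Fisher) Hessian of the discrepancy at x.

    ML: 2 Ic + 2 J' Sigma^-1 J on the free coordinates (the information of
    the mean-and-covariance model, on the discrepancy scale); ULS: the
    Gauss-Newton surrogate sum_pq dSigma_j dSigma_k + J'J.  Returns None when
    the implied Sigma is not positive definite (ML only).
    """
    Lam, Phi, delta, tau, kappa = par.unpack(x)
    Sigma = Lam @ Phi @ Lam.T + np.diag(delta)
    D = dsigma_stack(par, Lam, Phi)
    H = np.zeros((par.n_params, par.n_params))
    nt = par.n_theta
    if method == "ML":
        try:
            cho = sla.cho_factor(Sigma, lower=True, check_finite=False)
        except sla.LinAlgError:
            return None
        Sinv = sla.cho_solve(cho, np.eye(par.p), check_finite=False)
        E = np.matmul(Sinv, D)
        H[:nt, :nt] = np.einsum("aij,bji->ab", E, E)
        if par.include_means:
            J = mean_jacobian(par, Lam, kappa)
            H += 2.0 * J.T @ Sinv @ J
    else:
        H[:nt, :nt] = np.einsum("aij,bij->ab", D, D)
        if par.include_means:
            J = mean_jacobian(par, Lam, kappa)
            H += J.T @ J
    return H


def _ml_value_grad(x, par, S, xbar, logdetS):
    Lam, Phi, delta, Sigma, mu = _implied(par, x)
    try:
        cho = sla.cho_factor(Sigma, lower=True, check_finite=False)
    except sla.LinAlgError:
        return _PENALTY, np.zeros(par.n_params)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    Sinv = sla.cho_solve(cho, np.eye(par.p), check_finite=False)
    F = logdet + np.sum(S * Sinv) - logdetS - par.p
    A = S
    if par.include_means:
        d = xbar - mu
        Sid = Sinv @ d
        F += d @ Sid
        A = S + np.outer(d, d)
        g_mu = -2.0 * Sid
    else:
        g_mu = None
    G = Sinv - Sinv @ A @ Sinv
    return F, _chain_grad(par, Lam, Phi, G, g_mu, x[par.sl_kappa])


def _uls_value_grad(x, par, S, xbar):
    Lam, Phi, delta, Sigma, mu = _implied(par, x)
    R = Sigma - S
    F = 0.5 * np.sum(R * R)
    if par.include_means:
        d = xbar - mu
        F += 0.5 * d @ d
        g_mu = -d
    else:
        g_mu = None
    return F, _chain_grad(par, Lam, Phi, R, g_mu, x[par.sl_kappa])


def _safe_logdet(S):
    sign, val = np.linalg.slogdet(S)
    return val if sign > 0 and np.isfinite(val) else 0.0


def ml_discrepancy(params: ParameterSet, moments: SampleMoments,
                   include_means: bool | None = None) -> float:
    """Normal-theory ML fit function
    F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p  [+ (xbar-mu)' Sigma^-1 (xbar-mu)].
    """
    par = params.param
    if include_means is None:
        include_means = par.include_means
    if include_means and not par.include_means:
        raise ValueError("parameterization carries no mean structure")
    f, _ = _ml_value_grad(params.x, par, moments.S, moments.xbar,
                          _safe_logdet(moments.S))
    return float(f)


def uls_discrepancy(params: ParameterSet, moments: SampleMoments,
                    include_means: bool | None = None) -> float:
    """ULS fit function F = 1/2 tr[(S - Sigma)^2]  [+ 1/2 |xbar - mu|^2]."""
    par = params.param
    if include_means is None:
        include_means = par.include_means
    if include_means and not par.include_means:
        raise ValueError("parameterization carries no mean structure")
    f, _ = _uls_value_grad(params.x, par, moments.S, moments.xbar)
    return float(f)


# -- fitting ----------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of one estimation run."""

    estimates: ParameterSet
    converged: bool
    n_iter: int
    heywood: bool
    discrepancy: float
    standardized_loadings: np.ndarray
    method: str = "ML"

    @property
    def matrices(self):
        return self.estimates.matrices()

    @property
    def proper(self) -> bool:
        """Convergent, no Heywood case, and finite standardized solution."""
        return (
            self.converged
            and not self.heywood
            and bool(np.all(np.isfinite(self.standardized_loadings)))
        )


def standardize_loadings(spec: FactorModelSpec, Lam, Phi, delta) -> np.ndarray:
    """Rescale loadings to the unit-observed-variance metric:
    lam_std_ij = lam_ij sqrt(phi_jj) / sqrt(implied var of item i).

    Factors are sign-aligned so that the sum of each factor's pattern
    loadings is nonnegative (the covariance structure is invariant to factor
    reflection).  Negative estimated factor or item variances yield NaN,
    which marks the solution improper.
    """
    implied_var = np.einsum("ij,jk,ik->i", Lam, Phi, Lam)
    implied_var = implied_var + delta
    with np.errstate(invalid="ignore", divide="ignore"):
        std = Lam * np.sqrt(np.diag(Phi))[None, :] / np.sqrt(implied_var)[:, None]
    for j, items in enumerate(spec.factor_items):
        col = std[items, j]
        if np.all(np.isfinite(col)) and col.sum() < 0:
            std[:, j] = -std[:, j]
    return std


def fit(
    spec: FactorModelSpec,
    constraint: ConstraintPattern | None,
    moments: SampleMoments,
    method: str = "ML",
    max_iter: int = MAX_ITERATIONS,
    param: Parameterization | None = None,
) -> FitResult:
    """Minimize the ML or ULS discrepancy for one sample.

    constraint=None fits the covariance structure alone; otherwise the mean
    structure is estimated under the given intercept pattern.  Convergence is
    declared by the optimizer's relative-decrease/gradient test within
    ``max_iter`` iterations; hitting the cap or a failed line search flags the
    fit non-convergent (the result is retained).
    """
    if method not in ("ML", "ULS"):
        raise ValueError(f"unknown method {method!r}")
    par = (param if param is not None
           else Parameterization(spec, constraint, marker_scaling=False))
    S, xbar = moments.S, moments.xbar
    if method == "ML":
        logdetS = _safe_logdet(S)
        fun = lambda x: _ml_value_grad(x, par, S, xbar, logdetS)
    else:
        fun = lambda x: _uls_value_grad(x, par, S, xbar)

    x0 = par.start_values(moments)
    if fun(x0)[0] >= _PENALTY:
        # fallback start: near-null model with sample variances
        x0[par.sl_lam] = 0.3
        x0[par.sl_delta] = np.diag(S)
    x, f, n_iter, converged = _fisher_scoring(fun, par, method, x0, max_iter)
    Lam, Phi, delta, tau, kappa = par.unpack(x)
    heywood = bool(np.any(delta <= 0.0))
    std = standardize_loadings(spec, Lam, Phi, delta)
    return FitResult(
        estimates=ParameterSet.from_vector(x, par),
        converged=converged,
        n_iter=n_iter,
        heywood=heywood,
        discrepancy=float(f),
        standardized_loadings=std,
        method=method,
    )


def _fisher_scoring(fun, par, method, x0, max_iter=MAX_ITERATIONS, ftol=FTOL):
    """Damped Fisher-scoring iteration.

    Newton steps with the expected Hessian, ridged when the solve fails or
    yields a non-descent direction, and an Armijo step-halving line search.
    Convergence: relative discrepancy decrease <= ftol.  Returns
    (x, f, n_iter, converged).
    """
    x = x0
    f, g = fun(x)
    eye = np.eye(par.n_params)
    for it in range(1, max_iter + 1):
        if np.max(np.abs(g)) < 1e-9:
            return x, f, it, True
        H = _expected_hessian(x, par, method)
        delta = None
        ridge = 0.0
        scale = 1.0 if H is None else max(np.mean(np.abs(np.diag(H))), 1e-8)
        for _ in range(10):
            if H is None:
                break
            try:
                cho = sla.cho_factor(H + ridge * scale * eye, lower=True,
                                     check_finite=False)
                cand = -sla.cho_solve(cho, g, check_finite=False)
            except sla.LinAlgError:
                ridge = max(ridge * 10.0, 1e-8)
                continue
            if g @ cand < 0:
                delta = cand
                break
            ridge = max(ridge * 10.0, 1e-8)
        if delta is None:
            delta = -g / scale  # steepest-descent fallback
        slope = g @ delta
        step = 1.0
        accepted = False
        for _ in range(30):
            xn = x + step * delta
            fn, gn = fun(xn)
            if fn <= f + 1e-4 * step * slope:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            return x, f, it, False  # line search stalled
        rel = (f - fn) / max(abs(f), 1.0)
        x, f, g = xn, fn, gn
        if 0.0 <= rel <= ftol:
            return x, f, it, True
    return x, f, max_iter, False
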