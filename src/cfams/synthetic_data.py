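"""Seeded multivariate-normal data generation from model-implied moments.

Samples are drawn from N(mu, Sigma) with (Sigma, mu) the population moments of
a :class:`~cfams.population_models.FactorModelSpec`; latent variables are never
materialized, which is distributionally equivalent under the linear factor
model.  Raw data are immediately reduced to the sufficient statistics
(S, xbar, N) that both discrepancy functions consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population_models import FactorModelSpec, build_population_moments


@dataclass(frozen=True)
class SampleMoments:
    """Sample covariance (N-1 divisor), sample mean vector, and sample size."""

    S: np.ndarray
    xbar: np.ndarray
    N: int
    seed: int | None = None

    @property
    def p(self) -> int:
        return len(self.xbar)


def derive_seed(master_seed: int, *keys: int) -> int:
    """Deterministic child seed for a (cell, replicate) coordinate.

    Uses numpy's SeedSequence so that distinct coordinates give statistically
    independent streams while the whole study stays reproducible from one
    master seed.
    """
    state = np.random.SeedSequence([int(master_seed), *[int(k) for k in keys]])
    return int(state.generate_state(1, np.uint32)[0])


def simulate_sample(
    spec: FactorModelSpec,
    N: int,
    seed: int,
    return_raw: bool = False,
) -> SampleMoments | tuple[SampleMoments, np.ndarray]:
    """Draw N observations from the model-implied MVN and return moments.

    The same (spec, N, seed) always yields bitwise-identical output.
    """
    sigma, mu = build_population_moments(spec)
    p = spec.p
    if N < p + 1:
        raise ValueError(f"N={N} too small for a positive-definite S (need >= {p + 1})")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(sigma)
    X = rng.standard_normal((N, p)) @ chol.T + mu
    xbar = X.mean(axis=0)
    Xc = X - xbar
    S = (Xc.T @ Xc) / (N - 1)
    moments = SampleMoments(S=S, xbar=xbar, N=N, seed=int(seed))
    if return_raw:
        return moments, X
    return moments


def population_fixture(spec: FactorModelSpec, N: int = 10**6) -> SampleMoments:
    """Package the exact population moments as a pseudo-sample.

    Fitting any correctly specified model to this fixture drives the
    discrepancy to zero; used for estimator self-consistency checks.  N only
    labels the fixture (the moments are exact).
    """
    sigma, mu = build_population_moments(spec)
    return SampleMoments(S=sigma, xbar=mu, N=N, seed=None)


def export_raw_csv(X: np.ndarray, path) -> None:
    """Write a raw sample (one row per observation) as plain CSV."""
    header = ",".join(f"x{i + 1}" for i in range(X.shape[1]))
    np.savetxt(path, X, delimiter=",", header=header, comments="")
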