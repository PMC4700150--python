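import numpy as np
import pytest

from cfams.cfa_estimation import (
    ParameterSet,
    Parameterization,
    fit,
    ml_discrepancy,
    uls_discrepancy,
)
from cfams.population_models import (
    CONSTRAINTS,
    FactorModelSpec,
    constraint_pattern,
    make_model,
)
from cfams.synthetic_data import SampleMoments, population_fixture, simulate_sample


def _toy_two_item():
    """A 2-item, 1-factor pattern used only to evaluate the discrepancy
    formulas by hand (synthetic; not part of the study design)."""
    return FactorModelSpec(
        model_id="1F",
        Lambda=np.array([[0.3], [0.3]]),
        Phi=np.eye(1),
        ThetaDelta=np.array([0.91, 0.91]),
        tau=np.zeros(2),
        kappa=np.zeros(1),
    )


class TestDiscrepancies:
    def test_ml_hand_computed_value(self):
        # S = [[1, .5], [.5, 1]], Sigma(theta) = I:
        # F = ln|I| + tr(S) - ln|S| - p = -ln(0.75) = 0.287682
        spec = _toy_two_item()
        par = Parameterization(spec, None)
        x = par.pack(np.zeros((2, 1)), np.eye(1), np.ones(2))
        moments = SampleMoments(S=np.array([[1.0, 0.5], [0.5, 1.0]]),
                                xbar=np.zeros(2), N=100)
        f = ml_discrepancy(ParameterSet.from_vector(x, par), moments)
        assert f == pytest.approx(-np.log(0.75), abs=1e-10)

    def test_uls_hand_computed_value(self):
        spec = _toy_two_item()
        par = Parameterization(spec, None)
        x = par.pack(np.zeros((2, 1)), np.eye(1), np.ones(2))
        moments = SampleMoments(S=np.array([[1.0, 0.5], [0.5, 1.0]]),
                                xbar=np.zeros(2), N=100)
        f = uls_discrepancy(ParameterSet.from_vector(x, par), moments)
        assert f == pytest.approx(0.25, abs=1e-12)
        # Sigma = 0 against S = I at p = 2: 1/2 * 2 = 1
        x0 = par.pack(np.zeros((2, 1)), np.eye(1), np.zeros(2))
        f0 = uls_discrepancy(ParameterSet.from_vector(x0, par),
                             SampleMoments(S=np.eye(2), xbar=np.zeros(2), N=10))
        assert f0 == pytest.approx(1.0)

    def test_zero_at_truth_and_nonnegative(self, specs):
        rng = np.random.default_rng(0)
        for spec in specs.values():
            par = Parameterization(spec, None)
            fx = population_fixture(spec)
            truth = ParameterSet.from_vector(par.true_values(), par)
            assert ml_discrepancy(truth, fx) == pytest.approx(0.0, abs=1e-10)
            assert uls_discrepancy(truth, fx) == pytest.approx(0.0, abs=1e-12)
            for _ in range(5):
                x = par.true_values() + 0.05 * rng.standard_normal(par.n_params)
                ps = ParameterSet.from_vector(x, par)
                assert ml_discrepancy(ps, fx) >= 0
                assert uls_discrepancy(ps, fx) >= 0


class TestFitSelfConsistency:
    @pytest.mark.parametrize("method", ["ML", "ULS"])
    def test_recovers_truth_on_population_fixture(self, specs, method):
        for spec in specs.values():
            fx = population_fixture(spec)
            for cid in CONSTRAINTS[spec.model_id]:
                con = None if cid == "NONE" else constraint_pattern(spec.model_id, cid)
                res = fit(spec, con, fx, method)
                assert res.converged and not res.heywood, (spec.model_id, cid)
                mask = spec.Lambda != 0
                err = np.max(np.abs(res.standardized_loadings[mask] - spec.Lambda[mask]))
                assert err < 1e-4, (spec.model_id, cid, method, err)

    def test_tau_equivalent_constraint_forces_kappa(self, spec_1f, fixture_1f):
        # mu = 4.8 = 0.30 kappa under C2, so kappa must estimate 16
        con = constraint_pattern("1F", "C2")
        res = fit(spec_1f, con, fixture_1f, "ML")
        kappa = res.estimates.matrices()[4]
        assert kappa[0] == pytest.approx(16.0, abs=1e-4)

    def test_marker_and_variance_identifications_agree(self, spec_1f, fixture_1f):
        # C1 in marker scaling (loading fixed at 1) must, after
        # standardization, match the unit-factor-variance covariance-only fit
        c1 = constraint_pattern("1F", "C1")
        par_marker = Parameterization(spec_1f, c1, marker_scaling=True)
        res_marker = fit(spec_1f, c1, fixture_1f, "ML", param=par_marker)
        res_unitvar = fit(spec_1f, None, fixture_1f, "ML")
        np.testing.assert_allclose(
            res_marker.standardized_loadings,
            res_unitvar.standardized_loadings,
            atol=1e-4,
        )

    def test_degenerate_sample_never_a_silent_success(self, spec_1f):
        # rank-2 "covariance" from two observations
        rng = np.random.default_rng(1)
        X = rng.standard_normal((2, 12))
        S = np.cov(X, rowvar=False)
        moments = SampleMoments(S=S, xbar=X.mean(axis=0), N=2)
        res = fit(spec_1f, None, moments, "ML")
        assert not res.proper

    def test_iteration_cap_flags_nonconvergence(self, spec_1f):
        m = simulate_sample(spec_1f, 100, 99)
        res = fit(spec_1f, constraint_pattern("1F", "C2"), m, "ML", max_iter=2)
        assert not res.converged and res.n_iter <= 2


class TestParameterization:
    def test_pack_unpack_round_trip(self, specs):
        for spec in specs.values():
            for cid in CONSTRAINTS[spec.model_id]:
                con = None if cid == "NONE" else constraint_pattern(spec.model_id, cid)
                par = Parameterization(spec, con)
                x = par.true_values()
                assert len(x) == par.n_params
                assert np.array_equal(par.pack(*par.unpack(x)), x)
                assert len(par.parameter_names()) == par.n_params

    def test_theta_nu_split_counts(self, spec_1f):
        con = constraint_pattern("1F", "C3")
        par = Parameterization(spec_1f, con)
        ps = ParameterSet.from_vector(par.true_values(), par)
        # 12 loadings + 12 unique variances; 6 free tau + 1 kappa
        assert len(ps.theta) == 24
        assert len(ps.nu) == 7
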