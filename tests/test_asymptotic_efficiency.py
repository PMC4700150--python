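import dataclasses

import numpy as np
import pytest

from cfams.asymptotic_efficiency import (
    added_information,
    analytic_are,
    asymptotic_covariances,
    empirical_are,
    info_cov_only,
    information_blocks,
    net_information,
)
from cfams.cfa_estimation import Parameterization, _ml_value_grad, _safe_logdet
from cfams.population_models import CONSTRAINTS, constraint_pattern, make_model
from cfams.synthetic_data import population_fixture


def _zero_kappa(spec):
    return dataclasses.replace(spec, kappa=np.zeros(spec.q))


def _all_constraints():
    out = []
    for mid in ("1F", "2F", "3F"):
        for co in ([0.0] if mid == "1F" else [0.0, 0.5]):
            spec = make_model(mid, co)
            for cid in CONSTRAINTS[mid][1:]:
                out.append((spec, constraint_pattern(mid, cid)))
    return out


class TestInformationMatrices:
    def test_info_matches_numeric_hessian_of_ml_discrepancy(self, spec_1f):
        # central-difference Hessian of F at the truth, halved, equals Ic
        par = Parameterization(spec_1f, None)
        fx = population_fixture(spec_1f)
        logdetS = _safe_logdet(fx.S)
        grad = lambda x: _ml_value_grad(x, par, fx.S, fx.xbar, logdetS)[1]
        x0 = par.true_values()
        h = 1e-5
        H = np.zeros((par.n_params, par.n_params))
        for i in range(par.n_params):
            e = np.zeros(par.n_params)
            e[i] = h
            H[:, i] = (grad(x0 + e) - grad(x0 - e)) / (2 * h)
        Ic = info_cov_only(spec_1f)
        assert np.max(np.abs(0.5 * (H + H.T) / 2 - Ic)) < 1e-4

    def test_item_permutation_permutes_information(self, spec_1f):
        perm = np.array([3, 1, 0, 2, 5, 4, 7, 6, 9, 8, 11, 10])
        permuted = dataclasses.replace(
            spec_1f,
            Lambda=spec_1f.Lambda[perm],
            ThetaDelta=spec_1f.ThetaDelta[perm],
            tau=spec_1f.tau[perm],
        )
        Ic = info_cov_only(spec_1f)
        Ip = info_cov_only(permuted)
        # free-theta coordinates are [12 loadings, 12 unique variances]
        idx = np.concatenate([perm, 12 + perm])
        np.testing.assert_allclose(Ip, Ic[np.ix_(idx, idx)], atol=1e-12)

    def test_added_information_structure(self, spec_1f):
        # kappa kappa' (x) Sigma^-1 on the loading block, zero elsewhere
        I = added_information(spec_1f)
        sigma = (spec_1f.Lambda @ spec_1f.Phi @ spec_1f.Lambda.T
                 + np.diag(spec_1f.ThetaDelta))
        np.testing.assert_allclose(I[:12, :12], 36.0 * np.linalg.inv(sigma),
                                   atol=1e-12)
        assert np.all(I[12:, :] == 0) and np.all(I[:, 12:] == 0)

    def test_added_information_vanishes_without_factor_means(self, spec_1f):
        assert np.all(added_information(_zero_kappa(spec_1f)) == 0)


class TestNetInformation:
    def test_saturated_mean_structure_gains_nothing(self, spec_1f):
        net = net_information(spec_1f, constraint_pattern("1F", "C1"))
        assert np.max(np.abs(net)) < 1e-10

    def test_tau_equivalent_gain_is_psd_and_nonzero(self, spec_1f):
        net = net_information(spec_1f, constraint_pattern("1F", "C2"))
        eigs = np.linalg.eigvalsh(net)
        assert eigs[0] >= -1e-10 and eigs[-1] > 0

    @pytest.mark.parametrize("spec,con", _all_constraints(),
                             ids=lambda v: getattr(v, "constraint_id", None)
                             or f"{v.model_id}-co{v.factor_correlation}")
    def test_net_information_psd_everywhere(self, spec, con):
        eigs = np.linalg.eigvalsh(net_information(spec, con))
        assert eigs[0] >= -1e-10

    def test_block_inverse_identity(self):
        spec = make_model("2F", 0.5)
        blocks = information_blocks(spec, constraint_pattern("2F", "C3"))
        nt = blocks.param.n_theta
        V_full = np.linalg.inv(blocks.full)[:nt, :nt]
        V_schur = asymptotic_covariances(spec, constraint_pattern("2F", "C3")).V_meancov
        assert np.max(np.abs(V_full - V_schur)) < 1e-8


class TestAre:
    def test_saturated_constraint_gives_unit_ratios(self, spec_1f):
        ratios = analytic_are(spec_1f, constraint_pattern("1F", "C1"))
        np.testing.assert_allclose(ratios, 1.0, atol=1e-8)

    def test_tau_equivalent_ratios_below_one(self, spec_1f):
        ratios = analytic_are(spec_1f, constraint_pattern("1F", "C2"))
        assert np.all(ratios < 1)

    @pytest.mark.parametrize("spec,con", _all_constraints(),
                             ids=lambda v: getattr(v, "constraint_id", None)
                             or f"{v.model_id}-co{v.factor_correlation}")
    def test_variance_reduction_inequality(self, spec, con):
        # diag V_meancov <= diag V_cov_only whenever kappa != 0
        cov = asymptotic_covariances(spec, con)
        assert np.all(np.diag(cov.V_meancov) <= np.diag(cov.V_cov_only) + 1e-10)

    def test_empirical_are_identity_and_scale_freeness(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((100, 5))
        np.testing.assert_allclose(empirical_are(a, a), 1.0)
        b = rng.standard_normal((100, 5))
        np.testing.assert_allclose(empirical_are(a, b, N=100),
                                   empirical_are(a, b, N=500))

    def test_empirical_are_warns_when_unstable(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning):
            empirical_are(rng.standard_normal((10, 2)), rng.standard_normal((10, 2)))

    def test_mismatched_loading_sets_rejected(self):
        with pytest.raises(ValueError):
            empirical_are(np.zeros((40, 3)), np.zeros((40, 2)))
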