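"""Kinetic model solutions: closed forms, integrators, and invariants."""

import numpy as np
import pytest

from conftest import (
    random_protocol,
    random_rd_params,
    rd_oracle_total,
    tlk_oracle_total,
)
from dsbkin.exceptions import NumericalError, ValidationError
from dsbkin.inference import predictions_for
from dsbkin.models import (
    DSBState,
    LPLParams,
    RDParams,
    TLKParams,
    lpl_predict,
    lpl_solve,
    rd_predict,
    rd_propagate_segment,
    rd_residual_lq,
    rd_solve,
    tlk_predict,
    tlk_solve,
)
from dsbkin.protocols import ExposureProtocol


class TestRDClosedForm:
    def test_rest_segment_is_pure_exponential_decay(self, rd_sparse):
        state = DSBState(dsb1=10.0, dsb2=5.0, dsb3=2.0)
        t = 7.5
        out = rd_propagate_segment(state, rd_sparse, 0.0, t)
        assert out.dsb1 == pytest.approx(10.0 * np.exp(-rd_sparse.v1 * t), rel=1e-12)
        assert out.dsb2 == pytest.approx(5.0 * np.exp(-rd_sparse.v2 * t), rel=1e-12)
        assert out.dsb3 == 2.0

    def test_long_exposure_reaches_first_class_fixed_point(self, rd_sparse):
        # dsb1 -> k1*R/(v1 + q1*R) as the exposure becomes very long
        r = 50.0
        out = rd_propagate_segment(DSBState(), rd_sparse, r, 5000.0)
        expected = rd_sparse.k1 * r / (rd_sparse.v1 + rd_sparse.q1 * r)
        assert out.dsb1 == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_adaptive_ode_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            p = random_rd_params(rng)
            prot = random_protocol(rng)
            ours = rd_predict(p, prot)
            ref = rd_oracle_total(p, prot)
            assert ours == pytest.approx(ref, rel=1e-8, abs=1e-12)

    def test_degenerate_equal_rates_match_oracle(self):
        # force v1 + q1*R == v2 + q2*R (a removable singularity of the
        # exponential cascade) to within 1e-12 relative and exactly
        rng = np.random.default_rng(42)
        for wiggle in [0.0, 1e-14, 1e-10]:
            r = 1000.0
            p0 = random_rd_params(rng)
            v2 = p0.v1 + p0.q1 * r - p0.q2 * r + wiggle
            if v2 <= 0:
                continue
            p = RDParams(p0.k1, p0.k2, p0.k3, p0.v1, v2, p0.q1, p0.q2)
            prot = ExposureProtocol.single_dose(500.0, r, 12.0)
            assert rd_predict(p, prot) == pytest.approx(
                rd_oracle_total(p, prot), rel=1e-8
            )

    def test_structural_zero_rates_match_oracle(self, rd_dense):
        # the alpha-particle parameter set has k1 = v1 = q1 = 0 exactly
        prot = ExposureProtocol.single_dose(400.0, 1400.0, 24.0)
        assert rd_predict(rd_dense, prot) == pytest.approx(
            rd_oracle_total(rd_dense, prot), rel=1e-9
        )

    def test_zero_dose_predicts_zero(self, rd_sparse):
        prot = ExposureProtocol((), 24.0)
        assert rd_predict(rd_sparse, prot) == 0.0

    def test_negative_inputs_rejected(self, rd_sparse):
        with pytest.raises(ValidationError):
            rd_propagate_segment(DSBState(), rd_sparse, -1.0, 1.0)
        with pytest.raises(ValidationError):
            rd_propagate_segment(DSBState(), rd_sparse, 1.0, -1.0)


class TestTLKAndLPL:
    def test_linear_limit_equals_rd_reduction(self, tlk_sparse):
        # with all eta and epsilon zero the TLK system is exactly the RD
        # system with q1 = q2 = 0 and matched yields/rates
        rd_matched = RDParams(
            k1=tlk_sparse.c1, k2=tlk_sparse.c2, k3=tlk_sparse.c3,
            v1=tlk_sparse.lambda1, v2=tlk_sparse.lambda2, q1=0.0, q2=0.0,
        )
        for prot in [
            ExposureProtocol.single_dose(2400, 7800, 72),
            ExposureProtocol.split_dose(900, 7800, 16, 4),
            ExposureProtocol.single_dose(1650, 33, 22),
        ]:
            assert tlk_predict(tlk_sparse, prot) == pytest.approx(
                rd_predict(rd_matched, prot), rel=1e-6
            )

    def test_nonlinear_tlk_matches_oracle(self):
        p = TLKParams(
            c1=2.5e-2, c2=3.5e-2, c3=8e-3, lambda1=1.3, lambda2=6.7e-2,
            epsilon1=1e-2, epsilon2=5e-3, eta1=1e-4, eta2=2e-5, eta12=5e-5,
        )
        for prot in [
            ExposureProtocol.single_dose(2400, 7800, 72),
            ExposureProtocol.split_dose(1200, 7800, 24, 8),
        ]:
            assert tlk_predict(p, prot) == pytest.approx(
                tlk_oracle_total(p, prot), rel=1e-6
            )

    def test_batch_integrator_matches_scipy_path(self):
        # the compiled batch stepper used inside fitting must agree with
        # the public solve_ivp-based predictions
        rng = np.random.default_rng(11)
        protocols = [random_protocol(rng) for _ in range(6)]
        p = TLKParams(
            c1=3e-2, c2=2e-2, c3=5e-3, lambda1=0.9, lambda2=5e-2,
            epsilon1=2e-2, epsilon2=1e-3, eta1=5e-5, eta2=1e-5, eta12=2e-5,
        )
        batch = predictions_for("tlk", p, protocols, solver_tolerance=1e-8)
        single = [tlk_predict(p, prot) for prot in protocols]
        assert batch == pytest.approx(single, rel=1e-6)

    def test_lpl_linear_limit_closed_form(self):
        # with eta = 0: rejoinable pool cr*R*(1-e^{-lam*tau})/lam decays
        # as e^{-lam*T}; unrejoinable pool is cu*D at all times
        p = LPLParams(cr=0.05, cu=0.01, lam=0.3, eta=0.0)
        d, r, t = 600.0, 1400.0, 24.0
        tau = d / r
        expected = (
            p.cr * r * (1 - np.exp(-p.lam * tau)) / p.lam * np.exp(-p.lam * t)
            + p.cu * d
        )
        assert lpl_predict(p, ExposureProtocol.single_dose(d, r, t)) == pytest.approx(
            expected, rel=1e-7
        )
        # acute limit: total ~ cr*D*e^{-lam t} + cu*D
        acute = lpl_predict(p, ExposureProtocol.single_dose(d, 1e7, t))
        assert acute == pytest.approx(p.cr * d * np.exp(-p.lam * t) + p.cu * d, rel=1e-3)

    def test_lpl_unrejoinable_only(self):
        p = LPLParams(cr=0.0, cu=0.02, lam=0.5, eta=1e-4)
        for t in [0.0, 12.0, 72.0]:
            prot = ExposureProtocol.single_dose(500.0, 1400.0, t)
            assert lpl_predict(p, prot) == pytest.approx(0.02 * 500.0, rel=1e-9)

    def test_lpl_quadratic_matches_oracle(self):
        # independent oracle: embed in the TLK equations and integrate
        p = LPLParams(cr=0.1, cu=0.01, lam=0.2, eta=5e-4)
        tlk_embed = TLKParams(
            c1=p.cr, c2=0.0, c3=p.cu, lambda1=p.lam, lambda2=0.0, eta1=p.eta
        )
        prot = ExposureProtocol.single_dose(800.0, 2000.0, 10.0)
        assert lpl_predict(p, prot) == pytest.approx(
            tlk_oracle_total(tlk_embed, prot), rel=1e-6
        )

    def test_solver_tolerance_validated(self, tlk_sparse):
        with pytest.raises(ValidationError):
            tlk_predict(tlk_sparse, ExposureProtocol.single_dose(100, 1000, 1), 1e-3)


class TestInvariants:
    """Conservation, non-negativity and dose monotonicity on random inputs."""

    def test_rd_conservation(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = random_rd_params(rng)
            prot = random_protocol(rng)
            s = rd_solve(p, prot)
            produced = (p.k1 + p.k2 + p.k3) * prot.total_dose
            assert s.total_accounted == pytest.approx(produced, rel=1e-9)

    def test_tlk_conservation(self):
        p = TLKParams(
            c1=3e-2, c2=2e-2, c3=5e-3, lambda1=0.9, lambda2=5e-2,
            epsilon1=2e-2, epsilon2=1e-3, eta1=5e-5, eta2=1e-5, eta12=2e-5,
        )
        rng = np.random.default_rng(6)
        for _ in range(5):
            prot = random_protocol(rng)
            s = tlk_solve(p, prot)
            produced = (p.c1 + p.c2 + p.c3) * prot.total_dose
            assert s.total_accounted == pytest.approx(produced, rel=1e-6)

    def test_lpl_conservation(self):
        p = LPLParams(cr=0.1, cu=0.01, lam=0.2, eta=5e-4)
        prot = ExposureProtocol.split_dose(700.0, 1400.0, 12.0, 6.0)
        s = lpl_solve(p, prot)
        assert s.total_accounted == pytest.approx((p.cr + p.cu) * prot.total_dose, rel=1e-6)

    def test_states_stay_nonnegative(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            p = random_rd_params(rng)
            prot = random_protocol(rng)
            s = rd_solve(p, prot)
            for v in (s.dsb1, s.dsb2, s.dsb3, s.rejoined1, s.rejoined2):
                assert v >= 0.0

    def test_prediction_nondecreasing_in_dose(self, rd_sparse):
        rng = np.random.default_rng(13)
        for _ in range(10):
            p = random_rd_params(rng)
            rate = 10 ** rng.uniform(1.5, 4)
            t = rng.uniform(0, 72)
            doses = np.sort(10 ** rng.uniform(1, 3.4, 5))
            preds = [
                rd_predict(p, ExposureProtocol.single_dose(d, rate, t)) for d in doses
            ]
            assert np.all(np.diff(preds) >= -1e-10 * np.array(preds[1:]))


class TestResidualLQ:
    def test_no_conversion_gives_exact_linear_residual(self):
        p = RDParams(k1=0.05, k2=0.01, k3=2e-3, v1=1.0, v2=0.05, q1=1e-3, q2=0.0)
        for r in [33.0, 1400.0, 7800.0]:
            residual, alpha, beta = rd_residual_lq(p, 900.0, r)
            assert residual == pytest.approx(p.k3 * 900.0, rel=1e-9)
            assert alpha == p.k3
            assert abs(beta) < 1e-15

    def test_acute_quadratic_coefficient_from_numerical_differentiation(self, rd_sparse):
        # second derivative of the exact acute residual at D = 0 is k2*q2
        h = 0.01
        vals = [rd_residual_lq(rd_sparse, d, np.inf)[0] for d in (h, 2 * h)]
        second = (vals[1] - 2 * vals[0]) / h**2  # residual(0) = 0
        assert second == pytest.approx(rd_sparse.k2 * rd_sparse.q2, rel=1e-3)
        # residual/D -> 0 as D -> 0 when k3 = 0
        assert vals[0] / h < 1e-7

    def test_residual_decreases_toward_linear_term_at_low_dose_rate(self, rd_sparse):
        d = 1200.0
        rates = [1e5, 1e4, 1e3, 1e2, 1e1, 1e0, 1e-2]
        residuals = [rd_residual_lq(rd_sparse, d, r)[0] for r in rates]
        assert np.all(np.diff(residuals) < 0)
        # k3 = 0 here, so the residual itself vanishes at low dose rate
        assert residuals[-1] < 1e-3
        betas = [rd_residual_lq(rd_sparse, d, r)[2] for r in rates]
        assert betas[-1] < 1e-3 * betas[0]

    def test_acute_limit_beta_is_half_k2_q2(self, rd_sparse):
        _, _, beta = rd_residual_lq(rd_sparse, 0.01, np.inf)
        assert beta == pytest.approx(rd_sparse.k2 * rd_sparse.q2 / 2, rel=1e-3)

    def test_unrejoinable_content_without_decay_has_no_finite_residual(self):
        p = RDParams(k1=0.05, k2=0.01, k3=0.0, v1=0.0, v2=0.05, q1=1e-3, q2=1e-4)
        with pytest.raises(NumericalError, match="no finite residual"):
            rd_residual_lq(p, 500.0, 1400.0)
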