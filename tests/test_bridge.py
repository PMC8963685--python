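import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tndbridge as tb
from tndbridge import (BridgeModel, CellProbabilities, IdentificationError,
                       MomentSpec, closed_form_binary_bridge,
                       binary_moment_basis, estimate_bridge_params,
                       evaluate_bridge, moment_residuals)
from tndbridge.bridge import _residual_terms

from conftest import hand_sample


class TestEvaluate:
    def test_constant_saturated_model_is_one(self):
        model = BridgeModel("saturated-binary", tau=[1, 0, 0, 0])
        a = np.array([0, 1, 0, 1])
        z = np.array([0, 0, 1, 1])
        np.testing.assert_array_equal(evaluate_bridge(model, a, z), 1.0)

    def test_logistic_form_null_gives_two(self):
        # q = 1 + exp(0) = 2: inverse probability 1/2 at both levels
        model = BridgeModel("logistic-form", tau=[0, 0, 0, 0], n_x=1)
        q = evaluate_bridge(model, np.array([0.0]), np.array([0.0]),
                            np.array([[0.0]]))
        assert q[0] == 2.0

    def test_logistic_form_exceeds_one_everywhere(self):
        rng = np.random.default_rng(3)
        model = BridgeModel("logistic-form", tau=rng.normal(size=4), n_x=1)
        a = rng.integers(0, 2, 50).astype(float)
        z = rng.normal(size=50)
        x = rng.normal(size=(50, 1))
        assert (evaluate_bridge(model, a, z, x) > 1).all()

    def test_continuous_oracle_z_coefficient_is_confounding_ratio(self):
        # tau2 = mu_UA / mu_UZ
        cfg = tb.continuous_rare().replace(mu_ua=0.5, mu_uz=1.0)
        assert tb.oracle_bridge_continuous(cfg).tau[2] == pytest.approx(0.5)

    def test_covariate_dimension_mismatch_raises(self):
        model = BridgeModel("logistic-form", tau=[0, 0, 0, 1, 1], n_x=2)
        with pytest.raises(ValueError, match="width"):
            evaluate_bridge(model, np.array([1.0]), np.array([0.0]),
                            np.array([[1.0]]))

    def test_unset_parameters_raise(self):
        with pytest.raises(ValueError, match="not set"):
            evaluate_bridge(BridgeModel("saturated-binary"),
                            np.array([1.0]), np.array([0.0]))


class TestClosedForm:
    def test_perfectly_observed_confounder(self):
        # Z = U exactly: q(1, z) = 1 / P(A=1 | U=z)
        p = np.zeros((2, 2, 2))
        p[0, 1, 0], p[1, 1, 0] = 0.4, 0.0
        p[0, 1, 1], p[1, 1, 1] = 0.0, 0.8
        p[0, 0, 0] = 0.6
        p[1, 0, 1] = 0.2
        cells = CellProbabilities(p)
        q0, q1 = closed_form_binary_bridge(cells, 1)
        assert q0 == pytest.approx(2.5)
        assert q1 == pytest.approx(1.25)

    def test_matches_independent_linear_solve(self):
        p = np.zeros((2, 2, 2))
        p[0, 0, 0], p[1, 0, 0] = 0.5, 0.1
        p[0, 0, 1], p[1, 0, 1] = 0.2, 0.3
        p[0, 1, 0], p[1, 1, 0] = 0.3, 0.1
        p[0, 1, 1], p[1, 1, 1] = 0.2, 0.3
        q0, q1 = closed_form_binary_bridge(CellProbabilities(p), 0)
        # independent oracle: explicit 2x2 inversion by Cramer's rule
        det = 0.5 * 0.3 - 0.2 * 0.1
        assert q0 == pytest.approx((0.3 - 0.1) / det)
        assert q1 == pytest.approx((0.5 - 0.2) / det)
        assert q0 == pytest.approx(0.2 / 0.13)
        assert q1 == pytest.approx(0.3 / 0.13)

    def test_uninformative_nce_raises_identification_error(self):
        # identical rows across the conditioning level: determinant zero
        p = np.zeros((2, 2, 2))
        for c in (0, 1):
            p[0, 0, c], p[1, 0, c] = 0.3, 0.2
            p[0, 1, c], p[1, 1, c] = 0.3, 0.2
        with pytest.raises(IdentificationError, match="a=1"):
            closed_form_binary_bridge(CellProbabilities(p), 1)


def six_row_sample():
    return hand_sample(a=[0, 1, 1, 0, 1, 0], y=[0, 0, 1, 0, 0, 1],
                       z=[0, 1, 0, 1, 1, 0], w=[1, 0, 1, 1, 0, 0])


class TestMomentResiduals:
    def test_no_controls_is_an_error(self):
        s = hand_sample(a=[0, 1], y=[1, 1], z=[0, 1], w=[1, 0])
        with pytest.raises(ValueError, match="control"):
            moment_residuals(s, BridgeModel("saturated-binary"),
                             binary_moment_basis(), [1, 0, 0, 0])

    def test_constant_bridge_two_with_unit_moment_cancels(self):
        s = six_row_sample()
        m = MomentSpec(lambda w, a, x: np.ones((len(np.atleast_1d(a)), 1)), 1)
        r = moment_residuals(s, BridgeModel("saturated-binary"), m,
                             [2, 0, 0, 0])
        assert r == pytest.approx([0.0], abs=1e-15)

    def test_hand_summed_six_row_dataset(self):
        # independent oracle: term-by-term summation in pure python
        s = six_row_sample()
        tau = np.array([1.3, -0.2, 0.4, 0.1])
        total = np.zeros(4)
        for i in range(6):
            if s.y[i] == 1:
                continue
            a, z, w = float(s.a[i]), float(s.z[i, 0]), float(s.w[i, 0])
            q = tau[0] + tau[1] * z + tau[2] * a + tau[3] * z * a
            m_obs = np.array([1, w, a, w * a])
            m1 = np.array([1, w, 1, w])
            m0 = np.array([1, w, 0, 0])
            total += m_obs * q - m1 - m0
        expected = total / 6
        got = moment_residuals(s, BridgeModel("saturated-binary"),
                               binary_moment_basis(), tau)
        np.testing.assert_allclose(got, expected, atol=1e-14)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_cases_contribute_exactly_zero(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        s = hand_sample(a=rng.integers(0, 2, n), y=rng.integers(0, 2, n),
                        z=rng.integers(0, 2, n), w=rng.integers(0, 2, n))
        if s.n_controls == 0:
            return
        terms = _residual_terms(s, BridgeModel("saturated-binary"),
                                binary_moment_basis(), rng.normal(size=4))
        assert (terms[s.y == 1] == 0).all()


class TestEstimation:
    def test_no_confounding_reduces_to_inverse_frequencies(self):
        # Z independent of (A, W): the identified part of the bridge
        # collapses to the empirical inverse treatment frequencies among
        # controls (the Z coefficients themselves are unidentified in the
        # limit, so only the cell-averaged bridge is pinned down)
        rng = np.random.default_rng(11)
        n = 40_000
        a = rng.integers(0, 2, n)
        y = np.zeros(n)
        y[rng.random(n) < 0.1] = 1
        z = rng.integers(0, 2, n)
        w = rng.integers(0, 2, n)
        s = hand_sample(a=a, y=y, z=z, w=w)
        model, _ = estimate_bridge_params(
            s, BridgeModel("saturated-binary"), binary_moment_basis())
        ctl = s.y == 0
        p1 = s.a[ctl].mean()
        q = model(s.a[ctl], s.z[ctl])
        assert q[s.a[ctl] == 0].mean() == pytest.approx(1 / (1 - p1), rel=0.02)
        assert q[s.a[ctl] == 1].mean() == pytest.approx(1 / p1, rel=0.02)

    def test_saturated_fit_equals_closed_form_from_control_cells(
            self, binary_sample, fitted_binary):
        cells = CellProbabilities.from_controls(binary_sample)
        expect = np.array([closed_form_binary_bridge(cells, 0),
                           closed_form_binary_bridge(cells, 1)])
        got = tb.bridge_table(fitted_binary["model"])
        np.testing.assert_allclose(got, expect, atol=1e-8)

    def test_residuals_vanish_at_reported_solution(self, binary_sample,
                                                   fitted_binary):
        r = moment_residuals(binary_sample, fitted_binary["model"],
                             fitted_binary["m"], fitted_binary["model"].tau)
        assert np.max(np.abs(r)) <= 1e-8

    def test_redundant_moment_component_leaves_fit_unchanged(
            self, binary_sample, fitted_binary):
        base = binary_moment_basis()

        def f(w, a, x):
            mm = base(w, a, x)
            # fifth component is a linear combination of the first four
            return np.column_stack([mm, mm @ np.array([1.0, -2.0, 0.5, 1.0])])

        over = MomentSpec(f, 5)
        model, report = estimate_bridge_params(
            binary_sample, BridgeModel("saturated-binary"), over)
        assert report.method == "gmm-identity"
        np.testing.assert_allclose(model.tau, fitted_binary["model"].tau,
                                   atol=1e-6)

    def test_case_rows_do_not_influence_fit(self, binary_sample):
        s = binary_sample
        model, _ = estimate_bridge_params(
            s, BridgeModel("saturated-binary"), binary_moment_basis())
        # duplicate every case row: tau must be unchanged up to solver noise
        cases = s.y == 1
        s2 = tb.TNDSample(a=np.concatenate([s.a, s.a[cases]]),
                          y=np.concatenate([s.y, s.y[cases]]),
                          z=np.vstack([s.z, s.z[cases]]),
                          w=np.vstack([s.w, s.w[cases]]),
                          x=np.vstack([s.x, s.x[cases]]))
        model2, _ = estimate_bridge_params(
            s2, BridgeModel("saturated-binary"), binary_moment_basis())
        np.testing.assert_allclose(model2.tau, model.tau, atol=1e-8)

    def test_moment_dimension_below_parameters_rejected(self, binary_sample):
        m = MomentSpec(lambda w, a, x: np.ones((len(np.atleast_1d(a)), 2)), 2)
        with pytest.raises(ValueError, match="smaller"):
            estimate_bridge_params(binary_sample,
                                   BridgeModel("saturated-binary"), m)

    def test_logistic_form_recovers_oracle_parameters_at_scale(self):
        # parameter recovery against the analytic oracle on a large pool of
        # test-negative controls (every symptomatic non-case is tested)
        cfg = tb.continuous_rare(n=2_000_000).replace(p_select_symptomatic=1.0)
        pop = tb.simulate_continuous_population(cfg, seed=77)
        s = tb.select_tnd_sample(pop)
        assert s.n_controls > 200_000
        model, report = estimate_bridge_params(
            s, BridgeModel("logistic-form", n_x=1),
            tb.continuous_moment_basis(1))
        assert report.converged
        np.testing.assert_allclose(model.tau,
                                   tb.oracle_bridge_continuous(cfg).tau,
                                   atol=0.08)
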