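"""Hill kinetics, loop ODEs, closed-form steady states."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hiffl.dynamics import (
    IFFL_SIGN_TRIPLES,
    CircuitSpec,
    IFFLParams,
    derivatives,
    hill_act,
    hill_rep,
    response_curve,
    simulate,
    steady_state,
)
from hiffl.signals import Protocol, Segment, default_nho_protocol
from oracles import rk4_piecewise


class TestHill:
    def test_anchor_points(self):
        assert hill_act(0.0, 1.0, 2.0) == 0.0
        assert hill_act(1.0, 1.0, 2.0) == 0.5  # half-maximum at x = k
        assert hill_act(1e9, 1.0, 2.0) == pytest.approx(1.0, abs=1e-9)
        assert hill_rep(0.0, 1.0, 2.0) == 1.0
        assert hill_rep(1.0, 1.0, 2.0) == 0.5

    @settings(derandomize=True, max_examples=200)
    @given(x=st.floats(0, 1e6), k=st.floats(1e-3, 1e3), n=st.floats(1, 6))
    def test_complementarity_and_monotonicity(self, x, k, n):
        a, r = hill_act(x, k, n), hill_rep(x, k, n)
        assert a + r == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= a <= 1.0
        assert hill_act(x * 2 + 1e-9, k, n) >= a - 1e-12

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            hill_act(-0.1, 1.0, 2.0)
        with pytest.raises(ValueError):
            hill_rep(1.0, 0.0, 2.0)


class TestDerivatives:
    def test_type3_multiplicative_at_origin(self):
        """At HIF=0 both Hill arms are silent: dTF=0, dTarget = beta*A."""
        spec = CircuitSpec(3, "multiplicative",
                          IFFLParams(a_target=0.5, n_hill=2.0, k_h=1.0, k_tf=0.5))
        assert derivatives((0.0, 0.0), 0.0, spec) == (0.0, 0.5)

    def test_type3_tf_production_at_half_saturation(self):
        spec = CircuitSpec(3, "multiplicative",
                          IFFLParams(k_h=1.0, n_hill=2.0, a_target=0.5))
        dtf, _ = derivatives((0.0, 0.0), 1.0, spec)
        assert dtf == pytest.approx(0.5)

    def test_modes_coincide_at_zero_hif_for_type3(self):
        """With HIF=0 the repression factor is 1, so both modes reduce to
        beta*(f_ind + A) - alpha*Target."""
        for tf, tgt in [(0.0, 0.0), (0.3, 0.7), (1.2, 0.1)]:
            dm = derivatives((tf, tgt), 0.0, CircuitSpec(3, "multiplicative"))
            da = derivatives((tf, tgt), 0.0, CircuitSpec(3, "additive"))
            assert dm == pytest.approx(da)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            derivatives((-0.1, 0.0), 0.0, CircuitSpec())
        with pytest.raises(ValueError):
            derivatives((0.0, 0.0), -1.0, CircuitSpec())
        with pytest.raises(ValueError):
            CircuitSpec(5)
        with pytest.raises(ValueError):
            CircuitSpec(3, "divisive")


def _reference_rhs_factory(spec):
    """Independent RHS (plain Hill algebra) for the RK4 oracle."""
    p = spec.params
    s_xy, s_yz, s_xz = IFFL_SIGN_TRIPLES[spec.iffl_type]

    def h(sign, x, k):
        u = (x / k) ** p.n_hill
        return u / (1 + u) if sign > 0 else 1 / (1 + u)

    def factory(hif):
        fxy = h(s_xy, hif, p.k_h)
        fdir = h(s_xz, hif, p.k_h)

        def f(y):
            tf, tgt = y
            find = h(s_yz, max(tf, 0.0), p.k_tf)
            if spec.mode == "multiplicative":
                prod = (find + p.a_target) * fdir
            else:
                prod = find + p.a_target * fdir
            return np.array([
                p.beta_tf * fxy - p.alpha_tf * tf,
                p.beta_target * prod - p.alpha_target * tgt,
            ])

        return f

    return factory


class TestSimulate:
    def test_default_grid_has_901_samples(self):
        traj = simulate(CircuitSpec())
        assert len(traj.times) == 901
        assert traj.times[0] == -15.0 and traj.times[-1] == 30.0

    def test_zero_hif_closed_form(self):
        """With HIF=0 throughout, TF stays 0 and the Target relaxes to
        A*beta/alpha as a pure exponential (type 3)."""
        p = Protocol([Segment(0, 20, "constant", level_high=0.0)])
        spec = CircuitSpec(3, "multiplicative",
                          IFFLParams(a_target=0.5, alpha_target=1.0))
        traj = simulate(spec, p)
        assert np.allclose(traj.tf, 0.0, atol=1e-12)
        expected = 0.5 * (1 - np.exp(-traj.times))
        assert np.allclose(traj.target, expected, rtol=1e-6, atol=1e-8)

    def test_constant_hif_converges_to_steady_state(self, circuit):
        p = Protocol([Segment(0, 50, "constant", level_high=1.0)])
        traj = simulate(circuit, p)
        tf_ss, tgt_ss = steady_state(circuit, 1.0)
        assert traj.tf[-1] == pytest.approx(tf_ss, rel=1e-4)
        assert traj.target[-1] == pytest.approx(tgt_ss, rel=1e-4)

    def test_matches_rk4_oracle_on_default_protocol(self):
        spec = CircuitSpec(3, "additive")
        traj = simulate(spec)
        ref = rk4_piecewise(_reference_rhs_factory(spec), default_nho_protocol(),
                            [0.0, 0.0], traj.times, dt=1e-3)
        err = max(np.max(np.abs(traj.tf - ref[:, 0])),
                  np.max(np.abs(traj.target - ref[:, 1])))
        assert err < 1e-3

    def test_nonnegative_state(self, circuit):
        traj = simulate(circuit)
        assert traj.tf.min() >= 0.0
        assert traj.target.min() >= 0.0

    def test_bad_args(self):
        with pytest.raises(ValueError):
            simulate(CircuitSpec(), grid_step=0.0)
        with pytest.raises(ValueError):
            simulate(CircuitSpec(), init=(-1.0, 0.0))


class TestSteadyState:
    def test_type3_anchors(self):
        spec = CircuitSpec(3, "multiplicative",
                          IFFLParams(k_h=1.0, k_tf=0.5, n_hill=2.0, a_target=0.0))
        tf_ss, tgt_ss = steady_state(spec, 1.0)
        assert tf_ss == pytest.approx(0.5)
        assert tgt_ss == pytest.approx(0.25)  # hill_act(.5,.5,2)=.5 times rep .5

    def test_type3_zero_hif_both_modes(self):
        for mode in ("multiplicative", "additive"):
            spec = CircuitSpec(3, mode, IFFLParams(a_target=0.7))
            tf_ss, tgt_ss = steady_state(spec, 0.0)
            assert tf_ss == 0.0
            assert tgt_ss == pytest.approx(0.7)

    def test_negative_hif_rejected(self):
        with pytest.raises(ValueError):
            steady_state(CircuitSpec(), -0.5)


class TestResponseCurve:
    def test_interior_peak_flagged_non_monotonic(self):
        """A type 1 additive loop where activation saturates before
        repression peaks at intermediate HIF."""
        spec = CircuitSpec(1, "additive", IFFLParams(k_h=0.638, k_tf=0.534))
        targets, flag = response_curve(spec, np.linspace(0, 1, 21))
        assert flag
        assert targets.max() > max(targets[0], targets[-1])

    def test_dead_indirect_arm_is_monotone(self):
        """k_tf far above reachable TF keeps f_ind ~ 0: the multiplicative
        type 3 response is pure repression, monotone decreasing."""
        spec = CircuitSpec(3, "multiplicative", IFFLParams(k_tf=1e4))
        targets, flag = response_curve(spec, np.linspace(0, 1, 11))
        assert not flag
        assert np.all(np.diff(targets) <= 1e-12)

    def test_single_level_not_flagged(self):
        _, flag = response_curve(CircuitSpec(), [0.5])
        assert not flag

    def test_empty_levels_rejected(self):
        with pytest.raises(ValueError):
            response_curve(CircuitSpec(), [])
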