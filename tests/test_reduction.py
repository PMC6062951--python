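"""Reduction: eligibility, enumeration, steady-state elimination, greedy."""

import numpy as np
import pytest
from scipy.linalg import expm

from redeval import (
    BoundaryFlux,
    NetworkModel,
    ReductionSpec,
    eligible_complexes,
    enumerate_reductions,
    greedy_reduce,
    reduce_model,
    simulate,
    symmetric_error,
)
from redeval.metrics import ErrorConfig
from redeval.reduction import ReductionError, UnsupportedReductionError

K = dict(k1=0.44, k2=0.03, k3=0.55, k4=0.44, k5=0.42, k6=0.33)


class TestEligibility:
    def test_simple_example(self, simple, simple_eligible):
        """Only the complexes of the two intermediates are reduction
        candidates when M_I = {1, 4}."""
        assert simple_eligible == (1, 2)

    def test_all_important_means_nothing_eligible(self, simple):
        model, _ = simple
        everything = NetworkModel(
            model.compound_names, model.complex_names, model.Z, model.B,
            model.reaction_names, model.modifiers, model.boundary,
            important=tuple(range(4)))
        assert eligible_complexes(everything) == []


class TestEnumeration:
    @pytest.mark.parametrize("c,count", [(0, 1), (2, 4), (6, 64)])
    def test_power_set_count(self, c, count):
        specs = enumerate_reductions(list(range(c)))
        assert len(specs) == count
        assert len({s.bitmask for s in specs}) == count
        sizes = [s.size for s in specs]
        assert sizes == sorted(sizes)
        assert sizes.count(0) == 1 and sizes.count(c) == 1

    def test_two_element_power_set(self):
        specs = enumerate_reductions([4, 7])
        assert [s.reduced_complexes for s in specs] == [(), (4,), (7,), (4, 7)]

    def test_cap_refused(self):
        with pytest.raises(ReductionError, match="prefilter"):
            enumerate_reductions(list(range(17)))

    def test_bitmask_roundtrip(self):
        spec = ReductionSpec((2, 5), (1, 2, 5))
        assert spec.bitmask == "011"
        assert ReductionSpec.from_bitmask("011", (1, 2, 5)) == spec


class TestReducedModel:
    def test_empty_spec_reproduces_full_model(self, simple, simple_xss,
                                              simple_horizon):
        model, params = simple
        spec = ReductionSpec((), (1, 2))
        red = reduce_model(model, params, spec, simple_xss)
        a = simulate(model, params, simple_horizon, 200)
        b = simulate(red, params, simple_horizon, 200)
        assert np.max(np.abs(a.x - b.x)) < 1e-7

    def test_double_reduction_closed_form(self, simple, simple_xss):
        """Eliminating both intermediates leaves the two-variable system
        dx1 = k5 - (k1+k2) x1, dx4 = (k1+k2) x1 - k6 x4, with the
        intermediates given algebraically by x2 = k1 x1 / k3 and
        x3 = k2 x1 / k4."""
        model, params = simple
        red = reduce_model(model, params, ReductionSpec((1, 2), (1, 2)),
                           simple_xss)
        T = 20.0
        traj = simulate(red, params, T, 100)
        A = np.array([[-(K["k1"] + K["k2"]), 0.0],
                      [K["k1"] + K["k2"], -K["k6"]]])
        b = np.array([K["k5"], 0.0])
        xinf = np.linalg.solve(A, -b)
        x0 = np.array([0.4, 0.4])
        exact = np.array([xinf + expm(A * t) @ (x0 - xinf) for t in traj.t])
        np.testing.assert_allclose(traj.x[:, [0, 3]], exact, rtol=1e-6,
                                   atol=1e-9)
        np.testing.assert_allclose(traj.x[:, 1],
                                   K["k1"] * traj.x[:, 0] / K["k3"], rtol=1e-6)
        np.testing.assert_allclose(traj.x[:, 2],
                                   K["k2"] * traj.x[:, 0] / K["k4"], rtol=1e-6)

    def test_eliminated_compound_balances_and_converges(self, simple,
                                                        simple_xss):
        """The eliminated compound's net production is zero along the whole
        reduced trajectory, and its level converges to the full model's
        steady state."""
        model, params = simple
        red = reduce_model(model, params, ReductionSpec((1,), (1, 2)),
                           simple_xss)
        traj = simulate(red, params, 60.0, 100)
        for row in traj.x[::10]:
            assert model.rhs(params, row)[1] == pytest.approx(0.0, abs=1e-9)
        assert traj.x[-1, 1] == pytest.approx(simple_xss[1], rel=1e-3)

    def test_clamp_values_match_full_steady_state(self, simple, simple_xss):
        model, params = simple
        red = reduce_model(model, params, ReductionSpec((1, 2), (1, 2)),
                           simple_xss)
        np.testing.assert_allclose(red.clamp_values, simple_xss[[1, 2]])

    def test_specification_errors(self, simple, simple_xss):
        model, params = simple
        with pytest.raises(ReductionError):
            ReductionSpec((0,), (1, 2))
        with pytest.raises(ReductionError):
            reduce_model(model, params,
                         ReductionSpec((0,), (0, 1, 2)), simple_xss)

    def test_spec_is_order_invariant(self):
        assert ReductionSpec((2, 1), (1, 2)) == ReductionSpec((1, 2), (1, 2))

    def test_multi_compound_complex_rejected(self):
        """A two-compound eligible complex cannot be eliminated: the
        semantics are only defined for exclusive single-compound complexes."""
        # a + b -> c through the complex a+b; M_I = {c}
        Z = np.array([[1, 1, 0], [0, 1, 0], [0, 0, 1]])
        B = np.array([[0, -1], [-1, 1], [1, 0]])
        model = NetworkModel(
            ("a", "b", "c"), ("a", "ab", "c"), Z, B, ("k1", "k2"),
            ("mass_action", "mass_action"),
            (BoundaryFlux(0, "inflow", "k3"), BoundaryFlux(2, "outflow", "k4")),
            important=(2,))
        params_ok = np.ones(2)
        from redeval import ParameterSet
        params = ParameterSet(params_ok, np.ones(2), np.ones(3))
        elig = eligible_complexes(model)
        assert 1 in elig
        with pytest.raises(UnsupportedReductionError):
            reduce_model(model, params, ReductionSpec((1,), tuple(elig)),
                         np.ones(3))


class TestGreedy:
    def test_zero_threshold_keeps_full_model(self, simple, simple_xss,
                                             simple_horizon):
        model, params = simple
        assert greedy_reduce(model, params, 0.0, simple_horizon,
                             xss=simple_xss) == []

    def test_infinite_threshold_reduces_everything(self, simple, simple_xss,
                                                   simple_horizon):
        model, params = simple
        order = greedy_reduce(model, params, np.inf, simple_horizon,
                              xss=simple_xss)
        assert sorted(order) == [1, 2]

    def test_result_error_is_below_threshold(self, simple, simple_xss,
                                             simple_horizon):
        model, params = simple
        threshold = 0.08
        order = greedy_reduce(model, params, threshold, simple_horizon,
                              n_grid=400, xss=simple_xss)
        spec = ReductionSpec(tuple(order), (1, 2))
        red = reduce_model(model, params, spec, simple_xss)
        full = simulate(model, params, simple_horizon, 400)
        traj = simulate(red, params, simple_horizon, 400)
        err = symmetric_error(traj, full, model.important,
                              ErrorConfig(horizon=simple_horizon))
        assert err <= threshold
        assert spec.bitmask in {s.bitmask for s in enumerate_reductions((1, 2))}
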