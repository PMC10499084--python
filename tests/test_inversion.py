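"""Inversion routes and evaluation metrics (smoke-scale pipelines)."""

import time

import numpy as np
import pytest

from indentml.constitutive import MaterialParams, Model
from indentml.curves import IndentationCurve, SampleGeometry, as_curve
from indentml.design import DesignPoint, depth_grid
from indentml.generator import DEFAULT_R, simulate_curve
from indentml.inversion import (
    evaluate_inversions,
    invert_direct,
    invert_hertz,
    invert_least_squares,
    verify_by_forward_sim,
    InversionResult,
)
from indentml.nets import predict_forward

GRID = depth_grid()


class TestLeastSquares:
    def test_self_consistency_round_trip(self, smoke_nh):
        """A curve produced by the forward net itself is inverted back to
        its own parameters within optimizer tolerance, in under a second."""
        fwd = smoke_nh["forward_net"]
        point = DesignPoint(18.0, 12.0, MaterialParams(Model.NEO_HOOKEAN, 3.3e4))
        forces = predict_forward(fwd, point)
        curve = as_curve(GRID[1:], forces, DEFAULT_R,
                         SampleGeometry(DEFAULT_R, 18.0, 12.0))
        t0 = time.time()
        res = invert_least_squares(fwd, curve, seed=3)
        assert time.time() - t0 < 1.0
        assert res.converged
        assert res.params.mu == pytest.approx(3.3e4, rel=1e-4)

    def test_surrogate_curve_recovery(self, smoke_nh):
        fwd = smoke_nh["forward_net"]
        val = smoke_nh["datasets"]["validation"]
        res = invert_least_squares(fwd, val.curve(0), seed=3)
        assert res.params.mu == pytest.approx(val.designs[0].params.mu, rel=0.05)

    def test_all_zero_curve_flags_failure(self, smoke_nh):
        fwd = smoke_nh["forward_net"]
        curve = IndentationCurve(GRID * DEFAULT_R, np.zeros_like(GRID), DEFAULT_R,
                                 SampleGeometry(DEFAULT_R, 10.0, 10.0))
        res = invert_least_squares(fwd, curve, seed=1)
        assert not res.converged and res.at_bound

    def test_deterministic_given_seed(self, smoke_nh):
        fwd = smoke_nh["forward_net"]
        val = smoke_nh["datasets"]["validation"]
        a = invert_least_squares(fwd, val.curve(1), seed=9)
        b = invert_least_squares(fwd, val.curve(1), seed=9)
        assert a.params.mu == b.params.mu

    def test_shallow_curve_fits_available_range(self, smoke_nh):
        fwd = smoke_nh["forward_net"]
        val = smoke_nh["datasets"]["validation"]
        full = val.curve(2)
        half = IndentationCurve(full.depth[:60], full.force[:60], full.R,
                                full.geometry)
        res = invert_least_squares(fwd, half, seed=1)
        assert res.params.mu == pytest.approx(val.designs[2].params.mu, rel=0.1)

    def test_geometry_required(self, smoke_nh):
        curve = IndentationCurve(GRID * DEFAULT_R,
                                 np.where(GRID > 0, GRID**1.5, 0.0), DEFAULT_R)
        with pytest.raises(ValueError, match="geometry"):
            invert_least_squares(smoke_nh["forward_net"], curve)


class TestDirect:
    def test_stateless_and_iteration_free(self, smoke_nh):
        inv = smoke_nh["inverse_net"]
        val = smoke_nh["datasets"]["validation"]
        a = invert_direct(inv, val.curve(0))
        b = invert_direct(inv, val.curve(0))
        assert a.params.mu == b.params.mu
        assert a.n_iterations == 0

    def test_recovers_generator_parameters(self, smoke_nh):
        inv = smoke_nh["inverse_net"]
        val = smoke_nh["datasets"]["validation"]
        res = invert_direct(inv, val.curve(3))
        assert res.params.mu == pytest.approx(val.designs[3].params.mu, rel=0.2)

    def test_gent_returns_both_parameters(self, smoke_gent):
        inv = smoke_gent["inverse_net"]
        val = smoke_gent["datasets"]["validation"]
        res = invert_direct(inv, val.curve(0))
        assert res.params.model is Model.GENT
        assert res.params.Jm is not None and res.params.Jm > 0


class TestHertzBaselines:
    def test_hertz_corner_curve_recovers_modulus(self):
        point = DesignPoint(40.0, 40.0, MaterialParams(Model.NEO_HOOKEAN, 2e3))
        curve = simulate_curve(point)
        res = invert_hertz(curve, variant="modified_hertz")
        assert res.params.mu == pytest.approx(2e3, rel=0.05)
        assert res.young_modulus == pytest.approx(3 * res.params.mu)

    def test_modified_beats_plain_hertz_on_deep_curves(self):
        point = DesignPoint(40.0, 40.0, MaterialParams(Model.NEO_HOOKEAN, 2e3))
        curve = simulate_curve(point)
        plain = invert_hertz(curve, variant="hertz")
        corrected = invert_hertz(curve, variant="modified_hertz")
        assert abs(corrected.params.mu - 2e3) < abs(plain.params.mu - 2e3)


class TestEvaluateInversions:
    @staticmethod
    def _results(mus):
        return [InversionResult("direct", MaterialParams(Model.NEO_HOOKEAN, mu),
                                misfit_rmse=0.0) for mu in mus]

    def test_perfect_predictions(self):
        truth = [MaterialParams(Model.NEO_HOOKEAN, mu) for mu in (1e3, 1e4, 1e5)]
        summ = evaluate_inversions(self._results([1e3, 1e4, 1e5]), truth)
        assert summ.mean_rel_error["mu"] == 0.0
        assert summ.r2["mu"] == pytest.approx(1.0)

    def test_uniform_ten_percent_bias(self):
        mus = np.array([1e3, 1e4, 1e5])
        truth = [MaterialParams(Model.NEO_HOOKEAN, mu) for mu in mus]
        summ = evaluate_inversions(self._results(1.1 * mus), truth)
        assert summ.mean_rel_error["mu"] == pytest.approx(0.10, rel=1e-12)

    def test_length_mismatch(self):
        truth = [MaterialParams(Model.NEO_HOOKEAN, 1e3)]
        with pytest.raises(ValueError, match="results"):
            evaluate_inversions(self._results([1e3, 2e3]), truth)


class TestForwardVerification:
    def test_rmse_matches_inversion_misfit_scale(self, smoke_nh):
        fwd = smoke_nh["forward_net"]
        val = smoke_nh["datasets"]["validation"]
        curve = val.curve(0)
        res = invert_least_squares(fwd, curve, seed=1)
        rmse = verify_by_forward_sim(res.params, curve.geometry, curve)
        assert rmse < 0.05 * curve.force.max()

    def test_wrong_modulus_inflates_rmse(self):
        point = DesignPoint(20.0, 20.0, MaterialParams(Model.NEO_HOOKEAN, 1e3))
        curve = simulate_curve(point)
        wrong = MaterialParams(Model.NEO_HOOKEAN, 2e3)
        rmse = verify_by_forward_sim(wrong, curve.geometry, curve)
        # doubling mu doubles every force, so the RMSE is the curve's own RMS
        assert rmse == pytest.approx(np.sqrt(np.mean(curve.force**2)), rel=1e-9)

    def test_unknown_backend(self):
        params = MaterialParams(Model.NEO_HOOKEAN, 1e3)
        point = DesignPoint(20.0, 20.0, params)
        curve = simulate_curve(point)
        with pytest.raises(ValueError, match="backend"):
            verify_by_forward_sim(params, curve.geometry, curve, backend="febio")
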