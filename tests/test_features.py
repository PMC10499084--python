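"""Power-law curve parameterization."""

import logging

import numpy as np
import pytest

from indentml.constitutive import MaterialParams, Model
from indentml.contact import hertz_force
from indentml.curves import IndentationCurve, as_curve
from indentml.design import DesignPoint, depth_grid
from indentml.features import (
    PowerLawFeatures,
    PowerLawFeaturizer,
    eval_power_law,
    fit_power_law,
)
from indentml.generator import DEFAULT_R, simulate_forces

GRID = depth_grid()
R = DEFAULT_R


def power_curve(p=2.0, s=1.5):
    x = GRID
    return as_curve(x, p * x**s * R**2, R)  # forces chosen to be positive


class TestFitPowerLaw:
    def test_exact_power_law_machine_precision(self):
        x = GRID
        curve = as_curve(x, np.where(x > 0, 2.0 * x**1.5, 0.0), R)
        feats = fit_power_law(curve)
        assert feats.p == pytest.approx(2.0, rel=1e-12)
        assert feats.s == pytest.approx(1.5, rel=1e-12)
        assert feats.fit_rmse == pytest.approx(0.0, abs=1e-12)

    def test_hertz_curve_has_exponent_three_halves(self):
        curve = as_curve(GRID, hertz_force(1e3, R, GRID * R), R)
        assert fit_power_law(curve).s == pytest.approx(1.5, rel=1e-12)

    def test_noisy_hertz_matches_independent_regression(self, rng):
        force = np.asarray(hertz_force(1e3, R, GRID * R))
        noisy = force + rng.normal(0.0, 0.01 * force.max(), force.size)
        # restrict to the measured-depth design range 0.05 <= delta/R
        mask = (GRID >= 0.05) & (noisy > 0)
        curve = IndentationCurve(GRID[mask] * R, noisy[mask], R)
        feats = fit_power_law(curve)
        # independent oracle: numpy polyfit on the log-log points
        s_oracle, logp_oracle = np.polyfit(
            np.log(GRID[mask]), np.log(noisy[mask]), 1
        )
        assert feats.s == pytest.approx(s_oracle, rel=1e-12)
        assert np.log(feats.p) == pytest.approx(logp_oracle, rel=1e-9)
        assert 1.45 <= feats.s <= 1.55

    def test_force_rescaling_moves_p_not_s(self):
        curve = power_curve()
        scaled = IndentationCurve(curve.depth, 10.0 * curve.force, R)
        a, b = fit_power_law(curve), fit_power_law(scaled)
        assert b.s == pytest.approx(a.s, rel=1e-12)
        assert b.p == pytest.approx(10.0 * a.p, rel=1e-12)

    def test_exponent_grows_as_jm_shrinks(self):
        """Strain stiffening steepens the curve: s decreases with Jm."""
        ss = []
        for jm in (5e-4, 5e-3, 0.05, 0.5, 5.0):
            point = DesignPoint(20.0, 20.0, MaterialParams(Model.GENT, 1e3, Jm=jm))
            f = simulate_forces([point], GRID)[0]
            ss.append(fit_power_law(as_curve(GRID, f, R)).s)
        assert all(a > b for a, b in zip(ss, ss[1:]))
        assert ss[-1] == pytest.approx(1.5, abs=0.15)

    def test_too_few_points_raises(self):
        curve = IndentationCurve(np.array([1e-6, 2e-6]), np.array([1e-9, 2e-9]), R)
        with pytest.raises(ValueError, match=">= 3 points"):
            fit_power_law(curve)

    def test_exclusion_warning(self, caplog):
        x = GRID[:20]
        force = np.where(x > 0.05, x**1.5, 0.0)  # many zero-force points
        curve = as_curve(x, force, R)
        with caplog.at_level(logging.WARNING, logger="indentml.features"):
            fit_power_law(curve)
        assert any("excluded" in r.message for r in caplog.records)


class TestEvalPowerLaw:
    def test_values(self):
        feats = PowerLawFeatures(2.0, 1.5, 0.0)
        out = eval_power_law(feats, np.array([0.0, 4.0]))
        assert out[0] == 0.0
        assert out[1] == pytest.approx(16.0)

    def test_round_trip_identity(self):
        feats = PowerLawFeatures(0.37, 2.1, 0.0)
        forces = eval_power_law(feats, GRID)
        back = fit_power_law(as_curve(GRID, forces * R**2, R))
        # p scales by R^2 because the curve carries physical forces
        assert back.s == pytest.approx(2.1, rel=1e-12)
        assert back.p == pytest.approx(0.37 * R**2, rel=1e-10)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            eval_power_law(PowerLawFeatures(1.0, 1.5, 0.0), np.array([-1.0]))


class TestFeaturizer:
    def test_matches_per_curve_fit(self):
        points = [DesignPoint(10.0, 10.0, MaterialParams(Model.NEO_HOOKEAN, mu))
                  for mu in (1e2, 1e4, 1e6)]
        F = simulate_forces(points, GRID)
        feats = PowerLawFeaturizer(GRID[1:]).fit_transform(F[:, 1:])
        for row, f in zip(feats, F):
            ref = fit_power_law(as_curve(GRID, f, R))
            assert row[0] == pytest.approx(np.log10(ref.p), rel=1e-10)
            assert row[1] == pytest.approx(ref.s, rel=1e-10)

    def test_rejects_nonpositive_forces(self):
        with pytest.raises(ValueError, match="positive"):
            PowerLawFeaturizer(GRID[1:]).fit_transform(np.zeros((2, 100)))
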