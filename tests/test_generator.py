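"""Surrogate ground-truth generator: limits, trends, datasets."""

import time

import numpy as np
import pytest

from indentml.constitutive import MaterialParams, Model
from indentml.contact import hertz_force
from indentml.design import DesignPoint, DesignSpace, depth_grid
from indentml.generator import (
    DEFAULT_R,
    SyntheticDataset,
    build_dataset,
    simulate_curve,
    simulate_forces,
)

GRID = depth_grid()


def point(W=40.0, H=40.0, mu=1e3, jm=None):
    params = (MaterialParams(Model.GENT, mu, Jm=jm) if jm is not None
              else MaterialParams(Model.NEO_HOOKEAN, mu))
    return DesignPoint(W, H, params)


class TestSurrogateLimits:
    def test_hertzian_corner(self):
        """Large, thick sample at shallow depth reproduces the Hertz law."""
        curve = simulate_curve(point())
        shallow = (GRID > 0) & (GRID <= 0.05)
        hertz = hertz_force(1e3, DEFAULT_R, GRID[shallow] * DEFAULT_R)
        np.testing.assert_allclose(curve.force[shallow], hertz, rtol=0.02)

    def test_mu_doubling_is_exact(self):
        f1 = simulate_forces([point(mu=1e3)], GRID)
        f2 = simulate_forces([point(mu=2e3)], GRID)
        np.testing.assert_allclose(f2, 2.0 * f1, rtol=1e-15)

    def test_gent_large_jm_equals_neo_hookean(self):
        f_nh = simulate_forces([point(W=10, H=10)], GRID)[0]
        f_gent = simulate_forces([point(W=10, H=10, jm=1e6)], GRID)[0]
        np.testing.assert_allclose(f_gent[1:], f_nh[1:], rtol=1e-3)

    def test_gent_stiffening_monotone_in_jm(self):
        jms = [5e-4, 5e-3, 0.05, 0.5, 5.0]
        deep = [simulate_forces([point(jm=j)], GRID)[0][-1] for j in jms]
        assert all(a > b for a, b in zip(deep, deep[1:]))


class TestQualitativeTrends:
    def test_force_increases_with_depth(self):
        f = simulate_forces([point(W=10, H=10, jm=0.1)], GRID)[0]
        assert np.all(np.diff(f) > 0)

    def test_thinner_sample_pushes_back_harder(self):
        thick = simulate_forces([point(H=40)], GRID)[0][-1]
        thin = simulate_forces([point(H=5)], GRID)[0][-1]
        assert thin > thick

    def test_narrower_sample_is_softer(self):
        wide = simulate_forces([point(W=40)], GRID)[0][-1]
        narrow = simulate_forces([point(W=5)], GRID)[0][-1]
        assert narrow < wide

    def test_curves_are_smooth_and_start_at_zero(self):
        for p in (point(), point(W=5, H=5, jm=5e-4)):
            f = simulate_forces([p], GRID)[0]
            assert f[0] == 0.0
            assert np.all(np.isfinite(np.diff(f, n=2)))
            # second differences small relative to the force scale
            assert np.max(np.abs(np.diff(f, n=2))) < 0.05 * f[-1]


class TestValidationAndErrors:
    def test_out_of_space_point_rejected(self):
        with pytest.raises(ValueError, match="outside design bounds"):
            simulate_curve(point(W=50.0))

    def test_mixed_models_rejected(self):
        with pytest.raises(ValueError, match="mix"):
            simulate_forces([point(), point(jm=1.0)], GRID)

    def test_febio_backend_needs_path(self):
        with pytest.raises(ValueError, match="deck_path"):
            simulate_curve(point(), backend="febio_deck")


class TestDatasets:
    def test_smoke_build_is_fast_and_finite(self):
        t0 = time.time()
        tr, va, te = build_dataset(sizes=(50, 10, 10))
        assert time.time() - t0 < 1.0
        assert len(tr) + len(va) + len(te) == 70
        for ds in (tr, va, te):
            assert np.isfinite(ds.curves).all()
            assert ds.curves.shape[1] == 101

    def test_split_metadata(self):
        tr, va, te = build_dataset(sizes=(20, 5, 5), seeds=(1, 2, 3))
        assert [d.split for d in (tr, va, te)] == ["train", "validation", "test"]
        assert [d.seed for d in (tr, va, te)] == [1, 2, 3]
        assert tr.targets().shape == (20, 100)

    def test_byte_identical_archives(self, tmp_path):
        for run in ("a", "b"):
            tr, _, _ = build_dataset(sizes=(20, 5, 5))
            tr.save(tmp_path / f"{run}.zip")
        assert (tmp_path / "a.zip").read_bytes() == (tmp_path / "b.zip").read_bytes()

    def test_archive_round_trip(self, tmp_path):
        tr, _, _ = build_dataset(model="gent", sizes=(15, 5, 5))
        tr.save(tmp_path / "ds.zip")
        back = SyntheticDataset.load(tmp_path / "ds.zip")
        np.testing.assert_array_equal(back.curves, tr.curves)
        np.testing.assert_array_equal(back.grid, tr.grid)
        assert back.designs == tr.designs
        assert back.model is Model.GENT and back.space == tr.space

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            build_dataset(sizes=(0, 5, 5))
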