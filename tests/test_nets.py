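"""Forward and inverse network estimators: contracts, determinism, I/O."""

import logging

import numpy as np
import pytest

from indentml._nn import DenseNet
from indentml.constitutive import MaterialParams, Model
from indentml.design import DesignPoint
from indentml.generator import build_dataset
from indentml.nets import (
    ForwardCurveNet,
    InverseParamNet,
    inverse_features,
    inverse_targets,
    predict_forward,
    train_forward_net,
    train_inverse_net,
)


@pytest.fixture(scope="module")
def splits():
    return build_dataset(sizes=(200, 50, 50))


@pytest.fixture(scope="module")
def fwd(splits):
    tr, va, _ = splits
    return train_forward_net(tr, va, max_epochs=200, random_state=1)


class TestDenseNetCore:
    def test_seeded_training_is_bit_reproducible(self, rng):
        X = rng.normal(size=(80, 3))
        Y = (X[:, :1] ** 2 + X[:, 1:2]).repeat(2, axis=1)
        histories = []
        for _ in range(2):
            net = DenseNet([3, 8, 2], seed=5)
            histories.append(net.train(X[:60], Y[:60], X[60:], Y[60:],
                                       max_epochs=30, seed=5))
        assert histories[0]["train_loss"] == histories[1]["train_loss"]
        assert histories[0]["val_loss"] == histories[1]["val_loss"]

    def test_divergence_reports_epoch(self, rng):
        X = rng.normal(size=(40, 2))
        Y = rng.normal(size=(40, 1))
        net = DenseNet([2, 4, 1], seed=0)
        with pytest.raises(FloatingPointError, match="epoch"):
            net.train(X, Y, X, Y, learning_rate=1e200, max_epochs=50,
                      lr_decay="none", seed=0)

    def test_best_so_far_validation_is_non_increasing(self, rng):
        X = rng.normal(size=(100, 2))
        Y = X[:, :1] * 2.0
        net = DenseNet([2, 6, 1], seed=1)
        h = net.train(X[:80], Y[:80], X[80:], Y[80:], max_epochs=60, seed=1)
        best = np.array(h["best_val_so_far"])
        assert np.all(np.diff(best) <= 0)
        assert h["best_val_loss"] == best[-1]


class TestForwardCurveNet:
    def test_smoke_training_reaches_10_percent(self, fwd, splits):
        _, va, _ = splits
        err = fwd.validation_error(va.design_matrix(), va.targets())
        assert err["mean"] <= 0.10

    def test_seeded_determinism(self, splits):
        tr, va, _ = splits
        a = train_forward_net(tr, va, max_epochs=20, random_state=3)
        b = train_forward_net(tr, va, max_epochs=20, random_state=3)
        assert a.history_["train_loss"] == b.history_["train_loss"]
        np.testing.assert_array_equal(
            a.predict(va.design_matrix()), b.predict(va.design_matrix())
        )

    def test_normalization_round_trip(self, fwd, splits):
        _, va, _ = splits
        X, Y = va.design_matrix(), va.targets()
        T = fwd._to_targets(X, Y)
        back = fwd._denorm_predict(fwd._norm_t(T), X)
        np.testing.assert_allclose(back, Y, rtol=1e-10)

    def test_mu_decade_scaling_transfers_through_net(self, fwd):
        lo = DesignPoint(20.0, 20.0, MaterialParams(Model.NEO_HOOKEAN, 1.0e3))
        hi = DesignPoint(20.0, 20.0, MaterialParams(Model.NEO_HOOKEAN, 1.0e4))
        ratio = predict_forward(fwd, hi) / predict_forward(fwd, lo)
        # the generator is exactly linear in mu; the net sees log10 mu,
        # so the transferred ratio should be ~10 within twice its val error
        assert np.allclose(ratio, 10.0, rtol=0.05)

    def test_out_of_bounds_warning_still_predicts(self, fwd, caplog):
        row = np.array([[50.0, 20.0, 3.0]])  # W/R above the design bound
        with caplog.at_level(logging.WARNING, logger="indentml.nets"):
            out = fwd.predict(row)
        assert out.shape == (1, 100) and np.isfinite(out).all()
        assert any("extrapolation" in r.message for r in caplog.records)

    def test_archive_round_trip(self, fwd, splits, tmp_path):
        _, va, _ = splits
        fwd.save(tmp_path / "fwd.zip")
        back = ForwardCurveNet.load(tmp_path / "fwd.zip")
        np.testing.assert_array_equal(
            back.predict(va.design_matrix()), fwd.predict(va.design_matrix())
        )
        assert back.fingerprint_ == fwd.fingerprint_
        assert back.get_params()["hidden_layer_sizes"] == (4, 4, 100, 100, 100)

    def test_model_point_mismatch(self, fwd):
        gent_point = DesignPoint(10.0, 10.0, MaterialParams(Model.GENT, 1e3, Jm=1.0))
        with pytest.raises(ValueError, match="inputs"):
            predict_forward(fwd, gent_point)

    def test_bad_shapes_rejected(self):
        with pytest.raises(ValueError):
            ForwardCurveNet().fit(np.ones((5, 3)), np.ones((4, 100)))
        with pytest.raises(ValueError):
            ForwardCurveNet().fit(np.ones((5, 5)), np.ones((5, 100)))


class TestLearningCurve:
    def test_more_training_data_does_not_hurt(self):
        """Validation error shrinks (or stays, within noise) as the
        training set grows — the learning-curve sanity check."""
        errors = {}
        for n in (250, 1000):
            tr, va, _ = build_dataset(sizes=(n, 100, 10))
            net = train_forward_net(tr, va, max_epochs=120, random_state=1)
            errors[n] = net.validation_error(va.design_matrix(), va.targets())["mean"]
        assert errors[1000] < errors[250] * 1.2


class TestInverseParamNet:
    def test_smoke_recovery(self, splits):
        tr, va, _ = splits
        net = train_inverse_net(tr, va, max_epochs=400, random_state=1)
        err = net.validation_error(inverse_features(va), inverse_targets(va))
        assert err["mean"][0] <= 0.10

    def test_restart_selection_takes_best_validation_score(self, splits):
        tr, va, _ = splits
        net = train_inverse_net(tr, va, max_epochs=60, n_restarts=3, random_state=1)
        scores = [r["selection_score"] for r in net.restarts_]
        assert len(scores) == 3
        # winner's validation mu error equals the best selection score
        from indentml.nets import inverse_features, inverse_targets
        err = net.validation_error(inverse_features(va), inverse_targets(va))
        assert err["mean"][0] == pytest.approx(min(scores), rel=1e-12)

    def test_relative_and_absolute_targets_agree_roughly(self, splits):
        tr, va, _ = splits
        X, y = inverse_features(tr), inverse_targets(tr)
        Xv, yv = inverse_features(va), inverse_targets(va)
        preds = {}
        for mode in ("relative", "absolute"):
            net = InverseParamNet(mu_target=mode, max_epochs=400, random_state=1)
            net.fit(X, y, validation_data=(Xv, yv))
            preds[mode] = net.predict(Xv)
        # both parameterisations return absolute log10 mu near the truth
        for mode, pred in preds.items():
            assert np.mean(np.abs(pred[:, 0] - yv[:, 0])) < 0.1, mode

    def test_relative_target_requires_power_law_features(self):
        with pytest.raises(ValueError, match="power-law"):
            InverseParamNet(features="raw", mu_target="relative").fit(
                np.ones((10, 102)), np.ones((10, 1))
            )

    def test_archive_round_trip(self, splits, tmp_path):
        tr, va, _ = splits
        net = train_inverse_net(tr, va, max_epochs=60, random_state=1)
        net.save(tmp_path / "inv.zip")
        back = InverseParamNet.load(tmp_path / "inv.zip")
        Xv = inverse_features(va)
        np.testing.assert_array_equal(back.predict(Xv), net.predict(Xv))
        assert back.get_params()["mu_target"] == "relative"
        assert back.n_outputs_ == 1
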