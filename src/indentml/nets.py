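"""The two surrogate networks, as scikit-learn style estimators.

``ForwardCurveNet`` learns the forward map from design parameters
``(W/R, H/R, log10 mu[, log10 Jm])`` to the 100-point load-displacement
curve; ``InverseParamNet`` learns the direct inverse map from
``(W/R, H/R, log10 p, s)`` power-law features (or, optionally, raw curve
values) to the material parameters.

Normalisation conventions
-------------------------
Inputs are min-max scaled to [0, 1] — forward-net inputs against the
design-space bounds, inverse-net inputs against the training split (power
law features have no a-priori bounds).  Forward-net outputs are the
per-depth-point z-scores of ``log10`` of the mu-scaled non-dimensional
force ``F / (mu R^2)``: hyperelastic forces are exactly linear in ``mu``
at fixed ``K/mu``, so scaling ``mu`` out removes four decades of spread
and the log makes the remaining geometry/stiffening variation uniform in
relative terms.  Normalisation statistics always come from the training
split only.

Both estimators follow the scikit-learn contract (``fit`` / ``predict`` /
``get_params``; fitted attributes carry a trailing underscore) and
serialise to a portable archive (weights + normalisation + spec + data
fingerprint) so inversion runs without retraining.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import json
import logging
import zipfile

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from sklearn.base import BaseEstimator, RegressorMixin

from ._nn import DenseNet
from .constitutive import Model
from .design import DesignPoint, DesignSpace
from .features import PowerLawFeaturizer
from .generator import DEFAULT_R, SyntheticDataset

__all__ = [
    "ForwardCurveNet",
    "InverseParamNet",
    "train_forward_net",
    "train_inverse_net",
    "predict_forward",
    "validation_error",
]

logger = logging.getLogger(__name__)

_ARCHIVE_VERSION = 1


def _fingerprint(*arrays: NDArray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


class _ArchiveMixin:
    """Portable model archive: versioned zip of weights + stats + spec."""

    _norm_attrs: tuple[str, ...] = ()

    def save(self, path) -> None:
        state = self.net_.state()
        meta = {
            "archive_version": _ARCHIVE_VERSION,
            "class": type(self).__name__,
            "params": {
                k: ({"__design_space__": dataclasses.asdict(v)}
                    if isinstance(v, DesignSpace)
                    else list(v) if isinstance(v, tuple) else v)
                for k, v in self.get_params().items()
            },
            "sizes": state["sizes"],
            "alpha": state["alpha"],
            "fingerprint": self.fingerprint_,
        }
        members: dict[str, bytes] = {"meta.json": json.dumps(meta, sort_keys=True).encode()}
        arrays = {}
        for i, (W, b) in enumerate(zip(state["weights"], state["biases"])):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        for name in self._norm_attrs:
            arrays[name] = np.asarray(getattr(self, name + "_"))
        for name, arr in arrays.items():
            buf = _io.BytesIO()
            np.lib.format.write_array(buf, np.asarray(arr, dtype=float), allow_pickle=False)
            members[name + ".npy"] = buf.getvalue()
        members["history.csv"] = self.history_frame().to_csv(index=False).encode()
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            for name in sorted(members):
                info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
                info.compress_type = zipfile.ZIP_DEFLATED
                zf.writestr(info, members[name])

    @classmethod
    def load(cls, path):
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta["archive_version"] != _ARCHIVE_VERSION:
                raise ValueError(f"unsupported archive version {meta['archive_version']}")
            arrays = {
                name[:-4]: np.lib.format.read_array(_io.BytesIO(zf.read(name)))
                for name in zf.namelist() if name.endswith(".npy")
            }
            history = pd.read_csv(_io.BytesIO(zf.read("history.csv")))
        params = {}
        for k, v in meta["params"].items():
            if isinstance(v, dict) and "__design_space__" in v:
                kw = v["__design_space__"]
                for key in ("W_over_R", "H_over_R", "mu", "Jm"):
                    kw[key] = tuple(kw[key])
                params[k] = DesignSpace(**kw)
            elif isinstance(v, list):
                params[k] = tuple(v)
            else:
                params[k] = v
        est = cls(**params)
        n_layers = len(meta["sizes"]) - 1
        est.net_ = DenseNet.from_state({
            "sizes": meta["sizes"],
            "alpha": meta["alpha"],
            "weights": [arrays[f"W{i}"] for i in range(n_layers)],
            "biases": [arrays[f"b{i}"] for i in range(n_layers)],
        })
        for name in cls._norm_attrs:
            setattr(est, name + "_", arrays[name])
        est.fingerprint_ = meta["fingerprint"]
        est.n_features_in_ = meta["sizes"][0]
        est.n_outputs_ = meta["sizes"][-1]
        est.history_ = history.to_dict(orient="list")
        est.history_["best_epoch"] = int(history["epoch"].iloc[-1])
        return est

    def history_frame(self) -> pd.DataFrame:
        cols = {k: v for k, v in self.history_.items() if isinstance(v, list)}
        return pd.DataFrame(cols)


def _fit_restarts(est, sizes, Xn, Tn, Xvn, Tvn, val_metric, select_metric=None) -> None:
    """Train ``est.n_restarts`` nets from different seeds, keep the best.

    Selection uses ``select_metric(net)`` evaluated after each restart's
    training (with best-epoch weights restored), falling back to the
    validation loss.  The winner's network and history are installed on
    the estimator; per-restart scores are recorded in ``restarts_``.
    """
    best = None
    summary = []
    for i in range(max(1, est.n_restarts)):
        seed = est.random_state + 7919 * i
        net = DenseNet(sizes, alpha=est.alpha, seed=seed)
        history = net.train(
            Xn, Tn, Xvn, Tvn,
            loss=est.loss, learning_rate=est.learning_rate,
            batch_size=est.batch_size, max_epochs=est.max_epochs,
            patience=est.patience, seed=seed, val_metric=val_metric,
        )
        score = (float(select_metric(net)) if select_metric is not None
                 else history["best_val_loss"])
        summary.append({"seed": seed, "best_val_loss": history["best_val_loss"],
                        "selection_score": score})
        if best is None or score < best[0]:
            best = (score, net, history)
    est.net_, est.history_ = best[1], best[2]
    est.restarts_ = summary


class ForwardCurveNet(_ArchiveMixin, RegressorMixin, BaseEstimator):
    """Dense net mapping design parameters to a full indentation curve.

    Parameters follow the study architecture: five hidden layers
    (4, 4, 100, 100, 100), leaky-ReLU slope 0.3, linear output, MSE loss,
    Adam optimiser.

    ``fit`` expects ``X`` with columns ``(W/R, H/R, log10 mu)`` plus
    ``log10 Jm`` for the Gent model, and ``Y`` the force targets in N on
    the shared depth grid excluding the zero-depth point.
    """

    _norm_attrs = ("x_lo", "x_hi", "t_mean", "t_std")

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (4, 4, 100, 100, 100),
        alpha: float = 0.3,
        loss: str = "mse",
        learning_rate: float = 1.0e-3,
        batch_size: int = 64,
        max_epochs: int = 2000,
        patience: int = 2000,
        random_state: int = 0,
        n_restarts: int = 1,
        R: float = DEFAULT_R,
        space: DesignSpace | None = None,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.alpha = alpha
        self.loss = loss
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.random_state = random_state
        self.n_restarts = n_restarts
        self.R = R
        self.space = space

    # ---- normalisation ---------------------------------------------------
    def _bounds(self, n_cols: int) -> tuple[NDArray, NDArray]:
        space = self.space or DesignSpace()
        lo = [space.W_over_R[0], space.H_over_R[0], np.log10(space.mu[0])]
        hi = [space.W_over_R[1], space.H_over_R[1], np.log10(space.mu[1])]
        if n_cols == 4:
            lo.append(np.log10(space.Jm[0]))
            hi.append(np.log10(space.Jm[1]))
        elif n_cols != 3:
            raise ValueError(f"X must have 3 (neo-Hookean) or 4 (Gent) columns, got {n_cols}")
        return np.array(lo), np.array(hi)

    def _norm_x(self, X: NDArray) -> NDArray:
        return (X - self.x_lo_) / (self.x_hi_ - self.x_lo_)

    def _to_targets(self, X: NDArray, Y: NDArray) -> NDArray:
        mu = 10.0 ** X[:, 2]
        return np.log10(Y / (mu[:, None] * self.R**2))

    def _norm_t(self, T: NDArray) -> NDArray:
        return (T - self.t_mean_) / self.t_std_

    # ---- estimator API ---------------------------------------------------
    def fit(self, X, Y, validation_data=None):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must be 2-d with matching row counts")
        self.x_lo_, self.x_hi_ = self._bounds(X.shape[1])
        T = np.log10(Y / (10.0 ** X[:, 2][:, None] * self.R**2))
        self.t_mean_ = T.mean(axis=0)
        self.t_std_ = T.std(axis=0)
        self.t_std_ = np.where(self.t_std_ > 0, self.t_std_, 1.0)

        if validation_data is None:
            n_val = max(1, X.shape[0] // 10)
            rng = np.random.default_rng(self.random_state)
            idx = rng.permutation(X.shape[0])
            val_idx, train_idx = idx[:n_val], idx[n_val:]
            Xv, Yv = X[val_idx], Y[val_idx]
            X, Y, T = X[train_idx], Y[train_idx], T[train_idx]
        else:
            Xv, Yv = (np.asarray(a, dtype=float) for a in validation_data)
            if Xv.shape[1] != X.shape[1] or Yv.shape[1] != Y.shape[1]:
                raise ValueError("validation data shape mismatch with training data")

        Xn, Tn = self._norm_x(X), self._norm_t(T)
        Xvn = self._norm_x(Xv)
        Tvn = self._norm_t(self._to_targets(Xv, Yv))

        sizes = [X.shape[1], *self.hidden_layer_sizes, Y.shape[1]]

        def rel_curve_error(net: DenseNet) -> float:
            F = self._denorm_predict(net.forward(Xvn), Xv)
            return float(np.mean(
                np.linalg.norm(F - Yv, axis=1) / np.linalg.norm(Yv, axis=1)
            ))

        _fit_restarts(self, sizes, Xn, Tn, Xvn, Tvn, rel_curve_error)
        self.n_features_in_ = X.shape[1]
        self.fingerprint_ = _fingerprint(X, Y)
        return self

    def _denorm_predict(self, Tn: NDArray, X: NDArray) -> NDArray:
        T = Tn * self.t_std_ + self.t_mean_
        mu = 10.0 ** X[:, 2]
        return 10.0**T * (mu[:, None] * self.R**2)

    def predict(self, X) -> NDArray:
        """Predicted forces in N, shape ``(n, n_depth_points)``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if np.any(X < self.x_lo_) or np.any(X > self.x_hi_):
            logger.warning("predicting outside the training design space (extrapolation)")
        return self._denorm_predict(self.net_.forward(self._norm_x(X)), X)

    def validation_error(self, X, Y) -> dict:
        """Curve-level relative-error summary on held-out data."""
        F = self.predict(X)
        Y = np.asarray(Y, dtype=float)
        rel = np.linalg.norm(F - Y, axis=1) / np.linalg.norm(Y, axis=1)
        return {"mean": float(rel.mean()), "median": float(np.median(rel)),
                "max": float(rel.max())}


class InverseParamNet(_ArchiveMixin, RegressorMixin, BaseEstimator):
    """Dense net mapping curve features directly to material parameters.

    Study architecture: five hidden layers (4, 4, 4, 4, 2), leaky-ReLU
    slope 0.3, linear output sized to the parameter count (1 for
    neo-Hookean, 2 for Gent), MAE loss, Adam optimiser.  Inputs are
    ``(W/R, H/R, log10 p, s)`` by default (``features="power_law"``), or
    geometry plus the raw normalised curve (``features="raw"``, used to
    demonstrate why the power-law step matters under noise).  Outputs are
    ``log10 mu`` (and ``log10 Jm``).

    With ``mu_target="relative"`` (the default for power-law features)
    the network internally learns ``log10 mu - log10 p`` — the modulus is
    a known multiple of the power-law prefactor up to geometry and
    stiffening corrections, so learning only the correction is a much
    easier task for the deliberately narrow architecture.  ``predict``
    always returns absolute ``log10`` parameters.
    """

    _norm_attrs = ("x_lo", "x_hi", "y_lo", "y_hi")

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (4, 4, 4, 4, 2),
        alpha: float = 0.3,
        loss: str = "mae",
        learning_rate: float = 3.0e-3,
        batch_size: int = 64,
        max_epochs: int = 3000,
        patience: int = 3000,
        random_state: int = 0,
        n_restarts: int = 1,
        features: str = "power_law",
        mu_target: str = "relative",
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.alpha = alpha
        self.loss = loss
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.random_state = random_state
        self.n_restarts = n_restarts
        self.features = features
        self.mu_target = mu_target

    def _uses_relative_mu(self) -> bool:
        if self.mu_target not in ("relative", "absolute"):
            raise ValueError(f"mu_target must be 'relative' or 'absolute', got {self.mu_target}")
        if self.mu_target == "relative" and self.features != "power_law":
            raise ValueError("mu_target='relative' requires power-law features")
        return self.mu_target == "relative"

    def _to_internal(self, X: NDArray, y: NDArray) -> NDArray:
        """Map absolute log10 targets to the learned parameterisation."""
        if self._uses_relative_mu():
            y = y.copy()
            y[:, 0] -= X[:, 2]  # column 2 is log10 p
        return y

    def _from_internal(self, X: NDArray, y: NDArray) -> NDArray:
        if self._uses_relative_mu():
            y = y.copy()
            y[:, 0] += X[:, 2]
        return y

    def fit(self, X, y, validation_data=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]

        if validation_data is None:
            n_val = max(1, X.shape[0] // 10)
            rng = np.random.default_rng(self.random_state)
            idx = rng.permutation(X.shape[0])
            Xv, yv = X[idx[:n_val]], y[idx[:n_val]]
            X, y = X[idx[n_val:]], y[idx[n_val:]]
        else:
            Xv, yv = validation_data
            Xv = np.asarray(Xv, dtype=float)
            yv = np.asarray(yv, dtype=float)
            if yv.ndim == 1:
                yv = yv[:, None]

        t = self._to_internal(X, y)
        tv = self._to_internal(Xv, yv)
        self.x_lo_, self.x_hi_ = X.min(axis=0), X.max(axis=0)
        span = self.x_hi_ - self.x_lo_
        self.x_hi_ = np.where(span > 0, self.x_hi_, self.x_lo_ + 1.0)
        self.y_lo_, self.y_hi_ = t.min(axis=0), t.max(axis=0)

        Xn, tn = self._norm_x(X), self._norm_y(t)
        Xvn, tvn = self._norm_x(Xv), self._norm_y(tv)

        sizes = [X.shape[1], *self.hidden_layer_sizes, y.shape[1]]

        def rel_param_error(net: DenseNet) -> float:
            pred = self._from_internal(Xv, self._denorm_y(net.forward(Xvn)))
            rel = np.abs(10.0**pred - 10.0**yv) / 10.0**yv
            return float(rel.mean())

        def rel_mu_error(net: DenseNet) -> float:
            # restart selection targets the modulus, the primary parameter
            pred = self._from_internal(Xv, self._denorm_y(net.forward(Xvn)))
            rel = np.abs(10.0 ** pred[:, 0] - 10.0 ** yv[:, 0]) / 10.0 ** yv[:, 0]
            return float(rel.mean())

        _fit_restarts(self, sizes, Xn, tn, Xvn, tvn, rel_param_error,
                      select_metric=rel_mu_error)
        self.n_features_in_ = X.shape[1]
        self.n_outputs_ = y.shape[1]
        self.fingerprint_ = _fingerprint(X, y)
        return self

    def _norm_x(self, X: NDArray) -> NDArray:
        return (X - self.x_lo_) / (self.x_hi_ - self.x_lo_)

    def _norm_y(self, y: NDArray) -> NDArray:
        return (y - self.y_lo_) / (self.y_hi_ - self.y_lo_)

    def _denorm_y(self, yn: NDArray) -> NDArray:
        return yn * (self.y_hi_ - self.y_lo_) + self.y_lo_

    def predict(self, X) -> NDArray:
        """Predicted absolute ``log10`` parameters, shape ``(n, n_params)``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self._from_internal(X, self._denorm_y(self.net_.forward(self._norm_x(X))))

    def validation_error(self, X, y) -> dict:
        """Per-parameter mean relative error on the linear scale."""
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        pred = self.predict(X)
        rel = np.abs(10.0**pred - 10.0**y) / 10.0**y
        return {"mean": rel.mean(axis=0).tolist(), "max": rel.max(axis=0).tolist()}


# ---- thin functional wrappers over the estimators ------------------------

def train_forward_net(
    train: SyntheticDataset, val: SyntheticDataset, **net_params
) -> ForwardCurveNet:
    """Fit the forward surrogate network on a dataset split pair."""
    if not np.array_equal(train.grid, val.grid):
        raise ValueError("train and validation splits must share the depth grid")
    net = ForwardCurveNet(R=train.R, space=train.space, **net_params)
    return net.fit(
        train.design_matrix(), train.targets(),
        validation_data=(val.design_matrix(), val.targets()),
    )


def inverse_features(dataset: SyntheticDataset) -> NDArray:
    """(W/R, H/R, log10 p, s) feature matrix for a dataset's curves."""
    feats = PowerLawFeaturizer(dataset.grid[1:]).fit_transform(dataset.targets() / dataset.R**2)
    X = dataset.design_matrix()
    return np.column_stack([X[:, 0], X[:, 1], feats])


def inverse_targets(dataset: SyntheticDataset) -> NDArray:
    """log10 of the material parameters (mu[, Jm])."""
    X = dataset.design_matrix()
    return X[:, 2:]


def train_inverse_net(
    train: SyntheticDataset, val: SyntheticDataset, **net_params
) -> InverseParamNet:
    """Fit the direct inverse network on power-law features of the splits."""
    net = InverseParamNet(**net_params)
    return net.fit(
        inverse_features(train), inverse_targets(train),
        validation_data=(inverse_features(val), inverse_targets(val)),
    )


def predict_forward(model: ForwardCurveNet, point: DesignPoint) -> NDArray:
    """De-normalised force curve (N) for one design point."""
    row = [point.W_over_R, point.H_over_R, np.log10(point.params.mu)]
    if point.params.model is Model.GENT:
        row.append(np.log10(point.params.Jm))
    if len(row) != model.n_features_in_:
        raise ValueError(
            f"model expects {model.n_features_in_} inputs, design point has {len(row)}"
        )
    return model.predict(np.array([row]))[0]


def validation_error(model, X, Y) -> dict:
    """Relative-error summary of a trained model on held-out data."""
    return model.validation_error(X, Y)
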