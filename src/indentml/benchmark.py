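"""End-to-end study runner: generate, train, invert, evaluate.

Reproduces the full synthetic-study loop for one or both constitutive
models: latin-hypercube design -> surrogate curves (train/validation/test
= 10 000/1250/1250 per model) -> forward + direct-inverse network
training -> parameter identification on the held-out splits by all four
methods (least squares through the forward net, direct inverse net,
Hertz, modified Hertz) -> recovery metrics.

Per-model training schedules differ because the learning tasks do: the
neo-Hookean forward map is geometry-only and converges within a few
hundred epochs, while the Gent map must resolve strain stiffening over
nearly four decades of ``Jm`` and is trained longer; the Gent inverse
net additionally uses a few random restarts (best validation loss wins)
because its deliberately narrow architecture is sensitive to
initialisation.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field


from .constitutive import Model
from .contact import HertzVariant
from .design import DesignSpace
from .generator import SurrogateCoeffs, SyntheticDataset, build_dataset
from .inversion import (
    EvaluationSummary,
    evaluate_inversions,
    invert_direct,
    invert_hertz,
    invert_least_squares,
)
from .nets import (
    ForwardCurveNet,
    InverseParamNet,
    inverse_features,
    inverse_targets,
    train_forward_net,
    train_inverse_net,
)

__all__ = ["StudyScale", "FULL_SCALE", "SMOKE_SCALE", "run_model_study", "run_study"]


@dataclass(frozen=True)
class StudyScale:
    """Problem sizes and training schedules for one study run."""

    sizes: tuple[int, int, int] = (10_000, 1_250, 1_250)
    forward_epochs: dict = field(default_factory=lambda: {"neo_hookean": 200, "gent": 600})
    inverse_epochs: dict = field(default_factory=lambda: {"neo_hookean": 1500, "gent": 4000})
    inverse_restarts: dict = field(default_factory=lambda: {"neo_hookean": 1, "gent": 4})
    n_ls_starts: int = 5


FULL_SCALE = StudyScale()
SMOKE_SCALE = StudyScale(
    sizes=(400, 80, 80),
    forward_epochs={"neo_hookean": 120, "gent": 250},
    inverse_epochs={"neo_hookean": 250, "gent": 400},
    inverse_restarts={"neo_hookean": 1, "gent": 1},
    n_ls_starts=3,
)


def _ls_split(
    fwd: ForwardCurveNet, data: SyntheticDataset, seed: int, n_starts: int
) -> EvaluationSummary:
    results = [
        invert_least_squares(fwd, data.curve(i), seed=seed, n_starts=n_starts)
        for i in range(len(data))
    ]
    return evaluate_inversions(results, [p.params for p in data.designs])


def _direct_split(inv: InverseParamNet, data: SyntheticDataset) -> EvaluationSummary:
    results = [invert_direct(inv, data.curve(i)) for i in range(len(data))]
    return evaluate_inversions(results, [p.params for p in data.designs])


def _hertz_split(data: SyntheticDataset, variant: HertzVariant) -> EvaluationSummary:
    results = [invert_hertz(data.curve(i), variant=variant) for i in range(len(data))]
    return evaluate_inversions(results, [p.params for p in data.designs])


def run_model_study(
    model: Model | str,
    seed: int = 1,
    scale: StudyScale = FULL_SCALE,
    space: DesignSpace | None = None,
    coeffs: SurrogateCoeffs | None = None,
    *,
    hertz_baselines: bool = True,
    test_split: bool = True,
) -> dict:
    """Run the complete pipeline for one constitutive model.

    ``seed`` drives everything: dataset split seeds are
    ``(seed, seed + 1, seed + 2)`` and network/optimiser seeds derive
    from ``seed``.  Returns a dict of datasets, trained models,
    per-method :class:`EvaluationSummary` objects on the validation and
    test splits, and wall times.
    """
    model = Model(model)
    key = model.value
    t0 = time.time()
    train, val, test = build_dataset(
        space=space, model=model, sizes=scale.sizes,
        seeds=(seed, seed + 1, seed + 2), coeffs=coeffs,
    )
    t_gen = time.time() - t0

    t0 = time.time()
    fwd = train_forward_net(
        train, val, max_epochs=scale.forward_epochs[key], random_state=seed,
    )
    t_fwd = time.time() - t0

    t0 = time.time()
    inv = train_inverse_net(
        train, val, max_epochs=scale.inverse_epochs[key],
        n_restarts=scale.inverse_restarts[key], random_state=seed,
    )
    t_inv = time.time() - t0

    out = {
        "model": model,
        "datasets": {"train": train, "validation": val, "test": test},
        "forward_net": fwd,
        "inverse_net": inv,
        "forward_val_error": fwd.validation_error(val.design_matrix(), val.targets()),
        "inverse_val_error": inv.validation_error(
            inverse_features(val), inverse_targets(val)
        ),
    }

    t0 = time.time()
    out["ls_val"] = _ls_split(fwd, val, seed, scale.n_ls_starts)
    out["direct_val"] = _direct_split(inv, val)
    if test_split:
        out["ls_test"] = _ls_split(fwd, test, seed, scale.n_ls_starts)
        out["direct_test"] = _direct_split(inv, test)
    if hertz_baselines:
        target = test if test_split else val
        out["hertz_test"] = _hertz_split(target, HertzVariant.HERTZ)
        out["modified_hertz_test"] = _hertz_split(target, HertzVariant.MODIFIED_HERTZ)
    out["wall_times"] = {
        "generate": t_gen, "train_forward": t_fwd, "train_inverse": t_inv,
        "invert": time.time() - t0,
    }
    return out


def run_study(seed: int = 1, scale: StudyScale = FULL_SCALE, **kw) -> dict:
    """Run the pipeline for both constitutive models."""
    return {
        "neo_hookean": run_model_study(Model.NEO_HOOKEAN, seed=seed, scale=scale, **kw),
        "gent": run_model_study(Model.GENT, seed=seed, scale=scale, **kw),
    }


def headline_metrics(study: dict) -> dict:
    """The study's headline recovery numbers, as printed quantities.

    Percent values are on the 0-100 scale; R^2 values dimensionless.
    """
    nh, gent = study["neo_hookean"], study["gent"]
    n_val = nh["ls_val"].n

    def pct(x: float) -> float:
        return 100.0 * x

    out = {
        "mu_error_pct_worst_method_nh_test": {
            "value": pct(max(nh["ls_test"].mean_rel_error["mu"],
                             nh["direct_test"].mean_rel_error["mu"])),
            "n": nh["ls_test"].n,
        },
        "r2_mu_ls_nh_val": {"value": nh["ls_val"].r2["mu"], "n": n_val},
        "r2_mu_ls_gent_val": {"value": gent["ls_val"].r2["mu"], "n": n_val},
        "r2_jm_ls_gent_val": {"value": gent["ls_val"].r2["Jm"], "n": n_val},
        "r2_mu_direct_nh_val": {"value": nh["direct_val"].r2["mu"], "n": n_val},
        "r2_mu_direct_gent_val": {"value": gent["direct_val"].r2["mu"], "n": n_val},
        "jm_error_pct_ls_gent_val": {
            "value": pct(gent["ls_val"].mean_rel_error["Jm"]), "n": n_val,
        },
    }
    return out
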