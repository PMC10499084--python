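"""Single human-readable run configuration (YAML).

Gathers everything a study run needs: the design-space bounds, the
surrogate correction coefficients, both network specifications, the
least-squares inversion settings and unit declarations.  All fields have
the study defaults, so an empty file is a valid configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .design import DesignSpace
from .generator import DEFAULT_R, DEFAULT_SEEDS, DEFAULT_SIZES, SurrogateCoeffs

__all__ = ["NetConfig", "InversionConfig", "RunConfig"]


@dataclass
class NetConfig:
    hidden_layer_sizes: tuple[int, ...] = (4, 4, 100, 100, 100)
    alpha: float = 0.3
    loss: str = "mse"
    learning_rate: float = 1.0e-3
    batch_size: int = 64
    max_epochs: int = 2000
    patience: int = 2000
    random_state: int = 0
    n_restarts: int = 1

    def estimator_params(self) -> dict:
        return dataclasses.asdict(self)


def default_inverse_net() -> "NetConfig":
    return NetConfig(
        hidden_layer_sizes=(4, 4, 4, 4, 2), loss="mae",
        learning_rate=3.0e-3, max_epochs=3000, patience=3000,
    )


@dataclass
class InversionConfig:
    n_starts: int = 5
    seed: int = 0
    fit_on: str = "delta_over_R"
    trim_baseline: float | None = None


@dataclass
class RunConfig:
    space: DesignSpace = field(default_factory=DesignSpace)
    surrogate: SurrogateCoeffs = field(default_factory=SurrogateCoeffs)
    forward_net: NetConfig = field(default_factory=NetConfig)
    inverse_net: NetConfig = field(default_factory=default_inverse_net)
    inversion: InversionConfig = field(default_factory=InversionConfig)
    R: float = DEFAULT_R
    sizes: tuple[int, int, int] = DEFAULT_SIZES
    seeds: tuple[int, int, int] = DEFAULT_SEEDS
    units: dict = field(default_factory=lambda: {"depth": "m", "force": "N"})

    # ---- YAML round trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs: dict = {}
        if "space" in raw:
            sp = dict(raw["space"])
            for key in ("W_over_R", "H_over_R", "mu", "Jm"):
                if key in sp:
                    # YAML 1.1 reads unsigned exponents like 1.0e3 as strings
                    sp[key] = tuple(float(v) for v in sp[key])
            kwargs["space"] = DesignSpace(**sp)
        if "surrogate" in raw:
            sc = dict(raw["surrogate"])
            if "thickness" in sc:
                sc["thickness"] = tuple(sc["thickness"])
            kwargs["surrogate"] = SurrogateCoeffs(**sc)
        for key, factory in (("forward_net", NetConfig), ("inverse_net", NetConfig)):
            if key in raw:
                nc = dict(raw[key])
                if "hidden_layer_sizes" in nc:
                    nc["hidden_layer_sizes"] = tuple(nc["hidden_layer_sizes"])
                kwargs[key] = factory(**nc)
        if "inversion" in raw:
            kwargs["inversion"] = InversionConfig(**raw["inversion"])
        if "R" in raw:
            kwargs["R"] = float(raw["R"])
        if "units" in raw:
            kwargs["units"] = raw["units"]
        for key in ("sizes", "seeds"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        return cls(**kwargs)
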