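"""Model parameters for subchondral bone adaptation and microdamage.

The model is a lumped two-state ODE for a volume of subchondral bone in the
lateral condyle of the equine third metacarpus: bone volume fraction ``fBM``
adapts to the mechanical signal (strain energy density) through osteoblast and
osteoclast surface activities, while fatigue microdamage ``D*`` (a life
fraction, failure at 1) forms with every loading cycle and is repaired by
remodelling.  All constants live in :class:`ModelParameters`, the single
source of truth for symbols and units.

Two presets are shipped: ``"fitted"`` (the default; formation and
resorption maxima and the fatigue-law intercept re-estimated against bone
volume fraction and fracture-time data) and ``"pre-fit"`` (the
literature values those fits started from).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ModelParameters",
    "preset",
    "PRESETS",
    "SENSITIVITY_RANGES",
    "load_parameters",
    "save_parameters",
]


@dataclass(frozen=True)
class ModelParameters:
    """Constants of the bone adaptation / damage model.

    Units: lengths mm, stresses/stiffnesses MPa, times days, strain rate s^-1.
    Activities (``AOBL_*``, ``AOCL_*``) are bone thickness formed/resorbed per
    unit surface per day (mm/day).
    """

    a: float = 11.42        # surface law coefficient (1/mm)
    b: float = -0.02        # surface law shape (dimensionless)
    alpha: float = 0.19     # fraction of specific surface available for remodelling
    E0: float = 2500.0      # maximum bone stiffness (MPa)
    gammaE: float = 0.06    # strain-rate exponent of stiffness
    AOBL_min: float = 0.001094  # minimum formation activity (mm/day)
    AOBL_max: float = 0.00603   # maximum formation activity (mm/day), fitted
    deltaB: float = 7.0     # formation half-saturation (MPa)
    gammaB: float = 1.0     # formation Hill sigmoidicity
    AOCL_min: float = 0.001     # minimum resorption activity (mm/day)
    AOCL_max: float = 0.00358   # maximum resorption activity (mm/day), fitted
    deltaC: float = 1.0     # resorption half-saturation (MPa)
    gammaC: float = 2.0     # resorption Hill sigmoidicity
    sigma0: float = 139.0   # fatigue-life intercept stress (MPa), fitted
    sigma1: float = 14.1    # fatigue-life slope stress (MPa)
    Enom: float = 1714.1    # reference stiffness of the fatigue law (MPa)
    Fs: float = 5.0         # damage repair specificity factor (>= 1)

    def __post_init__(self) -> None:
        positive = {
            "a": self.a, "alpha": self.alpha, "E0": self.E0,
            "gammaE": self.gammaE, "deltaB": self.deltaB, "gammaB": self.gammaB,
            "deltaC": self.deltaC, "gammaC": self.gammaC, "sigma0": self.sigma0,
            "sigma1": self.sigma1, "Enom": self.Enom,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if not (0 < self.alpha <= 1):
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if not (self.AOBL_max >= self.AOBL_min >= 0):
            raise ValueError("require AOBL_max >= AOBL_min >= 0")
        if not (self.AOCL_max >= self.AOCL_min >= 0):
            raise ValueError("require AOCL_max >= AOCL_min >= 0")
        if not self.Fs >= 1:
            raise ValueError(f"Fs must be >= 1, got {self.Fs}")

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "ModelParameters":
        unknown = set(data) - set(cls.field_names())
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})


#: Named parameter presets.  "fitted" is the default everywhere; the
#: "pre-fit" preset keeps the pre-fit literature values (used e.g. when
#: reproducing the four-fold rest:training resorption tuning, which predates
#: the fit of AOCL_max).
PRESETS: dict[str, ModelParameters] = {
    "fitted": ModelParameters(),
    "pre-fit": ModelParameters(AOBL_max=0.0127, AOCL_max=0.011, sigma0=134.2),
}


def preset(name: str = "fitted") -> ModelParameters:
    """Return a named parameter preset."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


#: Sampling ranges for the global sensitivity analysis.  The three loading
#: quantities (sigma, strain_rate, vn) are sampled exactly like the material
#: parameters; "dummy" has no effect on the model and flags spurious
#: correlations.
SENSITIVITY_RANGES: dict[str, tuple[float, float]] = {
    "sigma": (30.0, 102.0),
    "strain_rate": (0.05, 0.46),
    "vn": (25.0, 120.0),
    "alpha": (0.095, 0.285),
    "a": (5.71, 17.13),
    "b": (-0.2, 0.2),
    "E0": (1250.0, 3750.0),
    "gammaE": (0.03, 0.09),
    "AOBL_min": (0.0, 0.00301),
    "AOBL_max": (0.00301, 0.00904),
    "deltaB": (3.5, 10.5),
    "gammaB": (1.0, 5.0),
    "AOCL_min": (0.0, 0.0018),
    "AOCL_max": (0.0018, 0.0054),
    "deltaC": (0.5, 1.5),
    "gammaC": (1.0, 5.0),
    "sigma0": (125.1, 152.9),
    "sigma1": (12.69, 15.51),
    "Enom": (857.0, 2571.2),
    "Fs": (1.0, 10.0),
    "dummy": (0.0, 1.0),
}


def load_parameters(path: str | Path) -> ModelParameters:
    """Load a parameter set from a flat YAML/JSON mapping.

    Keys must be named exactly as :class:`ModelParameters` fields; unknown
    keys are an error.  Missing keys fall back to the fitted defaults.
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path} must contain a flat key-value mapping")
    return ModelParameters.from_dict(data)


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write a parameter set as YAML (or JSON for .json paths)."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
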