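"""Algebraic laws and the coupled ODE right-hand side.

The state is ``(fBM, D*)``: bone volume fraction and fatigue damage as a life
fraction.  The laws composed here are

* the specific surface ``Sv = a sqrt(1-fBM) [1 - b (1-fBM)]`` available for
  remodelling,
* the strain-rate- and density-dependent tissue stiffness
  ``E = E0 eps_dot^gammaE fBM^3``,
* the mechanical signal ``psi = sigma^2 / (2 E)`` (strain energy density),
* Hill-type osteoblast/osteoclast activities ``AOBL(psi)`` (increasing) and
  ``AOCL(psi)`` (decreasing),
* the stiffness-adjusted fatigue life ``Nf* = 10^(-(sigma-sigma0)/sigma1) *
  E/Enom`` and per-cycle damage ``vD = 1/Nf*``,
* targeted damage repair ``Dr' = [AOBL + (Fs-1) AOCL] alpha Sv D*/fBM``.

The mass balances are ``dfBM/dt = (AOBL - AOCL) alpha Sv`` and
``dD*/dt = vD vn - Dr'``.  Compression is positive; tensile loads are outside
the fatigue law's fitted domain and are rejected.  All rates are per day;
the strain rate stays in 1/s and enters only through the stiffness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import ModelParameters

__all__ = [
    "BoneState",
    "LoadingCondition",
    "RateBundle",
    "specific_surface",
    "tissue_stiffness",
    "strain_energy_density",
    "formation_activity",
    "resorption_activity",
    "fatigue_life",
    "damage_per_cycle",
    "damage_formation_rate",
    "damage_repair_rate",
    "model_rhs",
]


@dataclass(frozen=True)
class BoneState:
    """State vector advanced by the ODE: bone volume fraction and damage."""

    fBM: float
    D: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.fBM <= 1):
            raise ValueError(f"fBM must lie in (0, 1], got {self.fBM}")
        if not (0 <= self.D <= 1):
            raise ValueError(f"D must lie in [0, 1], got {self.D}")


@dataclass(frozen=True)
class LoadingCondition:
    """A constant loading environment.

    sigma: joint contact pressure (MPa, compressive positive);
    strain_rate: loading strain rate (1/s); vn: loading cycles per day.
    """

    sigma: float
    strain_rate: float
    vn: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(
                f"sigma must be >= 0 (compression positive); got {self.sigma}. "
                "Tensile loading is outside the fatigue law's domain."
            )
        if not self.strain_rate > 0:
            raise ValueError(f"strain_rate must be > 0, got {self.strain_rate}")
        if self.vn < 0:
            raise ValueError(f"vn must be >= 0, got {self.vn}")


@dataclass(frozen=True)
class RateBundle:
    """Every intermediate of one right-hand-side evaluation.

    Keeping the intermediates lets downstream stages (traces, damage
    attribution) and tests audit the physics without recomputing it.
    """

    Sv: float        # specific surface (1/mm)
    E: float         # tissue stiffness (MPa)
    psi: float       # strain energy density (MPa)
    AOBL: float      # formation activity (mm/day)
    AOCL: float      # resorption activity (mm/day)
    Nf_adj: float    # stiffness-adjusted fatigue life Nf* (cycles)
    vD: float        # damage per cycle
    Df: float        # damage formation rate (1/day)
    Dr: float        # damage repair rate (1/day)
    dfBM_dt: float   # d(bone volume fraction)/dt (1/day)
    dD_dt: float     # d(damage)/dt (1/day)


def specific_surface(fBM: float, params: ModelParameters) -> float:
    """Bone specific surface Sv (1/mm) as a function of volume fraction.

    Square-root pore-surface law; zero at fBM = 1 (no marrow interface left).
    """
    if not (0 <= fBM <= 1):
        raise ValueError(f"fBM must lie in [0, 1], got {fBM}")
    u = 1.0 - fBM
    return params.a * math.sqrt(u) * (1.0 - params.b * u)


def tissue_stiffness(fBM: float, strain_rate: float, params: ModelParameters) -> float:
    """Tissue stiffness E = E0 * strain_rate^gammaE * fBM^3 (MPa)."""
    if not strain_rate > 0:
        raise ValueError(f"strain_rate must be > 0, got {strain_rate}")
    if not (0 < fBM <= 1):
        raise ValueError(f"fBM must lie in (0, 1], got {fBM}")
    return params.E0 * strain_rate**params.gammaE * fBM**3


def strain_energy_density(sigma: float, E: float) -> float:
    """Strain energy density psi = sigma^2 / (2 E) (MPa), the mechanical signal."""
    if not E > 0:
        raise ValueError(f"stiffness must be > 0, got {E}")
    return sigma * sigma / (2.0 * E)


def _hill(psi: float, delta: float, gamma: float) -> float:
    # psi^g / (d^g + psi^g) with the 0^g/(d^g) -> 0 convention, so that
    # gamma < 1 stays well defined at psi = 0.
    if psi == 0.0:
        return 0.0
    pg = psi**gamma
    return pg / (delta**gamma + pg)


def formation_activity(psi: float, params: ModelParameters) -> float:
    """Osteoblast activity AOBL(psi): increasing Hill function of the signal."""
    if psi < 0:
        raise ValueError(f"psi must be >= 0, got {psi}")
    h = _hill(psi, params.deltaB, params.gammaB)
    return params.AOBL_min + (params.AOBL_max - params.AOBL_min) * h


def resorption_activity(psi: float, params: ModelParameters) -> float:
    """Osteoclast activity AOCL(psi): decreasing Hill function of the signal.

    High loads inhibit resorption; at rest the activity approaches AOCL_max.
    """
    if psi < 0:
        raise ValueError(f"psi must be >= 0, got {psi}")
    h = _hill(psi, params.deltaC, params.gammaC)
    return params.AOCL_max - (params.AOCL_max - params.AOCL_min) * h


def fatigue_life(sigma: float, E: float, params: ModelParameters) -> float:
    """Stiffness-adjusted fatigue life Nf*(sigma, E) in cycles.

    Nf* = 10^(-(sigma - sigma0)/sigma1) * E / Enom.  The power law was fitted
    on trained bone at the reference stiffness Enom; stiffer bone resists
    fatigue proportionally longer.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if not E > 0:
        raise ValueError(f"stiffness must be > 0, got {E}")
    return 10.0 ** (-(sigma - params.sigma0) / params.sigma1) * E / params.Enom


def damage_per_cycle(sigma: float, E: float, params: ModelParameters) -> float:
    """Damage life-fraction incurred per loading cycle, vD = 1/Nf*."""
    return 1.0 / fatigue_life(sigma, E, params)


def damage_formation_rate(vD: float, vn: float) -> float:
    """Daily damage formation rate Df' = vD * vn (1/day)."""
    if vD < 0 or vn < 0:
        raise ValueError("vD and vn must be >= 0")
    return vD * vn


def damage_repair_rate(
    AOBL: float,
    AOCL: float,
    Sv: float,
    state: BoneState,
    params: ModelParameters,
) -> float:
    """Daily damage repair rate Dr' (1/day).

    Dr' = [AOBL + (Fs - 1) AOCL] alpha Sv D / fBM.  Formation dilutes
    microcracks over new matrix; resorption removes cracks only insofar as it
    targets them beyond chance (the Fs - 1 excess).  Linear in the damage.
    """
    if not state.fBM > 0:
        raise ValueError("fBM must be > 0 for repair")
    return (
        (AOBL + (params.Fs - 1.0) * AOCL)
        * params.alpha * Sv * state.D / state.fBM
    )


def model_rhs(
    t: float,
    state: BoneState,
    loading: LoadingCondition,
    params: ModelParameters,
) -> RateBundle:
    """Evaluate the coupled right-hand side at one state and loading.

    The model is autonomous; ``t`` is accepted for integrator compatibility.
    Every intermediate is reported in the returned :class:`RateBundle`.
    """
    Sv = specific_surface(state.fBM, params)
    E = tissue_stiffness(state.fBM, loading.strain_rate, params)
    psi = strain_energy_density(loading.sigma, E)
    AOBL = formation_activity(psi, params)
    AOCL = resorption_activity(psi, params)
    Nf_adj = fatigue_life(loading.sigma, E, params)
    vD = 1.0 / Nf_adj
    Df = damage_formation_rate(vD, loading.vn)
    Dr = damage_repair_rate(AOBL, AOCL, Sv, state, params)
    return RateBundle(
        Sv=Sv, E=E, psi=psi, AOBL=AOBL, AOCL=AOCL,
        Nf_adj=Nf_adj, vD=vD, Df=Df, Dr=Dr,
        dfBM_dt=(AOBL - AOCL) * params.alpha * Sv,
        dD_dt=Df - Dr,
    )
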