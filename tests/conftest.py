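"""Shared fixtures and the independent fixed-step oracle.

The Euler oracle below re-expresses the model's laws directly from their
closed forms, deliberately independent of the package's own right-hand side
and integrator, so trajectory tests compare two separately written codings
of the same physics.
"""

from __future__ import annotations

import numpy as np
import pytest

from osteofatigue import ModelParameters, preset


@pytest.fixture(scope="session")
def fitted() -> ModelParameters:
    return preset("fitted")


@pytest.fixture(scope="session")
def initial_preset() -> ModelParameters:
    return preset("pre-fit")


def euler_oracle(
    f0: float,
    D0: float,
    sigma: float,
    strain_rate: float,
    vn: float,
    p: dict[str, float],
    days: float,
    dt: float = 1e-3,
    sample_every: float = 1.0,
):
    """Fixed-step forward-Euler integration of the bone model, written from
    the closed-form laws.  Returns (times, fBM, D, failure_day).

    Vectorised over parameter draws if the loading/parameter entries are
    arrays of a common shape.
    """
    sigma = np.asarray(sigma, dtype=float)
    f = np.broadcast_to(np.asarray(f0, dtype=float), sigma.shape).copy() \
        if sigma.shape else np.float64(f0)
    D = np.broadcast_to(np.asarray(D0, dtype=float), sigma.shape).copy() \
        if sigma.shape else np.float64(D0)
    n_steps = int(round(days / dt))
    stride = max(1, int(round(sample_every / dt)))
    times, fs, Ds = [0.0], [np.array(f, copy=True)], [np.array(D, copy=True)]
    failure = np.full(sigma.shape if sigma.shape else (), np.nan)
    alive = np.ones_like(failure, dtype=bool)

    for step in range(1, n_steps + 1):
        fc = np.clip(f, 1e-9, 1 - 1e-9)
        u = 1.0 - fc
        Sv = p["a"] * np.sqrt(u) * (1.0 - p["b"] * u)
        E = p["E0"] * strain_rate ** p["gammaE"] * fc**3
        psi = sigma**2 / (2.0 * E)
        AOBL = p["AOBL_min"] + (p["AOBL_max"] - p["AOBL_min"]) * (
            psi ** p["gammaB"] / (p["deltaB"] ** p["gammaB"] + psi ** p["gammaB"])
        )
        AOCL = p["AOCL_min"] + (p["AOCL_max"] - p["AOCL_min"]) * (
            p["deltaC"] ** p["gammaC"] / (p["deltaC"] ** p["gammaC"] + psi ** p["gammaC"])
        )
        vD = 10.0 ** ((sigma - p["sigma0"]) / p["sigma1"]) * p["Enom"] / E
        Dr = (AOBL + (p["Fs"] - 1.0) * AOCL) * p["alpha"] * Sv * D / fc
        df = (AOBL - AOCL) * p["alpha"] * Sv
        dD = vD * vn - Dr
        f = np.clip(f + np.where(alive, dt * df, 0.0), 1e-9, 1 - 1e-9)
        D_new = D + np.where(alive, dt * dD, 0.0)
        crossed = alive & (D_new >= 1.0)
        if np.any(crossed):
            failure = np.where(crossed, step * dt, failure)
            D_new = np.where(crossed, 1.0, D_new)
            alive = alive & ~crossed
        D = D_new
        if step % stride == 0:
            times.append(step * dt)
            fs.append(np.array(f, copy=True))
            Ds.append(np.array(D, copy=True))
    return np.array(times), np.array(fs), np.array(Ds), failure
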