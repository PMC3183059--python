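"""Two-compartment microchamber O2 model shared by generator and estimator.

When the sensor lowers, a microchamber of volume ``V_ch`` forms over the
specimen.  Chamber O2 tension ``O_ch`` is depleted by the specimen and
replenished by diffusion from the plate wall compartment ``O_w`` (rate
``k_w``) and by atmospheric leak (rate ``k_a``):

    dO_ch/dt = -OCR / (V_ch * k_O2) + k_w  * (O_w  - O_ch) + k_a * (O_atm - O_ch)
    dO_w/dt  =                        k_w' * (O_ch - O_w)

With OCR constant over a measure phase this is a linear ODE, integrated
exactly with matrix exponentials.  The chamber value at each sample offset is
*affine* in (OCR, O_0) where O_0 is the common chamber/wall value at phase
start, which is what makes the estimator's per-cycle fit a plain linear
least-squares problem.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import expm

from .assay_model import ConfigError

__all__ = ["ChamberPhysics", "measure_phase_coefficients", "chamber_o2"]


@dataclass(frozen=True)
class ChamberPhysics:
    """Physical constants of the transient microchamber and its surroundings.

    Units: volumes in uL; ``k_o2`` in pmol O2 per uL per mmHg (Henry constant
    for the assay medium at 28.5 C); rate constants in 1/min; ``bc_chamber``
    in mpH per nmol H+ delivered into the microchamber.  ``o2_noise_sd``
    (mmHg) and ``ph_noise_sd`` (pH units) are additive sensor noise levels
    and may be zero.
    """

    v_ch_uL: float = 7.0
    k_o2: float = 1.4
    k_w: float = 0.06
    k_w_wall: float = 0.06
    k_a: float = 0.02
    o_atm_mmHg: float = 155.0
    bc_chamber: float = 10.0
    well_volume_uL: float = 700.0
    k_surface: float = 0.5
    ph0: float = 7.0
    o2_noise_sd: float = 0.2
    ph_noise_sd: float = 0.0005

    def __post_init__(self) -> None:
        for name in ("v_ch_uL", "k_o2", "o_atm_mmHg", "bc_chamber", "well_volume_uL", "k_surface"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"physics constant {name} must be positive")
        for name in ("k_w", "k_w_wall", "k_a", "o2_noise_sd", "ph_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"physics constant {name} must be non-negative")

    def noiseless(self) -> "ChamberPhysics":
        return replace(self, o2_noise_sd=0.0, ph_noise_sd=0.0)

    def _key(self) -> tuple:
        return (self.v_ch_uL, self.k_o2, self.k_w, self.k_w_wall, self.k_a, self.o_atm_mmHg)


_COEF_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def measure_phase_coefficients(
    physics: ChamberPhysics, offsets: tuple[float, ...]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Affine coefficients (alpha, beta, gamma) of the exact solution.

    For sample offsets ``t_k`` from measure-phase start, the chamber O2 is

        O_ch(t_k) = alpha_k + beta_k * OCR + gamma_k * O_0

    assuming wall and chamber start equilibrated at ``O_0`` (the mix phase
    re-homogenises the well).  Valid for singular dynamics too (k_w = k_a = 0
    reduces to a straight line).
    """
    key = (physics._key(), offsets)
    hit = _COEF_CACHE.get(key)
    if hit is not None:
        return hit
    A = np.array(
        [
            [-(physics.k_w + physics.k_a), physics.k_w],
            [physics.k_w_wall, -physics.k_w_wall],
        ]
    )
    # exp([[A, I], [0, 0]] t) = [[e^{At}, Phi(t)], [0, I]],  Phi = int_0^t e^{As} ds
    C = np.zeros((4, 4))
    C[:2, :2] = A
    C[:2, 2:] = np.eye(2)
    alpha = np.empty(len(offsets))
    beta = np.empty(len(offsets))
    gamma = np.empty(len(offsets))
    inv_vk = 1.0 / (physics.v_ch_uL * physics.k_o2)
    for k, dt in enumerate(offsets):
        E = expm(C * float(dt))
        M, Phi = E[:2, :2], E[:2, 2:]
        # forcing b = [-OCR * inv_vk + k_a * O_atm, 0]
        alpha[k] = Phi[0, 0] * physics.k_a * physics.o_atm_mmHg
        beta[k] = -Phi[0, 0] * inv_vk
        gamma[k] = M[0, 0] + M[0, 1]
    _COEF_CACHE[key] = (alpha, beta, gamma)
    return alpha, beta, gamma


def chamber_o2(
    physics: ChamberPhysics, offsets: tuple[float, ...], ocr_pmol_min: float, o_start: float
) -> np.ndarray:
    """Exact chamber O2 (mmHg) at the given offsets for a constant true OCR."""
    alpha, beta, gamma = measure_phase_coefficients(physics, offsets)
    return alpha + beta * ocr_pmol_min + gamma * o_start
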