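"""Closed-form forward model of surface-crowding depolymerization kinetics.

Adsorption of enzyme E onto substrate surface sites N is treated as a fast
quasi-equilibrium, giving the adsorbed complex [EN] as the smaller root of a
binding quadratic. Adsorbed enzymes partition between an uncrowded state
(rate constant k_cat_uc) and a crowded state (k_cat_c <= k_cat_uc) according
to the site coverage theta and the crowding equilibrium constant K_c. The
macroscopic degradation rate is

    dP/dt = k_cat_uc * [EN_uc] + k_cat_c * [EN_c] = k_app(theta) * [EN]

with k_app interpolating between k_cat_uc (theta=0) and k_cat_c (theta=1).
All functions here are pure; vectorized kernels (suffix ``_grid``) accept
numpy arrays for use by the fitting layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    InvalidParameterError,
    InvMMParameters,
    ReactionCondition,
    SCParameters,
)

__all__ = [
    "SurfaceState",
    "adsorbed_complex",
    "site_coverage",
    "partition_adsorbed",
    "apparent_kcat",
    "degradation_rate",
    "mukai_limit_rate",
    "inv_mm_rate",
    "adsorbed_complex_grid",
    "rate_grid",
    "inv_mm_rate_grid",
]


class InconsistencyError(ValueError):
    """Derived quantities violate a conservation or bound constraint."""


@dataclass(frozen=True)
class SurfaceState:
    """Equilibrium surface quantities at a single reaction condition.

    N_T: total site concentration Gamma*N_0, nM.
    EN: adsorbed enzyme, nM.  theta: site coverage EN/N_T in [0, 1].
    EN_uc / EN_c: uncrowded / crowded adsorbed enzyme, nM (sum to EN).
    k_app: apparent catalytic constant, mA260 min^-1 nM^-1.
    rate: macroscopic degradation rate dP/dt = k_app*EN, mA260/min.
    """

    N_T: float
    EN: float
    theta: float
    EN_uc: float
    EN_c: float
    k_app: float
    rate: float


def _en_quadratic(K_a: np.ndarray | float, N_T, E_T):
    """Smaller root of EN^2 - (E_T + N_T + 1/K_a) EN + E_T N_T = 0.

    Computed through the product of roots to avoid catastrophic cancellation
    when K_a is small (b dominated by 1/K_a).
    """
    b = E_T + N_T + 1.0 / K_a
    disc = b * b - 4.0 * E_T * N_T
    disc = np.maximum(disc, 0.0)
    en = 2.0 * E_T * N_T / (b + np.sqrt(disc))
    # clamp tiny negative round-off
    return np.where(en > -1e-12 * N_T, np.maximum(en, 0.0), en)


def adsorbed_complex_grid(K_a, Gamma, E_T, N_0):
    """Vectorized adsorbed-enzyme concentration [EN] (nM)."""
    N_T = np.asarray(Gamma, dtype=float) * np.asarray(N_0, dtype=float)
    return _en_quadratic(np.asarray(K_a, dtype=float), N_T, np.asarray(E_T, dtype=float))


def adsorbed_complex(params: SCParameters, cond: ReactionCondition) -> float:
    """Adsorbed enzyme [EN] (nM) at quasi-equilibrium.

    Smaller root of the mass-action binding quadratic
    K_a (E_T - EN)(Gamma N_0 - EN) = EN; satisfies 0 <= EN <= min(E_T, N_T).
    """
    en = float(adsorbed_complex_grid(params.K_a, params.Gamma, cond.E_T, cond.N_0))
    if en < 0.0:
        raise InconsistencyError(f"negative adsorbed complex {en}")
    return en


def site_coverage(EN: float, params: SCParameters, cond: ReactionCondition) -> float:
    """Site coverage theta = EN / (Gamma N_0), clamped to [0, 1]."""
    N_T = params.Gamma * cond.N_0
    if EN < 0.0 or EN > N_T * (1.0 + 1e-9):
        raise InconsistencyError(f"EN={EN} outside [0, N_T={N_T}]")
    return min(max(EN / N_T, 0.0), 1.0)


def partition_adsorbed(EN: float, theta: float, K_c: float) -> tuple[float, float]:
    """Split adsorbed enzyme into (uncrowded, crowded) amounts.

    EN_uc = EN (1-theta) / (K_c theta + 1 - theta);  EN_c = EN - EN_uc.
    The difference form keeps the conservation error EN_uc + EN_c - EN
    within one unit in the last place.
    """
    if not (0.0 <= theta <= 1.0):
        raise InconsistencyError(f"theta={theta} outside [0, 1]")
    if not (K_c > 0.0):
        raise InvalidParameterError(f"K_c must be > 0, got {K_c}")
    if EN < 0.0:
        raise InconsistencyError(f"EN={EN} negative")
    denom = K_c * theta + 1.0 - theta
    if denom == 0.0:
        raise ZeroDivisionError("degenerate partition denominator K_c*theta + 1 - theta = 0")
    en_uc = EN * (1.0 - theta) / denom
    return en_uc, EN - en_uc


def apparent_kcat(theta: float, params: SCParameters) -> float:
    """Apparent catalytic constant k_app(theta), the mean rate per adsorbed enzyme.

    k_app = k_cat_uc (1 - theta + c K_c theta) / (K_c theta + 1 - theta) with
    c = k_cat_c/k_cat_uc; equals k_cat_uc at theta=0 and k_cat_c at theta=1,
    strictly decreasing in theta whenever c < 1.
    """
    if not (0.0 <= theta <= 1.0):
        raise InconsistencyError(f"theta={theta} outside [0, 1]")
    c = params.c
    denom = params.K_c * theta + 1.0 - theta
    return params.k_cat_uc * (1.0 - theta + c * params.K_c * theta) / denom


def degradation_rate(params: SCParameters, cond: ReactionCondition) -> SurfaceState:
    """Full equilibrium state and macroscopic rate dP/dt at one condition."""
    N_T = params.Gamma * cond.N_0
    en = adsorbed_complex(params, cond)
    theta = site_coverage(en, params, cond)
    en_uc, en_c = partition_adsorbed(en, theta, params.K_c)
    k_app = apparent_kcat(theta, params)
    rate = params.k_cat_uc * en_uc + params.k_cat_c * en_c
    return SurfaceState(N_T=N_T, EN=en, theta=theta, EN_uc=en_uc, EN_c=en_c,
                        k_app=k_app, rate=rate)


def rate_grid(params: SCParameters, E_T, N_0) -> np.ndarray:
    """Vectorized macroscopic rate dP/dt (mA260/min) over condition arrays."""
    E_T = np.asarray(E_T, dtype=float)
    N_0 = np.asarray(N_0, dtype=float)
    N_T = params.Gamma * N_0
    en = _en_quadratic(params.K_a, N_T, E_T)
    theta = np.clip(np.divide(en, N_T, out=np.zeros_like(en * 1.0), where=N_T > 0), 0.0, 1.0)
    c = params.c
    denom = params.K_c * theta + 1.0 - theta
    k_app = params.k_cat_uc * (1.0 - theta + c * params.K_c * theta) / denom
    return k_app * en


def mukai_limit_rate(k_cat_uc: float, params_like: SCParameters, cond: ReactionCondition) -> float:
    """Rate in the adjacent-free-site limit of the model (K_c = 1, k_cat_c -> 0).

    With those substitutions the rate law collapses to k_cat_uc*EN*(1-theta):
    catalysis requires a free neighboring site and halts at full coverage,
    the classic behavior of two-domain PHA depolymerases.
    """
    tiny = k_cat_uc * 1e-300  # k_cat_c must stay positive; exact zero is the limit
    p = SCParameters(K_a=params_like.K_a, Gamma=params_like.Gamma, K_c=1.0,
                     k_cat_uc=k_cat_uc, k_cat_c=tiny)
    return degradation_rate(p, cond).rate


def inv_mm_rate(p: InvMMParameters, cond: ReactionCondition) -> float:
    """Inverse Michaelis-Menten rate: saturating in enzyme, linear in area.

    rate = k_inv * Gamma_inv * N_0 * E_T / (K_inv + E_T); plateaus at high
    enzyme load with no inhibition maximum.
    """
    return float(inv_mm_rate_grid(p, cond.E_T, cond.N_0))


def inv_mm_rate_grid(p: InvMMParameters, E_T, N_0) -> np.ndarray:
    E_T = np.asarray(E_T, dtype=float)
    N_0 = np.asarray(N_0, dtype=float)
    return p.k_inv * p.Gamma_inv * N_0 * E_T / (p.K_inv + E_T)
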