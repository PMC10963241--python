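"""Parameter containers and reference parameter sets.

Units are fixed package-wide: enzyme concentrations in nM, substrate surface
concentration N_0 in cm^2/L, site areal density Gamma in nmol/cm^2 (so that
Gamma * N_0 is nmol/L = nM with no conversion factor), and catalytic rate
constants in mA260 min^-1 nM^-1 (bulk product absorbance per minute per nM of
adsorbed enzyme).
"""

from __future__ import annotations

from dataclasses import dataclass


class InvalidParameterError(ValueError):
    """A kinetic or adsorption parameter violates its physical constraints."""


class InvalidConditionError(ValueError):
    """A reaction condition (enzyme load, substrate area) is unphysical."""


@dataclass(frozen=True)
class SCParameters:
    """The five constants of the surface-crowding (SC) rate law.

    Attributes
    ----------
    K_a : float
        Adsorption equilibrium constant k_a/k_d, nM^-1.
    Gamma : float
        Substrate-site areal density, nmol/cm^2 of film surface.
    K_c : float
        Crowding equilibrium constant k_c/k_uc, dimensionless. Governs how
        fast the per-enzyme rate decays from k_cat_uc to k_cat_c with
        increasing site coverage.
    k_cat_uc : float
        Catalytic rate constant of uncrowded adsorbed enzyme,
        mA260 min^-1 nM^-1. The maximum per-enzyme rate (coverage -> 0).
    k_cat_c : float
        Catalytic rate constant of crowded adsorbed enzyme, same units.
        Must not exceed k_cat_uc: crowded configurations are slower.

    The individual transition rate constants (k_a, k_d, k_c, k_uc) are not
    separately identifiable from steady-state data and are deliberately not
    stored; only their ratios K_a and K_c enter the rate law.
    """

    K_a: float
    Gamma: float
    K_c: float
    k_cat_uc: float
    k_cat_c: float

    def __post_init__(self) -> None:
        for name in ("K_a", "Gamma", "K_c", "k_cat_uc", "k_cat_c"):
            v = getattr(self, name)
            if not (v > 0.0):
                raise InvalidParameterError(f"{name} must be strictly positive, got {v!r}")
        if self.k_cat_c > self.k_cat_uc * (1.0 + 1e-12):
            raise InvalidParameterError(
                f"k_cat_c ({self.k_cat_c}) must not exceed k_cat_uc ({self.k_cat_uc}): "
                "crowded configurations have the lower catalytic rate constant"
            )

    @property
    def c(self) -> float:
        """Ratio k_cat_c / k_cat_uc in (0, 1]; derived, never stored."""
        return self.k_cat_c / self.k_cat_uc


@dataclass(frozen=True)
class ReactionCondition:
    """One macroscopic reaction condition.

    E_T: total enzyme concentration, nM (>= 0).
    N_0: substrate surface concentration, cm^2/L (> 0).
    """

    E_T: float
    N_0: float

    def __post_init__(self) -> None:
        if self.E_T < 0.0:
            raise InvalidConditionError(f"E_T must be >= 0, got {self.E_T!r}")
        if not (self.N_0 > 0.0):
            raise InvalidConditionError(f"N_0 must be > 0, got {self.N_0!r}")


@dataclass(frozen=True)
class InvMMParameters:
    """Inverse Michaelis-Menten comparison model (enzyme-saturating, no inhibition).

    rate = k_inv * Gamma_inv * N_0 * E_T / (K_inv + E_T)

    k_inv in mA260 min^-1 nM^-1, Gamma_inv in nmol/cm^2, K_inv in nM.
    """

    k_inv: float
    Gamma_inv: float
    K_inv: float

    def __post_init__(self) -> None:
        for name in ("k_inv", "Gamma_inv", "K_inv"):
            v = getattr(self, name)
            if not (v > 0.0):
                raise InvalidParameterError(f"{name} must be strictly positive, got {v!r}")


#: Reference fitted parameter sets for IsPETase variants degrading amorphous
#: PET film, used as generating truth for synthetic studies. Keyed by
#: temperature label then variant. WT = wild type; TS = thermostable
#: quintuple mutant; TSP = TS + T116P; TSPNP = TSP + S238N + S290P.
REFERENCE_PARAMETER_SETS: dict[str, dict[str, SCParameters]] = {
    "30C": {
        "WT": SCParameters(K_a=0.0290, Gamma=0.0291, K_c=0.890, k_cat_uc=0.445, k_cat_c=0.0588),
        "TS": SCParameters(K_a=0.00196, Gamma=0.141, K_c=20.4, k_cat_uc=1.11, k_cat_c=0.00441),
        "TSP": SCParameters(K_a=0.00579, Gamma=0.0859, K_c=6.71, k_cat_uc=0.932, k_cat_c=0.0386),
        "TSPNP": SCParameters(K_a=0.00847, Gamma=0.0701, K_c=6.89, k_cat_uc=1.01, k_cat_c=0.0555),
    },
    "55C": {
        "TS": SCParameters(K_a=0.00793, Gamma=0.214, K_c=21.2, k_cat_uc=3.77, k_cat_c=0.489),
        "TSP": SCParameters(K_a=0.00832, Gamma=0.228, K_c=22.8, k_cat_uc=4.71, k_cat_c=0.582),
        "TSPNP": SCParameters(K_a=0.00869, Gamma=0.269, K_c=22.5, k_cat_uc=4.23, k_cat_c=0.492),
    },
}

#: Enzyme-concentration grids (nM) used in the kinetic designs at each
#: temperature, and the substrate surface concentrations (cm^2/L) shared by
#: both: films from 2x5 mm to 19x5 mm in 1 ml give 200-1900 cm^2/L.
DEFAULT_ET_GRID = {
    "30C": (10.0, 20.0, 40.0, 60.0, 80.0, 100.0, 150.0, 200.0, 300.0, 400.0, 500.0, 600.0),
    "55C": (20.0, 50.0, 100.0, 200.0, 400.0, 600.0, 800.0, 1000.0, 1250.0, 1500.0),
}
DEFAULT_N0_GRID = (200.0, 500.0, 950.0, 1900.0)
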