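"""Synthetic-data generators with the statistical structure the analysis assumes.

Forward-simulates every input kind the package consumes: initial-rate grids
(enzyme x substrate-area designs with replicate Gaussian noise), adsorption
isotherms, linear early-time product time series, random point patterns, and
monotone standard curves. Every generator is a pure function of
(configuration, seed).

Default study conditions mirror the reference kinetic designs: enzyme grids
of 10-600 nM (ambient, 30 C label) or 20-1500 nM (elevated, 55 C label),
substrate areas 200-1900 cm^2/L, 3 replicates per cell, 5% relative noise
with an absolute floor of 0.5% of the largest model rate on the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import AdsorptionDataset, KineticDataset
from .geometry import DensitySpec, PointPattern, simulate_point_pattern
from .model import adsorbed_complex_grid, rate_grid
from .params import DEFAULT_ET_GRID, DEFAULT_N0_GRID, ReactionCondition, SCParameters
from .processing import CalibrationCurve, TimeSeries

__all__ = [
    "SimulationConfig", "generate_kinetics", "generate_adsorption",
    "generate_timeseries", "generate_point_pattern", "generate_calibration_curves",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Design of a synthetic initial-rate study."""

    params: SCParameters
    E_T_grid: tuple[float, ...] = DEFAULT_ET_GRID["30C"]
    N_0_grid: tuple[float, ...] = DEFAULT_N0_GRID
    n_replicates: int = 3
    cv: float = 0.05            # relative SD of replicate rates
    floor_frac: float = 0.005   # absolute noise floor, fraction of grid-max rate
    seed: int = 0
    variant: str | None = None
    temperature: str | None = None

    def __post_init__(self) -> None:
        if self.cv < 0.0 or self.floor_frac < 0.0:
            raise ValueError("cv and floor_frac must be >= 0")
        if not self.E_T_grid or not self.N_0_grid:
            raise ValueError("grids must be nonempty")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def generate_kinetics(cfg: SimulationConfig) -> KineticDataset:
    """Replicate initial-rate measurements over the full design grid.

    Each replicate is Normal(model rate, max(cv*rate, floor)) truncated at
    zero; the table records the per-cell mean and SD, as a rate experiment
    would report them.
    """
    rng = np.random.default_rng(cfg.seed)
    EE, NN = np.meshgrid(np.asarray(cfg.E_T_grid, float), np.asarray(cfg.N_0_grid, float),
                         indexing="ij")
    mu = rate_grid(cfg.params, EE.ravel(), NN.ravel())
    if cfg.cv > 0:
        floor = cfg.floor_frac * float(mu.max())
        sd = np.maximum(cfg.cv * mu, floor)
        reps = np.maximum(
            mu[:, None] + sd[:, None] * rng.standard_normal((mu.size, cfg.n_replicates)), 0.0)
    else:
        reps = np.repeat(mu[:, None], cfg.n_replicates, axis=1)
    table = pd.DataFrame({
        "enzyme_nM": EE.ravel(),
        "substrate_cm2_per_L": NN.ravel(),
        "rate_mA260_per_min": mu if cfg.cv == 0 else reps.mean(axis=1),
        "sd": reps.std(axis=1, ddof=1) if (cfg.n_replicates > 1 and cfg.cv > 0) else 0.0,
        "n": cfg.n_replicates,
    })
    return KineticDataset(table=table, variant=cfg.variant, temperature=cfg.temperature)


def generate_adsorption(params: SCParameters, E_T_grid, N_0: float,
                        cv: float = 0.05, seed: int = 0,
                        n_replicates: int = 3) -> AdsorptionDataset:
    """Solution-depletion isotherm at one substrate area.

    Observed adsorbed enzyme is the equilibrium binding value with relative
    Gaussian noise, truncated into [0, E_T]; the isotherm plateaus toward the
    site capacity Gamma * N_0.
    """
    E = np.asarray(E_T_grid, dtype=float)
    mu = adsorbed_complex_grid(params.K_a, params.Gamma, E, np.full_like(E, N_0))
    rng = np.random.default_rng(seed)
    if cv > 0:
        reps = np.clip(mu[:, None] * (1.0 + cv * rng.standard_normal((mu.size, n_replicates))),
                       0.0, E[:, None])
        obs, sd = reps.mean(axis=1), reps.std(axis=1, ddof=1)
    else:
        obs, sd = mu, np.zeros_like(mu)
    table = pd.DataFrame({"enzyme_nM": E, "adsorbed_nM": obs, "sd": sd})
    return AdsorptionDataset(table=table, N_0=N_0)


def generate_timeseries(params: SCParameters, cond: ReactionCondition, times,
                        cv: float = 0.05, seed: int = 0,
                        intercept: float = 2.0) -> TimeSeries:
    """Linear early-time product accumulation at the model's steady rate.

    signal = rate * t + intercept + noise, truncated at zero. The intercept
    emulates a small background absorbance at t = 0.
    """
    t = np.asarray(times, dtype=float)
    rate = rate_grid(params, np.array([cond.E_T]), np.array([cond.N_0]))[0]
    mu = rate * t + intercept
    rng = np.random.default_rng(seed)
    noise = cv * np.maximum(mu, 1e-12) * rng.standard_normal(t.shape) if cv > 0 else 0.0
    return TimeSeries(time=t, signal=np.maximum(mu + noise, 0.0),
                      E_T=cond.E_T, N_0=cond.N_0)


def generate_point_pattern(lam: float, window, boundary: str = "toroidal",
                           seed: int = 0) -> PointPattern:
    """Poisson pattern at areal density ``lam`` (nm^-2); thin wrapper."""
    return simulate_point_pattern(DensitySpec(lam=lam, provenance="simulated"),
                                  window, boundary=boundary, seed=seed)


def generate_calibration_curves(f_per_nM: float = 25.0, loss_scale: float = 4000.0,
                                mhet_half_uM: float = 150.0
                                ) -> tuple[CalibrationCurve, CalibrationCurve]:
    """(protein fluorescence curve, MHET fluorescence-loss curve).

    The protein curve is linear over the 10-1000 nM detection range
    (``f_per_nM`` fluorescence units per nM). The MHET loss curve is a
    monotone saturating set of knots (loss_scale * m/(m + half)), emulating
    product quench of intrinsic fluorescence. Both are deterministic.
    """
    conc = np.array([10.0, 50.0, 100.0, 250.0, 500.0, 750.0, 1000.0])
    protein = CalibrationCurve(x=conc, y=f_per_nM * conc, name="protein-fluorescence")
    mhet = np.array([0.0, 25.0, 50.0, 100.0, 200.0, 400.0, 800.0])
    loss = loss_scale * mhet / (mhet + mhet_half_uM)
    mhet_curve = CalibrationCurve(x=mhet, y=loss, name="mhet-fluorescence-loss")
    return protein, mhet_curve
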