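"""Raw-measurement processing: initial rates, depletion amounts, corrections.

Turns product-accumulation time series into initial-rate slopes, solution
depletion concentration differences into adsorbed amounts, and raw protein
fluorescence readings into MHET-corrected enzyme concentrations via
piecewise-linear standard curves (interpolation only, never extrapolation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TimeSeries", "CalibrationCurve", "initial_rate", "adsorbed_amount",
           "mhet_corrected_concentration"]


class ExtrapolationError(ValueError):
    """A query falls outside a standard curve's calibrated range."""


@dataclass
class TimeSeries:
    """Product signal over time: (time in min, signal in mA260)."""

    time: np.ndarray
    signal: np.ndarray
    E_T: float | None = None
    N_0: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @classmethod
    def from_csv(cls, path, **meta) -> "TimeSeries":
        df = pd.read_csv(path)
        return cls(time=df["time_min"].to_numpy(), signal=df["a260_mAU"].to_numpy(), **meta)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_min": self.time, "a260_mAU": self.signal}).to_csv(path, index=False)


def initial_rate(ts: TimeSeries, window: tuple[float, float]) -> tuple[float, float]:
    """OLS slope (mA260/min) and its standard error over a time window.

    The window is inclusive, e.g. (30, 210) min for ambient-temperature runs
    or (15, 105) min at elevated temperature, chosen to stay in the linear
    early-accumulation regime.
    """
    t0, t1 = window
    mask = (ts.time >= t0) & (ts.time <= t1)
    if mask.sum() < 3:
        raise ValueError(f"need >= 3 points inside window {window}, found {int(mask.sum())}")
    res = stats.linregress(ts.time[mask], ts.signal[mask])
    return float(res.slope), float(res.stderr)


def adsorbed_amount(conc_no_pet_nM: float, conc_with_pet_nM: float, volume_L: float) -> float:
    """Adsorbed enzyme (pmol) from solution depletion.

    (c_without - c_with) * volume; a negative difference (replicate noise)
    is floored at zero with a warning rather than raised.
    """
    if volume_L <= 0.0:
        raise ValueError("volume must be positive")
    pmol = (conc_no_pet_nM - conc_with_pet_nM) * volume_L * 1e3  # nmol/L * L -> nmol -> pmol
    if pmol < 0.0:
        warnings.warn(f"negative depletion ({pmol:.3g} pmol) floored to 0", UserWarning)
        return 0.0
    return pmol


@dataclass
class CalibrationCurve:
    """Ordered standard points with piecewise-linear interpolation.

    Querying outside [x_min, x_max] (or, for the inverse, outside the y
    range) raises ExtrapolationError; standard curves are never extrapolated.
    """

    x: np.ndarray
    y: np.ndarray
    name: str = "calibration"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.size < 2:
            raise ValueError("need >= 2 (x, y) standard points of equal length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("standard x values must be strictly increasing")

    @classmethod
    def from_csv(cls, path, name: str = "calibration") -> "CalibrationCurve":
        df = pd.read_csv(path)
        return cls(x=df["x"].to_numpy(), y=df["y"].to_numpy(), name=name)

    def interp(self, xq: float) -> float:
        if xq < self.x[0] or xq > self.x[-1]:
            raise ExtrapolationError(
                f"query {xq:g} outside calibrated range [{self.x[0]:g}, {self.x[-1]:g}] "
                f"of curve {self.name!r}")
        return float(np.interp(xq, self.x, self.y))

    def inverse(self, yq: float) -> float:
        """Inverse interpolation; requires strictly monotone y."""
        dy = np.diff(self.y)
        if np.all(dy > 0):
            xs, ys = self.x, self.y
        elif np.all(dy < 0):
            xs, ys = self.x[::-1], self.y[::-1]
        else:
            raise ValueError(f"curve {self.name!r} is not monotone; inverse is ambiguous")
        if yq < ys[0] or yq > ys[-1]:
            raise ExtrapolationError(
                f"query {yq:g} outside calibrated response range [{ys[0]:g}, {ys[-1]:g}] "
                f"of curve {self.name!r}")
        return float(np.interp(yq, ys, xs))


def mhet_corrected_concentration(F_raw: float, A260: float,
                                 mhet_curve: CalibrationCurve,
                                 a260_to_mhet: float,
                                 protein_curve: CalibrationCurve) -> float:
    """Enzyme concentration (nM) from intrinsic fluorescence with MHET correction.

    The soluble product MHET quenches intrinsic protein fluorescence, so the
    expected loss at the sample's MHET level (inferred from A260 via the
    ``a260_to_mhet`` slope) is added back onto the raw signal before inverse
    interpolation of the protein standard curve:

        MHET = a260_to_mhet * A260
        F_corrected = F_raw + loss(MHET)
        concentration = protein_curve^-1(F_corrected)
    """
    mhet = a260_to_mhet * A260
    loss = mhet_curve.interp(mhet)
    return protein_curve.inverse(F_raw + loss)
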