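"""Measurement-table containers and their CSV dialects.

KineticDataset rows: (enzyme_nM, substrate_cm2_per_L, rate_mA260_per_min, sd, n)
AdsorptionDataset rows: (enzyme_nM, adsorbed_nM, sd)

Both wrap a pandas DataFrame and validate on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KINETIC_COLUMNS = ["enzyme_nM", "substrate_cm2_per_L", "rate_mA260_per_min", "sd", "n"]
ADSORPTION_COLUMNS = ["enzyme_nM", "adsorbed_nM", "sd"]


@dataclass
class KineticDataset:
    """Initial-rate measurements over an enzyme x substrate-area grid."""

    table: pd.DataFrame
    variant: str | None = None
    temperature: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in KINETIC_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"kinetic table missing columns {missing}")
        t = self.table
        if (t["sd"] < 0).any():
            raise ValueError("rate SD must be >= 0")
        if (t["enzyme_nM"] <= 0).any() or (t["substrate_cm2_per_L"] <= 0).any():
            raise ValueError("enzyme_nM and substrate_cm2_per_L must be > 0")
        if t["enzyme_nM"].nunique() < 2:
            raise ValueError("need at least 2 distinct enzyme concentrations")

    def __len__(self) -> int:
        return len(self.table)

    def to_Xy(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(X, y, y_sd) with X columns (E_T, N_0) for the regressors."""
        X = self.table[["enzyme_nM", "substrate_cm2_per_L"]].to_numpy(float)
        y = self.table["rate_mA260_per_min"].to_numpy(float)
        sd = self.table["sd"].to_numpy(float)
        return X, y, sd

    @classmethod
    def from_csv(cls, path, **meta) -> "KineticDataset":
        return cls(pd.read_csv(path), **meta)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class AdsorptionDataset:
    """Solution-depletion adsorption isotherm at a fixed substrate area."""

    table: pd.DataFrame
    N_0: float = field(default=np.nan)  # cm^2/L at which the isotherm was measured

    def __post_init__(self) -> None:
        missing = [c for c in ADSORPTION_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"adsorption table missing columns {missing}")
        t = self.table
        if (t["sd"] < 0).any():
            raise ValueError("SD must be >= 0")
        if (t["adsorbed_nM"] < -1e-12).any():
            raise ValueError("adsorbed amounts must be >= 0")
        if (t["adsorbed_nM"] > t["enzyme_nM"] * (1 + 1e-9)).any():
            raise ValueError("adsorbed enzyme cannot exceed total enzyme")

    def __len__(self) -> int:
        return len(self.table)

    def to_Xy(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        E = self.table["enzyme_nM"].to_numpy(float)
        X = np.column_stack([E, np.full_like(E, self.N_0)])
        return X, self.table["adsorbed_nM"].to_numpy(float), self.table["sd"].to_numpy(float)

    @classmethod
    def from_csv(cls, path, N_0: float) -> "AdsorptionDataset":
        return cls(pd.read_csv(path), N_0=N_0)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)
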