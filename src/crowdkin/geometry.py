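"""Surface geometry: densities, separation distances, and point patterns.

Converts adsorbed amounts into areal densities (both film faces count, edges
neglected), relates densities to separation distances (square-grid spacing
1/sqrt(lambda) for even placement; mean nearest-neighbor distance
1/(2 sqrt(lambda)) for a homogeneous planar Poisson process), simulates
random point patterns, and summarizes single-molecule localization
coordinate tables quadrant-by-quadrant with blank subtraction.

Internal length unit: nm. Areas entering density conversions are cm^2
(1 cm^2 = 1e14 nm^2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

N_AVOGADRO = 6.02214076e23
CM2_TO_NM2 = 1e14

__all__ = [
    "DiscFilm", "RectFilm", "DensitySpec", "RectWindow", "CircleWindow",
    "PointPattern", "areal_density", "substrate_concentration", "grid_spacing",
    "poisson_nn_mean", "simulate_point_pattern", "nearest_neighbor_distances",
    "mean_min_distance", "scale_density_linear", "molar_to_spacing_3d",
    "spacing_to_molar_3d", "tirf_quadrant_analysis", "load_coordinates",
]


@dataclass(frozen=True)
class DiscFilm:
    """Circular film; ``diameter_cm`` across. Area counts both faces."""

    diameter_cm: float

    @property
    def area_cm2(self) -> float:
        r = self.diameter_cm / 2.0
        return 2.0 * math.pi * r * r


@dataclass(frozen=True)
class RectFilm:
    """Rectangular film, dimensions in cm. Area counts both faces."""

    width_cm: float
    height_cm: float

    @property
    def area_cm2(self) -> float:
        return 2.0 * self.width_cm * self.height_cm


@dataclass(frozen=True)
class DensitySpec:
    """Areal number density lambda in nm^-2, with provenance metadata."""

    lam: float
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if self.lam < 0.0:
            raise ValueError(f"density must be >= 0, got {self.lam}")


@dataclass(frozen=True)
class RectWindow:
    width: float   # nm
    height: float  # nm

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, xy: np.ndarray) -> np.ndarray:
        return ((xy[:, 0] >= 0) & (xy[:, 0] <= self.width)
                & (xy[:, 1] >= 0) & (xy[:, 1] <= self.height))


@dataclass(frozen=True)
class CircleWindow:
    radius: float  # nm
    center: tuple[float, float] = (0.0, 0.0)

    @property
    def area(self) -> float:
        return math.pi * self.radius ** 2

    def contains(self, xy: np.ndarray) -> np.ndarray:
        d2 = (xy[:, 0] - self.center[0]) ** 2 + (xy[:, 1] - self.center[1]) ** 2
        return d2 <= self.radius ** 2 * (1 + 1e-12)


@dataclass
class PointPattern:
    """Planar coordinates (nm) in a bounded window.

    boundary: 'bounded' (plain Euclidean nearest neighbors, no edge
    correction) or 'toroidal' (periodic distances; rectangular windows only).
    """

    xy: np.ndarray
    window: RectWindow | CircleWindow
    boundary: str = "bounded"
    seed: int | None = None
    density: DensitySpec | None = None

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if self.boundary not in ("bounded", "toroidal"):
            raise ValueError(f"boundary must be 'bounded' or 'toroidal', got {self.boundary!r}")
        if self.boundary == "toroidal" and not isinstance(self.window, RectWindow):
            raise ValueError("toroidal boundary requires a rectangular window")
        if len(self.xy) and not self.window.contains(self.xy).all():
            raise ValueError("all points must lie inside the window")

    def __len__(self) -> int:
        return len(self.xy)


def areal_density(amount_pmol: float, film) -> DensitySpec:
    """Molecules per nm^2 from an adsorbed amount spread over a film.

    lambda = amount * N_A / area, the film area counting both faces.
    """
    if amount_pmol < 0.0:
        raise ValueError("amount must be >= 0")
    area = film.area_cm2
    if area <= 0.0:
        raise ValueError("film area must be positive")
    lam = amount_pmol * 1e-12 * N_AVOGADRO / (area * CM2_TO_NM2)
    return DensitySpec(lam=lam, provenance="from amount+area")


def substrate_concentration(film, volume_L: float) -> float:
    """Substrate surface concentration N_0 (cm^2/L) of one film in a volume."""
    if volume_L <= 0.0:
        raise ValueError("volume must be positive")
    return film.area_cm2 / volume_L


def grid_spacing(d: DensitySpec) -> float:
    """Center-to-center spacing (nm) of evenly placed particles: 1/sqrt(lambda)."""
    if d.lam <= 0.0:
        raise ValueError("density must be positive")
    return 1.0 / math.sqrt(d.lam)


def poisson_nn_mean(d: DensitySpec) -> float:
    """Closed-form mean nearest-neighbor distance of a planar Poisson process.

    E[min distance] = 1/(2 sqrt(lambda)); the analytic benchmark for the
    random-placement Monte Carlo.
    """
    if d.lam <= 0.0:
        raise ValueError("density must be positive")
    return 0.5 / math.sqrt(d.lam)


def simulate_point_pattern(d: DensitySpec, window, boundary: str = "toroidal",
                           seed: int = 0) -> PointPattern:
    """Homogeneous Poisson pattern at density ``d`` in ``window``.

    Count ~ Poisson(lambda * area), positions uniform. Deterministic per seed.
    """
    expected = d.lam * window.area
    if expected < 2.0:
        raise ValueError(f"expected point count {expected:.3g} < 2; enlarge the window")
    rng = np.random.default_rng(seed)
    n = rng.poisson(expected)
    if isinstance(window, RectWindow):
        xy = rng.random((n, 2)) * np.array([window.width, window.height])
    else:
        r = window.radius * np.sqrt(rng.random(n))
        phi = rng.random(n) * 2.0 * math.pi
        xy = np.column_stack([r * np.cos(phi), r * np.sin(phi)]) + np.asarray(window.center)
    return PointPattern(xy=xy, window=window, boundary=boundary, seed=seed, density=d)


def nearest_neighbor_distances(p: PointPattern, method: str = "kdtree") -> np.ndarray:
    """Distance from each point to its nearest other point.

    method='kdtree' uses a spatial index (periodic for toroidal patterns);
    method='brute' is the O(n^2) double-loop reference — both give identical
    results and the tests check that.
    """
    n = len(p)
    if n < 2:
        raise ValueError("need at least 2 points for nearest-neighbor distances")
    xy = p.xy
    if method == "brute":
        out = np.empty(n)
        for i in range(n):
            diff = xy - xy[i]
            if p.boundary == "toroidal":
                box = np.array([p.window.width, p.window.height])
                diff = diff - box * np.round(diff / box)
            dist = np.hypot(diff[:, 0], diff[:, 1])
            dist[i] = np.inf
            out[i] = dist.min()
        return out
    if method != "kdtree":
        raise ValueError(f"unknown method {method!r}")
    if p.boundary == "toroidal":
        box = [p.window.width, p.window.height]
        xy = np.mod(xy, box)  # cKDTree requires coords strictly inside the box
        tree = cKDTree(xy, boxsize=box)
    else:
        tree = cKDTree(xy)
    dist, _ = tree.query(xy, k=2)
    return dist[:, 1]


def mean_min_distance(p: PointPattern, method: str = "kdtree") -> float:
    """Mean over points of the distance to the nearest other point (nm)."""
    return float(nearest_neighbor_distances(p, method=method).mean())


def scale_density_linear(reference: tuple[float, float], target_concentration: float) -> DensitySpec:
    """Scale a measured surface density linearly in solution concentration.

    ``reference`` is (concentration, mean nearest-neighbor distance in nm);
    the reference density is inverted from the Poisson mean-NN formula,
    lambda_ref = (1/(2 d_ref))^2, then scaled by target/reference. Both
    concentrations must share units (e.g. nM).
    """
    c_ref, d_ref = reference
    if c_ref <= 0.0 or target_concentration <= 0.0:
        raise ValueError("concentrations must be positive")
    if d_ref <= 0.0:
        raise ValueError("reference mean distance must be positive")
    lam_ref = (0.5 / d_ref) ** 2
    return DensitySpec(lam=lam_ref * target_concentration / c_ref,
                       provenance="from concentration scaling")


def molar_to_spacing_3d(c_molar: float) -> float:
    """Cubic-lattice center-to-center spacing (nm) at a molar concentration.

    spacing = (N_A * c)^(-1/3) with c in molecules per liter converted to
    molecules per nm^3; e.g. 2 mM corresponds to ~9.4 nm (94 Angstrom).
    """
    if c_molar <= 0.0:
        raise ValueError("concentration must be positive")
    per_nm3 = c_molar * N_AVOGADRO / 1e24  # mol/L -> molecules/nm^3
    return per_nm3 ** (-1.0 / 3.0)


def spacing_to_molar_3d(spacing_nm: float) -> float:
    """Inverse of :func:`molar_to_spacing_3d`."""
    if spacing_nm <= 0.0:
        raise ValueError("spacing must be positive")
    return 1e24 / (spacing_nm ** 3 * N_AVOGADRO)


def _quadrant_index(xy: np.ndarray, center: tuple[float, float]) -> np.ndarray:
    """Quadrant 0..3 (+x+y, -x+y, -x-y, +x-y); axis points go to the
    lower-index quadrant via the >= tie-break."""
    dx = xy[:, 0] - center[0]
    dy = xy[:, 1] - center[1]
    right = dx >= 0
    top = dy >= 0
    q = np.where(right & top, 0, np.where(~right & top, 1, np.where(~right & ~top, 2, 3)))
    return q


@dataclass
class TirfSummary:
    """Quadrant-level summary of localization fields after blank subtraction."""

    per_quadrant: pd.DataFrame  # columns: fov, quadrant, count, mean_min_distance_nm
    count_mean: float = field(init=False)
    count_sd: float = field(init=False)
    mmd_mean: float = field(init=False)
    mmd_sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.count_mean = float(self.per_quadrant["count"].mean())
        self.count_sd = float(self.per_quadrant["count"].std(ddof=1))
        mmd = self.per_quadrant["mean_min_distance_nm"].dropna()
        self.mmd_mean = float(mmd.mean()) if len(mmd) else float("nan")
        self.mmd_sd = float(mmd.std(ddof=1)) if len(mmd) > 1 else float("nan")


def tirf_quadrant_analysis(patterns: list[PointPattern], blank_counts, seed: int = 0) -> TirfSummary:
    """Blank-subtracted quadrant analysis of localization coordinate tables.

    For each field of view, removes ``blank_counts[i]`` coordinates uniformly
    at random (the count detected in the matched buffer blank), partitions the
    field into four quadrants through its center, and computes per-quadrant
    molecule counts and mean minimum separation distances (no edge
    correction). Summary statistics pool all quadrants of all fields.
    """
    if np.isscalar(blank_counts):
        blank_counts = [int(blank_counts)] * len(patterns)
    if len(blank_counts) != len(patterns):
        raise ValueError("blank_counts length must match number of fields of view")
    rng = np.random.default_rng(seed)
    rows = []
    for i, (p, nb) in enumerate(zip(patterns, blank_counts)):
        xy = p.xy
        nb = int(nb)
        if nb > len(xy):
            warnings.warn(f"field {i}: blank count {nb} exceeds detections {len(xy)}; "
                          "removing all", UserWarning)
            nb = len(xy)
        if nb > 0:
            keep = rng.permutation(len(xy))[nb:]
            xy = xy[np.sort(keep)]
        center = p.window.center if isinstance(p.window, CircleWindow) else (
            p.window.width / 2.0, p.window.height / 2.0)
        q = _quadrant_index(xy, center)
        for qi in range(4):
            sub = xy[q == qi]
            if len(sub) >= 2:
                sub_pat = PointPattern(xy=sub, window=p.window, boundary="bounded")
                mmd = mean_min_distance(sub_pat)
            else:
                mmd = float("nan")
            rows.append({"fov": i, "quadrant": qi, "count": len(sub),
                         "mean_min_distance_nm": mmd})
    return TirfSummary(per_quadrant=pd.DataFrame(rows))


def load_coordinates(path, default_units: str = "nm") -> list[PointPattern]:
    """Read a localization CSV with columns (fov_id, x, y[, units]) into
    per-field point patterns (coordinates converted to nm; windows are the
    bounding circles of each field, centered on the coordinate mean)."""
    df = pd.read_csv(path)
    for col in ("fov_id", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"coordinate table missing column {col!r}")
    scale = {"nm": 1.0, "um": 1e3, "µm": 1e3}
    patterns = []
    for _, g in df.groupby("fov_id", sort=True):
        units = g["units"].iloc[0] if "units" in g.columns else default_units
        if units not in scale:
            raise ValueError(f"unknown units {units!r}; expected nm or um")
        xy = g[["x", "y"]].to_numpy(float) * scale[units]
        center = xy.mean(axis=0)
        radius = float(np.max(np.hypot(*(xy - center).T))) * (1 + 1e-9) or 1.0
        patterns.append(PointPattern(xy=xy, window=CircleWindow(radius=radius,
                                                                center=tuple(center)),
                                     boundary="bounded"))
    return patterns
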