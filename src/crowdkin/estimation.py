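"""Objective functions, multi-start optimization, and model-selection utilities.

All fitting happens in the natural-log space of the parameters, which keeps
them positive and puts multiplicative uncertainty on an additive scale. The
two-step workflow is: (1) maximum-likelihood fit of the adsorption isotherm
for (K_a, Gamma); (2) maximum-a-posteriori fit of all five rate-law
parameters, with a quadratic log-space prior on (K_a, Gamma) taken from step
1 — parameters fit for the first time carry no prior cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "Prior",
    "FitResult",
    "weighted_ssr",
    "map_objective",
    "multistart_optimize",
    "bic",
    "gauss_newton_cov",
]


class ZeroVarianceError(ValueError):
    """A measurement-variance entry is zero; configure a variance floor."""


def weighted_ssr(observations, predictions, V_eps) -> float:
    """Weighted sum of squared residuals r^T V_eps^-1 r with diagonal V_eps.

    With V_eps = 1 this is the ordinary SSR.
    """
    obs = np.asarray(observations, dtype=float)
    pred = np.asarray(predictions, dtype=float)
    v = np.broadcast_to(np.asarray(V_eps, dtype=float), obs.shape)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if np.any(v <= 0.0):
        raise ZeroVarianceError(
            "measurement variance entries must be positive; apply a variance "
            "floor (e.g. (1% of the maximum observed value)^2) before fitting"
        )
    r = obs - pred
    return float(np.sum(r * r / v))


@dataclass(frozen=True)
class Prior:
    """Quadratic penalty on a subset of log parameters.

    mu: prior means of the ACTIVE log parameters (length m).
    V_mu: m x m covariance of those log parameters (symmetric PD).
    active_idx: indices of the active components within the full log-parameter
        vector; inactive components carry no prior cost.
    """

    mu: np.ndarray
    V_mu: np.ndarray
    active_idx: tuple[int, ...]

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        V = np.atleast_2d(np.asarray(self.V_mu, dtype=float))
        if len(self.active_idx) != mu.size or V.shape != (mu.size, mu.size):
            raise ValueError("prior dimension mismatch between mu, V_mu and active_idx")
        if mu.size:
            if not np.allclose(V, V.T):
                raise ValueError("V_mu must be symmetric")
            if np.any(np.linalg.eigvalsh(V) <= 0.0):
                raise ValueError("V_mu must be positive definite on active components")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "V_mu", V)
        object.__setattr__(self, "_V_inv", np.linalg.inv(V) if mu.size else V)

    @classmethod
    def empty(cls) -> "Prior":
        """A prior that penalizes nothing (MAP reduces to MLE)."""
        return cls(mu=np.empty(0), V_mu=np.empty((0, 0)), active_idx=())

    def cost(self, log_params: np.ndarray) -> float:
        """(z - mu)^T V_mu^-1 (z - mu) over the active components of log_params."""
        if not self.mu.size:
            return 0.0
        d = np.asarray(log_params, dtype=float)[list(self.active_idx)] - self.mu
        return float(d @ self._V_inv @ d)


def map_objective(log_params, dataset_y, dataset_V, model_fn: Callable, prior: Prior) -> float:
    """MAP cost: weighted SSR of model_fn(log_params) plus the prior penalty."""
    pred = model_fn(log_params)
    return weighted_ssr(dataset_y, pred, dataset_V) + prior.cost(np.asarray(log_params))


@dataclass
class MultistartRecord:
    """Per-start diagnostics from multistart_optimize."""

    x0: np.ndarray
    objectives: np.ndarray
    success: np.ndarray

    @property
    def converged_fraction(self) -> float:
        """Fraction of starts finishing within 1% (or 1e-8 abs) of the best."""
        finite = self.objectives[np.isfinite(self.objectives)]
        if finite.size == 0:
            return 0.0
        best = finite.min()
        tol = max(abs(best) * 0.01, 1e-8)
        return float(np.mean(self.objectives <= best + tol))


def multistart_optimize(
    objective: Callable[[np.ndarray], float],
    bounds_log: Sequence[tuple[float, float]],
    n_starts: int = 64,
    seed: int = 0,
    extra_x0: Sequence[np.ndarray] = (),
) -> tuple[np.ndarray, float, MultistartRecord]:
    """Minimize ``objective`` from log-uniform random starts within box bounds.

    Deterministic given (seed, n_starts, bounds). Returns the best point, its
    objective value, and per-start diagnostics. Raises RuntimeError with the
    first exemplar failure if every start fails.
    """
    bounds = [(float(lo), float(hi)) for lo, hi in bounds_log]
    if not all(np.isfinite(lo) and np.isfinite(hi) and lo < hi for lo, hi in bounds):
        raise ValueError("bounds_log must be finite with lo < hi")
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = list(np.asarray(x, dtype=float) for x in extra_x0)
    starts += list(lo + (hi - lo) * rng.random((n_starts, len(bounds))))

    objs = np.full(len(starts), np.inf)
    succ = np.zeros(len(starts), dtype=bool)
    best_x, best_f = None, np.inf
    first_error: Exception | None = None
    for i, x0 in enumerate(starts):
        try:
            res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                           options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 1000})
        except Exception as exc:  # pragma: no cover - defensive
            first_error = first_error or exc
            continue
        objs[i] = res.fun
        succ[i] = res.success
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
    if best_x is None:
        raise RuntimeError(f"all {len(starts)} optimization starts failed: {first_error!r}")
    # derivative-free polish: finite-difference gradient noise can stall
    # L-BFGS-B short of the bottom of a narrow valley
    polish = minimize(objective, best_x, method="Nelder-Mead", bounds=bounds,
                      options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
    if polish.fun < best_f:
        best_x, best_f = polish.x, float(polish.fun)
    record = MultistartRecord(x0=np.array(starts), objectives=objs, success=succ)
    return best_x, best_f, record


#: Multi-start count matching the original analysis workflow.
N_STARTS_PAPER_PROFILE = 2000


def bic(ssr: float, n_obs: int, k_params: int) -> float:
    """Bayesian information criterion, Gaussian-likelihood convention.

    BIC = n ln(ssr/n) + k ln(n). Lower is better; the k ln(n) term penalizes
    the extra parameters of the richer model.
    """
    if ssr <= 0.0:
        raise ValueError(f"ssr must be > 0 for the Gaussian BIC, got {ssr}")
    if n_obs <= k_params:
        raise ValueError(f"need n_obs ({n_obs}) > k_params ({k_params})")
    return float(n_obs * np.log(ssr / n_obs) + k_params * np.log(n_obs))


def gauss_newton_cov(model_fn: Callable, z_opt: np.ndarray, V_eps, rel_step: float = 1e-6) -> np.ndarray:
    """Log-space covariance (J^T V^-1 J)^-1 at the optimum.

    J is the Jacobian of the model predictions with respect to the log
    parameters, by central differences with absolute step ``rel_step`` (the
    log scale makes an absolute step a relative parameter perturbation).
    Singular information matrices fall back to the pseudo-inverse, which
    shows up as very wide intervals for weakly identified parameters.
    """
    z_opt = np.asarray(z_opt, dtype=float)
    f0 = np.asarray(model_fn(z_opt), dtype=float)
    J = np.empty((f0.size, z_opt.size))
    for j in range(z_opt.size):
        h = max(rel_step, rel_step * abs(z_opt[j]))
        zp, zm = z_opt.copy(), z_opt.copy()
        zp[j] += h
        zm[j] -= h
        J[:, j] = (np.asarray(model_fn(zp)) - np.asarray(model_fn(zm))) / (2.0 * h)
    v = np.broadcast_to(np.asarray(V_eps, dtype=float), f0.shape)
    info = J.T @ (J / v[:, None])
    try:
        return np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(info)


@dataclass
class FitResult:
    """Outcome of a multi-start fit.

    params: fitted parameter object (SCParameters, InvMMParameters, or a dict
        for the adsorption step). objective: minimized cost (weighted SSR plus
        any prior penalty). cov_log: covariance of the fitted log parameters.
    ssr: unweighted residual sum of squares (the quantity entering BIC).
    ci95: optional per-parameter (lo, hi) intervals on the natural scale.
    """

    params: object
    param_names: tuple[str, ...]
    log_params: np.ndarray
    objective: float
    cov_log: np.ndarray
    n_starts: int
    start_objectives: np.ndarray
    converged_fraction: float
    ssr: float
    n_obs: int
    bic: float | None = None
    ci95: dict | None = None
    flags: dict = field(default_factory=dict)

    def relative_se(self) -> dict[str, float]:
        """Approximate relative standard errors (SE of log params)."""
        se = np.sqrt(np.clip(np.diag(self.cov_log), 0.0, np.inf))
        return dict(zip(self.param_names, se))

    def summary(self) -> dict:
        out = {
            "parameters": {n: float(np.exp(z)) for n, z in zip(self.param_names, self.log_params)},
            "objective": self.objective,
            "ssr": self.ssr,
            "n_obs": self.n_obs,
            "n_starts": self.n_starts,
            "converged_fraction": self.converged_fraction,
            "bic": self.bic,
            "start_objectives": [float(v) for v in np.asarray(self.start_objectives)],
            "flags": {k: v for k, v in self.flags.items()
                      if isinstance(v, (bool, int, float, str))},
        }
        if self.ci95 is not None:
            out["ci95"] = {k: [float(a), float(b)] for k, (a, b) in self.ci95.items()}
        return out
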