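"""Scikit-learn-style estimators for the surface-crowding rate law.

``AdsorptionIsotherm`` fits (K_a, Gamma) to solution-depletion adsorption
data (step 1); its ``prior_`` attribute seeds ``SurfaceCrowdingRegressor``,
which fits all five rate-law parameters to initial-rate data by MAP (step 2).
``InverseMMRegressor`` is the three-parameter no-inhibition comparison model
for BIC-based model selection. All three follow the fit/predict contract,
X having columns (E_T in nM, N_0 in cm^2/L).
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.utils.validation import check_array, check_is_fitted

from .datasets import AdsorptionDataset, KineticDataset
from .estimation import (
    FitResult,
    Prior,
    bic,
    gauss_newton_cov,
    multistart_optimize,
    weighted_ssr,
)
from .model import adsorbed_complex_grid, inv_mm_rate_grid, rate_grid
from .params import InvMMParameters, SCParameters

__all__ = [
    "AdsorptionIsotherm",
    "SurfaceCrowdingRegressor",
    "InverseMMRegressor",
    "bootstrap_ci",
    "fit_adsorption",
    "fit_kinetics",
    "compare_models",
]

# Log-uniform start-sampling bounds; they bracket all reference parameter
# sets by at least an order of magnitude.
BOUNDS_KA = (1e-5, 1.0)       # nM^-1
BOUNDS_GAMMA = (1e-4, 10.0)   # nmol/cm^2
BOUNDS_KC = (1e-3, 1e3)
BOUNDS_KCAT_UC = (1e-3, 1e2)  # mA260 min^-1 nM^-1
BOUNDS_C = (1e-8, 1.0)        # k_cat_c / k_cat_uc


def _check_X(X) -> tuple[np.ndarray, np.ndarray]:
    X = check_array(X, ensure_min_features=2)
    return X[:, 0], X[:, 1]


def _variances(y: np.ndarray, y_sd, floor_frac: float) -> np.ndarray:
    sd = np.zeros_like(y) if y_sd is None else np.broadcast_to(np.asarray(y_sd, float), y.shape)
    floor = floor_frac * float(np.max(np.abs(y)))
    if floor <= 0.0:
        floor = 1.0  # all-zero data: unit weights
    return np.maximum(sd, floor) ** 2


def _log_bounds(pairs) -> list[tuple[float, float]]:
    return [(np.log(lo), np.log(hi)) for lo, hi in pairs]


class AdsorptionIsotherm(RegressorMixin, BaseEstimator):
    """Langmuir-type binding-quadratic isotherm fit for (K_a, Gamma).

    Maximum-likelihood in log-parameter space with multi-start L-BFGS-B.
    Fitted attributes: ``K_a_``, ``Gamma_``, ``cov_log_`` (Gauss-Newton
    covariance of the log parameters), ``prior_`` (ready to seed the kinetic
    MAP fit), ``gamma_upper_`` (adsorption-capacity bound for step 2:
    Gamma-hat * (1 + 2 * its relative SE)), and ``result_``.
    """

    _param_names = ("K_a", "Gamma")

    def __init__(self, n_starts: int = 16, random_state: int = 0,
                 variance_floor_frac: float = 0.01, bounds=None):
        self.n_starts = n_starts
        self.random_state = random_state
        self.variance_floor_frac = variance_floor_frac
        self.bounds = bounds

    def fit(self, X, y, y_sd=None):
        E_T, N_0 = _check_X(X)
        y = np.asarray(y, dtype=float)
        V = _variances(y, y_sd, self.variance_floor_frac)
        bounds = _log_bounds(self.bounds or (BOUNDS_KA, BOUNDS_GAMMA))

        def model_fn(z):
            return adsorbed_complex_grid(np.exp(z[0]), np.exp(z[1]), E_T, N_0)

        def objective(z):
            return weighted_ssr(y, model_fn(z), V)

        z_opt, f_opt, rec = multistart_optimize(objective, bounds, self.n_starts,
                                                seed=self.random_state)
        self.K_a_, self.Gamma_ = np.exp(z_opt)
        self.cov_log_ = gauss_newton_cov(model_fn, z_opt, V)
        se_log = np.sqrt(np.clip(np.diag(self.cov_log_), 0.0, np.inf))
        self.gamma_upper_ = float(self.Gamma_ * (1.0 + 2.0 * se_log[1]))
        self.prior_ = Prior(mu=z_opt, V_mu=self.cov_log_, active_idx=(0, 1))
        flags = {}
        if se_log[0] > 0.5:
            # 95% CI spans >~7-fold: plateau-only designs leave K_a nearly free
            flags["K_a_weakly_identified"] = True
        ssr = float(np.sum((y - model_fn(z_opt)) ** 2))
        self.result_ = FitResult(
            params={"K_a": float(self.K_a_), "Gamma": float(self.Gamma_)},
            param_names=self._param_names, log_params=z_opt, objective=f_opt,
            cov_log=self.cov_log_, n_starts=len(rec.objectives),
            start_objectives=rec.objectives, converged_fraction=rec.converged_fraction,
            ssr=ssr, n_obs=y.size, flags=flags,
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "K_a_")
        E_T, N_0 = _check_X(X)
        return adsorbed_complex_grid(self.K_a_, self.Gamma_, E_T, N_0)


class SurfaceCrowdingRegressor(RegressorMixin, BaseEstimator):
    """MAP fit of the five-parameter surface-crowding rate law.

    Requires a ``Prior`` on (log K_a, log Gamma) from :class:`AdsorptionIsotherm`
    (pass ``Prior.empty()`` to deliberately fit without one). The crowded-rate
    constraint k_cat_c <= k_cat_uc is built in by optimizing the ratio
    c = k_cat_c/k_cat_uc with an upper bound of 1. ``gamma_upper`` caps Gamma
    at the measured adsorption capacity.

    Fitted attributes: ``params_`` (SCParameters), ``cov_log_`` (5x5, in the
    natural parameter order K_a, Gamma, K_c, k_cat_uc, k_cat_c), ``ssr_``,
    ``bic_``, ``result_``.
    """

    _param_names = ("K_a", "Gamma", "K_c", "k_cat_uc", "k_cat_c")

    def __init__(self, prior: Prior | None = None, gamma_upper: float | None = None,
                 n_starts: int = 64, random_state: int = 0,
                 variance_floor_frac: float = 0.01, bounds=None):
        self.prior = prior
        self.gamma_upper = gamma_upper
        self.n_starts = n_starts
        self.random_state = random_state
        self.variance_floor_frac = variance_floor_frac
        self.bounds = bounds

    def _resolved_bounds(self):
        pairs = list(self.bounds or (BOUNDS_KA, BOUNDS_GAMMA, BOUNDS_KC, BOUNDS_KCAT_UC, BOUNDS_C))
        if self.gamma_upper is not None:
            lo, hi = pairs[1]
            pairs[1] = (lo, min(hi, float(self.gamma_upper)))
        return _log_bounds(pairs)

    @staticmethod
    def _params_from_z(z) -> SCParameters:
        k_uc = float(np.exp(z[3]))
        return SCParameters(K_a=float(np.exp(z[0])), Gamma=float(np.exp(z[1])),
                            K_c=float(np.exp(z[2])), k_cat_uc=k_uc,
                            k_cat_c=k_uc * float(min(np.exp(z[4]), 1.0)))

    def fit(self, X, y, y_sd=None):
        if self.prior is None:
            raise ValueError(
                "SurfaceCrowdingRegressor needs a log-space prior on (K_a, Gamma): "
                "run the two-step workflow (AdsorptionIsotherm().fit(...).prior_), "
                "or pass Prior.empty() to fit without adsorption data."
            )
        E_T, N_0 = _check_X(X)
        y = np.asarray(y, dtype=float)
        V = _variances(y, y_sd, self.variance_floor_frac)
        bounds = self._resolved_bounds()
        prior = self.prior

        def model_fn(z):
            return rate_grid(self._params_from_z(z), E_T, N_0)

        def objective(z):
            return weighted_ssr(y, model_fn(z), V) + prior.cost(z)

        extra = []
        if prior.mu.size == 2:
            # seed one start at the adsorption estimate, mid-box elsewhere
            mid = np.array([0.5 * (lo + hi) for lo, hi in bounds])
            lo2 = np.array([bounds[0][0], bounds[1][0]])
            hi2 = np.array([bounds[0][1], bounds[1][1]])
            mid[[0, 1]] = np.clip(prior.mu, lo2, hi2)
            extra.append(mid)
        z_opt, f_opt, rec = multistart_optimize(objective, bounds, self.n_starts,
                                                seed=self.random_state, extra_x0=extra)
        self.params_ = self._params_from_z(z_opt)
        cov_fit = gauss_newton_cov(model_fn, z_opt, V)
        # map (lnKa, lnG, lnKc, ln k_uc, ln c) -> natural logs; ln k_c = ln k_uc + ln c
        A = np.eye(5)
        A[4, 3] = 1.0
        self.cov_log_ = A @ cov_fit @ A.T
        log_nat = A @ z_opt
        resid = y - model_fn(z_opt)
        self.ssr_ = float(np.sum(resid ** 2))
        self.bic_ = bic(self.ssr_, y.size, 5)
        flags = {}
        if self.gamma_upper is not None and self.params_.Gamma >= self.gamma_upper * (1 - 1e-6):
            flags["gamma_at_upper_bound"] = True
        self.result_ = FitResult(
            params=self.params_, param_names=self._param_names, log_params=log_nat,
            objective=f_opt, cov_log=self.cov_log_, n_starts=len(rec.objectives),
            start_objectives=rec.objectives, converged_fraction=rec.converged_fraction,
            ssr=self.ssr_, n_obs=y.size, bic=self.bic_, flags=flags,
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        E_T, N_0 = _check_X(X)
        return rate_grid(self.params_, E_T, N_0)


class InverseMMRegressor(RegressorMixin, BaseEstimator):
    """Inverse Michaelis-Menten fit: rate = k_inv*Gamma_inv*N_0*E_T/(K_inv+E_T).

    The conventional enzyme-saturating law for heterogeneous biocatalysis;
    three parameters, no inhibition maximum. Fitted attributes ``params_``
    (InvMMParameters), ``ssr_``, ``bic_``, ``result_``.
    """

    _param_names = ("k_inv", "Gamma_inv", "K_inv")
    _default_bounds = ((1e-6, 1e3), (1e-6, 1e3), (1e-3, 1e6))

    def __init__(self, n_starts: int = 32, random_state: int = 0,
                 variance_floor_frac: float = 0.01, bounds=None):
        self.n_starts = n_starts
        self.random_state = random_state
        self.variance_floor_frac = variance_floor_frac
        self.bounds = bounds

    def fit(self, X, y, y_sd=None):
        E_T, N_0 = _check_X(X)
        y = np.asarray(y, dtype=float)
        V = _variances(y, y_sd, self.variance_floor_frac)
        bounds = _log_bounds(self.bounds or self._default_bounds)

        def model_fn(z):
            p = InvMMParameters(*np.exp(z))
            return inv_mm_rate_grid(p, E_T, N_0)

        def objective(z):
            return weighted_ssr(y, model_fn(z), V)

        z_opt, f_opt, rec = multistart_optimize(objective, bounds, self.n_starts,
                                                seed=self.random_state)
        self.params_ = InvMMParameters(*np.exp(z_opt))
        self.cov_log_ = gauss_newton_cov(model_fn, z_opt, V)
        self.ssr_ = float(np.sum((y - model_fn(z_opt)) ** 2))
        self.bic_ = bic(self.ssr_, y.size, 3)
        self.result_ = FitResult(
            params=self.params_, param_names=self._param_names, log_params=z_opt,
            objective=f_opt, cov_log=self.cov_log_, n_starts=len(rec.objectives),
            start_objectives=rec.objectives, converged_fraction=rec.converged_fraction,
            ssr=self.ssr_, n_obs=y.size, bic=self.bic_,
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        E_T, N_0 = _check_X(X)
        return inv_mm_rate_grid(self.params_, E_T, N_0)


def bootstrap_ci(estimator, X, y, y_sd=None, n_boot: int = 200, seed: int = 0,
                 level: float = 0.95) -> dict[str, tuple[float, float]]:
    """Residual-bootstrap percentile intervals for a fitted estimator.

    Resamples residuals around the fitted predictions, refits a clone on each
    replicate, and takes percentile intervals of the log parameters, mapped
    back to the natural scale. Deterministic given ``seed``.
    """
    if n_boot < 50:
        warnings.warn(f"n_boot={n_boot} is small; intervals will be noisy", UserWarning)
    check_is_fitted(estimator, "result_")
    yhat = estimator.predict(X)
    resid = np.asarray(y, dtype=float) - yhat
    ss = np.random.SeedSequence(seed)
    draws = []
    for child in ss.spawn(n_boot):
        rng = np.random.default_rng(child)
        y_b = np.maximum(yhat + rng.choice(resid, size=resid.size, replace=True), 0.0)
        est_b = clone(estimator)
        est_b.fit(X, y_b, y_sd=y_sd)
        draws.append(est_b.result_.log_params)
    Z = np.array(draws)
    alpha = (1.0 - level) / 2.0
    lo = np.exp(np.quantile(Z, alpha, axis=0))
    hi = np.exp(np.quantile(Z, 1.0 - alpha, axis=0))
    return {n: (float(a), float(b))
            for n, a, b in zip(estimator.result_.param_names, lo, hi)}


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimators

def fit_adsorption(ads: AdsorptionDataset, n_starts: int = 16, seed: int = 0,
                   **kwargs) -> FitResult:
    """Step 1: MLE of (K_a, Gamma) from a solution-depletion isotherm."""
    X, y, sd = ads.to_Xy()
    est = AdsorptionIsotherm(n_starts=n_starts, random_state=seed, **kwargs).fit(X, y, y_sd=sd)
    res = est.result_
    res.flags["prior"] = est.prior_
    res.flags["gamma_upper"] = est.gamma_upper_
    return res


def fit_kinetics(kin: KineticDataset, prior: Prior, gamma_upper: float | None = None,
                 n_starts: int = 64, seed: int = 0, **kwargs) -> FitResult:
    """Step 2: MAP fit of all five rate-law parameters."""
    X, y, sd = kin.to_Xy()
    est = SurfaceCrowdingRegressor(prior=prior, gamma_upper=gamma_upper,
                                   n_starts=n_starts, random_state=seed, **kwargs)
    est.fit(X, y, y_sd=sd)
    return est.result_


def compare_models(kin: KineticDataset, prior: Prior, gamma_upper: float | None = None,
                   n_starts: int = 32, seed: int = 0) -> dict:
    """Fit both rate laws to the same data and compare by BIC.

    Returns {"sc": FitResult, "inv_mm": FitResult, "delta_bic": BIC(SC)-BIC(invMM),
    "selected": "sc"|"inv_mm"}; negative delta_bic favors the crowding model.
    """
    X, y, sd = kin.to_Xy()
    sc = SurfaceCrowdingRegressor(prior=prior, gamma_upper=gamma_upper,
                                  n_starts=n_starts, random_state=seed).fit(X, y, y_sd=sd)
    imm = InverseMMRegressor(n_starts=n_starts, random_state=seed).fit(X, y, y_sd=sd)
    delta = sc.bic_ - imm.bic_
    return {"sc": sc.result_, "inv_mm": imm.result_, "delta_bic": float(delta),
            "selected": "sc" if delta < 0 else "inv_mm"}
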