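"""Regression models mapping PPG features to blood pressure (mmHg).

Seven regressors are exposed through one model/results interface:

====================  =====================================================
name                  estimator
====================  =====================================================
``linear``            ordinary least squares
``robust_linear``     iteratively reweighted least squares, Huber loss
``gpr_rq``            exact GP regression, rational quadratic kernel
``gpr_se``            exact GP regression, squared exponential kernel
``gpr_matern52``      exact GP regression, Matérn 5/2 kernel
``svm_linear``        ε-insensitive SVR, linear kernel
``svm_gaussian``      ε-insensitive SVR, Gaussian (RBF) kernel
====================  =====================================================

Features are z-scored inside ``fit`` and the constants stored with the
fitted model, so predictions are invariant to affine rescaling of any
feature column. GP hyperparameters are optimized by marginal-likelihood
maximization from three fixed deterministic starts; fits are reproducible
without a seed.

Usage follows the statsmodels convention: build a :class:`BPRegression`
model from data (or :meth:`BPRegression.from_feature_table`), call
``fit()``, and work with the returned :class:`BPRegressionResults`::

    model = BPRegression(y_sbp, X, spec="gpr_matern52")
    res = model.fit()
    res.predict(X_new)
    print(res.summary())
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    RBF,
    ConstantKernel,
    Matern,
    RationalQuadratic,
    WhiteKernel,
)
from sklearn.svm import SVR

__all__ = ["MODEL_NAMES", "ModelSpec", "BPRegression", "BPRegressionResults",
           "load_model"]

logger = logging.getLogger(__name__)

MODEL_NAMES = (
    "linear",
    "robust_linear",
    "gpr_rq",
    "gpr_se",
    "gpr_matern52",
    "svm_linear",
    "svm_gaussian",
)

_ARCHIVE_FORMAT = "ppg2bp-fitted-model"
_ARCHIVE_VERSION = 1


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one regressor.

    ``hyperparams`` keys (all optional, positive where applicable):

    * GPR: ``length_scale`` (initial σ_l), ``signal_variance`` (initial
      σ_f²), ``alpha`` (RQ shape), ``alpha_fixed`` (freeze the RQ shape),
      ``noise_floor`` (minimum noise variance relative to the normalized
      targets), ``as_printed`` (gpr_matern52 only: use the √3/Matérn-3/2
      form instead of the true Matérn 5/2), ``optimize`` (set False to skip
      marginal-likelihood optimization and keep the given hyperparameters).
    * SVR: ``C`` (box constraint), ``epsilon`` (tube width),
      ``kernel_scale`` (Gaussian kernel σ; default √p with p features).
    """

    name: str
    hyperparams: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(
                f"unknown model {self.name!r}; choose from {MODEL_NAMES}"
            )
        for key in ("length_scale", "signal_variance", "alpha", "C",
                    "epsilon", "kernel_scale", "noise_floor"):
            v = self.hyperparams.get(key)
            if v is not None and not v > 0:
                raise ValueError(f"hyperparameter {key!r} must be > 0, got {v}")


def _as_spec(spec: str | ModelSpec, hyperparams: dict | None = None) -> ModelSpec:
    if isinstance(spec, ModelSpec):
        return spec
    return ModelSpec(spec, dict(hyperparams or {}))


class BPRegression:
    """A blood-pressure regression model: targets ``endog`` (mmHg) against a
    feature matrix ``exog``.

    Parameters
    ----------
    endog : array, shape (n,)
        SBP or DBP references in mmHg.
    exog : array, shape (n, p)
        Feature matrix (24 columns in the standard pipeline).
    spec : str or ModelSpec
        One of :data:`MODEL_NAMES`, optionally with hyperparameters.
    """

    def __init__(self, endog, exog, spec: str | ModelSpec = "linear",
                 **hyperparams) -> None:
        self.endog = np.asarray(endog, dtype=np.float64).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=np.float64))
        self.spec = _as_spec(spec, hyperparams)
        if self.exog.shape[0] != len(self.endog):
            raise ValueError(
                f"endog has {len(self.endog)} rows, exog {self.exog.shape[0]}"
            )
        if not np.all(np.isfinite(self.endog)) or not np.all(np.isfinite(self.exog)):
            raise ValueError("non-finite values in endog/exog")

    @classmethod
    def from_feature_table(cls, table, target: str = "SBP",
                           spec: str | ModelSpec = "linear",
                           **hyperparams) -> "BPRegression":
        """Build the model from a :class:`~ppg2bp.signal_io.FeatureTable`."""
        return cls(table.y(target), table.X, spec, **hyperparams)

    # -- estimators ---------------------------------------------------------

    def _fit_linear(self, Xz: np.ndarray, y: np.ndarray):
        A = np.column_stack([np.ones(len(Xz)), Xz])
        if np.linalg.matrix_rank(A) < A.shape[1]:
            logger.warning("rank-deficient design; solving via pseudo-inverse")
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        return beta

    def _fit_robust(self, Xz: np.ndarray, y: np.ndarray):
        A = sm.add_constant(Xz, has_constant="add")
        if len(y) <= A.shape[1]:
            # IRLS needs residual degrees of freedom to estimate scale;
            # degenerate designs fall back to the least-squares solution
            logger.warning(
                "robust fit with n=%d <= p=%d: falling back to least squares",
                len(y), A.shape[1],
            )
            return self._fit_linear(Xz, y)
        rlm = sm.RLM(y, A, M=sm.robust.norms.HuberT(t=1.345))
        return rlm.fit().params

    def _gpr_kernel(self, p: int):
        hp = self.spec.hyperparams
        ls = hp.get("length_scale", 1.0)
        sf2 = hp.get("signal_variance", 1.0)
        const = ConstantKernel(sf2, (1e-4, 1e4))
        if self.spec.name == "gpr_rq":
            alpha = hp.get("alpha", 1.0)
            bounds = "fixed" if hp.get("alpha_fixed") else (1e-3, 1e7)
            core = RationalQuadratic(length_scale=ls, alpha=alpha,
                                     alpha_bounds=bounds)
        elif self.spec.name == "gpr_se":
            core = RBF(length_scale=ls)
        else:  # gpr_matern52; nu=1.5 gives the sqrt(3) exponential form
            nu = 1.5 if hp.get("as_printed") else 2.5
            core = Matern(length_scale=ls, nu=nu)
        noise_floor = hp.get("noise_floor", 1e-6)
        white = WhiteKernel(
            noise_level=max(1e-2, noise_floor),
            noise_level_bounds=(noise_floor, 1e2),
        )
        return const * core + white

    def _fit_gpr(self, Xz: np.ndarray, y: np.ndarray):
        import warnings

        from sklearn.exceptions import ConvergenceWarning

        from scipy.optimize import minimize

        def _lbfgs_capped(obj_func, initial_theta, bounds):
            # capped iteration budget: marginal-likelihood surfaces here are
            # benign and the multi-start covers basin choice
            res = minimize(
                obj_func, initial_theta, method="L-BFGS-B", jac=True,
                bounds=bounds, options={"maxiter": 40},
            )
            return res.x, res.fun

        if not self.spec.hyperparams.get("optimize", True):
            # fixed-hyperparameter fit (e.g. kernel-limit comparisons)
            gpr = GaussianProcessRegressor(
                kernel=self._gpr_kernel(Xz.shape[1]), alpha=1e-10,
                normalize_y=True, optimizer=None,
            )
            gpr.fit(Xz, y)
            return gpr
        # three fixed deterministic starts on the length scale
        best = None
        for ls0 in (0.5, 2.0, 8.0):
            hp = dict(self.spec.hyperparams)
            hp.setdefault("length_scale", 1.0)
            spec = ModelSpec(self.spec.name, {**hp, "length_scale": ls0})
            kernel = BPRegression(y, Xz, spec)._gpr_kernel(Xz.shape[1])
            gpr = GaussianProcessRegressor(
                kernel=kernel, alpha=1e-10, normalize_y=True,
                n_restarts_optimizer=0, optimizer=_lbfgs_capped,
            )
            with warnings.catch_warnings():
                # bound-hitting restarts are expected; the best start wins
                warnings.simplefilter("ignore", ConvergenceWarning)
                gpr.fit(Xz, y)
            lml = gpr.log_marginal_likelihood_value_
            if best is None or lml > best[0]:
                best = (lml, gpr)
        return best[1]

    def _fit_svr(self, Xz: np.ndarray, y: np.ndarray):
        hp = self.spec.hyperparams
        iqr = stats.iqr(y)
        C = hp.get("C", iqr / 1.349 if iqr > 0 else 1.0)
        epsilon = hp.get("epsilon", C / 10.0)
        if self.spec.name == "svm_linear":
            svr = SVR(kernel="linear", C=C, epsilon=epsilon)
        else:
            sigma = hp.get("kernel_scale", np.sqrt(Xz.shape[1]))
            svr = SVR(kernel="rbf", C=C, epsilon=epsilon,
                      gamma=1.0 / (2.0 * sigma**2))
        svr.fit(Xz, y)
        return svr

    def fit(self) -> "BPRegressionResults":
        """Estimate the model; returns a results object."""
        n, p = self.exog.shape
        mean = self.exog.mean(axis=0)
        sd = self.exog.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)  # constant columns pass through as zeros
        Xz = (self.exog - mean) / sd
        y = self.endog
        name = self.spec.name
        if name == "linear":
            estimator = self._fit_linear(Xz, y)
        elif name == "robust_linear":
            estimator = self._fit_robust(Xz, y)
        elif name.startswith("gpr_"):
            estimator = self._fit_gpr(Xz, y)
        else:
            estimator = self._fit_svr(Xz, y)
        return BPRegressionResults(self, estimator, mean, sd)


class BPRegressionResults:
    """Fitted state: learned parameters, standardization constants, and
    prediction/summary methods."""

    def __init__(self, model: BPRegression, estimator, feat_mean, feat_sd):
        self.model = model
        self.spec = model.spec
        self._estimator = estimator
        self.feature_mean = np.asarray(feat_mean)
        self.feature_sd = np.asarray(feat_sd)
        self.fittedvalues = self.predict(model.exog)
        self.resid = model.endog - self.fittedvalues

    # -- parameters ---------------------------------------------------------

    @property
    def params(self) -> np.ndarray | None:
        """[intercept, coefficients] on the *original* feature scale, for the
        linear-in-features models; None for kernel models."""
        if self.spec.name not in ("linear", "robust_linear"):
            return None
        beta = np.asarray(self._estimator)
        b0, bz = beta[0], beta[1:]
        coef = bz / self.feature_sd
        intercept = b0 - np.sum(bz * self.feature_mean / self.feature_sd)
        return np.concatenate([[intercept], coef])

    @property
    def kernel_(self):
        """Optimized kernel (GPR models only)."""
        if self.spec.name.startswith("gpr_"):
            return self._estimator.kernel_
        return None

    # -- prediction ---------------------------------------------------------

    def predict(self, exog, return_std: bool = False):
        """Predict blood pressure (mmHg) for new feature rows."""
        X = np.atleast_2d(np.asarray(exog, dtype=np.float64))
        if X.shape[1] != len(self.feature_mean):
            raise ValueError(
                f"expected {len(self.feature_mean)} feature columns, "
                f"got {X.shape[1]}"
            )
        Xz = (X - self.feature_mean) / self.feature_sd
        name = self.spec.name
        if name in ("linear", "robust_linear"):
            beta = np.asarray(self._estimator)
            pred = beta[0] + Xz @ beta[1:]
            if return_std:
                return pred, np.full(len(pred), np.nan)
            return pred
        if name.startswith("gpr_"):
            if return_std:
                return self._estimator.predict(Xz, return_std=True)
            return self._estimator.predict(Xz)
        pred = self._estimator.predict(Xz)
        if return_std:
            return pred, np.full(len(pred), np.nan)
        return pred

    # -- diagnostics --------------------------------------------------------

    @property
    def rmse(self) -> float:
        return float(np.sqrt(np.mean(self.resid**2)))

    @property
    def mae(self) -> float:
        return float(np.mean(np.abs(self.resid)))

    @property
    def rsquared(self) -> float:
        y = self.model.endog
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst == 0:
            return float("nan")
        return 1.0 - float(np.sum(self.resid**2)) / sst

    def summary(self) -> str:
        """Plain-text fit summary."""
        n, p = self.model.exog.shape
        lines = [
            "Blood-pressure regression results",
            "=" * 46,
            f"model:          {self.spec.name}",
            f"observations:   {n}",
            f"features:       {p}",
            f"train RMSE:     {self.rmse:.4f} mmHg",
            f"train MAE:      {self.mae:.4f} mmHg",
            f"train R^2:      {self.rsquared:.4f}",
        ]
        if self.params is not None:
            lines.append(f"intercept:      {self.params[0]:.4f}")
            coefs = ", ".join(f"{c:.3g}" for c in self.params[1:6])
            more = ", ..." if p > 5 else ""
            lines.append(f"coefficients:   [{coefs}{more}]")
        if self.kernel_ is not None:
            lines.append(f"kernel:         {self.kernel_}")
        hp = self.spec.hyperparams
        if hp:
            lines.append(f"hyperparams:    {hp}")
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Serialize to a small versioned archive (pickle payload)."""
        payload = {
            "format": _ARCHIVE_FORMAT,
            "version": _ARCHIVE_VERSION,
            "spec": self.spec,
            "results": self,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)


def load_model(path) -> BPRegressionResults:
    """Load a fitted model saved with :meth:`BPRegressionResults.save`."""
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format") != _ARCHIVE_FORMAT:
        raise ValueError(f"{path}: not a ppg2bp model archive")
    if payload.get("version") != _ARCHIVE_VERSION:
        raise ValueError(f"{path}: unsupported archive version "
                         f"{payload.get('version')}")
    return payload["results"]
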