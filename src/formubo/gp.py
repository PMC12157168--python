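"""Gaussian-process regression with the Matérn ν=5/2 kernel.

The surrogate models the response as f(x) ~ GP(μ(x), σ²(x)) with covariance

    K(x, x') = s² · (1 + √5 d/ℓ + 5 d²/(3ℓ²)) · exp(−√5 d/ℓ),

where d is the Euclidean distance between unit-scaled inputs and ℓ a single
isotropic length-scale.  Responses are standardized to zero mean / unit
variance before fitting and predictions are de-standardized, so the constant
GP mean is the training mean.  Hyperparameters (ℓ, s², noise σₙ²) are chosen
by multi-start quasi-Newton maximization of the log marginal likelihood on
log-parameters; the optimization is deterministic given the seed.

Replicate formulations produce duplicate rows, so the Gram matrix is
factorized with an escalating diagonal jitter (1e-10 up to 1e-6).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.spatial.distance import cdist

__all__ = [
    "MaternParams",
    "GPFitConfig",
    "GPState",
    "PosteriorPrediction",
    "matern52",
    "fit_gp",
    "predict_gp",
    "log_marginal_likelihood",
]

_SQRT5 = math.sqrt(5.0)
_JITTER_START = 1e-10
_JITTER_MAX = 1e-6


@dataclass(frozen=True)
class MaternParams:
    """Kernel hyperparameters.  ``nu`` is fixed at 5/2 and not configurable."""

    length_scale: float
    signal_variance: float = 1.0
    nu: float = field(default=2.5, init=False)

    def __post_init__(self) -> None:
        if not self.length_scale > 0:
            raise ValueError("length_scale must be > 0")
        if not self.signal_variance > 0:
            raise ValueError("signal_variance must be > 0")


@dataclass(frozen=True)
class GPFitConfig:
    """Options for :func:`fit_gp`.

    Multi-start bounds are on unit-scaled inputs and standardized responses.
    ``fix_noise`` pins the noise variance instead of fitting it (useful for
    interpolation tests and noise-free oracles).
    """

    seed: int = 0
    n_starts: int = 8
    length_scale_bounds: tuple[float, float] = (1e-2, 10.0)
    signal_variance_bounds: tuple[float, float] = (1e-3, 1e3)
    noise_variance_bounds: tuple[float, float] = (1e-8, 1e1)
    fix_noise: float | None = None


@dataclass
class PosteriorPrediction:
    """Posterior mean and variance in original response units."""

    mean: np.ndarray
    variance: np.ndarray

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(self.variance)


@dataclass
class GPState:
    """Fitted GP: training data (unit-scaled X, standardized y), kernel and
    noise parameters, standardization constants and the cached Cholesky
    factorization of K + (σₙ² + jitter)·I."""

    X: np.ndarray
    y: np.ndarray  # standardized
    params: MaternParams
    noise_variance: float
    y_mean: float
    y_sd: float
    L: np.ndarray = field(repr=False)
    alpha: np.ndarray = field(repr=False)
    jitter: float = _JITTER_START

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    @property
    def noise_variance_original(self) -> float:
        """Noise variance on the original (de-standardized) response scale."""
        return self.noise_variance * self.y_sd**2

    def with_data(self, X: np.ndarray, y_std: np.ndarray) -> "GPState":
        """Refactorize with new data under the *same* hyperparameters
        (constant-liar batch updates)."""
        L, jit = _factorize(X, self.params, self.noise_variance)
        alpha = cho_solve((L, True), y_std)
        return GPState(
            X=X, y=y_std, params=self.params, noise_variance=self.noise_variance,
            y_mean=self.y_mean, y_sd=self.y_sd, L=L, alpha=alpha, jitter=jit,
        )

    # -- serialization (training data by value; arrays are small) ------
    def to_json(self) -> str:
        return json.dumps({
            "length_scale": self.params.length_scale,
            "signal_variance": self.params.signal_variance,
            "noise_variance": self.noise_variance,
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "X": self.X.tolist(),
            "y": self.y.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "GPState":
        d = json.loads(text)
        params = MaternParams(d["length_scale"], d["signal_variance"])
        X = np.asarray(d["X"], dtype=float)
        y = np.asarray(d["y"], dtype=float)
        L, jit = _factorize(X, params, d["noise_variance"])
        alpha = cho_solve((L, True), y)
        return cls(X=X, y=y, params=params, noise_variance=d["noise_variance"],
                   y_mean=d["y_mean"], y_sd=d["y_sd"], L=L, alpha=alpha, jitter=jit)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "GPState":
        return cls.from_json(Path(path).read_text())


def matern52(d, params: MaternParams):
    """Matérn ν=5/2 covariance as a function of Euclidean distance d ≥ 0."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    r = _SQRT5 * d / params.length_scale
    return params.signal_variance * (1.0 + r + r**2 / 3.0) * np.exp(-r)


def _kernel_matrix(A: np.ndarray, B: np.ndarray, params: MaternParams) -> np.ndarray:
    return matern52(cdist(A, B), params)


def _factorize(X: np.ndarray, params: MaternParams, sn2: float):
    """Cholesky of K + (sn2 + jitter) I with jitter escalation ×10."""
    K = _kernel_matrix(X, X, params)
    jitter = _JITTER_START
    while True:
        try:
            L = cholesky(K + (sn2 + jitter) * np.eye(len(X)), lower=True)
            return L, jitter
        except np.linalg.LinAlgError:
            jitter *= 10.0
            if jitter > _JITTER_MAX:
                raise np.linalg.LinAlgError(
                    f"Gram matrix not positive definite even with jitter {_JITTER_MAX:g} "
                    f"(l={params.length_scale:g}, s2={params.signal_variance:g}, sn2={sn2:g})"
                )


def _lml(X: np.ndarray, y: np.ndarray, l: float, s2: float, sn2: float) -> float:
    """Log marginal likelihood −½ yᵀ(K+σₙ²I)⁻¹y − ½ log|K+σₙ²I| − n/2 log 2π."""
    n = len(y)
    L, _ = _factorize(X, MaternParams(l, s2), sn2)
    alpha = cho_solve((L, True), y)
    return float(
        -0.5 * y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * n * math.log(2.0 * math.pi)
    )


def log_marginal_likelihood(state: GPState) -> float:
    """LML of the fitted state via its cached factorization (standardized y)."""
    n = state.n
    return float(
        -0.5 * state.y @ state.alpha
        - np.sum(np.log(np.diag(state.L)))
        - 0.5 * n * math.log(2.0 * math.pi)
    )


def fit_gp(X: np.ndarray, y: np.ndarray, config: GPFitConfig | None = None) -> GPState:
    """Fit kernel and noise hyperparameters by maximizing the log marginal
    likelihood with seeded multi-start L-BFGS-B on log-parameters."""
    config = config or GPFitConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations to fit a GP")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in training data")

    y_mean = float(np.mean(y))
    y_sd = float(np.std(y))
    if y_sd == 0.0:
        y_sd = 1.0  # constant responses: keep the scale well-defined
    ys = (y - y_mean) / y_sd

    lb = np.log([config.length_scale_bounds[0], config.signal_variance_bounds[0]])
    ub = np.log([config.length_scale_bounds[1], config.signal_variance_bounds[1]])
    fit_noise = config.fix_noise is None
    if fit_noise:
        lb = np.append(lb, math.log(config.noise_variance_bounds[0]))
        ub = np.append(ub, math.log(config.noise_variance_bounds[1]))

    def unpack(theta):
        l, s2 = math.exp(theta[0]), math.exp(theta[1])
        sn2 = math.exp(theta[2]) if fit_noise else float(config.fix_noise)
        return l, s2, sn2

    def neg_lml(theta):
        try:
            return -_lml(X, ys, *unpack(theta))
        except np.linalg.LinAlgError:
            return 1e10

    rng = np.random.default_rng(config.seed)
    # one anchored start (moderate length-scale, unit signal, small noise)
    starts = [np.clip(
        np.log(np.array([0.5, 1.0, 1e-2][: len(lb)])), lb, ub)]
    for _ in range(max(0, config.n_starts - 1)):
        starts.append(lb + rng.random(len(lb)) * (ub - lb))

    best = None
    for x0 in starts:
        res = optimize.minimize(
            neg_lml, x0, method="L-BFGS-B", bounds=list(zip(lb, ub)),
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("GP hyperparameter fit failed: no finite likelihood found")

    l, s2, sn2 = unpack(best.x)
    params = MaternParams(l, s2)
    L, jit = _factorize(X, params, sn2)
    alpha = cho_solve((L, True), ys)
    return GPState(X=X, y=ys, params=params, noise_variance=sn2,
                   y_mean=y_mean, y_sd=y_sd, L=L, alpha=alpha, jitter=jit)


def predict_gp(state: GPState, x: np.ndarray) -> PosteriorPrediction:
    """Posterior mean/variance at unit-scaled point(s) x, in original units.

    Accepts a single point (1-D) or a matrix of points (2-D); variance is the
    latent-function variance (no observation noise added) and tiny negative
    round-off values are clipped at 0.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    Xs = x[None, :] if single else x
    if Xs.shape[1] != state.dim:
        raise ValueError(f"dimension mismatch: expected {state.dim}, got {Xs.shape[1]}")
    Ks = _kernel_matrix(Xs, state.X, state.params)
    mu_std = Ks @ state.alpha
    v = cho_solve((state.L, True), Ks.T)
    var_std = state.params.signal_variance - np.einsum("ij,ji->i", Ks, v)
    var_std = np.clip(var_std, 0.0, None)
    mean = state.y_mean + state.y_sd * mu_std
    var = state.y_sd**2 * var_std
    if single:
        return PosteriorPrediction(mean=mean[0], variance=var[0])
    return PosteriorPrediction(mean=mean, variance=var)
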