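"""Beta and log-normal creator-model families.

A creator's data-generation model is a distribution over a feature
frequency theta in (0, 1).  The beta family is the workhorse: its shape
pair ``(a, b)`` is in one-to-one correspondence with the mean and
standard deviation ``(mu, sigma)``, and the learning rule of the
evolutionary dynamics is exactly this moment-matching map.  The
log-normal family backs the closed-form log-potential comparison model.

Conversions::

    mu    = a / (a + b)
    sigma = sqrt(a b / (a + b + 1)) / (a + b)

with the inverse (nu = mu (1 - mu) / sigma^2 - 1)::

    a = mu nu,   b = (1 - mu) nu

valid only in the representable region sigma^2 < mu (1 - mu).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .errors import (
    FittingError,
    InvalidParameterError,
    NotBetaRepresentableError,
)

__all__ = [
    "BetaParams",
    "MomentPair",
    "LogNormalParams",
    "LogNormalMoments",
    "moments_from_beta",
    "beta_from_moments",
    "beta_density",
    "beta_mode",
    "fit_beta",
    "lognormal_moments",
    "lognormal_from_moments",
]

#: (mu, sigma) pairs closer than this to the representability boundary
#: sigma^2 = mu (1 - mu) are rejected as numerically degenerate.
REPRESENTABILITY_TOL = 1e-12


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters of a beta distribution on (0, 1).

    ``a`` governs the density near theta = 0 and ``b`` near theta = 1;
    both must be positive.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise InvalidParameterError(f"non-finite beta parameters ({self.a}, {self.b})")
        if self.a <= 0 or self.b <= 0:
            raise InvalidParameterError(f"beta parameters must be positive, got ({self.a}, {self.b})")

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b}

    @classmethod
    def from_dict(cls, d: dict) -> "BetaParams":
        return cls(float(d["a"]), float(d["b"]))


@dataclass(frozen=True)
class MomentPair:
    """Mean and standard deviation of a beta-representable distribution."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (0.0 < self.mu < 1.0):
            raise InvalidParameterError(f"mean must lie in (0, 1), got {self.mu}")
        if self.sigma <= 0:
            raise InvalidParameterError(f"sd must be positive, got {self.sigma}")
        if self.sigma**2 >= self.mu * (1.0 - self.mu) - REPRESENTABILITY_TOL:
            raise NotBetaRepresentableError(
                f"sigma^2 = {self.sigma**2:.6g} >= mu(1-mu) = "
                f"{self.mu * (1 - self.mu):.6g}; not beta-representable"
            )

    @property
    def ratio(self) -> float:
        """sigma / mu, the scale-invariant diagnostic of the dynamics."""
        return self.sigma / self.mu

    def to_dict(self) -> dict:
        return {"mu": self.mu, "sigma": self.sigma}

    @classmethod
    def from_dict(cls, d: dict) -> "MomentPair":
        return cls(float(d["mu"]), float(d["sigma"]))


@dataclass(frozen=True)
class LogNormalParams:
    """Log-mean and log-sd of a log-normal distribution on theta > 0."""

    mu_tilde: float
    sigma_tilde: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu_tilde):
            raise InvalidParameterError(f"non-finite log mean {self.mu_tilde}")
        if not (np.isfinite(self.sigma_tilde) and self.sigma_tilde > 0):
            raise InvalidParameterError(f"log sd must be positive, got {self.sigma_tilde}")

    def to_dict(self) -> dict:
        return {"mu_tilde": self.mu_tilde, "sigma_tilde": self.sigma_tilde}

    @classmethod
    def from_dict(cls, d: dict) -> "LogNormalParams":
        return cls(float(d["mu_tilde"]), float(d["sigma_tilde"]))


@dataclass(frozen=True)
class LogNormalMoments:
    """Mean/sd view of a log-normal model; the mean is not bounded by 1."""

    mu: float
    sigma: float

    @property
    def ratio(self) -> float:
        return self.sigma / self.mu


def moments_from_beta(params: BetaParams) -> MomentPair:
    """Mean and standard deviation of ``Beta(a, b)``.

    Satisfies the identity sigma/mu = sqrt((1 - mu) / (a + mu)).
    """
    a, b = params.a, params.b
    s = a + b
    mu = a / s
    sigma = np.sqrt(a * b / (s + 1.0)) / s
    return MomentPair(mu, sigma)


def beta_from_moments(moments: MomentPair) -> BetaParams:
    """The unique beta parameters with the given mean and sd.

    Raises
    ------
    NotBetaRepresentableError
        If ``sigma^2 >= mu (1 - mu)`` (already enforced by
        :class:`MomentPair`, re-checked here for raw inputs).
    """
    mu, sigma = moments.mu, moments.sigma
    nu = mu * (1.0 - mu) / sigma**2 - 1.0
    if nu <= 0:
        raise NotBetaRepresentableError(f"(mu={mu}, sigma={sigma}) not representable")
    return BetaParams(mu * nu, (1.0 - mu) * nu)


def beta_log_density(params: BetaParams, theta):
    """Log of the beta density; vectorised over theta in (0, 1)."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0.0) or np.any(theta >= 1.0):
        raise InvalidParameterError("theta must lie strictly in (0, 1)")
    a, b = params.a, params.b
    return (a - 1.0) * np.log(theta) + (b - 1.0) * np.log1p(-theta) - special.betaln(a, b)


def beta_density(params: BetaParams, theta):
    """Beta density theta^(a-1) (1-theta)^(b-1) / B(a, b)."""
    return np.exp(beta_log_density(params, theta))


def beta_mode(params: BetaParams) -> float:
    """Interior mode (a - 1) / (a + b - 2); requires a, b > 1.

    For a < b the mode lies strictly below the mean.
    """
    a, b = params.a, params.b
    if a <= 1.0 or b <= 1.0:
        raise InvalidParameterError(f"no interior mode for (a={a}, b={b}); requires a, b > 1")
    return (a - 1.0) / (a + b - 2.0)


def fit_beta(frequencies) -> BetaParams:
    """Maximum-likelihood beta fit to frequencies strictly inside (0, 1).

    Initialised by moment matching; the digamma score equations are then
    solved by the generic MLE machinery with the support held fixed at
    (0, 1).  If the optimiser fails to improve on the moment-matched
    start, that start is returned with a warning.

    Raises
    ------
    FittingError
        Fewer than 3 values, any value outside (0, 1) (callers must
        pre-filter zero-frequency pieces), or zero sample variance.
    """
    x = np.asarray(list(frequencies), dtype=float)
    if x.size < 3:
        raise FittingError(f"need at least 3 values to fit, got {x.size}")
    if np.any(x <= 0.0) or np.any(x >= 1.0):
        raise FittingError("all values must lie strictly in (0, 1); pre-filter zeros")
    mu = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd <= 1e-9 * mu:  # identical values up to rounding
        raise FittingError("zero sample variance")
    try:
        start = beta_from_moments(MomentPair(mu, sd))
    except (NotBetaRepresentableError, InvalidParameterError) as exc:
        raise FittingError(f"moment-matched start not representable: {exc}") from exc

    def negloglik(p):
        a, b = p
        if a <= 0 or b <= 0:
            return np.inf
        return -float(np.sum(stats.beta.logpdf(x, a, b)))

    res = optimize.minimize(
        negloglik,
        x0=[start.a, start.b],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000},
    )
    if res.success and negloglik(res.x) <= negloglik([start.a, start.b]):
        return BetaParams(float(res.x[0]), float(res.x[1]))
    warnings.warn("beta MLE did not improve on moment matching; returning moment-matched fit")
    return start


def lognormal_moments(params: LogNormalParams) -> LogNormalMoments:
    """Mean/sd of the log-normal: mu = exp(mu_tilde + sigma_tilde^2 / 2),
    sigma/mu = sqrt(exp(sigma_tilde^2) - 1)."""
    mt, st = params.mu_tilde, params.sigma_tilde
    mu = np.exp(mt + st**2 / 2.0)
    ratio = np.sqrt(np.expm1(st**2))
    return LogNormalMoments(float(mu), float(mu * ratio))


def lognormal_from_moments(mu: float, sigma: float) -> LogNormalParams:
    """Inverse of :func:`lognormal_moments`; round-trips to 1e-10."""
    if mu <= 0 or sigma <= 0:
        raise InvalidParameterError("mean and sd must be positive")
    st2 = np.log1p((sigma / mu) ** 2)
    return LogNormalParams(float(np.log(mu) - st2 / 2.0), float(np.sqrt(st2)))
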