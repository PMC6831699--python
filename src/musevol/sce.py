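"""The statistical creator-evaluator (SCE) generational map.

Each generation, a creator's beta model phi_t over a feature frequency
theta is reweighted by social selection,

    phi~_t(theta) = phi_t(theta)^(1 + beta_T) * exp(-beta_N phi_t(theta)),

where beta_T rewards style conformity (typicality, a log-density term)
and beta_N penalises similarity to abundant existing data (novelty).
The next-generation model phi_{t+1} is the beta distribution whose mean
and standard deviation match those of the normalised phi~_t (moment
matching).  Taking (mu_t, sigma_t) as state variables, the update is a
two-dimensional map.

Special cases admit closed forms:

* typicality only (beta_N = 0): phi~_t is itself a beta density with
  a' - 1 = (1 + beta_T)(a - 1), b' - 1 = (1 + beta_T)(b - 1), so the
  moment-matched update is exact; the mode is invariant and the sd
  decays to zero.
* novelty only (beta_T = 0): phi~_t develops two equal-height peaks of
  height 1/(e beta_N) at the solutions of phi(theta) = 1/beta_N; the
  asymmetric widths push the mean up, and orbits converge to a fixed
  point at mean 1/2.  En route the dynamics collapse onto a slow
  manifold where sigma/mu is nearly constant and slightly below 1 while
  the mean grows near-exponentially.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy import optimize, special, stats

from .distributions import (
    BetaParams,
    MomentPair,
    beta_density,
    beta_from_moments,
    beta_mode,
    moments_from_beta,
)
from .errors import (
    IllDefinedSelectionError,
    InvalidParameterError,
    NotBetaRepresentableError,
    NumericalError,
)
from .trajectory import TimeMap, Trajectory, TrajectoryState

__all__ = [
    "SelectionParams",
    "reweighted_density",
    "sce_update",
    "typicality_closed_form",
    "selection_peaks",
    "iterate",
    "ratio_diagnostics",
    "RatioDiagnostics",
]


@dataclass(frozen=True)
class SelectionParams:
    """Typicality (beta_T) and novelty (beta_N) selection coefficients.

    beta_T < -1 puts infinite weight on zero-probability theta and is
    ill-defined.  Negative beta_N and beta_T in (-1, 0) are accepted but
    the analysed (and tested) regime is beta_T, beta_N >= 0.
    """

    beta_T: float
    beta_N: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.beta_T) and np.isfinite(self.beta_N)):
            raise InvalidParameterError("selection coefficients must be finite")
        if self.beta_T <= -1.0:
            raise IllDefinedSelectionError(f"beta_T = {self.beta_T} <= -1 is ill-defined")

    def to_dict(self) -> dict:
        return {"beta_T": self.beta_T, "beta_N": self.beta_N}


def _boundary_exponents(params: BetaParams, sel: SelectionParams) -> tuple[float, float]:
    """Exponents of theta and (1-theta) in the unnormalised phi~."""
    c = 1.0 + sel.beta_T
    return c * (params.a - 1.0), c * (params.b - 1.0)


def _check_integrable(params: BetaParams, sel: SelectionParams) -> tuple[float, float]:
    A, B = _boundary_exponents(params, sel)
    if A <= -1.0 or B <= -1.0:
        raise IllDefinedSelectionError(
            f"reweighted density not integrable: boundary exponents ({A:.3g}, {B:.3g})"
        )
    return A, B


def reweighted_density(params: BetaParams, sel: SelectionParams, theta):
    """Unnormalised selection-reweighted density
    phi(theta)^(1+beta_T) exp(-beta_N phi(theta)).

    Reduces exactly to the beta density when beta_T = beta_N = 0.
    """
    _check_integrable(params, sel)
    phi = beta_density(params, theta)
    return phi ** (1.0 + sel.beta_T) * np.exp(-sel.beta_N * phi)


def typicality_closed_form(params: BetaParams, beta_T: float) -> BetaParams:
    """Exact one-step update under typicality-only selection.

    a' - 1 = (1 + beta_T)(a - 1), b' - 1 = (1 + beta_T)(b - 1).
    The interior mode (a-1)/(a+b-2) is invariant under this map.
    """
    if beta_T <= -1.0:
        raise IllDefinedSelectionError(f"beta_T = {beta_T} <= -1 is ill-defined")
    c = 1.0 + beta_T
    return BetaParams(1.0 + c * (params.a - 1.0), 1.0 + c * (params.b - 1.0))


# ---------------------------------------------------------------------------
# quadrature backends for the general (beta_N != 0) update
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _gl_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    return x, w


@lru_cache(maxsize=8)
def _de_nodes(k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Double-exponential (tanh-sinh) nodes on (0, 1), level k (h = 2^-k).

    Returns (log_theta, log_1m_theta, theta, log_weight); the node
    theta = expit(pi sinh(u)) with logs computed via log_expit so that
    endpoint-singular integrands theta^A (1-theta)^B with A, B > -1 are
    handled without under/overflow.
    """
    h = 2.0 ** (-k)
    m = int(round(6.5 / h))
    u = np.arange(-m, m + 1) * h
    s = 0.5 * np.pi * np.sinh(u)
    log_theta = special.log_expit(2.0 * s)
    log_1m = special.log_expit(-2.0 * s)
    theta = special.expit(2.0 * s)
    # dtheta/du = (pi/4) cosh(u) / cosh(s)^2, all in logs
    log_cosh_s = np.abs(s) + np.log1p(np.exp(-2.0 * np.abs(s))) - np.log(2.0)
    log_w = np.log(np.pi / 4.0) + np.log(np.cosh(u)) - 2.0 * log_cosh_s + np.log(h)
    return log_theta, log_1m, theta, log_w


def _log_phi(params: BetaParams, log_theta, log_1m) -> np.ndarray:
    return (
        (params.a - 1.0) * log_theta
        + (params.b - 1.0) * log_1m
        - special.betaln(params.a, params.b)
    )


def _weighted_moments(theta, log_f):
    """Mean and sd of the density proportional to exp(log_f) at nodes
    whose quadrature log-weights are already folded into log_f."""
    M = np.max(log_f)
    f = np.exp(log_f - M)
    i0 = f.sum()
    m1 = float((f * theta).sum() / i0)
    var = float((f * (theta - m1) ** 2).sum() / i0)
    return m1, var


def _novelty_term(params: BetaParams, sel: SelectionParams, log_theta, log_1m):
    """-beta_N * phi(theta) with the density clipped where it exceeds
    e^300: there the novelty weight underflows to zero anyway, and the
    clip keeps the beta_N = 0 cross-check path free of 0 * inf."""
    if sel.beta_N == 0.0:
        return 0.0
    log_phi = np.minimum(_log_phi(params, log_theta, log_1m), 300.0)
    return -sel.beta_N * np.exp(log_phi)


def _moments_de(params: BetaParams, sel: SelectionParams, A: float, B: float, level: int):
    log_theta, log_1m, theta, log_w = _de_nodes(level)
    log_f = A * log_theta + B * log_1m + _novelty_term(params, sel, log_theta, log_1m) + log_w
    return _weighted_moments(theta, log_f)


def _moments_gl(params: BetaParams, sel: SelectionParams, A: float, B: float, n: int):
    # window containing all but ~1e-18 of the mass of the beta factor
    env = stats.beta(A + 1.0, B + 1.0)
    lo = max(float(env.ppf(1e-18)), 1e-15)
    hi = min(float(env.isf(1e-18)), 1.0 - 1e-15)
    x, w = _gl_nodes(n)
    theta = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    log_theta = np.log(theta)
    log_1m = np.log1p(-theta)
    log_f = (
        A * log_theta + B * log_1m
        + _novelty_term(params, sel, log_theta, log_1m)
        + np.log(w * 0.5 * (hi - lo))
    )
    return _weighted_moments(theta, log_f)


def _reweighted_moments(
    params: BetaParams, sel: SelectionParams, rtol: float = 1e-9
) -> tuple[float, float]:
    """Mean and sd of the normalised phi~ by adaptive quadrature.

    The normalisation constant cancels in the moment ratios.  Peaked
    integrands (both boundary exponents >= 1) use Gauss-Legendre on a
    quantile-truncated window; integrands with an endpoint singularity
    use tanh-sinh nodes.  Convergence is verified by node doubling.
    """
    A, B = _check_integrable(params, sel)
    peaked = A >= 1.0 and B >= 1.0
    if peaked:
        resolutions = (256, 512, 1024, 2048)
        compute = lambda r: _moments_gl(params, sel, A, B, r)  # noqa: E731
    else:
        resolutions = (6, 7, 8, 9)
        compute = lambda r: _moments_de(params, sel, A, B, r)  # noqa: E731
    prev = compute(resolutions[0])
    for r in resolutions[1:]:
        cur = compute(r)
        dm = abs(cur[0] - prev[0]) / max(abs(cur[0]), 1e-300)
        dv = abs(cur[1] - prev[1]) / max(abs(cur[1]), 1e-300)
        if dm < rtol and dv < rtol:
            m1, var = cur
            if var <= 0:
                raise NumericalError("non-positive variance from quadrature")
            return m1, float(np.sqrt(var))
        prev = cur
    raise NumericalError(
        f"quadrature did not converge to rtol={rtol} for (a={params.a:.6g}, "
        f"b={params.b:.6g}, beta_T={sel.beta_T}, beta_N={sel.beta_N})"
    )


def sce_update(
    moments: MomentPair, sel: SelectionParams, *, method: str = "auto", rtol: float = 1e-9
) -> MomentPair:
    """One generation of the SCE map in (mu, sigma) coordinates.

    Parameters
    ----------
    moments : current creator-model mean and sd.
    sel : selection coefficients.
    method : "auto" uses the exact closed form when beta_N = 0 and
        quadrature otherwise; "quadrature" forces the numerical path
        (useful for cross-checking); "closed_form" requires beta_N = 0.
    rtol : relative tolerance of the adaptive quadrature.

    Raises
    ------
    NotBetaRepresentableError
        If the updated moments leave the representable region (reported,
        never silently clipped).
    """
    params = beta_from_moments(moments)
    if method not in ("auto", "quadrature", "closed_form"):
        raise InvalidParameterError(f"unknown method {method!r}")
    if method == "closed_form" and sel.beta_N != 0.0:
        raise InvalidParameterError("closed_form requires beta_N = 0")
    if sel.beta_N == 0.0 and method in ("auto", "closed_form"):
        return moments_from_beta(typicality_closed_form(params, sel.beta_T))
    mu, sigma = _reweighted_moments(params, sel, rtol=rtol)
    return MomentPair(mu, sigma)  # raises NotBetaRepresentableError if degenerate


def selection_peaks(params: BetaParams, beta_N: float) -> tuple[float, ...]:
    """Positions theta-/theta+ of the two peaks of the novelty-only
    reweighted density phi exp(-beta_N phi).

    The peaks solve phi(theta) = 1/beta_N and bracket the beta mode;
    both peaks have height 1/(e beta_N).  Returns an empty tuple when
    max phi < 1/beta_N (no crossing), a single position in the grazing
    case.  Requires a, b > 1 so phi is unimodal with phi(0)=phi(1)=0.
    """
    if beta_N <= 0:
        raise InvalidParameterError("beta_N must be positive")
    mode = beta_mode(params)  # enforces a, b > 1
    target = 1.0 / beta_N
    fmax = float(beta_density(params, mode))
    if fmax < target:
        return ()
    if fmax == target:
        return (mode,)

    def g(t: float) -> float:
        return float(beta_density(params, t)) - target

    def bracket_down(frm: float, toward: float) -> float:
        # walk geometrically toward the boundary until phi < target
        t = frm
        for _ in range(200):
            t = (t + toward) / 2.0
            if g(t) < 0:
                return t
        raise NumericalError("could not bracket selection peak")

    lo = bracket_down(mode, 0.0)
    hi = bracket_down(mode, 1.0)
    left = optimize.brentq(g, lo, mode, xtol=1e-14, rtol=1e-15)
    right = optimize.brentq(g, mode, hi, xtol=1e-14, rtol=1e-15)
    return (float(left), float(right))


def iterate(
    init: MomentPair,
    sel: SelectionParams,
    generations: int,
    *,
    method: str = "auto",
    rtol: float = 1e-9,
    time_map: Optional[TimeMap] = None,
) -> Trajectory:
    """Iterate the SCE map, recording both parameterisations per
    generation.  Halts early with a flagged terminal state if an update
    leaves the beta-representable region."""
    if generations < 1:
        raise InvalidParameterError("generations must be >= 1")
    traj = Trajectory(model="sce", time_map=time_map)
    cur = init
    traj.states.append(TrajectoryState(0, beta_from_moments(cur), cur.mu, cur.sigma))
    for t in range(1, generations + 1):
        try:
            cur = sce_update(cur, sel, method=method, rtol=rtol)
        except (NotBetaRepresentableError, NumericalError, InvalidParameterError) as exc:
            traj.terminated = True
            traj.termination_reason = f"generation {t}: {exc}"
            break
        traj.states.append(TrajectoryState(t, beta_from_moments(cur), cur.mu, cur.sigma))
    return traj


@dataclass
class RatioDiagnostics:
    """Per-generation sigma/mu and mean growth factors, with the longest
    near-constant-ratio run flagged as the slow-manifold plateau."""

    generations: np.ndarray
    ratios: np.ndarray
    growth_factors: np.ndarray  # mu_{t+1} / mu_t, aligned with generations[:-1]
    plateau_start: Optional[int]
    plateau_end: Optional[int]  # inclusive generation indices
    plateau_ratio: Optional[float]


def ratio_diagnostics(traj: Trajectory, plateau_tol: float = 1e-3) -> RatioDiagnostics:
    """Diagnose slow-manifold behaviour of an orbit.

    The plateau is the longest run of consecutive generations where the
    per-generation change of sigma/mu stays below ``plateau_tol``.
    """
    if len(traj) < 2:
        raise InvalidParameterError("trajectory must have at least 2 states")
    gens = traj.generations
    ratios = traj.ratios
    mus = traj.means
    growth = mus[1:] / mus[:-1]
    flat = np.abs(np.diff(ratios)) < plateau_tol
    best_len, best_start = 0, None
    i = 0
    while i < flat.size:
        if flat[i]:
            j = i
            while j < flat.size and flat[j]:
                j += 1
            if j - i > best_len:
                best_len, best_start = j - i, i
            i = j
        else:
            i += 1
    if best_start is None:
        return RatioDiagnostics(gens, ratios, growth, None, None, None)
    start, end = int(gens[best_start]), int(gens[best_start + best_len])
    plateau_ratio = float(np.mean(ratios[best_start : best_start + best_len + 1]))
    return RatioDiagnostics(gens, ratios, growth, start, end, plateau_ratio)
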