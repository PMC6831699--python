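"""The log-potential comparison model.

A scale-invariant Darwinian alternative to the SCE map: the evaluation
function is simply R(theta) = ln(theta) with selection coefficient beta,
and the creator's model is log-normal, which the selection reweighting
leaves within the family.  The dynamics solve in closed form:

    sigma_tilde_{t+1} = sigma_tilde_t
    mu_tilde_{t+1}    = mu_tilde_t + beta sigma_tilde^2

so in (mu, sigma) space the mean grows exactly geometrically with
factor exp(beta sigma_tilde^2) and the ratio sigma/mu is conserved
exactly.  Unlike the SCE slow manifold, the conserved ratio is set by
the initial condition, and the growth rate is very sensitive to beta.

The log-normal treats theta as a frequency only approximately: its
support extends above 1 and no truncation is applied, matching the
closed form.
"""

from __future__ import annotations

from typing import Optional

from .distributions import LogNormalParams, lognormal_moments
from .errors import InvalidParameterError
from .trajectory import TimeMap, Trajectory, TrajectoryState

__all__ = ["logpotential_update", "iterate_logpotential"]


def logpotential_update(params: LogNormalParams, beta: float) -> LogNormalParams:
    """One generation: the log-sd is unchanged and the log-mean shifts
    by beta * sigma_tilde^2."""
    return LogNormalParams(params.mu_tilde + beta * params.sigma_tilde**2, params.sigma_tilde)


def iterate_logpotential(
    init: LogNormalParams,
    beta: float,
    generations: int,
    *,
    time_map: Optional[TimeMap] = None,
) -> Trajectory:
    """Iterate the closed-form map, recording the (mu, sigma) view of
    each generation.  The mean sequence is exactly geometric."""
    if generations < 1:
        raise InvalidParameterError("generations must be >= 1")
    traj = Trajectory(model="log-potential", time_map=time_map)
    cur = init
    m = lognormal_moments(cur)
    traj.states.append(TrajectoryState(0, cur, m.mu, m.sigma))
    for t in range(1, generations + 1):
        cur = logpotential_update(cur, beta)
        m = lognormal_moments(cur)
        traj.states.append(TrajectoryState(t, cur, m.mu, m.sigma))
    return traj
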