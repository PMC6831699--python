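"""Fitting selection coefficients to observed moment trajectories.

Given one or more window series of (mean, sd) of a feature frequency,
the SCE coefficients (beta_T, beta_N) or the log-potential coefficient
beta are chosen to minimise the summed squared error of predicted means
and standard deviations over the whole time span.  Each model is
initialised from the mean and sd at the earliest time of each series,
and iterated one generation per data time step by default.  When
several series are fitted jointly, a single coefficient set must
explain all of them — the discriminating experiment of the approach.

The optimiser is a deterministic coarse grid (log-spaced above 0.1)
followed by Nelder-Mead refinement from the best grid point, which
keeps results reproducible even though the objective can be non-smooth
near the boundary of the beta-representable region (orbits that leave
the region are assigned an infinite objective).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize

from .distributions import (
    LogNormalParams,
    MomentPair,
    lognormal_from_moments,
)
from .errors import FittingError, InvalidParameterError, MusevolError
from .logpotential import iterate_logpotential, logpotential_update
from .sce import SelectionParams, iterate, sce_update
from .trajectory import Trajectory

__all__ = ["FitResult", "objective", "fit", "forecast"]

MODELS = ("sce", "log-potential")


@dataclass
class FitResult:
    """Outcome of a (possibly joint) trajectory fit."""

    model: str
    params: Union[SelectionParams, float]
    objective: float
    per_series_rmse: list[float]
    trajectories: list[Trajectory] = field(default_factory=list)
    generations_per_step: int = 1

    def to_dict(self) -> dict:
        p = self.params.to_dict() if isinstance(self.params, SelectionParams) else {"beta": self.params}
        return {
            "model": self.model,
            "params": p,
            "objective": self.objective,
            "per_series_rmse": self.per_series_rmse,
            "generations_per_step": self.generations_per_step,
        }


def _series_arrays(series: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if "mean" not in series.columns or "sd" not in series.columns:
        raise InvalidParameterError("series must have 'mean' and 'sd' columns")
    s = series.dropna(subset=["mean"]).reset_index(drop=True)
    mu = s["mean"].to_numpy(dtype=float)
    sd = s["sd"].to_numpy(dtype=float)
    if mu.size < 2:
        raise FittingError("series needs at least 2 time points with defined mean")
    if not np.isfinite(sd[0]) or sd[0] <= 0:
        raise FittingError("cannot initialise: sd undefined at the earliest time point")
    return mu, sd


def _model_moments(
    model: str,
    params,
    mu0: float,
    sd0: float,
    n_points: int,
    generations_per_step: int,
) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """Model (mean, sd) at each data point, or None if the orbit leaves
    the representable region before covering the series."""
    mus = np.empty(n_points)
    sds = np.empty(n_points)
    mus[0], sds[0] = mu0, sd0
    if model == "sce":
        try:
            state = MomentPair(mu0, sd0)
        except MusevolError:
            return None
        for k in range(1, n_points):
            try:
                for _ in range(generations_per_step):
                    state = sce_update(state, params)
            except MusevolError:
                return None
            mus[k], sds[k] = state.mu, state.sigma
    else:
        state = lognormal_from_moments(mu0, sd0)
        from .distributions import lognormal_moments

        for k in range(1, n_points):
            for _ in range(generations_per_step):
                state = logpotential_update(state, params)
            m = lognormal_moments(state)
            mus[k], sds[k] = m.mu, m.sigma
    return mus, sds


def objective(
    params,
    model: str,
    series_list: Sequence[pd.DataFrame],
    *,
    generations_per_step: int = 1,
    per_series: bool = False,
):
    """Sum over series and time points of squared mean and sd residuals.

    ``params`` is a :class:`SelectionParams` for the SCE model or a
    scalar beta for the log-potential model.  Time points with missing
    sd contribute only the mean residual.  Returns inf when the SCE
    orbit leaves the representable region within the data span.
    """
    if model not in MODELS:
        raise InvalidParameterError(f"model must be one of {MODELS}")
    totals = []
    for series in series_list:
        mu_d, sd_d = _series_arrays(series)
        out = _model_moments(model, params, mu_d[0], sd_d[0], mu_d.size, generations_per_step)
        if out is None:
            totals.append(np.inf)
            continue
        mu_m, sd_m = out
        res = np.sum((mu_m - mu_d) ** 2)
        ok = np.isfinite(sd_d)
        res += np.sum((sd_m[ok] - sd_d[ok]) ** 2)
        totals.append(float(res))
    if per_series:
        return totals
    return float(sum(totals))


def _grid_positive(n: int, upper: float) -> np.ndarray:
    """n grid values in [0, upper]: 0 then log-spaced from 0.1."""
    return np.concatenate([[0.0], np.geomspace(0.1, upper, n - 1)])


def fit(
    model: str,
    series_list: Sequence[pd.DataFrame],
    *,
    joint: bool = True,
    beta_max: float = 20.0,
    grid: int = 21,
    refine: bool = True,
    generations_per_step: int = 1,
) -> Union[FitResult, list[FitResult]]:
    """Least-squares fit of selection coefficients to window series.

    ``joint=True`` (default) finds one coefficient set for all series;
    ``joint=False`` fits each series separately and returns a list.
    Deterministic given inputs and grid configuration.
    """
    if model not in MODELS:
        raise InvalidParameterError(f"model must be one of {MODELS}")
    if not joint:
        return [
            fit(model, [s], joint=True, beta_max=beta_max, grid=grid, refine=refine,
                generations_per_step=generations_per_step)
            for s in series_list
        ]
    for s in series_list:
        _series_arrays(s)  # validate upfront

    if model == "sce":
        def make(x):
            return SelectionParams(max(0.0, min(x[0], beta_max)), max(0.0, min(x[1], beta_max)))

        vals = _grid_positive(grid, beta_max)
        best, best_x = np.inf, None
        for bt in vals:
            for bn in vals:
                obj = objective(SelectionParams(bt, bn), model, series_list,
                                generations_per_step=generations_per_step)
                if obj < best:
                    best, best_x = obj, (bt, bn)
        x0 = np.array(best_x)
    else:
        def make(x):
            return float(np.clip(x[0], -beta_max, beta_max))

        pos = np.geomspace(0.01, beta_max, grid)
        vals = np.concatenate([-pos[::-1], [0.0], pos])
        best, best_x = np.inf, None
        for b in vals:
            obj = objective(float(b), model, series_list,
                            generations_per_step=generations_per_step)
            if obj < best:
                best, best_x = obj, (b,)
        x0 = np.array(best_x)

    if best_x is None or not np.isfinite(best):
        raise FittingError("optimizer failure: objective not finite at any grid point")

    if refine:
        def f(x):
            return objective(make(x), model, series_list,
                             generations_per_step=generations_per_step)

        res = optimize.minimize(
            f, x0, method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-14, "maxiter": 2000},
        )
        if np.isfinite(res.fun) and res.fun <= best:
            best, params = float(res.fun), make(res.x)
        else:
            params = make(x0)
    else:
        params = make(x0)

    per_obj = objective(params, model, series_list,
                        generations_per_step=generations_per_step, per_series=True)
    rmse, trajs = [], []
    for s, o in zip(series_list, per_obj):
        mu_d, sd_d = _series_arrays(s)
        rmse.append(float(np.sqrt(o / (2.0 * mu_d.size))))
        n_gen = (mu_d.size - 1) * generations_per_step
        if model == "sce":
            trajs.append(iterate(MomentPair(mu_d[0], sd_d[0]), params, max(n_gen, 1)))
        else:
            trajs.append(iterate_logpotential(lognormal_from_moments(mu_d[0], sd_d[0]), params, max(n_gen, 1)))
    return FitResult(model, params, float(best), rmse, trajs, generations_per_step)


def forecast(result: FitResult, horizon: int, *, series_index: int = 0) -> Trajectory:
    """Continue the fitted map beyond the last data point.

    ``horizon`` counts model generations; 0 returns a trajectory holding
    only the last fitted state.
    """
    if horizon < 0:
        raise InvalidParameterError("horizon must be >= 0")
    traj = result.trajectories[series_index]
    last = traj.states[-1]
    if horizon == 0:
        out = Trajectory(model=traj.model, time_map=traj.time_map)
        out.states.append(last)
        return out
    if result.model == "sce":
        out = iterate(MomentPair(last.mu, last.sigma), result.params, horizon)
    else:
        out = iterate_logpotential(last.params, result.params, horizon)
    # re-index generations to continue the fitted trajectory
    from .trajectory import TrajectoryState

    shifted = Trajectory(model=out.model, time_map=traj.time_map,
                         terminated=out.terminated, termination_reason=out.termination_reason)
    for s in out.states:
        shifted.states.append(
            TrajectoryState(s.generation + last.generation, s.params, s.mu, s.sigma)
        )
    return shifted
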