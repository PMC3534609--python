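"""Fitting, validation and prediction pipeline for the weekly weight model.

Ties together the recursion (:mod:`weightdiffusion.diffusion_model`) and
the global optimizer (:mod:`weightdiffusion.scem_optimizer`): fit (α, β)
to an observed window of a weekly series by ISCEM on a sum-of-squares
posterior, then roll the fitted recursion forward over a later window to
predict, with posterior-predictive 95% intervals from the sampler draws.

The fitting posterior is the Box–Tiao noninformative form
p(θ|y) ∝ SSE(θ)^(−N/2); its maximum coincides with the least-squares
estimate, and the sampler draws double as an approximate posterior for
interval construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .diffusion_model import (
    DiffusionParams,
    WeightSeries,
    parse_week,
    r_squared,
    simulate,
    week_label,
)
from .scem_optimizer import (
    BoundsBox,
    IscemResult,
    LogPosterior,
    PosteriorSample,
    ScemConfig,
    iscem,
)

__all__ = [
    "DEFAULT_BOUNDS",
    "FitResult",
    "PredictionResult",
    "sse_log_posterior",
    "fit",
    "predict",
    "per_subject_fit",
]

logger = logging.getLogger(__name__)

#: deliberately over-wide prior box for (α, β); ISCEM shrinks it
DEFAULT_BOUNDS = BoundsBox([1e-6, 1e-6], [1.0, 10.0])


@dataclass(frozen=True)
class FitResult:
    """Point estimate, posterior draws and in-sample fit of one window."""

    params: DiffusionParams
    posterior_draws: list[PosteriorSample]
    fitted_trajectory: np.ndarray
    r2: float
    converged: bool
    objective: str
    mode: Literal["chained", "one_step_ahead"]
    window: tuple[int, int]
    iscem_result: IscemResult | None = None


@dataclass(frozen=True)
class PredictionResult:
    """Out-of-window trajectory with 95% posterior-predictive intervals."""

    predicted_trajectory: np.ndarray
    ci_halfwidth: np.ndarray
    ci_center: np.ndarray
    r2_vs_observed: float
    start_weight_source: Literal["observed_last_fit_week", "fitted_last_fit_week"]
    window: tuple[int, int]


def sse_log_posterior(
    observed: np.ndarray,
    net_intakes: np.ndarray,
    initial_weight: float,
    mode: Literal["chained", "one_step_ahead"] = "chained",
) -> LogPosterior:
    """log p(θ|y) = −(N/2)·log SSE(θ) for θ = (α, β) of the recursion."""
    observed = np.asarray(observed, float)
    net_intakes = np.asarray(net_intakes, float)
    n = len(observed)

    def log_posterior(theta: np.ndarray) -> float:
        alpha, beta = float(theta[0]), float(theta[1])
        if beta < 0:
            return -math.inf
        params = DiffusionParams(alpha=alpha, beta=beta, initial_weight=initial_weight)
        traj = simulate(
            initial_weight, net_intakes, params, mode=mode, observed=observed,
            warn_nonpositive=False,
        )
        sse = float(np.sum((observed - traj) ** 2))
        return -0.5 * n * math.log(max(sse, 1e-300))

    return log_posterior


def _resolve_window(series: WeightSeries, window: tuple[str | int, str | int]) -> tuple[int, int]:
    lo, hi = parse_week(window[0]), parse_week(window[1])
    for wk in (lo, hi):
        if not series.has_week(wk):
            raise ValueError(f"series has no record for week {week_label(wk)}")
    return lo, hi


def fit(
    series: WeightSeries,
    window: tuple[str | int, str | int],
    cfg: ScemConfig | None = None,
    bounds: BoundsBox | None = None,
    mode: Literal["chained", "one_step_ahead"] = "chained",
    epsilon: float = 1e-6,
) -> FitResult:
    """Fit (α, β) to ``series`` over a closed week window by ISCEM.

    The week preceding the window must be present in the series; its
    observed weight is the recursion's initial condition b.  Posterior
    draws are taken from the first (widest-box) SCEM-UA run, before the
    box refinement truncates the posterior.
    """
    cfg = cfg or ScemConfig()
    bounds = bounds or DEFAULT_BOUNDS
    lo, hi = _resolve_window(series, window)
    start_week = lo - 1
    if not series.has_week(start_week):
        raise ValueError(
            f"fitting window starts at {week_label(lo)} but the series has no "
            f"week {week_label(start_week)} record to supply the initial weight"
        )
    initial_weight = series.record_at(start_week).body_weight
    sub = series.window(lo, hi)
    observed = sub.weights
    nets = sub.net_intakes
    log_post = sse_log_posterior(observed, nets, initial_weight, mode=mode)
    result = iscem(log_post, bounds, cfg, epsilon=epsilon)
    alpha, beta = result.best.theta
    params = DiffusionParams(alpha=float(alpha), beta=float(beta), initial_weight=initial_weight)
    trajectory = simulate(initial_weight, nets, params, mode=mode, observed=observed)
    return FitResult(
        params=params,
        posterior_draws=result.runs[0].samples,
        fitted_trajectory=trajectory,
        r2=r_squared(observed, trajectory),
        converged=result.converged,
        objective="sse_boxtiao",
        mode=mode,
        window=(lo, hi),
        iscem_result=result,
    )


def predict(
    fit_result: FitResult,
    series: WeightSeries,
    window: tuple[str | int, str | int],
    start_weight_source: Literal[
        "observed_last_fit_week", "fitted_last_fit_week"
    ] = "observed_last_fit_week",
    ci_level: float = 0.95,
) -> PredictionResult:
    """Chained forecast over a window immediately following the fit window.

    The 95% band is the percentile envelope of chained trajectories
    simulated from the posterior draws (no observation-noise term),
    reported as center ± half-width.
    """
    lo, hi = _resolve_window(series, window)
    fit_lo, fit_hi = fit_result.window
    if lo != fit_hi + 1:
        raise ValueError(
            f"prediction window must start at {week_label(fit_hi + 1)}, immediately "
            f"after the fitted window {week_label(fit_lo)}:{week_label(fit_hi)}; "
            f"got {week_label(lo)}"
        )
    if start_weight_source == "observed_last_fit_week":
        start = series.record_at(fit_hi).body_weight
    elif start_weight_source == "fitted_last_fit_week":
        start = float(fit_result.fitted_trajectory[-1])
    else:
        raise ValueError(f"unknown start_weight_source {start_weight_source!r}")
    sub = series.window(lo, hi)
    nets = sub.net_intakes
    observed = sub.weights
    point = simulate(start, nets, fit_result.params, mode="chained")
    if fit_result.posterior_draws:
        trajs = np.array(
            [
                simulate(
                    start,
                    nets,
                    DiffusionParams(float(d.theta[0]), float(d.theta[1]), start),
                    mode="chained",
                )
                for d in fit_result.posterior_draws
            ]
        )
        tail = 100.0 * (1.0 - ci_level) / 2.0
        lo_env = np.percentile(trajs, tail, axis=0)
        hi_env = np.percentile(trajs, 100.0 - tail, axis=0)
    else:
        lo_env = hi_env = point
    return PredictionResult(
        predicted_trajectory=point,
        ci_halfwidth=(hi_env - lo_env) / 2.0,
        ci_center=(hi_env + lo_env) / 2.0,
        r2_vs_observed=r_squared(observed, point),
        start_weight_source=start_weight_source,
        window=(lo, hi),
    )


def backsolve_initial_weight(
    first_observed: float, first_net_intake: float, params: DiffusionParams
) -> float:
    """Invert one recursion step: f(0) = (f(1) − 7αl(1)·(1−e)) / e."""
    e = params.persistence
    if e == 0:
        raise ValueError("cannot back-solve the initial weight when erf(beta) = 0")
    from .diffusion_model import DAYS_PER_WEEK

    return (first_observed - params.alpha * DAYS_PER_WEEK * first_net_intake * (1 - e)) / e


def per_subject_fit(
    subject_weights: np.ndarray,
    group_net_intakes: np.ndarray,
    params: DiffusionParams | None = None,
    cfg: ScemConfig | None = None,
    bounds: BoundsBox | None = None,
    initial_weight_policy: Literal["backsolve"] | float = "backsolve",
) -> FitResult:
    """Apply or fit the recursion for one subject's observed S1–S24 weights.

    Subject baseline (week-0) weights are not published, so by default the
    initial weight is back-solved from the subject's first observed week.
    With ``params`` given, the group constants are applied directly; with
    ``cfg`` given, (α, β) are re-fitted to the subject, the back-solved
    start being recomputed for each candidate θ.
    """
    obs = np.asarray(subject_weights, float)
    nets = np.asarray(group_net_intakes, float)
    if len(obs) != len(nets):
        raise ValueError(f"{len(obs)} weights vs {len(nets)} net intakes")
    window = (1, len(obs))

    def start_for(p: DiffusionParams) -> float:
        if initial_weight_policy == "backsolve":
            return backsolve_initial_weight(obs[0], nets[0], p)
        return float(initial_weight_policy)

    if params is not None:
        f0 = start_for(params)
        traj = simulate(f0, nets, params, mode="chained")
        return FitResult(
            params=DiffusionParams(params.alpha, params.beta, f0),
            posterior_draws=[],
            fitted_trajectory=traj,
            r2=r_squared(obs, traj),
            converged=True,
            objective="applied_group_params",
            mode="chained",
            window=window,
        )

    cfg = cfg or ScemConfig()
    bounds = bounds or DEFAULT_BOUNDS
    n = len(obs)

    def log_post(theta: np.ndarray) -> float:
        alpha, beta = float(theta[0]), float(theta[1])
        if beta <= 0:
            return -math.inf
        p = DiffusionParams(alpha, beta, 1.0)
        try:
            f0 = start_for(p)
        except ValueError:
            return -math.inf
        if f0 <= 0:
            return -math.inf
        traj = simulate(f0, nets, p, mode="chained", warn_nonpositive=False)
        sse = float(np.sum((obs - traj) ** 2))
        return -0.5 * n * math.log(max(sse, 1e-300))

    result = iscem(log_post, bounds, cfg)
    alpha, beta = (float(v) for v in result.best.theta)
    p = DiffusionParams(alpha, beta, 1.0)
    f0 = start_for(p)
    p = DiffusionParams(alpha, beta, f0)
    traj = simulate(f0, nets, p, mode="chained")
    return FitResult(
        params=p,
        posterior_draws=result.runs[0].samples,
        fitted_trajectory=traj,
        r2=r_squared(obs, traj),
        converged=result.converged,
        objective="sse_boxtiao_backsolved_start",
        mode="chained",
        window=window,
        iscem_result=result,
    )
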