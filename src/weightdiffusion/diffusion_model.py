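"""Diffusion-equation model of body-weight change.

Body mass is treated as a quantity redistributed by a one-dimensional
diffusion process whose boundary condition is set by net energy intake.
The closed-form solution of the diffusion PDE ∂V/∂t = D ∂²V/∂x² with a
constant-source boundary is an error-function blend of the initial mass
``V0`` and the steady mass ``E/p`` supplied by intake.  Collapsing the
spatial coordinate to a constant yields a weekly recursion

    f(t) = f(t-1)·erf(β) + α·7·l(t)·[1 − erf(β)]

where ``f(t)`` is body weight (kg) at week ``t``, ``l(t)`` the daily net
energy intake (kcal/day) during that week, ``erf(β)`` the weekly weight
persistence and ``7·α·l`` the steady-state weight a constant intake would
sustain.  The factor 7 converts daily intake to a weekly energy dose.

This module houses the continuous solution, the weekly recursion, the
trajectory simulator and goodness-of-fit measures.  Parameter estimation
lives in :mod:`weightdiffusion.scem_optimizer` / :mod:`weightdiffusion.fit_predict`.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np

__all__ = [
    "DAYS_PER_WEEK",
    "ContinuousDiffusionInput",
    "DiffusionParams",
    "EnergyBalanceRecord",
    "WeightSeries",
    "continuous_weight",
    "step",
    "simulate",
    "r_squared",
    "steady_state",
    "parse_week",
    "week_label",
]

logger = logging.getLogger(__name__)

DAYS_PER_WEEK = 7

#: printed-rounding tolerance for net = intake − TEE bookkeeping (kcal/day)
NET_INTAKE_TOL = 0.02

_WEEK_RE = re.compile(r"^(?:0|S(\d+))$")


def parse_week(token: str | int) -> int:
    """Map a week token (``0`` or ``"S<k>"``) to its integer index."""
    if isinstance(token, int):
        if token < 0:
            raise ValueError(f"week index must be >= 0, got {token}")
        return token
    m = _WEEK_RE.match(token.strip())
    if not m:
        raise ValueError(f"unparseable week token {token!r} (expected '0' or 'S<k>')")
    return int(m.group(1)) if m.group(1) else 0


def week_label(index: int) -> str:
    """Inverse of :func:`parse_week`: 0 -> ``"0"``, k -> ``"S<k>"``."""
    return "0" if index == 0 else f"S{index}"


@dataclass(frozen=True)
class ContinuousDiffusionInput:
    """Inputs of the continuous error-function solution.

    Attributes
    ----------
    initial_mass:
        V0, body mass at t = 0 (kg).
    net_energy:
        E, net energy available for mass conversion (kcal).
    fat_energy_density:
        p, energy density of fat mass (kcal/kg); E/p is the steady mass.
    diffusion_coefficient:
        D, in length²/time units consistent with ``distance`` and ``time``.
    distance:
        x ≥ 0, depth into the medium.
    time:
        t > 0, elapsed time.
    """

    initial_mass: float
    net_energy: float
    fat_energy_density: float
    diffusion_coefficient: float
    distance: float
    time: float

    def __post_init__(self) -> None:
        if not self.fat_energy_density > 0:
            raise ValueError("fat_energy_density must be > 0")
        if not self.diffusion_coefficient > 0:
            raise ValueError("diffusion_coefficient must be > 0")
        if not self.time > 0:
            raise ValueError("time must be > 0")
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


def continuous_weight(c: ContinuousDiffusionInput) -> float:
    """Evaluate V(x, t) = (E/p)·[1 − erf(x/(2√(Dt)))] + V0·erf(x/(2√(Dt))).

    The result is a convex combination of the initial mass V0 and the
    steady mass E/p: at x = 0 the boundary value E/p is returned, and for
    x > 0 the solution relaxes from V0 (t → 0) towards E/p (t → ∞).
    """
    steady = c.net_energy / c.fat_energy_density
    arg = c.distance / (2.0 * math.sqrt(c.diffusion_coefficient * c.time))
    w = math.erf(arg)
    return steady * (1.0 - w) + c.initial_mass * w


@dataclass(frozen=True)
class DiffusionParams:
    """Fitted constants of the weekly recursion.

    ``alpha`` (kg per kcal/day, via the ×7 weekly dose) scales net intake
    into steady-state weight, ``beta`` sets the persistence erf(β), and
    ``initial_weight`` is the week-0 weight b (kg).
    """

    alpha: float
    beta: float
    initial_weight: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.alpha):
            raise ValueError("alpha must be finite")
        if not self.beta >= 0:
            raise ValueError("beta must be >= 0")
        if not self.initial_weight > 0:
            raise ValueError("initial_weight must be > 0")

    @property
    def persistence(self) -> float:
        """erf(β), the fraction of last week's weight carried over."""
        return math.erf(self.beta)


@dataclass(frozen=True)
class EnergyBalanceRecord:
    """One week's observed weight and energy-balance numbers."""

    week_index: int
    week_label: str
    body_weight: float
    tee: float
    mean_intake: float
    net_intake: float

    def __post_init__(self) -> None:
        if self.week_index < 0:
            raise ValueError("week_index must be >= 0")
        if not self.body_weight > 0:
            raise ValueError("body_weight must be > 0")
        imbalance = abs(self.net_intake - (self.mean_intake - self.tee))
        if imbalance > NET_INTAKE_TOL + 1e-9:
            raise ValueError(
                f"week {self.week_label}: net_intake {self.net_intake} differs from "
                f"intake - TEE = {self.mean_intake - self.tee:.2f} by {imbalance:.3f} "
                f"(> {NET_INTAKE_TOL} kcal/day)"
            )


@dataclass(frozen=True)
class WeightSeries:
    """Ordered weekly series of :class:`EnergyBalanceRecord`."""

    records: tuple[EnergyBalanceRecord, ...]

    def __init__(self, records: Iterable[EnergyBalanceRecord]) -> None:
        recs = tuple(records)
        for prev, cur in zip(recs, recs[1:]):
            if cur.week_index <= prev.week_index:
                raise ValueError(
                    f"week indices must strictly increase: {prev.week_label} -> {cur.week_label}"
                )
        object.__setattr__(self, "records", recs)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EnergyBalanceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> EnergyBalanceRecord:
        return self.records[i]

    @property
    def week_indices(self) -> np.ndarray:
        return np.array([r.week_index for r in self.records])

    @property
    def weights(self) -> np.ndarray:
        return np.array([r.body_weight for r in self.records])

    @property
    def net_intakes(self) -> np.ndarray:
        return np.array([r.net_intake for r in self.records])

    def record_at(self, week: str | int) -> EnergyBalanceRecord:
        idx = parse_week(week)
        for r in self.records:
            if r.week_index == idx:
                return r
        raise KeyError(f"no record for week {week_label(idx)}")

    def has_week(self, week: str | int) -> bool:
        idx = parse_week(week)
        return any(r.week_index == idx for r in self.records)

    def window(self, start: str | int, stop: str | int) -> "WeightSeries":
        """Closed sub-series from week ``start`` through week ``stop``."""
        lo, hi = parse_week(start), parse_week(stop)
        if lo > hi:
            raise ValueError(f"empty window {week_label(lo)}:{week_label(hi)}")
        sub = [r for r in self.records if lo <= r.week_index <= hi]
        if not sub:
            raise ValueError(f"window {week_label(lo)}:{week_label(hi)} selects no records")
        return WeightSeries(sub)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "week": [r.week_label for r in self.records],
                "body_weight_kg": [r.body_weight for r in self.records],
                "tee_kcal_day": [r.tee for r in self.records],
                "intake_kcal_day": [r.mean_intake for r in self.records],
                "net_intake_kcal_day": [r.net_intake for r in self.records],
            }
        )


def step(prev_weight: float, net_intake: float, params: DiffusionParams) -> float:
    """One week of the recursion: erf(β)·prev + 7·α·l·(1 − erf(β)).

    Linear in both ``prev_weight`` and ``net_intake``.
    """
    e = params.persistence
    return prev_weight * e + params.alpha * DAYS_PER_WEEK * net_intake * (1.0 - e)


def simulate(
    initial_weight: float,
    net_intakes: Sequence[float],
    params: DiffusionParams,
    mode: Literal["chained", "one_step_ahead"] = "chained",
    observed: WeightSeries | Sequence[float] | None = None,
    warn_nonpositive: bool = True,
) -> np.ndarray:
    """Run the weekly recursion over a net-intake schedule.

    ``chained`` feeds each prediction back as the next week's previous
    weight (pure model rollout); ``one_step_ahead`` conditions each week on
    the *observed* previous weight and therefore needs ``observed`` weights
    aligned with ``net_intakes``.
    """
    nets = np.asarray(net_intakes, dtype=float)
    e = params.persistence
    gain = params.alpha * DAYS_PER_WEEK * (1.0 - e)
    if mode == "chained":
        out = np.empty(len(nets))
        f = float(initial_weight)
        for i, l in enumerate(nets):
            f = f * e + gain * l
            out[i] = f
    elif mode == "one_step_ahead":
        if observed is None:
            raise ValueError("one_step_ahead mode requires the observed weight series")
        obs = observed.weights if isinstance(observed, WeightSeries) else np.asarray(observed, float)
        if len(obs) != len(nets):
            raise ValueError(
                f"observed length {len(obs)} does not match {len(nets)} net intakes"
            )
        prev = np.concatenate([[initial_weight], obs[:-1]])
        out = prev * e + gain * nets
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if warn_nonpositive and np.any(out <= 0):
        logger.warning(
            "simulated trajectory reaches non-positive weight (min %.3f kg); "
            "the recursion is not clamped", out.min()
        )
    return out


def r_squared(
    observed: Sequence[float],
    predicted: Sequence[float],
    kind: Literal["determination", "correlation"] = "determination",
) -> float:
    """Goodness of fit between observed and predicted weights.

    ``determination`` is the coefficient of determination 1 − SSE/SST with
    SST about the observed mean (can be negative for a bad model);
    ``correlation`` is the squared Pearson correlation, which is invariant
    to affine rescaling of the prediction and always in [0, 1].
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError(f"length mismatch: observed {o.shape}, predicted {p.shape}")
    if len(o) < 2:
        raise ValueError("need at least 2 points")
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("observed values are all identical; R^2 undefined")
    if kind == "determination":
        return 1.0 - float(np.sum((o - p) ** 2)) / sst
    if kind == "correlation":
        if np.all(p == p[0]):
            raise ValueError("predicted values are all identical; correlation undefined")
        return float(np.corrcoef(o, p)[0, 1] ** 2)
    raise ValueError(f"unknown kind {kind!r}")


def steady_state(params: DiffusionParams, net_intake: float) -> float:
    """Fixed point of :func:`step` under constant intake: 7·α·l.

    For β > 0 the chained recursion converges geometrically to this value
    at rate erf(β) per week; at β = 0 every weight maps onto it in one step.
    """
    return params.alpha * DAYS_PER_WEEK * net_intake
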