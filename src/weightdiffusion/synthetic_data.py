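"""Synthetic weekly weight series with the model's own generative structure.

The generator runs the deterministic weekly recursion from known "true"
constants under a configurable net-intake schedule and adds independent
Gaussian observation noise to the weekly weights.  The latent recursion
itself is noise-free, matching the residual structure assumed by the
sum-of-squares fitting objective, so generated series are the right
testbed for parameter-recovery and interval-calibration experiments.

Schedules: a constant daily net intake, a linear ramp, or a
``minnesota_like`` profile that piecewise-linearly interpolates the
packaged group's S1–S24 net-intake column (a realistic covariate pattern:
a deep initial deficit relaxing into a growing surplus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .diffusion_model import (
    DiffusionParams,
    EnergyBalanceRecord,
    WeightSeries,
    simulate,
    week_label,
)

__all__ = ["IntakeSchedule", "SyntheticSpec", "generate"]


@dataclass(frozen=True)
class IntakeSchedule:
    """Net-intake schedule: ``constant``, ``linear_ramp`` or ``minnesota_like``."""

    kind: Literal["constant", "linear_ramp", "minnesota_like"]
    level: float = 0.0  # constant: kcal/day
    start: float = 0.0  # linear_ramp endpoints, kcal/day
    stop: float = 0.0

    @classmethod
    def constant(cls, level: float) -> "IntakeSchedule":
        return cls("constant", level=level)

    @classmethod
    def linear_ramp(cls, start: float, stop: float) -> "IntakeSchedule":
        return cls("linear_ramp", start=start, stop=stop)

    @classmethod
    def minnesota_like(cls) -> "IntakeSchedule":
        return cls("minnesota_like")

    def values(self, weeks: int) -> np.ndarray:
        if self.kind == "constant":
            return np.full(weeks, self.level)
        if self.kind == "linear_ramp":
            return np.linspace(self.start, self.stop, weeks)
        if self.kind == "minnesota_like":
            from .datasets_io import load_group_series

            group = load_group_series().window(1, 24)
            src_weeks = group.week_indices.astype(float)
            targets = np.linspace(src_weeks[0], src_weeks[-1], weeks)
            return np.interp(targets, src_weeks, group.net_intakes)
        raise ValueError(f"unknown schedule kind {self.kind!r}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth and noise level for one synthetic series."""

    true_params: DiffusionParams
    weeks: int = 24
    intake_schedule: IntakeSchedule = field(
        default_factory=IntakeSchedule.minnesota_like
    )
    noise_sd: float = 0.0  # kg, additive Gaussian on observed weekly weight
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weeks < 2:
            raise ValueError("weeks must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate(spec: SyntheticSpec) -> tuple[WeightSeries, np.ndarray]:
    """Generate an observed series and its latent noise-free trajectory.

    The returned series has a week-0 record holding the exact initial
    weight (the known initial condition) followed by ``weeks`` records
    whose observed weight is latent + N(0, noise_sd²).  Intake columns are
    bookkept with TEE = 0 so that net = intake − TEE holds exactly.
    """
    rng = np.random.default_rng(spec.seed)
    nets = spec.intake_schedule.values(spec.weeks)
    latent = simulate(spec.true_params.initial_weight, nets, spec.true_params, mode="chained")
    observed = latent + rng.normal(0.0, spec.noise_sd, size=spec.weeks)
    records = [
        EnergyBalanceRecord(
            week_index=0,
            week_label="0",
            body_weight=spec.true_params.initial_weight,
            tee=0.0,
            mean_intake=0.0,
            net_intake=0.0,
        )
    ]
    for i in range(spec.weeks):
        records.append(
            EnergyBalanceRecord(
                week_index=i + 1,
                week_label=week_label(i + 1),
                body_weight=float(observed[i]),
                tee=0.0,
                mean_intake=float(nets[i]),
                net_intake=float(nets[i]),
            )
        )
    return WeightSeries(records), latent
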