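"""Shuffled Complex Evolution Metropolis (SCEM-UA) global optimizer.

SCEM-UA is a population MCMC scheme for calibrating nonlinear models: draw
``s`` points from a uniform prior box, rank them by posterior density,
deal them into ``q`` interleaved complexes, evolve each complex with a
Metropolis sampler seeded from the ranked population, then reshuffle and
repeat until the Gelman–Rubin potential-scale-reduction statistic of the
parallel sequences drops below a threshold.

The iterative wrapper (ISCEM) reruns SCEM-UA while shrinking the search
box around each run's best point, which removes the sensitivity of the
plain algorithm to an over-wide initial box: after the first run the upper
bound collapses onto the incumbent optimum, and subsequent runs bisect the
remaining box until successive best densities agree to a tolerance.

The inner Metropolis move ("SEM") is the standard variant: a Gaussian
proposal centred on the sequence's current point with covariance
``c_n²·Σ`` from the complex's sample covariance, re-centred on the
complex's best point whenever the sequence has drifted more than a factor
``T`` below the complex's mean density, with the proposal covariance
halved whenever the rolling acceptance rate falls below ``AR_min``.
Out-of-box proposals get density −∞ and are rejected, which keeps the
chain stationary with respect to the boxed posterior.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "ScemConfig",
    "BoundsBox",
    "PosteriorSample",
    "SamplerState",
    "ScemResult",
    "IscemResult",
    "LogPosterior",
    "initialize_population",
    "partition_complexes",
    "evolve_complex",
    "gelman_rubin",
    "scem_ua",
    "iscem",
]

logger = logging.getLogger(__name__)

#: log-density functional p(θ|y); may return -inf outside the support
LogPosterior = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class ScemConfig:
    """Sampler controls.

    ``population_size`` (s) must be a multiple of ``n_complexes`` (q) and
    at least 2q.  ``inner_iterations`` (L) defaults to m = s/q Metropolis
    steps per complex per shuffle; ``jump_rate`` (c_n) defaults to the
    Gaussian-optimal 2.4/√n.  ``density_ratio_threshold`` (T) and
    ``min_acceptance`` (AR_min) govern proposal re-centring and variance
    shrinking in the inner sampler.
    """

    population_size: int = 200
    n_complexes: int = 10
    inner_iterations: int | None = None
    density_ratio_threshold: float = 1e6
    min_acceptance: float = 0.1
    jump_rate: float | None = None
    gr_threshold: float = 1.2
    max_shuffles: int = 50
    min_shuffles: int = 15
    burn_in_fraction: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        s, q = self.population_size, self.n_complexes
        if q < 1 or s < 2 * q:
            raise ValueError(f"need population_size >= 2*n_complexes, got s={s}, q={q}")
        if s % q != 0:
            raise ValueError(f"population_size {s} not divisible by n_complexes {q}")
        if self.inner_iterations is not None and self.inner_iterations < 1:
            raise ValueError("inner_iterations must be >= 1")
        if not 0 < self.min_acceptance < 1:
            raise ValueError("min_acceptance must be in (0, 1)")
        if not 0 <= self.min_shuffles <= self.max_shuffles:
            raise ValueError("need 0 <= min_shuffles <= max_shuffles")
        if not self.gr_threshold > 1:
            raise ValueError("gr_threshold must be > 1")
        if not 0 <= self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must be in [0, 1)")

    @property
    def points_per_complex(self) -> int:
        return self.population_size // self.n_complexes

    def resolved_inner_iterations(self) -> int:
        return self.inner_iterations if self.inner_iterations is not None else self.points_per_complex

    def resolved_jump_rate(self, n_params: int) -> float:
        return self.jump_rate if self.jump_rate is not None else 2.4 / math.sqrt(n_params)


@dataclass(frozen=True)
class BoundsBox:
    """Axis-aligned parameter box, lower < upper elementwise."""

    lower: np.ndarray
    upper: np.ndarray

    def __init__(self, lower: Sequence[float], upper: Sequence[float]) -> None:
        lo = np.asarray(lower, dtype=float)
        hi = np.asarray(upper, dtype=float)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("lower and upper must be 1-D and of equal length")
        if not np.all(lo < hi):
            raise ValueError(f"need lower < upper elementwise, got {lo} vs {hi}")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def n_params(self) -> int:
        return len(self.lower)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, theta: np.ndarray) -> bool:
        return bool(np.all(theta >= self.lower) and np.all(theta <= self.upper))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(size, self.n_params))


@dataclass(frozen=True)
class PosteriorSample:
    theta: np.ndarray
    log_density: float


@dataclass
class SamplerState:
    """Ranked population plus the parallel sequences.

    ``points``/``log_densities`` hold the array D sorted by decreasing
    density (row 0 is the incumbent best).  ``sequences`` are the q
    Metropolis chains S¹…S^q; ``proposal_scales`` carry each sequence's
    accumulated AR_min variance shrinkage across shuffles.
    """

    points: np.ndarray
    log_densities: np.ndarray
    sequences: list[list[PosteriorSample]]
    proposal_scales: list[float]
    shuffles: int = 0


def _safe_log_density(log_posterior: LogPosterior, theta: np.ndarray) -> float:
    lp = float(log_posterior(theta))
    if math.isnan(lp):
        logger.warning("posterior returned NaN at %s; treating as -inf", theta)
        return -math.inf
    return lp


def _rank(points: np.ndarray, logps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # stable sort so equal densities keep draw order
    order = np.argsort(-logps, kind="stable")
    return points[order], logps[order]


def initialize_population(
    bounds: BoundsBox,
    cfg: ScemConfig,
    log_posterior: LogPosterior,
    rng: np.random.Generator,
) -> SamplerState:
    """Draw s uniform points, evaluate, rank, and seed the q sequences."""
    pts = bounds.sample(rng, cfg.population_size)
    logps = np.array([_safe_log_density(log_posterior, p) for p in pts])
    pts, logps = _rank(pts, logps)
    sequences = [
        [PosteriorSample(pts[k].copy(), float(logps[k]))] for k in range(cfg.n_complexes)
    ]
    return SamplerState(
        points=pts,
        log_densities=logps,
        sequences=sequences,
        proposal_scales=[1.0] * cfg.n_complexes,
    )


def partition_complexes(population_size: int, q: int) -> list[np.ndarray]:
    """Interleaved rank partition: complex k gets ranks {q(j−1)+k : j=1…m}.

    Returned indices are 0-based rows into the density-ranked array D, so
    complex 0 holds ranks 0, q, 2q, …  (the 1-based ranks 1, q+1, …).
    """
    if population_size % q != 0:
        raise ValueError(f"population size {population_size} not divisible by q={q}")
    return [np.arange(k, population_size, q) for k in range(q)]


def _proposal_cholesky(
    points: np.ndarray, scale: float, jump_rate: float, bounds: BoundsBox
) -> np.ndarray:
    cov = np.atleast_2d(np.cov(points.T))
    # ridge keeps the proposal non-degenerate when the complex collapses
    ridge = np.diag((1e-8 * bounds.width) ** 2) + 1e-300 * np.eye(bounds.n_params)
    cov = (jump_rate * scale) ** 2 * cov + ridge
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return np.diag(np.sqrt(np.diag(cov)))


def evolve_complex(
    points: np.ndarray,
    log_densities: np.ndarray,
    sequence: list[PosteriorSample],
    proposal_scale: float,
    cfg: ScemConfig,
    log_posterior: LogPosterior,
    bounds: BoundsBox,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[PosteriorSample], float]:
    """Run L Metropolis steps of one sequence against its complex.

    Accepted candidates are appended to the sequence and replace the
    complex's worst member when they improve on it, so the complex's best
    density is non-decreasing.  Returns the updated complex, sequence and
    proposal scale (halved if the acceptance rate fell below AR_min).
    """
    points = points.copy()
    log_densities = log_densities.copy()
    L = cfg.resolved_inner_iterations()
    jump = cfg.resolved_jump_rate(bounds.n_params)
    m = len(points)
    chol = _proposal_cholesky(points, proposal_scale, jump, bounds)
    log_T = math.log(cfg.density_ratio_threshold)
    accepted = 0
    for _ in range(L):
        current = sequence[-1]
        finite = np.isfinite(log_densities)
        log_mean = logsumexp(log_densities[finite]) - math.log(m) if finite.any() else -math.inf
        drifted = (
            not math.isfinite(current.log_density)
            or (math.isfinite(log_mean) and log_mean - current.log_density > log_T)
        )
        center = points[int(np.argmax(log_densities))] if drifted else current.theta
        candidate = center + chol @ rng.standard_normal(bounds.n_params)
        if bounds.contains(candidate):
            cand_lp = _safe_log_density(log_posterior, candidate)
        else:
            cand_lp = -math.inf
        if math.isinf(cand_lp) and cand_lp < 0:
            accept = False
        elif cand_lp >= current.log_density:
            accept = True
        else:
            accept = math.log(rng.uniform()) < cand_lp - current.log_density
        if accept:
            accepted += 1
            sequence.append(PosteriorSample(candidate.copy(), cand_lp))
            worst = int(np.argmin(log_densities))
            if cand_lp > log_densities[worst]:
                points[worst] = candidate
                log_densities[worst] = cand_lp
        else:
            sequence.append(current)
    rate = accepted / L
    if rate < cfg.min_acceptance:
        proposal_scale *= 0.5
        logger.debug(
            "acceptance %.2f < AR_min %.2f: halving proposal scale to %.3g",
            rate, cfg.min_acceptance, proposal_scale,
        )
    elif rate > 0.6 and proposal_scale < 1.0:
        # symmetric recovery keeps chains mobile once the complex has
        # adapted; without it noise-triggered halvings accumulate and
        # freeze the sequence
        proposal_scale = min(1.0, proposal_scale * 2.0)
    return points, log_densities, sequence, proposal_scale


def gelman_rubin(
    sequences: Sequence[Sequence[PosteriorSample]] | np.ndarray,
    burn_in_fraction: float = 0.0,
) -> np.ndarray:
    """Per-parameter potential scale reduction √[(n−1)/n + B/(nW)].

    ``sequences`` is either q chains of :class:`PosteriorSample` or an
    array of shape (q, n_draws, n_params).  When all chains are constant
    and identical (W = B = 0) the statistic is defined as 1.
    """
    if isinstance(sequences, np.ndarray):
        chains = sequences.astype(float)
    else:
        chains = np.array(
            [[np.atleast_1d(s.theta) for s in seq] for seq in sequences], dtype=float
        )
    if chains.ndim == 2:  # scalar parameter chains
        chains = chains[:, :, None]
    q, n_total, _ = chains.shape
    if q < 2:
        raise ValueError("need at least 2 chains")
    start = int(burn_in_fraction * n_total)
    chains = chains[:, start:, :]
    n = chains.shape[1]
    if n < 2:
        raise ValueError("need at least 2 post-burn-in draws per chain")
    within = chains.var(axis=1, ddof=1).mean(axis=0)          # W
    between_over_n = chains.mean(axis=1).var(axis=0, ddof=1)  # B/n
    rhat = np.empty_like(within)
    for i, (w, b_n) in enumerate(zip(within, between_over_n)):
        if w == 0.0:
            if b_n == 0.0:
                logger.debug("parameter %d: all chains constant and equal; R-hat := 1", i)
                rhat[i] = 1.0
            else:
                rhat[i] = math.inf
        else:
            rhat[i] = math.sqrt((n - 1) / n + b_n / w)
    return rhat


@dataclass(frozen=True)
class ScemResult:
    best: PosteriorSample
    samples: list[PosteriorSample]
    converged: bool
    rhat_trace: list[np.ndarray]
    n_shuffles: int


def scem_ua(
    log_posterior: LogPosterior,
    bounds: BoundsBox,
    cfg: ScemConfig,
    rng: np.random.Generator | None = None,
) -> ScemResult:
    """One SCEM-UA run: shuffle → evolve → re-rank until R̂ < threshold.

    Returns the best sample seen anywhere (population or chains), the
    post-burn-in chain samples, the convergence flag and the R̂ trace.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    state = initialize_population(bounds, cfg, log_posterior, rng)
    ibest = int(np.argmax(state.log_densities))
    best = PosteriorSample(state.points[ibest].copy(), float(state.log_densities[ibest]))
    rhat_trace: list[np.ndarray] = []
    converged = False
    shuffle = 0
    for shuffle in range(1, cfg.max_shuffles + 1):
        complexes = partition_complexes(cfg.population_size, cfg.n_complexes)
        for k, idx in enumerate(complexes):
            pts, lps, seq, scale = evolve_complex(
                state.points[idx],
                state.log_densities[idx],
                state.sequences[k],
                state.proposal_scales[k],
                cfg,
                log_posterior,
                bounds,
                rng,
            )
            state.points[idx] = pts
            state.log_densities[idx] = lps
            state.sequences[k] = seq
            state.proposal_scales[k] = scale
            tail = seq[-1]
            if tail.log_density > best.log_density:
                best = tail
            kbest = int(np.argmax(lps))
            if lps[kbest] > best.log_density:
                best = PosteriorSample(pts[kbest].copy(), float(lps[kbest]))
        state.points, state.log_densities = _rank(state.points, state.log_densities)
        state.shuffles = shuffle
        n_draws = len(state.sequences[0])
        if shuffle >= cfg.min_shuffles and n_draws - int(cfg.burn_in_fraction * n_draws) >= 2:
            rhat = gelman_rubin(state.sequences, cfg.burn_in_fraction)
            rhat_trace.append(rhat)
            if np.all(rhat < cfg.gr_threshold):
                converged = True
                break
    if not converged:
        logger.warning(
            "SCEM-UA did not reach R-hat < %.3g within %d shuffles",
            cfg.gr_threshold, cfg.max_shuffles,
        )
    samples: list[PosteriorSample] = []
    for seq in state.sequences:
        start = int(cfg.burn_in_fraction * len(seq))
        samples.extend(seq[start:])
    return ScemResult(best, samples, converged, rhat_trace, shuffle)


@dataclass(frozen=True)
class IscemResult:
    best: PosteriorSample
    runs: list[ScemResult]
    bounds_trace: list[BoundsBox]
    converged: bool


#: bound updates are padded outward by this fraction of the current box
#: width so the incumbent stays interior; placing it exactly on the new
#: boundary would exclude the (a.s. strictly better) optimum from every
#: later run whenever the incumbent sits on its wrong side
BOUND_PAD_FRACTION = 0.05


def _shrink(bounds: BoundsBox, theta: np.ndarray, side: str) -> BoundsBox:
    """Elementwise bound update; coordinates that would invert are left alone."""
    lo, hi = bounds.lower.copy(), bounds.upper.copy()
    pad = BOUND_PAD_FRACTION * bounds.width
    for i in range(bounds.n_params):
        if side == "upper":
            new_hi = min(hi[i], theta[i] + pad[i])
            if new_hi > lo[i]:
                hi[i] = new_hi
            else:
                logger.debug("upper update would invert coordinate %d; keeping %g", i, hi[i])
        else:
            new_lo = max(lo[i], theta[i] - pad[i])
            if new_lo < hi[i]:
                lo[i] = new_lo
            else:
                logger.debug("lower update would invert coordinate %d; keeping %g", i, lo[i])
    return BoundsBox(lo, hi)


def iscem(
    log_posterior: LogPosterior,
    initial_bounds: BoundsBox,
    cfg: ScemConfig,
    epsilon: float = 1e-6,
    max_outer: int = 12,
    rng: np.random.Generator | None = None,
) -> IscemResult:
    """Iterated SCEM-UA with search-box refinement.

    Run SCEM-UA, collapse the upper bound onto the incumbent optimum, then
    rerun: when a rerun's best density improves, the upper bound moves to
    its optimum, otherwise the lower bound does, until successive best
    log-densities agree within ``epsilon`` (relative) or ``max_outer``
    runs.  Returns the highest-density sample seen across all runs.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    bounds = initial_bounds
    bounds_trace = [bounds]
    first = scem_ua(log_posterior, bounds, cfg, rng)
    runs = [first]
    overall_best = first.best
    p_prev = first.best.log_density
    bounds = _shrink(bounds, first.best.theta, "upper")
    bounds_trace.append(bounds)
    converged = False
    for _ in range(max_outer):
        run = scem_ua(log_posterior, bounds, cfg, rng)
        runs.append(run)
        if run.best.log_density > overall_best.log_density:
            overall_best = run.best
        p_w = run.best.log_density
        if abs(p_prev - p_w) <= epsilon * max(1.0, abs(p_prev)):
            converged = True
            break
        side = "upper" if p_prev <= p_w else "lower"
        bounds = _shrink(bounds, run.best.theta, side)
        bounds_trace.append(bounds)
        p_prev = p_w
    if not converged:
        logger.warning("ISCEM hit the outer-iteration cap (%d runs)", max_outer)
    return IscemResult(overall_best, runs, bounds_trace, converged)
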