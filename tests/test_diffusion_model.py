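"""Unit and property tests for the continuous solution and weekly recursion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from weightdiffusion import (
    ContinuousDiffusionInput,
    DiffusionParams,
    EnergyBalanceRecord,
    WeightSeries,
    continuous_weight,
    r_squared,
    simulate,
    steady_state,
    step,
)
from weightdiffusion.diffusion_model import parse_week, week_label

from conftest import GROUP_PARAMS_S24


def erf_series(z: float, terms: int = 60) -> float:
    """Maclaurin-series error function, independent of math.erf/scipy."""
    total = 0.0
    for n in range(terms):
        total += (-1) ** n * z ** (2 * n + 1) / (math.factorial(n) * (2 * n + 1))
    return 2.0 / math.sqrt(math.pi) * total


#: erfinv(0.5): erf of this is 0.5 to well beyond 5 decimals
ERF_HALF_POINT = 0.4769362762044699


class TestContinuousWeight:
    def _inp(self, **kw):
        defaults = dict(
            initial_mass=70.0,
            net_energy=50.0 * 9400.0,
            fat_energy_density=9400.0,
            diffusion_coefficient=1.0,
            distance=1.0,
            time=1.0,
        )
        defaults.update(kw)
        return ContinuousDiffusionInput(**defaults)

    def test_boundary_value_at_zero_distance(self):
        # x = 0 gives the steady mass E/p regardless of V0, D, t
        assert continuous_weight(self._inp(distance=0.0)) == pytest.approx(50.0)

    def test_initial_value_at_small_time(self):
        # t -> 0+ with x > 0 recovers the initial mass
        assert continuous_weight(self._inp(time=1e-12)) == pytest.approx(70.0)

    def test_steady_value_at_large_time(self):
        assert continuous_weight(self._inp(time=1e12)) == pytest.approx(50.0, abs=2e-5)

    def test_halfway_blend_matches_series_oracle(self):
        # x/(2*sqrt(D*t)) at the erf = 1/2 point blends 70 and 50 to 60.000
        c = self._inp(distance=2.0 * ERF_HALF_POINT)
        assert erf_series(ERF_HALF_POINT) == pytest.approx(0.5, abs=5e-7)
        expected = 50.0 * (1 - erf_series(ERF_HALF_POINT)) + 70.0 * erf_series(ERF_HALF_POINT)
        assert continuous_weight(c) == pytest.approx(expected, abs=1e-9)
        assert continuous_weight(c) == pytest.approx(60.000, abs=1e-3)

    @pytest.mark.parametrize("bad", [
        dict(fat_energy_density=0.0),
        dict(diffusion_coefficient=-1.0),
        dict(time=0.0),
        dict(distance=-0.5),
    ])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            self._inp(**bad)

    @given(
        v0=st.floats(1.0, 200.0),
        steady=st.floats(1.0, 200.0),
        x=st.floats(0.0, 10.0),
        d=st.floats(1e-3, 10.0),
        t=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=200, deadline=None)
    def test_convex_combination_property(self, v0, steady, x, d, t):
        c = ContinuousDiffusionInput(v0, steady * 9400.0, 9400.0, d, x, t)
        v = continuous_weight(c)
        assert min(v0, steady) - 1e-9 <= v <= max(v0, steady) + 1e-9


class TestStep:
    def test_pure_persistence_limit(self):
        p = DiffusionParams(alpha=0.5, beta=40.0, initial_weight=70.0)
        assert step(63.2, -500.0, p) == pytest.approx(63.2)

    def test_zero_alpha_zero_beta_maps_to_zero(self):
        p = DiffusionParams(alpha=0.0, beta=0.0, initial_weight=70.0)
        assert step(63.2, 1800.0, p) == 0.0

    def test_first_starvation_week_arithmetic(self):
        # S1: 69.39 kg start, -226.53 kcal/day deficit, printed constants
        got = step(69.39, -226.53, GROUP_PARAMS_S24)
        e = float(__import__("scipy.special", fromlist=["erf"]).erf(1.7096))
        expected = 69.39 * e + 0.016337 * 7 * (-226.53) * (1 - e)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(67.90, abs=0.01)

    @given(w=st.floats(1.0, 200.0), l=st.floats(-3000.0, 3000.0),
           c=st.floats(0.1, 5.0))
    @settings(max_examples=100, deadline=None)
    def test_linearity_in_weight_and_intake(self, w, l, c):
        p = DiffusionParams(alpha=0.016, beta=1.7, initial_weight=70.0)
        assert step(c * w, l, p) + step(0.0, l, p) * (c - 1) == pytest.approx(
            c * step(w, l, p), rel=1e-9, abs=1e-9
        )


class TestSimulate:
    def test_single_step_equals_step(self):
        p = GROUP_PARAMS_S24
        assert simulate(69.39, [-226.53], p)[0] == pytest.approx(step(69.39, -226.53, p))

    def test_three_step_halving_toy(self):
        # erf(beta) = 1/2 and zero intake halves the weight every week
        p = DiffusionParams(alpha=0.123, beta=ERF_HALF_POINT, initial_weight=10.0)
        traj = simulate(10.0, [0.0, 0.0, 0.0], p)
        assert traj == pytest.approx([5.0, 2.5, 1.25], rel=1e-6)

    def test_chained_converges_to_fixed_point(self):
        p = DiffusionParams(alpha=0.016337, beta=1.7096, initial_weight=69.39)
        traj = simulate(69.39, [1000.0] * 10_000, p)
        assert abs(traj[-1] - steady_state(p, 1000.0)) < 1e-6

    def test_one_step_ahead_uses_observed_previous(self, s24):
        p = GROUP_PARAMS_S24
        osa = simulate(69.39, s24.net_intakes, p, mode="one_step_ahead", observed=s24)
        expected = [step(69.39, s24.net_intakes[0], p)] + [
            step(s24.weights[i - 1], s24.net_intakes[i], p) for i in range(1, 24)
        ]
        np.testing.assert_allclose(osa, expected, rtol=1e-12)

    def test_one_step_ahead_requires_observations(self):
        with pytest.raises(ValueError, match="observed"):
            simulate(69.39, [0.0, 0.0], GROUP_PARAMS_S24, mode="one_step_ahead")

    def test_monotone_in_any_net_intake(self):
        p = DiffusionParams(alpha=0.016, beta=1.7, initial_weight=70.0)
        nets = [-200.0, 100.0, 50.0, -50.0]
        base = simulate(70.0, nets, p)
        for j in range(len(nets)):
            bumped = list(nets)
            bumped[j] += 10.0
            traj = simulate(70.0, bumped, p)
            assert np.all(traj[j:] > base[j:])
            np.testing.assert_allclose(traj[:j], base[:j])

    def test_affine_in_initial_weight(self):
        p = DiffusionParams(alpha=0.016, beta=1.7, initial_weight=70.0)
        zero_intake = [0.0] * 6
        np.testing.assert_allclose(
            simulate(140.0, zero_intake, p), 2 * simulate(70.0, zero_intake, p), rtol=1e-12
        )

    def test_nonpositive_trajectory_warns(self, caplog):
        p = DiffusionParams(alpha=0.016, beta=0.5, initial_weight=10.0)
        with caplog.at_level("WARNING"):
            simulate(10.0, [-4000.0] * 20, p)
        assert any("non-positive" in r.message for r in caplog.records)


class TestRSquared:
    def test_perfect_fit(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_mean_prediction_scores_zero(self):
        obs = [1.0, 2.0, 3.0, 6.0]
        assert r_squared(obs, [3.0] * 4) == pytest.approx(0.0)

    def test_never_exceeds_one_and_distinguishes_variants(self):
        rng = np.random.default_rng(0)
        obs = rng.normal(size=30)
        pred = obs + rng.normal(scale=0.3, size=30)
        for kind in ("determination", "correlation"):
            assert r_squared(obs, pred, kind=kind) <= 1.0
        # adding a constant offset leaves only the correlation variant invariant
        shifted = pred + 5.0
        assert r_squared(obs, shifted, kind="correlation") == pytest.approx(
            r_squared(obs, pred, kind="correlation")
        )
        assert r_squared(obs, shifted) < r_squared(obs, pred) - 0.5

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            r_squared([2.0, 2.0], [1.0, 3.0])


class TestSteadyState:
    def test_zero_intake(self):
        assert steady_state(GROUP_PARAMS_S24, 0.0) == 0.0

    def test_printed_alpha_arithmetic(self):
        assert steady_state(GROUP_PARAMS_S24, 1000.0) == pytest.approx(114.359)

    def test_beta_zero_reached_in_one_step(self):
        p = DiffusionParams(alpha=0.02, beta=0.0, initial_weight=50.0)
        assert step(50.0, 800.0, p) == pytest.approx(steady_state(p, 800.0))


class TestDomainTypes:
    def test_params_validation(self):
        with pytest.raises(ValueError):
            DiffusionParams(alpha=math.inf, beta=1.0, initial_weight=70.0)
        with pytest.raises(ValueError):
            DiffusionParams(alpha=0.01, beta=-0.1, initial_weight=70.0)
        with pytest.raises(ValueError):
            DiffusionParams(alpha=0.01, beta=1.0, initial_weight=0.0)

    def test_record_requires_consistent_net_intake(self):
        with pytest.raises(ValueError, match="net_intake"):
            EnergyBalanceRecord(1, "S1", 68.35, 1884.53, 1658.0, -200.0)

    def test_series_rejects_duplicate_weeks(self):
        r = EnergyBalanceRecord(1, "S1", 68.35, 1884.53, 1658.0, -226.53)
        with pytest.raises(ValueError, match="strictly increase"):
            WeightSeries([r, r])

    def test_window_selection(self, group_series):
        sub = group_series.window("S5", "S8")
        assert [r.week_label for r in sub] == ["S5", "S6", "S7", "S8"]
        with pytest.raises(ValueError):
            group_series.window("S8", "S5")

    @pytest.mark.parametrize("token,idx", [("0", 0), ("S1", 1), ("S24", 24)])
    def test_week_token_round_trip(self, token, idx):
        assert parse_week(token) == idx
        assert week_label(idx) == token

    def test_bad_week_token(self):
        with pytest.raises(ValueError):
            parse_week("W3")
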