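"""Barrier model: readout monotonicities, decline law, repair persistence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bbbqsp.bbb import (
    BBBParams,
    BBBState,
    compute_permeability,
    compute_teer,
    healthy_trajectory_endpoint,
    infiltration_probability,
    simulate_bbb_cohort,
    step_bbb,
    teer_ohm_cm2,
)
from bbbqsp.errors import ValidationError


class TestReadouts:
    def test_fully_healthy_state_is_the_baseline(self, bbb_params):
        s = BBBState()
        assert compute_teer(s, bbb_params) == pytest.approx(bbb_params.teer_baseline)
        assert compute_permeability(s, bbb_params) == pytest.approx(
            bbb_params.perm_baseline
        )

    def test_zero_tjp_hits_the_paracellular_floor_not_zero(self, bbb_params):
        s = BBBState(tjp_level=0.0)
        teer = compute_teer(s, bbb_params)
        assert teer == pytest.approx(
            bbb_params.teer_floor_frac * bbb_params.teer_baseline
        )
        assert teer > 0

    def test_teer_strictly_increasing_in_tjp_and_bmec(self, bbb_params):
        grid = np.linspace(0.05, 1.0, 25)
        teers = [compute_teer(BBBState(tjp_level=x), bbb_params) for x in grid]
        assert all(b > a for a, b in zip(teers, teers[1:]))
        teers = [compute_teer(BBBState(bmec_density=x), bbb_params) for x in grid]
        assert all(b > a for a, b in zip(teers, teers[1:]))

    def test_permeability_strictly_decreasing_in_tjp(self, bbb_params):
        grid = np.linspace(0.05, 1.0, 25)
        perms = [compute_permeability(BBBState(tjp_level=x), bbb_params) for x in grid]
        assert all(b < a for a, b in zip(perms, perms[1:]))

    def test_lower_bmec_density_raises_permeability(self, bbb_params):
        half = compute_permeability(BBBState(bmec_density=0.5), bbb_params)
        full = compute_permeability(BBBState(bmec_density=1.0), bbb_params)
        assert half > full

    def test_permeability_and_teer_inversely_ordered(self, bbb_params):
        states = [
            BBBState(tjp_level=t, bmec_density=b)
            for t in (0.3, 0.6, 0.9)
            for b in (0.5, 1.0)
        ]
        for a in states:
            for b in states:
                if compute_teer(a, bbb_params) > compute_teer(b, bbb_params):
                    assert compute_permeability(a, bbb_params) < compute_permeability(
                        b, bbb_params
                    )

    def test_invitro_scale_reports_ohm_cm2(self, bbb_params):
        assert teer_ohm_cm2(BBBState(), bbb_params) == pytest.approx(
            bbb_params.teer_invitro_scale
        )

    def test_invalid_state_fields_raise(self, bbb_params):
        with pytest.raises(ValidationError):
            compute_teer(BBBState(tjp_level=1.2), bbb_params)
        with pytest.raises(ValidationError):
            compute_teer(BBBState(tjp_level=float("nan")), bbb_params)
        with pytest.raises(ValidationError):
            compute_teer(BBBState(damage=-0.1), bbb_params)


class TestDeclineLaw:
    def test_stepper_matches_analytic_solution_within_0p1pct(self, bbb_params):
        """Daily stepping over 30 years against the closed-form decay."""
        for disease in (False, True):
            s = BBBState()
            for day in range(30 * 365):
                s = step_bbb(s, bbb_params, 40 + day / 365, disease, 0.0, 0.0, 1.0)
            exact = healthy_trajectory_endpoint(bbb_params, 30.0, disease=disease)
            assert s.tjp_level == pytest.approx(exact, rel=1e-3)

    def test_untreated_trajectory_monotone_non_increasing(self, bbb_params):
        out = simulate_bbb_cohort(np.array([1.0]), bbb_params, True, 30 * 365)
        assert np.all(np.diff(out["tjp"][0]) <= 1e-15)
        assert np.all(np.diff(out["teer"][0]) <= 1e-12)

    def test_rrms_endpoint_about_15pct_below_healthy(self, bbb_params):
        healthy = healthy_trajectory_endpoint(bbb_params, 30.0)
        rrms = healthy_trajectory_endpoint(bbb_params, 30.0, disease=True)
        assert 100 * (1 - rrms / healthy) == pytest.approx(15.0, abs=1.5)

    def test_zero_step_is_identity(self, bbb_params):
        s = BBBState(tjp_level=0.8, damage=0.3)
        assert step_bbb(s, bbb_params, 40, True, 0.0, 0.0, 0.0) == s

    def test_damage_accumulates_and_only_repair_clears_it(self, bbb_params):
        s = BBBState()
        s = step_bbb(s, bbb_params, 40, True, 1000.0, 0.0, 1.0)
        assert s.damage > 0
        s2 = step_bbb(s, bbb_params, 40, True, 0.0, 0.0, 1.0)
        assert s2.damage >= s.damage  # non-decreasing absent repair
        s3 = step_bbb(s, bbb_params, 40, True, 0.0, 1.0, 1.0)
        assert s3.damage < s.damage

    def test_repair_raises_set_point_persistently(self, bbb_params):
        s = BBBState()
        s = step_bbb(s, bbb_params, 40, True, 0.0, 1.0, 1.0)
        assert s.repair_reserve > 0
        reserve = s.repair_reserve
        s = step_bbb(s, bbb_params, 40, True, 0.0, 0.0, 365.0)
        assert s.repair_reserve == reserve  # no wash-out

    def test_non_finite_inputs_raise(self, bbb_params):
        with pytest.raises(ValidationError):
            step_bbb(BBBState(), bbb_params, 40, True, float("inf"), 0.0, 1.0)
        with pytest.raises(ValidationError):
            step_bbb(BBBState(), bbb_params, 40, True, 0.0, -1.0, 1.0)

    def test_cohort_runner_matches_scalar_stepper(self, bbb_params):
        out = simulate_bbb_cohort(np.array([0.95]), bbb_params, True, 400)
        s = BBBState(tjp_level=0.95, tjp_baseline=0.95)
        for day in range(400):
            s = step_bbb(s, bbb_params, 40, True, 0.0, 0.0, 1.0)
        assert out["tjp"][0, -1] == pytest.approx(s.tjp_level, rel=1e-12)

    @given(
        mult=st.floats(min_value=1.05, max_value=5.0),
        rate=st.floats(min_value=0.002, max_value=0.05),
        floor=st.floats(min_value=0.05, max_value=0.6),
    )
    @settings(max_examples=50, deadline=None)
    def test_disease_always_lowers_the_30_year_endpoint(self, mult, rate, floor):
        p = BBBParams(
            healthy_decline_rate=rate,
            disease_decline_multiplier=mult,
            tjp_floor_frac=floor,
        )
        healthy = healthy_trajectory_endpoint(p, 30.0)
        diseased = healthy_trajectory_endpoint(p, 30.0, disease=True)
        assert diseased < healthy


class TestInfiltrationGate:
    def test_complete_blockade_gives_zero_probability(self, bbb_params):
        assert infiltration_probability(1.0, 1.0, 1.0, bbb_params) == 0.0

    def test_healthy_baseline_returns_configured_probability(self, bbb_params):
        p = infiltration_probability(
            bbb_params.perm_baseline, 1.0, 0.0, bbb_params
        )
        assert p == pytest.approx(bbb_params.infil_baseline_prob)

    def test_probability_non_decreasing_in_permeability(self, bbb_params):
        grid = np.linspace(0.5, 8.0, 40)
        probs = [infiltration_probability(x, 1.0, 0.0, bbb_params) for x in grid]
        assert all(b >= a for a, b in zip(probs, probs[1:]))
        assert all(0.0 <= p <= 1.0 for p in probs)

    def test_block_factor_out_of_range_raises(self, bbb_params):
        with pytest.raises(ValidationError):
            infiltration_probability(1.0, 1.0, 1.5, bbb_params)
        with pytest.raises(ValidationError):
            infiltration_probability(-1.0, 1.0, 0.0, bbb_params)
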