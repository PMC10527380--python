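"""Transition-matrix construction and natural-history dynamics."""

import numpy as np
import pytest

import lungscreen as ls
from lungscreen.natural_history import (
    ModelInconsistencyError,
    build_matrices,
    incidence_band,
)
from lungscreen.parameters import ValidationError, annual_to_cycle
from lungscreen.states import (
    DIAGNOSED_STATES,
    HealthState,
    N_STATES,
    PRECLINICAL_STATES,
)


def test_onset_probability_heavy_smoker_at_57(values):
    # annual band incidence x RR, then quarterly conversion
    annual = 0.0010131 * 6.10
    expected = 1 - (1 - annual) ** 0.25
    assert ls.onset_probability(57, "30plus", values) == pytest.approx(
        expected, rel=0, abs=1e-15
    )


def test_onset_probability_identity_rr(values):
    v = dict(values)
    v["relative_risk.30plus"] = 1.0
    assert ls.onset_probability(57, "30plus", v) == pytest.approx(
        annual_to_cycle(0.0010131)
    )


def test_onset_probability_zero_incidence(values):
    v = dict(values)
    v["incidence.55_59"] = 0.0
    assert ls.onset_probability(57, "30plus", v) == 0.0


def test_onset_age_outside_horizon(values):
    with pytest.raises(ValidationError):
        ls.onset_probability(39, "30plus", values)
    with pytest.raises(ValidationError):
        incidence_band(90)


@pytest.mark.parametrize("stratum", ["20_29", "30plus"])
def test_row_stochastic_over_whole_horizon(values, life_table, stratum):
    mats = build_matrices(values, life_table.weighted(0.98), stratum, 180)
    np.testing.assert_allclose(mats.sum(axis=2), 1.0, rtol=0, atol=1e-10)


def test_death_absorbing_and_no_backflow(values, life_table):
    mats = build_matrices(values, life_table.weighted(0.98), "30plus", 180)
    death_row = np.zeros(N_STATES)
    death_row[HealthState.DEATH] = 1.0
    np.testing.assert_array_equal(
        mats[:, HealthState.DEATH, :], np.tile(death_row, (180, 1))
    )
    for dx in DIAGNOSED_STATES:
        assert np.all(mats[:, dx, HealthState.NO_LC] == 0.0)
        for pre in PRECLINICAL_STATES:
            assert np.all(mats[:, dx, pre] == 0.0)


def test_stage_one_residual_stay_without_other_cause_death(values):
    matrix = ls.build_matrix(50, "30plus", values, annual_other_cause_q=0.0)
    # one minus the six tabulated stage-I exits (which sum to ~0.6545)
    exits = 0.3558 + 0.0328 + 1e-8 + 0.0869 + 0.0246 + 0.1544
    assert matrix[HealthState.PRE_I, HealthState.PRE_I] == pytest.approx(
        1 - exits, abs=1e-12
    )
    assert matrix[HealthState.PRE_I, HealthState.PRE_I] == pytest.approx(
        1 - 0.6545, abs=1e-7
    )


def test_diagnosed_stage_one_fatality_without_other_cause_death(values):
    matrix = ls.build_matrix(50, "30plus", values, annual_other_cause_q=0.0)
    assert matrix[HealthState.DX_I, HealthState.DEATH] == pytest.approx(
        0.0121, rel=0, abs=1e-15
    )


def test_all_exits_zeroed_gives_identity_except_death(values):
    v = {
        k: (0.0 if k.startswith(("progression.", "fatality.", "incidence.")) else p)
        for k, p in values.items()
    }
    matrix = ls.build_matrix(50, "30plus", v, annual_other_cause_q=0.0)
    np.testing.assert_allclose(matrix, np.eye(N_STATES), atol=1e-15)


def test_negative_residual_raises_named_error(values, life_table):
    v = dict(values)
    v["progression.IV.diagnosis"] = 0.9  # 0.9 + 0.2978 > 1
    with pytest.raises(ModelInconsistencyError, match="PRE_IV"):
        build_matrices(v, life_table.weighted(0.98), "30plus", 4)


def test_clamped_exits_remain_row_stochastic(values, life_table):
    v = dict(values)
    v["progression.IV.diagnosis"] = 0.9
    mats = build_matrices(
        v, life_table.weighted(0.98), "30plus", 4, clamp_exits=True
    )
    np.testing.assert_allclose(mats.sum(axis=2), 1.0, atol=1e-10)


def test_fatality_from_survival():
    assert ls.fatality_from_survival(1.0) == 0.0
    # inverse of the tabulated stage-I per-cycle fatality
    assert ls.fatality_from_survival(0.9068) == pytest.approx(0.01216, abs=1e-5)
    assert (1 - 0.0121) ** 8 == pytest.approx(0.907, abs=5e-4)
    assert ls.fatality_from_survival(0.25) == pytest.approx(1 - 0.25 ** 0.125)
    with pytest.raises(ValidationError):
        ls.fatality_from_survival(0.0)


def test_three_state_chain_matches_analytic_matrix_power(values, life_table):
    """Reduced chain (disease-free, preclinical I, death): engine occupancy
    equals the analytic product of per-cycle 3x3 matrices to 1e-12."""
    v = dict(values)
    for key in list(v):
        if key.startswith("progression.I.") and key != "progression.I.death":
            v[key] = 0.0
    n = 120
    baseline = ls.make_baseline_distribution(preclinical_mass=0.004)

    trace = ls.run_cohort(
        None, v, life_table, baseline, stratum="30plus", half_cycle=False
    )

    # independent 3-state oracle, using the same sex-weighted life table
    from lungscreen.parameters import sex_weights

    male_w, _ = sex_weights(v, 20)
    annual_q = life_table.weighted(male_w)
    p_death_lc = v["progression.I.death"]
    x = np.array(
        [
            baseline.fractions[HealthState.NO_LC],
            baseline.fractions[HealthState.PRE_I],
            0.0,
        ]
    )
    for t in range(n):
        age = 40 + t // 4
        q = 1 - (1 - annual_q[age - 40]) ** 0.25
        band = incidence_band(age)
        onset_annual = min(v[f"incidence.{band}"] * v["relative_risk.30plus"], 1.0)
        onset = 1 - (1 - onset_annual) ** 0.25
        m = np.array(
            [
                [(1 - q) * (1 - onset), (1 - q) * onset, q],
                [0.0, (1 - q) * (1 - p_death_lc), q + (1 - q) * p_death_lc],
                [0.0, 0.0, 1.0],
            ]
        )
        x = x @ m

    engine = trace.occupancy[n]
    # other preclinical stages only lose mass to death; states 0 and 1 are
    # exactly the reduced chain
    assert engine[HealthState.NO_LC] == pytest.approx(x[0], rel=0, abs=1e-12)
    assert engine[HealthState.PRE_I] == pytest.approx(x[1], rel=0, abs=1e-12)


def test_higher_relative_risk_increases_lifetime_incidence(
    values, life_table, baseline
):
    def cumulative_onset(rr):
        v = dict(values)
        v["relative_risk.30plus"] = rr
        mats = build_matrices(v, life_table.weighted(0.98), "30plus", 180)
        trace = ls.run_cohort(None, v, life_table, baseline, stratum="30plus")
        flux = trace.occupancy[:-1, HealthState.NO_LC] * mats[
            :, HealthState.NO_LC, HealthState.PRE_I
        ]
        return flux.sum()

    totals = [cumulative_onset(rr) for rr in (1.0, 2.7, 6.1, 8.0)]
    assert all(a < b for a, b in zip(totals, totals[1:]))
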