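"""Cohort engine: oracles, invariants, stratum blending, monotonicity."""

import numpy as np
import pytest

import lungscreen as ls
from lungscreen.engine import NO_SCREENING_LABEL
from lungscreen.parameters import ValidationError, stratum_weights
from lungscreen.states import HealthState


def no_disease_values(values, utilities_one=True, discount=0.0):
    v = dict(values)
    for key in v:
        if key.startswith("incidence."):
            v[key] = 0.0
    if utilities_one:
        v["utility.no_lc"] = 1.0
    v["discount_rate"] = discount
    return v


def test_two_state_chain_matches_geometric_series(values, flat_life_table):
    """Alive/dead with constant annual q: engine life-years equal the
    geometric closed form to 1e-10."""
    v = no_disease_values(values)
    baseline = ls.make_baseline_distribution(preclinical_mass=0.0)
    s = (1 - 0.25) ** 0.25  # per-cycle survival
    n = 180

    trace = ls.run_cohort(
        None, v, flat_life_table, baseline, stratum="30plus", half_cycle=False
    )
    expected = (1 - s ** n) / (1 - s) / 4
    assert trace.total_qalys == pytest.approx(expected, rel=0, abs=1e-10)

    trace_hcc = ls.run_cohort(
        None, v, flat_life_table, baseline, stratum="30plus", half_cycle=True
    )
    survivals = s ** np.arange(n + 1)
    expected_hcc = (0.5 * (survivals[:-1] + survivals[1:])).sum() / 4
    assert trace_hcc.total_qalys == pytest.approx(expected_hcc, rel=0, abs=1e-10)


def test_survival_weighted_life_years_from_life_table(values, life_table):
    """Utilities 1, no disease, no discounting: QALYs equal the
    survival-weighted years implied directly by the life table."""
    v = no_disease_values(values)
    baseline = ls.make_baseline_distribution(preclinical_mass=0.0)
    trace = ls.run_cohort(
        None, v, life_table, baseline, stratum="30plus", half_cycle=False
    )
    from lungscreen.parameters import sex_weights

    male_w, _ = sex_weights(v, 20)
    annual_q = life_table.weighted(male_w)
    q_c = 1 - (1 - annual_q[np.arange(180) // 4]) ** 0.25
    survival = np.cumprod(np.concatenate([[1.0], 1 - q_c]))[:-1]
    assert trace.total_qalys == pytest.approx(survival.sum() / 4, abs=1e-10)


def test_zero_discount_equalises_streams(values, life_table, baseline):
    v = dict(values)
    v["discount_rate"] = 0.0
    trace = ls.run_cohort(
        ls.Strategy(55, 79, 20), v, life_table, baseline, stratum="30plus"
    )
    np.testing.assert_array_equal(trace.disc_cost, trace.cost)
    np.testing.assert_array_equal(trace.disc_qaly, trace.qaly)


def test_trace_invariants(values, life_table, baseline):
    trace = ls.run_cohort(
        ls.Strategy(55, 79, 20), values, life_table, baseline, stratum="30plus"
    )
    totals = trace.occupancy.sum(axis=1) + trace.overdiagnosed
    np.testing.assert_allclose(totals, 1.0, rtol=0, atol=1e-12)
    death = trace.occupancy[:, HealthState.DEATH]
    assert np.all(np.diff(death) >= -1e-15)
    # positive discounting shrinks every cycle's streams
    assert np.all(trace.disc_cost <= trace.cost + 1e-12)
    assert np.all(trace.disc_qaly <= trace.qaly + 1e-12)


def test_engine_is_deterministic(values, life_table, baseline):
    a = ls.run_cohort(
        ls.Strategy(50, 74, 20), values, life_table, baseline, stratum="20_29"
    )
    b = ls.run_cohort(
        ls.Strategy(50, 74, 20), values, life_table, baseline, stratum="20_29"
    )
    np.testing.assert_array_equal(a.occupancy, b.occupancy)
    np.testing.assert_array_equal(a.disc_cost, b.disc_cost)
    np.testing.assert_array_equal(a.disc_qaly, b.disc_qaly)


def test_trace_dataframe_round_trip(values, life_table, baseline, tmp_path):
    trace = ls.run_cohort(
        ls.Strategy(55, 79, 20), values, life_table, baseline, stratum="30plus"
    )
    path = tmp_path / "trace.csv"
    frame = trace.to_dataframe()
    frame.to_csv(path, index=False)
    import pandas as pd

    back = pd.read_csv(path)
    np.testing.assert_allclose(
        back.filter(like="occ_").to_numpy(), trace.occupancy, atol=1e-12
    )


# -- stratum blending -------------------------------------------------------

def test_blend_criterion_30_equals_heavy_stratum_run(
    params, life_table, baseline
):
    strategy = ls.Strategy(65, 74, 30)
    cost, qalys = ls.blend_strata(strategy, params, life_table, baseline)
    trace = ls.run_cohort(
        strategy, params, life_table, baseline, stratum="30plus",
        cohort_criterion=30,
    )
    assert cost == trace.total_cost
    assert qalys == trace.total_qalys


def test_blend_is_population_weighted_mixture(params, life_table, baseline):
    strategy = ls.Strategy(55, 79, 20)
    cost, qalys = ls.blend_strata(strategy, params, life_table, baseline)
    weights = stratum_weights(params, 20)
    mix_cost = mix_q = 0.0
    for st, w in weights.items():
        trace = ls.run_cohort(
            strategy, params, life_table, baseline, stratum=st, cohort_criterion=20
        )
        mix_cost += w * trace.total_cost
        mix_q += w * trace.total_qalys
    assert cost == pytest.approx(mix_cost, abs=1e-12)
    assert qalys == pytest.approx(mix_q, abs=1e-12)


def test_identical_strata_parameters_collapse_the_mixture(
    values, life_table, baseline
):
    v = dict(values)
    v["relative_risk.20_29"] = v["relative_risk.30plus"]
    strategy = ls.Strategy(55, 79, 20)
    cost, qalys = ls.blend_strata(strategy, v, life_table, baseline)
    trace = ls.run_cohort(
        strategy, v, life_table, baseline, stratum="30plus", cohort_criterion=20
    )
    assert cost == pytest.approx(trace.total_cost, abs=1e-9)
    assert qalys == pytest.approx(trace.total_qalys, abs=1e-12)


def test_grid_outcomes_include_comparator_and_labels(params, life_table, baseline):
    outcomes = ls.run_grid(params, life_table, baseline)
    assert outcomes[0].label == NO_SCREENING_LABEL
    assert len(outcomes) == 1 + 36 + 3


# -- qualitative dominance structure ---------------------------------------

@pytest.mark.parametrize("criterion", [20, 30])
def test_widening_the_window_increases_cost_and_qalys(
    params, life_table, baseline, criterion
):
    """Earlier start or later stop weakly increases both totals."""
    windows = [(65, 69), (60, 74), (55, 79), (45, 79), (40, 79)]
    strategies = [ls.Strategy(a, b, criterion) for a, b in windows]
    outcomes = ls.evaluate_outcomes(
        [None, *strategies], params, life_table, baseline
    )
    costs = [o.cost for o in outcomes]
    qalys = [o.qalys for o in outcomes]
    assert all(a <= b + 1e-12 for a, b in zip(costs, costs[1:]))
    assert all(a <= b + 1e-12 for a, b in zip(qalys, qalys[1:]))


def test_screening_adds_cost_and_benefit(params, life_table, baseline):
    none, screened = ls.evaluate_outcomes(
        [None, ls.Strategy(55, 79, 20)], params, life_table, baseline
    )
    assert screened.cost > none.cost
    assert screened.qalys > none.qalys
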