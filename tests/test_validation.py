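"""SE/MSE definitions, published-table worked examples and noise recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from redgem import (
    generate_scenario,
    generate_toy_network,
    mean_squared_error,
    squared_error,
    validate_scenario,
)
from redgem.datasets import (
    CHEMOSTAT_PRINTED_MSE,
    chemostat_validation_table,
    fedbatch_comparison_table,
)
from redgem.synthetic import reference_fluxes


def test_squared_error_basics():
    assert squared_error(3.0, 3.0) == 0.0
    # oxygen uptake, batch stage: (-1.350 + 0.512)^2
    assert squared_error(-1.350, -0.512) == pytest.approx(0.702, abs=0.002)
    # carbon dioxide, fed-batch stage
    assert squared_error(1.4, 0.610) == pytest.approx(0.624, abs=0.001)


def test_mse_is_mean_over_available_rows_only():
    rows = pd.DataFrame(
        {"se": [1.0, 3.0, 99.0], "available": [1, 1, 0]}
    )
    assert mean_squared_error(rows) == pytest.approx(2.0)
    with pytest.raises(ValueError, match="p = 0"):
        mean_squared_error(pd.DataFrame({"se": [1.0], "available": [0]}))


def test_single_row_mse_equals_its_se():
    rows = pd.DataFrame({"se": [0.7], "available": [1]})
    assert mean_squared_error(rows) == 0.7


def printed_se_tolerance(x: float, xhat: float) -> float:
    """Tolerance for recomputing a printed SE cell from rates printed to
    three decimals: first-order propagation of the ±5e-4 input rounding
    (2·|x−x̂|·1e-3) plus the rounding of the printed SE itself."""
    return max(0.002, 2 * abs(x - xhat) * 1e-3 + 1e-3)


@pytest.mark.parametrize("dilution", [0.045, 0.035, 0.050])
def test_chemostat_table_se_cells_recompute_from_printed_rates(dilution):
    table = chemostat_validation_table()
    sub = table[(table.dilution == dilution) & (table.available == 1)]
    for _, row in sub.iterrows():
        se = squared_error(row["exp"], row["fba"])
        tol = printed_se_tolerance(row["exp"], row["fba"])
        assert se == pytest.approx(row["se_printed"], abs=tol), row["quantity"]


@pytest.mark.parametrize("dilution", [0.045, 0.035, 0.050])
def test_chemostat_mse_row_recomputes_as_mean_over_five_fluxes(dilution):
    table = chemostat_validation_table()
    sub = table[(table.dilution == dilution) & (table.available == 1)].copy()
    assert len(sub) == 5  # growth, O2, glycerol, CO2, clavulanate
    sub["se"] = [
        squared_error(x, xhat) for x, xhat in zip(sub["exp"], sub["fba"])
    ]
    mse = mean_squared_error(sub.assign(available=1))
    assert mse == pytest.approx(CHEMOSTAT_PRINTED_MSE[dilution], abs=0.002)


def test_fedbatch_table_aggregate_matches_sum_not_mean():
    """The printed aggregate of the fed-batch comparison equals the sum of
    the SE column; both sum and mean are recomputable."""
    table = fedbatch_comparison_table()
    for condition, printed in (("batch", 1.700), ("fed-batch", 0.860)):
        sub = table[table.condition == condition]
        sse = sum(
            squared_error(x, xhat) for x, xhat in zip(sub["exp"], sub["fba"])
        )
        assert sse == pytest.approx(printed, abs=0.01)
        assert sse / len(sub) != pytest.approx(printed, abs=0.1)


# ---- properties ----------------------------------------------------------


@given(
    ses=st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=20),
    c=st.floats(0.1, 10),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_mse_reorder_invariant_and_quadratic_scaling(ses, c):
    rows = pd.DataFrame({"se": ses, "available": 1})
    shuffled = rows.sample(frac=1, random_state=0)
    assert mean_squared_error(rows) == pytest.approx(
        mean_squared_error(shuffled)
    )
    # scaling all fluxes by c scales each SE by c², hence the MSE too
    scaled = pd.DataFrame({"se": [s * c * c for s in ses], "available": 1})
    assert mean_squared_error(scaled) == pytest.approx(
        c * c * mean_squared_error(rows), rel=1e-9
    )


# ---- scenario validation on the toy network ------------------------------


def test_self_generated_scenario_has_zero_mse(toy_model):
    fluxes = reference_fluxes(toy_model)
    scenario, rows = generate_scenario(toy_model, fluxes, noise_sd=0.0, seed=1)
    report = validate_scenario(toy_model, scenario, rows)
    assert report.status == "optimal"
    assert report.p == 4  # growth + three exchanges
    assert report.mse == pytest.approx(0.0, abs=1e-10)


def test_measurement_noise_recovered_as_mse(toy_model):
    """With N(0, σ²) measurement noise on the rows and constraints built
    from the true fluxes, E[SE] = σ² so the replicate-mean MSE ≈ σ²."""
    fluxes = reference_fluxes(toy_model)
    sigma = 0.1
    mses = []
    for seed in range(200):
        scenario, rows = generate_scenario(
            toy_model, fluxes, noise_sd=sigma, seed=seed
        )
        mses.append(validate_scenario(toy_model, scenario, rows).mse)
    assert np.mean(mses) == pytest.approx(sigma**2, rel=0.2)


def test_infeasible_scenario_reports_status_without_mse(toy_model):
    m = toy_model.copy()
    fluxes = reference_fluxes(m)
    scenario, rows = generate_scenario(m, fluxes, noise_sd=0.0, seed=1)
    scenario.lower_bounded["EX_glyc"] = -0.001  # starve the pinned growth
    report = validate_scenario(m, scenario, rows)
    assert report.status == "infeasible"
    assert report.rows.empty
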