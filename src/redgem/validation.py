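"""Quantitative validation of model predictions against measured exchange
fluxes.

For every measured flux ``X_i`` and model prediction ``X̂_i`` the squared
error is

    SE_i = (X_i - X̂_i)²

and a scenario's aggregate is the mean squared error over the ``p`` fluxes
with experimental values,

    MSE = (1/p) Σ SE_i .

Rows without an experimental value (``available = 0``) are excluded from
``p``.  The sum of squared errors (SSE) is reported alongside the mean:
published comparison tables for the fed-batch study print the sum as their
aggregate, so both statistics are emitted and neither is silently
"corrected".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import MetabolicModel
from .optimize import FluxSolution, Scenario, apply_scenario, two_step_fba

__all__ = [
    "squared_error",
    "mean_squared_error",
    "ValidationReport",
    "validate_scenario",
    "read_experimental_csv",
]


def squared_error(x: float, xhat: float) -> float:
    """Squared error between an experimental flux and a prediction."""
    if not (np.isfinite(x) and np.isfinite(xhat)):
        raise ValueError(f"non-finite flux value: x={x}, xhat={xhat}")
    return float((x - xhat) ** 2)


def mean_squared_error(rows: pd.DataFrame) -> float:
    """Mean of ``se`` over rows with an experimental value.

    ``rows`` must have columns ``se`` and ``available`` (truthy for rows
    with measurements).  Raises on ``p = 0``.
    """
    avail = rows[rows["available"].astype(bool)]
    if len(avail) == 0:
        raise ValueError("no rows with experimental values (p = 0)")
    return float(avail["se"].mean())


@dataclass
class ValidationReport:
    """SE/MSE comparison of one scenario.

    ``rows`` has one entry per compared flux: ``reaction_id``,
    ``experimental`` (X), ``predicted`` (X̂), ``se``, ``available``.
    ``p`` counts rows with experimental values; ``mse`` is their mean SE
    and ``sse`` their sum.
    """

    scenario_name: str
    rows: pd.DataFrame = field(default_factory=pd.DataFrame)
    status: str = "optimal"
    solution: FluxSolution | None = None

    @property
    def p(self) -> int:
        if self.rows.empty:
            return 0
        return int(self.rows["available"].astype(bool).sum())

    @property
    def mse(self) -> float:
        return mean_squared_error(self.rows)

    @property
    def sse(self) -> float:
        avail = self.rows[self.rows["available"].astype(bool)]
        return float(avail["se"].sum())

    def to_tsv(self, path: str | Path) -> Path:
        out = self.rows.copy()
        out.to_csv(path, sep="\t", index=False)
        with open(path, "a") as fh:
            if self.status == "optimal" and self.p:
                fh.write(f"# p\t{self.p}\n# MSE\t{self.mse:.6g}\n"
                         f"# SSE\t{self.sse:.6g}\n")
            else:
                fh.write(f"# status\t{self.status}\n")
        return Path(path)


def read_experimental_csv(path: str | Path) -> pd.DataFrame:
    """Experimental rows: columns ``reaction_id, value, available`` (0/1)."""
    df = pd.read_csv(path)
    required = {"reaction_id", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(required)}")
    if "available" not in df.columns:
        df["available"] = 1
    return df


def validate_scenario(
    model: MetabolicModel,
    scenario: Scenario,
    experimental: pd.DataFrame,
    objective_id: str | None = None,
) -> ValidationReport:
    """Constrain ``model`` with ``scenario``, run two-step FBA, and compare
    predicted exchange fluxes against ``experimental`` rows.

    Rows whose ``available`` flag is falsy (no measurement) are carried in
    the report but excluded from ``p`` and the MSE.  An infeasible
    constrained model yields a report with the failure status and no MSE.
    """
    constrained = apply_scenario(model, scenario)
    objective_id = (
        objective_id or scenario.objective_id or constrained.objective_id
    )
    sol = two_step_fba(constrained, objective_id)
    if not sol.optimal:
        return ValidationReport(
            scenario_name=scenario.name, rows=pd.DataFrame(), status=sol.status
        )
    rows = []
    for _, row in experimental.iterrows():
        rid = str(row["reaction_id"])
        available = bool(row.get("available", 1))
        x = float(row["value"]) if available else np.nan
        xhat = sol.fluxes.get(rid, np.nan)
        se = squared_error(x, xhat) if available and np.isfinite(xhat) else np.nan
        rows.append(
            {
                "reaction_id": rid,
                "experimental": x,
                "predicted": xhat,
                "se": se,
                "available": available and np.isfinite(xhat),
            }
        )
    return ValidationReport(
        scenario_name=scenario.name,
        rows=pd.DataFrame(rows),
        status="optimal",
        solution=sol,
    )
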