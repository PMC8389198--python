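"""Linear-programming core: FBA, two-step (objective-then-L1) FBA, FVA,
scenario constraints, and shadow prices from the LP dual.

Flux balance analysis solves

    max  c' v   s.t.  S v = 0,  lb <= v <= ub

with HiGHS (through :func:`scipy.optimize.linprog`).  The dual variable of
metabolite ``i``'s mass balance is its *shadow price*: the sensitivity
``dZ*/db_i`` of the optimum to a perturbation ``S v = b`` of that balance.
Shadow prices are reported in the convention used with CPLEX-style duals in
the metabolic-modelling literature:

* negative  -> the metabolite limits the objective (supplying more of it
  would raise the optimum);
* zero      -> the objective is insensitive to the metabolite;
* positive  -> the metabolite is in surplus (the network would benefit from
  disposing of it).

The raw solver duals are kept alongside for debugging
(:attr:`FluxSolution.raw_duals`).

The two-step procedure first maximises the stated objective (for the
clavulanic-acid study, the CA exchange flux), then minimises the Manhattan
norm ``sum_j |v_j|`` of the whole flux vector subject to the step-1 optimum,
selecting a parsimonious flux distribution among the optimal alternatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel, stoichiometric_matrix

logger = logging.getLogger(__name__)

#: Verification tolerance for mass balance, bounds and duality checks.
FEAS_TOL = 1e-6

#: Magnitude reported for an unbounded FVA direction.
BIG_M = 1e6

_SOLVER_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": 1e-9,
    "dual_feasibility_tolerance": 1e-9,
}


class InfeasibleModelError(RuntimeError):
    """The flux polytope is empty under the current constraints."""


# --------------------------------------------------------------------------
# solution container
# --------------------------------------------------------------------------


@dataclass
class FluxSolution:
    """Solution of one (or, for the two-step procedure, two) FBA LPs."""

    status: str  # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)
    shadow_prices: dict[str, float] = field(default_factory=dict)
    reduced_costs: dict[str, float] = field(default_factory=dict)
    raw_duals: dict[str, float] = field(default_factory=dict)
    sum_abs_flux: float | None = None
    dual_objective: float | None = None
    objective_id: str = ""
    sense: str = "max"

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    @property
    def duality_gap(self) -> float | None:
        if self.objective_value is None or self.dual_objective is None:
            return None
        return abs(self.objective_value - self.dual_objective)

    def flux_vector(self, reaction_ids: list[str]) -> np.ndarray:
        return np.array([self.fluxes[r] for r in reaction_ids])


@dataclass
class FluxRange:
    """FVA result for one reaction."""

    reaction_id: str
    minimum: float
    maximum: float

    @property
    def span(self) -> float:
        return self.maximum - self.minimum


# --------------------------------------------------------------------------
# low-level LP
# --------------------------------------------------------------------------

_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded"}


def _solve(
    S: sparse.csr_matrix,
    bounds: list[tuple[float, float]],
    c: np.ndarray,
    sense: str,
    b: np.ndarray | None = None,
    A_extra: sparse.csr_matrix | None = None,
    b_extra_lo: np.ndarray | None = None,
    b_extra_hi: np.ndarray | None = None,
):
    """Solve ``sense c'v  s.t. S v = b, lo <= A_extra v <= hi, bounds``.

    Returns the raw scipy result plus the objective in the stated sense.
    """
    n = S.shape[1]
    sign = -1.0 if sense == "max" else 1.0
    A_ub_rows, b_ub = [], []
    if A_extra is not None:
        if b_extra_hi is not None:
            finite = np.isfinite(b_extra_hi)
            if finite.any():
                A_ub_rows.append(A_extra[finite])
                b_ub.append(b_extra_hi[finite])
        if b_extra_lo is not None:
            finite = np.isfinite(b_extra_lo)
            if finite.any():
                A_ub_rows.append(-A_extra[finite])
                b_ub.append(-b_extra_lo[finite])
    A_ub = sparse.vstack(A_ub_rows).tocsr() if A_ub_rows else None
    res = linprog(
        c=sign * c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]) if b is None else b,
        A_ub=A_ub,
        b_ub=np.concatenate(b_ub) if b_ub else None,
        bounds=bounds,
        method="highs",
        options=_SOLVER_OPTIONS,
    )
    status = _STATUS.get(res.status, "failed")
    objective = sign * res.fun if res.status == 0 else None
    return res, status, objective, sign


def _dual_objective(res, b: np.ndarray, bounds, sign: float) -> float:
    """Dual objective of the solved LP, in the stated sense.

    For the internal minimisation, strong duality reads
    ``c'x = b'y + sum_j lb_j zl_j + ub_j zu_j`` (finite-bound terms only).
    """
    val = float(np.dot(b, res.eqlin.marginals))
    lbs = np.array([lo if np.isfinite(lo) else 0.0 for lo, _ in bounds])
    ubs = np.array([hi if np.isfinite(hi) else 0.0 for _, hi in bounds])
    val += float(np.dot(lbs, res.lower.marginals))
    val += float(np.dot(ubs, res.upper.marginals))
    return sign * val


# --------------------------------------------------------------------------
# FBA
# --------------------------------------------------------------------------


def _model_arrays(model: MetabolicModel):
    S = stoichiometric_matrix(model, as_sparse=True)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    return S, bounds


def fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    sense: str = "max",
    balance_shift: dict[str, float] | None = None,
) -> FluxSolution:
    """Flux balance analysis: optimise one reaction flux over the polytope.

    Parameters
    ----------
    model
        Validated metabolic model.
    objective_id
        Reaction to optimise; defaults to ``model.objective_id``.
    sense
        ``"max"`` or ``"min"``.
    balance_shift
        Optional perturbation ``b`` of the steady state (``S v = b``),
        keyed by metabolite id.  Used for finite-difference verification of
        shadow prices; production balances are zero by default.
    """
    objective_id = objective_id or model.objective_id
    if not objective_id:
        raise ValueError("no objective reaction given")
    rxn_ids = model.reaction_ids
    if objective_id not in rxn_ids:
        raise KeyError(f"objective reaction {objective_id!r} not in model")
    S, bounds = _model_arrays(model)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective_id)] = 1.0
    b = np.zeros(S.shape[0])
    if balance_shift:
        met_index = {m: i for i, m in enumerate(model.metabolite_ids)}
        for met, val in balance_shift.items():
            b[met_index[met]] = val
    res, status, objective, sign = _solve(S, bounds, c, sense, b=b)
    if status != "optimal":
        return FluxSolution(
            status=status, objective_value=None,
            objective_id=objective_id, sense=sense,
        )
    # Z = sign * (internal minimum), so dZ*/db_i = sign * marginal_i
    shadow = sign * res.eqlin.marginals
    reduced = sign * (res.lower.marginals + res.upper.marginals)
    dual_obj = _dual_objective(res, b, bounds, sign)
    return FluxSolution(
        status="optimal",
        objective_value=float(objective),
        fluxes=dict(zip(rxn_ids, (float(x) for x in res.x))),
        shadow_prices=dict(
            zip(model.metabolite_ids, (float(y) for y in shadow))
        ),
        reduced_costs=dict(zip(rxn_ids, (float(z) for z in reduced))),
        raw_duals=dict(
            zip(model.metabolite_ids, (float(y) for y in res.eqlin.marginals))
        ),
        dual_objective=float(dual_obj),
        objective_id=objective_id,
        sense=sense,
    )


def two_step_fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    shadow_source: str = "step1",
) -> FluxSolution:
    """Objective maximisation followed by Manhattan-norm minimisation.

    Step 1 maximises the objective flux, giving ``Z*``.  Step 2 minimises
    ``sum_j |v_j|`` over the whole flux vector subject to the objective flux
    staying at ``Z*``, via the split-variable reformulation
    ``v = v+ - v-`` with ``v+, v- >= 0``.  The returned fluxes are the
    step-2 optimum; :attr:`FluxSolution.sum_abs_flux` is the step-2
    objective.

    ``shadow_source`` selects which LP's duals populate
    :attr:`FluxSolution.shadow_prices`: ``"step1"`` (default — the stated
    sensitivity of the production objective) or ``"step2"``.
    """
    objective_id = objective_id or model.objective_id
    step1 = fba(model, objective_id, sense="max")
    if not step1.optimal:
        return step1
    z_star = step1.objective_value

    rxn_ids = model.reaction_ids
    n = len(rxn_ids)
    S = stoichiometric_matrix(model, as_sparse=True)
    # split variables: x = [v+, v-], v = v+ - v-
    S2 = sparse.hstack([S, -S]).tocsr()
    bounds2 = []
    for r in model.reactions:
        bounds2.append((0.0, max(r.upper_bound, 0.0)))
    for r in model.reactions:
        bounds2.append((0.0, max(-r.lower_bound, 0.0)))
    # original bounds may exclude 0 (e.g. hard growth): enforce v+ - v- in
    # [lb, ub] through an extra two-sided constraint for such reactions
    extra_rows, extra_lo, extra_hi = [], [], []
    for j, r in enumerate(model.reactions):
        if r.lower_bound > 0 or r.upper_bound < 0:
            row = sparse.csr_matrix(
                ([1.0, -1.0], ([0, 0], [j, n + j])), shape=(1, 2 * n)
            )
            extra_rows.append(row)
            extra_lo.append(r.lower_bound)
            extra_hi.append(r.upper_bound)
    j_obj = rxn_ids.index(objective_id)
    obj_row = sparse.csr_matrix(
        ([1.0, -1.0], ([0, 0], [j_obj, n + j_obj])), shape=(1, 2 * n)
    )

    c2 = np.ones(2 * n)

    def _try(target_lo: float, target_hi: float):
        rows = extra_rows + [obj_row]
        lo = np.array(extra_lo + [target_lo])
        hi = np.array(extra_hi + [target_hi])
        A = sparse.vstack(rows).tocsr()
        return _solve(S2, bounds2, c2, "min", A_extra=A,
                      b_extra_lo=lo, b_extra_hi=hi)

    res, status, norm, _ = _try(z_star, z_star)
    if status != "optimal":
        relaxed = z_star - max(abs(z_star), 1.0) * 1e-9
        logger.warning(
            "two_step_fba: step 2 infeasible at Z*=%g; retrying with "
            "objective >= %g", z_star, relaxed,
        )
        res, status, norm, _ = _try(relaxed, np.inf)
        if status != "optimal":
            raise InfeasibleModelError(
                f"two_step_fba: step 2 {status} even after relaxing the "
                f"step-1 optimum {z_star!r}"
            )
    v = res.x[:n] - res.x[n:]
    if shadow_source == "step1":
        shadow = step1.shadow_prices
        raw = step1.raw_duals
    else:
        shadow = dict(
            zip(model.metabolite_ids, (float(y) for y in res.eqlin.marginals))
        )
        raw = shadow
    return FluxSolution(
        status="optimal",
        objective_value=float(z_star),
        fluxes=dict(zip(rxn_ids, (float(x) for x in v))),
        shadow_prices=shadow,
        reduced_costs=step1.reduced_costs,
        raw_duals=raw,
        sum_abs_flux=float(norm),
        dual_objective=step1.dual_objective,
        objective_id=objective_id,
        sense="max",
    )


def fva(
    model: MetabolicModel,
    fraction_of_optimum: float | None = 1.0,
    reactions: list[str] | None = None,
    objective_id: str | None = None,
) -> list[FluxRange]:
    """Flux variability analysis: per-reaction flux min/max.

    With ``fraction_of_optimum=f`` the objective flux is first maximised to
    ``Z*`` and every subsequent LP carries the constraint
    ``c'v >= Z* - (1-f)|Z*|`` (which is ``f Z*`` for non-negative optima).
    ``fraction_of_optimum=None`` drops the optimality constraint and
    explores the raw polytope.  Two LPs are solved per reaction.
    """
    rxn_ids = model.reaction_ids
    targets = reactions if reactions is not None else rxn_ids
    S, bounds = _model_arrays(model)
    n = len(rxn_ids)
    A_extra = b_lo = b_hi = None
    if fraction_of_optimum is not None:
        objective_id = objective_id or model.objective_id
        base = fba(model, objective_id, sense="max")
        if not base.optimal:
            raise InfeasibleModelError(
                f"FVA: base FBA is {base.status}"
            )
        z = base.objective_value
        threshold = z - (1.0 - fraction_of_optimum) * abs(z)
        j_obj = rxn_ids.index(objective_id)
        A_extra = sparse.csr_matrix(([1.0], ([0], [j_obj])), shape=(1, n))
        b_lo = np.array([threshold])
        b_hi = np.array([np.inf])
    ranges = []
    index = {r: j for j, r in enumerate(rxn_ids)}
    for rid in targets:
        c = np.zeros(n)
        c[index[rid]] = 1.0
        lo_hi = []
        for sense in ("min", "max"):
            _, status, val, _ = _solve(
                S, bounds, c, sense, A_extra=A_extra,
                b_extra_lo=b_lo, b_extra_hi=b_hi,
            )
            if status == "unbounded":
                logger.warning("FVA: %s unbounded towards %s; reporting %g",
                               rid, sense, BIG_M)
                val = -BIG_M if sense == "min" else BIG_M
            elif status != "optimal":
                raise InfeasibleModelError(f"FVA LP for {rid} is {status}")
            lo_hi.append(float(val))
        vmin, vmax = lo_hi
        if vmin > vmax:  # numerical jitter on a fixed flux
            vmin, vmax = vmax, vmin
        ranges.append(FluxRange(rid, vmin, vmax))
    return ranges


# --------------------------------------------------------------------------
# scenarios
# --------------------------------------------------------------------------


@dataclass
class Scenario:
    """Measured exchange rates of one cultivation state, applied as bounds.

    The measured growth rate is a *hard* constraint (both bounds), uptake
    rates (negative values) become *lower* bounds of the corresponding
    exchange reactions, secretion rates (positive) become *upper* bounds —
    the soft-constraint convention of chemostat/fed-batch comparison tables.
    """

    name: str
    growth_rate: float | None = None
    growth_reaction_id: str = ""
    lower_bounded: dict[str, float] = field(default_factory=dict)
    upper_bounded: dict[str, float] = field(default_factory=dict)
    objective_id: str = ""

    def validate(self) -> None:
        bad = {r: v for r, v in self.lower_bounded.items() if v > 0}
        if bad:
            raise ValueError(f"uptake (lower-bound) entries must be <= 0: {bad}")
        bad = {r: v for r, v in self.upper_bounded.items() if v < 0}
        if bad:
            raise ValueError(f"secretion (upper-bound) entries must be >= 0: {bad}")


def apply_scenario(model: MetabolicModel, scenario: Scenario) -> MetabolicModel:
    """Return a copy of ``model`` constrained by ``scenario``.

    Growth bounds are pinned to the measured rate; each lower-bounded
    exchange gets its lower bound replaced (upper untouched) and vice versa.
    A resulting ``lb > ub`` raises a :class:`ValueError` naming the
    reaction.
    """
    scenario.validate()
    out = model.copy()
    if scenario.growth_rate is not None:
        gid = scenario.growth_reaction_id
        if not gid:
            raise ValueError("scenario has a growth rate but no growth reaction id")
        g = out.reaction(gid)
        if not (g.lower_bound - FEAS_TOL <= scenario.growth_rate
                <= g.upper_bound + FEAS_TOL):
            raise ValueError(
                f"growth rate {scenario.growth_rate} outside model bounds "
                f"[{g.lower_bound}, {g.upper_bound}] of {gid!r}"
            )
        g.lower_bound = g.upper_bound = scenario.growth_rate
    for rid, val in scenario.lower_bounded.items():
        r = out.reaction(rid)
        r.lower_bound = val
        if r.lower_bound > r.upper_bound:
            raise ValueError(
                f"scenario {scenario.name!r}: contradictory bounds on {rid!r} "
                f"({r.lower_bound} > {r.upper_bound})"
            )
    for rid, val in scenario.upper_bounded.items():
        r = out.reaction(rid)
        r.upper_bound = val
        if r.lower_bound > r.upper_bound:
            raise ValueError(
                f"scenario {scenario.name!r}: contradictory bounds on {rid!r} "
                f"({r.lower_bound} > {r.upper_bound})"
            )
    if scenario.objective_id:
        out.objective_id = scenario.objective_id
    return out


def read_scenario_csv(path: str | Path, name: str | None = None) -> Scenario:
    """Read a scenario table: columns ``reaction_id, value, role`` with role
    in ``{hard_growth, lower, upper}``.
    """
    df = pd.read_csv(path)
    required = {"reaction_id", "value", "role"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: scenario CSV needs columns {sorted(required)}"
        )
    sc = Scenario(name=name or Path(path).stem)
    for _, row in df.iterrows():
        role = str(row["role"]).strip()
        rid, val = str(row["reaction_id"]), float(row["value"])
        if role == "hard_growth":
            sc.growth_rate = val
            sc.growth_reaction_id = rid
        elif role == "lower":
            sc.lower_bounded[rid] = val
        elif role == "upper":
            sc.upper_bounded[rid] = val
        else:
            raise ValueError(f"{path}: unknown role {role!r} for {rid!r}")
    return sc


def write_scenario_csv(scenario: Scenario, path: str | Path) -> Path:
    rows = []
    if scenario.growth_rate is not None:
        rows.append((scenario.growth_reaction_id, scenario.growth_rate,
                     "hard_growth"))
    rows += [(r, v, "lower") for r, v in scenario.lower_bounded.items()]
    rows += [(r, v, "upper") for r, v in scenario.upper_bounded.items()]
    pd.DataFrame(rows, columns=["reaction_id", "value", "role"]).to_csv(
        path, index=False
    )
    return Path(path)


def write_solution_tsv(
    solution: FluxSolution, path: str | Path
) -> Path:
    """Write fluxes/reduced costs and shadow prices of a solution as TSV."""
    lines = ["kind\tid\tvalue"]
    for rid, v in solution.fluxes.items():
        lines.append(f"flux\t{rid}\t{v:.10g}")
    for rid, v in solution.reduced_costs.items():
        lines.append(f"reduced_cost\t{rid}\t{v:.10g}")
    for mid, v in solution.shadow_prices.items():
        lines.append(f"shadow_price\t{mid}\t{v:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def verify_solution(
    model: MetabolicModel, solution: FluxSolution, tol: float = FEAS_TOL
) -> dict[str, float]:
    """Residuals of the optimality certificates for a solved FBA.

    Returns max mass-balance violation, max bound violation and the duality
    gap; raises nothing (callers assert).
    """
    S = stoichiometric_matrix(model)
    v = solution.flux_vector(model.reaction_ids)
    balance = float(np.max(np.abs(S @ v))) if v.size else 0.0
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    bound_violation = float(
        max(np.max(lb - v, initial=0.0), np.max(v - ub, initial=0.0))
    )
    return {
        "max_balance_violation": balance,
        "max_bound_violation": bound_violation,
        "duality_gap": solution.duality_gap if solution.duality_gap is not None
        else float("nan"),
    }
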