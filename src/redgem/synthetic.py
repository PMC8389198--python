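"""Synthetic toy networks with known ground truth.

The generated network miniaturises the metabolism relevant to clavulanic
acid (CA) production in *S. clavuligerus*: a glycerol-fed glycolytic chain
down to a C3 node, a TCA-like cycle with a glyoxylate-shunt analogue, an
anaplerotic C3→C4 step, a lumped arginine (C5) branch, and a clavam-pathway
lump condensing the C3 and C5 precursors into a CA analogue while releasing
a succinate analogue — the stoichiometric signature of the clavaminate
synthase steps.  Exchanges follow the uptake-negative convention and a
lumped biomass reaction provides a growth flux in h⁻¹.

Every optional blemish (internal two-reaction loop, dead-end metabolites,
an unreachable branch, a prunable "minor" subsystem, redundant parallel
routes) is recorded in :class:`GroundTruth`, so reduction, loop correction
and sampling can be tested against exact expectations.  The analytic CA
optimum is a closed form of the uptake bound: each CA requires three
units of carbon substrate (one as C3 precursor, two through the cycle to
regenerate the C5 precursor), so ``max CA = uptake / 3`` at zero growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path

import numpy as np

from .model import MetabolicModel, Metabolite, Reaction
from .optimize import Scenario, fba, two_step_fba

__all__ = [
    "ToyNetworkConfig",
    "GroundTruth",
    "generate_toy_network",
    "generate_scenario",
    "reference_fluxes",
    "brute_force_fba_oracle",
    "random_bounded_variant",
    "write_fixture_bundle",
]

OBJECTIVE_ID = "EX_ca"
GROWTH_ID = "BIOMASS"

#: Biomass demand per unit growth: precursor id -> coefficient.
_BIOMASS_STOICH = {"g3p_c": -0.5, "oaa_c": -0.3, "akg_c": -0.2}

#: Carbon substrate consumed per unit of CA-analogue produced (closed form
#: of the toy stoichiometry) and per unit of growth.
_SUBSTRATE_PER_CA = 3.0
_SUBSTRATE_PER_GROWTH = 1.2


@dataclass
class ToyNetworkConfig:
    """Switches for the toy network generator.

    ``bound_scale`` is the substrate uptake capacity in
    mmol·gDCW⁻¹·h⁻¹; all optional counts are non-negative.
    """

    include_tic: bool = False
    include_dead_ends: int = 0
    include_unreachable_branch: bool = False
    include_minor_subsystem: bool = False
    n_parallel_routes: int = 0
    seed: int = 0
    bound_scale: float = 10.0

    def __post_init__(self) -> None:
        if self.include_dead_ends < 0 or self.n_parallel_routes < 0:
            raise ValueError("counts must be >= 0")
        if self.bound_scale <= 0:
            raise ValueError("bound_scale must be positive")


@dataclass
class GroundTruth:
    """What the generator planted, for exact assertions downstream."""

    analytic_optimum: float
    objective_id: str = OBJECTIVE_ID
    growth_id: str = GROWTH_ID
    max_growth: float = 0.0
    tic_loops: list[set[str]] = field(default_factory=list)
    dead_end_metabolites: set[str] = field(default_factory=set)
    unreachable_reactions: set[str] = field(default_factory=set)
    minor_subsystem_reactions: set[str] = field(default_factory=set)
    parallel_route_reactions: set[str] = field(default_factory=set)
    core_subsystems: set[str] = field(default_factory=set)
    n_reactions: int = 0
    n_metabolites: int = 0
    n_genes: int = 0


def _met(mid: str, name: str = "") -> Metabolite:
    comp = mid.rsplit("_", 1)[-1] if "_" in mid else "c"
    return Metabolite(id=mid, name=name or mid, compartment=comp)


def generate_toy_network(
    config: ToyNetworkConfig | None = None,
) -> tuple[MetabolicModel, GroundTruth]:
    """Build the toy CA-production network and its ground truth."""
    cfg = config or ToyNetworkConfig()
    scale = cfg.bound_scale
    model = MetabolicModel(id=f"toy_clav_{cfg.seed}", objective_id=OBJECTIVE_ID)

    for mid in (
        "glyc_e", "g3p_c", "pyr_c", "oaa_c", "icit_c",
        "akg_c", "succ_c", "mal_c", "arg_c", "ca_c",
    ):
        model.add_metabolite(_met(mid))

    def rxn(rid, stoich, lb, ub, subsystem, gene_rule="", **kw):
        model.add_reaction(
            Reaction(id=rid, name=rid, stoichiometry=stoich,
                     lower_bound=lb, upper_bound=ub, subsystem=subsystem,
                     gene_rule=gene_rule, **kw)
        )

    rxn("EX_glyc", {"glyc_e": -1}, -scale, 0.0, "exchange", is_exchange=True)
    rxn("GLYCt", {"glyc_e": -1, "g3p_c": 1}, 0, 1000, "glycolysis", "glpK")
    rxn("PYK", {"g3p_c": -1, "pyr_c": 1}, 0, 1000, "glycolysis",
        "pyk1 or pyk2")
    rxn("PPC", {"pyr_c": -1, "oaa_c": 1}, 0, 1000, "anaplerotic", "ppc")
    rxn("CS", {"pyr_c": -1, "oaa_c": -1, "icit_c": 1}, 0, 1000, "tca", "gltA")
    rxn("ICDH", {"icit_c": -1, "akg_c": 1}, 0, 1000, "tca", "icd")
    rxn("ICL", {"icit_c": -1, "succ_c": 1, "mal_c": 1}, 0, 1000,
        "glyoxylate_shunt", "aceA")
    rxn("MDH", {"mal_c": -1, "oaa_c": 1}, 0, 1000, "tca", "mdh")
    rxn("LMPD_arg", {"akg_c": -1, "arg_c": 1}, 0, 1000, "lumped",
        "argA and argB", is_lumped=True)
    rxn("CEAS", {"g3p_c": -1, "arg_c": -1, "ca_c": 1, "succ_c": 1},
        0, 1000, "clavam", "ceaS and cas2")
    rxn("EX_ca", {"ca_c": -1}, 0, 1000, "exchange", is_exchange=True)
    rxn("EX_succ", {"succ_c": -1}, 0, 1000, "exchange", is_exchange=True)
    rxn(GROWTH_ID, dict(_BIOMASS_STOICH), 0, 1000, "biomass")

    truth = GroundTruth(
        analytic_optimum=scale / _SUBSTRATE_PER_CA,
        max_growth=scale / _SUBSTRATE_PER_GROWTH,
        core_subsystems={
            "exchange", "glycolysis", "anaplerotic", "tca",
            "glyoxylate_shunt", "lumped", "clavam", "biomass",
        },
    )

    if cfg.include_tic:
        model.add_metabolite(_met("loopX_c"))
        model.add_metabolite(_met("loopY_c"))
        # two parallel conversions of the same pair: the reversible one can
        # run against the irreversible one, a circulation with no exchange
        rxn("TIC_A", {"loopX_c": -1, "loopY_c": 1}, -1000, 1000, "artificial")
        rxn("TIC_B", {"loopX_c": -1, "loopY_c": 1}, 0, 1000, "artificial")
        truth.tic_loops.append({"TIC_A", "TIC_B"})

    for i in range(cfg.include_dead_ends):
        orphan = f"orphan{i}_c"
        model.add_metabolite(_met(orphan))
        rxn(f"DEAD_{i}", {"g3p_c": -1, orphan: 1}, 0, 1000, "artificial")
        truth.dead_end_metabolites.add(orphan)

    if cfg.include_unreachable_branch:
        for mid in ("u1_c", "u2_c", "u3_c"):
            model.add_metabolite(_met(mid))
        rxn("UNR_1", {"u1_c": -1, "u2_c": 1}, 0, 1000, "artificial")
        rxn("UNR_2", {"u2_c": -1, "u3_c": 1}, 0, 1000, "artificial")
        rxn("UNR_3", {"u3_c": -1, "ca_c": 1}, 0, 1000, "artificial")
        truth.unreachable_reactions = {"UNR_1", "UNR_2", "UNR_3"}

    if cfg.include_minor_subsystem:
        for mid in ("m1_c", "m2_c", "m3_c"):
            model.add_metabolite(_met(mid))
        rxn("MIN_1", {"pyr_c": -1, "m1_c": 1}, 0, 1000, "minor")
        rxn("MIN_2", {"m1_c": -1, "m2_c": 1}, 0, 1000, "minor")
        rxn("MIN_3", {"m2_c": -1, "m3_c": 1}, 0, 1000, "minor")
        rxn("EX_m3", {"m3_c": -1}, 0, 1000, "minor", is_exchange=True)
        truth.minor_subsystem_reactions = {"MIN_1", "MIN_2", "MIN_3", "EX_m3"}

    for i in range(cfg.n_parallel_routes):
        alt = f"alt{i}_c"
        model.add_metabolite(_met(alt))
        rxn(f"ALT_{i}a", {"g3p_c": -1, alt: 1}, 0, 1000, "glycolysis_alt")
        rxn(f"ALT_{i}b", {alt: -1, "pyr_c": 1}, 0, 1000, "glycolysis_alt")
        truth.parallel_route_reactions |= {f"ALT_{i}a", f"ALT_{i}b"}

    model.genes = sorted({g for r in model.reactions for g in r.genes()})
    model.validate()
    truth.n_reactions = len(model.reactions)
    truth.n_metabolites = len(model.metabolites)
    truth.n_genes = len(model.genes)
    return model, truth


# --------------------------------------------------------------------------
# scenarios with known truth
# --------------------------------------------------------------------------


def reference_fluxes(
    model: MetabolicModel, growth_fraction: float = 0.3
) -> dict[str, float]:
    """A reproducible "true" flux state: growth pinned at a fraction of its
    maximum, CA production maximised, Manhattan norm minimised."""
    mu_max = fba(model, GROWTH_ID, sense="max").objective_value
    pinned = model.copy()
    growth = pinned.reaction(GROWTH_ID)
    growth.lower_bound = growth.upper_bound = growth_fraction * mu_max
    sol = two_step_fba(pinned, model.objective_id or OBJECTIVE_ID)
    if not sol.optimal:
        raise RuntimeError(f"reference state is {sol.status}")
    return sol.fluxes


def generate_scenario(
    model: MetabolicModel,
    true_fluxes: dict[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    name: str = "synthetic",
    growth_reaction_id: str = GROWTH_ID,
) -> tuple[Scenario, "pd.DataFrame"]:
    """Emulate a measured cultivation state from a known flux vector.

    The scenario's *constraints* take the true exchange fluxes (uptakes as
    lower bounds, secretions as upper bounds, growth hard), emulating the
    role assignment of published comparison tables.  The *experimental
    rows* carry the same quantities perturbed by Gaussian measurement noise
    of standard deviation ``noise_sd``, so under a well-specified model the
    expected MSE of :func:`~redgem.validation.validate_scenario` equals
    ``noise_sd²``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    scenario = Scenario(
        name=name,
        growth_rate=float(true_fluxes[growth_reaction_id]),
        growth_reaction_id=growth_reaction_id,
        objective_id=model.objective_id,
    )
    rows = [
        {
            "reaction_id": growth_reaction_id,
            "value": float(true_fluxes[growth_reaction_id])
            + rng.normal(0.0, noise_sd),
            "available": 1,
        }
    ]
    for r in model.reactions:
        if not model.is_exchange(r):
            continue
        v = float(true_fluxes[r.id])
        if v < 0:
            scenario.lower_bounded[r.id] = v
        else:
            scenario.upper_bounded[r.id] = v
        rows.append(
            {
                "reaction_id": r.id,
                "value": v + rng.normal(0.0, noise_sd),
                "available": 1,
            }
        )
    return scenario, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# brute-force oracle
# --------------------------------------------------------------------------


def brute_force_fba_oracle(
    model: MetabolicModel,
    objective_id: str | None = None,
    tol: float = 1e-8,
) -> dict:
    """FBA optimum by exhaustive vertex enumeration (networks <= 14
    reactions).

    Every vertex of ``{S v = 0, lb <= v <= ub}`` has at least ``n - rank(S)``
    flux coordinates at a bound; all such active sets are enumerated, the
    remaining coordinates solved from the balance equations, and feasible
    vertices scored.  Independent of the LP solver by construction.

    Returns ``{"status": "optimal"|"infeasible", "objective_value": float,
    "vertex": dict}``.
    """
    n = len(model.reactions)
    if n > 14:
        raise ValueError(f"oracle limited to 14 reactions, model has {n}")
    objective_id = objective_id or model.objective_id
    from .model import stoichiometric_matrix

    S = stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise ValueError("oracle requires finite bounds")
    c = np.zeros(n)
    c[model.reaction_ids.index(objective_id)] = 1.0
    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_fixed = n - rank

    best_val, best_v = None, None
    scale = max(1.0, float(np.abs(np.concatenate([lb, ub])).max()))
    for fixed_t in combinations(range(n), n_fixed):
        fixed = list(fixed_t)
        free = [j for j in range(n) if j not in fixed]
        S_free = S[:, free]
        if free and np.linalg.matrix_rank(S_free) < len(free):
            continue  # not a basis: any vertex here shows up elsewhere
        for pattern in product((0, 1), repeat=n_fixed):
            v = np.zeros(n)
            for j, side in zip(fixed, pattern):
                v[j] = lb[j] if side == 0 else ub[j]
            rhs = -S[:, fixed] @ v[fixed] if n_fixed else np.zeros(S.shape[0])
            if free:
                sol, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
                v[free] = sol
            if np.max(np.abs(S @ v), initial=0.0) > tol * scale:
                continue
            if np.any(v < lb - tol * scale) or np.any(v > ub + tol * scale):
                continue
            val = float(c @ v)
            if best_val is None or val > best_val:
                best_val, best_v = val, v
    if best_val is None:
        return {"status": "infeasible", "objective_value": None, "vertex": None}
    return {
        "status": "optimal",
        "objective_value": best_val,
        "vertex": dict(zip(model.reaction_ids, (float(x) for x in best_v))),
    }


def random_bounded_variant(
    model: MetabolicModel, rng: np.random.Generator
) -> MetabolicModel:
    """Perturb a copy of ``model``: rescale substrate uptake and tighten a
    couple of internal reaction capacities.  Used to exercise the LP
    against the vertex-enumeration oracle on many distinct polytopes."""
    out = model.copy()
    for r in out.reactions:
        if out.is_exchange(r) and r.lower_bound < 0:
            r.lower_bound = float(r.lower_bound * rng.uniform(0.5, 1.5))
    internals = [r for r in out.reactions
                 if not out.is_exchange(r) and r.id != GROWTH_ID]
    scale = max(abs(r.lower_bound) for r in out.reactions
                if r.lower_bound < 0)
    for r in rng.choice(len(internals), size=min(2, len(internals)),
                        replace=False):
        internals[int(r)].upper_bound = float(rng.uniform(0.2, 1.2) * scale)
    return out


# --------------------------------------------------------------------------
# fixture bundle
# --------------------------------------------------------------------------


def write_fixture_bundle(
    out_dir: str | Path,
    config: ToyNetworkConfig | None = None,
    noise_sd: float = 0.0,
) -> dict[str, Path]:
    """Emit model JSON + scenario CSV + ground-truth JSON into ``out_dir``."""
    import json

    from .io import save_model
    from .optimize import write_scenario_csv

    cfg = config or ToyNetworkConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model, truth = generate_toy_network(cfg)
    fluxes = reference_fluxes(model)
    scenario, rows = generate_scenario(
        model, fluxes, noise_sd=noise_sd, seed=cfg.seed
    )
    paths = {
        "model": save_model(model, out_dir / "model.json"),
        "scenario": write_scenario_csv(scenario, out_dir / "scenario.csv"),
    }
    rows.to_csv(out_dir / "experimental.csv", index=False)
    paths["experimental"] = out_dir / "experimental.csv"
    truth_dict = {
        "analytic_optimum": truth.analytic_optimum,
        "objective_id": truth.objective_id,
        "growth_id": truth.growth_id,
        "max_growth": truth.max_growth,
        "tic_loops": [sorted(s) for s in truth.tic_loops],
        "dead_end_metabolites": sorted(truth.dead_end_metabolites),
        "unreachable_reactions": sorted(truth.unreachable_reactions),
        "minor_subsystem_reactions": sorted(truth.minor_subsystem_reactions),
        "counts": {
            "n_reactions": truth.n_reactions,
            "n_metabolites": truth.n_metabolites,
            "n_genes": truth.n_genes,
        },
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(truth_dict, indent=1))
    paths["ground_truth"] = out_dir / "ground_truth.json"
    return paths
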