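"""Bottom-up model reduction: dead-end and blocked-reaction pruning, lumped
reactions, biomass-precursor producibility, greedy gap filling, and
detection/correction of thermodynamically infeasible cycles (TICs).

The workflow condenses a genome-scale reconstruction to the subsystems of
interest (for the clavulanic-acid study: central carbon metabolism plus the
clavam pathway), keeps it functional by re-connecting broken producibility
chains, and removes internal loops that would carry flux without any
exchange — violations of the loop law.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .model import MetabolicModel, Metabolite, ModelIntegrityError, Reaction
from .optimize import InfeasibleModelError, fba, fva

logger = logging.getLogger(__name__)

#: Flux below which a reaction is considered unable to carry flux.
DEFAULT_FLUX_TOL = 1e-9

#: Dead band (kJ·mol⁻¹) inside which Gibbs-energy evidence is considered
#: inconclusive for assigning a reaction direction.
DEFAULT_DG_THRESHOLD = 5.0


# --------------------------------------------------------------------------
# bookkeeping types
# --------------------------------------------------------------------------


@dataclass
class ReductionLog:
    """Ordered record of reduction passes; replaying it on the input model
    reproduces the output model."""

    passes: list[dict] = field(default_factory=list)

    def record(self, action: str, **payload) -> None:
        self.passes.append({"action": action, **payload})

    def replay(self, model: MetabolicModel) -> MetabolicModel:
        out = model.copy()
        for entry in self.passes:
            action = entry["action"]
            if action == "remove_reactions":
                out.remove_reactions(entry["reaction_ids"])
            elif action == "remove_metabolites":
                out.remove_metabolites(entry["metabolite_ids"])
            elif action == "add_reaction":
                out.add_reaction(_reaction_from_payload(entry))
            elif action == "add_metabolite":
                out.add_metabolite(Metabolite(**entry["metabolite"]))
            elif action == "drop_biomass_precursors":
                rxn = out.reaction(entry["biomass_id"])
                for met in entry["precursors"]:
                    rxn.stoichiometry.pop(met, None)
            elif action == "set_bounds":
                rxn = out.reaction(entry["reaction_id"])
                rxn.lower_bound, rxn.upper_bound = entry["new_bounds"]
            else:
                raise ValueError(f"unknown log action {action!r}")
        return out

    def to_tsv(self, path: str | Path) -> Path:
        lines = ["pass\taction\tdetail"]
        for i, entry in enumerate(self.passes):
            detail = {k: v for k, v in entry.items() if k != "action"}
            lines.append(f"{i}\t{entry['action']}\t{detail}")
        Path(path).write_text("\n".join(lines) + "\n")
        return Path(path)


def _reaction_from_payload(entry: dict) -> Reaction:
    d = entry["reaction"]
    return Reaction(**d)


@dataclass
class DirectionalityEvidence:
    """Standard Gibbs energy changes (kJ·mol⁻¹) with uncertainties, keyed by
    reaction id.  Typically exported from a thermodynamics database."""

    dg: dict[str, float] = field(default_factory=dict)
    uncertainty: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        import math

        for rid, val in self.dg.items():
            if not math.isfinite(val):
                raise ValueError(f"non-finite ΔG for {rid!r}: {val}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DirectionalityEvidence":
        df = pd.read_csv(path)
        if "reaction_id" not in df.columns or "dg_kj_mol" not in df.columns:
            raise ValueError(
                f"{path}: evidence CSV needs columns reaction_id, dg_kj_mol"
            )
        dg = dict(zip(df["reaction_id"].astype(str), df["dg_kj_mol"].astype(float)))
        unc = {}
        if "uncertainty" in df.columns:
            unc = dict(
                zip(df["reaction_id"].astype(str), df["uncertainty"].astype(float))
            )
        return cls(dg=dg, uncertainty=unc)


@dataclass
class TICReport:
    """Thermodynamically infeasible cycles found in a model.

    ``loops`` are sets of reaction ids that can carry a circulation with all
    exchanges closed; ``corrected`` lists directionality restrictions
    applied, as ``(reaction_id, old_bounds, new_bounds)``; ``unresolved``
    are loop members without decisive evidence.
    """

    loops: list[set[str]] = field(default_factory=list)
    corrected: list[tuple[str, tuple[float, float], tuple[float, float]]] = field(
        default_factory=list
    )
    unresolved: list[str] = field(default_factory=list)

    @property
    def loop_reactions(self) -> set[str]:
        return set().union(*self.loops) if self.loops else set()


# --------------------------------------------------------------------------
# dead ends and blocked reactions
# --------------------------------------------------------------------------


def find_dead_end_metabolites(model: MetabolicModel) -> set[str]:
    """Metabolites that can only be produced or only consumed.

    A reversible reaction counts as both producer and consumer of every
    participant.  Metabolites referenced by no reaction are dead ends too.
    At steady state such metabolites force zero flux through all their
    reactions.
    """
    producible: set[str] = set()
    consumable: set[str] = set()
    for r in model.reactions:
        fwd = r.upper_bound > 0
        rev = r.lower_bound < 0
        for met, coeff in r.stoichiometry.items():
            if coeff > 0:
                if fwd:
                    producible.add(met)
                if rev:
                    consumable.add(met)
            elif coeff < 0:
                if fwd:
                    consumable.add(met)
                if rev:
                    producible.add(met)
    return {
        m.id
        for m in model.metabolites
        if not (m.id in producible and m.id in consumable)
    }


def find_blocked_reactions(
    model: MetabolicModel, tol: float = DEFAULT_FLUX_TOL
) -> set[str]:
    """Reactions unable to carry flux in any steady state with all
    exchanges open (FVA min and max both within ``±tol`` of zero)."""
    opened = model.copy()
    for r in opened.reactions:
        if opened.is_exchange(r):
            r.lower_bound = min(r.lower_bound, -1000.0)
            r.upper_bound = max(r.upper_bound, 1000.0)
    ranges = fva(opened, fraction_of_optimum=None)
    return {
        fr.reaction_id
        for fr in ranges
        if abs(fr.minimum) <= tol and abs(fr.maximum) <= tol
    }


# --------------------------------------------------------------------------
# pruning
# --------------------------------------------------------------------------


def prune(
    model: MetabolicModel,
    keep_subsystems: set[str],
    protected: set[str] | None = None,
    tol: float = DEFAULT_FLUX_TOL,
) -> tuple[MetabolicModel, ReductionLog]:
    """Restrict the model to ``keep_subsystems`` (plus ``protected``
    reactions and the objective), then iteratively strip dead-end
    metabolites and blocked reactions to a fixed point.
    """
    if not keep_subsystems:
        raise ValueError("keep_subsystems must be non-empty")
    protected = set(protected or set())
    if model.objective_id:
        protected.add(model.objective_id)
    log = ReductionLog()
    out = model.copy()

    drop = [
        r.id
        for r in out.reactions
        if r.subsystem not in keep_subsystems and r.id not in protected
    ]
    if model.objective_id and model.objective_id in drop:
        raise ValueError("pruning would remove the objective reaction")
    if drop:
        out.remove_reactions(drop)
        log.record("remove_reactions", reaction_ids=drop,
                   reason="subsystem not kept")
        orphans = out.orphan_metabolites()
        if orphans:
            out.remove_metabolites(orphans)
            log.record("remove_metabolites", metabolite_ids=orphans,
                       reason="orphaned by subsystem pruning")

    while True:
        dead = find_dead_end_metabolites(out) - {
            m for r in out.reactions if r.id in protected
            for m in r.stoichiometry
        }
        dead_rxns = [
            r.id
            for r in out.reactions
            if r.id not in protected and any(m in dead for m in r.stoichiometry)
        ]
        changed = False
        if dead_rxns:
            if model.objective_id in dead_rxns:
                raise ValueError("pruning would remove the objective reaction")
            out.remove_reactions(dead_rxns)
            log.record("remove_reactions", reaction_ids=dead_rxns,
                       reason="touch dead-end metabolite")
            changed = True
        orphans = [m for m in out.orphan_metabolites()]
        if orphans:
            out.remove_metabolites(orphans)
            log.record("remove_metabolites", metabolite_ids=orphans,
                       reason="orphaned")
            changed = True
        if not changed:
            blocked = sorted(find_blocked_reactions(out, tol) - protected)
            if blocked:
                out.remove_reactions(blocked)
                log.record("remove_reactions", reaction_ids=blocked,
                           reason="blocked (FVA)")
                changed = True
        if not changed:
            break
    out.validate()
    return out, log


# --------------------------------------------------------------------------
# lumped reactions
# --------------------------------------------------------------------------


def add_lumped_reaction(
    model: MetabolicModel,
    rxn_id: str,
    stoichiometry: dict[str, float],
    bounds: tuple[float, float] = (0.0, 1000.0),
    genes: str = "",
    log: ReductionLog | None = None,
) -> MetabolicModel:
    """Add a lumped (net-stoichiometry) reaction in place.

    Unknown metabolites are auto-created in the cytosol with a logged note;
    a null reaction (net stoichiometry empty after cancelling, e.g. A→A) is
    rejected.
    """
    if model.has_reaction(rxn_id):
        raise ModelIntegrityError(f"duplicate reaction id {rxn_id!r}")
    net = {m: c for m, c in stoichiometry.items() if c != 0}
    if not net:
        raise ValueError(
            f"lumped reaction {rxn_id!r} has null net stoichiometry"
        )
    for met in net:
        if not model.has_metabolite(met):
            logger.warning(
                "lumped reaction %s: metabolite %s not in model; creating it",
                rxn_id, met,
            )
            model.add_metabolite(Metabolite(id=met, name=met))
            if log is not None:
                log.record("add_metabolite",
                           metabolite={"id": met, "name": met,
                                       "compartment": "c"})
    rxn = Reaction(
        id=rxn_id,
        name=rxn_id,
        stoichiometry=net,
        lower_bound=bounds[0],
        upper_bound=bounds[1],
        subsystem="lumped",
        gene_rule=genes,
        is_lumped=True,
    )
    model.add_reaction(rxn)
    if log is not None:
        log.record(
            "add_reaction",
            reaction={
                "id": rxn_id, "name": rxn_id, "stoichiometry": net,
                "lower_bound": bounds[0], "upper_bound": bounds[1],
                "subsystem": "lumped", "gene_rule": genes,
                "is_lumped": True,
            },
        )
    return model


# --------------------------------------------------------------------------
# biomass precursors
# --------------------------------------------------------------------------


def _max_sink_flux(model: MetabolicModel, met_id: str) -> float:
    """Maximum flux of a temporary sink ``met -> ∅`` (model untouched)."""
    probe = model.copy()
    sink_id = "SINK_PROBE__"
    while probe.has_reaction(sink_id):
        sink_id += "_"
    probe.add_reaction(
        Reaction(id=sink_id, stoichiometry={met_id: -1.0},
                 lower_bound=0.0, upper_bound=1000.0, is_exchange=True)
    )
    sol = fba(probe, objective_id=sink_id, sense="max")
    if not sol.optimal:
        raise InfeasibleModelError(
            f"producibility probe for {met_id!r}: base model {sol.status}"
        )
    return sol.objective_value


def check_biomass_precursors(
    model: MetabolicModel,
    biomass_id: str,
    tol: float = DEFAULT_FLUX_TOL,
) -> dict[str, bool]:
    """Per-precursor producibility of the biomass substrates.

    Each substrate (negative coefficient in the biomass reaction) gets a
    temporary sink which is maximised; the precursor is producible iff the
    maximum sink flux exceeds ``tol``.  The model is not modified.
    """
    biomass = model.reaction(biomass_id)
    flags = {}
    for met, coeff in biomass.stoichiometry.items():
        if coeff < 0:
            flags[met] = _max_sink_flux(model, met) > tol
    return flags


def drop_unproducible_precursors(
    model: MetabolicModel,
    biomass_id: str,
    flags: dict[str, bool],
    log: ReductionLog | None = None,
) -> MetabolicModel:
    """Remove unproducible precursors from the biomass reaction in place.

    Remaining coefficients are left unchanged (no renormalisation: the
    dropped precursors' carbon contribution is assumed negligible, which is
    the rationale for dropping rather than re-fitting the biomass
    equation).
    """
    if flags and not any(flags.values()):
        raise ValueError("all biomass precursors are unproducible")
    to_drop = [m for m, ok in flags.items() if not ok]
    biomass = model.reaction(biomass_id)
    for met in to_drop:
        biomass.stoichiometry.pop(met, None)
    if to_drop and log is not None:
        log.record("drop_biomass_precursors", biomass_id=biomass_id,
                   precursors=to_drop)
    return model


# --------------------------------------------------------------------------
# gap filling
# --------------------------------------------------------------------------


def gap_fill(
    model: MetabolicModel,
    pool: list[Reaction],
    targets: list[str],
    tol: float = DEFAULT_FLUX_TOL,
) -> list[str]:
    """Greedy minimal-addition gap filling.

    Repeatedly adds the pool reaction that newly enables producibility of
    the most still-unproducible targets (ties broken by pool order) until
    every target is producible or no candidate helps.  Modifies ``model``
    in place and returns the added reaction ids in order.  Targets left
    unproducible trigger a logged warning, not an error.
    """
    def unproducible(m: MetabolicModel) -> list[str]:
        out = []
        for t in targets:
            if not m.has_metabolite(t):
                out.append(t)
            elif _max_sink_flux(m, t) <= tol:
                out.append(t)
        return out

    added: list[str] = []
    remaining = unproducible(model)
    pool = list(pool)
    while remaining:
        best = None
        best_gain = 0
        best_remaining = remaining
        for cand in pool:
            if model.has_reaction(cand.id):
                continue
            trial = model.copy()
            for met in cand.stoichiometry:
                if not trial.has_metabolite(met):
                    trial.add_metabolite(Metabolite(id=met, name=met))
            trial.add_reaction(cand)
            rem = unproducible(trial)
            gain = len(remaining) - len(rem)
            if gain > best_gain:
                best, best_gain, best_remaining = cand, gain, rem
        if best is None:
            logger.warning("gap_fill: targets remain unproducible: %s",
                           remaining)
            break
        for met in best.stoichiometry:
            if not model.has_metabolite(met):
                model.add_metabolite(Metabolite(id=met, name=met))
        model.add_reaction(best)
        added.append(best.id)
        remaining = best_remaining
    return added


# --------------------------------------------------------------------------
# thermodynamically infeasible cycles
# --------------------------------------------------------------------------


def _closed_model(model: MetabolicModel) -> MetabolicModel:
    closed = model.copy()
    for r in closed.reactions:
        if closed.is_exchange(r):
            r.lower_bound = r.upper_bound = 0.0
    return closed


def detect_tics(
    model: MetabolicModel, tol: float = 1e-6
) -> TICReport:
    """Find internal loops able to carry flux with every exchange closed.

    With exchanges at zero, any reaction whose closed-system FVA range is
    not ``{0}`` participates in a circulation ``S v = 0`` with no exchange —
    a loop-law violation.  Members are grouped into loops by the connected
    components of circulation supports: for each member, its flux is pushed
    to the corresponding extreme and the support of the resulting
    circulation links its members.
    """
    closed = _closed_model(model)
    ranges = fva(closed, fraction_of_optimum=None)
    members = {
        fr.reaction_id: fr
        for fr in ranges
        if abs(fr.minimum) > tol or abs(fr.maximum) > tol
    }
    if not members:
        return TICReport()

    # union-find over loop members via circulation supports
    parent = {rid: rid for rid in members}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for rid, fr in members.items():
        sense = "max" if abs(fr.maximum) > tol else "min"
        sol = fba(closed, objective_id=rid, sense=sense)
        if not sol.optimal:
            continue
        support = [
            r for r, v in sol.fluxes.items()
            if abs(v) > tol and r in members
        ]
        for other in support:
            union(rid, other)

    groups: dict[str, set[str]] = {}
    for rid in members:
        groups.setdefault(find(rid), set()).add(rid)
    loops = sorted(groups.values(), key=lambda s: sorted(s))
    return TICReport(loops=list(loops))


def correct_tics(
    model: MetabolicModel,
    report: TICReport,
    evidence: DirectionalityEvidence,
    dg_threshold: float = DEFAULT_DG_THRESHOLD,
    log: ReductionLog | None = None,
) -> tuple[MetabolicModel, TICReport]:
    """Restrict directionality of loop members using Gibbs-energy evidence.

    For a loop member with evidence: ΔG° < -threshold makes the reaction
    forward-only (lower bound raised to 0), ΔG° > +threshold reverse-only
    (upper bound dropped to 0); values inside the dead band leave the
    reaction untouched and listed as unresolved.  A correction that makes
    the open model infeasible is reverted and the reaction marked
    unresolved.  Loops are re-detected afterwards and the residuals
    reported.
    """
    out = model.copy()
    corrected = []
    unresolved = []
    for loop in report.loops:
        for rid in sorted(loop):
            dg = evidence.dg.get(rid)
            if dg is None:
                unresolved.append(rid)
                continue
            rxn = out.reaction(rid)
            old = (rxn.lower_bound, rxn.upper_bound)
            if dg < -dg_threshold and rxn.lower_bound < 0:
                new = (0.0, rxn.upper_bound)
            elif dg > dg_threshold and rxn.upper_bound > 0:
                new = (rxn.lower_bound, 0.0)
            else:
                unresolved.append(rid)
                continue
            rxn.lower_bound, rxn.upper_bound = new
            check = fba(out, out.objective_id or rid, sense="max") \
                if out.objective_id else None
            feasible = check is None or check.optimal
            if not feasible:
                logger.warning(
                    "correct_tics: restricting %s to %s makes the model "
                    "infeasible; reverting", rid, new,
                )
                rxn.lower_bound, rxn.upper_bound = old
                unresolved.append(rid)
                continue
            corrected.append((rid, old, new))
            if log is not None:
                log.record("set_bounds", reaction_id=rid, old_bounds=old,
                           new_bounds=new)
    residual = detect_tics(out)
    return out, TICReport(
        loops=residual.loops,
        corrected=corrected,
        unresolved=sorted(set(unresolved)),
    )
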