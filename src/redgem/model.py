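"""Core data model for constraint-based metabolic networks.

A :class:`MetabolicModel` is the standard constraint-based representation:
a set of metabolites, a set of bounded reactions with signed stoichiometric
coefficients, and an objective reaction.  Together these define the
steady-state flux polytope

    {v : S v = 0,  lb <= v <= ub}

where ``S`` is the stoichiometric matrix (metabolites x reactions) returned
by :func:`stoichiometric_matrix`.

Flux units are mmol·gDCW⁻¹·h⁻¹ throughout; a growth (biomass) reaction
carries h⁻¹.  Uptake through exchange reactions is negative by convention,
secretion positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

#: Default flux bound applied when a file does not state one.
DEFAULT_BOUND = 1000.0

#: Identifier prefix conventionally marking exchange reactions.
EXCHANGE_PREFIX = "EX_"

#: Identifier prefix marking lumped (pathway-summarising) reactions.
LUMPED_PREFIX = "LMPD_"


class ModelIntegrityError(ValueError):
    """A structural invariant of the model is violated."""


class ModelFormatError(ValueError):
    """A model file could not be parsed in the named format."""


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    Parameters
    ----------
    id
        Unique identifier within the model, e.g. ``"succ_c"`` or
        ``"btn[c]"`` (both underscore and bracket compartment suffixes
        occur in the wild and are accepted verbatim).
    name
        Human-readable name.
    compartment
        Non-empty compartment token, e.g. ``"c"`` (cytosol) or ``"e"``
        (extracellular).
    formula
        Optional elemental formula string.
    charge
        Optional integer charge.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelIntegrityError("metabolite id must be non-empty")
        if not self.compartment:
            raise ModelIntegrityError(
                f"metabolite {self.id!r}: compartment must be non-empty"
            )


@dataclass
class Reaction:
    """A bounded biochemical conversion.

    ``stoichiometry`` maps metabolite id to a signed coefficient, negative
    for consumed species.  Bounds are fluxes in mmol·gDCW⁻¹·h⁻¹ (h⁻¹ for a
    growth reaction).  ``gene_rule`` is a boolean expression over gene ids
    ("g1 and (g2 or g3)"); it is carried, not evaluated.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    subsystem: str = ""
    gene_rule: str = ""
    is_exchange: bool = False
    is_lumped: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelIntegrityError("reaction id must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ModelIntegrityError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} exceeds "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def genes(self) -> set[str]:
        """Gene ids appearing in the gene rule."""
        tokens = (
            self.gene_rule.replace("(", " ").replace(")", " ").split()
        )
        return {t for t in tokens if t.lower() not in {"and", "or", "not"}}


def _infer_exchange(rxn: Reaction) -> bool:
    """Exchange detection: id prefix wins; single-metabolite is the fallback.

    When the stored flag disagrees with the inference, the id prefix takes
    precedence and the disagreement is logged.
    """
    by_prefix = rxn.id.startswith(EXCHANGE_PREFIX)
    by_shape = len(rxn.stoichiometry) == 1
    inferred = by_prefix or (by_shape and rxn.is_exchange) or (by_shape and not rxn.id)
    if by_prefix != rxn.is_exchange and rxn.stoichiometry:
        logger.debug(
            "reaction %s: is_exchange flag %s disagrees with EX_ prefix; "
            "prefix wins", rxn.id, rxn.is_exchange,
        )
    return by_prefix or (rxn.is_exchange and by_shape)


@dataclass
class MetabolicModel:
    """A constraint-based metabolic network.

    Invariants (enforced by :meth:`validate`): metabolite and reaction ids
    are unique, every stoichiometry key resolves to a model metabolite,
    exchange reactions touch exactly one metabolite, and the objective
    reaction exists.
    """

    id: str = "model"
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    objective_id: str = ""
    annotations: dict[str, str] = field(default_factory=dict)

    # ---- indexing -------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def has_metabolite(self, met_id: str) -> bool:
        return any(m.id == met_id for m in self.metabolites)

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if self.is_exchange(r)]

    def is_exchange(self, rxn: Reaction | str) -> bool:
        if isinstance(rxn, str):
            rxn = self.reaction(rxn)
        if rxn.id.startswith(EXCHANGE_PREFIX):
            return True
        return rxn.is_exchange and len(rxn.stoichiometry) == 1

    # ---- validation -----------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ModelIntegrityError` on the first violated invariant."""
        met_ids = self.metabolite_ids
        if len(set(met_ids)) != len(met_ids):
            dupes = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ModelIntegrityError(f"duplicate metabolite ids: {dupes}")
        rxn_ids = self.reaction_ids
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ModelIntegrityError(f"duplicate reaction ids: {dupes}")
        known = set(met_ids)
        dangling = sorted(
            {
                met
                for r in self.reactions
                for met in r.stoichiometry
                if met not in known
            }
        )
        if dangling:
            raise ModelIntegrityError(
                f"reactions reference unknown metabolites: {dangling}"
            )
        for r in self.reactions:
            if r.id.startswith(EXCHANGE_PREFIX) and len(r.stoichiometry) != 1:
                raise ModelIntegrityError(
                    f"exchange reaction {r.id!r} must touch exactly one "
                    f"metabolite, touches {len(r.stoichiometry)}"
                )
        if self.objective_id and not self.has_reaction(self.objective_id):
            raise ModelIntegrityError(
                f"objective reaction {self.objective_id!r} not in model"
            )

    # ---- editing --------------------------------------------------------

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[
                replace(r, stoichiometry=dict(r.stoichiometry))
                for r in self.reactions
            ],
            genes=list(self.genes),
            objective_id=self.objective_id,
            annotations=dict(self.annotations),
        )

    def add_metabolite(self, met: Metabolite) -> None:
        if self.has_metabolite(met.id):
            raise ModelIntegrityError(f"duplicate metabolite id {met.id!r}")
        self.metabolites.append(met)

    def add_reaction(self, rxn: Reaction) -> None:
        if self.has_reaction(rxn.id):
            raise ModelIntegrityError(f"duplicate reaction id {rxn.id!r}")
        missing = [m for m in rxn.stoichiometry if not self.has_metabolite(m)]
        if missing:
            raise ModelIntegrityError(
                f"reaction {rxn.id!r} references unknown metabolites: {missing}"
            )
        self.reactions.append(rxn)

    def remove_reactions(self, rxn_ids: set[str] | list[str]) -> None:
        drop = set(rxn_ids)
        self.reactions = [r for r in self.reactions if r.id not in drop]

    def remove_metabolites(self, met_ids: set[str] | list[str]) -> None:
        drop = set(met_ids)
        used = {m for r in self.reactions for m in r.stoichiometry}
        still_used = drop & used
        if still_used:
            raise ModelIntegrityError(
                f"cannot remove metabolites still used by reactions: "
                f"{sorted(still_used)}"
            )
        self.metabolites = [m for m in self.metabolites if m.id not in drop]

    def orphan_metabolites(self) -> list[str]:
        """Metabolites not referenced by any reaction."""
        used = {m for r in self.reactions for m in r.stoichiometry}
        return [m.id for m in self.metabolites if m.id not in used]


# ---- structural queries -------------------------------------------------


def stoichiometric_matrix(
    model: MetabolicModel, as_sparse: bool = False
) -> np.ndarray | sparse.csr_matrix:
    """Stoichiometric matrix ``S`` with rows in metabolite order and columns
    in reaction order.

    ``S[i, j]`` is the coefficient of metabolite ``i`` in reaction ``j``;
    unreferenced entries are zero.  The steady-state assumption of flux
    balance analysis is ``S v = 0``: net production and consumption of every
    metabolite cancel.
    """
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rows, cols, vals = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met, coeff in rxn.stoichiometry.items():
            rows.append(met_index[met])
            cols.append(j)
            vals.append(float(coeff))
    S = sparse.csr_matrix(
        (vals, (rows, cols)),
        shape=(len(model.metabolites), len(model.reactions)),
    )
    return S if as_sparse else S.toarray()


def model_report(model: MetabolicModel) -> dict:
    """Structural summary: entity counts, exchange/lumped tallies and a
    per-subsystem breakdown.
    """
    subsystems: dict[str, int] = {}
    for r in model.reactions:
        key = r.subsystem or "(none)"
        subsystems[key] = subsystems.get(key, 0) + 1
    genes = set(model.genes)
    for r in model.reactions:
        genes |= r.genes()
    return {
        "n_reactions": len(model.reactions),
        "n_metabolites": len(model.metabolites),
        "n_genes": len(genes),
        "n_exchanges": sum(1 for r in model.reactions if model.is_exchange(r)),
        "n_lumped": sum(
            1
            for r in model.reactions
            if r.is_lumped or r.id.startswith(LUMPED_PREFIX)
        ),
        "n_reversible": sum(1 for r in model.reactions if r.reversible),
        "subsystems": dict(sorted(subsystems.items())),
    }
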