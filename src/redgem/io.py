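"""Model readers and writers.

Two formats are supported:

* a JSON dialect: one object with ``"metabolites"``, ``"reactions"``,
  ``"genes"`` and ``"objective"`` keys; reaction stoichiometry is a
  ``{metabolite_id: coefficient}`` mapping (negative = consumed);
* SBML Level 3 with the flux-bounds (``fbc``) package.  When the fbc
  package is absent on read, bounds fall back to ±1000 with a logged
  warning.  Gene rules and subsystems travel in COBRA-style notes.

Bounds missing from a file default to ±1000 mmol·gDCW⁻¹·h⁻¹.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import libsbml

from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelFormatError,
    ModelIntegrityError,
    Reaction,
    model_report,
)

logger = logging.getLogger(__name__)

__all__ = ["load_model", "save_model", "write_report_tsv"]


# --------------------------------------------------------------------------
# JSON dialect
# --------------------------------------------------------------------------


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"formula": m.formula} if m.formula is not None else {}),
                **({"charge": m.charge} if m.charge is not None else {}),
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "subsystem": r.subsystem,
                "gene_rule": r.gene_rule,
                "is_exchange": r.is_exchange,
                "is_lumped": r.is_lumped,
            }
            for r in model.reactions
        ],
        "genes": model.genes,
        "objective": model.objective_id,
        "annotations": model.annotations,
    }


def _model_from_dict(data: dict) -> MetabolicModel:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=m.get("formula"),
                charge=m.get("charge"),
            )
            for m in data["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
                upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                subsystem=r.get("subsystem", ""),
                gene_rule=r.get("gene_rule", ""),
                is_exchange=bool(r.get("is_exchange", False)),
                is_lumped=bool(r.get("is_lumped", False)),
            )
            for r in data["reactions"]
        ]
    except KeyError as exc:  # missing mandatory key
        raise ModelFormatError(f"JSON model missing required key: {exc}") from exc
    model = MetabolicModel(
        id=data.get("id", "model"),
        metabolites=mets,
        reactions=rxns,
        genes=list(data.get("genes", [])),
        objective_id=data.get("objective", ""),
        annotations=dict(data.get("annotations", {})),
    )
    model.validate()
    return model


# --------------------------------------------------------------------------
# SBML (Level 3 + fbc)
# --------------------------------------------------------------------------

_SID_OK = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _encode_sid(prefix: str, raw: str) -> str:
    """Escape an arbitrary id into a valid SBML SId (COBRA-style __ord__)."""
    out = []
    for ch in raw:
        if ch.isalnum() or ch == "_":
            out.append(ch)
        else:
            out.append(f"__{ord(ch)}__")
    return prefix + "".join(out)


def _decode_sid(prefix: str, sid: str) -> str:
    if sid.startswith(prefix):
        sid = sid[len(prefix):]
    return re.sub(r"__(\d+)__", lambda m: chr(int(m.group(1))), sid)


def _notes_xhtml(pairs: dict[str, str]) -> str:
    body = "".join(
        f"<p>{key}: {value}</p>" for key, value in pairs.items() if value
    )
    return f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'


def _parse_notes(notes: str) -> dict[str, str]:
    pairs = {}
    for m in re.finditer(r"<p>\s*([A-Z_]+):\s*(.*?)\s*</p>", notes, re.S):
        pairs[m.group(1)] = m.group(2)
    return pairs


def _sbml_write(model: MetabolicModel, path: Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_encode_sid("", model.id) if model.id else "model")
    smp = sm.getPlugin("fbc")
    smp.setStrict(False)

    compartments = sorted({m.compartment for m in model.metabolites}) or ["c"]
    for comp in compartments:
        c = sm.createCompartment()
        c.setId(_encode_sid("", comp))
        c.setConstant(True)

    for met in model.metabolites:
        s = sm.createSpecies()
        s.setId(_encode_sid("M_", met.id))
        s.setName(met.name or met.id)
        s.setCompartment(_encode_sid("", met.compartment))
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
        sp = s.getPlugin("fbc")
        if met.formula is not None:
            sp.setChemicalFormula(met.formula)
        if met.charge is not None:
            sp.setCharge(int(met.charge))

    # flux bounds live in global parameters referenced per reaction
    bound_params: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"FB_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(float(value))
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for gid in sorted(
        set(model.genes) | {g for r in model.reactions for g in r.genes()}
    ):
        gp = smp.createGeneProduct()
        gp.setId(_encode_sid("G_", gid))
        gp.setLabel(gid)

    for rxn in model.reactions:
        r = sm.createReaction()
        r.setId(_encode_sid("R_", rxn.id))
        r.setName(rxn.name or rxn.id)
        r.setReversible(rxn.lower_bound < 0)
        r.setFast(False)
        for met, coeff in rxn.stoichiometry.items():
            ref = r.createReactant() if coeff < 0 else r.createProduct()
            ref.setSpecies(_encode_sid("M_", met))
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
        rp = r.getPlugin("fbc")
        rp.setLowerFluxBound(_bound_param(rxn.lower_bound))
        rp.setUpperFluxBound(_bound_param(rxn.upper_bound))
        notes = _notes_xhtml(
            {
                "GENE_ASSOCIATION": rxn.gene_rule,
                "SUBSYSTEM": rxn.subsystem,
                "LUMPED": "true" if rxn.is_lumped else "",
                "EXCHANGE": "true" if rxn.is_exchange else "",
            }
        )
        if "<p>" in notes:
            r.setNotes(notes)

    if model.objective_id:
        obj = smp.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        smp.setActiveObjectiveId("obj")
        fo = obj.createFluxObjective()
        fo.setReaction(_encode_sid("R_", model.objective_id))
        fo.setCoefficient(1.0)

    libsbml.writeSBMLToFile(doc, str(path))


def _sbml_read(path: Path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors() > 0:
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise ModelFormatError(
                    f"SBML parse error at line {err.getLine()}: "
                    f"{err.getMessage()}"
                )
    sm = doc.getModel()
    if sm is None:
        raise ModelFormatError(f"{path}: no <model> element found")
    smp = sm.getPlugin("fbc")

    mets = []
    for i in range(sm.getNumSpecies()):
        s = sm.getSpecies(i)
        sp = s.getPlugin("fbc")
        mets.append(
            Metabolite(
                id=_decode_sid("M_", s.getId()),
                name=s.getName(),
                compartment=_decode_sid("", s.getCompartment()) or "c",
                formula=(
                    sp.getChemicalFormula()
                    if sp is not None and sp.isSetChemicalFormula()
                    else None
                ),
                charge=(
                    sp.getCharge()
                    if sp is not None and sp.isSetCharge()
                    else None
                ),
            )
        )

    def _param_value(pid: str, default: float) -> float:
        p = sm.getParameter(pid)
        return p.getValue() if p is not None else default

    rxns = []
    for i in range(sm.getNumReactions()):
        r = sm.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            met = _decode_sid("M_", ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            met = _decode_sid("M_", ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        rp = r.getPlugin("fbc")
        if rp is not None and rp.isSetLowerFluxBound():
            lb = _param_value(rp.getLowerFluxBound(), -DEFAULT_BOUND)
            ub = _param_value(rp.getUpperFluxBound(), DEFAULT_BOUND)
        else:
            logger.warning(
                "reaction %s: no fbc flux bounds; applying defaults ±%g",
                r.getId(), DEFAULT_BOUND,
            )
            lb = -DEFAULT_BOUND if r.getReversible() else 0.0
            ub = DEFAULT_BOUND
        notes = _parse_notes(r.getNotesString()) if r.isSetNotes() else {}
        rxns.append(
            Reaction(
                id=_decode_sid("R_", r.getId()),
                name=r.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                subsystem=notes.get("SUBSYSTEM", ""),
                gene_rule=notes.get("GENE_ASSOCIATION", ""),
                is_exchange=notes.get("EXCHANGE", "") == "true",
                is_lumped=notes.get("LUMPED", "") == "true",
            )
        )

    objective_id = ""
    if smp is not None and smp.getNumObjectives() > 0:
        obj = smp.getObjective(smp.getActiveObjectiveId()) or smp.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective_id = _decode_sid(
                "R_", obj.getFluxObjective(0).getReaction()
            )

    genes = []
    if smp is not None:
        genes = [
            smp.getGeneProduct(i).getLabel()
            or _decode_sid("G_", smp.getGeneProduct(i).getId())
            for i in range(smp.getNumGeneProducts())
        ]

    model = MetabolicModel(
        id=_decode_sid("", sm.getId()) or "model",
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        objective_id=objective_id,
    )
    model.validate()
    return model


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------


def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a model from ``path`` in the JSON dialect or SBML L3+fbc.

    ``format`` is ``"json"`` or ``"sbml"``; when omitted it is inferred from
    the file suffix (``.json`` vs ``.xml``/``.sbml``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelFormatError(
                f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}"
            ) from exc
        if not isinstance(data, dict):
            raise ModelFormatError(f"{path}: top-level JSON must be an object")
        try:
            return _model_from_dict(data)
        except ModelIntegrityError:
            raise
    if fmt == "sbml":
        return _sbml_read(path)
    raise ValueError(f"unknown model format {fmt!r}")


def save_model(
    model: MetabolicModel, path: str | Path, format: str | None = None
) -> Path:
    """Write ``model`` to ``path``; round-trips through :func:`load_model`."""
    model.validate()
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "json":
        path.write_text(json.dumps(_model_to_dict(model), indent=1))
    elif fmt == "sbml":
        _sbml_write(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")
    return path


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in {".xml", ".sbml"}:
        return "sbml"
    raise ValueError(f"cannot infer model format from suffix {suffix!r}")


def write_report_tsv(model: MetabolicModel, path: str | Path) -> Path:
    """Write the :func:`~redgem.model.model_report` summary as TSV."""
    rep = model_report(model)
    lines = ["item\tcount"]
    for key in (
        "n_reactions", "n_metabolites", "n_genes",
        "n_exchanges", "n_lumped", "n_reversible",
    ):
        lines.append(f"{key}\t{rep[key]}")
    for sub, n in rep["subsystems"].items():
        lines.append(f"subsystem:{sub}\t{n}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path
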