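"""Data structures and I/O for constraint-based metabolic models.

A model is a list of metabolites and reactions whose signed stoichiometric
coefficients form the stoichiometric matrix S (metabolites x reactions).
Boundary ("exchange") reactions touch a single extracellular metabolite;
by convention a negative exchange flux is uptake and a positive one is
secretion. Reversibility is encoded purely through the bounds
(reversible <=> lower_bound < 0 < upper_bound); there is no separate flag.

Two on-disk formats are supported: SBML (Level 2 with COBRA-style
kinetic-law bound parameters, Level 3 with the fbc package) and a plain
TSV "table" format (a directory holding ``reactions.tsv`` and
``metabolites.tsv`` with a human-readable equation grammar).
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

COMPARTMENTS = ("cytosol", "extracellular")

#: coefficients and bounds closer than this are treated as equal
FLOAT_TOL = 1e-9

DEFAULT_BOUND = 1000.0


class ModelValidationError(ValueError):
    """The model violates a structural invariant."""


class ModelFormatError(ValueError):
    """A file could not be parsed in the requested format."""


class CurationError(ValueError):
    """A curation step cannot be applied to the model."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "cytosol"
    formula: str | None = None

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {self.id!r}: unknown compartment {self.compartment!r}"
            )


@dataclass(frozen=True)
class Reaction:
    """A reaction with signed stoichiometry (negative = consumed)."""

    id: str
    stoichiometry: Mapping[str, float]
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    annotation: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound + FLOAT_TOL:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))
        object.__setattr__(self, "annotation", tuple(self.annotation))

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def metabolite_ids(self) -> tuple[str, ...]:
        return tuple(self.stoichiometry)


def _is_exchange(reaction: Reaction, metabolites: Mapping[str, Metabolite]) -> bool:
    ids = reaction.metabolite_ids()
    if len(ids) != 1:
        return False
    met = metabolites.get(ids[0])
    return met is not None and met.compartment == "extracellular"


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_id: str
    version_tag: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------
    @property
    def metabolites_by_id(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    @property
    def reactions_by_id(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions_by_id[rid]
        except KeyError:
            raise KeyError(f"no reaction {rid!r} in model {self.version_tag!r}")

    def is_exchange(self, rid: str) -> bool:
        return _is_exchange(self.reaction(rid), self.metabolites_by_id)

    def exchange_ids(self) -> list[str]:
        mets = self.metabolites_by_id
        return [r.id for r in self.reactions if _is_exchange(r, mets)]

    def exchange_for(self, metabolite_id: str) -> str | None:
        """Id of the exchange reaction of an (extracellular) metabolite."""
        mets = self.metabolites_by_id
        for r in self.reactions:
            if _is_exchange(r, mets) and r.metabolite_ids()[0] == metabolite_id:
                return r.id
        return None

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        known = set(met_ids)
        for r in self.reactions:
            missing = [m for m in r.stoichiometry if m not in known]
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id!r} references undeclared metabolites {missing}"
                )
        # a reaction-less model is a permitted degenerate (its S is 0 x 0);
        # otherwise the objective must name an existing reaction
        if self.reactions and self.objective_id not in set(rxn_ids):
            raise ModelValidationError(
                f"objective reaction {self.objective_id!r} not in model"
            )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            objective_id=self.objective_id,
            version_tag=self.version_tag,
        )

    def with_reaction_bounds(self, rid: str, lb: float, ub: float) -> "MetabolicModel":
        """Copy of the model with one reaction's bounds replaced."""
        new = self.copy()
        idx = [i for i, r in enumerate(new.reactions) if r.id == rid]
        if not idx:
            raise KeyError(f"no reaction {rid!r}")
        new.reactions[idx[0]] = replace(
            new.reactions[idx[0]], lower_bound=lb, upper_bound=ub
        )
        return new


def stoichiometric_matrix(model: MetabolicModel) -> sparse.csc_matrix:
    """S as a sparse (n_metabolites x n_reactions) matrix.

    Rows follow ``model.metabolites`` order, columns ``model.reactions``.
    """
    model.validate()
    row_of = {m.id: i for i, m in enumerate(model.metabolites)}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for j, rxn in enumerate(model.reactions):
        for mid, coef in rxn.stoichiometry.items():
            rows.append(row_of[mid])
            cols.append(j)
            vals.append(float(coef))
    return sparse.csc_matrix(
        (vals, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )


# ---------------------------------------------------------------------------
# structural equality
# ---------------------------------------------------------------------------

def _stoich_equal(a: Mapping[str, float], b: Mapping[str, float]) -> bool:
    keys = set(a) | set(b)
    return all(abs(a.get(k, 0.0) - b.get(k, 0.0)) <= FLOAT_TOL for k in keys)


def models_equal(a: MetabolicModel, b: MetabolicModel) -> bool:
    """Structural equality: ignores list order and float noise below 1e-9."""
    if a.objective_id != b.objective_id:
        return False
    amets, bmets = a.metabolites_by_id, b.metabolites_by_id
    if set(amets) != set(bmets):
        return False
    for mid, m in amets.items():
        if m.compartment != bmets[mid].compartment:
            return False
    arxns, brxns = a.reactions_by_id, b.reactions_by_id
    if set(arxns) != set(brxns):
        return False
    for rid, ra in arxns.items():
        rb = brxns[rid]
        if not _stoich_equal(ra.stoichiometry, rb.stoichiometry):
            return False
        if abs(ra.lower_bound - rb.lower_bound) > FLOAT_TOL:
            return False
        if abs(ra.upper_bound - rb.upper_bound) > FLOAT_TOL:
            return False
    return True


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------

CURATION_KINDS = ("remove_reaction", "add_reaction", "set_bounds")


@dataclass(frozen=True)
class CurationStep:
    """One model edit: remove/add a reaction or reset its bounds.

    ``payload`` is a reaction id for ``remove_reaction``, a :class:`Reaction`
    for ``add_reaction`` and a ``(reaction_id, lb, ub)`` triple for
    ``set_bounds``. Reactions that introduce new metabolites must declare
    them in ``new_metabolites``.
    """

    kind: str
    payload: object
    rationale: str = ""
    new_metabolites: tuple[Metabolite, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in CURATION_KINDS:
            raise CurationError(f"unknown curation kind {self.kind!r}")
        if self.kind == "remove_reaction" and not isinstance(self.payload, str):
            raise CurationError("remove_reaction payload must be a reaction id")
        if self.kind == "add_reaction" and not isinstance(self.payload, Reaction):
            raise CurationError("add_reaction payload must be a Reaction")
        if self.kind == "set_bounds":
            ok = (
                isinstance(self.payload, (tuple, list))
                and len(self.payload) == 3
                and isinstance(self.payload[0], str)
            )
            if not ok:
                raise CurationError("set_bounds payload must be (reaction_id, lb, ub)")
            object.__setattr__(self, "payload", tuple(self.payload))
        object.__setattr__(self, "new_metabolites", tuple(self.new_metabolites))


@dataclass(frozen=True)
class CurationLogEntry:
    step: CurationStep
    before: object  # Reaction/bounds present before the step, or None
    after: object


@dataclass
class CurationLog:
    entries: list[CurationLogEntry] = field(default_factory=list)

    def steps(self) -> list[CurationStep]:
        return [e.step for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def apply_curation(
    model: MetabolicModel, steps: Sequence[CurationStep]
) -> tuple[MetabolicModel, CurationLog]:
    """Apply edits in order; the input model is left untouched.

    Replaying ``log.steps()`` on the source model reproduces the result.
    """
    mets = list(model.metabolites)
    rxns = list(model.reactions)
    log = CurationLog()
    for step in steps:
        rxn_index = {r.id: i for i, r in enumerate(rxns)}
        if step.kind == "remove_reaction":
            rid = step.payload  # type: ignore[assignment]
            if rid not in rxn_index:
                raise CurationError(f"cannot remove absent reaction {rid!r}")
            before = rxns.pop(rxn_index[rid])
            log.entries.append(CurationLogEntry(step, before=before, after=None))
        elif step.kind == "add_reaction":
            rxn: Reaction = step.payload  # type: ignore[assignment]
            if rxn.id in rxn_index:
                raise CurationError(f"cannot add duplicate reaction id {rxn.id!r}")
            known = {m.id for m in mets}
            for nm in step.new_metabolites:
                if nm.id not in known:
                    mets.append(nm)
                    known.add(nm.id)
            missing = [m for m in rxn.stoichiometry if m not in known]
            if missing:
                raise CurationError(
                    f"reaction {rxn.id!r} references undeclared metabolites {missing}"
                )
            rxns.append(rxn)
            log.entries.append(CurationLogEntry(step, before=None, after=rxn))
        else:  # set_bounds
            rid, lb, ub = step.payload  # type: ignore[misc]
            if rid not in rxn_index:
                raise CurationError(f"cannot set bounds on absent reaction {rid!r}")
            old = rxns[rxn_index[rid]]
            new = replace(old, lower_bound=float(lb), upper_bound=float(ub))
            rxns[rxn_index[rid]] = new
            log.entries.append(
                CurationLogEntry(
                    step,
                    before=(old.lower_bound, old.upper_bound),
                    after=(new.lower_bound, new.upper_bound),
                )
            )
    curated = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective_id=model.objective_id,
        version_tag=model.version_tag,
    )
    return curated, log


def diff_models(a: MetabolicModel, b: MetabolicModel) -> CurationLog:
    """Curation log turning ``a`` into ``b`` (up to list ordering)."""
    arxns, brxns = a.reactions_by_id, b.reactions_by_id
    amets = a.metabolites_by_id
    bmets = b.metabolites_by_id
    steps: list[CurationStep] = []
    for rid in sorted(set(arxns) - set(brxns)):
        steps.append(CurationStep("remove_reaction", rid, rationale="diff: removed"))
    # a reaction whose stoichiometry changed is replaced wholesale
    for rid in sorted(set(arxns) & set(brxns)):
        ra, rb = arxns[rid], brxns[rid]
        if not _stoich_equal(ra.stoichiometry, rb.stoichiometry):
            steps.append(CurationStep("remove_reaction", rid, rationale="diff: changed"))
            new_mets = tuple(
                bmets[m] for m in rb.stoichiometry if m not in amets
            )
            steps.append(
                CurationStep("add_reaction", rb, rationale="diff: changed",
                             new_metabolites=new_mets)
            )
        elif (
            abs(ra.lower_bound - rb.lower_bound) > FLOAT_TOL
            or abs(ra.upper_bound - rb.upper_bound) > FLOAT_TOL
        ):
            steps.append(
                CurationStep(
                    "set_bounds", (rid, rb.lower_bound, rb.upper_bound),
                    rationale="diff: bounds",
                )
            )
    for rid in sorted(set(brxns) - set(arxns)):
        rb = brxns[rid]
        new_mets = tuple(bmets[m] for m in rb.stoichiometry if m not in amets)
        steps.append(
            CurationStep("add_reaction", rb, rationale="diff: added",
                         new_metabolites=new_mets)
        )
    _, log = apply_curation(a, steps)
    return log


# -- JSON (de)serialisation of curation recipes -----------------------------

def _reaction_to_dict(r: Reaction) -> dict:
    return {
        "id": r.id,
        "name": r.name,
        "stoichiometry": dict(r.stoichiometry),
        "lower_bound": r.lower_bound,
        "upper_bound": r.upper_bound,
        "annotation": list(r.annotation),
    }


def _reaction_from_dict(d: Mapping) -> Reaction:
    return Reaction(
        id=d["id"],
        name=d.get("name", ""),
        stoichiometry={k: float(v) for k, v in d["stoichiometry"].items()},
        lower_bound=float(d.get("lower_bound", 0.0)),
        upper_bound=float(d.get("upper_bound", DEFAULT_BOUND)),
        annotation=tuple(d.get("annotation", ())),
    )


def curation_steps_to_json(steps: Iterable[CurationStep], path: str) -> None:
    out = []
    for s in steps:
        payload: object
        if s.kind == "add_reaction":
            payload = _reaction_to_dict(s.payload)  # type: ignore[arg-type]
        elif s.kind == "set_bounds":
            payload = list(s.payload)  # type: ignore[arg-type]
        else:
            payload = s.payload
        out.append(
            {
                "kind": s.kind,
                "payload": payload,
                "rationale": s.rationale,
                "new_metabolites": [dataclasses.asdict(m) for m in s.new_metabolites],
            }
        )
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)


def curation_steps_from_json(path: str) -> list[CurationStep]:
    with open(path) as fh:
        raw = json.load(fh)
    steps = []
    for d in raw:
        kind = d["kind"]
        payload: object = d["payload"]
        if kind == "add_reaction":
            payload = _reaction_from_dict(payload)  # type: ignore[arg-type]
        elif kind == "set_bounds":
            payload = tuple(payload)  # type: ignore[arg-type]
        steps.append(
            CurationStep(
                kind,
                payload,
                rationale=d.get("rationale", ""),
                new_metabolites=tuple(
                    Metabolite(**m) for m in d.get("new_metabolites", ())
                ),
            )
        )
    return steps


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_model(path: str, format: str = "sbml") -> MetabolicModel:
    """Read a model from SBML (Level 2 or 3) or the TSV table format."""
    if format == "sbml":
        return _read_sbml(path)
    if format == "table":
        return _read_table(path)
    raise ValueError(f"unknown format {format!r}")


def write_model(model: MetabolicModel, path: str, format: str = "sbml") -> None:
    model.validate()
    if format == "sbml":
        _write_sbml(model, path)
    elif format == "table":
        _write_table(model, path)
    else:
        raise ValueError(f"unknown format {format!r}")


# -- SBML -------------------------------------------------------------------

_COMPARTMENT_CODE = {"cytosol": "cytosol", "extracellular": "extracellular"}


def _read_sbml(path: str) -> MetabolicModel:
    import libsbml

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelFormatError(f"SBML parse error: {err.getMessage().strip()}")
    sm = doc.getModel()
    if sm is None:
        raise ModelFormatError(f"{path}: no <model> element")

    compartments: dict[str, str] = {}
    for i in range(sm.getNumCompartments()):
        comp = sm.getCompartment(i)
        cid = comp.getId()
        name = (comp.getName() or cid).lower()
        if cid in COMPARTMENTS:
            compartments[cid] = cid
        elif "extra" in name or cid in ("e", "ext", "Extra_organism"):
            compartments[cid] = "extracellular"
        else:
            compartments[cid] = "cytosol"

    metabolites = []
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        if sp.getBoundaryCondition():
            continue  # boundary species are outside the balanced system
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=compartments.get(sp.getCompartment(), "cytosol"),
            )
        )
    met_ids = {m.id for m in metabolites}

    fbc = sm.getPlugin("fbc")
    objective_id = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective_id = obj.getFluxObjective(0).getReaction()

    reactions = []
    for i in range(sm.getNumReactions()):
        rx = sm.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            if sr.getSpecies() in met_ids:
                stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            if sr.getSpecies() in met_ids:
                stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if abs(v) > 0}
        if not stoich:
            raise ModelFormatError(
                f"reaction {rx.getId()!r}: no balanced species in stoichiometry"
            )

        lb = ub = None
        # precedence: fbc flux bounds > kinetic-law parameters > reversibility default
        rfbc = rx.getPlugin("fbc")
        if rfbc is not None:
            for getter, which in ((rfbc.getLowerFluxBound, "lb"),
                                  (rfbc.getUpperFluxBound, "ub")):
                pid = getter()
                if pid:
                    par = sm.getParameter(pid)
                    if par is not None:
                        if which == "lb":
                            lb = par.getValue()
                        else:
                            ub = par.getValue()
        kl = rx.getKineticLaw()
        if kl is not None:
            for j in range(kl.getNumParameters()):
                par = kl.getParameter(j)
                if par.getId() == "LOWER_BOUND" and lb is None:
                    lb = par.getValue()
                elif par.getId() == "UPPER_BOUND" and ub is None:
                    ub = par.getValue()
                elif par.getId() == "OBJECTIVE_COEFFICIENT" and par.getValue() != 0:
                    if objective_id is None:
                        objective_id = rx.getId()
        if lb is None:
            lb = -DEFAULT_BOUND if rx.getReversible() else 0.0
        if ub is None:
            ub = DEFAULT_BOUND
        reactions.append(
            Reaction(
                id=rx.getId(),
                name=rx.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
            )
        )

    if objective_id is None:
        # fall back to a biomass naming convention
        for r in reactions:
            if "biomass" in r.id.lower() or "biomass" in r.name.lower():
                objective_id = r.id
                break
    if objective_id is None:
        raise ModelFormatError(f"{path}: no objective reaction found")
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_id=objective_id,
        version_tag=sm.getId() or "",
    )


def _write_sbml(model: MetabolicModel, path: str) -> None:
    import libsbml

    doc = libsbml.SBMLDocument(2, 4)
    sm = doc.createModel()
    sm.setId(_sanitize_sid(model.version_tag) or "model")
    for comp_id in COMPARTMENTS:
        comp = sm.createCompartment()
        comp.setId(comp_id)
        comp.setSize(1.0)
    for met in model.metabolites:
        sp = sm.createSpecies()
        if sp.setId(met.id) != libsbml.LIBSBML_OPERATION_SUCCESS:
            raise ModelFormatError(f"metabolite id {met.id!r} is not a valid SBML SId")
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setInitialAmount(0.0)
    for rxn in model.reactions:
        rx = sm.createReaction()
        if rx.setId(rxn.id) != libsbml.LIBSBML_OPERATION_SUCCESS:
            raise ModelFormatError(f"reaction id {rxn.id!r} is not a valid SBML SId")
        rx.setName(rxn.name)
        rx.setReversible(rxn.reversible)
        for mid, coef in rxn.stoichiometry.items():
            if coef < 0:
                sr = rx.createReactant()
                sr.setSpecies(mid)
                sr.setStoichiometry(-coef)
            else:
                sr = rx.createProduct()
                sr.setSpecies(mid)
                sr.setStoichiometry(coef)
        kl = rx.createKineticLaw()
        kl.setMath(libsbml.parseL3Formula("FLUX_VALUE"))
        for pid, val in (
            ("LOWER_BOUND", rxn.lower_bound),
            ("UPPER_BOUND", rxn.upper_bound),
            ("FLUX_VALUE", 0.0),
            ("OBJECTIVE_COEFFICIENT", 1.0 if rxn.id == model.objective_id else 0.0),
        ):
            par = kl.createParameter()
            par.setId(pid)
            par.setValue(val)
    if libsbml.writeSBMLToFile(doc, path) != 1:
        raise OSError(f"could not write SBML to {path}")


def _sanitize_sid(s: str) -> str:
    return re.sub(r"[^A-Za-z0-9_]", "_", s)


# -- TSV table format -------------------------------------------------------

_ARROW_REV = "<=>"
_ARROW_IRR = "-->"


def equation_string(rxn: Reaction) -> str:
    """Render stoichiometry as e.g. ``2 A + B --> C`` (``<=>`` if reversible)."""

    def side(items: list[tuple[str, float]]) -> str:
        parts = []
        for mid, coef in items:
            coef = abs(coef)
            parts.append(mid if abs(coef - 1.0) <= FLOAT_TOL else f"{coef:.12g} {mid}")
        return " + ".join(parts)

    lhs = [(m, c) for m, c in rxn.stoichiometry.items() if c < 0]
    rhs = [(m, c) for m, c in rxn.stoichiometry.items() if c > 0]
    arrow = _ARROW_REV if rxn.reversible else _ARROW_IRR
    return f"{side(lhs)} {arrow} {side(rhs)}".strip()


def parse_equation(eq: str) -> dict[str, float]:
    """Parse the equation grammar back into signed stoichiometry."""
    if _ARROW_REV in eq:
        lhs, rhs = eq.split(_ARROW_REV)
    elif _ARROW_IRR in eq:
        lhs, rhs = eq.split(_ARROW_IRR)
    else:
        raise ModelFormatError(f"equation {eq!r} has no reaction arrow")

    def side(text: str, sign: float) -> dict[str, float]:
        out: dict[str, float] = {}
        text = text.strip()
        if not text:
            return out
        for term in text.split(" + "):
            term = term.strip()
            if not term:
                continue
            bits = term.split()
            if len(bits) == 1:
                mid, coef = bits[0], 1.0
            elif len(bits) == 2:
                try:
                    coef = float(bits[0])
                except ValueError:
                    raise ModelFormatError(f"bad coefficient in term {term!r}")
                mid = bits[1]
            else:
                raise ModelFormatError(f"cannot parse equation term {term!r}")
            out[mid] = out.get(mid, 0.0) + sign * coef
        return out

    stoich = side(lhs, -1.0)
    for mid, c in side(rhs, +1.0).items():
        stoich[mid] = stoich.get(mid, 0.0) + c
    return {k: v for k, v in stoich.items() if abs(v) > 0}


def _write_table(model: MetabolicModel, path: str) -> None:
    rids = [r.id for r in model.reactions]
    if len(set(rids)) != len(rids):  # defensive; validate() also rejects
        raise ModelValidationError("duplicate reaction ids; refusing to write")
    os.makedirs(path, exist_ok=True)
    with open(os.path.join(path, "metabolites.tsv"), "w") as fh:
        fh.write("id\tname\tcompartment\tformula\n")
        for m in model.metabolites:
            fh.write(f"{m.id}\t{m.name}\t{m.compartment}\t{m.formula or ''}\n")
    with open(os.path.join(path, "reactions.tsv"), "w") as fh:
        fh.write("id\tname\tequation\tlower_bound\tupper_bound\tobjective\tannotation\n")
        for r in model.reactions:
            obj = 1 if r.id == model.objective_id else 0
            ann = ";".join(r.annotation)
            fh.write(
                f"{r.id}\t{r.name}\t{equation_string(r)}\t{r.lower_bound:.12g}"
                f"\t{r.upper_bound:.12g}\t{obj}\t{ann}\n"
            )
    with open(os.path.join(path, "model.json"), "w") as fh:
        json.dump({"version_tag": model.version_tag}, fh)


def _read_table(path: str) -> MetabolicModel:
    import pandas as pd

    met_path = os.path.join(path, "metabolites.tsv")
    rxn_path = os.path.join(path, "reactions.tsv")
    for p in (met_path, rxn_path):
        if not os.path.exists(p):
            raise ModelFormatError(f"table model is missing {os.path.basename(p)}")
    mets_df = pd.read_csv(met_path, sep="\t", dtype=str).fillna("")
    rxns_df = pd.read_csv(rxn_path, sep="\t", dtype=str).fillna("")
    metabolites = [
        Metabolite(
            id=row["id"], name=row["name"], compartment=row["compartment"],
            formula=row["formula"] or None,
        )
        for _, row in mets_df.iterrows()
    ]
    reactions = []
    objective_id = None
    for _, row in rxns_df.iterrows():
        stoich = parse_equation(row["equation"])
        reactions.append(
            Reaction(
                id=row["id"],
                name=row["name"],
                stoichiometry=stoich,
                lower_bound=float(row["lower_bound"]),
                upper_bound=float(row["upper_bound"]),
                annotation=tuple(a for a in row["annotation"].split(";") if a),
            )
        )
        if row["objective"] not in ("", "0"):
            objective_id = row["id"]
    if objective_id is None:
        raise ModelFormatError(f"{path}: no reaction marked as objective")
    meta_path = os.path.join(path, "model.json")
    version_tag = ""
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            version_tag = json.load(fh).get("version_tag", "")
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_id=objective_id,
        version_tag=version_tag,
    )
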