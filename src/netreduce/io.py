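"""Model and protection-spec I/O.

Supported model formats:

* SBML Level 3 (+ FBC v2 for flux bounds and the objective); Level 2 files
  are accepted when bounds are given as the conventional ``LOWER_BOUND`` /
  ``UPPER_BOUND`` kinetic-law parameters.  Missing bounds are an error —
  there are no silent defaults.  Species with ``boundaryCondition=true`` (or
  whose compartment is listed in *external_compartments*) become external.
* A TSV pair: a stoichiometry file of ``metabolite<TAB>reaction<TAB>coeff``
  triples (optional 4th column ``external`` with 0/1; the id suffix
  ``_ext`` also marks a species external) and a bounds file of
  ``reaction<TAB>lb<TAB>ub<TAB>objective_coeff`` rows.

Protection specifications are YAML (schema shipped in
``netreduce/schemas/protection_spec.schema.json``).  Scenario constraints
are linear expressions over reaction ids with literal coefficients, e.g.
``"R_glc_up <= 10"`` or ``"-mu <= -0.999 * FBA_MAX(mu)"``.  The
``FBA_MAX(reaction)`` token is resolved at load time by maximising that
reaction's flux on the *full* model under the same scenario's bound
overrides and plain constraints — this is how "99.9 % of the full model's
maximal growth rate" is expressed without hard-coding a number.
"""

from __future__ import annotations

import csv
import logging
import re
from pathlib import Path
from typing import Mapping

import libsbml
import numpy as np
import yaml

from .model import LinearConstraint, MetabolicModel, ModelError, ProtectionSpec, Scenario
from . import lp

logger = logging.getLogger(__name__)

_INF = float("inf")


# ---------------------------------------------------------------------------
# SBML


def _sid(raw: str) -> str:
    """Sanitise an identifier into a valid SBML SId."""
    s = re.sub(r"[^A-Za-z0-9_]", "_", raw)
    if not s or not re.match(r"[A-Za-z_]", s[0]):
        s = "_" + s
    return s


def read_sbml(
    path: str | Path,
    external_compartments: tuple[str, ...] = (),
) -> MetabolicModel:
    """Read an SBML model into a :class:`MetabolicModel`.

    ``boundaryCondition=true`` wins over compartment membership when
    deciding whether a species is external.  Raises :class:`ModelError` on
    parse failures or missing flux bounds.
    """
    path = Path(path)
    if not path.exists():
        raise ModelError(f"SBML file not found: {path}")
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        err = doc.getError(0)
        raise ModelError(
            f"SBML parse error in {path.name}: {err.getMessage().strip()}"
        )
    sm = doc.getModel()
    if sm is None:
        raise ModelError(f"no <model> element in {path.name}")

    internal: list[str] = []
    external: list[str] = []
    compartments: dict[str, str] = {}
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        if sp.getBoundaryCondition() or sp.getCompartment() in external_compartments:
            external.append(sp.getId())
        else:
            internal.append(sp.getId())
            compartments[sp.getId()] = sp.getCompartment()
    int_idx = {s: i for i, s in enumerate(internal)}
    ext_idx = {s: i for i, s in enumerate(external)}

    n = sm.getNumReactions()
    rids = [sm.getReaction(j).getId() for j in range(n)]
    S = np.zeros((len(internal), n))
    S_ext = np.zeros((len(external), n))
    lb = np.empty(n)
    ub = np.empty(n)
    for j in range(n):
        rxn = sm.getReaction(j)
        for ref, sign in [
            (rxn.getListOfReactants(), -1.0),
            (rxn.getListOfProducts(), +1.0),
        ]:
            for k in range(ref.size()):
                sr = ref.get(k)
                sp, coef = sr.getSpecies(), sign * sr.getStoichiometry()
                if sp in int_idx:
                    S[int_idx[sp], j] += coef
                else:
                    S_ext[ext_idx[sp], j] += coef
        lb[j], ub[j] = _reaction_bounds(sm, rxn)

    c = np.zeros(n)
    mfbc = sm.getPlugin("fbc")
    if mfbc is not None and mfbc.getNumObjectives():
        obj = mfbc.getActiveObjective() or mfbc.getObjective(0)
        sense = -1.0 if obj.getType() == "minimize" else 1.0
        ridx = {r: j for j, r in enumerate(rids)}
        for k in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(k)
            if fo.getReaction() not in ridx:
                raise ModelError(
                    f"objective references unknown reaction {fo.getReaction()!r}"
                )
            c[ridx[fo.getReaction()]] = sense * fo.getCoefficient()

    return MetabolicModel(
        metabolite_ids=internal,
        reaction_ids=rids,
        S=S,
        lower_bounds=lb,
        upper_bounds=ub,
        objective=c,
        external_species=external,
        S_ext=S_ext,
        compartments=compartments,
        name=sm.getId() or path.stem,
    )


def _reaction_bounds(sm, rxn) -> tuple[float, float]:
    rfbc = rxn.getPlugin("fbc")
    if rfbc is not None and rfbc.isSetLowerFluxBound() and rfbc.isSetUpperFluxBound():
        vals = []
        for pid in (rfbc.getLowerFluxBound(), rfbc.getUpperFluxBound()):
            par = sm.getParameter(pid)
            if par is None:
                raise ModelError(
                    f"reaction {rxn.getId()!r} references missing bound "
                    f"parameter {pid!r}"
                )
            vals.append(par.getValue())
        return vals[0], vals[1]
    kl = rxn.getKineticLaw()
    if kl is not None:
        lo = kl.getParameter("LOWER_BOUND")
        hi = kl.getParameter("UPPER_BOUND")
        if lo is not None and hi is not None:
            return lo.getValue(), hi.getValue()
    raise ModelError(
        f"reaction {rxn.getId()!r} has no flux bounds (FBC or kinetic-law); "
        "refusing to guess defaults"
    )


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Write a :class:`MetabolicModel` as SBML L3V1 + FBC v2.

    Identifiers containing characters outside the SBML SId alphabet (e.g.
    ``*`` in lumped-reaction names) are sanitised; the original id is kept
    in the ``name`` attribute.
    """
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sid(model.name))
    mfbc = sm.getPlugin("fbc")
    mfbc.setStrict(True)

    comp_ids = set(model.compartments.values()) or {"c"}
    comp_ids.add("env")
    for cid in sorted(comp_ids):
        comp = sm.createCompartment()
        comp.setId(_sid(cid))
        comp.setConstant(True)

    for mid in model.metabolite_ids:
        sp = sm.createSpecies()
        sp.setId(_sid(mid))
        sp.setName(mid)
        sp.setCompartment(_sid(model.compartments.get(mid, "c")))
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)
    for mid in model.external_species:
        sp = sm.createSpecies()
        sp.setId(_sid(mid))
        sp.setName(mid)
        sp.setCompartment("env")
        sp.setBoundaryCondition(True)
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"bnd_{len(bound_params)}"
            par = sm.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for j, rid in enumerate(model.reaction_ids):
        rxn = sm.createReaction()
        rxn.setId(_sid(rid))
        rxn.setName(rid)
        rxn.setReversible(bool(model.lower_bounds[j] < 0))
        rxn.setFast(False)
        for mids, M in ((model.metabolite_ids, model.S), (model.external_species, model.S_ext)):
            for i, mid in enumerate(mids):
                coef = M[i, j]
                if coef == 0:
                    continue
                sr = rxn.createReactant() if coef < 0 else rxn.createProduct()
                sr.setSpecies(_sid(mid))
                sr.setStoichiometry(abs(float(coef)))
                sr.setConstant(True)
        rfbc = rxn.getPlugin("fbc")
        rfbc.setLowerFluxBound(bound_param(float(model.lower_bounds[j])))
        rfbc.setUpperFluxBound(bound_param(float(model.upper_bounds[j])))

    obj = mfbc.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    mfbc.setActiveObjectiveId("obj")
    for j, rid in enumerate(model.reaction_ids):
        if model.objective[j] != 0:
            fo = obj.createFluxObjective()
            fo.setReaction(_sid(rid))
            fo.setCoefficient(float(model.objective[j]))
    libsbml.writeSBMLToFile(doc, str(path))


# ---------------------------------------------------------------------------
# TSV


def read_tsv_model(
    stoich_path: str | Path, bounds_path: str | Path
) -> MetabolicModel:
    """Read the TSV model pair (see module docstring for the format)."""
    stoich_path, bounds_path = Path(stoich_path), Path(bounds_path)
    triples: dict[tuple[str, str], float] = {}
    external: dict[str, bool] = {}
    with open(stoich_path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, 1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0].lower() in ("metabolite", "met"):
                continue
            if len(row) < 3:
                raise ModelError(
                    f"{stoich_path.name}:{lineno}: expected "
                    "metabolite<TAB>reaction<TAB>coefficient"
                )
            mid, rid, raw = row[0], row[1], row[2]
            try:
                coef = float(raw)
            except ValueError:
                raise ModelError(
                    f"{stoich_path.name}:{lineno}: coefficient {raw!r} is not numeric"
                ) from None
            if (mid, rid) in triples:
                raise ModelError(
                    f"{stoich_path.name}:{lineno}: duplicate entry for "
                    f"({mid}, {rid})"
                )
            triples[(mid, rid)] = coef
            is_ext = mid.endswith("_ext")
            if len(row) >= 4 and row[3] != "":
                is_ext = row[3].strip() in ("1", "true", "True")
            external.setdefault(mid, is_ext)
    if not triples:
        raise ModelError(f"{stoich_path.name}: empty stoichiometry file")

    bounds: dict[str, tuple[float, float, float]] = {}
    rid_order: list[str] = []
    with open(bounds_path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, 1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0].lower() in ("reaction", "rxn"):
                continue
            if len(row) < 4:
                raise ModelError(
                    f"{bounds_path.name}:{lineno}: expected "
                    "reaction<TAB>lb<TAB>ub<TAB>objective_coeff"
                )
            rid = row[0]
            try:
                lo, hi, c = (float(x) for x in row[1:4])
            except ValueError:
                raise ModelError(
                    f"{bounds_path.name}:{lineno}: non-numeric bound/objective"
                ) from None
            bounds[rid] = (lo, hi, c)
            rid_order.append(rid)

    stoich_rids = {rid for _, rid in triples}
    unknown = set(bounds) - stoich_rids
    if unknown:
        raise ModelError(
            f"{bounds_path.name}: bounds for unknown reactions {sorted(unknown)}"
        )
    missing = stoich_rids - set(bounds)
    if missing:
        raise ModelError(
            f"{bounds_path.name}: no bounds for reactions {sorted(missing)}"
        )

    internal = sorted(m for m, is_ext in external.items() if not is_ext)
    ext = sorted(m for m, is_ext in external.items() if is_ext)
    rids = [r for r in rid_order if r in stoich_rids]
    S = np.zeros((len(internal), len(rids)))
    S_ext = np.zeros((len(ext), len(rids)))
    int_idx = {m: i for i, m in enumerate(internal)}
    ext_idx = {m: i for i, m in enumerate(ext)}
    ridx = {r: j for j, r in enumerate(rids)}
    for (mid, rid), coef in triples.items():
        if mid in int_idx:
            S[int_idx[mid], ridx[rid]] = coef
        else:
            S_ext[ext_idx[mid], ridx[rid]] = coef
    arr = np.array([bounds[r] for r in rids])
    return MetabolicModel(
        metabolite_ids=internal,
        reaction_ids=rids,
        S=S,
        lower_bounds=arr[:, 0],
        upper_bounds=arr[:, 1],
        objective=arr[:, 2],
        external_species=ext,
        S_ext=S_ext,
        name=stoich_path.stem,
    )


def write_tsv_model(
    model: MetabolicModel, stoich_path: str | Path, bounds_path: str | Path
) -> None:
    """Write the TSV model pair (inverse of :func:`read_tsv_model`)."""
    with open(stoich_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["metabolite", "reaction", "coefficient", "external"])
        for mids, M, flag in (
            (model.metabolite_ids, model.S, "0"),
            (model.external_species, model.S_ext, "1"),
        ):
            for i, mid in enumerate(mids):
                for j, rid in enumerate(model.reaction_ids):
                    if M[i, j] != 0:
                        w.writerow([mid, rid, repr(float(M[i, j])), flag])
    with open(bounds_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["reaction", "lb", "ub", "objective_coeff"])
        for j, rid in enumerate(model.reaction_ids):
            w.writerow(
                [
                    rid,
                    repr(float(model.lower_bounds[j])),
                    repr(float(model.upper_bounds[j])),
                    repr(float(model.objective[j])),
                ]
            )


# ---------------------------------------------------------------------------
# protection specs


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<fbamax>FBA_MAX\(\s*(?P<fm_id>[A-Za-z_][\w.\-]*)\s*\))"
    r"|(?P<num>[0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?)"
    r"|(?P<id>[A-Za-z_][\w.\-]*)"
    r"|(?P<op>[+\-*]))"
)


def _parse_side(text: str, where: str):
    """Parse one side of a constraint into (coefs, const, fbamax terms).

    Grammar: signed terms separated by +/-, each term being a number, an
    identifier, ``FBA_MAX(id)``, or ``number [*] (identifier|FBA_MAX(id))``.
    """
    toks: list[tuple[str, object]] = []
    pos = 0
    while pos < len(text):
        if text[pos].isspace():
            pos += 1
            continue
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            raise ModelError(f"cannot parse constraint {where}: {text[pos:]!r}")
        pos = m.end()
        if m.group("fbamax") is not None:
            toks.append(("fbamax", m.group("fm_id")))
        elif m.group("num") is not None:
            toks.append(("num", float(m.group("num"))))
        elif m.group("id") is not None:
            toks.append(("id", m.group("id")))
        else:
            toks.append(("op", m.group("op")))

    coefs: dict[str, float] = {}
    const = 0.0
    fbamax: list[tuple[float, str]] = []
    i = 0
    while i < len(toks):
        sign = 1.0
        while i < len(toks) and toks[i][0] == "op" and toks[i][1] in "+-":
            if toks[i][1] == "-":
                sign = -sign
            i += 1
        if i >= len(toks):
            raise ModelError(f"dangling sign in constraint {where}")
        kind, val = toks[i]
        if kind == "num":
            coef = sign * float(val)
            i += 1
            if i < len(toks) and toks[i] == ("op", "*"):
                i += 1
                if i >= len(toks) or toks[i][0] not in ("id", "fbamax"):
                    raise ModelError(f"'*' without operand in constraint {where}")
            if i < len(toks) and toks[i][0] in ("id", "fbamax"):
                kind2, val2 = toks[i]
                i += 1
                if kind2 == "id":
                    coefs[val2] = coefs.get(val2, 0.0) + coef
                else:
                    fbamax.append((coef, str(val2)))
            else:
                const += coef
        elif kind == "id":
            coefs[val] = coefs.get(val, 0.0) + sign
            i += 1
        elif kind == "fbamax":
            fbamax.append((sign, str(val)))
            i += 1
        else:
            raise ModelError(f"unexpected {val!r} in constraint {where}")
    return coefs, const, fbamax


_REL_RE = re.compile(r"(<=|>=|==|=|<|>)")


def parse_constraint(text: str):
    """Parse ``"a*R1 + b*R2 <= rhs"``-style strings.

    Returns ``(coefs, relation, rhs_const, fbamax_terms)`` where
    *fbamax_terms* is a list of ``(coefficient, reaction_id)`` pairs whose
    resolved values are added to the right-hand side.
    """
    parts = _REL_RE.split(text)
    if len(parts) != 3:
        raise ModelError(
            f"constraint {text!r} must contain exactly one relation (<=, >=, =)"
        )
    lhs, rel, rhs = parts
    lc, lconst, lfm = _parse_side(lhs, f"{text!r} (lhs)")
    rc, rconst, rfm = _parse_side(rhs, f"{text!r} (rhs)")
    coefs = dict(lc)
    for rid, coef in rc.items():
        coefs[rid] = coefs.get(rid, 0.0) - coef
    const = rconst - lconst
    fbamax = [(c, rid) for c, rid in rfm] + [(-c, rid) for c, rid in lfm]
    return coefs, rel, const, fbamax


def read_protection_spec(
    path: str | Path, model: MetabolicModel
) -> ProtectionSpec:
    """Load and validate a YAML protection spec against *model*.

    ``FBA_MAX(reaction)`` tokens in scenario constraints are resolved by LP
    on the full model (under the scenario's bound overrides and plain
    constraints); the resolved values are logged and stored on the returned
    spec as ``fba_max_resolutions``.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ModelError(f"{path.name}: protection spec must be a mapping")
    return build_protection_spec(raw, model)


def build_protection_spec(
    raw: Mapping, model: MetabolicModel
) -> ProtectionSpec:
    """Build a :class:`ProtectionSpec` from an already-parsed mapping."""
    known = {
        "protected_metabolites",
        "protected_reactions",
        "enforce_protected_feasibility",
        "scenarios",
        "dof_min",
        "n_min",
    }
    unknown = set(raw) - known
    if unknown:
        raise ModelError(f"unknown protection-spec keys: {sorted(unknown)}")

    resolutions: dict[str, float] = {}
    scenarios: list[Scenario] = []
    for sdata in raw.get("scenarios", []) or []:
        name = sdata.get("name", f"scenario_{len(scenarios) + 1}")
        overrides = {}
        for rid, pair in (sdata.get("bound_overrides") or {}).items():
            if rid not in model.reaction_ids:
                raise ModelError(
                    f"scenario {name!r}: bound override for unknown reaction {rid!r}"
                )
            overrides[rid] = (float(pair[0]), float(pair[1]))
        scen = Scenario(name=name, bound_overrides=overrides)
        deferred = []
        for text in sdata.get("constraints", []) or []:
            coefs, rel, const, fbamax = parse_constraint(str(text))
            unknown_r = set(coefs) - set(model.reaction_ids)
            if unknown_r:
                raise ModelError(
                    f"scenario {name!r}: constraint {text!r} references "
                    f"unknown reactions {sorted(unknown_r)}"
                )
            if fbamax:
                deferred.append((text, coefs, rel, const, fbamax))
            else:
                scen.add(coefs, rel, const)
        # resolve FBA_MAX tokens against the full model under this
        # scenario's plain constraints and bound overrides
        for text, coefs, rel, const, fbamax in deferred:
            rhs = const
            for coef, rid in fbamax:
                if rid not in model.reaction_ids:
                    raise ModelError(
                        f"scenario {name!r}: FBA_MAX references unknown "
                        f"reaction {rid!r}"
                    )
                res = lp.fba(model, {rid: 1.0}, scen)
                if res.status != "optimal":
                    raise ModelError(
                        f"scenario {name!r}: FBA_MAX({rid}) is {res.status} "
                        "on the full model"
                    )
                key = f"{name}:FBA_MAX({rid})"
                resolutions[key] = res.objective_value
                logger.info("resolved %s = %.6g", key, res.objective_value)
                rhs += coef * res.objective_value
            scen.add(coefs, rel, rhs)
        scenarios.append(scen)

    spec = ProtectionSpec(
        protected_metabolites=set(raw.get("protected_metabolites") or []),
        protected_reactions=set(raw.get("protected_reactions") or []),
        enforce_protected_feasibility=bool(
            raw.get("enforce_protected_feasibility", False)
        ),
        scenarios=scenarios,
        dof_min=int(raw.get("dof_min", 1)),
        n_min=int(raw.get("n_min", 1)),
    )
    spec.validate_against(model)
    spec.fba_max_resolutions = resolutions  # type: ignore[attr-defined]
    return spec


# ---------------------------------------------------------------------------
# model transforms


def add_biomass_tracker(
    model: MetabolicModel,
    biomass_reaction_id: str,
    metabolite_id: str = "biomass",
    export_id: str = "EX_biomass",
) -> MetabolicModel:
    """Add a biomass pseudo-metabolite and its export reaction.

    The biomass reaction gains the pseudo-metabolite as a product with
    coefficient 1 and a new irreversible export reaction drains it; the
    export flux then equals the growth rate and the coefficient of the
    biomass compound stays visible through compression.  Never applied
    silently — callers opt in.
    """
    j = model.reaction_index(biomass_reaction_id)
    if metabolite_id in model.metabolite_ids or metabolite_id in model.external_species:
        raise ModelError(f"metabolite {metabolite_id!r} already exists")
    if export_id in model.reaction_ids:
        raise ModelError(f"reaction {export_id!r} already exists")
    m = model.copy()
    row = np.zeros((1, m.n_reactions))
    row[0, j] = 1.0
    S = np.vstack([m.S, row])
    col = np.zeros((S.shape[0], 1))
    col[-1, 0] = -1.0
    S = np.hstack([S, col])
    S_ext = np.hstack([m.S_ext, np.zeros((m.S_ext.shape[0], 1))])
    return MetabolicModel(
        metabolite_ids=m.metabolite_ids + [metabolite_id],
        reaction_ids=m.reaction_ids + [export_id],
        S=S,
        lower_bounds=np.append(m.lower_bounds, 0.0),
        upper_bounds=np.append(m.upper_bounds, _INF),
        objective=np.append(m.objective, 0.0),
        external_species=m.external_species,
        S_ext=S_ext,
        compartments=m.compartments,
        name=m.name,
    )
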