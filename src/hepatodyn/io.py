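"""Readers and writers: the native structured-text model format (source of
truth), SBML Level 3 interchange, boundary-profile tables, and run
manifests.  All file writes are atomic (temp file + rename)."""

from __future__ import annotations

import datetime
import hashlib
import json
import os
import tempfile

import numpy as np
import pandas as pd
import sympy as sp

from .boundary import BoundaryProfile
from .model import (Compartment, KineticModel, MembranePotential, Parameter,
                    PhosphoFunction, Reaction, Species)
from .ratelaws import RateLaw

SCHEMA = "hepatodyn-model/1"
ANNOT_NS = "https://hepatodyn.invalid/sbml/annotations"


class ModelIOError(ValueError):
    pass


def atomic_write_text(path, text: str) -> None:
    path = os.fspath(path)
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", suffix="~")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ------------------------------------------------------------- native format

def model_to_dict(model: KineticModel) -> dict:
    return {
        "schema": SCHEMA,
        "id": model.id,
        "notes": model.notes,
        "compartments": [{"id": c.id, "volume_fraction": c.volume_fraction,
                          "name": c.name} for c in model.compartments.values()],
        "species": [{"id": s.id, "compartment": s.compartment, "role": s.role,
                     "initial_concentration": s.initial_concentration,
                     "bounds": list(s.bounds) if s.bounds else None,
                     "name": s.name} for s in model.species.values()],
        "parameters": [{"id": p.id, "value": p.value, "category": p.category,
                        "unit": p.unit, "reaction": p.reaction, "note": p.note}
                       for p in model.parameters.values()],
        "phospho_functions": [{"id": f.id, "half_saturation": f.half_saturation,
                               "steepness": f.steepness, "direction": f.direction,
                               "glucose_species": f.glucose_species}
                              for f in model.phospho_functions.values()],
        "membrane_potential": (
            {"capacitance": model.membrane_potential.capacitance,
             "initial_mv": model.membrane_potential.initial_mv}
            if model.membrane_potential else None),
        "reactions": [{"id": r.id, "stoichiometry": dict(r.stoichiometry),
                       "charge_transfer": r.charge_transfer,
                       "pathway": r.pathway, "name": r.name,
                       "vmax_ref": r.vmax_ref,
                       "rate_law": {"kind": r.rate_law.kind,
                                    "expression": r.rate_law.expression,
                                    "modifiers": [list(mo) for mo in
                                                  r.rate_law.modifiers],
                                    "vmax_params": list(r.rate_law.vmax_params)}}
                      for r in model.reactions.values()],
    }


def model_from_dict(doc: dict) -> KineticModel:
    if doc.get("schema") != SCHEMA:
        raise ModelIOError(f"unsupported model schema {doc.get('schema')!r}")
    m = KineticModel(id=doc["id"], notes=doc.get("notes", ""))
    for c in doc["compartments"]:
        m.compartments[c["id"]] = Compartment(c["id"], c["volume_fraction"],
                                              c.get("name", ""))
    for s in doc["species"]:
        m.species[s["id"]] = Species(
            s["id"], s["compartment"], s.get("role", "internal"),
            s.get("initial_concentration", 0.0),
            tuple(s["bounds"]) if s.get("bounds") else None, s.get("name", ""))
    for p in doc["parameters"]:
        m.parameters[p["id"]] = Parameter(p["id"], p["value"],
                                          p.get("category", "OTHER"),
                                          p.get("unit", ""),
                                          p.get("reaction"), p.get("note", ""))
    for f in doc.get("phospho_functions", []):
        m.phospho_functions[f["id"]] = PhosphoFunction(
            f["id"], f["half_saturation"], f["steepness"], f["direction"],
            f.get("glucose_species", "glc_ext"))
    mp = doc.get("membrane_potential")
    if mp:
        m.membrane_potential = MembranePotential(mp["capacitance"],
                                                 mp.get("initial_mv", 150.0))
    for r in doc["reactions"]:
        rl = r["rate_law"]
        law = RateLaw(kind=rl["kind"], expression=rl["expression"],
                      modifiers=[tuple(mo) for mo in rl.get("modifiers", [])],
                      vmax_params=list(rl.get("vmax_params", [])))
        m.reactions[r["id"]] = Reaction(
            r["id"], dict(r["stoichiometry"]), law, r.get("vmax_ref"),
            r.get("charge_transfer", 0.0), r.get("pathway", ""),
            r.get("name", ""))
    m.validate()
    return m


def write_model(model: KineticModel, path, fmt: str | None = None) -> None:
    fmt = fmt or _guess_format(path)
    if fmt == "native":
        atomic_write_text(path, json.dumps(model_to_dict(model), indent=2) + "\n")
    elif fmt == "sbml":
        atomic_write_text(path, model_to_sbml(model))
    else:
        raise ModelIOError(f"unknown model format {fmt!r}")


def read_model(path, fmt: str | None = None) -> KineticModel:
    fmt = fmt or _guess_format(path)
    with open(path) as fh:
        text = fh.read()
    if fmt == "native":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ModelIOError(f"{path}: not valid JSON ({exc})") from exc
        return model_from_dict(doc)
    if fmt == "sbml":
        return model_from_sbml(text)
    raise ModelIOError(f"unknown model format {fmt!r}")


def _guess_format(path) -> str:
    p = os.fspath(path).lower()
    if p.endswith((".xml", ".sbml")):
        return "sbml"
    return "native"


# ------------------------------------------------------------------- SBML L3

def _l3_formula(expr: sp.Expr) -> str:
    """Render a sympy expression as an SBML L3 formula string."""
    if isinstance(expr, sp.Piecewise):
        parts = []
        for val, cond in expr.args:
            if cond == sp.true:
                parts.append(_l3_formula(val))
            else:
                parts.extend([_l3_formula(val), _l3_formula(cond)])
        return "piecewise(" + ", ".join(parts) + ")"
    if isinstance(expr, sp.Abs):
        return f"abs({_l3_formula(expr.args[0])})"
    if isinstance(expr, sp.exp):
        return f"exp({_l3_formula(expr.args[0])})"
    if isinstance(expr, sp.StrictLessThan):
        return f"({_l3_formula(expr.args[0])} < {_l3_formula(expr.args[1])})"
    if isinstance(expr, sp.Add):
        return "(" + " + ".join(_l3_formula(a) for a in expr.args) + ")"
    if isinstance(expr, sp.Mul):
        return "(" + " * ".join(_l3_formula(a) for a in expr.args) + ")"
    if isinstance(expr, sp.Pow):
        return f"({_l3_formula(expr.base)} ^ {_l3_formula(expr.exp)})"
    if isinstance(expr, (sp.Symbol,)):
        return expr.name
    if expr.is_Number:
        return repr(float(expr)) if not expr.is_Integer else str(int(expr))
    raise ModelIOError(f"cannot render {type(expr).__name__} as SBML math")


def model_to_sbml(model: KineticModel) -> str:
    """Serialize to an executable SBML Level 3 document.

    Kinetic laws are written as L3 math; package-specific metadata
    (parameter categories, canonical rate-law strings, charge transfers,
    phosphorylation functions) travels in annotations so a round trip
    through SBML reproduces simulations exactly.
    """
    import libsbml
    doc = libsbml.SBMLDocument(3, 2)
    sm = doc.createModel()
    sm.setId(model.id.replace("-", "_"))
    for c in model.compartments.values():
        sc = sm.createCompartment()
        sc.setId(c.id)
        sc.setSize(c.volume_fraction)
        sc.setConstant(True)
        sc.setSpatialDimensions(3)
    for s in model.species.values():
        ss = sm.createSpecies()
        ss.setId(s.id)
        ss.setCompartment(s.compartment)
        ss.setInitialConcentration(s.initial_concentration)
        ss.setBoundaryCondition(s.role == "external")
        ss.setConstant(False)
        ss.setHasOnlySubstanceUnits(False)
        if s.bounds:
            ss.setAnnotation(
                f'<h:species xmlns:h="{ANNOT_NS}" '
                f'min="{s.bounds[0]!r}" max="{s.bounds[1]!r}"/>')
    for p in model.parameters.values():
        spar = sm.createParameter()
        spar.setId(p.id)
        spar.setValue(p.value)
        spar.setConstant(True)
        spar.setAnnotation(
            f'<h:parameter xmlns:h="{ANNOT_NS}" category="{p.category}"/>')
    if model.membrane_potential is not None:
        spar = sm.createParameter()
        spar.setId("dpsi")
        spar.setValue(model.membrane_potential.initial_mv)
        spar.setConstant(False)
        rule = sm.createRateRule()
        rule.setVariable("dpsi")
        terms = [f"({r.charge_transfer!r} * {r.id})"
                 for r in model.reactions.values() if r.charge_transfer]
        cap = model.membrane_potential.capacitance
        ast = libsbml.parseL3Formula(f"({' + '.join(terms) or '0'}) / {cap!r}")
        rule.setMath(ast)
    for r in model.reactions.values():
        sr = sm.createReaction()
        sr.setId(r.id)
        sr.setReversible(True)
        for sid, coeff in r.stoichiometry.items():
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
        kl = sr.createKineticLaw()
        ast = libsbml.parseL3Formula(_l3_formula(r.rate_law.expr))
        if ast is None:
            raise ModelIOError(f"reaction {r.id!r}: kinetic law failed to parse")
        kl.setMath(ast)
        meta = {"kind": r.rate_law.kind, "expression": r.rate_law.expression,
                "modifiers": [list(mo) for mo in r.rate_law.modifiers],
                "vmax_params": list(r.rate_law.vmax_params),
                "charge_transfer": r.charge_transfer, "pathway": r.pathway,
                "vmax_ref": r.vmax_ref}
        sr.setAnnotation(
            f'<h:reaction xmlns:h="{ANNOT_NS}"><![CDATA['
            + json.dumps(meta) + "]]></h:reaction>")
    header = {"schema": SCHEMA, "notes": model.notes,
              "phospho_functions": [
                  {"id": f.id, "half_saturation": f.half_saturation,
                   "steepness": f.steepness, "direction": f.direction,
                   "glucose_species": f.glucose_species}
                  for f in model.phospho_functions.values()],
              "membrane_potential": (
                  {"capacitance": model.membrane_potential.capacitance,
                   "initial_mv": model.membrane_potential.initial_mv}
                  if model.membrane_potential else None),
              "species_roles": {s.id: s.role for s in model.species.values()},
              "model_id": model.id}
    sm.setAnnotation(f'<h:model xmlns:h="{ANNOT_NS}"><![CDATA['
                     + json.dumps(header) + "]]></h:model>")
    return libsbml.writeSBMLToString(doc)


def _annotation_json(node) -> dict | None:
    """Extract the JSON payload of a package annotation element (libsbml
    flattens CDATA sections into entity-escaped text)."""
    if node is None or not node.isSetAnnotation():
        return None
    import re
    from xml.sax.saxutils import unescape
    text = node.getAnnotationString()
    mm = re.search(r"<h:(?:reaction|model)[^>]*>(.*?)</h:(?:reaction|model)>",
                   text, re.S)
    if not mm:
        return None
    payload = unescape(mm.group(1), {"&quot;": '"', "&apos;": "'"}).strip()
    payload = payload.replace("<![CDATA[", "").replace("]]>", "")
    if not payload:
        return None
    try:
        return json.loads(payload)
    except json.JSONDecodeError:
        return None


def _attr_annotation(node, names) -> dict:
    out = {}
    if node is None or not node.isSetAnnotation():
        return out
    text = node.getAnnotationString()
    import re
    for n in names:
        mm = re.search(rf'{n}="([^"]+)"', text)
        if mm:
            out[n] = mm.group(1)
    return out


def model_from_sbml(text: str) -> KineticModel:
    import libsbml
    doc = libsbml.readSBMLFromString(text)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelIOError(
            f"SBML parse error at line {err.getLine()}: {err.getMessage()}")
    sm = doc.getModel()
    if sm is None:
        raise ModelIOError("SBML document contains no model")
    header = _annotation_json(sm) or {}
    roles = header.get("species_roles", {})
    m = KineticModel(id=header.get("model_id", sm.getId() or "sbml-model"),
                     notes=header.get("notes", ""))
    for i in range(sm.getNumCompartments()):
        c = sm.getCompartment(i)
        m.compartments[c.getId()] = Compartment(
            c.getId(), c.getSize() if c.isSetSize() else 1.0, c.getName() or "")
    for i in range(sm.getNumSpecies()):
        s = sm.getSpecies(i)
        role = roles.get(s.getId(),
                         "external" if s.getBoundaryCondition() else "internal")
        ann = _attr_annotation(s, ["min", "max"])
        bounds = (float(ann["min"]), float(ann["max"])) if ann else None
        conc = s.getInitialConcentration() if s.isSetInitialConcentration() else 0.0
        m.species[s.getId()] = Species(s.getId(), s.getCompartment(), role,
                                       conc, bounds, s.getName() or "")
    for i in range(sm.getNumParameters()):
        p = sm.getParameter(i)
        if p.getId() == "dpsi":
            continue
        cat = _attr_annotation(p, ["category"]).get("category", "OTHER")
        m.parameters[p.getId()] = Parameter(p.getId(), p.getValue(), cat)
    for f in header.get("phospho_functions", []):
        m.phospho_functions[f["id"]] = PhosphoFunction(
            f["id"], f["half_saturation"], f["steepness"], f["direction"],
            f.get("glucose_species", "glc_ext"))
    mp = header.get("membrane_potential")
    if mp:
        m.membrane_potential = MembranePotential(mp["capacitance"],
                                                 mp.get("initial_mv", 150.0))
    for i in range(sm.getNumReactions()):
        r = sm.getReaction(i)
        meta = _annotation_json(r)
        stoich = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) \
                - ref.getStoichiometry()
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) \
                + ref.getStoichiometry()
        if meta is not None:
            law = RateLaw(kind=meta["kind"], expression=meta["expression"],
                          modifiers=[tuple(mo) for mo in meta["modifiers"]],
                          vmax_params=list(meta["vmax_params"]))
            charge = meta.get("charge_transfer", 0.0)
            pathway = meta.get("pathway", "")
            vmax_ref = meta.get("vmax_ref")
        else:
            kl = r.getKineticLaw()
            if kl is None or kl.getMath() is None:
                raise ModelIOError(f"reaction {r.getId()!r}: no kinetic law")
            formula = libsbml.formulaToL3String(kl.getMath())
            if "piecewise" in formula:
                raise ModelIOError(
                    f"reaction {r.getId()!r}: piecewise kinetic laws need "
                    f"package annotations to import")
            from .ratelaws import custom
            law = custom(formula.replace("^", "**"))
            charge, pathway, vmax_ref = 0.0, "", None
        m.reactions[r.getId()] = Reaction(r.getId(), stoich, law, vmax_ref,
                                          charge, pathway, r.getName() or "")
    unknown = set()
    for rxn in m.reactions.values():
        unknown |= rxn.rate_law.symbols() - set(m.species) - set(m.parameters) \
            - {"dpsi", "t"}
    if unknown:
        raise ModelIOError(f"SBML kinetic laws reference undefined entities: "
                           f"{sorted(unknown)}")
    m.validate()
    return m


# ------------------------------------------------------------ boundary files

def write_boundary_profile(profile: BoundaryProfile, path) -> None:
    df = pd.DataFrame({"time_h": profile.times})
    for sid in profile.species_ids:
        df[sid] = profile.values[sid]
    atomic_write_text(path, df.to_csv(sep="\t", index=False))


def read_boundary_profile(path, period: float = 24.0) -> BoundaryProfile:
    """Read a delimited profile (header row, first column time in hours).

    Negative concentrations are rejected with their row number;
    periodicity is auto-detected when the span is one period and every
    column's endpoints agree within 1e-6.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ModelIOError(f"{path}: need a time column plus >= 1 species")
    t = df.iloc[:, 0].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 2
        raise ModelIOError(f"{path}: time not strictly increasing at row {bad}")
    values = {}
    for col in df.columns[1:]:
        v = df[col].to_numpy(float)
        if np.any(v < 0):
            bad = int(np.argmax(v < 0)) + 2
            raise ModelIOError(f"{path}: negative concentration for "
                               f"{col!r} at row {bad}")
        values[col] = v
    periodic = bool(np.isclose(t[-1] - t[0], period)
                    and all(abs(v[0] - v[-1]) <= 1e-6 * max(1.0, abs(v[0]))
                            for v in values.values()))
    return BoundaryProfile(t, values, periodic=periodic, period=period)


# --------------------------------------------------------------- manifests

def run_manifest(command: str, seed=None, config: dict | None = None,
                 model: KineticModel | None = None,
                 integrator: dict | None = None) -> dict:
    from . import __version__
    cfg_text = json.dumps(config or {}, sort_keys=True, default=str)
    return {
        "command": command,
        "tool": "hepatodyn",
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest()[:16],
        "config": config or {},
        "model_hash": model.content_hash() if model is not None else None,
        "integrator": integrator or {},
        "timestamp_utc": datetime.datetime.now(datetime.timezone.utc)
                         .isoformat(timespec="seconds"),
    }


def write_manifest(manifest: dict, path) -> None:
    atomic_write_text(path, json.dumps(manifest, indent=2, default=str) + "\n")
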