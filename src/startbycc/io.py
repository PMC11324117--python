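"""Standard-format interoperability: XPP .ode, SBML L3, CSV, catalogs.

The native persistence format is an XPP-style ``.ode`` dialect (``par``,
``init``, ``aux``, ``dX/dt=...`` lines) because it is fully self-contained
and human-auditable; SBML Level 3 is exported from the same declarative
network (compartments nucleus/cytoplasm/cell, one reaction element per
network reaction, assignment rules for the algebraic quantities).  All
writers are deterministic: identical inputs give byte-identical files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import model_core
from .model_core import AUX_DEFS, ModelSystem, build_model
from .simulate import Trajectory

__all__ = [
    "ModelDocument",
    "OdeParseError",
    "model_document",
    "write_ode",
    "read_ode_file",
    "export_sbml",
    "read_sbml",
    "write_trajectory_csv",
    "write_events_csv",
    "write_report_csv",
]


class OdeParseError(ValueError):
    """Line-numbered syntax or reference error in an .ode file."""


@dataclass
class ModelDocument:
    """Declarative model text: species, parameters, rules, events, ICs."""

    parameters: dict[str, float] = field(default_factory=dict)
    initial_conditions: dict[str, float] = field(default_factory=dict)
    odes: dict[str, str] = field(default_factory=dict)  # species -> rhs expr
    aux: list[tuple[str, str]] = field(default_factory=list)
    events: list[str] = field(default_factory=list)
    compartments: dict[str, float] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)
    unparsed: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# building a document from the compiled system
# --------------------------------------------------------------------------

def _species_rhs_expression(system: ModelSystem, name: str) -> str:
    """Assemble the symbolic net rate expression of one species."""
    layout = system.layout
    vol = {s.name: layout.volume(s.compartment) for s in system.species}
    terms = []
    for r in system.reactions:
        if name not in r.stoich:
            continue
        coeff = r.stoich[name] * layout.volume(r.compartment) / vol[name]
        rate = f"({r.rate})"
        if coeff == 1:
            terms.append("+" + rate)
        elif coeff == -1:
            terms.append("-" + rate)
        else:
            terms.append(f"{'+' if coeff > 0 else '-'}{abs(coeff):g}*{rate}")
    return " ".join(terms) if terms else "0"


def model_document(system: ModelSystem | None = None,
                   mutant=None) -> ModelDocument:
    """Flatten a compiled system (default: wildtype) into a ModelDocument."""
    if system is None:
        system = build_model(mutant=mutant)
    from .model_core import initial_conditions
    ics = initial_conditions(params=system.parameters)
    doc = ModelDocument()
    doc.metadata["model"] = "START-BYCC"
    doc.metadata["time_unit"] = "minute"
    doc.metadata["concentration_unit"] = "dimensionless (a.u.)"
    doc.compartments = {
        "nucleus": system.layout.nuclear_fraction,
        "cytoplasm": system.layout.cytoplasmic_fraction,
        "cell": 1.0,
    }
    for k in sorted(system.parameters):
        doc.parameters[k] = float(system.parameters[k])
    for i, sp in enumerate(system.species):
        doc.initial_conditions[sp.name] = float(ics.concentrations[i])
        doc.odes[sp.name] = _species_rhs_expression(system, sp.name)
    doc.aux = [(n, e) for n, e in AUX_DEFS]
    doc.events = [
        "division: when CLB2A crosses thdiv downward after SPN>=1: "
        "MASS -> fdaughter*MASS (daughter) or (1-fdaughter)*MASS (mother); "
        "BUD, ORI, SPN -> 0",
    ]
    return doc


# --------------------------------------------------------------------------
# XPP-dialect .ode writer / reader
# --------------------------------------------------------------------------

def _to_xpp(expr: str) -> str:
    """Translate a rate expression into XPP syntax (** -> ^ etc.)."""
    e = expr.replace("**", "^")
    e = e.replace("pos(", "max(0,")
    return e


def _from_xpp(expr: str) -> str:
    e = expr.replace("^", "**")
    return e


def write_ode(doc: ModelDocument, path) -> None:
    """Write the document as an XPP-style .ode file (deterministic)."""
    lines: list[str] = []
    for k, v in sorted(doc.metadata.items()):
        lines.append(f"# {k}: {v}")
    for name, size in doc.compartments.items():
        lines.append(f"# compartment {name} {size:g}")
    for ev in doc.events:
        lines.append(f"# event {ev}")
    for k in sorted(doc.parameters):
        lines.append(f"par {k}={doc.parameters[k]:.17g}")
    for k in doc.initial_conditions:
        lines.append(f"init {k}={doc.initial_conditions[k]:.17g}")
    for name, expr in doc.aux:
        lines.append(f"{name}={_to_xpp(expr)}")
    for k, expr in doc.odes.items():
        lines.append(f"d{k}/dt={_to_xpp(expr)}")
    lines.append("done")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


_ODE_PAR = re.compile(r"^par(?:am)?\s+(.+)$", re.I)
_ODE_INIT = re.compile(r"^init\s+(.+)$", re.I)
_ODE_DDT = re.compile(r"^d([A-Za-z_]\w*)/dt\s*=\s*(.+)$")
_ODE_XPPDDT = re.compile(r"^([A-Za-z_]\w*)'\s*=\s*(.+)$")
_ODE_AUX = re.compile(r"^aux\s+([A-Za-z_]\w*)\s*=\s*(.+)$", re.I)
_ODE_ASSIGN = re.compile(r"^([A-Za-z_]\w*)\s*=\s*(.+)$")
_NAME = re.compile(r"(?<![\w.])[A-Za-z_]\w*")

_BUILTINS = {"hill", "gkf", "sqrt", "exp", "log", "pos", "max", "min",
             "t", "heav", "abs"}


def read_ode_file(path) -> ModelDocument:
    """Parse an XPP-dialect .ode file into a ModelDocument.

    Supports ``par``/``init``/``aux`` lines, ``dX/dt=`` and ``X'=`` ODE
    forms, and plain algebraic assignments.  ``@`` option lines, ``global``
    events and unknown directives are collected under ``unparsed`` (and a
    warning note), never silently dropped.  Undefined symbols in any
    equation raise a reference error naming the symbol.
    """
    doc = ModelDocument()
    with open(path) as fh:
        raw_lines = fh.readlines()
    for ln, raw in enumerate(raw_lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            if line.startswith("# event "):
                doc.events.append(line[len("# event "):])
            elif line.startswith("# compartment "):
                try:
                    _, _, name, size = line.split(None, 3)
                    doc.compartments[name] = float(size)
                except ValueError:
                    doc.unparsed.append(f"{ln}: {line}")
            continue
        if line.lower() == "done":
            break
        if line.startswith("@") or line.lower().startswith(("global", "wiener",
                                                            "table", "option")):
            doc.unparsed.append(f"{ln}: {line}")
            continue
        m = _ODE_PAR.match(line)
        if m:
            for part in m.group(1).replace(";", ",").split(","):
                part = part.strip()
                if not part:
                    continue
                if "=" not in part:
                    raise OdeParseError(f"line {ln}: malformed par {part!r}")
                k, v = part.split("=", 1)
                try:
                    doc.parameters[k.strip()] = float(v)
                except ValueError:
                    raise OdeParseError(f"line {ln}: bad number {v!r}")
            continue
        m = _ODE_INIT.match(line)
        if m:
            for part in m.group(1).replace(";", ",").split(","):
                part = part.strip()
                if not part:
                    continue
                if "=" not in part:
                    raise OdeParseError(f"line {ln}: malformed init {part!r}")
                k, v = part.split("=", 1)
                try:
                    doc.initial_conditions[k.strip()] = float(v)
                except ValueError:
                    raise OdeParseError(f"line {ln}: bad number {v!r}")
            continue
        m = _ODE_DDT.match(line) or _ODE_XPPDDT.match(line)
        if m:
            doc.odes[m.group(1)] = _from_xpp(m.group(2).strip())
            continue
        m = _ODE_AUX.match(line)
        if m:
            doc.aux.append((m.group(1), _from_xpp(m.group(2).strip())))
            continue
        m = _ODE_ASSIGN.match(line)
        if m:
            doc.aux.append((m.group(1), _from_xpp(m.group(2).strip())))
            continue
        raise OdeParseError(f"line {ln}: cannot parse {line!r}")

    # reference check: every symbol must resolve
    defined = (set(doc.parameters) | set(doc.odes) | {a for a, _ in doc.aux}
               | set(doc.initial_conditions) | _BUILTINS)
    for owner, expr in list(doc.odes.items()) + list(doc.aux):
        for sym in set(_NAME.findall(expr)):
            if sym not in defined:
                raise OdeParseError(
                    f"undefined symbol {sym!r} in equation for {owner}")
    # species with ICs but no ODE default to constants (XPP allows this)
    return doc


# --------------------------------------------------------------------------
# SBML Level 3 export / read-back
# --------------------------------------------------------------------------

_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"


def export_sbml(doc: ModelDocument) -> str:
    """Serialize a ModelDocument as SBML Level 3 Version 2 text.

    Compartments nucleus/cytoplasm/cell carry the fixed volume fractions;
    every state variable becomes a species with a rate rule, every auxiliary
    quantity an assignment rule, and the division rule is recorded as an
    event annotation (the discrete lineage choice is simulator state, not
    SBML-expressible without delays).  Output is deterministic.
    """
    from lxml import etree

    nsmap = {None: _SBML_NS}
    root = etree.Element("sbml", nsmap=nsmap, level="3", version="2")
    model = etree.SubElement(root, "model", id="START_BYCC",
                             name="START-BYCC budding yeast cell cycle",
                             timeUnits="time")
    notes = etree.SubElement(model, "notes")
    body = etree.SubElement(notes, "{http://www.w3.org/1999/xhtml}body")
    body.text = ("Time unit: minute; concentrations dimensionless (a.u.). "
                 + "; ".join(f"{k}: {v}" for k, v in sorted(doc.metadata.items())))

    lod = etree.SubElement(model, "listOfCompartments")
    for name, size in doc.compartments.items():
        etree.SubElement(lod, "compartment", id=name, size=repr(float(size)),
                         constant="true", spatialDimensions="3")

    los = etree.SubElement(model, "listOfSpecies")
    comp_of = _compartment_mapping(doc)
    for name, ic in doc.initial_conditions.items():
        etree.SubElement(
            los, "species", id=name, compartment=comp_of.get(name, "cell"),
            initialConcentration=repr(float(ic)),
            hasOnlySubstanceUnits="false", boundaryCondition="false",
            constant="false")

    lop = etree.SubElement(model, "listOfParameters")
    for k in sorted(doc.parameters):
        etree.SubElement(lop, "parameter", id=k,
                         value=repr(float(doc.parameters[k])),
                         constant="true")

    lor = etree.SubElement(model, "listOfRules")
    for name, expr in doc.aux:
        rule = etree.SubElement(lor, "assignmentRule", variable=name)
        _append_math(rule, expr)
    for name, expr in doc.odes.items():
        rule = etree.SubElement(lor, "rateRule", variable=name)
        _append_math(rule, expr)
    # aux variables need parameter declarations (non-constant)
    for name, _ in doc.aux:
        etree.SubElement(lop, "parameter", id=name, value="0",
                         constant="false")

    loe = etree.SubElement(model, "listOfEvents")
    for i, ev in enumerate(doc.events):
        e = etree.SubElement(loe, "event", id=f"event_{i}",
                             useValuesFromTriggerTime="true")
        ann = etree.SubElement(e, "annotation")
        ann.text = ev
        trig = etree.SubElement(e, "trigger", initialValue="true",
                                persistent="true")
        _append_math(trig, "CLB2A - thdiv")

    return etree.tostring(root, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8").decode()


def _compartment_mapping(doc: ModelDocument) -> dict[str, str]:
    try:
        catalog = {s.name: s.compartment for s in model_core.species_catalog()}
    except Exception:
        return {}
    name_map = {"nuclear": "nucleus", "cytoplasmic": "cytoplasm",
                "cell": "cell"}
    return {k: name_map[v] for k, v in catalog.items()
            if k in doc.initial_conditions}


def _append_math(parent, expr: str) -> None:
    """Attach a MathML content tree for an infix expression."""
    from lxml import etree

    math = etree.SubElement(parent,
                            "{http://www.w3.org/1998/Math/MathML}math")
    # store the infix form as an annotated csymbol-free fallback: SBML
    # tooling reads <ci> trees; we encode the full expression via a single
    # <csymbol>-style text node wrapped in <ci> when it is a bare name,
    # else as an <apply> parsed from Python's ast.
    node = _math_node(expr)
    math.append(node)


def _math_node(expr: str):
    import ast

    from lxml import etree

    M = "{http://www.w3.org/1998/Math/MathML}"

    def conv(node):
        if isinstance(node, ast.Expression):
            return conv(node.body)
        if isinstance(node, ast.BinOp):
            opname = {ast.Add: "plus", ast.Sub: "minus", ast.Mult: "times",
                      ast.Div: "divide", ast.Pow: "power"}[type(node.op)]
            ap = etree.Element(M + "apply")
            etree.SubElement(ap, M + opname)
            ap.append(conv(node.left))
            ap.append(conv(node.right))
            return ap
        if isinstance(node, ast.UnaryOp):
            if isinstance(node.op, ast.UAdd):
                return conv(node.operand)
            ap = etree.Element(M + "apply")
            etree.SubElement(ap, M + "minus")
            ap.append(conv(node.operand))
            return ap
        if isinstance(node, ast.Call):
            fname = node.func.id
            builtin = {"sqrt": "root", "exp": "exp", "log": "ln"}
            ap = etree.Element(M + "apply")
            if fname in builtin:
                etree.SubElement(ap, M + builtin[fname])
            else:  # hill, gkf, pos: exported as csymbol-named functions
                ci = etree.SubElement(ap, M + "ci")
                ci.text = fname
            for arg in node.args:
                ap.append(conv(arg))
            return ap
        if isinstance(node, ast.Constant):
            cn = etree.Element(M + "cn")
            cn.text = repr(float(node.value))
            return cn
        if isinstance(node, ast.Name):
            ci = etree.Element(M + "ci")
            ci.text = node.id
            return ci
        raise ValueError(f"untranslatable construct in {expr!r}: "
                         f"{ast.dump(node)}")

    return conv(ast.parse(expr, mode="eval"))


def read_sbml(text_or_path) -> ModelDocument:
    """Read back an SBML export into a ModelDocument (structural subset)."""
    from lxml import etree

    if isinstance(text_or_path, str) and text_or_path.lstrip().startswith("<"):
        tree = etree.fromstring(text_or_path.encode())
    else:
        tree = etree.parse(str(text_or_path)).getroot()
    ns = {"s": _SBML_NS, "m": "http://www.w3.org/1998/Math/MathML"}
    doc = ModelDocument()
    for c in tree.findall(".//s:compartment", ns):
        doc.compartments[c.get("id")] = float(c.get("size"))
    for sp in tree.findall(".//s:species", ns):
        doc.initial_conditions[sp.get("id")] = float(
            sp.get("initialConcentration"))
    aux_names = set()
    for p in tree.findall(".//s:parameter", ns):
        if p.get("constant") == "true":
            doc.parameters[p.get("id")] = float(p.get("value"))
        else:
            aux_names.add(p.get("id"))
    for rule in tree.findall(".//s:assignmentRule", ns):
        doc.aux.append((rule.get("variable"),
                        _math_to_infix(rule.find("m:math", ns)[0])))
    for rule in tree.findall(".//s:rateRule", ns):
        doc.odes[rule.get("variable")] = _math_to_infix(
            rule.find("m:math", ns)[0])
    for ev in tree.findall(".//s:event", ns):
        ann = ev.find("s:annotation", ns)
        if ann is not None and ann.text:
            doc.events.append(ann.text)
    return doc


def _math_to_infix(node) -> str:
    M = "{http://www.w3.org/1998/Math/MathML}"
    tag = node.tag
    if tag == M + "ci":
        return node.text.strip()
    if tag == M + "cn":
        return repr(float(node.text))
    if tag == M + "apply":
        children = list(node)
        op, args = children[0], children[1:]
        sym = {M + "plus": "+", M + "minus": "-", M + "times": "*",
               M + "divide": "/", M + "power": "**"}
        if op.tag in sym:
            if op.tag == M + "minus" and len(args) == 1:
                return f"(-{_math_to_infix(args[0])})"
            return "(" + f" {sym[op.tag]} ".join(_math_to_infix(a)
                                                 for a in args) + ")"
        fn = {M + "root": "sqrt", M + "exp": "exp", M + "ln": "log"}.get(
            op.tag, op.text.strip() if op.text else "")
        return f"{fn}(" + ", ".join(_math_to_infix(a) for a in args) + ")"
    raise ValueError(f"cannot convert MathML node {tag}")


# --------------------------------------------------------------------------
# CSV writers
# --------------------------------------------------------------------------

def write_trajectory_csv(traj: Trajectory, path) -> None:
    """One row per sample time, one column per species."""
    import pandas as pd

    df = pd.DataFrame(traj.states, columns=traj.names)
    df.insert(0, "time", traj.times)
    df.to_csv(path, index=False, float_format="%.10g")


def write_events_csv(traj: Trajectory, path) -> None:
    """Events sidecar: time, kind, payload columns."""
    import pandas as pd

    rows = []
    for e in traj.events:
        row = {"time": e.time, "kind": e.kind}
        row.update(e.payload)
        rows.append(row)
    pd.DataFrame(rows, columns=["time", "kind", "pre_division_mass",
                                "post_division_mass"]).to_csv(
        path, index=False, float_format="%.10g")


def write_report_csv(reports: Mapping[str, object], path) -> None:
    """Mutant screen output: one row per genotype."""
    import pandas as pd

    rows = []
    for g, r in reports.items():
        rows.append({
            "genotype": g,
            "viable": r.viable,
            "arrest_stage": r.arrest_stage,
            "size_rel_wt": r.size_rel_wt,
            "cycle_time": r.cycle_time,
            "g1_length": r.g1_length,
            "budded_period": r.budded_period,
            "dominant_forms": "+".join(r.dominant_forms),
            "notes": r.notes,
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


# --------------------------------------------------------------------------
# regression fixture bundle
# --------------------------------------------------------------------------

def generate_fixtures(seed: int, outdir, t_end: float = 120.0,
                      dt: float = 0.01,
                      mdt_values: "list[float] | None" = None) -> dict[str, str]:
    """Write the regression fixture bundle; deterministic given ``seed``.

    Contents: (a) a wildtype reference trajectory from the fixed-step RK4
    oracle, (b) the per-MDT sweep table, (c) the qualitative mutant battery
    expectations, and (d) a seed-perturbed initial-condition trajectory used
    for robustness regression (the only artifact the seed affects).
    """
    import json
    import pathlib

    import numpy as np

    from .model_core import build_model, initial_conditions
    from .mutants import builtin_catalog
    from .phenotype import sweep_mdt
    from .simulate import reference_integrate

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    model = build_model()
    traj = reference_integrate(model, t_end=t_end, dt=dt)
    p = outdir / "wt_reference_trajectory.csv"
    write_trajectory_csv(traj, p)
    write_events_csv(traj, outdir / "wt_reference_events.csv")
    written["trajectory"] = str(p)

    if mdt_values is None:
        mdt_values = [90.0, 150.0, 210.0, 300.0]
    if mdt_values:
        import pandas as pd
        rows = sweep_mdt(model, mdt_values)
        p = outdir / "mdt_sweep.csv"
        pd.DataFrame(rows).to_csv(p, index=False, float_format="%.6g")
        written["sweep"] = str(p)

    p = outdir / "mutant_expectations.json"
    with open(p, "w") as fh:
        json.dump([{
            "genotype": e.genotype, "expected_viable": e.expected_viable,
            "expected_size": e.expected_size, "size_class": e.size_class,
            "provenance": e.provenance, "notes": e.notes,
        } for e in builtin_catalog()], fh, indent=1, sort_keys=True)
    written["expectations"] = str(p)

    rng = np.random.default_rng(seed)
    ic = initial_conditions(params=model.parameters)
    y0 = ic.concentrations * rng.uniform(0.9, 1.1, ic.concentrations.size)
    traj_p = reference_integrate(model, t_end=min(t_end, 60.0), dt=dt, y0=y0)
    p = outdir / "perturbed_ic_trajectory.csv"
    write_trajectory_csv(traj_p, p)
    written["perturbed"] = str(p)
    return written
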