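"""Reader/writer for the plain-text BNGL-subset dialect.

Supported blocks (each ``begin <name>`` ... ``end <name>``):

* ``parameters`` — ``name value`` (value a numeric literal, scientific
  notation accepted)
* ``compartments`` — ``name dimension size [scale_factor]`` (optional block)
* ``molecule types`` — ``Name(comp~s1~s2,comp,...)`` with optional ``@Home``
  compartment suffix
* ``seed species`` — ``species copies`` (copies an integer or parameter name)
* ``observables`` — ``Molecules|Species name pattern[,pattern...]``
* ``reaction rules`` — ``[name:] r1 + r2 -> p1 + p2 rate`` or
  ``... <-> ... kf, kr``; ``0`` denotes an empty reactant/product side

Molecule syntax is ``Name(comp~state!bond,...)`` with bond markers ``!n``
(explicit), ``!+`` (bound to anything), ``!?`` (unconstrained) and state
wildcard ``~?`` (equivalent to omitting the state).  In a pattern, a
component written without a bond marker is *unbound*; a component omitted
entirely is unconstrained — this distinction is load-bearing for embedding
counts.  ``#`` starts a comment; files are UTF-8.

Reversible rules are split into two unidirectional rules linked via
``reversible_partner`` (suffixes ``_fwd``/``_rev``), which the
detailed-balance machinery relies on.
"""
from __future__ import annotations

import re
from typing import Optional

from .core import (Compartment, Component, ComponentDef, Model, Molecule,
                   MoleculeTypeDef, Observable, Parameter, Rule, SiteGraph,
                   SourceSpan, derive_transformations)


class BnglSyntaxError(ValueError):
    def __init__(self, message: str, span: SourceSpan):
        super().__init__(f"line {span.line}, col {span.column}: {message}"
                         + (f" (near {span.snippet!r})" if span.snippet else ""))
        self.span = span


_IDENT = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_NUMBER = re.compile(r"[-+]?(\d+\.?\d*|\.\d+)([eE][-+]?\d+)?")


class _Scanner:
    """Character scanner over a single logical line."""

    def __init__(self, text: str, line: int = 1, col0: int = 0):
        self.text = text
        self.pos = 0
        self.line = line
        self.col0 = col0

    def span(self) -> SourceSpan:
        return SourceSpan(self.line, self.col0 + self.pos + 1,
                          self.text[self.pos:self.pos + 16])

    def error(self, msg: str):
        raise BnglSyntaxError(msg, self.span())

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos] in " \t":
            self.pos += 1

    def eof(self) -> bool:
        self.skip_ws()
        return self.pos >= len(self.text)

    def peek(self) -> str:
        self.skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def take(self, ch: str) -> bool:
        if self.peek() == ch:
            self.pos += 1
            return True
        return False

    def expect(self, ch: str) -> None:
        if not self.take(ch):
            self.error(f"expected {ch!r}")

    def ident(self) -> str:
        self.skip_ws()
        m = _IDENT.match(self.text, self.pos)
        if not m:
            self.error("expected identifier")
        self.pos = m.end()
        return m.group(0)

    def number(self) -> Optional[float]:
        self.skip_ws()
        m = _NUMBER.match(self.text, self.pos)
        if not m:
            return None
        self.pos = m.end()
        return float(m.group(0))


def _parse_molecule(sc: _Scanner) -> Molecule:
    name = sc.ident()
    comps: list[Component] = []
    if sc.take("("):
        if not sc.take(")"):
            while True:
                cname = sc.ident()
                state = None
                bond = None
                while sc.peek() in "~!":
                    if sc.take("~"):
                        if sc.take("?"):
                            state = None
                        else:
                            state = sc.ident()
                    elif sc.take("!"):
                        if sc.take("+"):
                            bond = "+"
                        elif sc.take("?"):
                            bond = "?"
                        else:
                            n = sc.number()
                            if n is None or int(n) != n:
                                sc.error("expected bond index after '!'")
                            bond = int(n)
                comps.append(Component(cname, state, bond))
                if sc.take(")"):
                    break
                sc.expect(",")
    compartment = None
    if sc.take("@"):
        compartment = sc.ident()
    return Molecule(name, comps, compartment)


def _parse_pattern(sc: _Scanner) -> SiteGraph:
    span = sc.span()
    mols = [_parse_molecule(sc)]
    while sc.take("."):
        mols.append(_parse_molecule(sc))
    g = SiteGraph(mols, span)
    for prob in g.check_bonds():
        raise BnglSyntaxError(prob, span)
    return g


def parse_pattern(text: str, line: int = 1) -> SiteGraph:
    """Parse a single pattern expression (e.g. ``"R(y~P!+)"``)."""
    sc = _Scanner(text, line)
    g = _parse_pattern(sc)
    if not sc.eof():
        sc.error("trailing text after pattern")
    return g


def _parse_side(sc: _Scanner) -> list[SiteGraph]:
    """Reactant or product side: '+'-separated patterns, or '0' for empty."""
    sc.skip_ws()
    if sc.peek() == "0":
        nxt = sc.text[sc.pos + 1:sc.pos + 2]
        if not nxt or not (nxt.isalnum() or nxt in "_.(~!"):
            sc.pos += 1
            return []
    sides = [_parse_pattern(sc)]
    while sc.take("+"):
        sides.append(_parse_pattern(sc))
    return sides


def _parse_molecule_type(sc: _Scanner) -> MoleculeTypeDef:
    span = sc.span()
    name = sc.ident()
    comps: list[ComponentDef] = []
    if sc.take("("):
        if not sc.take(")"):
            while True:
                cname = sc.ident()
                states = []
                while sc.take("~"):
                    states.append(sc.ident())
                comps.append(ComponentDef(cname, tuple(states)))
                if sc.take(")"):
                    break
                sc.expect(",")
    home = None
    if sc.take("@"):
        home = sc.ident()
    return MoleculeTypeDef(name, tuple(comps), home, span)


_BLOCK_ALIASES = {
    "parameters": "parameters",
    "compartments": "compartments",
    "molecule types": "molecule types",
    "seed species": "seed species",
    "species": "seed species",
    "observables": "observables",
    "reaction rules": "reaction rules",
}


def parse_model(text: str) -> Model:
    """Parse a BNGL-subset model file into a :class:`Model`.

    Syntax errors raise :class:`BnglSyntaxError` with a source span; semantic
    problems (undeclared names, malformed species) are deferred to
    :func:`rulesim.core.validate_model`.
    """
    model = Model()
    block: Optional[str] = None
    seen_blocks: set[str] = set()
    rule_counter = 0

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        low = line.lower()
        if low.startswith("begin "):
            name = " ".join(low.split()[1:])
            if name not in _BLOCK_ALIASES:
                raise BnglSyntaxError(f"unknown block {name!r}",
                                      SourceSpan(lineno, 1, line))
            block_name = _BLOCK_ALIASES[name]
            if block is not None:
                raise BnglSyntaxError(f"nested block {name!r}",
                                      SourceSpan(lineno, 1, line))
            if block_name in seen_blocks:
                raise BnglSyntaxError(f"duplicate block {name!r}",
                                      SourceSpan(lineno, 1, line))
            seen_blocks.add(block_name)
            block = block_name
            continue
        if low.startswith("end "):
            name = " ".join(low.split()[1:])
            if block is None or _BLOCK_ALIASES.get(name) != block:
                raise BnglSyntaxError(f"unmatched end {name!r}",
                                      SourceSpan(lineno, 1, line))
            block = None
            continue
        if block is None:
            raise BnglSyntaxError("statement outside any block",
                                  SourceSpan(lineno, 1, line))

        sc = _Scanner(line, lineno)
        if block == "parameters":
            pname = sc.ident()
            val = sc.number()
            if val is None:
                sc.error("expected numeric parameter value")
            if not sc.eof():
                sc.error("trailing text after parameter")
            model.parameters[pname] = Parameter(pname, val,
                                                span=SourceSpan(lineno, 1, line))
        elif block == "compartments":
            cname = sc.ident()
            dim = sc.number()
            size = sc.number()
            if dim is None or size is None:
                sc.error("expected: name dimension size [scale_factor]")
            scale = sc.number()
            if not sc.eof():
                sc.error("trailing text after compartment")
            model.compartments[cname] = Compartment(
                cname, int(dim), size, scale if scale is not None else 1.0,
                SourceSpan(lineno, 1, line))
        elif block == "molecule types":
            mt = _parse_molecule_type(sc)
            if not sc.eof():
                sc.error("trailing text after molecule type")
            model.molecule_types[mt.name] = mt
        elif block == "seed species":
            g = _parse_pattern(sc)
            n = sc.number()
            if n is None:
                pname = sc.ident()
                model.seed_species.append((g, pname))  # resolved below
            else:
                if int(n) != n:
                    sc.error("seed copy number must be an integer")
                model.seed_species.append((g, int(n)))
            if not sc.eof():
                sc.error("trailing text after seed species")
        elif block == "observables":
            kind = sc.ident()
            oname = sc.ident()
            pats = [_parse_pattern(sc)]
            while sc.take(","):
                pats.append(_parse_pattern(sc))
            if not sc.eof():
                sc.error("trailing text after observable")
            model.observables.append(
                Observable(oname, kind, pats, SourceSpan(lineno, 1, line)))
        elif block == "reaction rules":
            # optional "name:" prefix (name may contain @enzyme= suffix)
            rname = None
            if ":" in line:
                head, rest = line.split(":", 1)
                if re.fullmatch(r"[A-Za-z_][\w@=.\-]*", head.strip()):
                    rname = head.strip()
                    sc = _Scanner(rest, lineno, col0=len(head) + 1)
            reactants = _parse_side(sc)
            sc.skip_ws()
            arrow = None
            if sc.text.startswith("<->", sc.pos):
                arrow = "<->"
                sc.pos += 3
            elif sc.text.startswith("->", sc.pos):
                arrow = "->"
                sc.pos += 2
            else:
                sc.error("expected '->' or '<->'")
            products = _parse_side(sc)
            rates: list = []
            first = sc.number()
            if first is None:
                rates.append(sc.ident())
            else:
                rates.append(first)
            if sc.take(","):
                second = sc.number()
                rates.append(second if second is not None else sc.ident())
            if not sc.eof():
                sc.error("trailing text after rule")
            if arrow == "<->" and len(rates) != 2:
                sc.error("reversible rule needs two rates 'kf, kr'")
            if arrow == "->" and len(rates) != 1:
                sc.error("irreversible rule takes a single rate")
            rule_counter += 1
            base = rname or f"rule{rule_counter}"
            span = SourceSpan(lineno, 1, line)
            try:
                if arrow == "->":
                    tfs = derive_transformations(reactants, products, base)
                    model.rules.append(Rule(base, reactants, tfs, rates[0],
                                            None, products, span))
                else:
                    fwd = f"{base}_fwd"
                    rev = f"{base}_rev"
                    tf_f = derive_transformations(reactants, products, fwd)
                    tf_r = derive_transformations(products, reactants, rev)
                    model.rules.append(Rule(fwd, reactants, tf_f, rates[0],
                                            rev, products, span))
                    model.rules.append(Rule(rev, products, tf_r, rates[1],
                                            fwd, reactants, span))
            except ValueError as exc:   # ambiguous / non-corresponding sides
                raise BnglSyntaxError(str(exc), span)
    if block is not None:
        raise BnglSyntaxError(f"unterminated block {block!r}",
                              SourceSpan(len(text.splitlines()) + 1, 1))

    # Resolve parameter-named seed copy numbers.
    resolved = []
    for g, copies in model.seed_species:
        if isinstance(copies, str):
            if copies not in model.parameters:
                raise BnglSyntaxError(
                    f"seed copy parameter {copies!r} undeclared",
                    g.span or SourceSpan(1, 1))
            copies = int(round(model.parameters[copies].value))
        resolved.append((g, copies))
    model.seed_species = resolved
    return model


# ---------------------------------------------------------------------------
# Writer

def format_molecule(mol: Molecule) -> str:
    parts = []
    for c in mol.comps:
        s = c.name
        if c.state is not None:
            s += f"~{c.state}"
        if c.bond is not None:
            s += f"!{c.bond}"
        parts.append(s)
    tag = f"@{mol.compartment}" if mol.compartment else ""
    return f"{mol.typename}({','.join(parts)}){tag}"


def format_pattern(g: SiteGraph) -> str:
    g2 = g.copy()
    g2.renumber_bonds()
    return ".".join(format_molecule(m) for m in g2.molecules)


def format_side(patterns: list[SiteGraph]) -> str:
    if not patterns:
        return "0"
    return " + ".join(format_pattern(g) for g in patterns)


def _format_number(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


def write_model(model: Model) -> str:
    """Serialize a model; output is deterministic and round-trips through
    :func:`parse_model` to a structurally identical model."""
    out: list[str] = []

    out.append("begin parameters")
    for p in model.parameters.values():
        out.append(f"  {p.name} {_format_number(p.value)}")
    out.append("end parameters")

    if model.compartments:
        out.append("begin compartments")
        for c in model.compartments.values():
            line = f"  {c.name} {c.dimension} {_format_number(c.size)}"
            if c.scale_factor != 1.0:
                line += f" {_format_number(c.scale_factor)}"
            out.append(line)
        out.append("end compartments")

    out.append("begin molecule types")
    for mt in model.molecule_types.values():
        comps = ",".join(
            cd.name + "".join(f"~{s}" for s in cd.states)
            for cd in mt.components)
        home = f"@{mt.home_compartment}" if mt.home_compartment else ""
        out.append(f"  {mt.name}({comps}){home}")
    out.append("end molecule types")

    out.append("begin seed species")
    for g, copies in model.seed_species:
        out.append(f"  {format_pattern(g)} {copies}")
    out.append("end seed species")

    out.append("begin observables")
    for obs in model.observables:
        pats = ", ".join(format_pattern(g) for g in obs.patterns)
        out.append(f"  {obs.kind} {obs.name} {pats}")
    out.append("end observables")

    out.append("begin reaction rules")
    written: set[str] = set()
    for rule in model.rules:
        if rule.name in written:
            continue
        products = rule.products if rule.products is not None \
            else rule.derived_products()
        if rule.reversible_partner is not None:
            try:
                partner = model.rule_by_name(rule.reversible_partner)
            except KeyError:
                partner = None
            if partner is not None and partner.name not in written:
                base = rule.name[:-4] if rule.name.endswith("_fwd") else rule.name
                kf = rule.rate_param
                kr = partner.rate_param
                out.append(
                    f"  {base}: {format_side(rule.reactants)} <-> "
                    f"{format_side(products)} "
                    f"{kf if isinstance(kf, str) else _format_number(kf)}, "
                    f"{kr if isinstance(kr, str) else _format_number(kr)}")
                written.add(rule.name)
                written.add(partner.name)
                continue
        kf = rule.rate_param
        out.append(f"  {rule.name}: {format_side(rule.reactants)} -> "
                   f"{format_side(products)} "
                   f"{kf if isinstance(kf, str) else _format_number(kf)}")
        written.add(rule.name)
    out.append("end reaction rules")
    return "\n".join(out) + "\n"
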