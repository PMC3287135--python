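"""Reading and writing reaction networks.

Native dialect: a line-oriented plain-text format that is diffable and
trivially parseable.  Example::

    # comment
    network my_model
    units count
    species A = 100
    species B = 0
    species E = 10
    A + B -> C [k=0.1]
    2 A -> B [k=0.05] @dimerise
    A -> 0 [rate="0.2 * A / (1 + A)"] {modifiers: E}

``0`` denotes an empty reactant or product side; ``{modifiers: E, 2 F}``
lists catalytic species; ``@name`` optionally names the reaction.

SBML Level 3 import (species, reactions, mass-action or explicit kinetic
laws) is available when python-libsbml is installed.
"""

from __future__ import annotations

import re
from pathlib import Path

from .network import KineticLaw, Reaction, ReactionNetwork, Species

__all__ = ["read_network", "write_network", "parse_network", "format_network"]

_SPECIES_RE = re.compile(r"^species\s+(\S+)\s*=\s*(\S+)$")
_TERM_RE = re.compile(r"^(?:(\d+)\s+)?([A-Za-z_][\w.\-]*)$")


class NetworkParseError(ValueError):
    """Raised on malformed native-dialect input; message carries the line number."""


def _parse_side(text: str, lineno: int) -> dict[str, int]:
    text = text.strip()
    if text == "0" or text == "":
        return {}
    side: dict[str, int] = {}
    for term in text.split("+"):
        m = _TERM_RE.match(term.strip())
        if m is None:
            raise NetworkParseError(
                f"line {lineno}: cannot parse species term {term.strip()!r}"
            )
        mult = int(m.group(1)) if m.group(1) else 1
        name = m.group(2)
        side[name] = side.get(name, 0) + mult
    return side


def _parse_reaction(line: str, lineno: int) -> Reaction:
    name = None
    m = re.search(r"@(\S+)\s*$", line)
    if m:
        name = m.group(1)
        line = line[: m.start()]
    modifiers: dict[str, int] = {}
    m = re.search(r"\{modifiers:\s*([^}]*)\}", line)
    if m:
        modifiers = _parse_side(m.group(1).replace(",", "+"), lineno)
        line = line[: m.start()] + line[m.end():]
    m = re.search(r"\[(.*)\]", line)
    if m is None:
        raise NetworkParseError(f"line {lineno}: missing kinetics bracket [...]")
    kin_text = m.group(1).strip()
    line = line[: m.start()] + line[m.end():]
    if kin_text.startswith("rate="):
        expr = kin_text[len("rate="):].strip()
        if len(expr) >= 2 and expr[0] == expr[-1] and expr[0] in "\"'":
            expr = expr[1:-1]
        kinetics = KineticLaw("custom", rate_expression=expr)
    elif kin_text.startswith("k="):
        try:
            kinetics = KineticLaw("mass_action", float(kin_text[2:]))
        except ValueError:
            raise NetworkParseError(
                f"line {lineno}: bad rate constant {kin_text!r}"
            ) from None
    else:
        raise NetworkParseError(
            f"line {lineno}: kinetics must be k=<value> or rate=\"<expr>\""
        )
    if "->" not in line:
        raise NetworkParseError(f"line {lineno}: missing '->'")
    left, right = line.split("->", 1)
    return Reaction(
        _parse_side(left, lineno), _parse_side(right, lineno), modifiers,
        kinetics, name,
    )


def parse_network(text: str) -> ReactionNetwork:
    """Parse the native dialect from a string."""
    net = ReactionNetwork(units_mode="count")
    saw_anything = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        saw_anything = True
        if line.startswith("network"):
            net.name = line[len("network"):].strip()
        elif line.startswith("units"):
            mode = line[len("units"):].strip()
            if mode not in ("count", "concentration"):
                raise NetworkParseError(f"line {lineno}: unknown units {mode!r}")
            net.units_mode = mode
        elif line.startswith("species"):
            m = _SPECIES_RE.match(line)
            if m is None:
                raise NetworkParseError(f"line {lineno}: bad species line")
            try:
                amount = float(m.group(2))
            except ValueError:
                raise NetworkParseError(
                    f"line {lineno}: bad initial amount {m.group(2)!r}"
                ) from None
            net.species.append(Species(m.group(1), amount))
        else:
            net.reactions.append(_parse_reaction(line, lineno))
    if not saw_anything:
        raise NetworkParseError("empty network file")
    return net


def _format_side(side: dict[str, int]) -> str:
    if not side:
        return "0"
    return " + ".join(
        name if mult == 1 else f"{mult} {name}" for name, mult in side.items()
    )


def _format_amount(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() else repr(float(x))


def format_network(net: ReactionNetwork) -> str:
    """Render a network in the native dialect (inverse of :func:`parse_network`)."""
    lines = []
    if net.name:
        lines.append(f"network {net.name}")
    lines.append(f"units {net.units_mode}")
    for sp in net.species:
        lines.append(f"species {sp.name} = {_format_amount(sp.initial_amount)}")
    for rxn in net.reactions:
        law = rxn.kinetics
        if law.form == "mass_action":
            kin = f"[k={repr(float(law.rate_constant))}]"
        elif isinstance(law.rate_expression, str):
            kin = f'[rate="{law.rate_expression}"]'
        else:
            raise ValueError(
                f"reaction {rxn.name or '?'}: callable custom laws cannot be "
                "serialised to the native dialect"
            )
        parts = [_format_side(rxn.reactants), "->", _format_side(rxn.products), kin]
        if rxn.modifiers:
            parts.append("{modifiers: " + _format_side(rxn.modifiers).replace(" + ", ", ") + "}")
        if rxn.name:
            parts.append(f"@{rxn.name}")
        lines.append(" ".join(parts))
    return "\n".join(lines) + "\n"


def write_network(net: ReactionNetwork, path: str | Path) -> None:
    Path(path).write_text(format_network(net))


def read_network(path: str | Path, dialect: str = "native") -> ReactionNetwork:
    """Read a network file.

    ``dialect="native"`` parses the plain-text format above;
    ``dialect="sbml"`` imports an SBML Level 3 file (requires python-libsbml).
    """
    path = Path(path)
    if dialect == "native":
        try:
            return parse_network(path.read_text())
        except NetworkParseError as err:
            raise NetworkParseError(f"{path}: {err}") from None
    if dialect == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_sbml(path: Path) -> ReactionNetwork:
    try:
        import libsbml
    except ImportError:
        raise ImportError(
            "SBML import requires the optional dependency python-libsbml "
            "(pip install python-libsbml)"
        ) from None
    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors() > 0 and doc.getError(0).getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
        raise NetworkParseError(f"{path}: {doc.getError(0).getMessage()}")
    model = doc.getModel()
    if model is None:
        raise NetworkParseError(f"{path}: no model element")
    net = ReactionNetwork(units_mode="concentration", name=model.getId() or "")
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        amount = sp.getInitialConcentration()
        if sp.isSetInitialAmount():
            amount = sp.getInitialAmount()
            net.units_mode = "count"
        net.species.append(Species(sp.getId(), float(amount)))
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        reactants = {
            rxn.getReactant(j).getSpecies(): int(rxn.getReactant(j).getStoichiometry())
            for j in range(rxn.getNumReactants())
        }
        products = {
            rxn.getProduct(j).getSpecies(): int(rxn.getProduct(j).getStoichiometry())
            for j in range(rxn.getNumProducts())
        }
        modifiers = {
            rxn.getModifier(j).getSpecies(): 1 for j in range(rxn.getNumModifiers())
        }
        kl = rxn.getKineticLaw()
        if kl is None:
            raise NetworkParseError(f"{path}: reaction {rxn.getId()} lacks a kinetic law")
        formula = libsbml.formulaToString(kl.getMath())
        params = {
            kl.getParameter(j).getId(): kl.getParameter(j).getValue()
            for j in range(kl.getNumParameters())
        }
        # substitute local parameter values into the formula
        for pid, val in params.items():
            formula = re.sub(rf"\b{re.escape(pid)}\b", repr(val), formula)
        net.reactions.append(
            Reaction(reactants, products, modifiers,
                     KineticLaw("custom", rate_expression=formula),
                     rxn.getId() or None)
        )
    return net
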