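"""Workflow specification model: command markup, port links, macros, JSON round-trip.

A workflow is a directed acyclic graph of named *steps*.  Each step is a
shell command annotated with a lightweight markup:

* ``<name>``  — an input port (a file the step consumes),
* ``[name]``  — an output port (a file the step produces),
* ``#NAME#``  — a macro placeholder bound to a concrete value at run time,
* ``##``      — an escaped literal ``#``.

Step and port names use lowercase letters, digits and underscores; macro
names use uppercase letters, digits and underscores.  Links connect an
upstream output port to a downstream input port; at export time the linked
input token is replaced by an ``@{step.port}`` expression referencing the
upstream output, which the importer inverts back into a port token.

The exported document has exactly two content fields, ``macro`` and
``workflow`` (plus a ``schema_version``), and its serialization is
deterministic: steps sorted by name, link statements in port appearance
order, macros sorted by name.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

import networkx as nx

from .errors import CycleError, MarkupError, ValidationError

SCHEMA_VERSION = "1.0"

_STEP_NAME_RE = re.compile(r"^[a-z0-9_]+$")
_MACRO_NAME_RE = re.compile(r"^[A-Z0-9_]+$")

# Token kinds produced by tokenize().
INPUT, OUTPUT, MACRO, LITERAL_HASH = "input", "output", "macro", "literal_hash"


def is_step_name(name: str) -> bool:
    return bool(_STEP_NAME_RE.match(name))


def is_macro_name(name: str) -> bool:
    return bool(_MACRO_NAME_RE.match(name))


@dataclass(frozen=True)
class Token:
    """A markup token found in a raw command.

    ``start``/``end`` delimit the whole token (including its delimiters) in
    the raw command string, so splicing tokens back at their offsets
    reconstructs the command exactly.
    """

    kind: str
    name: str
    start: int
    end: int

    @property
    def text(self) -> str:
        if self.kind == INPUT:
            return f"<{self.name}>"
        if self.kind == OUTPUT:
            return f"[{self.name}]"
        if self.kind == MACRO:
            return f"#{self.name}#"
        return "##"


def tokenize(command: str) -> list[Token]:
    """Scan *command* for markup tokens, in order of appearance.

    Raises :class:`MarkupError` for an unclosed ``<`` or ``[`` or an
    unmatched ``#``; the error names the offending offset.
    """
    tokens: list[Token] = []
    i, n = 0, len(command)
    while i < n:
        ch = command[i]
        if ch == "<":
            j = command.find(">", i + 1)
            if j < 0:
                raise MarkupError("unclosed '<' input-port delimiter", offset=i)
            tokens.append(Token(INPUT, command[i + 1 : j], i, j + 1))
            i = j + 1
        elif ch == "[":
            j = command.find("]", i + 1)
            if j < 0:
                raise MarkupError("unclosed '[' output-port delimiter", offset=i)
            tokens.append(Token(OUTPUT, command[i + 1 : j], i, j + 1))
            i = j + 1
        elif ch == "#":
            if i + 1 < n and command[i + 1] == "#":
                tokens.append(Token(LITERAL_HASH, "", i, i + 2))
                i += 2
                continue
            j = command.find("#", i + 1)
            if j < 0:
                raise MarkupError("unmatched '#' macro delimiter", offset=i)
            tokens.append(Token(MACRO, command[i + 1 : j], i, j + 1))
            i = j + 1
        else:
            i += 1
    return tokens


@dataclass(frozen=True)
class StepSpec:
    """One workflow step: a named, markup-annotated shell command."""

    name: str
    raw_command: str
    input_ports: tuple[str, ...]
    output_ports: tuple[str, ...]
    macro_refs: frozenset[str]

    def tokens(self) -> list[Token]:
        return tokenize(self.raw_command)


@dataclass(frozen=True)
class MacroDecl:
    name: str
    default_value: str | None = None


@dataclass(frozen=True)
class PortLink:
    """Connects an upstream output port to a downstream input port."""

    from_step: str
    from_port: str
    to_step: str
    to_port: str


def parse_step_markup(name: str, command: str) -> StepSpec:
    """Parse a raw command into a :class:`StepSpec`.

    Input ports are the ``<...>`` tokens in order of appearance, output
    ports the ``[...]`` tokens, macro references the ``#...#`` tokens.
    The raw command is preserved verbatim.
    """
    if not is_step_name(name):
        raise ValidationError(
            f"invalid step name {name!r}: must be nonempty lowercase letters, digits, underscores"
        )
    if not command:
        raise ValidationError(f"step {name!r}: command must be nonempty")
    tokens = tokenize(command)
    inputs: list[str] = []
    outputs: list[str] = []
    macros: set[str] = set()
    for tok in tokens:
        if tok.kind == INPUT:
            if not is_step_name(tok.name):
                raise ValidationError(f"step {name!r}: invalid input port name {tok.name!r}")
            if tok.name in inputs:
                raise ValidationError(f"step {name!r}: duplicate input port {tok.name!r}")
            inputs.append(tok.name)
        elif tok.kind == OUTPUT:
            if not is_step_name(tok.name):
                raise ValidationError(f"step {name!r}: invalid output port name {tok.name!r}")
            if tok.name in outputs:
                raise ValidationError(f"step {name!r}: duplicate output port {tok.name!r}")
            outputs.append(tok.name)
        elif tok.kind == MACRO:
            if not is_macro_name(tok.name):
                raise ValidationError(f"step {name!r}: invalid macro name {tok.name!r}")
            macros.add(tok.name)
    return StepSpec(name, command, tuple(inputs), tuple(outputs), frozenset(macros))


@dataclass
class WorkflowSpec:
    """Steps, port links and macro table — the in-memory twin of the JSON export."""

    steps: dict[str, StepSpec] = field(default_factory=dict)
    links: list[PortLink] = field(default_factory=list)
    macros: dict[str, MacroDecl] = field(default_factory=dict)

    # -- construction -------------------------------------------------

    def add_step(self, name: str, command: str) -> StepSpec:
        if name in self.steps:
            raise ValidationError(f"duplicate step name {name!r}")
        step = parse_step_markup(name, command)
        self.steps[name] = step
        for m in step.macro_refs:
            self.macros.setdefault(m, MacroDecl(m))
        return step

    def declare_macro(self, name: str, default_value: str | None = None) -> None:
        if not is_macro_name(name):
            raise ValidationError(f"invalid macro name {name!r}")
        self.macros[name] = MacroDecl(name, default_value)

    # -- graph helpers ------------------------------------------------

    def graph(self) -> "nx.DiGraph":
        g = nx.DiGraph()
        g.add_nodes_from(self.steps)
        for link in self.links:
            g.add_edge(link.from_step, link.to_step)
        return g

    def upstream_of(self, step: str) -> set[str]:
        return {l.from_step for l in self.links if l.to_step == step}

    def downstream_closure(self, step: str) -> set[str]:
        return nx.descendants(self.graph(), step)

    def topological_order(self) -> list[str]:
        """Deterministic topological order (lexicographic tie-break)."""
        return list(nx.lexicographical_topological_sort(self.graph()))

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        for name, step in self.steps.items():
            if name != step.name:
                raise ValidationError(f"step key {name!r} != step name {step.name!r}")
            missing = step.macro_refs - set(self.macros)
            if missing:
                raise ValidationError(f"step {name!r} references undeclared macros {sorted(missing)}")
        targets: set[tuple[str, str]] = set()
        for link in self.links:
            _check_link_endpoints(self, link)
            tgt = (link.to_step, link.to_port)
            if tgt in targets:
                raise ValidationError(
                    f"input port {link.to_port!r} of step {link.to_step!r} has multiple incoming links"
                )
            targets.add(tgt)
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = [u for u, _ in nx.find_cycle(g)]
            raise CycleError(cycle)

    def linked_inputs(self, step: str) -> dict[str, PortLink]:
        return {l.to_port: l for l in self.links if l.to_step == step}


def _check_link_endpoints(spec: WorkflowSpec, link: PortLink) -> None:
    if link.from_step == link.to_step:
        raise ValidationError(f"self-link on step {link.from_step!r} is not allowed")
    for s in (link.from_step, link.to_step):
        if s not in spec.steps:
            raise ValidationError(f"link references unknown step {s!r}")
    if link.from_port not in spec.steps[link.from_step].output_ports:
        raise ValidationError(
            f"step {link.from_step!r} has no output port {link.from_port!r}"
        )
    if link.to_port not in spec.steps[link.to_step].input_ports:
        raise ValidationError(f"step {link.to_step!r} has no input port {link.to_port!r}")


def link_steps(spec: WorkflowSpec, link: PortLink) -> WorkflowSpec:
    """Append *link* to *spec* after checking endpoints, target uniqueness
    and acyclicity.  Returns the (mutated) spec for chaining."""
    _check_link_endpoints(spec, link)
    for existing in spec.links:
        if (existing.to_step, existing.to_port) == (link.to_step, link.to_port):
            raise ValidationError(
                f"input port {link.to_port!r} of step {link.to_step!r} is already linked"
            )
    g = spec.graph()
    g.add_edge(link.from_step, link.to_step)
    if not nx.is_directed_acyclic_graph(g):
        cycle = [u for u, _ in nx.find_cycle(g)]
        raise CycleError(cycle)
    spec.links.append(link)
    return spec


# ---------------------------------------------------------------------------
# JSON export / import
# ---------------------------------------------------------------------------

def output_ref(step: str, port: str) -> str:
    """The expression a linked input serializes to in the exported command."""
    return "@{" + step + "." + port + "}"


def _serialized_command(spec: WorkflowSpec, step: StepSpec) -> str:
    """Raw command with each linked input token replaced by its upstream
    output reference.  Unlinked ports and macros stay verbatim."""
    linked = spec.linked_inputs(step.name)
    out: list[str] = []
    pos = 0
    for tok in step.tokens():
        out.append(step.raw_command[pos : tok.start])
        if tok.kind == INPUT and tok.name in linked:
            link = linked[tok.name]
            out.append(output_ref(link.from_step, link.from_port))
        else:
            out.append(step.raw_command[tok.start : tok.end])
        pos = tok.end
    out.append(step.raw_command[pos:])
    return "".join(out)


def export_json(spec: WorkflowSpec) -> dict:
    """Serialize *spec* to the two-field workflow document.

    Deterministic: macros sorted by name, steps sorted by name, link
    statements listed in the downstream port's order of appearance.
    """
    spec.validate()
    macro = {m.name: m.default_value for m in sorted(spec.macros.values(), key=lambda m: m.name)}
    workflow = []
    for name in sorted(spec.steps):
        step = spec.steps[name]
        linked = spec.linked_inputs(name)
        from_stmts = [
            {
                "from": linked[p].from_step,
                "frompid": linked[p].from_port,
                "topid": p,
            }
            for p in step.input_ports
            if p in linked
        ]
        to_stmts = [
            {"to": l.to_step, "frompid": l.from_port, "topid": l.to_port}
            for l in sorted(
                (l for l in spec.links if l.from_step == name),
                key=lambda l: (l.to_step, l.to_port),
            )
        ]
        workflow.append(
            {
                "name": name,
                "command": _serialized_command(spec, step),
                "from": from_stmts,
                "to": to_stmts,
            }
        )
    return {"schema_version": SCHEMA_VERSION, "macro": macro, "workflow": workflow}


def dumps_workflow(spec: WorkflowSpec) -> str:
    """Canonical byte-stable JSON text of the exported document."""
    return json.dumps(export_json(spec), indent=2, ensure_ascii=False) + "\n"


def import_json(doc: dict) -> WorkflowSpec:
    """Reconstruct a :class:`WorkflowSpec` from an exported document.

    ``import_json(export_json(s))`` is structurally equal to ``s``.
    """
    if not isinstance(doc, dict):
        raise ValidationError("workflow document must be a JSON object")
    for fld in ("macro", "workflow"):
        if fld not in doc:
            raise ValidationError(f"workflow document is missing the {fld!r} field")
    version = doc.get("schema_version", SCHEMA_VERSION)
    if str(version).split(".")[0] != SCHEMA_VERSION.split(".")[0]:
        raise ValidationError(f"unsupported schema_version {version!r}")
    if not isinstance(doc["macro"], dict) or not isinstance(doc["workflow"], list):
        raise ValidationError("'macro' must be an object and 'workflow' an array")

    spec = WorkflowSpec()
    for mname, default in doc["macro"].items():
        spec.declare_macro(mname, default)

    pending_links: list[PortLink] = []
    seen_names: set[str] = set()
    for entry in doc["workflow"]:
        if not isinstance(entry, dict) or "name" not in entry or "command" not in entry:
            raise ValidationError("each workflow entry needs 'name' and 'command'")
        name = entry["name"]
        if name in seen_names:
            raise ValidationError(f"duplicate step name {name!r} in document")
        seen_names.add(name)
        command = entry["command"]
        for stmt in entry.get("from", []):
            for key in ("from", "frompid", "topid"):
                if key not in stmt:
                    raise ValidationError(f"step {name!r}: from-statement missing {key!r}")
            ref = output_ref(stmt["from"], stmt["frompid"])
            if ref not in command:
                raise ValidationError(
                    f"step {name!r}: command lacks the output reference {ref!r} "
                    f"declared by its from-statement"
                )
            command = command.replace(ref, f"<{stmt['topid']}>", 1)
            pending_links.append(
                PortLink(stmt["from"], stmt["frompid"], name, stmt["topid"])
            )
        spec.add_step(name, command)

    for link in pending_links:
        if link.from_step not in spec.steps:
            raise ValidationError(f"from-statement references unknown step {link.from_step!r}")
        link_steps(spec, link)

    # "to" statements are redundant mirrors; verify consistency when present.
    declared_to = {
        (entry["name"], stmt["to"], stmt["frompid"], stmt["topid"])
        for entry in doc["workflow"]
        for stmt in entry.get("to", [])
    }
    if declared_to:
        actual = {(l.from_step, l.to_step, l.from_port, l.to_port) for l in spec.links}
        if declared_to != actual:
            raise ValidationError("'to' statements disagree with 'from' statements")

    spec.validate()
    return spec


def loads_workflow(text: str) -> WorkflowSpec:
    return import_json(json.loads(text))


def specs_equal(a: WorkflowSpec, b: WorkflowSpec) -> bool:
    """Structural equality: same steps, same link set, same macro table."""
    return (
        a.steps == b.steps
        and set(a.links) == set(b.links)
        and a.macros == b.macros
    )
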