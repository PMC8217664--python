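"""Render and execute workflows: macro substitution, parallel DAG scheduling,
auxiliary logs, and resume after interruption.

Execution model
---------------
Each step runs as a shell command in its own working directory
``run_dir/<step_name>/``.  The scheduler repeatedly launches every *ready*
step (pending with all upstream steps succeeded), lexicographically by
name, up to ``max_parallel`` concurrent processes; a step succeeds iff its
exit status is zero.  On a failure the steps downstream of it never start,
but independent branches keep running to completion.

Four auxiliary files are kept under the run directory, named with the run
directory's basename:

* ``<run>.command.log`` — every executed concrete command, in launch order,
* ``<run>.ok.log``      — successful steps, appended and flushed to disk the
  moment each completes (before any dependent becomes ready), so a resumed
  run can trust it after a sudden interruption,
* ``<run>.out`` / ``<run>.err`` — the children's standard output/error,
  concatenated with per-step delimiters in completion order.

A fingerprint of (exported workflow JSON, sorted macro bindings) is stored
in the run directory; :func:`resume` refuses to reuse state written by a
different workflow or bindings.
"""

from __future__ import annotations

import hashlib
import json
import os
import subprocess
import time
from dataclasses import dataclass, field
from pathlib import Path

from .errors import (
    EngineInterrupted,
    SetupError,
    StaleStateError,
    UnboundInputError,
    UnboundMacroError,
)
from .workflow import INPUT, MACRO, OUTPUT, WorkflowSpec, dumps_workflow

PENDING, READY, RUNNING, SUCCEEDED, FAILED = (
    "pending",
    "ready",
    "running",
    "succeeded",
    "failed",
)

_POLL_INTERVAL = 0.004  # seconds between scheduler polls
_STEP_DELIM = "==== step: {name} ===="


@dataclass
class MacroBindings:
    """Concrete values for macros and for unlinked external input ports.

    Macro names follow the uppercase grammar; keys for external inputs may
    be the (lowercase) port name itself.  :meth:`lookup` tries the exact
    name first, then its uppercase form.
    """

    values: dict[str, str] = field(default_factory=dict)

    def lookup(self, name: str) -> str | None:
        if name in self.values:
            return self.values[name]
        return self.values.get(name.upper())

    @classmethod
    def from_file(cls, path: str | Path) -> "MacroBindings":
        """Read bindings from a JSON object or flat ``key=value`` lines."""
        text = Path(path).read_text()
        stripped = text.lstrip()
        if stripped.startswith("{"):
            data = json.loads(text)
            return cls({str(k): str(v) for k, v in data.items()})
        values = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            k, _, v = line.partition("=")
            values[k.strip()] = v.strip()
        return cls(values)


@dataclass
class RenderedStep:
    """A step with macros resolved and ports substituted by concrete paths."""

    name: str
    command: str
    input_paths: dict[str, str]
    output_paths: dict[str, str]
    workdir: str


@dataclass
class RunState:
    """Per-step lifecycle of one run plus the ok-log used for resume."""

    statuses: dict[str, str]
    ok_entries: list[str]
    run_dir: str
    interrupted: bool = False
    failure_reasons: dict[str, str] = field(default_factory=dict)

    @property
    def succeeded(self) -> set[str]:
        return {s for s, st in self.statuses.items() if st == SUCCEEDED}

    @property
    def failed(self) -> set[str]:
        return {s for s, st in self.statuses.items() if st == FAILED}

    @property
    def all_succeeded(self) -> bool:
        return all(st == SUCCEEDED for st in self.statuses.values())


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render(
    spec: WorkflowSpec, bindings: MacroBindings, run_dir: str | Path
) -> list[RenderedStep]:
    """Render every step of *spec* into a concrete command.

    Output port tokens become ``run_dir/<step>/<port>``; linked input
    tokens become the upstream step's output path; unlinked inputs resolve
    from *bindings*; macros resolve from *bindings* or their declared
    default.  Deterministic given (spec, bindings, run_dir).  Steps are
    returned in the deterministic topological order.
    """
    spec.validate()
    # absolute: commands run with cwd = their own workdir, so relative
    # run_dir paths would resolve against the wrong directory
    run_dir = Path(run_dir).resolve()
    rendered: list[RenderedStep] = []
    out_path = lambda step, port: str(run_dir / step / port)

    for name in spec.topological_order():
        step = spec.steps[name]
        workdir = str(run_dir / name)
        linked = spec.linked_inputs(name)
        input_paths: dict[str, str] = {}
        for port in step.input_ports:
            if port in linked:
                link = linked[port]
                input_paths[port] = out_path(link.from_step, link.from_port)
            else:
                bound = bindings.lookup(port)
                if bound is None:
                    raise UnboundInputError(
                        f"step {name!r}: unlinked input port {port!r} has no binding"
                    )
                input_paths[port] = bound
        output_paths = {port: out_path(name, port) for port in step.output_ports}

        parts: list[str] = []
        pos = 0
        for tok in step.tokens():
            parts.append(step.raw_command[pos : tok.start])
            if tok.kind == INPUT:
                parts.append(input_paths[tok.name])
            elif tok.kind == OUTPUT:
                parts.append(output_paths[tok.name])
            elif tok.kind == MACRO:
                value = bindings.lookup(tok.name)
                if value is None:
                    decl = spec.macros.get(tok.name)
                    value = decl.default_value if decl else None
                if value is None:
                    raise UnboundMacroError(
                        f"step {name!r}: macro {tok.name!r} has no value and no default"
                    )
                parts.append(value)
            else:  # escaped literal '#'
                parts.append("#")
            pos = tok.end
        parts.append(step.raw_command[pos:])
        rendered.append(RenderedStep(name, "".join(parts), input_paths, output_paths, workdir))
    return rendered


# ---------------------------------------------------------------------------
# Log files
# ---------------------------------------------------------------------------

class RunLogs:
    """The four auxiliary files of a run, named after the run directory."""

    def __init__(self, run_dir: str | Path):
        self.run_dir = Path(run_dir)
        base = self.run_dir.name
        self.command_log = self.run_dir / f"{base}.command.log"
        self.ok_log = self.run_dir / f"{base}.ok.log"
        self.out_file = self.run_dir / f"{base}.out"
        self.err_file = self.run_dir / f"{base}.err"
        self.fingerprint_file = self.run_dir / f"{base}.fingerprint"

    def ensure(self) -> None:
        for p in (self.command_log, self.ok_log, self.out_file, self.err_file):
            p.touch()

    def append_command(self, command: str) -> None:
        with open(self.command_log, "a") as fh:
            fh.write(command + "\n")
            fh.flush()
            os.fsync(fh.fileno())

    def append_ok(self, step: str) -> None:
        # Durability matters: the entry must hit disk before any dependent
        # step becomes ready, or a crash could re-run a finished step.
        with open(self.ok_log, "a") as fh:
            fh.write(step + "\n")
            fh.flush()
            os.fsync(fh.fileno())

    def read_ok(self) -> list[str]:
        if not self.ok_log.exists():
            return []
        return [l for l in self.ok_log.read_text().splitlines() if l]

    def append_stream(self, target: Path, step: str, payload: str) -> None:
        with open(target, "a") as fh:
            fh.write(_STEP_DELIM.format(name=step) + "\n")
            if payload:
                fh.write(payload)
                if not payload.endswith("\n"):
                    fh.write("\n")


def write_logs(state: RunState, steps: list[RenderedStep], run_dir: str | Path) -> RunLogs:
    """Ensure the four auxiliary files exist for *run_dir* and return them.

    The engine writes the logs incrementally during :func:`execute`; this
    creates any missing file so a finished (or empty) run always exposes
    the full set.
    """
    logs = RunLogs(run_dir)
    logs.ensure()
    return logs


def fingerprint(spec: WorkflowSpec, bindings: MacroBindings) -> str:
    payload = dumps_workflow(spec) + json.dumps(sorted(bindings.values.items()))
    return hashlib.sha256(payload.encode()).hexdigest()


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------

@dataclass
class _Running:
    step: RenderedStep
    proc: subprocess.Popen
    out_path: Path
    err_path: Path


def execute(
    steps: list[RenderedStep],
    spec: WorkflowSpec,
    max_parallel: int | None = None,
    *,
    state: RunState | None = None,
    on_step_end=None,
) -> RunState:
    """Run *steps* in dependency order with up to *max_parallel* concurrent
    processes.

    A step starts only after all its upstream steps succeeded; ready steps
    are launched lexicographically by name.  On failure, running steps
    finish, nothing downstream of the failure starts, and the final state
    is returned.  *on_step_end*, if given, is called as
    ``on_step_end(state, step_name)`` after each completion; it may raise
    :class:`EngineInterrupted` to stop the run at that step boundary
    (running steps are drained, nothing new starts).
    """
    if max_parallel is None:
        max_parallel = os.cpu_count() or 1
    if max_parallel < 1:
        raise ValueError("max_parallel must be >= 1")

    by_name = {s.name: s for s in steps}
    if set(by_name) != set(spec.steps):
        raise ValueError("rendered steps do not match the workflow spec")

    if state is None:
        state = RunState({name: PENDING for name in spec.steps}, [], "")
    run_dir = Path(steps[0].workdir).parent if steps else Path(".")
    state.run_dir = str(run_dir)
    logs = RunLogs(run_dir)
    try:
        run_dir.mkdir(parents=True, exist_ok=True)
        logs.ensure()
    except OSError as exc:
        raise SetupError(f"run directory {run_dir} is not writable: {exc}") from exc

    upstream = {name: spec.upstream_of(name) for name in spec.steps}
    blocked: set[str] = set()
    running: list[_Running] = []
    stop_launching = False

    def ready_steps() -> list[str]:
        out = []
        for name, st in state.statuses.items():
            if st != PENDING or name in blocked:
                continue
            if all(state.statuses[u] == SUCCEEDED for u in upstream[name]):
                out.append(name)
        return sorted(out)

    def block_downstream(name: str) -> None:
        for d in spec.downstream_closure(name):
            if state.statuses[d] == PENDING:
                blocked.add(d)

    # Steps downstream of anything already failed never start.
    for name, st in state.statuses.items():
        if st == FAILED:
            block_downstream(name)

    def launch(name: str) -> None:
        step = by_name[name]
        wd = Path(step.workdir)
        try:
            wd.mkdir(parents=True, exist_ok=True)
            out_path = wd / ".step.out"
            err_path = wd / ".step.err"
            out_fh = open(out_path, "w")
            err_fh = open(err_path, "w")
            logs.append_command(step.command)
            proc = subprocess.Popen(
                step.command, shell=True, cwd=str(wd), stdout=out_fh, stderr=err_fh
            )
            out_fh.close()
            err_fh.close()
        except OSError as exc:
            state.statuses[name] = FAILED
            state.failure_reasons[name] = f"spawn failure: {exc}"
            block_downstream(name)
            return
        state.statuses[name] = RUNNING
        running.append(_Running(step, proc, out_path, err_path))

    def reap() -> list[str]:
        done: list[str] = []
        for r in list(running):
            rc = r.proc.poll()
            if rc is None:
                continue
            running.remove(r)
            name = r.step.name
            logs.append_stream(logs.out_file, name, r.out_path.read_text())
            logs.append_stream(logs.err_file, name, r.err_path.read_text())
            if rc == 0:
                state.statuses[name] = SUCCEEDED
                state.ok_entries.append(name)
                logs.append_ok(name)
            else:
                state.statuses[name] = FAILED
                state.failure_reasons[name] = f"exit status {rc}"
                block_downstream(name)
            done.append(name)
        return done

    while True:
        if not stop_launching:
            for name in ready_steps():
                if len(running) >= max_parallel:
                    break
                launch(name)
        if not running and (stop_launching or not ready_steps()):
            break
        completed = reap()
        for name in completed:
            if on_step_end is not None:
                try:
                    on_step_end(state, name)
                except EngineInterrupted:
                    stop_launching = True
                    state.interrupted = True
        if not completed:
            time.sleep(_POLL_INTERVAL)
    return state


def run(
    spec: WorkflowSpec,
    bindings: MacroBindings,
    run_dir: str | Path,
    max_parallel: int | None = None,
    *,
    on_step_end=None,
) -> RunState:
    """Render and execute a fresh run in *run_dir*, storing the fingerprint."""
    run_dir = Path(run_dir)
    steps = render(spec, bindings, run_dir)
    try:
        run_dir.mkdir(parents=True, exist_ok=True)
        logs = RunLogs(run_dir)
        logs.ensure()
        logs.fingerprint_file.write_text(fingerprint(spec, bindings) + "\n")
    except OSError as exc:
        raise SetupError(f"run directory {run_dir} is not writable: {exc}") from exc
    return execute(steps, spec, max_parallel, on_step_end=on_step_end)


def resume(
    spec: WorkflowSpec,
    bindings: MacroBindings,
    run_dir: str | Path,
    max_parallel: int | None = None,
    *,
    on_step_end=None,
) -> RunState:
    """Continue an interrupted run: steps in the ok-log are not re-spawned.

    Refuses (:class:`StaleStateError`) when the stored fingerprint does not
    match (spec, bindings) or the ok-log names a step absent from *spec*.
    A completed run resumed is a no-op.
    """
    run_dir = Path(run_dir)
    logs = RunLogs(run_dir)
    if not logs.fingerprint_file.exists():
        raise StaleStateError(f"{run_dir}: no fingerprint; was this directory run before?")
    stored = logs.fingerprint_file.read_text().strip()
    if stored != fingerprint(spec, bindings):
        raise StaleStateError(
            f"{run_dir}: fingerprint mismatch; run directory belongs to a different "
            f"workflow or bindings"
        )
    ok = logs.read_ok()
    unknown = [s for s in ok if s not in spec.steps]
    if unknown:
        raise StaleStateError(f"{run_dir}: ok-log names unknown step(s) {unknown}")

    steps = render(spec, bindings, run_dir)
    statuses = {name: (SUCCEEDED if name in ok else PENDING) for name in spec.steps}
    state = RunState(statuses, list(ok), str(run_dir))
    remaining = [s for s in steps if statuses[s.name] != SUCCEEDED]
    if not remaining:
        return state
    return execute(steps, spec, max_parallel, state=state, on_step_end=on_step_end)
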