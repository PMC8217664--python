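import pathlib

import pytest

from flowcall import engine, fixtures
from flowcall.errors import EngineInterrupted


def tree_snapshot(run_dir) -> dict[str, bytes]:
    """File tree of a run directory with the run-dir name/path normalized,
    so two runs of the same workflow in different directories compare equal."""
    run_dir = pathlib.Path(run_dir)
    out = {}
    for p in sorted(run_dir.rglob("*")):
        if not p.is_file():
            continue
        rel = str(p.relative_to(run_dir)).replace(run_dir.name + ".", "RUN.")
        data = p.read_bytes().replace(str(run_dir.resolve()).encode(), b"RUNDIR")
        out[rel] = data
    return out


def run_interrupted(spec, bindings, run_dir, stop_after: int, max_parallel=1):
    """Run a workflow but stop (as after a sudden interruption) once
    *stop_after* steps have completed."""
    seen = {"n": 0}

    def cb(state, name):
        seen["n"] += 1
        if seen["n"] >= stop_after:
            raise EngineInterrupted()

    return engine.run(spec, bindings, run_dir, max_parallel, on_step_end=cb)


@pytest.fixture
def qc_bwa_spec():
    """The two-step worked example: read cleaning feeding an aligner."""
    from flowcall import PortLink, WorkflowSpec, link_steps

    spec = WorkflowSpec()
    spec.add_step("qc", "fastp -i <r1> -o [clean1] -w #THREADS#")
    spec.add_step("bwa", "bwa mem <reads> > [bam]")
    link_steps(spec, PortLink("qc", "clean1", "bwa", "reads"))
    return spec


@pytest.fixture
def small_cohort(tmp_path):
    """A seeded 3-caller toy cohort with its ground truth."""
    paths, truths = fixtures.make_vcf_cohort(
        tmp_path / "cohort", n_variants=60, n_callers=3, seed=42
    )
    return paths, truths
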