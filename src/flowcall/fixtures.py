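"""Seeded synthetic fixtures: stub-command workflows and toy VCF cohorts.

The workflow fixtures build random DAGs of shell one-liners (file touches,
sleeps, timestamp writes, injected failures) so the scheduler can be
exercised without any bioinformatics tool installed.  The VCF fixtures
write small, syntactically valid multi-caller cohorts with a known
ground-truth evidence table, seeded allele fractions/depths, deliberately
varied indel representations (padded vs minimal) and a controlled fraction
of common-population-frequency spikes, so consensus and filtering results
are checkable exactly.

All generation is deterministic given the seed (byte-identical outputs).
Defaults are sized for fast tests, not for emulating any real cohort.
"""

from __future__ import annotations

import random
import sys
from dataclasses import dataclass
from pathlib import Path

from .consensus import VariantKey, normalize_variant
from .engine import MacroBindings
from .workflow import PortLink, WorkflowSpec, link_steps

_ACGT = "ACGT"


# ---------------------------------------------------------------------------
# Workflow fixtures
# ---------------------------------------------------------------------------

@dataclass
class WorkflowOracle:
    """Brute-force expectations for a fixture workflow."""

    edges: list[tuple[str, str]]
    step_names: list[str]
    fail_at: str | None = None

    def downstream_closure(self, step: str) -> set[str]:
        out: set[str] = set()
        frontier = [step]
        while frontier:
            u = frontier.pop()
            for a, b in self.edges:
                if a == u and b not in out:
                    out.add(b)
                    frontier.append(b)
        return out

    def expected_outcomes(self) -> dict[str, str]:
        """succeeded / failed / never_ran per step under the injected failure."""
        if self.fail_at is None:
            return {s: "succeeded" for s in self.step_names}
        blocked = self.downstream_closure(self.fail_at)
        out = {}
        for s in self.step_names:
            if s == self.fail_at:
                out[s] = "failed"
            elif s in blocked:
                out[s] = "never_ran"
            else:
                out[s] = "succeeded"
        return out


def _step_name(i: int) -> str:
    return f"step_{i:02d}"


def make_workflow_fixture(
    n_steps: int,
    edge_probability: float = 0.3,
    seed: int = 0,
    step_kind: str = "instant",
    sleep_seconds: float = 0.2,
    fail_at: int | None = None,
) -> tuple[WorkflowSpec, MacroBindings, WorkflowOracle]:
    """Random acyclic stub workflow plus its execution oracle.

    Edges only go from lower to higher index, so the graph is acyclic by
    construction.  ``step_kind`` selects the stub command:

    * ``instant``      — deterministic file writes (safe for byte-level
      run-directory comparisons),
    * ``timestamping`` — additionally writes ``start.ns``/``finish.ns``
      wall-clock nanosecond stamps for dependency-order checks,
    * ``sleep``        — timestamping plus a ``sleep`` to force overlap.

    ``fail_at`` makes that step exit nonzero before producing output.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = random.Random(seed)
    names = [_step_name(i) for i in range(n_steps)]
    edges = [
        (names[i], names[j])
        for i in range(n_steps)
        for j in range(i + 1, n_steps)
        if rng.random() < edge_probability
    ]

    spec = WorkflowSpec()
    spec.declare_macro("TAG", "fixture")
    upstream: dict[str, list[str]] = {n: [] for n in names}
    for a, b in edges:
        upstream[b].append(a)
    for i, name in enumerate(names):
        parts = []
        if step_kind in ("timestamping", "sleep"):
            parts.append("date +%s%N > start.ns")
        ins = upstream[name]
        if ins:
            parts.append("cat " + " ".join(f"<in_{u}>" for u in ins) + " > merged_inputs.txt")
        if step_kind == "sleep":
            parts.append(f"sleep {sleep_seconds}")
        if fail_at is not None and i == fail_at:
            # still declares its output port, but fails before finishing
            parts.append(f"echo partial_{name} > [out] && exit 3")
        else:
            parts.append(f"echo payload_{name}_#TAG# > [out]")
            if step_kind in ("timestamping", "sleep"):
                parts.append("date +%s%N > finish.ns")
        spec.add_step(name, " && ".join(parts))
    for a, b in edges:
        link_steps(spec, PortLink(a, "out", b, f"in_{a}"))

    bindings = MacroBindings({"TAG": "run"})
    oracle = WorkflowOracle(
        edges, names, fail_at=_step_name(fail_at) if fail_at is not None else None
    )
    return spec, bindings, oracle


def make_diamond_fixture(
    sleep_seconds: float = 1.0,
) -> tuple[WorkflowSpec, MacroBindings, WorkflowOracle]:
    """The a -> {b, c} -> d diamond with sleeping middle steps (timestamped)."""
    spec = WorkflowSpec()
    spec.add_step("a", "date +%s%N > start.ns && echo seed > [out] && date +%s%N > finish.ns")
    for mid in ("b", "c"):
        spec.add_step(
            mid,
            "date +%s%N > start.ns && cat <in_a> > merged_inputs.txt && "
            f"sleep {sleep_seconds} && echo {mid} > [out] && date +%s%N > finish.ns",
        )
    spec.add_step(
        "d",
        "date +%s%N > start.ns && cat <in_b> <in_c> > [out] && date +%s%N > finish.ns",
    )
    link_steps(spec, PortLink("a", "out", "b", "in_a"))
    link_steps(spec, PortLink("a", "out", "c", "in_a"))
    link_steps(spec, PortLink("b", "out", "d", "in_b"))
    link_steps(spec, PortLink("c", "out", "d", "in_c"))
    edges = [("a", "b"), ("a", "c"), ("b", "d"), ("c", "d")]
    return spec, MacroBindings(), WorkflowOracle(edges, ["a", "b", "c", "d"])


def make_chain_fixture(n_steps: int = 6) -> tuple[WorkflowSpec, MacroBindings, WorkflowOracle]:
    """A deterministic linear chain of instant stub steps."""
    spec = WorkflowSpec()
    names = [_step_name(i) for i in range(n_steps)]
    for i, name in enumerate(names):
        if i == 0:
            spec.add_step(name, f"echo payload_{name} > [out]")
        else:
            # 'out' is referenced once as a port; the append reuses the
            # relative path since each step runs in its own workdir
            spec.add_step(name, f"cat <in_{names[i-1]}> > [out] && echo {name} >> out")
    for i in range(1, n_steps):
        link_steps(spec, PortLink(names[i - 1], "out", names[i], f"in_{names[i-1]}"))
    edges = [(names[i - 1], names[i]) for i in range(1, n_steps)]
    return spec, MacroBindings(), WorkflowOracle(edges, names)


def read_timestamps(run_dir: str | Path, step_names: list[str]) -> dict[str, tuple[int, int]]:
    """Read per-step (start_ns, finish_ns) stamps written by timestamping stubs."""
    run_dir = Path(run_dir)
    out = {}
    for name in step_names:
        start = run_dir / name / "start.ns"
        finish = run_dir / name / "finish.ns"
        if start.exists() and finish.exists():
            out[name] = (int(start.read_text().strip()), int(finish.read_text().strip()))
    return out


# ---------------------------------------------------------------------------
# VCF cohort fixtures
# ---------------------------------------------------------------------------

@dataclass
class CohortTruth:
    """Ground truth for one synthetic variant."""

    key: VariantKey
    callers: frozenset[str]
    vaf: float
    tumor_depth: int
    normal_depth: int
    popfreq_common: bool
    max_popfreq: float | None


def reference_base(chrom: str, pos: int) -> str:
    """Deterministic pseudo-reference base used by cohort generation.

    Not a real genome: a fixed hash of (chrom, pos) into ACGT so padded
    indel representations stay consistent across callers and runs.
    """
    h = (hash_stable(chrom) * 1_000_003 + pos * 2_654_435_761) & 0xFFFFFFFF
    return _ACGT[h % 4]


def hash_stable(s: str) -> int:
    h = 2166136261
    for ch in s:
        h = ((h ^ ord(ch)) * 16777619) & 0xFFFFFFFF
    return h


def reference_window(chrom: str, pos: int, flank: int = 10) -> tuple[int, str]:
    start = max(1, pos - flank)
    seq = "".join(reference_base(chrom, p) for p in range(start, pos + flank + 1))
    return start, seq


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=flowcall-fixture caller={caller}
##contig=<ID=chr1>
##contig=<ID=chr2>
##FILTER=<ID=LowQual,Description="Low quality">
##INFO=<ID=GNOMAD_AF,Number=1,Type=Float,Description="gnomAD allele frequency">
##INFO=<ID=AF_1000G,Number=1,Type=Float,Description="1000 Genomes allele frequency">
##INFO=<ID=ESP_AF,Number=1,Type=Float,Description="ESP allele frequency">
##INFO=<ID=EXAC_AF,Number=1,Type=Float,Description="ExAC allele frequency">
##FORMAT=<ID=AF,Number=1,Type=Float,Description="Allele fraction">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\tTUMOR
"""

DEFAULT_CALLERS = ("strelka2", "vardict", "varscan2", "pindel", "mutect")


def make_vcf_cohort(
    outdir: str | Path,
    n_variants: int = 100,
    n_callers: int = 3,
    seed: int = 0,
    caller_probability: float = 0.6,
    vaf_range: tuple[float, float] = (0.05, 0.45),
    depth_range: tuple[int, int] = (600, 1400),
    popfreq_spike_fraction: float = 0.2,
    indel_fraction: float = 0.3,
) -> tuple[dict[str, Path], list[CohortTruth]]:
    """Write one toy VCF per caller plus the exact ground-truth table.

    Each variant is assigned to each caller independently with
    *caller_probability* (at least one caller always reports it).  Odd-
    numbered callers write indels in a padded representation (one extra
    base of reference context on the left) and report allele fraction only
    through ``AD``, exercising normalization and the VAF fallback chain.
    A *popfreq_spike_fraction* of variants carries a population frequency
    above 1%; all others are below 1% or unannotated.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    callers = list(DEFAULT_CALLERS[:n_callers])
    if n_callers > len(DEFAULT_CALLERS):
        callers += [f"caller{i}" for i in range(len(DEFAULT_CALLERS), n_callers)]

    # distinct, well-separated loci so normalized keys never collide
    positions: list[tuple[str, int]] = []
    used: set[tuple[str, int]] = set()
    while len(positions) < n_variants:
        chrom = "chr1" if rng.random() < 0.6 else "chr2"
        pos = rng.randrange(1000, 5_000_000, 20)
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            positions.append((chrom, pos))

    truths: list[CohortTruth] = []
    rows_by_caller: dict[str, list[tuple[str, int, str]]] = {c: [] for c in callers}
    for chrom, pos in positions:
        ref_base = reference_base(chrom, pos)
        r = rng.random()
        if r < 1.0 - indel_fraction:  # SNV
            alt = rng.choice([b for b in _ACGT if b != ref_base])
            ref, alt_allele = ref_base, alt
        elif r < 1.0 - indel_fraction / 2:  # insertion
            ins = "".join(rng.choice(_ACGT) for _ in range(rng.randint(1, 3)))
            if ins[-1] == ref_base:
                # avoid repeat-context ambiguity: an event ending in its
                # anchor base has several equivalent unaligned encodings
                ins = ins[:-1] + rng.choice([b for b in _ACGT if b != ref_base])
            ref, alt_allele = ref_base, ref_base + ins
        else:  # deletion (skip repeat-ambiguous contexts, see above)
            choice = None
            for del_len in (1, 2, 3):
                deleted = "".join(
                    reference_base(chrom, pos + 1 + i) for i in range(del_len)
                )
                if deleted[-1] != ref_base:
                    choice = deleted
                    break
            if choice is None:
                alt = rng.choice([b for b in _ACGT if b != ref_base])
                ref, alt_allele = ref_base, alt  # fall back to an SNV
            else:
                ref, alt_allele = ref_base + choice, ref_base

        key = normalize_variant(chrom, pos, ref, alt_allele)
        members = frozenset(c for c in callers if rng.random() < caller_probability)
        if not members:
            members = frozenset({rng.choice(callers)})
        vaf = round(rng.uniform(*vaf_range), 4)
        tumor_depth = rng.randint(*depth_range)
        normal_depth = rng.randint(*depth_range)

        spiked = rng.random() < popfreq_spike_fraction
        freq_info: list[str] = []
        max_freq: float | None = None
        if spiked:
            f = round(rng.uniform(0.02, 0.2), 4)
            source = rng.choice(["GNOMAD_AF", "AF_1000G", "EXAC_AF"])
            freq_info.append(f"{source}={f}")
            if rng.random() < 0.5:  # second, rarer source
                freq_info.append(f"ESP_AF={round(rng.uniform(0.001, 0.009), 4)}")
            max_freq = f
        elif rng.random() < 0.3:
            f = round(rng.uniform(0.0001, 0.009), 4)
            freq_info.append(f"GNOMAD_AF={f}")
            max_freq = f

        truths.append(
            CohortTruth(key, members, vaf, tumor_depth, normal_depth, spiked, max_freq)
        )

        alt_reads = max(1, round(vaf * tumor_depth))
        for idx, caller in enumerate(callers):
            if caller not in members:
                continue
            c_pos, c_ref, c_alt = pos, ref, alt_allele
            padded = idx % 2 == 1 and len(ref) != len(alt_allele)
            if padded:  # pad one extra reference base on the left
                pad = reference_base(chrom, pos - 1)
                c_pos, c_ref, c_alt = pos - 1, pad + ref, pad + alt_allele
            info = ";".join(freq_info) if freq_info else "."
            if idx % 2 == 1:  # AD-only caller: VAF must come from the AD ratio
                fmt = "AD:DP"
                normal_s = f"{normal_depth},0:{normal_depth}"
                tumor_s = f"{tumor_depth - alt_reads},{alt_reads}:{tumor_depth}"
            else:
                fmt = "AF:DP"
                normal_s = f"0:{normal_depth}"
                tumor_s = f"{vaf}:{tumor_depth}"
            line = (
                f"{key.chrom}\t{c_pos}\t.\t{c_ref}\t{c_alt}\t.\tPASS\t{info}"
                f"\t{fmt}\t{normal_s}\t{tumor_s}"
            )
            rows_by_caller[caller].append((key.chrom, c_pos, line))

    paths: dict[str, Path] = {}
    for caller in callers:
        rows = sorted(rows_by_caller[caller], key=lambda r: (r[0], r[1]))
        path = outdir / f"{caller}.vcf"
        path.write_text(
            _VCF_HEADER.format(caller=caller) + "\n".join(r[2] for r in rows) + "\n"
        )
        paths[caller] = path
    return paths, truths


def truth_evidence_oracle(truths: list[CohortTruth]) -> dict[VariantKey, frozenset[str]]:
    """Brute-force dictionary-of-sets evidence oracle from the truth table."""
    return {t.key: t.callers for t in truths}


def truth_to_dataframe(truths: list[CohortTruth]):
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [t.key.chrom for t in truths],
            "pos": [t.key.pos for t in truths],
            "ref": [t.key.ref for t in truths],
            "alt": [t.key.alt for t in truths],
            "variant_class": [t.key.variant_class for t in truths],
            "callers": [",".join(sorted(t.callers)) for t in truths],
            "n_callers": [len(t.callers) for t in truths],
            "vaf": [t.vaf for t in truths],
            "tumor_depth": [t.tumor_depth for t in truths],
            "normal_depth": [t.normal_depth for t in truths],
            "popfreq_common": [t.popfreq_common for t in truths],
            "max_popfreq": [t.max_popfreq for t in truths],
        }
    )


# ---------------------------------------------------------------------------
# End-to-end stub pipeline (the bundled example topology)
# ---------------------------------------------------------------------------

def example_somatic_workflow(
    cohort_dir: str | Path | None = None,
    callers: tuple[str, ...] = ("strelka2", "vardict", "varscan2", "pindel"),
    target_bp: int = 1_000_000,
    interpreter: str | None = None,
) -> WorkflowSpec:
    """The stub somatic-pipeline topology used as living documentation:
    qc -> align -> four parallel caller steps -> merge -> report.

    The qc/align/caller steps are stubs (the real tools are external);
    caller steps copy a pre-generated per-caller VCF from ``#COHORT#`` into
    their output port, then the merge and report steps run this package's
    own subcommands on them.
    """
    py = interpreter or sys.executable
    spec = WorkflowSpec()
    spec.declare_macro("COHORT", str(cohort_dir) if cohort_dir else None)
    spec.declare_macro("SAMPLE", "sample01")
    spec.declare_macro("TARGET_BP", str(target_bp))
    spec.add_step("qc", "echo qc of <raw_reads> > [clean_reads]")
    spec.add_step("align", "echo aligned <reads> > [bam]")
    link_steps(spec, PortLink("qc", "clean_reads", "align", "reads"))
    for caller in callers:
        spec.add_step(
            f"{caller}_somatic", f"cat <bam> > /dev/null && cp #COHORT#/{caller}.vcf [vcf]"
        )
        link_steps(spec, PortLink("align", "bam", f"{caller}_somatic", "bam"))
    merge_inputs = " ".join(
        f"--caller {c}=<vcf_{c}>" for c in callers
    )
    spec.add_step(
        "merge",
        f"{py} -m flowcall merge {merge_inputs} --min-callers 2 "
        f"--out [merged] --out-table [table]",
    )
    for caller in callers:
        link_steps(spec, PortLink(f"{caller}_somatic", "vcf", "merge", f"vcf_{caller}"))
    spec.add_step(
        "report",
        f"{py} -m flowcall maf --in <merged> --sample #SAMPLE# "
        f"--target-bp #TARGET_BP# --maf [maf] --report-dir . "
        # the engine's command log lives one level up, named after the run dir
        f'--commands-log "$(ls ../*.command.log | head -n 1)"',
    )
    link_steps(spec, PortLink("merge", "merged", "report", "merged"))
    spec.validate()
    return spec
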