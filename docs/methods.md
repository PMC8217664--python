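# Methods

This note documents the models, conventions and design choices behind
flowcall: the workflow engine, the multi-caller consensus procedure, the
MAF/summary layer, and the synthetic fixtures the tests rely on.

## Workflow model

A workflow is a finite set of named steps, each a shell command string
annotated with markup tokens, plus a set of port links and a macro table.
Grammar and naming rules:

* step and port names: nonempty, lowercase letters, digits, underscores;
* macro names: nonempty, uppercase letters, digits, underscores;
* `<port>` marks an input, `[port]` an output, `#MACRO#` a macro; a
  literal `#` must be written `##`. Tokens may not nest; an unclosed
  delimiter is a parse error reported with its character offset.

Port identity is by *name*, not position: names survive command edits,
which positional indices would not. Each input port may be the target of
at most one link; an output port may fan out to any number of downstream
inputs (nothing in the format forbids it, and fan-out is the common case
for an aligned-reads output feeding several callers). The step graph must
be acyclic; cycle checking is delegated to networkx and cross-checked in
tests against a brute-force reachability oracle.

### JSON serialization

The exported document has `schema_version` (currently `"1.0"`), `macro`
(name → default or null) and `workflow` (array of step objects with
`name`, `command`, and `from`/`to` link statements carrying
`frompid`/`topid`). Serialization is canonical — macros and steps sorted
by name, from-statements in the downstream port's order of appearance —
so export is byte-stable. On export each linked input token is replaced
by the expression `@{step.port}` naming the upstream output; the importer
uses the from-statements to replace those expressions back with the
original `<topid>` tokens before re-parsing the markup, making
import ∘ export the identity on valid specs. The `@{...}` form is
reserved: a raw command must not contain it literally. The `to`
statements are redundant mirrors kept for readability; the importer
verifies their consistency when present.

## Engine

Rendering maps the symbolic workflow onto a run directory: every step
gets its own working directory `run_dir/<step>/`, output port `p` of step
`s` becomes the file `run_dir/<s>/<p>`, linked inputs become the upstream
output path, unlinked inputs and macros resolve from the bindings (exact
name first, then the uppercase form — macros are uppercase by grammar,
while external input ports are lowercase; allowing the lowercase key in
the bindings file keeps one flat namespace). A missing macro value with
no declared default, or an unbound external input, aborts rendering with
an error naming the offender. The run directory is resolved to an
absolute path because each command executes with its own workdir as cwd.

Scheduling is the classic ready-set loop: a step is ready when pending
with all upstream steps succeeded; ready steps launch in lexicographic
order up to `max_parallel` concurrent processes (default: CPU count).
Success is exit status zero — the only portable notion of success for
arbitrary shell commands. On failure, running steps finish, steps
downstream of the failure never start, and independent branches continue
(fail-downstream-only maximizes salvageable work before a resume). With
`max_parallel=1` the launch order is the deterministic lexicographic
topological order, so `command.log` is byte-identical across runs.

Four auxiliary files named after the run directory's basename record the
run: `*.command.log` (every launched concrete command, launch order),
`*.ok.log` (successful steps, append-only), `*.out`/`*.err` (children's
standard streams, concatenated with `==== step: NAME ====` delimiters in
completion order; per-step capture files are kept in each workdir). The
ok-log entry is flushed and fsynced *before* any dependent step can
become ready: after a sudden interruption the ok-log never claims a step
that did not complete, which is the invariant resume depends on.

Resume re-renders the workflow against the same run directory, marks
every ok-log step succeeded without respawning it, and schedules the
remainder. Staleness is detected by a SHA-256 fingerprint of the
canonical exported JSON plus the sorted bindings, written to
`*.fingerprint` on the first run; a mismatch, or an ok-log entry naming
an unknown step, refuses the resume. For testing, interruption is
modelled by an `on_step_end` callback that raises `EngineInterrupted` at
a chosen step boundary: the scheduler stops launching, drains running
processes, and returns. This reproduces every interruption point
deterministically; killing processes mid-write would add nondeterminism
without exercising any additional engine logic, at the cost of leaving
the interrupted step's files half-written (a case the ok-log invariant
already covers: an unfinished step is simply re-run).

## Variant consensus

### Normalization

Callers encode the same event differently (extra shared context bases,
pre-trimmed alleles). Every call is reduced to a canonical key
(chrom, pos, ref, alt):

1. trim the shared suffix; when an allele is down to one base, extend
   both alleles leftward from the reference window (when supplied) —
   this is what left-aligns indels through repeat runs;
2. trim the shared prefix, advancing pos, keeping at least one base per
   allele.

Without a reference window the result is the minimal anchored (VCF-style)
representation; with a window it is additionally left-aligned. The
operation is idempotent. A caller emitting an empty allele (pre-trimmed
indel) is re-anchored from the window; without one this is an error,
since the anchor base is simply unknown. Equal-length multi-base
substitutions that survive trimming are classified `MNV` alongside the
`SNV`/`insertion`/`deletion` classes.

Matching across callers is exact equality of normalized keys. No fuzzy
position-window matching is attempted: exact matching is deterministic,
oracle-testable, and sufficient once representations are normalized.
Multi-allelic VCF rows are split per alt allele before normalization,
because caller evidence is a per-allele notion.

### Merge and filters

Callers are registered in input order and given integer codes starting at
1; the code is an identifier, not a ranking. Merging produces one record
per distinct key with the evidence set (codes of reporting callers) and
retained per-caller attributes, sorted by contig order of first
appearance (stable without requiring a reference genome), then position
and alleles.

Candidate selection keeps a record iff

* |evidence| ≥ `min_callers` (default 2 — the consensus rule),
* best reported VAF > `min_vaf` (default 0.01, strict inequality),
* when the depth filter is enabled, every reported tumor/normal depth
  (per `apply_depth_to`) is ≥ `min_depth` (disabled by default; 500
  matches a high-depth panel baseline).

Missing per-caller values never disqualify a record: the filters remove
proven violations only, consistent with the keep-if-unknown population
rule below. VAF extraction tries the tumor sample's `AF` FORMAT field,
then the `AD`-derived ratio alt/(ref+alt), then an `AF` INFO field;
depths come from per-sample `DP`. The tumor sample is the one named
`TUMOR` (case-insensitive); otherwise, with two samples, the second is
assumed tumor (the NORMAL/TUMOR column convention); a lone sample is
tumor. Records whose FILTER column is not PASS are excluded unless
`--include-nonpass` is given.

The merged output is a text VCF defined by this package (INFO keys
`CALLER_CODES`, `CALLERS`, `NCALLERS`, `MAX_VAF`, `TDP`, `NDP`, plus
carried population frequencies); tests re-read it with a strict VCF
parser.

## Population filter, MAF, summary

The population frequency of a locus is the **maximum** over the sources
that annotate it (1000 Genomes, gnomAD, ESP, ExAC; INFO keys default to
`AF_1000G`, `GNOMAD_AF`, `ESP_AF`, `EXAC_AF` and are overridable). Loci
with max frequency > 1% are dropped; loci with no annotation anywhere
are kept — the filter removes proven-common variants only, which is the
conservative choice for somatic candidates.

MAF conversion (1-based inclusive): an SNV keeps its position; a deletion
drops the VCF anchor base (start = pos+1, reference = deleted bases,
tumor allele `-`); an insertion spans the flanking positions
(start = pos, end = pos+1, reference `-`). Equal-length multi-base
substitutions map to DNP/TNP/ONP. The anchor base is genuinely lost in
this conversion; the inverse used by the round-trip property test takes
it as an argument. Unannotated rows get gene `Unknown` and
classification `Targeted_Region` (a deliberate convention for panel
data); functional annotation itself is consumed from a sidecar table,
never computed — annotators are external tools.

Summary statistics: class proportions over surviving records (sum to 1
when nonempty); Ti/Tv = transitions / transversions over single-base
substitutions only, reported as undefined (JSON `null`) when there are no
transversions; TMB = surviving SNVs + indels per megabase of the supplied
target size (`--target-bp`), configurable to SNV-only in the library. The
report is self-contained HTML with three sections — commands/parameters,
QC/alignment metrics passed through from upstream tools (an explicit
"not available" placeholder when absent), and the mutation landscape —
plus a `report.json` twin that serializes every number deterministically
(sorted keys), so regeneration is byte-identical.

## Synthetic fixtures

Workflow fixtures generate random DAGs with edges only from lower to
higher index (acyclic by construction) and stub shell commands: pure file
writes (`instant`, safe for byte-level run-tree comparison), wall-clock
nanosecond `start.ns`/`finish.ns` stamps (`timestamping`, for
dependency-order checks), optional `sleep` (to force overlap) and an
injected nonzero exit (`fail_at`). The paired oracle computes downstream
closures and expected per-step outcomes by brute force.

VCF cohorts place well-separated loci on two contigs of a deterministic
pseudo-reference (a fixed hash of chrom/pos into ACGT — not a real
genome), assign each variant to each caller independently (p = 0.6, at
least one caller guaranteed), and draw VAF from 0.05–0.45 and depths from
600–1400 so that default filters are exercised from the passing side.
Odd-numbered callers write indels padded with one extra left context base
and report only `AD` (no `AF`), exercising normalization and the VAF
fallback chain. A configurable fraction (default 20%) of loci is spiked
with a population frequency of 2–20%; all other annotated loci stay
≤ 0.9%, so the 1% filter's correct answer is known exactly. Indel events
whose sequence ends in its own anchor base are avoided: such events have
several equivalent unaligned encodings (repeat-context ambiguity), which
only a reference genome could reconcile — the generator models callers
that agree on the event locus up to padding, not reference-free
left-alignment. Everything is seeded and byte-deterministic.

These fixtures establish correctness of the plumbing — scheduling,
normalization, set arithmetic, filters, format round-trips. They do not
emulate read-level noise, caller-specific error profiles, sequencing
artifacts or real population-frequency distributions, so passing tests
say nothing about real-data sensitivity/specificity of any particular
caller combination.

## Problem sizes and numerical choices

The property sweeps use 200 random DAGs of ≤ 30 steps (scheduling), 100
workflow documents (round-trip), 100 cohorts of 30–200 variants × 3–5
callers (consensus), 10,000 random keys (normalization idempotence) and
every interruption point of a 6-step chain and a 6-step diamond
(crash-resume) — sizes chosen so the full sweep completes in well under a
minute while covering the combinatorics many times over. The scheduler
polls at 4 ms; ties among ready steps break lexicographically; floats in
generated VCFs are written with fixed precision so outputs are
byte-stable. Ti/Tv with zero transversions, empty record lists, and a
missing TMB target size are all defined non-throwing cases (undefined
marker / empty stats), except that a nonpositive target size is a
configuration error.

## Known limitations

* The engine runs commands through the system shell with the inherited
  environment; there is no sandboxing, retry policy, or cluster
  submission.
* `*.out`/`*.err` are per-step-delimited concatenations in completion
  order, not real-time interleavings of the children's streams.
* Consensus matching is exact on normalized keys; two callers reporting
  a complex event in structurally different (non-pad-equivalent) forms
  without a reference window will not merge.
* MAF output carries a minimal standard column set plus
  `caller_evidence`; cohort-level MAF aggregation across samples is out
  of scope.
* Pathogenicity scoring and driver/susceptibility-gene calling are not
  performed; an optional user-supplied gene list can flag rows in the
  report, but the scoring itself belongs to external tools.
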