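# flowcall

A lightweight workflow engine plus a multi-caller somatic-variant
consensus layer, aimed at cancer genome sequencing pipelines where several
variant callers (e.g. Strelka2, VarDict, VarScan 2, Pindel) must be run in
parallel and their disagreeing outputs reconciled into a single candidate
mutation list with caller evidence, a MAF table and a summary report.

## What it does

**Workflow engine.** A workflow is a DAG of named shell steps written in a
three-token markup:

* `<name>` — an input port (a file the step consumes),
* `[name]` — an output port (a file the step produces),
* `#NAME#` — a macro placeholder bound at run time (`##` escapes a literal `#`).

Steps are connected by linking an upstream output port to a downstream
input port. The workflow serializes to a JSON document with two content
fields, `macro` and `workflow`, whose `from`/`to` statements carry
`frompid`/`topid` port names; export replaces each linked input token with
a reference to the upstream output, and import inverts it, so documents
round-trip exactly. The scheduler repeatedly launches every step whose
upstream steps have all succeeded (up to `--max-parallel` concurrently),
records four auxiliary files in the run directory
(`<run>.command.log`, `<run>.ok.log`, `<run>.out`, `<run>.err`), and can
resume an interrupted run from the ok-log without re-executing any
finished step.

**Consensus layer.** Per-caller VCFs are reduced to minimal, anchored,
left-alignable variant keys (so padded and minimal indel encodings of the
same event compare equal), merged into one record per distinct key with
the set of supporting callers attached (callers are identified by small
integers in registration order — the code carries no priority meaning),
and filtered:

* consensus rule: keep variants supported by at least *k* callers
  (default *k* = 2);
* site filters: best reported variant allele fraction (VAF) > 0.01 by
  default, optional minimum tumor/normal depth (500× reproduces a common
  high-depth panel baseline);
* population filter: drop loci whose maximum allele frequency over the
  1000 Genomes / gnomAD / ESP / ExAC INFO annotations exceeds 1%
  (unannotated loci are kept).

Survivors are converted to MAF (Mutation Annotation Format, 1-based
inclusive coordinates, `-` alleles for indels, a custom `caller_evidence`
column) and summarized: mutation-class proportions, transition/transversion
ratio (Ti/Tv; transitions are A↔G and C↔T), and tumor mutation burden
(TMB = mutations per megabase of target territory). A three-part HTML
report (commands, QC pass-through, mutation landscape) is written with a
machine-readable `report.json` twin.

## Worked example

Build the two-step read-cleaning → alignment workflow and run it:

```python
import flowcall as fc
spec = fc.WorkflowSpec()
spec.add_step("qc", "fastp -i <r1> -o [clean1] -w #THREADS#")
spec.add_step("bwa", "bwa mem <reads> > [bam]")
fc.link_steps(spec, fc.PortLink("qc", "clean1", "bwa", "reads"))
print(fc.export_json(spec)["workflow"][0]["command"])
```

prints the exported downstream command with the port substitution applied:

```
bwa mem @{qc.clean1} > [bam]
```

At render time `@{qc.clean1}` becomes `<run_dir>/qc/clean1` and `[bam]`
becomes `<run_dir>/bwa/bam`; `#THREADS#` and the unlinked `<r1>` come from
the bindings file.

A complete stub somatic pipeline (qc → align → four parallel caller steps
→ merge → report) ships in `examples/wes_somatic_stub.json`. Generate a
toy cohort and run it:

```sh
flowcall fixture cohort --n-variants 60 --n-callers 4 --seed 5 --out cohort/
flowcall run examples/wes_somatic_stub.json \
    --macros examples/wes_somatic_bindings.json --out runout --max-parallel 4
```

which ends with

```
run complete: 8 step(s) succeeded
```

and leaves one directory per step plus the four log files under `runout/`.
`runout/report/report.json` then contains the mutation landscape, e.g.

```
"n_variants": 54, "tmb": 54.0, "titv_ratio": 2.0588...
```

meaning 54 variants survived the ≥2-caller and 1%-population-frequency
filters over the declared 1 Mb target (hence TMB 54 mutations/Mb).
The consensus subcommands can equally be run directly:

```sh
flowcall merge --caller strelka2=a.vcf --caller vardict=b.vcf \
    --min-callers 2 --min-vaf 0.01 --out merged.vcf --out-table candidates.tsv
flowcall maf --in merged.vcf --sample S1 --target-bp 1760000 \
    --maf out.maf --report-dir report/
```

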