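"""Population-frequency filtering, MAF conversion and the summary report.

The Mutation Annotation Format (MAF) is the tab-delimited, cohort-level
mutation table originated by The Cancer Genome Atlas; it is the standard
input to downstream tools such as maftools.  Coordinate conventions are
1-based inclusive: SNVs keep their position, a deletion drops the VCF
anchor base (start shifts one right, reference is the deleted sequence,
tumor allele is ``-``), and an insertion spans the two flanking positions
with a ``-`` reference.  Converting an indel row back to a VCF-style key
therefore needs the anchor base again, which MAF does not store.

Summary statistics follow the usual definitions: transitions are the
purine-purine / pyrimidine-pyrimidine substitutions (A<->G, C<->T),
transversions everything else among SNVs; tumor mutation burden (TMB) is
the number of qualifying mutations per megabase of sequenced target
territory.
"""

from __future__ import annotations

import html
import json
from dataclasses import dataclass, field
from pathlib import Path

from .consensus import SNV, CallerRegistry, VariantKey, VariantRecord
from .errors import ConfigError, NormalizationError

POPFREQ_SOURCES = ("thousand_genomes", "gnomad", "esp", "exac")

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

MAF_COLUMNS = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "End_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Type",
    "Variant_Classification",
    "Tumor_Sample_Barcode",
    "caller_evidence",
]


# ---------------------------------------------------------------------------
# Population-frequency filter
# ---------------------------------------------------------------------------

def max_popfreq(freqs: dict[str, float]) -> float | None:
    """Maximum allele frequency over the sources that report one."""
    present = [v for v in freqs.values() if v is not None]
    return max(present) if present else None


def popfreq_filter(
    records: list[VariantRecord], threshold: float = 0.01
) -> list[VariantRecord]:
    """Drop records whose population frequency exceeds *threshold*.

    The population frequency of a record is the maximum over its reporting
    sources; records with no frequency data in any source are kept (only
    proven-common loci are removed).  Order is preserved.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ConfigError("popfreq threshold must be in [0, 1]")
    out = []
    for rec in records:
        mx = max_popfreq(rec.popfreqs)
        if mx is not None and mx > threshold:
            continue
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# MAF conversion
# ---------------------------------------------------------------------------

@dataclass
class MafRecord:
    hugo_symbol: str
    chromosome: str
    start_position: int
    end_position: int
    reference_allele: str
    tumor_seq_allele2: str
    variant_type: str  # SNP / DNP / TNP / ONP / INS / DEL
    variant_classification: str
    tumor_sample_barcode: str
    caller_evidence: str = ""

    def row(self) -> list[str]:
        return [
            self.hugo_symbol,
            self.chromosome,
            str(self.start_position),
            str(self.end_position),
            self.reference_allele,
            self.tumor_seq_allele2,
            self.variant_type,
            self.variant_classification,
            self.tumor_sample_barcode,
            self.caller_evidence,
        ]


def key_to_maf_coords(key: VariantKey) -> tuple[int, int, str, str, str]:
    """(start, end, ref, alt, variant_type) under MAF conventions."""
    ref, alt, pos = key.ref, key.alt, key.pos
    if len(ref) == len(alt):
        vt = {1: "SNP", 2: "DNP", 3: "TNP"}.get(len(ref), "ONP")
        return pos, pos + len(ref) - 1, ref, alt, vt
    if len(ref) > len(alt):  # deletion: drop the anchor base
        deleted = ref[len(alt):]
        start = pos + len(alt)
        return start, start + len(deleted) - 1, deleted, "-", "DEL"
    inserted = alt[len(ref):]  # insertion: flanking positions, '-' reference
    return pos + len(ref) - 1, pos + len(ref), "-", inserted, "INS"


def maf_to_key(
    chromosome: str,
    start: int,
    end: int,
    ref: str,
    alt: str,
    variant_type: str,
    anchor_base: str | None = None,
) -> VariantKey:
    """Invert :func:`key_to_maf_coords`.

    Indel rows lost their VCF anchor base in the conversion, so
    *anchor_base* (the reference base immediately left of the event) must
    be supplied for INS/DEL rows.
    """
    if variant_type in ("SNP", "DNP", "TNP", "ONP"):
        return VariantKey(chromosome, start, ref, alt)
    if anchor_base is None:
        raise NormalizationError(
            f"{variant_type} row needs the reference anchor base to rebuild a VCF key"
        )
    if variant_type == "DEL":
        return VariantKey(chromosome, start - 1, anchor_base + ref, anchor_base)
    if variant_type == "INS":
        return VariantKey(chromosome, start, anchor_base, anchor_base + alt)
    raise ConfigError(f"unknown variant_type {variant_type!r}")


def vcf_to_maf(
    records: list[VariantRecord],
    annotations: dict[VariantKey, tuple[str, str]] | None,
    sample_id: str,
    registry: CallerRegistry | None = None,
) -> list[MafRecord]:
    """One MAF row per record; caller evidence goes into a custom column.

    *annotations* maps keys to ``(gene, classification)`` pairs from an
    external functional annotator; unannotated records get gene
    ``Unknown`` and classification ``Targeted_Region``.
    """
    annotations = annotations or {}
    out = []
    for rec in records:
        start, end, ref, alt, vt = key_to_maf_coords(rec.key)
        gene, classification = annotations.get(rec.key, ("Unknown", "Targeted_Region"))
        codes = sorted(rec.evidence)
        if registry is not None:
            evidence = ",".join(f"{registry.name(c)}:{c}" for c in codes)
        else:
            evidence = ",".join(map(str, codes))
        out.append(
            MafRecord(
                gene, rec.key.chrom, start, end, ref, alt, vt, classification,
                sample_id, evidence,
            )
        )
    return out


def write_maf(maf_records: list[MafRecord], path: str | Path) -> None:
    lines = ["\t".join(MAF_COLUMNS)]
    lines += ["\t".join(m.row()) for m in maf_records]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

@dataclass
class SummaryStats:
    n_variants: int
    class_proportions: dict[str, float]
    titv_ratio: float | None  # None when transversions == 0 (undefined)
    tmb: float | None
    per_caller_counts: dict[str, int] = field(default_factory=dict)
    consensus_histogram: dict[int, int] = field(default_factory=dict)
    n_transitions: int = 0
    n_transversions: int = 0

    def to_dict(self) -> dict:
        return {
            "n_variants": self.n_variants,
            "class_proportions": dict(sorted(self.class_proportions.items())),
            "titv_ratio": self.titv_ratio,
            "n_transitions": self.n_transitions,
            "n_transversions": self.n_transversions,
            "tmb": self.tmb,
            "per_caller_counts": dict(sorted(self.per_caller_counts.items())),
            "consensus_histogram": {
                str(k): v for k, v in sorted(self.consensus_histogram.items())
            },
        }


def is_transition(ref: str, alt: str) -> bool:
    return (ref, alt) in _TRANSITIONS


def summarize(
    records: list[VariantRecord],
    target_size_bp: int | None = None,
    caller_registry: CallerRegistry | None = None,
) -> SummaryStats:
    """Mutation-landscape aggregates over the surviving records.

    Ti/Tv counts only single-base substitutions; TMB is computed when
    *target_size_bp* is given and is ``n / (target_size_bp / 1e6)``.
    """
    if target_size_bp is not None and target_size_bp <= 0:
        raise ConfigError("target_size_bp must be positive when TMB is requested")
    n = len(records)
    class_counts: dict[str, int] = {}
    ti = tv = 0
    per_caller: dict[str, int] = {}
    histogram: dict[int, int] = {}
    for rec in records:
        vc = rec.variant_class
        class_counts[vc] = class_counts.get(vc, 0) + 1
        if vc == SNV:
            if is_transition(rec.key.ref, rec.key.alt):
                ti += 1
            else:
                tv += 1
        size = len(rec.evidence)
        histogram[size] = histogram.get(size, 0) + 1
        for code in rec.evidence:
            name = caller_registry.name(code) if caller_registry else str(code)
            per_caller[name] = per_caller.get(name, 0) + 1
    proportions = {c: k / n for c, k in class_counts.items()} if n else {}
    titv = (ti / tv) if tv > 0 else None
    tmb = (n / (target_size_bp / 1e6)) if target_size_bp else None
    return SummaryStats(
        n_variants=n,
        class_proportions=proportions,
        titv_ratio=titv,
        tmb=tmb,
        per_caller_counts=per_caller,
        consensus_histogram=histogram,
        n_transitions=ti,
        n_transversions=tv,
    )


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

_REPORT_TEMPLATE = """<!DOCTYPE html>
<html>
<head><meta charset="utf-8"><title>Variant analysis report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; }}
td, th {{ border: 1px solid #999; padding: 4px 10px; }}
h2 {{ border-bottom: 2px solid #333; }}
.missing {{ color: #888; font-style: italic; }}
</style></head>
<body>
<h1>Variant analysis report</h1>
<h2>1. Commands and parameters</h2>
{commands}
<h2>2. Quality control and alignment metrics</h2>
{qc}
<h2>3. Mutation landscape</h2>
{landscape}
</body>
</html>
"""

_NOT_AVAILABLE = '<p class="missing">not available</p>'


def _table(rows: list[tuple[str, str]]) -> str:
    body = "\n".join(
        f"<tr><td>{html.escape(str(k))}</td><td>{html.escape(str(v))}</td></tr>"
        for k, v in rows
    )
    return f"<table>\n{body}\n</table>"


def render_report(
    stats: SummaryStats,
    run_meta: dict | None,
    out: str | Path,
) -> tuple[Path, Path]:
    """Write ``report.html`` and its machine-readable twin ``report.json``.

    *run_meta* may carry ``commands`` (list of executed command lines) and
    ``qc_metrics`` (mapping of pass-through metrics from upstream tools);
    missing sections are rendered with an explicit "not available" marker.
    Deterministic: the same inputs produce byte-identical files.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    run_meta = run_meta or {}

    commands = run_meta.get("commands")
    if commands:
        cmd_html = "<pre>" + html.escape("\n".join(commands)) + "</pre>"
    else:
        cmd_html = _NOT_AVAILABLE
    qc = run_meta.get("qc_metrics")
    qc_html = _table(sorted(qc.items())) if qc else _NOT_AVAILABLE

    d = stats.to_dict()
    landscape_rows = [
        ("variants", d["n_variants"]),
        ("Ti/Tv ratio", "undefined" if d["titv_ratio"] is None else f"{d['titv_ratio']:.6g}"),
        ("transitions", d["n_transitions"]),
        ("transversions", d["n_transversions"]),
        ("TMB (mutations/Mb)", "not computed" if d["tmb"] is None else f"{d['tmb']:.6g}"),
    ]
    landscape_rows += [
        (f"proportion {cls}", f"{p:.6g}") for cls, p in d["class_proportions"].items()
    ]
    landscape_rows += [
        (f"supported by {k} caller(s)", v) for k, v in d["consensus_histogram"].items()
    ]
    landscape_rows += [(f"calls by {c}", v) for c, v in d["per_caller_counts"].items()]
    # genes from a user-supplied watch list (e.g. known driver or
    # susceptibility genes) found among the surviving mutations
    flagged = sorted(run_meta.get("flagged_genes") or [])
    if flagged:
        landscape_rows.append(("flagged genes", ", ".join(flagged)))

    html_text = _REPORT_TEMPLATE.format(
        commands=cmd_html, qc=qc_html, landscape=_table(landscape_rows)
    )
    twin = {
        "commands": commands or [],
        "qc_metrics": qc or {},
        "flagged_genes": flagged,
        "mutation_landscape": d,
    }
    html_path = out / "report.html"
    json_path = out / "report.json"
    html_path.write_text(html_text)
    json_path.write_text(json.dumps(twin, indent=2, sort_keys=True) + "\n")
    return html_path, json_path
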