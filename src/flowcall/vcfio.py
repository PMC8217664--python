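"""Read per-caller VCFs and write the merged, evidence-annotated VCF.

Reading goes through :mod:`cyvcf2`.  Multi-allelic rows are split into
bi-allelic calls before normalization.  Allele fraction is taken from the
tumor sample's ``AF`` FORMAT field when present, else derived from ``AD``
(alt / total), else from an ``AF`` INFO field; depths come from the
per-sample ``DP`` field.  The tumor sample is the one named ``TUMOR``
(case-insensitive) if any, else the second of two samples (the common
NORMAL/TUMOR column convention), else the only sample.

Population allele frequencies are collected from configurable INFO keys;
the defaults cover the four public databases commonly used for common-
variant filtering (1000 Genomes, gnomAD, ESP, ExAC).
"""

from __future__ import annotations

import math
from pathlib import Path

from cyvcf2 import VCF

from .consensus import (
    CallerCall,
    CallerRegistry,
    VariantKey,
    VariantRecord,
    normalize_variant,
)
from .errors import NormalizationError

#: default INFO keys carrying population allele frequencies, per source
DEFAULT_POPFREQ_KEYS = {
    "thousand_genomes": "AF_1000G",
    "gnomad": "GNOMAD_AF",
    "esp": "ESP_AF",
    "exac": "EXAC_AF",
}


def _sample_indices(samples: list[str]) -> tuple[int | None, int | None]:
    """(tumor_index, normal_index) for a VCF's sample columns."""
    tumor = normal = None
    for i, s in enumerate(samples):
        up = s.upper()
        if "TUMOR" in up or up.startswith("TU"):
            tumor = i
        elif "NORMAL" in up or up.startswith("NO"):
            normal = i
    if tumor is None:
        if len(samples) == 1:
            tumor = 0
        elif len(samples) >= 2:
            normal = 0 if normal is None else normal
            tumor = 1
    return tumor, normal


def _fmt_value(variant, key: str, sample_idx: int, allele_idx: int = 0):
    try:
        arr = variant.format(key)
    except KeyError:
        return None
    if arr is None:
        return None
    row = arr[sample_idx]
    try:
        vals = list(row)
    except TypeError:
        vals = [row]
    idx = min(allele_idx, len(vals) - 1)
    v = vals[idx]
    if v is None:
        return None
    f = float(v)
    return None if math.isnan(f) or f < 0 else f


def _vaf(variant, tumor_idx: int | None, alt_index: int) -> float | None:
    """Allele fraction of the alt allele: FORMAT AF, then AD ratio, then INFO AF."""
    if tumor_idx is not None:
        af = _fmt_value(variant, "AF", tumor_idx, alt_index)
        if af is not None:
            return af
        try:
            ad = variant.format("AD")
        except KeyError:
            ad = None
        if ad is not None:
            row = [int(x) for x in ad[tumor_idx] if x is not None and int(x) >= 0]
            if len(row) > alt_index + 1:
                total = sum(row)
                if total > 0:
                    return row[alt_index + 1] / total
    info_af = variant.INFO.get("AF")
    if info_af is not None:
        if isinstance(info_af, tuple):
            info_af = info_af[min(alt_index, len(info_af) - 1)]
        return float(info_af)
    return None


def _depth(variant, idx: int | None) -> int | None:
    if idx is None:
        return None
    d = _fmt_value(variant, "DP", idx)
    return int(d) if d is not None else None


def read_caller_vcf(
    path: str | Path,
    *,
    include_nonpass: bool = False,
    popfreq_keys: dict[str, str] | None = None,
    reference_window_for=None,
) -> tuple[list[tuple[VariantKey, CallerCall]], list[str], dict[VariantKey, dict[str, float]]]:
    """Read one caller's VCF into normalized (key, call) pairs.

    Returns ``(calls, contig_order, popfreqs_by_key)``.  Multi-allelic rows
    are split per alt allele; non-PASS rows are excluded unless
    *include_nonpass*.  *reference_window_for*, if given, is a callable
    ``(chrom, pos) -> (start, seq) | None`` supplying flanking reference
    for left alignment.
    """
    popfreq_keys = popfreq_keys or DEFAULT_POPFREQ_KEYS
    vcf = VCF(str(path))
    tumor_idx, normal_idx = _sample_indices(list(vcf.samples))
    contigs: list[str] = []
    calls: list[tuple[VariantKey, CallerCall]] = []
    popfreqs: dict[VariantKey, dict[str, float]] = {}
    for variant in vcf:
        chrom = variant.CHROM
        if chrom not in contigs:
            contigs.append(chrom)
        filt = variant.FILTER or "PASS"  # cyvcf2 reports PASS as None
        if filt != "PASS" and not include_nonpass:
            continue
        for alt_index, alt in enumerate(variant.ALT):
            if not set(alt.upper()) <= set("ACGT"):
                continue  # symbolic/spanning alleles are out of scope
            window = reference_window_for(chrom, variant.POS) if reference_window_for else None
            try:
                key = normalize_variant(chrom, variant.POS, variant.REF, alt, window)
            except NormalizationError:
                continue
            call = CallerCall(
                vaf=_vaf(variant, tumor_idx, alt_index),
                tumor_depth=_depth(variant, tumor_idx),
                normal_depth=_depth(variant, normal_idx),
                filter_status=filt,
            )
            calls.append((key, call))
            freqs = {}
            for source, info_key in popfreq_keys.items():
                v = variant.INFO.get(info_key)
                if v is not None:
                    if isinstance(v, tuple):
                        v = v[min(alt_index, len(v) - 1)]
                    freqs[source] = float(v)
            if freqs:
                popfreqs.setdefault(key, {}).update(freqs)
    vcf.close()
    return calls, contigs, popfreqs


def read_caller_vcfs(
    paths_by_caller: dict[str, str | Path],
    registry: CallerRegistry | None = None,
    **kwargs,
) -> tuple[dict[str, list[tuple[VariantKey, CallerCall]]], CallerRegistry, list[str], dict]:
    """Read several caller VCFs; returns (calls_by_caller, registry,
    contig_order, popfreqs_by_key)."""
    registry = registry or CallerRegistry()
    calls_by_caller: dict[str, list] = {}
    contig_order: list[str] = []
    popfreqs: dict[VariantKey, dict[str, float]] = {}
    for caller, path in paths_by_caller.items():
        registry.register(caller)
        calls, contigs, pf = read_caller_vcf(path, **kwargs)
        calls_by_caller[caller] = calls
        for c in contigs:
            if c not in contig_order:
                contig_order.append(c)
        for k, d in pf.items():
            popfreqs.setdefault(k, {}).update(d)
    return calls_by_caller, registry, contig_order, popfreqs


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_MERGED_HEADER = """\
##fileformat=VCFv4.2
##source=flowcall-merge
##INFO=<ID=CALLER_CODES,Number=.,Type=Integer,Description="Codes of callers supporting this variant (registration order; no priority semantics)">
##INFO=<ID=CALLERS,Number=.,Type=String,Description="Names of callers supporting this variant">
##INFO=<ID=NCALLERS,Number=1,Type=Integer,Description="Number of supporting callers">
##INFO=<ID=MAX_VAF,Number=1,Type=Float,Description="Maximum allele fraction reported by any supporting caller">
##INFO=<ID=TDP,Number=1,Type=Integer,Description="Maximum tumor depth reported by any supporting caller">
##INFO=<ID=NDP,Number=1,Type=Integer,Description="Maximum normal depth reported by any supporting caller">
"""


def write_merged_vcf(
    records,
    registry: CallerRegistry,
    path: str | Path,
    contig_order: list[str] | None = None,
    popfreq_keys: dict[str, str] | None = None,
) -> None:
    """Write merged records as a VCF with caller-evidence INFO annotations."""
    popfreq_keys = popfreq_keys or DEFAULT_POPFREQ_KEYS
    contigs = list(contig_order or [])
    for rec in records:
        if rec.key.chrom not in contigs:
            contigs.append(rec.key.chrom)
    lines = [_MERGED_HEADER.rstrip("\n")]
    for source, info_key in popfreq_keys.items():
        lines.append(
            f'##INFO=<ID={info_key},Number=1,Type=Float,'
            f'Description="Population allele frequency ({source})">'
        )
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for rec in records:
        codes = sorted(rec.evidence)
        info = [
            "CALLER_CODES=" + ",".join(map(str, codes)),
            "CALLERS=" + ",".join(registry.name(c) for c in codes),
            f"NCALLERS={len(codes)}",
        ]
        mv = rec.max_vaf
        if mv is not None:
            info.append(f"MAX_VAF={mv:.6g}")
        tds = [c.tumor_depth for c in rec.per_caller.values() if c.tumor_depth is not None]
        nds = [c.normal_depth for c in rec.per_caller.values() if c.normal_depth is not None]
        if tds:
            info.append(f"TDP={max(tds)}")
        if nds:
            info.append(f"NDP={max(nds)}")
        for source, info_key in popfreq_keys.items():
            if source in rec.popfreqs:
                info.append(f"{info_key}={rec.popfreqs[source]:.6g}")
        k = rec.key
        lines.append(
            f"{k.chrom}\t{k.pos}\t.\t{k.ref}\t{k.alt}\t.\tPASS\t" + ";".join(info)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_merged_vcf(
    path: str | Path, popfreq_keys: dict[str, str] | None = None
) -> tuple[list[VariantRecord], CallerRegistry, list[str]]:
    """Read back a merged VCF written by :func:`write_merged_vcf`."""
    popfreq_keys = popfreq_keys or DEFAULT_POPFREQ_KEYS
    vcf = VCF(str(path))
    registry = CallerRegistry()
    records: list[VariantRecord] = []
    contigs: list[str] = []
    for variant in vcf:
        if variant.CHROM not in contigs:
            contigs.append(variant.CHROM)
        codes_raw = variant.INFO.get("CALLER_CODES")
        names_raw = variant.INFO.get("CALLERS")
        if codes_raw is None:
            codes = []
        elif isinstance(codes_raw, (tuple, list)):
            codes = [int(c) for c in codes_raw]
        else:
            codes = [int(c) for c in str(codes_raw).split(",")]
        names = str(names_raw).split(",") if names_raw is not None else []
        for name in names:
            registry.register(name)
        key = VariantKey(variant.CHROM, variant.POS, variant.REF, variant.ALT[0])
        rec = VariantRecord(key, set(codes))
        mv = variant.INFO.get("MAX_VAF")
        tdp = variant.INFO.get("TDP")
        ndp = variant.INFO.get("NDP")
        if codes:
            rec.per_caller[codes[0]] = CallerCall(
                vaf=float(mv) if mv is not None else None,
                tumor_depth=int(tdp) if tdp is not None else None,
                normal_depth=int(ndp) if ndp is not None else None,
            )
        for source, info_key in popfreq_keys.items():
            v = variant.INFO.get(info_key)
            if v is not None:
                rec.popfreqs[source] = float(v)
        records.append(rec)
    vcf.close()
    return records, registry, contigs


def write_candidate_table(records, registry: CallerRegistry, path: str | Path) -> None:
    """Tab-separated candidate table (one row per surviving variant)."""
    import pandas as pd

    rows = []
    for rec in records:
        codes = sorted(rec.evidence)
        rows.append(
            {
                "chrom": rec.key.chrom,
                "pos": rec.key.pos,
                "ref": rec.key.ref,
                "alt": rec.key.alt,
                "variant_class": rec.variant_class,
                "n_callers": len(codes),
                "caller_codes": ",".join(map(str, codes)),
                "callers": ",".join(registry.name(c) for c in codes),
                "max_vaf": rec.max_vaf,
                "filters_passed": ";".join(rec.filters_passed),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
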