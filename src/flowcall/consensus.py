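"""Multi-caller variant consensus: normalize, merge, and filter per-caller VCFs.

Somatic variant callers disagree both on which sites they report and on how
they encode the same event (padded vs minimal indel representations).  This
module reduces every call to a canonical :class:`VariantKey` (shared suffix
then prefix trimmed, indels anchored and optionally left-aligned against a
reference window), merges calls across callers into evidence-tagged
records, and applies the candidate-selection rule — by default a variant
must be supported by at least two callers — together with site-level
allele-fraction and depth filters.

Caller identity is encoded as a small integer assigned by registration
order; the code is an identifier only and carries no priority semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import NormalizationError, RegistryError

_BASES = frozenset("ACGT")

SNV, INSERTION, DELETION, MNV = "SNV", "insertion", "deletion", "MNV"


@dataclass(frozen=True, order=True)
class VariantKey:
    """Canonical (chrom, pos, ref, alt) in minimal anchored representation."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    @property
    def variant_class(self) -> str:
        if len(self.ref) == len(self.alt):
            return SNV if len(self.ref) == 1 else MNV
        return INSERTION if len(self.alt) > len(self.ref) else DELETION


@dataclass(frozen=True)
class CallerCall:
    """Per-caller attributes attached to one variant."""

    vaf: float | None = None
    tumor_depth: int | None = None
    normal_depth: int | None = None
    filter_status: str = "PASS"


@dataclass
class VariantRecord:
    """A merged variant with the set of callers supporting it."""

    key: VariantKey
    evidence: set[int]
    per_caller: dict[int, CallerCall] = field(default_factory=dict)
    popfreqs: dict[str, float] = field(default_factory=dict)
    filters_passed: list[str] = field(default_factory=list)

    @property
    def variant_class(self) -> str:
        return self.key.variant_class

    @property
    def max_vaf(self) -> float | None:
        vafs = [c.vaf for c in self.per_caller.values() if c.vaf is not None]
        return max(vafs) if vafs else None


class CallerRegistry:
    """Ordered caller-name → integer-code registry.

    Codes start at 1 and follow registration order; they identify callers
    in the merged output and do not rank algorithms.
    """

    def __init__(self, names: list[str] | None = None):
        self._codes: dict[str, int] = {}
        for name in names or []:
            self.register(name)

    def register(self, name: str) -> int:
        if name not in self._codes:
            self._codes[name] = len(self._codes) + 1
        return self._codes[name]

    def code(self, name: str) -> int:
        if name not in self._codes:
            raise RegistryError(f"caller {name!r} is not registered")
        return self._codes[name]

    def name(self, code: int) -> str:
        for n, c in self._codes.items():
            if c == code:
                return n
        raise RegistryError(f"no caller with code {code}")

    @property
    def entries(self) -> list[tuple[str, int]]:
        return list(self._codes.items())

    def __contains__(self, name: str) -> bool:
        return name in self._codes

    def __len__(self) -> int:
        return len(self._codes)


@dataclass
class FilterPolicy:
    """Candidate-selection thresholds.

    ``min_callers=2`` is the default consensus rule; ``min_vaf`` is a
    strict lower bound on the best reported allele fraction; ``min_depth``
    (disabled by default; 500 reproduces a typical high-depth panel
    baseline) applies to tumor and/or normal depth of every supporting
    caller that reports the field.
    """

    min_callers: int = 2
    min_vaf: float = 0.01
    min_depth: int | None = None
    apply_depth_to: str = "both"  # tumor | normal | both

    def __post_init__(self):
        if self.min_callers < 1:
            raise ValueError("min_callers must be >= 1")
        if not 0.0 <= self.min_vaf <= 1.0:
            raise ValueError("min_vaf must be in [0, 1]")
        if self.apply_depth_to not in {"tumor", "normal", "both"}:
            raise ValueError("apply_depth_to must be tumor, normal or both")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def _window_base(reference_window, pos: int) -> str | None:
    """Base at 1-based *pos* from a (start_pos, sequence) window, if covered."""
    if reference_window is None:
        return None
    start, seq = reference_window
    idx = pos - start
    if 0 <= idx < len(seq):
        return seq[idx].upper()
    return None


def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference_window: tuple[int, str] | None = None,
) -> VariantKey:
    """Reduce a variant to its minimal, anchored, left-aligned key.

    The shared suffix is trimmed first, then the shared prefix (advancing
    ``pos``), always keeping at least one base per allele; pure indels are
    left-aligned when *reference_window* (a ``(start_pos, sequence)`` pair
    of flanking reference) is supplied.  Idempotent.  An allele emptied by
    a caller's pre-trimmed encoding is re-anchored from the window; if no
    anchor base is available a :class:`NormalizationError` is raised.
    """
    if pos < 1:
        raise NormalizationError(f"position must be >= 1, got {pos}")
    ref, alt = ref.upper(), alt.upper()
    for allele in (ref, alt):
        if not set(allele) <= _BASES:
            raise NormalizationError(f"allele {allele!r} contains non-ACGT characters")

    # Re-anchor empty alleles (some tools emit pre-trimmed indels).
    if not ref or not alt:
        anchor = _window_base(reference_window, pos - 1)
        if anchor is None:
            raise NormalizationError(
                f"{chrom}:{pos} {ref or '-'}>{alt or '-'}: empty allele and no "
                f"anchor base available (supply a reference window)"
            )
        ref, alt, pos = anchor + ref, anchor + alt, pos - 1

    if ref == alt:
        raise NormalizationError(f"{chrom}:{pos}: ref and alt are identical ({ref})")

    # Trim the shared suffix; when an allele is down to its anchor base,
    # extend both alleles left from the reference window so indels shift
    # through repeat context (left alignment).  Without a window the
    # anchor base is simply kept.
    while ref[-1] == alt[-1]:
        if len(ref) == 1 or len(alt) == 1:
            prev = _window_base(reference_window, pos - 1)
            if prev is None:
                break
            ref, alt, pos = prev + ref, prev + alt, pos - 1
        ref, alt = ref[:-1], alt[:-1]
    # Trim the shared prefix, advancing pos, keeping one base per allele.
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1

    return VariantKey(chrom, pos, ref, alt)


# ---------------------------------------------------------------------------
# Merge and candidate selection
# ---------------------------------------------------------------------------

def merge_callers(
    calls_by_caller: dict[str, list[tuple[VariantKey, CallerCall]]],
    registry: CallerRegistry,
    contig_order: list[str] | None = None,
) -> list[VariantRecord]:
    """Merge normalized per-caller calls into one record per distinct key.

    ``evidence`` is the set of caller codes reporting the key; per-caller
    attributes are retained.  Output is sorted by (contig order, position,
    ref, alt); contig order defaults to order of first appearance.
    """
    merged: dict[VariantKey, VariantRecord] = {}
    contigs: list[str] = list(contig_order or [])
    for caller, calls in calls_by_caller.items():
        code = registry.code(caller)  # raises RegistryError if unknown
        for key, call in calls:
            if key.chrom not in contigs:
                contigs.append(key.chrom)
            rec = merged.get(key)
            if rec is None:
                rec = VariantRecord(key, set())
                merged[rec.key] = rec
            rec.evidence.add(code)
            rec.per_caller[code] = call
    rank = {c: i for i, c in enumerate(contigs)}
    return sorted(
        merged.values(), key=lambda r: (rank[r.key.chrom], r.key.pos, r.key.ref, r.key.alt)
    )


def _depth_ok(rec: VariantRecord, policy: FilterPolicy) -> bool:
    if policy.min_depth is None:
        return True
    for call in rec.per_caller.values():
        checks = []
        if policy.apply_depth_to in ("tumor", "both"):
            checks.append(call.tumor_depth)
        if policy.apply_depth_to in ("normal", "both"):
            checks.append(call.normal_depth)
        # only reported fields are constrained; missing values do not fail
        if any(d is not None and d < policy.min_depth for d in checks):
            return False
    return True


def select_candidates(
    records: list[VariantRecord], policy: FilterPolicy
) -> list[VariantRecord]:
    """Apply the consensus rule and the site-level filters.

    Keeps records supported by at least ``min_callers`` callers whose best
    reported allele fraction exceeds ``min_vaf`` and (when the depth filter
    is enabled) whose reported depths all reach ``min_depth``.  Order is
    preserved; survivors are annotated with the filters they passed.
    """
    out: list[VariantRecord] = []
    for rec in records:
        passed = []
        if len(rec.evidence) >= policy.min_callers:
            passed.append(f"callers>={policy.min_callers}")
        else:
            continue
        mv = rec.max_vaf
        if mv is None or mv > policy.min_vaf:
            passed.append(f"vaf>{policy.min_vaf}")
        else:
            continue
        if _depth_ok(rec, policy):
            if policy.min_depth is not None:
                passed.append(f"depth>={policy.min_depth}:{policy.apply_depth_to}")
        else:
            continue
        rec.filters_passed = passed
        out.append(rec)
    return out
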