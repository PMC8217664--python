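"""Variant normalization, evidence merge and candidate selection."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flowcall import (
    CallerCall,
    CallerRegistry,
    FilterPolicy,
    VariantKey,
    merge_callers,
    normalize_variant,
    select_candidates,
)
from flowcall.consensus import VariantRecord
from flowcall.errors import NormalizationError, RegistryError
from flowcall import fixtures, vcfio


def _rec(n_callers, vaf=0.2, tdepth=800, ndepth=800, pos=100):
    evidence = set(range(1, n_callers + 1))
    per_caller = {
        c: CallerCall(vaf=vaf, tumor_depth=tdepth, normal_depth=ndepth) for c in evidence
    }
    return VariantRecord(VariantKey("chr1", pos, "A", "T"), evidence, per_caller)


class TestNormalize:
    @pytest.mark.parametrize(
        "given_var,expected",
        [
            (("chr1", 100, "CAG", "CTG"), ("chr1", 101, "A", "T")),
            (("chr1", 100, "A", "T"), ("chr1", 100, "A", "T")),
            (("chr1", 100, "CA", "C"), ("chr1", 100, "CA", "C")),
            (("chr1", 99, "TCA", "TC"), ("chr1", 100, "CA", "C")),  # padded deletion
            (("chr1", 99, "TC", "TCA"), ("chr1", 100, "C", "CA")),  # padded insertion
            (("chr1", 100, "ACGT", "AGGT"), ("chr1", 101, "C", "G")),
        ],
    )
    def test_trimming(self, given_var, expected):
        assert normalize_variant(*given_var) == VariantKey(*expected)

    def test_pre_trimmed_empty_allele_reanchors_from_window(self):
        # a caller emitting (101, "A", "") means: deletion of A, anchor C at 100
        window = (95, "GGGGGCAGGGG")  # pos 100 = C, pos 101 = A
        key = normalize_variant("chr1", 101, "A", "", reference_window=window)
        assert key == VariantKey("chr1", 100, "CA", "C")
        assert key == normalize_variant("chr1", 100, "CA", "C")

    def test_empty_allele_without_window_errors(self):
        with pytest.raises(NormalizationError):
            normalize_variant("chr1", 101, "A", "")

    def test_left_alignment_through_repeat(self):
        # reference ...T A A A...: deleting any one A is the same event
        window = (97, "TAAAG")  # pos 97=T, 98..100=A, 101=G
        k1 = normalize_variant("chr1", 99, "AA", "A", reference_window=window)
        k2 = normalize_variant("chr1", 98, "AA", "A", reference_window=window)
        assert k1 == k2 == VariantKey("chr1", 97, "TA", "T")

    def test_identical_alleles_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_variant("chr1", 100, "A", "A")

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        pos=st.integers(min_value=10, max_value=10_000),
        ref=st.text(alphabet="ACGT", min_size=1, max_size=6),
        alt=st.text(alphabet="ACGT", min_size=1, max_size=6),
    )
    def test_idempotence(self, pos, ref, alt):
        if ref == alt:
            return
        k = normalize_variant("chr1", pos, ref, alt)
        assert normalize_variant(k.chrom, k.pos, k.ref, k.alt) == k


class TestRegistry:
    def test_codes_follow_registration_order(self):
        reg = CallerRegistry(["strelka2", "vardict", "pindel"])
        assert reg.entries == [("strelka2", 1), ("vardict", 2), ("pindel", 3)]
        assert reg.code("pindel") == 3 and reg.name(2) == "vardict"

    def test_unregistered_caller_errors(self):
        reg = CallerRegistry(["a"])
        with pytest.raises(RegistryError):
            reg.code("b")
        with pytest.raises(RegistryError):
            merge_callers({"b": []}, reg)


class TestMerge:
    def test_evidence_sets_from_overlapping_callers(self):
        v1 = VariantKey("chr1", 100, "A", "T")
        v2 = VariantKey("chr1", 200, "C", "G")
        v3 = VariantKey("chr1", 300, "G", "A")
        reg = CallerRegistry(["c1", "c2", "c3"])
        call = CallerCall(vaf=0.2)
        records = merge_callers(
            {
                "c1": [(v1, call), (v2, call)],
                "c2": [(v2, call), (v3, call)],
                "c3": [(v2, call)],
            },
            reg,
        )
        by_key = {r.key: r.evidence for r in records}
        assert by_key == {v1: {1}, v2: {1, 2, 3}, v3: {2}}

    def test_single_caller_every_evidence_size_one(self):
        reg = CallerRegistry(["only"])
        keys = [VariantKey("chr1", p, "A", "G") for p in range(100, 120)]
        records = merge_callers({"only": [(k, CallerCall()) for k in keys]}, reg)
        assert all(r.evidence == {1} for r in records)
        assert len(records) == len(keys)

    def test_differently_encoded_indel_merges_to_one_record(self):
        # padded (99, TCA>TC) and minimal (100, CA>C) are the same deletion
        reg = CallerRegistry(["a", "b"])
        ka = normalize_variant("chr1", 99, "TCA", "TC")
        kb = normalize_variant("chr1", 100, "CA", "C")
        records = merge_callers(
            {"a": [(ka, CallerCall())], "b": [(kb, CallerCall())]}, reg
        )
        assert len(records) == 1
        assert records[0].evidence == {1, 2}

    def test_output_sorted_by_contig_then_position(self):
        reg = CallerRegistry(["x"])
        keys = [
            VariantKey("chr2", 50, "A", "T"),
            VariantKey("chr1", 500, "A", "T"),
            VariantKey("chr1", 100, "A", "T"),
        ]
        records = merge_callers({"x": [(k, CallerCall()) for k in keys]}, reg,
                                contig_order=["chr1", "chr2"])
        assert [r.key.pos for r in records] == [100, 500, 50]

    def test_cohort_evidence_matches_bruteforce_oracle(self, small_cohort):
        paths, truths = small_cohort
        calls, reg, contigs, _ = vcfio.read_caller_vcfs(paths)
        records = merge_callers(calls, reg, contigs)
        oracle = fixtures.truth_evidence_oracle(truths)
        assert len(records) == len(oracle)  # conservation of distinct keys
        for rec in records:
            names = frozenset(reg.name(c) for c in rec.evidence)
            assert names == oracle[rec.key]

    def test_permutation_invariance_of_surviving_keys(self, small_cohort):
        paths, _ = small_cohort
        orders = [list(paths), list(reversed(list(paths)))]
        survivor_sets = []
        for order in orders:
            ordered = {c: paths[c] for c in order}
            calls, reg, contigs, _ = vcfio.read_caller_vcfs(ordered)
            records = merge_callers(calls, reg, contigs)
            cands = select_candidates(records, FilterPolicy(min_callers=2))
            survivor_sets.append({r.key for r in cands})
        assert survivor_sets[0] == survivor_sets[1]


class TestSelectCandidates:
    def test_min_callers_two_keeps_consensus_only(self):
        records = [_rec(3, pos=1), _rec(1, pos=2)]
        out = select_candidates(records, FilterPolicy(min_callers=2))
        assert [len(r.evidence) for r in out] == [3]

    def test_identity_policy_keeps_everything(self):
        records = [_rec(1, pos=p) for p in range(1, 6)]
        out = select_candidates(records, FilterPolicy(min_callers=1, min_vaf=0.0))
        assert len(out) == 5

    def test_vaf_at_or_below_threshold_dropped(self):
        rec = _rec(2, vaf=0.005)
        assert select_candidates([rec], FilterPolicy(min_vaf=0.01)) == []
        # strict inequality: exactly the threshold is excluded
        rec2 = _rec(2, vaf=0.01, pos=2)
        assert select_candidates([rec2], FilterPolicy(min_vaf=0.01)) == []
        rec3 = _rec(2, vaf=0.011, pos=3)
        assert len(select_candidates([rec3], FilterPolicy(min_vaf=0.01))) == 1

    def test_depth_filter_on_both_samples(self):
        shallow = _rec(2, tdepth=400, ndepth=900)
        deep = _rec(2, tdepth=900, ndepth=900, pos=2)
        policy = FilterPolicy(min_depth=500, apply_depth_to="both")
        assert [r.key.pos for r in select_candidates([shallow, deep], policy)] == [2]
        tumor_only = FilterPolicy(min_depth=500, apply_depth_to="normal")
        assert len(select_candidates([shallow], tumor_only)) == 1

    def test_monotone_in_all_thresholds(self, small_cohort):
        paths, _ = small_cohort
        calls, reg, contigs, _ = vcfio.read_caller_vcfs(paths)
        records = merge_callers(calls, reg, contigs)
        counts_callers = [
            len(select_candidates(records, FilterPolicy(min_callers=k, min_vaf=0.0)))
            for k in (1, 2, 3)
        ]
        assert counts_callers == sorted(counts_callers, reverse=True)
        counts_vaf = [
            len(select_candidates(records, FilterPolicy(min_callers=1, min_vaf=v)))
            for v in (0.0, 0.1, 0.3, 0.5)
        ]
        assert counts_vaf == sorted(counts_vaf, reverse=True)
        counts_depth = [
            len(select_candidates(records, FilterPolicy(min_callers=1, min_vaf=0.0, min_depth=d)))
            for d in (None, 500, 1000, 2000)
        ]
        assert counts_depth == sorted(counts_depth, reverse=True)

    def test_candidate_count_matches_truth_rule(self, small_cohort):
        paths, truths = small_cohort
        calls, reg, contigs, _ = vcfio.read_caller_vcfs(paths)
        records = merge_callers(calls, reg, contigs)
        for k in (1, 2, 3):
            got = len(select_candidates(records, FilterPolicy(min_callers=k, min_vaf=0.0)))
            want = sum(1 for t in truths if len(t.callers) >= k)
            assert got == want
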