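"""Variant filter rules, boundary pinning, monotonicity, and CNV calls."""

import dataclasses
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methmarker.core import ValidationError
from methmarker.genomic import (
    Consequence,
    CopyNumberState,
    FilterRule,
    VariantCall,
    association_test_binary,
    call_copy_number,
    classify_variant,
    filter_variants,
)
from methmarker.simulate import simulate_variant_boundary_cases


def make_variant(**overrides) -> VariantCall:
    base = dict(
        sample_id="s1", gene="TP53", chromosome="chr17", position=7_577_000,
        ref_allele="C", alt_allele="T", tumor_vaf=0.15, normal_vaf=0.005,
        homopolymer_len=2, fwd_alt_reads=6, rev_alt_reads=7, coverage=250,
        consequence=Consequence.missense,
    )
    base.update(overrides)
    return VariantCall(**base)


class TestClassifyVariant:
    def test_all_rules_satisfied(self):
        d = classify_variant(make_variant())
        assert d.passed and d.failed_rules == []

    @pytest.mark.parametrize(
        "overrides, rule",
        [
            ({"tumor_vaf": 0.10}, FilterRule.tumor_vaf),       # needs > 10%
            ({"normal_vaf": 0.01}, FilterRule.normal_vaf),     # needs < 1%
            ({"homopolymer_len": 3}, FilterRule.homopolymer),  # needs < 3
            ({"fwd_alt_reads": 4}, FilterRule.strand_support),  # needs >= 5 each
            ({"coverage": 100}, FilterRule.coverage),          # needs > 100
            ({"consequence": Consequence.synonymous}, FilterRule.consequence),
            ({"consequence": Consequence.noncoding}, FilterRule.consequence),
        ],
    )
    def test_single_rule_boundary_failures(self, overrides, rule):
        d = classify_variant(make_variant(**overrides))
        assert not d.passed and d.failed_rules == [rule]

    @pytest.mark.parametrize(
        "overrides",
        [
            {"tumor_vaf": 0.101},
            {"normal_vaf": 0.0099},
            {"fwd_alt_reads": 5, "rev_alt_reads": 5},
            {"coverage": 101},
            {"consequence": Consequence.splice},
            {"consequence": Consequence.frameshift},
        ],
    )
    def test_boundary_pass_side(self, overrides):
        assert classify_variant(make_variant(**overrides)).passed

    def test_multiple_failures_all_enumerated(self):
        d = classify_variant(make_variant(tumor_vaf=0.05, coverage=90))
        assert set(d.failed_rules) == {FilterRule.tumor_vaf, FilterRule.coverage}

    def test_total_strand_rule_variant(self):
        v = make_variant(fwd_alt_reads=2, rev_alt_reads=4)
        assert not classify_variant(v).passed
        assert classify_variant(v, strand_rule="total").passed

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        tumor=st.floats(0, 1), normal=st.floats(0, 1),
        hp=st.integers(0, 10), fwd=st.integers(0, 50), rev=st.integers(0, 50),
        extra_cov=st.integers(0, 400),
        cons=st.sampled_from(list(Consequence)),
        weaken=st.sampled_from(["tumor", "normal", "fwd", "rev", "cov"]),
        amount=st.floats(0.01, 0.5),
    )
    def test_weakening_evidence_never_rescues(
        self, tumor, normal, hp, fwd, rev, extra_cov, cons, weaken, amount
    ):
        """Monotonicity: degrading any single evidence field never turns a
        failing variant into a passing one."""
        v = make_variant(
            tumor_vaf=tumor, normal_vaf=normal, homopolymer_len=hp,
            fwd_alt_reads=fwd, rev_alt_reads=rev, coverage=fwd + rev + extra_cov,
            consequence=cons,
        )
        before = classify_variant(v).passed
        w = dataclasses.replace(v)
        if weaken == "tumor":
            w.tumor_vaf = max(0.0, v.tumor_vaf - amount)
        elif weaken == "normal":
            w.normal_vaf = min(1.0, v.normal_vaf + amount)
        elif weaken == "fwd":
            w.fwd_alt_reads = max(0, v.fwd_alt_reads - 1)
        elif weaken == "rev":
            w.rev_alt_reads = max(0, v.rev_alt_reads - 1)
        else:
            w.coverage = max(v.fwd_alt_reads + v.rev_alt_reads, v.coverage - 50)
        after = classify_variant(w).passed
        assert not (after and not before)


class TestBoundaryTable:
    def test_exactly_one_retained(self):
        table = simulate_variant_boundary_cases()
        assert len(table) == 14
        retained, _ = filter_variants(table)
        assert [v.sample_id for v in retained] == ["all_pass"]

    def test_each_record_fails_its_intended_rule_only(self):
        _, decisions = filter_variants(simulate_variant_boundary_cases())
        by_id = {d.variant.sample_id: d for d in decisions}
        for rule in FilterRule:
            stem = "strand" if rule is FilterRule.strand_support else rule.value
            for kind in ("boundary_fail", "clear_fail"):
                name = f"{stem}_{kind}"
                assert by_id[name].failed_rules == [rule], name
        assert set(by_id["all_fail"].failed_rules) == set(FilterRule)

    def test_empty_and_duplicate_inputs(self):
        assert filter_variants([]) == ([], [])
        v = make_variant()
        retained, _ = filter_variants([v, v, v])
        assert retained == [v, v, v]


class TestCopyNumber:
    def test_threshold_states(self):
        calls = call_copy_number(
            {"gain": 500, "neutral": 200, "loss": 90},
            {"gain": 200, "neutral": 200, "loss": 200},
            1e6, 1e6,
        )
        states = {c.region_id: (c.state, c.fold_change) for c in calls}
        assert states["gain"] == (CopyNumberState.gain, pytest.approx(2.5))
        assert states["neutral"] == (CopyNumberState.neutral, pytest.approx(1.0))
        assert states["loss"] == (CopyNumberState.loss, pytest.approx(0.45))

    def test_boundary_folds_are_neutral(self):
        calls = call_copy_number({"a": 400, "b": 100}, {"a": 200, "b": 200}, 1e6, 1e6)
        # fold exactly 2 and exactly 0.5: strict comparisons keep both neutral
        assert all(c.state is CopyNumberState.neutral for c in calls)

    def test_zero_depth_handling(self):
        calls = call_copy_number({"a": 50, "b": 0}, {"a": 0, "b": 0}, 1e6, 1e6)
        by_id = {c.region_id: c for c in calls}
        assert by_id["a"].state is CopyNumberState.gain and math.isinf(by_id["a"].fold_change)
        assert by_id["b"].state is CopyNumberState.neutral and math.isnan(by_id["b"].fold_change)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValidationError):
            call_copy_number({"a": -1}, {"a": 10}, 100, 100)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        depths=st.lists(
            st.tuples(st.integers(0, 1000), st.integers(0, 1000)), min_size=1, max_size=6
        ),
        scale=st.floats(0.1, 100),
    )
    def test_scaling_invariance(self, depths, scale):
        """Multiplying all depths and totals by one constant changes nothing."""
        tumor = {f"r{i}": t for i, (t, _) in enumerate(depths)}
        normal = {f"r{i}": n for i, (_, n) in enumerate(depths)}
        a = call_copy_number(tumor, normal, 1e6, 2e6)
        b = call_copy_number(
            {k: v * scale for k, v in tumor.items()},
            {k: v * scale for k, v in normal.items()},
            1e6 * scale, 2e6 * scale,
        )
        for ca, cb in zip(a, b):
            assert ca.state is cb.state
            if math.isfinite(ca.fold_change):
                assert ca.fold_change == pytest.approx(cb.fold_change)


class TestAssociation:
    def test_perfect_association(self):
        marker = {f"s{i}": i < 5 for i in range(10)}
        outcome = {f"s{i}": i < 5 for i in range(10)}
        res = association_test_binary(marker, outcome)
        assert res["odds_table"] == [[5, 0], [0, 5]]
        assert res["p"] == pytest.approx(2 / 252)

    def test_single_outcome_group_rejected(self):
        with pytest.raises(ValidationError):
            association_test_binary({"a": True}, {"a": True})

    def test_mismatched_ids_rejected(self):
        with pytest.raises(ValidationError):
            association_test_binary({"a": True}, {"b": True})
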