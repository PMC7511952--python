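"""Universe selection, site classifier metrics, region aggregation and
planted-marker recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methmarker.core import BetaMatrix, ProbeAnnotation, RegionClass, ValidationError
from methmarker.methylation import (
    MethDirection,
    SiteScreenResult,
    aggregate_regions,
    annotation_filter,
    region_level,
    screen_sites,
    select_unmethylated_universe,
    site_classifier_metrics,
    validate_marker_levels,
)


def beta_of(rows, probes=None, samples=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    probes = probes or [f"p{i}" for i in range(rows.shape[0])]
    samples = samples or [f"s{j}" for j in range(rows.shape[1])]
    return BetaMatrix(pd.DataFrame(rows, index=probes, columns=samples))


class TestUniverse:
    @pytest.mark.parametrize(
        "refs, included",
        [
            ([0.05, 0.10, 0.15], True),
            ([0.05, 0.25, 0.10], False),  # one reference >= 0.2
            ([0.20, 0.10, 0.10], False),  # boundary: strict <
            ([0.199, 0.199, 0.199], True),
        ],
    )
    def test_membership(self, refs, included):
        ref = beta_of([refs], probes=["p"])
        universe = select_unmethylated_universe(ref)
        assert ("p" in universe) is included

    def test_empty_reference_rejected(self):
        with pytest.raises(ValidationError):
            select_unmethylated_universe(beta_of(np.empty((1, 0)), probes=["p"], samples=[]))


class TestSiteClassifier:
    def test_hand_counted_example(self):
        betas = [0.6, 0.5, 0.1, 0.7, 0.1, 0.05, 0.4, 0.1]
        outcomes = [True] * 4 + [False] * 4
        res = site_classifier_metrics(betas, outcomes)
        assert res.accuracy == pytest.approx(6 / 8)
        assert res.specificity == pytest.approx(3 / 4)

    def test_perfect_separation(self):
        res = site_classifier_metrics(
            [0.8, 0.8, 0.05, 0.05], [True, True, False, False]
        )
        assert res.accuracy == 1.0 and res.specificity == 1.0 and res.passed

    def test_degenerate_all_unmethylated(self):
        # classifier predicts non-pCR for everyone: accuracy = non-pCR
        # fraction, specificity = 1
        res = site_classifier_metrics([0.0] * 5, [True, True, False, False, False])
        assert res.accuracy == pytest.approx(3 / 5)
        assert res.specificity == 1.0

    def test_beta_cut_is_strict(self):
        full = site_classifier_metrics([0.31, 0.05], [True, False])
        at_cut = site_classifier_metrics([0.30, 0.05], [True, False])
        assert full.accuracy == 1.0
        assert at_cut.accuracy == 0.5  # 0.30 counts as unmethylated

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        betas=st.lists(st.floats(0, 1), min_size=2, max_size=50),
        seed=st.integers(0, 10_000),
    )
    def test_matches_confusion_matrix_recount(self, betas, seed):
        rng = np.random.default_rng(seed)
        outcomes = rng.random(len(betas)) < 0.5
        if outcomes.all() or not outcomes.any():
            outcomes[0] = not outcomes[0]
        res = site_classifier_metrics(betas, outcomes)
        calls = [b > 0.3 for b in betas]
        tp = sum(c and o for c, o in zip(calls, outcomes))
        tn = sum((not c) and (not o) for c, o in zip(calls, outcomes))
        n_non = sum(not o for o in outcomes)
        assert res.accuracy == pytest.approx((tp + tn) / len(betas))
        assert res.specificity == pytest.approx(tn / n_non)


class TestScreenSites:
    def test_label_swap_flips_directions_preserving_set(self, bundle, outcomes, screening_ids):
        # first 500 probes already include the planted marker region
        sub = bundle.beta.subset_probes(bundle.beta.probe_ids[:500])
        sub = sub.subset_samples(screening_ids)
        assert set(bundle.marker_probe_ids) <= set(sub.probe_ids)
        swapped = {s: not v for s, v in outcomes.items()}
        a = screen_sites(sub, outcomes)
        b = screen_sites(sub, swapped)
        flip = {
            MethDirection.hyper_in_pcr: MethDirection.hyper_in_nonpcr,
            MethDirection.hyper_in_nonpcr: MethDirection.hyper_in_pcr,
        }
        assert {s.probe_id for s in a} == {s.probe_id for s in b}
        dir_a = {s.probe_id: s.direction for s in a}
        dir_b = {s.probe_id: s.direction for s in b}
        assert all(dir_b[p] is flip[d] for p, d in dir_a.items())

    def test_unattainable_gate_returns_nothing(self, bundle, outcomes, screening_ids):
        sub = bundle.beta.subset_probes(list(bundle.marker_probe_ids)).subset_samples(screening_ids)
        assert screen_sites(sub, outcomes, acc_threshold=1.01) == []

    def test_zero_thresholds_return_all_probes(self, bundle, outcomes, screening_ids):
        sub = bundle.beta.subset_probes(bundle.beta.probe_ids[:50]).subset_samples(screening_ids)
        res = screen_sites(sub, outcomes, acc_threshold=0.0, spec_threshold=0.0)
        assert len(res) == 50

    def test_planted_probes_pass_and_background_fails(self, bundle, outcomes, screening_ids):
        sub = bundle.beta.subset_samples(screening_ids)
        passing = {s.probe_id for s in screen_sites(sub, outcomes)}
        assert set(bundle.marker_probe_ids) <= passing
        background = passing - set(bundle.marker_probe_ids)
        assert len(background) / len(bundle.beta.probe_ids) < 0.01


def ann(probe, pos, region="R", rclass=RegionClass.cpg_island, chrom="chr1", gene="G"):
    return ProbeAnnotation(
        probe_id=probe, chromosome=chrom, position=pos, gene=gene,
        region_class=rclass, region_id=region,
    )


def site(probe, direction=MethDirection.hyper_in_pcr):
    return SiteScreenResult(
        probe_id=probe, direction=direction, accuracy=0.9, specificity=0.95, passed=True
    )


class TestAnnotationFilter:
    def test_keeps_islands_and_genic_only(self):
        annotation = {
            "a": ann("a", 1, rclass=RegionClass.cpg_island),
            "b": ann("b", 2, rclass=RegionClass.genic),
            "c": ann("c", 3, rclass=RegionClass.intergenic),
        }
        kept = annotation_filter([site("a"), site("b"), site("c")], annotation)
        assert [s.probe_id for s in kept] == ["a", "b"]

    def test_empty_input(self):
        assert annotation_filter([], {}) == []

    def test_unannotated_site_rejected(self):
        with pytest.raises(ValidationError, match="x"):
            annotation_filter([site("x")], {})


class TestAggregateRegions:
    def annotation_run(self, n=5):
        return {f"P{i}": ann(f"P{i}", 100 * i) for i in range(1, n + 1)}

    def test_full_run_single_region(self):
        regions = aggregate_regions(
            [site(f"P{i}") for i in range(1, 6)], self.annotation_run(5)
        )
        assert len(regions) == 1
        assert regions[0].n_consecutive == 5
        assert regions[0].probe_ids == ("P1", "P2", "P3", "P4", "P5")

    def test_interrupted_runs_too_short(self):
        # P3 not passing: runs of 2 and 2 fall below the minimum of 3
        sites = [site(p) for p in ("P1", "P2", "P4", "P5")]
        assert aggregate_regions(sites, self.annotation_run(5)) == []

    def test_direction_change_breaks_run(self):
        sites = [
            site("P1"), site("P2"),
            site("P3", MethDirection.hyper_in_nonpcr),
            site("P4"),
        ]
        assert aggregate_regions(sites, self.annotation_run(4)) == []

    def test_gap_allowance_bridges_single_failure(self):
        sites = [site(p) for p in ("P1", "P2", "P4", "P5")]
        regions = aggregate_regions(sites, self.annotation_run(5), max_gap=1)
        assert len(regions) == 1 and regions[0].n_consecutive == 4

    def test_invariant_to_input_order_and_region_rename(self):
        annotation = self.annotation_run(5)
        sites = [site(f"P{i}") for i in range(1, 6)]
        a = aggregate_regions(sites, annotation)
        b = aggregate_regions(sites[::-1], annotation)
        assert a == b
        renamed = {
            p: ProbeAnnotation(p, x.chromosome, x.position, x.gene, x.region_class, "ZZZ")
            for p, x in annotation.items()
        }
        c = aggregate_regions(sites, renamed)
        assert c[0].probe_ids == a[0].probe_ids and c[0].region_id == "ZZZ"

    def test_regions_do_not_mix(self):
        annotation = {
            **{f"P{i}": ann(f"P{i}", 100 * i, region="R1") for i in (1, 2)},
            **{f"Q{i}": ann(f"Q{i}", 1000 + 100 * i, region="R2") for i in (1, 2)},
        }
        # 2 passing in each of two adjacent regions: no run of 3 anywhere
        sites = [site(p) for p in ("P1", "P2", "Q1", "Q2")]
        assert aggregate_regions(sites, annotation) == []


class TestValidateMarkerLevels:
    def test_separated_levels_pinned(self):
        levels = {"a": 0.6, "b": 0.5, "c": 0.7, "d": 0.1, "e": 0.2, "f": 0.15}
        outcomes = {k: k in "abc" for k in levels}
        assert validate_marker_levels(levels, outcomes).p == pytest.approx(0.1)

    def test_planted_marker_validates_on_held_out_cohort(self, bundle, outcomes):
        from methmarker.core import CohortSet

        val_ids = [s.sample_id for s in bundle.samples if s.cohort_set is CohortSet.validation]
        levels = region_level(bundle.beta, bundle.marker_probe_ids)
        res = validate_marker_levels({s: levels[s] for s in val_ids}, outcomes)
        assert res.p < 0.05
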