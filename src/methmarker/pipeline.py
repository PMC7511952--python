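"""End-to-end orchestration: screen -> validate -> evaluate -> monitor.

Runs the stages in their study order on one input bundle:

1. *genomic* — six-rule variant filtering and copy-number calls on the
   screening set; Fisher association of mutation presence and of the
   ERBB2-like gain with outcome.
2. *expression* — volcano screen plus abundance filter on the screening
   set's normalized expression matrix.
3. *methylation* — unmethylated-universe selection from the normal
   references, per-site classifier screen, CpG-island/genic filter and
   consecutive-probe region aggregation on the screening set.
4. *validation* / *re-validation* — Mann-Whitney comparison of candidate
   region methylation levels in the held-out cohorts; a candidate survives
   a stage when p < ``validation_alpha``.
5. *performance* — dichotomized validated-marker levels combined with
   ER-negative status, Table-style stratified contingency report over all
   outcome-labelled samples.
6. *response* — paired baseline/on-treatment delta classification and
   signed-rank test, with the Ki-67-like comparator marker.

Cohort membership comes exclusively from the sample sheet.  Screening
statistics read only screening-set columns (the leakage guard tested in
the suite), validation stages only their own cohorts.  The run is fully
deterministic: identical config + inputs give identical outputs, and the
manifest records the config with its hash.

Every filtering stage contributes to a funnel audit trail (counts in/out),
mirroring how a genome-wide screen's funnel is reported on real data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .core import CohortSet, ERStatus, ValidationError
from .expression import abundance_filter, volcano_screen
from .genomic import association_test_binary, call_copy_number, filter_variants
from .methylation import (
    aggregate_regions,
    annotation_filter,
    region_level,
    screen_sites,
    select_unmethylated_universe,
    validate_marker_levels,
)
from .monitor import classify_large_decrease, compare_response_markers, paired_change_test, pairs_from_frame
from .performance import dichotomize, er_negative_calls, stratified_report
from .simulate import SimulatedBundle

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage thresholds, in one round-trippable record.

    Defaults are the screen's published operating points; the
    ``methylation_cutoff`` for dichotomizing locus methylation levels has
    NO default — it must come from calibration data and is required
    whenever the performance stage runs.
    """

    # variant rules
    min_tumor_vaf: float = 0.10
    max_normal_vaf: float = 0.01
    max_homopolymer: int = 3
    min_reads_per_strand: int = 5
    min_coverage: int = 100
    # CNV
    cnv_gain_fold: float = 2.0
    cnv_loss_fold: float = 0.5
    # expression volcano
    volcano_p: float = 0.001
    volcano_fc: float = 4.0
    min_mean_intensity: float = 0.5
    volcano_test: str = "welch"
    # methylation screen
    beta_universe_max: float = 0.2
    beta_cut: float = 0.3
    acc_threshold: float = 0.67
    spec_threshold: float = 0.85
    min_consecutive: int = 3
    max_gap: int = 0
    # validation
    validation_alpha: float = 0.05
    # performance
    methylation_cutoff: Optional[float] = None
    age_breaks: tuple[int, ...] = (45, 55)
    # response monitoring
    delta_convention: str = "absolute_points"
    delta_threshold: float = 50.0
    # stage toggles
    run_genomic: bool = True
    run_expression: bool = True
    run_methylation: bool = True
    run_performance: bool = True
    run_response: bool = True

    def __post_init__(self) -> None:
        self.age_breaks = tuple(self.age_breaks)
        for name in ("min_tumor_vaf", "max_normal_vaf", "volcano_p",
                     "beta_universe_max", "beta_cut", "acc_threshold",
                     "spec_threshold", "validation_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if self.volcano_fc <= 0 or self.cnv_gain_fold <= 0 or self.cnv_loss_fold <= 0:
            raise ValidationError("fold-change thresholds must be > 0")
        if self.min_consecutive < 1 or self.max_gap < 0:
            raise ValidationError("min_consecutive >= 1 and max_gap >= 0 required")
        if self.delta_convention not in ("absolute_points", "relative_to_baseline"):
            raise ValidationError(f"unknown delta_convention {self.delta_convention!r}")
        if self.methylation_cutoff is not None and not 0.0 <= self.methylation_cutoff <= 1.0:
            raise ValidationError("methylation_cutoff must be in [0,1]")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_breaks"] = list(self.age_breaks)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    funnel: dict = field(default_factory=dict)  # stage -> {in/out counts}
    skipped: list = field(default_factory=list)
    genomic: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    methylation: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)
    performance: dict = field(default_factory=dict)
    response: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _cohort(samples, cohort: CohortSet):
    return [s for s in samples if s.cohort_set is cohort and s.pcr is not None]


def run_pipeline(
    bundle: SimulatedBundle,
    config: Optional[PipelineConfig] = None,
    outdir=None,
) -> PipelineResult:
    """Run all enabled stages on one bundle; optionally write a run directory.

    When ``outdir`` is given, per-stage TSVs, a ``manifest.json`` (config,
    config hash, package version) and a plain-text log are written there.
    """
    config = config or PipelineConfig()
    result = PipelineResult(config=config)
    log: list[str] = []

    samples = bundle.samples
    screening = _cohort(samples, CohortSet.screening)
    validation = _cohort(samples, CohortSet.validation)
    revalidation = _cohort(samples, CohortSet.revalidation)
    scr_ids = [s.sample_id for s in screening]
    outcomes_all = {s.sample_id: bool(s.pcr) for s in samples if s.pcr is not None}
    outcomes_scr = {s.sample_id: bool(s.pcr) for s in screening}
    log.append(
        f"cohorts: screening={len(screening)} validation={len(validation)} "
        f"revalidation={len(revalidation)}"
    )

    if config.run_genomic:
        retained, decisions = filter_variants(
            [v for v in bundle.variants if v.sample_id in outcomes_scr],
            min_tumor_vaf=config.min_tumor_vaf,
            max_normal_vaf=config.max_normal_vaf,
            max_homopolymer=config.max_homopolymer,
            min_reads_per_strand=config.min_reads_per_strand,
            min_coverage=config.min_coverage,
        )
        mutated = {s: False for s in scr_ids}
        for v in retained:
            mutated[v.sample_id] = True
        cnv_calls = []
        gain_first_region = {}
        for sid in bundle.coverage.tumor.columns:
            calls = call_copy_number(
                bundle.coverage.tumor[sid].to_dict(),
                bundle.coverage.normal[sid].to_dict(),
                float(bundle.coverage.tumor_totals[sid]),
                float(bundle.coverage.normal_totals[sid]),
                sample_id=sid,
                gain_threshold=config.cnv_gain_fold,
                loss_threshold=config.cnv_loss_fold,
            )
            cnv_calls.extend(calls)
            gain_first_region[sid] = any(
                c.state.value == "gain" and c.region_id == bundle.coverage.tumor.index[0]
                for c in calls
            )
        result.genomic = {
            "n_variants_in": len(decisions),
            "n_variants_retained": len(retained),
            "retained": retained,
            "decisions": decisions,
            "mutation_association": association_test_binary(mutated, outcomes_scr),
            "cnv_calls": cnv_calls,
            "erbb2_gain_association": association_test_binary(gain_first_region, outcomes_scr),
        }
        result.funnel["variants"] = {
            "in": len(decisions), "out": len(retained)
        }
        log.append(f"genomic: {len(retained)}/{len(decisions)} variants retained")
    else:
        result.skipped.append("genomic")

    if config.run_expression:
        from .core import ExpressionMatrix

        expr = ExpressionMatrix(bundle.expression[scr_ids])
        volcano = volcano_screen(
            expr, outcomes_scr,
            p_threshold=config.volcano_p, fc_threshold=config.volcano_fc,
            test=config.volcano_test,
        )
        selected = [r for r in volcano if r.selected]
        abundant = abundance_filter(volcano, config.min_mean_intensity)
        result.expression = {
            "volcano": volcano,
            "n_selected": len(selected),
            "abundant_genes": abundant,
        }
        result.funnel["expression"] = {
            "in": len(volcano), "selected": len(selected), "abundant": len(abundant)
        }
        log.append(
            f"expression: {len(selected)}/{len(volcano)} genes selected, "
            f"{len(abundant)} abundant"
        )
    else:
        result.skipped.append("expression")

    candidates = []
    if config.run_methylation:
        universe = select_unmethylated_universe(bundle.reference, config.beta_universe_max)
        beta_scr = bundle.beta.subset_probes(universe).subset_samples(scr_ids)
        sites = screen_sites(
            beta_scr, outcomes_scr,
            beta_cut=config.beta_cut,
            acc_threshold=config.acc_threshold,
            spec_threshold=config.spec_threshold,
        )
        ann_map = {a.probe_id: a for a in bundle.annotation}
        annotated_sites = annotation_filter(sites, ann_map)
        candidates = aggregate_regions(
            annotated_sites, ann_map,
            min_consecutive=config.min_consecutive, max_gap=config.max_gap,
        )
        result.methylation = {
            "universe_size": len(universe),
            "sites_passing": sites,
            "sites_annotated": annotated_sites,
            "candidate_regions": candidates,
        }
        result.funnel["methylation"] = {
            "probes": len(bundle.beta.probe_ids),
            "universe": len(universe),
            "sites_passing": len(sites),
            "sites_in_islands_or_genic": len(annotated_sites),
            "regions": len(candidates),
        }
        log.append(
            f"methylation: {len(bundle.beta.probe_ids)} probes -> "
            f"{len(universe)} universe -> {len(sites)} passing sites -> "
            f"{len(annotated_sites)} island/genic -> {len(candidates)} regions"
        )

        # held-out validation and re-validation of candidate regions
        validated, revalidated = [], []
        tests = {}
        for region in candidates:
            lv = region_level(
                bundle.beta, region.probe_ids
            )
            lv_val = {s.sample_id: lv[s.sample_id] for s in validation}
            res_val = validate_marker_levels(lv_val, outcomes_all)
            tests[region.region_id] = {"validation_p": res_val.p}
            if res_val.p < config.validation_alpha:
                validated.append(region)
                lv_rev = {s.sample_id: lv[s.sample_id] for s in revalidation}
                res_rev = validate_marker_levels(lv_rev, outcomes_all)
                tests[region.region_id]["revalidation_p"] = res_rev.p
                if res_rev.p < config.validation_alpha:
                    revalidated.append(region)
        result.validation = {
            "tests": tests,
            "validated": validated,
            "revalidated": revalidated,
        }
        result.funnel["validation"] = {
            "candidates": len(candidates),
            "validated": len(validated),
            "revalidated": len(revalidated),
        }
        log.append(
            f"validation: {len(candidates)} candidates -> {len(validated)} "
            f"validated -> {len(revalidated)} re-validated"
        )
    else:
        result.skipped.append("methylation")

    if config.run_performance:
        if "methylation" in result.skipped:
            raise ValidationError(
                "performance stage requires methylation candidates but the "
                "methylation stage was disabled"
            )
        if config.methylation_cutoff is None:
            raise ValidationError(
                "methylation_cutoff is required for the performance stage; "
                "set it explicitly (no default is shipped)"
            )
        final = result.validation["revalidated"] or result.validation["validated"]
        if final:
            marker = final[0]
            labelled = [s for s in samples if s.pcr is not None
                        and s.er_status is not ERStatus.unknown and s.age is not None]
            levels = region_level(bundle.beta, marker.probe_ids)
            meth_calls = dichotomize(
                {s.sample_id: levels[s.sample_id] for s in labelled},
                config.methylation_cutoff,
            )
            er_calls = er_negative_calls(labelled)
            report = stratified_report(labelled, meth_calls, er_calls, config.age_breaks)
            result.performance = {
                "marker_region_id": marker.region_id,
                "report": report,
                "n_samples": len(labelled),
            }
            log.append(
                f"performance: marker {marker.region_id} evaluated on "
                f"{len(labelled)} samples"
            )
        else:
            result.performance = {"marker_region_id": None, "report": None}
            log.append("performance: no validated marker to evaluate")
    else:
        result.skipped.append("performance")

    if config.run_response:
        pairs = pairs_from_frame(bundle.paired_beta)
        classified = classify_large_decrease(
            pairs, threshold=config.delta_threshold, convention=config.delta_convention
        )
        shift = paired_change_test(
            bundle.paired_beta["baseline"], bundle.paired_beta["on_treatment"]
        )
        comparison = compare_response_markers(
            {"methylation": pairs, "ki67": pairs_from_frame(bundle.paired_ki67)},
            threshold=config.delta_threshold, convention=config.delta_convention,
        )
        result.response = {
            "classified": classified,
            "paired_test": shift,
            "marker_comparison": comparison,
        }
        s = classified["summary"]
        log.append(
            f"response: {s['n_large']} large decreases, {s['n_large_pcr']} of them pCR"
        )
    else:
        result.skipped.append("response")

    result.manifest = {
        "package_version": __version__,
        "config": config.as_dict(),
        "config_hash": config.config_hash(),
        "seed": getattr(bundle.config, "seed", None),
        "skipped_stages": list(result.skipped),
        "funnel": result.funnel,
    }

    if outdir is not None:
        _write_run_dir(result, bundle, Path(outdir), log)
    return result


def _write_run_dir(result: PipelineResult, bundle, outdir: Path, log: list[str]) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    if result.genomic:
        rows = [
            {
                "sample_id": d.variant.sample_id, "gene": d.variant.gene,
                "passed": d.passed,
                "failed_rules": ",".join(r.value for r in d.failed_rules),
            }
            for d in result.genomic["decisions"]
        ]
        pd.DataFrame(rows).to_csv(outdir / "variant_decisions.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"region_id": c.region_id, "sample_id": c.sample_id,
                 "fold_change": c.fold_change, "state": c.state.value}
                for c in result.genomic["cnv_calls"]
            ]
        ).to_csv(outdir / "cnv_calls.tsv", sep="\t", index=False)
    if result.expression:
        pd.DataFrame(
            [
                {"gene_id": r.gene_id, "log2_fc": r.log2_fc, "p": r.p,
                 "mean_intensity": r.mean_intensity, "selected": r.selected,
                 "direction": r.direction.value}
                for r in result.expression["volcano"]
            ]
        ).to_csv(outdir / "volcano.tsv", sep="\t", index=False)
    if result.methylation:
        pd.DataFrame(
            [
                {"probe_id": s.probe_id, "direction": s.direction.value,
                 "accuracy": s.accuracy, "specificity": s.specificity}
                for s in result.methylation["sites_passing"]
            ]
        ).to_csv(outdir / "passing_sites.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"region_id": r.region_id, "gene": r.gene,
                 "n_consecutive": r.n_consecutive, "direction": r.direction.value,
                 "probes": ",".join(r.probe_ids),
                 **result.validation["tests"].get(r.region_id, {})}
                for r in result.methylation["candidate_regions"]
            ]
        ).to_csv(outdir / "candidate_regions.tsv", sep="\t", index=False)
    if result.performance and result.performance.get("report") is not None:
        pd.DataFrame(result.performance["report"].as_rows()).to_csv(
            outdir / "performance_report.tsv", sep="\t", index=False
        )
    if result.response:
        pd.DataFrame(
            [
                {"sample_id": p.sample_id, "baseline": p.baseline,
                 "on_treatment": p.on_treatment, "delta": p.delta,
                 "large_decrease": p.large_decrease, "pcr": p.pcr}
                for p in result.response["classified"]["classified"]
            ]
        ).to_csv(outdir / "response_monitoring.tsv", sep="\t", index=False)
        result.response["marker_comparison"].to_csv(
            outdir / "marker_comparison.tsv", sep="\t", index=False
        )
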