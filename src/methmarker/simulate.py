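"""Seeded synthetic cohorts with the structure every pipeline stage assumes.

The generator emulates, at desk scale, a three-cohort neoadjuvant-therapy
study: a screening set assayed genome-wide (methylation array, expression
array, targeted tumor/normal sequencing) and validation / re-validation
sets measured only at candidate loci.  Cohort sizes default to the
screening 14 pCR / 20 non-pCR, validation 17/30 and re-validation 17/38
outcome splits.

Methylation model: beta-values are drawn from a two-component Beta
mixture — a low-methylation background (mode ~0.05) and a methylated
component (mode ~0.6) — chosen to straddle the screen's 0.2 (universe) and
0.3 (call) thresholds.  One annotated CpG-island region carries the
planted marker: each sample is methylated across that region's probes with
probability ``penetrance_pcr`` (responders) or ``penetrance_nonpcr``
(non-responders).  The non-responder prevalence defaults to 0.02: the
per-site specificity gate (> 0.85 over 20 non-pCR samples) tolerates at
most 2 methylated non-responders, and a 2% prevalence keeps the planted
region recoverable in ~99% of replicates, whereas e.g. 10% would make
recovery a coin flip (P(Binom(20, 0.1) <= 2) = 0.68).  Reference profiles
(one mammary-epithelial-like, two leukocyte-like) are clean background
draws (high concentration) so the planted region reliably sits inside the
unmethylated universe.

Expression model: gene baselines on log2 scale, planted DE genes shifted
by ``log2_fold_change`` in responders, per-sample noise, passed through
75th-percentile normalization.

Paired monitoring model: on-treatment marker level = baseline x
(1 - ``responder_delta_fraction``) in responders, baseline plus small
noise otherwise; a Ki-67-like comparator decreases in most samples of BOTH
groups (hence carries little response information).

All randomness flows from one integer seed through named
``numpy.random.SeedSequence`` children (one per data layer), so layers are
individually reproducible and the whole bundle is byte-deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    BetaMatrix,
    CohortSet,
    ERStatus,
    ProbeAnnotation,
    RegionClass,
    SampleRecord,
    ValidationError,
)
from .expression import normalize_expression
from .genomic import Consequence, VariantCall

__all__ = [
    "MarkerRegionConfig",
    "DEGeneConfig",
    "SimulationConfig",
    "CoverageBundle",
    "SimulatedBundle",
    "simulate_cohort",
    "simulate_variant_boundary_cases",
    "write_bundle",
    "load_bundle",
]


@dataclass
class MarkerRegionConfig:
    n_consecutive_probes: int = 4
    beta_methylated_mean: float = 0.6
    beta_background_mean: float = 0.05
    penetrance_pcr: float = 0.8
    penetrance_nonpcr: float = 0.02

    def __post_init__(self) -> None:
        if self.n_consecutive_probes < 1:
            raise ValidationError("n_consecutive_probes must be >= 1")
        for name in ("beta_methylated_mean", "beta_background_mean",
                     "penetrance_pcr", "penetrance_nonpcr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")


@dataclass
class DEGeneConfig:
    count: int = 10
    log2_fold_change: float = 2.5


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort bundle."""

    seed: int = 0
    n_pcr: int = 14
    n_nonpcr: int = 20
    n_pcr_validation: int = 17
    n_nonpcr_validation: int = 30
    n_pcr_revalidation: int = 17
    n_nonpcr_revalidation: int = 38
    n_probes: int = 10000
    n_genes: int = 2000
    marker_region: MarkerRegionConfig = field(default_factory=MarkerRegionConfig)
    de_genes: DEGeneConfig = field(default_factory=DEGeneConfig)
    responder_delta_fraction: float = 0.8
    expression_noise_sd: float = 0.3
    #: Beta-distribution concentration (a+b) for tumor beta draws
    beta_concentration: float = 20.0
    #: concentration for normal reference profiles (clean background)
    reference_concentration: float = 100.0
    #: P(ER-negative | pCR) and P(ER-negative | non-pCR)
    er_negative_given_pcr: float = 0.8
    er_negative_given_nonpcr: float = 0.35
    probes_per_region: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.responder_delta_fraction <= 1.0:
            raise ValidationError("responder_delta_fraction must be in [0,1]")
        if self.marker_region.penetrance_pcr <= self.marker_region.penetrance_nonpcr:
            warnings.warn(
                "penetrance_pcr <= penetrance_nonpcr: the planted marker is "
                "undetectable (or direction-flipped) by design"
            )


@dataclass
class CoverageBundle:
    """Region x sample depth tables for matched tumor/normal panels."""

    tumor: pd.DataFrame
    normal: pd.DataFrame
    tumor_totals: pd.Series
    normal_totals: pd.Series


@dataclass
class SimulatedBundle:
    config: SimulationConfig
    samples: list[SampleRecord]
    beta: BetaMatrix  # probes x all baseline samples
    annotation: list[ProbeAnnotation]
    reference: BetaMatrix  # probes x 3 normal profiles
    expression: pd.DataFrame  # normalized log2, screening samples
    variants: list[VariantCall]
    coverage: CoverageBundle
    paired_beta: pd.DataFrame  # sample_id, baseline, on_treatment, pcr
    paired_ki67: pd.DataFrame
    marker_region_id: str = "REG_MARKER"
    marker_probe_ids: tuple[str, ...] = ()
    marker_truth: dict = field(default_factory=dict)  # sample_id -> region methylated


_REGION_CLASS_CYCLE = (
    RegionClass.cpg_island,
    RegionClass.genic,
    RegionClass.intergenic,
    RegionClass.cpg_island,
    RegionClass.genic,
    RegionClass.intergenic,
    RegionClass.intergenic,
    RegionClass.genic,
    RegionClass.cpg_island,
    RegionClass.intergenic,
)


def _beta_draw(rng: np.random.Generator, mean: float, concentration: float, size) -> np.ndarray:
    mean = min(max(mean, 1e-6), 1 - 1e-6)
    a, b = mean * concentration, (1 - mean) * concentration
    return np.clip(rng.beta(a, b, size=size), 0.0, 1.0)


def _make_samples(cfg: SimulationConfig, rng: np.random.Generator) -> list[SampleRecord]:
    samples: list[SampleRecord] = []
    plan = [
        (CohortSet.screening, cfg.n_pcr, cfg.n_nonpcr),
        (CohortSet.validation, cfg.n_pcr_validation, cfg.n_nonpcr_validation),
        (CohortSet.revalidation, cfg.n_pcr_revalidation, cfg.n_nonpcr_revalidation),
    ]
    idx = 0
    for cohort, n_pos, n_neg in plan:
        for pcr in ([True] * n_pos + [False] * n_neg):
            idx += 1
            p_neg = cfg.er_negative_given_pcr if pcr else cfg.er_negative_given_nonpcr
            er = ERStatus.negative if rng.random() < p_neg else ERStatus.positive
            age = int(np.clip(round(rng.normal(54, 10)), 30, 80))
            samples.append(
                SampleRecord(
                    sample_id=f"S{idx:03d}",
                    cohort_set=cohort,
                    pcr=pcr,
                    er_status=er,
                    age=age,
                )
            )
    return samples


def _make_annotation(cfg: SimulationConfig) -> tuple[list[ProbeAnnotation], tuple[str, ...]]:
    """Lay probes along one synthetic chromosome in fixed-size regions.

    The planted marker region is a CpG island of ``n_consecutive_probes``
    probes inserted as region index 7 (arbitrary fixed interior position).
    """
    annotations: list[ProbeAnnotation] = []
    marker_probes: list[str] = []
    pos = 1000
    probe_idx = 0
    region_idx = 0
    marker_emitted = False
    while probe_idx < cfg.n_probes or not marker_emitted:
        if region_idx == 7 and not marker_emitted:
            n_in_region, rclass, region_id, gene = (
                cfg.marker_region.n_consecutive_probes,
                RegionClass.cpg_island,
                "REG_MARKER",
                "MARKER1",
            )
            marker_emitted = True
        else:
            n_in_region = cfg.probes_per_region
            rclass = _REGION_CLASS_CYCLE[region_idx % len(_REGION_CLASS_CYCLE)]
            region_id = f"REG{region_idx:05d}"
            gene = f"G{region_idx:05d}" if rclass is not RegionClass.intergenic else ""
        for _ in range(n_in_region):
            probe_idx += 1
            pid = f"cg{probe_idx:07d}" if region_id != "REG_MARKER" else f"cgM{len(marker_probes) + 1:02d}"
            if region_id == "REG_MARKER":
                marker_probes.append(pid)
            annotations.append(
                ProbeAnnotation(
                    probe_id=pid,
                    chromosome="chr1",
                    position=pos,
                    gene=gene,
                    region_class=rclass,
                    region_id=region_id,
                )
            )
            pos += 500
        pos += 5000
        region_idx += 1
    return annotations, tuple(marker_probes)


def simulate_cohort(config: SimulationConfig) -> SimulatedBundle:
    """Generate one deterministic cohort bundle from the configuration."""
    cfg = config
    mrk = cfg.marker_region
    children = np.random.SeedSequence(cfg.seed).spawn(8)
    rng_samples, rng_beta, rng_ref, rng_expr, rng_var, rng_cov, rng_pair, rng_ki67 = (
        np.random.default_rng(s) for s in children
    )

    samples = _make_samples(cfg, rng_samples)
    baseline_samples = [s for s in samples if s.pcr is not None]
    sample_ids = [s.sample_id for s in baseline_samples]

    annotation, marker_probes = _make_annotation(cfg)
    probe_ids = [a.probe_id for a in annotation]
    n_probes_total = len(probe_ids)
    marker_rows = np.array([probe_ids.index(p) for p in marker_probes])

    # tumor beta: background everywhere, then overwrite the marker region in
    # samples drawn methylated under their outcome's penetrance
    beta_vals = _beta_draw(
        rng_beta, mrk.beta_background_mean, cfg.beta_concentration,
        (n_probes_total, len(sample_ids)),
    )
    marker_truth: dict[str, bool] = {}
    for j, s in enumerate(baseline_samples):
        pen = mrk.penetrance_pcr if s.pcr else mrk.penetrance_nonpcr
        methylated = bool(rng_beta.random() < pen)
        marker_truth[s.sample_id] = methylated
        if methylated:
            beta_vals[marker_rows, j] = _beta_draw(
                rng_beta, mrk.beta_methylated_mean, cfg.beta_concentration,
                marker_rows.size,
            )
    beta = BetaMatrix(pd.DataFrame(beta_vals, index=probe_ids, columns=sample_ids))

    reference = BetaMatrix(
        pd.DataFrame(
            _beta_draw(
                rng_ref, mrk.beta_background_mean, cfg.reference_concentration,
                (n_probes_total, 3),
            ),
            index=probe_ids,
            columns=["HMEC_like", "leukocyte_1", "leukocyte_2"],
        )
    )

    # expression: screening samples only (array assay on the screening set)
    screening = [s for s in baseline_samples if s.cohort_set is CohortSet.screening]
    scr_ids = [s.sample_id for s in screening]
    gene_ids = [f"GENE{i:05d}" for i in range(cfg.n_genes)]
    baselines = rng_expr.normal(0.0, 1.5, size=cfg.n_genes)
    de_idx = np.arange(min(cfg.de_genes.count, cfg.n_genes))
    baselines[de_idx] = 2.0  # abundant, so planted genes survive the abundance gate
    log = baselines[:, None] + rng_expr.normal(
        0.0, cfg.expression_noise_sd, size=(cfg.n_genes, len(scr_ids))
    )
    is_pcr_scr = np.array([s.pcr for s in screening], dtype=bool)
    log[np.ix_(de_idx, np.flatnonzero(is_pcr_scr))] += cfg.de_genes.log2_fold_change
    expression = normalize_expression(
        pd.DataFrame(np.exp2(log), index=gene_ids, columns=scr_ids)
    ).df

    variants = _simulate_variants(screening, rng_var)
    coverage = _simulate_coverage(screening, rng_cov)
    paired_beta = _simulate_paired_marker(
        baseline_samples, beta, marker_probes, cfg, rng_pair
    )
    paired_ki67 = _simulate_paired_ki67(baseline_samples, rng_ki67)

    return SimulatedBundle(
        config=cfg,
        samples=samples,
        beta=beta,
        annotation=annotation,
        reference=reference,
        expression=expression,
        variants=variants,
        coverage=coverage,
        paired_beta=paired_beta,
        paired_ki67=paired_ki67,
        marker_probe_ids=marker_probes,
        marker_truth=marker_truth,
    )


_VARIANT_GENES = ("TP53", "PIK3CA", "ERBB2", "GATA3", "MAP3K1", "AKT1")


def _simulate_variants(screening, rng: np.random.Generator) -> list[VariantCall]:
    """Per-sample candidate variants, most passing, some failing one rule."""
    variants: list[VariantCall] = []
    for s in screening:
        for k in range(int(rng.integers(2, 5))):
            gene = _VARIANT_GENES[int(rng.integers(len(_VARIANT_GENES)))]
            coverage = int(rng.integers(150, 900))
            vaf = float(rng.uniform(0.15, 0.6))
            alt = max(10, int(coverage * vaf * 0.9))
            fwd = int(rng.integers(5, max(6, alt - 5)))
            rev = max(5, alt - fwd)
            v = VariantCall(
                sample_id=s.sample_id,
                gene=gene,
                chromosome="chr17",
                position=int(rng.integers(1, 5_000_000)),
                ref_allele="C",
                alt_allele="T",
                tumor_vaf=vaf,
                normal_vaf=float(rng.uniform(0.0, 0.008)),
                homopolymer_len=int(rng.integers(0, 3)),
                fwd_alt_reads=fwd,
                rev_alt_reads=rev,
                coverage=max(coverage, fwd + rev),
                consequence=Consequence.missense,
            )
            if rng.random() < 0.35:  # knock out one rule at random
                rule = int(rng.integers(4))
                if rule == 0:
                    v.tumor_vaf = float(rng.uniform(0.0, 0.1))
                elif rule == 1:
                    v.normal_vaf = float(rng.uniform(0.01, 0.2))
                elif rule == 2:
                    v.homopolymer_len = int(rng.integers(3, 8))
                else:
                    v.consequence = Consequence.synonymous
            variants.append(v)
    return variants


def _simulate_coverage(screening, rng: np.random.Generator) -> CoverageBundle:
    """Matched tumor/normal region depths with an ERBB2-like gain enriched
    in responders and one recurrent loss region."""
    regions = [f"PANEL_{g}" for g in
               ("ERBB2", "TP53", "PIK3CA", "MYC", "PTEN", "RB1", "CCND1", "EGFR",
                "BRCA1", "BRCA2", "AKT3", "NRAS", "MAP2K4", "CDH1", "GATA3")]
    base = rng.uniform(80, 300, size=len(regions))
    tumor = {}
    normal = {}
    for s in screening:
        n_depth = base * rng.lognormal(0.0, 0.05, size=len(regions))
        t_depth = base * rng.lognormal(0.0, 0.05, size=len(regions))
        p_gain = 0.7 if s.pcr else 0.3
        if rng.random() < p_gain:
            t_depth[0] *= 3.0  # ERBB2-like gain
        if rng.random() < 0.2:
            t_depth[5] *= 0.3  # RB1-like loss
        tumor[s.sample_id] = t_depth
        normal[s.sample_id] = n_depth
    tumor_df = pd.DataFrame(tumor, index=regions)
    normal_df = pd.DataFrame(normal, index=regions)
    scale = 1e6 / 3000.0  # panel depths are a small fixed fraction of the run
    return CoverageBundle(
        tumor=tumor_df,
        normal=normal_df,
        tumor_totals=tumor_df.sum(axis=0) * scale,
        normal_totals=normal_df.sum(axis=0) * scale,
    )


def _simulate_paired_marker(
    baseline_samples, beta: BetaMatrix, marker_probes, cfg: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    levels = beta.df.loc[list(marker_probes)].mean(axis=0)
    rows = []
    for s in baseline_samples:
        b = float(levels[s.sample_id])
        if s.pcr:
            t = b * (1.0 - cfg.responder_delta_fraction)
        else:
            t = float(np.clip(b + rng.normal(0.0, 0.03), 0.0, 1.0))
        rows.append({"sample_id": s.sample_id, "baseline": b, "on_treatment": t, "pcr": s.pcr})
    return pd.DataFrame(rows)


def _simulate_paired_ki67(baseline_samples, rng: np.random.Generator) -> pd.DataFrame:
    """Ki-67-like index decreasing in most samples of both outcome groups."""
    rows = []
    for s in baseline_samples:
        b = float(rng.uniform(0.3, 0.9))
        if rng.random() < 0.9:
            t = b * float(rng.uniform(0.2, 0.6))
        else:
            t = float(np.clip(b * rng.uniform(1.0, 1.2), 0.0, 1.0))
        rows.append({"sample_id": s.sample_id, "baseline": b, "on_treatment": t, "pcr": s.pcr})
    return pd.DataFrame(rows)


def simulate_variant_boundary_cases() -> list[VariantCall]:
    """Fixed 14-record table pinning every filter-rule boundary.

    Twelve records each violate exactly ONE rule — one at the comparison
    boundary (e.g. coverage exactly 100 under the strict "> 100"), one
    clearly — plus an ``all_pass`` record built from boundary-PASSING
    values (tumor VAF 0.101, normal VAF 0.009, homopolymer 2, 5 alt reads
    per strand, coverage 101) and an ``all_fail`` record violating all six
    rules.  Exactly one record (``all_pass``) survives the filter.
    """
    base = dict(
        gene="GENE_X", chromosome="chr1", position=1000, ref_allele="C",
        alt_allele="T", tumor_vaf=0.15, normal_vaf=0.005, homopolymer_len=2,
        fwd_alt_reads=6, rev_alt_reads=7, coverage=250,
        consequence=Consequence.missense,
    )

    def rec(name: str, **overrides) -> VariantCall:
        return VariantCall(sample_id=name, **{**base, **overrides})

    return [
        rec("tumor_vaf_boundary_fail", tumor_vaf=0.10),       # rule needs > 0.10
        rec("tumor_vaf_clear_fail", tumor_vaf=0.02),
        rec("normal_vaf_boundary_fail", normal_vaf=0.01),     # rule needs < 0.01
        rec("normal_vaf_clear_fail", normal_vaf=0.05),
        rec("homopolymer_boundary_fail", homopolymer_len=3),  # rule needs < 3
        rec("homopolymer_clear_fail", homopolymer_len=6),
        rec("strand_boundary_fail", fwd_alt_reads=4, rev_alt_reads=7),  # needs >= 5 each
        rec("strand_clear_fail", fwd_alt_reads=0, rev_alt_reads=13),
        rec("coverage_boundary_fail", coverage=100),          # rule needs > 100
        rec("coverage_clear_fail", coverage=60),
        rec("consequence_boundary_fail", consequence=Consequence.synonymous),
        rec("consequence_clear_fail", consequence=Consequence.noncoding),
        rec("all_pass", tumor_vaf=0.101, normal_vaf=0.009, homopolymer_len=2,
            fwd_alt_reads=5, rev_alt_reads=5, coverage=101,
            consequence=Consequence.splice),
        rec("all_fail", tumor_vaf=0.05, normal_vaf=0.02, homopolymer_len=4,
            fwd_alt_reads=1, rev_alt_reads=2, coverage=80,
            consequence=Consequence.synonymous),
    ]


def write_bundle(bundle: SimulatedBundle, outdir) -> dict[str, Path]:
    """Write every bundle component as TSV into ``outdir``; returns the paths."""
    from . import io as mio  # local import: io depends on genomic types

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": outdir / "samples.tsv",
        "beta": outdir / "beta.tsv",
        "annotation": outdir / "probes.tsv",
        "reference": outdir / "reference_beta.tsv",
        "expression": outdir / "expression.tsv",
        "variants": outdir / "variants.tsv",
        "coverage_tumor": outdir / "coverage_tumor.tsv",
        "coverage_normal": outdir / "coverage_normal.tsv",
        "coverage_totals": outdir / "coverage_totals.tsv",
        "paired_beta": outdir / "paired_beta.tsv",
        "paired_ki67": outdir / "paired_ki67.tsv",
    }
    mio.write_sample_sheet(bundle.samples, paths["samples"])
    mio.write_beta_matrix(bundle.beta, paths["beta"])
    mio.write_probe_annotation(bundle.annotation, paths["annotation"])
    mio.write_beta_matrix(bundle.reference, paths["reference"])
    bundle.expression.rename_axis("gene_id").to_csv(paths["expression"], sep="\t")
    mio.write_variant_table(bundle.variants, paths["variants"])
    bundle.coverage.tumor.rename_axis("region_id").to_csv(paths["coverage_tumor"], sep="\t")
    bundle.coverage.normal.rename_axis("region_id").to_csv(paths["coverage_normal"], sep="\t")
    pd.DataFrame(
        {"tumor_total": bundle.coverage.tumor_totals,
         "normal_total": bundle.coverage.normal_totals}
    ).rename_axis("sample_id").to_csv(paths["coverage_totals"], sep="\t")
    mio.write_paired_table(bundle.paired_beta, paths["paired_beta"])
    mio.write_paired_table(bundle.paired_ki67, paths["paired_ki67"])
    return paths


def load_bundle(indir) -> SimulatedBundle:
    """Read a bundle directory written by :func:`write_bundle`.

    The round trip is lossless for every pipeline-relevant field; the
    generator-internal ground truth (``marker_truth``) is not serialised
    and comes back empty.
    """
    from . import io as mio

    indir = Path(indir)
    samples = mio.read_sample_sheet(indir / "samples.tsv")
    beta, annotation = mio.read_beta_matrix(indir / "beta.tsv", indir / "probes.tsv")
    ref_df = pd.read_csv(indir / "reference_beta.tsv", sep="\t", index_col=0)
    expression = pd.read_csv(indir / "expression.tsv", sep="\t", index_col=0)
    variants = mio.read_variant_table(indir / "variants.tsv")
    tumor = pd.read_csv(indir / "coverage_tumor.tsv", sep="\t", index_col=0)
    normal = pd.read_csv(indir / "coverage_normal.tsv", sep="\t", index_col=0)
    totals = pd.read_csv(indir / "coverage_totals.tsv", sep="\t", index_col=0)
    marker_probes = tuple(
        a.probe_id for a in annotation if a.region_id == "REG_MARKER"
    )
    return SimulatedBundle(
        config=SimulationConfig(),
        samples=samples,
        beta=beta,
        annotation=annotation,
        reference=BetaMatrix(ref_df),
        expression=expression,
        variants=variants,
        coverage=CoverageBundle(
            tumor=tumor,
            normal=normal,
            tumor_totals=totals["tumor_total"],
            normal_totals=totals["normal_total"],
        ),
        paired_beta=mio.read_paired_table(indir / "paired_beta.tsv"),
        paired_ki67=mio.read_paired_table(indir / "paired_ki67.tsv"),
        marker_probe_ids=marker_probes,
    )
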