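"""Genome-wide methylation marker screen with consecutive-probe regions.

The screening workflow, run on a probe x sample beta-value matrix of the
screening cohort:

1. **Unmethylated universe** — keep only probes with beta < 0.2 in every
   normal reference profile (mammary epithelial cells and peripheral
   leukocytes), so candidate markers are cancer-specific gains of
   methylation, not tissue background.
2. **Per-site threshold classifier** — a sample is "methylated" at a probe
   when beta > 0.3.  For each probe and each direction (hypermethylated in
   pCR, or in non-pCR) this defines a pCR predictor whose accuracy and
   specificity are evaluated against the outcome labels; a site passes
   when accuracy > 0.67 and specificity > 0.85 in at least one direction.
   Specificity is computed on the group the site is NOT hypermethylated in
   (that direction's negative class), which is the only orientation under
   which both directions face the same gates.
3. **Annotation filter** — keep passing sites in CpG islands or genic
   regions.
4. **Region aggregation** — within each annotated region (gene/island),
   order probes by genomic position and emit a marker region for every
   maximal run of >= 3 adjacent passing probes sharing a direction (a
   non-passing probe of the same region, or a direction change, breaks the
   run; ``max_gap`` relaxes this).

Candidate regions are then validated on held-out cohorts by comparing
locus-assay methylation levels between outcome groups (Mann-Whitney).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core import BetaMatrix, ProbeAnnotation, RegionClass, ValidationError
from .stats import MannWhitneyResult, mann_whitney_u

__all__ = [
    "MethDirection",
    "SiteScreenResult",
    "MarkerRegion",
    "select_unmethylated_universe",
    "site_classifier_metrics",
    "screen_sites",
    "annotation_filter",
    "aggregate_regions",
    "region_level",
    "validate_marker_levels",
]


class MethDirection(str, Enum):
    hyper_in_pcr = "hyper_in_pcr"
    hyper_in_nonpcr = "hyper_in_nonpcr"


@dataclass(frozen=True)
class SiteScreenResult:
    probe_id: str
    direction: MethDirection
    accuracy: float
    specificity: float
    passed: bool


@dataclass(frozen=True)
class MarkerRegion:
    """A maximal run of consecutive passing probes within one annotated region."""

    region_id: str
    gene: str
    probe_ids: tuple[str, ...]  # ordered by genomic position
    n_consecutive: int
    direction: MethDirection
    per_probe: tuple[SiteScreenResult, ...]


def select_unmethylated_universe(
    reference: BetaMatrix, beta_max: float = 0.2
) -> list[str]:
    """Probes with beta strictly below ``beta_max`` in EVERY reference profile.

    Order follows the matrix's probe order.  Raises on an empty reference.
    """
    if not reference.sample_ids:
        raise ValidationError("reference matrix has no profiles")
    keep = (reference.values < beta_max).all(axis=1)
    return [p for p, k in zip(reference.probe_ids, keep) if k]


def _metrics_for_direction(
    meth: np.ndarray, is_pcr: np.ndarray, direction: MethDirection
) -> tuple[float, float]:
    """Accuracy and specificity of the beta>cut classifier for one direction.

    For ``hyper_in_pcr`` the classifier predicts pCR for methylated
    samples; specificity is the fraction of non-pCR samples called
    unmethylated.  ``hyper_in_nonpcr`` is the mirror image.
    """
    n = meth.size
    if direction is MethDirection.hyper_in_pcr:
        correct = np.count_nonzero(meth & is_pcr) + np.count_nonzero(~meth & ~is_pcr)
        spec = np.count_nonzero(~meth & ~is_pcr) / np.count_nonzero(~is_pcr)
    else:
        correct = np.count_nonzero(meth & ~is_pcr) + np.count_nonzero(~meth & is_pcr)
        spec = np.count_nonzero(~meth & is_pcr) / np.count_nonzero(is_pcr)
    return correct / n, spec


def site_classifier_metrics(
    betas: Mapping[str, float] | Sequence[float],
    outcomes: Mapping[str, bool] | Sequence[bool],
    *,
    beta_cut: float = 0.3,
    direction: MethDirection = MethDirection.hyper_in_pcr,
    acc_threshold: float = 0.67,
    spec_threshold: float = 0.85,
    probe_id: str = "",
) -> SiteScreenResult:
    """Evaluate one probe's threshold classifier in a fixed direction.

    A sample counts as methylated iff beta > ``beta_cut`` (strict; a value
    exactly at the cut is unmethylated).
    """
    if isinstance(betas, Mapping):
        ids = list(betas)
        b = np.array([betas[s] for s in ids], dtype=float)
        o = np.array([bool(outcomes[s]) for s in ids])
    else:
        b = np.asarray(betas, dtype=float)
        o = np.asarray(outcomes, dtype=bool)
    if b.size != o.size:
        raise ValidationError("betas and outcomes differ in length")
    if o.all() or not o.any():
        raise ValidationError("both outcome groups must be non-empty")
    direction = MethDirection(direction)
    meth = b > beta_cut
    acc, spec = _metrics_for_direction(meth, o, direction)
    return SiteScreenResult(
        probe_id=probe_id,
        direction=direction,
        accuracy=acc,
        specificity=spec,
        passed=bool(acc > acc_threshold and spec > spec_threshold),
    )


def screen_sites(
    beta: BetaMatrix,
    outcomes: Mapping[str, bool],
    *,
    beta_cut: float = 0.3,
    acc_threshold: float = 0.67,
    spec_threshold: float = 0.85,
) -> list[SiteScreenResult]:
    """Evaluate both directions at every probe; return passing sites only.

    When both directions pass at one probe (degenerate small-n case) the
    higher-accuracy direction is recorded, ties going to hyper-in-pCR.
    Fully vectorised: the whole matrix is thresholded once and the per-site
    confusion counts come from boolean row sums.
    """
    sample_ids = beta.sample_ids
    missing = [s for s in sample_ids if s not in outcomes]
    if missing:
        raise ValidationError(f"samples without outcome label: {missing}")
    is_pcr = np.array([bool(outcomes[s]) for s in sample_ids])
    if is_pcr.all() or not is_pcr.any():
        raise ValidationError("both outcome groups must be non-empty")
    n = len(sample_ids)
    n_pcr = int(is_pcr.sum())
    n_non = n - n_pcr

    meth = beta.values > beta_cut  # probes x samples
    meth_pcr = meth[:, is_pcr].sum(axis=1)
    meth_non = meth[:, ~is_pcr].sum(axis=1)

    acc_pcr = (meth_pcr + (n_non - meth_non)) / n
    spec_pcr = (n_non - meth_non) / n_non
    acc_non = (meth_non + (n_pcr - meth_pcr)) / n
    spec_non = (n_pcr - meth_pcr) / n_pcr

    pass_pcr = (acc_pcr > acc_threshold) & (spec_pcr > spec_threshold)
    pass_non = (acc_non > acc_threshold) & (spec_non > spec_threshold)

    results: list[SiteScreenResult] = []
    for i, probe in enumerate(beta.probe_ids):
        if pass_pcr[i] and pass_non[i]:
            use_pcr = acc_pcr[i] >= acc_non[i]  # tie -> hyper_in_pcr
        elif pass_pcr[i] or pass_non[i]:
            use_pcr = bool(pass_pcr[i])
        else:
            continue
        if use_pcr:
            results.append(
                SiteScreenResult(probe, MethDirection.hyper_in_pcr,
                                 float(acc_pcr[i]), float(spec_pcr[i]), True)
            )
        else:
            results.append(
                SiteScreenResult(probe, MethDirection.hyper_in_nonpcr,
                                 float(acc_non[i]), float(spec_non[i]), True)
            )
    return results


def annotation_filter(
    sites: Sequence[SiteScreenResult], annotation: Mapping[str, ProbeAnnotation]
) -> list[SiteScreenResult]:
    """Keep sites located in CpG islands or genic regions."""
    unannotated = [s.probe_id for s in sites if s.probe_id not in annotation]
    if unannotated:
        raise ValidationError(f"sites missing annotation: {unannotated}")
    keep = {RegionClass.cpg_island, RegionClass.genic}
    return [s for s in sites if annotation[s.probe_id].region_class in keep]


def aggregate_regions(
    passing_sites: Sequence[SiteScreenResult],
    annotation: Mapping[str, ProbeAnnotation] | Iterable[ProbeAnnotation],
    *,
    min_consecutive: int = 3,
    max_gap: int = 0,
) -> list[MarkerRegion]:
    """Collapse passing sites into consecutive-probe marker regions.

    ``annotation`` must cover the region's FULL probe complement (not just
    passing sites): consecutiveness is adjacency in the region's complete
    position-ordered probe list, so an intervening non-passing probe breaks
    a run unless ``max_gap`` > 0 allows up to that many consecutive
    non-passing probes inside a run.  Runs must also share a direction.
    Output is sorted by (region_id, first probe position) and is invariant
    to the input order of sites.
    """
    if not isinstance(annotation, Mapping):
        annotation = {a.probe_id: a for a in annotation}
    unannotated = [s.probe_id for s in passing_sites if s.probe_id not in annotation]
    if unannotated:
        raise ValidationError(f"sites missing annotation: {unannotated}")
    by_probe = {s.probe_id: s for s in passing_sites}

    # full probe ordering of every region that contains a passing site
    regions_with_hits = {annotation[p].region_id for p in by_probe}
    region_probes: dict[str, list[ProbeAnnotation]] = {r: [] for r in regions_with_hits}
    for ann in annotation.values():
        if ann.region_id in region_probes:
            region_probes[ann.region_id].append(ann)

    out: list[MarkerRegion] = []
    for region_id in sorted(regions_with_hits):
        probes = sorted(region_probes[region_id], key=lambda a: (a.chromosome, a.position))
        runs: list[list[SiteScreenResult]] = []
        current: list[SiteScreenResult] = []
        gap = 0
        for ann in probes:
            site = by_probe.get(ann.probe_id)
            if site is None:
                gap += 1
                if current and gap > max_gap:
                    runs.append(current)
                    current = []
            elif current and site.direction != current[-1].direction:
                runs.append(current)
                current = [site]
                gap = 0
            else:
                current.append(site)
                gap = 0
        if current:
            runs.append(current)
        for idx, run in enumerate(r for r in runs if len(r) >= min_consecutive):
            genes = {annotation[s.probe_id].gene for s in run} - {""}
            out.append(
                MarkerRegion(
                    region_id=region_id if idx == 0 else f"{region_id}.{idx + 1}",
                    gene=sorted(genes)[0] if genes else "",
                    probe_ids=tuple(s.probe_id for s in run),
                    n_consecutive=len(run),
                    direction=run[0].direction,
                    per_probe=tuple(run),
                )
            )
    return out


def region_level(beta: BetaMatrix, probe_ids: Sequence[str]) -> dict[str, float]:
    """Per-sample marker level: mean beta over the region's probes.

    Emulates a locus assay (e.g. pyrosequencing over the marker CpGs) for
    validation cohorts where only the candidate region is measured.
    """
    sub = beta.df.loc[list(probe_ids)]
    return {s: float(v) for s, v in sub.mean(axis=0).items()}


def validate_marker_levels(
    levels: Mapping[str, float], outcomes: Mapping[str, bool]
) -> MannWhitneyResult:
    """Mann-Whitney comparison of locus methylation levels between outcomes."""
    ids = list(levels)
    missing = [s for s in ids if s not in outcomes]
    if missing:
        raise ValidationError(f"samples without outcome label: {missing}")
    x = [levels[s] for s in ids if outcomes[s]]
    y = [levels[s] for s in ids if not outcomes[s]]
    if not x or not y:
        raise ValidationError("both outcome groups must be non-empty")
    return mann_whitney_u(x, y)
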