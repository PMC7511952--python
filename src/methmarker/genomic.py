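"""Somatic-variant filtering and coverage-based copy-number calls.

Variants arrive pre-summarised from a targeted tumor/normal panel (one row
per candidate call with allele frequencies, strand-split alt-read counts,
coverage, homopolymer context and predicted consequence).  A call is kept
as a functional somatic mutation only when all six rules hold:

1. tumor variant allele frequency > 10%
2. matched-normal variant allele frequency < 1%
3. homopolymer length at the site < 3
4. alt allele supported by >= 5 reads on each strand
5. total coverage > 100 reads
6. the variant alters protein sequence or splicing
   (missense / nonsense / frameshift / splice; synonymous and
   noncoding calls fail)

The comparison strictness follows the rule wording literally (strict for
>10%, <1%, <3, >100; inclusive for >=5).  Rule 4 is read as >= 5
supporting reads on EACH strand; ``min_reads_per_strand`` and
``strand_rule`` make the alternative total-count reading selectable.

Copy number is called from normalized region coverage of matched
tumor/normal pairs: each region's mean depth is divided by the sample's
total reads, and the tumor/normal ratio of these depth fractions is the
fold change.  Fold change > 2 is a gain, < 0.5 a loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import math

from .core import ValidationError
from .stats import fisher_exact_2x2

__all__ = [
    "Consequence",
    "FilterRule",
    "VariantCall",
    "FilterDecision",
    "CopyNumberState",
    "CopyNumberCall",
    "classify_variant",
    "filter_variants",
    "call_copy_number",
    "association_test_binary",
]


class Consequence(str, Enum):
    missense = "missense"
    nonsense = "nonsense"
    frameshift = "frameshift"
    splice = "splice"
    synonymous = "synonymous"
    noncoding = "noncoding"


#: consequence classes that satisfy the functional rule
FUNCTIONAL_CONSEQUENCES = frozenset(
    {Consequence.missense, Consequence.nonsense, Consequence.frameshift, Consequence.splice}
)


class FilterRule(str, Enum):
    tumor_vaf = "tumor_vaf"
    normal_vaf = "normal_vaf"
    homopolymer = "homopolymer"
    strand_support = "strand_support"
    coverage = "coverage"
    consequence = "consequence"


@dataclass
class VariantCall:
    """One tumor/normal variant observation with the fields the filter tests."""

    sample_id: str
    gene: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    tumor_vaf: float
    normal_vaf: float
    homopolymer_len: int
    fwd_alt_reads: int
    rev_alt_reads: int
    coverage: int
    consequence: Consequence

    def __post_init__(self) -> None:
        self.consequence = Consequence(self.consequence)
        for name in ("tumor_vaf", "normal_vaf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if self.fwd_alt_reads < 0 or self.rev_alt_reads < 0:
            raise ValidationError("strand read counts must be >= 0")
        if self.coverage < self.fwd_alt_reads + self.rev_alt_reads:
            raise ValidationError(
                f"coverage ({self.coverage}) below total alt reads "
                f"({self.fwd_alt_reads + self.rev_alt_reads})"
            )


@dataclass
class FilterDecision:
    variant: VariantCall
    passed: bool
    failed_rules: list[FilterRule] = field(default_factory=list)


def classify_variant(
    v: VariantCall,
    *,
    min_tumor_vaf: float = 0.10,
    max_normal_vaf: float = 0.01,
    max_homopolymer: int = 3,
    min_reads_per_strand: int = 5,
    min_coverage: int = 100,
    strand_rule: str = "per_strand",
) -> FilterDecision:
    """Apply the six functional-mutation rules to one variant.

    Comparison strictness is fixed (strictly above ``min_tumor_vaf`` and
    ``min_coverage``, strictly below ``max_normal_vaf`` and
    ``max_homopolymer``, at least ``min_reads_per_strand``); only the
    threshold values are configurable.  Pure predicate: ``passed`` is true
    iff ``failed_rules`` is empty, and every violated rule is enumerated
    (not just the first).
    """
    failed: list[FilterRule] = []
    if not v.tumor_vaf > min_tumor_vaf:
        failed.append(FilterRule.tumor_vaf)
    if not v.normal_vaf < max_normal_vaf:
        failed.append(FilterRule.normal_vaf)
    if not v.homopolymer_len < max_homopolymer:
        failed.append(FilterRule.homopolymer)
    if strand_rule == "per_strand":
        strand_ok = min(v.fwd_alt_reads, v.rev_alt_reads) >= min_reads_per_strand
    elif strand_rule == "total":
        strand_ok = (
            v.fwd_alt_reads + v.rev_alt_reads >= min_reads_per_strand
            and v.fwd_alt_reads >= 1
            and v.rev_alt_reads >= 1
        )
    else:
        raise ValueError(f"unknown strand_rule {strand_rule!r}")
    if not strand_ok:
        failed.append(FilterRule.strand_support)
    if not v.coverage > min_coverage:
        failed.append(FilterRule.coverage)
    if v.consequence not in FUNCTIONAL_CONSEQUENCES:
        failed.append(FilterRule.consequence)
    return FilterDecision(variant=v, passed=not failed, failed_rules=failed)


def filter_variants(
    table: Sequence[VariantCall], **kwargs
) -> tuple[list[VariantCall], list[FilterDecision]]:
    """Classify every variant; return (retained in input order, all decisions)."""
    decisions = [classify_variant(v, **kwargs) for v in table]
    retained = [d.variant for d in decisions if d.passed]
    return retained, decisions


class CopyNumberState(str, Enum):
    gain = "gain"
    neutral = "neutral"
    loss = "loss"


@dataclass(frozen=True)
class CopyNumberCall:
    region_id: str
    sample_id: str
    fold_change: float  # may be inf (normal depth 0) or nan (both depths 0)
    state: CopyNumberState


def call_copy_number(
    tumor_depths: Mapping[str, float],
    normal_depths: Mapping[str, float],
    tumor_total_reads: float,
    normal_total_reads: float,
    *,
    sample_id: str = "",
    gain_threshold: float = 2.0,
    loss_threshold: float = 0.5,
) -> list[CopyNumberCall]:
    """Gain/loss calls from depth fractions of matched tumor/normal panels.

    fold_change(region) = (tumor_depth / tumor_total) / (normal_depth /
    normal_total); gain iff fold > 2, loss iff fold < 0.5 (defaults).
    A region with normal depth 0 but tumor signal is an unbounded gain
    (fold = inf); a region silent in both is neutral with fold = nan.
    """
    if tumor_total_reads <= 0 or normal_total_reads <= 0:
        raise ValidationError("total read counts must be > 0")
    if set(tumor_depths) != set(normal_depths):
        raise ValidationError("tumor and normal depth tables cover different regions")
    calls: list[CopyNumberCall] = []
    for region in tumor_depths:
        td, nd = float(tumor_depths[region]), float(normal_depths[region])
        if td < 0 or nd < 0:
            raise ValidationError(f"negative depth at region {region!r}")
        t_frac = td / tumor_total_reads
        n_frac = nd / normal_total_reads
        if n_frac == 0 and t_frac == 0:
            fold, state = math.nan, CopyNumberState.neutral
        elif n_frac == 0:
            fold, state = math.inf, CopyNumberState.gain
        else:
            fold = t_frac / n_frac
            if fold > gain_threshold:
                state = CopyNumberState.gain
            elif fold < loss_threshold:
                state = CopyNumberState.loss
            else:
                state = CopyNumberState.neutral
        calls.append(
            CopyNumberCall(region_id=region, sample_id=sample_id, fold_change=fold, state=state)
        )
    return calls


def association_test_binary(
    marker_calls: Mapping[str, bool], outcomes: Mapping[str, bool]
) -> dict:
    """Fisher exact association between a binary marker and pCR outcome.

    Returns ``{"odds_table": [[a, b], [c, d]], "p": float}`` where rows are
    marker-positive / marker-negative and columns pCR / non-pCR.  Requires
    identical sample-id sets and at least one sample per outcome group.
    """
    if set(marker_calls) != set(outcomes):
        raise ValidationError("marker calls and outcomes cover different samples")
    ids = list(marker_calls)
    n_pcr = sum(bool(outcomes[s]) for s in ids)
    if n_pcr == 0 or n_pcr == len(ids):
        raise ValidationError("association test requires at least one sample per outcome group")
    a = sum(marker_calls[s] and outcomes[s] for s in ids)
    b = sum(marker_calls[s] and not outcomes[s] for s in ids)
    c = sum((not marker_calls[s]) and outcomes[s] for s in ids)
    d = sum((not marker_calls[s]) and not outcomes[s] for s in ids)
    table = [[a, b], [c, d]]
    return {"odds_table": table, "p": fisher_exact_2x2(table)}
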