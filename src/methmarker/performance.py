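"""Marker dichotomization, combination, and stratified performance reports.

A continuous marker level (e.g. pyrosequencing methylation percentage) is
dichotomized at a configured cutoff into marker-positive/negative calls;
binary markers (ER-negative status) are used directly; markers combine
elementwise (the combined predictor of interest is methylation-high AND
ER-negative).  Performance against the pCR outcome is reported as a 2x2
contingency per marker, overall and within age strata (<45, 45-55 inclusive
on both ends, >55), with exact fractions kept internally and 1-dp half-up
percentages for rendering.

The dichotomization cutoff is deliberately a required argument with no
default: a clinically meaningful cutoff must come from calibration data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .core import (
    ContingencyResult,
    ERStatus,
    SampleRecord,
    ValidationError,
    contingency_metrics,
)

__all__ = [
    "dichotomize",
    "evaluate_marker",
    "combine_markers",
    "AgeStratum",
    "StratifiedReport",
    "stratified_report",
    "er_negative_calls",
]


def dichotomize(
    levels: Mapping[str, float], threshold: float, comparator: str = "gt"
) -> dict[str, bool]:
    """Marker-positive calls from continuous levels in [0, 1].

    ``comparator`` is ``"gt"`` (level > threshold) or ``"ge"``.
    """
    if comparator not in ("gt", "ge"):
        raise ValueError(f"comparator must be 'gt' or 'ge', got {comparator!r}")
    out: dict[str, bool] = {}
    for sid, level in levels.items():
        if not 0.0 <= level <= 1.0:
            raise ValidationError(f"sample {sid!r}: level {level} outside [0,1]")
        out[sid] = level > threshold if comparator == "gt" else level >= threshold
    return out


def er_negative_calls(samples: Sequence[SampleRecord]) -> dict[str, bool]:
    """ER-negative status as a binary marker (predicts pCR when negative).

    Samples with unknown ER status raise, since they cannot be scored.
    """
    unknown = [s.sample_id for s in samples if s.er_status is ERStatus.unknown]
    if unknown:
        raise ValidationError(f"samples with unknown ER status: {unknown}")
    return {s.sample_id: s.er_status is ERStatus.negative for s in samples}


def evaluate_marker(
    samples: Sequence[SampleRecord], calls: Mapping[str, bool]
) -> ContingencyResult:
    """2x2 performance of a binary marker against the pCR outcome.

    Positive class = pCR; marker-positive = predicted pCR.  Every sample
    must carry an outcome label and a call.
    """
    missing_call = [s.sample_id for s in samples if s.sample_id not in calls]
    if missing_call:
        raise ValidationError(f"samples without marker call: {missing_call}")
    missing_outcome = [s.sample_id for s in samples if s.pcr is None]
    if missing_outcome:
        raise ValidationError(f"samples without pCR outcome: {missing_outcome}")
    tp = fp = fn = tn = 0
    for s in samples:
        call = bool(calls[s.sample_id])
        if call and s.pcr:
            tp += 1
        elif call:
            fp += 1
        elif s.pcr:
            fn += 1
        else:
            tn += 1
    return contingency_metrics(tp, fp, fn, tn)


def combine_markers(
    calls_a: Mapping[str, bool], calls_b: Mapping[str, bool], mode: str = "and"
) -> dict[str, bool]:
    """Elementwise AND/OR of two binary markers over the same samples."""
    if set(calls_a) != set(calls_b):
        raise ValidationError("marker call sets cover different samples")
    if mode == "and":
        return {s: bool(calls_a[s]) and bool(calls_b[s]) for s in calls_a}
    if mode == "or":
        return {s: bool(calls_a[s]) or bool(calls_b[s]) for s in calls_a}
    raise ValueError(f"mode must be 'and' or 'or', got {mode!r}")


@dataclass(frozen=True)
class AgeStratum:
    label: str
    lo: Optional[int]  # inclusive lower bound, None = open
    hi: Optional[int]  # inclusive upper bound, None = open

    def contains(self, age: int) -> bool:
        return (self.lo is None or age >= self.lo) and (self.hi is None or age <= self.hi)


@dataclass(frozen=True)
class StratumResult:
    stratum: AgeStratum
    n: int
    markers: dict  # marker name -> ContingencyResult


@dataclass(frozen=True)
class StratifiedReport:
    overall: StratumResult
    strata: tuple[StratumResult, ...]

    def as_rows(self) -> list[dict]:
        """Flat rows (stratum x marker) with counts, exact fractions and
        1-dp percentages, for TSV rendering."""
        rows = []
        for res in (self.overall, *self.strata):
            for marker, ct in res.markers.items():
                rows.append(
                    {
                        "stratum": res.stratum.label,
                        "marker": marker,
                        **ct.as_dict(),
                        "positive_rate_pct": ct.percent("positive_rate"),
                        "pcr_rate_overall_pct": ct.percent("pcr_rate_overall"),
                        "ppv_pct": ct.percent("ppv"),
                        "sensitivity_pct": ct.percent("sensitivity"),
                        "specificity_pct": ct.percent("specificity"),
                    }
                )
        return rows


def _strata_from_breaks(age_breaks: Sequence[int]) -> list[AgeStratum]:
    """Default two breaks [45, 55] give <45, 45-55 (inclusive both ends), >55.

    Generalised: breaks [b1 < b2 < ...] give <b1, b1-b2, (b2+1)-b3, ..., >bk
    — with the first interior stratum inclusive of its lower break to match
    the <lo / lo-hi / >hi partition convention.
    """
    breaks = sorted(age_breaks)
    if not breaks:
        return []
    strata = [AgeStratum(label=f"<{breaks[0]}", lo=None, hi=breaks[0] - 1)]
    lo = breaks[0]
    for hi in breaks[1:]:
        strata.append(AgeStratum(label=f"{lo}-{hi}", lo=lo, hi=hi))
        lo = hi + 1
    strata.append(AgeStratum(label=f">{breaks[-1]}", lo=lo, hi=None))
    return strata


def stratified_report(
    samples: Sequence[SampleRecord],
    methylation_calls: Mapping[str, bool],
    er_calls: Mapping[str, bool],
    age_breaks: Sequence[int] = (45, 55),
) -> StratifiedReport:
    """Overall and per-age-stratum contingency for the three markers.

    Markers reported: ``methylation`` (methylation-high), ``er``
    (ER-negative), ``combined`` (methylation-high AND ER-negative, built
    here from the two call sets).  Strata from ``age_breaks`` (default
    <45 / 45-55 / >55) partition all ages, so stratum counts sum to the
    overall table.
    """
    ageless = [s.sample_id for s in samples if s.age is None]
    if ageless:
        raise ValidationError(f"samples without age: {ageless}")
    combined = combine_markers(methylation_calls, er_calls, mode="and")
    markers = {"methylation": methylation_calls, "er": er_calls, "combined": combined}

    def result_for(subset: Sequence[SampleRecord], stratum: AgeStratum) -> StratumResult:
        return StratumResult(
            stratum=stratum,
            n=len(subset),
            markers={name: evaluate_marker(subset, calls) for name, calls in markers.items()},
        )

    overall = result_for(list(samples), AgeStratum(label="all", lo=None, hi=None))
    strata = []
    for st in _strata_from_breaks(age_breaks):
        subset = [s for s in samples if st.contains(s.age)]
        if subset:
            strata.append(result_for(subset, st))
    return StratifiedReport(overall=overall, strata=tuple(strata))
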