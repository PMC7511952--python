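"""On-treatment response monitoring from paired marker measurements.

Each patient contributes a baseline and an on-treatment measurement of a
marker (methylation level of the marker locus, Ki-67 index, tumor size).
The change is summarised as a delta on a 0-100 scale under one of two
conventions:

* ``absolute_points`` (default): (baseline - on_treatment) x 100 — a drop
  of the beta-value by 0.5 is a delta of 50.  This is the default reading
  of a "delta-beta >= 50%" rule since beta is itself a fraction.
* ``relative_to_baseline``: (baseline - on_treatment)/baseline x 100.

Pairs with delta >= 50 (default) are "large decreases"; the summary
reports how many large-decrease samples achieved pCR.  The paired shift of
a marker across the cohort is tested with the Wilcoxon signed-rank test,
and markers are compared by how selectively they decrease in responders
versus non-responders (a marker that falls in everyone carries no
response information).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import math

import pandas as pd

from .core import ValidationError
from .stats import WilcoxonResult, wilcoxon_signed_rank

__all__ = [
    "PairedObservation",
    "compute_delta",
    "classify_large_decrease",
    "paired_change_test",
    "compare_response_markers",
]

_CONVENTIONS = ("absolute_points", "relative_to_baseline")


@dataclass
class PairedObservation:
    sample_id: str
    baseline: float
    on_treatment: float
    pcr: bool
    delta: Optional[float] = None
    large_decrease: Optional[bool] = None

    def __post_init__(self) -> None:
        for name in ("baseline", "on_treatment"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")


def compute_delta(baseline: float, on_treatment: float, convention: str = "absolute_points") -> float:
    """Delta on a 0-100 scale; positive = decrease under treatment."""
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}, got {convention!r}")
    if not (0.0 <= baseline <= 1.0 and 0.0 <= on_treatment <= 1.0):
        raise ValidationError("baseline and on_treatment must be in [0,1]")
    if convention == "relative_to_baseline":
        if baseline == 0:
            raise ValidationError("relative delta undefined for baseline 0")
        return (baseline - on_treatment) / baseline * 100.0
    return (baseline - on_treatment) * 100.0


def classify_large_decrease(
    pairs: Sequence[PairedObservation],
    *,
    threshold: float = 50.0,
    convention: str = "absolute_points",
) -> dict:
    """Flag large decreases (delta >= threshold) and summarise their outcomes.

    Returns ``{"classified": [...], "summary": {"n_large", "n_large_pcr",
    "fraction_pcr"}}``; ``fraction_pcr`` is None when no pair qualifies.
    """
    classified: list[PairedObservation] = []
    for p in pairs:
        delta = compute_delta(p.baseline, p.on_treatment, convention)
        # tolerance so a drop that equals the threshold in exact arithmetic
        # is not lost to floating-point subtraction
        is_large = delta >= threshold or math.isclose(delta, threshold, rel_tol=1e-12)
        classified.append(
            PairedObservation(
                sample_id=p.sample_id,
                baseline=p.baseline,
                on_treatment=p.on_treatment,
                pcr=p.pcr,
                delta=delta,
                large_decrease=is_large,
            )
        )
    large = [p for p in classified if p.large_decrease]
    n_large = len(large)
    n_large_pcr = sum(p.pcr for p in large)
    return {
        "classified": classified,
        "summary": {
            "n_large": n_large,
            "n_large_pcr": n_large_pcr,
            "fraction_pcr": None if n_large == 0 else n_large_pcr / n_large,
        },
    }


def paired_change_test(baseline, on_treatment) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test of the baseline -> on-treatment shift."""
    return wilcoxon_signed_rank(baseline, on_treatment)


def pairs_from_frame(df: pd.DataFrame) -> list[PairedObservation]:
    """Build paired observations from a sample_id/baseline/on_treatment/pcr frame."""
    return [
        PairedObservation(
            sample_id=str(r.sample_id),
            baseline=float(r.baseline),
            on_treatment=float(r.on_treatment),
            pcr=bool(r.pcr),
        )
        for r in df.itertuples()
    ]


def compare_response_markers(
    markers: dict[str, Sequence[PairedObservation]],
    *,
    threshold: float = 50.0,
    convention: str = "absolute_points",
) -> pd.DataFrame:
    """Per-marker decrease consistency in responders vs non-responders.

    ``markers`` maps a marker name to its paired observations; all markers
    must cover the same sample ids.  For each marker and outcome group the
    table reports the fraction of samples with ANY decrease and with a
    large decrease (delta >= threshold).  A selective response marker shows
    high consistency in pCR samples and low in non-pCR; a marker that
    decreases in everyone shows high consistency in both.
    """
    if not markers:
        raise ValidationError("no markers given")
    id_sets = {name: {p.sample_id for p in pairs} for name, pairs in markers.items()}
    reference = next(iter(id_sets.values()))
    mismatched = [name for name, ids in id_sets.items() if ids != reference]
    if mismatched:
        raise ValidationError(f"markers cover different samples: {mismatched}")
    rows = []
    for name, pairs in markers.items():
        classified = classify_large_decrease(
            pairs, threshold=threshold, convention=convention
        )["classified"]
        for outcome, label in ((True, "pcr"), (False, "nonpcr")):
            group = [p for p in classified if p.pcr == outcome]
            if group:
                any_dec = sum(p.delta > 0 for p in group) / len(group)
                large_dec = sum(p.large_decrease for p in group) / len(group)
            else:
                any_dec = large_dec = math.nan
            rows.append(
                {
                    "marker": name,
                    "group": label,
                    "n": len(group),
                    "consistency_any_decrease": any_dec,
                    "consistency_large_decrease": large_dec,
                }
            )
    return pd.DataFrame(rows)
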