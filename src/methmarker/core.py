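"""Domain types shared by every pipeline stage.

The pipeline operates on four kinds of tabular data: a clinical sample
sheet (one row per patient/biopsy with the pCR outcome label), a probe x
sample matrix of Infinium-style methylation beta-values with per-probe
genomic annotation, a gene x sample matrix of normalized log2 expression
intensities, and summarised tumor/normal variant observations.  This module
defines the validated in-memory containers for those inputs plus the 2x2
contingency arithmetic used by every marker-evaluation step.

Conventions fixed here and relied on everywhere else:

* the positive class is pCR (pathological complete response) and
  "marker-positive" always means "predicted pCR";
* beta-values live in [0, 1], 0 = unmethylated, 1 = fully methylated,
  missing values are rejected;
* genomic coordinates are 1-based;
* percentages are rendered to one decimal with round-half-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "CohortSet",
    "ERStatus",
    "Timepoint",
    "RegionClass",
    "SampleRecord",
    "BetaMatrix",
    "ProbeAnnotation",
    "ExpressionMatrix",
    "ContingencyResult",
    "contingency_metrics",
    "percent_1dp",
]


class ValidationError(ValueError):
    """Input violates a documented invariant (range, uniqueness, coverage)."""


class FormatError(ValueError):
    """File is structurally malformed (missing column, bad header)."""


class CohortSet(str, Enum):
    screening = "screening"
    validation = "validation"
    revalidation = "revalidation"


class ERStatus(str, Enum):
    positive = "positive"
    negative = "negative"
    unknown = "unknown"


class Timepoint(str, Enum):
    baseline = "baseline"
    on_treatment = "on_treatment"


class RegionClass(str, Enum):
    cpg_island = "cpg_island"
    genic = "genic"
    intergenic = "intergenic"


@dataclass
class SampleRecord:
    """One patient/sample: the unit of all contingency analysis.

    ``pcr`` is the binary outcome label (absence of invasive and
    intraductal tumor cells at surgery).  ``cohort_set`` assigns the sample
    to the fixed screening / validation / re-validation split; the split is
    declared in the sample sheet, never computed.
    """

    sample_id: str
    cohort_set: CohortSet
    pcr: Optional[bool]
    er_status: ERStatus = ERStatus.unknown
    age: Optional[int] = None
    timepoint: Timepoint = Timepoint.baseline
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cohort_set = CohortSet(self.cohort_set)
        self.er_status = ERStatus(self.er_status)
        self.timepoint = Timepoint(self.timepoint)
        if self.age is not None and self.age < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: age must be >= 0, got {self.age}"
            )


@dataclass
class ProbeAnnotation:
    """Genomic annotation of one array probe.

    ``region_id`` is the grouping key (typically the gene or CpG-island
    name) within which consecutive-probe aggregation is performed; probes
    sharing a region_id must share a chromosome.
    """

    probe_id: str
    chromosome: str
    position: int  # 1-based
    gene: str = ""
    region_class: RegionClass = RegionClass.intergenic
    region_id: str = ""

    def __post_init__(self) -> None:
        self.region_class = RegionClass(self.region_class)
        if self.position < 1:
            raise ValidationError(
                f"probe {self.probe_id!r}: position must be >= 1 (1-based), "
                f"got {self.position}"
            )


class BetaMatrix:
    """Probe x sample matrix of methylation beta-values, all in [0, 1].

    Thin validated wrapper around a pandas DataFrame (probes in rows,
    samples in columns).  Construction rejects non-finite or out-of-range
    entries with the offending probe/sample coordinates, so downstream
    threshold logic never has to re-check ranges.
    """

    def __init__(self, beta: pd.DataFrame):
        if beta.index.has_duplicates:
            dups = beta.index[beta.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dups}")
        if beta.columns.has_duplicates:
            dups = beta.columns[beta.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        values = beta.to_numpy(dtype=float, copy=False)
        bad = ~np.isfinite(values) | (values < 0.0) | (values > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value out of [0,1] at probe {beta.index[i]!r}, "
                f"sample {beta.columns[j]!r}: {values[i, j]!r}"
            )
        self._df = beta.astype(float)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def probe_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(self._df.loc[list(probe_ids)])

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        return BetaMatrix(self._df[list(sample_ids)])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"BetaMatrix({self._df.shape[0]} probes x {self._df.shape[1]} samples)"


class ExpressionMatrix:
    """Gene x sample matrix of normalized log2 intensities.

    The normalization convention (the per-sample 75th percentile of all
    probes equals 0) is checked on request via :meth:`assert_normalized`,
    not at construction, because raw log matrices pass through here too.
    """

    def __init__(self, log_intensity: pd.DataFrame):
        if log_intensity.index.has_duplicates:
            raise ValidationError("duplicate gene ids in expression matrix")
        values = log_intensity.to_numpy(dtype=float, copy=False)
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite expression value at gene "
                f"{log_intensity.index[i]!r}, sample {log_intensity.columns[j]!r}"
            )
        self._df = log_intensity.astype(float)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def gene_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    def assert_normalized(self, tol: float = 1e-9) -> None:
        q75 = np.percentile(self._df.to_numpy(), 75, axis=0)
        worst = float(np.abs(q75).max()) if q75.size else 0.0
        if worst > tol:
            raise ValidationError(
                f"expression matrix not 75th-percentile normalized "
                f"(max |q75| = {worst:g} > {tol:g})"
            )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self._df.shape[0]} genes x {self._df.shape[1]} samples)"


def percent_1dp(numerator: int, denominator: int) -> float:
    """Exact count ratio as a percentage rounded to 1 decimal, half-up.

    Rounding is done on the exact rational (Decimal), not the float, so
    e.g. 40/128 renders as 31.3 and 43/128 as 33.6.
    """
    if denominator == 0:
        raise ValidationError("percentage of an empty denominator is undefined")
    pct = Decimal(numerator) / Decimal(denominator) * 100
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 marker x outcome counts with derived performance metrics.

    Orientation: positive class = pCR; marker-positive = predicted pCR.
    So ``tp`` = marker-positive samples that achieved pCR, ``tn`` =
    marker-negative samples that did not.  A metric whose denominator is
    zero is ``None`` (undefined), never silently 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"count {name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValidationError("contingency table must contain at least one sample")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @staticmethod
    def _ratio(num: int, den: int) -> Optional[float]:
        return None if den == 0 else num / den

    @property
    def sensitivity(self) -> Optional[float]:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> Optional[float]:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> Optional[float]:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def positive_rate(self) -> float:
        return (self.tp + self.fp) / self.n

    @property
    def pcr_rate_overall(self) -> float:
        return (self.tp + self.fn) / self.n

    @property
    def pcr_rate_marker_pos(self) -> Optional[float]:
        return self.ppv

    @property
    def pcr_rate_marker_neg(self) -> Optional[float]:
        return self._ratio(self.fn, self.fn + self.tn)

    def percent(self, metric: str) -> Optional[float]:
        """A metric as a 1-dp half-up percentage computed on exact counts."""
        pairs = {
            "sensitivity": (self.tp, self.tp + self.fn),
            "specificity": (self.tn, self.tn + self.fp),
            "ppv": (self.tp, self.tp + self.fp),
            "npv": (self.tn, self.tn + self.fn),
            "positive_rate": (self.tp + self.fp, self.n),
            "pcr_rate_overall": (self.tp + self.fn, self.n),
            "pcr_rate_marker_pos": (self.tp, self.tp + self.fp),
            "pcr_rate_marker_neg": (self.fn, self.fn + self.tn),
        }
        num, den = pairs[metric]
        if den == 0:
            return None
        return percent_1dp(num, den)

    def as_dict(self) -> dict:
        out = {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn, "n": self.n}
        for m in (
            "sensitivity",
            "specificity",
            "ppv",
            "npv",
            "positive_rate",
            "pcr_rate_overall",
            "pcr_rate_marker_pos",
            "pcr_rate_marker_neg",
        ):
            v = getattr(self, m)
            out[m] = math.nan if v is None else v
        return out


def contingency_metrics(tp: int, fp: int, fn: int, tn: int) -> ContingencyResult:
    """Build a :class:`ContingencyResult` from the four cell counts.

    Raises :class:`ValidationError` on negative counts or an all-zero table.
    """
    return ContingencyResult(tp=int(tp), fp=int(fp), fn=int(fn), tn=int(tn))
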