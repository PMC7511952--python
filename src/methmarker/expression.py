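"""Expression normalization and volcano screening between outcome groups.

Microarray-style intensities are log2-transformed and shifted per sample so
that the 75th percentile of all probes is exactly 0; everything downstream
("average intensity > 0.5", fold changes) is on this normalized log2 scale.
The percentile uses linear interpolation (numpy's default), which makes the
transform idempotent and invariant to per-sample multiplicative rescaling
of the raw intensities.

The volcano screen tests each gene between pCR and non-pCR samples
(Welch's t-test by default; Mann-Whitney selectable — published gene lists
can differ by test choice) and selects genes with p below the p threshold
and linear fold change above the fold-change threshold (defaults 0.001 and
4).  The abundance filter then keeps selected genes whose grand-mean
normalized intensity exceeds 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ExpressionMatrix, ValidationError
from .stats import MannWhitneyResult, mann_whitney_u

__all__ = [
    "Direction",
    "VolcanoResult",
    "normalize_expression",
    "renormalize_log",
    "volcano_screen",
    "abundance_filter",
    "group_compare_continuous",
]


class Direction(str, Enum):
    up_in_pcr = "up_in_pcr"
    down_in_pcr = "down_in_pcr"


@dataclass(frozen=True)
class VolcanoResult:
    gene_id: str
    log2_fc: float  # mean(pCR) - mean(non-pCR) on the normalized log2 scale
    p: float
    mean_intensity: float  # grand mean across all samples
    selected: bool
    direction: Direction


def normalize_expression(raw: pd.DataFrame) -> ExpressionMatrix:
    """log2-transform and anchor each sample's 75th percentile at 0.

    ``raw`` is a gene x sample matrix of strictly positive intensities
    (or an already-normalized log matrix wrapped in a DataFrame — the
    transform is idempotent up to the log/linear distinction only when
    applied to its own linear-scale output, so idempotence is exposed via
    :func:`renormalize_log`).
    """
    values = raw.to_numpy(dtype=float)
    if not np.isfinite(values).all() or (values <= 0).any():
        bad = np.argwhere(~np.isfinite(values) | (values <= 0))[0]
        raise ValidationError(
            f"raw intensities must be positive and finite; offending entry at "
            f"gene {raw.index[bad[0]]!r}, sample {raw.columns[bad[1]]!r}"
        )
    log = np.log2(values)
    q75 = np.percentile(log, 75, axis=0)  # linear interpolation
    return ExpressionMatrix(pd.DataFrame(log - q75, index=raw.index, columns=raw.columns))


def renormalize_log(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Re-anchor an already-log-scale matrix's per-sample 75th percentile at 0.

    Idempotent: applying it to its own output is the identity.
    """
    log = expr.df.to_numpy()
    q75 = np.percentile(log, 75, axis=0)
    return ExpressionMatrix(pd.DataFrame(log - q75, index=expr.df.index, columns=expr.df.columns))


def _split_groups(sample_ids: Sequence[str], outcomes: Mapping[str, bool]):
    missing = [s for s in sample_ids if s not in outcomes]
    if missing:
        raise ValidationError(f"samples without outcome label: {missing}")
    pcr = [s for s in sample_ids if outcomes[s]]
    non = [s for s in sample_ids if not outcomes[s]]
    return pcr, non


def volcano_screen(
    expr: ExpressionMatrix,
    outcomes: Mapping[str, bool],
    *,
    p_threshold: float = 0.001,
    fc_threshold: float = 4.0,
    test: str = "welch",
) -> list[VolcanoResult]:
    """Per-gene differential test between pCR and non-pCR samples.

    Selection requires p < ``p_threshold`` AND linear fold change
    (2^|log2_fc|) strictly above ``fc_threshold``.  Needs >= 2 samples per
    group.  ``test`` is ``"welch"`` (unequal-variance t-test) or
    ``"mannwhitney"``.
    """
    pcr, non = _split_groups(expr.sample_ids, outcomes)
    if len(pcr) < 2 or len(non) < 2:
        raise ValidationError(
            f"volcano screen needs >= 2 samples per group (got {len(pcr)} pCR, {len(non)} non-pCR)"
        )
    a = expr.df[pcr].to_numpy()
    b = expr.df[non].to_numpy()
    log2_fc = a.mean(axis=1) - b.mean(axis=1)
    if test == "welch":
        with np.errstate(invalid="ignore", divide="ignore"):
            p = sps.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical groups
    elif test == "mannwhitney":
        p = np.array([mann_whitney_u(a[i], b[i]).p for i in range(a.shape[0])])
    else:
        raise ValueError(f"unknown test {test!r}")
    mean_intensity = expr.df.to_numpy().mean(axis=1)
    results = []
    for i, gene in enumerate(expr.gene_ids):
        fc = 2.0 ** abs(log2_fc[i])
        results.append(
            VolcanoResult(
                gene_id=gene,
                log2_fc=float(log2_fc[i]),
                p=float(p[i]),
                mean_intensity=float(mean_intensity[i]),
                selected=bool(p[i] < p_threshold and fc > fc_threshold),
                direction=Direction.up_in_pcr if log2_fc[i] >= 0 else Direction.down_in_pcr,
            )
        )
    return results


def abundance_filter(
    results: Sequence[VolcanoResult], intensity_threshold: float = 0.5
) -> list[str]:
    """Selected genes whose grand-mean normalized intensity is strictly above
    the threshold, in input order."""
    return [
        r.gene_id for r in results if r.selected and r.mean_intensity > intensity_threshold
    ]


def group_compare_continuous(
    values: Mapping[str, float], outcomes: Mapping[str, bool]
) -> MannWhitneyResult:
    """Mann-Whitney comparison of per-sample levels between pCR and non-pCR.

    Used for validation/re-validation of single-gene or single-locus levels
    (RT-PCR expression, pyrosequencing methylation).
    """
    ids = list(values)
    missing = [s for s in ids if s not in outcomes]
    if missing:
        raise ValidationError(f"samples without outcome label: {missing}")
    x = [values[s] for s in ids if outcomes[s]]
    y = [values[s] for s in ids if not outcomes[s]]
    if not x or not y:
        raise ValidationError("both outcome groups must be non-empty")
    return mann_whitney_u(x, y)
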