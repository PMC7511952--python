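"""Readers and writers for the pipeline's tabular file formats.

All formats are plain delimited text (TSV by default, CSV selectable),
parsed with pandas.  Readers validate into the typed containers of
:mod:`methmarker.core`; writers round-trip losslessly so that
``read(write(x)) == x`` field for field.

Formats
-------
sample sheet
    columns ``sample_id, cohort_set, pcr, er_status, age, timepoint``;
    extra columns are preserved in ``SampleRecord.metadata``.
beta matrix
    first column ``probe_id``, remaining columns sample ids; companion
    annotation TSV with ``probe_id, chrom, pos, gene, region_class,
    region_id``.
expression matrix
    first column ``gene_id``, remaining columns sample ids.
variant table
    columns ``sample_id, gene, chrom, pos, ref, alt, tumor_vaf,
    normal_vaf, homopolymer_len, fwd_alt, rev_alt, coverage, consequence``.
paired marker table
    columns ``sample_id, baseline, on_treatment, pcr``.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    BetaMatrix,
    CohortSet,
    ERStatus,
    ExpressionMatrix,
    FormatError,
    ProbeAnnotation,
    SampleRecord,
    Timepoint,
    ValidationError,
)
from .genomic import Consequence, VariantCall

__all__ = [
    "read_sample_sheet",
    "write_sample_sheet",
    "read_beta_matrix",
    "write_beta_matrix",
    "write_probe_annotation",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_variant_table",
    "write_variant_table",
    "read_paired_table",
    "write_paired_table",
]

_SHEET_COLUMNS = ["sample_id", "cohort_set", "pcr", "er_status", "age", "timepoint"]
_ANNOT_COLUMNS = ["probe_id", "chrom", "pos", "gene", "region_class", "region_id"]
_VARIANT_COLUMNS = [
    "sample_id", "gene", "chrom", "pos", "ref", "alt",
    "tumor_vaf", "normal_vaf", "homopolymer_len",
    "fwd_alt", "rev_alt", "coverage", "consequence",
]

_TRUE = {"true", "1", "yes", "y", "pcr"}
_FALSE = {"false", "0", "no", "n", "non-pcr", "nonpcr", "non_pcr"}


def _sep(dialect: str) -> str:
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    return "," if dialect == "csv" else "\t"


def _parse_bool(raw, context: str) -> bool | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
        return None
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise FormatError(f"{context}: cannot interpret {raw!r} as a pCR label")


def read_sample_sheet(path, dialect: str = "tsv") -> list[SampleRecord]:
    """Read a clinical sample sheet into validated :class:`SampleRecord` s.

    Blank ``er_status`` becomes ``unknown``, blank ``timepoint`` becomes
    ``baseline`` and blank ``pcr``/``age`` become ``None``.  Unknown columns
    are carried along in ``metadata``.  Duplicate sample ids raise
    :class:`ValidationError`; a missing required column raises
    :class:`FormatError` naming it.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str, keep_default_na=False)
    missing = [c for c in ("sample_id", "cohort_set") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    extra_cols = [c for c in df.columns if c not in _SHEET_COLUMNS]
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = row["sample_id"].strip()
        if sid in seen:
            raise ValidationError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        age_raw = row.get("age", "")
        er_raw = str(row.get("er_status", "")).strip()
        tp_raw = str(row.get("timepoint", "")).strip()
        records.append(
            SampleRecord(
                sample_id=sid,
                cohort_set=CohortSet(row["cohort_set"].strip()),
                pcr=_parse_bool(row.get("pcr", ""), f"{path} sample {sid}"),
                er_status=ERStatus(er_raw) if er_raw else ERStatus.unknown,
                age=int(age_raw) if str(age_raw).strip() != "" else None,
                timepoint=Timepoint(tp_raw) if tp_raw else Timepoint.baseline,
                metadata={c: row[c] for c in extra_cols},
            )
        )
    return records


def write_sample_sheet(records: Sequence[SampleRecord], path, dialect: str = "tsv") -> None:
    path = Path(path)
    extra = sorted({k for r in records for k in r.metadata})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=_sep(dialect))
        writer.writerow(_SHEET_COLUMNS + extra)
        for r in records:
            writer.writerow(
                [
                    r.sample_id,
                    r.cohort_set.value,
                    "" if r.pcr is None else str(r.pcr).lower(),
                    r.er_status.value,
                    "" if r.age is None else r.age,
                    r.timepoint.value,
                ]
                + [r.metadata.get(k, "") for k in extra]
            )


def read_beta_matrix(path, annotation_path, dialect: str = "tsv"):
    """Read a probe x sample beta matrix plus its probe annotation.

    Returns ``(BetaMatrix, list[ProbeAnnotation])`` aligned by probe id.
    Every probe in the matrix must be annotated; unannotated probes raise
    :class:`ValidationError` listing them.  Out-of-range beta values raise
    with the probe/sample coordinates (from BetaMatrix validation).
    """
    path, annotation_path = Path(path), Path(annotation_path)
    df = pd.read_csv(path, sep=_sep(dialect), float_precision="round_trip")
    first = df.columns[0]
    df = df.set_index(first)
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric beta value ({exc})") from exc
    beta = BetaMatrix(df)

    ann = pd.read_csv(annotation_path, sep=_sep(dialect), dtype=str, keep_default_na=False)
    missing_cols = [c for c in _ANNOT_COLUMNS if c not in ann.columns]
    if missing_cols:
        raise FormatError(f"{annotation_path}: missing column(s) {missing_cols}")
    annotations = [
        ProbeAnnotation(
            probe_id=row.probe_id,
            chromosome=row.chrom,
            position=int(row.pos),
            gene=row.gene,
            region_class=row.region_class,
            region_id=row.region_id,
        )
        for row in ann.itertuples()
    ]
    annotated = {a.probe_id for a in annotations}
    orphans = [p for p in beta.probe_ids if p not in annotated]
    if orphans:
        raise ValidationError(f"probes missing annotation: {orphans}")
    return beta, annotations


def write_beta_matrix(beta: BetaMatrix, path, dialect: str = "tsv") -> None:
    beta.df.rename_axis("probe_id").to_csv(
        Path(path), sep=_sep(dialect), float_format="%.17g"
    )


def write_probe_annotation(annotations: Iterable[ProbeAnnotation], path, dialect: str = "tsv") -> None:
    rows = [
        {
            "probe_id": a.probe_id,
            "chrom": a.chromosome,
            "pos": a.position,
            "gene": a.gene,
            "region_class": a.region_class.value,
            "region_id": a.region_id,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=_ANNOT_COLUMNS).to_csv(Path(path), sep=_sep(dialect), index=False)


def read_expression_matrix(path, dialect: str = "tsv") -> ExpressionMatrix:
    df = pd.read_csv(Path(path), sep=_sep(dialect))
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return ExpressionMatrix(df.astype(float))


def write_expression_matrix(expr: ExpressionMatrix, path, dialect: str = "tsv") -> None:
    expr.df.rename_axis("gene_id").to_csv(Path(path), sep=_sep(dialect))


def read_variant_table(path, dialect: str = "tsv") -> list[VariantCall]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(dialect), float_precision="round_trip")
    missing = [c for c in _VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return [
        VariantCall(
            sample_id=str(row.sample_id),
            gene=str(row.gene),
            chromosome=str(row.chrom),
            position=int(row.pos),
            ref_allele=str(row.ref),
            alt_allele=str(row.alt),
            tumor_vaf=float(row.tumor_vaf),
            normal_vaf=float(row.normal_vaf),
            homopolymer_len=int(row.homopolymer_len),
            fwd_alt_reads=int(row.fwd_alt),
            rev_alt_reads=int(row.rev_alt),
            coverage=int(row.coverage),
            consequence=Consequence(str(row.consequence)),
        )
        for row in df.itertuples()
    ]


def write_variant_table(variants: Sequence[VariantCall], path, dialect: str = "tsv") -> None:
    rows = [
        {
            "sample_id": v.sample_id,
            "gene": v.gene,
            "chrom": v.chromosome,
            "pos": v.position,
            "ref": v.ref_allele,
            "alt": v.alt_allele,
            "tumor_vaf": v.tumor_vaf,
            "normal_vaf": v.normal_vaf,
            "homopolymer_len": v.homopolymer_len,
            "fwd_alt": v.fwd_alt_reads,
            "rev_alt": v.rev_alt_reads,
            "coverage": v.coverage,
            "consequence": v.consequence.value,
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS).to_csv(
        Path(path), sep=_sep(dialect), index=False, float_format="%.17g"
    )


def read_paired_table(path, dialect: str = "tsv") -> pd.DataFrame:
    """Paired baseline/on-treatment marker levels, one row per sample."""
    df = pd.read_csv(Path(path), sep=_sep(dialect), float_precision="round_trip")
    missing = [c for c in ("sample_id", "baseline", "on_treatment", "pcr") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df["pcr"] = df["pcr"].map(lambda v: _parse_bool(v, str(path)))
    return df


def write_paired_table(df: pd.DataFrame, path, dialect: str = "tsv") -> None:
    df.to_csv(Path(path), sep=_sep(dialect), index=False, float_format="%.17g")
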