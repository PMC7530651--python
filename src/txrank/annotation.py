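"""Transcript/gene annotation tables and MANE/RefSeq cross-references.

The internal annotation table is a :class:`pandas.DataFrame` with one row per
transcript and the columns in :data:`ANNOTATION_COLUMNS`.  All Ensembl-style
accessions are stored versionless (``ENST00000367439``, never
``ENST00000367439.5``) so that tables from different annotation releases join
cleanly.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = [
    "transcript_id",
    "gene_id",
    "gene_name",
    "transcript_name",
    "biotype",
    "transcript_length",
    "cds_length",
]

MANE_COLUMNS = ["gene_id", "mane_transcript_id", "refseq_id"]

_VERSION_RE = re.compile(r"\.\d+$")
_GTF_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"')


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation inputs."""


def strip_version(accession: str) -> str:
    """Drop a trailing ``.N`` version suffix from an accession.

    Idempotent: ``strip_version(strip_version(x)) == strip_version(x)``.
    """
    return _VERSION_RE.sub("", accession)


def _strip_versions(series: pd.Series) -> pd.Series:
    return series.astype(str).str.replace(_VERSION_RE, "", regex=True)


def validate_annotation(table: pd.DataFrame) -> pd.DataFrame:
    """Check the TranscriptAnnotation invariants, returning the table.

    Raises :class:`AnnotationError` on duplicate transcript IDs, empty
    biotypes, non-positive transcript lengths, negative CDS lengths, or
    ``cds_length > transcript_length``.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise AnnotationError(f"annotation is missing columns: {missing}")
    if table["transcript_id"].duplicated().any():
        dups = table.loc[table["transcript_id"].duplicated(), "transcript_id"]
        raise AnnotationError(f"duplicate transcript IDs: {sorted(set(dups))}")
    if len(table):
        if (table["biotype"].astype(str).str.len() == 0).any():
            raise AnnotationError("empty biotype encountered")
        if (table["transcript_length"] < 1).any():
            raise AnnotationError("transcript_length must be >= 1")
        if (table["cds_length"] < 0).any():
            raise AnnotationError("cds_length must be >= 0")
        bad = table["cds_length"] > table["transcript_length"]
        if bad.any():
            ids = table.loc[bad, "transcript_id"].tolist()
            raise AnnotationError(f"cds_length > transcript_length for: {ids}")
    return table


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    return dict(_GTF_ATTR_RE.findall(attr_field))


def read_annotation_gtf(path: str | Path) -> pd.DataFrame:
    """Read a GENCODE-dialect GTF into a TranscriptAnnotation table.

    ``transcript_length`` is the sum of exon spans per transcript and
    ``cds_length`` the sum of CDS spans (0 when the transcript has no CDS
    feature).  Coordinates are 1-based inclusive, so a span contributes
    ``end - start + 1``.  Biotype comes from the transcript-level
    ``transcript_type`` (or ``transcript_biotype``) attribute and all IDs are
    version-stripped.
    """
    path = Path(path)
    transcripts: dict[str, dict] = {}
    exon_len: dict[str, int] = {}
    cds_len: dict[str, int] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}: malformed GTF line {lineno}: expected 9 "
                    f"tab-separated fields, got {len(fields)}"
                )
            feature = fields[2]
            if feature not in ("transcript", "exon", "CDS"):
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: malformed GTF line {lineno}: non-integer coordinates"
                ) from exc
            attrs = _parse_gtf_attributes(fields[8])
            tid = attrs.get("transcript_id")
            if tid is None:
                raise AnnotationError(
                    f"{path}: malformed GTF line {lineno}: missing transcript_id"
                )
            tid = strip_version(tid)
            span = end - start + 1
            if feature == "transcript":
                biotype = attrs.get("transcript_type") or attrs.get(
                    "transcript_biotype", ""
                )
                transcripts[tid] = {
                    "transcript_id": tid,
                    "gene_id": strip_version(attrs.get("gene_id", "")),
                    "gene_name": attrs.get("gene_name", ""),
                    "transcript_name": attrs.get("transcript_name", ""),
                    "biotype": biotype,
                }
            elif feature == "exon":
                exon_len[tid] = exon_len.get(tid, 0) + span
            elif feature == "CDS":
                cds_len[tid] = cds_len.get(tid, 0) + span

    records = []
    for tid, rec in transcripts.items():
        if tid not in exon_len:
            raise AnnotationError(f"transcript {tid} has no exon features")
        rec = dict(rec)
        rec["transcript_length"] = exon_len[tid]
        rec["cds_length"] = cds_len.get(tid, 0)
        if rec["cds_length"] == 0 and rec["biotype"] == "protein_coding":
            logger.warning(
                "protein_coding transcript %s has no CDS feature; cds_length=0", tid
            )
        records.append(rec)
    table = pd.DataFrame(records, columns=ANNOTATION_COLUMNS)
    table["transcript_length"] = table["transcript_length"].astype(int)
    table["cds_length"] = table["cds_length"].astype(int)
    return validate_annotation(table)


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    """Read a flat TSV with the six annotation fields (fixture-friendly path)."""
    table = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "gene_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise AnnotationError(f"annotation TSV {path} is missing columns: {missing}")
    table = table[ANNOTATION_COLUMNS].copy()
    if len(table) == 0:
        table["transcript_length"] = table["transcript_length"].astype(int)
        table["cds_length"] = table["cds_length"].astype(int)
        return table
    table["transcript_id"] = _strip_versions(table["transcript_id"])
    table["gene_id"] = _strip_versions(table["gene_id"])
    table["transcript_length"] = table["transcript_length"].astype(int)
    table["cds_length"] = table["cds_length"].astype(int)
    return validate_annotation(table)


def write_annotation_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def write_annotation_gtf(table: pd.DataFrame, path: str | Path) -> None:
    """Emit a minimal GENCODE-style GTF equivalent to the annotation table.

    Each transcript is written as one transcript feature, one exon covering
    ``[1, transcript_length]``, and (if ``cds_length > 0``) one CDS covering
    ``[1, cds_length]``, which round-trips exactly through
    :func:`read_annotation_gtf`.
    """
    with open(path, "w") as fh:
        fh.write("##provider: txrank synthetic annotation\n")
        for rec in table.to_dict("records"):
            attrs = (
                f'gene_id "{rec["gene_id"]}"; '
                f'transcript_id "{rec["transcript_id"]}"; '
                f'gene_name "{rec["gene_name"]}"; '
                f'transcript_name "{rec["transcript_name"]}"; '
                f'transcript_type "{rec["biotype"]}";'
            )
            base = ["chr1", "txrank", None, "1", None, ".", "+", ".", attrs]
            for feature, end in (
                ("transcript", rec["transcript_length"]),
                ("exon", rec["transcript_length"]),
                ("CDS", rec["cds_length"]),
            ):
                if feature == "CDS" and rec["cds_length"] == 0:
                    continue
                row = list(base)
                row[2] = feature
                row[4] = str(end)
                fh.write("\t".join(row) + "\n")


def read_mane_summary(path: str | Path) -> pd.DataFrame:
    """Read a MANE summary TSV into a (gene_id, mane_transcript_id, refseq_id) table.

    Accepts either the NCBI summary dialect (``Ensembl_Gene``, ``Ensembl_nuc``,
    ``RefSeq_nuc`` columns, MANE Select rows only) or a plain three-column TSV
    with the internal column names.  IDs are stored versionless and exact
    duplicate rows are collapsed; a gene listed with two different transcripts
    is an error (MANE-select is unique per gene).
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    raw.columns = [c.lstrip("#") for c in raw.columns]
    if "Ensembl_Gene" in raw.columns:
        if "MANE_status" in raw.columns:
            raw = raw[raw["MANE_status"].str.contains("Select", case=False, na=False)]
        table = pd.DataFrame(
            {
                "gene_id": raw["Ensembl_Gene"],
                "mane_transcript_id": raw["Ensembl_nuc"],
                "refseq_id": raw["RefSeq_nuc"],
            }
        )
    else:
        missing = [c for c in MANE_COLUMNS if c not in raw.columns]
        if missing:
            raise AnnotationError(f"MANE summary {path} is missing columns: {missing}")
        table = raw[MANE_COLUMNS].copy()
    for col in MANE_COLUMNS:
        table[col] = _strip_versions(table[col])
    table = table.drop_duplicates().reset_index(drop=True)
    conflicted = table["gene_id"].duplicated()
    if conflicted.any():
        genes = sorted(set(table.loc[conflicted, "gene_id"]))
        raise AnnotationError(
            f"MANE summary assigns multiple select transcripts to genes: {genes}"
        )
    return table


def read_gene2ensembl(path: str | Path) -> pd.DataFrame:
    """Read an NCBI gene2ensembl TSV, keeping the RefSeq↔Ensembl transcript map.

    Returns columns ``ncbi_gene_id``, ``gene_id`` (Ensembl), ``refseq_id``,
    ``transcript_id`` (Ensembl), version-stripped.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    raw.columns = [c.lstrip("#") for c in raw.columns]
    colmap = {
        "GeneID": "ncbi_gene_id",
        "Ensembl_gene_identifier": "gene_id",
        "RNA_nucleotide_accession.version": "refseq_id",
        "Ensembl_rna_identifier": "transcript_id",
    }
    missing = [c for c in colmap if c not in raw.columns]
    if missing:
        raise AnnotationError(f"gene2ensembl {path} is missing columns: {missing}")
    table = raw[list(colmap)].rename(columns=colmap)
    for col in ("gene_id", "refseq_id", "transcript_id"):
        table[col] = _strip_versions(table[col])
    return table.drop_duplicates().reset_index(drop=True)


def classify_gene_biotype(annotation: pd.DataFrame) -> pd.DataFrame:
    """Flag each gene as protein-coding or not.

    A gene is protein-coding iff at least one of its transcripts has biotype
    ``protein_coding``.  Returns a DataFrame with columns ``gene_id`` and
    ``coding`` (bool), one row per gene.
    """
    if len(annotation) == 0:
        raise AnnotationError("cannot classify an empty annotation")
    coding = (
        annotation.assign(is_pc=annotation["biotype"].eq("protein_coding"))
        .groupby("gene_id", sort=True)["is_pc"]
        .any()
    )
    return coding.rename("coding").reset_index()
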