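"""GCT matrix I/O and tissue-level aggregation.

Expression values are TPM.  Matrices are held dense as
:class:`pandas.DataFrame` objects with a version-stripped transcript-ID index;
:class:`SampleMatrix` columns are sample IDs, :class:`TissueMatrix` columns
are tissue labels (unique, alphabetically ordered after collapse).
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from txrank.annotation import _strip_versions

logger = logging.getLogger(__name__)


class GctError(ValueError):
    """Raised for malformed GCT input."""


def _check_matrix(tpm: pd.DataFrame, kind: str) -> None:
    if tpm.index.duplicated().any():
        dups = sorted(set(tpm.index[tpm.index.duplicated()]))
        raise ValueError(f"{kind}: duplicate transcript IDs: {dups[:10]}")
    if tpm.columns.duplicated().any():
        raise ValueError(f"{kind}: duplicate column labels")
    if tpm.size and (tpm.to_numpy() < 0).any():
        raise ValueError(f"{kind}: negative TPM values")


@dataclass
class SampleMatrix:
    """Transcript × sample TPM matrix.

    ``description`` optionally carries the GCT Description column (GTEx puts
    the gene accession there), aligned with ``tpm.index``.
    """

    tpm: pd.DataFrame
    description: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        _check_matrix(self.tpm, "SampleMatrix")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tpm.columns)


@dataclass
class TissueMatrix:
    """Transcript × tissue mean-TPM matrix."""

    tpm: pd.DataFrame
    description: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        _check_matrix(self.tpm, "TissueMatrix")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.tpm.columns)


def _open_text(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode.replace("t", ""))


def read_gct(path: str | Path, *, as_tissues: bool = False) -> SampleMatrix | TissueMatrix:
    """Read a GCT 1.2 matrix (gzip transparent).

    The ``Name`` column becomes the (version-stripped) transcript index; the
    ``Description`` column is retained as auxiliary metadata.  The declared
    dimensions line is validated against the actual table.  With
    ``as_tissues=True`` the columns are interpreted as tissue labels and a
    :class:`TissueMatrix` is returned (the ``--already-collapsed`` path).
    """
    path = Path(path)
    with _open_text(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise GctError(f"{path}: expected '#1.2' header, found {version!r}")
        dims = fh.readline().strip().split("\t")
        if len(dims) < 2:
            raise GctError(f"{path}: malformed dimensions line")
        try:
            n_rows, n_cols = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise GctError(f"{path}: non-integer dimensions line") from exc
        table = pd.read_csv(fh, sep="\t", header=0, dtype={"Name": str})
    if list(table.columns[:2]) != ["Name", "Description"]:
        raise GctError(f"{path}: header must start with Name\\tDescription")
    if len(table) != n_rows or table.shape[1] - 2 != n_cols:
        raise GctError(
            f"{path}: dimension mismatch: declared {n_rows}x{n_cols}, "
            f"observed {len(table)}x{table.shape[1] - 2}"
        )
    names = _strip_versions(table["Name"]) if len(table) else table["Name"]
    tpm = table.drop(columns=["Name", "Description"]).astype(float)
    tpm.index = pd.Index(names, name="transcript_id")
    if tpm.size and (tpm.to_numpy() < 0).any():
        raise GctError(f"{path}: negative TPM values")
    desc = table["Description"].copy()
    desc.index = tpm.index
    cls = TissueMatrix if as_tissues else SampleMatrix
    return cls(tpm=tpm, description=desc)


def write_gct(matrix: SampleMatrix | TissueMatrix, path: str | Path) -> None:
    """Write a matrix as GCT 1.2 with a correct dimensions line."""
    path = Path(path)
    tpm = matrix.tpm
    desc = matrix.description
    if desc is None:
        desc = pd.Series(["na"] * len(tpm), index=tpm.index)
    with _open_text(path, "wt") as fh:
        fh.write("#1.2\n")
        fh.write(f"{tpm.shape[0]}\t{tpm.shape[1]}\n")
        header = ["Name", "Description", *map(str, tpm.columns)]
        fh.write("\t".join(header) + "\n")
        for tid, row in zip(tpm.index, tpm.to_numpy()):
            values = "\t".join(repr(float(v)) for v in row)
            line = f"{tid}\t{desc.loc[tid]}"
            if values:
                line += "\t" + values
            fh.write(line + "\n")


def read_sample_map(path: str | Path) -> pd.DataFrame:
    """Read a sample→tissue TSV.

    Accepts the GTEx sample-attribute dialect (``SAMPID``/``SMTSD``) or a
    generic two-column ``sample``/``tissue`` file.  Returns columns
    ``sample`` and ``tissue``.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if {"SAMPID", "SMTSD"}.issubset(raw.columns):
        return raw[["SAMPID", "SMTSD"]].rename(
            columns={"SAMPID": "sample", "SMTSD": "tissue"}
        )
    if {"sample", "tissue"}.issubset(raw.columns):
        return raw[["sample", "tissue"]].copy()
    raise ValueError(
        f"sample map {path} needs SAMPID/SMTSD or sample/tissue columns"
    )


def collapse_to_tissues(
    matrix: SampleMatrix,
    sample_map: pd.DataFrame,
    *,
    drop_unmapped: bool = False,
    statistic: str = "mean",
) -> TissueMatrix:
    """Average samples into tissues.

    Each tissue column is the equal-weight arithmetic mean (or, with
    ``statistic="median"``, the median) of its member samples' TPM, and
    tissues are ordered alphabetically.  Samples absent from ``sample_map``
    are an error unless ``drop_unmapped`` is set; tissues that end up with no
    samples are excluded with a warning.
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    mapping = dict(zip(sample_map["sample"], sample_map["tissue"]))
    unmapped = [s for s in matrix.sample_ids if s not in mapping]
    if unmapped and not drop_unmapped:
        raise ValueError(f"samples missing from sample map: {unmapped[:10]}")
    kept = [s for s in matrix.sample_ids if s in mapping]
    if not kept:
        raise ValueError("no samples remain after applying the sample map")
    if unmapped:
        logger.warning("dropping %d unmapped samples", len(unmapped))
    mapped_tissues = {mapping[s] for s in kept}
    empty = sorted(set(sample_map["tissue"]) - mapped_tissues)
    if empty:
        warnings.warn(f"tissues with zero samples excluded: {empty}", stacklevel=2)
    sub = matrix.tpm[kept]
    groups = pd.Series([mapping[s] for s in kept], index=kept)
    agg = sub.T.groupby(groups).mean() if statistic == "mean" else sub.T.groupby(groups).median()
    tissue_tpm = agg.T.sort_index(axis=1)
    tissue_tpm.columns.name = None
    return TissueMatrix(tpm=tissue_tpm, description=matrix.description)


def filter_expressed(matrix: TissueMatrix) -> tuple[TissueMatrix, int]:
    """Drop transcripts whose TPM is exactly 0 in every tissue.

    Returns the filtered matrix and the number of transcripts removed;
    ``kept + removed == input`` rows always.  Idempotent.
    """
    if matrix.tpm.shape[1] == 0:
        expressed = pd.Series(False, index=matrix.tpm.index)
    else:
        expressed = (matrix.tpm > 0).any(axis=1)
    removed = int((~expressed).sum())
    kept = matrix.tpm.loc[expressed]
    desc = matrix.description.loc[expressed] if matrix.description is not None else None
    return TissueMatrix(tpm=kept, description=desc), removed
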