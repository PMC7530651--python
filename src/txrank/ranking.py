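"""Per-gene isoform ranking, expression fractions, CV scores, and summaries.

Within each gene and ranking scope (the cross-tissue average or a single
tissue), isoforms are sorted descending by TPM, breaking exact TPM ties by
larger CDS length, then larger transcript length, then ascending transcript
ID — the final key makes ranking fully deterministic.  Fractions of gene
expression are NaN wherever the gene's TPM is 0 in that scope, and NaN is
excluded from every average (never imputed as 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from txrank.annotation import ANNOTATION_COLUMNS, validate_annotation
from txrank.expression import TissueMatrix

OVERALL = "overall"

_SORT_KEYS = ["gene_id", "tpm", "cds_length", "transcript_length", "transcript_id"]
_SORT_ASCENDING = [True, False, False, False, True]


@dataclass
class GeneExpression:
    """Gene-level TPM obtained by summing member isoform TPM.

    ``per_tissue`` is gene × tissue; ``overall_mean_tpm`` is the mean of the
    per-tissue values; ``transcript_count`` counts expressed isoforms only.
    """

    per_tissue: pd.DataFrame
    overall_mean_tpm: pd.Series
    transcript_count: pd.Series


@dataclass
class RankTable:
    """All per-transcript rank statistics for one dataset.

    ``summary`` is indexed by transcript_id with columns: gene_id, gene_name,
    transcript_name, biotype, transcript_length, cds_length,
    overall_mean_tpm, overall_rank, overall_fraction, gene_overall_tpm,
    transcript_count, cv_tpm, cv_rank, rank1_tissue_count (NaN for rows that
    are not overall rank1).  The tissue-indexed frames are transcript × tissue.
    """

    summary: pd.DataFrame
    tissue_tpm: pd.DataFrame
    tissue_rank: pd.DataFrame
    tissue_fraction: pd.DataFrame

    @property
    def tissues(self) -> list[str]:
        return list(self.tissue_tpm.columns)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(directory / "summary.tsv", sep="\t")
        self.tissue_tpm.to_csv(directory / "tissue_tpm.tsv", sep="\t")
        self.tissue_rank.to_csv(directory / "tissue_rank.tsv", sep="\t")
        self.tissue_fraction.to_csv(directory / "tissue_fraction.tsv", sep="\t")

    @classmethod
    def load(cls, directory: str | Path) -> "RankTable":
        directory = Path(directory)
        read = lambda name: pd.read_csv(directory / name, sep="\t", index_col=0)
        summary = read("summary.tsv")
        return cls(
            summary=summary,
            tissue_tpm=read("tissue_tpm.tsv"),
            tissue_rank=read("tissue_rank.tsv").astype(int),
            tissue_fraction=read("tissue_fraction.tsv"),
        )


def _aligned_annotation(matrix: TissueMatrix, annotation: pd.DataFrame) -> pd.DataFrame:
    validate_annotation(annotation)
    ann = annotation.set_index("transcript_id")
    orphans = [t for t in matrix.transcript_ids if t not in ann.index]
    if orphans:
        raise ValueError(f"transcripts absent from annotation: {orphans[:10]}")
    return ann.loc[matrix.transcript_ids]


def gene_expression(matrix: TissueMatrix, annotation: pd.DataFrame) -> GeneExpression:
    """Sum isoform TPM to gene TPM per tissue (RSEM-consistent definition)."""
    ann = _aligned_annotation(matrix, annotation)
    genes = pd.Series(ann["gene_id"].to_numpy(), index=matrix.tpm.index)
    per_tissue = matrix.tpm.groupby(genes, sort=True).sum()
    per_tissue.index.name = "gene_id"
    counts = genes.groupby(genes).size()
    counts.index.name = "gene_id"
    return GeneExpression(
        per_tissue=per_tissue,
        overall_mean_tpm=per_tissue.mean(axis=1),
        transcript_count=counts.rename("transcript_count"),
    )


def _scope_tpm(matrix: TissueMatrix, scope: str) -> pd.Series:
    if scope == OVERALL:
        return matrix.tpm.mean(axis=1)
    if scope not in matrix.tpm.columns:
        raise KeyError(f"unknown scope {scope!r}")
    return matrix.tpm[scope]


def rank_isoforms(
    matrix: TissueMatrix, annotation: pd.DataFrame, scope: str = OVERALL
) -> pd.Series:
    """Assign within-gene ranks 1..k for one scope.

    Ranks are a permutation of 1..k per gene; the sort is stable and the
    tie-break cascade (TPM desc, CDS length desc, transcript length desc,
    transcript ID asc) makes the result deterministic.
    """
    ann = _aligned_annotation(matrix, annotation)
    df = pd.DataFrame(
        {
            "transcript_id": matrix.transcript_ids,
            "gene_id": ann["gene_id"].to_numpy(),
            "tpm": _scope_tpm(matrix, scope).to_numpy(),
            "cds_length": ann["cds_length"].to_numpy(),
            "transcript_length": ann["transcript_length"].to_numpy(),
        }
    )
    ordered = df.sort_values(_SORT_KEYS, ascending=_SORT_ASCENDING, kind="mergesort")
    ranks = ordered.groupby("gene_id", sort=False).cumcount() + 1
    out = pd.Series(ranks.to_numpy(), index=ordered["transcript_id"], name=f"rank_{scope}")
    return out.loc[matrix.transcript_ids].astype(int)


def expression_fractions(
    matrix: TissueMatrix,
    gene_expr: GeneExpression,
    annotation: pd.DataFrame,
    scope: str = OVERALL,
) -> pd.Series:
    """Transcript TPM as a fraction of its gene's TPM in one scope.

    NaN marks tissues where the gene's TPM is 0 (undefined, never 0).
    """
    ann = _aligned_annotation(matrix, annotation)
    tx_tpm = _scope_tpm(matrix, scope)
    if scope == OVERALL:
        gene_tpm = gene_expr.overall_mean_tpm
    else:
        gene_tpm = gene_expr.per_tissue[scope]
    denom = gene_tpm.loc[ann["gene_id"]].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(denom > 0, tx_tpm.to_numpy() / denom, np.nan)
    return pd.Series(frac, index=matrix.tpm.index, name=f"fraction_{scope}")


def cv(values) -> float:
    """Coefficient of variation: sample (n−1) standard deviation over mean.

    Returns NaN for vectors shorter than 2 or with non-positive mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        return float("nan")
    mean = arr.mean()
    if mean <= 0:
        return float("nan")
    return float(arr.std(ddof=1) / mean)


def build_rank_table(matrix: TissueMatrix, annotation: pd.DataFrame) -> RankTable:
    """Compute the full rank table: overall and per-tissue ranks, fractions,
    CV statistics, and rank1 tissue counts.

    Expects ``filter_expressed`` to have been applied already.
    """
    ann = _aligned_annotation(matrix, annotation)
    gene_expr = gene_expression(matrix, annotation)
    tissues = matrix.tissues

    overall_rank = rank_isoforms(matrix, annotation, OVERALL)
    overall_fraction = expression_fractions(matrix, gene_expr, annotation, OVERALL)

    tissue_rank = pd.DataFrame(index=matrix.tpm.index, columns=tissues, dtype=int)
    tissue_fraction = pd.DataFrame(index=matrix.tpm.index, columns=tissues, dtype=float)
    for tissue in tissues:
        tissue_rank[tissue] = rank_isoforms(matrix, annotation, tissue)
        tissue_fraction[tissue] = expression_fractions(
            matrix, gene_expr, annotation, tissue
        )

    tpm_arr = matrix.tpm.to_numpy(dtype=float)
    rank_arr = tissue_rank.to_numpy(dtype=float)
    if len(tissues) >= 2:
        tpm_mean = tpm_arr.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv_tpm = np.where(
                tpm_mean > 0, tpm_arr.std(axis=1, ddof=1) / tpm_mean, np.nan
            )
        cv_rank = rank_arr.std(axis=1, ddof=1) / rank_arr.mean(axis=1)
    else:
        cv_tpm = np.full(len(matrix.tpm), np.nan)
        cv_rank = np.full(len(matrix.tpm), np.nan)

    gene_ids = ann["gene_id"]
    summary = pd.DataFrame(
        {
            "gene_id": gene_ids.to_numpy(),
            "gene_name": ann["gene_name"].to_numpy(),
            "transcript_name": ann["transcript_name"].to_numpy(),
            "biotype": ann["biotype"].to_numpy(),
            "transcript_length": ann["transcript_length"].to_numpy(),
            "cds_length": ann["cds_length"].to_numpy(),
            "overall_mean_tpm": matrix.tpm.mean(axis=1).to_numpy(),
            "overall_rank": overall_rank.to_numpy(),
            "overall_fraction": overall_fraction.to_numpy(),
            "gene_overall_tpm": gene_expr.overall_mean_tpm.loc[gene_ids].to_numpy(),
            "transcript_count": gene_expr.transcript_count.loc[gene_ids].to_numpy(),
            "cv_tpm": cv_tpm,
            "cv_rank": cv_rank,
        },
        index=matrix.tpm.index,
    )
    is_rank1 = summary["overall_rank"] == 1
    r1_counts = (tissue_rank.loc[is_rank1] == 1).sum(axis=1)
    summary["rank1_tissue_count"] = np.nan
    summary.loc[is_rank1, "rank1_tissue_count"] = r1_counts.astype(float)
    return RankTable(
        summary=summary,
        tissue_tpm=matrix.tpm.copy(),
        tissue_rank=tissue_rank,
        tissue_fraction=tissue_fraction,
    )


def rank_summary(
    rank_table: RankTable, max_rank: int = 10, *, exclude_single_transcript: bool = False
) -> pd.Series:
    """Mean overall TPM per overall-rank class 1..max_rank.

    Rank classes with no members are absent from the result, not reported
    as 0.  ``exclude_single_transcript`` drops single-isoform genes first
    (their sole transcript is rank1 by construction and runs hot).
    """
    df = rank_table.summary
    if exclude_single_transcript:
        df = df[df["transcript_count"] > 1]
    df = df[df["overall_rank"] <= max_rank]
    means = df.groupby("overall_rank")["overall_mean_tpm"].mean()
    means.index.name = "rank"
    return means.rename("mean_tpm")


def dominance_by_isoform_class(
    rank_table: RankTable, max_class: int = 10
) -> pd.DataFrame:
    """Mean overall expression fraction per (isoform-count class, rank).

    Rows are genes' expressed-isoform counts 1..max_class, columns overall
    ranks; cell (c, r) is the equal-gene-weight mean fraction of rank-r
    transcripts among genes with c isoforms.  NaN above the diagonal (a gene
    with c isoforms has no rank > c).
    """
    df = rank_table.summary
    df = df[df["transcript_count"] <= max_class]
    table = df.pivot_table(
        index="transcript_count",
        columns="overall_rank",
        values="overall_fraction",
        aggfunc="mean",
    )
    table = table.reindex(
        index=range(1, max_class + 1), columns=range(1, max_class + 1)
    )
    table.index.name = "isoform_count"
    table.columns.name = "rank"
    return table


def tissue_rank_distribution(
    rank_table: RankTable, max_rank: int = 5, *, label_mode: str = "overall"
) -> pd.DataFrame:
    """Mean per-tissue expression fraction per (tissue, rank label).

    With ``label_mode="overall"`` (default) transcripts are labeled by their
    overall rank and their per-tissue fractions averaged — the labeling under
    which a tissue-specific switch shows up as a dip of the rank1 curve in
    that tissue.  ``label_mode="per_tissue"`` labels by each tissue's own
    ranking instead.  Undefined (NaN) fractions are excluded from means.
    """
    if label_mode not in ("overall", "per_tissue"):
        raise ValueError(f"unknown label_mode {label_mode!r}")
    tissues = rank_table.tissues
    out = pd.DataFrame(index=tissues, columns=range(1, max_rank + 1), dtype=float)
    overall = rank_table.summary["overall_rank"]
    for r in range(1, max_rank + 1):
        if label_mode == "overall":
            mask = overall == r
            out[r] = rank_table.tissue_fraction.loc[mask].mean(axis=0, skipna=True)
        else:
            masked = rank_table.tissue_fraction.where(rank_table.tissue_rank == r)
            out[r] = masked.mean(axis=0, skipna=True)
    out.index.name = "tissue"
    out.columns.name = "rank"
    return out


def _round_half_up(value: float, decimals: int) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def transcripts_per_gene(transcript_count: int, gene_count: int) -> float:
    """Transcripts-per-gene ratio, rounded half-up to 2 decimals."""
    if gene_count <= 0:
        raise ValueError("gene_count must be positive")
    return _round_half_up(transcript_count / gene_count, 2)


def percentage(part: float, whole: float, decimals: int = 1) -> float:
    """100 × part / whole, rounded half-up for reporting."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return _round_half_up(100.0 * part / whole, decimals)


def coding_noncoding_mwu(rank_table: RankTable):
    """Mann–Whitney U comparison of coding vs noncoding isoform expression.

    Within protein-coding genes (genes with ≥1 protein_coding isoform),
    tests whether protein_coding transcripts have greater overall mean TPM
    than their noncoding siblings.  Returns the scipy result object
    (``.statistic``, ``.pvalue``).
    """
    df = rank_table.summary
    coding_genes = df.loc[df["biotype"] == "protein_coding", "gene_id"].unique()
    sub = df[df["gene_id"].isin(coding_genes)]
    coding = sub.loc[sub["biotype"] == "protein_coding", "overall_mean_tpm"]
    noncoding = sub.loc[sub["biotype"] != "protein_coding", "overall_mean_tpm"]
    if len(coding) == 0 or len(noncoding) == 0:
        raise ValueError("need both coding and noncoding transcripts for the test")
    return stats.mannwhitneyu(coding, noncoding, alternative="greater")


def download_table(rank_table: RankTable, max_rank: int | None = None) -> pd.DataFrame:
    """Per-transcript table in the published download-file schema.

    Columns: gene ID, transcript ID, gene name, transcript name, transcript
    count, transcript expression value, gene expression value,
    transcript/gene expression percentage, biotype, transcript length, CDS
    length.  Sorted by gene then rank; optionally truncated at ``max_rank``.
    """
    df = rank_table.summary.sort_values(["gene_id", "overall_rank"])
    if max_rank is not None:
        df = df[df["overall_rank"] <= max_rank]
    pct = df["overall_fraction"] * 100.0
    return pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "transcript_id": df.index,
            "gene_name": df["gene_name"],
            "transcript_name": df["transcript_name"],
            "transcript_count": df["transcript_count"],
            "transcript_tpm": df["overall_mean_tpm"],
            "gene_tpm": df["gene_overall_tpm"],
            "expression_percentage": pct,
            "biotype": df["biotype"],
            "transcript_length": df["transcript_length"],
            "cds_length": df["cds_length"],
        }
    ).reset_index(drop=True)


def dataset_summary(matrix: TissueMatrix, annotation: pd.DataFrame) -> pd.DataFrame:
    """Transcript/gene bookkeeping table (counts, ratios, mean TPM).

    Rows: the full input set, the expressed set, and the expressed
    protein-coding-gene subset; columns: transcript and gene counts,
    transcripts-per-gene, and mean TPM of expressed transcripts and genes.
    """
    from txrank.annotation import classify_gene_biotype
    from txrank.expression import filter_expressed

    ann = _aligned_annotation(matrix, annotation)
    expressed, removed = filter_expressed(matrix)
    exp_ann = annotation[annotation["transcript_id"].isin(expressed.tpm.index)]
    coding_flags = classify_gene_biotype(exp_ann).set_index("gene_id")["coding"]
    coding_genes = set(coding_flags[coding_flags].index)
    pc_ann = exp_ann[exp_ann["gene_id"].isin(coding_genes)]

    gene_expr = gene_expression(expressed, exp_ann) if len(exp_ann) else None

    def row(n_tx, n_genes, mean_tx, mean_gene):
        return {
            "transcripts": n_tx,
            "genes": n_genes,
            "transcripts_per_gene": transcripts_per_gene(n_tx, n_genes)
            if n_genes
            else float("nan"),
            "mean_transcript_tpm": mean_tx,
            "mean_gene_tpm": mean_gene,
        }

    rows = {}
    rows["all"] = row(
        len(matrix.tpm), annotation["gene_id"].nunique(), float("nan"), float("nan")
    )
    if gene_expr is not None:
        exp_means = expressed.tpm.mean(axis=1)
        rows["expressed"] = row(
            len(expressed.tpm),
            exp_ann["gene_id"].nunique(),
            float(exp_means.mean()),
            float(gene_expr.overall_mean_tpm.mean()),
        )
        pc_tx = expressed.tpm.loc[expressed.tpm.index.isin(pc_ann["transcript_id"])]
        pc_gene_tpm = gene_expr.overall_mean_tpm.loc[
            gene_expr.overall_mean_tpm.index.isin(coding_genes)
        ]
        rows["expressed_protein_coding"] = row(
            len(pc_tx),
            pc_ann["gene_id"].nunique(),
            float(pc_tx.mean(axis=1).mean()) if len(pc_tx) else float("nan"),
            float(pc_gene_tpm.mean()) if len(pc_gene_tpm) else float("nan"),
        )
    out = pd.DataFrame(rows).T
    out["removed_zero_transcripts"] = [removed, float("nan"), float("nan")][: len(out)]
    out.index.name = "subset"
    return out
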