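"""Rank1 switch events: genes whose per-tissue dominant isoform differs from
the overall rank1 isoform in at least one tissue.

For a dataset with T tissues, ``rank1_tissue_count + len(switch_tissues) == T``
holds for every gene; the web-style filter "tissue count 53 of 54" therefore
means exactly one switch tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from txrank.ranking import RankTable


@dataclass
class SwitchEvent:
    gene_id: str
    gene_name: str
    overall_rank1_transcript: str
    rank1_tissue_count: int
    switch_tissues: list[str] = field(default_factory=list)
    switching_transcripts: dict[str, str] = field(default_factory=dict)
    rank1_tpm: float = float("nan")
    rank1_cv_tpm: float = float("nan")
    rank1_overall_fraction: float = float("nan")


def _rank1_row(rank_table: RankTable, gene_id: str) -> pd.Series:
    df = rank_table.summary
    rows = df[(df["gene_id"] == gene_id) & (df["overall_rank"] == 1)]
    if len(rows) == 0:
        raise KeyError(f"unknown gene {gene_id!r}")
    return rows.iloc[0]


def rank1_tissue_count(rank_table: RankTable, gene_id: str) -> int:
    """Number of tissues in which the gene's overall rank1 transcript also
    holds per-tissue rank 1."""
    row = _rank1_row(rank_table, gene_id)
    tid = row.name
    return int((rank_table.tissue_rank.loc[tid] == 1).sum())


def _event_for(rank_table: RankTable, tid: str, row: pd.Series) -> SwitchEvent:
    tissue_ranks = rank_table.tissue_rank.loc[tid]
    switch_tissues = [t for t in rank_table.tissues if tissue_ranks[t] != 1]
    gene_mask = rank_table.summary["gene_id"] == row["gene_id"]
    sibling_ranks = rank_table.tissue_rank.loc[gene_mask]
    switching = {
        t: sibling_ranks.index[(sibling_ranks[t] == 1).to_numpy()][0]
        for t in switch_tissues
    }
    return SwitchEvent(
        gene_id=row["gene_id"],
        gene_name=row["gene_name"],
        overall_rank1_transcript=tid,
        rank1_tissue_count=int(row["rank1_tissue_count"]),
        switch_tissues=switch_tissues,
        switching_transcripts=switching,
        rank1_tpm=float(row["overall_mean_tpm"]),
        rank1_cv_tpm=float(row["cv_tpm"]),
        rank1_overall_fraction=float(row["overall_fraction"]),
    )


def detect_switch_events(
    rank_table: RankTable,
    min_count: int,
    max_count: int,
    cv_cutoff: float | None = None,
    min_rank1_fraction: float | None = None,
) -> list[SwitchEvent]:
    """Genes whose rank1 tissue count falls in [min_count, max_count].

    Optional filters: ``cv_cutoff`` keeps genes whose rank1 transcript has
    cross-tissue TPM CV ≥ the cutoff; ``min_rank1_fraction`` keeps genes whose
    rank1 overall expression fraction is ≥ the threshold.  Only genes with at
    least one switch tissue are events, so counts equal to the tissue number
    never appear.  Sorted by gene_id.
    """
    if min_count > max_count:
        raise ValueError(f"min_count {min_count} > max_count {max_count}")
    n_tissues = len(rank_table.tissues)
    df = rank_table.summary
    rank1 = df[df["overall_rank"] == 1]
    counts = rank1["rank1_tissue_count"].astype(int)
    keep = (counts >= min_count) & (counts <= max_count) & (counts < n_tissues)
    if cv_cutoff is not None:
        keep &= rank1["cv_tpm"] >= cv_cutoff
    if min_rank1_fraction is not None:
        keep &= rank1["overall_fraction"] >= min_rank1_fraction
    selected = rank1[keep].sort_values("gene_id")
    return [_event_for(rank_table, tid, row) for tid, row in selected.iterrows()]


def switch_events_frame(events: list[SwitchEvent]) -> pd.DataFrame:
    """Flatten events into the switch-event TSV schema."""
    return pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "gene_name": e.gene_name,
                "overall_rank1_transcript": e.overall_rank1_transcript,
                "rank1_tissue_count": e.rank1_tissue_count,
                "switch_tissues": ",".join(e.switch_tissues),
                "switching_transcripts": ",".join(
                    e.switching_transcripts[t] for t in e.switch_tissues
                ),
                "rank1_tpm": e.rank1_tpm,
                "rank1_fraction": e.rank1_overall_fraction,
                "cv_tpm": e.rank1_cv_tpm,
            }
            for e in events
        ],
        columns=[
            "gene_id",
            "gene_name",
            "overall_rank1_transcript",
            "rank1_tissue_count",
            "switch_tissues",
            "switching_transcripts",
            "rank1_tpm",
            "rank1_fraction",
            "cv_tpm",
        ],
    )


def gene_switch_report(rank_table: RankTable, gene_id: str) -> pd.DataFrame:
    """Long-format tissue × transcript display table for one gene.

    One row per (tissue, transcript): TPM, per-tissue fraction (NaN where the
    gene is unexpressed in the tissue), per-tissue rank, and overall rank —
    enough to redraw per-gene rank/percentage panels.  Warns on
    single-isoform genes (the report is trivially flat).
    """
    import warnings

    df = rank_table.summary
    members = df[df["gene_id"] == gene_id]
    if len(members) == 0:
        raise KeyError(f"unknown gene {gene_id!r}")
    if len(members) < 2:
        warnings.warn(f"gene {gene_id} has a single isoform; trivial report",
                      stacklevel=2)
    rows = []
    for tid, row in members.iterrows():
        for tissue in rank_table.tissues:
            rows.append(
                {
                    "tissue": tissue,
                    "transcript_id": tid,
                    "tpm": float(rank_table.tissue_tpm.at[tid, tissue]),
                    "fraction": float(rank_table.tissue_fraction.at[tid, tissue]),
                    "tissue_rank": int(rank_table.tissue_rank.at[tid, tissue]),
                    "overall_rank": int(row["overall_rank"]),
                }
            )
    return pd.DataFrame(rows)
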