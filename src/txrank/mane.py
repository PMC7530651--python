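"""Concordance between MANE-select transcripts and computed rank classes."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from txrank.ranking import RankTable


@dataclass
class ManeConcordance:
    """Cross-tabulation of MANE-select transcripts against overall ranks.

    ``per_rank_counts[r]`` counts matched MANE transcripts whose overall rank
    is r; ``unmatched_transcripts`` counts MANE records whose
    (gene, transcript) pair is absent from the ranked expression set — this
    includes transcripts that were removed as never-expressed.  Conservation:
    ``sum(per_rank_counts.values()) + unmatched_transcripts == records``.
    """

    records: int = 0
    matched_genes: int = 0
    per_rank_counts: dict[int, int] = field(default_factory=dict)
    unmatched_transcripts: int = 0
    coverage_top5: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"rank": r, "mane_transcripts": n}
            for r, n in sorted(self.per_rank_counts.items())
        ]
        return pd.DataFrame(rows, columns=["rank", "mane_transcripts"])

    def summary_line(self) -> str:
        matched = sum(self.per_rank_counts.values())
        top5 = "nan" if pd.isna(self.coverage_top5) else f"{self.coverage_top5:.3f}"
        return (
            f"MANE records: {self.records}; matched genes: {self.matched_genes}; "
            f"matched transcripts: {matched}; unmatched: "
            f"{self.unmatched_transcripts}; top5 coverage: {top5}"
        )


def compare_mane(rank_table: RankTable, mane: pd.DataFrame) -> ManeConcordance:
    """Join MANE-select records onto the rank table and tabulate their ranks.

    The join is on the (gene_id, transcript_id) pair with both sides already
    version-stripped, so versioned and versionless MANE inputs are
    equivalent.  An empty MANE table yields a zero-filled result.
    """
    if len(mane) == 0:
        return ManeConcordance()
    summary = rank_table.summary
    ranked = pd.DataFrame(
        {
            "gene_id": summary["gene_id"].to_numpy(),
            "transcript_id": summary.index,
            "overall_rank": summary["overall_rank"].to_numpy(),
        }
    )
    joined = mane.merge(
        ranked,
        left_on=["gene_id", "mane_transcript_id"],
        right_on=["gene_id", "transcript_id"],
        how="left",
    )
    matched = joined.dropna(subset=["overall_rank"])
    per_rank = (
        matched["overall_rank"].astype(int).value_counts().sort_index().to_dict()
    )
    gene_set = set(summary["gene_id"])
    matched_genes = int(mane["gene_id"].isin(gene_set).sum())
    n_matched = len(matched)
    coverage = (
        float((matched["overall_rank"] <= 5).sum() / n_matched)
        if n_matched
        else float("nan")
    )
    return ManeConcordance(
        records=len(mane),
        matched_genes=matched_genes,
        per_rank_counts=per_rank,
        unmatched_transcripts=len(mane) - n_matched,
        coverage_top5=coverage,
    )
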