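"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately avoid the implementation's vectorized code paths: plain
Python loops and sorted() only.
"""

from __future__ import annotations

import pandas as pd


def naive_ranks(tpm: pd.DataFrame, annotation: pd.DataFrame, scope: str) -> pd.Series:
    """Per-gene ranks by (TPM desc, CDS desc, length desc, ID asc), via sorted()."""
    if scope == "overall":
        values = {t: float(tpm.loc[t].mean()) for t in tpm.index}
    else:
        values = {t: float(tpm.at[t, scope]) for t in tpm.index}
    ann = annotation.set_index("transcript_id")
    by_gene: dict[str, list[str]] = {}
    for tid in tpm.index:
        by_gene.setdefault(ann.at[tid, "gene_id"], []).append(tid)
    ranks: dict[str, int] = {}
    for tids in by_gene.values():
        order = sorted(
            tids,
            key=lambda t: (
                -values[t],
                -int(ann.at[t, "cds_length"]),
                -int(ann.at[t, "transcript_length"]),
                t,
            ),
        )
        for i, tid in enumerate(order, start=1):
            ranks[tid] = i
    return pd.Series(ranks)


def naive_gene_sums(tpm: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-gene per-tissue TPM sums via explicit loops."""
    ann = annotation.set_index("transcript_id")
    sums: dict[str, dict[str, float]] = {}
    for tid in tpm.index:
        gene = ann.at[tid, "gene_id"]
        row = sums.setdefault(gene, {c: 0.0 for c in tpm.columns})
        for col in tpm.columns:
            row[col] += float(tpm.at[tid, col])
    return pd.DataFrame.from_dict(sums, orient="index").sort_index()[list(tpm.columns)]


def naive_tissue_means(tpm: pd.DataFrame, sample_to_tissue: dict[str, str]) -> pd.DataFrame:
    """Per-tissue sample means via explicit loops."""
    tissues = sorted(set(sample_to_tissue.values()))
    out = {}
    for tissue in tissues:
        members = [s for s in tpm.columns if sample_to_tissue.get(s) == tissue]
        col = {}
        for tid in tpm.index:
            col[tid] = sum(float(tpm.at[tid, s]) for s in members) / len(members)
        out[tissue] = col
    return pd.DataFrame(out).loc[tpm.index]
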