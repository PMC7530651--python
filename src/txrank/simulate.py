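"""Synthetic GTEx-like TPM matrices with known ground truth.

Each gene draws an isoform count, per-isoform lengths/biotypes, a skewed
Dirichlet usage vector (the dominant-isoform structure), and a lognormal
gene-level TPM.  Per tissue the usage is perturbed by multiplicative
lognormal noise; in designated switch genes and tissues the promoted
isoform's usage is swapped with the currently dominant one, so the switch is
guaranteed whatever the noise level.  Everything is reproducible from the
seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from txrank.annotation import (
    ANNOTATION_COLUMNS,
    validate_annotation,
    write_annotation_gtf,
    write_annotation_tsv,
)
from txrank.expression import SampleMatrix, TissueMatrix, write_gct

NONCODING_BIOTYPES = ("processed_transcript", "retained_intron", "nonsense_mediated_decay")


@dataclass
class SimConfig:
    n_genes: int = 200
    # P(gene has k isoforms), k = 1..len(weights)
    isoform_count_distribution: tuple = (
        0.25, 0.20, 0.15, 0.12, 0.09, 0.07, 0.05, 0.03, 0.02, 0.02,
    )
    # usage skew; a gene with k isoforms uses the first k components.
    # The decaying tail keeps the dominant isoform above 50% and the top five
    # above 95% of gene expression even for 10-isoform genes.
    dirichlet_alpha: tuple = (8.0, 1.0, 0.5, 0.3, 0.2, 0.15, 0.12, 0.1, 0.08, 0.06)
    gene_expression_log_mean: float = 1.0
    gene_expression_log_sd: float = 1.0
    n_tissues: int = 54
    n_switch_genes: int = 0
    switch_tissues_per_gene: int = 1
    noncoding_isoform_fraction: float = 0.3
    zero_transcript_fraction: float = 0.05
    noise_sd: float = 0.0
    samples_per_tissue: int = 1
    sample_noise_sd: float = 0.0
    single_transcript_boost: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        weights = np.asarray(self.isoform_count_distribution, dtype=float)
        if (weights < 0).any() or not np.isclose(weights.sum(), 1.0):
            raise ValueError("isoform_count_distribution must be a probability vector")
        if len(self.dirichlet_alpha) < len(weights):
            raise ValueError("dirichlet_alpha must cover the maximum isoform count")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ValueError("dirichlet_alpha components must be positive")
        for name in ("noncoding_isoform_fraction", "zero_transcript_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.n_switch_genes > self.n_genes:
            raise ValueError("n_switch_genes exceeds n_genes")
        if self.n_tissues < 1:
            raise ValueError("n_tissues must be >= 1")
        if not 1 <= self.switch_tissues_per_gene <= self.n_tissues:
            raise ValueError("switch_tissues_per_gene out of range")
        if self.samples_per_tissue < 1:
            raise ValueError("samples_per_tissue must be >= 1")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    annotation: pd.DataFrame
    usage: pd.DataFrame  # baseline usage, transcript × tissue
    switch_genes: dict[str, list[tuple[str, str]]]  # gene -> [(tissue, promoted)]
    intended_rank1: dict[str, str]
    zeroed_transcripts: list[str]
    tissues: list[str]
    sample_map: pd.DataFrame | None = None


def _gene_id(i: int) -> str:
    return f"ENSG{i:011d}"


def _transcript_id(gene_index: int, isoform_index: int) -> str:
    return f"ENST{gene_index * 1000 + isoform_index:011d}"


def simulate(config: SimConfig) -> tuple[SampleMatrix | TissueMatrix, SimTruth]:
    """Generate a TPM matrix plus matching annotation and truth.

    Returns a :class:`TissueMatrix` when ``samples_per_tissue == 1`` (already
    collapsed), otherwise a :class:`SampleMatrix` whose sample map is in the
    truth object.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tissues = [f"tissue{i:03d}" for i in range(1, config.n_tissues + 1)]
    weights = np.asarray(config.isoform_count_distribution, dtype=float)
    k_values = rng.choice(np.arange(1, len(weights) + 1), size=config.n_genes, p=weights)

    ann_rows: list[dict] = []
    gene_levels: dict[str, float] = {}
    baseline_usage: dict[str, np.ndarray] = {}
    gene_transcripts: dict[str, list[str]] = {}
    intended_rank1: dict[str, str] = {}

    for gi, k in enumerate(k_values, start=1):
        gid = _gene_id(gi)
        k = int(k)
        if k == 1:
            u = np.array([1.0])
        else:
            u = rng.dirichlet(np.asarray(config.dirichlet_alpha[:k], dtype=float))
        dominant = int(np.argmax(u))
        tids = [_transcript_id(gi, j) for j in range(1, k + 1)]
        gene_transcripts[gid] = tids
        baseline_usage.update(dict(zip(tids, u)))
        for j, tid in enumerate(tids):
            if j == dominant:
                coding = True
            else:
                coding = rng.random() >= config.noncoding_isoform_fraction
            tx_len = int(rng.integers(500, 5001))
            cds_len = int(rng.integers(150, tx_len + 1)) if coding else 0
            ann_rows.append(
                {
                    "transcript_id": tid,
                    "gene_id": gid,
                    "gene_name": f"GENE{gi}",
                    "transcript_name": f"GENE{gi}-{j + 1:03d}",
                    "biotype": "protein_coding" if coding else str(
                        rng.choice(NONCODING_BIOTYPES)
                    ),
                    "transcript_length": tx_len,
                    "cds_length": cds_len,
                }
            )
        level = float(rng.lognormal(config.gene_expression_log_mean,
                                    config.gene_expression_log_sd))
        if k == 1:
            level *= config.single_transcript_boost
        gene_levels[gid] = level
        intended_rank1[gid] = tids[dominant]

    annotation = validate_annotation(pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS))

    # pick switch genes among multi-isoform genes; promote the runner-up isoform
    multi = [g for g in gene_transcripts if len(gene_transcripts[g]) >= 2]
    if config.n_switch_genes > len(multi):
        raise ValueError(
            f"requested {config.n_switch_genes} switch genes but only "
            f"{len(multi)} genes have >= 2 isoforms"
        )
    if config.n_switch_genes:
        switch_gene_ids = sorted(
            rng.choice(multi, size=config.n_switch_genes, replace=False).tolist()
        )
    else:
        switch_gene_ids = []
    switch_plan: dict[str, list[tuple[str, str]]] = {}
    for gid in switch_gene_ids:
        tids = gene_transcripts[gid]
        u = np.array([baseline_usage[t] for t in tids])
        order = np.argsort(-u)
        promoted = tids[int(order[1])]
        chosen = rng.choice(
            len(tissues), size=config.switch_tissues_per_gene, replace=False
        )
        switch_plan[gid] = [(tissues[int(t)], promoted) for t in sorted(chosen)]

    # assemble the transcript × tissue TPM matrix gene by gene
    all_tids = [t for g in gene_transcripts.values() for t in g]
    tpm = pd.DataFrame(0.0, index=pd.Index(all_tids, name="transcript_id"),
                       columns=tissues)
    usage_df = pd.DataFrame(0.0, index=tpm.index, columns=tissues)
    for gid, tids in gene_transcripts.items():
        u = np.array([baseline_usage[t] for t in tids])
        k = len(tids)
        switch_by_tissue = {t: promoted for t, promoted in switch_plan.get(gid, [])}
        for tissue in tissues:
            if config.noise_sd > 0 and k > 1:
                w = u * np.exp(config.noise_sd * rng.standard_normal(k))
                w = w / w.sum()
            else:
                w = u.copy()
            promoted = switch_by_tissue.get(tissue)
            if promoted is not None:
                p_idx = tids.index(promoted)
                top_idx = int(np.argmax(w))
                w[p_idx], w[top_idx] = w[top_idx], w[p_idx]
            usage_df.loc[tids, tissue] = w
            tpm.loc[tids, tissue] = gene_levels[gid] * w

    # silence a fraction of transcripts everywhere, never a truth-bearing one
    protected = set(intended_rank1.values())
    for plan in switch_plan.values():
        protected.update(promoted for _, promoted in plan)
    candidates = [t for t in all_tids if t not in protected]
    n_zero = min(int(round(config.zero_transcript_fraction * len(all_tids))),
                 len(candidates))
    zeroed = sorted(rng.choice(candidates, size=n_zero, replace=False).tolist()) \
        if n_zero else []
    if zeroed:
        tpm.loc[zeroed, :] = 0.0

    truth = SimTruth(
        annotation=annotation,
        usage=usage_df,
        switch_genes=switch_plan,
        intended_rank1=intended_rank1,
        zeroed_transcripts=zeroed,
        tissues=tissues,
    )

    if config.samples_per_tissue == 1:
        return TissueMatrix(tpm=tpm), truth

    sample_cols: dict[str, np.ndarray] = {}
    records = []
    for tissue in tissues:
        base = tpm[tissue].to_numpy()
        for s in range(1, config.samples_per_tissue + 1):
            sid = f"{tissue}-s{s:02d}"
            if config.sample_noise_sd > 0:
                noise = np.exp(config.sample_noise_sd
                               * rng.standard_normal(len(base)))
            else:
                noise = 1.0
            sample_cols[sid] = base * noise
            records.append({"sample": sid, "tissue": tissue})
    sample_tpm = pd.DataFrame(sample_cols, index=tpm.index)
    truth.sample_map = pd.DataFrame(records)
    return SampleMatrix(tpm=sample_tpm), truth


def write_fixture_bundle(
    matrix: SampleMatrix | TissueMatrix,
    truth: SimTruth,
    directory: str | Path,
    config: SimConfig | None = None,
) -> dict[str, Path]:
    """Write GCT + annotation (TSV and GTF) + sample map + truth JSON.

    The bundle is sufficient to exercise the CLI end-to-end from disk and to
    check recovered results against the generator's truth.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "gct": directory / "expression.gct",
        "annotation_tsv": directory / "annotation.tsv",
        "annotation_gtf": directory / "annotation.gtf",
        "truth": directory / "truth.json",
    }
    write_gct(matrix, paths["gct"])
    write_annotation_tsv(truth.annotation, paths["annotation_tsv"])
    write_annotation_gtf(truth.annotation, paths["annotation_gtf"])

    sample_map = truth.sample_map
    if sample_map is None:
        sample_map = pd.DataFrame(
            {"sample": truth.tissues, "tissue": truth.tissues}
        )
    paths["sample_map"] = directory / "sample_map.tsv"
    sample_map.to_csv(paths["sample_map"], sep="\t", index=False)

    truth_payload = {
        "tissues": truth.tissues,
        "intended_rank1": truth.intended_rank1,
        "switch_genes": {
            g: [[t, p] for t, p in plan] for g, plan in truth.switch_genes.items()
        },
        "zeroed_transcripts": truth.zeroed_transcripts,
        "config": asdict(config) if config is not None else None,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_payload, fh, indent=1)
    return paths
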