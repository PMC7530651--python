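import numpy as np
import pandas as pd
import pytest

from txrank.expression import TissueMatrix, filter_expressed
from txrank.ranking import build_rank_table
from txrank.simulate import SimConfig, simulate


ANNOTATION_COLUMNS = [
    "transcript_id", "gene_id", "gene_name", "transcript_name",
    "biotype", "transcript_length", "cds_length",
]


def make_annotation(rows):
    """Build an annotation frame from (tid, gid, biotype, tx_len, cds_len) tuples."""
    return pd.DataFrame(
        [
            {
                "transcript_id": tid,
                "gene_id": gid,
                "gene_name": f"NAME-{gid}",
                "transcript_name": f"NAME-{tid}",
                "biotype": biotype,
                "transcript_length": tx_len,
                "cds_length": cds_len,
            }
            for tid, gid, biotype, tx_len, cds_len in rows
        ],
        columns=ANNOTATION_COLUMNS,
    )


def random_dataset(rng, n_genes, tissues, max_isoforms=6, tie_fraction=0.2):
    """Random annotation + tissue matrix with engineered exact TPM ties."""
    ann_rows, tpm_rows, index = [], [], []
    for gi in range(1, n_genes + 1):
        gid = f"G{gi:05d}"
        k = int(rng.integers(1, max_isoforms + 1))
        tie = rng.random() < tie_fraction and k >= 2
        base = np.round(rng.gamma(2.0, 5.0, size=(k, len(tissues))), 3)
        if tie:
            base[1] = base[0]  # exact tie in every tissue -> tie-break cascade
        for j in range(k):
            tid = f"T{gi:05d}x{j + 1:02d}"
            cds = int(rng.integers(0, 900))
            if tie and j == 1:
                cds = int(base[0].sum()) % 900  # occasionally equals sibling's
            ann_rows.append(
                (tid, gid, "protein_coding" if j == 0 else "retained_intron",
                 int(rng.integers(900, 5000)), cds)
            )
            index.append(tid)
            tpm_rows.append(base[j])
    annotation = make_annotation(ann_rows)
    tpm = pd.DataFrame(np.array(tpm_rows), index=pd.Index(index, name="transcript_id"),
                       columns=tissues)
    return annotation, TissueMatrix(tpm=tpm)


@pytest.fixture(scope="session")
def sim_small():
    config = SimConfig(n_genes=60, n_tissues=8, n_switch_genes=6, seed=11)
    matrix, truth = simulate(config)
    return config, matrix, truth


@pytest.fixture(scope="session")
def rank_table_small(sim_small):
    _, matrix, truth = sim_small
    expressed, _ = filter_expressed(matrix)
    return build_rank_table(expressed, truth.annotation)


@pytest.fixture(scope="session")
def sim_default():
    """Default synthetic profile (skewed Dirichlet, 54 tissues)."""
    config = SimConfig(n_genes=400, seed=7)
    matrix, truth = simulate(config)
    expressed, _ = filter_expressed(matrix)
    return config, truth, build_rank_table(expressed, truth.annotation)
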