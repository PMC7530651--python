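import math

import numpy as np
import pandas as pd
import pytest

from txrank.expression import TissueMatrix, filter_expressed
from txrank.ranking import (
    build_rank_table,
    coding_noncoding_mwu,
    cv,
    dataset_summary,
    dominance_by_isoform_class,
    download_table,
    expression_fractions,
    gene_expression,
    percentage,
    rank_isoforms,
    rank_summary,
    tissue_rank_distribution,
    transcripts_per_gene,
)
from txrank.simulate import SimConfig, simulate

from conftest import make_annotation, random_dataset
from oracles import naive_gene_sums, naive_ranks


def matrix_of(rows, tissues):
    index = pd.Index(list(rows), name="transcript_id")
    return TissueMatrix(tpm=pd.DataFrame(list(rows.values()), index=index, columns=tissues))


class TestGeneExpression:
    def test_sum_of_isoforms(self):
        ann = make_annotation([("T1", "G1", "protein_coding", 100, 50),
                               ("T2", "G1", "retained_intron", 80, 0)])
        matrix = matrix_of({"T1": [1.0, 2.0], "T2": [3.0, 4.0]}, ["a", "b"])
        ge = gene_expression(matrix, ann)
        assert list(ge.per_tissue.loc["G1"]) == [4.0, 6.0]
        assert ge.transcript_count["G1"] == 2

    def test_single_transcript_identity(self):
        ann = make_annotation([("T1", "G1", "protein_coding", 100, 50)])
        matrix = matrix_of({"T1": [1.5, 2.5]}, ["a", "b"])
        ge = gene_expression(matrix, ann)
        assert list(ge.per_tissue.loc["G1"]) == [1.5, 2.5]

    def test_orphan_transcript_error(self):
        ann = make_annotation([("T1", "G1", "protein_coding", 100, 50)])
        matrix = matrix_of({"T1": [1.0], "Torphan": [2.0]}, ["a"])
        with pytest.raises(ValueError, match="Torphan"):
            gene_expression(matrix, ann)

    def test_against_groupby_sum_oracle(self):
        rng = np.random.default_rng(1)
        ann, matrix = random_dataset(rng, n_genes=100, tissues=["x", "y", "z"])
        ge = gene_expression(matrix, ann)
        expected = naive_gene_sums(matrix.tpm, ann)
        pd.testing.assert_frame_equal(ge.per_tissue, expected,
                                      check_names=False, atol=1e-12)


class TestRankIsoforms:
    def test_strict_ordering(self):
        ann = make_annotation([("T1", "G1", "protein_coding", 100, 50),
                               ("T2", "G1", "protein_coding", 100, 50),
                               ("T3", "G1", "protein_coding", 100, 50)])
        matrix = matrix_of({"T1": [10.0], "T2": [2.0], "T3": [1.0]}, ["a"])
        ranks = rank_isoforms(matrix, ann)
        assert list(ranks[["T1", "T2", "T3"]]) == [1, 2, 3]

    def test_cds_length_breaks_tpm_tie(self):
        ann = make_annotation([("T1", "G1", "protein_coding", 500, 150),
                               ("T2", "G1", "protein_coding", 500, 300)])
        matrix = matrix_of({"T1": [5.0], "T2": [5.0]}, ["a"])
        ranks = rank_isoforms(matrix, ann)
        assert ranks["T2"] == 1  # longer CDS wins
        assert ranks["T1"] == 2

    def test_transcript_length_breaks_remaining_tie(self):
        # gene all-zero in the tissue, cds 0/0 -> longer transcript ranks first
        ann = make_annotation([("T1", "G1", "retained_intron", 400, 0),
                               ("T2", "G1", "retained_intron", 500, 0)])
        matrix = matrix_of({"T1": [0.0, 1.0], "T2": [0.0, 0.5]}, ["a", "b"])
        ranks_a = rank_isoforms(matrix, ann, scope="a")
        assert ranks_a["T2"] == 1
        assert ranks_a["T1"] == 2

    def test_transcript_id_final_tiebreak(self):
        ann = make_annotation([("T2", "G1", "protein_coding", 500, 100),
                               ("T1", "G1", "protein_coding", 500, 100)])
        matrix = matrix_of({"T2": [1.0], "T1": [1.0]}, ["a"])
        ranks = rank_isoforms(matrix, ann)
        assert ranks["T1"] == 1  # lexicographically smaller ID

    def test_against_naive_sort_oracle(self):
        rng = np.random.default_rng(2)
        tissues = ["t1", "t2", "t3", "t4"]
        ann, matrix = random_dataset(rng, n_genes=200, tissues=tissues)
        for scope in ["overall", *tissues]:
            got = rank_isoforms(matrix, ann, scope)
            expected = naive_ranks(matrix.tpm, ann, scope)
            assert got.sort_index().equals(expected.sort_index().astype(int)), scope

    def test_unknown_scope(self):
        ann = make_annotation([("T1", "G1", "protein_coding", 100, 50)])
        matrix = matrix_of({"T1": [1.0]}, ["a"])
        with pytest.raises(KeyError):
            rank_isoforms(matrix, ann, scope="nope")


class TestExpressionFractions:
    def test_simple_fraction(self):
        ann = make_annotation([("T1", "G1", "protein_coding", 100, 50),
                               ("T2", "G1", "retained_intron", 80, 0)])
        matrix = matrix_of({"T1": [9.0], "T2": [3.0]}, ["a"])
        ge = gene_expression(matrix, ann)
        frac = expression_fractions(matrix, ge, ann)
        assert frac["T1"] == pytest.approx(0.75)

    def test_single_transcript_gene_fraction_one(self):
        ann = make_annotation([("T1", "G1", "protein_coding", 100, 50)])
        matrix = matrix_of({"T1": [4.0, 0.0]}, ["a", "b"])
        ge = gene_expression(matrix, ann)
        assert expression_fractions(matrix, ge, ann, "a")["T1"] == 1.0
        assert math.isnan(expression_fractions(matrix, ge, ann, "b")["T1"])

    def test_fractions_sum_to_one_across_genes(self):
        rng = np.random.default_rng(3)
        ann, matrix = random_dataset(rng, n_genes=500, tissues=["a", "b"])
        matrix, _ = filter_expressed(matrix)
        ann = ann[ann["transcript_id"].isin(matrix.tpm.index)]
        ge = gene_expression(matrix, ann)
        for scope in ("overall", "a", "b"):
            frac = expression_fractions(matrix, ge, ann, scope)
            genes = ann.set_index("transcript_id").loc[frac.index, "gene_id"]
            sums = frac.groupby(genes.to_numpy()).sum()
            gene_tpm = ge.overall_mean_tpm if scope == "overall" else ge.per_tissue[scope]
            positive = gene_tpm[gene_tpm > 0].index
            assert np.allclose(sums.loc[positive], 1.0, atol=1e-9)


class TestCv:
    def test_constant_vector(self):
        assert cv([5, 5, 5, 5]) == 0.0

    def test_closed_form_two_values(self):
        # stdev(2,4) = sqrt(2), mean = 3
        assert cv([2, 4]) == pytest.approx(math.sqrt(2) / 3, abs=1e-12)
        assert cv([2, 4]) == pytest.approx(0.4714, abs=1e-4)

    def test_degenerate_cases(self):
        assert math.isnan(cv([0.0, 0.0, 0.0]))
        assert math.isnan(cv([7.0]))


class TestRankSummary:
    @pytest.fixture()
    def two_gene_table(self):
        ann = make_annotation([("T1", "G1", "protein_coding", 100, 50),
                               ("T2", "G1", "retained_intron", 80, 0),
                               ("T3", "G2", "protein_coding", 100, 60)])
        matrix = matrix_of({"T1": [10.0], "T2": [5.0], "T3": [20.0]}, ["a"])
        return build_rank_table(matrix, ann)

    def test_class_means(self, two_gene_table):
        means = rank_summary(two_gene_table, max_rank=10)
        assert means[1] == pytest.approx(15.0)  # (10 + 20) / 2
        assert means[2] == pytest.approx(5.0)

    def test_empty_rank_class_absent(self, two_gene_table):
        means = rank_summary(two_gene_table, max_rank=10)
        assert 3 not in means.index

    def test_exclude_single_transcript(self, two_gene_table):
        means = rank_summary(two_gene_table, max_rank=10, exclude_single_transcript=True)
        assert means[1] == pytest.approx(10.0)  # G2 (single isoform) excluded

    def test_against_filtered_mean_oracle(self, rank_table_small):
        means = rank_summary(rank_table_small, max_rank=10)
        df = rank_table_small.summary
        for r in means.index:
            rows = [v for v, rr in zip(df["overall_mean_tpm"], df["overall_rank"]) if rr == r]
            assert means[r] == pytest.approx(sum(rows) / len(rows))


class TestDominanceByClass:
    def test_single_transcript_class_is_one(self, rank_table_small):
        table = dominance_by_isoform_class(rank_table_small)
        assert table.loc[1, 1] == pytest.approx(1.0)

    def test_two_isoform_class_conserves(self, rank_table_small):
        table = dominance_by_isoform_class(rank_table_small)
        if not math.isnan(table.loc[2, 1]):
            assert table.loc[2, 1] + table.loc[2, 2] == pytest.approx(1.0, abs=1e-9)

    def test_dirichlet_order_statistic_recovery(self):
        # all genes have 3 isoforms with Dirichlet(8,1,1) usage and no noise:
        # the class-3 rank1 mean fraction estimates E[max(Dirichlet(8,1,1))]
        config = SimConfig(
            n_genes=2000,
            isoform_count_distribution=(0.0, 0.0, 1.0),
            dirichlet_alpha=(8.0, 1.0, 1.0),
            n_tissues=3,
            zero_transcript_fraction=0.0,
            seed=21,
        )
        matrix, truth = simulate(config)
        table = build_rank_table(matrix, truth.annotation)
        got = dominance_by_isoform_class(table, max_class=3).loc[3, 1]
        oracle_rng = np.random.default_rng(99)  # independent Monte-Carlo oracle
        draws = oracle_rng.dirichlet((8.0, 1.0, 1.0), size=20000).max(axis=1)
        assert got == pytest.approx(draws.mean(), abs=4 * draws.std() / np.sqrt(2000))


class TestTissueRankDistribution:
    def test_sole_isoform_everywhere(self):
        ann = make_annotation([("T1", "G1", "protein_coding", 100, 50)])
        matrix = matrix_of({"T1": [3.0, 4.0]}, ["a", "b"])
        table = build_rank_table(matrix, ann)
        dist = tissue_rank_distribution(table, max_rank=1)
        assert (dist[1] == 1.0).all()

    def test_switch_tissue_dips(self):
        config = SimConfig(n_genes=150, n_tissues=12, n_switch_genes=8,
                           switch_tissues_per_gene=1, seed=13)
        matrix, truth = simulate(config)
        expressed, _ = filter_expressed(matrix)
        table = build_rank_table(expressed, truth.annotation)
        dist = tissue_rank_distribution(table)
        switch_tissue_counts = pd.Series(
            [t for plan in truth.switch_genes.values() for t, _ in plan]
        ).value_counts()
        hot = switch_tissue_counts.idxmax()
        cold = [t for t in truth.tissues if t not in switch_tissue_counts.index]
        assert cold, "need at least one tissue without injected switches"
        assert dist.loc[hot, 1] < min(dist.loc[c, 1] for c in cold)

    def test_per_tissue_fraction_conservation(self, rank_table_small):
        frac = rank_table_small.tissue_fraction
        genes = rank_table_small.summary["gene_id"]
        for tissue in rank_table_small.tissues:
            sums = frac[tissue].groupby(genes.to_numpy()).sum()
            assert np.allclose(sums.dropna(), 1.0, atol=1e-9)

    def test_per_tissue_label_mode(self, rank_table_small):
        dist = tissue_rank_distribution(rank_table_small, max_rank=1,
                                        label_mode="per_tissue")
        # per-tissue rank1 is each tissue's max-fraction isoform: mean >= overall labeling
        overall = tissue_rank_distribution(rank_table_small, max_rank=1)
        assert (dist[1] >= overall[1] - 1e-12).all()


class TestReportingRatios:
    def test_paper_ratio_342(self):
        assert transcripts_per_gene(199324, 58219) == 3.42

    def test_paper_ratio_743(self):
        assert transcripts_per_gene(145571, 19591) == 7.43

    def test_identity(self):
        assert transcripts_per_gene(10, 10) == 1.00

    def test_zero_genes(self):
        with pytest.raises(ValueError):
            transcripts_per_gene(5, 0)

    def test_percentage_rounding_half_up(self):
        assert percentage(1, 8, 1) == 12.5
        assert percentage(25, 1000, 1) == 2.5
        assert percentage(145571, 194146, 1) == 75.0


class TestDeterminism:
    def test_rank_table_byte_identical(self, tmp_path, sim_small):
        _, matrix, truth = sim_small
        expressed, _ = filter_expressed(matrix)
        a = build_rank_table(expressed, truth.annotation)
        b = build_rank_table(expressed, truth.annotation)
        a.save(tmp_path / "a")
        b.save(tmp_path / "b")
        for name in ("summary.tsv", "tissue_rank.tsv", "tissue_tpm.tsv",
                     "tissue_fraction.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()


def test_coding_noncoding_mwu_direction(sim_default):
    _, _, table = sim_default
    result = coding_noncoding_mwu(table)
    assert result.pvalue < 0.05
    df = table.summary
    coding_genes = df.loc[df["biotype"] == "protein_coding", "gene_id"].unique()
    sub = df[df["gene_id"].isin(coding_genes)]
    assert sub.loc[sub["biotype"] == "protein_coding", "overall_mean_tpm"].mean() > \
        sub.loc[sub["biotype"] != "protein_coding", "overall_mean_tpm"].mean()


def test_download_table_schema(rank_table_small):
    table = download_table(rank_table_small)
    assert list(table.columns) == [
        "gene_id", "transcript_id", "gene_name", "transcript_name",
        "transcript_count", "transcript_tpm", "gene_tpm",
        "expression_percentage", "biotype", "transcript_length", "cds_length",
    ]
    assert len(table) == len(rank_table_small.summary)


def test_dataset_summary_bookkeeping(sim_small):
    _, matrix, truth = sim_small
    summary = dataset_summary(matrix, truth.annotation)
    assert summary.loc["all", "transcripts"] == len(matrix.tpm)
    removed = summary.loc["all", "removed_zero_transcripts"]
    assert summary.loc["expressed", "transcripts"] == len(matrix.tpm) - removed
    assert removed == len(truth.zeroed_transcripts)
    assert summary.loc["expressed_protein_coding", "transcripts"] <= \
        summary.loc["expressed", "transcripts"]
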