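"""FPKM fold-change, volcano, and cluster-direction checks."""

import numpy as np
import pandas as pd
import pytest

from fluxprot.expression import (
    class_percentages,
    cluster_direction_summary,
    fold_change_table,
    log2_fold_change,
    match_genes_to_proteins,
    round_half_away,
    validate_ontology_map,
    volcano_classify,
)


def make_expression(genes, stage_means, n_rep=4, noise=0.0, seed=0):
    """Long-format FPKM table with per-stage means per gene."""
    rng = np.random.default_rng(seed)
    rows = []
    for stage, means in stage_means.items():
        for g, mean in zip(genes, means):
            for rep in range(1, n_rep + 1):
                val = mean * (1 + noise * rng.standard_normal()) if noise else mean
                rows.append({"gene_id": g, "stage": stage, "replicate": rep, "fpkm": max(val, 0.0)})
    return pd.DataFrame(rows)


class TestLog2FoldChange:
    def test_equal_means_zero(self):
        assert log2_fold_change([3.0, 5.0], [4.0, 4.0]) == 0.0

    def test_fourfold_is_about_two(self):
        assert log2_fold_change([40.0], [10.0]) == pytest.approx(2.0, abs=0.02)

    def test_zero_vs_zero_is_zero(self):
        assert log2_fold_change([0.0, 0.0], [0.0]) == 0.0

    def test_requires_replicates(self):
        with pytest.raises(ValueError):
            log2_fold_change([], [1.0])


class TestRounding:
    @pytest.mark.parametrize(
        "value, expected",
        [(71.05, 71.1), (14.85, 14.9), (-71.05, -71.1), (4.72, 4.7)],
    )
    def test_half_away_from_zero(self, value, expected):
        assert round_half_away(value, 1) == pytest.approx(expected)

    def test_class_percentages_sum_near_100(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            counts = rng.integers(0, 5000, size=3)
            if counts.sum() == 0:
                continue
            pcts = class_percentages(*counts)
            assert sum(pcts) == pytest.approx(100.0, abs=0.2)


class TestVolcanoClassify:
    def test_boundary_p_is_significant(self):
        df = pd.DataFrame(
            {
                "stage": ["s"] * 3,
                "log2_fc": [1.0, -1.0, 1.0],
                "p_value": [0.05, 0.05, 0.051],
            }
        )
        v = volcano_classify(df, alpha=0.05)
        assert (v.n_up, v.n_down, v.n_ns) == (1, 1, 1)

    def test_empty_input(self):
        df = pd.DataFrame({"stage": [], "log2_fc": [], "p_value": []})
        v = volcano_classify(df)
        assert (v.n_up, v.n_down, v.n_ns) == (0, 0, 0)

    def test_missing_p_counts_as_ns(self):
        df = pd.DataFrame(
            {"stage": ["s"] * 2, "log2_fc": [2.0, 2.0], "p_value": [np.nan, 0.001]}
        )
        v = volcano_classify(df)
        assert (v.n_up, v.n_ns) == (1, 1)

    def test_counts_sum_to_total(self):
        df = pd.DataFrame(
            {
                "stage": ["s"] * 100,
                "log2_fc": np.linspace(-2, 2, 100),
                "p_value": np.linspace(0.0, 1.0, 100),
            }
        )
        v = volcano_classify(df)
        assert v.n_up + v.n_down + v.n_ns == v.n_total == 100


class TestFoldChangeTable:
    def test_planted_fold_change_and_significance(self):
        genes = [f"g{i}" for i in range(6)]
        case = [40.0, 10.0, 10.0, 5.0, 80.0, 10.0]
        ctrl = [10.0] * 6
        expr = make_expression(
            genes, {"Stage": case, "Control": ctrl}, n_rep=5, noise=0.05, seed=1
        )
        fc = fold_change_table(expr, "Stage", "Control")
        byg = fc.set_index("gene_id")
        assert byg.loc["g0", "log2_fc"] == pytest.approx(2.0, abs=0.2)
        assert byg.loc["g0", "class"] == "up"
        assert byg.loc["g3", "class"] == "down"
        assert byg.loc["g1", "class"] == "ns"

    def test_single_replicate_flagged_ns(self):
        expr = make_expression(["g"], {"Stage": [40.0], "Control": [10.0]}, n_rep=1)
        fc = fold_change_table(expr, "Stage", "Control")
        assert fc["p_missing"].iloc[0]
        assert fc["class"].iloc[0] == "ns"

    def test_missing_stage_rejected(self):
        expr = make_expression(["g"], {"Stage": [1.0]})
        with pytest.raises(ValueError):
            fold_change_table(expr, "Stage", "Control")


class TestOntologyMatching:
    def test_duplicate_mapping_rejected(self):
        bad = pd.DataFrame(
            {
                "accession": ["P1", "P1"],
                "gene_id": ["gA", "gB"],
                "cluster": ["X", "X"],
            }
        )
        with pytest.raises(ValueError):
            validate_ontology_map(bad)

    def test_pairing_and_unmatched_reporting(self):
        prot = pd.DataFrame(
            {"protein_accession": ["P1", "P2", "P3"], "log2_fc_fsr": [1.0, -1.0, 0.5]}
        )
        onto = pd.DataFrame(
            {
                "accession": ["P1", "P2"],
                "gene_id": ["gA", "gB"],
                "cluster": ["X", "Y"],
            }
        )
        genes = pd.DataFrame({"gene_id": ["gA"], "log2_fc": [2.0]})
        paired, unmatched = match_genes_to_proteins(prot, onto, genes)
        assert len(paired) == 1
        assert paired.iloc[0]["gene_id"] == "gA"
        assert set(unmatched["protein_accession"]) == {"P2", "P3"}
        assert len(paired) <= min(len(prot), len(genes))

    def test_empty_map_reports_all_unmatched(self):
        prot = pd.DataFrame({"protein_accession": ["P1"], "log2_fc_fsr": [1.0]})
        onto = pd.DataFrame({"accession": [], "gene_id": [], "cluster": []})
        genes = pd.DataFrame({"gene_id": [], "log2_fc": []})
        paired, unmatched = match_genes_to_proteins(prot, onto, genes)
        assert paired.empty and len(unmatched) == 1

    def test_order_independence(self):
        prot = pd.DataFrame(
            {"protein_accession": ["P2", "P1"], "log2_fc_fsr": [-1.0, 1.0]}
        )
        onto = pd.DataFrame(
            {"accession": ["P1", "P2"], "gene_id": ["gA", "gB"], "cluster": ["X", "Y"]}
        )
        genes = pd.DataFrame({"gene_id": ["gB", "gA"], "log2_fc": [0.5, 2.0]})
        a, _ = match_genes_to_proteins(prot, onto, genes)
        b, _ = match_genes_to_proteins(
            prot.iloc[::-1].reset_index(drop=True), onto, genes
        )
        pd.testing.assert_frame_equal(a, b)


class TestClusterDirectionSummary:
    def test_unanimous_cluster_closed_form(self):
        df = pd.DataFrame({"cluster": ["glyco"] * 12, "delta": [1.0] * 12})
        out = cluster_direction_summary(df, "delta")
        row = out.iloc[0]
        assert (row["n_increased"], row["n_decreased"]) == (12, 0)
        assert row["p_value"] == pytest.approx(2.0**-12)

    def test_split_and_singleton(self):
        df = pd.DataFrame(
            {"cluster": ["a", "a", "b"], "delta": [1.0, -1.0, 2.0]}
        )
        out = cluster_direction_summary(df, "delta").set_index("cluster")
        assert out.loc["a", "p_value"] == pytest.approx(0.75)
        assert out.loc["b", "p_value"] == pytest.approx(0.5)

    def test_ties_excluded_from_denominator(self):
        df = pd.DataFrame({"cluster": ["c"] * 4, "delta": [1.0, 1.0, 0.0, -1.0]})
        row = cluster_direction_summary(df, "delta").iloc[0]
        assert row["n_ties"] == 1
        assert row["n_increased"] + row["n_decreased"] == 3

    def test_planted_shifts_detected_with_high_power(self):
        """Clusters shifted by 1.5 member-SD with >=12 members are flagged
        at alpha 0.05 in >=90% of replicates; null clusters rarely are."""
        rng = np.random.default_rng(2024)
        n_rep = 200
        hits_planted = 0
        hits_null = 0
        for _ in range(n_rep):
            planted = rng.normal(1.5, 1.0, size=12)
            null = rng.normal(0.0, 1.0, size=12)
            df = pd.DataFrame(
                {
                    "cluster": ["planted"] * 12 + ["null"] * 12,
                    "delta": np.concatenate([planted, null]),
                }
            )
            out = cluster_direction_summary(df, "delta").set_index("cluster")
            hits_planted += out.loc["planted", "p_value"] < 0.05
            hits_null += out.loc["null", "p_value"] < 0.05
        assert hits_planted / n_rep >= 0.9
        assert hits_null / n_rep <= 0.2
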