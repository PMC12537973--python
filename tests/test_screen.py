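"""Differential-dependency statistics, selection and filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from depscreen import (
    CellLineGrouping,
    DependencyMatrix,
    GeneSetCollection,
    SelectionConfig,
    compute_gene_stats,
    essentiality_filter,
    run_screen,
    select_top_candidates,
)
from depscreen.simulate import ScreenSimConfig, gen_dependency_matrix, gen_gene_sets

from conftest import welch_oracle


def _dep_from_rows(rows: dict, target, background):
    cols = list(target) + list(background)
    scores = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    dep = DependencyMatrix(scores=scores)
    grouping = CellLineGrouping(
        mapping={**{c: "AML" for c in target}, **{c: "OTHER" for c in background}},
        target_label="AML",
    )
    return dep, grouping


class TestComputeGeneStats:
    def test_median_arithmetic(self, tiny_dependency):
        dep, grouping = tiny_dependency
        stats = compute_gene_stats(dep, grouping).set_index("gene")
        row = stats.loc["SEL1"]
        assert row["median_target"] == pytest.approx(-0.9)
        assert row["median_background"] == pytest.approx(0.0)
        assert row["median_diff"] == pytest.approx(-0.9)
        # invariant: stored difference of stored medians
        assert row["median_diff"] == row["median_target"] - row["median_background"]

    def test_welch_p_matches_closed_form(self, tiny_dependency):
        dep, grouping = tiny_dependency
        stats = compute_gene_stats(dep, grouping).set_index("gene")
        t_ref, p_ref = welch_oracle([-0.9, -0.8, -1.0], [0.0, 0.1, -0.1])
        assert stats.loc["SEL1", "t_stat"] == pytest.approx(t_ref, rel=1e-12)
        assert stats.loc["SEL1", "p_value"] == pytest.approx(p_ref, rel=1e-12)
        assert stats.loc["SEL1", "neg_log10_p"] == pytest.approx(
            -np.log10(p_ref), rel=1e-12
        )

    def test_student_variant_matches_scipy(self, tiny_dependency):
        from scipy.stats import ttest_ind

        dep, grouping = tiny_dependency
        stats = compute_gene_stats(dep, grouping, equal_var=True).set_index("gene")
        t_ref, p_ref = ttest_ind([-0.9, -0.8, -1.0], [0.0, 0.1, -0.1], equal_var=True)
        assert stats.loc["SEL1", "t_stat"] == pytest.approx(t_ref, rel=1e-12)
        assert stats.loc["SEL1", "p_value"] == pytest.approx(p_ref, rel=1e-12)

    def test_degenerate_constant_gene(self, tiny_dependency):
        dep, grouping = tiny_dependency
        stats = compute_gene_stats(dep, grouping).set_index("gene")
        row = stats.loc["FLAT1"]
        assert row["median_diff"] == 0
        assert row["t_stat"] == 0
        assert row["p_value"] == 1

    def test_min_group_size_exclusion(self):
        dep, grouping = _dep_from_rows(
            {"G1": [-0.9, np.nan, np.nan, 0.0, 0.1, -0.1]},
            ["T1", "T2", "T3"],
            ["B1", "B2", "B3"],
        )
        stats = compute_gene_stats(dep, grouping, min_group_size=3).set_index("gene")
        assert np.isnan(stats.loc["G1", "p_value"])
        assert stats.loc["G1", "n_target_used"] == 1

    def test_orientation_flip_negates_median_diff(self, tiny_dependency):
        dep, grouping = tiny_dependency
        flipped = DependencyMatrix(scores=-dep.scores)
        s1 = compute_gene_stats(dep, grouping)
        s2 = compute_gene_stats(flipped, grouping)
        np.testing.assert_array_equal(
            s1["median_diff"].to_numpy(), -s2["median_diff"].to_numpy()
        )

    @given(st.floats(min_value=-5, max_value=5, allow_nan=False))
    def test_location_invariance(self, c):
        scores = pd.DataFrame(
            np.random.default_rng(7).normal(0, 0.3, (4, 8)),
            index=list("ABCD"),
            columns=[f"L{i}" for i in range(8)],
        )
        grouping = CellLineGrouping(
            mapping={f"L{i}": ("AML" if i < 4 else "X") for i in range(8)},
            target_label="AML",
        )
        s1 = compute_gene_stats(DependencyMatrix(scores=scores), grouping)
        s2 = compute_gene_stats(DependencyMatrix(scores=scores + c), grouping)
        np.testing.assert_allclose(
            s1["median_diff"], s2["median_diff"], atol=1e-10
        )
        np.testing.assert_allclose(s1["t_stat"], s2["t_stat"], atol=1e-8)

    def test_empty_group_raises(self, tiny_dependency):
        dep, _ = tiny_dependency
        with pytest.raises(ValueError):
            compute_gene_stats(
                dep,
                CellLineGrouping(mapping={"Z1": "AML", "Z2": "X"}, target_label="AML"),
            )


def _stats_table(entries):
    """entries: gene -> (median_diff, p)."""
    return pd.DataFrame(
        {
            "gene": list(entries),
            "median_target": [v[0] for v in entries.values()],
            "median_background": 0.0,
            "median_diff": [v[0] for v in entries.values()],
            "t_stat": 0.0,
            "p_value": [v[1] for v in entries.values()],
            "neg_log10_p": 0.0,
            "n_target_used": 5,
            "n_background_used": 5,
        }
    )


class TestSelectTopCandidates:
    ENTRIES = {
        "g1": (-0.5, 0.001),
        "g2": (0.2, 0.0001),
        "g3": (-0.1, 0.01),
        "g4": (-0.3, 0.01),
    }

    def test_sign_filter_and_tie_break(self):
        got = select_top_candidates(_stats_table(self.ENTRIES), SelectionConfig(top_k=2))
        assert got == ["g1", "g4"]

    def test_k_exceeding_eligible_returns_all(self):
        got = select_top_candidates(
            _stats_table(self.ENTRIES), SelectionConfig(top_k=10)
        )
        assert got == ["g1", "g4", "g3"]

    def test_no_negative_diff_gives_empty(self):
        table = _stats_table({"a": (0.1, 0.001), "b": (0.0, 0.01)})
        assert select_top_candidates(table, SelectionConfig(top_k=5)) == []

    @given(st.integers(min_value=1, max_value=6), st.integers(min_value=1, max_value=6))
    def test_prefix_property(self, k1, k2):
        k1, k2 = min(k1, k2), max(k1, k2)
        table = _stats_table(
            {f"g{i}": (-0.1 * (i + 1), 0.01 * (i % 3 + 1)) for i in range(6)}
        )
        short = select_top_candidates(table, SelectionConfig(top_k=k1))
        long = select_top_candidates(table, SelectionConfig(top_k=k2))
        assert long[: len(short)] == short


class TestEssentialityFilter:
    CFG = SelectionConfig()

    @pytest.mark.parametrize(
        "median_target,median_background,kept",
        [
            (-0.85, -0.2, True),  # both strict inequalities hold
            (-0.5, -0.2, False),  # boundary excluded by strict < -0.5
            (-0.9, -0.6, False),  # background itself essential
            (-0.9, -0.5, False),  # background boundary excluded by strict > -0.5
        ],
    )
    def test_dual_threshold(self, median_target, median_background, kept):
        table = pd.DataFrame(
            {
                "gene": ["g"],
                "median_target": [median_target],
                "median_background": [median_background],
                "median_diff": [median_target - median_background],
                "t_stat": [0.0],
                "p_value": [0.01],
                "neg_log10_p": [2.0],
                "n_target_used": [5],
                "n_background_used": [5],
            }
        )
        out = essentiality_filter(["g"], table, self.CFG)
        assert (len(out) == 1) is kept

    def test_unknown_gene_named_in_error(self):
        table = _stats_table({"g1": (-0.9, 0.01)})
        with pytest.raises(KeyError, match="gX"):
            essentiality_filter(["g1", "gX"], table, self.CFG)

    def test_ranks_are_contiguous_and_p_ordered(self):
        table = _stats_table(
            {"a": (-0.9, 0.03), "b": (-0.8, 0.01), "c": (-0.7, 0.02)}
        )
        table["median_background"] = 0.0
        out = essentiality_filter(["a", "b", "c"], table, self.CFG)
        assert list(out["rank"]) == [1, 2, 3]
        assert list(out["gene"]) == ["b", "c", "a"]


class TestRunScreen:
    def test_recovers_planted_genes_small(self):
        cfg = ScreenSimConfig(
            seed=42, n_genes=500, n_background_lines=100,
            n_planted_selective=10, n_common_essential=20,
        )
        dep, grouping, truth = gen_dependency_matrix(cfg)
        sets = gen_gene_sets(truth, n_sets=15, set_size=25, seed=42)
        report = run_screen(dep, grouping, sets, SelectionConfig(top_k=50))
        planted = set(truth.genes_of_class("planted_selective"))
        recovered = planted & set(report.final_candidates["gene"])
        assert len(recovered) >= 9

    def test_empty_gene_sets_falls_back_to_top_k(self, tiny_dependency):
        dep, grouping = tiny_dependency
        report = run_screen(
            dep, grouping, GeneSetCollection(), SelectionConfig(top_k=2)
        )
        assert report.enrichment.empty
        assert set(report.final_candidates["gene"]) <= set(report.top_candidates)
        assert "SEL1" in set(report.final_candidates["gene"])

    def test_stage_counts_monotone(self):
        cfg = ScreenSimConfig(
            seed=3, n_genes=300, n_background_lines=60,
            n_planted_selective=5, n_common_essential=10,
        )
        dep, grouping, truth = gen_dependency_matrix(cfg)
        sets = gen_gene_sets(truth, n_sets=8, set_size=20, seed=3)
        report = run_screen(dep, grouping, sets, SelectionConfig(top_k=30))
        c = report.stage_counts
        assert c["genes_total"] >= c["genes_tested"] >= c["top_candidates"]
        assert c["top_candidates"] >= c["in_enriched_pathways"]
        assert c["in_enriched_pathways"] >= c["final_candidates"]

    def test_report_written_tables(self, tmp_path, tiny_dependency):
        dep, grouping = tiny_dependency
        report = run_screen(dep, grouping, GeneSetCollection(), SelectionConfig(top_k=2))
        report.write(tmp_path)
        for name in (
            "gene_stats.tsv",
            "top_candidates.tsv",
            "enrichment.tsv",
            "final_candidates.tsv",
            "stage_counts.tsv",
        ):
            assert (tmp_path / name).exists()
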