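"""Differential-dependency screen: per-gene statistics, top-K selection,
pathway refinement, and the dual essentiality-threshold filter.

The screen compares, gene by gene, the median dependency score of a target
entity's cell lines against the median of all other cell lines.  Genes are
ranked by the p-value of a two-sided two-sample t-test (Welch by default),
restricted to negative median differences (stronger dependency in the
target entity), cut to the top K, refined through pathway
over-representation, and finally filtered so that the target-group median
indicates essentiality (< -0.5 by convention) while the background median
does not (> -0.5).  Survivors are re-ranked by significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as _enrichment
from ._stats import floor_p, rowwise_t_test
from .io import CellLineGrouping, DependencyMatrix, GeneSetCollection, write_table

__all__ = [
    "SelectionConfig",
    "ScreenReport",
    "compute_gene_stats",
    "select_top_candidates",
    "essentiality_filter",
    "run_screen",
]

STATS_COLUMNS = [
    "gene",
    "median_target",
    "median_background",
    "median_diff",
    "t_stat",
    "p_value",
    "neg_log10_p",
    "n_target_used",
    "n_background_used",
]

CANDIDATE_COLUMNS = [
    "gene",
    "median_target",
    "median_background",
    "median_diff",
    "p_value",
    "rank",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Tunable thresholds of the selection workflow.

    top_k
        Number of most significant genes carried into pathway analysis.
    essential_threshold
        Dependency-score cutoff for essentiality; the filter keeps genes
        whose target-group median is strictly below it and whose
        background median is strictly above it.
    require_negative_diff
        Restrict the top-K step to genes more dependent in the target
        group (median difference strictly < 0).
    min_group_size
        Minimum non-missing scores per group for a gene to be tested.
    equal_var
        Use the pooled (Student) t-test instead of Welch.
    """

    top_k: int = 200
    essential_threshold: float = -0.5
    require_negative_diff: bool = True
    min_group_size: int = 3
    equal_var: bool = False

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not np.isfinite(self.essential_threshold):
            raise ValueError("essential_threshold must be finite")


def compute_gene_stats(
    dep: DependencyMatrix,
    grouping: CellLineGrouping,
    min_group_size: int = 3,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-gene group medians, median difference and two-sample t-test.

    For every gene, missing scores are dropped per group; the group median
    uses the mean-of-central-order-statistics convention for even sizes.
    Genes with fewer than ``min_group_size`` usable scores in either group
    are reported with missing statistics and are excluded downstream.
    A gene with zero variance and identical means in both groups is
    reported with t = 0, p = 1 (uninformative, not an error).
    """
    target_lines = [c for c in grouping.target if c in dep.scores.columns]
    background_lines = [c for c in grouping.background if c in dep.scores.columns]
    if not target_lines:
        raise ValueError("no target cell line present in the dependency matrix")
    if not background_lines:
        raise ValueError("no background cell line present in the dependency matrix")

    a = dep.scores[target_lines].to_numpy()
    b = dep.scores[background_lines].to_numpy()

    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    eligible = (n_a >= min_group_size) & (n_b >= min_group_size)

    med_a = np.full(len(dep.genes), np.nan)
    med_b = np.full(len(dep.genes), np.nan)
    if eligible.any():
        med_a[eligible] = np.nanmedian(a[eligible], axis=1)
        med_b[eligible] = np.nanmedian(b[eligible], axis=1)

    t, p, _, _ = rowwise_t_test(a, b, equal_var=equal_var,
                                min_per_group=min_group_size)
    t[~eligible] = np.nan
    p[~eligible] = np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        neg_log10 = -np.log10(floor_p(p))

    return pd.DataFrame(
        {
            "gene": dep.genes,
            "median_target": med_a,
            "median_background": med_b,
            "median_diff": med_a - med_b,
            "t_stat": t,
            "p_value": p,
            "neg_log10_p": neg_log10,
            "n_target_used": n_a,
            "n_background_used": n_b,
        }
    )


def _ordered(stats: pd.DataFrame) -> pd.DataFrame:
    """Significance ordering with a deterministic tie-break.

    Primary key ascending p; ties broken by more-negative median difference,
    then lexicographic gene symbol, so output is platform-independent.
    """
    return stats.sort_values(
        ["p_value", "median_diff", "gene"], ascending=[True, True, True],
        kind="mergesort",
    )


def select_top_candidates(stats: pd.DataFrame, cfg: SelectionConfig) -> list[str]:
    """The top-K most significant genes with median difference < 0.

    Returns all eligible genes when fewer than ``cfg.top_k`` remain.
    """
    if stats.empty:
        raise ValueError("stats table is empty")
    eligible = stats.dropna(subset=["p_value"])
    if cfg.require_negative_diff:
        eligible = eligible[eligible["median_diff"] < 0]
    return _ordered(eligible)["gene"].head(cfg.top_k).tolist()


def essentiality_filter(
    genes: list[str], stats: pd.DataFrame, cfg: SelectionConfig
) -> pd.DataFrame:
    """Keep genes essential in the target group but not in the background.

    Both inequalities are strict: target median < threshold AND background
    median > threshold; a gene sitting exactly on the threshold in either
    group is excluded.  Survivors are ranked by p ascending (same tie-break
    as the top-K step) with ranks 1..n.
    """
    indexed = stats.set_index("gene")
    unknown = [g for g in genes if g not in indexed.index]
    if unknown:
        raise KeyError(f"gene(s) absent from stats table: {', '.join(unknown)}")
    sub = indexed.loc[genes].reset_index()
    thr = cfg.essential_threshold
    kept = sub[(sub["median_target"] < thr) & (sub["median_background"] > thr)]
    kept = _ordered(kept).reset_index(drop=True)
    kept["rank"] = np.arange(1, len(kept) + 1)
    return kept[CANDIDATE_COLUMNS]


@dataclass
class ScreenReport:
    """Full output of one screen run, with per-stage survivor counts."""

    gene_stats: pd.DataFrame
    top_candidates: list[str]
    enrichment: pd.DataFrame
    pathway_genes: list[str]
    final_candidates: pd.DataFrame
    stage_counts: dict[str, int] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(self.gene_stats, outdir / "gene_stats.tsv")
        write_table(
            pd.DataFrame({"gene": self.top_candidates}), outdir / "top_candidates.tsv"
        )
        write_table(self.enrichment, outdir / "enrichment.tsv")
        write_table(self.final_candidates, outdir / "final_candidates.tsv")
        counts = pd.DataFrame(
            {"stage": list(self.stage_counts), "genes": list(self.stage_counts.values())}
        )
        write_table(counts, outdir / "stage_counts.tsv")


def run_screen(
    dep: DependencyMatrix,
    grouping: CellLineGrouping,
    gene_sets: GeneSetCollection,
    cfg: SelectionConfig = SelectionConfig(),
    alpha: float = 0.05,
    universe: str = "tested",
) -> ScreenReport:
    """Execute the full selection workflow on one dependency matrix.

    Stages: per-gene statistics -> top-K selection -> pathway
    over-representation on the top-K list -> restriction to genes inside
    enriched pathways -> dual essentiality-threshold filter.  With an empty
    gene-set collection the pathway stages are skipped and the filter is
    applied to the top-K list directly.

    ``universe`` chooses the over-representation background: ``"tested"``
    (all genes with computed statistics — the screen's sampling frame) or
    ``"gmt"`` (the union of gene-set members).
    """
    stats = compute_gene_stats(
        dep, grouping, min_group_size=cfg.min_group_size, equal_var=cfg.equal_var
    )
    tested = stats.dropna(subset=["p_value"])["gene"].tolist()
    top = select_top_candidates(stats, cfg)

    if len(gene_sets) == 0:
        enr_frame = _enrichment.results_to_frame([])
        pathway_genes: list[str] = []
        filter_input = top
    else:
        if universe == "tested":
            uni = tested
        elif universe == "gmt":
            uni = sorted({g for s in gene_sets for g in s.members})
        else:
            raise ValueError(f"unknown universe policy: {universe!r}")
        results = _enrichment.ora(top, gene_sets, uni)
        enr_frame = _enrichment.results_to_frame(results)
        pathway_genes = _enrichment.member_overlap(results, top, alpha=alpha)
        filter_input = pathway_genes

    final = essentiality_filter(filter_input, stats, cfg)
    if final.empty:
        warnings.warn("no gene survived the essentiality filter", stacklevel=2)

    n_enriched = int((enr_frame["adjusted_p"] < alpha).sum()) if len(enr_frame) else 0
    stage_counts = {
        "genes_total": len(stats),
        "genes_tested": len(tested),
        "top_candidates": len(top),
        "enriched_sets": n_enriched,
        "in_enriched_pathways": len(pathway_genes),
        "final_candidates": len(final),
    }
    return ScreenReport(
        gene_stats=stats,
        top_candidates=top,
        enrichment=enr_frame,
        pathway_genes=pathway_genes,
        final_candidates=final,
        stage_counts=stage_counts,
    )
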