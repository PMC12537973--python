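"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analyses assume:

* dependency scores — Gaussian noise around a class mean: 0 for
  non-essential genes, -1 for common-essential genes, and an
  entity-specific shift of ``-delta`` in target-entity cell lines only for
  planted selective genes (the signal the screen must recover);
* gene sets — one planted pathway enriched for the selective genes among
  random filler sets;
* read counts — negative-binomial with a planted signed log2 effect in the
  knockdown group for a subset of genes;
* survival — exponential event times whose hazard depends log-linearly on
  a standard-normal expression covariate, with independent exponential
  censoring.

Every generator is a pure function of its configuration including the
seed; per-gene random streams are spawned from the master seed so a gene's
draws do not depend on how many genes precede it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CellLineGrouping,
    ClinicalTable,
    DependencyMatrix,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    write_dependency_csv,
    write_expression_tsv,
    write_gmt,
    write_table,
)

__all__ = [
    "ScreenSimConfig",
    "TruthTable",
    "gen_dependency_matrix",
    "gen_gene_sets",
    "gen_counts",
    "gen_survival",
    "write_fixture_dir",
    "TARGET_ENTITY",
    "PLANTED_PATHWAY",
]

TARGET_ENTITY = "AML"
BACKGROUND_ENTITY = "OTHER"
PLANTED_PATHWAY = "PLANTED_PATHWAY"

GENE_CLASSES = ("nonessential", "common_essential", "planted_selective")


@dataclass(frozen=True)
class ScreenSimConfig:
    """Conditions of a simulated dependency screen.

    Defaults mirror the real screen's shape: 26 target-entity cell lines
    against a pan-cancer background (300 lines by default so end-to-end
    runs take seconds; the full 1124-line background is a parameter away),
    a planted target-specific dependency shift of delta = 0.8 score units
    and per-score noise sigma = 0.15, small against the one-unit gap
    between the non-essential (0) and essential (-1) class means.
    """

    seed: int = 0
    n_genes: int = 2000
    n_target_lines: int = 26
    n_background_lines: int = 300
    n_planted_selective: int = 10
    n_common_essential: int = 50
    delta: float = 0.8
    sigma: float = 0.15
    nonessential_mean: float = 0.0
    essential_mean: float = -1.0

    def __post_init__(self) -> None:
        if self.n_planted_selective + self.n_common_essential > self.n_genes:
            raise ValueError("planted + common-essential genes exceed n_genes")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if min(self.n_genes, self.n_target_lines, self.n_background_lines) < 1:
            raise ValueError("all dimensions must be >= 1")


@dataclass
class TruthTable:
    """Ground truth planted by the generators; the oracle for recovery tests."""

    gene_class: dict[str, str] = field(default_factory=dict)
    deg_effect: dict[str, float] = field(default_factory=dict)  # signed log2 effect
    survival_beta: float | None = None

    def genes_of_class(self, cls: str) -> list[str]:
        if cls not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {cls!r}")
        return [g for g, c in self.gene_class.items() if c == cls]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "class": c, "deg_effect": self.deg_effect.get(g, 0.0)}
            for g, c in self.gene_class.items()
        ]
        if not rows and self.deg_effect:
            rows = [
                {"gene": g, "class": "", "deg_effect": e}
                for g, e in self.deg_effect.items()
            ]
        return pd.DataFrame(rows, columns=["gene", "class", "deg_effect"])


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def gen_dependency_matrix(
    cfg: ScreenSimConfig,
) -> tuple[DependencyMatrix, CellLineGrouping, TruthTable]:
    """Simulate a gene x cell-line dependency matrix with planted signal.

    Gene classes are assigned by a seeded permutation so planted genes sit
    at random positions.  Scores are Normal(class mean, sigma); planted
    selective genes have mean ``-delta`` in target lines and the
    non-essential mean in background lines.
    """
    genes = _gene_names(cfg.n_genes)
    target_lines = [f"TL{i:04d}" for i in range(1, cfg.n_target_lines + 1)]
    background_lines = [f"BL{i:04d}" for i in range(1, cfg.n_background_lines + 1)]

    master = np.random.SeedSequence(cfg.seed)
    assign_rng = np.random.default_rng(master.spawn(1)[0])
    order = assign_rng.permutation(cfg.n_genes)
    classes = np.array(["nonessential"] * cfg.n_genes, dtype=object)
    classes[order[: cfg.n_planted_selective]] = "planted_selective"
    classes[
        order[cfg.n_planted_selective : cfg.n_planted_selective + cfg.n_common_essential]
    ] = "common_essential"

    n_lines = cfg.n_target_lines + cfg.n_background_lines
    scores = np.empty((cfg.n_genes, n_lines))
    gene_streams = master.spawn(cfg.n_genes + 1)[1:]
    for i, (cls, ss) in enumerate(zip(classes, gene_streams)):
        rng = np.random.default_rng(ss)
        if cls == "nonessential":
            mu_t = mu_b = cfg.nonessential_mean
        elif cls == "common_essential":
            mu_t = mu_b = cfg.essential_mean
        else:
            mu_t = cfg.nonessential_mean - cfg.delta
            mu_b = cfg.nonessential_mean
        scores[i, : cfg.n_target_lines] = rng.normal(mu_t, cfg.sigma,
                                                     cfg.n_target_lines)
        scores[i, cfg.n_target_lines :] = rng.normal(mu_b, cfg.sigma,
                                                     cfg.n_background_lines)

    frame = pd.DataFrame(scores, index=genes, columns=target_lines + background_lines)
    dep = DependencyMatrix(scores=frame)
    grouping = CellLineGrouping(
        mapping={
            **{c: TARGET_ENTITY for c in target_lines},
            **{c: BACKGROUND_ENTITY for c in background_lines},
        },
        target_label=TARGET_ENTITY,
    )
    truth = TruthTable(gene_class=dict(zip(genes, classes)))
    return dep, grouping, truth


def gen_gene_sets(
    truth: TruthTable,
    n_sets: int = 20,
    set_size: int = 30,
    enrichment_fraction: float = 1.0,
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene sets plus one pathway enriched for planted genes.

    The planted pathway holds ``enrichment_fraction`` of the planted
    selective genes (rounded) topped up with random fillers to
    ``set_size``; the remaining ``n_sets - 1`` sets are uniform draws from
    all genes.
    """
    if not 0 <= enrichment_fraction <= 1:
        raise ValueError("enrichment_fraction must lie in [0, 1]")
    all_genes = list(truth.gene_class)
    planted = truth.genes_of_class("planted_selective")
    others = [g for g in all_genes if g not in set(planted)]
    rng = np.random.default_rng(np.random.SeedSequence([seed, len(all_genes)]))

    n_in = int(round(enrichment_fraction * len(planted)))
    chosen = list(rng.choice(planted, size=n_in, replace=False)) if n_in else []
    n_fill = max(set_size - len(chosen), 0)
    fillers = list(rng.choice(others, size=min(n_fill, len(others)), replace=False))
    members = chosen + fillers
    rng.shuffle(members)
    sets = [GeneSet(PLANTED_PATHWAY, "pathway enriched for planted genes",
                    tuple(members))]
    for i in range(1, n_sets):
        draw = rng.choice(all_genes, size=min(set_size, len(all_genes)),
                          replace=False)
        sets.append(GeneSet(f"RANDOM_SET_{i:02d}", "uniform random set", tuple(draw)))
    return GeneSetCollection(sets)


def gen_counts(
    n_genes: int = 2000,
    n_per_group: int = 3,
    n_de: int = 50,
    log2_effect: float = 2.0,
    nb_dispersion: float = 0.1,
    base_mean: float = 500.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.Series, TruthTable]:
    """Negative-binomial counts with planted differential expression.

    Control-group means are ``base_mean`` for every gene; ``n_de`` genes
    get mean ``base_mean * 2**(s * log2_effect)`` in the knockdown group,
    with the sign s alternating between planted genes.  The NB
    parameterization is mean/dispersion: var = mu + dispersion * mu^2.
    """
    if n_de > n_genes:
        raise ValueError("n_de cannot exceed n_genes")
    if nb_dispersion <= 0 or base_mean <= 0:
        raise ValueError("nb_dispersion and base_mean must be > 0")
    genes = _gene_names(n_genes)
    ctrl = [f"ctrl_{i}" for i in range(1, n_per_group + 1)]
    kd = [f"kd_{i}" for i in range(1, n_per_group + 1)]

    master = np.random.SeedSequence([seed, n_genes, n_per_group])
    pick_rng = np.random.default_rng(master.spawn(1)[0])
    de_idx = pick_rng.choice(n_genes, size=n_de, replace=False)
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)

    effects = np.zeros(n_genes)
    effects[de_idx] = signs * log2_effect

    size = 1.0 / nb_dispersion  # NB shape parameter
    counts = np.empty((n_genes, 2 * n_per_group), dtype=int)
    gene_streams = master.spawn(n_genes + 1)[1:]
    for i, ss in enumerate(gene_streams):
        rng = np.random.default_rng(ss)
        mu_ctrl = base_mean
        mu_kd = base_mean * 2.0 ** effects[i]
        p_ctrl = size / (size + mu_ctrl)
        p_kd = size / (size + mu_kd)
        counts[i, :n_per_group] = rng.negative_binomial(size, p_ctrl, n_per_group)
        counts[i, n_per_group:] = rng.negative_binomial(size, p_kd, n_per_group)

    frame = pd.DataFrame(counts, index=genes, columns=ctrl + kd)
    expr = ExpressionMatrix(values=frame, is_counts=True)
    labels = pd.Series(
        {**{s: "control" for s in ctrl}, **{s: "knockdown" for s in kd}}
    )
    truth = TruthTable(deg_effect={genes[i]: float(effects[i]) for i in de_idx})
    return expr, labels, truth


def gen_survival(
    n_patients: int = 179,
    beta: float = 1.0,
    baseline_hazard: float = 0.02,
    censor_rate: float = 0.2,
    seed: int = 0,
) -> ClinicalTable:
    """Exponential survival with a log-linear expression effect.

    The covariate z is standard normal (an expression z-score); event
    times are Exponential(rate = baseline_hazard * exp(beta * z));
    censoring times are independent Exponential with rate tuned so the
    expected censored fraction is ``censor_rate`` at beta = 0 (approximate
    otherwise).  Observed time is the minimum; event = 1 when death is
    observed first.
    """
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must lie in [0, 1)")
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, n_patients]))
    z = rng.normal(0.0, 1.0, n_patients)
    rate = baseline_hazard * np.exp(beta * z)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        c_rate = baseline_hazard * censor_rate / (1.0 - censor_rate)
        t_censor = rng.exponential(1.0 / c_rate, n_patients)
    else:
        t_censor = np.full(n_patients, np.inf)
    observed = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return ClinicalTable(
        data=pd.DataFrame(
            {
                "sample": [f"P{i:04d}" for i in range(1, n_patients + 1)],
                "expression": z,
                "os_time": observed,
                "os_event": event,
            }
        )
    )


def write_fixture_dir(
    outdir: str | Path,
    cfg: ScreenSimConfig = ScreenSimConfig(),
    n_sets: int = 20,
    set_size: int = 30,
    enrichment_fraction: float = 1.0,
    counts_kwargs: dict | None = None,
    survival_kwargs: dict | None = None,
) -> Path:
    """Emit a complete input fixture: dependency CSV, grouping TSV, GMT,
    counts TSV with labels, clinical TSV, and the planted truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    dep, grouping, truth = gen_dependency_matrix(cfg)
    sets = gen_gene_sets(truth, n_sets=n_sets, set_size=set_size,
                         enrichment_fraction=enrichment_fraction, seed=cfg.seed)
    expr, labels, deg_truth = gen_counts(seed=cfg.seed, **(counts_kwargs or {}))
    clinical = gen_survival(seed=cfg.seed, **(survival_kwargs or {}))

    write_dependency_csv(dep, outdir / "dependency.csv")
    write_table(
        pd.DataFrame(
            {"cell_line": list(grouping.mapping), "entity": list(grouping.mapping.values())}
        ),
        outdir / "grouping.tsv",
    )
    write_gmt(sets, outdir / "gene_sets.gmt")
    write_expression_tsv(expr, outdir / "counts.tsv")
    write_table(
        pd.DataFrame({"sample": labels.index, "group": labels.to_numpy()}),
        outdir / "labels.tsv",
    )
    write_table(clinical.data, outdir / "clinical.tsv")
    merged = truth.to_frame()
    deg_frame = deg_truth.to_frame()
    write_table(merged, outdir / "truth_dependency.tsv")
    write_table(deg_frame, outdir / "truth_deg.tsv")
    return outdir
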