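"""Median-based differential expression on read counts, plus 2^(-ddCt)
relative quantification for qPCR.

The differential-expression statistic is deliberately simple: read counts
are transformed as log2(count + pseudocount), the per-gene effect size is
the difference of group medians on that scale (knockdown minus control),
and significance comes from a two-sided unpaired t-test on the transformed
values with no multiple-testing cutoff by default (a BH-adjusted column is
emitted alongside for users who want one).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._stats import floor_p, rowwise_t_test
from .io import ExpressionMatrix

__all__ = ["compute_deg", "relative_expression_ddct", "DEG_COLUMNS"]

DEG_COLUMNS = [
    "gene",
    "log2fc",
    "p_value",
    "bh_p",
    "neg_log10_p",
    "significant",
    "direction",
]


def compute_deg(
    expr: ExpressionMatrix,
    labels: pd.Series | dict,
    pseudocount: float = 1.0,
    alpha: float = 0.05,
    control_label: str = "control",
    knockdown_label: str = "knockdown",
    cpm_normalize: bool = False,
) -> pd.DataFrame:
    """Per-gene median log2 fold change and unpaired t-test.

    ``labels`` maps sample id -> group; both groups need >= 2 samples.
    log2fc is median(log2(knockdown + pc)) - median(log2(control + pc)), so
    genes repressed by the knockdown come out negative.  A gene with zero
    counts everywhere (or any gene with identical transformed values in
    both groups) is reported with log2fc 0, p 1.  ``cpm_normalize``
    rescales each sample to counts-per-million before the transform; off by
    default because the statistic is defined on raw counts.
    """
    labels = pd.Series(labels)
    ctrl = [s for s in expr.samples if labels.get(s) == control_label]
    kd = [s for s in expr.samples if labels.get(s) == knockdown_label]
    if len(ctrl) < 2 or len(kd) < 2:
        raise ValueError(
            f"need >= 2 samples per group; got {len(ctrl)} {control_label!r} "
            f"and {len(kd)} {knockdown_label!r}"
        )

    values = expr.values
    if cpm_normalize:
        values = values / values.sum(axis=0) * 1e6

    log_values = np.log2(values.to_numpy() + pseudocount)
    a = log_values[:, [expr.samples.index(s) for s in kd]]
    b = log_values[:, [expr.samples.index(s) for s in ctrl]]

    log2fc = np.median(a, axis=1) - np.median(b, axis=1)
    t, p, _, _ = rowwise_t_test(a, b, equal_var=False)

    bh = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        bh[ok] = multipletests(p[ok], method="fdr_bh")[1]

    significant = (p < alpha) & ok
    direction = np.where(
        significant & (log2fc > 0),
        "up",
        np.where(significant & (log2fc < 0), "down", "ns"),
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        neg_log10 = -np.log10(floor_p(p))
    return pd.DataFrame(
        {
            "gene": expr.genes,
            "log2fc": log2fc,
            "p_value": p,
            "bh_p": bh,
            "neg_log10_p": neg_log10,
            "significant": significant,
            "direction": direction,
        }
    )


def relative_expression_ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the 2^(-ddCt) method.

    ddCt = (Ct_target - Ct_reference) in the sample minus the same
    difference in the control; the fold change relative to the control,
    normalized to the reference gene (e.g. GAPDH), is 2^(-ddCt).
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control)
    if not all(np.isfinite(c) for c in cts):
        raise ValueError("all Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))
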