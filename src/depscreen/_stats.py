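"""Vectorized two-sample t statistics shared by the screen and DEG modules.

Implements the Welch (unequal-variance) and Student (pooled) two-sample
t-test row-wise over matrices with missing values, with the degenerate-case
contract used throughout the package: when both groups have zero variance
and identical means the test is uninformative and reports t = 0, p = 1;
when variances are zero but means differ, p underflows and is floored at
the smallest positive normal float before any -log10 transform.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

P_FLOOR = float(np.finfo(float).tiny)


def floor_p(p: np.ndarray | float) -> np.ndarray | float:
    """Floor p-values at the smallest positive normal magnitude.

    Keeps -log10(p) finite for volcano-style outputs.
    """
    return np.maximum(p, P_FLOOR)


def rowwise_t_test(
    a: np.ndarray,
    b: np.ndarray,
    equal_var: bool = False,
    min_per_group: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Two-sided two-sample t-test applied to each row of ``a`` vs ``b``.

    NaNs are dropped per row and group.  Rows with fewer than
    ``min_per_group`` non-missing values in either group get NaN statistics.

    Returns ``(t, p, n_a, n_b)`` where ``n_a``/``n_b`` count the non-missing
    values actually used per row.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
        b = b[None, :]

    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    eligible = (n_a >= max(min_per_group, 2)) & (n_b >= max(min_per_group, 2))

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_a = np.where(n_a > 0, np.nansum(a, axis=1) / np.maximum(n_a, 1), np.nan)
        mean_b = np.where(n_b > 0, np.nansum(b, axis=1) / np.maximum(n_b, 1), np.nan)
        # ddof=1 sample variances; rows below the size floor are masked later
        var_a = _nanvar1(a, n_a)
        var_b = _nanvar1(b, n_b)

        if equal_var:
            df = n_a + n_b - 2
            pooled = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
            se2 = pooled * (1.0 / n_a + 1.0 / n_b)
        else:
            se2 = var_a / n_a + var_b / n_b
            num = se2**2
            den = (var_a / n_a) ** 2 / (n_a - 1) + (var_b / n_b) ** 2 / (n_b - 1)
            df = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)

        diff = mean_a - mean_b
        t = diff / np.sqrt(se2)

    # degenerate rows: zero pooled standard error
    degen = eligible & ~(se2 > 0)
    equal_means = degen & (diff == 0)
    unequal_means = degen & (diff != 0)

    p = np.full(t.shape, np.nan)
    ok = eligible & (se2 > 0) & np.isfinite(df)
    if ok.any():
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    t = np.where(equal_means, 0.0, t)
    p = np.where(equal_means, 1.0, p)
    t = np.where(unequal_means, np.copysign(np.inf, np.nan_to_num(diff, nan=1.0)), t)
    p = np.where(unequal_means, 0.0, p)

    t[~eligible] = np.nan
    p[~eligible] = np.nan
    return t, p, n_a, n_b


def _nanvar1(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Row-wise sample variance (ddof=1) ignoring NaNs; NaN where n < 2."""
    out = np.full(x.shape[0], np.nan)
    mask = n >= 2
    if mask.any():
        with np.errstate(invalid="ignore"):
            out[mask] = np.nanvar(x[mask], axis=1, ddof=1)
    return out


def welch_t_test(a, b, equal_var: bool = False) -> tuple[float, float]:
    """Scalar convenience wrapper: two-sided t-test on two 1-D samples."""
    t, p, _, _ = rowwise_t_test(np.asarray(a, float), np.asarray(b, float),
                                equal_var=equal_var)
    return float(t[0]), float(p[0])
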