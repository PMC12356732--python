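"""Behavioral scoring: d', pooled standardization, category aggregates, group tests.

Six tasks measure three visual-recognition categories, one memory and one
matching test each: faces (CFMT+, VFMT), cars (CCMT, VCMT) and novel
objects (NOMT, NOMaT).  Five tasks are scored as proportion correct; the
novel-object matching task is a same/different task scored as
signal-detection sensitivity d' = z(hit rate) - z(false-alarm rate).
A category aggregate is the mean of the two standardized task scores for
that category, standardized over the pooled sample (both groups together)
so that genuine group differences survive standardization.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SchemaError

__all__ = ["dprime", "standardize", "aggregates", "group_compare",
           "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = (
    "group", "cfmt_acc", "ccmt_acc", "nomt_acc", "vfmt_acc", "vcmt_acc",
    "nomat_hits", "nomat_fas", "nomat_n_same", "nomat_n_diff",
)


def dprime(hits, fas, n_same, n_diff, correction: str = "half") -> float:
    """Signal-detection sensitivity for a same/different task.

    Parameters
    ----------
    hits, fas
        Hit and false-alarm counts.
    n_same, n_diff
        Number of same (signal) and different (noise) trials.
    correction
        ``"half"`` (default) clamps extreme rates to 1/(2N) and 1 - 1/(2N),
        keeping d' finite when a rate is 0 or 1; ``"none"`` applies no
        adjustment and returns +/-inf at extreme rates.
    """
    if n_same <= 0 or n_diff <= 0:
        raise ValueError("d' undefined with zero trials")
    if not (0 <= hits <= n_same) or not (0 <= fas <= n_diff):
        raise ValueError("counts must satisfy 0 <= hits <= n_same, 0 <= fas <= n_diff")
    hr = hits / n_same
    far = fas / n_diff
    if correction == "half":
        hr = min(max(hr, 1.0 / (2 * n_same)), 1.0 - 1.0 / (2 * n_same))
        far = min(max(far, 1.0 / (2 * n_diff)), 1.0 - 1.0 / (2 * n_diff))
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    return float(stats.norm.ppf(hr) - stats.norm.ppf(far))


def standardize(values, pooling: str = "pooled") -> np.ndarray:
    """z-scores with sample SD (ddof=1) over the pooled sample.

    ``pooling`` is kept as an explicit argument to document the convention;
    only pooled standardization is meaningful for between-group analyses.
    """
    if pooling != "pooled":
        raise ValueError("only pooled standardization is supported")
    x = np.asarray(values, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("cannot standardize a constant (zero-variance) input")
    return (x - x.mean()) / x.std(ddof=1)


def aggregates(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject face/car/novel aggregate indices.

    face = mean(z_CFMT+, z_VFMT); car = mean(z_CCMT, z_VCMT);
    novel = mean(z_NOMT, z_NOMaT-d').  All z-scores are pooled across groups.
    Returns a copy of the table with ``nomat_dprime``, ``face_agg``,
    ``car_agg`` and ``novel_agg`` columns appended.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"behavior table is missing columns: {missing}")
    out = table.copy()
    out["nomat_dprime"] = [
        dprime(r.nomat_hits, r.nomat_fas, r.nomat_n_same, r.nomat_n_diff)
        for r in table.itertuples()
    ]
    z = {c: standardize(out[c]) for c in
         ("cfmt_acc", "vfmt_acc", "ccmt_acc", "vcmt_acc", "nomt_acc",
          "nomat_dprime")}
    out["face_agg"] = (z["cfmt_acc"] + z["vfmt_acc"]) / 2.0
    out["car_agg"] = (z["ccmt_acc"] + z["vcmt_acc"]) / 2.0
    out["novel_agg"] = (z["nomt_acc"] + z["nomat_dprime"]) / 2.0
    return out


def group_compare(
    table: pd.DataFrame,
    test_columns: Sequence[str],
    alpha: float = 0.05,
    m_corrections: int = 6,
    groups: Sequence[str] = ("TD", "AUT"),
    equal_var: bool = True,
) -> pd.DataFrame:
    """Directional two-sample comparisons of the first group against the second.

    For each column, a pooled-variance (default) or Welch t-test of the
    hypothesis that the first group scores higher, with one-tailed p,
    Cohen's d from the pooled SD, and Bonferroni adjustment over
    ``m_corrections`` tests.
    """
    g1 = table.loc[table["group"] == groups[0]]
    g2 = table.loc[table["group"] == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("both groups need at least two subjects")
    rows = []
    for col in test_columns:
        a, b = g1[col].to_numpy(float), g2[col].to_numpy(float)
        t, _ = stats.ttest_ind(a, b, equal_var=equal_var)
        if equal_var:
            df = len(a) + len(b) - 2
        else:
            va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
        p_one = float(stats.t.sf(t, df))  # one-tailed, direction groups[0] > groups[1]
        sd_pool = np.sqrt(((len(a) - 1) * a.var(ddof=1)
                           + (len(b) - 1) * b.var(ddof=1))
                          / (len(a) + len(b) - 2))
        d = float((a.mean() - b.mean()) / sd_pool) if sd_pool > 0 else 0.0
        p_bonf = min(1.0, p_one * m_corrections)
        rows.append({"test": col, "t": float(t), "df": float(df),
                     "p_raw": p_one, "p_bonf": p_bonf, "d": d,
                     "significant": p_bonf < alpha})
    return pd.DataFrame(rows)
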