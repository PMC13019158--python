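"""Recurrent genomic-alteration scoring (G-score and M-score aggregation).

Copy-number recurrence: a gene counts as a putative SCNA driver in one
cancer type when it (1) sits in a significantly recurrent focal peak
(q <= 0.25), (2) has G-score >= 0.1, (3) is detectably expressed (90th
percentile of FPKM >= 1), and (4) shows a positive copy-number-expression
Pearson correlation with p < 0.001 on log(FPKM + 0.001).  The pan-cancer
overall G-score is the unweighted sum of G-scores over passing cancer
types.

Mutation recurrence: M-score = mutation index x mutation frequency, where
the index (0-5) counts the independent driver-detection programs calling
the gene; cancers with index < 2 contribute 0 to the overall sum.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["scna_criteria", "overall_g_score", "m_score", "overall_m_score",
           "cn_expr_corr", "detectability", "log_fpkm"]


def scna_criteria(record, q_max: float = 0.25, g_min: float = 0.1,
                  detect_min: float = 1.0, corr_p_max: float = 0.001) -> bool:
    """Four-criteria pass flag for one gene x cancer recurrence record.

    ``record`` is any mapping with keys ``in_peak``, ``q_value``, ``g_score``,
    ``detectability`` (90th-percentile FPKM) and ``corr_p``.  Boundary
    semantics: q <= q_max, G >= g_min, detectability >= detect_min, and a
    strict corr_p < corr_p_max.
    """
    return bool(
        record["in_peak"]
        and record["q_value"] <= q_max
        and record["g_score"] >= g_min
        and record["detectability"] >= detect_min
        and record["corr_p"] < corr_p_max
    )


def overall_g_score(records: pd.DataFrame, **criteria) -> float:
    """Unweighted sum of G-scores over cancer types passing all criteria."""
    if records.empty:
        return 0.0
    if records["gene"].nunique() > 1:
        raise ValueError("overall_g_score expects records for a single gene")
    mask = records.apply(lambda r: scna_criteria(r, **criteria), axis=1)
    return float(records.loc[mask, "g_score"].sum())


def m_score(mutation_index: int, mutation_frequency: float) -> float:
    """Per-cancer M-score = mutation index x mutation frequency."""
    if not 0 <= mutation_index <= 5 or mutation_index != int(mutation_index):
        raise ValueError("mutation index must be an integer in [0, 5]")
    if not 0.0 <= mutation_frequency <= 1.0:
        raise ValueError("mutation frequency must be in [0, 1]")
    return float(mutation_index * mutation_frequency)


def overall_m_score(records: pd.DataFrame, min_index: int = 2,
                    gate_sum: bool = True) -> float:
    """Unweighted sum of per-cancer M-scores across cancer types.

    With ``gate_sum`` (default) only recurrently mutated cancers
    (mutation index >= ``min_index``) contribute; without it every cancer's
    M-score is summed and the gate only labels recurrence.
    """
    if records.empty:
        return 0.0
    total = 0.0
    for _, r in records.iterrows():
        if gate_sum and r["mutation_index"] < min_index:
            continue
        total += m_score(int(r["mutation_index"]), float(r["mutation_frequency"]))
    return total


def log_fpkm(values) -> np.ndarray:
    """The expression transform used for copy-number correlation."""
    return np.log(np.asarray(values, dtype=float) + 0.001)


def cn_expr_corr(copy_number, expression_log):
    """Pearson r and two-sided p between copy number and log expression.

    Returns (nan, nan) with a defined=False third element when either
    vector is constant.
    """
    cn = np.asarray(copy_number, dtype=float)
    ex = np.asarray(expression_log, dtype=float)
    if cn.size != ex.size or cn.size < 3:
        raise ValueError("need >= 3 paired samples")
    if np.ptp(cn) == 0 or np.ptp(ex) == 0:
        return math.nan, math.nan, False
    r, p = stats.pearsonr(cn, ex)
    return float(r), float(p), True


def detectability(expression_values, percentile: float = 90,
                  threshold: float = 1.0) -> bool:
    """Whether the empirical percentile reaches ``threshold``.

    Uses percentile-rank linear interpolation between closest order
    statistics (Weibull plotting positions, R type 6), under which a gene
    expressed in the top 10% of samples clears the 90th-percentile rule
    even when exactly 10% of samples express it.
    """
    values = np.asarray(expression_values, dtype=float)
    if values.size == 0:
        raise ValueError("expression vector is empty")
    return bool(np.percentile(values, percentile, method="weibull") >= threshold)
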