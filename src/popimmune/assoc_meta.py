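"""Ancestry-stratified association, Fisher sumlog meta-p, local-ancestry
normalization.

Within each ancestry stratum the phenotype is regressed (OLS) on a binary
genotype-group indicator plus categorical covariate dummies (e.g. cancer
type); the stratum p-values are combined by Fisher's method:
``X = -2 * sum(ln p) ~ chi-square(2k)``.  Local ancestry at a locus is
normalized by dividing each ancestry proportion by the individual's global
proportion, then proportionally rescaled to sum to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["StratifiedAssocResult", "MetaResult", "stratified_assoc",
           "fisher_sumlog", "normalize_local_ancestry", "P_FLOOR"]

P_FLOOR = 1e-300  # applied before log to keep sumlog finite


@dataclass
class StratifiedAssocResult:
    stratum: str
    effect: float
    stderr: float
    p_value: float
    n_group0: int
    n_group1: int
    excluded: bool = False
    reason: str = ""


@dataclass
class MetaResult:
    statistic: float  # -2 * sum(ln p)
    df: int           # 2k
    p_value: float


def stratified_assoc(phenotype, group, strata, covariates=None) -> list:
    """Per-stratum OLS of phenotype on a binary group with covariate dummies.

    Parameters
    ----------
    phenotype, group, strata
        Aligned vectors: a real phenotype, binary (0/1 or two-level) group
        labels, and stratum labels.
    covariates
        Optional DataFrame (or dict of vectors) of categorical factors,
        expanded to dummies within each stratum.

    Strata missing a group, with < 2 samples per group, or with a singular
    design are flagged ``excluded`` and should be dropped from the meta
    step by the caller (see :func:`fisher_sumlog`).
    """
    y = np.asarray(phenotype, dtype=float)
    grp = pd.Series(group).reset_index(drop=True)
    levels = pd.unique(grp.dropna())
    if len(levels) != 2:
        raise ValueError("group must have exactly two levels overall")
    g01 = (grp == levels[1]).astype(float).to_numpy()
    strata = pd.Series(strata).reset_index(drop=True)
    cov = pd.DataFrame(covariates).reset_index(drop=True) if covariates is not None else None

    results = []
    for stratum in pd.unique(strata):
        idx = (strata == stratum).to_numpy()
        ys, gs = y[idx], g01[idx]
        n1, n0 = int(gs.sum()), int((1 - gs).sum())
        if n0 < 2 or n1 < 2:
            results.append(StratifiedAssocResult(str(stratum), math.nan, math.nan,
                                                 math.nan, n0, n1, True,
                                                 "fewer than 2 samples in a group"))
            continue
        X = pd.DataFrame({"group": gs})
        if cov is not None:
            dummies = pd.get_dummies(cov.loc[idx].astype(str), drop_first=True,
                                     dtype=float).reset_index(drop=True)
            X = pd.concat([X.reset_index(drop=True), dummies], axis=1)
        X = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            results.append(StratifiedAssocResult(str(stratum), math.nan, math.nan,
                                                 math.nan, n0, n1, True,
                                                 "singular design"))
            continue
        fit = sm.OLS(ys, X).fit()
        results.append(StratifiedAssocResult(
            str(stratum), float(fit.params["group"]), float(fit.bse["group"]),
            float(fit.pvalues["group"]), n0, n1))
    return results


def fisher_sumlog(pvals) -> MetaResult:
    """Fisher's combined probability: -2 sum(ln p) vs chi-square(2k)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("fisher_sumlog requires at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]; floor zeros with P_FLOOR first")
    statistic = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return MetaResult(statistic, df, float(stats.chi2.sf(statistic, df)))


def normalize_local_ancestry(local, global_props):
    """Local/global ancestry ratio, proportionally rescaled to sum to 1.

    Entries where the local proportion is positive but the global proportion
    is zero are undefined and returned as NaN (with the remaining entries
    rescaled over the defined mass).
    """
    loc = np.asarray(local, dtype=float)
    glo = np.asarray(global_props, dtype=float)
    if loc.shape != glo.shape:
        raise ValueError("local and global vectors must align")
    if (loc < 0).any() or (glo < 0).any():
        raise ValueError("ancestry proportions must be non-negative")
    undefined = (loc > 0) & (glo == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(glo > 0, loc / np.where(glo > 0, glo, 1.0), 0.0)
    ratio = np.where(undefined, np.nan, ratio)
    total = np.nansum(ratio)
    if total == 0:
        return ratio
    return ratio / total
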