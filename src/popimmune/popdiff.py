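"""Allele-frequency statistics and Wright's fixation index F_ST.

F_ST is computed in the Nei G_ST form from expected heterozygosities:
``F_ST = (HT - HS) / HT`` with ``HT = 2 p_bar (1 - p_bar)`` from the
(by default unweighted) mean allele frequency across populations and
``HS`` the mean within-population expected heterozygosity
``2 p_k (1 - p_k)``.  Sites monomorphic in the pooled sample have
``HT = 0`` and are flagged undefined.  Small negative values from finite
sampling are reported as computed unless ``clamp_zero`` is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = ["PopFreqTable", "FstResult", "allele_stats", "qc_filter",
           "site_fst", "pairwise_fst", "gene_fst", "bn_f_estimate"]


@dataclass
class PopFreqTable:
    """Per-site x population allele frequencies with pooled QC statistics.

    ``freq`` / ``n_called`` are (n_sites, n_pops) arrays; a population with
    zero called samples at a site has NaN frequency. ``pooled`` carries the
    pooled alternate frequency, MAF, and call rate per site.
    """

    site_ids: pd.Index
    populations: list
    freq: np.ndarray = field(repr=False)
    n_called: np.ndarray = field(repr=False)  # called allele counts (2 per sample)
    pooled: pd.DataFrame = field(repr=False)
    sites: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freq, index=self.site_ids,
                          columns=[f"freq_{p}" for p in self.populations])
        return pd.concat([df, self.pooled], axis=1)


@dataclass
class FstResult:
    """Per-site HT/HS/F_ST plus optional per-gene and pairwise aggregates."""

    per_site: pd.DataFrame = field(repr=False)  # ht, hs, fst, defined
    populations: list = field(default_factory=list)
    pairwise: pd.DataFrame | None = field(repr=False, default=None)
    sites: pd.DataFrame = field(repr=False, default=None)


def allele_stats(g: GenotypeMatrix) -> PopFreqTable:
    """Per-population alternate-allele frequency, MAF, and call rate.

    Missing dosages are excluded from both numerator and denominator; the
    alternate frequency is (sum of dosages over called samples) / (2 * n).
    """
    pops = g.populations
    n_sites = g.n_sites
    freq = np.full((n_sites, len(pops)), np.nan)
    n_called = np.zeros((n_sites, len(pops)), dtype=int)
    for k, pop in enumerate(pops):
        sub = g.dosages[g.population_labels == pop]
        called = sub != MISSING
        alleles = 2 * called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[:, k] = np.where(alleles > 0, alt / np.maximum(alleles, 1), np.nan)
        freq[alleles == 0, k] = np.nan
        n_called[:, k] = alleles
    called_all = g.dosages != MISSING
    total_alleles = 2 * called_all.sum(axis=0)
    alt_all = np.where(called_all, g.dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled_freq = np.where(total_alleles > 0, alt_all / np.maximum(total_alleles, 1), np.nan)
    pooled = pd.DataFrame(
        {
            "pooled_freq": pooled_freq,
            "pooled_maf": np.minimum(pooled_freq, 1 - pooled_freq),
            "n_called_alleles": total_alleles,
            "call_rate": called_all.mean(axis=0),
        },
        index=g.site_ids,
    )
    return PopFreqTable(g.site_ids, pops, freq, n_called, pooled, g.sites)


def qc_filter(t: PopFreqTable, min_call_rate: float = 0.95,
              min_maf: float = 0.01) -> pd.Index:
    """Sites passing pooled call rate > ``min_call_rate`` and MAF > ``min_maf``.

    Both inequalities are strict, matching the usual "call rate > 95% and
    MAF > 1%" genotype-QC convention.
    """
    if not (0 <= min_call_rate <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must be in [0, 1]")
    keep = (t.pooled["call_rate"] > min_call_rate) & (t.pooled["pooled_maf"] > min_maf)
    return t.site_ids[keep.to_numpy()]


def _nei_fst(freq: np.ndarray, weights=None):
    """HT, HS, F_ST per site from a (n_sites, n_pops) frequency array."""
    if weights is None:
        p_bar = np.nanmean(freq, axis=1)
        hs = np.nanmean(2 * freq * (1 - freq), axis=1)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
        p_bar = np.nansum(freq * w, axis=1)
        hs = np.nansum(2 * freq * (1 - freq) * w, axis=1)
    ht = 2 * p_bar * (1 - p_bar)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1.0), np.nan)
    return ht, hs, fst


def site_fst(t: PopFreqTable, populations=None, weighted: bool = False,
             clamp_zero: bool = False) -> FstResult:
    """Per-site global F_ST over the selected populations.

    Monomorphic-everywhere sites (HT = 0) are flagged undefined. With
    ``weighted=True`` population means are weighted by called allele counts
    instead of the default unweighted mean.
    """
    pops = list(populations) if populations is not None else t.populations
    if len(pops) < 2:
        raise ValueError("site_fst requires at least two populations")
    cols = [t.populations.index(p) for p in pops]
    freq = t.freq[:, cols]
    weights = None
    if weighted:
        # per-site weights vary; handle row-wise
        n = t.n_called[:, cols].astype(float)
        wsum = n.sum(axis=1, keepdims=True)
        w = np.where(wsum > 0, n / np.maximum(wsum, 1), np.nan)
        p_bar = np.nansum(freq * w, axis=1)
        hs = np.nansum(2 * freq * (1 - freq) * w, axis=1)
        ht = 2 * p_bar * (1 - p_bar)
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1.0), np.nan)
    else:
        ht, hs, fst = _nei_fst(freq)
    if clamp_zero:
        fst = np.where(np.isnan(fst), np.nan, np.maximum(fst, 0.0))
    per_site = pd.DataFrame(
        {"ht": ht, "hs": hs, "fst": fst, "defined": ht > 0}, index=t.site_ids
    )
    return FstResult(per_site, pops, sites=t.sites)


def pairwise_fst(t: PopFreqTable, clamp_zero: bool = False) -> pd.DataFrame:
    """Population x population matrix of mean per-site F_ST.

    Each pair's F_ST is the same Nei statistic restricted to that pair,
    averaged over its defined sites. The matrix is symmetric with a zero
    diagonal.
    """
    pops = t.populations
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            _, _, fst = _nei_fst(t.freq[:, [i, j]])
            if clamp_zero:
                fst = np.maximum(fst, 0.0)
            val = float(np.nanmean(fst)) if np.isfinite(fst).any() else np.nan
            out.iloc[i, j] = out.iloc[j, i] = val
    return out


def bn_f_estimate(t: PopFreqTable) -> float:
    """Superpopulation differentiation parameter F from many sites.

    The descriptive G_ST statistic of :func:`site_fst` is downward biased
    when the number of demes K is small — its expectation under a
    Balding-Nichols superpopulation with parameter F is roughly
    ``F (1 - 1/K) / (1 - F/K)``, not F.  This method-of-moments estimator
    targets F itself: per site, the unbiased across-population frequency
    variance (K-1 denominator, with the binomial sampling variance of the
    per-population frequency estimates subtracted) is divided by an
    unbiased estimate of the superpopulation heterozygosity term
    ``p(1-p)``, combining sites as a ratio of sums to avoid per-site
    Jensen bias.  Requires complete per-population frequencies.
    """
    freq = t.freq
    K = freq.shape[1]
    if K < 2:
        raise ValueError("need at least two populations")
    ok = ~np.isnan(freq).any(axis=1)
    freq = freq[ok]
    n_alleles = t.n_called[ok]
    p_bar = freq.mean(axis=1)
    s2 = freq.var(axis=1, ddof=1)
    # binomial noise in p-hat inflates s2 by mean p(1-p)/(2n-1) per pop
    correction = (freq * (1 - freq) / np.maximum(n_alleles - 1, 1)).mean(axis=1)
    s2_adj = s2 - correction
    num = s2_adj.sum()
    den = (p_bar * (1 - p_bar) + s2_adj / K).sum()
    return float(num / den)


def gene_fst(f: FstResult, annotations=None) -> pd.DataFrame:
    """Per-gene mean and max of defined per-site F_ST values.

    ``annotations`` maps site id -> gene; by default the ``gene`` column of
    the site table carried on the result is used. Sites without a defined
    F_ST are skipped; genes with no defined site are omitted.
    """
    if annotations is None:
        if f.sites is None:
            raise ValueError("no site annotations available")
        annotations = f.sites["gene"]
    genes = pd.Series(annotations).reindex(f.per_site.index)
    df = f.per_site.assign(gene=genes.to_numpy())
    df = df[df["defined"] & df["fst"].notna() & df["gene"].notna()]
    if df.empty:
        return pd.DataFrame(columns=["mean_fst", "max_fst", "n_sites"])
    out = df.groupby("gene")["fst"].agg(mean_fst="mean", max_fst="max", n_sites="size")
    out["n_sites"] = out["n_sites"].astype(int)
    return out
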