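"""Candidate nsSNP prioritization by a composite impact score.

The pipeline mirrors a ranking (rather than GWAS-threshold) strategy for
linking germline nsSNPs in innate-immunity sensor (PRR) genes to intrinsic
type-I interferon activity in cancer cell lines:

1. four-step candidate filter: PRR gene membership, host-gene expression
   (FPKM > 1 in > 95% of lines), host-gene max F_ST > 0.1, pooled MAF > 0.2;
2. per SNP, a genotype-group differential-expression ranking (log2 fold
   change, median-of-ratios normalized) and a pre-ranked enrichment score
   of the interferon-stimulated-gene (ISG) signature;
3. BH adjustment of the per-SNP enrichment p-values across the run;
4. min-max scaling of the average ranks of |ES|, literature-evidence
   (publication) count, and F_ST;
5. impact score = w1*zES + w2*zPub + w3*zFst with (w1, w2, w3) = (1, 1, 0.5);
   SNPs with adjusted p > 0.05 are eliminated before scoring, and the pass
   flag marks score > 1.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import enrichment
from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "CandidateFilterConfig",
    "merge_genotype_calls",
    "candidate_filter",
    "de_rank",
    "snp_isg_es",
    "rank_scale",
    "impact_score",
    "prioritize_pipeline",
]

DEFAULT_WEIGHTS = (1.0, 1.0, 0.5)
SOURCE_PRIORITY = ("array", "wes", "imputed")


@dataclass
class CandidateFilterConfig:
    """Thresholds of the four-step candidate nsSNP filter."""

    gene_list: frozenset
    min_expressed_fraction: float = 0.95
    expression_threshold: float = 1.0  # FPKM cutoff defining "expressed"
    min_gene_fst: float = 0.1
    min_maf: float = 0.2

    def __post_init__(self) -> None:
        self.gene_list = frozenset(self.gene_list)
        for v in (self.min_expressed_fraction, self.min_maf):
            if not 0.0 <= v <= 1.0:
                raise ValueError("fractional thresholds must be in [0, 1]")


def merge_genotype_calls(sources: dict, priority=SOURCE_PRIORITY,
                         site_info: dict | None = None):
    """Merge per-source dosage tables by call priority (array > WES > imputed).

    Parameters
    ----------
    sources
        Mapping of source tag -> dosage DataFrame (sites x samples, -1
        missing).  Tags outside ``priority`` raise.
    site_info
        Optional mapping of source tag -> DataFrame with ``ref``/``alt``
        columns; conflicting site definitions raise, naming the site.

    Returns
    -------
    (DataFrame, DataFrame)
        Merged dosages and a same-shaped provenance table naming the source
        that supplied each call ('' where all sources were missing).
    """
    unknown = set(sources) - set(priority)
    if unknown:
        raise ValueError(f"unknown genotype sources: {sorted(unknown)}")
    if site_info:
        ref_alt: dict = {}
        for tag, info in site_info.items():
            for site, row in info.iterrows():
                key = (row["ref"], row["alt"])
                if site in ref_alt and ref_alt[site] != key:
                    raise ValueError(f"conflicting ref/alt definition at site {site}")
                ref_alt.setdefault(site, key)
    ordered = [sources[tag] for tag in priority if tag in sources]
    all_sites = ordered[0].index
    all_samples = ordered[0].columns
    for df in ordered[1:]:
        all_sites = all_sites.union(df.index, sort=False)
        all_samples = all_samples.union(df.columns, sort=False)
    merged = pd.DataFrame(MISSING, index=all_sites, columns=all_samples, dtype=int)
    provenance = pd.DataFrame("", index=all_sites, columns=all_samples)
    for tag in priority:
        if tag not in sources:
            continue
        df = sources[tag].reindex(index=all_sites, columns=all_samples,
                                  fill_value=MISSING)
        take = (merged == MISSING) & (df != MISSING)
        merged = merged.where(~take, df)
        provenance = provenance.where(~take, tag)
    return merged, provenance


def candidate_filter(snps: pd.DataFrame, gene_fst: pd.DataFrame,
                     expression: pd.DataFrame, cfg: CandidateFilterConfig):
    """Sequential four-step filter with per-step survivor tallies.

    ``snps`` is indexed by SNP id with columns ``gene`` and ``maf`` (pooled);
    ``gene_fst`` carries ``max_fst`` per gene; ``expression`` is an FPKM
    matrix (genes x cell lines) used for the detectable-expression step.

    Returns (surviving SNP index, tally DataFrame).
    """
    tallies = [{"step": "input", "n_remaining": len(snps), "n_removed": 0}]
    current = snps

    in_genes = current["gene"].isin(cfg.gene_list)
    nxt = current[in_genes]
    tallies.append({"step": "prr_gene", "n_remaining": len(nxt),
                    "n_removed": len(current) - len(nxt)})
    current = nxt

    expressed_frac = (expression > cfg.expression_threshold).mean(axis=1)
    expressed_genes = set(expressed_frac.index[expressed_frac > cfg.min_expressed_fraction])
    nxt = current[current["gene"].isin(expressed_genes)]
    tallies.append({"step": "expressed", "n_remaining": len(nxt),
                    "n_removed": len(current) - len(nxt)})
    current = nxt

    max_fst = gene_fst["max_fst"]
    hi_fst = set(max_fst.index[max_fst > cfg.min_gene_fst])
    nxt = current[current["gene"].isin(hi_fst)]
    tallies.append({"step": "gene_fst", "n_remaining": len(nxt),
                    "n_removed": len(current) - len(nxt)})
    current = nxt

    nxt = current[current["maf"] > cfg.min_maf]
    tallies.append({"step": "maf", "n_remaining": len(nxt),
                    "n_removed": len(current) - len(nxt)})
    return nxt.index, pd.DataFrame(tallies).set_index("step")


def _size_factors(counts: np.ndarray) -> np.ndarray:
    # median-of-ratios against the geometric-mean pseudo-reference;
    # genes with any zero drop out of the estimation only
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        totals = counts.sum(axis=0).astype(float)
        return totals / np.exp(np.mean(np.log(np.maximum(totals, 1.0))))
    logc = np.log(counts[positive])
    log_ref = logc.mean(axis=1, keepdims=True)
    return np.exp(np.median(logc - log_ref, axis=0))


def de_rank(counts: pd.DataFrame, carrier_mask) -> pd.Series:
    """Ranked log2 fold change (carriers vs reference homozygotes).

    Counts are normalized by median-of-ratios size factors; the per-gene
    log2 fold change uses a 0.5 pseudocount on the normalized group means.
    The result is deterministically ranked descending.
    """
    mask = np.asarray(carrier_mask, dtype=bool)
    if mask.all() or not mask.any():
        raise ValueError("both genotype groups must be non-empty")
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    norm = mat / _size_factors(mat)
    mean_carrier = norm[:, mask].mean(axis=1)
    mean_ref = norm[:, ~mask].mean(axis=1)
    log2fc = np.log2(mean_carrier + 0.5) - np.log2(mean_ref + 0.5)
    return enrichment.make_ranked_list(pd.Series(log2fc, index=counts.index))


def snp_isg_es(ranked: pd.Series, isg_set, n_perm: int = 1000,
               seed: int = 0, name: str = "") -> enrichment.EnrichmentResult:
    """ISG-signature enrichment of one SNP's DE ranking."""
    return enrichment.permutation_p(ranked, isg_set, n_perm=n_perm,
                                    seed=seed, name=name)


def rank_scale(values) -> np.ndarray:
    """Average ranks min-max scaled to [0, 1]; undefined for constant input."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("rank scaling needs >= 2 distinct values")
    ranks = stats.rankdata(x, method="average")
    return (ranks - ranks.min()) / (ranks.max() - ranks.min())


def impact_score(z_es: float, z_pub: float, z_fst: float,
                 weights=DEFAULT_WEIGHTS) -> float:
    """Weighted-voting composite score over the three scaled ranks."""
    for z in (z_es, z_pub, z_fst):
        if not 0.0 <= z <= 1.0:
            raise ValueError("scaled components must lie in [0, 1]")
    w1, w2, w3 = weights
    return float(w1 * z_es + w2 * z_pub + w3 * z_fst)


def _snp_seed(seed: int, snp_id: str) -> int:
    # order-invariant per-SNP substream: hash of (seed, snp id)
    digest = hashlib.sha256(f"{seed}:{snp_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def prioritize_pipeline(genotypes: GenotypeMatrix, expression: pd.DataFrame,
                        gene_fst: pd.DataFrame, publication_counts: pd.Series,
                        isg_set, cfg: CandidateFilterConfig,
                        site_fst: pd.Series | None = None,
                        fpkm: pd.DataFrame | None = None,
                        n_perm: int = 1000, seed: int = 0,
                        weights=DEFAULT_WEIGHTS, alpha: float = 0.05,
                        group_mode: str = "carrier",
                        fst_level: str = "site"):
    """End-to-end nsSNP prioritization.

    Parameters
    ----------
    genotypes
        Cohort dosages for the candidate SNPs (samples = cell lines, in the
        same order as ``expression`` columns).
    expression
        RNA count matrix (genes x samples) for the DE rankings.
    gene_fst
        Per-gene ``mean_fst``/``max_fst`` table (see popdiff.gene_fst).
    publication_counts
        SNP-indexed literature-evidence counts.
    site_fst
        Per-SNP F_ST used for the score's third component (default); with
        ``fst_level='gene'`` the host gene's max F_ST is used instead.
    fpkm
        Expression matrix for the detectable-expression filter step;
        defaults to ``expression``.
    group_mode
        'carrier' contrasts reference homozygotes with dosage >= 1 carriers;
        'hom' contrasts the two homozygote classes.

    Returns
    -------
    (DataFrame, DataFrame)
        The impact-record table (one row per candidate, ranked by score)
        and the filter tally table.
    """
    if group_mode not in ("carrier", "hom"):
        raise ValueError("group_mode must be 'carrier' or 'hom'")
    if fst_level not in ("site", "gene"):
        raise ValueError("fst_level must be 'site' or 'gene'")
    if expression.shape[1] != genotypes.n_samples:
        raise ValueError("expression columns must align with genotype samples")

    # pooled MAF per SNP from the cohort dosages
    called = genotypes.dosages != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(called, genotypes.dosages, 0).sum(axis=0) / np.maximum(
            2 * called.sum(axis=0), 1)
    snps = pd.DataFrame(
        {"gene": genotypes.sites["gene"].to_numpy(),
         "maf": np.minimum(freq, 1 - freq)},
        index=genotypes.site_ids,
    )
    survivors, tallies = candidate_filter(
        snps, gene_fst, expression if fpkm is None else fpkm, cfg)
    if len(survivors) < 2:
        raise ValueError(
            f"only {len(survivors)} candidate SNPs passed the filter; rank "
            "scaling needs >= 2 — relax the filter thresholds or supply more SNPs"
        )

    rows = []
    for snp in sorted(survivors, key=str):
        j = genotypes.site_ids.get_loc(snp)
        dos = genotypes.dosages[:, j]
        valid = dos != MISSING
        if group_mode == "carrier":
            mask, keep = dos >= 1, valid
        else:
            keep = valid & (dos != 1)
            mask = dos == 2
        sub = expression.loc[:, expression.columns[keep]]
        ranked = de_rank(sub, mask[keep])
        res = snp_isg_es(ranked, isg_set, n_perm=n_perm,
                         seed=_snp_seed(seed, str(snp)), name=str(snp))
        gene = snps.loc[snp, "gene"]
        if fst_level == "site" and site_fst is not None:
            fst_val = float(site_fst.loc[snp])
        else:
            fst_val = float(gene_fst.loc[gene, "max_fst"])
        rows.append({"snp": str(snp), "gene": gene, "es": res.es,
                     "abs_es": abs(res.es), "p_value": res.p_value,
                     "publications": float(publication_counts.loc[snp]),
                     "fst": fst_val})
    table = pd.DataFrame(rows).set_index("snp")
    table["p_adjusted"] = enrichment.adjust_bh(table["p_value"])
    table["z_es"] = rank_scale(table["abs_es"])
    table["z_pub"] = rank_scale(table["publications"])
    table["z_fst"] = rank_scale(table["fst"])

    significant = table["p_adjusted"] <= alpha
    score = np.where(
        significant,
        [impact_score(r.z_es, r.z_pub, r.z_fst, weights) for r in table.itertuples()],
        np.nan,
    )
    table["impact_score"] = score
    table["passed"] = (table["p_adjusted"] < alpha) & (table["impact_score"] > 1.0)
    table = table.sort_values(["impact_score", "snp"],
                              ascending=[False, True], na_position="last")
    return table, tallies
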