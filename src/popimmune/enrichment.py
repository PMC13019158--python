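"""Pre-ranked gene-set enrichment, BH adjustment, and 2x2 exact enrichment.

The enrichment score (ES) is the signed maximum-magnitude deviation of a
running sum over a descending-ranked list: hits add
``|score|^q / sum_hits |score|^q`` (q = ``weight_exponent``; q = 0 gives the
unweighted Kolmogorov-Smirnov form) and misses subtract ``1 / (N - n_hits)``.
The permutation null resamples identifier labels of the set's size without
replacement; the two-sided p-value is ``(1 + #{|ES_null| >= |ES_obs|}) /
(1 + n_perm)``, which floors p away from zero.

Ties in the ranking are broken deterministically by (score descending,
identifier ascending) so results are platform-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "make_ranked_list",
    "enrichment_score",
    "permutation_p",
    "adjust_bh",
    "adjust_results_bh",
    "fisher_2x2",
    "pathway_fst_profile",
    "read_gmt",
    "write_gmt",
]


@dataclass
class EnrichmentResult:
    name: str
    es: float
    p_value: float
    n_hits: int
    p_adjusted: float | None = None
    degenerate: bool = False


def make_ranked_list(scores) -> pd.Series:
    """Deterministically ranked list: score descending, identifier ascending."""
    s = pd.Series(scores, dtype=float)
    if s.index.has_duplicates:
        raise ValueError("ranked-list identifiers must be unique")
    order = sorted(s.index, key=lambda i: (-s[i], str(i)))
    return s.loc[order]


def _hit_mask(ranked: pd.Series, gene_set) -> np.ndarray:
    return np.asarray(ranked.index.isin(list(gene_set)))


def enrichment_score(ranked, gene_set, weight_exponent: float = 1.0) -> float:
    """Running-sum ES of ``gene_set`` against a ranked (id -> score) list."""
    r = make_ranked_list(ranked)
    hits = _hit_mask(r, gene_set)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked list")
    n = len(r)
    if n_hits == n:  # every item is a hit; the running sum has no misses
        return 1.0
    w = np.abs(r.to_numpy()) ** weight_exponent
    return _es_from_mask(w, hits)


def _es_from_mask(weights: np.ndarray, hits: np.ndarray) -> float:
    n = hits.size
    n_hits = int(hits.sum())
    steps = np.full(n, -1.0 / (n - n_hits))
    hit_w = weights[hits]
    total = hit_w.sum()
    if total == 0:  # all hit scores exactly zero: fall back to equal steps
        steps[hits] = 1.0 / n_hits
    else:
        steps[hits] = hit_w / total
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def permutation_p(ranked, gene_set, n_perm: int = 1000, seed: int = 0,
                  weight_exponent: float = 1.0, name: str = "") -> EnrichmentResult:
    """Label-permutation ES p-value (two-sided on |ES|), seeded.

    A set spanning the whole list is degenerate: ES is reported as 1 with
    p = 1 and the ``degenerate`` flag raised.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    r = make_ranked_list(ranked)
    hits = _hit_mask(r, gene_set)
    n_hits = int(hits.sum())
    n = len(r)
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hits == n:
        return EnrichmentResult(name, 1.0, 1.0, n_hits, degenerate=True)
    w = np.abs(r.to_numpy()) ** weight_exponent
    es_obs = _es_from_mask(w, hits)
    rng = np.random.default_rng(seed)
    # n_perm random hit-position sets of size n_hits, without replacement
    pos = np.argpartition(rng.random((n_perm, n)), n_hits - 1, axis=1)[:, :n_hits]
    null = _batch_es(w, pos, n)
    p = (1.0 + np.count_nonzero(np.abs(null) >= abs(es_obs))) / (1.0 + n_perm)
    return EnrichmentResult(name, es_obs, float(p), n_hits)


def _batch_es(weights: np.ndarray, hit_positions: np.ndarray, n: int) -> np.ndarray:
    """ES for each row of hit positions (P, m) against shared weights."""
    P, m = hit_positions.shape
    steps = np.full((P, n), -1.0 / (n - m))
    hit_w = weights[hit_positions]  # (P, m)
    totals = hit_w.sum(axis=1, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    vals = np.where(totals > 0, hit_w / safe, 1.0 / m)
    np.put_along_axis(steps, hit_positions, vals, axis=1)
    running = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(P), idx]


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("adjust_bh requires at least one p-value")
    return multipletests(p, method="fdr_bh")[1]


def adjust_results_bh(results) -> list:
    padj = adjust_bh([r.p_value for r in results])
    return [replace(r, p_adjusted=float(q)) for r, q in zip(results, padj)]


def fisher_2x2(a: int, b: int, c: int, d: int):
    """Odds ratio, log2 OR, and two-sided exact p for [[a, b], [c, d]].

    Zero cells get the Haldane-Anscombe +0.5 correction for the odds ratio
    only; the exact test always uses the raw counts.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0 or c + d == 0:
        raise ValueError("each row of the 2x2 table must have a positive total")
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = a, b, c, d
    odds = (aa * dd) / (bb * cc)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(np.log2(odds)), float(p)


def pathway_fst_profile(gene_fst: pd.DataFrame, pathways: dict,
                        n_perm: int = 1000, seed: int = 0,
                        site_weighted: bool = False) -> pd.DataFrame:
    """Per-pathway mean F_ST plus enrichment against the F_ST gene ranking.

    ``gene_fst`` is the per-gene table from :func:`popimmune.popdiff.gene_fst`
    (columns ``mean_fst``, ``n_sites``).  The pathway mean is the mean of
    member genes' mean F_ST (``site_weighted=True`` weights genes by their
    site counts instead).  Enrichment uses the permutation ES of the member
    set against genes ranked by mean F_ST; pathways with no scored gene are
    omitted. BH adjustment runs across the reported pathways.
    """
    ranked = make_ranked_list(gene_fst["mean_fst"])
    rows, results = [], []
    ss = np.random.SeedSequence(seed).spawn(len(pathways))
    for (pname, members), sub_seed in zip(pathways.items(), ss):
        present = [m for m in members if m in gene_fst.index]
        if not present:
            continue
        sub = gene_fst.loc[present]
        if site_weighted:
            mean = float(np.average(sub["mean_fst"], weights=sub["n_sites"]))
        else:
            mean = float(sub["mean_fst"].mean())
        res = permutation_p(ranked, present, n_perm=n_perm,
                            seed=int(sub_seed.generate_state(1)[0] % (2 ** 31)),
                            name=pname)
        results.append(res)
        rows.append({"pathway": pname, "mean_fst": mean, "n_genes": len(present)})
    if not rows:
        return pd.DataFrame(columns=["mean_fst", "n_genes", "es", "p_value", "p_adjusted"])
    results = adjust_results_bh(results)
    df = pd.DataFrame(rows).set_index("pathway")
    df["es"] = [r.es for r in results]
    df["p_value"] = [r.p_value for r in results]
    df["p_adjusted"] = [r.p_adjusted for r in results]
    return df.sort_values("mean_fst", ascending=False)


def read_gmt(path) -> dict:
    """GMT gene sets: name <tab> description <tab> members..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [m for m in parts[2:] if m]
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *map(str, members)]) + "\n")
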