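"""Haplotype-frequency EM, pairwise LD, and named haplotype groups.

For a small locus (k <= 12 SNPs) the 2^k haplotype space is enumerable, so
frequencies are estimated from unphased genotypes by expectation-
maximization: the E-step distributes each individual's genotype over the
compatible haplotype pairs in proportion to the current frequency products,
the M-step re-estimates frequencies from the expected counts, and the
log-likelihood is non-decreasing at every iteration.

LD statistics follow the textbook definitions on two-locus haplotype
frequencies (alt alleles as A/B): D = f(AB) - pA*pB, D' = |D|/Dmax, and
r^2 = D^2 / (pA(1-pA) pB(1-pB)).

Named haplotype groups (the STING1 WT/REF/HAQ/AQ rule set) are data, not
code: rules ship as a YAML config mapping group names to ref/alt patterns
over an ordered SNP list.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .genotypes import MISSING

__all__ = [
    "HaplotypeTable",
    "LDResult",
    "HaplotypeGroupRule",
    "em_haplotypes",
    "ld_from_freqs",
    "ld_pair",
    "ld_matrix",
    "load_group_rules",
    "sting1_rules",
    "classify_haplotype",
    "classify_diplotype",
    "population_hap_freqs",
]

MAX_SNPS = 12


@dataclass
class HaplotypeTable:
    """EM output: haplotype strings (0=ref, 1=alt per SNP) with frequencies."""

    snp_ids: list
    frequencies: pd.Series = field(repr=False)  # index = haplotype strings
    log_likelihood: float = math.nan
    n_iter: int = 0
    loglik_trace: list = field(default_factory=list, repr=False)
    degenerate: bool = False

    def frequency(self, hap: str) -> float:
        return float(self.frequencies.get(hap, 0.0))

    def marginal_pair(self, snp_a, snp_b) -> np.ndarray:
        """2x2 joint frequency of (allele at a, allele at b)."""
        ia, ib = self.snp_ids.index(snp_a), self.snp_ids.index(snp_b)
        out = np.zeros((2, 2))
        for hap, f in self.frequencies.items():
            out[int(hap[ia]), int(hap[ib])] += f
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frequency": self.frequencies}).rename_axis("haplotype")


@dataclass
class LDResult:
    snp_a: str
    snp_b: str
    d: float
    d_prime: float
    r2: float
    defined: bool = True


# --------------------------------------------------------------------- EM

def _compatible_pairs(genotype: tuple, k: int):
    """Unordered haplotype-index pairs consistent with one genotype vector."""
    het = [i for i, g in enumerate(genotype) if g == 1]
    miss = [i for i, g in enumerate(genotype) if g == MISSING]
    base = sum(1 << i for i, g in enumerate(genotype) if g == 2)
    pairs = set()
    for het_bits in itertools.product((0, 1), repeat=len(het)):
        h1 = base + sum(b << i for b, i in zip(het_bits, het))
        h2 = base + sum((1 - b) << i for b, i in zip(het_bits, het))
        for m1 in itertools.product((0, 1), repeat=len(miss)):
            a = h1 + sum(b << i for b, i in zip(m1, miss))
            for m2 in itertools.product((0, 1), repeat=len(miss)):
                b_ = h2 + sum(b << i for b, i in zip(m2, miss))
                pairs.add((min(a, b_), max(a, b_)))
    return sorted(pairs)


def em_haplotypes(dosages, snp_ids=None, tol: float = 1e-8,
                  max_iter: int = 5000, seed: int = 0,
                  n_starts: int = 1) -> HaplotypeTable:
    """Maximum-likelihood haplotype frequencies from unphased dosages.

    Parameters
    ----------
    dosages
        (n_individuals, k) array of alt-allele dosages (0/1/2, -1 missing),
        k <= 12.  All-missing individuals are skipped.
    n_starts
        Extra random restarts (seeded) to escape symmetric fixed points;
        the best log-likelihood wins, and near-tied starts with different
        frequency vectors raise the ``degenerate`` flag.
    """
    G = np.asarray(dosages)
    if G.ndim != 2:
        raise ValueError("dosages must be a 2-D (individuals x SNPs) array")
    n, k = G.shape
    if k > MAX_SNPS:
        raise ValueError(f"at most {MAX_SNPS} SNPs supported (2^k haplotype space)")
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(k)]
    keep = ~(G == MISSING).all(axis=1)
    G = G[keep]
    if G.shape[0] == 0:
        raise ValueError("no individuals with any called genotype")

    # group identical genotype vectors; enumerate compatible pairs once each
    counts: dict = {}
    for row in map(tuple, G):
        counts[row] = counts.get(row, 0) + 1
    geno_pairs = {g: _compatible_pairs(g, k) for g in counts}
    observed = sorted({h for pairs in geno_pairs.values() for ab in pairs for h in ab})
    hap_index = {h: i for i, h in enumerate(observed)}
    H = len(observed)

    # per-genotype arrays of pair member indices and homozygosity factor
    packed = []
    for g, pairs in geno_pairs.items():
        a = np.array([hap_index[p[0]] for p in pairs])
        b = np.array([hap_index[p[1]] for p in pairs])
        mult = np.where(a == b, 1.0, 2.0)
        packed.append((counts[g], a, b, mult))

    def run(f0: np.ndarray):
        f = f0.copy()
        trace = []
        prev = -np.inf
        it = 0
        for it in range(1, max_iter + 1):
            new = np.zeros(H)
            ll = 0.0
            for m, a, b, mult in packed:
                w = mult * f[a] * f[b]
                tot = w.sum()
                if tot <= 0:
                    # genotype has zero likelihood under current f; re-seed
                    # its pairs uniformly to keep the chain alive
                    w = np.ones_like(w)
                    tot = w.sum()
                    ll += m * math.log(1e-300)
                else:
                    ll += m * math.log(tot)
                post = m * w / tot
                np.add.at(new, a, post)
                np.add.at(new, b, post)
            f = new / new.sum()
            trace.append(ll)
            if ll - prev < tol and it > 1:
                break
            prev = ll
        return f, trace, it

    uniform = np.full(H, 1.0 / H)
    runs = [run(uniform)]
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_starts - 1)):
        runs.append(run(rng.dirichlet(np.ones(H))))
    best = max(runs, key=lambda r: r[1][-1])
    degenerate = any(
        r is not best
        and abs(r[1][-1] - best[1][-1]) < 1e-6
        and np.max(np.abs(r[0] - best[0])) > 1e-3
        for r in runs
    )
    f, trace, n_iter = best
    hap_strings = ["".join(str((h >> j) & 1) for j in range(k)) for h in observed]
    freqs = pd.Series(f, index=hap_strings).sort_values(ascending=False)
    freqs = freqs[freqs > 0]
    freqs = freqs / freqs.sum()
    return HaplotypeTable(list(snp_ids), freqs, trace[-1], n_iter, trace, degenerate)


# --------------------------------------------------------------------- LD

def ld_from_freqs(f_ab: float = None, f_aB: float = None, f_Ab: float = None,
                  f_AB: float = None, *, joint: np.ndarray = None,
                  snp_a: str = "a", snp_b: str = "b") -> LDResult:
    """LD statistics from two-locus haplotype frequencies.

    Either pass the four frequencies f(ab), f(aB), f(Ab), f(AB) positionally
    (lowercase = ref allele), or ``joint`` as a 2x2 array indexed
    [allele_a, allele_b]. Monomorphic loci are flagged undefined.
    """
    if joint is None:
        joint = np.array([[f_ab, f_aB], [f_Ab, f_AB]], dtype=float)
    joint = np.asarray(joint, dtype=float)
    joint = joint / joint.sum()
    pA = joint[1].sum()
    pB = joint[:, 1].sum()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return LDResult(snp_a, snp_b, math.nan, math.nan, math.nan, defined=False)
    d = joint[1, 1] - pA * pB
    if d > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = abs(d) / dmax if dmax > 0 else math.nan
    r2 = d * d / (pA * (1 - pA) * pB * (1 - pB))
    return LDResult(snp_a, snp_b, float(d), float(d_prime), float(r2))


def ld_pair(hap: HaplotypeTable, snp_a, snp_b) -> LDResult:
    return ld_from_freqs(joint=hap.marginal_pair(snp_a, snp_b),
                         snp_a=str(snp_a), snp_b=str(snp_b))


def ld_matrix(hap: HaplotypeTable):
    """(D', r^2) DataFrames over all SNP pairs of a haplotype table."""
    ids = hap.snp_ids
    dp = pd.DataFrame(np.nan, index=ids, columns=ids)
    r2 = pd.DataFrame(np.nan, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i == j:
                continue
            res = ld_pair(hap, a, b)
            dp.loc[a, b] = res.d_prime
            r2.loc[a, b] = res.r2
    return dp, r2


# ------------------------------------------------------- named groups

@dataclass
class HaplotypeGroupRule:
    """Named ref/alt patterns over an ordered SNP list; fall-through 'other'."""

    locus: str
    snp_ids: list
    patterns: dict  # name -> tuple of 0/1 alleles

    def __post_init__(self) -> None:
        pats = list(self.patterns.values())
        if len({tuple(p) for p in pats}) != len(pats):
            raise ValueError("group patterns must be mutually exclusive")


def load_group_rules(path) -> HaplotypeGroupRule:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    conv = {"ref": 0, "alt": 1, 0: 0, 1: 1}
    patterns = {
        name: tuple(conv[a] for a in alleles)
        for name, alleles in raw["groups"].items()
    }
    return HaplotypeGroupRule(raw.get("locus", ""), list(raw["snps"]), patterns)


def sting1_rules() -> HaplotypeGroupRule:
    """The packaged four-SNP STING1 rule set (WT/REF/HAQ/AQ)."""
    ref = resources.files("popimmune").joinpath("data/sting1_haplotype_groups.yaml")
    with resources.as_file(ref) as path:
        return load_group_rules(path)


def classify_haplotype(alleles, rules: HaplotypeGroupRule) -> str:
    """Map one haplotype (0/1 per rule SNP) to its named group or 'other'."""
    key = tuple(int(a) for a in alleles)
    if len(key) != len(rules.snp_ids):
        raise ValueError("allele vector length does not match rule SNPs")
    for name, pattern in rules.patterns.items():
        if key == pattern:
            return name
    return "other"


def classify_diplotype(dosages, rules: HaplotypeGroupRule,
                       hap_table: HaplotypeTable | None = None) -> tuple:
    """Classify an individual's unphased calls into an unordered group pair.

    Up to one heterozygous site phases unambiguously. With two or more het
    sites the most probable compatible haplotype pair under ``hap_table``
    resolves the phase. A missing call returns ("unclassifiable",).
    """
    g = tuple(int(d) for d in dosages)
    if len(g) != len(rules.snp_ids):
        raise ValueError("dosage vector length does not match rule SNPs")
    if any(d == MISSING for d in g):
        return ("unclassifiable",)
    het = sum(1 for d in g if d == 1)
    k = len(g)
    if het >= 2:
        if hap_table is None:
            raise ValueError(
                "ambiguous phase (>=2 heterozygous sites) needs a HaplotypeTable"
            )
        pairs = _compatible_pairs(g, k)
        def hap_str(h):
            return "".join(str((h >> j) & 1) for j in range(k))
        def prob(pair):
            a, b = pair
            fa, fb = hap_table.frequency(hap_str(a)), hap_table.frequency(hap_str(b))
            return (1.0 if a == b else 2.0) * fa * fb
        a, b = max(pairs, key=prob)
        h1 = [(a >> j) & 1 for j in range(k)]
        h2 = [(b >> j) & 1 for j in range(k)]
    else:
        h1 = [1 if d == 2 else (1 if d == 1 else 0) for d in g]
        h2 = [1 if d == 2 else 0 for d in g]
    labels = sorted([classify_haplotype(h1, rules), classify_haplotype(h2, rules)])
    return tuple(labels)


def population_hap_freqs(assignments, population_labels) -> pd.DataFrame:
    """Per-population haplotype-group frequencies from diplotype labels.

    ``assignments`` holds one unordered label pair per individual (output of
    :func:`classify_diplotype`); unclassifiable individuals are dropped.
    Each row of the result sums to 1.
    """
    pops = np.asarray(population_labels)
    rows = []
    for pair, pop in zip(assignments, pops):
        if pair == ("unclassifiable",):
            continue
        for label in pair:
            rows.append({"population": pop, "group": label})
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame()
    table = pd.crosstab(df["population"], df["group"])
    return table.div(table.sum(axis=1), axis=0)
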